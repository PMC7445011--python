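"""Toy genome and transcript models.

A single linear contig carries protein-coding genes (5' UTR / CDS with
optional introns / 3' UTR), plus a few ncRNA genes and retrogenes so that the
full region hierarchy used downstream is represented. Coordinates are 0-based,
half-open throughout. The 5' and 3' UTRs are intron-free, so each transcript's
3' UTR occupies one contiguous genomic interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .config import SimConfig

_COMPLEMENT = bytes.maketrans(b"ACGTN", b"TGCAN")

STOP_CODONS = ("TAA", "TAG", "TGA")


def revcomp(seq: str) -> str:
    return seq.encode()[::-1].translate(_COMPLEMENT).decode()


@dataclass
class TranscriptModel:
    """One transcript of one gene, with genomic exon blocks and CDS bounds."""

    gene_id: str
    tx_id: str
    contig: str
    strand: str  # '+' or '-'
    exons: list[tuple[int, int]]  # sorted ascending genomic half-open blocks
    cds_start: int  # genomic thickStart; == cds_end for non-coding
    cds_end: int
    biotype: str = "protein_coding"  # protein_coding | ncrna | retrogene

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def is_coding(self) -> bool:
        return self.cds_end > self.cds_start

    def _split(self, lo: int, hi: int) -> list[tuple[int, int]]:
        """Exon blocks clipped to the genomic interval [lo, hi)."""
        out = []
        for s, e in self.exons:
            s2, e2 = max(s, lo), min(e, hi)
            if s2 < e2:
                out.append((s2, e2))
        return out

    @property
    def cds_intervals(self) -> list[tuple[int, int]]:
        return self._split(self.cds_start, self.cds_end) if self.is_coding else []

    @property
    def utr5_intervals(self) -> list[tuple[int, int]]:
        if not self.is_coding:
            return []
        if self.strand == "+":
            return self._split(self.start, self.cds_start)
        return self._split(self.cds_end, self.end)

    @property
    def utr3_intervals(self) -> list[tuple[int, int]]:
        if not self.is_coding:
            return []
        if self.strand == "+":
            return self._split(self.cds_end, self.end)
        return self._split(self.start, self.cds_start)

    @property
    def intron_intervals(self) -> list[tuple[int, int]]:
        return [
            (e0[1], e1[0]) for e0, e1 in zip(self.exons[:-1], self.exons[1:])
        ]

    # -- 3' UTR coordinate system ------------------------------------------
    @property
    def utr3_len(self) -> int:
        return sum(e - s for s, e in self.utr3_intervals)

    def utr3_positions(self) -> np.ndarray:
        """Genomic positions of 3' UTR nucleotides in transcript 5'->3' order."""
        ivs = self.utr3_intervals
        if not ivs:
            return np.empty(0, dtype=np.int64)
        pos = np.concatenate([np.arange(s, e, dtype=np.int64) for s, e in ivs])
        return pos if self.strand == "+" else pos[::-1]

    def utr3_offset_to_genomic(self, offset: int) -> int:
        """Map a 0-based offset from the 3' UTR 5' start to a genomic position."""
        (s, e), = self.utr3_intervals  # UTRs are intron-free by construction
        if not 0 <= offset < e - s:
            raise IndexError(f"offset {offset} outside 3' UTR of {self.tx_id}")
        return s + offset if self.strand == "+" else e - 1 - offset

    def genomic_to_utr3_offset(self, pos: int) -> int:
        (s, e), = self.utr3_intervals
        if not s <= pos < e:
            raise IndexError(f"position {pos} outside 3' UTR of {self.tx_id}")
        return pos - s if self.strand == "+" else e - 1 - pos

    def utr3_sequence(self, genome: dict[str, bytearray]) -> str:
        """3' UTR sequence in transcript sense (DNA alphabet)."""
        (s, e), = self.utr3_intervals
        raw = bytes(genome[self.contig][s:e]).decode()
        return raw if self.strand == "+" else revcomp(raw)

    def cds_sequence(self, genome: dict[str, bytearray]) -> str:
        parts = [bytes(genome[self.contig][s:e]).decode() for s, e in self.cds_intervals]
        seq = "".join(parts)
        return seq if self.strand == "+" else revcomp(seq)


def _random_seq(rng: np.random.Generator, n: int, freqs: np.ndarray) -> str:
    return "".join(rng.choice(list("ACGT"), size=n, p=freqs))


def _random_cds(rng: np.random.Generator, n_codons: int, freqs: np.ndarray) -> str:
    """ATG + internal codons free of in-frame stops + one stop codon."""
    body = []
    while len(body) < n_codons - 2:
        codon = _random_seq(rng, 3, freqs)
        if codon not in STOP_CODONS:
            body.append(codon)
    stop = STOP_CODONS[rng.integers(0, 3)]
    return "ATG" + "".join(body) + stop


def build_genome(config: SimConfig) -> tuple[dict[str, bytearray], list[TranscriptModel]]:
    """Generate the toy genome and its transcript annotation.

    Genes alternate between strands, are separated by intergenic gaps, and
    each protein-coding gene has a 5' UTR, a CDS (length divisible by three,
    AUG start, stop end, no internal in-frame stops) interrupted by up to
    ``max_introns`` introns, and a 3' UTR.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([101, config.seed]))
    freqs = np.asarray(config.motif_alphabet_freqs, dtype=float)
    contig = "chrT"
    chunks: list[str] = []
    cursor = 0
    transcripts: list[TranscriptModel] = []

    def gap() -> None:
        nonlocal cursor
        n = int(rng.integers(*config.intergenic_gap_range, endpoint=True))
        chunks.append(_random_seq(rng, n, freqs))
        cursor += n

    gap()
    for i in range(config.n_genes):
        gene_id = f"g{i:04d}"
        tx_id = f"{gene_id}.t1"
        strand = "+" if i % 2 == 0 else "-"
        u = rng.random()
        if u < config.ncrna_fraction:
            biotype = "ncrna"
        elif u < config.ncrna_fraction + config.retrogene_fraction:
            biotype = "retrogene"
        else:
            biotype = "protein_coding"

        if biotype == "protein_coding":
            utr5 = _random_seq(rng, int(rng.integers(*config.utr5_length_range, endpoint=True)), freqs)
            n_codons = int(rng.integers(*config.cds_codon_range, endpoint=True))
            cds = _random_cds(rng, n_codons, freqs)
            utr3 = _random_seq(rng, int(rng.integers(*config.utr3_length_range, endpoint=True)), freqs)
            mrna = utr5 + cds + utr3
            # insert introns at codon boundaries inside the CDS
            n_introns = int(rng.integers(0, config.max_introns, endpoint=True))
            cut_sites = sorted(
                int(c)
                for c in rng.choice(np.arange(1, n_codons - 1), size=n_introns, replace=False)
            ) if n_introns else []
            locus_parts = []
            exon_bounds = []  # in locus (transcript-orientation) coordinates
            prev = 0
            locus_len = 0
            for c in cut_sites:
                tpos = len(utr5) + 3 * c
                locus_parts.append(mrna[prev:tpos])
                exon_bounds.append((locus_len, locus_len + (tpos - prev)))
                locus_len += tpos - prev
                ilen = int(rng.integers(*config.intron_length_range, endpoint=True))
                locus_parts.append(_random_seq(rng, ilen, freqs))
                locus_len += ilen
                prev = tpos
            locus_parts.append(mrna[prev:])
            exon_bounds.append((locus_len, locus_len + len(mrna) - prev))
            locus_len += len(mrna) - prev
            locus = "".join(locus_parts)
            cds_lo_t, cds_hi_t = len(utr5), len(utr5) + len(cds)

            # locus offset of a transcript offset (CDS span includes introns)
            def t2l(t: int) -> int:
                off = 0
                covered = 0
                for (ls, le) in exon_bounds:
                    blk = le - ls
                    if t <= covered + blk:
                        return ls + (t - covered)
                    covered += blk
                raise AssertionError
            cds_lo_l = t2l(cds_lo_t)
            cds_hi_l = t2l(cds_hi_t)
        else:
            length = int(rng.integers(*config.utr3_length_range, endpoint=True)) + 200
            locus = _random_seq(rng, length, freqs)
            exon_bounds = [(0, length)]
            cds_lo_l = cds_hi_l = 0

        if strand == "-":
            L = len(locus)
            genome_seg = revcomp(locus)
            exons_g = sorted((L - e, L - s) for s, e in exon_bounds)
            cds_g = (L - cds_hi_l, L - cds_lo_l) if cds_hi_l > cds_lo_l else (0, 0)
        else:
            genome_seg = locus
            exons_g = exon_bounds
            cds_g = (cds_lo_l, cds_hi_l)

        exons = [(cursor + s, cursor + e) for s, e in exons_g]
        cds_start = cursor + cds_g[0] if cds_g[1] > cds_g[0] else exons[0][0]
        cds_end = cursor + cds_g[1] if cds_g[1] > cds_g[0] else exons[0][0]
        chunks.append(genome_seg)
        cursor += len(genome_seg)
        transcripts.append(
            TranscriptModel(
                gene_id=gene_id,
                tx_id=tx_id,
                contig=contig,
                strand=strand,
                exons=exons,
                cds_start=cds_start,
                cds_end=cds_end,
                biotype=biotype,
            )
        )
        gap()

    genome = {contig: bytearray("".join(chunks).encode())}
    return genome, transcripts


# -- I/O ---------------------------------------------------------------------

def write_fasta(genome: dict[str, bytearray], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(bytes(seq).decode()), id=name, description="")
        for name, seq in genome.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, bytearray]:
    return {
        rec.id: bytearray(str(rec.seq).upper().encode())
        for rec in SeqIO.parse(str(path), "fasta")
    }


def write_bed12(transcripts: list[TranscriptModel], path: str | Path) -> None:
    """BED12 with thickStart/thickEnd = CDS; biotype carried in column 13."""
    with open(path, "w") as fh:
        for t in transcripts:
            sizes = ",".join(str(e - s) for s, e in t.exons)
            starts = ",".join(str(s - t.start) for s, e in t.exons)
            fh.write(
                "\t".join(
                    map(
                        str,
                        [
                            t.contig,
                            t.start,
                            t.end,
                            f"{t.gene_id}|{t.tx_id}",
                            0,
                            t.strand,
                            t.cds_start,
                            t.cds_end,
                            0,
                            len(t.exons),
                            sizes,
                            starts,
                            t.biotype,
                        ],
                    )
                )
                + "\n"
            )


def read_bed12(path: str | Path) -> list[TranscriptModel]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith(("#", "track")):
            continue
        f = line.split("\t")
        chrom, start = f[0], int(f[1])
        name, strand = f[3], f[5]
        gene_id, _, tx_id = name.partition("|")
        sizes = [int(x) for x in f[10].rstrip(",").split(",")]
        offs = [int(x) for x in f[11].rstrip(",").split(",")]
        exons = [(start + o, start + o + sz) for o, sz in zip(offs, sizes)]
        biotype = f[12] if len(f) > 12 else "protein_coding"
        out.append(
            TranscriptModel(
                gene_id=gene_id or tx_id,
                tx_id=tx_id or gene_id,
                contig=chrom,
                strand=strand,
                exons=exons,
                cds_start=int(f[6]),
                cds_end=int(f[7]),
                biotype=biotype,
            )
        )
    return out
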