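"""Synthetic study generator with planted ground truth.

Every input the pipeline consumes is generated here from one
:class:`~utrclip.config.SimConfig`: a toy genome and annotation, multiplexed
iCLIP reads with the 3+4+2-nt barcode layout and PCR duplication, per-sample
alignment records, an IgG-style background control, germ-cell and 12-tissue
expression tables, RiboTag count matrices with a planted translational effect,
and per-nucleotide conservation tracks elevated at planted binding sites.

The generator's planted quantities are the oracle for every downstream
recovery test: target genes are exactly the genes with at least one planted
site, crosslink reads start one nucleotide 3' of the planted crosslink
nucleotide, and the RiboTag model is the inverse of the estimator's design.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ConfigError, SimConfig
from .genome import TranscriptModel, build_genome, revcomp, write_bed12, write_fasta

CONTROL_SAMPLE = "IgG"

# transcript-sense DNA spellings of the planted motif UGUU(U/A)
MOTIF_MEMBERS_DNA = ("TGTTT", "TGTTA")
# crosslink sits on the first U of the UU core, i.e. motif position 2
MOTIF_XL_OFFSET = 2


@dataclass
class TruthSet:
    """Planted ground truth for one simulated study."""

    planted_sites: dict[str, list[int]]  # tx_id -> sorted 3' UTR offsets
    target_genes: set[str]
    planted_te: dict[str, float]  # gene -> specific-term log2 coefficient
    tissue_class: dict[str, str]  # gene -> testis-specific | broad
    planted_motif: str = "UGUU(U/A)"

    def to_json(self, path: str | Path) -> None:
        d = {
            "planted_sites": {k: list(map(int, v)) for k, v in sorted(self.planted_sites.items())},
            "target_genes": sorted(self.target_genes),
            "planted_te": {k: float(v) for k, v in sorted(self.planted_te.items())},
            "tissue_class": dict(sorted(self.tissue_class.items())),
            "planted_motif": self.planted_motif,
        }
        Path(path).write_text(json.dumps(d, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthSet":
        d = json.loads(Path(path).read_text())
        return cls(
            planted_sites={k: list(v) for k, v in d["planted_sites"].items()},
            target_genes=set(d["target_genes"]),
            planted_te=d["planted_te"],
            tissue_class=d["tissue_class"],
            planted_motif=d.get("planted_motif", "UGUU(U/A)"),
        )


def _normalize_tpm(raw: np.ndarray) -> np.ndarray:
    return raw / raw.sum() * 1e6


def plant_sites_and_expression(
    genome: dict[str, bytearray],
    transcripts: list[TranscriptModel],
    config: SimConfig,
) -> tuple[TruthSet, pd.DataFrame, pd.DataFrame]:
    """Choose target genes, write motif instances into their 3' UTRs, and
    generate the germ-cell TPM table and the 12-tissue atlas.

    Returns ``(truth, germ_tpm, atlas)``. ``germ_tpm`` has one column
    ``germ``; ``atlas`` has ``n_tissues`` columns including ``testis``.
    Both are renormalized so each column sums to 1e6. The genome is edited in
    place: each planted site places one motif member such that the planted
    crosslink nucleotide is the first U of the motif's UU core.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([202, config.seed]))
    coding = [t for t in transcripts if t.biotype == "protein_coding"]
    genes = [t.gene_id for t in transcripts]

    # ---- germ-cell expression --------------------------------------------
    raw = rng.lognormal(mean=2.0, sigma=1.2, size=len(transcripts))
    low = rng.random(len(transcripts)) < 0.05  # a few genes below the TPM>=1 filter
    raw[low] *= 1e-5
    germ = pd.DataFrame({"germ": _normalize_tpm(raw)}, index=genes)

    # ---- target choice ----------------------------------------------------
    motif_len = len(MOTIF_MEMBERS_DNA[0])
    n_targets = int(round(config.target_fraction * config.n_genes))
    if config.target_fraction > 1:
        raise ConfigError("target_fraction must be <= 1")
    min_len = max(config.end_window[1], config.start_window[1]) + 20
    eligible = [
        t
        for t in coding
        if t.utr3_len >= min_len and germ.loc[t.gene_id, "germ"] >= 1.0 and not low[genes.index(t.gene_id)]
    ]
    if n_targets > len(eligible):
        n_targets = len(eligible)
    chosen = sorted(
        rng.choice(len(eligible), size=n_targets, replace=False).tolist()
    )
    target_txs = [eligible[i] for i in chosen]

    # ---- site placement ---------------------------------------------------
    planted_sites: dict[str, list[int]] = {}
    bias = np.asarray(config.site_position_bias, dtype=float)
    for tx in target_txs:
        L = tx.utr3_len
        n_sites = int(rng.integers(*config.sites_per_target, endpoint=True))
        offsets: list[int] = []
        attempts = 0
        while len(offsets) < n_sites and attempts < 200:
            attempts += 1
            comp = rng.choice(3, p=bias)
            if comp == 0:  # end-proximal window, measured from the UTR 3' end
                d = int(rng.integers(*config.end_window, endpoint=True))
                off = (L - 1) - d
            elif comp == 1:  # start-proximal window
                off = int(rng.integers(*config.start_window, endpoint=True))
            else:
                off = int(rng.integers(0, L))
            if off < MOTIF_XL_OFFSET or off > L - (motif_len - MOTIF_XL_OFFSET) - 1:
                continue
            if any(abs(off - o) < motif_len + 3 for o in offsets):
                continue
            offsets.append(off)
        offsets.sort()
        planted_sites[tx.tx_id] = offsets
        # write the motif into the genome, transcript-sense
        for off in offsets:
            member = MOTIF_MEMBERS_DNA[rng.integers(0, len(MOTIF_MEMBERS_DNA))]
            (s, e), = tx.utr3_intervals
            if tx.strand == "+":
                g0 = s + (off - MOTIF_XL_OFFSET)
                genome[tx.contig][g0 : g0 + motif_len] = member.encode()
            else:
                g_hi = e - 1 - (off - MOTIF_XL_OFFSET)  # genomic pos of motif 5' start
                genome[tx.contig][g_hi - motif_len + 1 : g_hi + 1] = revcomp(member).encode()

    target_genes = {tx.gene_id for tx in target_txs if planted_sites[tx.tx_id]}
    planted_sites = {k: v for k, v in planted_sites.items() if v}

    # ---- 12-tissue atlas --------------------------------------------------
    # targets are planted broader (smaller cross-tissue noise) and testis-
    # specific genes are drawn preferentially from nontargets, mirroring the
    # depletion/breadth directions the analysis is meant to detect
    tissues = ["testis"] + [f"tissue{i:02d}" for i in range(1, config.n_tissues)]
    is_target_arr = np.array([g in {t.gene_id for t in target_txs} for g in genes])
    base = rng.lognormal(mean=2.0, sigma=1.0, size=len(genes))
    sigma_per_gene = np.where(is_target_arr, 0.35, 0.8)
    noise = np.exp(rng.normal(0.0, 1.0, size=(len(genes), config.n_tissues)) * sigma_per_gene[:, None])
    raw_atlas = base[:, None] * noise
    spec_weights = np.where(is_target_arr, 0.05, 1.0)
    spec_weights = spec_weights / spec_weights.sum()
    spec_idx = rng.choice(
        len(genes),
        size=int(round(config.testis_specific_fraction * len(genes))),
        replace=False,
        p=spec_weights,
    )
    raw_atlas[spec_idx, 0] = base[spec_idx] * 50.0
    raw_atlas[spec_idx, 1:] = rng.uniform(0.0001, 0.001, size=(len(spec_idx), config.n_tissues - 1))
    atlas = pd.DataFrame(
        np.apply_along_axis(_normalize_tpm, 0, raw_atlas), index=genes, columns=tissues
    )
    from .traits import is_testis_specific  # deferred: truth uses the analysis rule

    tissue_class = {
        g: ("testis-specific" if is_testis_specific(atlas.loc[g]) else "broad") for g in genes
    }

    # ---- planted translational program ------------------------------------
    base_te = rng.normal(0.0, 0.15, size=len(genes))
    planted_te = {
        g: float(base_te[i] + (config.te_effect if g in target_genes else 0.0))
        for i, g in enumerate(genes)
    }

    truth = TruthSet(
        planted_sites=planted_sites,
        target_genes=target_genes,
        planted_te=planted_te,
        tissue_class=tissue_class,
    )
    return truth, germ, atlas


# ---------------------------------------------------------------------------
# iCLIP read simulation
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _random_barcodes(rng: np.random.Generator, n: int, k: int) -> list[str]:
    if n == 0:
        return []
    idx = rng.integers(0, 4, size=(n, k))
    return ["".join("ACGT"[j] for j in row) for row in idx]


@dataclass
class IclipSample:
    """Unique molecules of one demultiplexed iCLIP sample."""

    sample: str
    # one row per unique molecule (post-collapse truth)
    alignments: pd.DataFrame  # contig, start, end, name, score, strand
    emissions: dict[tuple[str, str, int], int]  # (contig, strand, xl_pos) -> molecules


def simulate_iclip(
    genome: dict[str, bytearray],
    transcripts: list[TranscriptModel],
    truth: TruthSet,
    germ_tpm: pd.DataFrame,
    config: SimConfig,
) -> tuple[list[str], dict[str, IclipSample]]:
    """Simulate the multiplexed iCLIP lane and per-sample alignments.

    Returns ``(fastq_lines, samples)``. Reads carry a 3-nt random barcode, the
    4-nt sample barcode, then a 2-nt random barcode, followed by a fixed-length
    insert. Signal reads start one nucleotide 3' of a planted crosslink
    nucleotide (strand-aware); background reads are uniform over exonic
    positions of expressed transcripts with per-nucleotide intensity
    proportional to TPM; the control sample has background only. A fraction
    ``pcr_duplication_rate`` of lane reads are exact duplicates of an earlier
    molecule from the same sample.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([303, config.seed]))
    tx_by_id = {t.tx_id: t for t in transcripts}
    rlen = config.read_length
    lib = config.library_sizes
    mean_tpm = 1e6 / max(len(germ_tpm), 1)

    # exonic position pool for background, weighted by TPM
    pool_pos: list[np.ndarray] = []
    pool_strand: list[str] = []
    pool_w: list[float] = []
    for t in transcripts:
        tpm = float(germ_tpm.loc[t.gene_id, "germ"])
        if tpm <= 0:
            continue
        for s, e in t.exons:
            pool_pos.append(np.arange(s, e, dtype=np.int64))
            pool_strand.append(t.strand)
            pool_w.append(tpm)
    flat_pos = np.concatenate(pool_pos) if pool_pos else np.empty(0, dtype=np.int64)
    flat_strand = np.concatenate(
        [np.full(len(p), 0 if st == "+" else 1, dtype=np.int8) for p, st in zip(pool_pos, pool_strand)]
    ) if pool_pos else np.empty(0, dtype=np.int8)
    flat_w = np.concatenate(
        [np.full(len(p), w / mean_tpm, dtype=float) for p, w in zip(pool_pos, pool_w)]
    ) if pool_pos else np.empty(0)

    lane_entries: list[tuple[str, str]] = []  # (sample, full read sequence)
    samples: dict[str, IclipSample] = {}
    contig = transcripts[0].contig if transcripts else "chrT"
    contig_len = len(genome[contig]) if genome else 0

    for sample, code in config.barcode_map.items():
        is_control = sample == CONTROL_SAMPLE
        xl_list: list[tuple[int, int]] = []  # (pos, strand01)
        if not is_control and config.crosslink_signal_rate > 0:
            per_site = config.crosslink_signal_rate * lib / 1e6
            for tx_id in sorted(truth.planted_sites):
                tx = tx_by_id[tx_id]
                for off in truth.planted_sites[tx_id]:
                    g = tx.utr3_offset_to_genomic(off)
                    n = int(rng.poisson(per_site))
                    xl_list.extend([(g, 0 if tx.strand == "+" else 1)] * n)
        if config.background_rate > 0 and len(flat_pos):
            per_nt = config.background_rate * lib / 1e6
            n_bg = int(rng.poisson(per_nt * flat_w.sum()))
            if n_bg:
                idx = rng.choice(len(flat_pos), size=n_bg, p=flat_w / flat_w.sum())
                xl_list.extend(zip(flat_pos[idx].tolist(), flat_strand[idx].tolist()))

        # crosslink -> alignment; drop reads overhanging the contig
        mols: list[tuple[int, int, int]] = []  # (start, end, strand01)
        for pos, st in xl_list:
            if st == 0:
                s, e = pos + 1, pos + 1 + rlen
            else:
                s, e = pos - rlen, pos
            if s < 0 or e > contig_len:
                continue
            mols.append((s, e, st))
        order = rng.permutation(len(mols))
        mols = [mols[i] for i in order]

        bc5 = _random_barcodes(rng, len(mols), 3)
        bc3 = _random_barcodes(rng, len(mols), 2)
        raw = bytes(genome[contig]) if genome else b""
        # molecules whose random barcodes collide at the same position are
        # sequence-identical and indistinguishable after collapse; keep one
        full_reads: list[str] = []
        names: list[str] = []
        seen: set[str] = set()
        kept_mols: list[tuple[int, int, int]] = []
        for i, (s, e, st) in enumerate(mols):
            insert = raw[s:e].decode()
            if st == 1:
                insert = revcomp(insert)
            read = bc5[i] + code + bc3[i] + insert
            if read in seen:
                continue
            seen.add(read)
            kept_mols.append((s, e, st))
            full_reads.append(read)
            names.append(f"{sample}_m{len(names):06d}")
        mols = kept_mols

        aln = pd.DataFrame(
            {
                "contig": contig,
                "start": [m[0] for m in mols],
                "end": [m[1] for m in mols],
                "name": names,
                "score": 0,
                "strand": ["+" if m[2] == 0 else "-" for m in mols],
            }
        )
        emissions: dict[tuple[str, str, int], int] = {}
        for s, e, st in mols:
            key = (contig, "+", s - 1) if st == 0 else (contig, "-", e)
            emissions[key] = emissions.get(key, 0) + 1
        samples[sample] = IclipSample(sample=sample, alignments=aln, emissions=emissions)

        # PCR duplication: emit each molecule once plus duplicate draws
        d = config.pcr_duplication_rate
        lane_entries.extend((sample, r) for r in full_reads)
        if d > 0 and full_reads:
            n_dup = int(round(len(full_reads) * d / (1.0 - d)))
            src = rng.integers(0, len(full_reads), size=n_dup)
            lane_entries.extend((sample, full_reads[j]) for j in src)

    order = rng.permutation(len(lane_entries))
    fastq_lines: list[str] = []
    for k, i in enumerate(order):
        sample, seq = lane_entries[i]
        fastq_lines.append(f"@read{k:07d}")
        fastq_lines.append(seq)
        fastq_lines.append("+")
        fastq_lines.append("I" * len(seq))
    return fastq_lines, samples


# ---------------------------------------------------------------------------
# RiboTag counts
# ---------------------------------------------------------------------------

def ribotag_design(n_reps: int = 3) -> pd.DataFrame:
    """Sample metadata for the four library groups of the RiboTag design."""
    rows = []
    for grp, spec, nonspec, germ in [
        ("IP_HApos", 1, 1, 1),
        ("IP_HAneg", 0, 1, 0),
        ("input", 0, 0, 0),
        ("germRNA", 0, 0, 1),
    ]:
        for r in range(1, n_reps + 1):
            rows.append(
                {
                    "sample": f"{grp}_{r}",
                    "assay": "IP" if grp.startswith("IP") else ("germ-RNA" if grp == "germRNA" else "input"),
                    "genotype": "HA+" if grp in ("IP_HApos", "input", "germRNA") else "HA-",
                    "RiboTag.specific": spec,
                    "RiboTag.nonspecific": nonspec,
                    "germ.cell.specific": germ,
                }
            )
    return pd.DataFrame(rows).set_index("sample")


def simulate_ribotag(
    truth: TruthSet,
    germ_tpm: pd.DataFrame,
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate RiboTag IP / control-IP / input / germ RNA-seq count matrices.

    log2 expected counts are a library offset plus the gene-specific effects
    of the three design indicators; the specific term is the planted TE (base
    plus ``te_effect`` for targets). Counts are negative-binomial with
    variance mu + alpha mu^2; alpha = 0 degenerates to rounding the mean.

    Returns ``(counts, meta)`` with genes x samples counts.
    """
    config.validate()
    if config.nb_dispersion < 0:
        raise ConfigError("nb_dispersion must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence([404, config.seed]))
    genes = list(germ_tpm.index)
    meta = ribotag_design(config.n_ribotag_replicates)
    q = germ_tpm["germ"].to_numpy(dtype=float)
    q = np.maximum(q, 1e-3)
    q = q / q.sum()

    te = np.array([truth.planted_te[g] for g in genes])
    b_nonspec = rng.normal(-2.0, 0.3, size=len(genes))
    b_germ = rng.normal(0.5, 0.2, size=len(genes))

    counts = np.zeros((len(genes), len(meta)), dtype=np.int64)
    for j, (sample, row) in enumerate(meta.iterrows()):
        log2mu = (
            np.log2(q * config.ribotag_depth)
            + te * row["RiboTag.specific"]
            + b_nonspec * row["RiboTag.nonspecific"]
            + b_germ * row["germ.cell.specific"]
        )
        mu = np.power(2.0, log2mu)
        if config.nb_dispersion == 0:
            counts[:, j] = np.round(mu).astype(np.int64)
        else:
            r = 1.0 / config.nb_dispersion
            p = r / (r + mu)
            counts[:, j] = rng.negative_binomial(r, p)
    return pd.DataFrame(counts, index=genes, columns=meta.index), meta


def make_te_truth(
    n_genes: int, target_fraction: float, te_effect: float, seed: int = 0
) -> tuple[TruthSet, pd.DataFrame]:
    """Gene-level truth + expression for RiboTag-only simulations.

    The TE analysis is gene-level, so recovery experiments can run at
    transcriptome-like gene counts without building a genome.
    """
    rng = np.random.default_rng(np.random.SeedSequence([441, seed]))
    genes = [f"g{i:05d}" for i in range(n_genes)]
    tpm = _normalize_tpm(rng.lognormal(2.0, 1.2, size=n_genes))
    n_t = int(round(target_fraction * n_genes))
    targets = set(rng.choice(genes, size=n_t, replace=False).tolist())
    base = rng.normal(0.0, 0.15, size=n_genes)
    te = {g: float(base[i] + (te_effect if g in targets else 0.0)) for i, g in enumerate(genes)}
    truth = TruthSet(
        planted_sites={}, target_genes=targets, planted_te=te, tissue_class={}
    )
    return truth, pd.DataFrame({"germ": tpm}, index=genes)


# ---------------------------------------------------------------------------
# conservation tracks
# ---------------------------------------------------------------------------

def simulate_conservation(
    transcripts: list[TranscriptModel],
    truth: TruthSet,
    config: SimConfig,
) -> pd.DataFrame:
    """Per-nucleotide conservation scores over all coding 3' UTRs.

    ``phastcons`` is a bounded track in [0, 1] (baseline Beta(1, 6));
    ``phylop`` is unbounded (baseline standard normal). Planted crosslink
    nucleotides are shifted upward by ``conservation_boost`` (clipped to
    [0, 1] for the bounded track).
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([505, config.seed]))
    tx_by_id = {t.tx_id: t for t in transcripts}
    rows = []
    for t in transcripts:
        if t.biotype != "protein_coding" or t.utr3_len == 0:
            continue
        (s, e), = t.utr3_intervals
        rows.append((t.contig, s, e))
    if not rows:
        return pd.DataFrame(columns=["contig", "pos", "phastcons", "phylop"])
    pos = np.concatenate([np.arange(s, e) for _, s, e in rows])
    contigs = np.concatenate([np.full(e - s, c, dtype=object) for c, s, e in rows])
    phastcons = rng.beta(1.0, 6.0, size=len(pos))
    phylop = rng.normal(0.0, 1.0, size=len(pos))

    boosted = set()
    for tx_id, offs in truth.planted_sites.items():
        tx = tx_by_id[tx_id]
        for off in offs:
            boosted.add((tx.contig, tx.utr3_offset_to_genomic(off)))
    if boosted and config.conservation_boost != 0:
        mask = np.fromiter(
            ((c, p) in boosted for c, p in zip(contigs, pos)), dtype=bool, count=len(pos)
        )
        phastcons[mask] = np.clip(phastcons[mask] + config.conservation_boost, 0.0, 1.0)
        phylop[mask] = phylop[mask] + config.conservation_boost

    return pd.DataFrame(
        {"contig": contigs, "pos": pos, "phastcons": phastcons, "phylop": phylop}
    )


# ---------------------------------------------------------------------------
# gene-trait annotation tables
# ---------------------------------------------------------------------------

def simulate_annotations(
    truth: TruthSet, genes: list[str], config: SimConfig
) -> pd.DataFrame:
    """Ortholog / selection / dosage / miRNA-conservation annotations.

    Planted so targets show the expected directions: more likely to be
    regulators and to have yeast orthologs, lower dN/dS, higher dosage
    sensitivity and haploinsufficiency, higher mean P_CT.
    """
    rng = np.random.default_rng(np.random.SeedSequence([606, config.seed]))
    is_t = np.array([g in truth.target_genes for g in genes])
    n = len(genes)
    regulator = rng.random(n) < np.where(is_t, 0.10, 0.02)
    yeast = rng.random(n) < np.where(is_t, 0.30, 0.20)
    one2one = rng.random(n) < 0.85
    ds = rng.gamma(4.0, 0.1, size=n)
    dn = ds * np.exp(rng.normal(np.where(is_t, -2.0, -1.4), 0.5, size=n))
    miss = rng.random(n) < 0.05
    dn[miss] = np.nan
    cnv = rng.normal(np.where(is_t, 0.6, 0.0), 1.0, size=n)
    hi = 1.0 / (1.0 + np.exp(-rng.normal(np.where(is_t, 0.5, -0.5), 1.0, size=n)))
    pct_mean = np.clip(rng.normal(np.where(is_t, 0.35, 0.25), 0.1, size=n), 0.0, 1.0)
    return pd.DataFrame(
        {
            "regulator": regulator.astype(int),
            "yeast_ortholog": yeast.astype(int),
            "one2one_human": one2one.astype(int),
            "dN": dn,
            "dS": ds,
            "cnv_intolerance": cnv,
            "deletion_intolerance": cnv + rng.normal(0, 0.3, n),
            "duplication_intolerance": cnv + rng.normal(0, 0.3, n),
            "haploinsufficiency": hi,
            "mean_pct": pct_mean,
        },
        index=genes,
    )


# ---------------------------------------------------------------------------
# bundle
# ---------------------------------------------------------------------------

@dataclass
class Bundle:
    """In-memory fixture bundle: everything downstream modules consume."""

    config: SimConfig
    genome: dict[str, bytearray]
    transcripts: list[TranscriptModel]
    truth: TruthSet
    germ_tpm: pd.DataFrame
    atlas: pd.DataFrame
    fastq_lines: list[str]
    iclip: dict[str, IclipSample]
    ribotag_counts: pd.DataFrame
    ribotag_meta: pd.DataFrame
    conservation: pd.DataFrame
    annotations: pd.DataFrame


def simulate_bundle(config: SimConfig, outdir: str | Path | None = None) -> Bundle:
    """Run every generator; optionally write the full fixture bundle to disk."""
    genome, transcripts = build_genome(config)
    truth, germ, atlas = plant_sites_and_expression(genome, transcripts, config)
    fastq_lines, iclip = simulate_iclip(genome, transcripts, truth, germ, config)
    counts, meta = simulate_ribotag(truth, germ, config)
    cons = simulate_conservation(transcripts, truth, config)
    ann = simulate_annotations(truth, list(germ.index), config)
    bundle = Bundle(
        config=config,
        genome=genome,
        transcripts=transcripts,
        truth=truth,
        germ_tpm=germ,
        atlas=atlas,
        fastq_lines=fastq_lines,
        iclip=iclip,
        ribotag_counts=counts,
        ribotag_meta=meta,
        conservation=cons,
        annotations=ann,
    )
    if outdir is not None:
        write_bundle(bundle, outdir)
    return bundle


def write_bundle(bundle: Bundle, outdir: str | Path) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(bundle.genome, out / "genome.fa")
    write_bed12(bundle.transcripts, out / "transcripts.bed")
    (out / "lane.fastq").write_text("\n".join(bundle.fastq_lines) + ("\n" if bundle.fastq_lines else ""))
    for sample, s in bundle.iclip.items():
        s.alignments.to_csv(out / f"aln_{sample}.bed", sep="\t", header=False, index=False)
    bundle.germ_tpm.to_csv(out / "expression_germ.tsv", sep="\t", index_label="gene")
    bundle.atlas.to_csv(out / "atlas.tsv", sep="\t", index_label="gene")
    bundle.ribotag_counts.to_csv(out / "ribotag_counts.tsv", sep="\t", index_label="gene")
    bundle.ribotag_meta.to_csv(out / "ribotag_meta.tsv", sep="\t", index_label="sample")
    bundle.conservation.to_csv(out / "conservation.tsv", sep="\t", index=False)
    bundle.annotations.to_csv(out / "annotations.tsv", sep="\t", index_label="gene")
    bundle.truth.to_json(out / "truth.json")
    bundle.config.to_json(out / "config.json")
    barcodes = pd.DataFrame(
        {"sample": list(bundle.config.barcode_map), "code": list(bundle.config.barcode_map.values())}
    )
    barcodes.to_csv(out / "barcodes.tsv", sep="\t", index=False)
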