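"""iCLIP preprocessing: from raw multiplexed reads to crosslink-event tracks.

Processing order mirrors the truncated-cDNA iCLIP protocol: quality-trimmed
reads are collapsed on full sequence identity (the random barcodes are still
attached, so identical sequence means the same molecule), demultiplexed on the
4-nt sample barcode, and mapped reads are converted to crosslink nucleotides —
the nucleotide immediately 5', in transcript orientation, of the read's first
mapped nucleotide.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class BarcodeScheme:
    """3-nt random + 4-nt sample + 2-nt random barcode layout."""

    sample_map: dict[str, str]  # code -> sample-id
    random5_len: int = 3
    sample_len: int = 4
    random3_len: int = 2

    def __post_init__(self) -> None:
        codes = list(self.sample_map)
        if len(set(codes)) != len(codes):
            raise ValueError("sample codes must be pairwise distinct")
        for code in codes:
            if len(code) != self.sample_len or set(code) - set("ACGT"):
                raise ValueError(f"invalid sample code {code!r}")

    @property
    def total_len(self) -> int:
        return self.random5_len + self.sample_len + self.random3_len

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BarcodeScheme":
        df = pd.read_csv(path, sep="\t")
        return cls(sample_map={row["code"]: row["sample"] for _, row in df.iterrows()})


@dataclass
class DemuxResult:
    by_sample: dict[str, list[str]]
    unassigned: int = 0
    dropped_short: int = 0

    @property
    def n_assigned(self) -> int:
        return sum(len(v) for v in self.by_sample.values())


def collapse_duplicates(reads: list[str]) -> list[str]:
    """Collapse exact PCR duplicates: distinct full-length sequences, first
    occurrence order preserved. Random barcodes are still attached, so two
    reads are duplicates only if every nucleotide matches."""
    return list(dict.fromkeys(reads))


def demultiplex(reads: list[str], scheme: BarcodeScheme) -> DemuxResult:
    """Assign reads to samples on the 4-nt code and strip all barcodes.

    Reads shorter than the barcode layout are dropped and counted; reads with
    an unknown code are counted in the unassigned bin.
    """
    out: dict[str, list[str]] = {s: [] for s in scheme.sample_map.values()}
    unassigned = dropped = 0
    lo = scheme.random5_len
    hi = lo + scheme.sample_len
    total = scheme.total_len
    for read in reads:
        if len(read) <= total:
            dropped += 1
            continue
        sample = scheme.sample_map.get(read[lo:hi])
        if sample is None:
            unassigned += 1
            continue
        out[sample].append(read[total:])
    if dropped:
        log.info("demultiplex: dropped %d reads shorter than barcode layout", dropped)
    if unassigned:
        log.info("demultiplex: %d reads with unmatched sample code", unassigned)
    return DemuxResult(by_sample=out, unassigned=unassigned, dropped_short=dropped)


@dataclass
class CrosslinkTrack:
    """Sparse per-nucleotide crosslink-event counts for one sample."""

    sample: str
    counts: Counter = field(default_factory=Counter)  # (contig, strand, pos) -> n
    discarded: int = 0  # events that fell off the contig

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"contig": c, "strand": st, "pos": p, "count": n}
            for (c, st, p), n in sorted(self.counts.items())
        ]
        return pd.DataFrame(rows, columns=["contig", "strand", "pos", "count"])

    def to_bed6(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for (c, st, p), n in sorted(self.counts.items()):
                fh.write(f"{c}\t{p}\t{p + 1}\t{self.sample}\t{n}\t{st}\n")

    @classmethod
    def from_bed6(cls, path: str | Path, sample: str | None = None) -> "CrosslinkTrack":
        counts: Counter = Counter()
        name = sample
        for line in Path(path).read_text().splitlines():
            if not line:
                continue
            c, s, _e, nm, score, st = line.split("\t")[:6]
            counts[(c, st, int(s))] += int(score)
            name = name or nm
        return cls(sample=name or "track", counts=counts)


def extract_crosslink(
    contig: str, start: int, end: int, strand: str, contig_len: int | None = None
) -> tuple[str, str, int] | None:
    """Crosslink nucleotide of one alignment, or None if it falls off the
    contig (plus-strand read starting at 0, minus-strand read at contig end).

    Plus strand: position = start - 1. Minus strand: position = end — the
    nucleotide 5'-adjacent to the read's first nucleotide in transcript
    orientation.
    """
    if strand == "+":
        pos = start - 1
        if pos < 0:
            return None
    else:
        pos = end
        if contig_len is not None and pos >= contig_len:
            return None
    return (contig, strand, pos)


def pileup(
    events: list[tuple[str, str, int]], sample: str = "sample"
) -> CrosslinkTrack:
    """Count crosslink events per (contig, strand, position)."""
    track = CrosslinkTrack(sample=sample)
    track.counts.update(events)
    return track


def crosslink_track_from_alignments(
    alignments: pd.DataFrame,
    sample: str,
    contig_lengths: dict[str, int] | None = None,
) -> CrosslinkTrack:
    """Convert alignment records (BED6-like frame) to a crosslink track."""
    events: list[tuple[str, str, int]] = []
    discarded = 0
    for row in alignments.itertuples(index=False):
        clen = contig_lengths.get(row.contig) if contig_lengths else None
        ev = extract_crosslink(row.contig, int(row.start), int(row.end), row.strand, clen)
        if ev is None:
            discarded += 1
        else:
            events.append(ev)
    track = pileup(events, sample=sample)
    track.discarded = discarded
    if discarded:
        log.info("%s: discarded %d edge-overhanging events", sample, discarded)
    return track


def read_fastq(path: str | Path) -> list[str]:
    lines = Path(path).read_text().splitlines()
    return [lines[i] for i in range(1, len(lines), 4)]


def read_bed6_alignments(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["contig", "start", "end", "name", "score", "strand"],
    )
    return df
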