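"""Abundance-aware crosslink peak calling and replicate-consensus sites.

Per-nucleotide crosslink counts are tested against a Poisson background whose
rate is the larger of (i) an abundance-scaled global rate proportional to the
host gene's TPM and (ii) the scaled control (IgG) rate in the same region,
floored at a small positive constant. P-values are Benjamini-Hochberg
corrected globally across all tested (count >= 1) nucleotides. Nucleotides
called at FDR < 0.05 in at least two of three replicates are merged into
binding sites over runs of consecutive positions, restricted to 3' UTRs of
protein-coding genes expressed at >= 1 TPM.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .genome import TranscriptModel
from .preprocess import CrosslinkTrack

log = logging.getLogger(__name__)

REGION_HIERARCHY = ["utr3", "utr5", "cds", "ncrna", "retrogene", "intron", "intergenic"]
_RANK = {r: i for i, r in enumerate(REGION_HIERARCHY)}

BACKGROUND_FLOOR = 1e-3  # events per nt per million


class AnnotationIndex:
    """Strand-aware interval lookup over transcript region features."""

    def __init__(self, transcripts: list[TranscriptModel]):
        self.transcripts = transcripts
        self.by_tx = {t.tx_id: t for t in transcripts}
        self.by_gene: dict[str, list[TranscriptModel]] = {}
        for t in transcripts:
            self.by_gene.setdefault(t.gene_id, []).append(t)
        self.trees: dict[tuple[str, str], IntervalTree] = {}
        self.contigs: set[str] = set()
        for t in transcripts:
            self.contigs.add(t.contig)
            tree = self.trees.setdefault((t.contig, t.strand), IntervalTree())
            if t.biotype == "protein_coding":
                feats = (
                    [("utr3", iv) for iv in t.utr3_intervals]
                    + [("utr5", iv) for iv in t.utr5_intervals]
                    + [("cds", iv) for iv in t.cds_intervals]
                )
            else:
                feats = [(t.biotype, iv) for iv in [(s, e) for s, e in t.exons]]
            feats += [("intron", iv) for iv in t.intron_intervals]
            for cls, (s, e) in feats:
                if e > s:
                    tree[s:e] = (cls, t.gene_id, t.tx_id)

    def assign_region(self, contig: str, pos: int, strand: str) -> str:
        """Region class at a position: highest class in the hierarchy among
        strand-matched overlapping features; intergenic if none."""
        if contig not in self.contigs:
            raise KeyError(f"unknown contig {contig!r}")
        tree = self.trees.get((contig, strand))
        hits = tree[pos] if tree is not None else ()
        if not hits:
            return "intergenic"
        return min((h.data[0] for h in hits), key=_RANK.__getitem__)

    def host_gene(self, contig: str, pos: int, strand: str) -> tuple[str, str] | None:
        """(gene_id, tx_id) of the best-ranked feature at a position."""
        tree = self.trees.get((contig, strand))
        hits = tree[pos] if tree is not None else ()
        if not hits:
            return None
        best = min(hits, key=lambda h: _RANK[h.data[0]])
        return best.data[1], best.data[2]


def assign_region(index: AnnotationIndex, contig: str, pos: int, strand: str) -> str:
    return index.assign_region(contig, pos, strand)


def most_expressed_isoform(
    index: AnnotationIndex, gene_id: str, tpm: pd.Series
) -> TranscriptModel:
    """Highest-TPM transcript of a gene; ties broken by longest 3' UTR, then
    lexicographic id. (TPM is per gene here, so the tie-breaks decide.)"""
    txs = index.by_gene[gene_id]
    return sorted(
        txs, key=lambda t: (-float(tpm.get(t.gene_id, 0.0)), -t.utr3_len, t.tx_id)
    )[0]


def call_peaks(
    track: CrosslinkTrack,
    control: CrosslinkTrack,
    tpm: pd.Series,
    index: AnnotationIndex,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Call FDR-filtered crosslink peaks for one replicate.

    Returns a frame with contig, strand, pos, count, expected, p_value, fdr,
    region_class, gene_id. Only nucleotides with count >= 1 inside annotated
    transcripts are tested; BH correction is global across tested nucleotides.
    """
    if track.total == 0:
        return pd.DataFrame(
            columns=["contig", "strand", "pos", "count", "expected", "p_value", "fdr", "region_class", "gene_id"]
        )
    s_total = float(track.total)
    c_total = float(control.total)

    # abundance calibration: expected events-per-million per nt at TPM t is
    # c_global * t, with c_global fixed by total exonic TPM-weighted length
    denom = 0.0
    for t in index.transcripts:
        g_tpm = float(tpm.get(t.gene_id, 0.0))
        denom += g_tpm * sum(e - s for s, e in t.exons)
    c_global = 1e6 / denom if denom > 0 else 0.0

    def _sorted_arrays(tr: CrosslinkTrack) -> dict[tuple[str, str], tuple[np.ndarray, np.ndarray]]:
        by_key: dict[tuple[str, str], list[tuple[int, int]]] = {}
        for (c, st, p), n in tr.counts.items():
            by_key.setdefault((c, st), []).append((p, n))
        out = {}
        for key, pairs in by_key.items():
            pairs.sort()
            out[key] = (
                np.array([p for p, _ in pairs], dtype=np.int64),
                np.array([n for _, n in pairs], dtype=np.int64),
            )
        return out

    sig = _sorted_arrays(track)
    ctl = _sorted_arrays(control)

    rows = []
    for t in index.transcripts:
        lo, hi = t.start, t.end
        g_tpm = tpm.get(t.gene_id)
        span = hi - lo
        key = (t.contig, t.strand)
        # control events-per-million per nt within the transcript span
        if c_total > 0 and key in ctl:
            cpos, ccnt = ctl[key]
            i, j = np.searchsorted(cpos, [lo, hi])
            ctrl_rate = ccnt[i:j].sum() / c_total * 1e6 / span
        else:
            ctrl_rate = 0.0
        if g_tpm is None or (isinstance(g_tpm, float) and np.isnan(g_tpm)):
            log.info("call_peaks: no TPM for gene %s; control/floor background only", t.gene_id)
            abundance_rate = 0.0
        else:
            abundance_rate = c_global * float(g_tpm)
        lam_per_m = max(abundance_rate, ctrl_rate, BACKGROUND_FLOOR)
        lam_raw = lam_per_m * s_total / 1e6
        if key in sig:
            spos, scnt = sig[key]
            i, j = np.searchsorted(spos, [lo, hi])
            for p, n in zip(spos[i:j].tolist(), scnt[i:j].tolist()):
                rows.append((t.contig, t.strand, p, n, lam_raw, t.gene_id))
    if not rows:
        return pd.DataFrame(
            columns=["contig", "strand", "pos", "count", "expected", "p_value", "fdr", "region_class", "gene_id"]
        )
    df = pd.DataFrame(rows, columns=["contig", "strand", "pos", "count", "expected", "gene_id"])
    # a nucleotide can sit in overlapping transcripts; keep the most lenient
    # background once (max expected), one test per nucleotide
    df = (
        df.sort_values("expected")
        .groupby(["contig", "strand", "pos"], as_index=False)
        .last()
    )
    df["p_value"] = stats.poisson.sf(df["count"] - 1, df["expected"])
    # only count>=1 nucleotides are tested, so BH runs on the zero-truncated
    # tail P(X >= k | X >= 1); the unconditional tail alone would make every
    # singleton event at a low-rate position spuriously significant
    p_trunc = np.minimum(df["p_value"] / stats.poisson.sf(0, df["expected"]), 1.0)
    from statsmodels.stats.multitest import multipletests

    df["fdr"] = multipletests(p_trunc, method="fdr_bh")[1]
    df = df[df["fdr"] < fdr].copy()
    df["region_class"] = [
        index.assign_region(c, p, st)
        for c, p, st in zip(df["contig"], df["pos"], df["strand"])
    ]
    return df.sort_values(["contig", "strand", "pos"]).reset_index(drop=True)


def replicate_consensus(
    peaks_by_replicate: list[pd.DataFrame], min_replicates: int = 2
) -> pd.DataFrame:
    """Crosslink nucleotides called in at least ``min_replicates`` replicates.

    Returns contig, strand, pos, support, min_p (smallest constituent
    p-value across supporting replicates).
    """
    if len(peaks_by_replicate) < 2:
        raise ValueError("need at least 2 replicate peak sets")
    support: dict[tuple[str, str, int], list[float]] = {}
    for df in peaks_by_replicate:
        for row in df.itertuples(index=False):
            support.setdefault((row.contig, row.strand, row.pos), []).append(row.p_value)
    rows = [
        {"contig": c, "strand": st, "pos": p, "support": len(ps), "min_p": min(ps)}
        for (c, st, p), ps in support.items()
        if len(ps) >= min_replicates
    ]
    df = pd.DataFrame(rows, columns=["contig", "strand", "pos", "support", "min_p"])
    return df.sort_values(["contig", "strand", "pos"]).reset_index(drop=True)


@dataclass
class BindingSite:
    """Run of consecutive replicated crosslink nucleotides in a 3' UTR."""

    contig: str
    strand: str
    start: int
    end: int  # half-open
    gene_id: str
    tx_id: str
    representative: int  # 5'-most crosslinked nucleotide (strand-aware)
    n_replicates_support: int
    min_p: float


@dataclass
class TargetSet:
    """Bound genes, their sites, and the expressed universe."""

    targets: set[str]
    sites: list[BindingSite]
    universe: set[str]  # protein-coding genes at TPM >= threshold
    site_index: dict[str, list[BindingSite]] = field(default_factory=dict)
    n_discarded_nucleotides: int = 0

    def sites_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "contig": s.contig,
                    "strand": s.strand,
                    "start": s.start,
                    "end": s.end,
                    "gene_id": s.gene_id,
                    "tx_id": s.tx_id,
                    "representative": s.representative,
                    "support": s.n_replicates_support,
                    "min_p": s.min_p,
                }
                for s in self.sites
            ]
        )


def merge_sites(
    consensus: pd.DataFrame,
    index: AnnotationIndex,
    tpm: pd.Series,
    min_tpm: float = 1.0,
) -> TargetSet:
    """Merge replicated 3' UTR nucleotides into binding sites and define the
    target set over the expressed protein-coding universe.

    Consecutive (genomic distance exactly 1) same-strand nucleotides form one
    site, assigned to the host gene's most-expressed isoform; genes below
    ``min_tpm`` are excluded from universe and targets; the representative is
    the 5'-most crosslinked nucleotide.
    """
    universe = {
        g
        for g, txs in index.by_gene.items()
        if any(t.biotype == "protein_coding" for t in txs)
        and float(tpm.get(g, 0.0)) >= min_tpm
    }
    kept: list[tuple[str, str, int, int, float, str, str]] = []
    discarded = 0
    for row in consensus.itertuples(index=False):
        host = index.host_gene(row.contig, row.pos, row.strand)
        if host is None:
            discarded += 1
            continue
        gene_id, _ = host
        if gene_id not in universe:
            discarded += 1
            continue
        iso = most_expressed_isoform(index, gene_id, tpm)
        in_utr3 = any(s <= row.pos < e for s, e in iso.utr3_intervals)
        if not in_utr3 or iso.strand != row.strand:
            discarded += 1
            continue
        kept.append((row.contig, row.strand, row.pos, row.support, row.min_p, gene_id, iso.tx_id))
    if discarded:
        log.info("merge_sites: discarded %d nucleotides outside expressed 3' UTRs", discarded)

    sites: list[BindingSite] = []
    kept.sort(key=lambda r: (r[0], r[1], r[6], r[2]))
    run: list[tuple] = []

    def flush() -> None:
        if not run:
            return
        positions = [r[2] for r in run]
        start, end = positions[0], positions[-1] + 1
        strand = run[0][1]
        rep = start if strand == "+" else end - 1
        sites.append(
            BindingSite(
                contig=run[0][0],
                strand=strand,
                start=start,
                end=end,
                gene_id=run[0][5],
                tx_id=run[0][6],
                representative=rep,
                n_replicates_support=max(r[3] for r in run),
                min_p=min(r[4] for r in run),
            )
        )

    prev = None
    for r in kept:
        if (
            prev is not None
            and r[0] == prev[0]
            and r[1] == prev[1]
            and r[6] == prev[6]
            and r[2] == prev[2] + 1
        ):
            run.append(r)
        else:
            flush()
            run = [r]
        prev = r
    flush()

    site_index: dict[str, list[BindingSite]] = {}
    for s in sites:
        site_index.setdefault(s.gene_id, []).append(s)
    targets = set(site_index)
    return TargetSet(
        targets=targets,
        sites=sites,
        universe=universe,
        site_index=site_index,
        n_discarded_nucleotides=discarded,
    )


def transcriptome_share(targets: TargetSet, tpm: pd.Series) -> tuple[float, float]:
    """(gene fraction, mRNA-molecule fraction) of the universe bound.

    Gene fraction = |targets| / |universe|; molecule fraction = summed TPM of
    targets over summed TPM of the universe.
    """
    if not targets.universe:
        raise ValueError("empty expressed universe")
    uni_tpm = sum(float(tpm.get(g, 0.0)) for g in targets.universe)
    tgt_tpm = sum(float(tpm.get(g, 0.0)) for g in targets.targets)
    return len(targets.targets) / len(targets.universe), tgt_tpm / uni_tpm
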