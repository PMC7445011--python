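"""Positional metagene analysis of binding sites along 3' UTRs.

Relative position maps the 3' UTR to [0, 1] (start = 0, end = 1); absolute
positions are nt distances from either anchor. The positional null draws, per
transcript, one uniform 3' UTR offset per observed site, so multiplicity and
length structure are preserved; observed and null distributions are compared
with a two-sample Kolmogorov-Smirnov test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


@dataclass
class UTRMap:
    """Per-transcript 3' UTR length, sorted site representative offsets, and
    transcript-sense UTR sequence."""

    entries: dict[str, tuple[int, list[int], str]]  # tx -> (length, offsets, seq)

    def __post_init__(self) -> None:
        for tx, (length, offsets, _seq) in self.entries.items():
            if any(not 0 <= o < length for o in offsets):
                raise ValueError(f"offset outside 3' UTR for {tx}")
            self.entries[tx] = (length, sorted(offsets), _seq)


def relative_positions(utr_map: UTRMap) -> np.ndarray:
    """Site offsets scaled to [0, 1] as offset / (length - 1)."""
    vals = []
    for tx, (length, offsets, _s) in sorted(utr_map.entries.items()):
        if length < 2:
            if offsets:
                log.info("relative_positions: degenerate length-1 UTR %s", tx)
                vals.extend(0.0 for _ in offsets)
            continue
        vals.extend(o / (length - 1) for o in offsets)
    return np.asarray(vals, dtype=float)


def absolute_positions(utr_map: UTRMap, anchor: str = "end") -> np.ndarray:
    """Distances (nt) of sites from the 3' UTR start or end."""
    if anchor not in ("start", "end"):
        raise ValueError("anchor must be 'start' or 'end'")
    vals = []
    for _tx, (length, offsets, _s) in sorted(utr_map.entries.items()):
        for o in offsets:
            vals.append(o if anchor == "start" else (length - 1) - o)
    return np.asarray(vals, dtype=float)


def inter_site_distances(utr_map: UTRMap) -> tuple[np.ndarray, float]:
    """Adjacent-site distances for transcripts with >= 2 sites, and their
    overall median (nan when no transcript qualifies)."""
    dists = []
    for _tx, (_l, offsets, _s) in sorted(utr_map.entries.items()):
        if len(offsets) >= 2:
            dists.extend(np.diff(offsets).tolist())
    arr = np.asarray(dists, dtype=float)
    return arr, (float(np.median(arr)) if len(arr) else float("nan"))


@dataclass
class PositionalNull:
    offsets: dict[str, list[int]]
    seed: int

    def relative(self, utr_map: UTRMap) -> np.ndarray:
        vals = []
        for tx in sorted(self.offsets):
            length = utr_map.entries[tx][0]
            if length < 2:
                continue
            vals.extend(o / (length - 1) for o in self.offsets[tx])
        return np.asarray(vals, dtype=float)


def positional_null(utr_map: UTRMap, seed: int = 0) -> PositionalNull:
    """Per transcript, draw uniformly (with replacement) as many random 3'
    UTR offsets as observed sites; deterministic given the seed."""
    rng = np.random.default_rng(np.random.SeedSequence([1010, seed]))
    null: dict[str, list[int]] = {}
    for tx, (length, offsets, _s) in sorted(utr_map.entries.items()):
        if offsets:
            null[tx] = sorted(rng.integers(0, length, size=len(offsets)).tolist())
    return PositionalNull(offsets=null, seed=seed)


def ks_compare(observed: np.ndarray, null: np.ndarray) -> tuple[float, float]:
    """Two-sample two-sided Kolmogorov-Smirnov test; exact p for small
    samples (n + m <= 30), asymptotic otherwise."""
    observed = np.asarray(observed, dtype=float)
    null = np.asarray(null, dtype=float)
    if len(observed) == 0 or len(null) == 0:
        raise ValueError("empty sample")
    method = "exact" if len(observed) + len(null) <= 30 else "asymp"
    res = stats.ks_2samp(observed, null, method=method)
    return float(res.statistic), float(res.pvalue)


def conservation_compare(
    bound_scores: np.ndarray, unbound_scores: np.ndarray
) -> dict[str, float]:
    """Two-sided Mann-Whitney U of crosslinked vs non-crosslinked 3' UTR
    nucleotide scores (tie-corrected normal approximation), with medians."""
    bound = np.asarray(bound_scores, dtype=float)
    unbound = np.asarray(unbound_scores, dtype=float)
    n_missing = int(np.isnan(bound).sum() + np.isnan(unbound).sum())
    bound = bound[~np.isnan(bound)]
    unbound = unbound[~np.isnan(unbound)]
    if n_missing:
        log.info("conservation_compare: excluded %d missing scores", n_missing)
    if len(bound) == 0 or len(unbound) == 0:
        raise ValueError("empty score group")
    u, p = stats.mannwhitneyu(bound, unbound, alternative="two-sided", method="asymptotic")
    return {
        "U": float(u),
        "p": float(p),
        "median_bound": float(np.median(bound)),
        "median_unbound": float(np.median(unbound)),
        "n_bound": len(bound),
        "n_unbound": len(unbound),
        "n_missing": n_missing,
    }


def site_count_correlates(
    site_counts: pd.Series,
    tpm: pd.Series,
    utr_lengths: pd.Series,
    motif_counts: pd.Series,
) -> pd.DataFrame:
    """Spearman rank correlations of per-gene site counts with abundance,
    3' UTR length, and motif count. Degenerate inputs give rho = 0 with a
    flag."""
    genes = site_counts.index
    if len(genes) < 3:
        raise ValueError("need at least 3 genes")
    rows = []
    for name, other in [("tpm", tpm), ("utr3_length", utr_lengths), ("motif_count", motif_counts)]:
        y = other.reindex(genes).to_numpy(dtype=float)
        x = site_counts.to_numpy(dtype=float)
        if np.all(x == x[0]) or np.all(y == y[0]):
            rows.append({"variable": name, "rho": 0.0, "p": float("nan"), "degenerate": True})
            continue
        rho, p = stats.spearmanr(x, y)
        rows.append({"variable": name, "rho": float(rho), "p": float(p), "degenerate": False})
    return pd.DataFrame(rows)
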