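"""Target-set characterization: enrichment statistics and per-gene traits.

Gene-set overlaps use the one-tailed hypergeometric test (upper tail for
enrichment, lower tail for depletion); per-gene quantitative traits are
compared between targets and nontargets with one- or two-sided Mann-Whitney U
tests. Tissue specificity and expression breadth follow a 12-tissue atlas:
"log2 normalized expression" is interpreted as log2(TPM + 1) throughout (the
pseudocount is recorded here because the choice is not forced by the rule
itself).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

LOG2_PSEUDOCOUNT = 1.0


def renormalize_tpm(table: pd.DataFrame) -> pd.DataFrame:
    """Rescale each column of a TPM table to sum to 1e6 (after subsetting)."""
    out = table.copy().astype(float)
    for col in out.columns:
        s = out[col].sum()
        if s <= 0:
            raise ValueError(f"zero-sum column {col!r}")
        out[col] *= 1e6 / s
    return out


def hypergeom_enrichment(
    universe_size: int, annotated: int, sample_size: int, overlap: int, tail: str = "upper"
) -> float:
    """One-tailed hypergeometric p for a gene-set overlap.

    Upper tail: P(X >= overlap) — enrichment. Lower tail: P(X <= overlap) —
    depletion. Exact, accurate deep into the tail.
    """
    N, K, n, k = universe_size, annotated, sample_size, overlap
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise ValueError(f"inconsistent counts N={N} K={K} n={n} k={k}")
    if tail == "upper":
        return float(stats.hypergeom.sf(k - 1, N, K, n))
    if tail == "lower":
        return float(stats.hypergeom.cdf(k, N, K, n))
    raise ValueError("tail must be 'upper' or 'lower'")


def _log2p1(x: np.ndarray) -> np.ndarray:
    return np.log2(np.asarray(x, dtype=float) + LOG2_PSEUDOCOUNT)


def is_testis_specific(row: pd.Series, testis_col: str = "testis") -> bool:
    """Testis-specificity rule: testis TPM >= 5 and the testis contributes at
    least 25% of the gene's log2(TPM+1) expression summed over all tissues."""
    testis = float(row[testis_col])
    if testis < 5.0:
        return False
    logs = _log2p1(row.to_numpy())
    total = logs.sum()
    if total <= 0:
        return False
    return float(np.log2(testis + LOG2_PSEUDOCOUNT)) / total >= 0.25


def expression_breadth(row: pd.Series) -> float:
    """Mean of per-tissue log2(TPM+1) values normalized by the gene's maximum;
    in (0, 1]; NaN for all-zero genes (excluded upstream)."""
    logs = _log2p1(row.to_numpy())
    m = logs.max()
    if m <= 0:
        return float("nan")
    return float(np.mean(logs / m))


def dnds(annotations: pd.DataFrame) -> pd.Series:
    """dN/dS per gene over 1:1 orthologs; rows with missing dN/dS or dS = 0
    are removed (and counted in the log)."""
    df = annotations
    if "one2one_human" in df.columns:
        df = df[df["one2one_human"] == 1]
    ok = df["dN"].notna() & df["dS"].notna() & (df["dS"] != 0)
    removed = int((~ok).sum())
    if removed:
        log.info("dnds: removed %d genes with missing dN/dS or dS=0", removed)
    sub = df[ok]
    return sub["dN"] / sub["dS"]


def mean_pct(scores: list[float | None]) -> float:
    """Mean of non-null conserved-miRNA-targeting scores; NaN if none."""
    vals = [s for s in scores if s is not None and not (isinstance(s, float) and np.isnan(s))]
    return float(np.mean(vals)) if vals else float("nan")


def mwu_compare(
    first: np.ndarray, second: np.ndarray, alternative: str = "two-sided"
) -> tuple[float, float]:
    """Mann-Whitney U of the first sample against the second.

    ``alternative`` refers to the first sample's tendency. Exact enumeration
    when n + m <= 30 (and no ties), tie-corrected normal otherwise.
    """
    first = np.asarray(first, dtype=float)
    second = np.asarray(second, dtype=float)
    if len(first) == 0 or len(second) == 0:
        raise ValueError("empty group")
    small = len(first) + len(second) <= 30
    method = "exact" if small and len(np.unique(np.concatenate([first, second]))) == len(first) + len(second) else "asymptotic"
    u, p = stats.mannwhitneyu(first, second, alternative=alternative, method=method)
    return float(u), float(p)


def differentiation_odds(counts: pd.DataFrame) -> pd.DataFrame:
    """Differentiation-rate comparison between two conditions from tubule
    cell counts (columns: condition, kit, zbtb16, sox9).

    Per-condition rate = (KIT per 100 Sertoli) / (ZBTB16 per 100 Sertoli) =
    KIT total / ZBTB16 total. The odds ratio is computed from the 2x2 table
    of summed KIT vs (ZBTB16 - KIT, floored at 0) counts with a two-sided
    Fisher exact p.
    """
    conds = list(dict.fromkeys(counts["condition"]))
    if len(conds) != 2:
        raise ValueError("exactly two conditions required")
    per = {}
    table = []
    for cond in conds:
        sub = counts[counts["condition"] == cond]
        kit, zbtb, sox9 = sub["kit"].sum(), sub["zbtb16"].sum(), sub["sox9"].sum()
        if zbtb <= 0 or sox9 <= 0:
            raise ValueError(f"ZBTB16 and SOX9 totals must be > 0 in {cond!r}")
        rate = (kit / sox9 * 100) / (zbtb / sox9 * 100)
        undiff = zbtb - kit
        if undiff < 0:
            log.warning("differentiation_odds: KIT > ZBTB16 in %s; flooring 2x2 cell", cond)
            undiff = 0
        per[cond] = rate
        table.append([int(kit), int(undiff)])
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return pd.DataFrame(
        {
            "condition": conds,
            "rate": [per[c] for c in conds],
            "odds_ratio": [float(odds)] * 2,
            "p": [float(p)] * 2,
        }
    )


def trait_summary(
    targets: set[str],
    universe: set[str],
    atlas: pd.DataFrame,
    annotations: pd.DataFrame,
) -> pd.DataFrame:
    """All target-vs-nontarget trait tests in one table.

    Enrichment (regulators, yeast orthologs) and depletion (testis-specific)
    by one-tailed hypergeometric; breadth, dN/dS, dosage scores and mean P_CT
    by one-sided Mann-Whitney U in the directions the study design plants.
    """
    uni = sorted(universe)
    tgt = sorted(targets & universe)
    non = sorted(universe - targets)
    N, n = len(uni), len(tgt)
    rows = []

    def hyper(name: str, flagged: set[str], tail: str) -> None:
        K = len(flagged & universe)
        k = len(flagged & set(tgt))
        rows.append(
            {
                "test": name,
                "kind": f"hypergeometric-{tail}",
                "statistic": float(k),
                "p": hypergeom_enrichment(N, K, n, k, tail=tail),
                "n_target": n,
                "n_universe": N,
            }
        )

    ann = annotations.reindex(uni)
    hyper("regulator_enrichment", set(ann.index[ann["regulator"] == 1]), "upper")
    hyper("yeast_ortholog_enrichment", set(ann.index[ann["yeast_ortholog"] == 1]), "upper")
    atlas_u = atlas.reindex(uni)
    specific = {g for g in uni if is_testis_specific(atlas_u.loc[g])}
    hyper("testis_specific_depletion", specific, "lower")

    def mwu(name: str, series: pd.Series, alternative: str) -> None:
        a = series.reindex(tgt).dropna().to_numpy()
        b = series.reindex(non).dropna().to_numpy()
        u, p = mwu_compare(a, b, alternative=alternative)
        rows.append(
            {"test": name, "kind": f"mwu-{alternative}", "statistic": u, "p": p,
             "n_target": len(a), "n_universe": len(a) + len(b)}
        )

    breadth = atlas_u.apply(expression_breadth, axis=1)
    mwu("expression_breadth", breadth, "greater")
    mwu("dnds", dnds(annotations), "less")
    for col in ("cnv_intolerance", "deletion_intolerance", "duplication_intolerance", "haploinsufficiency"):
        mwu(col, ann[col], "greater")
    mwu("mean_pct", ann["mean_pct"], "greater")
    return pd.DataFrame(rows)
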