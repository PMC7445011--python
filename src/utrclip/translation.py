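"""RiboTag translational-efficiency estimation and covariate modeling.

Per-gene translational efficiency (TE) is the coefficient of the
tag-specific-binding indicator in an ordinary least-squares fit of
log2(normalized count + 0.5) on the three design indicators (specific,
nonspecific, germ-cell-specific) plus an intercept — the 1-vs-0 contrast of
the specific term. Downstream, TE is modeled log-linearly on transcript
abundance, CDS length, 3' UTR length, codon adaptation (CAI), and the binary
target flag; the target effect is quantified both by matched-sampling median
differences and by the regression coefficient, with a likelihood-ratio test
for nested model comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .traits import mwu_compare

log = logging.getLogger(__name__)

TE_PSEUDOCOUNT = 0.5
DESIGN_COLS = ["RiboTag.specific", "RiboTag.nonspecific", "germ.cell.specific"]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization factors.

    Reference = per-gene geometric mean over samples (genes with any zero
    excluded); each sample's factor is the median ratio of its counts to the
    reference.
    """
    mat = counts.to_numpy(dtype=float)
    all_nonzero = (mat > 0).all(axis=1)
    if not all_nonzero.any():
        raise ValueError("no gene with nonzero counts in every sample; filter first")
    sub = mat[all_nonzero]
    ref = np.exp(np.mean(np.log(sub), axis=1))
    factors = np.median(sub / ref[:, None], axis=0)
    return pd.Series(factors, index=counts.columns)


def filter_genes(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    factors: pd.Series,
    min_ip: float = 15.0,
    min_rna: float = 10.0,
    per_sample: bool = False,
) -> pd.Index:
    """Genes with enough normalized counts in the tag-positive IP samples
    (sum >= ``min_ip``) and in the germ RNA-seq samples (sum >= ``min_rna``).
    ``per_sample=True`` applies the thresholds to each sample's minimum
    instead of the group sum."""
    norm = counts / factors
    ip_cols = meta.index[(meta["RiboTag.specific"] == 1)]
    rna_cols = meta.index[(meta["assay"] == "germ-RNA")]
    if per_sample:
        keep = (norm[ip_cols].min(axis=1) >= min_ip) & (norm[rna_cols].min(axis=1) >= min_rna)
    else:
        keep = (norm[ip_cols].sum(axis=1) >= min_ip) & (norm[rna_cols].sum(axis=1) >= min_rna)
    return counts.index[keep]


def estimate_te(counts: pd.DataFrame, meta: pd.DataFrame) -> pd.Series:
    """Per-gene TE: OLS coefficient of the specific indicator on
    log2(normalized count + 0.5), fitted over all samples at once."""
    factors = size_factors(counts)
    X = np.column_stack(
        [np.ones(len(meta))] + [meta[c].to_numpy(dtype=float) for c in DESIGN_COLS]
    )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # name the aliased columns for the caller
        aliased = [
            c
            for i, c in enumerate(["intercept"] + DESIGN_COLS)
            if np.linalg.matrix_rank(np.delete(X, i, axis=1)) == np.linalg.matrix_rank(X)
        ]
        raise ValueError(f"rank-deficient design; aliased columns: {aliased}")
    norm = counts.to_numpy(dtype=float) / factors.to_numpy()
    Y = np.log2(norm + TE_PSEUDOCOUNT).T  # samples x genes
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    te = beta[1]  # coefficient of RiboTag.specific
    return pd.Series(te, index=counts.index, name="te")


# ---------------------------------------------------------------------------
# codon adaptation index
# ---------------------------------------------------------------------------

_CODON_TABLE = {
    # standard genetic code, DNA codons -> amino acid (stop = '*')
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

_SYNONYMS: dict[str, list[str]] = {}
for _c, _a in _CODON_TABLE.items():
    _SYNONYMS.setdefault(_a, []).append(_c)


def _codons(cds: str) -> list[str]:
    cds = cds.upper().replace("U", "T")
    if len(cds) % 3:
        raise ValueError("CDS length must be divisible by 3")
    return [cds[i : i + 3] for i in range(0, len(cds), 3)]


def relative_adaptiveness(reference: list[str]) -> dict[str, float]:
    """Per-codon w = codon frequency / frequency of the most-used synonymous
    codon, from a reference CDS set. Codons unseen in the reference fall back
    to add-0.5 smoothed counts within their family (flagged in the log)."""
    if not reference:
        raise ValueError("empty reference set")
    counts: dict[str, int] = {c: 0 for c in _CODON_TABLE}
    for cds in reference:
        for c in _codons(cds):
            if c in counts:
                counts[c] += 1
    w: dict[str, float] = {}
    smoothed = False
    for aa, codons in _SYNONYMS.items():
        if aa == "*":
            continue
        fam = {c: counts[c] for c in codons}
        if min(fam.values()) == 0:
            fam = {c: v + 0.5 for c, v in fam.items()}
            smoothed = True
        m = max(fam.values())
        for c, v in fam.items():
            w[c] = v / m
    if smoothed:
        log.info("relative_adaptiveness: smoothed unseen codons with +0.5 counts")
    return w


def cai(cds: str, reference: list[str] | dict[str, float]) -> float:
    """Codon adaptation index: geometric mean of relative adaptiveness over
    the query's codons, stop codons excluded. In (0, 1]; 1.0 when the query
    uses only reference-maximal codons."""
    w = reference if isinstance(reference, dict) else relative_adaptiveness(reference)
    logs = [np.log(w[c]) for c in _codons(cds) if _CODON_TABLE.get(c, "*") != "*"]
    if not logs:
        raise ValueError("CDS has no non-stop codons")
    return float(np.exp(np.mean(logs)))


def cai_reference_from_expression(
    cds_by_gene: dict[str, str], tpm: pd.Series, top_fraction: float = 0.05
) -> list[str]:
    """Reference set: CDSs of the top ``top_fraction`` of expressed genes."""
    expressed = tpm[tpm > 0].sort_values(ascending=False)
    n = max(1, int(round(top_fraction * len(expressed))))
    return [cds_by_gene[g] for g in expressed.index[:n] if g in cds_by_gene]


# ---------------------------------------------------------------------------
# matched sampling and regression
# ---------------------------------------------------------------------------

def matched_subsample(
    values: pd.Series,
    targets: set[str],
    seed: int = 0,
    n_bins: int = 50,
    on_empty_bin: str = "error",
) -> list[str]:
    """Nontargets sampled to match the targets' distribution of a matching
    variable (on the log2 scale) within quantile bins.

    Sampling is without replacement per bin; a short bin falls back to
    replacement (flagged). A bin with no nontargets at all raises by
    default; ``on_empty_bin="nearest"`` instead borrows the nontargets
    closest in value (for target tails outside the nontarget range). Returns
    a list of nontarget gene ids of the same size as the target set.
    """
    rng = np.random.default_rng(np.random.SeedSequence([1111, seed]))
    tgt = [g for g in values.index if g in targets]
    non = [g for g in values.index if g not in targets]
    if not tgt or not non:
        raise ValueError("empty target or nontarget group")
    lv = np.log2(values.astype(float).clip(lower=1e-12))
    tvals = lv.reindex(tgt).to_numpy()
    if np.allclose(tvals, tvals[0]):
        return [non[i] for i in rng.choice(len(non), size=len(tgt), replace=len(non) < len(tgt))]
    edges = np.quantile(tvals, np.linspace(0, 1, n_bins + 1))
    edges[0], edges[-1] = -np.inf, np.inf
    t_bins = np.searchsorted(edges, tvals, side="right") - 1
    n_bins_v = np.searchsorted(edges, lv.reindex(non).to_numpy(), side="right") - 1
    chosen: list[str] = []
    for b in range(n_bins):
        need = int((t_bins == b).sum())
        if need == 0:
            continue
        avail = [non[i] for i in np.flatnonzero(n_bins_v == b)]
        if not avail:
            if on_empty_bin != "nearest":
                raise ValueError(f"no nontargets available in matching bin {b}")
            center = float(np.mean(tvals[t_bins == b]))
            nvals = lv.reindex(non).to_numpy()
            order = np.argsort(np.abs(nvals - center), kind="stable")
            avail = [non[i] for i in order[: max(need, 3)]]
            log.info("matched_subsample: bin %d empty; borrowing %d nearest nontargets", b, len(avail))
        if len(avail) < need:
            log.info("matched_subsample: bin %d short (%d < %d), sampling with replacement", b, len(avail), need)
            idx = rng.choice(len(avail), size=need, replace=True)
        else:
            idx = rng.choice(len(avail), size=need, replace=False)
        chosen.extend(avail[i] for i in idx)
    return chosen


@dataclass
class RegressionFit:
    """OLS fit of TE on log2 covariates plus the binary target flag."""

    params: pd.Series  # const, log2_tpm, log2_cds, log2_utr3, log2_cai, target
    bse: pd.Series
    rss: float
    n: int
    correlations: pd.DataFrame

    @property
    def target_coefficient(self) -> float:
        return float(self.params["target"])


TE_COVARIATES = ["log2_tpm", "log2_cds", "log2_utr3", "log2_cai"]


def build_te_table(
    te: pd.Series,
    tpm: pd.Series,
    cds_lengths: pd.Series,
    utr3_lengths: pd.Series,
    cai_values: pd.Series,
    targets: set[str],
) -> pd.DataFrame:
    """Assemble the per-gene TE table with log2 covariates and target flag."""
    df = pd.DataFrame({"te": te})
    df["log2_tpm"] = np.log2(tpm.reindex(df.index).astype(float))
    df["log2_cds"] = np.log2(cds_lengths.reindex(df.index).astype(float))
    df["log2_utr3"] = np.log2(utr3_lengths.reindex(df.index).astype(float))
    df["log2_cai"] = np.log2(cai_values.reindex(df.index).astype(float))
    df["target"] = [int(g in targets) for g in df.index]
    df = df.replace([np.inf, -np.inf], np.nan).dropna()
    return df


def fit_loglinear(te_table: pd.DataFrame, covariates: list[str] | None = None) -> RegressionFit:
    """OLS of TE on the log2 covariates and the target flag, with
    point-biserial correlation for the flag and Spearman rank correlations
    for continuous covariates."""
    covs = covariates if covariates is not None else TE_COVARIATES + ["target"]
    if len(te_table) < 50:
        raise ValueError("need at least 50 genes")
    X = sm.add_constant(te_table[covs].astype(float))
    cond = np.linalg.cond(X.to_numpy())
    if cond > 1e8:
        raise ValueError(f"collinear covariates (condition number {cond:.3g})")
    fit = sm.OLS(te_table["te"].astype(float), X).fit()
    params = fit.params.rename(index={"const": "const"})
    corr_rows = []
    for c in covs:
        if set(te_table[c].unique()) <= {0, 1}:
            r, p = stats.pointbiserialr(te_table[c], te_table["te"])
            kind = "point-biserial"
        else:
            r, p = stats.spearmanr(te_table[c], te_table["te"])
            kind = "spearman"
        corr_rows.append({"covariate": c, "r": float(r), "p": float(p), "kind": kind})
    return RegressionFit(
        params=params,
        bse=fit.bse,
        rss=float(fit.ssr),
        n=int(fit.nobs),
        correlations=pd.DataFrame(corr_rows),
    )


def lrt_nested(fit_full: RegressionFit, fit_reduced: RegressionFit) -> tuple[float, float]:
    """Likelihood-ratio test of nested OLS fits: statistic
    n * ln(RSS_reduced / RSS_full), chi-square with df = parameter-count
    difference."""
    full_terms = set(fit_full.params.index)
    red_terms = set(fit_reduced.params.index)
    if not red_terms < full_terms or fit_full.n != fit_reduced.n:
        raise ValueError("models are not nested on the same genes")
    df = len(full_terms) - len(red_terms)
    stat = fit_full.n * np.log(fit_reduced.rss / fit_full.rss)
    return float(stat), float(stats.chi2.sf(stat, df))


def adjusted_te(te_table: pd.DataFrame, fit: RegressionFit) -> pd.Series:
    """TE minus the modeled covariate contributions (intercept and target
    term not subtracted)."""
    if len(te_table) != fit.n:
        raise ValueError("fit and table cover different gene sets")
    contribution = np.zeros(len(te_table))
    for c in TE_COVARIATES:
        if c in fit.params.index:
            contribution = contribution + fit.params[c] * te_table[c].to_numpy(dtype=float)
    return pd.Series(te_table["te"].to_numpy() - contribution, index=te_table.index, name="adjusted_te")


def median_te_effect(te: pd.Series, targets: set[str]) -> float:
    """Median TE of targets minus median TE of nontargets (log2 units)."""
    is_t = te.index.isin(list(targets))
    return float(te[is_t].median() - te[~is_t].median())


def geneset_te_compare(te_table: pd.DataFrame, gene_set: set[str]) -> dict[str, float]:
    """Two-sided Mann-Whitney U of a gene set's TE against the complement."""
    inset = te_table.index.isin(list(gene_set))
    if not inset.any():
        raise ValueError("gene set does not intersect the TE table")
    if inset.all():
        raise ValueError("gene set covers the whole table; empty complement")
    a = te_table.loc[inset, "te"].to_numpy()
    b = te_table.loc[~inset, "te"].to_numpy()
    u, p = mwu_compare(a, b, alternative="two-sided")
    return {
        "U": u,
        "p": p,
        "median_set": float(np.median(a)),
        "median_rest": float(np.median(b)),
        "n_set": int(inset.sum()),
        "n_rest": int((~inset).sum()),
    }
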