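import numpy as np
import pandas as pd
import pytest
from scipy import stats

from utrclip.config import SimConfig
from utrclip.simulate import make_te_truth, ribotag_design, simulate_ribotag
from utrclip.translation import (
    TE_COVARIATES,
    adjusted_te,
    build_te_table,
    cai,
    estimate_te,
    filter_genes,
    fit_loglinear,
    geneset_te_compare,
    lrt_nested,
    matched_subsample,
    median_te_effect,
    relative_adaptiveness,
    size_factors,
)


# ---------------------------------------------------------------------------
# size factors
# ---------------------------------------------------------------------------

def test_size_factors_trivia_and_scaling():
    rng = np.random.default_rng(0)
    base = pd.DataFrame(rng.poisson(100, size=(200, 4)) + 1, columns=list("abcd"))
    identical = pd.concat([base["a"]] * 4, axis=1, keys=list("abcd"))
    assert np.allclose(size_factors(identical), 1.0)
    doubled = base.copy()
    doubled["b"] = base["b"] * 2
    f0 = size_factors(base)
    f1 = size_factors(doubled)
    # doubling a column doubles its factor relative to the others (the
    # geometric-mean reference itself shifts by 2^(1/m))
    assert (f1["b"] / f1["a"]) / (f0["b"] / f0["a"]) == pytest.approx(2.0, rel=1e-12)
    for c in "cd":
        assert f1[c] / f1["a"] == pytest.approx(f0[c] / f0["a"], rel=1e-12)


def test_size_factors_match_formula_oracle():
    rng = np.random.default_rng(1)
    counts = pd.DataFrame(rng.poisson(50, size=(100, 6)) + 1, columns=[f"s{i}" for i in range(6)])
    got = size_factors(counts)
    mat = counts.to_numpy(dtype=float)
    ref = np.exp(np.mean(np.log(mat), axis=1))
    for j, col in enumerate(counts.columns):
        assert got[col] == pytest.approx(np.median(mat[:, j] / ref), rel=1e-12)


def test_size_factors_require_all_nonzero_gene():
    counts = pd.DataFrame([[0, 1], [1, 0]], columns=["a", "b"])
    with pytest.raises(ValueError):
        size_factors(counts)


# ---------------------------------------------------------------------------
# gene filter
# ---------------------------------------------------------------------------

def test_filter_boundary_inclusive_and_oracle():
    meta = ribotag_design(3)
    rng = np.random.default_rng(2)
    counts = pd.DataFrame(
        rng.poisson(30, size=(1000, len(meta))) + 1,
        columns=meta.index,
        index=[f"g{i}" for i in range(1000)],
    )
    ip = meta.index[meta["RiboTag.specific"] == 1]
    rna = meta.index[meta["assay"] == "germ-RNA"]
    counts.loc["g0", :] = 20
    counts.loc["g0", ip] = [5, 5, 5]  # sum exactly 15
    counts.loc["g0", rna] = [4, 3, 3]  # sum exactly 10
    counts.loc["g1", ip] = 0  # dropped
    factors = pd.Series(1.0, index=meta.index)
    kept = filter_genes(counts, meta, factors)
    assert "g0" in kept and "g1" not in kept
    norm = counts / factors
    oracle = counts.index[(norm[ip].sum(axis=1) >= 15) & (norm[rna].sum(axis=1) >= 10)]
    assert list(kept) == list(oracle)


# ---------------------------------------------------------------------------
# TE estimation
# ---------------------------------------------------------------------------

def test_te_zero_for_flat_gene_and_one_for_doubled():
    meta = ribotag_design(3)
    counts = pd.DataFrame(100, index=[f"g{i}" for i in range(100)], columns=meta.index)
    ip = meta.index[meta["RiboTag.specific"] == 1]
    counts.loc["g0", ip] = 200  # exactly 2x the no-specific-term prediction
    te = estimate_te(counts, meta)
    assert te["g1"] == pytest.approx(0.0, abs=1e-9)
    # exact doubling up to the 0.5 pseudocount: log2(200.5) - log2(100.5)
    assert te["g0"] == pytest.approx(1.0, abs=0.01)


def test_te_scaling_invariance():
    """Multiplying one sample's counts by a constant is absorbed by the size
    factors and leaves TE unchanged up to the pseudocount's
    O(pseudocount/count) footprint (the geometric-mean reference shifts by
    k^(1/m), which interacts with the +0.5 offset)."""
    truth, germ = make_te_truth(300, 0.2, 0.3, seed=5)
    counts, meta = simulate_ribotag(truth, germ, SimConfig(seed=5))
    counts = counts + 1
    te0 = estimate_te(counts, meta)
    scaled = counts.copy()
    scaled.iloc[:, 0] = scaled.iloc[:, 0] * 3
    te1 = estimate_te(scaled, meta)
    assert np.allclose(te0, te1, atol=5e-3)


@pytest.mark.parametrize("delta", [0.0, 0.2, 0.4])
def test_te_recovery_matched_and_regression(delta):
    """Planted effects are recovered within +/-0.1 by both the matched-
    sampling median difference and the regression coefficient."""
    matched_est, beta_est = [], []
    for seed in range(4):
        truth, germ = make_te_truth(2000, 0.2, delta, seed=seed)
        counts, meta = simulate_ribotag(truth, germ, SimConfig(seed=seed))
        kept = filter_genes(counts, meta, size_factors(counts))
        te = estimate_te(counts.loc[kept], meta)
        genes = te.index
        rng = np.random.default_rng(seed)
        cds = pd.Series(rng.integers(300, 3000, size=len(genes)) * 3, index=genes)
        utr = pd.Series(rng.integers(100, 2000, size=len(genes)), index=genes)
        cai_s = pd.Series(rng.uniform(0.5, 1.0, size=len(genes)), index=genes)
        table = build_te_table(te, germ["germ"].reindex(genes), cds, utr, cai_s, truth.target_genes)
        matched = matched_subsample(
            np.power(2.0, table["log2_tpm"]), truth.target_genes & set(table.index), seed=seed
        )
        tgt = [g for g in table.index if g in truth.target_genes]
        matched_est.append(float(table.loc[tgt, "te"].median() - table.loc[matched, "te"].median()))
        beta_est.append(fit_loglinear(table).target_coefficient)
    assert abs(np.mean(matched_est) - delta) <= 0.1
    assert abs(np.mean(beta_est) - delta) <= 0.1
    assert abs(np.mean(matched_est) - np.mean(beta_est)) <= 0.1


# ---------------------------------------------------------------------------
# CAI
# ---------------------------------------------------------------------------

def test_cai_optimal_codons_give_one():
    reference = ["ATGGCTGCTGCTTAA"] * 3  # Ala always GCT
    assert cai("ATGGCTGCTTAA", reference) == pytest.approx(1.0)


def test_cai_single_codon_amino_acids():
    # Met (ATG) and Trp (TGG) have no synonyms: w = 1 by definition
    reference = ["ATGTGGATGTGGTAA"]
    assert cai("ATGTGGTAA", reference) == pytest.approx(1.0)


def test_cai_hand_computed_toy():
    # reference: Phe TTT x3, TTC x1 -> w(TTT)=1, w(TTC)=1/3
    reference = ["ATGTTTTTTTTTTTCTAA"]
    w = relative_adaptiveness(reference)
    assert w["TTT"] == pytest.approx(1.0)
    assert w["TTC"] == pytest.approx(1 / 3)
    # query Phe-TTC + Phe-TTT: CAI = sqrt(1 * 1/3); ATG contributes w=1
    got = cai("ATGTTCTTTTAA", reference)
    assert got == pytest.approx(np.exp(np.mean(np.log([1.0, 1 / 3, 1.0]))))


def test_cai_rejects_partial_codons():
    with pytest.raises(ValueError):
        cai("ATGTT", ["ATGTAA"])


# ---------------------------------------------------------------------------
# matched sampling
# ---------------------------------------------------------------------------

def test_matched_subsample_determinism_and_degenerate():
    rng = np.random.default_rng(3)
    vals = pd.Series(rng.lognormal(3, 1, 500), index=[f"g{i}" for i in range(500)])
    targets = set(vals.index[:100])
    a = matched_subsample(vals, targets, seed=4, n_bins=20)
    b = matched_subsample(vals, targets, seed=4, n_bins=20)
    assert a == b
    assert len(a) == 100
    assert set(a) & targets == set()
    const = pd.Series(5.0, index=vals.index)
    c = matched_subsample(const, targets, seed=4, n_bins=20)
    assert len(c) == 100


def test_matched_subsample_ks_calibration():
    """When nontargets follow the targets' distribution, the matched set
    passes a KS test on the matching variable (p > 0.1) in >= 95% of seeds."""
    rng = np.random.default_rng(5)
    vals = pd.Series(rng.lognormal(3, 1, 2000), index=[f"g{i}" for i in range(2000)])
    targets = set(vals.index[:400])
    n_pass = 0
    for seed in range(100):
        matched = matched_subsample(vals, targets, seed=seed)
        p = stats.ks_2samp(
            np.log2(vals[list(targets)]), np.log2(vals[matched])
        ).pvalue
        n_pass += p > 0.1
    assert n_pass >= 95


# ---------------------------------------------------------------------------
# regression, LRT, adjusted TE
# ---------------------------------------------------------------------------

def _noiseless_table(n=500, beta=(0.1, -0.2, 0.15, 0.3, 0.4), seed=6):
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(n)]
    df = pd.DataFrame(
        {
            "log2_tpm": rng.normal(5, 2, n),
            "log2_cds": rng.normal(10, 1, n),
            "log2_utr3": rng.normal(9, 1, n),
            "log2_cai": rng.normal(-0.3, 0.1, n),
            "target": rng.integers(0, 2, n),
        },
        index=genes,
    )
    df["te"] = (
        1.0
        + beta[0] * df["log2_tpm"]
        + beta[1] * df["log2_cds"]
        + beta[2] * df["log2_utr3"]
        + beta[3] * df["log2_cai"]
        + beta[4] * df["target"]
    )
    return df, beta


def test_fit_noiseless_identifiability():
    df, beta = _noiseless_table()
    fit = fit_loglinear(df)
    got = [fit.params[c] for c in TE_COVARIATES + ["target"]]
    assert np.allclose(got, beta, atol=1e-8)
    assert fit.params["const"] == pytest.approx(1.0, abs=1e-8)


def test_fit_null_flag_within_three_se():
    """With the target flag permuted at random, the flag coefficient lies
    within +/-3 SE of zero in >= 95% of runs."""
    df, _ = _noiseless_table()
    rng = np.random.default_rng(7)
    n_ok = 0
    for _ in range(100):
        shuffled = df.copy()
        shuffled["te"] = df["te"] - 0.4 * df["target"] + rng.normal(0, 0.5, len(df))
        shuffled["target"] = rng.permutation(df["target"].to_numpy())
        fit = fit_loglinear(shuffled)
        n_ok += abs(fit.params["target"]) <= 3 * fit.bse["target"]
    assert n_ok >= 95


def test_fit_guards():
    df, _ = _noiseless_table(n=40)
    with pytest.raises(ValueError):
        fit_loglinear(df)
    df2, _ = _noiseless_table()
    df2["log2_cds"] = df2["log2_tpm"] * 2  # collinear
    with pytest.raises(ValueError):
        fit_loglinear(df2)


def test_lrt_trivia_null_and_power():
    df, beta = _noiseless_table()
    rng = np.random.default_rng(8)
    df["te"] = df["te"] + rng.normal(0, 0.3, len(df))
    full = fit_loglinear(df)
    with pytest.raises(ValueError):
        lrt_nested(full, full)  # not strictly nested
    red = fit_loglinear(df, covariates=TE_COVARIATES)
    stat, p = lrt_nested(full, red)
    assert p < 1e-10  # beta_target = 0.4 at n=500

    # null calibration of the LRT
    n_sig = 0
    n_runs = 200
    for seed in range(n_runs):
        rng = np.random.default_rng(seed + 1000)
        null_df = df.copy()
        null_df["te"] = (
            0.1 * df["log2_tpm"] + rng.normal(0, 0.5, len(df))
        )
        null_df["target"] = rng.permutation(df["target"].to_numpy())
        f = fit_loglinear(null_df)
        r = fit_loglinear(null_df, covariates=TE_COVARIATES)
        _, pv = lrt_nested(f, r)
        n_sig += pv < 0.05
    assert 0.02 * n_runs <= n_sig <= 0.08 * n_runs


def test_adjusted_te_identities():
    df, beta = _noiseless_table()
    fit = fit_loglinear(df)
    adj = adjusted_te(df, fit)
    # covariate contributions removed exactly: median difference is beta_target
    tgt = df["target"] == 1
    assert adj[tgt].median() - adj[~tgt].median() == pytest.approx(beta[4], abs=1e-8)
    # refit of adjusted TE: no covariate signal remains (given the flag)
    df2 = df.copy()
    df2["te"] = adj
    refit = fit_loglinear(df2)
    for c in TE_COVARIATES:
        assert abs(refit.params[c]) < 1e-6


def test_geneset_te_compare_guards_and_power():
    df, _ = _noiseless_table()
    rng = np.random.default_rng(9)
    df["te"] = rng.normal(0, 0.5, len(df))
    genes = list(df.index)
    deficit = set(genes[:50])
    df.loc[list(deficit), "te"] -= 1.0
    res = geneset_te_compare(df, deficit)
    assert res["p"] < 1e-4
    assert res["median_set"] < res["median_rest"]
    with pytest.raises(ValueError):
        geneset_te_compare(df, set())
    with pytest.raises(ValueError):
        geneset_te_compare(df, set(genes))
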