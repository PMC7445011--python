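import math

import numpy as np
import pandas as pd
import pytest

from utrclip.config import SimConfig
from utrclip.genome import build_genome
from utrclip.peaks import (
    AnnotationIndex,
    REGION_HIERARCHY,
    call_peaks,
    merge_sites,
    replicate_consensus,
    transcriptome_share,
)
from utrclip.preprocess import crosslink_track_from_alignments, CrosslinkTrack, pileup
from utrclip.simulate import CONTROL_SAMPLE, plant_sites_and_expression, simulate_iclip


def poisson_sf_series(k: int, lam: float) -> float:
    """Brute-force upper tail P(X >= k) by direct series summation."""
    return 1.0 - sum(math.exp(-lam) * lam**i / math.factorial(i) for i in range(k))


@pytest.fixture(scope="module")
def fixture(small_genome):
    cfg, genome, txs = small_genome
    truth, germ, _ = plant_sites_and_expression(genome, txs, cfg)
    fastq, samples = simulate_iclip(genome, txs, truth, germ, cfg)
    lengths = {k: len(v) for k, v in genome.items()}
    tracks = {
        name: crosslink_track_from_alignments(s.alignments, name, lengths)
        for name, s in samples.items()
    }
    return cfg, genome, txs, truth, germ, tracks


# ---------------------------------------------------------------------------
# region assignment
# ---------------------------------------------------------------------------

def test_region_hierarchy_prefers_utr3_over_intron():
    """A position in both a 3' UTR (one gene) and an intron (another) is
    classified utr3, per the region hierarchy."""
    from utrclip.genome import TranscriptModel

    a = TranscriptModel("gA", "gA.t1", "c", "+", [(0, 300)], 50, 200)
    b = TranscriptModel("gB", "gB.t1", "c", "+", [(0, 100), (400, 500)], 0, 500)
    idx = AnnotationIndex([a, b])
    # 250 is in gA's 3' UTR (cds_end=200..300) and inside gB's intron
    assert idx.assign_region("c", 250, "+") == "utr3"
    assert idx.assign_region("c", 350, "+") == "intron"
    assert idx.assign_region("c", 1000, "+") == "intergenic"
    with pytest.raises(KeyError):
        idx.assign_region("nope", 0, "+")


def test_region_assignment_matches_bruteforce(small_genome):
    cfg, genome, txs = small_genome
    idx = AnnotationIndex(txs)
    rng = np.random.default_rng(0)
    L = len(genome["chrT"])

    def brute(pos, strand):
        best = "intergenic"
        rank = {r: i for i, r in enumerate(REGION_HIERARCHY)}
        for t in txs:
            if t.strand != strand:
                continue
            feats = []
            if t.biotype == "protein_coding":
                feats += [("utr3", iv) for iv in t.utr3_intervals]
                feats += [("utr5", iv) for iv in t.utr5_intervals]
                feats += [("cds", iv) for iv in t.cds_intervals]
            else:
                feats += [(t.biotype, iv) for iv in t.exons]
            feats += [("intron", iv) for iv in t.intron_intervals]
            for cls, (s, e) in feats:
                if s <= pos < e and rank[cls] < rank[best]:
                    best = cls
        return best

    for pos in rng.integers(0, L, size=1000).tolist():
        strand = "+" if pos % 2 else "-"
        assert idx.assign_region("chrT", pos, strand) == brute(pos, strand)


# ---------------------------------------------------------------------------
# peak calling
# ---------------------------------------------------------------------------

def test_poisson_tail_matches_series_sum():
    from scipy import stats

    for k in range(1, 51):
        for lam in (0.1, 1.0, 5.0):
            assert stats.poisson.sf(k - 1, lam) == pytest.approx(
                poisson_sf_series(k, lam), abs=1e-12
            )


def test_single_nucleotide_tail_example():
    from scipy import stats

    expected = 1.0 - sum(
        math.exp(-0.1) * 0.1**i / math.factorial(i) for i in range(10)
    )
    assert stats.poisson.sf(9, 0.1) == pytest.approx(expected, rel=1e-9)


def test_planted_peaks_recovered(fixture):
    """Strong planted signal over flat background: all planted nucleotides
    called at FDR < 0.05 and few false positives."""
    cfg, genome, txs, truth, germ, tracks = fixture
    idx = AnnotationIndex(txs)
    tx_by_id = {t.tx_id: t for t in txs}
    planted = {
        (tx_by_id[tx].contig, tx_by_id[tx].strand, tx_by_id[tx].utr3_offset_to_genomic(off))
        for tx, offs in truth.planted_sites.items()
        for off in offs
    }
    rep = next(s for s in tracks if s != CONTROL_SAMPLE)
    peaks = call_peaks(tracks[rep], tracks[CONTROL_SAMPLE], germ["germ"], idx)
    called = set(zip(peaks["contig"], peaks["strand"], peaks["pos"]))
    assert len(planted & called) >= 0.95 * len(planted)
    assert len(called - planted) <= max(2, 0.05 * len(called))


def test_empty_track_no_peaks(fixture):
    cfg, genome, txs, truth, germ, tracks = fixture
    idx = AnnotationIndex(txs)
    empty = CrosslinkTrack(sample="empty")
    assert len(call_peaks(empty, tracks[CONTROL_SAMPLE], germ["germ"], idx)) == 0


def test_fdr_monotonicity(fixture):
    cfg, genome, txs, truth, germ, tracks = fixture
    idx = AnnotationIndex(txs)
    rep = next(s for s in tracks if s != CONTROL_SAMPLE)
    loose = call_peaks(tracks[rep], tracks[CONTROL_SAMPLE], germ["germ"], idx, fdr=0.05)
    strict = call_peaks(tracks[rep], tracks[CONTROL_SAMPLE], germ["germ"], idx, fdr=0.01)
    assert set(zip(strict["contig"], strict["pos"])) <= set(zip(loose["contig"], loose["pos"]))


def test_null_fixture_rarely_yields_peaks():
    """With no planted sites, <= 10% of background-only fixtures produce any
    FDR < 0.05 peak (50 seeds)."""
    cfg = SimConfig(seed=21, n_genes=15, target_fraction=0.0, library_sizes=20_000)
    genome, txs = build_genome(cfg)
    idx = AnnotationIndex(txs)
    n_any = 0
    for seed in range(50):
        c = SimConfig(**{**cfg.to_dict(), "seed": seed})
        truth, germ, _ = plant_sites_and_expression(genome, txs, c)
        _, samples = simulate_iclip(genome, txs, truth, germ, c)
        lengths = {k: len(v) for k, v in genome.items()}
        rep = next(n for n in samples if n != CONTROL_SAMPLE)
        track = crosslink_track_from_alignments(samples[rep].alignments, rep, lengths)
        control = crosslink_track_from_alignments(
            samples[CONTROL_SAMPLE].alignments, CONTROL_SAMPLE, lengths
        )
        peaks = call_peaks(track, control, germ["germ"], idx)
        if len(peaks):
            n_any += 1
    assert n_any <= 5


# ---------------------------------------------------------------------------
# consensus and site merging
# ---------------------------------------------------------------------------

def _peak_frame(positions):
    return pd.DataFrame(
        {
            "contig": "c",
            "strand": "+",
            "pos": list(positions),
            "count": 5,
            "expected": 0.1,
            "p_value": 1e-6,
            "fdr": 1e-4,
            "region_class": "utr3",
            "gene_id": "g",
        }
    )


def test_replicate_consensus_rules():
    reps = [_peak_frame([10, 20]), _peak_frame([10, 30]), _peak_frame([40])]
    cons = replicate_consensus(reps)
    assert set(cons["pos"]) == {10}
    assert cons.loc[cons["pos"] == 10, "support"].item() == 2
    with pytest.raises(ValueError):
        replicate_consensus([_peak_frame([1])])


def test_replicate_consensus_matches_incidence_oracle():
    rng = np.random.default_rng(5)
    reps = [_peak_frame(sorted(rng.choice(200, size=60, replace=False))) for _ in range(3)]
    cons = replicate_consensus(reps)
    from collections import Counter

    counts = Counter(p for df in reps for p in df["pos"])
    expected = {p for p, n in counts.items() if n >= 2}
    assert set(cons["pos"]) == expected


def test_merge_sites_run_length_example(small_genome):
    """Consensus positions {100,101,102,110} within one 3' UTR merge into
    two sites: [100,103) and [110,111)."""
    cfg, genome, txs = small_genome
    t = next(t for t in txs if t.biotype == "protein_coding" and t.strand == "+" and t.utr3_len > 150)
    (s, e), = t.utr3_intervals
    base = s + 20
    cons = pd.DataFrame(
        {
            "contig": t.contig,
            "strand": "+",
            "pos": [base, base + 1, base + 2, base + 10],
            "support": 2,
            "min_p": 1e-8,
        }
    )
    idx = AnnotationIndex(txs)
    tpm = pd.Series(10.0, index=[x.gene_id for x in txs])
    ts = merge_sites(cons, idx, tpm)
    spans = sorted((x.start, x.end) for x in ts.sites)
    assert spans == [(base, base + 3), (base + 10, base + 11)]
    assert all(x.representative == x.start for x in ts.sites)
    assert ts.targets == {t.gene_id}


def test_merge_sites_minus_strand_representative(small_genome):
    cfg, genome, txs = small_genome
    t = next(t for t in txs if t.biotype == "protein_coding" and t.strand == "-" and t.utr3_len > 150)
    (s, e), = t.utr3_intervals
    base = s + 30
    cons = pd.DataFrame(
        {"contig": t.contig, "strand": "-", "pos": [base, base + 1], "support": 3, "min_p": 1e-9}
    )
    idx = AnnotationIndex(txs)
    tpm = pd.Series(10.0, index=[x.gene_id for x in txs])
    ts = merge_sites(cons, idx, tpm)
    (site,) = ts.sites
    # 5'-most on the minus strand is the highest genomic coordinate
    assert site.representative == site.end - 1


def test_low_tpm_gene_excluded(small_genome):
    cfg, genome, txs = small_genome
    t = next(t for t in txs if t.biotype == "protein_coding")
    (s, e), = t.utr3_intervals
    cons = pd.DataFrame(
        {"contig": t.contig, "strand": t.strand, "pos": [s + 5], "support": 2, "min_p": 1e-8}
    )
    idx = AnnotationIndex(txs)
    tpm = pd.Series(10.0, index=[x.gene_id for x in txs])
    tpm[t.gene_id] = 0.5
    ts = merge_sites(cons, idx, tpm)
    assert t.gene_id not in ts.universe
    assert t.gene_id not in ts.targets
    assert ts.sites == []


def test_transcriptome_share_hand_arithmetic():
    from utrclip.peaks import TargetSet

    tpm = pd.Series({"g1": 10.0, "g2": 30.0, "g3": 40.0, "g4": 20.0})
    ts = TargetSet(targets={"g1", "g2"}, sites=[], universe={"g1", "g2", "g3", "g4"})
    gene_frac, mol_frac = transcriptome_share(ts, tpm)
    assert gene_frac == pytest.approx(0.5)
    assert mol_frac == pytest.approx(0.4)
    assert transcriptome_share(
        TargetSet(targets=set(), sites=[], universe={"g1"}), tpm
    ) == (0.0, 0.0)
    with pytest.raises(ValueError):
        transcriptome_share(TargetSet(targets=set(), sites=[], universe=set()), tpm)


def test_recovery_across_seeds():
    """Signal >= 20x background: site-level recall and gene-level precision
    >= 0.95 across seeds."""
    recalls, precisions = [], []
    for seed in range(10):
        cfg = SimConfig(seed=seed, n_genes=30, library_sizes=30_000)
        genome, txs = build_genome(cfg)
        truth, germ, _ = plant_sites_and_expression(genome, txs, cfg)
        _, samples = simulate_iclip(genome, txs, truth, germ, cfg)
        lengths = {k: len(v) for k, v in genome.items()}
        idx = AnnotationIndex(txs)
        tracks = {
            n: crosslink_track_from_alignments(s.alignments, n, lengths)
            for n, s in samples.items()
        }
        control = tracks[CONTROL_SAMPLE]
        peak_sets = [
            call_peaks(tracks[n], control, germ["germ"], idx)
            for n in tracks
            if n != CONTROL_SAMPLE
        ]
        ts = merge_sites(replicate_consensus(peak_sets), idx, germ["germ"])
        tx_by_id = {t.tx_id: t for t in txs}
        planted = {
            (tx_by_id[tx].contig, tx_by_id[tx].strand, tx_by_id[tx].utr3_offset_to_genomic(off))
            for tx, offs in truth.planted_sites.items()
            for off in offs
        }
        recovered = {
            (s_.contig, s_.strand, p)
            for s_ in ts.sites
            for p in range(s_.start, s_.end)
        }
        if planted:
            recalls.append(len(planted & recovered) / len(planted))
        truth_genes = truth.target_genes & ts.universe
        if ts.targets:
            precisions.append(len(ts.targets & truth_genes) / len(ts.targets))
    assert np.mean(recalls) >= 0.95
    assert np.mean(precisions) >= 0.95
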