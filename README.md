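# utrclip

**utrclip** is a Python package for analyzing the 3' UTR regulatory program of
an RNA-binding protein (RBP) in germ cells, from raw iCLIP reads to
replicate-consensus binding sites, crosslink-anchored motif statistics,
positional and conservation analyses along the 3' UTR, target-trait
enrichment tests, and RiboTag-based translational-efficiency (TE) modeling.
It is aimed at computational biologists who want each of these stages as a
tested, reusable library function rather than a chain of one-off scripts.

Because real iCLIP/RiboTag studies require large deposited sequencing data,
the package ships a first-class synthetic-data generator
(`utrclip.simulate`) that produces every input with planted ground truth — a
toy genome with gene models, multiplexed iCLIP reads with the 3+4+2-nt
barcode layout and PCR duplication, an IgG background library, expression
tables, RiboTag count matrices, and conservation tracks — so the whole
pipeline is testable end to end, offline, with known answers.

## The analysis in brief

- **Crosslink nucleotides.** Truncated iCLIP cDNAs start one nucleotide 3'
  of the protein contact, so each alignment's crosslink is the nucleotide
  immediately 5' of the read start in transcript orientation (plus strand:
  `start − 1`; minus strand: `end`). PCR duplicates are collapsed on full
  sequence identity before barcodes are removed.
- **Peaks and binding sites.** Per-nucleotide counts are tested against a
  Poisson background with rate λ = max(abundance-scaled rate ∝ gene TPM,
  scaled IgG control rate, floor), with Benjamini–Hochberg control across
  tested nucleotides (zero-truncated tail, since only observed nucleotides
  are tested). Nucleotides significant (FDR < 0.05) in ≥ 2 of 3 replicates
  are merged over consecutive positions into binding sites, restricted to
  3' UTRs of protein-coding genes expressed at ≥ 1 TPM.
- **Motifs.** The U-rich recognition element UGUU(U/A) is analyzed as an
  explicit member set {UGUUU, UGUUA}: nearest-GUU anchored weighted logos,
  motif-start offset profiles against resampled background, the fraction of
  sites with a motif start within ±10 nt of the site's 5'-most crosslinked
  nucleotide (with an exact dynamic-programming expectation under a 0-order
  background), and Wilcoxon rank-sum enrichment against mononucleotide
  shuffles with Bonferroni correction.
- **Site geography.** Relative position offset/(L−1) in [0, 1] and absolute
  distances from either UTR anchor, compared by two-sample KS tests to a
  per-transcript uniform resampling null; inter-site spacing; Mann–Whitney
  comparison of phastCons/phyloP scores at crosslinked vs non-crosslinked
  nucleotides of the same UTRs.
- **Target traits.** One-tailed hypergeometric enrichment/depletion
  (`P(X ≥ k)` / `P(X ≤ k)`), a testis-specificity rule (testis TPM ≥ 5 and
  ≥ 25% share of summed log₂(TPM+1)), expression breadth, dN/dS, dosage
  sensitivity, and mean miRNA-conservation (P_CT) comparisons.
- **Translational efficiency.** Per gene, log₂(normalized count + 0.5) is
  fit by OLS on the design indicators (tag-specific binding, nonspecific
  antibody binding, germ-cell transcriptome); TE is the specific-binding
  coefficient. The target effect is then quantified two ways: median TE
  difference against abundance-matched nontargets, and the target
  coefficient of `TE ~ log2(TPM) + log2(CDS) + log2(UTR3) + log2(CAI) +
  target` with a likelihood-ratio test and covariate-adjusted TE.

## Worked example

```python
from utrclip import SimConfig
from utrclip.pipeline import run_all

results = run_all(SimConfig(seed=1))
for key, value in results["report"].items():
    print(key, value)
```

prints (seed 1):

```
n_sites 169
n_target_genes 40
gene_fraction_pct 22.22222222222222
molecule_fraction_pct 21.676124460369103
target_precision 1.0
target_recall 1.0
median_intersite_nt 38.0
positional_ks_p 2.0181032477712207e-08
site_motif_fraction_pct 100.0
expected_motif_fraction_pct 4.026323494547706
te_effect_matched 0.3734918095585742
te_effect_regression 0.3881853975503393
lrt_p 6.396801188640372e-16
conservation_phastcons_p 2.4071497892696838e-111
conservation_phylop_p 5.788929766075375e-78
ranksum_p_adj[UGUU(U/A)] 2.0076634656140906e-59
ranksum_p_adj[GUUG] 1.0
ranksum_p_adj[GUUC] 1.0
ranksum_p_adj[UUU(C/G)UUU] 0.036579939097625705
```

Reading: the caller recovered all 40 planted target genes (precision and
recall 1.0) covering 22.2% of the expressed universe and 21.7% of its mRNA
molecules; site positions reject uniformity along the 3' UTR (KS p = 2e-8),
consistent with the planted end-proximal bias; every recovered site carries
the planted motif within ±10 nt of its representative nucleotide, against a
4.0% expectation in random 21-mers; crosslinked nucleotides are more
conserved than their UTR background; and the planted +0.4 log₂ translational
effect is recovered as 0.37 (matched sampling) and 0.39 (regression), which
agree within noise.

The same run is available from the shell:

```bash
utrclip simulate --out bundle/            # write the fixture bundle
utrclip run --seed 1 --out run/           # full pipeline + report.tsv
utrclip report --manifest run/manifest.json
```

## Layout

```
src/utrclip/
  config.py       simulation configuration (SimConfig)
  genome.py       toy genome + transcript models, FASTA/BED12 I/O
  simulate.py     ground-truth generators (iCLIP, RiboTag, atlas, tracks)
  preprocess.py   collapse, demultiplex, crosslink extraction, pileup
  peaks.py        peak calling, replicate consensus, binding sites
  motifs.py       anchored logos, offset profiles, motif fractions, AME-style
                  rank-sum enrichment
  geography.py    positional metagene analysis, nulls, conservation
  traits.py       hypergeometric/Mann-Whitney trait tests
  translation.py  size factors, TE estimation, CAI, matched sampling, OLS/LRT
  pipeline.py     end-to-end orchestration and reporting
  cli.py          `utrclip` console entry point
```

See `docs/methods.md` for the statistical models, parameter defaults, and
known limitations.
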