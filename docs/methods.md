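# Methods

This note documents the statistical models behind each `utrclip` stage, the
parameters that matter, what the synthetic generator does and does not
emulate, and the numerical choices an implementer had to make.

## Coordinate conventions

All coordinates are 0-based, half-open. The crosslink nucleotide of an
alignment is the nucleotide immediately 5' of the read's first mapped
nucleotide in transcript orientation: `start − 1` on the plus strand and
`end` on the minus strand. The minus-strand rule is our interpretation of
"the nucleotide preceding the first nucleotide of the read" under
strand-symmetric truncation chemistry; it is a convention of this package,
and reads whose crosslink would fall off the contig are discarded rather
than clamped. All motif and positional work is done in transcript-sense RNA
coordinates after reverse-complementing minus-strand genomic windows.

## Synthetic study generator

The generator is a pure function of a `SimConfig` (including its seed);
identical configurations give byte-identical fixture bundles. It emulates:

- a single linear contig (~300 kb at the 200-gene default) with genes on
  both strands separated by intergenic gaps; protein-coding genes with 5'
  UTR (80–200 nt), CDS (100–300 codons, AUG start, stop end, no internal
  in-frame stops, up to 2 introns at codon boundaries), and intron-free 3'
  UTR (250–800 nt — long enough that the planted positional program is
  geometrically meaningful); plus a few ncRNA genes and retrogenes so every
  level of the region hierarchy (3' UTR > 5' UTR > CDS > ncRNA > retrogene
  > intron > intergenic) is populated;
- a planted binding program: 20% of expressed, long-UTR genes carry 2–6
  sites; each site writes one UGUU(U/A) member into the UTR with the
  crosslink nucleotide on the first U of the UU core; site positions mix an
  end-proximal window (20–100 nt from the UTR end, weight 0.5), a
  start-proximal window (100–240 nt from the start, weight 0.3), and a
  uniform component (0.2);
- iCLIP lanes with the 3-nt random + 4-nt sample + 2-nt random barcode
  layout, 35-nt inserts, constant quality strings (quality trimming is a
  pre-applied input condition), a configurable exact-duplicate fraction, and
  an IgG-like background-only control. Signal reads start exactly 1 nt 3'
  of the planted crosslink; background reads fall on exonic positions with
  per-nucleotide intensity proportional to TPM, which is exactly the
  background model the peak caller assumes. Molecules whose random barcodes
  collide at the same position are sequence-identical and therefore merged
  at generation time, since no downstream step could distinguish them;
- RiboTag count matrices for four groups (tag-positive IP, tag-negative IP,
  input, sorted germ RNA; 3 replicates each) generated from the inverse of
  the estimation model: log2 expected count = library offset +
  gene-specific nonspecific-binding and germ-transcriptome terms + a
  specific-binding term equal to a base TE (normal, sd 0.15) plus the
  planted effect δ (default +0.4 log2) for targets. Counts are negative
  binomial with variance μ + αμ²; α = 0 degenerates to rounding the mean
  so exact tests are possible. The defaults α = 0.01 and base-TE sd 0.15
  keep the 40-target fixture's realized median effect concentrated near δ,
  so that recovery, not generator shot noise, is what the tests measure;
- conservation tracks over all coding 3' UTRs: a bounded phastCons-like
  track (baseline Beta(1,6), clipped to [0,1]) and an unbounded phyloP-like
  track (baseline standard normal), both shifted by `conservation_boost`
  (default +2.0, in phyloP-like units) at planted crosslink nucleotides;
- a 12-tissue atlas (including testis) and per-gene annotation tables
  (regulator and yeast-ortholog flags, dN/dS, dosage-sensitivity and
  haploinsufficiency scores, mean P_CT) with planted target-vs-nontarget
  directions: targets are built broader (smaller cross-tissue spread),
  testis-specific genes are drawn preferentially from nontargets, and the
  quantitative traits are shifted in the directions the analysis tests.

Not emulated: sequencing error and quality-score models, splice-junction
reads, multi-isoform genes (one transcript per gene, so the
most-expressed-isoform rule is exercised only through its tie-breaks),
genome-scale sequence composition, and correlated biological replicates.
Passing tests therefore demonstrate the correctness of the computational
machinery under a well-specified generative model, not robustness to the
full messiness of real libraries.

## Peak calling

For one replicate, each nucleotide with at least one crosslink event inside
an annotated transcript is tested against a Poisson rate
λ = max(c·TPM_gene, control rate, floor), where c calibrates the
events-per-million scale to the TPM-weighted exonic length of the
annotation, the control rate is the scaled IgG event density over the
transcript span, and the floor is 1e-3 events/nt/million. The reported
`p_value` is the unconditional upper tail P(X ≥ k). Because only observed
(count ≥ 1) nucleotides enter the testing set, Benjamini–Hochberg is applied
to the zero-truncated tail P(X ≥ k | X ≥ 1): with the unconditional tail a
single event at a low-abundance gene would be declared significant, and in
simulation 36/50 background-only fixtures yielded FDR < 0.05 peaks; with
truncation the empirical null rate is at the nominal level. FDR is
controlled globally across all tested nucleotides (one interpretable error
rate) rather than per region class. "Consecutive" in site merging means
genomic distance exactly 1; a gap of one untested nucleotide splits sites.
The representative nucleotide of a site is its 5'-most crosslinked
nucleotide (minimum genomic coordinate on the plus strand, maximum on the
minus strand). Isoform assignment uses the gene's highest-TPM transcript,
ties broken by longest 3' UTR then lexicographic id. The expressed universe
is protein-coding genes at ≥ 1 TPM.

## Motif statistics

Degenerate motifs expand to explicit member sets before any computation
(UGUU(U/A) → {UGUUU, UGUUA}). Nearest-GUU anchoring searches ±10 nt around
the crosslink; equidistant GUUs resolve to the 5' one (deterministic and
strand-consistent). Window weights are −log10 of the peak p-value — base 10
chosen, configurable in spirit since the weighting only enters a ratio —
normalized to mean 1 before the weighted two-proportion z so a handful of
extreme peaks cannot dominate. The background is one unbound GUU per
foreground window by default. The logo statistic is a stand-in for the
weighted-logo tool family; positions inside the anchor itself are GUU in
both foreground and background by construction and carry no signal — the
flanks do.

The expected motif fraction in a random window is computed exactly by
dynamic programming over the Aho–Corasick automaton of the member set under
a 0-order (i.i.d.) base model; it matches exhaustive enumeration to 1e-12
for small windows. Rank-sum enrichment scores each foreground window by the
average motif-start indicator and compares against per-sequence
mononucleotide shuffles (Wilcoxon rank-sum, one-sided, Bonferroni over the
motifs tested in the run). Foreground windows are sized so the motif's UU
core can overlap the crosslink: half-width max(2, motif_len − 2), i.e. ±2
for GUU/GUUG/GUUC, ±3 for UGUU(U/A), ±5 for UUU(C/G)UUU.

## Positional and conservation analysis

Relative position is offset/(L−1) so the UTR start maps to 0 and the end to
1; length-1 UTRs contribute 0 and are logged. The positional null draws,
per transcript, as many uniform offsets as observed sites (with
replacement — observed data can have adjacent sites, and the resampling
preserves per-transcript multiplicity). Distributions are
compared with the two-sample two-sided KS test (exact for n+m ≤ 30,
asymptotic otherwise). Conservation compares crosslinked vs non-crosslinked
nucleotides of the same bound 3' UTRs by two-sided Mann–Whitney U with
tie-corrected normal approximation; missing scores are excluded pairwise
and counted. The normal approximation is a mid-range tool: at n = m = 12 it
tracks exact enumeration within ~10% for moderate p but diverges
multiplicatively in the far tail, which is why extreme-case tests assert
minimality rather than a tail value.

## Target traits

Enrichment uses the upper hypergeometric tail P(X ≥ k), depletion the lower
tail P(X ≤ k). The testis-specificity rule is testis TPM ≥ 5 and a testis
share ≥ 25% of the summed log2 expression; "log2 normalized expression" is
interpreted as log2(TPM + 1) for both the rule and expression breadth — the
pseudocount avoids −∞ at zero TPM and is recorded here because the rule
itself does not force an offset. Mann–Whitney p-values use exact
enumeration when n + m ≤ 30 and there are no ties, the tie-corrected
normal otherwise. The differentiation-rate odds ratio is computed from the
2×2 table of summed differentiating-marker counts (KIT) against
undifferentiated-marker counts minus differentiating (ZBTB16 − KIT, floored
at 0) with a two-sided Fisher exact test; the table layout is this
package's concretization of the cited ratio comparison.

## Translational efficiency

Counts are normalized by median-of-ratios size factors (per-gene geometric
mean reference over all samples; genes with any zero excluded; the factor
is the literal median of count/reference ratios). Gene filters — summed
normalized counts ≥ 15 in the tag-positive IPs and ≥ 10 in germ RNA — are
group sums by default (a per-sample-minimum mode exists); the thresholds
are inclusive. TE is the specific-binding coefficient of a per-gene OLS of
log2(normalized count + 0.5) on [intercept, specific, nonspecific,
germ-specific]; the 0.5 pseudocount handles zeros and bounds the residual
effects of one-sample rescaling at O(pseudocount/count) (~1e-3), which is
why the scaling-invariance test uses that tolerance rather than machine
precision.

CAI uses relative adaptiveness w computed from the CDSs of the top 5% of
expressed genes; codons unseen in the reference fall back to add-0.5
smoothed family counts (flagged). Stop codons are excluded; single-codon
amino acids have w = 1.

Matched sampling bins targets into 50 quantile bins of the log2 matching
variable (abundance or CDS length) and samples nontargets without
replacement per bin, with replacement when a bin is short (flagged). A bin
with no nontargets at all raises by default; the pipeline enables a
nearest-value fallback because at a 200-gene scale the top abundance bin of
the targets routinely exceeds the entire nontarget range. At desk scale the
pipeline also averages the matched median difference over 25 independent
matched draws: with only 40 targets, a single draw's median carries ~0.05
log2 units of sampling noise, and averaging removes the part attributable
to which nontargets happened to be drawn. The regression route fits
TE ~ log2(TPM) + log2(CDS) + log2(UTR3) + log2(CAI) + target by OLS
(condition-number guard at 1e8), reports the point-biserial correlation for
the binary flag and Spearman correlations for continuous covariates, and
compares nested models by the likelihood-ratio statistic n·ln(RSS_r/RSS_f)
against χ² with the parameter-count difference. Adjusted TE subtracts the
fitted covariate contributions but neither the intercept nor the target
term.

## Problem sizes and runtime choices

The default end-to-end fixture uses 200 genes, 100k reads per iCLIP sample,
and 3 replicates per arm; it runs in a few seconds. Transcriptome-scale TE
recovery experiments use 2,000 genes, where the median-difference and
regression estimators recover planted δ ∈ {0, 0.2, 0.4} within ±0.1 per
seed. Null-calibration checks run each inferential test ≥ 200 times on
small direct fixtures. These sizes were chosen so the full suite exercises
every stage, including resampling nulls, in well under typical CI budgets.

## Known limitations

- The peak caller is a re-specified Poisson model, not a reimplementation
  of any published caller; abundance scaling assumes background density
  proportional to TPM within a transcript.
- One isoform per gene in the simulator means isoform-selection logic is
  only exercised through its deterministic tie-breaks.
- The weighted logo z statistic is a pragmatic stand-in; its null
  calibration is verified by simulation rather than derived exactly under
  weighting.
- TE is reported in log2 enrichment units; converting an effect to
  "ribosomes per transcript" depends on an external calibration that is out
  of scope here.
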