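# Methods

Statistical models, default parameters, and the numerical and design
choices behind them. Module references are to `src/acrip/`.

## Peak calling (`peaks.py`)

The transcriptome is tiled into fixed windows (default 50 bp, contiguous on
the simulated chromosome). For each sample, window IP counts are tested
against a Poisson null whose rate is the input coverage scaled by the
library-size ratio:

    lambda_w = max(input_w * (lib_IP / lib_input), lambda_floor)
    p_w      = P(X >= ip_w | X ~ Poisson(lambda_w))  = poisson.sf(ip_w - 1, lambda_w)

- `lambda_floor = 0.5` keeps windows with zero input coverage testable
  without making them trivially significant.
- p-values are Benjamini–Hochberg adjusted **across all windows of the
  sample**; windows with q < `q_max` (0.05) are significant.
- Significant windows are merged into peaks if separated by at most
  `merge_gap` (1) non-significant windows; the peak interval spans the gap.
  Peaks need `min_windows` (2) significant windows. The summit is the
  window with the smallest p-value (ties: leftmost).
- `chrom_blacklist` (default `("chrM",)`) removes chromosomes where the
  Poisson input model is known to fail on real data.

The window test is exactly calibrated under Poisson sampling. Under
overdispersed (negative-binomial) counts it is anticonservative at the
window level — a property shared by Poisson window scans generally. False
discovery control of the *pipeline* therefore does not rest on the window
test alone but on the downstream chain (multi-window peaks, fold-enrichment
and IgG filters, replicate consensus); the acceptance recovery metric
measures the realized false peak-gene rate (≈ 0 at default settings).

## Peak filtering (`filters.py`)

Fold enrichment uses depth-normalized (CPM) coverage means over the peak:

    FE = (acRIP - IgG) / max(Input, input_floor)        input_floor = 0.5

Filter chain (order-independent; verified by permutation tests):

1. **Significance**: peak q < 0.05.
2. **Enrichment**: FE > 1.
3. **Exonic**: ≥ 50% of the peak must overlap the exon union of a
   protein-coding transcript; the host transcript is the one with maximal
   overlap (ties: smallest transcript id); the region label (5'UTR / CDS /
   3'UTR) is taken at the summit midpoint.
4. **IgG calibration**: drop a peak overlapping (≥ 1 bp) any IgG peak of
   the same sample — antibody-nonspecific pulldown.
5. **Consensus**: single-linkage clustering of the surviving peaks across
   replicates (≥ 1 bp overlap links two peaks); a cluster with peaks from
   ≥ 2 distinct replicates becomes a consensus peak spanning the union
   interval, with FE = mean of member FEs.
6. **RNA validation**: the host mRNA must be detected by RNA-seq
   (count > 1 in ≥ 2 replicates of the group).

## Quantification (`quantify.py`)

- Per-mRNA fold enrichment: **sum** of the mRNA's consensus-peak FEs.
- Per-mRNA fold change: `FC = (FE_case + 1) / (FE_control + 1)` — the
  pseudocount makes group-exclusive mRNAs (FE = 0 in one group) finite.
- RNA: TPM with gene length = union exon length of the longest transcript
  (ties: smallest transcript id).
- Protein: fraction-of-total (FOT × 1e6) per sample; missing stays missing
  (NaN encodes "not detected"; zero is a measurement).

## Differential calling (`differential.py`)

### Moderated t (protein overlay; ac4C overlay on log2(replicate FE + 1))

Smyth-style empirical-Bayes variance shrinkage. Per-feature residual
variances s² with d residual degrees of freedom get a scaled
inverse-chi-square prior (d0, s0²) estimated by moment matching on the log
scale:

    e_g   = log s_g² − digamma(d/2) + log(d/2)
    var(e) − trigamma(d/2)  >  0  ⇒  d0 = 2 · trigamma⁻¹(var(e) − trigamma(d/2))
                                     s0² = exp( mean(e) + digamma(d0/2) − log(d0/2) )
    otherwise (no excess variance) ⇒  d0 = ∞, s0² = exp(mean(e))

    s²_post = (d0 s0² + d s²) / (d0 + d)
    t       = lfc / sqrt(s²_post (1/n1 + 1/n2)),   df = d + d0

Notes:

- In the complete-shrinkage case (all s² equal to a constant c), the closed
  form gives s0² = c · exp(log(d/2) − digamma(d/2)) — slightly above c — not
  s0² = c; this is the correct moment-matching solution (the log of a
  chi-square variate has mean below the log of its mean) and matches the
  reference R implementation (limma `fitFDist`), against which the test
  suite cross-checks via Rscript.
- `trigamma_inverse` is a Newton iteration with asymptotic shortcuts
  (y < 1e-6 → 1/y, y > 1e7 → 1/√y); agreement with an independent bisection
  solver is therefore ~1e-6 relative on d0 itself, while per-feature
  statistics agree to 1e-10 and p-values to 1e-6 relative (tail functions
  amplify argument error by ≈ |t|).
- d0 = ∞ uses the normal reference distribution; d0 → 0 recovers the
  ordinary pooled t.
- Features with missing values or < 2 replicates per group are excluded
  from the overlay test — they belong to the exclusive-detection path.
- p-values are clipped to (0, 1] so BH (which requires p > 0) is defined.

### Exact count test (RNA)

Conditional on the total n = c1 + c2, c1 ~ Binomial(n, π0) under the null
with π0 = lib1/(lib1 + lib2); the two-sided p-value sums all outcomes no
more likely than the observed one (scipy `binomtest`, minimum-likelihood
rule). The test is discrete: its size is ≤ the nominal level but cannot
equal it for small totals.

### Verdicts (`call_de`)

Overlay features: significant (adjusted p < 0.05; RNA optionally raw p) and
FC ≥ 2 → up, FC ≤ 0.5 → down. Exclusive features: proteins detected in
only one group are called unconditionally (detection itself is the
evidence); exclusive ac4C mRNAs must still clear the FC cut (their
pseudocounted FC is computable from one group); RNA has no exclusive rule.

## Integration (`integrate.py`)

- **Cross-omics numbering**: the 3×3 (protein, ac4C) verdict grid is
  enumerated row-major over (up, ns, down) × (up, ns, down) with the third
  row reversed, fixing the two anchors group 1 = up/up and
  group 7 = down/down; "differential at both levels" = corner groups
  1 + 3 + 7 + 9.
- KS: scipy two-sample, asymptotic p. Yates χ²: hand-computed
  `max(|O−E|−0.5, 0)²/E` (clamped at zero; identical to scipy's corrected
  2×2 test). φ: (ad−bc)/√(row/col margins).
- PCA: drop features with any missing value, apply a variance floor, keep
  the top 50% by median absolute deviation (quantile rule `higher`, ties
  kept), center per feature, SVD on samples × features.
- FE distribution: least-squares Gaussian fit to the histogram of log10 FE
  (0.1-wide bins); reported area = amplitude · sd · √(2π).
- Stage specificity across timepoints t1, t2:
  `1 − (overlap_up + overlap_down) / (t1_up + t1_down)`, where overlap
  counts genes with the same non-ns verdict at both timepoints.

## Synthetic data generator (`simulate.py`)

One toy chromosome (`chrS`) carries non-overlapping genes aligned to the
window grid, each with UTR/CDS segmentation. Window counts are negative
binomial (`var = mu + phi mu²`, default `background_mean = 20`,
`nb_dispersion = 0.05`, so var/mean = 2); planted peaks multiply the acRIP
mean by `enrichment_effect` (8) inside CDS windows of `peak_fraction` (0.3)
of genes; IgG artifact runs cover `igg_peak_rate` (0.01) of windows in all
samples. RNA counts are NB around a shared per-gene mean (the disease model
shows minimal transcript-level change); proteins are log-normal with a
planted ±2 log2 fold change on `protein_de_fraction` (0.1) of genes and
disjoint group-exclusive detections. Per-gene RNG substreams
(`default_rng((seed, stage, index))`) make every output deterministic in
the seed.

Composition generators (`simulate_protein_composition`,
`simulate_ac4c_composition`, `verdict_composition`) plant an *exact*
detection/effect composition (counts of overlay up/down/ns and per-group
exclusives) so that classification arithmetic can be checked against known
totals independently of sampling noise.

### Realism and limits

- The NB window model reproduces the mean–variance relationship of count
  data but not positional autocorrelation, GC/mappability bias, or
  fragment-level effects; enrichment is a flat multiplier over the planted
  peak, so peak shapes are rectangular.
- Peak planting and IgG placement draw from global streams: changing
  `n_genes` re-randomizes the whole layout (outputs are deterministic in
  the seed, not extension-stable).
- FOT normalization is compositional: with very few proteins a single
  strongly changed, highly abundant protein can carry a large share of a
  sample's total and shift every other protein's apparent abundance
  (≈ 0.7 log2 observed at 150 genes in an adverse seed). At realistic
  feature counts the max share is small and the artifact vanishes; the
  acceptance recovery runs use 400 genes for this reason, and the effect
  is worth remembering when interpreting real small-panel FOT data.
- The simulated IgG track is genuinely enriched at its artifact windows in
  every sample, which is what the IgG calibration filter assumes; planted
  ac4C peaks that happen to overlap an IgG run are removed by that filter
  by design (and excluded from recovery oracles accordingly).

## Pipeline defaults (`pipeline.py`)

| Parameter | Default | Rationale |
|---|---|---|
| `q_max` | 0.05 | window/peak FDR level |
| `fe_min` | 1.0 | enrichment must exceed input |
| `min_windows` | 2 | one significant window is not a peak |
| `merge_gap` | 1 | bridge single noisy windows |
| `lambda_floor`, `input_floor` | 0.5 | zero-coverage guards |
| `exon_overlap_frac` | 0.5 | majority-exonic rule |
| `consensus_min` | 2 | reproducibility in ≥ 2 replicates |
| `alpha`, `fc_cut` | 0.05, 2.0 | verdict thresholds |
| `chrom_blacklist` | `("chrM",)` | mitochondrial coverage artifacts |

Stage outputs are plain text (TSV/BED/GTF/JSON/YAML, floats at 6 decimals)
and every stage can be re-run from the files of the previous one. Group
order is taken from the configuration, never inferred from on-disk column
order (TSV columns are stored sorted).
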