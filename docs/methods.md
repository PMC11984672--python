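# Methods

## Reference-anchored BioAge

Each omic layer is first put on a scale where distances are meaningful:
centered log-ratio with a half-minimum pseudocount for microbiome relative
abundances, M-values (log2 β/(1−β)) for methylation, total-sum scaling to
the cohort median depth followed by log2(x+1) for mRNA counts, natural log
for metabolites and hormones, and the raw scale for the nine blood
biomarkers. These are the conventional variance-stabilizing choices per
data family; the method itself is agnostic to them.

The reference model is the per-feature mean μ and SD σ over the young
reference (yWD) samples; zero-variance features are dropped and recorded.
A sample's raw distance is D = sqrt((x−μ)ᵀΣ⁻¹(x−μ)) and its BioAge score
is D/√p. Two covariance modes:

* **diagonal** (default): Σ = diag(σ²), i.e. standardized Euclidean
  distance. With six reference samples the sample covariance has rank ≤ 5,
  so this is the only mode defined at every layer size.
* **shrinkage**: Σλ = (1−λ)·S + λ·diag(S), Cholesky-verified positive
  definite; intended for the low-dimensional layers (hormones, pheno).
  λ = 0 recovers the full Mahalanobis form (affine-invariant when
  p ≤ n_ref − 1), λ = 1 recovers the diagonal mode.

D/√p was chosen over cohort z-scoring because it preserves the anchor
"0 = identical to the young reference mean" while still making layers of
different dimensionality comparable: under the reference distribution
E[D²] = p, so reference-like samples score near 1 in every layer.
Missing values are a hard error by default; an explicit flag enables
reference-median imputation, since silent imputation shrinks distances.

Group comparisons are two-tailed pairwise t-tests with pooled within-group
MSE and Tukey–Kramer (studentized range, unequal-n) adjustment at α = 0.05;
degenerate all-equal groups return p = 1. The summary-statistic ANOVA
(SSB from n-weighted means, MSW from pooled (n−1)·sd²) is exact: it equals
the raw-data ANOVA whenever the summaries come from the data.

Sensitivity biomarkers: a generic linear-clock applier (coefficients are
user-supplied two-column TSVs; a ridge fitter exists for synthetic
round-trips), age acceleration as OLS residuals of predicted on
chronological age, and the epigenetic mutation load (EML): per CpG,
reference bounds Q1 − k·IQR and Q3 + k·IQR (k = 3), a sample's load is the
count of CpGs strictly outside, zero-IQR CpGs excluded and reported, and
EML_AA the residual of log1p(load) on age. Without an explicit reference,
every sample is scored against all others (leave-one-out) to avoid
self-inflation at small n.

## Multi-block sparse PLS-DA

Blocks are the transformed, column-standardized layer matrices for the two
contrast groups; the outcome is a standardized class-indicator block. The
design matrix connects every block to the outcome with weight 1 and blocks
to each other with weight 0.1 ("sparse connection" default), configurable.
Per component, each block's loading starts at the leading singular
direction of X_bᵀY and is iterated:

a_b ∝ soft_threshold_topk( X_bᵀ Σ_k d[b,k]·t̂_k , keepX_b ),

where t̂_k are the **unit-normalized** score vectors of the other blocks
and the outcome, and soft_threshold_topk keeps the keepX largest-magnitude
entries, soft-thresholds them by the (keepX+1)-th magnitude, and
renormalizes (boundary ties go to the lower index). Blocks are deflated by
their own scores; convergence is max loading change < 1e-6 within 100
iterations, with non-convergence recorded rather than fatal.

The score normalization inside the design-weighted sum is a deliberate
numerical choice: at n ≈ 24, the leading spurious eigenvalue of a
p = 2000 block's sample covariance is large (order p/n), so unnormalized
scores from high-dimensional blocks can be ~8× longer than the outcome
score and the nominal 0.1 block-block weights would dominate the weight-1
outcome link, pulling the consensus component off the class contrast
(observed as a drop in selection precision from 0.84 to 0.35 on one seed).
Normalizing makes the design weights mean what they say; the single-block
fixed point (leading singular pair of XᵀY) is unchanged.

Defaults: one component for two-class problems; prediction assigns each
block's nearest class centroid in score space and takes a majority vote
across blocks, ties broken by smallest summed centroid distance. keepX is
tuned on a sparse-to-dense ladder ({5,10,15,25,50,100} clipped per block;
2..p for blocks with p ≤ 15) by stratified 5-fold CV; standardization is
re-fit inside each training fold; 100 repeats by default (20 in tests and
analysis drivers to keep runtimes in seconds). Ties on mean BER go to the
smallest total keepX. On pure-noise data the CV-mean BER for one fixed
dataset has spread ~0.05–0.09 around its theoretical 0.5, so null
calibration checks average several datasets.

Signatures are the union of nonzero-loading features per block, tagged
with the sign of the intervention-minus-control mean difference on the
preprocessed scale. Overlap between two signatures is tested per layer
(hypergeometric upper tail), combined across layers by Edgington, and on
the pooled universe (sizes summed across layers, one test). The three
variants answer different questions: the per-layer + Edgington route is
conservative and dominated by small layers, whose overlaps are nearly
saturated by chance; the pooled test weighs each feature equally and is
the sensitive summary when most features live in the large layers.

## Enrichment

`hypergeom_upper_tail` computes P(X ≥ k) by logsumexp over log-gamma
binomial terms, exact and overflow-free at N ~ 3.5e5. Edgington's combined
p is the Irwin–Hall CDF of the p-value sum, clamped to [0,1]; FDR is
Benjamini–Hochberg.

Methylation enrichment uses a CpG-resampling test: selected CpGs map to a
selected gene set (a gene counts once however many of its CpGs are
selected); the null redraws the same number of CpGs uniformly from the CpG
universe and maps them identically, which reproduces the CpG-per-gene and
multi-annotation biases by construction. Empirical p-values use the
add-one convention (1+b)/(1+B), so they are valid and never zero. With a
uniform CpG-per-gene map this reduces to the plain gene-level
hypergeometric (tested); with CpG-dense pathways the naive hypergeometric
is demonstrably anti-conservative while the resampling test stays
calibrated.

The multi-layer analysis runs per-layer overrepresentation (microbiome
OTUs map directly to pathways; metabolites and genes through their own
namespaces), skips pathways with no annotated feature in a layer rather
than assigning p = 1 (which would dilute Edgington with uninformative
values), combines available layers by Edgington, and applies BH across
pathways at q < 0.05.

The targeted (inflammatory) test partitions each layer's gene universe by
the candidate pathways plus "other" (first-come assignment for genes in
several pathways) and draws B multivariate-hypergeometric null selections
of the observed selection size. Per pathway and layer, the empirical p is
the add-one tail of the observed count in the null counts; layers combine
by Edgington. Family-wise correction reuses the same draws: each draw is
converted to its own per-pathway combined p, the minimum over pathways
forms the null of the best combined p (the min-p Westfall–Young
construction), and the corrected p is the add-one tail of the observed
combined p in that null, floored at the uncorrected value for step-down
monotonicity. Min-p was preferred over a raw max-count statistic because
pathway sizes differ by an order of magnitude, making raw counts
incomparable across pathways; BH q-values are reported alongside.
Permutation p-values are discrete; calibration is assessed on the
attainable grid (randomized PIT in the tests).

## Synthetic cohort generator

The generator emulates the study design, not any particular dataset:

* **Groups and covariates.** Default sizes 41/41/35/6 (full study) or
  12/11/12/6 (multi-omic subset). Adult ages are *matched* across CR, EX
  and WD — EX and WD ages are jittered (SD 2 y) copies of the CR draws,
  clipped to each group's observed range — because the study recruited
  age- and sex-matched groups; independent draws would create group
  mean-age differences with no real-world counterpart. Sex is Bernoulli
  with the observed per-group male fractions; BMI and body fat are
  truncated normals with the observed group means, SDs and ranges.
* **Layers.** Six layers with family-appropriate observation models on a
  shared latent Gaussian scale: compositional lognormal (closed to sum 1;
  optional multinomial counts at configurable depth), logit-normal betas,
  Poisson-lognormal counts (latent log-mean 4.0, reflecting post-QC
  expression-filtered genes), lognormal intensities, and Gaussian blood
  biomarkers. Test-scale feature counts 200/2000/1000/108/14/9; full-scale
  counts available via config.
* **Age structure.** Each sample has a latent biological age =
  chronological age + N(0, 3 y) offset. A fraction of features per layer
  (0.3 by default; 1.0 for the pheno biomarkers, which are age-associated
  by construction; 0.7 for hormones; 0.15 for methylation, whose
  responsive fraction is proportionally sparser at array scale) drifts
  linearly with biological age at 0.045 latent-SD per year — a 60-year-old
  sits ~1.6 SD from the young mean on drifting features, the strong end of
  cross-sectional age associations.
* **Intervention effects.** Effect features are drawn from the aging pool
  and shifted *against* the drift by `effect_size` (default 1.0 SD) in the
  treated group only — interventions partially restore youthful levels,
  which is exactly the signal the BioAge analysis is designed to detect.
  Planting effects on drift-free features would push treated samples away
  from the young reference, inverting the intended phenotype. The CR and
  EX sets share round(overlap_fraction × n) features (default 0.3); the
  default footprint is half of each layer's aging features. All effects
  are planted on the latent scale, so `effect_size` is a standardized mean
  difference after the downstream transforms.
* **Annotations.** Pathways are gene sets (shared by mRNA and, via a
  right-skewed CpG→gene map with ~10% multi-gene CpGs, methylation) plus
  metabolite sets and an OTU→pathway map. Planted-enriched pathways draw
  90% of their members from effect features, split evenly between
  mRNA-effect genes and CpG-derived effect genes so every layer reading
  the pathway sees signal; unplanted pathways sample the whole universe,
  so effect features appear at base rate.

What the generator does **not** emulate: read-level sequencing noise,
batch effects beyond an optional scalar offset, real pathway topology or
KEGG content, correlated feature modules within layers, and non-linear age
trajectories. Passing recovery tests therefore show the pipeline detects
the *kind* of structure it assumes at the study's sample sizes — not that
the original data contain that structure.

## Problem sizes and numerical choices

Tests and analysis drivers run the subset design (n = 41 total) at
test-scale feature counts, 20 CV repeats, and 2,000–10,000 permutations;
these keep the full suite in a few minutes while leaving every code path
identical to full-scale runs. Degenerate inputs are handled explicitly:
zero-variance features are dropped and logged, all-equal group comparisons
return p = 1, empty selections return all-null enrichment, a zero vector
cannot be soft-thresholded (error), non-convergent fits return a
diagnostic flag, and empirical p-values are floored at 1/(B+1).

## Known limitations

* With 6 reference samples, per-feature reference SDs are χ²₅-noisy; the
  small layers' BioAge scores (9–14 features) are volatile at n = 12 per
  group, so cohort-level ordering claims there are best made on the
  composite (mean of the six standardized scores).
* The Edgington combination is conservative when a pathway is genuinely
  enriched in only a subset of layers; this is a property of the method,
  preferred here for type-I control at small n.
* The CV tie rule (smallest keepX among BER ties) favors minimal
  signatures; analyses that feed enrichment may prefer the one-SE rule in
  the liberal direction, as the signature driver does.
* CR-vs-EX discrimination quality depends directly on the generator's
  overlap_fraction; it is reported, not asserted.
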