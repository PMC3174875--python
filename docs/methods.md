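# Methods

## Design and data flow

The pipeline analyses paired two-color hybridizations: each array carries
one subject's pre-infusion (T = 0) and post-infusion (T = 1 h or 4 h)
monocyte cDNA in opposite channels, so the per-spot quantity of interest is
the oriented log-ratio M = log₂(net_post / net_pre) with net intensity =
foreground median − background median. Channel roles are defined by the
`dye_of_post_sample` metadata field, never by column order, and cells with
a non-positive net intensity in either channel are marked invalid rather
than clipped. The LPS and saline arms are analysed separately throughout.

Stages: sample gate → spot QC → ratio matrix → normalization → gene-level
inclusion → mixed-model fit → empirical-Bayes moderation → call gates →
overlap/candidate analysis → ΔΔCt validation. Each stage writes its output
before the next begins, and a failed stage leaves a `FAILED` marker with
partial outputs retained.

## Quality control

*Sample gate.* Samples require FACS purity strictly greater than
`min_purity` (default 80 %). `select_top_samples` ranks gated subjects by
their minimum purity across timepoints (a paired hybridization needs both
samples clean) and breaks ties lexicographically by subject ID, so the
selection is deterministic.

*Spot criteria.* Five per-spot predicates: unflagged;
|median − mean| / median < 0.1; saturation < 20 %; mean/SD > 2; and
percentages of feature pixels above background + 1 SD (> 90 %) and + 2 SD
(> 80 %). All thresholds are strict — a spot exactly at a boundary fails —
and criteria (ii)–(v) are evaluated on **both** channels with the spot
failing if either channel fails, since a ratio needs two trustworthy
channels. A zero foreground median trips the median–mean criterion through
a divide-by-zero sentinel instead of crashing. Every excluded spot records
the full set of criteria it failed, and per-array pass fractions are
reported.

*Gene-level inclusion.* After normalization, a gene needs valid cells on at
least 50 % of arrays, and the larger of its up/down fractions among valid
arrays must reach 50 % (ties at exactly 50 % are retained; M = 0 counts in
neither direction). Denominators use valid arrays only, so missingness from
spot QC does not silently count as "not regulated". With continuous data
and no invalid cells the direction rule is almost always met; it bites when
QC has thinned a gene's measurements.

## Normalization

Default is per-array median-centering of M — the conservative choice for a
ratio design with a small spot complement. A loess alternative
(M ~ A with span 0.4, via statsmodels lowess) removes intensity-dependent
trends and is exercised in tests against a generator-injected linear trend.
No between-array normalization is applied; the mixed model's array effect
absorbs array-level shifts that centering leaves behind.

## The per-gene model

M_gar = μ_g + u_a + ε_gar with u_a ~ N(0, τ²) and ε ~ N(0, σ²) is the
minimal mixed structure consistent with duplicate spots nested in arrays.
Two estimation paths:

* **Default (duplicates averaged).** Per-array means reduce inference on
  μ_g to a one-sample problem with variance σ_B² = τ² + σ²/r; μ̂ is the
  mean of per-array means, se = s_B/√a, df = a − 1. This path is fully
  vectorized over genes.
* **Replicate-level.** With spot replicates retained, balanced designs use
  the closed-form ANOVA estimators (identical to REML for the balanced
  one-way random-effects model; se² = MSB/(a·r), df = a − 1); unbalanced
  designs maximize the REML likelihood profiled to the single ratio
  λ = τ²/σ². Both agree with statsmodels MixedLM in the test suite.

Genes with fewer than 3 valid arrays are marked untestable and excluded
from moderation. Variance components are constrained non-negative.

## Moderation, posterior probability, FDR

The gene-wise variances s_B² (df d) are shrunk toward an ensemble scale s₀²
via a scaled inverse-χ² prior with fixed prior degrees of freedom d₀
(`prior_df`, default 4): s̃² = (d₀·s₀² + d·s²)/(d₀ + d). s₀² is estimated
from the ensemble by the log-moment identity
E[log s²] = log σ² + ψ(d/2) − log(d/2), mapped onto the prior df. The
moderated t = μ̂/(s̃·u) is referred to a t distribution on d + d₀ degrees
of freedom (u is the unscaled standard deviation, 1/√a in the default
path). The moderated standard error is floored at 10⁻⁶ log₂ units so
degenerate zero-variance genes yield finite statistics.

The posterior probability of differential expression is the logistic
transform of the B-statistic log-odds under a two-component prior: a point
mass at μ = 0 with weight 1 − p and a N(0, v₀σ²) slab with weight p
(`pi0_de`, default 0.01); v₀ is estimated by moment-matching the top
p-quantile of |t| against its null quantiles (the tmixture construction),
truncated at zero when the extremes carry no excess signal. Under a pure
null this collapses the posterior to ≈ p, so the 0.95 posterior gate is
conservative there by construction.

Benjamini–Hochberg q-values are computed by the step-up rule; the
implementation is property-tested against a brute-force evaluation of the
defining minimum and cross-checked against statsmodels.

A gene is called DE when q < 0.005, posterior > 0.95, FC > 2 or < 0.5, and
the ≥2-fold change appears in ≥ 70 % of its valid arrays in the called
direction. Down-regulation is represented as FC < 1, and the fold gate is
symmetric on the ratio scale.

## Overlap and candidates

Overlaps are exact set intersections keyed on Ensembl IDs (HUGO symbols are
display-only); mixing namespaces raises an error. The packaged published
tables list 11 (1 h) and 28 (4 h) genes — 39 entries, 38 distinct IDs
because one gene appears at both timepoints; both counts are reported,
labelled. The in-vitro comparison list is consumed as a one-column gene-ID
file; the packaged default is a synthetic stub (six established candidate
genes plus decoy IDs) so a real list plugs in identically.

## ΔΔCt validation

ΔCt = Ct_target − Ct_reference per sample; ΔΔCt = ΔCt_post − ΔCt_pre per
subject; fold change = 2^(−mean ΔΔCt), i.e. the geometric mean of
per-subject fold changes with amplification efficiency assumed exactly 2
(no standard-curve correction). Unpaired subjects are excluded with a
warning. The construction is antisymmetric under pre/post label swap and
invariant to per-subject plate shifts; concordance with the array calls is
summarized as direction agreement ("k of n"), with genes present on only
one side listed as untested and excluded from n.

## The synthetic generator

The generator emulates the study conditions: 5 subjects × duplicate
hybridizations = 10 LPS arrays plus 4 saline-control arrays for the 4-hour
contrast, 2 duplicate spots per gene, spiked DE genes (default 5 %) with
|log₂ FC| uniform over the published fold-change range 2.0–5.9 and 10 %
of spiked genes down-regulated (matching the published 4-of-39 proportion),
between-array effect τ = 0.2, spot noise σ = 0.3, per-array dye bias
SD 0.1 (all log₂ units). Control arrays are generated with all true fold
changes at zero. Per-gene average log-intensities A are uniform on
[8, 14]; channel foreground medians are background + 2^(A ± M/2), which
makes background subtraction exact by construction and gives realistic MA
structure for the loess path. Pixel-summary statistics are drawn so clean
spots pass every QC criterion with margin, while independent Bernoulli
fractions of spots violate each criterion individually (defaults: 5 %
flagged, 2 % each for saturation, SNR, median–mean and background
exceedance), so each QC rule is exercised separately and the expected pass
fraction is the product of survival probabilities (~88 %).

The real arrays of this study type pass far fewer spots (~19–26 %), because
whole-array content — control and empty features, weak probes — dominates
attrition there; the generator only lays down genuine gene probes, so its
defaults model per-probe failure, not platform-level attrition. Passing
recovery tests therefore demonstrates the pipeline's statistical behaviour,
not robustness to 80 % missingness. Other simplifications: purity is a
scalar metadata draw (85–99 %, so the default design survives the gate);
no cell-type contamination transcripts; no dye-swap pairs by default (an
optional flag enables them); noise is Gaussian in log space.

qPCR tables are generated with exact reference-gene wells and Gaussian
noise on target wells only, so the per-subject ΔΔCt noise SD is
√2·ct_noise_sd and E[ΔΔCt] = −true log₂ FC exactly.

All randomness flows from one integer seed through named substreams
(truth, intensities, per-arm arrays, metadata, qPCR); identical config and
seed reproduce every emitted file byte for byte.

## Numerical and scale choices

* Duplicate spots are averaged before the model by default (config-exposed
  via the replicate-level path) — with 2 spots per gene the information
  loss is negligible and the vectorized path keeps a full 2000-gene
  replicate under a second.
* The null-control experiment uses 100 replicates (2000 genes × 10 arrays)
  and the spike-recovery experiment 50 replicates — sizes chosen so the
  binomial error on the reported rates is a few percent while the whole
  suite runs in well under a minute.
* Empirical-Bayes moderation requires ≥ 20 testable genes; below that the
  ensemble scale is not estimable and the fit refuses with an explicit
  override.
* BH ties share a q-value; ranks use a stable sort.
* Monotonicity guarantees (relaxing any QC threshold never shrinks the
  passing set; loosening any call gate never drops a called gene) are
  enforced by property tests.

## Known limitations

* The mixed model assumes a common τ across genes only implicitly (each
  gene is fit marginally); no information is shared across genes about τ.
* The posterior probability depends on `pi0_de` and the v₀ estimate; with
  very few DE genes v₀ is noisy, which mainly affects genes near the 0.95
  gate.
* The loess span (0.4) is fixed by config, not cross-validated.
* Real scanner exports carry an ATF preamble and many more columns; only
  the documented down-converted dialect is parsed.
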