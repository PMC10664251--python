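# Methods

## Model and assumptions

Two-sample Mendelian randomization treats genetic variants as instruments
for an exposure X measured in one GWAS, with outcome associations taken
from a second, non-overlapping GWAS. For instrument j with exposure
association γ_j (estimated β̂_xj, SE σ_xj) and outcome association
Γ_j (β̂_yj, σ_yj), the structural model is

    Γ_j = θ·γ_j + α_j,

where θ is the causal effect of interest and α_j the horizontal-pleiotropy
(direct) effect of variant j on the outcome. The estimators differ in what
they assume about α:

- **IVW** assumes α_j = 0 for all j. It is the weighted through-origin
  regression of β̂_y on β̂_x with weights 1/σ_y², equivalently the
  1/Var-weighted mean of the Wald ratios β̂_yj/β̂_xj.
- **MR-Egger** allows a common directional component: under InSIDE
  (instrument strength independent of direct effects), the weighted
  regression with a free intercept estimates θ as the slope and the mean
  pleiotropic effect as the intercept. Rows are re-signed so β̂_x ≥ 0
  before fitting — the intercept is meaningless otherwise.
- **Weighted median** is consistent when instruments carrying > 50% of the
  inverse-variance weight are valid. The estimate is the 50% point of the
  cumulative, midpoint-adjusted weight over the ordered ratios, linearly
  interpolated.
- **Mode estimators** (simple = unit weights, weighted = inverse-variance
  weights) take the argmax of a Gaussian-kernel density of the ratios;
  consistent when the largest group of instruments shares the true ratio
  (zero modal pleiotropy).

## Inference conventions

- IVW fixed effects force the residual variance to 1 (SE = 1/√Σw·β̂_x²);
  random effects multiply by √max(1, Q/(k−1)). `effects="auto"` — used by
  the pipeline — picks random effects when Cochran's Q has p < 0.05.
  Wald/IVW p-values are normal.
- Egger (univariable and multivariable) uses a t distribution with k−2
  (resp. k−m−1) degrees of freedom and a multiplicative random-effects
  scale floored at 1. The floor means a perfect fit still reports a
  positive SE; exact-data tests assert the point estimates exactly and the
  SE's positivity.
- Wald-ratio SEs are first-order delta method σ_y/|β̂_x| by default; the
  second-order form √(σ_y²/β̂_x² + β̂_y²σ_x²/β̂_x⁴) is available by flag.
- Weighted-median and mode SEs come from a parametric bootstrap (β̂_x,
  β̂_y redrawn from normals at their estimates/SEs; default 1000
  resamples, seeded). `n_boot=0` returns the point estimate alone — used
  by the replicate studies, which need only means.
- Mode bandwidth: `bandwidth_factor` × 0.9·min(SD, 1.4826·MAD)·k^(−1/5)
  (modified Silverman). All ratios identical → the common value is
  returned directly. Density argmax is evaluated on a 512-point grid over
  the ratio range padded by 3 bandwidths.
- Monte-Carlo p-values (MR-PRESSO global and per-SNP) use the add-one
  convention (count+1)/(n_sim+1): never exactly zero, and below 1/n_sim
  when no simulated statistic exceeds the observed one.

## MR-PRESSO

The global test predicts each SNP's outcome effect from the IVW slope
fitted without it, forms the weighted residual sum of squares, and compares
it against `n_sim` parametric simulations of the outcome effects under the
no-pleiotropy model (normal draws at the leave-one-out predictions with the
observed SEs; the leave-one-out machinery is re-run on every simulated
panel). The per-SNP outlier test does the same comparison on each SNP's own
squared distance, Bonferroni-corrected across SNPs at `outlier_sig`
(default 0.05). When outliers are found the IVW is refitted without them
and a distortion test compares the observed estimate shift against the
shifts from removing random same-size subsets of the inliers (enumerated
exhaustively when few, sampled otherwise). The computation sorts rows by
SNP id first, so the result is invariant to input row order and
bit-reproducible given the seed. Fewer than 4 instruments yields a
not-estimable marker rather than an error.

A note on the outlier-corrected estimate: removing one outlier of offset
c·σ changes the IVW estimate by ≈ c·z_j/Σz² while the estimate's sampling
SD is 1/√Σz², so the benefit-to-noise ratio is ≈ c/√k, independent of
instrument strength. At the 10-SE offset used in the power studies the
corrected estimate beats the uncorrected one nearly always for panels of
≤ ~9 instruments (measured ≥ 95% at k = 8) but only ~90% of the time at
k = 13. Detection of the outlier itself is essentially certain at either
size.

## Leave-one-out flagging

Each SNP's removal re-estimates IVW (auto effects). A removal is flagged
when the sub-estimate flips sign or leaves the full-table *fixed-effects*
CI. The fixed-effects interval is deliberately the reference: a single
driving SNP inflates Q and hence the random-effects interval enough to
hide its own influence.

## Harmonization

Outcome alleles are matched to the exposure's effect/other alleles
directly, after swapping (flip the β sign, EAF → 1−EAF), or after a strand
flip (A↔T, C↔G); unresolvable pairs drop with reason `allele_mismatch`,
SNPs absent from the outcome with `not_in_outcome`. Palindromic variants
(A/T, C/G) cannot be strand-resolved from alleles: the default policy
drops them when the minor-allele frequency exceeds 0.42 in either study
(or when a frequency is missing) and otherwise orients them so the
frequencies agree. Harmonization is idempotent and is invariant to
relabelling the outcome's effect allele.

## Multivariable MR and conditional F

The joint model regresses outcome effects on the (k × m) matrix of
exposure effects without intercept (random-effect IVW; scale
max(1, Q/(k−m))) or with one (Egger, rows oriented to the first exposure).
Rank-deficient designs raise an error naming the involved exposures.

No closed-form conditional F is universally agreed for summary-data MVMR;
this package residualizes each exposure's instrument effects on the other
exposures' effects (weighted least squares, weights 1/σ_y²) and scales the
residual signal by the exposure's own measurement error:

    F_cond(i) = Σ_j r_ij²/σ_x,ij² / (k − m + 1).

A duplicated exposure gives F ≈ 0; an exposure orthogonal to the others
recovers its mean per-SNP univariable chi-square (≈ its univariable F);
an exposure whose effects are small against their SEs falls below the
conventional adequacy cutoff of 10. The statistic is an approximation in
the Sanderson–Windmeijer spirit, and is labelled as such in output
metadata.

## Screening pipeline

Per exposure–outcome pair: select instruments (two-stage threshold 5×10⁻⁸
relaxed to 5×10⁻⁶ when < 3 survive clumping) → harmonize → Steiger filter →
five estimators → sensitivity suite. When MR-PRESSO flags outliers the
headline estimates are refit without them; the uncorrected batch is kept
in the sensitivity bundle. Failures are isolated per pair
(`not_estimable` with a reason; e.g. taxa with no extractable
instruments), and the per-level Bonferroni denominators are the counts of
taxa actually estimable in the run, so thresholds adapt to how many taxa
survive rather than being hard-coded. Per-pair seeds derive
deterministically from the config seed and the taxon name (CRC32, kept
below 2³¹), making batch output byte-identical across runs.

## Synthetic generator

`generate_pair` draws per-SNP minor-allele frequencies uniformly on the
configured range, sets SE_j = 1/√(2·maf_j(1−maf_j)·N) per trait
(standardized-trait algebra, so generated records satisfy
R² = β²/(β² + N·SE²) exactly in expectation), plants `n_strong` instrument
effects with |z| ~ Uniform(strong_z_range) — one per LD block, so clumping
keeps them — and fills the rest with small Normal(0, 0.004²) effects.
Outcome effects follow Γ = θγ + α with α per pleiotropy mode (none /
balanced / directional). With `reverse_theta` set, the direct effects act
on the outcome and propagate back, flipping the per-SNP variance-explained
ordering that Steiger filtering tests. `generate_taxa_panel` builds the
211-taxon hierarchy (9/16/20/35/131 per level) over a shared SNP map, with
per-taxon instrument counts uniform on 3–13 and a configurable few causal
taxa. Sample-size defaults are the real studies' 38,602 (exposure trait)
and 18,340 (microbiome panel).

Default `strong_z_range = (6, 9)` puts selected-instrument F statistics
(≈ z²) in the tens — the band where the F > 10 filter and the two-stage
p-value protocol are actually exercised. The estimator *calibration*
studies instead use |z| ~ Uniform(45, 80) ("large n"): ratio estimators
carry a regression-dilution bias of roughly −θ·E[σ_x²/γ²] from exposure
measurement error, and the strong regime keeps that bias (~1×10⁻⁴ at
θ = 0.5) an order of magnitude below the Monte-Carlo resolution of
200-replicate studies, so recovery tests measure the estimators rather
than the generator's noise regime. Study sizes (200 recovery replicates,
1000 type-I replicates, 100 MR-PRESSO replicates at n_sim = 1000) keep the
whole validation suite to a few CPU-seconds.

What the generator does *not* emulate: realistic genome-wide LD (blocks
are rectangular with a single within-block r²), sample overlap between the
two GWAS, winner's-curse inflation from discovery-based selection beyond
what the planted-z design induces, allele-frequency differences between
studies, and microbiome count-data noise (only GWAS-level summary
statistics of abundance traits are modelled). Passing tests therefore
demonstrate the correctness and calibration of the statistical machinery
under its stated assumptions, not robustness to those real-data
complications.

## Degenerate inputs and tie-breaks

Clumping breaks p-value ties by chromosome, position, then SNP id; pairs
absent from the LD reference count as r² = 0; a SNP missing from the
position map is a hard error. All-zero exposure effects raise a degenerate
design error in IVW; a single instrument makes IVW the Wald ratio and
marks the other methods not-estimable. Empty harmonization intersections
warn and return an empty table rather than raising, so batch screens
continue. Steiger rows lacking EAF or N pass through with verdict
"untestable" and a warning.

## Known limitations

- The weighted-median/mode bootstrap treats instruments as independent
  (true post-clumping by construction here, approximate on real data).
- MR-Egger inference ignores the I²_GX weak-instrument correction
  (SIMEX); with the F > 10 filter upstream this is second-order.
- The conditional-F convention above is one of several in use; values
  should be compared against a threshold (10), not across software.
- Bonferroni per level ignores correlation between taxa (phylogenetic
  nesting), so the screen is conservative for deeply nested panels.
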