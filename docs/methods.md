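# Methods

## The model

A folded cortical sheet of finite thickness that balances mechanical
forces while remaining self-avoiding obeys, across species, individuals
and lobes, the scaling law `At·√T = k·Ae^(5/4)`.  foldmorph works in the
log-area space `p = (log₁₀At, log₁₀Ae, log₁₀T²)` where the law is the
plane `p·κ = log k` with normal `κ = (1, −5/4, 1/4)`.  Completing κ with
the isometric direction `ι = (1, 1, 1)` and the shape direction
`σ = (3/2, 3/4, −9/4)` gives an orthogonal (not orthonormal) basis; the
projections `K = p·κ`, `I = p·ι`, `S = p·σ` are the package's central
quantities.  Exact rational identities — `κ·ι = κ·σ = ι·σ = 0`,
`Σκᵢ = Σσᵢ = 0`, `|κ|² = 21/8`, `|ι|² = 3`, `|σ|² = 63/8` — are asserted
in `Fraction` arithmetic in the test suite, and the inverse projection
divides by the squared lengths, so `p ↔ (K, I, S)` is an exact bijection
(round-trip error below 1e−12 over the plausible domain).

Two sign/orientation conventions were genuinely open and are fixed as
follows.  σ is the *negative* of the right-handed cross product κ×ι;
this orientation makes S increase with folding amplitude, matching how
the shape term is usually discussed, and only flips the sign of S.
Logarithms are base 10 throughout; switching to natural logs multiplies
all three components by the same constant ln 10, and every downstream
z-score and effect size is invariant to that choice (asserted by test).
A normalized-basis option divides each direction by its length; it
rescales components by constants and likewise leaves all z-scored output
unchanged.

## Scaling-law fit

`fit_scaling_law` regresses `y = log₁₀At + ¼·log₁₀T²` on `log₁₀Ae` by
OLS (statsmodels); the slope is the exponent α, the intercept log k, and
the 95% CI is the two-sided t interval with n−2 degrees of freedom.
Hemispheres are treated as independent observations.  OLS in this
parameterisation is the default because published slope CIs for this law
are regression CIs; a total-least-squares option (orthogonal regression
via SVD in the (x, y) plane) exists for users who object to attributing
all noise to y, but its interval is only the OLS width recentered and is
labelled as a rough guide.  Noise-free on-plane input recovers
α = 1.25 to 1e−10 regardless of the in-plane point spread.  The implied
self-similar surface dimension is 2α (5/2 at the theoretical exponent;
2 in the smooth limit α = 1).

## Covariate correction

`fit_linear_correction` fits `v = β₀ + β_age·age + β_sex·sex` per log
variable on the reference cohort only (no interaction term) and
`apply_correction` subtracts the *full* fitted value — intercept
included — from every cohort.  Full residualization is deliberate: it
places the corrected reference exactly at the origin of log space
(mean K = I = S = 0, i.e. controls align on the plane K = 0), and since
all group statistics are z-scores the absolute level carries no
information anyway.  Sex is dummy-coded 0/1 from the sorted input
labels (the residuals are identical under effect coding; only the
printed coefficients differ).  A covariate that is constant in the
reference is unidentifiable; its β is set to 0 with a warning rather
than failing, degrading gracefully to an intercept-only model.  For
narrow age bands `sex_mean_center` is provided instead: each log
variable is centered to zero within each sex, with no age term.
Because the projections are linear, correcting logs then projecting
equals projecting then correcting components with projected
coefficients; the test suite asserts this commutation at 1e−12.

## Group comparison

Pipeline order is fixed and logged in provenance: hemisphere selection →
covariate correction → projection → z-score → bootstrap.  Every measure
is z-scored against the mean and n−1 SD of the reference cohort
(reference rows against their own statistics).  Cohort means are
bootstrapped with 100 with-replacement resamples by default — enough to
stabilise a mean estimate against outliers, and kept configurable — and
the effect size `d` is the difference of average bootstrapped means,
positive when the comparison cohort is higher.  Bootstrapping is over
rows (hemispheres); hemispheres of one subject are treated as separate
datapoints, which overstates independence slightly — a subject-level
block bootstrap is a known omission, noted under limitations.  The
p-value is a two-sided Wilcoxon rank-sum on the raw z-scores via
`scipy.stats.mannwhitneyu`: exact enumeration when the pooled sample has
at most 12 tie-free values, otherwise the normal approximation with tie
and continuity corrections.  The test suite carries an independent
brute-force oracle that enumerates all rank assignments and confirms the
exact branch.  Significance is flagged at p < 0.05 with no multiplicity
correction, and p-values are reported for continuity with common
practice rather than for selection.  Per-measure bootstrap streams are
spawned from one `SeedSequence`, so a single seed reproduces the whole
effects table byte-for-byte.

Trajectory points re-express each condition as its displacement
`(d_K, d_S, d_I)` from the reference at the origin; the plotted 2D
projection shows (K, S) with d_I annotated.

## Synthetic cohorts

`generate_cohort` draws hemispheres directly in component space —
`(K, I, S) = baseline + age·slopes + sex·offsets + group offsets +
N(0, diag(sd_K², sd_I², sd_S²))` — and maps back to raw `(At, Ae, T)`
through the exact inverse projection.  Component-space noise is the
point: the generated K and S are independent by construction, which is
the structure the decomposition is designed to expose, and imposed group
offsets propagate to measured effect sizes without distortion.  Default
baseline `(At₀, Ae₀, T₀) = (100 000 mm², 40 000 mm², 2.5 mm)` is a
plausible adult hemisphere; default SDs `(0.01, 0.05, 0.05)` encode the
empirical near-constancy of K relative to size and shape variation
(1:5 ratio).  Age slopes and sex offsets default to zero; analyses that
need covariate structure state it explicitly (the correction tests and
the acceptance script use slopes `(−2e−4, −1e−3, 5e−4)` per year and sex
offsets `(0.003, 0.02, 0.01)` in log₁₀ units — small drifts of the order
of a few percent per decade).  Both hemispheres of a subject share age
and sex but draw independent component noise.  `generate_on_plane`
instead samples I and S freely and pins K to a given log k exactly,
producing data that any correct plane fit must resolve to α = 5/4.

What the generator does *not* emulate: scanner/site effects, segmentation
error correlated across variables, non-linear age trends, left–right
asymmetry, or within-subject hemisphere correlation.  Passing tests
therefore demonstrate correctness of the estimators under the model's
own assumptions, not robustness to real-world artefacts.

## Folded-ribbon toy model

The ribbon is a sinusoid with `n_folds = 8` oscillations wrapped around
a circle, `r(θ) = R0 + a·sin(nθ)`, with thickness T; it is a visual
analogy, not a mechanical folding simulation, so only the signs of the
component responses are treated as meaningful.  The arc length is
integrated by adaptive quadrature over one period (relative tolerance
1e−9, checked against a 10⁶-panel trapezoid oracle).  Each parameter
drives one morphometric analog: the base-circle perimeter `2πR0` stands
in for Ae, the folded midline arc length for At, and T enters as T².
Options exist to grow the envelope to the fold crests (`R0 + a`) or by
the outer half-thickness, and to count both ribbon faces instead of the
midline; the crest option weakens the tension term's amplitude response
near a = 0 (the envelope then widens faster than the midline lengthens),
which is why the one-parameter-one-analog mapping is the default.
Default grid ranges R0 ∈ [8, 16], a ∈ [0, 2], T ∈ [0.2, 1] keep the
inner face radius `R0 − a − T/2` positive everywhere.  On this grid the
central-difference signs are: K rises with T and a, falls with R0;
I rises with T, R0 and a; S rises with R0 and a, falls with T.  Note the
ribbon's isometry scales lengths (R0, a) by c and thickness by √c, so
that all three log-area coordinates shift equally; scaling T by c itself
would move T² by c² and change K.

## Numerical and testing choices

Recovery of imposed group effects is validated by simulation: at 120
hemispheres per cohort a single draw has a per-component sampling SD of
roughly 0.11–0.14 in d units, so the recovery test averages 20 seeded
replicates (SD of the mean ≈ 0.03) and asserts the mean recovered
`(d_K, d_I, d_S)` within ±0.15 of the imposed `(+0.35, −0.4, +0.48)`.
Slope-CI coverage is checked over 100 seeded noisy replicates with a
≥ 93/100 pass criterion.  Problem sizes throughout the suite (up to 10⁴
rows for moment checks, 10⁵ points for PCA isotropy) keep the full run
in a few seconds.  Degenerate inputs fail loudly and specifically:
zero-variance predictors, empty bootstrap samples, zero reference
spread, non-positive morphometrics, self-intersecting ribbons.

## Limitations

Whole-table rows are accepted from any source (whole-hemisphere or
lobar), but nothing mesh-based is computed here — exposed area must come
from an upstream surface pipeline.  No mixed-effects handling of the
two-hemispheres-per-subject dependence.  No harmonisation across
scanners.  The correction model is linear in age; cohorts spanning
childhood or very old age would need a richer model.  How a reference
cohort should be lateralized when comparing against ipsilateral patient
hemispheres is a design choice the package exposes (`select_hemisphere_records`
keeps unlabelled reference rows whole) rather than decides.
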