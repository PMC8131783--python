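# Methods

## Diet quantification

A scat's point-frame counts give occupancy percentages over all counted
items. Scats qualify when ≥ 200 points were counted; scats containing
salmon qualify at any count when the sample's wet weight is ≥ 50 g, because
salmon is digested almost completely and washed salmon scats rarely retain
200 countable points. Items of nonfood category are excluded from corrected
compositions; bear-hair items are nonfood (grooming residue) at ≤ 0.5% of
the scat and food (conspecific consumption) above it — the threshold is per
scat, so the nonfood set is resolved per profile.

EDC weights fecal volumes by the dry-matter correction factors CF_D and
renormalizes over food items. For EDEC the package multiplies the EDC
weight by CF_E (volume → dry matter → digestible energy, the
composition-then-energy convention); the weighting is a single hook
(`compute_edec(..., weight=)`) for users whose factor tables are defined
against a different base. Correction factors are inputs: the shipped
example table is deliberately marked non-authoritative because published CF
values are source- and study-specific. Period summaries use the unweighted
arithmetic mean of per-scat percent profiles — the scat, not the point, is
the sampling unit — plus percent frequency of occurrence and group sizes;
formatted output renders positive values below 0.05% as `tr` and exact
zeros as an em-dash. Semimonthly grouping uses day-of-month ≤ 15 as
"early"; scats of unknown day stay in monthly but not semimonthly
summaries.

Visually estimated volumes (vFV) are folded into EDC comparisons by
per-category regression through the origin of EDC on vFV (slope
Σxy/Σx², the through-origin least-squares estimate); categories without
pairs pass through with slope 1, and calibrated profiles are renormalized
to 100. Calibration is at category level because cross-method comparisons
are reported at category level. Consumption-year classification compares
each year's August pine-nut and September salmon EDC to the across-year
mean with a strict inequality ("exceeds the mean"), so a year exactly at
the mean is not high; high-both years form diet class 1, low-both years
diet class 2.

## Body condition

Photographs with any grading attribute scored 3 (poor) are removed; the
attribute set is configurable (default: focus, lateral orientation,
posture, obstruction, ground visibility) — only the "any 3 removes" rule
is fixed. Landmarks are rotated by the negative ground angle so the ground
line is horizontal; TH is read as a vertical distance and HTL as a
horizontal distance on the rectified coordinates (the vertical/horizontal
reading is the package's interpretation of "perpendicular/parallel to the
ground"). TH:HTL is the ratio of the three-replicate means. Session values
need ≥ 2 usable photographs and take the median (even counts: mean of the
central pair). Bear-years need ≥ 2 sessions, re-checked after the
offspring-loss truncation, which by default drops the loss session itself
(`loss_rule="inclusive"`; "subsequent sessions" is ambiguous, and the
conservative reading avoids mixing pre- and post-loss condition —
`"exclusive"` keeps the loss session). Reproductive status is collapsed to
solitary vs with-young, since mothers with cubs and with yearlings show
similar condition. Image digitization is out of scope; the package starts
from exported landmark coordinates.

## Condition GAMMs

The response TH:HTL is strictly positive with roughly constant coefficient
of variation, hence the gamma family with log link. The linear predictor
combines a low-rank 1-D thin-plate regression spline of session (radial
basis |x−x′|³ on the unique session values, eigen-truncated to k functions
with a linear, unpenalized null space; sum-to-zero centering absorbs the
constant), optional factor-by smooths (one centered smooth and one
smoothing parameter per level), fixed effects, and crossed year/bear
random intercepts represented as identity-penalized indicator blocks —
random effects and smooths share one penalized-likelihood framework.

Fitting is penalized IRLS; for the gamma/log pair the working weights are
constant, so each outer step reduces to a penalized Gaussian problem for
the working response z = η + (y−μ)/μ. Smoothing and variance parameters
minimize the restricted likelihood of that working model ("performance
iteration"): −2·lr = (n−M_p)·(log 2πφ̂ + 1) + log|XᵀX+S_λ| − log|S_λ|₊
with the scale profiled out, optimized over log-λ by bounded Powell search
(bounds ±18, warm-started between outer iterations). Outer iterations cap
at 200 with relative tolerance 1e-8 and a convergence flag on the result;
non-convergence is flagged, never silent. Default k = 5 per smooth: eight
distinct session values cap what is estimable, and the seasonal pattern
(one decline, one recovery) needs few degrees of freedom; k is a
parameter.

Effective degrees of freedom are traces of the corresponding blocks of the
influence matrix (XᵀX+S_λ)⁻¹XᵀX. The dispersion is the Pearson estimate on
n − edf degrees of freedom, coefficient covariances are φ̂·(XᵀX+S_λ)⁻¹, and
smooth-term F/p values are Wald-type approximations that ignore
smoothing-parameter uncertainty — they are labelled approximate in all
outputs. For AICc, the effective parameter count defaults to fixed +
summed smooth edf + one per random-variance parameter + dispersion
(`keff_mode="edf"`; `"params"` counts raw columns instead — the accounting
is configurable because conventions differ between software families).
AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1); Akaike weights are exp(−Δ/2)
normalized. Population-level prediction curves set random intercepts to
zero and transform η ± 1.96·SE through the inverse link; grids beyond the
observed session range warn rather than fail. Splines are not cyclic by
design: June and November condition are not constrained to meet.

## Synthetic-study generator

The generator's defaults are the study conditions. Diet stream: per
month-year category profiles follow the published seasonal means, with the
August pine-nut and September salmon shares replaced by per-year scenario
values (high ≈ 43–47% pine, 54–72% salmon; low years filled so the
across-year means sit near the published means) and the remaining
categories rescaled. Each scat draws a true ingested composition from a
Dirichlet around the item-level profile (concentration 6 — scats are
typically dominated by a few items, so moderate overdispersion is the
realistic choice), converts it to expected fecal composition by dividing
by CF_D and renormalizing (the exact inverse of the EDC computation), adds
a small Beta-distributed nonfood (debris) share, and counts points
multinomially (200–320 points; 60–200 for salmon-dominated scats, which
mirrors why the wet-weight exception exists). Scat counts per month-year
match the published sample sizes (point-frame years) and monthly totals
(the visual year). Visual records carry rounded, lognormal-noised percent
estimates; parallel period-level (vFV, EDC) pairs support calibration.

Condition stream: log TH:HTL follows one of two session trajectories —
shallow with a mid-July minimum in high-consumption years, deeper with a
late-August minimum otherwise — plus a −0.025 offset for females with
dependent young (the published top-model estimate), year and bear random
intercepts (SD 0.012 and 0.015), and gamma photo-level noise (shape 600,
CV ≈ 4%). Photographs per bear-session are Poisson(3.6) with 85% session
presence and a 15% unusable rate; offspring loss follows a per-session
hazard of 0.04. Landmarks are constructed so the measurement routine
returns the drawn ratio exactly at zero replicate jitter (default jitter
1.5 px, a ≈0.3% perturbation), then rotated by a uniform ±8° ground angle.
Determinism: one RNG substream per component via `SeedSequence.spawn`, so
identical (config, seed) give byte-identical files.

What the generator does not emulate: observer disagreement in point-frame
counts, per-scat variation in digestibility (an optional stress test could
jitter CF_D; the default keeps the distortion deterministic), spatial or
individual heterogeneity in diet, correlation between a bear's diet and
her condition (the two streams share only the year classification), and
posture-driven measurement bias in photographs. Passing recovery tests
therefore demonstrates that the estimators invert the modelled distortions
(digestibility, counting noise, photo noise, the exclusion rules) — not
that field data are free of the unmodelled ones.

## Numerical notes and limitations

Degenerate inputs raise typed errors: all-zero counts, zero food volume
after nonfood exclusion, all-zero calibrated profiles, zero-length
landmark distances, non-positive responses under the gamma family, and
AICc with n ≤ k_eff + 1. Penalty matrices are symmetrized with round-off
negative eigenvalues clipped to zero; a constant response drives random
variances to the lower boundary and is handled by a dispersion floor. The
through-origin slope falls back to 1 (with a warning) when a category's
vFV values are all zero. Model-selection results at the study's own sample
size should be read through the Akaike weights, not as a single winner:
with ~400 observations several candidate structures can be close, exactly
as in the motivating analysis. Printed tables from the motivating study
are not bit-targets for the GAMM: its exact effective-parameter accounting
and sample size are not recoverable, which is why the package's checks
rest on in-table arithmetic and synthetic-recovery properties instead.
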