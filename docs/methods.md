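# Methods

## Problem setting

Implant placement planning asks, for a candidate plan described by six
variables — implant length `L`, implant diameter `D`, cancellous-bone
Young's modulus `E_c`, front–rear and left–right insertion angles
`θ_fr`, `θ_lr`, and cortical-bone thickness `t_c` — how much von Mises
stress the 100 N masticatory load induces in the cortical bone. Stress
overload there jeopardizes osseointegration, so a plan is acceptable when
the predicted cortical stress stays under 40 MPa. A finite-element solution
of one configuration is far too slow for interactive use; the toolkit
replaces it with a chain of cheap, testable components.

## Design space and experimental designs

Each variable carries five grid levels (units in parentheses):
`L ∈ {8.5, 10, 11.5, 13, 15}` (mm), `D ∈ {3.0, 3.5, 4.0, 4.5, 5.0}` (mm),
`E_c ∈ {0.5, 2.0, 4.5, 7.0, 9.5}` (GPa), `θ_fr, θ_lr ∈ {0, 2.5, 5, 7.5, 10}`
(deg), `t_c ∈ {1.5, 1.75, 2.0, 2.25, 2.5}` (mm). Angles are treated as
magnitudes; the published single-factor sweeps report one value per
magnitude, so direction adds no information here. The tooth region
(anterior / premolar / posterior) enters as a categorical tag — one
surrogate per region — not as a seventh continuous variable. Prediction
queries may be off-grid but must stay inside each variable's range; the
emulator never extrapolates.

The L25(5⁶) orthogonal array is generated over GF(5): rows indexed by
`(a, b) ∈ {0..4}²` in row-major order, columns `a, b, a+b, a+2b, a+3b, a+4b
(mod 5)` mapped to sorted level values, variables assigned to columns in the
fixed order `(L, D, E_c, θ_fr, θ_lr, t_c)`. Any two columns have linearly
independent coefficient vectors over GF(5), which proves the pairwise
balance property; the test suite re-verifies it by brute-force enumeration.
Any column-to-variable assignment of a 5-level orthogonal array is
statistically equivalent for main effects, so the fixed order is purely a
determinism choice.

## Anchored response emulator

The emulator is exact at the thirty published single-factor cortical-stress
values (five levels × six variables, all sharing the baseline
`(11.5 mm, 4.0 mm, 7.0 GPa, 0°, 0°, 1.5 mm) → 13.81 MPa`) and composes
joint variation multiplicatively:

    σ(x) = region_scale · σ₀ · ∏ᵢ fᵢ(xᵢ) / σ₀ ,   σ₀ = 13.81 MPa

with `fᵢ` the piecewise-linear interpolant through variable *i*'s anchor
table. No joint-variation reference values are available, so *any*
composition rule is a modelling choice; the multiplicative one is the
simplest that preserves every anchor exactly and keeps stresses positive.
Piecewise-linear (rather than spline) interpolation is shape-preserving,
which matters for the `t_c` anchor — it is genuinely non-monotone
(13.81, 9.26, 17.22, 10.04, 11.58 MPa), reflecting two offsetting physical
effects (thicker cortical shell distributes load, but shrinks the
cancellous volume), and the emulator keeps that deviation rather than
smoothing it.

Companion channels exist so all three response columns of a simulation
campaign can be exercised: implant stress is a fixed ratio (default 2.0) of
the cortical stress, and deformation is `0.01 · σ / E_c` mm, giving ≈20 µm
at baseline — the physiological micromotion scale. Both are synthetic
scalings, clearly so in their docstrings, and are not quality or acceptance
surfaces. Optional noise multiplies each channel by an independent
lognormal factor with unit median and coefficient of variation `noise_cv`
(`s² = ln(1 + cv²)`); the lognormal preserves positivity, and unit median
keeps the noise-free value the central one. `region_scale` defaults to 1.0
for all regions because the published sweeps used a single geometry.

What the emulator does *not* emulate: geometric stress concentrations,
contact nonlinearity, and any interaction structure beyond the
multiplicative rule. Pipeline tests passing against it show the DOE /
fitting / ranking / classification machinery is correct — not that a
quadratic surrogate would reach any particular accuracy on real FEA data.

## Surrogate and genetic term selection

Variables are affinely normalized to [−1, 1] over their design range before
basis expansion (raw units span three orders of magnitude; the normalized
Vandermonde matrix is far better conditioned, and predictions are invariant
to unit changes absorbed by the map). The basis contains all monomials up
to a total order (default 2, with cross terms: 28 terms over six
variables), ordered by total order then lexicographically. Fitting is
ordinary least squares; rank-deficient bases are rejected with the
collinear terms named, as are data sets with fewer rows than terms.

Term subsets are selected by a genetic algorithm: one bit per non-intercept
candidate term (the intercept is always kept), fitness = cross-validated
CoP of the subset's least-squares fit, binary tournament selection, uniform
crossover (p = 0.9), bit-flip mutation (p = 1/length), elitism 2,
population 40, 60 generations. Ties in fitness prefer fewer terms, then the
lexicographically smallest chromosome, so a run is a pure function of
(data, settings, seed). Chromosomes too large for leave-one-out fitting are
penalized in proportion to their excess size rather than rejected. The
leave-one-out fitness uses the hat-matrix identity
(`e_i^{LOO} = e_i/(1−h_ii)`), which is algebraically exact for full-rank
least squares; the test suite verifies its equality with an explicit
refit-every-point loop, and the generic `cop_cv` routine remains an
explicit per-fold refit usable with any fit→predict procedure.

## Quality metrics

CoD is the in-sample explained-variance ratio; for least-squares fits with
an intercept it equals `1 − SS_res/SS_tot`, and the residual form, clamped
to [0, 1], is the default for arbitrary predictors. CoP partitions the data
into folds (leave-one-out up to 30 rows, else 5-fold), predicts each fold
from its complement, pools all held-out pairs, and reports the squared
Pearson correlation. Pooling one correlation instead of averaging per-fold
correlations keeps LOO well defined. Degenerate pooled predictions give
CoP = 0.

One deliberate deviation from the plain squared-correlation definition:
the correlation is clamped to [0, 1] *before* squaring. Squaring alone
rewards anticorrelated predictors — the leave-one-out mean predictor,
`ŷ_i = (nμ − y_i)/(n−1)`, is *perfectly* anticorrelated with the
observations and would score CoP = 1, and a subset search maximizing that
figure collapses to the empty model. Treating negative correlation as zero
prognostic power removes the pathology without affecting any predictor
that actually tracks the response.

## Planner

Classification is strict: predicted cortical stress < threshold (default
40 MPa) → green, otherwise red; exactly 40 MPa is red. The assessment
records the predictor that produced the number (anchored emulator or a
fitted surrogate), and a fitted surrogate answers in constant time — a
stored polynomial evaluation, no simulation. An optional ordered band list
generalizes the two-colour rule to a gradation. Batch assessment preserves
row order, reports green/red counts, and records per-row validation errors
without abandoning the remaining rows.

## Numerical and design choices

- OLS via `numpy.linalg.lstsq`/QR; interpolation via `numpy.interp`.
- Off-design queries through a surrogate set an extrapolation flag (outside
  the normalization cube) and warn, but still return the value.
- Folds are deterministic given `(n, scheme, seed)`; LOO is index-ordered.
- A cross-validation training fold with fewer rows than basis terms falls
  back to the largest admissible prefix of the order-sorted basis and flags
  the report (`basis_truncated_on_small_fold`).
- Relative range in the sensitivity module is `100·(max−min)/max`
  (verified against the published percentages; the `/min` variant does not
  reproduce them), rounded to one decimal only for reporting. "No clear
  trend" is operationalized as non-monotonicity across the five grid
  points.
- The sensitivity report carries a note that cross-variable comparison of
  relative ranges mixes the variables' physical scales.

## Problem sizes

Tests run the pipeline at desk scale: the L25 array (n = 25), random
in-range designs of 30–60 points for oracle comparisons, 10⁴ draws for the
noise-moment check, and 20-seed replicates for the statistical properties
(prognosis decreasing in noise; subset selection beating the saturated
basis on sparse-truth data, one-sided sign test). The full 5⁶ factorial
(15,625 runs/region) simulates in under a second through the emulator and
supports surrogate training in ~20 s.

## Known limitations

- A surrogate trained on only 25 runs with a near-saturated subset can
  interpolate the design (high CoD and LOO CoP) yet behave badly off-design
  — including physically impossible negative stress predictions at corners
  of the cube. This is a property of small-sample polynomial ROMs, not a
  defect of the search; train on a larger design (the full factorial, or
  any custom design) for a deployable model, and treat the extrapolation
  flag as a hard warning.
- The quadratic default basis cannot fully capture the emulator's sharp
  `E_c` response (stress triples from 9.5 to 0.5 GPa); global CoD for a
  quadratic over the full space plateaus around 0.8–0.9. Raising
  `candidate_max_order` helps at the cost of more data.
- Only the GARS-style polynomial backend is implemented; support-vector and
  neural-network surrogates would slot into the same fit/predict/quality
  contract but are out of scope.
- The emulator's per-region scaling defaults to 1.0; regional differences
  are carried only as a tag unless the user overrides the scale map.
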