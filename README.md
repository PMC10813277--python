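# implantrom

Parametric reduced-order modelling (ROM) toolkit for dental implant
placement planning.

A full finite-element analysis (FEA) of the stress an implant induces in
the surrounding bone takes hours per configuration — far too slow for
interactive surgical planning. `implantrom` implements the surrogate
pipeline that replaces it: sample the placement design space with a small
designed experiment, fit a polynomial metamodel ("1-D CAE solver") whose
terms are chosen by a genetic algorithm with cross-validated prognosis as
fitness, rank the influence of the placement variables, and assess candidate
placements in real time against a cortical-bone stress safety threshold.
It is aimed at biomechanics and CAE engineers building digital-twin
planning tools, and at anyone studying surrogate quality for structural
response models.

## The model

Six placement variables `x = (L, D, E_c, θ_fr, θ_lr, t_c)` describe a
candidate plan: implant length `L` (8.5–15 mm) and diameter `D`
(3.0–5.0 mm), Young's modulus of the cancellous bone `E_c` (0.5–9.5 GPa,
patient-dependent), front–rear and left–right insertion angles (0–10°), and
cortical bone thickness `t_c` (1.5–2.5 mm), each on a five-level grid, under
a fixed 100 N masticatory load. The response of record is the von Mises
stress `σ` in the cortical bone.

- **Design of experiments** — a Taguchi L25(5⁶) orthogonal array covers the
  six five-level factors in 25 runs (every level five times per column,
  every ordered level pair exactly once per column pair), built by the
  two-generator construction over GF(5). A 5⁶ full factorial is also
  available.
- **Anchored emulator** — a deterministic stand-in for the 3-D FEA solver,
  exact at the thirty published single-factor stress values:
  `σ(x) = σ₀ ∏ᵢ fᵢ(xᵢ)/σ₀` with `σ₀ = 13.81 MPa` the baseline stress and
  `fᵢ` the piecewise-linear interpolant through variable *i*'s published
  sweep. Optional multiplicative lognormal noise with unit median.
- **Surrogate** — polynomial in the variables normalized to [−1, 1],
  `ŷ(x) = Σₖ βₖ ∏ᵢ x̃ᵢ^{eₖᵢ}`, fitted by least squares. Term subsets are
  selected by a genetic algorithm (GARS-style) maximizing the coefficient of
  prognosis **CoP** — the squared correlation between held-out observations
  and cross-validated predictions — while the coefficient of determination
  **CoD** reports in-sample quality.
- **Planner** — a placement is shown **green** when the predicted cortical
  stress is under 40 MPa and **red** otherwise.

Single-factor sensitivity reproduces the published influence ordering
`E_c > D > θ_fr > θ_lr > L` (relative ranges 71.9, 57.9, 42.5, 42.0,
30.0 %), with `t_c` excluded for showing no clear trend.

## Worked example

```sh
$ implantrom doe --design l25 --out design.csv
wrote 25 runs (l25) to design.csv

$ implantrom simulate --design design.csv --out results.csv
wrote 25 simulated runs to results.csv

$ implantrom fit --data results.csv --method gars --seed 1 --out model.json
fitted gars surrogate: 22 terms, CoD=1.0000, CoP=0.9958 (loo); wrote model.json

$ implantrom predict --length 13.0 --diameter 4.5 --emodulus 2.0
{
  "predicted": {
    "cortical_stress_MPa": 15.526261285754057,
    "implant_stress_MPa": 31.052522571508113,
    "deformation_mm": 0.07763130642877028
  },
  "status": "green",
  "threshold_MPa": 40.0,
  ...
}

$ implantrom predict --length 10.0 --diameter 3.5 --emodulus 0.5 --fr-angle 7.5
{
  "predicted": { "cortical_stress_MPa": 80.91169743660983, ... },
  "status": "red",
  ...
}
```

The first prediction (a long, wide implant in moderately stiff bone) keeps
the cortical stress at 15.5 MPa — comfortably green. The second (short,
narrow, tilted, in the softest bone) drives it to 80.9 MPa, twice the safety
threshold, and is flagged red. `implantrom sensitivity` prints the sweep
table and influence ranking as JSON.

The same pipeline is available as a library (`implantrom.build_default_space`,
`taguchi_l25`, `build_anchored_emulator`, `run_doe`, `gars_select`,
`assess_placement`, …); see `docs/methods.md` for the modelling details and
caveats — in particular, surrogates trained on only 25 runs predict well on
the design but can behave badly off-design; train on a larger design (e.g.
`--design full`) for a deployable model.

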