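"""Real-time placement assessment against the cortical-stress safety rule.

A candidate placement is judged by its predicted cortical von Mises stress:
below 40 MPa the plan is displayed green (safe), at or above it red.  The
boundary itself is red — "under 40 MPa" is read strictly.  Prediction can
come from a fitted polynomial surrogate (a constant-time formula, suitable
for interactive planning) or directly from the anchored emulator; the
assessment records which model produced the number.

An optional multi-band gradation (e.g. green / amber / red) is supported
for finer feedback, defaulting to the two-band rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .design_space import DesignMatrix, PlacementConfig, validate_config
from .fea_emulator import EmulatorConfig, evaluate_outputs
from .rom import PolynomialSurrogate

DEFAULT_THRESHOLD_MPA = 40.0


@dataclass(frozen=True)
class PlanAssessment:
    """Verdict for one candidate placement."""

    config: PlacementConfig
    region: str
    predicted: Mapping[str, float]
    status: str  # "green" | "red" (or a custom band label)
    threshold_MPa: float
    extrapolation_flag: bool
    model_id: str

    @property
    def cortical_stress_MPa(self) -> float:
        return self.predicted["cortical_stress_MPa"]


@dataclass(frozen=True)
class BatchAssessment:
    """Order-preserving batch of assessments plus summary counts."""

    assessments: tuple[PlanAssessment, ...]
    errors: tuple[tuple[int, str], ...] = ()  # (row index, message)

    @property
    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for a in self.assessments:
            out[a.status] = out.get(a.status, 0) + 1
        return out

    @property
    def n_green(self) -> int:
        return self.counts.get("green", 0)

    @property
    def n_red(self) -> int:
        return self.counts.get("red", 0)


def classify(stress_MPa: float, threshold_MPa: float = DEFAULT_THRESHOLD_MPA,
             bands: Sequence[tuple[float, str]] | None = None) -> str:
    """Map a stress to a band label.

    Default two-band rule: strictly below the threshold is green, at or
    above is red.  ``bands`` is an ordered list of (upper_bound, label);
    the first band whose bound strictly exceeds the stress wins, and
    stresses at or above the last bound take the final label.
    """
    if threshold_MPa <= 0:
        raise ValueError(f"threshold must be positive, got {threshold_MPa}")
    if bands is None:
        bands = ((threshold_MPa, "green"),)
        final = "red"
    else:
        bands = tuple(bands)
        final = bands[-1][1]
        bands = bands[:-1]
    for bound, label in bands:
        if stress_MPa < bound:
            return label
    return final


def _predict_channels(
    predictor: EmulatorConfig | PolynomialSurrogate, cfg: PlacementConfig
) -> tuple[dict[str, float], bool, str]:
    if isinstance(predictor, EmulatorConfig):
        result = evaluate_outputs(predictor, cfg)
        channels = {
            "cortical_stress_MPa": result.cortical_stress_MPa,
            "implant_stress_MPa": result.implant_stress_MPa,
            "deformation_mm": result.deformation_mm,
        }
        return channels, False, "anchored_emulator"
    if isinstance(predictor, PolynomialSurrogate):
        value, extrapolating = predictor.predict_config(cfg)
        model_id = f"surrogate:{predictor.provenance.get('method', 'ols')}:{predictor.response}"
        return {predictor.response: value, "cortical_stress_MPa": value}, extrapolating, model_id
    raise TypeError(
        f"predictor must be an EmulatorConfig or PolynomialSurrogate, got {type(predictor)!r}"
    )


def assess_placement(
    predictor: EmulatorConfig | PolynomialSurrogate,
    cfg: PlacementConfig | Mapping[str, float],
    threshold_MPa: float = DEFAULT_THRESHOLD_MPA,
    bands: Sequence[tuple[float, str]] | None = None,
) -> PlanAssessment:
    """Assess one candidate placement against the safety threshold."""
    if isinstance(predictor, EmulatorConfig):
        cfg = validate_config(predictor.space, cfg)
    elif not isinstance(cfg, PlacementConfig):
        raise TypeError("surrogate assessment requires a validated PlacementConfig")
    channels, extrapolating, model_id = _predict_channels(predictor, cfg)
    status = classify(channels["cortical_stress_MPa"], threshold_MPa, bands=bands)
    return PlanAssessment(
        config=cfg,
        region=cfg.region,
        predicted=channels,
        status=status,
        threshold_MPa=threshold_MPa,
        extrapolation_flag=extrapolating,
        model_id=model_id,
    )


def batch_assess(
    predictor: EmulatorConfig | PolynomialSurrogate,
    candidates: DesignMatrix | Sequence[PlacementConfig],
    threshold_MPa: float = DEFAULT_THRESHOLD_MPA,
    bands: Sequence[tuple[float, str]] | None = None,
) -> BatchAssessment:
    """Assess a batch of candidates, order-preserving.

    A row that fails validation is recorded in ``errors`` with its index;
    the remaining rows are still assessed.
    """
    rows = candidates.rows if isinstance(candidates, DesignMatrix) else tuple(candidates)
    assessments, errors = [], []
    for i, cfg in enumerate(rows):
        try:
            assessments.append(assess_placement(predictor, cfg, threshold_MPa, bands=bands))
        except (ValueError, TypeError) as exc:
            errors.append((i, str(exc)))
    return BatchAssessment(assessments=tuple(assessments), errors=tuple(errors))
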