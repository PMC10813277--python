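"""Deterministic stress/deformation emulator anchored to single-factor FEA sweeps.

A full 3-D finite-element run of the implant model takes hours per
configuration; desk-scale pipeline development needs a response function that
is cheap, deterministic, and faithful to the published single-factor
behaviour.  This module provides one.

The emulator is anchored to the six published single-factor sweeps of the
cortical-bone von Mises stress: for each variable, the stress at its five
grid levels with every other variable held at the baseline placement
(length 11.5 mm, diameter 4.0 mm, cancellous modulus 7.0 GPa, both angles
0 deg, cortical thickness 1.5 mm; baseline stress 13.81 MPa).  Joint
variation composes multiplicatively in ratios to baseline::

    sigma(x) = region_scale * sigma0 * prod_i  f_i(x_i) / sigma0

where ``f_i`` is the piecewise-linear interpolant through variable *i*'s
anchor table.  By construction every single-factor sweep reproduces its
anchor table exactly; between grid points the interpolant is shape
preserving (no overshoot, which matters for the non-monotone cortical
thickness anchor).  No extrapolation outside the level range is allowed.

Two companion output channels exist so the full three-channel pipeline
(implant stress, cortical stress, deformation) can be exercised; both are
synthetic scalings documented on :func:`evaluate_outputs`, not anchored
values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .design_space import (
    DesignMatrix,
    DesignSpace,
    PlacementConfig,
    REGIONS,
    validate_config,
)

#: baseline placement shared by all six anchor sweeps
BASELINE_VALUES: dict[str, float] = {
    "length": 11.5,
    "diameter": 4.0,
    "cancellous_modulus": 7.0,
    "front_rear_angle": 0.0,
    "left_right_angle": 0.0,
    "cortical_thickness": 1.5,
}

BASELINE_STRESS_MPA = 13.81

#: published cortical von Mises stress (MPa) at each variable's five levels,
#: all other variables at baseline
ANCHOR_STRESS_MPA: dict[str, tuple[float, ...]] = {
    "length": (14.98, 14.87, 13.81, 13.28, 10.49),
    "diameter": (20.08, 16.14, 13.81, 9.91, 8.46),
    "cancellous_modulus": (44.53, 22.50, 15.74, 13.81, 12.51),
    "front_rear_angle": (13.81, 13.86, 14.87, 19.94, 24.03),
    "left_right_angle": (13.81, 15.04, 15.30, 18.81, 23.83),
    "cortical_thickness": (13.81, 9.26, 17.22, 10.04, 11.58),
}

#: Young's modulus (GPa) and Poisson ratio of the three materials
DEFAULT_MATERIAL_PROPS: dict[str, tuple[float, float]] = {
    "implant": (105.0, 0.37),
    "cortical": (13.0, 0.3),
    "cancellous": (7.0, 0.3),
}

RESPONSE_CHANNELS = ("cortical_stress_MPa", "implant_stress_MPa", "deformation_mm")


@dataclass(frozen=True)
class AnchorTable:
    """Published single-factor sweep for one variable: grid levels + stresses."""

    variable: str
    grid: tuple[float, ...]
    stress_MPa: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "grid", tuple(float(v) for v in self.grid))
        object.__setattr__(self, "stress_MPa", tuple(float(v) for v in self.stress_MPa))
        if len(self.grid) != len(self.stress_MPa):
            raise ValueError(
                f"anchor table for {self.variable!r}: grid and stress lengths differ"
            )
        if any(b <= a for a, b in zip(self.grid, self.grid[1:])):
            raise ValueError(f"anchor grid for {self.variable!r} must be increasing")
        if any(s <= 0 for s in self.stress_MPa):
            raise ValueError(f"anchor stresses for {self.variable!r} must be positive")

    def interpolate(self, value: float) -> float:
        if not (self.grid[0] <= value <= self.grid[-1]):
            raise ValueError(
                f"{self.variable} {value} outside anchor range "
                f"[{self.grid[0]}, {self.grid[-1]}]; no extrapolation"
            )
        return float(np.interp(value, self.grid, self.stress_MPa))


@dataclass(frozen=True)
class SimulationResult:
    """One emulated FEA run: the three response channels for a placement."""

    config: PlacementConfig
    cortical_stress_MPa: float
    implant_stress_MPa: float
    deformation_mm: float


@dataclass(frozen=True)
class EmulatorConfig:
    """Fully specified emulator: anchors, baseline, scalings, noise model."""

    space: DesignSpace
    anchors: Mapping[str, AnchorTable]
    baseline: PlacementConfig
    baseline_stress_MPa: float = BASELINE_STRESS_MPA
    region_scale: Mapping[str, float] = field(
        default_factory=lambda: {r: 1.0 for r in REGIONS}
    )
    noise_cv: float = 0.0
    seed: int = 0
    material_props: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_MATERIAL_PROPS)
    )
    implant_stress_ratio: float = 2.0
    deformation_compliance: float = 0.01

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError(f"noise_cv must be >= 0, got {self.noise_cv}")
        if any(s <= 0 for s in self.region_scale.values()):
            raise ValueError("region_scale values must be positive")
        if self.implant_stress_ratio <= 0 or self.deformation_compliance <= 0:
            raise ValueError("output scalings must be positive")


def build_anchored_emulator(space: DesignSpace, **overrides) -> EmulatorConfig:
    """Build the emulator anchored to the embedded single-factor tables.

    ``overrides`` may replace any :class:`EmulatorConfig` field (for example
    ``noise_cv`` or ``region_scale``); override anchors must use grids
    consistent with the space's levels.
    """
    anchors = overrides.pop("anchors", None)
    if anchors is None:
        anchors = {
            name: AnchorTable(name, space.variable(name).levels, ANCHOR_STRESS_MPA[name])
            for name in space.names
        }
    for name, table in anchors.items():
        if table.grid != space.variable(name).levels:
            raise ValueError(
                f"anchor grid for {name!r} {table.grid} does not match "
                f"space levels {space.variable(name).levels}"
            )
    baseline = overrides.pop(
        "baseline", PlacementConfig(BASELINE_VALUES, region=space.region)
    )
    baseline = validate_config(space, baseline)
    return EmulatorConfig(space=space, anchors=anchors, baseline=baseline, **overrides)


def evaluate_stress(emu: EmulatorConfig, cfg: PlacementConfig | Mapping[str, float]) -> float:
    """Cortical von Mises stress (MPa) for one in-range placement.

    Multiplicative composition of the single-factor anchor responses in
    ratios to the baseline stress; exact at every anchor grid point when the
    other variables sit at baseline.
    """
    cfg = validate_config(emu.space, cfg)
    sigma0 = emu.baseline_stress_MPa
    stress = emu.region_scale.get(cfg.region, 1.0) * sigma0
    for name in emu.space.names:
        stress *= emu.anchors[name].interpolate(cfg[name]) / sigma0
    return stress


def evaluate_outputs(
    emu: EmulatorConfig, cfg: PlacementConfig | Mapping[str, float]
) -> SimulationResult:
    """All three response channels for one placement (noise-free).

    The implant-stress and deformation channels are synthetic by design:
    implant stress is ``implant_stress_ratio`` times the cortical stress, and
    deformation is ``deformation_compliance * stress / E_cancellous`` (mm) --
    softer cancellous bone deforms more under the same load.
    """
    cfg = validate_config(emu.space, cfg)
    stress = evaluate_stress(emu, cfg)
    return SimulationResult(
        config=cfg,
        cortical_stress_MPa=stress,
        implant_stress_MPa=emu.implant_stress_ratio * stress,
        deformation_mm=emu.deformation_compliance * stress / cfg["cancellous_modulus"],
    )


def sample_noisy(
    emu: EmulatorConfig, cfg: PlacementConfig | Mapping[str, float], seed: int
) -> SimulationResult:
    """One stochastic emulator draw.

    Each channel is multiplied by an independent lognormal factor with unit
    median and coefficient of variation ``emu.noise_cv``; the draw is a pure
    function of (emulator, config, seed).  ``noise_cv = 0`` reduces to
    :func:`evaluate_outputs`.
    """
    clean = evaluate_outputs(emu, cfg)
    if emu.noise_cv == 0:
        return clean
    s = np.sqrt(np.log1p(emu.noise_cv**2))
    rng = np.random.default_rng(seed)
    factors = np.exp(s * rng.standard_normal(3))
    return SimulationResult(
        config=clean.config,
        cortical_stress_MPa=clean.cortical_stress_MPa * factors[0],
        implant_stress_MPa=clean.implant_stress_MPa * factors[1],
        deformation_mm=clean.deformation_mm * factors[2],
    )


def run_doe(emu: EmulatorConfig, design: DesignMatrix) -> pd.DataFrame:
    """Evaluate every design row; return the response table.

    Columns: the six variable names, ``region``, then the three response
    channels.  Row order follows the design.  With ``emu.noise_cv > 0`` each
    row gets an independent noise draw seeded deterministically from
    ``emu.seed`` and the row index.
    """
    records = []
    for i, cfg in enumerate(design.rows):
        try:
            if emu.noise_cv > 0:
                row_seed = int(np.random.SeedSequence((emu.seed, i)).generate_state(1)[0])
                result = sample_noisy(emu, cfg, seed=row_seed)
            else:
                result = evaluate_outputs(emu, cfg)
        except ValueError as exc:
            raise ValueError(f"design row {i}: {exc}") from exc
        record = result.config.as_row()
        record["cortical_stress_MPa"] = result.cortical_stress_MPa
        record["implant_stress_MPa"] = result.implant_stress_MPa
        record["deformation_mm"] = result.deformation_mm
        records.append(record)
    return pd.DataFrame(records)
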