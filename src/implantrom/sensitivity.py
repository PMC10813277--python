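"""Single-factor sweeps and influence ranking of the placement variables.

Each variable is swept over its five grid levels with the other five held
at the baseline placement, and summarized by the relative range of the
cortical stress,

    100 * (max - min) / max   [percent],

reported to one decimal.  Variables whose sweep is strictly one-directional
are ranked by descending relative range; a variable with no clear trend
across its grid (the cortical thickness, whose thinning-bone and
stiffening-bone effects offset) is excluded from the ranking with a stated
reason.  Because the sweep ranges sit on each variable's own physical scale,
the comparison across variables is indicative rather than exact; the report
carries a note to that effect.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .design_space import DesignSpace, PlacementConfig
from .fea_emulator import EmulatorConfig, evaluate_stress

SCALE_NOTE = (
    "relative ranges compare sweeps on each variable's own physical scale; "
    "cross-variable ordering is indicative, not exact"
)


@dataclass(frozen=True)
class SweepResult:
    """One variable's grid sweep with the others at baseline."""

    variable: str
    grid: tuple[float, ...]
    stress_MPa: tuple[float, ...]
    monotone_flag: str  # "increasing" | "decreasing" | "none"

    @property
    def min_MPa(self) -> float:
        return min(self.stress_MPa)

    @property
    def max_MPa(self) -> float:
        return max(self.stress_MPa)

    @property
    def relative_range_pct(self) -> float:
        """Unrounded 100 * (max - min) / max."""
        return relative_range(self.stress_MPa)

    def to_dict(self) -> dict:
        return {
            "variable": self.variable,
            "grid": list(self.grid),
            "stress_MPa": list(self.stress_MPa),
            "min_MPa": self.min_MPa,
            "max_MPa": self.max_MPa,
            "relative_range_pct": round(self.relative_range_pct, 1),
            "monotone_flag": self.monotone_flag,
        }


@dataclass(frozen=True)
class SensitivityReport:
    """All six sweeps, the influence ranking, and exclusions."""

    sweeps: tuple[SweepResult, ...]
    ranking: tuple[str, ...]
    excluded: tuple[tuple[str, str], ...]  # (variable, reason)
    ties: tuple[tuple[str, str], ...] = ()
    note: str = SCALE_NOTE

    def to_dict(self) -> dict:
        return {
            "sweeps": [s.to_dict() for s in self.sweeps],
            "ranking": list(self.ranking),
            "excluded": [{"variable": v, "reason": r} for v, r in self.excluded],
            "ties": [list(t) for t in self.ties],
            "note": self.note,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def relative_range(stress_values) -> float:
    """100 * (max - min) / max for a sweep of positive stresses (percent)."""
    values = np.asarray(stress_values, dtype=float)
    if values.size == 0 or np.max(values) <= 0:
        raise ValueError("relative range needs positive stress values")
    return float(100.0 * (np.max(values) - np.min(values)) / np.max(values))


def _monotone_flag(values) -> str:
    diffs = np.diff(np.asarray(values, dtype=float))
    if np.all(diffs > 0):
        return "increasing"
    if np.all(diffs < 0):
        return "decreasing"
    return "none"


def single_factor_sweep(
    source: EmulatorConfig | pd.DataFrame,
    variable: str,
    baseline: PlacementConfig | None = None,
    space: DesignSpace | None = None,
) -> SweepResult:
    """Sweep one variable over its grid, the other five held at baseline.

    ``source`` is either an emulator (evaluated directly) or a response
    table containing the sweep rows (matched on the off-baseline variable).
    """
    if isinstance(source, EmulatorConfig):
        space = source.space
        baseline = baseline or source.baseline
        grid = space.variable(variable).levels
        stresses = []
        for level in grid:
            values = dict(baseline.values)
            values[variable] = level
            stresses.append(
                evaluate_stress(source, PlacementConfig(values, region=baseline.region))
            )
    else:
        if baseline is None or space is None:
            raise ValueError("sweeping a response table requires baseline and space")
        grid = space.variable(variable).levels
        others = [n for n in space.names if n != variable]
        mask = np.ones(len(source), dtype=bool)
        for name in others:
            mask &= np.isclose(source[name].to_numpy(dtype=float), baseline[name])
        rows = source.loc[mask].sort_values(variable).drop_duplicates(subset=[variable])
        found = rows[variable].to_numpy(dtype=float)
        if len(found) != len(grid) or not np.allclose(found, grid):
            raise ValueError(
                f"response table does not contain a full baseline sweep of {variable!r}; "
                f"found levels {found.tolist()}"
            )
        stresses = rows["cortical_stress_MPa"].to_list()
    return SweepResult(
        variable=variable,
        grid=tuple(grid),
        stress_MPa=tuple(float(s) for s in stresses),
        monotone_flag=_monotone_flag(stresses),
    )


def rank_influence(sweeps) -> SensitivityReport:
    """Rank variables by descending relative range; exclude no-trend sweeps.

    Ties in the statistic are broken alphabetically and flagged.
    """
    sweeps = tuple(sweeps)
    if not sweeps:
        raise ValueError("rank_influence requires at least one sweep")
    names = [s.variable for s in sweeps]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate sweep variables: {names}")
    excluded = tuple(
        (s.variable, "no clear trend") for s in sweeps if s.monotone_flag == "none"
    )
    ranked_sweeps = sorted(
        (s for s in sweeps if s.monotone_flag != "none"),
        key=lambda s: (-s.relative_range_pct, s.variable),
    )
    ties = []
    for a, b in zip(ranked_sweeps, ranked_sweeps[1:]):
        if np.isclose(a.relative_range_pct, b.relative_range_pct):
            ties.append((a.variable, b.variable))
    return SensitivityReport(
        sweeps=sweeps,
        ranking=tuple(s.variable for s in ranked_sweeps),
        excluded=excluded,
        ties=tuple(ties),
    )


def analyze(source: EmulatorConfig, baseline: PlacementConfig | None = None) -> SensitivityReport:
    """Run all six sweeps on an emulator and rank the variables."""
    sweeps = [
        single_factor_sweep(source, name, baseline=baseline) for name in source.space.names
    ]
    return rank_influence(sweeps)
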