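"""Six-variable implant placement design space and experimental designs.

The placement problem is parameterised by six controllable variables:
implant length and diameter (mm), Young's modulus of the cancellous bone
(GPa), the front-rear and left-right insertion angles (degrees, magnitudes),
and the cortical bone thickness (mm).  Each variable takes five discrete
levels; off-grid values inside the range are permitted for prediction
queries.  The tooth region (anterior / premolar / posterior) is carried as a
categorical tag, and the masticatory load is fixed at 100 N.

This module defines the variables, validates candidate placements, and
generates experimental designs: the Taguchi L25(5^6) orthogonal array used
to sample the space in 25 runs, and the 5^6 full factorial.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

REGIONS = ("anterior", "premolar", "posterior")

#: canonical variable order: length, diameter, cancellous modulus,
#: front-rear angle, left-right angle, cortical thickness
VARIABLE_ORDER = (
    "length",
    "diameter",
    "cancellous_modulus",
    "front_rear_angle",
    "left_right_angle",
    "cortical_thickness",
)

DEFAULT_LEVELS: dict[str, tuple[float, ...]] = {
    "length": (8.5, 10.0, 11.5, 13.0, 15.0),
    "diameter": (3.0, 3.5, 4.0, 4.5, 5.0),
    "cancellous_modulus": (0.5, 2.0, 4.5, 7.0, 9.5),
    "front_rear_angle": (0.0, 2.5, 5.0, 7.5, 10.0),
    "left_right_angle": (0.0, 2.5, 5.0, 7.5, 10.0),
    "cortical_thickness": (1.5, 1.75, 2.0, 2.25, 2.5),
}

DEFAULT_UNITS: dict[str, str] = {
    "length": "mm",
    "diameter": "mm",
    "cancellous_modulus": "GPa",
    "front_rear_angle": "deg",
    "left_right_angle": "deg",
    "cortical_thickness": "mm",
}


@dataclass(frozen=True)
class DesignVariable:
    """One placement variable with its five grid levels.

    ``lower`` / ``upper`` are derived from the level list; queries may fall
    anywhere in ``[lower, upper]`` but designs use only the grid levels.
    """

    name: str
    unit: str
    levels: tuple[float, ...]

    def __post_init__(self) -> None:
        levels = tuple(float(v) for v in self.levels)
        object.__setattr__(self, "levels", levels)
        if len(levels) != 5:
            raise ValueError(
                f"variable {self.name!r} must have exactly 5 levels, got {len(levels)}"
            )
        if any(b <= a for a, b in zip(levels, levels[1:])):
            raise ValueError(
                f"variable {self.name!r} levels must be strictly increasing: {levels}"
            )

    @property
    def lower(self) -> float:
        return self.levels[0]

    @property
    def upper(self) -> float:
        return self.levels[-1]

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper


@dataclass(frozen=True)
class DesignSpace:
    """Ordered collection of design variables plus region tag and load."""

    variables: tuple[DesignVariable, ...]
    region: str
    load_N: float = 100.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "variables", tuple(self.variables))
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate variable names: {names}")
        if self.region not in REGIONS:
            raise ValueError(
                f"unknown region {self.region!r}; valid regions: {sorted(REGIONS)}"
            )
        if not self.load_N > 0:
            raise ValueError(f"load_N must be positive, got {self.load_N}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables)

    def variable(self, name: str) -> DesignVariable:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(f"unknown variable {name!r}; known: {list(self.names)}")

    def to_dict(self) -> dict:
        return {
            "region": self.region,
            "load_N": self.load_N,
            "variables": [
                {"name": v.name, "unit": v.unit, "levels": list(v.levels)}
                for v in self.variables
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "DesignSpace":
        variables = tuple(
            DesignVariable(v["name"], v.get("unit", ""), tuple(v["levels"]))
            for v in d["variables"]
        )
        return cls(variables=variables, region=d["region"], load_N=float(d.get("load_N", 100.0)))

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict(), sort_keys=False)
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "DesignSpace":
        path = Path(path)
        text = path.read_text()
        d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(d)


@dataclass(frozen=True)
class PlacementConfig:
    """One concrete assignment of the six variables: a candidate plan."""

    values: Mapping[str, float]
    region: str

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "values", {k: float(v) for k, v in dict(self.values).items()}
        )

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def as_row(self) -> dict:
        row = dict(self.values)
        row["region"] = self.region
        return row


@dataclass(frozen=True)
class DesignMatrix:
    """A list of placement configurations plus how they were generated."""

    rows: tuple[PlacementConfig, ...]
    design_kind: str  # "l25" | "full_factorial" | "custom"

    def __post_init__(self) -> None:
        object.__setattr__(self, "rows", tuple(self.rows))
        if self.design_kind == "l25" and len(self.rows) != 25:
            raise ValueError(f"l25 design must have 25 rows, got {len(self.rows)}")

    def __len__(self) -> int:
        return len(self.rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([cfg.as_row() for cfg in self.rows])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, design_kind: str = "custom") -> "DesignMatrix":
        var_cols = [c for c in frame.columns if c != "region"]
        rows = tuple(
            PlacementConfig({c: row[c] for c in var_cols}, region=row["region"])
            for _, row in frame.iterrows()
        )
        return cls(rows=rows, design_kind=design_kind)

    @classmethod
    def from_csv(cls, path: str | Path, design_kind: str = "custom") -> "DesignMatrix":
        return cls.from_frame(pd.read_csv(path), design_kind=design_kind)


def build_default_space(region: str) -> DesignSpace:
    """Build the standard six-variable space for one tooth region.

    Levels: length 8.5-15 mm, diameter 3.0-5.0 mm, cancellous Young's modulus
    0.5-9.5 GPa, both insertion angles 0-10 deg, cortical thickness
    1.5-2.5 mm; applied load 100 N.
    """
    if region not in REGIONS:
        raise ValueError(
            f"unknown region {region!r}; valid regions: {sorted(REGIONS)}"
        )
    variables = tuple(
        DesignVariable(name, DEFAULT_UNITS[name], DEFAULT_LEVELS[name])
        for name in VARIABLE_ORDER
    )
    return DesignSpace(variables=variables, region=region)


def taguchi_l25(space: DesignSpace) -> DesignMatrix:
    """Generate the L25(5^6) orthogonal array over the space's grid levels.

    Construction over GF(5): rows are indexed by (a, b) with a, b in 0..4 in
    row-major order, and the six columns are the level indices
    ``a, b, (a+b), (a+2b), (a+3b), (a+4b) mod 5``.  Any two columns have
    linearly independent coefficient vectors over GF(5), so every ordered
    level pair occurs exactly once per column pair, and each level occurs
    five times per column.  The output is deterministic.
    """
    if len(space.variables) != 6:
        raise ValueError(
            f"L25 construction requires exactly 6 variables, got {len(space.variables)}: "
            f"{list(space.names)}"
        )
    for v in space.variables:
        if len(v.levels) != 5:
            raise ValueError(
                f"L25 construction requires 5 levels per variable; "
                f"variable {v.name!r} has {len(v.levels)}"
            )
    rows = []
    for a in range(5):
        for b in range(5):
            idx = (a, b, (a + b) % 5, (a + 2 * b) % 5, (a + 3 * b) % 5, (a + 4 * b) % 5)
            values = {
                var.name: var.levels[i] for var, i in zip(space.variables, idx)
            }
            rows.append(PlacementConfig(values, region=space.region))
    return DesignMatrix(rows=tuple(rows), design_kind="l25")


def full_factorial(space: DesignSpace) -> DesignMatrix:
    """Cartesian product of all grid levels in lexicographic order."""
    rows = []
    for combo in itertools.product(*(v.levels for v in space.variables)):
        values = dict(zip(space.names, combo))
        rows.append(PlacementConfig(values, region=space.region))
    return DesignMatrix(rows=tuple(rows), design_kind="full_factorial")


def validate_config(
    space: DesignSpace, cfg: PlacementConfig | Mapping[str, float]
) -> PlacementConfig:
    """Check a placement against the space; return the normalized config.

    Values may be off-grid but must lie within each variable's range.  The
    key set must match the space's variable names exactly.
    """
    if isinstance(cfg, PlacementConfig):
        values, region = dict(cfg.values), cfg.region
    else:
        values = {k: v for k, v in dict(cfg).items() if k != "region"}
        region = dict(cfg).get("region", space.region)
    missing = set(space.names) - set(values)
    extra = set(values) - set(space.names)
    if missing:
        raise ValueError(f"missing variables in placement config: {sorted(missing)}")
    if extra:
        raise ValueError(f"unknown variables in placement config: {sorted(extra)}")
    if region != space.region:
        raise ValueError(
            f"config region {region!r} does not match space region {space.region!r}"
        )
    for name in space.names:
        var = space.variable(name)
        value = float(values[name])
        if not var.contains(value):
            raise ValueError(
                f"{name} {value} outside [{var.lower}, {var.upper}]"
            )
    return PlacementConfig({name: values[name] for name in space.names}, region=region)
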