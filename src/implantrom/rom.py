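"""Polynomial reduced-order models with genetic basis-term selection.

The deployed surrogate ("1-D CAE solver") is a polynomial in the six design
variables, each affinely normalized to [-1, 1] over its design-space range
before basis expansion — the raw units span three orders of magnitude and an
unnormalized polynomial basis is badly conditioned.  Two fitting routes are
provided:

* :func:`fit_polynomial` — ordinary least squares on a fixed basis;
* :func:`gars_select` — a genetic algorithm over subsets of a candidate
  basis, with cross-validated prognosis (CoP, leave-one-out by default) as
  fitness.  Subset selection guards against overfitting small DOE samples
  with a full quadratic-plus-interactions basis.

The GA uses a binary chromosome (one bit per non-intercept candidate term;
the intercept is always included), tournament selection, uniform crossover,
bit-flip mutation and elitism.  Chromosomes too large to leave-one-out fit
are penalized rather than rejected.  Ties in fitness are broken toward fewer
terms, then toward the lexicographically smallest chromosome, so runs are
reproducible bit for bit given the seed.

Fitted models serialize to a small versioned JSON document.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design_space import DesignSpace, PlacementConfig, build_default_space
from . import quality as q

MODEL_FORMAT_VERSION = "1"

N_VARS = 6


@dataclass(frozen=True)
class BasisTerm:
    """One monomial: an exponent per design variable."""

    exponents: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "exponents", tuple(int(e) for e in self.exponents))
        if any(e < 0 for e in self.exponents):
            raise ValueError(f"exponents must be nonnegative: {self.exponents}")

    @property
    def order(self) -> int:
        return sum(self.exponents)

    @property
    def is_intercept(self) -> bool:
        return self.order == 0


def build_basis(
    max_order: int = 2, include_interactions: bool = True, n_vars: int = N_VARS
) -> list[BasisTerm]:
    """All monomials up to ``max_order``, deterministically ordered.

    Ordering: by total order, then lexicographically on the exponent
    vectors.  ``include_interactions=False`` keeps only pure powers.  With
    interactions and ``max_order=2`` over six variables this yields
    1 + 6 + 6 + 15 = 28 terms.
    """
    if max_order < 1:
        raise ValueError(f"max_order must be >= 1, got {max_order}")
    terms = []
    for total in range(max_order + 1):
        level = []
        for combo in itertools.product(range(total + 1), repeat=n_vars):
            if sum(combo) != total:
                continue
            if not include_interactions and sum(1 for e in combo if e > 0) > 1:
                continue
            level.append(BasisTerm(combo))
        level.sort(key=lambda t: t.exponents)
        terms.extend(level)
    return terms


@dataclass(frozen=True)
class Normalization:
    """Per-variable affine maps from raw units onto [-1, 1]."""

    ranges: tuple[tuple[str, float, float], ...]  # (name, lower, upper)

    @classmethod
    def from_space(cls, space: DesignSpace) -> "Normalization":
        return cls(tuple((v.name, v.lower, v.upper) for v in space.variables))

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _, _ in self.ranges)

    def transform(self, frame: pd.DataFrame) -> np.ndarray:
        cols = []
        for name, lo, hi in self.ranges:
            x = frame[name].to_numpy(dtype=float)
            cols.append(2.0 * (x - lo) / (hi - lo) - 1.0)
        return np.column_stack(cols)

    def transform_config(self, cfg: PlacementConfig | Mapping[str, float]) -> np.ndarray:
        values = cfg.values if isinstance(cfg, PlacementConfig) else cfg
        return np.array(
            [2.0 * (float(values[name]) - lo) / (hi - lo) - 1.0 for name, lo, hi in self.ranges]
        )


def _design_matrix(x_norm: np.ndarray, terms: Sequence[BasisTerm]) -> np.ndarray:
    x_norm = np.atleast_2d(x_norm)
    cols = [
        np.prod(x_norm ** np.asarray(t.exponents, dtype=float), axis=1) for t in terms
    ]
    return np.column_stack(cols)


@dataclass(frozen=True)
class PolynomialSurrogate:
    """A fitted polynomial ROM: terms, coefficients, normalization, quality."""

    region: str
    response: str
    terms: tuple[BasisTerm, ...]
    coefficients: tuple[float, ...]
    normalization: Normalization
    quality: q.QualityReport | None = None
    provenance: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.terms) != len(self.coefficients):
            raise ValueError("terms and coefficients must have equal length")

    def predict_frame(self, frame: pd.DataFrame) -> np.ndarray:
        x = self.normalization.transform(frame)
        return _design_matrix(x, self.terms) @ np.asarray(self.coefficients)

    def predict_config(
        self, cfg: PlacementConfig | Mapping[str, float]
    ) -> tuple[float, bool]:
        """Predict one placement; returns (value, extrapolation_flag)."""
        x = self.normalization.transform_config(cfg)
        extrapolating = bool(np.any(np.abs(x) > 1.0 + 1e-9))
        value = float(
            (_design_matrix(x[None, :], self.terms) @ np.asarray(self.coefficients))[0]
        )
        return value, extrapolating


def predict(model: PolynomialSurrogate, cfg: PlacementConfig | Mapping[str, float]) -> float:
    """Evaluate the fitted polynomial at one placement (a pure formula).

    Emits a warning when the query lies outside the training range; the
    value is still returned (the caller decides how to treat extrapolation).
    """
    value, extrapolating = model.predict_config(cfg)
    if extrapolating:
        warnings.warn(
            "placement query outside the surrogate's training range; "
            "prediction is an extrapolation",
            stacklevel=2,
        )
    return value


def _space_for(data: pd.DataFrame, space: DesignSpace | None) -> DesignSpace:
    if space is not None:
        return space
    regions = data["region"].unique().tolist() if "region" in data else ["anterior"]
    if len(regions) != 1:
        raise ValueError(
            f"response table mixes regions {regions}; fit one surrogate per region"
        )
    return build_default_space(regions[0])


def fit_polynomial(
    data: pd.DataFrame,
    response: str,
    terms: Sequence[BasisTerm],
    space: DesignSpace | None = None,
    quality_scheme: str = "none",
    seed: int = 0,
) -> PolynomialSurrogate:
    """Least-squares fit of a fixed polynomial basis to a response table.

    Requires at least as many rows as terms and a full-rank design matrix;
    rank deficiency is reported with the offending (collinear) terms.  The
    attached quality report carries the in-sample CoD; pass
    ``quality_scheme="auto"|"loo"|"kfold"`` to also cross-validate CoP
    (refitting the same basis per fold).
    """
    space = _space_for(data, space)
    terms = tuple(terms)
    y = data[response].to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError(f"response {response!r} contains non-finite values")
    if len(data) < len(terms):
        raise ValueError(
            f"need at least as many rows as basis terms: n={len(data)} < {len(terms)} terms"
        )
    norm = Normalization.from_space(space)
    X = _design_matrix(norm.transform(data), terms)
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < len(terms):
        collinear = _collinear_terms(X, terms)
        raise ValueError(
            f"rank-deficient basis (rank {rank} < {len(terms)} terms); "
            f"collinear terms: {[t.exponents for t in collinear]}"
        )
    model = PolynomialSurrogate(
        region=space.region,
        response=response,
        terms=terms,
        coefficients=tuple(float(b) for b in beta),
        normalization=norm,
        provenance={"method": "ols", "n": len(data), "seed": seed},
    )
    in_sample = model.predict_frame(data)
    if quality_scheme == "none":
        report = q.QualityReport(
            cod=q.cod(y, in_sample, form="residual"),
            cop=0.0,
            n=len(data),
            cv_scheme="none",
            response=response,
            flags=("cop_not_computed",),
        )
    else:
        report = q.cop_cv(
            data,
            response,
            _refit_procedure(terms, space, response),
            scheme=quality_scheme,
            seed=seed,
            cod_predictions=in_sample,
        )
    return replace(model, quality=report)


def _collinear_terms(X: np.ndarray, terms: Sequence[BasisTerm]) -> list[BasisTerm]:
    """Greedy scan for the terms whose columns do not extend the rank."""
    bad, kept = [], []
    for j, term in enumerate(terms):
        cand = X[:, kept + [j]]
        if np.linalg.matrix_rank(cand) == len(kept) + 1:
            kept.append(j)
        else:
            bad.append(term)
    return bad


def _refit_procedure(terms: Sequence[BasisTerm], space: DesignSpace, response: str):
    """fit->predict closure for cop_cv; shrinks the basis on tiny folds.

    A training fold with fewer rows than terms falls back to the largest
    admissible prefix of the (order-sorted) basis, keeping the intercept.
    """
    norm = Normalization.from_space(space)

    def fit(train: pd.DataFrame):
        fold_terms = tuple(terms[: max(1, min(len(terms), len(train)))])
        if len(fold_terms) < len(terms) and "basis_truncated_on_small_fold" not in fit.flags:
            fit.flags.append("basis_truncated_on_small_fold")
        X = _design_matrix(norm.transform(train), fold_terms)
        y = train[response].to_numpy(dtype=float)
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)

        def predicts(frame: pd.DataFrame) -> np.ndarray:
            return _design_matrix(norm.transform(frame), fold_terms) @ beta

        return predicts

    fit.flags: list[str] = []
    return fit


# ---------------------------------------------------------------------------
# Genetic subset selection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GarsSettings:
    """Hyperparameters of the genetic term search."""

    population: int = 40
    generations: int = 60
    crossover_prob: float = 0.9
    mutation_prob: float | None = None  # default 1 / chromosome length
    elitism: int = 2
    fitness: str = "cop_loo"  # or "cop_kfold"
    kfold_k: int = 5
    seed: int = 0
    candidate_max_order: int = 2

    def __post_init__(self) -> None:
        if self.population < 4:
            raise ValueError(f"population must be >= 4, got {self.population}")
        if not 0.0 <= self.crossover_prob <= 1.0:
            raise ValueError("crossover_prob must lie in [0, 1]")
        if self.mutation_prob is not None and not 0.0 <= self.mutation_prob <= 1.0:
            raise ValueError("mutation_prob must lie in [0, 1]")
        if self.elitism >= self.population:
            raise ValueError("elitism must be smaller than the population")
        if self.fitness not in ("cop_loo", "cop_kfold"):
            raise ValueError(f"unknown fitness {self.fitness!r}")


def _chromosome_fitness(
    mask: tuple[int, ...],
    X_full: np.ndarray,
    y: np.ndarray,
    settings: GarsSettings,
) -> float:
    """CoP of the OLS fit on the selected terms; oversize/singular -> penalty.

    Column 0 of ``X_full`` is the intercept and is always included.  The
    leave-one-out CoP uses the closed-form hat-matrix identity, which equals
    the explicit refit loop for full-rank least squares.
    """
    cols = [0] + [j + 1 for j, bit in enumerate(mask) if bit]
    n = len(y)
    if len(cols) >= n:
        return -1.0 - (len(cols) - n)  # infeasible: penalize by excess size
    X = X_full[:, cols]
    try:
        if settings.fitness == "cop_loo":
            loo_pred = q.loo_predictions_ols(X, y)
            return q.squared_correlation(y, loo_pred)
        folds = q.make_folds(n, "kfold", k=settings.kfold_k, seed=settings.seed)
        pooled = np.empty(n)
        for fold_id in range(settings.kfold_k):
            test = folds == fold_id
            beta, _, rank, _ = np.linalg.lstsq(X[~test], y[~test], rcond=None)
            if rank < X.shape[1]:
                return -0.5
            pooled[test] = X[test] @ beta
        return q.squared_correlation(y, pooled)
    except np.linalg.LinAlgError:
        return -0.5  # singular subset


def gars_select(
    data: pd.DataFrame,
    response: str,
    settings: GarsSettings | None = None,
    space: DesignSpace | None = None,
    candidate_terms: Sequence[BasisTerm] | None = None,
) -> PolynomialSurrogate:
    """Genetic search for a robust polynomial term subset.

    Chromosomes are inclusion masks over the non-intercept candidate terms;
    fitness is the cross-validated CoP of the corresponding least-squares
    fit.  Returns the best subset refitted on all data, with a quality
    report (in-sample CoD + cross-validated CoP).  Identical data, settings
    and seed give identical results.
    """
    settings = settings or GarsSettings()
    space = _space_for(data, space)
    if candidate_terms is None:
        candidate_terms = build_basis(settings.candidate_max_order, include_interactions=True)
    candidate_terms = tuple(candidate_terms)
    if not candidate_terms[0].is_intercept:
        raise ValueError("candidate basis must start with the intercept term")
    free_terms = candidate_terms[1:]
    n_bits = len(free_terms)
    if n_bits == 0:
        raise ValueError("candidate basis has no selectable terms")

    norm = Normalization.from_space(space)
    X_full = _design_matrix(norm.transform(data), candidate_terms)
    y = data[response].to_numpy(dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError(f"need at least 3 rows for cross-validated selection, got {n}")

    mut_p = settings.mutation_prob if settings.mutation_prob is not None else 1.0 / n_bits
    rng = np.random.default_rng(settings.seed)
    cache: dict[tuple[int, ...], float] = {}

    def fitness(mask: tuple[int, ...]) -> float:
        if mask not in cache:
            cache[mask] = _chromosome_fitness(mask, X_full, y, settings)
        return cache[mask]

    def sort_key(mask: tuple[int, ...]):
        # higher fitness first, then fewer terms, then lexicographic mask
        return (-fitness(mask), sum(mask), mask)

    # seed population: sparse random masks sized to stay LOO-feasible
    max_terms = max(1, min(n_bits, n - 2))
    population = []
    for _ in range(settings.population):
        size = int(rng.integers(1, max_terms + 1))
        mask = np.zeros(n_bits, dtype=int)
        mask[rng.choice(n_bits, size=min(size, n_bits), replace=False)] = 1
        population.append(tuple(int(b) for b in mask))

    for _ in range(settings.generations):
        ranked = sorted(population, key=sort_key)
        next_pop = list(ranked[: settings.elitism])
        while len(next_pop) < settings.population:
            parents = []
            for _ in range(2):  # binary tournament
                i, j = rng.integers(0, settings.population, size=2)
                a, b = population[int(i)], population[int(j)]
                parents.append(min(a, b, key=sort_key))
            child = np.array(parents[0], dtype=int)
            if rng.random() < settings.crossover_prob:
                swap = rng.random(n_bits) < 0.5
                child[swap] = np.array(parents[1], dtype=int)[swap]
            flip = rng.random(n_bits) < mut_p
            child[flip] = 1 - child[flip]
            next_pop.append(tuple(int(b) for b in child))
        population = next_pop

    best = min(population, key=sort_key)
    best_terms = (candidate_terms[0],) + tuple(
        t for t, bit in zip(free_terms, best) if bit
    )
    model = fit_polynomial(data, response, best_terms, space=space)
    if settings.fitness == "cop_loo":
        # hat-matrix LOO identity: exact, avoids n explicit refits
        X_best = _design_matrix(norm.transform(data), best_terms)
        cop = q.squared_correlation(y, q.loo_predictions_ols(X_best, y))
        report = q.QualityReport(
            cod=q.cod(y, model.predict_frame(data), form="residual"),
            cop=cop,
            n=n,
            cv_scheme="loo",
            response=response,
            fold_assignments=tuple(range(n)),
        )
    else:
        report = q.cop_cv(
            data,
            response,
            _refit_procedure(best_terms, space, response),
            scheme="kfold",
            k=settings.kfold_k,
            seed=settings.seed,
            cod_predictions=model.predict_frame(data),
        )
    return replace(
        model,
        quality=report,
        provenance={
            "method": "gars",
            "n": n,
            "seed": settings.seed,
            "fitness": settings.fitness,
            "best_fitness": fitness(best),
            "candidate_terms": len(candidate_terms),
        },
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def save_model(model: PolynomialSurrogate, path: str | Path | None = None) -> str:
    """Serialize a fitted surrogate to versioned JSON; optionally write it."""
    doc = {
        "version": MODEL_FORMAT_VERSION,
        "region": model.region,
        "response": model.response,
        "terms": [list(t.exponents) for t in model.terms],
        "coefficients": list(model.coefficients),
        "normalization": [list(r) for r in model.normalization.ranges],
        "quality": model.quality.to_dict() if model.quality else None,
        "provenance": dict(model.provenance),
    }
    text = json.dumps(doc, indent=2)
    if path is not None:
        Path(path).write_text(text)
    return text


def load_model(source: str | Path) -> PolynomialSurrogate:
    """Load a surrogate from a JSON string or file; validates the schema."""
    if isinstance(source, Path):
        text = source.read_text()
    elif source.lstrip().startswith("{"):
        text = source
    else:
        text = Path(source).read_text()
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ValueError(f"invalid model JSON: {exc}") from exc
    required = {"version", "region", "response", "terms", "coefficients", "normalization"}
    missing = required - set(doc)
    if missing:
        raise ValueError(f"model document missing fields: {sorted(missing)}")
    if doc["version"] != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"unsupported model format version {doc['version']!r}; "
            f"this build reads version {MODEL_FORMAT_VERSION!r}"
        )
    quality_report = None
    if doc.get("quality"):
        qd = doc["quality"]
        quality_report = q.QualityReport(
            cod=qd["cod"],
            cop=qd["cop"],
            n=qd["n"],
            cv_scheme=qd["cv_scheme"],
            response=qd["response"],
            flags=tuple(qd.get("flags", ())),
        )
    return PolynomialSurrogate(
        region=doc["region"],
        response=doc["response"],
        terms=tuple(BasisTerm(tuple(e)) for e in doc["terms"]),
        coefficients=tuple(float(c) for c in doc["coefficients"]),
        normalization=Normalization(
            tuple((str(n_), float(lo), float(hi)) for n_, lo, hi in doc["normalization"])
        ),
        quality=quality_report,
        provenance=doc.get("provenance", {}),
    )
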