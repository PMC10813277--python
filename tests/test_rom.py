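"""Polynomial surrogate fitting, genetic term selection, and serialization."""

import itertools
import json
import math

import numpy as np
import pandas as pd
import pytest

import implantrom as ir
from implantrom import quality as q
from implantrom import rom
from implantrom.design_space import PlacementConfig
from implantrom.rom import BasisTerm, GarsSettings, Normalization


def norm_x(space, frame):
    return Normalization.from_space(space).transform(frame)


def make_frame(space, n, seed, response_fn=None):
    """Seeded random in-range placements; response from response_fn(x_norm)."""
    rng = np.random.default_rng(seed)
    data = {
        v.name: rng.uniform(v.lower, v.upper, size=n) for v in space.variables
    }
    frame = pd.DataFrame(data)
    frame["region"] = space.region
    if response_fn is not None:
        frame["y"] = response_fn(norm_x(space, frame))
    return frame


class TestBuildBasis:
    @pytest.mark.parametrize(
        "max_order,interactions,expected",
        [(2, True, 28), (1, True, 7), (2, False, 13), (1, False, 7)],
    )
    def test_term_counts(self, max_order, interactions, expected):
        assert len(rom.build_basis(max_order, interactions)) == expected

    def test_intercept_first_and_order_sorted(self):
        terms = rom.build_basis(2, True)
        assert terms[0].is_intercept
        orders = [t.order for t in terms]
        assert orders == sorted(orders)

    def test_deterministic_ordering(self):
        assert rom.build_basis(2, True) == rom.build_basis(2, True)

    def test_invalid_order_rejected(self):
        with pytest.raises(ValueError):
            rom.build_basis(0)


class TestFitPolynomial:
    def test_exact_linear_recovery(self, space):
        frame = make_frame(space, 12, seed=1, response_fn=lambda x: 2.0 + 3.0 * x[:, 0])
        terms = [BasisTerm((0,) * 6), BasisTerm((1, 0, 0, 0, 0, 0))]
        model = rom.fit_polynomial(frame, "y", terms, space=space)
        assert model.coefficients == pytest.approx((2.0, 3.0), abs=1e-10)
        assert model.quality.cod == pytest.approx(1.0)

    def test_coefficients_match_normal_equations_oracle(self, space):
        # 5-point quadratic toy set in one variable, oracle = explicit
        # normal-equations solve with hand-built design matrix
        lengths = np.array([8.5, 10.0, 11.5, 13.0, 15.0])
        frame = make_frame(space, 5, seed=2)
        frame["length"] = lengths
        y = np.array([3.0, 1.2, 0.7, 1.9, 4.4])
        frame["y"] = y
        terms = [
            BasisTerm((0,) * 6),
            BasisTerm((1, 0, 0, 0, 0, 0)),
            BasisTerm((2, 0, 0, 0, 0, 0)),
        ]
        xt = 2.0 * (lengths - 8.5) / (15.0 - 8.5) - 1.0
        X = np.column_stack([np.ones(5), xt, xt**2])
        beta_oracle = np.linalg.solve(X.T @ X, X.T @ y)
        model = rom.fit_polynomial(frame, "y", terms, space=space)
        assert np.allclose(model.coefficients, beta_oracle, atol=1e-9)

    def test_ols_optimality_under_coefficient_perturbation(self, space):
        frame = make_frame(
            space, 20, seed=3, response_fn=lambda x: 1.0 + x[:, 0] - 0.5 * x[:, 1]
        )
        frame["y"] += np.random.default_rng(4).normal(0, 0.2, size=20)
        terms = rom.build_basis(1, True)
        model = rom.fit_polynomial(frame, "y", terms, space=space)
        y = frame["y"].to_numpy()

        def sse(coeffs):
            perturbed = rom.PolynomialSurrogate(
                region=model.region,
                response=model.response,
                terms=model.terms,
                coefficients=tuple(coeffs),
                normalization=model.normalization,
            )
            return float(np.sum((y - perturbed.predict_frame(frame)) ** 2))

        base = sse(model.coefficients)
        for j in range(len(model.coefficients)):
            for delta in (-1e-2, 1e-2):
                bumped = list(model.coefficients)
                bumped[j] += delta
                assert sse(bumped) > base

    def test_rank_deficiency_names_collinear_terms(self, space):
        frame = make_frame(space, 10, seed=5, response_fn=lambda x: x[:, 0])
        dup = BasisTerm((1, 0, 0, 0, 0, 0))
        terms = [BasisTerm((0,) * 6), dup, dup]
        with pytest.raises(ValueError, match="collinear"):
            rom.fit_polynomial(frame, "y", terms, space=space)

    def test_fewer_rows_than_terms_rejected(self, space):
        frame = make_frame(space, 10, seed=6, response_fn=lambda x: x[:, 0])
        with pytest.raises(ValueError, match="rows as basis terms"):
            rom.fit_polynomial(frame, "y", rom.build_basis(2, True), space=space)

    def test_gars_subset_fit_on_l25_has_high_in_sample_cod(self, l25_table):
        model = rom.gars_select(
            l25_table, "cortical_stress_MPa", GarsSettings(seed=3)
        )
        assert model.quality.cod >= 0.95
        # in-sample round trip: predictions at the 25 design points track the
        # emulator responses closely
        pred = model.predict_frame(l25_table)
        obs = l25_table["cortical_stress_MPa"].to_numpy()
        assert q.squared_correlation(obs, pred) >= 0.95


class TestPredict:
    def test_intercept_only_model_is_constant(self, space, emulator):
        model = rom.PolynomialSurrogate(
            region="anterior",
            response="cortical_stress_MPa",
            terms=(BasisTerm((0,) * 6),),
            coefficients=(13.81,),
            normalization=Normalization.from_space(space),
        )
        assert rom.predict(model, emulator.baseline) == pytest.approx(13.81)

    def test_exact_fit_reproduces_generating_function_off_design(self, space):
        frame = make_frame(
            space, 15, seed=7, response_fn=lambda x: 4.0 - 2.0 * x[:, 2] + x[:, 5]
        )
        terms = [
            BasisTerm((0,) * 6),
            BasisTerm((0, 0, 1, 0, 0, 0)),
            BasisTerm((0, 0, 0, 0, 0, 1)),
        ]
        model = rom.fit_polynomial(frame, "y", terms, space=space)
        probe = make_frame(space, 8, seed=8)
        x = norm_x(space, probe)
        expected = 4.0 - 2.0 * x[:, 2] + x[:, 5]
        assert np.allclose(model.predict_frame(probe), expected, atol=1e-9)

    def test_extrapolation_warns_but_returns(self, space):
        frame = make_frame(space, 10, seed=9, response_fn=lambda x: x[:, 0])
        terms = [BasisTerm((0,) * 6), BasisTerm((1, 0, 0, 0, 0, 0))]
        model = rom.fit_polynomial(frame, "y", terms, space=space)
        outside = {v.name: v.upper for v in space.variables}
        outside["length"] = 16.5
        with pytest.warns(UserWarning, match="extrapolation"):
            value = rom.predict(model, PlacementConfig(outside, "anterior"))
        assert np.isfinite(value)

    def test_normalization_absorbs_unit_changes(self, space):
        # same data expressed with length in cm instead of mm: identical
        # normalized coordinates, hence identical predictions
        frame = make_frame(
            space, 14, seed=10, response_fn=lambda x: 1.0 + 0.5 * x[:, 0] - x[:, 3]
        )
        terms = rom.build_basis(1, True)
        model_mm = rom.fit_polynomial(frame, "y", terms, space=space)

        cm_vars = []
        for v in space.variables:
            levels = tuple(l / 10.0 for l in v.levels) if v.name == "length" else v.levels
            cm_vars.append(ir.DesignVariable(v.name, v.unit, levels))
        space_cm = ir.DesignSpace(tuple(cm_vars), region="anterior")
        frame_cm = frame.copy()
        frame_cm["length"] = frame_cm["length"] / 10.0
        model_cm = rom.fit_polynomial(frame_cm, "y", terms, space=space_cm)

        probe = make_frame(space, 6, seed=11)
        probe_cm = probe.copy()
        probe_cm["length"] = probe_cm["length"] / 10.0
        assert np.allclose(
            model_mm.predict_frame(probe), model_cm.predict_frame(probe_cm), atol=1e-9
        )


def exhaustive_best_subset(space, frame, candidate_terms):
    """Independent oracle: enumerate all subsets, score by explicit LOO-CoP
    refits, break ties toward fewer terms then lexicographic mask."""
    free = candidate_terms[1:]
    norm = Normalization.from_space(space)
    y = frame["y"].to_numpy()
    n = len(y)

    def loo_cop(terms):
        pooled = np.empty(n)
        Xall = np.column_stack(
            [np.prod(norm.transform(frame) ** np.array(t.exponents), axis=1) for t in terms]
        )
        for i in range(n):
            mask = np.arange(n) != i
            beta, *_ = np.linalg.lstsq(Xall[mask], y[mask], rcond=None)
            pooled[i] = Xall[i] @ beta
        r = min(max(np.corrcoef(y, pooled)[0, 1], 0.0), 1.0)
        return r * r

    best = None
    for mask in itertools.product((0, 1), repeat=len(free)):
        terms = (candidate_terms[0],) + tuple(t for t, b in zip(free, mask) if b)
        key = (-loo_cop(terms), sum(mask), mask)
        if best is None or key < best[0]:
            best = (key, terms)
    return best[1]


class TestGarsSelect:
    CANDIDATES = [
        BasisTerm((0, 0, 0, 0, 0, 0)),
        BasisTerm((1, 0, 0, 0, 0, 0)),
        BasisTerm((0, 1, 0, 0, 0, 0)),
        BasisTerm((1, 1, 0, 0, 0, 0)),
        BasisTerm((0, 2, 0, 0, 0, 0)),
    ]

    def test_matches_exhaustive_subset_oracle(self, space):
        def truth(x):
            return 1.0 + 2.0 * x[:, 0] - 1.5 * x[:, 1] ** 2

        frame = make_frame(space, 30, seed=12, response_fn=truth)
        frame["y"] += np.random.default_rng(13).normal(0, 0.1, size=30)
        oracle_terms = exhaustive_best_subset(space, frame, self.CANDIDATES)
        model = rom.gars_select(
            frame,
            "y",
            GarsSettings(population=12, generations=15, seed=0),
            space=space,
            candidate_terms=self.CANDIDATES,
        )
        assert model.terms == oracle_terms

    def test_recovers_sparse_structure_noise_free(self, space):
        active = {
            BasisTerm((1, 0, 0, 0, 0, 0)),
            BasisTerm((0, 0, 2, 0, 0, 0)),
            BasisTerm((0, 1, 0, 1, 0, 0)),
        }

        def truth(x):
            return 3.0 + 2.0 * x[:, 0] + 1.5 * x[:, 2] ** 2 - x[:, 1] * x[:, 3]

        frame = make_frame(space, 40, seed=14, response_fn=truth)
        model = rom.gars_select(
            frame, "y", GarsSettings(population=40, generations=40, seed=1), space=space
        )
        assert active <= set(model.terms)
        assert model.quality.cop >= 1.0 - 1e-6

    def test_seeded_determinism(self, l25_table):
        settings = GarsSettings(population=20, generations=10, seed=5)
        a = rom.gars_select(l25_table, "cortical_stress_MPa", settings)
        b = rom.gars_select(l25_table, "cortical_stress_MPa", settings)
        assert a.terms == b.terms
        assert a.coefficients == b.coefficients

    def test_evolution_never_worse_than_initial_population(self, l25_table):
        base = GarsSettings(population=20, generations=0, seed=8)
        evolved = GarsSettings(population=20, generations=20, seed=8)
        f0 = rom.gars_select(l25_table, "cortical_stress_MPa", base).provenance[
            "best_fitness"
        ]
        f1 = rom.gars_select(l25_table, "cortical_stress_MPa", evolved).provenance[
            "best_fitness"
        ]
        assert f1 >= f0

    def test_beats_full_basis_prognosis_on_noisy_sparse_truth(self, space):
        """One-sided sign test over 20 seeds: subset selection should out-predict
        the saturated 28-term quadratic on sparse-truth data with noise."""

        def truth(x):
            return 5.0 + 2.0 * x[:, 0] - 3.0 * x[:, 1] + 1.5 * x[:, 0] * x[:, 1]

        full_terms = rom.build_basis(2, True)
        wins = losses = 0
        for seed in range(20):
            frame = make_frame(space, 35, seed=100 + seed, response_fn=truth)
            frame["y"] += np.random.default_rng(200 + seed).normal(0, 0.4, size=35)
            gars = rom.gars_select(
                frame,
                "y",
                GarsSettings(population=24, generations=25, seed=seed),
                space=space,
            )
            full_report = q.cop_cv(
                frame, "y", rom._refit_procedure(full_terms, space, "y"), scheme="loo"
            )
            if gars.quality.cop > full_report.cop:
                wins += 1
            elif gars.quality.cop < full_report.cop:
                losses += 1
        n = wins + losses
        # exact one-sided binomial tail under p = 1/2
        p = sum(math.comb(n, i) for i in range(wins, n + 1)) / 2**n
        assert p < 0.05, f"wins={wins}, losses={losses}, p={p:.4f}"

    def test_infeasible_oversized_population_does_not_crash(self, space):
        frame = make_frame(space, 8, seed=15, response_fn=lambda x: 1.0 + x[:, 0])
        model = rom.gars_select(
            frame,
            "y",
            GarsSettings(population=8, generations=5, seed=2),
            space=space,
        )
        assert len(model.terms) <= len(frame)


class TestSerialization:
    def test_round_trip_predicts_identically_on_l25(self, space, l25_table, tmp_path):
        model = rom.gars_select(
            l25_table, "cortical_stress_MPa", GarsSettings(population=20, generations=10, seed=5)
        )
        path = tmp_path / "model.json"
        rom.save_model(model, path)
        loaded = rom.load_model(path)
        assert np.allclose(
            model.predict_frame(l25_table), loaded.predict_frame(l25_table), atol=0
        )
        assert loaded.quality.cop == pytest.approx(model.quality.cop)

    def test_document_carries_version_tag(self, space, l25_table):
        model = rom.fit_polynomial(
            l25_table, "cortical_stress_MPa", rom.build_basis(1, True)
        )
        doc = json.loads(rom.save_model(model))
        assert doc["version"] == rom.MODEL_FORMAT_VERSION

    def test_truncated_json_rejected(self, l25_table):
        model = rom.fit_polynomial(
            l25_table, "cortical_stress_MPa", rom.build_basis(1, True)
        )
        text = rom.save_model(model)
        with pytest.raises(ValueError, match="invalid model JSON"):
            rom.load_model(text[: len(text) // 2])

    def test_unknown_version_rejected(self, l25_table):
        model = rom.fit_polynomial(
            l25_table, "cortical_stress_MPa", rom.build_basis(1, True)
        )
        doc = json.loads(rom.save_model(model))
        doc["version"] = "99"
        with pytest.raises(ValueError, match="version"):
            rom.load_model(json.dumps(doc))

    def test_missing_fields_rejected(self):
        with pytest.raises(ValueError, match="missing fields"):
            rom.load_model(json.dumps({"version": "1"}))
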