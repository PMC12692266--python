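"""Sobol estimators against analytic oracles; local sensitivity coefficients."""

import numpy as np
import pytest

from glycoforge.sensitivity import (local_sensitivity, sobol_indices,
                                    sobol_sample)


def _evaluate(design, f):
    y_a = np.array([f(x) for x in design.A])
    y_b = np.array([f(x) for x in design.B])
    y_ab = np.array([[f(x) for x in design.AB[j]]
                     for j in range(len(design.names))])
    return y_a, y_b, y_ab


class TestSobolSampling:
    def test_reproducible_for_fixed_seed(self):
        r = {"a": (0.0, 1.0), "b": (2.0, 4.0)}
        d1 = sobol_sample(r, 64, seed=5)
        d2 = sobol_sample(r, 64, seed=5)
        assert np.array_equal(d1.A, d2.A) and np.array_equal(d1.B, d2.B)

    def test_samples_stay_within_ranges(self):
        d = sobol_sample({"x": (0.5, 1.5)}, 1000, seed=0)
        assert d.A.min() >= 0.5 and d.A.max() <= 1.5

    def test_uniform_moments(self):
        # mean of U(lo, hi) is the midpoint, within 3 standard errors
        lo, hi = 0.5, 1.5
        n = 4000
        d = sobol_sample({"x": (lo, hi)}, n, seed=1)
        se = (hi - lo) / np.sqrt(12 * n)
        assert abs(d.A.mean() - 1.0) < 3 * se

    def test_degenerate_range_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="degenerate"):
            d = sobol_sample({"x": (0.0, 1.0), "y": (2.0, 2.0)}, 16, seed=0)
        assert d.names == ("x",) and d.excluded == ("y",)

    def test_evaluation_budget(self):
        d = sobol_sample({"a": (0, 1), "b": (0, 1), "c": (0, 1)}, 100, seed=0)
        assert d.n_evaluations == (2 + 3) * 100


class TestSobolIndices:
    def test_linear_two_input_model(self):
        """Y = X1 + 2 X2 on equal uniform ranges: S1 = 0.2, S2 = 0.8.

        Low-discrepancy sampling keeps the estimator error well inside the
        0.02 band at N = 10,000 for every seed.
        """
        d = sobol_sample({"x1": (0.0, 1.0), "x2": (0.0, 1.0)}, 10_000, seed=2,
                         sampler="qmc")
        y_a, y_b, y_ab = _evaluate(d, lambda x: x[0] + 2.0 * x[1])
        S, ST, valid = sobol_indices(y_a, y_b, y_ab)
        assert valid.all()
        assert S[0, 0] == pytest.approx(0.2, abs=0.02)
        assert S[1, 0] == pytest.approx(0.8, abs=0.02)
        assert ST[0, 0] == pytest.approx(0.2, abs=0.02)
        assert ST[1, 0] == pytest.approx(0.8, abs=0.02)

    def test_inactive_input_has_null_indices(self):
        d = sobol_sample({"x1": (0.0, 1.0), "x2": (0.0, 1.0)}, 4000, seed=3)
        y_a, y_b, y_ab = _evaluate(d, lambda x: 3.0 * x[0])
        S, ST, _ = sobol_indices(y_a, y_b, y_ab)
        assert abs(S[1, 0]) < 0.02 and ST[1, 0] < 0.02

    def test_ishigami_closed_forms(self):
        """Ishigami function (a=7, b=0.1): standard analytic indices."""
        a, b = 7.0, 0.1
        lo, hi = -np.pi, np.pi
        d = sobol_sample({f"x{i}": (lo, hi) for i in (1, 2, 3)}, 10_000, seed=4,
                         sampler="qmc")

        def ishigami(x):
            return (np.sin(x[0]) + a * np.sin(x[1]) ** 2
                    + b * x[2] ** 4 * np.sin(x[0]))

        y_a, y_b, y_ab = _evaluate(d, ishigami)
        S, ST, _ = sobol_indices(y_a, y_b, y_ab)
        v1 = 0.5 * (1 + b * np.pi ** 4 / 5) ** 2
        v2 = a ** 2 / 8
        v13 = b ** 2 * np.pi ** 8 * (1 / 18 - 1 / 50)
        var = v1 + v2 + v13
        expect_s = np.array([v1 / var, v2 / var, 0.0])
        expect_st = np.array([(v1 + v13) / var, v2 / var, v13 / var])
        assert S[:, 0] == pytest.approx(expect_s, abs=0.05)
        assert ST[:, 0] == pytest.approx(expect_st, abs=0.05)

    def test_estimator_consistency_with_sample_size(self):
        """Indices at N = 10,000 and N = 40,000 differ by < 0.03."""
        def f(x):
            return x[0] * x[1] + 0.5 * x[2]

        ranges = {f"x{i}": (0.0, 1.0) for i in (1, 2, 3)}
        out = []
        for n, seed in ((10_000, 6), (40_000, 7)):
            d = sobol_sample(ranges, n, seed=seed)
            S, ST, _ = sobol_indices(*_evaluate(d, f))
            out.append((S[:, 0], ST[:, 0]))
        assert np.abs(out[0][0] - out[1][0]).max() < 0.03
        assert np.abs(out[0][1] - out[1][1]).max() < 0.03

    def test_constant_output_excluded(self):
        d = sobol_sample({"x": (0.0, 1.0)}, 500, seed=8)
        y_a, y_b, y_ab = _evaluate(d, lambda x: 3.0)
        S, ST, valid = sobol_indices(y_a, y_b, y_ab)
        assert not valid[0]
        assert np.isnan(S).all() and np.isnan(ST).all()


class TestLocalSensitivity:
    def test_linear_map_has_unit_coefficient(self):
        for da in (0.5, 0.01, 1e-6):
            assert local_sensitivity(lambda a: 4.2 * a, 3.0,
                                     delta_rel=da) == pytest.approx(1.0)

    def test_independent_output_is_zero(self):
        assert local_sensitivity(lambda a: 7.7, 2.0) == 0.0

    def test_quadratic_limit_is_two(self):
        ss = local_sensitivity(lambda a: a ** 2, 1.5, delta_rel=1e-7)
        assert ss == pytest.approx(2.0, abs=1e-5)

    def test_zero_parameter_rejected(self):
        with pytest.raises(ValueError):
            local_sensitivity(lambda a: a, 0.0)

    def test_zero_baseline_reported_as_nan(self):
        assert np.isnan(local_sensitivity(lambda a: a - 1.0, 1.0))


class TestModelSensitivity:
    def test_dominant_enzymes_match_biosynthesis_roles(self, model, compiled):
        """At the median point, galactosylation controls the FA2/FA2G2 peaks
        and GnT I controls the oligomannose peak."""
        from glycoforge.sensitivity import enzyme_sensitivity

        rep = enzyme_sensitivity(model, n_samples=256, seed=3,
                                 compiled=compiled)
        assert rep.dominant_enzyme("GP14") == "GalT"
        assert rep.dominant_enzyme("GP4") == "GalT"
        assert rep.dominant_enzyme("GP5") == "GnTI"
        assert rep.dominant_enzyme("GP23") == "SiaT"

    def test_local_sensitivities_reflect_substrate_product_roles(
            self, model, compiled):
        from glycoforge.sensitivity import local_enzyme_sensitivity

        ss = local_enzyme_sensitivity(model, compiled=compiled)
        assert ss.loc["GP14", "GalT"] > 0     # GalT makes FA2G2
        assert ss.loc["GP4", "GalT"] < 0      # and consumes FA2
        assert ss.loc["GP5", "GnTI"] < 0      # GnT I consumes M5
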