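"""Agreement statistics: Dice, fixed-shift circle model, regression, B-A."""

import numpy as np
import pytest

from ezseg import evalstats, metrics, phantom
from ezseg.evalstats import (DegenerateInputError, ShiftModelParams,
                             bland_altman, correlation_regression, dice,
                             fixed_shift_dsc, macular_circle_area,
                             subgroup_label)


def mc_circle_dice(area, shift, n=10**6, seed=0):
    """Monte-Carlo oracle: Dice of two equal circles at a lateral shift,
    estimated by uniform sampling over a box covering both circles."""
    r = np.sqrt(area / np.pi)
    rng = np.random.default_rng(seed)
    lo, hi = -r, shift + r
    pts = rng.uniform(lo, hi, size=(n, 2))
    pts[:, 1] = rng.uniform(-r, r, size=n)
    in_a = (pts[:, 0] ** 2 + pts[:, 1] ** 2) <= r * r
    in_b = ((pts[:, 0] - shift) ** 2 + pts[:, 1] ** 2) <= r * r
    inter = (in_a & in_b).mean()
    a = in_a.mean()
    b = in_b.mean()
    if a + b == 0:
        return 0.0
    return 2 * inter / (a + b)


class TestDice:
    def test_identical_maps(self):
        m = np.zeros((4, 5), bool)
        m[1:3, 1:4] = True
        assert dice(m, m) == 1.0

    def test_disjoint_maps(self):
        a = np.zeros((4, 4), bool)
        b = np.zeros((4, 4), bool)
        a[0, 0] = b[3, 3] = True
        assert dice(a, b) == 0.0

    def test_direct_formula(self):
        a = np.array([[1, 1, 0, 0]], bool)
        b = np.array([[0, 1, 1, 0]], bool)
        assert dice(a, b) == 0.5

    def test_symmetry(self, rng):
        a = rng.random((8, 8)) > 0.5
        b = rng.random((8, 8)) > 0.5
        assert dice(a, b) == dice(b, a)

    def test_errors(self):
        with pytest.raises(ValueError):
            dice(np.zeros((2, 2), bool), np.zeros((3, 3), bool))
        with pytest.raises(DegenerateInputError):
            dice(np.zeros((2, 2), bool), np.zeros((2, 2), bool))


class TestFixedShiftModel:
    def test_zero_shift_gives_one(self):
        assert fixed_shift_dsc(ShiftModelParams(0.0, 5.0)) == 1.0

    def test_tangent_circles_give_zero(self):
        assert fixed_shift_dsc(ShiftModelParams(2.0, np.pi)) == 0.0

    def test_unit_circles_shift_one(self):
        # lens-area formula vs Monte-Carlo rasterisation oracle
        got = fixed_shift_dsc(ShiftModelParams(1.0, np.pi))
        assert got == pytest.approx(0.391, abs=0.005)
        assert got == pytest.approx(mc_circle_dice(np.pi, 1.0), abs=0.01)

    def test_monotone_in_area_and_shift(self):
        areas = np.linspace(0.5, 30, 12)
        d = 0.315
        vals = [fixed_shift_dsc(ShiftModelParams(d, a)) for a in areas]
        assert all(np.diff(vals) >= 0)
        shifts = np.linspace(0, 3, 10)
        vals2 = [fixed_shift_dsc(ShiftModelParams(s, 7.0)) for s in shifts]
        assert all(np.diff(vals2) <= 0)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            ShiftModelParams(-0.1, 1.0)
        with pytest.raises(ValueError):
            ShiftModelParams(0.1, 0.0)


class TestCorrelationRegression:
    def test_perfect_linear_relation(self):
        x = np.arange(1.0, 6.0)
        res = correlation_regression(x, 2 * x)
        assert res.r == pytest.approx(1.0)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(0.0, abs=1e-12)
        assert res.r2 == pytest.approx(res.r ** 2)

    def test_antisymmetry_under_sign_flip(self):
        rng = np.random.default_rng(2)
        x = rng.random(20)
        y = 3 * x + rng.normal(0, 0.1, 20)
        a = correlation_regression(x, y)
        b = correlation_regression(-x, y)
        assert b.r == pytest.approx(-a.r)
        assert b.slope == pytest.approx(-a.slope)

    def test_against_closed_form_ols(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.1, 1.9, 3.2, 3.8])
        res = correlation_regression(x, y)
        # hand OLS: slope = Sxy/Sxx with the usual t-based 95% CI
        xm, ym = x.mean(), y.mean()
        sxx = ((x - xm) ** 2).sum()
        slope = ((x - xm) * (y - ym)).sum() / sxx
        resid = y - (ym + slope * (x - xm))
        se = np.sqrt((resid ** 2).sum() / 2 / sxx)
        from scipy import stats

        tcrit = stats.t.ppf(0.975, 2)
        assert res.slope == pytest.approx(slope)
        assert res.slope_ci[0] == pytest.approx(slope - tcrit * se)
        assert res.slope_ci[1] == pytest.approx(slope + tcrit * se)
        assert res.r_ci[0] < res.r < res.r_ci[1]

    def test_degenerate_inputs(self):
        with pytest.raises(DegenerateInputError):
            correlation_regression([1, 2], [1, 2])
        with pytest.raises(DegenerateInputError):
            correlation_regression([1, 1, 1], [1, 2, 3])


class TestBlandAltman:
    def test_identical_series_all_zero(self):
        x = np.array([1.0, 2.0, 3.0])
        ba = bland_altman(x, x)
        assert ba.mean_diff == 0 and ba.sd_diff == 0 and ba.cor == 0
        assert ba.limits == (0, 0) and ba.mean_abs_error == 0

    def test_hand_arithmetic(self):
        ba = bland_altman(np.array([1.0, 2.0, 3.0]), np.array([1.0, 1.0, 1.0]))
        # differences (0, 1, 2): mean 1, SD 1, CoR 1.96
        assert ba.mean_diff == pytest.approx(1.0)
        assert ba.sd_diff == pytest.approx(1.0)
        assert ba.cor == pytest.approx(1.96)
        assert ba.se_diff == pytest.approx(1 / np.sqrt(3))
        assert ba.limits == (pytest.approx(-0.96), pytest.approx(2.96))

    def test_swap_antisymmetry(self, rng):
        x, y = rng.random(15), rng.random(15)
        a, b = bland_altman(x, y), bland_altman(y, x)
        assert b.mean_diff == pytest.approx(-a.mean_diff)
        assert b.sd_diff == pytest.approx(a.sd_diff)
        assert b.cor == pytest.approx(a.cor)

    def test_cor_is_196_sd_always(self, rng):
        for _ in range(5):
            x, y = rng.random(9), rng.random(9)
            ba = bland_altman(x, y)
            assert ba.cor == pytest.approx(1.96 * ba.sd_diff, rel=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            bland_altman([1.0, 2.0], [1.0])


class TestSubgroups:
    @pytest.mark.parametrize("area,label", [
        (0.0, "very_small"), (0.5, "very_small"), (0.999, "very_small"),
        (1.0, "small"), (6.9, "small"), (7.0, "medium"), (29.9, "medium"),
        (30.0, "large"), (50.0, "large")])
    def test_etdrs_cuts(self, area, label):
        assert subgroup_label(area) == label

    def test_negative_area_rejected(self):
        with pytest.raises(ValueError):
            subgroup_label(-1.0)

    def test_macular_reference_circles(self):
        assert macular_circle_area(3.0) == pytest.approx(np.pi * 9)
        assert macular_circle_area(1.5) == pytest.approx(np.pi * 2.25)


class TestEndToEndParameterRecovery:
    def test_ground_truth_areas_recover_analytic(self, rng):
        """EZ areas measured from ground-truth boundaries of 20 phantoms
        (footprints 0.5-40 mm^2) track the analytic areas: r > 0.999,
        slope within [0.98, 1.02]."""
        g = phantom.ScanGeometry(n_cols=384, n_rows=256, n_lines=61)
        measured, analytic = [], []
        for area in np.linspace(0.5, 40, 20):
            ecc = rng.uniform(0.85, 1.15)
            a = float(np.sqrt(area / np.pi) * ecc)
            b = float(area / np.pi / a)
            spec = phantom.PhantomSpec.flat(
                g, rows=(50, 120, 150, 170, 180),
                ez_center_mm=(4.5, 4.5), ez_semi_axes_mm=(a, b),
                noise_level=0.0)
            presence = phantom.ez_footprint_mask(spec, np.arange(g.n_lines))
            measured.append(metrics.ez_area_from_presence(presence, g))
            analytic.append(spec.analytic_footprint_area)
        res = correlation_regression(measured, analytic)
        assert res.r > 0.999
        assert 0.98 <= res.slope <= 1.02

    def test_evaluate_combines_reports(self, rng):
        x = rng.random(12) * 10
        y = x + rng.normal(0, 0.2, 12)
        maps_a = [rng.random((5, 5)) > 0.4 for _ in range(3)]
        rep = evalstats.evaluate(x, y, maps_a, maps_a)
        assert rep.dice_per_scan == [1.0, 1.0, 1.0]
        assert rep.to_dict()["regression"]["n"] == 12
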