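"""Calibration: regression fits, quartic composition, sweep structure."""

import numpy as np
import pytest

from wiop.calibration import (PUBLISHED_EQ5, PUBLISHED_EQ6,
                              PUBLISHED_WIOP_QUARTIC, WiopCalibration,
                              compose_wiop, fit_quadratic, table1_cases)


def round_sig(x, n):
    if x == 0:
        return 0.0
    from math import floor, log10
    return round(x, -int(floor(log10(abs(x)))) + n - 1)


class TestFitQuadratic:
    def test_exact_quadratic_recovered(self):
        x = np.linspace(-2, 3, 7)
        y = 1.7 * x ** 2 - 0.3 * x + 4.0
        (a, b, c), r2 = fit_quadratic(x, y)
        assert (a, b, c) == pytest.approx((1.7, -0.3, 4.0), abs=1e-10)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_noisy_published_polynomial_recovered(self, rng):
        """Points from the published pressurization quadratic with 1%
        noise: coefficients recovered within 5%."""
        a, b, c = PUBLISHED_EQ5
        x = np.linspace(0.0, 0.12, 12)     # the work range the quadratic spans
        y = a * x ** 2 + b * x + c
        y = y * (1 + 0.01 * rng.standard_normal(len(y)))
        (af, bf, cf), r2 = fit_quadratic(x, y)
        assert af == pytest.approx(a, rel=0.10)    # curvature is noise-sensitive
        assert bf == pytest.approx(b, rel=0.05)
        assert cf == pytest.approx(c, rel=0.05)
        assert r2 > 0.99

    def test_constant_data_gives_zero_slopes(self):
        x = np.linspace(0, 1, 5)
        (a, b, c), r2 = fit_quadratic(x, np.full(5, 2.5))
        assert abs(a) < 1e-10 and abs(b) < 1e-10
        assert c == pytest.approx(2.5)

    def test_rank_deficient_design_rejected(self):
        with pytest.raises(ValueError):
            fit_quadratic([1.0, 1.0, 1.0, 1.0], [1, 2, 3, 4])
        with pytest.raises(ValueError):
            fit_quadratic([1.0, 2.0], [1, 2])


class TestComposeWiop:
    def test_identity_like_composition(self):
        assert compose_wiop((0, 1, 0), (0, 1, 0)) == (0, 0, 0, 1, 0)

    def test_published_coefficients_compose_to_published_quartic(self):
        """Substituting the printed timing quadratic into the printed
        pressurization quadratic reproduces the printed quartic at its
        printed precision."""
        q = compose_wiop(PUBLISHED_EQ5, PUBLISHED_EQ6)
        for got, printed in zip(q[:4], PUBLISHED_WIOP_QUARTIC[:4]):
            assert round_sig(got, 3) == pytest.approx(printed)
        assert round(q[4], 2) == pytest.approx(PUBLISHED_WIOP_QUARTIC[4])

    def test_pointwise_equals_nested_evaluation(self, rng):
        for _ in range(20):
            eq5 = tuple(rng.standard_normal(3))
            eq6 = tuple(rng.standard_normal(3))
            q = compose_wiop(eq5, eq6)
            for t in rng.uniform(-3, 3, 5):
                inner = np.polyval(eq6, t)
                expected = np.polyval(eq5, inner)
                got = np.polyval(q, t)
                assert got == pytest.approx(expected, rel=1e-12, abs=1e-12)


class TestTable1Design:
    def test_sixteen_cases_with_expected_structure(self):
        cases = table1_cases()
        assert len(cases) == 16
        assert [c.iop_mmhg for c in cases[:5]] == [10, 15, 20, 25, 30]
        assert all(c.iop_mmhg == 15.0 for c in cases[5:])
        assert {c.cct_um for c in cases[13:]} == {484.0, 525.0, 600.0}
        assert all(c.varies == "material" for c in cases[5:13])


class TestSweepStructure:
    """Structural claims of the sixteen-case sweep (shared session run)."""

    def test_all_cases_complete(self, sweep_df):
        assert len(sweep_df) == 16
        assert sweep_df.initial_work_mJ.notna().all()

    def test_intersection_time_monotone_in_iop(self, sweep_df):
        iop_rows = sweep_df[sweep_df.varies == "iop"].sort_values("iop_mmhg")
        t = iop_rows.t_intersection_ms.to_numpy()
        assert np.all(np.diff(t) > 0)

    def test_maxvel_time_monotone_in_iop(self, sweep_df):
        iop_rows = sweep_df[sweep_df.varies == "iop"].sort_values("iop_mmhg")
        assert np.all(np.diff(iop_rows.t_maxvel_ms.to_numpy()) > 0)

    def test_material_and_cct_spread_much_smaller_than_iop_spread(self, sweep_df):
        """The intersection time is (nearly) material- and
        thickness-independent: its coefficient of variation across the
        material/CCT rows stays below one third of the CV across the IOP
        rows."""
        t_iop = sweep_df.t_intersection_ms[sweep_df.varies == "iop"]
        t_mat = sweep_df.t_intersection_ms[sweep_df.varies != "iop"]
        cv_iop = t_iop.std(ddof=1) / t_iop.mean()
        cv_mat = t_mat.std(ddof=1) / t_mat.mean()
        assert cv_mat < cv_iop / 3.0

    def test_fit_produces_tight_quadratics(self, sweep_df):
        results = WiopCalibration(sweep_df).fit()
        c = results.calibration
        assert c.eq5_r2 >= 0.98
        assert c.eq6_r2 >= 0.95
        assert c.t_range[0] < c.t_range[1]
        # composed quartic equals the nested evaluation
        for t in np.linspace(*c.t_range, 7):
            nested = np.polyval(c.eq5_coeffs, np.polyval(c.eq6_coeffs, t))
            assert results.predict(t) == pytest.approx(nested, rel=1e-12)

    def test_summary_mentions_key_quantities(self, sweep_df):
        text = WiopCalibration(sweep_df).fit().summary()
        assert "R^2" in text and "quartic" in text


def test_calibration_json_roundtrip(tmp_path):
    from wiop.calibration import CalibrationFit
    fit = CalibrationFit(eq5_coeffs=PUBLISHED_EQ5, eq6_coeffs=PUBLISHED_EQ6,
                         eq5_r2=0.98, eq6_r2=0.98, t_range=(5.0, 11.0))
    path = tmp_path / "cal.json"
    fit.to_json(path)
    back = CalibrationFit.from_json(path)
    assert back.eq5_coeffs == tuple(PUBLISHED_EQ5)
    assert back.quartic == pytest.approx(fit.quartic)
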