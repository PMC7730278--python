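"""Dose-response arithmetic: viability, interpolation, indices, tests."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings, strategies as st

import invresist as ir
from invresist.cytotox import GRID_LEVELS

from conftest import make_well_data


def curve_from_points(pairs, line="L", drug="PTX", unit="nM"):
    pts = pd.DataFrame(
        [(c, v, 0.0, 4) for c, v in pairs],
        columns=["conc", "mean_viab", "sd", "n"],
    )
    return ir.ViabilityCurve(line, drug, unit, pts)


class TestPercentViability:
    def test_control_equal_treated_gives_100(self, noiseless_cfg):
        """If drug wells behave exactly like controls, viability is 100%."""
        plate = ir.simulate_plate(noiseless_cfg, "A2780", "PTX")
        lay = plate.layout
        ctrl_mask = lay["role"] == "control"
        r0, c0 = lay.loc[ctrl_mask, ["row", "col"]].iloc[0]
        for rec in lay[lay["role"] == "drug"].itertuples(index=False):
            plate.a570.at[rec.row, rec.col] = plate.a570.at[r0, c0]
            plate.a600.at[rec.row, rec.col] = plate.a600.at[r0, c0]
        curve = ir.percent_viability(plate)
        assert np.allclose(curve.points["mean_viab"], 100.0)

    def test_half_reduction_gives_50(self, noiseless_cfg):
        """Treated dye reduction at half the control level reads 50%."""
        from invresist.simulate import _absorbance_from_reduction, _CONTROL_REDUCTION
        plate = ir.simulate_plate(noiseless_cfg, "A2780", "PTX")
        lay = plate.layout
        half = _CONTROL_REDUCTION / 2.0
        a570, a600 = _absorbance_from_reduction(np.array([half]))
        for rec in lay[lay["role"] == "drug"].itertuples(index=False):
            plate.a570.at[rec.row, rec.col] = a570[0]
            plate.a600.at[rec.row, rec.col] = a600[0]
        curve = ir.percent_viability(plate)
        assert np.allclose(curve.points["mean_viab"], 50.0, atol=1e-9)

    def test_noiseless_viability_matches_logistic(self, noiseless_cfg):
        plate = ir.simulate_plate(noiseless_cfg, "A8PTX", "CDDP")
        curve = ir.percent_viability(plate)
        expected = ir.logistic_viability(
            curve.points["conc"], noiseless_cfg.true_ic50[("A8PTX", "CDDP")],
            noiseless_cfg.hill_slope,
        )
        assert np.allclose(curve.points["mean_viab"], expected, atol=1e-9)

    def test_degenerate_plate_raises(self, noiseless_cfg):
        plate = ir.simulate_plate(noiseless_cfg, "A2780", "PTX")
        lay = plate.layout
        blank_vals_570 = plate.a570.copy()
        for rec in lay[lay["role"] == "control"].itertuples(index=False):
            b = lay[lay["role"] == "blank"].iloc[0]
            plate.a570.at[rec.row, rec.col] = blank_vals_570.at[b.row, b.col]
            plate.a600.at[rec.row, rec.col] = plate.a600.at[b.row, b.col]
        with pytest.raises(ir.DegeneratePlateError):
            ir.percent_viability(plate)


class TestViabilityGrid:
    def test_midpoint(self):
        curve = curve_from_points([(1.0, 60.0), (3.0, 40.0)])
        grid = ir.viability_grid(curve, levels=(50.0,))
        assert grid.conc_at_level[50.0] == pytest.approx(2.0)

    def test_observed_level_returns_observed_concentration(self):
        curve = curve_from_points([(1.0, 80.0), (2.0, 60.0), (4.0, 30.0)])
        grid = ir.viability_grid(curve, levels=(60.0,))
        assert grid.conc_at_level[60.0] == 2.0

    def test_unbracketed_level_is_nan(self):
        curve = curve_from_points([(1.0, 80.0), (2.0, 60.0)])
        grid = ir.viability_grid(curve, levels=(20.0,))
        assert np.isnan(grid.conc_at_level[20.0])

    def test_extrapolation_extends_terminal_segment(self):
        curve = curve_from_points([(1.0, 80.0), (2.0, 60.0)])
        grid = ir.viability_grid(curve, levels=(40.0,), extrapolate=True)
        assert grid.conc_at_level[40.0] == pytest.approx(3.0)

    def test_duplicate_concentrations_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            curve_from_points([(1.0, 80.0), (1.0, 60.0)])

    def test_multi_crossing_warns_and_uses_first(self):
        curve = curve_from_points(
            [(1.0, 80.0), (2.0, 40.0), (3.0, 60.0), (4.0, 20.0)]
        )
        with pytest.warns(ir.MultiCrossingWarning):
            grid = ir.viability_grid(curve, levels=(50.0,))
        assert 1.0 < grid.conc_at_level[50.0] < 2.0

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.floats(1.0, 99.0), min_size=2, max_size=10, unique=True))
    def test_piecewise_linear_exactness(self, viabs):
        """Re-evaluating the interpolant at each grid concentration
        reproduces the requested level to machine precision."""
        concs = np.arange(1.0, len(viabs) + 1.0)
        viabs = np.array(viabs)
        curve = curve_from_points(list(zip(concs, viabs)))
        import warnings as w
        with w.catch_warnings():
            w.simplefilter("ignore", ir.MultiCrossingWarning)
            grid = ir.viability_grid(curve, levels=GRID_LEVELS)
        for level, conc in grid.conc_at_level.items():
            if np.isnan(conc):
                continue
            back = np.interp(conc, concs, viabs)
            # only the first crossing is returned; np.interp evaluates the
            # same piecewise-linear function, so the level must match there
            seg = np.searchsorted(concs, conc, side="right") - 1
            seg = min(seg, len(concs) - 2)
            y1, y2 = viabs[seg], viabs[seg + 1]
            if min(y1, y2) <= level <= max(y1, y2):
                assert back == pytest.approx(level, abs=1e-9)

    def test_noiseless_4pl_grid_roundtrip_within_oracle_bound(self, noiseless_cfg):
        """All 8 levels: plugging each grid concentration back into the
        logistic recovers the level within the secant linearisation error
        computed by a dense-grid oracle."""
        key = ("A16PTX", "PTX")
        plate = ir.simulate_plate(noiseless_cfg, *key)
        curve = ir.percent_viability(plate)
        grid = ir.viability_grid(curve)
        true, hill = noiseless_cfg.true_ic50[key], noiseless_cfg.hill_slope
        concs = curve.points["conc"].to_numpy()
        viabs = curve.points["mean_viab"].to_numpy()
        for level, conc in grid.conc_at_level.items():
            if np.isnan(conc):
                continue
            back = ir.logistic_viability(conc, true, hill)
            i = np.searchsorted(-viabs, -level) - 1
            i = np.clip(i, 0, len(concs) - 2)
            dense = np.linspace(concs[i], concs[i + 1], 5001)
            secant = np.interp(dense, concs, viabs)
            exact = ir.logistic_viability(dense, true, hill)
            bound = np.abs(secant - exact).max()
            assert abs(back - level) <= bound + 1e-9


class TestIC50AndPIC50:
    def test_simple_bracket(self):
        assert ir.ic50(curve_from_points([(1.0, 60.0), (3.0, 40.0)])) == pytest.approx(2.0)

    def test_never_crossing_raises(self):
        curve = curve_from_points([(1.0, 95.0), (2.0, 85.0), (3.0, 75.0)])
        with pytest.raises(ir.BracketError):
            ir.ic50(curve)

    @pytest.mark.parametrize(
        "value,unit,expected",
        [(1.0, "uM", 6.0), (1.0, "nM", 9.0), (4.62, "nM", 8.3354)],
    )
    def test_pic50_values(self, value, unit, expected):
        assert ir.pic50(value, unit) == pytest.approx(expected, abs=5e-5)

    def test_pic50_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            ir.pic50(0.0, "nM")

    def test_pic50_strictly_decreasing_in_ic50(self):
        vals = [ir.pic50(x, "nM") for x in (0.5, 1.0, 5.0, 50.0)]
        assert all(a > b for a, b in zip(vals, vals[1:]))


class TestIndices:
    def test_reported_index_examples(self):
        assert ir.round_half_away(ir.resistance_index(77.54, 4.62)) == 16.78
        assert ir.round_half_away(ir.sensitivity_index(4.58, 0.65)) == 7.05

    def test_reference_to_itself_is_one(self):
        assert ir.resistance_index(4.62, 4.62) == 1.0
        assert ir.sensitivity_index(4.58, 4.58) == 1.0

    def test_scale_invariance(self):
        for c in (0.1, 3.7, 1e3):
            assert ir.resistance_index(77.54 * c, 4.62 * c) == pytest.approx(
                ir.resistance_index(77.54, 4.62)
            )
            assert ir.sensitivity_index(4.58 * c, 0.65 * c) == pytest.approx(
                ir.sensitivity_index(4.58, 0.65)
            )

    def test_unit_mismatch_rejected(self):
        with pytest.raises(ValueError, match="unit"):
            ir.resistance_index(1.0, 1.0, unit_sub="nM", unit_ref="uM")

    def test_rounding_half_away_from_zero(self):
        assert ir.round_half_away(2.475, 2) == 2.48
        assert ir.round_half_away(-2.475, 2) == -2.48
        assert ir.round_half_away(1.005, 2) == 1.01


class TestFoldChanges:
    def test_reported_consecutive_folds(self):
        ptx = {"A2780": 4.62, "A8PTX": 18.71, "A16PTX": 77.54}
        profs = ir.resistance_profiles(ptx, "PTX", "nM", "A2780", "RI")
        folds = ir.fold_change_consecutive(profs)
        assert folds.loc[folds["pair"] == "A8PTX-A16PTX", "fold_rounded"].iloc[0] == 4.14
        cddp = {"A2780": 4.58, "A8PTX": 2.12, "A16PTX": 0.65}
        profs = ir.resistance_profiles(cddp, "CDDP", "uM", "A2780", "SI")
        folds = ir.fold_change_consecutive(profs)
        assert folds.loc[folds["pair"] == "A8PTX-A16PTX", "fold_rounded"].iloc[0] == 3.26

    def test_identical_series_gives_unit_folds(self):
        profs = ir.resistance_profiles(
            {"L1": 5.0, "L2": 5.0, "L3": 5.0}, "PTX", "nM", "L1", "RI"
        )
        folds = ir.fold_change_consecutive(profs)
        assert (folds["fold_rounded"] == 1.0).all()

    def test_fewer_than_two_profiles_errors(self):
        profs = ir.resistance_profiles({"L1": 5.0}, "PTX", "nM", "L1", "RI")
        with pytest.raises(ValueError):
            ir.fold_change_consecutive(profs)

    def test_product_of_unrounded_folds_equals_end_to_end(self):
        """Multiplicativity before rounding, for both index kinds."""
        ic50s = dict(zip("ABCDEFG", [4.62, 11.47, 18.71, 77.54, 148.47, 173.86, 272.47]))
        for kind in ("RI", "SI"):
            profs = ir.resistance_profiles(ic50s, "PTX", "nM", "A", kind)
            folds = ir.fold_change_consecutive(profs)
            end_to_end = profs[-1].index
            assert folds["fold"].prod() == pytest.approx(end_to_end, abs=1e-9)


class TestCompareLMM:
    def test_identical_datasets_zero_slope_difference(self, rng):
        concs = 4.62 * 2.0 ** np.arange(-3.5, 4.0, 1.0)
        d = make_well_data(rng, concs, {"L1": -0.6})
        d2 = d.copy()
        d2["cell_line"] = "L2"
        res = ir.compare_lmm(pd.concat([d, d2]), fit_model=False)
        assert abs(res.slope_diff) < 1e-10
        assert res.lmm_p == 1.0

    def test_distinct_slopes_detected(self, rng):
        concs = 4.62 * 2.0 ** np.arange(-3.5, 4.0, 1.0)
        d = make_well_data(rng, concs, {"L1": -0.6, "L2": -1.5}, noise=2.0)
        res = ir.compare_lmm(d)
        assert res.lmm_p < 0.01
        assert res.slope_estimates["L2"] < res.slope_estimates["L1"]
        lo, hi = res.ci95
        assert lo <= res.slope_diff <= hi

    def test_requires_two_concentrations(self, rng):
        d = make_well_data(rng, [1.0], {"L1": -0.5, "L2": -0.5})
        with pytest.raises(ValueError):
            ir.compare_lmm(d, fit_model=False)

    def test_power_large_slope_difference(self, rng):
        """Slopes 5 noise-sd apart are detected in >= 95% of simulations."""
        concs = 4.62 * 2.0 ** np.arange(-3.5, 4.0, 1.0)
        hits = 0
        n = 200
        for _ in range(n):
            d = make_well_data(rng, concs, {"L1": -0.6, "L2": -0.9}, noise=3.0)
            if ir.compare_lmm(d, fit_model=False).lmm_p < 0.05:
                hits += 1
        assert hits / n >= 0.95


class TestCompareTTest:
    def test_identical_replicates_p_one(self):
        res = ir.compare_ttest_pic50([8.0, 8.0, 8.0], [8.0, 8.0, 8.0])
        assert res.ttest_p == 1.0

    def test_matches_hand_computed_pooled_t(self):
        a = np.array([8.0, 8.1, 8.2])
        b = np.array([9.0, 9.1, 9.2])
        res = ir.compare_ttest_pic50(a, b)
        # closed-form pooled (Student) t
        sp2 = (a.var(ddof=1) * 2 + b.var(ddof=1) * 2) / 4
        t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        p = 2 * scipy.stats.t.sf(abs(t), 4)
        assert res.tstat == pytest.approx(t, abs=1e-12)
        assert res.ttest_p == pytest.approx(p, abs=1e-12)

    def test_requires_two_replicates(self):
        with pytest.raises(ValueError):
            ir.compare_ttest_pic50([8.0], [8.0, 8.1])
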