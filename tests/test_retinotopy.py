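import numpy as np
import pandas as pd
import pytest

from ssvepmap import (
    ResponseTable,
    average_error_rates,
    central_peripheral_ttest,
    error_rate,
    error_rate_table,
    layer_average,
    position_mean_response,
    response_map,
    surface_grid,
)
from ssvepmap.reference_data import (
    REFERENCE_AVERAGE_ROW,
    REFERENCE_ERROR_RATES,
)
from ssvepmap.retinotopy import surface_interpolator


def make_table(layout, central, layer_values, n_runs=12, participant="a"):
    """Response table with fixed central value and per-(run, stimulus)
    values for layer-2 stimuli given by ``layer_values[run][stim_pos]``."""
    records = []
    layer2 = layout.stimuli_in_layer(2)
    for run in range(1, n_runs + 1):
        if central.get(run) is not None:
            records.append((participant, run, 1, central[run]))
        for j, stim in enumerate(layer2):
            records.append((participant, run, int(stim), layer_values[run][j]))
    return ResponseTable.from_records(records)


class TestPositionMeans:
    def test_identical_values(self, layout):
        records = [("a", r, 1, 0.7) for r in range(1, 13)]
        table = ResponseTable.from_records(records)
        assert position_mean_response(table, "a", 1) == pytest.approx(0.7)

    def test_two_values(self):
        table = ResponseTable.from_records([("a", 1, 5, 0.2), ("a", 2, 5, 0.4)])
        assert position_mean_response(table, "a", 5) == pytest.approx(0.3)

    def test_missing_stimulus_warns_nan(self):
        table = ResponseTable.from_records([("a", 1, 1, 0.5)])
        with pytest.warns(UserWarning, match="no valid trials"):
            assert np.isnan(position_mean_response(table, "a", 2))


class TestLayerAverage:
    def test_uniform_responses(self, layout):
        m = pd.Series(0.42, index=range(1, 47))
        means = layer_average(m, layout)
        assert np.allclose(means.to_numpy(), 0.42)

    def test_layer_one_is_central_mean(self, layout):
        vals = np.linspace(0.1, 0.9, 46)
        m = pd.Series(vals, index=range(1, 47))
        means = layer_average(m, layout)
        assert means.loc[1] == pytest.approx(vals[0])

    def test_simulated_falloff_strictly_decreasing(self, layout, montage):
        """A seeded default-parameter simulation yields strictly decreasing
        layer means (the eccentricity-falloff pattern)."""
        from ssvepmap import SimParams, build_reference, cca_coefficient, simulate_session
        from ssvepmap.preprocess import apply_filters

        ses = simulate_session(SimParams(seed=17, p_excursion=0.0), layout,
                               montage, n_runs=6)
        ref = build_reference(15.0, 3, 500.0, 2000)
        subset = montage.indices(montage.analysis_subset)
        records = [
            ("a", t.run, t.stimulus,
             cca_coefficient(apply_filters(np.asarray(t.eeg, float), 500.0)[subset],
                             ref).R)
            for t in ses.valid_trials()
        ]
        table = ResponseTable.from_records(records)
        means = layer_average(response_map(table, "a", layout), layout)
        assert np.all(np.diff(means.to_numpy()) < 0)


class TestErrorRate:
    def test_single_exceedance_in_twelve_runs(self, layout):
        central = {r: 0.5 for r in range(1, 13)}
        layer_values = {r: [0.4, 0.4, 0.4] for r in range(1, 13)}
        layer_values[5] = [0.4, 0.6, 0.4]  # one run with an exceedance
        table = make_table(layout, central, layer_values)
        rate, n = error_rate(table, layout, "a", 2.0)
        assert rate == pytest.approx(100.0 / 12)
        assert n == 12

    def test_eleven_run_denominator(self, layout):
        central = {r: 0.5 for r in range(1, 13)}
        central[12] = None  # dropped central trial -> 11 usable runs
        layer_values = {r: [0.4, 0.4, 0.4] for r in range(1, 13)}
        layer_values[3] = [0.7, 0.4, 0.4]
        table = make_table(layout, central, layer_values)
        rate, n = error_rate(table, layout, "a", 2.0)
        assert rate == pytest.approx(100.0 / 11)
        assert n == 11

    def test_no_exceedances_zero(self, layout):
        central = {r: 0.9 for r in range(1, 13)}
        layer_values = {r: [0.1, 0.2, 0.3] for r in range(1, 13)}
        table = make_table(layout, central, layer_values)
        rate, _ = error_rate(table, layout, "a", 2.0)
        assert rate == 0.0

    def test_pooled_variant_counts_each_comparison(self, layout):
        central = {r: 0.5 for r in range(1, 13)}
        layer_values = {r: [0.4, 0.4, 0.4] for r in range(1, 13)}
        layer_values[5] = [0.6, 0.6, 0.4]  # 2 of 36 comparisons exceed
        table = make_table(layout, central, layer_values)
        rate, _ = error_rate(table, layout, "a", 2.0, variant="pooled")
        assert rate == pytest.approx(100.0 * 2 / 36)

    def test_monotone_transform_invariance(self, layout):
        """The error rate depends only on within-run response order."""
        rng = np.random.default_rng(3)
        central = {r: float(rng.uniform(0.3, 0.9)) for r in range(1, 13)}
        layer_values = {r: list(rng.uniform(0.1, 1.0, 3)) for r in range(1, 13)}
        table = make_table(layout, central, layer_values)
        base, _ = error_rate(table, layout, "a", 2.0)
        squared = ResponseTable(table.data.assign(response=table.data["response"] ** 2))
        transformed, _ = error_rate(squared, layout, "a", 2.0)
        assert transformed == pytest.approx(base)

    def test_bad_angle_rejected(self, layout):
        table = ResponseTable.from_records([("a", 1, 1, 0.5)])
        with pytest.raises(ValueError):
            error_rate(table, layout, "a", 3.0)


class TestAverageErrorRates:
    def test_reference_table_average_row(self):
        """Averaging the eight published per-participant error-rate vectors
        reproduces the published AVE row exactly at 2 decimals."""
        ave = average_error_rates(REFERENCE_ERROR_RATES)
        assert np.array_equal(ave, REFERENCE_AVERAGE_ROW)

    def test_identical_rates_unchanged(self):
        rates = np.tile([7.5, 2.5, 0.0], (4, 1))
        assert np.array_equal(average_error_rates(rates), [7.5, 2.5, 0.0])


class TestTTest:
    def test_identical_groups_p_one(self, layout):
        central = {r: [0.2, 0.4, 0.6][r % 3] for r in range(1, 13)}
        layer_values = {r: [[0.2, 0.4, 0.6][r % 3]] * 3 for r in range(1, 13)}
        table = make_table(layout, central, layer_values)
        # identical means and overlapping spread -> p near 1
        p = central_peripheral_ttest(table, layout, "a", 2.0)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_separated_groups_significant(self, layout):
        rng = np.random.default_rng(5)
        central = {r: float(rng.normal(0.8, 0.01)) for r in range(1, 13)}
        layer_values = {r: list(rng.normal(0.2, 0.01, 3)) for r in range(1, 13)}
        table = make_table(layout, central, layer_values)
        p = central_peripheral_ttest(table, layout, "a", 2.0)
        assert p < 0.001
        # permutation oracle on the mean difference agrees on significance
        sub = table.data
        c = sub.loc[sub["stimulus"] == 1, "response"].to_numpy()
        g = sub.loc[sub["stimulus"] != 1, "response"].to_numpy()
        pooled = np.concatenate([c, g])
        obs = abs(c.mean() - g.mean())
        perm_rng = np.random.default_rng(6)
        count = sum(
            abs((s := perm_rng.permutation(pooled))[: c.size].mean()
                - s[c.size:].mean()) >= obs
            for _ in range(2000)
        )
        assert (count + 1) / 2001 < 0.001 + 1e-3

    def test_two_sided_symmetry(self, layout):
        rng = np.random.default_rng(8)
        central = {r: float(rng.normal(0.3, 0.05)) for r in range(1, 13)}
        layer_values = {r: list(rng.normal(0.7, 0.05, 3)) for r in range(1, 13)}
        table = make_table(layout, central, layer_values)
        p_forward = central_peripheral_ttest(table, layout, "a", 2.0)
        # swap roles by negating responses around the midpoint
        swapped = ResponseTable(table.data.assign(response=1.0 - table.data["response"]))
        p_swapped = central_peripheral_ttest(swapped, layout, "a", 2.0)
        assert p_forward == pytest.approx(p_swapped, rel=1e-9)

    def test_degenerate_variance_convention(self, layout):
        central = {r: 0.5 for r in range(1, 13)}
        layer_values = {r: [0.5, 0.5, 0.5] for r in range(1, 13)}
        table = make_table(layout, central, layer_values)
        with pytest.warns(UserWarning, match="zero variance"):
            assert central_peripheral_ttest(table, layout, "a", 2.0) == 1.0


class TestErrorRateTable:
    def test_ave_row_is_mean_of_participants(self, layout, rng):
        records = []
        for p in ("a", "b"):
            for run in range(1, 5):
                for stim in range(1, 47):
                    records.append((p, run, stim, float(rng.uniform(0, 1))))
        table = ResponseTable.from_records(records)
        df = error_rate_table(table, layout)
        for d in (2, 4, 6, 8, 10):
            col = f"rate_{d}"
            expected = round(df.loc[["a", "b"], col].mean(), 2)
            assert df.loc["AVE", col] == pytest.approx(expected)


class TestSurface:
    def test_interpolation_identity_at_stimuli(self, layout, rng):
        m = pd.Series(rng.uniform(0, 1, 46), index=range(1, 47))
        interp = surface_interpolator(m, layout)
        for idx in (1, 5, 20, 46):
            x, y = layout.position(idx)
            assert interp(x, y) == pytest.approx(m.loc[idx], abs=1e-12)

    def test_uniform_map_flat_surface(self, layout):
        m = pd.Series(0.5, index=range(1, 47))
        _, _, grid = surface_grid(m, layout, grid_resolution=1.0)
        inside = grid[~np.isnan(grid)]
        assert np.allclose(inside, 0.5)

    def test_hull_edge_midpoint_linearity(self, layout):
        m = pd.Series(0.1, index=range(1, 47))
        outer = layout.stimuli_in_layer(6)[:2]  # adjacent outermost nodes
        m.loc[outer] = 0.8
        interp = surface_interpolator(m, layout)
        p1 = np.array(layout.position(int(outer[0])))
        p2 = np.array(layout.position(int(outer[1])))
        midpoint = (p1 + p2) / 2 * (1 - 1e-12)  # nudge inside the hull
        assert interp(*midpoint) == pytest.approx(0.8, abs=1e-6)

    def test_outside_hull_nan(self, layout):
        m = pd.Series(0.5, index=range(1, 47))
        interp = surface_interpolator(m, layout)
        assert np.isnan(interp(11.0, 11.0))

    def test_collinear_positions_error(self):
        from ssvepmap.layout import StimulusLayout

        lay = StimulusLayout(
            positions=np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]]),
            layer_index=np.array([1, 2, 3]),
            flicker_diameter=0.5, layer_spacing=1.0, ring_counts=(1, 1),
        )
        m = pd.Series([0.1, 0.2, 0.3], index=[1, 2, 3])
        with pytest.raises(ValueError, match="collinear"):
            surface_interpolator(m, lay)
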