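import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from migetsim import (
    CompartmentGrid,
    ConfigurationError,
    DataError,
    PerfusionDistribution,
    VQDistributionModel,
    build_grid,
    bypass_units,
    default_panel,
    five_unit_circuit,
    predict_retentions,
    recover_distribution,
    retention_kernel,
    rss_quality,
    shunt_from_distribution,
)
from ._oracles import simplex_lstsq_bruteforce


class TestBuildGrid:
    def test_default_grid_shape_and_bounds(self, default_grid):
        vq = default_grid.vq_ratios
        assert default_grid.n_compartments == 50
        assert vq[0] == 0.0
        assert vq[1] == pytest.approx(0.005)
        assert vq[-1] == pytest.approx(100.0)
        assert np.all(np.diff(vq) > 0)

    def test_log_spacing_small_grid(self):
        vq = build_grid(5, 0.01, 10.0).vq_ratios
        np.testing.assert_allclose(vq, [0.0, 0.01, 0.1, 1.0, 10.0], rtol=1e-12)

    @pytest.mark.parametrize(
        "n, lo, hi", [(3, 1.0, 1.0), (3, -1.0, 10.0), (2, 0.01, 10.0), (3, 5.0, 1.0)]
    )
    def test_degenerate_grids_rejected(self, n, lo, hi):
        with pytest.raises(ConfigurationError):
            build_grid(n, lo, hi)

    def test_grid_must_start_at_zero(self):
        with pytest.raises(ConfigurationError):
            CompartmentGrid(np.array([0.01, 0.1, 1.0]))


class TestRetentionKernel:
    def test_shunt_column_is_ones_and_entries_in_unit_interval(
        self, default_grid, blood_panel
    ):
        a = retention_kernel(default_grid, blood_panel)
        assert a.shape == (6, 50)
        np.testing.assert_allclose(a[:, 0], 1.0)
        assert np.all((a > 0) & (a <= 1))

    def test_unit_vq_unit_lambda_entry(self, blood_panel):
        from migetsim import GasPanel, InertGas

        grid = build_grid(5, 0.01, 100.0)
        panel = GasPanel((InertGas("A", 1.0), InertGas("B", 2.0)), "blood")
        a = retention_kernel(grid, panel)
        col = np.argmin(np.abs(grid.vq_ratios - 1.0))
        assert a[0, col] == pytest.approx(1.0 / (1.0 + grid.vq_ratios[col]))

    def test_rows_increase_with_lambda_for_ventilated_compartments(
        self, default_grid, blood_panel, rng
    ):
        a = retention_kernel(default_grid, blood_panel)
        cols = rng.integers(1, 50, size=10)
        assert np.all(np.diff(a[:, cols], axis=0) > 0)


class TestRoundTrips:
    @pytest.mark.parametrize("k", range(5))
    def test_noiseless_forward_inverse_recovers_preset_shunt(
        self, nominal_circuit, blood_panel, default_grid, k
    ):
        """Forward-inverse consistency without regularization: shunt to 2e-2,
        near-zero residual."""
        rec = predict_retentions(bypass_units(nominal_circuit, k), blood_panel)
        dist = recover_distribution(
            rec, blood_panel, grid=default_grid, smoothing_weight=0.0
        )
        assert dist.shunt == pytest.approx(k / 5, abs=0.02)
        assert dist.rss < 1e-6

    @pytest.mark.parametrize("k", range(5))
    def test_default_smoothing_still_recovers_shunt(
        self, nominal_circuit, blood_panel, k
    ):
        rec = predict_retentions(bypass_units(nominal_circuit, k), blood_panel)
        dist = recover_distribution(rec, blood_panel)
        assert dist.shunt == pytest.approx(k / 5, abs=0.02)

    def test_all_ones_retentions_give_pure_shunt(self, blood_panel):
        dist = recover_distribution(np.ones(6), blood_panel)
        assert dist.shunt == pytest.approx(1.0, abs=1e-6)
        assert dist.rss < 1e-10

    def test_single_compartment_retentions_place_mass_near_vq_one(
        self, blood_panel, default_grid
    ):
        lam = blood_panel.partition_coefficients
        dist = recover_distribution(
            lam / (lam + 1.0), blood_panel, smoothing_weight=0.0
        )
        assert dist.shunt < 0.02
        vq = default_grid.vq_ratios
        mass_near_one = dist.fractions[(vq > 0.3) & (vq < 3.0)].sum()
        assert mass_near_one > 0.9


class TestOracleEquivalence:
    def test_nnls_matches_bruteforce_simplex_solution_on_small_grids(
        self, blood_panel, rng
    ):
        """Production solver vs exact exhaustive-support constrained LS."""
        for _ in range(20):
            n = int(rng.integers(3, 7))
            grid = build_grid(n, 0.005, 100.0)
            r = rng.uniform(0.0, 1.0, 6)
            model = VQDistributionModel(
                r, blood_panel, grid=grid, smoothing_weight=0.0
            )
            q_pkg = model.fit().fractions
            q_oracle = simplex_lstsq_bruteforce(np.clip(r, 0, 1), model.kernel)
            np.testing.assert_allclose(q_pkg, q_oracle, atol=1e-3)


class TestSolverProperties:
    def test_rss_nondecreasing_in_smoothing_weight(self, blood_panel, rng):
        r = np.clip(
            predict_retentions(
                bypass_units(five_unit_circuit(), 2), default_panel("blood")
            ).retentions
            * rng.normal(1, 0.02, 6),
            0,
            1,
        )
        rss = [
            recover_distribution(r, blood_panel, smoothing_weight=z).rss
            for z in (0.0, 1.0, 10.0, 40.0, 200.0)
        ]
        assert all(b >= a - 1e-12 for a, b in zip(rss, rss[1:]))
        assert rss[0] == min(rss)

    def test_solution_depends_only_on_retention_ratios(self, blood_panel):
        from migetsim import RetentionRecord

        rec = predict_retentions(
            bypass_units(five_unit_circuit(), 2), blood_panel
        )
        scaled = RetentionRecord(
            rec.gas_names,
            rec.upstream_pressures * 37.0,
            rec.downstream_pressures * 37.0,
            perfusate="blood",
        )
        d1 = recover_distribution(rec, blood_panel)
        d2 = recover_distribution(scaled, blood_panel)
        np.testing.assert_allclose(d1.fractions, d2.fractions, atol=1e-10)

    def test_out_of_range_retentions_clipped_with_warning(self, blood_panel):
        r = np.array([0.1, 0.2, 0.4, 0.7, 0.9, 1.1])
        with pytest.warns(UserWarning, match="clipped"):
            model = VQDistributionModel(r, blood_panel)
        assert model.retentions[-1] == 1.0

    def test_all_zero_retentions_rejected(self, blood_panel):
        with pytest.raises(DataError, match="zero"):
            VQDistributionModel(np.zeros(6), blood_panel)

    def test_too_few_finite_retentions_rejected(self, blood_panel):
        r = np.full(6, np.nan)
        r[0] = 0.5
        with pytest.raises(DataError, match="finite"):
            VQDistributionModel(r, blood_panel)

    @given(st.integers(0, 4))
    def test_fractions_always_a_probability_vector(self, k):
        panel = default_panel("blood")
        rec = predict_retentions(bypass_units(five_unit_circuit(), k), panel)
        dist = recover_distribution(rec, panel)
        assert np.all(dist.fractions >= 0)
        assert dist.fractions.sum() == pytest.approx(1.0, abs=1e-8)


class TestShuntExtraction:
    def _dist(self, grid, fractions):
        model = None
        q = np.asarray(fractions, float)
        a = retention_kernel(grid, default_panel("blood"))
        return PerfusionDistribution(
            grid=grid, fractions=q, shunt=float(q[grid.shunt_mask].sum()),
            rss=0.0, model=model,
        )

    def test_mass_at_zero_vq_counts(self):
        grid = build_grid(5, 0.01, 10.0)
        q = np.array([0.3, 0.2, 0.2, 0.2, 0.1])
        assert shunt_from_distribution(self._dist(grid, q)) == pytest.approx(0.3)

    def test_mass_above_threshold_does_not_count(self):
        grid = build_grid(5, 0.01, 10.0)
        q = np.array([0.0, 0.25, 0.25, 0.25, 0.25])
        assert shunt_from_distribution(self._dist(grid, q)) == 0.0

    def test_compartment_exactly_at_threshold_excluded(self):
        grid = build_grid(4, 0.005, 10.0)  # second compartment sits at 0.005
        assert grid.vq_ratios[1] == pytest.approx(0.005)
        q = np.array([0.1, 0.5, 0.2, 0.2])
        assert shunt_from_distribution(self._dist(grid, q)) == pytest.approx(0.1)


class TestRssQuality:
    def test_counting(self):
        out = rss_quality([1.0, 6.0, 12.0, 3.0], thresholds=(5.0, 10.0))
        assert out == {5.0: 0.5, 10.0: 0.75}

    def test_all_zero_rss(self):
        assert rss_quality([0.0, 0.0]) == {5.0: 1.0, 10.0: 1.0}

    def test_monotone_in_threshold(self, rng):
        vals = rng.exponential(5.0, 100)
        out = rss_quality(vals, thresholds=(1.0, 5.0, 10.0, 50.0))
        fracs = [out[t] for t in (1.0, 5.0, 10.0, 50.0)]
        assert fracs == sorted(fracs)

    def test_empty_input_rejected(self):
        with pytest.raises(DataError):
            rss_quality([])


def test_summary_reports_shunt_and_fit(blood_panel):
    rec = predict_retentions(bypass_units(five_unit_circuit(), 2), blood_panel)
    text = recover_distribution(rec, blood_panel).summary()
    assert "shunt" in text and "RSS" in text and "SF6" in text
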