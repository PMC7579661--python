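"""First-order kinetics: simulation, fitting, biodegradability, mix prediction."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from admethane.kinetics import (
    FeedSchedule,
    FirstOrderModel,
    KineticParams,
    MethaneSeries,
    batch_curve,
    biodegradability,
    fedbatch_simulate,
    fit_first_order,
    pool_replicates,
    predict_mix_fedbatch,
)
from admethane.substrates import MixSpec
from admethane.synthetic import SynthConfig, make_batch_dataset

from conftest import analytic_fedbatch


class TestBatchCurve:
    def test_zero_at_time_zero(self):
        s = batch_curve(KineticParams(0.3, 0.2), 20.0, 0.002, [0.0, 1.0])
        assert s.cumulative_volume[0] == 0.0

    def test_asymptote(self):
        p = KineticParams(0.3, 0.5)
        t_large = 20.0 / p.k
        s = batch_curve(p, 20.0, 0.002, [t_large])
        assert s.cumulative_volume[-1] == pytest.approx(
            20.0 * 0.002 * 0.3, rel=1e-8
        )

    def test_hand_evaluated_specific_yield(self):
        # 0.22 * (1 - e^(-0.31*18)) per kg VS
        s = batch_curve(KineticParams(0.22, 0.31), 1.0, 1.0, [18.0])
        assert s.cumulative_volume[0] == pytest.approx(0.2192, abs=5e-5)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            batch_curve(KineticParams(0.3, 0.2), 20.0, 0.002, [-1.0, 1.0])

    @given(k=st.floats(0.05, 1.5), b0=st.floats(0.05, 0.6))
    @settings(max_examples=40, deadline=None)
    def test_increasing_and_concave(self, k, b0):
        """Cumulative methane rises monotonically, with decaying rate, and
        the initial slope is VS*V*B0*k.  Evaluated over k*t <= 8 where the
        curve is not yet float-saturated at its asymptote."""
        t = np.linspace(0.0, 8.0 / k, 400)
        s = batch_curve(KineticParams(b0, k), 20.0, 0.002, t)
        diffs = np.diff(s.cumulative_volume)
        assert np.all(diffs > 0)
        assert np.all(np.diff(diffs) < 1e-12)
        slope0 = diffs[0] / (t[1] - t[0])
        assert slope0 == pytest.approx(20.0 * 0.002 * b0 * k, rel=0.05)


class TestFedBatchSimulate:
    def test_matches_analytic_piecewise_solution(self, weekly_schedule):
        """Numeric integrator vs independent closed-form superposition
        oracle on a 5-event schedule: agreement to 1e-5 relative."""
        p = KineticParams(0.24, 0.26)
        times = np.linspace(0.5, 35.0, 70)
        pool, series = fedbatch_simulate(p, weekly_schedule, 0.004, times)
        o_pool, o_methane = analytic_fedbatch(
            p, weekly_schedule.times, weekly_schedule.masses, 0.004, times
        )
        assert np.max(
            np.abs(series.cumulative_volume - o_methane) / o_methane.max()
        ) < 1e-5
        assert np.max(np.abs(pool - o_pool) / o_pool.max()) < 1e-5

    def test_single_impulse_reduces_to_batch_closed_form(self):
        """One feeding at t=0 is a batch test: the simulated curve equals
        the closed form with the same initial VS charge."""
        p = KineticParams(0.33, 0.24)
        t = np.linspace(0.0, 30.0, 60)
        sched = FeedSchedule(events=((0.0, 0.04),))
        _, fb = fedbatch_simulate(p, sched, 0.002, t)
        closed = batch_curve(p, 0.04 / 0.002, 0.002, t)
        ref = closed.cumulative_volume.max()
        assert np.max(np.abs(fb.cumulative_volume - closed.cumulative_volume)) < (
            1e-6 * ref
        )

    def test_single_impulse_y_at_entry_scales_charge(self):
        p = KineticParams(0.33, 0.24, y=0.60)
        t = np.linspace(0.0, 30.0, 40)
        sched = FeedSchedule(events=((0.0, 0.04),))
        _, fb = fedbatch_simulate(p, sched, 0.002, t, y_at_entry=True)
        closed = batch_curve(p, 0.60 * 0.04 / 0.002, 0.002, t)
        ref = closed.cumulative_volume.max()
        assert np.max(np.abs(fb.cumulative_volume - closed.cumulative_volume)) < (
            1e-6 * ref
        )

    def test_mass_additivity_two_feeds(self):
        """Two feedings of mass m digested to completion yield 2*Y*m*B0
        under the Y-at-entry convention."""
        p = KineticParams(0.30, 0.4, y=0.5)
        sched = FeedSchedule(events=((0.0, 0.02), (10.0, 0.02)))
        t = np.array([0.0, 10.0, 10.0 + 20.0 / p.k])
        _, fb = fedbatch_simulate(p, sched, 0.004, t, y_at_entry=True)
        assert fb.cumulative_volume[-1] == pytest.approx(
            2 * 0.5 * 0.02 * 0.30, rel=1e-5
        )

    def test_conservation_of_degradable_mass(self, weekly_schedule):
        """Remaining pool plus degraded mass equals total fed at all times."""
        p = KineticParams(0.24, 0.26)
        times = np.linspace(0.0, 35.0, 71)
        pool, series = fedbatch_simulate(p, weekly_schedule, 0.004, times)
        remaining = pool * 0.004
        degraded = series.cumulative_volume / p.b0
        fed = np.array([
            weekly_schedule.masses[weekly_schedule.times <= t].sum()
            for t in times
        ])
        assert np.max(np.abs(remaining + degraded - fed)) < 1e-6 * fed.max()

    def test_monotone_output(self, weekly_schedule):
        p = KineticParams(0.24, 0.26)
        _, series = fedbatch_simulate(
            p, weekly_schedule, 0.004, np.linspace(0.0, 35.0, 200)
        )
        assert np.all(np.diff(series.cumulative_volume) >= 0)

    def test_feed_outside_window_rejected(self):
        p = KineticParams(0.24, 0.26)
        sched = FeedSchedule(events=((0.0, 0.01), (40.0, 0.01)))
        with pytest.raises(ValueError, match="window"):
            fedbatch_simulate(p, sched, 0.004, np.linspace(0.0, 35.0, 10))

    def test_y_at_entry_requires_y(self):
        with pytest.raises(ValueError, match="y"):
            fedbatch_simulate(
                KineticParams(0.3, 0.2),
                FeedSchedule(events=((0.0, 0.01),)),
                0.004,
                [0.0, 5.0],
                y_at_entry=True,
            )


class TestFit:
    def _noiseless_series(self, b0=0.33, k=0.24):
        times = np.arange(1.0, 19.0)
        return batch_curve(KineticParams(b0, k), 20.0, 0.002, times)

    def test_noiseless_self_consistency(self):
        """Fitting a noiseless synthetic curve returns the generating
        parameters to 1e-4 relative."""
        res = FirstOrderModel(self._noiseless_series()).fit()
        assert res.params.b0 == pytest.approx(0.33, rel=1e-4)
        assert res.params.k == pytest.approx(0.24, rel=1e-4)
        assert res.rss < 1e-12

    def test_fit_idempotence(self):
        """Refitting the curve generated from fitted params reproduces them."""
        res = FirstOrderModel(self._noiseless_series()).fit()
        regenerated = batch_curve(
            res.params, 20.0, 0.002, self._noiseless_series().times
        )
        res2 = FirstOrderModel(regenerated).fit()
        assert res2.params.b0 == pytest.approx(res.params.b0, rel=1e-6)
        assert res2.params.k == pytest.approx(res.params.k, rel=1e-6)

    def test_optimizer_not_beaten_by_dense_grid(self):
        """The two-stage search attains an RSS no worse than the best point
        of an exhaustive 500x500 grid over the same bounded box."""
        cfg = SynthConfig(
            true_params=KineticParams(0.22, 0.31), blank_yield_frac=0.0, seed=7
        )
        tests, _, _ = make_batch_dataset(cfg)
        model = FirstOrderModel(tests[0])
        res = model.fit()
        (b0_lo, b0_hi) = res.search_bounds["b0"]
        (k_lo, k_hi) = res.search_bounds["k"]
        b0s = np.linspace(b0_lo, b0_hi, 500)
        ks = np.linspace(k_lo, k_hi, 500)
        grid = model._batch_objective_grid(b0s, ks)
        assert res.rss <= grid.min() + 1e-15

    def test_noisy_recovery_single_seed(self):
        """One weekday-sampled noisy dataset at the default 2% reading
        noise: B0 within 5%, k within 15% of truth."""
        cfg = SynthConfig(
            true_params=KineticParams(0.22, 0.31), blank_yield_frac=0.0, seed=3
        )
        tests, _, _ = make_batch_dataset(cfg)
        res = FirstOrderModel(tests[0]).fit()
        assert res.params.b0 == pytest.approx(0.22, rel=0.05)
        assert res.params.k == pytest.approx(0.31, rel=0.15)

    def test_fedbatch_fit_recovers_truth(self, weekly_schedule):
        p = KineticParams(0.24, 0.26)
        times = np.arange(1.0, 36.0)
        _, series = fedbatch_simulate(p, weekly_schedule, 0.004, times)
        res = FirstOrderModel(
            series, mode="fedbatch", schedule=weekly_schedule
        ).fit()
        assert res.params.b0 == pytest.approx(0.24, rel=1e-3)
        assert res.params.k == pytest.approx(0.26, rel=1e-3)

    def test_functional_wrapper(self):
        params, rss, diag = fit_first_order(self._noiseless_series())
        assert params.b0 == pytest.approx(0.33, rel=1e-4)
        assert diag["n_obs"] == 18
        assert diag["n_objective_evals"] > 0

    def test_requires_four_observations(self):
        s = batch_curve(KineticParams(0.3, 0.2), 20.0, 0.002, [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="4 observations"):
            FirstOrderModel(s)

    def test_all_zero_series_rejected(self):
        s = MethaneSeries(
            times=np.arange(1.0, 6.0),
            cumulative_volume=np.zeros(5),
            volume_m3=0.002,
            vs_conc_kg_m3=20.0,
        )
        with pytest.raises(ValueError, match="degenerate"):
            FirstOrderModel(s)

    def test_non_monotone_series_warns_but_fits(self):
        times = np.arange(1.0, 15.0)
        clean = batch_curve(KineticParams(0.3, 0.3), 20.0, 0.002, times)
        vols = clean.cumulative_volume.copy()
        vols[7] = vols[6] - 1e-5  # a locally decreasing pair of readings
        with pytest.warns(UserWarning, match="decreases"):
            s = MethaneSeries(
                times=times, cumulative_volume=vols,
                volume_m3=0.002, vs_conc_kg_m3=20.0,
            )
        res = FirstOrderModel(s).fit()
        assert res.params.b0 == pytest.approx(0.3, rel=0.05)

    def test_fedbatch_requires_schedule(self):
        with pytest.raises(ValueError, match="schedule"):
            FirstOrderModel(self._noiseless_series(), mode="fedbatch")


class TestBiodegradability:
    @pytest.mark.parametrize(
        "b0, bth, expected",
        [(0.22, 0.50, 0.44), (0.33, 0.55, 0.60), (0.5, 0.5, 1.0)],
    )
    def test_reference_values(self, b0, bth, expected):
        y = biodegradability(KineticParams(b0, 0.3), bth)
        assert round(y, 2) == pytest.approx(expected)

    def test_above_unity_warns(self):
        with pytest.warns(UserWarning, match="exceeds 1"):
            y = biodegradability(KineticParams(0.6, 0.3), 0.5)
        assert y == pytest.approx(1.2)

    def test_nonpositive_bth_rejected(self):
        with pytest.raises(ValueError):
            biodegradability(KineticParams(0.3, 0.3), 0.0)


class TestPredictMixFedbatch:
    def test_pure_mix_equals_single_substrate(self, weekly_schedule):
        params = {"a": KineticParams(0.25, 0.3, y=0.5)}
        mix = MixSpec(components=(("a", 1.0),))
        times = np.arange(1.0, 36.0)
        pred = predict_mix_fedbatch(params, mix, weekly_schedule, 0.004, times)
        _, direct = fedbatch_simulate(
            params["a"], weekly_schedule, 0.004, times
        )
        np.testing.assert_allclose(
            pred.cumulative_volume, direct.cumulative_volume, rtol=1e-9
        )

    def test_blend_asymptote_is_weighted_b0(
        self, single_params, mixes, weekly_schedule
    ):
        """The predicted blend curve plateaus at the fraction-weighted B0
        per kg VS fed (0.2465 Nm3/kgVS for the plant A recipe)."""
        times = np.array([200.0])  # k*t >> 1, fully digested
        sched = FeedSchedule(events=((0.0, 0.01),))
        pred = predict_mix_fedbatch(
            single_params, mixes["plant_a"], sched, 0.004, times
        )
        specific = pred.cumulative_volume[-1] / 0.01
        assert specific == pytest.approx(0.2465, abs=1e-4)

    def test_prediction_close_to_direct_fit_on_synthetic_blend(
        self, single_params, mixes, weekly_schedule
    ):
        """Cross-validation: the curve predicted from single-substrate
        parameters tracks a synthetic blend generated at the measured blend
        kinetics to within 15% RMSE of the asymptote."""
        truth = KineticParams(0.24, 0.26)
        times = np.arange(1.0, 36.0)
        _, measured = fedbatch_simulate(truth, weekly_schedule, 0.004, times)
        pred = predict_mix_fedbatch(
            single_params, mixes["plant_a"], weekly_schedule, 0.004, times
        )
        asymptote = truth.b0 * weekly_schedule.total_vs_kg
        rmse = np.sqrt(
            np.mean((pred.cumulative_volume - measured.cumulative_volume) ** 2)
        )
        assert rmse <= 0.15 * asymptote

    def test_missing_component_raises(self, mixes, weekly_schedule):
        with pytest.raises(KeyError, match="fitted params"):
            predict_mix_fedbatch(
                {"pellets": KineticParams(0.22, 0.31)},
                mixes["plant_a"],
                weekly_schedule,
                0.004,
                np.arange(1.0, 36.0),
            )


class TestPoolReplicates:
    def test_mean_and_half_range(self):
        pooled, hr = pool_replicates(
            [KineticParams(0.21, 0.30), KineticParams(0.23, 0.32)]
        )
        assert pooled.b0 == pytest.approx(0.22)
        assert pooled.k == pytest.approx(0.31)
        assert hr["b0"] == pytest.approx(0.01)
        assert hr["k"] == pytest.approx(0.01)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pool_replicates([])


class TestParamValidation:
    @pytest.mark.parametrize("kwargs", [
        dict(b0=0.0, k=0.3), dict(b0=0.3, k=-0.1), dict(b0=0.3, k=0.3, y=1.5),
    ])
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            KineticParams(**kwargs)
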