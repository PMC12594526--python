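"""MSD machinery against brute-force oracles and simulated truth."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rodspt import (SimConfig, Track, adaptive_link_radius, eata_msd,
                    ensemble_D, fit_D_histogram, fit_track_D,
                    time_averaged_msd, tracks_from_dataframe)
from rodspt.synthetic_data import simulate_free_tracks

DT = 0.0217


def brute_force_tamsd(xy, max_k):
    """Independent double-loop TA-MSD."""
    n = len(xy)
    out = []
    for k in range(1, max_k + 1):
        acc = 0.0
        for i in range(n - k):
            d = xy[i + k] - xy[i]
            acc += d @ d
        out.append(acc / (n - k))
    return np.array(out)


def make_track(xy):
    xy = np.asarray(xy, float)
    return Track(frames=np.arange(len(xy)), xy=xy, dt=DT)


class TestTamsd:
    def test_stationary_is_zero(self):
        msd = time_averaged_msd(make_track(np.zeros((10, 2))), 4)
        np.testing.assert_array_equal(msd.msd, 0.0)

    def test_ballistic_closed_form(self):
        v = 0.3
        xy = np.column_stack([v * DT * np.arange(12), np.zeros(12)])
        msd = time_averaged_msd(make_track(xy), 5)
        expected = (v * msd.lags) ** 2
        np.testing.assert_allclose(msd.msd, expected, rtol=1e-12)

    def test_counts_are_length_minus_lag(self):
        msd = time_averaged_msd(make_track(np.zeros((9, 2))), 3)
        np.testing.assert_array_equal(msd.counts, [8, 7, 6])

    def test_brute_force_oracle_five_point_track(self):
        xy = np.array([[0.0, 0.0], [1.0, 0.5], [0.3, -0.2], [2.0, 1.0],
                       [1.5, 0.7]])
        msd = time_averaged_msd(make_track(xy), 4)
        np.testing.assert_allclose(msd.msd, brute_force_tamsd(xy, 4),
                                   rtol=0, atol=1e-15)

    def test_gap_rejected(self):
        with pytest.raises(ValueError, match="gap"):
            Track(frames=np.array([0, 1, 3, 4]), xy=np.zeros((4, 2)), dt=DT)

    def test_brute_force_oracle_random_tracks(self, rng):
        for _ in range(5):
            xy = rng.normal(size=(30, 2))
            msd = time_averaged_msd(make_track(xy), 10)
            np.testing.assert_allclose(msd.msd, brute_force_tamsd(xy, 10),
                                       atol=1e-12)


class TestEata:
    def test_single_track_equals_its_tamsd(self):
        xy = np.cumsum(np.ones((15, 2)), axis=0)
        t = make_track(xy)
        np.testing.assert_allclose(eata_msd([t], 4).msd,
                                   time_averaged_msd(t, 4).msd)

    def test_matches_brute_force_average(self, rng):
        xys = [rng.normal(size=(20, 2)) for _ in range(3)]
        ens = eata_msd([make_track(xy) for xy in xys], 5)
        expected = np.mean([brute_force_tamsd(xy, 5) for xy in xys], axis=0)
        np.testing.assert_allclose(ens.msd, expected, atol=1e-12)


class TestFitD:
    def test_exact_line_recovered(self):
        D, b = 0.05, 0.001
        lags = DT * np.arange(1, 4)
        from rodspt.diffusion import MsdCurve
        msd = MsdCurve(lags=lags, msd=4 * D * lags + b,
                       counts=np.array([9, 8, 7]))
        est = fit_track_D(msd, DT)
        assert est.D == pytest.approx(D, rel=1e-12)
        assert est.b == pytest.approx(b, rel=1e-12)

    def test_intercept_formula_on_blurred_tracks(self):
        # ensemble-mean intercept matches b = -4*D*dt/3 + 4*sigma^2
        cfg = SimConfig(sigma_loc=0.02, seed=8)
        D = 0.1
        xys = simulate_free_tracks(8000, 20, D, cfg)
        bs = [fit_track_D(time_averaged_msd(make_track(xy), 3), DT).b
              for xy in xys]
        expected = -4 * D * DT / 3 + 4 * 0.02 ** 2
        assert abs(np.mean(bs) - expected) < 0.2 * abs(expected)

    def test_stationary_emitter_static_error(self):
        cfg = SimConfig(sigma_loc=0.02, seed=9)
        xys = simulate_free_tracks(3000, 20, 0.0, cfg)
        ests = [fit_track_D(time_averaged_msd(make_track(xy), 3), DT)
                for xy in xys]
        assert abs(np.mean([e.D for e in ests])) < 5e-4
        assert np.mean([e.b for e in ests]) == pytest.approx(4 * 0.02 ** 2,
                                                             rel=0.05)

    def test_sigma_recovered_from_intercept(self):
        from rodspt.diffusion import DiffusionEstimate
        est = DiffusionEstimate(D=0.05, b=-4 * 0.05 * DT / 3 + 4 * 0.02 ** 2)
        assert est.recover_sigma(DT) == pytest.approx(0.02)


class TestEnsemble:
    def test_identical_tracks_zero_sem(self):
        xy = np.cumsum(np.full((15, 2), 0.01), axis=0)
        mean, sem, Ds = ensemble_D([make_track(xy)] * 5)
        assert sem == 0.0

    def test_free_diffusion_unbiased(self):
        cfg = SimConfig(seed=10)
        D = 0.0184
        xys = simulate_free_tracks(4000, 15, D, cfg)
        mean, sem, Ds = ensemble_D([make_track(xy) for xy in xys])
        assert abs(mean - D) < 3 * sem

    def test_split_consistency(self):
        cfg = SimConfig(seed=12)
        xys = simulate_free_tracks(3000, 15, 0.05, cfg)
        tracks = [make_track(xy) for xy in xys]
        m1, s1, _ = ensemble_D(tracks[:1500])
        m2, s2, _ = ensemble_D(tracks[1500:])
        assert abs(m1 - m2) < 3 * np.hypot(s1, s2)

    def test_short_tracks_excluded(self):
        long = make_track(np.cumsum(np.full((15, 2), 0.01), axis=0))
        short = make_track(np.zeros((6, 2)))
        _, _, Ds = ensemble_D([long, long, short])
        assert len(Ds) == 2


class TestDHistogram:
    def test_single_gaussian_degenerate_two_pop(self, rng):
        Ds = rng.normal(0.05, 0.01, 3000)
        one = fit_D_histogram(Ds, mode="one")
        two = fit_D_histogram(Ds, mode="two")
        assert one.params["mu"] == pytest.approx(0.05, rel=0.05)
        close_mus = abs(two.params["mu1"] - two.params["mu2"]) < 0.01
        extreme_a = two.params["a"] < 0.05 or two.params["a"] > 0.95
        assert close_mus or extreme_a
        assert two.residual_norm < 1.5 * one.residual_norm + 1e-9

    def test_mixture_ratio_recovered(self, rng):
        a = 0.93
        n = 20000
        n1 = rng.binomial(n, a)
        Ds = np.concatenate([rng.normal(0.018, 0.008, n1),
                             rng.normal(0.09, 0.03, n - n1)])
        fit = fit_D_histogram(Ds, mode="two", fixed_a=a)
        mu1, mu2 = fit.params["mu1"], fit.params["mu2"]
        if mu1 > mu2:
            mu1, mu2 = mu2, mu1
        assert abs(mu2 / mu1 - 5.0) < 0.25 * 5.0

    def test_fixed_a_one_reduces_to_single(self, rng):
        Ds = rng.normal(0.05, 0.01, 2000)
        one = fit_D_histogram(Ds, mode="one")
        two = fit_D_histogram(Ds, mode="two", fixed_a=1.0)
        assert two.params["mu1"] == pytest.approx(one.params["mu"])
        assert two.params["sigma1"] == pytest.approx(one.params["sigma"])

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            fit_D_histogram(np.ones(50))


class TestLinkRadius:
    def test_printed_thresholds(self):
        # exact switch points (k*px)^2/(16*dt) round to the printed values
        eps = 1e-9
        d12 = (1 * 0.160) ** 2 / (16 * 0.0217)
        d23 = (2 * 0.160) ** 2 / (16 * 0.0217)
        assert round(d12, 4) == 0.0737
        assert round(d23, 3) == 0.295
        assert adaptive_link_radius(d12 - eps) == 1
        assert adaptive_link_radius(d12 + eps) == 2
        assert adaptive_link_radius(d23 - eps) == 2
        assert adaptive_link_radius(d23 + eps) == 3

    def test_example_value(self):
        assert adaptive_link_radius(0.05) == 1

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            adaptive_link_radius(-0.01)

    @settings(deadline=None, max_examples=60)
    @given(st.floats(min_value=0.0, max_value=2.0),
           st.floats(min_value=0.001, max_value=2.0))
    def test_nondecreasing_in_D(self, D, delta):
        assert adaptive_link_radius(D + delta) >= adaptive_link_radius(D)


class TestDataFrameAdapter:
    def test_round_trip_units(self):
        import pandas as pd
        df = pd.DataFrame({"movie_id": 0, "track_id": 0,
                           "frame": np.arange(4),
                           "x_px": [0.0, 1.0, 2.0, 3.0],
                           "y_px": [0.0, 0.0, 0.0, 0.0]})
        (t,) = tracks_from_dataframe(df, pixel_size=0.16, dt=DT)
        np.testing.assert_allclose(t.xy[:, 0], [0.0, 0.16, 0.32, 0.48])
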