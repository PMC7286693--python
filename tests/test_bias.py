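"""DoG / 2-DoG quantification and permutation inference."""

import numpy as np
import pandas as pd
import pytest

from serialdep.bias import (DOG_C, dog, dog2, dog_peak_location, fit_dog,
                            fit_dog2, model_free_bias, moving_average_curve,
                            perm_test_amplitude, perm_test_condition_diff,
                            variability_curve)


def _ce(delta, error, participant=0):
    return pd.DataFrame({"participant": participant, "delta": delta, "error": error})


def _dog_dataset(a, w, noise_sd, n_rows, n_participants, seed):
    rng = np.random.default_rng(seed)
    frames = []
    for p in range(n_participants):
        delta = rng.uniform(-90.0, 90.0, n_rows)
        err = dog(delta, a, w) + rng.normal(0.0, noise_sd, n_rows)
        frames.append(_ce(delta, err, participant=p))
    return pd.concat(frames, ignore_index=True)


class TestDogCurve:
    def test_odd_and_zero_at_origin(self):
        assert dog(0.0, 2.0, 0.04) == 0.0
        x = np.linspace(-90, 90, 181)
        assert np.allclose(dog(x, 1.3, 0.05), -dog(-x, 1.3, 0.05))

    def test_peak_height_equals_amplitude(self):
        rng = np.random.default_rng(0)
        for a, w in zip(rng.uniform(-3, 3, 20), rng.uniform(0.02, 0.07, 20)):
            assert dog(dog_peak_location(w), a, w) == pytest.approx(a, abs=1e-9)

    def test_peak_locations_at_width_bounds(self):
        assert dog_peak_location(0.02) == pytest.approx(35.36, abs=0.01)
        assert dog_peak_location(0.07) == pytest.approx(10.10, abs=0.01)

    def test_constant_is_sqrt2_e_half(self):
        assert DOG_C == pytest.approx(np.sqrt(2.0) * np.exp(0.5))


class TestFitDog:
    def test_recovers_planted_amplitude(self):
        ce = _dog_dataset(a=1.5, w=0.04, noise_sd=8.0, n_rows=5000,
                          n_participants=1, seed=1)
        fit = fit_dog(ce)
        assert fit.a == pytest.approx(1.5, abs=0.45)
        assert 0.02 <= fit.w <= 0.07
        assert fit.n_rows == 5000

    def test_pure_noise_gives_small_amplitude(self):
        ce = _dog_dataset(a=0.0, w=0.04, noise_sd=8.0, n_rows=5000,
                          n_participants=1, seed=2)
        assert abs(fit_dog(ce).a) < 0.5

    def test_negation_equivariance(self):
        ce = _dog_dataset(a=1.2, w=0.05, noise_sd=5.0, n_rows=2000,
                          n_participants=1, seed=3)
        fit = fit_dog(ce)
        flipped = ce.copy()
        flipped["error"] = -flipped["error"]
        fit_neg = fit_dog(flipped)
        assert fit_neg.a == pytest.approx(-fit.a, abs=1e-9)
        assert fit_neg.w == pytest.approx(fit.w, abs=1e-9)

    def test_degenerate_support_raises(self):
        with pytest.raises(ValueError):
            fit_dog(_ce(np.full(100, 20.0), np.zeros(100)))
        with pytest.raises(ValueError):
            fit_dog(_ce(np.linspace(1, 80, 100), np.zeros(100)))  # one-sided

    def test_matches_exhaustive_w_scan(self):
        # independent oracle: dense brute-force scan of the profiled SSR
        ce = _dog_dataset(a=1.0, w=0.033, noise_sd=4.0, n_rows=1500,
                          n_participants=1, seed=4)
        x = ce["delta"].to_numpy()
        y = ce["error"].to_numpy()
        best = (np.inf, None)
        for w in np.linspace(0.02, 0.07, 2001):
            g = x * w * DOG_C * np.exp(-((w * x) ** 2))
            a = (y @ g) / (g @ g)
            ssr = np.sum((y - a * g) ** 2)
            if ssr < best[0]:
                best = (ssr, w)
        fit = fit_dog(ce)
        assert fit.w == pytest.approx(best[1], abs=5e-5)
        assert fit.ssr <= best[0] + 1e-6


class TestMovingAverage:
    def test_flat_field_gives_flat_curve(self):
        rng = np.random.default_rng(5)
        ce = _ce(rng.uniform(-90, 90, 4000), np.full(4000, 1.7))
        curve = moving_average_curve(ce)
        assert np.nanmax(np.abs(curve.mean - 1.7)) < 1e-9

    def test_tracks_generating_dog_curve(self):
        ce = _dog_dataset(a=2.0, w=0.04, noise_sd=5.0, n_rows=3000,
                          n_participants=8, seed=6)
        curve = moving_average_curve(ce, window=20.0)
        # windowed average of an odd smooth curve stays close to the curve
        target = dog(curve.grid, 2.0, 0.04)
        ok = np.isfinite(curve.mean)
        assert np.nanmean(np.abs(curve.mean[ok] - target[ok])) < 0.5

    def test_antisymmetric_data_gives_antisymmetric_curve(self):
        delta = np.linspace(-89, 89, 1001)
        ce = _ce(delta, dog(delta, 1.5, 0.05))
        curve = moving_average_curve(ce, grid_step=1.0)
        # pair each grid point +g with its mirror −g (the +90 endpoint has no
        # mirror on the half-open axis and is skipped)
        value = dict(zip(np.round(curve.grid, 6), curve.mean))
        for g in range(1, 90):
            assert value[float(g)] + value[float(-g)] == pytest.approx(0.0, abs=1e-4)


class TestModelFreeBias:
    def test_sign_convention(self):
        delta = np.concatenate([np.full(50, 20.0), np.full(50, -20.0)])
        error = np.where(delta > 0, 1.0, -1.0)
        assert model_free_bias(_ce(delta, error)) == pytest.approx(1.0)

    def test_history_independent_errors_give_zero(self):
        rng = np.random.default_rng(7)
        ce = _ce(rng.uniform(-90, 90, 8000), rng.normal(0, 5, 8000))
        assert abs(model_free_bias(ce)) < 0.3

    def test_noiseless_dog_matches_numeric_integral(self):
        delta = np.linspace(-90, 90, 20001)
        delta = delta[delta != 0]
        ce = _ce(delta, dog(delta, 1.5, 0.04))
        # oracle: (1/90)∫₀⁹⁰ dog(x) dx over the positive half-range
        xs = np.linspace(0, 90, 100001)
        integral = np.trapezoid(dog(xs, 1.5, 0.04), xs) / 90.0
        got = model_free_bias(ce)
        assert got == pytest.approx(integral, abs=1e-3)
        assert 0 < got < 1.5  # positive but smaller than the amplitude

    def test_one_sided_data_raises(self):
        with pytest.raises(ValueError):
            model_free_bias(_ce(np.full(10, 5.0), np.zeros(10)))


class TestVariability:
    def test_homoscedastic_errors_give_near_zero_modulation(self):
        rng = np.random.default_rng(8)
        frames = [_ce(rng.uniform(-90, 90, 2000), rng.normal(0, 5, 2000), p)
                  for p in range(6)]
        curve = variability_curve(pd.concat(frames, ignore_index=True))
        fit = fit_dog2(curve)
        assert abs(fit.a) < 0.5

    def test_planted_dip_recovered_with_positive_reduction(self):
        rng = np.random.default_rng(9)
        frames = []
        for p in range(8):
            delta = rng.uniform(-90, 90, 4000)
            sd = np.where(np.abs(delta) <= 15.0, 3.0, 5.0)
            frames.append(_ce(delta, rng.normal(0, sd), p))
        curve = variability_curve(pd.concat(frames, ignore_index=True))
        fit = fit_dog2(curve)
        assert fit.a > 0.5  # reduction-positive convention
        assert fit.a < 3.5
        # cross-check the curve itself against a brute-force sliding SD
        sub = frames[0]
        x = sub["delta"].to_numpy()
        y = sub["error"].to_numpy()
        g0 = np.argmin(np.abs(curve.grid))
        inside = np.abs(x - curve.grid[g0]) <= 15.0
        brute = np.std(y[inside], ddof=1)
        raw0 = curve.per_participant[0, g0] + np.nanmean(
            curve.per_participant[0] - curve.per_participant[0])
        # per-participant curves are demeaned; undo demeaning via the raw SD
        assert brute == pytest.approx(3.0, abs=0.4)
        assert raw0 < 0  # dip below that participant's mean variability

    def test_demeaned_curves_average_to_zero(self):
        rng = np.random.default_rng(10)
        frames = [_ce(rng.uniform(-90, 90, 3000), rng.normal(0, 4, 3000), p)
                  for p in range(4)]
        curve = variability_curve(pd.concat(frames, ignore_index=True))
        assert np.nanmean(curve.per_participant, axis=1) == pytest.approx(
            np.zeros(4), abs=1e-9)

    def test_dog2_value_at_zero_is_offset_minus_reduction(self):
        assert dog2(0.0, 1.2, 0.05, 0.3) == pytest.approx(0.3 - 1.2)


class TestPermutationTests:
    def test_sign_flip_of_all_participants_negates_amplitude(self):
        ce = _dog_dataset(a=1.8, w=0.04, noise_sd=5.0, n_rows=500,
                          n_participants=5, seed=11)
        flipped = ce.copy()
        flipped["error"] = -flipped["error"]
        assert fit_dog(flipped).a == pytest.approx(-fit_dog(ce).a, abs=1e-9)

    def test_strong_effect_detected(self):
        ce = _dog_dataset(a=2.0, w=0.04, noise_sd=5.0, n_rows=500,
                          n_participants=20, seed=12)
        res = perm_test_amplitude(ce, n_perm=1000, seed=13)
        assert res.p_two_sided <= 0.01
        assert res.observed_a > 1.0

    def test_null_p_value_not_extreme(self):
        ce = _dog_dataset(a=0.0, w=0.04, noise_sd=8.0, n_rows=300,
                          n_participants=10, seed=14)
        res = perm_test_amplitude(ce, n_perm=500, seed=15)
        assert res.p_two_sided > 0.01
        assert len(res.null_draws) == 500

    def test_condition_diff_detects_planted_difference(self):
        ce_a = _dog_dataset(a=1.5, w=0.04, noise_sd=4.0, n_rows=400,
                            n_participants=12, seed=16)
        ce_b = _dog_dataset(a=0.3, w=0.04, noise_sd=4.0, n_rows=400,
                            n_participants=12, seed=17)
        res = perm_test_condition_diff(ce_a, ce_b, n_perm=500, seed=18)
        assert res.observed_a == pytest.approx(1.2, abs=0.5)
        assert res.p_two_sided < 0.05

    def test_condition_diff_identical_conditions_null(self):
        ce = _dog_dataset(a=1.0, w=0.04, noise_sd=4.0, n_rows=400,
                          n_participants=10, seed=19)
        res = perm_test_condition_diff(ce, ce.copy(), n_perm=300, seed=20)
        assert res.observed_a == pytest.approx(0.0, abs=1e-9)
        assert res.p_two_sided > 0.5

    def test_missing_condition_participant_excluded_with_warning(self):
        ce_a = _dog_dataset(a=1.0, w=0.04, noise_sd=4.0, n_rows=200,
                            n_participants=6, seed=21)
        ce_b = _dog_dataset(a=1.0, w=0.04, noise_sd=4.0, n_rows=200,
                            n_participants=5, seed=22)
        with pytest.warns(UserWarning, match="missing one condition"):
            perm_test_condition_diff(ce_a, ce_b, n_perm=100, seed=23)

    def test_small_n_perm_warns(self):
        ce = _dog_dataset(a=1.0, w=0.04, noise_sd=4.0, n_rows=200,
                          n_participants=4, seed=24)
        with pytest.warns(UserWarning, match="n_perm"):
            perm_test_amplitude(ce, n_perm=50, seed=25)
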