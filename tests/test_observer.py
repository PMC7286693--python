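"""Transition kernels, mixture priors, efficient likelihoods and decoding."""

import numpy as np
import pytest

from serialdep.bias import fit_dog
from serialdep.circular import signed_diff
from serialdep.observer import (DensityError, ObserverParams, OrientationGrid,
                                TransitionModel, decode, efficient_likelihood,
                                expected_estimate, gaussian_likelihood,
                                mixture_prior, mixture_weights,
                                simulate_batch, simulate_batch_multi,
                                simulate_sequence, single_step_prediction,
                                transition_pdf, with_variant)


def _centered_density(grid, mu, sigma):
    d = signed_diff(np.full(grid.n, mu), grid.centers)
    return grid.normalize(np.exp(-0.5 * (d / sigma) ** 2))


class TestTransitionPdf:
    def test_pure_uniform_when_p_same_zero(self, grid):
        k = transition_pdf(TransitionModel(0.0, 10.0), grid)
        assert np.allclose(k, 1.0 / 180.0)

    def test_integrates_to_one(self, grid):
        for p_same, s in [(0.3, 5.0), (0.8, 11.0), (1.0, 40.0)]:
            k = transition_pdf(TransitionModel(p_same, s), grid)
            assert k.sum() * grid.dx == pytest.approx(1.0, abs=1e-12)

    def test_matches_fine_grid_oracle_at_zero(self, grid):
        # oracle: normalise the mixture at 10x resolution, compare peak value
        tm = TransitionModel(0.5, 10.0)
        fine = OrientationGrid(3600)
        k = transition_pdf(tm, grid)
        k_fine = transition_pdf(tm, fine)
        assert k[0] == pytest.approx(k_fine[0], abs=1e-6)


class TestSingleStepPrediction:
    def test_delta_knowledge_returns_centered_kernel(self, grid):
        tm = TransitionModel(0.7, 12.0)
        delta = np.zeros(grid.n)
        i0 = 100
        delta[i0] = 1.0 / grid.dx
        pred = single_step_prediction(delta, tm, grid)
        kernel = transition_pdf(tm, grid)
        assert np.allclose(pred, np.roll(kernel, i0), atol=1e-9)

    def test_uniform_knowledge_stays_uniform(self, grid):
        pred = single_step_prediction(grid.uniform(), TransitionModel(0.9, 8.0), grid)
        assert np.allclose(pred, 1.0 / 180.0, atol=1e-12)

    def test_gaussian_widths_add_in_quadrature(self, grid):
        know = _centered_density(grid, 90.0, 5.0)
        pred = single_step_prediction(know, TransitionModel(1.0, 10.0), grid)
        # closed form: convolution of Gaussians, SD = sqrt(25 + 100)
        mean = grid.circ_mean(pred)
        var = np.sum(pred * signed_diff(grid.centers, np.full(grid.n, mean)) ** 2) * grid.dx
        assert np.sqrt(var) == pytest.approx(np.sqrt(125.0), rel=0.01)

    def test_unnormalized_input_rejected(self, grid):
        with pytest.raises(DensityError):
            single_step_prediction(np.ones(grid.n), TransitionModel(0.5, 10.0), grid)


class TestMixturePrior:
    def test_empty_buffer_is_uniform(self, grid):
        assert np.allclose(mixture_prior([], 2.0, grid), 1.0 / 180.0)

    def test_single_entry_returned_unchanged(self, grid):
        dens = _centered_density(grid, 45.0, 7.0)
        assert np.allclose(mixture_prior([dens], 3.0, grid), dens)

    def test_weights_sum_to_one_and_half_life_identity(self):
        tau = 3.7
        w = mixture_weights(50, tau)
        assert w.sum() == pytest.approx(1.0)
        # weight at lag tau*ln2 is half the lag-0 weight (exact in the formula)
        lag_half = tau * np.log(2.0)
        assert np.exp(-lag_half / tau) == pytest.approx(0.5, abs=1e-15)
        # discrete weights decay monotonically toward older entries
        assert np.all(np.diff(w) < 0)

    def test_tiny_tau_concentrates_on_most_recent(self, grid):
        old = _centered_density(grid, 30.0, 5.0)
        new = _centered_density(grid, 120.0, 5.0)
        mix = mixture_prior([old, new], 0.05, grid)
        assert np.allclose(mix, new, atol=1e-6)


class TestEfficientLikelihood:
    def test_uniform_prior_reduces_to_symmetric_gaussian(self, grid):
        m, lik = efficient_likelihood(70.0, grid.uniform(), 8.0, grid,
                                      measurement=70.0)
        m2, lik2 = gaussian_likelihood(70.0, 8.0, grid, measurement=70.0)
        assert m == m2 == 70.0
        assert np.allclose(lik, lik2, atol=1e-12)
        # symmetric about the measurement
        d = signed_diff(grid.centers, np.full(grid.n, 70.0))
        order = np.argsort(d)
        assert np.allclose(lik[order], lik[order][::-1], atol=1e-9)

    def test_skew_points_away_from_prior_peak(self, grid):
        # realistic prediction prior: Gaussian-plus-uniform mixture peaked at 90°
        prior = np.roll(transition_pdf(TransitionModel(0.8, 11.0), grid),
                        grid.n // 2)
        f_true = grid.cdf_at(prior, 105.0)
        _, lik = efficient_likelihood(105.0, prior, 8.0, grid, measurement=f_true)
        mean = grid.circ_mean(lik)
        d = signed_diff(grid.centers, np.full(grid.n, mean))
        third = np.sum(lik * d**3) * grid.dx
        assert third > 0  # long tail toward 180, away from the 90° prior peak
        assert signed_diff(mean, 105.0) > 0  # likelihood mass shifted away too

    def test_estimator_sd_smaller_at_prior_peak_than_flank(self, grid, full_params):
        prior = transition_pdf(TransitionModel(0.8, 11.0), grid)
        prior = np.roll(prior, grid.n // 2)  # peak at 90°
        enc_only = with_variant(full_params, "encode_only")
        _, sd_peak = expected_estimate(90.0, prior, enc_only, grid)
        _, sd_flank = expected_estimate(130.0, prior, enc_only, grid)
        assert sd_peak < sd_flank


class TestDecode:
    def test_uniform_prior_returns_likelihood(self, grid):
        _, lik = gaussian_likelihood(60.0, 6.0, grid, measurement=60.0)
        post, est = decode(lik, grid.uniform(), grid)
        assert np.allclose(post, lik, atol=1e-12)
        assert est == pytest.approx(60.0, abs=grid.dx)

    def test_conjugate_gaussian_posterior_mean(self, grid):
        lik = _centered_density(grid, 85.0, 4.0)
        prior = _centered_density(grid, 95.0, 6.0)
        post, est = decode(lik, prior, grid)
        expected = (85.0 / 16.0 + 95.0 / 36.0) / (1.0 / 16.0 + 1.0 / 36.0)
        assert est == pytest.approx(expected, abs=0.05)
        assert post.sum() * grid.dx == pytest.approx(1.0, abs=1e-12)


class TestSimulation:
    def test_first_trial_with_forced_true_measurement_is_unbiased(self, grid):
        # uniform priors on the first trial: estimate equals the stimulus
        _, lik = efficient_likelihood(42.0, grid.uniform(), 10.0, grid,
                                      measurement=42.0)
        _, est = decode(lik, grid.uniform(), grid)
        assert est == pytest.approx(42.0, abs=0.02)

    def test_scalar_and_batch_paths_agree(self, grid, full_params):
        rng = np.random.default_rng(0)
        stim = 180.0 - rng.random(60) * 180.0
        blocks = np.repeat([0, 1], 30)
        for variant in ("full", "decode_only", "encode_only", "single_prior"):
            params = (ObserverParams.single_prior(10.0, TransitionModel(0.8, 8.0), 1.5)
                      if variant == "single_prior" else with_variant(full_params, variant))
            scalar = [o.estimate for o in
                      simulate_sequence(stim, params, seed=5, blocks=blocks, grid=grid)]
            batch = simulate_batch(stim[None, :], params, seed=5, blocks=blocks,
                                   grid=grid)[0]
            assert np.allclose(scalar, batch, atol=1e-10)

    def test_multi_candidate_matches_single(self, grid, full_params):
        rng = np.random.default_rng(1)
        stim = 180.0 - rng.random((3, 40)) * 180.0
        other = ObserverParams(sigma_s=15.0, enc=full_params.enc,
                               dec=full_params.dec, tau_enc=4.0, tau_dec=1.0)
        multi = simulate_batch_multi(stim, [full_params, other], seed=3, grid=grid)
        single = simulate_batch(stim, full_params, seed=3, grid=grid)
        assert np.allclose(multi[0], single, atol=1e-12)

    def test_all_densities_stay_normalized(self, grid, full_params):
        rng = np.random.default_rng(2)
        stim = 180.0 - rng.random(30) * 180.0
        outs = simulate_sequence(stim, full_params, seed=7, grid=grid,
                                 retain_densities=True)
        for o in outs:
            for dens in (o.likelihood, o.prior_enc, o.prior_dec, o.posterior):
                assert dens.sum() * grid.dx == pytest.approx(1.0, abs=1e-8)

    def test_history_free_when_p_same_zero(self, coarse_grid):
        params = ObserverParams(sigma_s=10.0, enc=TransitionModel(0.0, 10.0),
                                dec=TransitionModel(0.0, 10.0),
                                tau_enc=8.0, tau_dec=1.5)
        rng = np.random.default_rng(3)
        stim = 180.0 - rng.random((8, 1500)) * 180.0
        est = simulate_batch(stim, params, seed=11, grid=coarse_grid)
        delta = signed_diff(stim[:, :-1], stim[:, 1:]).ravel()
        err = signed_diff(est[:, 1:], stim[:, 1:]).ravel()
        # null amplitude noise floor is ~0.1-0.2° at this n; no systematic bias
        assert abs(fit_dog((delta, err)).a) < 0.4

    def test_block_boundary_resets_history(self, coarse_grid, full_params):
        rng = np.random.default_rng(4)
        stim = 180.0 - rng.random(40) * 180.0
        blocks = np.repeat([0, 1], 20)
        outs = simulate_sequence(stim, full_params, seed=9, blocks=blocks,
                                 grid=coarse_grid, retain_densities=True)
        # first trial of the new block sees uniform priors again
        assert np.allclose(outs[20].prior_enc, 1.0 / 180.0)
        assert np.allclose(outs[20].prior_dec, 1.0 / 180.0)

    def test_invalid_variant_rejected(self, full_params):
        with pytest.raises(ValueError):
            ObserverParams(sigma_s=10.0, enc=full_params.enc, dec=full_params.dec,
                           tau_enc=1.0, tau_dec=1.0, variant="bogus")

    def test_parameter_bounds_enforced(self, full_params):
        with pytest.raises(ValueError):
            ObserverParams(sigma_s=60.0, enc=full_params.enc, dec=full_params.dec,
                           tau_enc=1.0, tau_dec=1.0)
        with pytest.raises(ValueError):
            TransitionModel(p_same=1.2, sigma_td=5.0)
        with pytest.raises(ValueError):
            TransitionModel(p_same=0.5, sigma_td=0.0)
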