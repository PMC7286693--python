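"""Ideal observer for orientation estimation in a temporally stable environment.

The observer family combines two history-dependent stages:

* **Efficient encoding** — sensory resources (Fisher information) are
  allocated in proportion to a prediction of the upcoming orientation, so
  that mutual information between stimulus and measurement is maximised.
  Operationally, the cumulative of the encoding prior defines a monotone
  mapping F(θ) onto a sensory space with uniform Fisher information; sensory
  noise is homogeneous Gaussian in that space, and mapping the measurement
  back to stimulus space yields a likelihood that is skewed away from the
  prior peak — the source of repulsive biases.
* **Bayesian decoding** — the (possibly skewed) likelihood is multiplied
  with a prediction of the current orientation and the posterior mean is
  reported, producing attractive biases toward recent history.

Predictions at both stages are exponential recency-weighted mixtures of
single-step predictions, each obtained by convolving knowledge about a past
stimulus with a transition kernel (Gaussian-plus-uniform mixture).  Encoding
predictions are based on past (normalised) likelihoods; decoding predictions
on past posteriors.  The two stages may use distinct transition kernels and
integration time constants, which is what lets the full model produce
short-term attraction and long-term repulsion concurrently.

Four variants are supported: ``decode_only`` (plain Gaussian likelihood,
history enters decoding only), ``encode_only`` (efficient likelihood,
uniform decoding prior), ``single_prior`` (one shared prediction for both
stages) and ``full`` (separate predictions).

All densities live on a uniform grid over (0, 180] and are kept normalised
(sum × binwidth = 1) after every operation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.fft import irfft, rfft

from .circular import wrap_orientation

VARIANTS = ("decode_only", "encode_only", "single_prior", "full")

_NORM_TOL = 1e-8


class DensityError(ValueError):
    """Raised when a grid density is unnormalised or degenerate."""


class OrientationGrid:
    """Uniform discretisation of the orientation domain (0, 180].

    Bin centers sit at (j + 1/2)·Δ with Δ = 180/n_bins.  Densities are
    arrays ρ with sum(ρ)·Δ = 1.
    """

    def __init__(self, n_bins: int = 360):
        if n_bins < 8 or n_bins % 2:
            raise ValueError("n_bins must be an even integer >= 8")
        self.n = int(n_bins)
        self.dx = 180.0 / self.n
        self.centers = self.dx * (np.arange(self.n) + 0.5)
        # signed offset of bin j relative to bin 0, wrapped to (-90, 90]
        off = np.mod(self.dx * np.arange(self.n), 180.0)
        self.offsets = np.where(off > 90.0, off - 180.0, off)
        two_theta = np.deg2rad(2.0 * self.centers)
        self._cos2 = np.cos(two_theta)
        self._sin2 = np.sin(two_theta)

    def uniform(self) -> np.ndarray:
        return np.full(self.n, 1.0 / 180.0)

    def normalize(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        s = values.sum(axis=-1, keepdims=True) * self.dx
        if np.any(~np.isfinite(s)) or np.any(s <= 0.0):
            raise DensityError("cannot normalize: non-finite or zero total mass")
        return values / s

    def check_density(self, rho: np.ndarray) -> np.ndarray:
        rho = np.asarray(rho, dtype=float)
        if rho.shape[-1] != self.n:
            raise DensityError(f"density has wrong length {rho.shape[-1]} != {self.n}")
        if np.any(np.abs(rho.sum(axis=-1) * self.dx - 1.0) > _NORM_TOL):
            raise DensityError("density does not integrate to 1")
        return rho

    def circ_mean(self, rho: np.ndarray) -> np.ndarray:
        """Posterior-mean readout: circular mean via angle doubling, in (0, 180]."""
        c = rho @ self._cos2
        s = rho @ self._sin2
        mean = 0.5 * np.degrees(np.arctan2(s, c))
        return wrap_orientation(mean)

    def wrapped_gaussian(self, mu_offsets: np.ndarray, sigma) -> np.ndarray:
        """Unnormalised wrapped Gaussian over signed offsets in (−90, 90].

        The k = ±1 wrap terms are included only when they are numerically
        relevant (σ > 18°, where the largest neglected term would exceed
        ~4e-6 of the peak); below that the central term alone is exact to
        well under the density tolerance.
        """
        d = np.asarray(mu_offsets, dtype=float)
        out = np.exp(-0.5 * (d / sigma) ** 2)
        if np.max(sigma) > 18.0:
            out = out + np.exp(-0.5 * ((d + 180.0) / sigma) ** 2)
            out = out + np.exp(-0.5 * ((d - 180.0) / sigma) ** 2)
        return out

    def cdf_map(self, rho: np.ndarray) -> np.ndarray:
        """Sensory mapping F(θ) = 180 × CDF of ``rho``, at the bin centers.

        The density is treated as piecewise constant, so the CDF is piecewise
        linear; at center j it equals the mass of bins 0..j−1 plus half the
        mass of bin j.  Supports a leading batch axis.
        """
        mass = rho * self.dx
        cum = np.cumsum(mass, axis=-1)
        return 180.0 * (cum - 0.5 * mass)

    def cdf_at(self, rho: np.ndarray, theta) -> np.ndarray:
        """F(θ) = 180 × CDF evaluated at arbitrary orientations θ ∈ (0, 180].

        ``rho`` may have a leading batch axis matching ``theta``.
        """
        theta = np.asarray(theta, dtype=float)
        j = np.minimum((theta / self.dx).astype(int), self.n - 1)
        mass = rho * self.dx
        cum = np.cumsum(mass, axis=-1)
        if rho.ndim == 1:
            below = np.where(j > 0, cum[j - 1], 0.0)
            dens = rho[j]
        else:
            rows = np.arange(rho.shape[0])
            below = np.where(j > 0, cum[rows, np.maximum(j - 1, 0)], 0.0)
            dens = rho[rows, j]
        return 180.0 * (below + dens * (theta - j * self.dx))


@dataclass(frozen=True)
class TransitionModel:
    """Gaussian-plus-uniform model of orientation change between trials.

    With probability ``p_same`` the new orientation is drawn from a wrapped
    Gaussian of SD ``sigma_td`` around the previous one; with probability
    1 − p_same it changes unpredictably (uniform on (0, 180]).
    """

    p_same: float
    sigma_td: float

    def __post_init__(self):
        if not 0.0 <= self.p_same <= 1.0:
            raise ValueError("p_same must be in [0, 1]")
        if self.sigma_td <= 0.0:
            raise ValueError("sigma_td must be > 0")


@dataclass(frozen=True)
class ObserverParams:
    """Parameters of the encoding-decoding observer.

    sigma_s : sensory noise SD in sensory-space degrees, 0 < sigma_s < 60
    enc, dec : transition models for the encoding and decoding predictions
    tau_enc, tau_dec : exponential integration time constants (trials)
    variant : one of decode_only / encode_only / single_prior / full
    motor_sd : wrapped-Gaussian motor noise added to the report (degrees)
    """

    sigma_s: float
    enc: TransitionModel
    dec: TransitionModel
    tau_enc: float
    tau_dec: float
    variant: str = "full"
    motor_sd: float = 0.0

    def __post_init__(self):
        if not 0.0 < self.sigma_s < 60.0:
            raise ValueError("sigma_s must be in (0, 60)")
        if self.tau_enc <= 0.0 or self.tau_dec <= 0.0:
            raise ValueError("integration time constants must be > 0")
        if self.motor_sd < 0.0:
            raise ValueError("motor_sd must be >= 0")
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected one of {VARIANTS}")
        if self.variant == "single_prior":
            if self.enc != self.dec or self.tau_enc != self.tau_dec:
                raise ValueError("single_prior requires enc == dec and tau_enc == tau_dec")

    @classmethod
    def single_prior(cls, sigma_s: float, tm: TransitionModel, tau: float, motor_sd: float = 0.0):
        return cls(sigma_s=sigma_s, enc=tm, dec=tm, tau_enc=tau, tau_dec=tau,
                   variant="single_prior", motor_sd=motor_sd)


@dataclass
class TrialOutput:
    """Per-trial record of a simulated observer."""

    estimate: float
    measurement: float
    likelihood: np.ndarray | None = None
    prior_enc: np.ndarray | None = None
    prior_dec: np.ndarray | None = None
    posterior: np.ndarray | None = None


@dataclass
class BeliefState:
    """Buffers of single-step predictions for the two mixture priors."""

    enc_predictions: list = field(default_factory=list)
    dec_predictions: list = field(default_factory=list)
    trial_count: int = 0

    def reset(self):
        self.enc_predictions.clear()
        self.dec_predictions.clear()
        self.trial_count = 0


def transition_pdf(tm: TransitionModel, grid: OrientationGrid) -> np.ndarray:
    """Transition kernel density over the grid's signed-offset axis.

    The Gaussian component is normalised numerically on the grid, so the
    kernel integrates to exactly 1 at the working resolution.
    """
    gauss = grid.wrapped_gaussian(grid.offsets, tm.sigma_td)
    gauss = grid.normalize(gauss)
    return tm.p_same * gauss + (1.0 - tm.p_same) * grid.uniform()


def _kernel_fft(kernel: np.ndarray, grid: OrientationGrid) -> np.ndarray:
    return rfft(kernel) * grid.dx


def single_step_prediction(knowledge: np.ndarray, tm: TransitionModel,
                           grid: OrientationGrid) -> np.ndarray:
    """Predict the next orientation by convolving knowledge with the transition.

    ``knowledge`` is the observer's (normalised) distribution over the
    previous orientation: the normalised likelihood at encoding, the
    posterior at decoding.
    """
    knowledge = grid.check_density(knowledge)
    kernel = transition_pdf(tm, grid)
    out = irfft(rfft(knowledge, axis=-1) * _kernel_fft(kernel, grid), n=grid.n, axis=-1)
    np.clip(out, 0.0, None, out=out)
    return grid.normalize(out)


def mixture_prior(buffer, tau: float, grid: OrientationGrid) -> np.ndarray:
    """Exponential recency-weighted mixture of buffered single-step predictions.

    The last buffer entry is the most recent prediction and receives the
    largest weight; weight at lag L is proportional to exp(−L/τ), normalised
    to sum to 1.  An empty buffer returns the uniform density (start of the
    inference process).
    """
    if tau <= 0.0:
        raise ValueError("tau must be > 0")
    buffer = list(buffer)
    if not buffer:
        return grid.uniform()
    lags = np.arange(len(buffer))[::-1]  # oldest entry has the largest lag
    w = np.exp(-lags / tau)
    w /= w.sum()
    mix = np.tensordot(w, np.asarray(buffer), axes=(0, 0))
    return grid.normalize(mix)


def mixture_weights(n: int, tau: float) -> np.ndarray:
    """Normalised exponential weights over lags 0..n−1 (lag 0 most recent)."""
    w = np.exp(-np.arange(n) / tau)
    return w / w.sum()


def _sensory_likelihood(measurement, f_centers, sigma_s, grid):
    d = np.mod(measurement - f_centers, 180.0)
    d = np.where(d > 90.0, d - 180.0, d)
    return grid.normalize(grid.wrapped_gaussian(d, sigma_s))


def efficient_likelihood(theta_true: float, prior: np.ndarray, sigma_s: float,
                         grid: OrientationGrid, rng=None, measurement=None):
    """Efficiently-coded measurement and likelihood for a single stimulus.

    The prior's cumulative defines the mapping F(θ) onto sensory space
    (scaled to (0, 180] so a uniform prior makes F the identity).  A
    measurement is sampled from a wrapped Gaussian of SD ``sigma_s`` around
    F(theta_true) — or taken from ``measurement`` if given — and the
    likelihood over θ is the sensory Gaussian evaluated at F(θ).  Because θ
    enters only through F, no Jacobian appears; the likelihood in stimulus
    space is skewed away from the prior peak.

    Returns ``(measurement, likelihood)`` with the likelihood normalised for
    storage.
    """
    prior = grid.check_density(prior)
    f_theta = grid.cdf_at(prior, theta_true)
    if measurement is None:
        if rng is None:
            raise ValueError("provide either rng or a fixed measurement")
        measurement = wrap_orientation(f_theta + sigma_s * rng.standard_normal())
    f_centers = grid.cdf_map(prior)
    lik = _sensory_likelihood(measurement, f_centers, sigma_s, grid)
    return float(measurement), lik


def gaussian_likelihood(theta_true: float, sigma_s: float, grid: OrientationGrid,
                        rng=None, measurement=None):
    """History-independent encoding: symmetric wrapped Gaussian likelihood."""
    if measurement is None:
        if rng is None:
            raise ValueError("provide either rng or a fixed measurement")
        measurement = wrap_orientation(theta_true + sigma_s * rng.standard_normal())
    d = np.mod(measurement - grid.centers, 180.0)
    d = np.where(d > 90.0, d - 180.0, d)
    lik = grid.normalize(grid.wrapped_gaussian(d, sigma_s))
    return float(measurement), lik


def decode(likelihood: np.ndarray, prior_dec: np.ndarray, grid: OrientationGrid):
    """Bayes rule: posterior ∝ likelihood × prior; report the posterior mean."""
    likelihood = grid.check_density(likelihood)
    prior_dec = grid.check_density(prior_dec)
    post = likelihood * prior_dec
    s = post.sum() * grid.dx
    if not np.isfinite(s) or s <= 0.0:
        raise DensityError("posterior has zero mass: grid-support pathology")
    post = post / s
    return post, float(grid.circ_mean(post))


def simulate_sequence(stimuli, params: ObserverParams, seed=None, blocks=None,
                      grid: OrientationGrid | None = None,
                      retain_densities: bool = False):
    """Simulate the observer on one stimulus sequence (reference implementation).

    ``blocks`` optionally gives a block label per trial; belief buffers are
    reset (uniform priors) at every block boundary, since predictions are
    only maintained within a block.  Returns a list of :class:`TrialOutput`.

    This scalar path is written for clarity out of the module's primitive
    operations; :func:`simulate_batch` is the fast path and is tested to
    agree with it.
    """
    grid = grid or OrientationGrid()
    stimuli = np.asarray(stimuli, dtype=float)
    if stimuli.size == 0:
        raise ValueError("stimuli must be nonempty")
    if blocks is None:
        blocks = np.zeros(stimuli.size)
    blocks = np.asarray(blocks)
    rng = np.random.default_rng(seed)
    belief = BeliefState()
    outputs = []
    for t, theta in enumerate(stimuli):
        if t > 0 and blocks[t] != blocks[t - 1]:
            belief.reset()
        if params.variant == "single_prior":
            shared = mixture_prior(belief.dec_predictions, params.tau_dec, grid)
            prior_enc, prior_dec = shared, shared
        else:
            prior_enc = mixture_prior(belief.enc_predictions, params.tau_enc, grid)
            prior_dec = mixture_prior(belief.dec_predictions, params.tau_dec, grid)
        if params.variant == "decode_only":
            m, lik = gaussian_likelihood(theta, params.sigma_s, grid, rng=rng)
        else:
            m, lik = efficient_likelihood(theta, prior_enc, params.sigma_s, grid, rng=rng)
        if params.variant == "encode_only":
            post, est = decode(lik, grid.uniform(), grid)
        else:
            post, est = decode(lik, prior_dec, grid)
        if params.motor_sd > 0.0:
            est = wrap_orientation(est + params.motor_sd * rng.standard_normal())
        if params.variant in ("full", "encode_only"):
            belief.enc_predictions.append(single_step_prediction(lik, params.enc, grid))
        if params.variant in ("full", "decode_only", "single_prior"):
            belief.dec_predictions.append(single_step_prediction(post, params.dec, grid))
        belief.trial_count += 1
        out = TrialOutput(estimate=est, measurement=m)
        if retain_densities:
            out.likelihood, out.prior_enc = lik, prior_enc
            out.prior_dec, out.posterior = prior_dec, post
        outputs.append(out)
    return outputs


def simulate_batch(stimuli: np.ndarray, params: ObserverParams, seed=None,
                   blocks=None, grid: OrientationGrid | None = None) -> np.ndarray:
    """Vectorised observer simulation over many sequences at once.

    ``stimuli`` has shape (n_seq, n_trials); all sequences share the same
    block structure (``blocks`` is a per-trial label vector).  Returns the
    matrix of reported estimates with the same shape.

    Mixture priors are maintained by the exact geometric recursion
    M_t = P_t + exp(−1/τ)·M_{t−1} (renormalised on use), equivalent to the
    explicit weighted sum over the full buffer.
    """
    return simulate_batch_multi(stimuli, [params], seed=seed, blocks=blocks,
                                grid=grid)[0]


def simulate_batch_multi(stimuli: np.ndarray, params_list, seed=None,
                         blocks=None, grid: OrientationGrid | None = None,
                         antithetic: bool = False) -> np.ndarray:
    """Simulate several same-variant parameterisations on shared sequences.

    All candidates see identical measurement-noise draws (common random
    numbers), which makes objective comparisons between candidates during a
    grid search well posed.  With ``antithetic=True`` the second half of the
    sequence rows receives the negated noise draws of the first half (the
    caller pairs rows accordingly), a variance-reduction device for
    Monte-Carlo curve estimates.  Returns estimates of shape
    (n_candidates, n_seq, n_trials).
    """
    grid = grid or OrientationGrid()
    stimuli = np.atleast_2d(np.asarray(stimuli, dtype=float))
    n_seq, n_trials = stimuli.shape
    if blocks is None:
        blocks = np.zeros(n_trials)
    blocks = np.asarray(blocks)
    rng = np.random.default_rng(seed)

    variant = params_list[0].variant
    if any(p.variant != variant for p in params_list):
        raise ValueError("all candidates must share the same variant")
    n_c = len(params_list)
    kern_enc = np.stack([_kernel_fft(transition_pdf(p.enc, grid), grid)
                         for p in params_list])[:, None, :]
    kern_dec = np.stack([_kernel_fft(transition_pdf(p.dec, grid), grid)
                         for p in params_list])[:, None, :]
    decay_enc = np.array([np.exp(-1.0 / p.tau_enc) for p in params_list])[:, None, None]
    decay_dec = np.array([np.exp(-1.0 / p.tau_dec) for p in params_list])[:, None, None]
    sigma_s = np.array([p.sigma_s for p in params_list])[:, None]
    motor_sd = np.array([p.motor_sd for p in params_list])[:, None]
    any_motor = np.any(motor_sd > 0.0)
    uniform = np.broadcast_to(grid.uniform(), (n_c, n_seq, grid.n))
    centers_b = np.broadcast_to(grid.centers, (n_c, n_seq, grid.n))
    rows = np.arange(n_seq)

    mix_enc = None  # unnormalised mixture accumulators, (n_c, n_seq, n)
    mix_dec = None
    estimates = np.empty((n_c, n_seq, n_trials))
    for t in range(n_trials):
        if t > 0 and blocks[t] != blocks[t - 1]:
            mix_enc = None
            mix_dec = None
        theta = stimuli[:, t]
        if variant == "single_prior":
            prior_enc = uniform if mix_dec is None else grid.normalize(mix_dec)
            prior_dec = prior_enc
        else:
            prior_enc = uniform if mix_enc is None else grid.normalize(mix_enc)
            prior_dec = uniform if mix_dec is None else grid.normalize(mix_dec)

        if antithetic:
            z = rng.standard_normal(n_seq // 2)
            noise = np.concatenate([z, -z])
        else:
            noise = rng.standard_normal(n_seq)
        if variant == "decode_only":
            f_theta = np.broadcast_to(theta, (n_c, n_seq))
            f_centers = centers_b
        else:
            mass = prior_enc * grid.dx
            cum = np.cumsum(mass, axis=-1)
            f_centers = 180.0 * (cum - 0.5 * mass)
            j = np.minimum((theta / grid.dx).astype(int), grid.n - 1)
            below = np.where(j > 0, cum[:, rows, np.maximum(j - 1, 0)], 0.0)
            f_theta = 180.0 * (below + prior_enc[:, rows, j] * grid.dx * 0
                               + prior_enc[:, rows, j] * (theta - j * grid.dx))
        m = wrap_orientation(f_theta + sigma_s * noise)
        d = np.mod(m[..., None] - f_centers, 180.0)
        d = np.where(d > 90.0, d - 180.0, d)
        lik = grid.normalize(grid.wrapped_gaussian(d, sigma_s[..., None]))

        if variant == "encode_only":
            post = lik
        else:
            post = grid.normalize(lik * prior_dec)
        est = grid.circ_mean(post)
        if any_motor:
            est = wrap_orientation(est + motor_sd * rng.standard_normal(n_seq))
        estimates[:, :, t] = est

        if variant in ("full", "encode_only"):
            pred = irfft(rfft(lik, axis=-1) * kern_enc, n=grid.n, axis=-1)
            np.clip(pred, 0.0, None, out=pred)
            pred = grid.normalize(pred)
            mix_enc = pred if mix_enc is None else pred + decay_enc * mix_enc
        if variant in ("full", "decode_only", "single_prior"):
            pred = irfft(rfft(post, axis=-1) * kern_dec, n=grid.n, axis=-1)
            np.clip(pred, 0.0, None, out=pred)
            pred = grid.normalize(pred)
            mix_dec = pred if mix_dec is None else pred + decay_dec * mix_dec
    return estimates


def expected_estimate(theta_true: float, prior_enc: np.ndarray, params: ObserverParams,
                      grid: OrientationGrid | None = None, prior_dec=None, n_quad: int = 61):
    """Deterministic single-trial statistics by quadrature over measurements.

    Integrates the estimate over the wrapped-Gaussian measurement
    distribution with Gauss–Hermite quadrature (``n_quad`` nodes).  Returns
    ``(mean_estimate, sd_estimate)`` where both are computed circularly
    (period 180).  ``prior_dec`` defaults to uniform (history-independent
    decoding), which is the configuration used to probe pure efficient-coding
    biases.
    """
    grid = grid or OrientationGrid()
    prior_enc = grid.check_density(prior_enc)
    if prior_dec is None:
        prior_dec = grid.uniform()
    nodes, weights = np.polynomial.hermite.hermgauss(n_quad)
    weights = weights / np.sqrt(np.pi)
    if params.variant == "decode_only":
        f_theta = theta_true
        f_centers = grid.centers
    else:
        f_theta = grid.cdf_at(prior_enc, theta_true)
        f_centers = grid.cdf_map(prior_enc)
    ests = np.empty(n_quad)
    for i, x in enumerate(nodes):
        m = wrap_orientation(f_theta + np.sqrt(2.0) * params.sigma_s * x)
        lik = _sensory_likelihood(m, f_centers, params.sigma_s, grid)
        _, ests[i] = decode(lik, prior_dec, grid)
    ang = np.deg2rad(2.0 * ests)
    c = weights @ np.cos(ang)
    s = weights @ np.sin(ang)
    mean = wrap_orientation(0.5 * np.degrees(np.arctan2(s, c)))
    r = min(np.hypot(c, s), 1.0)
    sd = np.degrees(np.sqrt(-2.0 * np.log(max(r, 1e-300)))) / 2.0
    return float(mean), float(sd)


def with_variant(params: ObserverParams, variant: str) -> ObserverParams:
    """Return a copy of ``params`` with a different variant flag."""
    return replace(params, variant=variant)
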