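"""2AFC inducer analysis: adapt-bin assignment, psychometric fits, ΔPSE and decay.

Trials are binned by the choice direction that repulsive adaptation to the
n-back inducer would favor.  If the n-back inducer was counter-clockwise of
the current right-hemifield 2AFC stimulus (or clockwise of the left-hemifield
one), repulsion pushes the perceived orientation so that a "right is more
clockwise" report becomes more likely: such trials land in the *adapt-right*
bin; the mirror cases land in *adapt-left*.  Trials whose relative
orientation is exactly 0° carry no predicted direction and are excluded
(counted).  Binning is done separately for same- and different-location
overlap between the n-back inducer and the current same-side 2AFC stimulus.

Per bin a psychometric function

    Ψ(x; α, β, λ) = λ + (1 − 2λ)·Φ((x − α)/β),   λ fixed at 0.01,

is fit by Bernoulli maximum likelihood, where x is the right-minus-left
orientation difference and α the point of subjective equality (PSE).  The
per-inducer perceptual bias is half the PSE difference between the two
adapt bins, signed so that positive values mark attraction toward the
inducer and negative values repulsion.  The decay of the bias over lags is
summarised by N(n) = N0·exp(−λ_d·n) with half-life t1/2 = ln 2 / λ_d.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit, minimize
from scipy.stats import norm

from .circular import signed_diff_free

PSE_BOUNDS = (-45.0, 45.0)
SLOPE_BOUNDS = (0.05, 50.0)


@dataclass
class PsychFit:
    alpha: float          # PSE (degrees)
    beta: float           # slope scale: SD of the cumulative Gaussian (degrees)
    lam: float = 0.01
    converged: bool = True


@dataclass
class DecayFit:
    n0: float             # initial bias (degrees, signed)
    lam: float            # decay constant (per trial)
    t_half_trials: float
    t_half_seconds: float | None
    r_squared: float


@dataclass
class BinResult:
    table: pd.DataFrame   # columns: participant, x, choice_right, adapt_bin, overlap
    n_excluded: int       # trials with zero relative orientation


def bin_adapt(table: pd.DataFrame, lag: int) -> BinResult:
    """Assign each eligible trial to an adapt-left / adapt-right bin.

    Eligible trials have their n-back inducer within the same block.  The
    relative orientation is that of the n-back inducer with respect to the
    current 2AFC stimulus on the inducer's side of fixation.
    """
    if lag < 1:
        raise ValueError("lag must be >= 1")
    frames = []
    n_excluded = 0
    for (participant, block), sub in table.groupby(["participant", "block"], sort=False):
        if len(sub) <= lag:
            continue
        sub = sub.sort_values("trial_index")
        side = sub["side"].to_numpy()
        sameside = np.where(side == "right",
                            sub["right_tilt"].to_numpy(float),
                            sub["left_tilt"].to_numpy(float))
        ind_tilt = sub["inducer_tilt"].to_numpy(float)
        ind_pos = sub["inducer_pos"].to_numpy()
        afc_pos = sub["afc_pos"].to_numpy()
        cur = slice(lag, None)
        prev = slice(None, -lag)
        rel = signed_diff_free(ind_tilt[prev], sameside[cur])
        zero = rel == 0.0
        n_excluded += int(zero.sum())
        right_side = side[cur] == "right"
        adapt_right = np.where(right_side, rel < 0, rel > 0)
        frame = pd.DataFrame({
            "participant": participant,
            "x": (sub["right_tilt"].to_numpy(float) - sub["left_tilt"].to_numpy(float))[cur],
            "choice_right": (sub["choice"].to_numpy() == "right")[cur],
            "adapt_bin": np.where(adapt_right, "adapt_right", "adapt_left"),
            "overlap": np.where(ind_pos[prev] == afc_pos[cur], "same", "different"),
        })
        frames.append(frame.loc[~zero])
    if not frames:
        raise ValueError(f"no eligible trials at lag {lag}")
    return BinResult(table=pd.concat(frames, ignore_index=True), n_excluded=n_excluded)


def fit_psychometric(df: pd.DataFrame, lapse: float = 0.01) -> PsychFit:
    """Maximum-likelihood cumulative-Gaussian psychometric fit.

    ``df`` needs columns ``x`` (right-minus-left orientation difference,
    degrees) and ``choice_right`` (bool).  The lapse rate is fixed.  With
    complete separation (all responses identical) the PSE runs to its bound
    and a warning is issued.
    """
    x = df["x"].to_numpy(float)
    r = df["choice_right"].to_numpy(bool)
    levels, inverse = np.unique(x, return_inverse=True)
    if levels.size < 2:
        raise ValueError("need at least 2 distinct orientation-difference levels")
    n = np.bincount(inverse)
    k = np.bincount(inverse, weights=r.astype(float))
    separated = r.all() or not r.any()
    if separated:
        warnings.warn("complete separation: PSE estimate pinned at its bound", stacklevel=2)

    def nll(theta):
        alpha, beta = theta
        psi = lapse + (1.0 - 2.0 * lapse) * norm.cdf((levels - alpha) / beta)
        psi = np.clip(psi, 1e-12, 1.0 - 1e-12)
        return -np.sum(k * np.log(psi) + (n - k) * np.log(1.0 - psi))

    p_hat = np.clip(k / n, 0.02, 0.98)
    z = norm.ppf(p_hat)
    slope, intercept = np.polyfit(levels, z, 1) if levels.size > 1 else (0.3, 0.0)
    beta0 = float(np.clip(1.0 / max(slope, 1e-3), *SLOPE_BOUNDS))
    alpha0 = float(np.clip(-intercept * beta0, *PSE_BOUNDS))
    res = minimize(nll, x0=[alpha0, beta0], method="L-BFGS-B",
                   bounds=[PSE_BOUNDS, SLOPE_BOUNDS])
    alpha, beta = res.x
    return PsychFit(alpha=float(alpha), beta=float(beta), lam=lapse,
                    converged=bool(res.success) and not separated)


def bias_from_delta_pse(fit_adapt_left: PsychFit, fit_adapt_right: PsychFit) -> float:
    """Per-inducer perceptual bias, 0.5·(PSE_adapt_right − PSE_adapt_left).

    Under repulsive adaptation the adapt-right bin's curve shifts toward
    'right' responses (PSE < 0) and the adapt-left bin's the other way, so
    repulsion yields a negative bias and attraction a positive one.
    Antisymmetric under bin exchange.
    """
    return 0.5 * (fit_adapt_right.alpha - fit_adapt_left.alpha)


def nback_bias_table(table: pd.DataFrame, lags=range(1, 11),
                     lapse: float = 0.01) -> pd.DataFrame:
    """Per-participant, per-lag, per-overlap bias estimates.

    For every lag the trials are adapt-binned; per participant and overlap
    condition a psychometric function is fit to each bin and the ΔPSE bias
    recorded.  Returns a tidy frame with columns ``participant, lag,
    overlap, bias``.
    """
    rows = []
    for lag in lags:
        binned = bin_adapt(table, lag).table
        for overlap in ("same", "different"):
            sub_o = binned[binned["overlap"] == overlap]
            for participant, sub in sub_o.groupby("participant", sort=True):
                left = sub[sub["adapt_bin"] == "adapt_left"]
                right = sub[sub["adapt_bin"] == "adapt_right"]
                if len(left) < 10 or len(right) < 10:
                    continue
                fit_l = fit_psychometric(left, lapse=lapse)
                fit_r = fit_psychometric(right, lapse=lapse)
                rows.append({"participant": participant, "lag": lag,
                             "overlap": overlap,
                             "bias": bias_from_delta_pse(fit_l, fit_r)})
    return pd.DataFrame(rows)


def group_bias_curve(bias_table: pd.DataFrame, overlap: str) -> pd.DataFrame:
    """Group-average bias per lag for one overlap condition."""
    sub = bias_table[bias_table["overlap"] == overlap]
    out = sub.groupby("lag")["bias"].agg(["mean", "sem", "count"]).reset_index()
    return out


def fit_decay(biases, lags, trial_duration_s: float | None = None) -> DecayFit:
    """Least-squares exponential decay fit N(n) = N0·exp(−λn) over lags.

    ``t_half_trials = ln 2 / λ`` (infinite, flagged by λ ≈ 0, for constant
    input); ``t_half_seconds`` additionally scales by the mean trial
    duration when given.  A poor fit (e.g. sign-alternating input) shows up
    as low ``r_squared``.
    """
    biases = np.asarray(biases, dtype=float)
    lags = np.asarray(lags, dtype=float)
    if biases.size < 3:
        raise ValueError("need at least 3 lags for a decay fit")

    def model(n, n0, lam):
        return n0 * np.exp(-lam * n)

    # log-linear start where the sign is consistent
    if np.all(biases > 0) or np.all(biases < 0):
        sign = np.sign(biases[0])
        slope, intercept = np.polyfit(lags, np.log(np.abs(biases)), 1)
        p0 = [sign * np.exp(intercept), max(-slope, 1e-3)]
    else:
        p0 = [biases[0] if biases[0] != 0 else 0.1, 0.1]
    try:
        popt, _ = curve_fit(model, lags, biases, p0=p0,
                            bounds=([-90.0, 0.0], [90.0, 10.0]), maxfev=10000)
    except RuntimeError:
        popt = p0
    n0, lam = float(popt[0]), float(popt[1])
    resid = biases - model(lags, n0, lam)
    ss_tot = float(np.sum((biases - biases.mean()) ** 2))
    r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 0.0
    t_half = np.log(2.0) / lam if lam > 0 else np.inf
    t_half_s = t_half * trial_duration_s if trial_duration_s is not None else None
    return DecayFit(n0=n0, lam=lam, t_half_trials=float(t_half),
                    t_half_seconds=t_half_s, r_squared=r2)
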