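"""Fitting observer variants to n-back serial-dependence curves.

The objective is the sum of squared residuals between the group-average
moving-average bias curves of the data (lags 1..L on a fixed
relative-orientation grid) and the same curves computed from simulating a
candidate observer on the participants' stimulus sequences.  The stochastic
simulation uses common random numbers — the same seed for every candidate —
so grid comparisons and local refinement are well posed.

Fitting proceeds in two stages: a coarse grid search over parameter
combinations, then bounded least-squares refinement from the grid optimum.
Parameter bounds: 0 < σs < 60, σtd > 0, 0 ≤ p_same ≤ 1, τ > 0.

Model evaluation follows an odd/even-block cross-validation: fit on odd
blocks, simulate the fitted observer on the even-block sequences, and score
the Pearson correlation between predicted and observed stacked curves
against a baseline in which the model's trial-level predicted responses are
shuffled within each participant (1000 permutations by default).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .bias import _window_stats
from .circular import signed_diff
from .observer import (ObserverParams, TransitionModel, simulate_batch,
                       simulate_batch_multi)
from .preprocessing import condition_on_nback
from .synth import design_matrices

PARAM_NAMES = {
    "decode_only": ("sigma_s", "sigma_td_dec", "p_same_dec", "tau_dec"),
    "encode_only": ("sigma_s", "sigma_td_enc", "p_same_enc", "tau_enc"),
    "single_prior": ("sigma_s", "sigma_td", "p_same", "tau"),
    "full": ("sigma_s", "sigma_td_enc", "p_same_enc", "tau_enc",
             "sigma_td_dec", "p_same_dec", "tau_dec"),
}

_BOUNDS = {
    "sigma_s": (0.5, 59.5),
    "sigma_td": (0.5, 80.0),
    "p_same": (0.0, 1.0),
    "tau": (0.05, 60.0),
}

DEFAULT_GRID = {
    "sigma_s": (5.0, 10.0, 15.0, 20.0, 25.0, 30.0),
    "sigma_td": (5.0, 10.0, 15.0, 20.0, 30.0),
    "p_same": (0.2, 0.5, 0.8, 1.0),
    "tau": (0.5, 1.0, 2.0, 4.0, 8.0, 16.0),
}


def _bound_for(name: str):
    for key, b in _BOUNDS.items():
        if name == key or name.startswith(key):
            return b
    raise KeyError(name)


def params_from_vector(variant: str, vec) -> ObserverParams:
    """Build ObserverParams from the variant's free-parameter vector."""
    names = PARAM_NAMES[variant]
    vals = dict(zip(names, map(float, vec)))
    if variant == "decode_only":
        tm = TransitionModel(vals["p_same_dec"], vals["sigma_td_dec"])
        return ObserverParams(vals["sigma_s"], enc=tm, dec=tm,
                              tau_enc=vals["tau_dec"], tau_dec=vals["tau_dec"],
                              variant=variant)
    if variant == "encode_only":
        tm = TransitionModel(vals["p_same_enc"], vals["sigma_td_enc"])
        return ObserverParams(vals["sigma_s"], enc=tm, dec=tm,
                              tau_enc=vals["tau_enc"], tau_dec=vals["tau_enc"],
                              variant=variant)
    if variant == "single_prior":
        tm = TransitionModel(vals["p_same"], vals["sigma_td"])
        return ObserverParams.single_prior(vals["sigma_s"], tm, vals["tau"])
    enc = TransitionModel(vals["p_same_enc"], vals["sigma_td_enc"])
    dec = TransitionModel(vals["p_same_dec"], vals["sigma_td_dec"])
    return ObserverParams(vals["sigma_s"], enc=enc, dec=dec,
                          tau_enc=vals["tau_enc"], tau_dec=vals["tau_dec"],
                          variant="full")


def vector_from_params(variant: str, params: ObserverParams) -> np.ndarray:
    lookup = {
        "sigma_s": params.sigma_s,
        "sigma_td_enc": params.enc.sigma_td, "p_same_enc": params.enc.p_same,
        "tau_enc": params.tau_enc,
        "sigma_td_dec": params.dec.sigma_td, "p_same_dec": params.dec.p_same,
        "tau_dec": params.tau_dec,
        "sigma_td": params.dec.sigma_td, "p_same": params.dec.p_same,
        "tau": params.tau_dec,
    }
    return np.array([lookup[n] for n in PARAM_NAMES[variant]])


@dataclass
class CurveStack:
    """Stacked 1..L-back group-average bias curves on a common delta grid."""

    lags: np.ndarray
    grid: np.ndarray
    matrix: np.ndarray  # (n_lags, n_grid), NaN where no data

    @property
    def vector(self) -> np.ndarray:
        return self.matrix.ravel()


@dataclass
class FitResult:
    variant: str
    params: ObserverParams
    ssr: float
    grid_params: ObserverParams
    grid_ssr: float
    refined: bool


@dataclass
class CVResult:
    r: float
    p_perm: float
    n_perm: int
    fit: FitResult


def bias_curves(table: pd.DataFrame, lags=range(1, 21), window: float = 30.0,
                grid_step: float = 3.0) -> CurveStack:
    """Group-average moving-average bias curves for each lag, from a trial table."""
    lags = np.asarray(list(lags))
    grid = np.arange(-90.0 + grid_step, 90.0 + grid_step / 2, grid_step)
    mat = np.full((lags.size, grid.size), np.nan)
    for i, lag in enumerate(lags):
        ce = condition_on_nback(table, int(lag))
        if not len(ce):
            continue
        parts = ce["participant"].unique()
        curves = np.full((parts.size, grid.size), np.nan)
        for j, p in enumerate(parts):
            sub = ce[ce["participant"] == p]
            curves[j] = _window_stats(sub["delta"].to_numpy(float),
                                      sub["error"].to_numpy(float),
                                      grid, window / 2.0, "mean")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            mat[i] = np.nanmean(curves, axis=0)
    return CurveStack(lags=lags, grid=grid, matrix=mat)


def curves_from_matrices(stim: np.ndarray, est: np.ndarray, blocks: np.ndarray,
                         lags, window: float = 30.0, grid_step: float = 3.0,
                         rows_per_participant: int = 1) -> CurveStack:
    """Bias curves computed directly from stimulus/estimate matrices.

    ``est`` may hold several simulation repetitions per stimulus sequence
    (``rows_per_participant`` consecutive rows per participant); repetitions
    are pooled into that participant's curve.
    """
    lags = np.asarray(list(lags))
    grid = np.arange(-90.0 + grid_step, 90.0 + grid_step / 2, grid_step)
    n_rows = est.shape[0]
    n_parts = n_rows // rows_per_participant
    stim_rows = np.repeat(stim, rows_per_participant, axis=0) if stim.shape[0] != n_rows else stim
    mat = np.full((lags.size, grid.size), np.nan)
    t = np.arange(stim.shape[1])
    for i, lag in enumerate(lags):
        valid = t[lag:][blocks[lag:] == blocks[:-lag]]
        if valid.size == 0:
            continue
        delta = signed_diff(stim_rows[:, valid - lag], stim_rows[:, valid])
        err = signed_diff(est[:, valid], stim_rows[:, valid])
        curves = np.empty((n_parts, grid.size))
        for p in range(n_parts):
            rows = slice(p * rows_per_participant, (p + 1) * rows_per_participant)
            curves[p] = _window_stats(delta[rows].ravel(), err[rows].ravel(),
                                      grid, window / 2.0, "mean")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            mat[i] = np.nanmean(curves, axis=0)
    return CurveStack(lags=lags, grid=grid, matrix=mat)


def model_curves(candidate: ObserverParams, stim: np.ndarray, blocks: np.ndarray,
                 seed, n_reps: int = 10, lags=range(1, 21), window: float = 30.0,
                 grid_step: float = 3.0, sim_grid=None) -> CurveStack:
    """Simulate a candidate on the given sequences and compute its bias curves."""
    stim_rep = np.repeat(stim, n_reps, axis=0)
    est = simulate_batch(stim_rep, candidate, seed=seed, blocks=blocks, grid=sim_grid)
    return curves_from_matrices(stim, est, blocks, lags, window, grid_step,
                                rows_per_participant=n_reps)


def objective_ssr(candidate: ObserverParams, data: CurveStack, stim: np.ndarray,
                  blocks: np.ndarray, seed, n_reps: int = 10,
                  window: float = 30.0, sim_grid=None) -> float:
    """SSR between candidate-model and data curves (common random numbers)."""
    model = model_curves(candidate, stim, blocks, seed=seed, n_reps=n_reps,
                         lags=data.lags, window=window,
                         grid_step=float(data.grid[1] - data.grid[0]),
                         sim_grid=sim_grid)
    diff = model.vector - data.vector
    return float(np.nansum(diff * diff))


def cross_ssr(candidate_or_list, data: CurveStack, stim: np.ndarray,
              blocks: np.ndarray, seed, n_reps: int = 4,
              window: float = 30.0, sim_grid=None) -> np.ndarray:
    """Debiased SSR estimate from two independent half-budget model curves.

    The plain SSR of Monte-Carlo model curves contains the curves' own
    sampling variance, which penalises high-noise candidates when the
    simulation budget is small.  Splitting the ``2·n_reps`` repetitions into
    two halves and scoring Σ (m₁ − d)(m₂ − d) removes that variance term
    (the data's own noise enters only as a candidate-independent constant),
    leaving an unbiased estimate of the true curve mismatch up to that
    constant.  Accepts one candidate or a list (all same variant, simulated
    with common random numbers); returns an array of scores.
    """
    single = isinstance(candidate_or_list, ObserverParams)
    cands = [candidate_or_list] if single else list(candidate_or_list)
    n_seq = stim.shape[0]
    n_rep_total = 2 * n_reps
    # rep-major layout so that rep r and rep r + n_reps share (negated) noise
    stim_rep = np.tile(stim, (n_rep_total, 1))
    use_anti = n_reps % 2 == 0
    est = simulate_batch_multi(stim_rep, cands, seed=seed, blocks=blocks,
                               grid=sim_grid, antithetic=use_anti)
    rows_idx = np.arange(n_rep_total * n_seq)
    rep_of_row = rows_idx // n_seq
    part_of_row = rows_idx % n_seq
    if use_anti:
        # each half holds matched antithetic pairs; halves stay independent
        h1_reps = list(range(n_reps // 2)) + list(range(n_reps, n_reps + n_reps // 2))
    else:
        h1_reps = list(range(n_reps))
    in_h1 = np.isin(rep_of_row, h1_reps)
    h1 = rows_idx[in_h1]
    h1 = h1[np.argsort(part_of_row[h1], kind="stable")]
    h2 = rows_idx[~in_h1]
    h2 = h2[np.argsort(part_of_row[h2], kind="stable")]
    grid_step = float(data.grid[1] - data.grid[0])
    d = data.vector
    scores = np.empty(len(cands))
    for i in range(len(cands)):
        c1 = curves_from_matrices(stim, est[i][h1], blocks, data.lags,
                                  window, grid_step, rows_per_participant=n_reps)
        c2 = curves_from_matrices(stim, est[i][h2], blocks, data.lags,
                                  window, grid_step, rows_per_participant=n_reps)
        ok = np.isfinite(c1.vector) & np.isfinite(c2.vector) & np.isfinite(d)
        scores[i] = np.sum((c1.vector[ok] - d[ok]) * (c2.vector[ok] - d[ok]))
    return scores if not single else scores[:1]


def _grid_candidates(variant: str, grid_spec: dict):
    names = PARAM_NAMES[variant]
    axes = []
    for name in names:
        if name in grid_spec:
            axes.append(grid_spec[name])
        else:
            base = next(k for k in ("sigma_s", "sigma_td", "p_same", "tau")
                        if name == k or name.startswith(k))
            axes.append(grid_spec.get(base, DEFAULT_GRID[base]))
    return itertools.product(*axes)


def fit_observer(variant: str, data: CurveStack, stim: np.ndarray,
                 blocks: np.ndarray, grid_spec: dict | None = None, seed=0,
                 n_reps: int = 10, window: float = 30.0, refine: bool = True,
                 max_nfev: int = 40, objective: str = "cross",
                 chunk: int = 64, sim_grid=None, screen_top: int = 24,
                 refine_method: str = "least_squares", n_starts: int = 1,
                 verbose: bool = False) -> FitResult:
    """Two-stage observer fit: coarse grid search, then bounded refinement.

    Every candidate is evaluated with the same simulation seed (common
    random numbers), making the objective deterministic.  The grid stage
    scores candidates with the debiased :func:`cross_ssr` by default
    (``objective='ssr'`` selects the plain SSR); candidates are simulated
    together in chunks, sharing noise draws.  If the local least-squares
    refinement fails or does not improve, the grid-stage result is returned
    flagged unrefined.
    """
    grid_spec = grid_spec or {}
    vecs, cands = [], []
    for cand in _grid_candidates(variant, grid_spec):
        vec = np.asarray(cand, dtype=float)
        try:
            cands.append(params_from_vector(variant, vec))
        except ValueError:
            continue
        vecs.append(vec)
    if not cands:
        raise ValueError("empty or infeasible parameter grid")
    def _score(cand_subset, reps, pass_seed):
        out = np.empty(len(cand_subset))
        for start in range(0, len(cand_subset), chunk):
            sub = cand_subset[start:start + chunk]
            if objective == "cross":
                out[start:start + len(sub)] = cross_ssr(
                    sub, data, stim, blocks, seed=pass_seed,
                    n_reps=max(reps // 2, 1), window=window, sim_grid=sim_grid)
            else:
                for k, c in enumerate(sub):
                    out[start + k] = objective_ssr(c, data, stim, blocks,
                                                   seed=pass_seed, n_reps=reps,
                                                   window=window, sim_grid=sim_grid)
            if verbose:
                print(f"  grid {start + len(sub)}/{len(cand_subset)}")
        return out

    # screening pass over the whole grid, then a higher-budget re-score of the
    # leaders on fresh noise (avoids the winner's-curse of noisy selection)
    scores = _score(cands, n_reps, seed)
    if screen_top and screen_top < len(cands):
        leaders = np.argsort(scores)[:screen_top]
        rescored = _score([cands[i] for i in leaders], 4 * n_reps,
                          None if seed is None else seed + 1)
        best = int(leaders[int(np.argmin(rescored))])
        best_score = float(rescored[int(np.argmin(rescored))])
    else:
        best = int(np.argmin(scores))
        best_score = float(scores[best])
    best_vec, best_ssr = vecs[best], best_score
    grid_params = cands[best]

    if not refine:
        return FitResult(variant, grid_params, best_ssr, grid_params, best_ssr, False)

    if refine_method == "nelder-mead":
        starts = [best_vec]
        if n_starts > 1 and screen_top and screen_top < len(cands):
            # add leaders from a different sigma_s basin (ridge insurance)
            order = leaders[np.argsort(rescored)]
            for idx in order[1:]:
                if len(starts) >= n_starts:
                    break
                vec = vecs[int(idx)]
                if all(abs(vec[0] - s[0]) > 2.0 for s in starts):
                    starts.append(vec)
        return _refine_nm(variant, data, stim, blocks, starts, best_ssr, seed,
                          n_reps, window, max_nfev, sim_grid)

    # refinement minimises the plain SSR; re-score the grid optimum on that scale
    best_ssr = objective_ssr(grid_params, data, stim, blocks, seed=seed,
                             n_reps=n_reps, window=window, sim_grid=sim_grid)
    names = PARAM_NAMES[variant]
    lo = np.array([_bound_for(n)[0] for n in names])
    hi = np.array([_bound_for(n)[1] for n in names])
    finite = np.isfinite(data.vector)
    target = data.vector[finite]

    def residuals(vec):
        params = params_from_vector(variant, np.clip(vec, lo, hi))
        model = model_curves(params, stim, blocks, seed=seed, n_reps=n_reps,
                             lags=data.lags, window=window,
                             grid_step=float(data.grid[1] - data.grid[0]),
                             sim_grid=sim_grid)
        resid = model.vector[finite] - target
        return np.nan_to_num(resid, nan=0.0)

    try:
        sol = least_squares(residuals, x0=np.clip(best_vec, lo, hi),
                            bounds=(lo, hi), diff_step=0.05, max_nfev=max_nfev)
        refined_params = params_from_vector(variant, sol.x)
        refined_ssr = float(2.0 * sol.cost)
    except Exception as exc:  # refinement failure falls back to grid stage
        warnings.warn(f"refinement failed ({exc}); returning grid-stage fit", stacklevel=2)
        return FitResult(variant, grid_params, best_ssr, grid_params, best_ssr, False)
    if refined_ssr <= best_ssr + 1e-9:
        return FitResult(variant, refined_params, refined_ssr, grid_params, best_ssr, True)
    return FitResult(variant, grid_params, best_ssr, grid_params, best_ssr, False)


def _refine_nm(variant, data, stim, blocks, start_vecs, start_score, seed,
               n_reps, window, max_nfev, sim_grid) -> FitResult:
    """Nelder–Mead refinement on the debiased cross-SSR objective.

    The objective is deterministic under the frozen seed (common random
    numbers), so the simplex walks a fixed surface; bounds are enforced by
    clipping.  One simplex is started per entry of ``start_vecs`` (grid
    leaders from different basins); the winner is chosen by a common
    higher-repetition evaluation on fresh noise, falling back to the grid
    optimum if no refined point beats it.
    """
    from scipy.optimize import minimize

    names = PARAM_NAMES[variant]
    lo = np.array([_bound_for(n)[0] for n in names])
    hi = np.array([_bound_for(n)[1] for n in names])
    half = max(n_reps // 2, 1)

    def f(vec):
        params = params_from_vector(variant, np.clip(vec, lo, hi))
        return float(cross_ssr(params, data, stim, blocks, seed=seed,
                               n_reps=half, window=window,
                               sim_grid=sim_grid)[0])

    grid_params = params_from_vector(variant, start_vecs[0])
    refined = []
    for x0 in start_vecs:
        try:
            res = minimize(f, x0=np.asarray(x0, dtype=float),
                           method="Nelder-Mead",
                           options={"maxfev": max_nfev, "xatol": 0.05,
                                    "fatol": 0.1})
        except Exception as exc:
            warnings.warn(f"refinement start failed ({exc})", stacklevel=3)
            continue
        refined.append(params_from_vector(variant, np.clip(res.x, lo, hi)))
    if not refined:
        warnings.warn("all refinement starts failed; returning grid-stage fit",
                      stacklevel=3)
        return FitResult(variant, grid_params, start_score, grid_params,
                         start_score, False)
    # common high-budget comparison on fresh noise
    check_seed = None if seed is None else seed + 7919
    scores = cross_ssr([grid_params] + refined, data, stim, blocks,
                       seed=check_seed, n_reps=2 * n_reps, window=window,
                       sim_grid=sim_grid)
    best = int(np.argmin(scores))
    if best == 0:
        return FitResult(variant, grid_params, float(scores[0]), grid_params,
                         start_score, False)
    return FitResult(variant, refined[best - 1], float(scores[best]),
                     grid_params, start_score, True)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if a.size < 3 or a.std() == 0 or b.std() == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def cross_validate(variant: str, table: pd.DataFrame, grid_spec: dict | None = None,
                   seed=0, n_reps: int = 10, lags=range(1, 21),
                   window: float = 30.0, grid_step: float = 3.0,
                   n_perm: int = 1000, refine: bool = True,
                   max_nfev: int = 40, sim_grid=None) -> CVResult:
    """Odd/even-block cross-validation of an observer variant.

    The variant is fit to the bias curves of each participant's odd-numbered
    blocks, the fitted observer is simulated on the even-block stimulus
    sequences, and the Pearson correlation between predicted and observed
    stacked curves is compared against a null in which the model's predicted
    responses are shuffled across trials within each participant.
    Participants with fewer than two blocks are excluded with a warning.
    """
    keep = []
    for p, sub in table.groupby("participant"):
        if sub["block"].nunique() >= 2:
            keep.append(p)
        else:
            warnings.warn(f"participant {p} has a single block; excluded", stacklevel=2)
    table = table[table["participant"].isin(keep)]

    def half(parity):
        parts = []
        for p, sub in table.groupby("participant"):
            order = {b: i for i, b in enumerate(sorted(sub["block"].unique()))}
            sel = sub["block"].map(lambda b: order[b] % 2 == parity)
            parts.append(sub[sel])
        return pd.concat(parts, ignore_index=True)

    train, test = half(0), half(1)
    train_curves = bias_curves(train, lags=lags, window=window, grid_step=grid_step)
    stim_tr, blocks_tr, _ = design_matrices(train)
    fit = fit_observer(variant, train_curves, stim_tr, blocks_tr,
                       grid_spec=grid_spec, seed=seed, n_reps=n_reps,
                       window=window, refine=refine, max_nfev=max_nfev,
                       sim_grid=sim_grid)

    test_curves = bias_curves(test, lags=lags, window=window, grid_step=grid_step)
    stim_te, blocks_te, _ = design_matrices(test)
    stim_rep = np.repeat(stim_te, n_reps, axis=0)
    est = simulate_batch(stim_rep, fit.params, seed=seed, blocks=blocks_te,
                         grid=sim_grid)
    pred = curves_from_matrices(stim_te, est, blocks_te, lags, window, grid_step,
                                rows_per_participant=n_reps)
    r_obs = _pearson(pred.vector, test_curves.vector)

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        shuffled = est.copy()
        for row in range(shuffled.shape[0]):
            rng.shuffle(shuffled[row])
        perm = curves_from_matrices(stim_te, shuffled, blocks_te, lags, window,
                                    grid_step, rows_per_participant=n_reps)
        null[i] = _pearson(perm.vector, test_curves.vector)
    p = float(np.mean(null >= r_obs))
    return CVResult(r=r_obs, p_perm=max(p, 1.0 / n_perm), n_perm=n_perm, fit=fit)


def half_life_trials(tau: float) -> float:
    """Half-life of the exponential integration weights, τ·ln 2 (trials)."""
    return tau * np.log(2.0)


def half_life_seconds(tau: float, trial_duration_s: float) -> float:
    """Half-life converted to seconds via the mean trial duration."""
    return half_life_trials(tau) * trial_duration_s
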