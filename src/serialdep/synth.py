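"""Synthetic experiment designs and observer-generated responses.

Templates mirror the four study designs this package analyses:

* ``exp1`` — orientation adjustment, 23 participants × 10 blocks × 82
  trials, hemifield alternating between blocks, mean trial duration 5.38 s.
* ``exp2`` — as exp1 but stimulus position varies between two locations on
  a trial-by-trial basis, counterbalanced over consecutive trials;
  24 × 8 × 101 trials, 6.55 s.
* ``exp3`` — variable working-memory delay ({short, long}) counterbalanced
  over consecutive trials; 24 × 12 × 101 trials, 8.25 s.
* ``exp4`` — adjustment inducer followed by a 2AFC comparison; 24 × 8 × 56
  trials; inducer tilted ±20° from the same-side 2AFC stimulus, 2AFC
  orientation differences in {−9, −6, −3, 0, 3, 6, 9}°.

Stimulus orientations are uniform on (0, 180].  Responses come from a
parameterised ideal observer (plus optional uniform lapses); everything is
deterministic under (spec, truth, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .circular import signed_diff_free, wrap_orientation
from .observer import ObserverParams, TransitionModel, simulate_batch

TEMPLATE_DEFAULTS = {
    "exp1": dict(n_participants=23, n_blocks=10, trials_per_block=82, trial_duration_s=5.38),
    "exp2": dict(n_participants=24, n_blocks=8, trials_per_block=101, trial_duration_s=6.55),
    "exp3": dict(n_participants=24, n_blocks=12, trials_per_block=101, trial_duration_s=8.25),
    "exp4": dict(n_participants=24, n_blocks=8, trials_per_block=56, trial_duration_s=10.0),
}

AFC_LEVELS = np.arange(-9.0, 9.1, 3.0)
AFC_TILT_RANGE = 14.5
INDUCER_OFFSET = 20.0


@dataclass(frozen=True)
class DesignSpec:
    """Experiment geometry; template fills unspecified fields."""

    experiment_template: str = "exp1"
    n_participants: int | None = None
    n_blocks: int | None = None
    trials_per_block: int | None = None
    trial_duration_s: float | None = None
    seed: int = 0

    def resolved(self) -> dict:
        if self.experiment_template not in TEMPLATE_DEFAULTS:
            raise ValueError(f"unknown template {self.experiment_template!r}")
        out = dict(TEMPLATE_DEFAULTS[self.experiment_template])
        for key in ("n_participants", "n_blocks", "trials_per_block", "trial_duration_s"):
            val = getattr(self, key)
            if val is not None:
                out[key] = val
        return out


def default_observer(variant: str = "full") -> ObserverParams:
    """Canonical generating observer.

    Parameter values are representative of the fits to human adjustment
    data: moderate sensory noise (σs = 10°), a broader/slower encoding
    prediction (σtd = 11°, τ = 8 trials) and a narrower/faster decoding
    prediction (σtd = 8°, τ = 1.5 trials), both with p_same = 0.8.
    """
    params = ObserverParams(
        sigma_s=10.0,
        enc=TransitionModel(p_same=0.8, sigma_td=11.0),
        dec=TransitionModel(p_same=0.8, sigma_td=8.0),
        tau_enc=8.0,
        tau_dec=1.5,
        variant="full",
    )
    if variant == "single_prior":
        return ObserverParams.single_prior(10.0, TransitionModel(0.8, 8.0), 1.5)
    if variant != "full":
        from .observer import with_variant

        return with_variant(params, variant)
    return params


@dataclass(frozen=True)
class GroundTruth:
    """Generating observer plus response-stage nuisance processes."""

    observer: ObserverParams = field(default_factory=default_observer)
    lapse_rate: float = 0.0
    seed: int = 0


def _balanced_transitions(n_trials: int, labels, rng) -> np.ndarray:
    """Binary label sequence with same/different transitions counterbalanced."""
    n_tr = n_trials - 1
    trans = np.array(["same"] * (n_tr // 2) + ["different"] * (n_tr - n_tr // 2))
    rng.shuffle(trans)
    seq = np.empty(n_trials, dtype=object)
    seq[0] = labels[rng.integers(2)]
    for i, tr in enumerate(trans):
        if tr == "same":
            seq[i + 1] = seq[i]
        else:
            seq[i + 1] = labels[1] if seq[i] == labels[0] else labels[0]
    return seq


def gen_design(spec: DesignSpec) -> pd.DataFrame:
    """Generate a stimulus schedule for an adjustment-task template.

    Returns a trial table without responses: participant, block,
    trial_index, stimulus, plus the template's factor columns.
    """
    cfg = spec.resolved()
    if spec.experiment_template == "exp4":
        raise ValueError("use gen_2afc for the exp4 template")
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(1)[0])
    rows = []
    for p in range(cfg["n_participants"]):
        for b in range(cfg["n_blocks"]):
            n = cfg["trials_per_block"]
            stim = 180.0 - rng.random(n) * 180.0  # uniform on (0, 180]
            frame = pd.DataFrame({
                "participant": p,
                "block": b,
                "trial_index": np.arange(1, n + 1),
                "stimulus": stim,
                "trial_duration": cfg["trial_duration_s"],
            })
            if spec.experiment_template == "exp1":
                frame["location"] = "left" if b % 2 == 0 else "right"
            elif spec.experiment_template == "exp2":
                frame["location"] = _balanced_transitions(n, ("up", "down"), rng)
            elif spec.experiment_template == "exp3":
                frame["delay"] = _balanced_transitions(n, ("short", "long"), rng)
            rows.append(frame)
    return pd.concat(rows, ignore_index=True)


def design_matrices(design: pd.DataFrame):
    """Stack a schedule into (stimulus matrix, block vector, participant ids).

    Requires all participants to share the same (block, trial count)
    geometry, which generated designs do by construction.
    """
    parts = sorted(design["participant"].unique())
    mats = []
    blocks_ref = None
    for p in parts:
        sub = design[design["participant"] == p].sort_values(["block", "trial_index"])
        mats.append(sub["stimulus"].to_numpy(float))
        blocks = sub["block"].to_numpy()
        if blocks_ref is None:
            blocks_ref = blocks
        elif not np.array_equal(blocks, blocks_ref):
            raise ValueError("participants have unequal block structure")
    return np.vstack(mats), blocks_ref, np.asarray(parts)


def gen_responses(design: pd.DataFrame, truth: GroundTruth) -> pd.DataFrame:
    """Simulate observer responses for a schedule, returning a full trial table.

    Responses are the observer's reported estimates (including any motor
    noise configured on the observer); a fraction ``lapse_rate`` of trials
    is replaced by uniform random responses.
    """
    stim, blocks, parts = design_matrices(design)
    seeds = np.random.SeedSequence(truth.seed).spawn(2)
    est = simulate_batch(stim, truth.observer, seed=seeds[0], blocks=blocks)
    rng = np.random.default_rng(seeds[1])
    if truth.lapse_rate > 0.0:
        lapses = rng.random(est.shape) < truth.lapse_rate
        est = np.where(lapses, 180.0 - rng.random(est.shape) * 180.0, est)
    table = design.sort_values(["participant", "block", "trial_index"]).copy()
    order = np.argsort(parts)
    resp = np.concatenate([est[i] for i in order])
    table["response"] = resp
    return table.reset_index(drop=True)


def exponential_kernel(n0_same: float, n0_diff: float, lam: float, max_lag: int = 10):
    """Per-lag injected 2AFC bias kernel b(lag, overlap) = N0·exp(−λ·lag)."""

    def kernel(lag: int, overlap: str) -> float:
        n0 = n0_same if overlap == "same" else n0_diff
        return n0 * np.exp(-lam * lag) if 1 <= lag <= max_lag else 0.0

    return kernel


def gen_2afc(spec: DesignSpec, kernel=None, slope_sd: float = 1.5,
             lapse: float = 0.01, max_lag: int = 10) -> pd.DataFrame:
    """Generate a 2AFC inducer experiment with a known injected bias kernel.

    Each trial holds an inducer (adjustment) stimulus tilted ±20° from the
    same-side 2AFC stimulus, two near-vertical 2AFC tilts differing by a
    level from {−9..9 step 3}°, and a simulated left/right choice.  The
    choice probability is a cumulative Gaussian (slope ``slope_sd``) of the
    orientation difference plus the summed injected biases of the past
    ``max_lag`` inducers: ``kernel(lag, overlap)`` degrees (negative =
    repulsion), applied in the adaptation direction implied by each past
    inducer's relative orientation.  Tilts are stored as signed degrees
    around vertical.
    """
    cfg = spec.resolved()
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(3)[2])
    if kernel is None:
        kernel = lambda lag, overlap: 0.0  # noqa: E731
    from scipy.stats import norm

    rows = []
    for p in range(cfg["n_participants"]):
        for b in range(cfg["n_blocks"]):
            n = cfg["trials_per_block"]
            side = "left" if b % 2 == 0 else "right"
            inducer_pos = _balanced_transitions(n, ("up", "down"), rng)
            afc_pos = np.where(rng.random(n) < 0.5, inducer_pos,
                               np.where(inducer_pos == "up", "down", "up"))
            x = rng.choice(AFC_LEVELS, size=n)
            lo = np.maximum(-AFC_TILT_RANGE, -AFC_TILT_RANGE - x)
            hi = np.minimum(AFC_TILT_RANGE, AFC_TILT_RANGE - x)
            left_tilt = lo + rng.random(n) * (hi - lo)
            right_tilt = left_tilt + x
            sameside = right_tilt if side == "right" else left_tilt
            inducer_tilt = sameside + rng.choice([-INDUCER_OFFSET, INDUCER_OFFSET], size=n)

            shift = np.zeros(n)
            for t in range(n):
                for lag in range(1, max_lag + 1):
                    tp = t - lag
                    if tp < 0:
                        break
                    rel = signed_diff_free(inducer_tilt[tp], sameside[t])
                    if rel == 0.0:
                        continue
                    if side == "right":
                        direction = 1.0 if rel < 0 else -1.0  # +1: repulsion favors 'right'
                    else:
                        direction = 1.0 if rel > 0 else -1.0
                    overlap = "same" if inducer_pos[tp] == afc_pos[t] else "different"
                    # negative kernel (repulsion) shifts perceived x toward 'adapt' side
                    shift[t] += -direction * kernel(lag, overlap)
            p_right = lapse + (1.0 - 2.0 * lapse) * norm.cdf((x + shift) / slope_sd)
            choice = np.where(rng.random(n) < p_right, "right", "left")
            rows.append(pd.DataFrame({
                "participant": p,
                "block": b,
                "trial_index": np.arange(1, n + 1),
                "side": side,
                "inducer_pos": inducer_pos,
                "afc_pos": afc_pos,
                "inducer_tilt": inducer_tilt,
                "left_tilt": left_tilt,
                "right_tilt": right_tilt,
                "choice": choice,
                "trial_duration": cfg["trial_duration_s"],
            }))
    return pd.concat(rows, ignore_index=True)
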