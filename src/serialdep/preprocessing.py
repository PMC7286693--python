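"""Cleaning and n-back conditioning of trial-level adjustment data.

A trial table is a tidy :class:`pandas.DataFrame` with columns

``participant, block, trial_index, stimulus, response``

plus optional ``location`` (categorical), ``delay`` ({'short', 'long'}) and
``trial_duration`` (seconds).  Orientations are degrees in (0, 180];
``trial_index`` is strictly increasing within each (participant, block).

The cleaning step removes lapse-like responses (error further than three
circular standard deviations from the participant's mean error) and then
subtracts the mean response error to remove a general clockwise /
counter-clockwise bias.  Conditioning expresses each response error against
the relative orientation of the stimulus ``n`` trials back within the same
block.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .circular import circ_sd, signed_diff, signed_diff_free, wrap_orientation

REQUIRED_COLUMNS = ("participant", "block", "trial_index", "stimulus", "response")
OPTIONAL_COLUMNS = ("location", "delay", "trial_duration")


@dataclass
class CleanReport:
    """Per-participant bookkeeping of the outlier-correction pass."""

    table: pd.DataFrame  # columns: participant, group, n_trials, n_dropped, mean_error


def validate_trial_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"trial table is missing required columns: {missing}")
    for col in ("stimulus", "response"):
        vals = table[col].to_numpy(dtype=float)
        bad = np.flatnonzero(~((vals > 0.0) & (vals <= 180.0)))
        if bad.size:
            raise ValueError(
                f"column {col!r} has orientations outside (0, 180] at rows {bad[:5].tolist()}"
            )
    grouped = table.groupby(["participant", "block"], sort=False)["trial_index"]
    if not grouped.apply(lambda s: bool(np.all(np.diff(s.to_numpy()) > 0))).all():
        raise ValueError("trial_index must be strictly increasing within (participant, block)")
    return table


def response_errors(table: pd.DataFrame) -> np.ndarray:
    """Signed response error (response − stimulus) in (−90, 90]."""
    return signed_diff(table["response"].to_numpy(float), table["stimulus"].to_numpy(float))


def clean(table: pd.DataFrame, group_by: str | None = None):
    """Outlier correction and removal of the general response bias.

    Per participant (and per level of ``group_by``, e.g. ``'delay'`` when
    short- and long-delay trials are cleaned separately), trials whose
    response error lies further than three circular standard deviations from
    the mean response error are dropped; afterwards, the mean error of the
    surviving trials is subtracted from all responses.  The mean is the
    arithmetic mean of the signed errors, which live well inside (−90, 90]
    for realistic data; the SD is circular (period 180).

    Returns ``(cleaned_table, CleanReport)``.
    """
    validate_trial_table(table)
    if group_by is not None and group_by not in table.columns:
        raise ValueError(f"group_by column {group_by!r} not present")
    keys = ["participant"] if group_by is None else ["participant", group_by]
    out_frames = []
    report_rows = []
    for key, sub in table.groupby(keys, sort=False):
        if len(sub) < 2:
            raise ValueError(f"fewer than 2 trials for group {key}")
        err = response_errors(sub)
        mean0 = float(np.mean(err))
        sd0 = circ_sd(err, period=180.0)
        dev = np.abs(signed_diff_free(err, mean0))
        keep = dev <= 3.0 * sd0
        if not keep.any():
            raise ValueError(f"all trials removed for group {key}")
        kept = sub.loc[keep].copy()
        mean1 = float(np.mean(err[keep]))
        new_err = signed_diff_free(err[keep], mean1)
        kept["response"] = wrap_orientation(kept["stimulus"].to_numpy(float) + new_err)
        out_frames.append(kept)
        report_rows.append({
            "participant": key[0] if isinstance(key, tuple) else key,
            "group": key[1] if isinstance(key, tuple) and len(key) > 1 else None,
            "n_trials": len(sub),
            "n_dropped": int((~keep).sum()),
            "mean_error": mean1,
        })
    cleaned = pd.concat(out_frames).sort_index()
    return cleaned, CleanReport(table=pd.DataFrame(report_rows))


def condition_on_nback(table: pd.DataFrame, lag: int) -> pd.DataFrame:
    """Condition response errors on the stimulus ``lag`` trials back.

    Only trials with an n-back stimulus in the same block are eligible, so
    the first ``lag`` trials of every block are excluded.  Returns one row
    per eligible trial with columns ``participant, block, trial_index, lag,
    delta, error`` where ``delta = signed_diff(n-back stimulus, current
    stimulus)`` and ``error = signed_diff(response, current stimulus)``;
    optional factor columns are carried as ``location`` / ``delay`` (current
    trial) and ``location_nback`` (n-back trial).
    """
    if lag < 1:
        raise ValueError("lag must be >= 1")
    validate_trial_table(table)
    rows = []
    for (participant, block), sub in table.groupby(["participant", "block"], sort=False):
        if len(sub) <= lag:
            continue
        stim = sub["stimulus"].to_numpy(float)
        resp = sub["response"].to_numpy(float)
        cur = slice(lag, None)
        prev = slice(None, -lag)
        frame = pd.DataFrame({
            "participant": participant,
            "block": block,
            "trial_index": sub["trial_index"].to_numpy()[cur],
            "lag": lag,
            "delta": signed_diff(stim[prev], stim[cur]),
            "error": signed_diff(resp[cur], stim[cur]),
        })
        if "location" in sub.columns:
            frame["location"] = sub["location"].to_numpy()[cur]
            frame["location_nback"] = sub["location"].to_numpy()[prev]
        if "delay" in sub.columns:
            frame["delay"] = sub["delay"].to_numpy()[cur]
        if "trial_duration" in sub.columns:
            frame["trial_duration"] = sub["trial_duration"].to_numpy()[cur]
        rows.append(frame)
    if not rows:
        warnings.warn(f"lag {lag} leaves no eligible trials", stacklevel=2)
        return pd.DataFrame(columns=["participant", "block", "trial_index", "lag",
                                     "delta", "error"])
    return pd.concat(rows, ignore_index=True)


def pool_lags(table: pd.DataFrame, lags) -> pd.DataFrame:
    """Concatenate conditioned errors over several lags (e.g. 4- to 9-back)."""
    return pd.concat([condition_on_nback(table, lag) for lag in lags], ignore_index=True)


def split_by(ce: pd.DataFrame, factor: str) -> dict:
    """Partition conditioned errors by a condition factor.

    ``factor='location'`` splits by spatial overlap between the current and
    the n-back trial (keys ``'same'`` / ``'different'``); ``factor='delay'``
    splits by the *current* trial's delay condition (keys ``'short'`` /
    ``'long'``).  The partition is disjoint and exhaustive.
    """
    if factor == "location":
        if "location" not in ce.columns or "location_nback" not in ce.columns:
            raise ValueError("conditioned errors carry no location factor")
        same = ce["location"].to_numpy() == ce["location_nback"].to_numpy()
        return {"same": ce.loc[same], "different": ce.loc[~same]}
    if factor == "delay":
        if "delay" not in ce.columns:
            raise ValueError("conditioned errors carry no delay factor")
        short = ce["delay"].to_numpy() == "short"
        return {"short": ce.loc[short], "long": ce.loc[~short]}
    raise ValueError(f"unknown split factor {factor!r}")
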