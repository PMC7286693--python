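"""CSV readers/writers and the configurable analysis runner.

Trial tables are plain comma-separated files with a header.  Required
columns: ``participant, block, trial_index, stimulus, response`` (the
response column may be absent for pure stimulus schedules); optional:
``location, delay, trial_duration``.  2AFC tables use
``participant, block, trial_index, side, inducer_pos, afc_pos,
inducer_tilt, left_tilt, right_tilt, choice`` (+ ``trial_duration``).

Every result bundle written by :func:`run` records the configuration hash
and the seeds used, so re-running a config reproduces outputs exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bias as bq
from .preprocessing import (OPTIONAL_COLUMNS, REQUIRED_COLUMNS, clean,
                            condition_on_nback, validate_trial_table)

TWOAFC_COLUMNS = ("participant", "block", "trial_index", "side", "inducer_pos",
                  "afc_pos", "inducer_tilt", "left_tilt", "right_tilt", "choice")


def load_trial_table(path) -> pd.DataFrame:
    """Load and validate a trial table CSV; errors name offending rows."""
    table = pd.read_csv(path)
    validate_trial_table(table)
    keep = [c for c in (*REQUIRED_COLUMNS, *OPTIONAL_COLUMNS) if c in table.columns]
    return table[keep]


def save_trial_table(table: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)


def load_twoafc_table(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in TWOAFC_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"2AFC table missing columns: {missing}")
    bad = ~table["choice"].isin(["left", "right"])
    if bad.any():
        raise ValueError(f"invalid choice labels at rows {list(table.index[bad][:5])}")
    return table


@dataclass
class AnalysisConfig:
    """Configuration of the standard adjustment-task analysis pipeline."""

    input: str
    output_dir: str = "results"
    lags: list = field(default_factory=lambda: list(range(1, 21)))
    window: float = 30.0
    n_perm: int = 10000
    seed: int = 0
    clean_group_by: str | None = None

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        allowed = cls.__dataclass_fields__.keys()
        unknown = set(raw) - set(allowed)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "input" not in raw:
            raise ValueError("config must name an 'input' trial-table CSV")
        return cls(**raw)

    def digest(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:12]


def observer_from_yaml(path):
    """Load an observer configuration from a YAML file.

    Schema::

        variant: full            # decode_only | encode_only | single_prior | full
        sigma_s: 10.0
        enc: {p_same: 0.8, sigma_td: 11.0}
        dec: {p_same: 0.8, sigma_td: 8.0}
        tau_enc: 8.0
        tau_dec: 1.5
        motor_sd: 0.0            # optional
        n_bins: 360              # optional grid resolution
        seed: 0                  # optional
        n_reps: 1                # optional simulation repetitions

    Returns ``(ObserverParams, extras)`` where ``extras`` holds the grid
    resolution, seed and repetition count.
    """
    from .observer import ObserverParams, TransitionModel

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    enc = TransitionModel(**raw["enc"])
    dec = TransitionModel(**raw.get("dec", raw["enc"]))
    params = ObserverParams(
        sigma_s=raw["sigma_s"], enc=enc, dec=dec,
        tau_enc=raw["tau_enc"], tau_dec=raw.get("tau_dec", raw["tau_enc"]),
        variant=raw.get("variant", "full"), motor_sd=raw.get("motor_sd", 0.0),
    )
    extras = {"n_bins": raw.get("n_bins", 360), "seed": raw.get("seed", 0),
              "n_reps": raw.get("n_reps", 1)}
    return params, extras


def run(config: AnalysisConfig) -> dict:
    """Execute clean → condition → DoG quantification (+ permutation tests).

    Writes a per-lag DoG parameter table (columns lag, a, w, ssr, p, n) and
    a run log; returns the results as a dict.  ``n_perm=0`` skips the
    permutation inference but still emits fits.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = load_trial_table(config.input)
    cleaned, report = clean(table, group_by=config.clean_group_by)
    rows = []
    for lag in config.lags:
        ce = condition_on_nback(cleaned, lag)
        if not len(ce):
            continue
        fit = bq.fit_dog(ce)
        p_val = np.nan
        if config.n_perm > 0:
            res = bq.perm_test_amplitude(ce, n_perm=config.n_perm,
                                         seed=config.seed + lag)
            p_val = res.p_two_sided
        rows.append({"lag": lag, "a": fit.a, "w": fit.w, "ssr": fit.ssr,
                     "p": p_val, "n": fit.n_rows})
    dog_table = pd.DataFrame(rows)
    dog_table.to_csv(out / "dog_parameters.csv", index=False)
    report.table.to_csv(out / "clean_report.csv", index=False)
    from . import __version__

    log = {
        "config": asdict(config),
        "config_hash": config.digest(),
        "seed": config.seed,
        "version": __version__,
        "n_trials_in": int(len(table)),
        "n_trials_clean": int(len(cleaned)),
    }
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2)
    return {"dog_table": dog_table, "clean_report": report.table, "log": log}
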