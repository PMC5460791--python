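"""Reading and writing the pipeline's delimited-text artifacts.

Dialect is pinned: UTF-8, comma separator, "." decimal, mandatory header
row.  External choice tables (e.g. deposited datasets with their own
column layout) are adapted through an explicit column mapping supplied in
the run configuration, never guessed.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .cohort import TRIAL_COLUMNS, Cohort, ground_truth_table
from .effort import SubjectParams

__all__ = [
    "write_trials",
    "read_trials",
    "read_external_trials",
    "write_ground_truth",
    "read_ground_truth",
    "load_config",
]

_REQUIRED = ["subject_id", "F_R_N", "F_T_N", "n_ref_repeats", "choice"]


def _validate_trials(df: pd.DataFrame, path) -> pd.DataFrame:
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    bad = set(df["choice"].unique()) - {"reference", "test"}
    if bad:
        raise ValueError(f"{path}: invalid choice values {sorted(bad)}")
    for col in ("F_R_N", "F_T_N"):
        df[col] = df[col].astype(float)
        if (df[col] < 0).any():
            raise ValueError(f"{path}: negative forces in column {col}")
    df["n_ref_repeats"] = df["n_ref_repeats"].astype(int)
    return df


def write_trials(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, encoding="utf-8")


def read_trials(path) -> pd.DataFrame:
    df = pd.read_csv(path, encoding="utf-8")
    return _validate_trials(df, path)


def read_external_trials(path, column_map: dict[str, str],
                         choice_map: dict[str, str] | None = None,
                         n_ref_repeats: int | None = None) -> pd.DataFrame:
    """Adapt an externally deposited choice table to the pipeline schema.

    ``column_map`` maps external column names to the pipeline's names
    (at least subject_id, F_R_N, F_T_N, choice); ``choice_map`` optionally
    recodes choice labels and ``n_ref_repeats`` fills the repeat count when
    the external table has no such column.
    """
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in column_map if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: mapped columns {missing} not present")
    df = df.rename(columns=column_map)
    if choice_map:
        df["choice"] = df["choice"].map(choice_map)
        if df["choice"].isna().any():
            raise ValueError(f"{path}: choice labels outside the mapping")
    if "n_ref_repeats" not in df.columns:
        if n_ref_repeats is None:
            raise ValueError("n_ref_repeats column absent and no default given")
        df["n_ref_repeats"] = n_ref_repeats
    for col in TRIAL_COLUMNS:
        if col not in df.columns:
            df[col] = "" if col in ("session", "condition_id", "direction",
                                    "duration_window_ms") else 0
    return _validate_trials(df[TRIAL_COLUMNS].copy(), path)


def write_ground_truth(cohort: Cohort, path) -> None:
    payload = {
        "seed": cohort.seed,
        "subjects": {sid: {"alpha": p.alpha, "beta": p.beta, "gamma": p.gamma}
                     for sid, p in cohort.subjects.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")


def read_ground_truth(path) -> Cohort:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    subjects = {sid: SubjectParams(**vals)
                for sid, vals in payload["subjects"].items()}
    return Cohort(subjects=subjects, seed=payload["seed"])


def load_config(path) -> dict:
    """YAML (or JSON, a YAML subset) run configuration."""
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return cfg
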