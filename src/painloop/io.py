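"""Tabular artifact readers/writers with strict schema validation.

All behavioral artifacts are long-format CSV (one observation per row) so
fixtures diff cleanly and stay language-agnostic; voxel datasets travel as
a compressed NPZ container with a JSON ground-truth sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import LABELS, TrialSequence, VoxelTrialDataset

__all__ = [
    "SEQUENCE_SCHEMA",
    "EMISSION_SCHEMA",
    "RATING_SCHEMA",
    "TRACE_SCHEMA",
    "write_sequences",
    "read_sequences",
    "write_emissions",
    "read_emissions",
    "write_ratings",
    "read_ratings",
    "write_traces",
    "read_traces",
    "write_voxel_dataset",
    "read_voxel_dataset",
]

SEQUENCE_SCHEMA = ["subject", "session", "trial", "label"]
EMISSION_SCHEMA = ["subject", "session", "trial", "label", "p_pain"]
RATING_SCHEMA = ["subject", "session", "trial", "label", "rating"]
TRACE_SCHEMA = ["subject", "group", "condition", "trial", "time_s", "rating", "phase"]


def _check_schema(df: pd.DataFrame, schema: list, what: str) -> pd.DataFrame:
    if list(df.columns) != schema:
        raise ValueError(
            f"{what} CSV schema mismatch: expected columns {schema}, got {list(df.columns)}"
        )
    return df


def _check_labels(values, what: str) -> None:
    bad = set(values) - set(LABELS)
    if bad:
        raise ValueError(f"{what} contains invalid labels {sorted(bad)}; expected {LABELS}")


def write_sequences(sequences: dict[str, TrialSequence], path) -> None:
    rows = [
        {"subject": sid, "session": s, "trial": t, "label": lab}
        for sid, seq in sequences.items()
        for s, sess in enumerate(seq.sessions)
        for t, lab in enumerate(sess)
    ]
    pd.DataFrame(rows, columns=SEQUENCE_SCHEMA).to_csv(path, index=False)


def read_sequences(path) -> dict[str, TrialSequence]:
    df = _check_schema(pd.read_csv(path), SEQUENCE_SCHEMA, "sequence")
    _check_labels(df["label"].unique(), "sequence CSV")
    out = {}
    for sid, g in df.groupby("subject", sort=False):
        sessions = [
            list(gs.sort_values("trial")["label"]) for _, gs in g.groupby("session", sort=True)
        ]
        out[sid] = TrialSequence(str(sid), sessions)
    return out


def write_emissions(log: pd.DataFrame, path) -> None:
    _check_schema(log[EMISSION_SCHEMA], EMISSION_SCHEMA, "emission").to_csv(path, index=False)


def read_emissions(path) -> pd.DataFrame:
    df = _check_schema(pd.read_csv(path), EMISSION_SCHEMA, "emission")
    _check_labels(df["label"].unique(), "emission CSV")
    p = df["p_pain"]
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("emission CSV contains P(pain) outside [0, 1]")
    return df


def write_ratings(ratings: pd.DataFrame, path) -> None:
    _check_schema(ratings[RATING_SCHEMA], RATING_SCHEMA, "rating").to_csv(path, index=False)


def read_ratings(path) -> pd.DataFrame:
    df = _check_schema(pd.read_csv(path), RATING_SCHEMA, "rating")
    _check_labels(df["label"].unique(), "rating CSV")
    r = df["rating"]
    if ((r < 0) | (r > 10)).any():
        raise ValueError("rating CSV contains ratings outside [0, 10]")
    return df


def write_traces(traces: pd.DataFrame, path) -> None:
    _check_schema(traces[TRACE_SCHEMA], TRACE_SCHEMA, "trace").to_csv(path, index=False)


def read_traces(path) -> pd.DataFrame:
    df = _check_schema(pd.read_csv(path), TRACE_SCHEMA, "trace")
    bad = set(df["phase"].unique()) - {"T1", "T2", "T3"}
    if bad:
        raise ValueError(f"trace CSV contains invalid phases {sorted(bad)}")
    r = df["rating"]
    if ((r < 0) | (r > 10)).any():
        raise ValueError("trace CSV contains ratings outside [0, 10]")
    return df


def write_voxel_dataset(dataset: VoxelTrialDataset, path) -> None:
    """NPZ array container plus a `.json` ground-truth sidecar."""
    path = Path(path)
    np.savez_compressed(
        path,
        baseline=dataset.baseline,
        trials=dataset.trials,
        labels=dataset.labels.astype("U4"),
        session_id=dataset.session_id,
    )
    gt = dict(dataset.ground_truth)
    gt["informative"] = [int(i) for i in gt["informative"]]
    path.with_suffix(".json").write_text(json.dumps(gt, indent=2))


def read_voxel_dataset(path) -> VoxelTrialDataset:
    path = Path(path)
    with np.load(path) as z:
        arrays = {k: z[k] for k in ("baseline", "trials", "labels", "session_id")}
    gt = json.loads(path.with_suffix(".json").read_text())
    gt["informative"] = np.asarray(gt["informative"], dtype=int)
    _check_labels(np.unique(arrays["labels"]), "voxel dataset")
    return VoxelTrialDataset(ground_truth=gt, **arrays)
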