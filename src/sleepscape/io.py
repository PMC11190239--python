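"""Plain-text serialization of every pipeline artifact.

All interchange is CSV (long-format hypnograms, nights, survey, symptom,
feature, period, label and matrix tables) plus JSON / JSON-lines for
configs and ground truth.  Dates are ISO-8601; timestamps are UTC.
"""

from __future__ import annotations

import datetime as dt
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import EpochSeries

HYPNOGRAM_COLUMNS = (
    "individual_id",
    "night_date",
    "epoch_index",
    "epoch_start_utc",
    "stage_code",
)
NIGHTS_COLUMNS = (
    "individual_id",
    "night_date",
    "sleep_onset_utc",
    "wake_onset_utc",
    "nonwear_hours",
)


def write_hypnograms(nights: list[EpochSeries], epochs_path, nights_path) -> None:
    """Write the long-format epoch table and the per-night companion table."""
    frames = []
    for n in nights:
        frames.append(
            pd.DataFrame(
                {
                    "individual_id": n.individual_id,
                    "night_date": n.night_date.isoformat(),
                    "epoch_index": np.arange(n.n_epochs),
                    "epoch_start_utc": np.datetime_as_string(n.epoch_starts, unit="s"),
                    "stage_code": n.stages,
                }
            )
        )
    epochs = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=list(HYPNOGRAM_COLUMNS))
    )
    epochs.to_csv(epochs_path, index=False)

    meta = pd.DataFrame(
        [
            {
                "individual_id": n.individual_id,
                "night_date": n.night_date.isoformat(),
                "sleep_onset_utc": np.datetime_as_string(n.sleep_onset, unit="s"),
                "wake_onset_utc": np.datetime_as_string(n.wake_onset, unit="s"),
                "nonwear_hours": n.nonwear_hours,
            }
            for n in nights
        ],
        columns=list(NIGHTS_COLUMNS),
    )
    meta.to_csv(nights_path, index=False)


def read_hypnograms(epochs_path, nights_path) -> list[EpochSeries]:
    """Reconstruct EpochSeries objects from the two CSV files."""
    epochs = pd.read_csv(epochs_path)
    meta = pd.read_csv(nights_path)
    stage_map = {
        (ind, date): grp.sort_values("epoch_index")["stage_code"].to_numpy(np.int8)
        for (ind, date), grp in epochs.groupby(["individual_id", "night_date"])
    }
    nights = []
    for row in meta.itertuples(index=False):
        stages = stage_map.get(
            (row.individual_id, row.night_date), np.empty(0, np.int8)
        )
        nights.append(
            EpochSeries(
                individual_id=row.individual_id,
                night_date=dt.date.fromisoformat(row.night_date),
                sleep_onset=np.datetime64(row.sleep_onset_utc, "s"),
                wake_onset=np.datetime64(row.wake_onset_utc, "s"),
                stages=stages,
                nonwear_hours=float(row.nonwear_hours),
            )
        )
    return nights


def write_truth(truth, path) -> None:
    """Ground truth as JSON lines: a header record, then one per individual."""
    path = Path(path)
    with path.open("w") as fh:
        header = {
            "record": "header",
            "archetype_names": list(truth.archetype_names),
            "start_date": truth.start_date.isoformat(),
            "block_nights": truth.block_nights,
            "base_matrix": np.asarray(truth.base_matrix).tolist()
            if truth.base_matrix is not None
            else None,
            "effect_matrices": {
                k: np.asarray(v).tolist() for k, v in truth.effect_matrices.items()
            },
        }
        fh.write(json.dumps(header) + "\n")
        for ind in truth.individual_ids:
            rec = {
                "record": "individual",
                "individual_id": ind,
                "block_labels": truth.block_labels[ind].tolist(),
                "night_labels": truth.night_labels[ind].tolist(),
                "missing": truth.missing.get(ind, np.zeros(0, bool)).astype(int).tolist(),
                "chronic_positive": sorted(
                    c for c, m in truth.chronic_positive.items() if ind in m
                ),
                "acute_reports": {
                    c: r[ind].isoformat()
                    for c, r in truth.acute_reports.items()
                    if ind in r
                },
            }
            fh.write(json.dumps(rec) + "\n")


def _date_cols(df: pd.DataFrame, cols) -> pd.DataFrame:
    df = df.copy()
    for c in cols:
        if c in df.columns:
            df[c] = df[c].map(
                lambda d: dt.date.fromisoformat(d) if isinstance(d, str) else d
            )
    return df


def write_periods(periods: pd.DataFrame, path) -> None:
    out = periods.copy()
    if "night_dates" in out.columns:
        out["night_dates"] = out["night_dates"].map(
            lambda ds: json.dumps([d.isoformat() for d in ds])
        )
    out.to_csv(path, index=False)


def read_periods(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "night_dates" in df.columns:
        df["night_dates"] = df["night_dates"].map(
            lambda s: tuple(dt.date.fromisoformat(d) for d in json.loads(s))
        )
    return _date_cols(df, ["start_date"])


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_table(path, date_cols=()) -> pd.DataFrame:
    return _date_cols(pd.read_csv(path), date_cols)


def write_matrix(matrix: np.ndarray, nodes, path) -> None:
    """Labelled square matrix CSV: rows = from, columns = to."""
    pd.DataFrame(matrix, index=list(nodes), columns=list(nodes)).to_csv(
        path, index_label="from"
    )


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (dt.date, dt.datetime)):
        return obj.isoformat()
    raise TypeError(f"not JSON serializable: {type(obj)}")
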