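"""Plain-text readers and writers for the pipeline's file interfaces.

Formats:

* tracking trial — CSV with columns ``time_s,u,y`` plus a JSON sidecar
  (same stem, ``.json``) holding the generating spec and seed;
* ROI series — TSV, T rows by R named columns;
* subject manifest — CSV with ``subject_id,group,score``;
* strengths — CSV, one row per subject, one column per edge label;
* per-run metrics — CSV with the response-metric columns.

All floats are written with repr-level precision so a rerun with the same
inputs is byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from rigidnet.preprocess import ROITimeSeries
from rigidnet.tracking import TrackingTrial

FLOAT_FMT = "%.17g"


def write_trial(path: str | Path, trial: TrackingTrial, meta: Mapping | None = None) -> None:
    path = Path(path)
    df = pd.DataFrame({"time_s": trial.time, "u": trial.u, "y": trial.y})
    df.to_csv(path, index=False, float_format=FLOAT_FMT)
    if meta is not None:
        path.with_suffix(".json").write_text(json.dumps(dict(meta), indent=2, sort_keys=True))


def read_trial(path: str | Path) -> TrackingTrial:
    df = pd.read_csv(path)
    for col in ("time_s", "u", "y"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    time = df["time_s"].to_numpy(float)
    dt = float(np.median(np.diff(time)))
    return TrackingTrial(time=time, u=df["u"].to_numpy(float), y=df["y"].to_numpy(float), dt=dt)


def write_roi_series(path: str | Path, series: ROITimeSeries) -> None:
    pd.DataFrame(series.data, columns=list(series.roi_names)).to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FMT
    )


def read_roi_series(
    path: str | Path,
    tr: float,
    subject_id: str | None = None,
    group: str | None = None,
) -> ROITimeSeries:
    df = pd.read_csv(path, sep="\t")
    return ROITimeSeries(
        data=df.to_numpy(float),
        tr=tr,
        roi_names=tuple(df.columns),
        subject_id=subject_id,
        group=group,
    )


def write_strengths(path: str | Path, strengths: "pd.DataFrame") -> None:
    strengths.to_csv(path, index=True, index_label="subject_id", float_format=FLOAT_FMT)


def read_strengths(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="subject_id")


def write_manifest_csv(path: str | Path, rows: list[dict]) -> None:
    pd.DataFrame(rows).to_csv(path, index=False, float_format=FLOAT_FMT)
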