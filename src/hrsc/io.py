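"""CSV/JSON readers and writers for pipeline artifacts.

Breath files use columns ``t_sec, vo2_mlmin, vco2_mlmin, hr_bpm, po_w``
(UTF-8, header row, empty field = missing).  Populations are one row
per subject; trial ground truth goes to a sidecar keyed by subject and
trial label.  Models and agreement reports are JSON.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, List

import numpy as np
import pandas as pd

from .errors import InputError
from .schrmodel import SchrModel
from .types import AgreementReport, BreathSeries, SubjectProfile, TrialTruth

__all__ = [
    "write_breath_csv",
    "read_breath_csv",
    "write_population_csv",
    "read_population_csv",
    "write_truth_csv",
    "write_model_json",
    "read_model_json",
    "write_report_json",
]

_BREATH_COLS = {"t_sec": "t", "vo2_mlmin": "vo2", "vco2_mlmin": "vco2",
                "hr_bpm": "hr", "po_w": "po"}


def write_breath_csv(series: BreathSeries, path) -> None:
    df = pd.DataFrame({col: getattr(series, attr) for col, attr in _BREATH_COLS.items()})
    df.to_csv(path, index=False)


def read_breath_csv(path, meta: dict | None = None) -> BreathSeries:
    df = pd.read_csv(path)
    missing = set(_BREATH_COLS) - set(df.columns)
    if missing:
        raise InputError(f"breath CSV missing columns: {sorted(missing)}")
    return BreathSeries(
        meta=dict(meta or {}),
        **{attr: df[col].to_numpy(dtype=float) for col, attr in _BREATH_COLS.items()},
    )


def write_population_csv(profiles: Iterable[SubjectProfile], path) -> None:
    pd.DataFrame([dataclasses.asdict(p) for p in profiles]).to_csv(path, index=False)


def read_population_csv(path) -> List[SubjectProfile]:
    df = pd.read_csv(path)
    fields = [f.name for f in dataclasses.fields(SubjectProfile)]
    missing = set(fields) - set(df.columns)
    if missing:
        raise InputError(f"population CSV missing columns: {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        kwargs = {f: row[f] for f in fields}
        kwargs["subject_id"] = str(kwargs["subject_id"])
        kwargs["sex"] = str(kwargs["sex"])
        out.append(SubjectProfile(**{
            k: (v if isinstance(v, str) else float(v)) for k, v in kwargs.items()
        }))
    return out


def write_truth_csv(rows: Iterable[tuple], path) -> None:
    """Write (subject_id, trial_label, TrialTruth) rows to a sidecar CSV."""
    records = []
    for subject_id, trial_label, truth in rows:
        rec = dataclasses.asdict(truth)
        rec["outlier_indices"] = ";".join(str(i) for i in rec["outlier_indices"])
        records.append({"subject_id": subject_id, "trial_label": trial_label, **rec})
    pd.DataFrame(records).to_csv(path, index=False)


def write_model_json(model: SchrModel, path) -> None:
    Path(path).write_text(json.dumps(model.to_dict(), indent=2, sort_keys=True) + "\n")


def read_model_json(path) -> SchrModel:
    return SchrModel.from_dict(json.loads(Path(path).read_text()))


def write_report_json(report: AgreementReport, path) -> None:
    Path(path).write_text(
        json.dumps(dataclasses.asdict(report), indent=2, sort_keys=True) + "\n"
    )
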