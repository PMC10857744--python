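"""Tabular input/output: volume series, configs, cohort and ROC exports."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .classify import AnovaResult, RocResult
from .compartmental import FitResult, VolumeSeries
from .dsbms import DsbmsConfig, LesionVolumeTrace

__all__ = [
    "read_volume_series",
    "write_volume_series",
    "load_dsbms_config",
    "dump_dsbms_config",
    "write_trace",
    "write_roc",
    "write_summary",
    "write_fit_result",
]

_SERIES_COLUMNS = ["lesion_id", "time_days", "volume_cm3"]


def read_volume_series(path: str | Path) -> list[VolumeSeries]:
    """Read lesion volume series from a CSV with a required header.

    Expected columns: ``lesion_id,time_days,volume_cm3``; one series per
    lesion id, rows sorted by time within each lesion.
    """
    df = pd.read_csv(path)
    missing = set(_SERIES_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"missing columns in {path}: {sorted(missing)}")
    out = []
    for lesion_id, grp in df.groupby("lesion_id", sort=False):
        grp = grp.sort_values("time_days")
        out.append(
            VolumeSeries(
                lesion_id=str(lesion_id),
                times=grp["time_days"].to_numpy(dtype=float),
                volumes=grp["volume_cm3"].to_numpy(dtype=float),
            )
        )
    return out


def write_volume_series(series: Iterable[VolumeSeries], path: str | Path) -> None:
    rows = [
        {"lesion_id": s.lesion_id, "time_days": t, "volume_cm3": v}
        for s in series
        for t, v in zip(s.times, s.volumes)
    ]
    pd.DataFrame(rows, columns=_SERIES_COLUMNS).to_csv(path, index=False)


def load_dsbms_config(path: str | Path) -> DsbmsConfig:
    """Load a simulator configuration from YAML (or JSON) key: value pairs."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a mapping")
    valid = {f.name for f in dataclasses.fields(DsbmsConfig)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return DsbmsConfig(**data)


def dump_dsbms_config(config: DsbmsConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=False)


def write_trace(trace: LesionVolumeTrace, path: str | Path) -> None:
    trace.to_frame().to_csv(path, index=False)


def write_roc(roc: RocResult, path: str | Path) -> None:
    pd.DataFrame(
        {"fpr": roc.fpr, "tpr": roc.tpr, "threshold": roc.thresholds}
    ).to_csv(path, index=False)


def write_summary(
    path: str | Path,
    roc: RocResult | None = None,
    anova: AnovaResult | None = None,
    extra: dict | None = None,
) -> None:
    payload: dict = {}
    if roc is not None:
        payload.update(
            auc=roc.auc,
            beta_star=roc.threshold,
            sensitivity=roc.sensitivity,
            specificity=roc.specificity,
            n_inflammation=roc.n_positive,
            n_progression=roc.n_negative,
        )
    if anova is not None:
        payload.update(anova_F=anova.F, anova_p=anova.p_value)
    if extra:
        payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_json_default)
        fh.write("\n")


def write_fit_result(fit: FitResult, path: str | Path) -> None:
    payload = {
        "params": dataclasses.asdict(fit.params),
        "residual_norm": fit.residual_norm,
        "converged": fit.converged,
        "n_evaluations": fit.n_evaluations,
        "message": fit.message,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
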