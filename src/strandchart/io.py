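"""Reading and writing patient-record CSV, chart-output CSV, and YAML config.

CSV is the canonical exchange format.  Patient files carry the columns
``patient_id, surgery_time, z, survival_time, died`` (renameable through a
column map); chart output files carry one row per strand update.  Censored
records are normalised to ``survival_time = d`` on write so that "alive at d"
is unambiguous.
"""

from __future__ import annotations

import os
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .datamodel import (
    PATIENT_COLUMNS,
    GateConfig,
    ChartConfig,
    PatientRecord,
    ValidationError,
)

__all__ = ["read_patients", "write_patients", "write_chart", "read_chart", "load_config"]

CHART_COLUMNS = [
    "strand",
    "update_index",
    "calendar_time",
    "patient_id",
    "y",
    "mu_hat_patient",
    "adjusted_value",
    "m",
    "ci_lo",
    "ci_hi",
    "signal",
]

_TRUTHY = {"true", "1", "yes", "t", "y"}
_FALSY = {"false", "0", "no", "f", "n"}


def _parse_bool(value, row: int) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    raise ValidationError(f"row {row}: cannot parse died flag {value!r}")


def read_patients(
    path, dialect: Mapping[str, str] | None = None, d: float = 30.0
) -> list:
    """Read and validate patient records from a CSV file.

    Parameters
    ----------
    path : path-like
    dialect : mapping, optional
        Maps canonical column names (``patient_id``, ``surgery_time``, ``z``,
        ``survival_time``, ``died``) to the names used in the file.
    d : float
        Censoring window in days; censored records must have
        ``survival_time >= d``.

    Returns
    -------
    list of PatientRecord, in file order.  Rows are validated against the
    record invariants; the first offending row is reported by its 1-based
    data-row number.
    """
    dialect = dict(dialect or {})
    frame = pd.read_csv(path)
    colmap = {dialect.get(c, c): c for c in PATIENT_COLUMNS}
    missing = [src for src in colmap if src not in frame.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    frame = frame.rename(columns=colmap)

    records = []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        rec = PatientRecord(
            patient_id=str(row.patient_id),
            surgery_time=float(row.surgery_time),
            z=int(row.z),
            survival_time=float(row.survival_time),
            died=_parse_bool(row.died, i),
        )
        try:
            rec.validate(d=d)
        except ValidationError as exc:
            raise ValidationError(f"row {i}: {exc}") from None
        records.append(rec)
    return records


def write_patients(records, path, d: float = 30.0) -> None:
    """Write patient records to CSV, normalising censored times to exactly d."""
    from .datamodel import as_frame

    frame = as_frame(records).copy()
    frame.loc[~frame["died"].astype(bool), "survival_time"] = float(d)
    frame.to_csv(path, index=False)


def write_chart(result, path) -> None:
    """Write a ChartResult to CSV, one row per strand update.

    Values round-trip through :func:`read_chart` at full float precision
    (written with ``repr`` precision, 17 significant digits).
    """
    frame = result.frame
    out = frame[CHART_COLUMNS]
    out.to_csv(path, index=False, float_format="%.17g")


def read_chart(path) -> pd.DataFrame:
    """Read a chart CSV written by :func:`write_chart`."""
    frame = pd.read_csv(
        path,
        dtype={"patient_id": str, "signal": str},
        keep_default_na=False,
        float_precision="round_trip",
    )
    missing = [c for c in CHART_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"{path}: missing chart column(s) {missing}")
    for col in ("strand", "update_index"):
        frame[col] = frame[col].astype(int)
    for col in ("calendar_time", "y", "mu_hat_patient", "adjusted_value", "m", "ci_lo", "ci_hi"):
        frame[col] = frame[col].astype(float)
    return frame


def load_config(path) -> dict:
    """Load a YAML run configuration with sections gates, chart, simulate, io."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    gates_sec = raw.get("gates", {}) or {}
    chart_sec = raw.get("chart", {}) or {}
    cfg = {
        "gates": GateConfig(
            gates=tuple(gates_sec.get("gates", (0.5, 2.0, 10.0, 20.0, 30.0))),
            d=float(gates_sec.get("d", 30.0)),
        ),
        "chart": ChartConfig(
            kappa=chart_sec.get("kappa"),
            alpha_low=float(chart_sec.get("alpha_low", 0.025)),
            alpha_high=float(chart_sec.get("alpha_high", 0.975)),
            targets=chart_sec.get("targets"),
            pilot_cutoff=chart_sec.get("pilot_cutoff"),
        ),
        "simulate": raw.get("simulate", {}) or {},
        "io": raw.get("io", {}) or {},
    }
    return cfg


def write_models(models, kappa, targets, z_b, path) -> None:
    """Serialise fitted per-gate risk models plus chart tuning to YAML."""
    payload = {
        "z_b": int(z_b),
        "strands": [
            {
                "gate": float(m.gate),
                "beta": float(m.beta),
                "z_b": int(m.z_b),
                "m0": float(m.m0),
                "n_pilot": int(m.n_pilot),
                "kappa": float(k),
                "target": float(t),
            }
            for m, k, t in zip(models, kappa, targets)
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def read_models(path):
    """Load models written by :func:`write_models`; returns (models, kappa, targets)."""
    from .risk import RiskModel

    with open(path) as fh:
        payload = yaml.safe_load(fh)
    models, kappa, targets = [], [], []
    for i, s in enumerate(payload["strands"]):
        models.append(
            RiskModel(
                gate_index=i,
                gate=float(s["gate"]),
                beta=float(s["beta"]),
                z_b=int(s["z_b"]),
                m0=float(s["m0"]),
                n_pilot=int(s.get("n_pilot", 0)),
            )
        )
        kappa.append(float(s["kappa"]))
        targets.append(float(s["target"]))
    return models, kappa, targets
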