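"""Domain types for STRAND-chart monitoring of censored survival outcomes.

A monitored cohort is a sequence of surgeries.  Each patient carries a
calendar surgery time (days since the start of monitoring), an integer
preoperative risk score (Parsonnet-style), and a censored survival time:
either an observed death within the follow-up window of ``d`` days, or
censoring at exactly ``d`` days.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PatientRecord",
    "GateConfig",
    "ChartConfig",
    "ValidationError",
    "records_to_frame",
    "frame_to_records",
]


class ValidationError(ValueError):
    """A record or configuration violates a domain invariant."""


@dataclass(frozen=True)
class PatientRecord:
    """One surgery.

    Parameters
    ----------
    patient_id : str
        Opaque identifier.
    surgery_time : float
        Calendar time of surgery in days since the start of monitoring (>= 0 by
        convention; any finite value is accepted).
    z : int
        Integer risk score (>= 0), e.g. the Parsonnet score.
    survival_time : float
        Days from surgery to death (if ``died``) or to censoring (> 0).
    died : bool
        True if death was observed at ``survival_time``; False if the patient
        was censored alive, in which case ``survival_time`` must be at least
        the censoring window ``d``.
    """

    patient_id: str
    surgery_time: float
    z: int
    survival_time: float
    died: bool

    def validate(self, d: float = 30.0) -> None:
        if not np.isfinite(self.surgery_time):
            raise ValidationError(
                f"patient {self.patient_id!r}: surgery_time must be finite"
            )
        if self.z < 0:
            raise ValidationError(
                f"patient {self.patient_id!r}: risk score must be >= 0, got {self.z}"
            )
        if not self.survival_time > 0:
            raise ValidationError(
                f"patient {self.patient_id!r}: survival_time must be > 0, "
                f"got {self.survival_time}"
            )
        if not self.died and self.survival_time < d:
            raise ValidationError(
                f"patient {self.patient_id!r}: censored record with "
                f"survival_time={self.survival_time} < censoring window d={d} "
                "(early loss to follow-up is not supported)"
            )


@dataclass(frozen=True)
class GateConfig:
    """The strand layout: survival gates t_1 < ... < t_N and censoring window d.

    Strand ``n`` records, for every patient, failure (death) at or before
    ``t_n`` days after surgery.  The last gate must not exceed the censoring
    window.
    """

    gates: tuple = (0.5, 2.0, 10.0, 20.0, 30.0)
    d: float = 30.0

    def __post_init__(self):
        object.__setattr__(self, "gates", tuple(float(t) for t in self.gates))
        if len(self.gates) < 1:
            raise ValidationError("at least one gate is required")
        if any(t <= 0 for t in self.gates):
            raise ValidationError("gates must be > 0")
        if any(b <= a for a, b in zip(self.gates, self.gates[1:])):
            raise ValidationError("gates must be strictly increasing")
        if self.gates[-1] > self.d:
            raise ValidationError(
                f"last gate {self.gates[-1]} exceeds censoring window d={self.d}"
            )

    @property
    def n_strands(self) -> int:
        return len(self.gates)


@dataclass
class ChartConfig:
    """Per-strand chart tuning.

    ``kappa`` and ``targets`` hold one value per strand; ``None`` entries (or a
    ``None`` vector) mean "derive from the calibrated baseline rate": kappa via
    the guide formula 0.993 - 0.192*m0 and target = m0 itself.
    """

    kappa: Sequence | None = None
    alpha_low: float = 0.025
    alpha_high: float = 0.975
    targets: Sequence | None = None
    pilot_cutoff: float | None = None

    def __post_init__(self):
        if not (0.0 < self.alpha_low < self.alpha_high < 1.0):
            raise ValidationError(
                f"CI percentiles must satisfy 0 < alpha_low < alpha_high < 1, "
                f"got ({self.alpha_low}, {self.alpha_high})"
            )
        if self.kappa is not None:
            for k in self.kappa:
                if not (0.0 < k < 1.0):
                    raise ValidationError(f"kappa must lie in (0, 1), got {k}")
        if self.targets is not None:
            for t in self.targets:
                if not (0.0 < t < 1.0):
                    raise ValidationError(f"targets must lie in (0, 1), got {t}")


PATIENT_COLUMNS = ["patient_id", "surgery_time", "z", "survival_time", "died"]


def records_to_frame(records: Iterable[PatientRecord]) -> pd.DataFrame:
    """Tabulate records into the canonical patient DataFrame (input order)."""
    rec = list(records)
    return pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in rec],
            "surgery_time": np.array([r.surgery_time for r in rec], dtype=float),
            "z": np.array([r.z for r in rec], dtype=int),
            "survival_time": np.array([r.survival_time for r in rec], dtype=float),
            "died": np.array([r.died for r in rec], dtype=bool),
        }
    )


def frame_to_records(frame: pd.DataFrame) -> list:
    return [
        PatientRecord(
            patient_id=str(row.patient_id),
            surgery_time=float(row.surgery_time),
            z=int(row.z),
            survival_time=float(row.survival_time),
            died=bool(row.died),
        )
        for row in frame.itertuples(index=False)
    ]


def as_frame(records) -> pd.DataFrame:
    """Accept either a patient DataFrame or an iterable of PatientRecord."""
    if isinstance(records, pd.DataFrame):
        missing = [c for c in PATIENT_COLUMNS if c not in records.columns]
        if missing:
            raise ValidationError(f"patient frame missing columns: {missing}")
        return records.reset_index(drop=True)
    return records_to_frame(records)
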