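"""Per-gate logistic risk adjustment.

Each strand carries its own logistic model linking a patient's odds of failure
at gate t_n to a baseline patient's odds:

    odds(z) = odds(z_b) * exp(beta * (z - z_b))

calibrated by maximum likelihood on pilot data.  During monitoring the current
baseline rate is taken to be the previous chart value m_{i-1}, so each arriving
patient's predicted rate is obtained by scaling m_{i-1} on the odds scale, and
the observed 0/1 outcome is mapped back to the baseline metric as
y - mu_patient + mu_baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .datamodel import ValidationError, as_frame

__all__ = [
    "RiskModel",
    "CalibrationError",
    "select_baseline_score",
    "fit_gate_model",
    "predict_patient_rate",
    "adjust_outcome",
]


class CalibrationError(RuntimeError):
    """The pilot data cannot support a logistic fit at this gate."""


@dataclass(frozen=True)
class RiskModel:
    """A fitted per-gate logistic risk model.

    Attributes
    ----------
    gate_index : int
        Strand index n (0-based).
    gate : float
        The gate time t_n in days.
    beta : float
        Slope on the centred risk score (z - z_b), log-odds per score unit.
    z_b : int
        Baseline risk score (typically the pilot median).
    m0 : float
        Baseline failure rate at this gate: the fitted probability at z = z_b,
        i.e. inverse-logit of the intercept.  Serves as the chart's starting
        value and default target.
    n_pilot : int
        Number of pilot records used in the fit.
    """

    gate_index: int
    gate: float
    beta: float
    z_b: int
    m0: float
    n_pilot: int = 0

    def __post_init__(self):
        if not (0.0 < self.m0 < 1.0):
            raise ValidationError(f"m0 must lie in (0, 1), got {self.m0}")
        if not math.isfinite(self.beta):
            raise ValidationError(f"beta must be finite, got {self.beta}")


def select_baseline_score(pilot) -> int:
    """Median risk score of the pilot data, as an integer baseline score.

    For an even record count the mean of the two central scores is rounded
    half-up so the baseline is a valid integer score.
    """
    frame = as_frame(pilot)
    if len(frame) == 0:
        raise ValidationError("cannot select a baseline score from an empty pilot set")
    z = np.sort(frame["z"].to_numpy())
    n = len(z)
    if n % 2 == 1:
        return int(z[n // 2])
    mid = (z[n // 2 - 1] + z[n // 2]) / 2.0
    return int(math.floor(mid + 0.5))


def gate_outcomes(frame, gate: float) -> np.ndarray:
    """0/1 failure indicator at a gate: death at or before t_n (inclusive)."""
    died = frame["died"].to_numpy(dtype=bool)
    t = frame["survival_time"].to_numpy(dtype=float)
    return (died & (t <= gate)).astype(float)


def fit_gate_model(
    pilot, gate: float, z_b: int, gate_index: int = 0, penalize: bool = False
) -> RiskModel:
    """Maximum-likelihood logistic fit of gate failure on (z - z_b).

    Parameters
    ----------
    pilot : records
        Pilot patient records; must contain both outcomes at this gate and a
        risk score that varies.
    gate : float
        Gate time t_n in days.
    z_b : int
        Baseline score at which the intercept is anchored.
    penalize : bool
        If True, fall back to a weakly ridge-penalised fit instead of raising
        on perfect separation (useful for tiny pilots).

    Returns
    -------
    RiskModel with ``beta`` the fitted slope and ``m0`` the fitted failure
    probability of a baseline patient (inverse-logit of the intercept).
    """
    frame = as_frame(pilot)
    if len(frame) == 0:
        raise CalibrationError("empty pilot set")
    y = gate_outcomes(frame, gate)
    zc = frame["z"].to_numpy(dtype=float) - float(z_b)
    if y.min() == y.max():
        raise CalibrationError(
            f"gate {gate}: all pilot outcomes identical ({int(y[0])}); "
            "widen the pilot window"
        )
    if zc.min() == zc.max():
        raise CalibrationError(
            f"gate {gate}: risk score is constant in the pilot data; "
            "widen the pilot window"
        )
    exog = sm.add_constant(zc)
    model = sm.Logit(y, exog)
    try:
        if penalize:
            fit = model.fit_regularized(alpha=1.0, L1_wt=0.0, disp=0)
        else:
            fit = model.fit(disp=0)
    except Exception as exc:  # statsmodels raises PerfectSeparationError etc.
        raise CalibrationError(
            f"gate {gate}: logistic calibration failed ({exc}); "
            "widen the pilot window or enable penalize=True"
        ) from exc
    intercept, beta = float(fit.params[0]), float(fit.params[1])
    if not (math.isfinite(intercept) and math.isfinite(beta)):
        raise CalibrationError(
            f"gate {gate}: non-finite logistic estimates (possible separation)"
        )
    m0 = 1.0 / (1.0 + math.exp(-intercept))
    return RiskModel(
        gate_index=gate_index,
        gate=float(gate),
        beta=beta,
        z_b=int(z_b),
        m0=m0,
        n_pilot=len(frame),
    )


def predict_patient_rate(m_prev: float, model: RiskModel, z) -> float:
    """Predicted failure rate for a patient with score z, given baseline rate.

    Scales the current baseline odds m_prev/(1-m_prev) by
    exp(beta*(z - z_b)) and maps back to a probability; always in (0, 1) and
    exactly m_prev when z == z_b or beta == 0.
    """
    if not (0.0 < m_prev < 1.0):
        raise ValidationError(f"baseline rate must lie in (0, 1), got {m_prev}")
    scale = np.exp(model.beta * (np.asarray(z, dtype=float) - model.z_b))
    odds = m_prev / (1.0 - m_prev) * scale
    out = odds / (1.0 + odds)
    if np.ndim(z) == 0:
        return float(out)
    return out


def adjust_outcome(y, mu_patient: float, mu_baseline: float):
    """Map an observed 0/1 outcome to the baseline-patient metric.

    Returns ``y - mu_patient + mu_baseline``; unbiased for the baseline rate
    when mu_patient is the patient's true rate.  May legitimately fall outside
    [0, 1].
    """
    for name, mu in (("mu_patient", mu_patient), ("mu_baseline", mu_baseline)):
        if not (0.0 < mu < 1.0):
            raise ValidationError(f"{name} must lie in (0, 1), got {mu}")
    return y - mu_patient + mu_baseline
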