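"""The STRAND chart engine.

The chart is a stack of N "strands", one per survival gate t_n.  Strand n is a
Bayesian Bernoulli risk-adjusted EWMA of the 0/1 indicator "death at or before
t_n days after surgery", updated in continuous calendar time.  Each patient
generates one event per strand, scheduled at calendar time

    surgery_time + t_n,

which is the moment the patient's status at that gate resolves.  Scheduling on
the surgery clock (rather than the death clock) is what keeps patient ordering
intact on every strand: within a strand, updates occur in surgery order, so a
cluster of unusual outcomes among patients operated on around the same time
stays contiguous on the chart, while early deaths still cannot influence a
gate before that gate's delay has elapsed.

The EWMA m_i estimates the failure rate of a baseline patient.  Under the
mean-steady model (prior mean carried forward, prior precision decaying by a
factor kappa per step) the posterior mean is

    m_i = kappa * m_{i-1} + (1 - kappa) * [y_i - mu_patient + m_{i-1}],

and the steady-state posterior precision is 1/(1 - kappa).  Credible limits
are percentiles of the conjugate Beta distribution with mean m_i and precision
(shape sum) 1/(1 - kappa); the chart signals when that interval excludes the
strand's target rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .datamodel import ChartConfig, GateConfig, ValidationError, as_frame
from .risk import RiskModel, fit_gate_model, select_baseline_score

__all__ = [
    "EPS",
    "kappa_from_baseline",
    "kappa_by_mse",
    "ewma_update",
    "credible_interval",
    "check_signal",
    "build_event_schedule",
    "run_chart",
    "ChartResult",
    "StrandChart",
]

# Clamp for the EWMA before Beta construction: adjusted values are not confined
# to [0,1], so m can stray outside the open unit interval the Beta mean needs.
EPS = 1e-6


def kappa_from_baseline(m0: float) -> float:
    """Guide value for the smoothing parameter: kappa = 0.993 - 0.192 * m0.

    Calibrated for processes with small failure rates; valid for any
    m0 in [0, 1] (the result is clamped into the open interval (0, 1),
    although for valid m0 the clamp is never active).
    """
    if not (0.0 <= m0 <= 1.0):
        raise ValidationError(f"m0 must lie in [0, 1], got {m0}")
    kappa = 0.993 - 0.192 * m0
    return min(max(kappa, EPS), 1.0 - EPS)


def ewma_update(m_prev: float, value: float, kappa: float) -> float:
    """One EWMA step: kappa * m_prev + (1 - kappa) * value."""
    if not (0.0 < kappa < 1.0):
        raise ValidationError(f"kappa must lie in (0, 1), got {kappa}")
    return kappa * m_prev + (1.0 - kappa) * value


def kappa_by_mse(stream, grid, m0: float | None = None) -> float:
    """Choose kappa from a grid by one-step prediction error on a pilot stream.

    For each candidate kappa the EWMA is replayed over the ordered pilot
    values and the mean of (value_i - m_{i-1})^2 is computed; the minimiser is
    returned, ties broken toward the larger kappa (for Bernoulli-like data the
    MSE curve flattens as kappa -> 1, so the largest kappa within a tie is the
    most smoothing choice consistent with the data).

    Parameters
    ----------
    stream : sequence of float
        Ordered (risk-adjusted) pilot values, length >= 2.
    grid : sequence of float
        Candidate kappa values in (0, 1).
    m0 : float, optional
        Starting chart value; defaults to the stream mean.
    """
    values = np.asarray(list(stream), dtype=float)
    grid = np.asarray(list(grid), dtype=float)
    if values.size < 2:
        raise ValidationError("pilot stream must contain at least 2 values")
    if grid.size == 0:
        raise ValidationError("kappa grid is empty")
    if np.any((grid <= 0.0) | (grid >= 1.0)):
        raise ValidationError("kappa grid values must lie in (0, 1)")
    start = float(np.mean(values)) if m0 is None else float(m0)

    best_kappa, best_mse = None, np.inf
    for kappa in np.sort(grid):
        m = start
        sse = 0.0
        for v in values:
            err = v - m
            sse += err * err
            m = kappa * m + (1.0 - kappa) * v
        mse = sse / values.size
        if mse <= best_mse + 1e-12:  # ties (within tolerance) go to larger kappa
            best_kappa, best_mse = float(kappa), min(mse, best_mse)
    return best_kappa


def _beta_shapes(m, kappa):
    m = np.clip(m, EPS, 1.0 - EPS)
    precision = 1.0 / (1.0 - kappa)
    return m * precision, (1.0 - m) * precision


def credible_interval(m, kappa, alpha_low: float = 0.025, alpha_high: float = 0.975):
    """Beta credible limits for the baseline rate at steady-state precision.

    The posterior is Beta(a, b) with a = m/(1-kappa), b = (1-m)/(1-kappa), so
    the mean is m and the precision (a + b) is 1/(1-kappa).  Returns the
    (alpha_low, alpha_high) quantiles.  Accepts scalars or arrays of m.
    """
    if not (0.0 < alpha_low < alpha_high < 1.0):
        raise ValidationError(
            f"percentiles must satisfy 0 < low < high < 1, got ({alpha_low}, {alpha_high})"
        )
    if not (0.0 < kappa < 1.0):
        raise ValidationError(f"kappa must lie in (0, 1), got {kappa}")
    a, b = _beta_shapes(m, kappa)
    lo = stats.beta.ppf(alpha_low, a, b)
    hi = stats.beta.ppf(alpha_high, a, b)
    if np.ndim(m) == 0:
        return float(lo), float(hi)
    return lo, hi


def check_signal(lo: float, hi: float, target: float) -> str:
    """Signal rule: the credible interval excludes the target.

    'up' when target < lo (rate credibly above target), 'down' when
    target > hi, 'none' otherwise; a target exactly on a bound does not
    signal.
    """
    if not lo < hi:
        raise ValidationError(f"interval must satisfy lo < hi, got ({lo}, {hi})")
    if target < lo:
        return "up"
    if target > hi:
        return "down"
    return "none"


def build_event_schedule(records, gates: GateConfig, horizon: float | None = None):
    """Per-strand ordered update streams.

    For each strand n and patient j there is one event at calendar time
    surgery_time_j + t_n carrying the 0/1 outcome "died at or before t_n"
    (inclusive at the boundary).  Within a strand, events are ordered by
    surgery time with ties kept in input order.  Events whose calendar time
    exceeds ``horizon`` are omitted: their outcome has not resolved by then.

    Returns a list of DataFrames (one per strand) with columns
    ``calendar_time, patient_id, z, y, surgery_time``.
    """
    frame = as_frame(records)
    order = np.argsort(frame["surgery_time"].to_numpy(), kind="stable")
    surgery = frame["surgery_time"].to_numpy(dtype=float)[order]
    z = frame["z"].to_numpy(dtype=int)[order]
    surv = frame["survival_time"].to_numpy(dtype=float)[order]
    died = frame["died"].to_numpy(dtype=bool)[order]
    pid = frame["patient_id"].to_numpy(dtype=object)[order]

    schedules = []
    for t_n in gates.gates:
        calendar = surgery + t_n
        keep = slice(None) if horizon is None else calendar <= horizon
        schedules.append(
            pd.DataFrame(
                {
                    "calendar_time": calendar[keep],
                    "patient_id": pid[keep],
                    "z": z[keep],
                    "y": (died[keep] & (surv[keep] <= t_n)).astype(float),
                    "surgery_time": surgery[keep],
                }
            )
        )
    return schedules


@dataclass
class ChartResult:
    """Ordered per-strand update series produced by :func:`run_chart`.

    ``frame`` has one row per strand update with columns
    strand, update_index, calendar_time, patient_id, y, mu_hat_patient,
    adjusted_value, m, ci_lo, ci_hi, signal.
    """

    frame: pd.DataFrame
    gates: GateConfig

    def strand(self, n: int) -> pd.DataFrame:
        return self.frame[self.frame["strand"] == n].reset_index(drop=True)

    @property
    def n_strands(self) -> int:
        return self.gates.n_strands

    def first_signals(self) -> dict:
        """Per-strand calendar time of the first up- and down-signal (or None)."""
        out = {}
        for n in range(self.n_strands):
            sub = self.strand(n)
            entry = {}
            for direction in ("up", "down"):
                hits = sub.loc[sub["signal"] == direction, "calendar_time"]
                entry[direction] = float(hits.iloc[0]) if len(hits) else None
            out[n] = entry
        return out

    def first_signal_time(self, direction: str = "any") -> float | None:
        """Earliest signal calendar time across all strands, or None."""
        if direction == "any":
            mask = self.frame["signal"] != "none"
        else:
            mask = self.frame["signal"] == direction
        times = self.frame.loc[mask, "calendar_time"]
        return float(times.min()) if len(times) else None


def run_chart(
    records,
    gates: GateConfig,
    models,
    config: ChartConfig,
    horizon: float | None = None,
) -> ChartResult:
    """Run the full N-strand chart over a monitoring stream.

    For each strand the EWMA starts at the calibrated baseline rate m0 and,
    at every scheduled event, the arriving patient's rate is predicted by
    scaling the current baseline odds, the observed outcome is adjusted back
    to the baseline metric, the EWMA is updated and clamped to
    [EPS, 1 - EPS], and Beta credible limits are checked against the strand
    target (default: m0 itself).
    """
    models = list(models)
    if len(models) != gates.n_strands:
        raise ValidationError(
            f"{len(models)} risk models for {gates.n_strands} strands"
        )
    kappas = _per_strand(config.kappa, gates.n_strands, "kappa")
    if kappas is None:
        kappas = [kappa_from_baseline(m.m0) for m in models]
    targets = _per_strand(config.targets, gates.n_strands, "targets")
    if targets is None:
        targets = [m.m0 for m in models]

    schedules = build_event_schedule(records, gates, horizon=horizon)
    pieces = []
    for n, (sched, model, kappa, target) in enumerate(
        zip(schedules, models, kappas, targets)
    ):
        y_arr = sched["y"].to_numpy()
        scale = np.exp(model.beta * (sched["z"].to_numpy(dtype=float) - model.z_b))
        m = model.m0
        one_minus_k = 1.0 - kappa
        mu_vals = np.empty(len(sched))
        adj_vals = np.empty(len(sched))
        m_vals = np.empty(len(sched))
        for i, (yj, ej) in enumerate(zip(y_arr.tolist(), scale.tolist())):
            odds = m / (1.0 - m) * ej
            mu = odds / (1.0 + odds)
            adj = yj - mu + m
            m = kappa * m + one_minus_k * adj
            m = EPS if m < EPS else (1.0 - EPS if m > 1.0 - EPS else m)
            mu_vals[i] = mu
            adj_vals[i] = adj
            m_vals[i] = m

        lo, hi = credible_interval(m_vals, kappa, config.alpha_low, config.alpha_high)
        lo = np.atleast_1d(lo)
        hi = np.atleast_1d(hi)
        signal = np.where(target < lo, "up", np.where(target > hi, "down", "none"))
        pieces.append(
            pd.DataFrame(
                {
                    "strand": n,
                    "update_index": np.arange(len(sched)),
                    "calendar_time": sched["calendar_time"].to_numpy(),
                    "patient_id": sched["patient_id"].to_numpy(),
                    "y": y_arr,
                    "mu_hat_patient": mu_vals,
                    "adjusted_value": adj_vals,
                    "m": m_vals,
                    "ci_lo": lo,
                    "ci_hi": hi,
                    "signal": signal,
                }
            )
        )
    frame = (
        pd.concat(pieces, ignore_index=True)
        if pieces
        else pd.DataFrame(
            columns=[
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
        )
    )
    return ChartResult(frame=frame, gates=gates)


def _per_strand(values, n: int, name: str):
    if values is None:
        return None
    if np.ndim(values) == 0:
        return [float(values)] * n
    values = [float(v) for v in values]
    if len(values) != n:
        raise ValidationError(f"{name}: expected {n} per-strand values, got {len(values)}")
    return values


class StrandChart(BaseEstimator):
    """N-strand risk-adjusted survival control chart, as a fit/transform pair.

    ``fit`` calibrates the chart on pilot data: it selects the baseline risk
    score (pilot median), fits one logistic risk model per gate, chooses the
    smoothing parameter kappa per strand, and sets per-strand targets.
    ``transform`` runs the calibrated chart over a monitoring stream and
    returns a :class:`ChartResult`.

    Parameters
    ----------
    gates : sequence of float
        Survival gates t_1 < ... < t_N in days (default (0.5, 2, 10, 20, 30)).
    d : float
        Censoring window in days (default 30).
    kappa : float, sequence, or None
        Fixed smoothing value(s); None selects per strand via ``kappa_method``.
    kappa_method : {"guide", "mse"}
        "guide" uses 0.993 - 0.192*m0; "mse" minimises one-step prediction
        error on the risk-adjusted pilot stream over ``kappa_grid``.
    kappa_grid : sequence of float, optional
        Candidates for the "mse" method (default 0.90 ... 0.999).
    alpha_low, alpha_high : float
        Credible-limit percentiles (default symmetric 95%: 0.025 / 0.975).
    targets : float, sequence, or None
        Signalling targets per strand; None uses each strand's pilot rate m0.
    penalize : bool
        Allow a weakly penalised logistic fit on tiny/separated pilots.

    Attributes
    ----------
    z_b_ : int
        Baseline risk score (pilot median).
    models_ : list of RiskModel
        Per-gate logistic risk models.
    kappa_ : list of float
        Chosen smoothing parameter per strand.
    targets_ : list of float
        Signalling target per strand.
    """

    def __init__(
        self,
        gates=(0.5, 2.0, 10.0, 20.0, 30.0),
        d: float = 30.0,
        kappa=None,
        kappa_method: str = "guide",
        kappa_grid=None,
        alpha_low: float = 0.025,
        alpha_high: float = 0.975,
        targets=None,
        penalize: bool = False,
    ):
        self.gates = gates
        self.d = d
        self.kappa = kappa
        self.kappa_method = kappa_method
        self.kappa_grid = kappa_grid
        self.alpha_low = alpha_low
        self.alpha_high = alpha_high
        self.targets = targets
        self.penalize = penalize

    def _gate_config(self) -> GateConfig:
        return GateConfig(gates=tuple(self.gates), d=self.d)

    def fit(self, X, y=None):
        """Calibrate risk models, kappa and targets on pilot records ``X``."""
        pilot = as_frame(X)
        gc = self._gate_config()
        self.z_b_ = select_baseline_score(pilot)
        self.models_ = [
            fit_gate_model(pilot, t, self.z_b_, gate_index=n, penalize=self.penalize)
            for n, t in enumerate(gc.gates)
        ]
        kappas = _per_strand(self.kappa, gc.n_strands, "kappa")
        if kappas is None:
            if self.kappa_method == "guide":
                kappas = [kappa_from_baseline(m.m0) for m in self.models_]
            elif self.kappa_method == "mse":
                grid = (
                    self.kappa_grid
                    if self.kappa_grid is not None
                    else np.arange(0.90, 1.0, 0.001)
                )
                kappas = []
                for sched, model in zip(
                    build_event_schedule(pilot, gc), self.models_
                ):
                    # adjusted pilot stream relative to the fixed pilot rate m0
                    mu = np.exp(model.beta * (sched["z"].to_numpy(dtype=float) - model.z_b))
                    mu = model.m0 / (1.0 - model.m0) * mu
                    mu = mu / (1.0 + mu)
                    adjusted = sched["y"].to_numpy() - mu + model.m0
                    kappas.append(kappa_by_mse(adjusted, grid, m0=model.m0))
            else:
                raise ValidationError(
                    f"unknown kappa_method {self.kappa_method!r} (use 'guide' or 'mse')"
                )
        self.kappa_ = kappas
        targets = _per_strand(self.targets, gc.n_strands, "targets")
        self.targets_ = targets if targets is not None else [m.m0 for m in self.models_]
        return self

    def transform(self, X, horizon: float | None = None) -> ChartResult:
        """Run the calibrated chart over monitoring records ``X``."""
        if not hasattr(self, "models_"):
            raise ValidationError("StrandChart is not fitted; call fit(pilot) first")
        config = ChartConfig(
            kappa=self.kappa_,
            alpha_low=self.alpha_low,
            alpha_high=self.alpha_high,
            targets=self.targets_,
        )
        return run_chart(X, self._gate_config(), self.models_, config, horizon=horizon)

    def fit_transform(self, X, y=None, **kwargs):
        # fitting and charting the same records is rarely meaningful for a
        # control chart, but the sklearn contract is honoured
        return self.fit(X).transform(X, **kwargs)
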