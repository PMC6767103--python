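"""Updating EWMA (uEWMA) comparator chart with 30-day survival scores.

The uEWMA weights each patient's *current* contribution to a chosen survival
summary by how recently they were operated on.  With patients listed in
surgery order j = 1..J_t at chart time t, the statistic is

    S_t = k*S_{J,t} + k(1-k)*S_{J-1,t} + ... + k(1-k)^{J-1}*S_{1,t},

so older cohorts are geometrically damped.  Here the per-patient contribution
is the risk-adjusted 30-day death indicator, y - mu_patient + mu_baseline,
once the patient's 30-day status has resolved, and its null expectation
mu_baseline while the patient is still inside the censoring window.  The
statistic is reflected at a lower barrier h_l and signals deterioration when
it reaches the upper barrier h_u.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .datamodel import ValidationError, as_frame
from .risk import RiskModel, fit_gate_model, predict_patient_rate, select_baseline_score

__all__ = ["UEWMAConfig", "UEWMAResult", "uewma_statistic", "uewma_run", "UEWMAChart"]


@dataclass(frozen=True)
class UEWMAConfig:
    """uEWMA chart settings (defaults: the 30-day-survival variant).

    k is the recency weight; h_l the lower reflecting barrier; h_u the upper
    signal barrier; s0 the chart's initial value, which enters the
    cross-sectional weighted sum as a fading remnant term (1-k)^J * s0; d the
    censoring window; block an optional truncation length for the weighted
    sum (None derives one so the neglected tail weight is below 1e-12).
    """

    k: float = 0.01
    h_l: float = 0.01
    h_u: float = 0.048
    s0: float = 0.025
    d: float = 30.0
    block: int | None = None

    def __post_init__(self):
        if not (0.0 < self.k < 1.0):
            raise ValidationError(f"k must lie in (0, 1), got {self.k}")
        if not (self.h_l < self.s0 < self.h_u):
            raise ValidationError(
                f"need h_l < s0 < h_u, got ({self.h_l}, {self.s0}, {self.h_u})"
            )

    def effective_block(self) -> int:
        if self.block is not None:
            return int(self.block)
        # smallest B with (1-k)^B < 1e-12
        return int(math.ceil(math.log(1e-12) / math.log(1.0 - self.k)))


def uewma_statistic(contributions, k: float, block: int | None = None) -> float:
    """The recency-weighted sum of Eq.-2 form over an ordered contribution list.

    ``contributions`` are ordered oldest-first (surgery order); the most
    recent patient gets weight k, the one before k(1-k), and so on.  With
    ``block`` set, the sum runs over at most the most recent ``block``
    patients — the neglected tail weight is (1-k)^block.
    """
    c = np.asarray(list(contributions), dtype=float)
    if c.size == 0:
        raise ValidationError("contribution list is empty")
    if not (0.0 < k < 1.0):
        raise ValidationError(f"k must lie in (0, 1), got {k}")
    take = c.size if block is None else min(c.size, int(block))
    tail = c[c.size - take :][::-1]  # most recent first
    weights = k * (1.0 - k) ** np.arange(take)
    return float(weights @ tail)


@dataclass
class UEWMAResult:
    """Trace of one uEWMA run: the statistic after every arrival/resolution."""

    frame: pd.DataFrame  # columns: time, n_patients, S, signal
    config: UEWMAConfig

    def first_signal_time(self) -> float | None:
        hits = self.frame.loc[self.frame["signal"], "time"]
        return float(hits.iloc[0]) if len(hits) else None

    def run_length(self, records, unit: str = "patients", horizon: float = np.inf):
        """(run length, signalled?) in the requested unit."""
        t_sig = self.first_signal_time()
        surgery = as_frame(records)["surgery_time"].to_numpy(dtype=float)
        if t_sig is None:
            return (
                float(min(horizon, len(surgery)))
                if unit == "patients"
                else float(np.max(surgery) + self.config.d),
                False,
            )
        if unit == "patients":
            return float(np.count_nonzero(surgery <= t_sig)), True
        return float(t_sig), True


def uewma_run(records, config: UEWMAConfig, risk_model_30d: RiskModel) -> UEWMAResult:
    """Run the uEWMA chart over a monitoring stream.

    The chart updates at every patient arrival and at every resolution (death,
    or censoring at d days).  After each event the statistic is recomputed
    over the current contribution list, the initial-value remnant
    (1-k)^J * s0 is added, the result is reflected at h_l, and an up-signal is
    recorded when it reaches h_u.
    """
    frame = as_frame(records)
    order = np.argsort(frame["surgery_time"].to_numpy(), kind="stable")
    surgery = frame["surgery_time"].to_numpy(dtype=float)[order]
    z = frame["z"].to_numpy(dtype=float)[order]
    surv = frame["survival_time"].to_numpy(dtype=float)[order]
    died = frame["died"].to_numpy(dtype=bool)[order]
    n = len(surgery)

    mu_b = risk_model_30d.m0
    mu_j = predict_patient_rate(mu_b, risk_model_30d, z) if n else np.empty(0)
    mu_j = np.atleast_1d(mu_j)
    y30 = (died & (surv <= config.d)).astype(float)
    resolved_contrib = y30 - mu_j + mu_b
    resolution = surgery + np.where(died, surv, config.d)

    # event list: arrivals then resolutions, time-ordered (arrivals first on ties)
    events = [(surgery[j], 0, j) for j in range(n)]
    events += [(resolution[j], 1, j) for j in range(n)]
    events.sort()

    k = config.k
    block = config.effective_block()
    weights = k * (1.0 - k) ** np.arange(block)
    contrib = np.empty(n)
    n_arrived = 0

    times, counts, stats_, signals = [], [], [], []
    for t, kind, j in events:
        if kind == 0:
            contrib[n_arrived] = mu_b  # null expectation while unresolved
            n_arrived += 1
        else:
            contrib[j] = resolved_contrib[j]
        take = min(n_arrived, block)
        s = float(weights[:take] @ contrib[n_arrived - take : n_arrived][::-1])
        s += (1.0 - k) ** n_arrived * config.s0
        s = max(s, config.h_l)  # lower reflecting barrier
        times.append(t)
        counts.append(n_arrived)
        stats_.append(s)
        signals.append(s >= config.h_u)

    trace = pd.DataFrame(
        {"time": times, "n_patients": counts, "S": stats_, "signal": signals}
    )
    return UEWMAResult(frame=trace, config=config)


def run_length_uewma(
    stream_factory,
    config: UEWMAConfig,
    risk_model_30d: RiskModel,
    n_runs: int = 100,
    unit: str = "patients",
    horizon: int = 10_000,
    seed=0,
    q: float = 1.0,
):
    """Run-length summary for the uEWMA, mirroring :func:`simulate.run_length`."""
    from .simulate import RunLengthResult

    seeds = np.random.SeedSequence(seed).spawn(n_runs)
    lengths = np.empty(n_runs)
    signalled = np.empty(n_runs, dtype=bool)
    for r, ss in enumerate(seeds):
        records = stream_factory(ss)
        result = uewma_run(records, config, risk_model_30d)
        lengths[r], signalled[r] = result.run_length(records, unit=unit, horizon=horizon)
    frac = 1.0 - float(np.mean(signalled))
    return RunLengthResult(
        q=q,
        n_runs=n_runs,
        unit=unit,
        median_rl=float(np.median(lengths)),
        censor_horizon=float(horizon),
        fraction_censored=frac,
        median_censored=frac >= 0.5,
        run_lengths=lengths,
    )


class UEWMAChart(BaseEstimator):
    """uEWMA comparator as a fit/transform estimator.

    ``fit`` calibrates the 30-day logistic risk model on pilot records (shared
    baseline-score convention with :class:`~strandchart.chart.StrandChart`);
    ``transform`` runs the chart over a monitoring stream and returns a
    :class:`UEWMAResult`.
    """

    def __init__(
        self,
        k: float = 0.01,
        h_l: float = 0.01,
        h_u: float = 0.048,
        s0: float = 0.025,
        d: float = 30.0,
        block: int | None = None,
        penalize: bool = False,
    ):
        self.k = k
        self.h_l = h_l
        self.h_u = h_u
        self.s0 = s0
        self.d = d
        self.block = block
        self.penalize = penalize

    def _config(self) -> UEWMAConfig:
        return UEWMAConfig(
            k=self.k, h_l=self.h_l, h_u=self.h_u, s0=self.s0, d=self.d, block=self.block
        )

    def fit(self, X, y=None):
        pilot = as_frame(X)
        self.z_b_ = select_baseline_score(pilot)
        self.model_ = fit_gate_model(
            pilot, self.d, self.z_b_, gate_index=0, penalize=self.penalize
        )
        return self

    def transform(self, X) -> UEWMAResult:
        if not hasattr(self, "model_"):
            raise ValidationError("UEWMAChart is not fitted; call fit(pilot) first")
        return uewma_run(X, self._config(), self.model_)
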