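"""Synthetic cohorts, bootstrap streams, and run-length estimation.

The performance of a monitoring chart is summarised by its run length: the
amount of monitoring (patients, or calendar days) until the first signal.
Process deterioration is emulated with an accelerated-failure-time shift:
survival times are divided by an acceleration factor q >= 1, so larger q
means earlier deaths and, for a well-behaved chart, shorter run lengths.

The synthetic cohort generator emulates the structure of post-cardiac-surgery
monitoring data: Poisson arrivals of a few patients per day, integer
Parsonnet-style risk scores with a long right tail, small 30-day death rates
whose odds scale as exp(beta * (z - z_ref)), and front-loaded death times
within the 30-day window (Weibull shape 0.5, truncated).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .chart import ChartResult, run_chart
from .datamodel import ChartConfig, GateConfig, ValidationError, as_frame

__all__ = [
    "SimConfig",
    "RunLengthResult",
    "synth_cohort",
    "bootstrap_stream",
    "run_length",
    "mrl_curve",
]


@dataclass(frozen=True)
class SimConfig:
    """Synthetic-cohort generator settings.

    Defaults describe an in-control, cardiac-surgery-scale process: 3.2
    arrivals/day, negative-binomial risk scores with mean ~7 truncated to
    0..70, a 5% baseline 30-day death rate at the reference score z_ref = 7
    with log-odds slope 0.07 per score point, and Weibull(shape 0.5,
    scale 30) death times truncated to the 30-day window so that deaths are
    front-loaded toward the first days after surgery.
    """

    n_patients: int = 1000
    arrival_rate: float = 3.2          # patients per day (Poisson process)
    score_nbinom_n: float = 1.5        # nbinom shape; mean = n*(1-p)/p
    score_nbinom_p: float = 1.5 / 8.5  # gives mean 7
    score_max: int = 70
    beta_true: float = 0.07            # log-odds per score point
    m30_baseline: float = 0.05         # 30-day death rate at z = z_ref
    z_ref: int = 7
    weibull_shape: float = 0.5
    weibull_scale: float = 30.0
    q: float = 1.0                     # acceleration factor (q > 1: earlier deaths)
    d: float = 30.0
    seed: int = 0

    def __post_init__(self):
        if self.q < 1.0:
            raise ValidationError(f"acceleration factor q must be >= 1, got {self.q}")
        if self.arrival_rate <= 0:
            raise ValidationError("arrival_rate must be positive")
        if not (0.0 < self.m30_baseline < 1.0):
            raise ValidationError("m30_baseline must lie in (0, 1)")
        if self.weibull_shape <= 0 or self.weibull_scale <= 0:
            raise ValidationError("Weibull parameters must be positive")


@dataclass(frozen=True)
class RunLengthResult:
    """Run-length distribution summary for one (scenario, q) pair."""

    q: float
    n_runs: int
    unit: str                    # "patients" or "days"
    median_rl: float
    censor_horizon: float
    fraction_censored: float
    median_censored: bool        # True when >= half the runs never signalled
    run_lengths: np.ndarray = field(repr=False, default=None)


def _truncated_weibull(u, shape, scale, d):
    """Inverse-CDF sample of Weibull(shape, scale) truncated to (0, d]."""
    cap = -np.expm1(-((d / scale) ** shape))  # F(d)
    return scale * (-np.log1p(-u * cap)) ** (1.0 / shape)


def synth_cohort(config: SimConfig) -> pd.DataFrame:
    """Generate a synthetic patient cohort.

    Arrival times come from a homogeneous Poisson process; risk scores are
    i.i.d. truncated negative-binomial; each patient dies within the d-day
    window with probability given by scaling the baseline odds of
    ``m30_baseline`` by exp(beta_true * (z - z_ref)); conditional death times
    follow the truncated Weibull law; survivors are censored at d.  Finally
    death times are divided by q (survivors stay censored at d).

    Returns the canonical patient DataFrame, deterministically reproducible
    from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    arrivals = np.cumsum(rng.exponential(1.0 / config.arrival_rate, size=n))
    z = rng.negative_binomial(config.score_nbinom_n, config.score_nbinom_p, size=n)
    z = np.minimum(z, config.score_max)

    base_odds = config.m30_baseline / (1.0 - config.m30_baseline)
    odds = base_odds * np.exp(config.beta_true * (z - config.z_ref))
    p30 = odds / (1.0 + odds)
    died = rng.random(n) < p30

    death_time = _truncated_weibull(
        rng.random(n), config.weibull_shape, config.weibull_scale, config.d
    )
    survival = np.where(died, death_time / config.q, config.d)

    return pd.DataFrame(
        {
            "patient_id": [f"s{i}" for i in range(n)],
            "surgery_time": arrivals,
            "z": z.astype(int),
            "survival_time": survival,
            "died": died,
        }
    )


def bootstrap_stream(
    source, n: int, q: float = 1.0, seed=0, d: float = 30.0, arrival_rate: float = 3.2
) -> pd.DataFrame:
    """Empirical bootstrap of (survival_time, z) pairs, without replacement.

    Pairs are drawn without replacement from the source records (reshuffling
    and continuing when n exceeds the source size).  Survival times of
    recorded deaths are divided by q; a source death remains a death when its
    accelerated time is within the censoring window.  Censored source records
    stay censored at d — their true survival beyond d is unknown, so they are
    never accelerated into deaths.  Fresh Poisson arrival times are attached.
    """
    frame = as_frame(source)
    if len(frame) == 0:
        raise ValidationError("bootstrap source is empty")
    if q < 1.0:
        raise ValidationError(f"acceleration factor q must be >= 1, got {q}")
    rng = np.random.default_rng(seed)

    idx = []
    while len(idx) < n:
        idx.extend(rng.permutation(len(frame)).tolist())
    idx = np.asarray(idx[:n])

    surv = frame["survival_time"].to_numpy(dtype=float)[idx]
    z = frame["z"].to_numpy(dtype=int)[idx]
    died_src = frame["died"].to_numpy(dtype=bool)[idx]

    accel = surv / q
    died = died_src & (accel <= d)
    survival = np.where(died, accel, d)

    arrivals = np.cumsum(rng.exponential(1.0 / arrival_rate, size=n))
    return pd.DataFrame(
        {
            "patient_id": [f"b{i}" for i in range(n)],
            "surgery_time": arrivals,
            "z": z,
            "survival_time": survival,
            "died": died,
        }
    )


def _run_length_one(
    records, gates, models, config, unit, horizon_patients, direction
):
    """Run length of one chart run: patients (or days) until the first signal."""
    result = run_chart(records, gates, models, config)
    t_sig = result.first_signal_time(direction)
    surgery = as_frame(records)["surgery_time"].to_numpy(dtype=float)
    if t_sig is None:
        return float(horizon_patients) if unit == "patients" else float(np.max(surgery) + gates.d), False
    if unit == "patients":
        return float(np.count_nonzero(surgery <= t_sig)), True
    return float(t_sig), True


def run_length(
    stream_factory,
    gates: GateConfig,
    models,
    config: ChartConfig,
    n_runs: int = 100,
    unit: str = "patients",
    horizon: int = 10_000,
    seed=0,
    q: float = 1.0,
    direction: str = "any",
) -> RunLengthResult:
    """Estimate the run-length distribution of a chart over fresh streams.

    Parameters
    ----------
    stream_factory : callable(run_seed) -> patient records
        Produces one monitoring stream of ``horizon`` patients per run.
    gates, models, config :
        The calibrated chart to evaluate (chart state starts at each strand's
        m0 with steady-state precision).
    n_runs : int
        Number of independent chart runs.
    unit : {"patients", "days"}
        "patients" counts surgeries up to and including the first signal;
        "days" records the signal's calendar time.
    horizon : int
        Stream length in patients; runs with no signal are censored there.
    direction : {"any", "up", "down"}
        Which signals terminate a run.

    The median treats censored runs as >= horizon; ``median_censored`` flags
    the case where at least half the runs never signalled.
    """
    if unit not in ("patients", "days"):
        raise ValidationError(f"unknown run-length unit {unit!r}")
    if horizon < 1:
        raise ValidationError("horizon must cover at least one patient")
    seeds = np.random.SeedSequence(seed).spawn(n_runs)
    lengths = np.empty(n_runs)
    signalled = np.empty(n_runs, dtype=bool)
    for r, ss in enumerate(seeds):
        records = stream_factory(ss)
        lengths[r], signalled[r] = _run_length_one(
            records, gates, models, config, unit, horizon, direction
        )
    frac_censored = 1.0 - float(np.mean(signalled))
    return RunLengthResult(
        q=q,
        n_runs=n_runs,
        unit=unit,
        median_rl=float(np.median(lengths)),
        censor_horizon=float(horizon),
        fraction_censored=frac_censored,
        median_censored=frac_censored >= 0.5,
        run_lengths=lengths,
    )


def mrl_curve(
    q_grid,
    stream_factory_for_q,
    gates: GateConfig,
    models,
    config: ChartConfig,
    n_runs: int = 100,
    unit: str = "patients",
    horizon: int = 10_000,
    seed=0,
    direction: str = "any",
) -> list:
    """Median run length as a function of the acceleration factor q.

    ``stream_factory_for_q(q)`` must return a stream factory as accepted by
    :func:`run_length`.  The same base seed is reused for every q, pairing
    runs across the grid (common random numbers) to reduce the Monte-Carlo
    variance of the comparison.
    """
    results = []
    for q in q_grid:
        if q < 1.0:
            raise ValidationError(f"acceleration factor q must be >= 1, got {q}")
        results.append(
            run_length(
                stream_factory_for_q(q),
                gates,
                models,
                config,
                n_runs=n_runs,
                unit=unit,
                horizon=horizon,
                seed=seed,
                q=q,
                direction=direction,
            )
        )
    return results
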