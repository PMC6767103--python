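"""Chart engine: EWMA recursion, Beta credible limits, scheduling, signals."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.optimize import brentq
from scipy.special import betainc

from strandchart import (
    ChartConfig,
    GateConfig,
    PatientRecord,
    RiskModel,
    SimConfig,
    ValidationError,
    build_event_schedule,
    check_signal,
    credible_interval,
    ewma_update,
    kappa_by_mse,
    kappa_from_baseline,
    run_chart,
    synth_cohort,
)
from strandchart.chart import EPS, _beta_shapes


class TestKappaGuide:
    @pytest.mark.parametrize(
        "m0,expected", [(0.0, 0.993), (0.05, 0.9834), (1.0, 0.801)]
    )
    def test_closed_form(self, m0, expected):
        assert kappa_from_baseline(m0) == pytest.approx(expected, abs=1e-15)

    def test_rejects_rates_outside_unit_interval(self):
        for bad in (-0.1, 1.1):
            with pytest.raises(ValidationError):
                kappa_from_baseline(bad)


class TestKappaByMse:
    def test_constant_stream_returns_largest_grid_value(self):
        grid = [0.9, 0.95, 0.99]
        assert kappa_by_mse([0.02] * 10, grid, m0=0.02) == 0.99

    def test_matches_brute_force_on_noise(self, rng):
        """Selected kappa = largest grid value whose replayed MSE ties the min."""
        values = 0.05 + 0.01 * rng.standard_normal(400)
        grid = np.linspace(0.5, 0.99, 25)

        def brute_mse(kappa):
            m, sse = float(np.mean(values)), 0.0
            for v in values:
                sse += (v - m) ** 2
                m = kappa * m + (1 - kappa) * v
            return sse / len(values)

        mses = np.array([brute_mse(k) for k in grid])
        best = mses.min()
        expected = max(g for g, e in zip(grid, mses) if e <= best + 1e-12)
        assert kappa_by_mse(values, grid) == pytest.approx(expected)

    def test_short_stream_and_empty_grid_error(self):
        with pytest.raises(ValidationError):
            kappa_by_mse([0.1], [0.9])
        with pytest.raises(ValidationError):
            kappa_by_mse([0.1, 0.2], [])


class TestEwmaUpdate:
    def test_arithmetic(self):
        assert ewma_update(0.1, 0.0, 0.9) == pytest.approx(0.09)

    def test_fixed_point(self):
        assert ewma_update(0.37, 0.37, 0.8) == pytest.approx(0.37)

    def test_recursion_equals_closed_form(self, rng):
        """kappa^i m0 + (1-kappa) sum kappa^(i-r) v_r, random streams."""
        for _ in range(20):
            kappa = rng.uniform(0.5, 0.999)
            m0 = rng.uniform(0.01, 0.2)
            values = rng.standard_normal(1000) * 0.1 + 0.05
            m = m0
            for v in values:
                m = ewma_update(m, v, kappa)
            i = len(values)
            powers = kappa ** (i - np.arange(1, i + 1))
            closed = kappa**i * m0 + (1 - kappa) * float(powers @ values)
            assert abs(m - closed) < 1e-10

    def test_kappa_bounds(self):
        with pytest.raises(ValidationError):
            ewma_update(0.1, 0.2, 1.0)


class TestCredibleInterval:
    def test_uniform_case_exact(self):
        # m=0.5, kappa=0.5 -> Beta(1,1): quantiles are the percentiles themselves
        assert credible_interval(0.5, 0.5) == pytest.approx((0.025, 0.975), abs=1e-14)

    def test_shape_computation(self):
        a, b = _beta_shapes(0.02, 0.985)
        assert a == pytest.approx(4 / 3, rel=1e-12)
        assert b == pytest.approx(196 / 3, rel=1e-12)

    def test_mean_is_m(self):
        for m in (0.001, 0.02, 0.5, 0.97):
            for kappa in (0.5, 0.9, 0.993):
                a, b = _beta_shapes(m, kappa)
                assert a / (a + b) == pytest.approx(m, abs=1e-12)
                assert a + b == pytest.approx(1 / (1 - kappa), rel=1e-12)

    def test_quantiles_match_cdf_inversion_oracle(self):
        """Quantiles of Beta(4/3, 196/3) at (0.05, 0.975) via brentq on betainc."""
        a, b = 4 / 3, 196 / 3

        def invert(alpha):
            return brentq(lambda x: betainc(a, b, x) - alpha, 1e-15, 1 - 1e-15, xtol=1e-14)

        lo, hi = credible_interval(0.02, 0.985, 0.05, 0.975)
        assert lo == pytest.approx(invert(0.05), abs=1e-8)
        assert hi == pytest.approx(invert(0.975), abs=1e-8)

    def test_width_nonincreasing_in_kappa(self):
        m = 0.04
        widths = []
        for kappa in np.linspace(0.5, 0.995, 30):
            lo, hi = credible_interval(m, kappa)
            widths.append(hi - lo)
        assert np.all(np.diff(widths) <= 1e-12)

    def test_m_outside_unit_interval_is_clamped(self):
        # clamped to m = 1e-6: quantiles collapse toward 0 but stay ordered
        lo, hi = credible_interval(-0.3, 0.9)
        assert 0.0 <= lo <= hi <= 1.0
        lo, hi = credible_interval(1.4, 0.993)
        assert 0.0 <= lo <= hi <= 1.0
        assert lo > 0.9

    def test_invalid_percentiles(self):
        with pytest.raises(ValidationError):
            credible_interval(0.5, 0.9, 0.9, 0.1)


class TestCheckSignal:
    @pytest.mark.parametrize(
        "lo,hi,target,expected",
        [
            (0.01, 0.04, 0.02, "none"),
            (0.025, 0.04, 0.02, "up"),
            (0.001, 0.015, 0.02, "down"),
            (0.02, 0.04, 0.02, "none"),  # target exactly on a bound
            (0.01, 0.02, 0.02, "none"),
        ],
    )
    def test_rule(self, lo, hi, target, expected):
        assert check_signal(lo, hi, target) == expected

    @settings(max_examples=200, derandomize=True)
    @given(
        lo=st.floats(min_value=0, max_value=0.5),
        width=st.floats(min_value=1e-6, max_value=0.5),
        target=st.floats(min_value=0, max_value=1),
    )
    def test_trichotomy(self, lo, width, target):
        outcomes = [check_signal(lo, lo + width, target)]
        assert outcomes[0] in ("none", "up", "down")


class TestEventSchedule:
    def test_definition_example(self):
        records = [
            PatientRecord("A", 0.0, 5, 0.25, True),
            PatientRecord("B", 1.0, 5, 30.0, False),
        ]
        scheds = build_event_schedule(records, GateConfig(gates=(0.5, 2.0)))
        s1, s2 = scheds
        assert list(s1["calendar_time"]) == [0.5, 1.5]
        assert list(s1["y"]) == [1.0, 0.0]
        assert list(s2["calendar_time"]) == [2.0, 3.0]
        assert list(s2["y"]) == [1.0, 0.0]

    def test_death_at_exactly_gate_counts(self):
        records = [PatientRecord("A", 0.0, 5, 2.0, True)]
        scheds = build_event_schedule(records, GateConfig(gates=(2.0, 10.0)))
        assert scheds[0]["y"].iloc[0] == 1.0
        assert scheds[1]["y"].iloc[0] == 1.0

    def test_empty_records(self):
        scheds = build_event_schedule([], GateConfig(gates=(0.5,)))
        assert all(len(s) == 0 for s in scheds)

    def test_horizon_omits_unresolved_events(self):
        records = [PatientRecord("A", 10.0, 5, 30.0, False)]
        scheds = build_event_schedule(records, GateConfig(gates=(0.5, 30.0)), horizon=20.0)
        assert len(scheds[0]) == 1  # resolves at day 10.5
        assert len(scheds[1]) == 0  # would resolve at day 40

    def test_ties_keep_input_order(self):
        records = [
            PatientRecord("x", 5.0, 1, 30.0, False),
            PatientRecord("y", 5.0, 2, 30.0, False),
        ]
        scheds = build_event_schedule(records, GateConfig(gates=(1.0,)))
        assert list(scheds[0]["patient_id"]) == ["x", "y"]


def _baseline_model(m0=0.02, beta=0.07, z_b=7, gate=0.5, n=0):
    return RiskModel(n, gate, beta=beta, z_b=z_b, m0=m0)


class TestRunChart:
    def test_no_deaths_at_baseline_score_decays_geometrically(self):
        records = [PatientRecord(str(i), float(i), 7, 30.0, False) for i in range(50)]
        gates = GateConfig(gates=(0.5,))
        model = _baseline_model(m0=0.02)
        res = run_chart(records, gates, [model], ChartConfig(kappa=[0.99]))
        m = res.strand(0)["m"].to_numpy()
        expected = 0.02 * 0.99 ** np.arange(1, 51)
        np.testing.assert_allclose(m, expected, rtol=1e-12)
        assert np.all(np.diff(m) < 0)

    def test_matches_independent_replay_oracle(self, fitted_chart):
        """Every column equals a from-scratch re-derivation of the update rules."""
        monitor = synth_cohort(SimConfig(n_patients=300, seed=21, q=1.5))
        res = fitted_chart.transform(monitor)
        frame = monitor.sort_values("surgery_time", kind="stable")
        for n, gate in enumerate(fitted_chart._gate_config().gates):
            model = fitted_chart.models_[n]
            kappa = fitted_chart.kappa_[n]
            target = fitted_chart.targets_[n]
            m = model.m0
            rows = []
            for rec in frame.itertuples(index=False):
                y = float(rec.died and rec.survival_time <= gate)
                odds = m / (1 - m) * np.exp(model.beta * (rec.z - model.z_b))
                mu = odds / (1 + odds)
                adj = y - mu + m
                m = min(max(kappa * m + (1 - kappa) * adj, EPS), 1 - EPS)
                a, b = m / (1 - kappa), (1 - m) / (1 - kappa)
                lo = stats.beta.ppf(0.025, a, b)
                hi = stats.beta.ppf(0.975, a, b)
                sig = "up" if target < lo else ("down" if target > hi else "none")
                rows.append((rec.surgery_time + gate, y, mu, adj, m, lo, hi, sig))
            oracle = pd.DataFrame(
                rows,
                columns=["calendar_time", "y", "mu_hat_patient", "adjusted_value",
                         "m", "ci_lo", "ci_hi", "signal"],
            )
            got = res.strand(n)
            for col in ("calendar_time", "y", "mu_hat_patient", "adjusted_value", "m",
                        "ci_lo", "ci_hi"):
                np.testing.assert_allclose(
                    got[col].to_numpy(), oracle[col].to_numpy(), rtol=0, atol=1e-12
                )
            assert list(got["signal"]) == list(oracle["signal"])

    def test_all_baseline_scores_reduce_to_plain_ewma(self, rng):
        """With z == z_b everywhere the chart is an unadjusted EWMA of raw outcomes."""
        n = 200
        died = rng.random(n) < 0.05
        records = [
            PatientRecord(str(i), float(i), 7, 0.3 if died[i] else 30.0, bool(died[i]))
            for i in range(n)
        ]
        gates = GateConfig(gates=(0.5,))
        model = _baseline_model(m0=0.03)
        kappa = 0.97
        res = run_chart(records, gates, [model], ChartConfig(kappa=[kappa]))
        m = model.m0
        for i, row in res.strand(0).iterrows():
            m = kappa * m + (1 - kappa) * row["y"]
            assert abs(row["m"] - m) < 1e-12

    def test_ordering_matches_surgery_order(self, fitted_chart, rng):
        monitor = synth_cohort(SimConfig(n_patients=150, seed=33))
        shuffled = monitor.sample(frac=1.0, random_state=5).reset_index(drop=True)
        res = fitted_chart.transform(shuffled)
        by_surgery = monitor.sort_values("surgery_time", kind="stable")["patient_id"]
        for n in range(res.n_strands):
            assert list(res.strand(n)["patient_id"]) == list(by_surgery)
            assert np.all(np.diff(res.strand(n)["calendar_time"]) >= 0)

    def test_strand_blind_to_post_gate_information(self, fitted_chart):
        """Changing what happens after t_n never changes strand n."""
        monitor = synth_cohort(SimConfig(n_patients=150, seed=44))
        gate = 2.0  # strand index 1
        res_a = fitted_chart.transform(monitor)
        altered = monitor.copy()
        # flip every outcome that resolves after the 2-day gate
        late = altered["survival_time"] > gate
        altered.loc[late & altered["died"], "survival_time"] = 30.0
        altered.loc[late & altered["died"], "died"] = False
        res_b = fitted_chart.transform(altered)
        a, b = res_a.strand(1), res_b.strand(1)
        np.testing.assert_allclose(a["m"].to_numpy(), b["m"].to_numpy(), atol=0)
        assert list(a["signal"]) == list(b["signal"])

    def test_strand_count_mismatch_errors(self):
        records = [PatientRecord("A", 0.0, 7, 30.0, False)]
        gates = GateConfig(gates=(0.5, 2.0))
        with pytest.raises(ValidationError):
            run_chart(records, gates, [_baseline_model()], ChartConfig())

    def test_first_signals_consistent_with_recomputation(self, fitted_chart):
        monitor = synth_cohort(SimConfig(n_patients=800, seed=55, q=3.0))
        res = fitted_chart.transform(monitor)
        firsts = res.first_signals()
        for n in range(res.n_strands):
            sub = res.strand(n)
            for direction in ("up", "down"):
                hits = sub.loc[sub["signal"] == direction, "calendar_time"]
                expected = float(hits.iloc[0]) if len(hits) else None
                assert firsts[n][direction] == expected


class TestStrandChartEstimator:
    def test_sklearn_params_roundtrip(self):
        from strandchart import StrandChart

        est = StrandChart(alpha_low=0.05)
        params = est.get_params()
        assert params["alpha_low"] == 0.05
        est.set_params(alpha_high=0.99)
        assert est.alpha_high == 0.99

    def test_transform_before_fit_errors(self):
        from strandchart import StrandChart

        with pytest.raises(ValidationError):
            StrandChart().transform([])

    def test_kappa_mse_method_selects_from_grid(self, pilot_cohort):
        from strandchart import StrandChart

        est = StrandChart(
            gates=(30.0,), kappa_method="mse", kappa_grid=[0.95, 0.98, 0.99]
        ).fit(pilot_cohort.iloc[:4000])
        assert est.kappa_[0] in (0.95, 0.98, 0.99)

    def test_fixed_scalar_kappa_broadcasts(self, pilot_cohort):
        from strandchart import StrandChart

        est = StrandChart(kappa=0.98).fit(pilot_cohort.iloc[:4000])
        assert est.kappa_ == [0.98] * 5
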