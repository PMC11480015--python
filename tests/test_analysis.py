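"""Feature extraction, recovery ratio, exponential/Boltzmann fits,
curve families, batch statistics."""

import numpy as np
import pytest
from scipy import optimize

from kvclamp.analysis import (
    CurvePoint,
    RecoveryMeasurement,
    cumulative_inactivation,
    extract_features,
    fit_biexp,
    fit_boltzmann,
    fit_monoexp,
    gv_curve,
    inactivation_curve,
    normalize_batch,
    recovery_curve,
    recovery_ratio,
    stars_for_p,
    summarize,
)
from kvclamp.channels import NoiseSpec, SolutionSpec
from kvclamp.errors import (
    BoundsError,
    DegenerateTraceError,
    FitError,
    InsufficientDataError,
    ProtocolMismatchError,
)
from kvclamp.protocols import (
    build_amplitude_protocol,
    build_gv_protocol,
    build_inactivation_protocol,
    build_recovery_protocol,
    build_train_protocol,
)
from kvclamp.simulate import SweepTrace, simulate_protocol


def _trace(t, i, v=None):
    t = np.asarray(t, float)
    return SweepTrace(
        time_ms=t,
        voltage_mv=np.zeros_like(t) if v is None else np.asarray(v, float),
        current_ua=np.asarray(i, float),
    )


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------


def test_constant_trace_peak_equals_end_of_step():
    t = np.arange(0, 100, 0.1)
    feats = extract_features(_trace(t, np.full_like(t, 3.5)), (0.0, 100.0))
    assert feats.peak == 3.5
    assert feats.end_of_step == 3.5


def test_peak_location_matches_analytic_maximum():
    # rising-then-decaying product of exponentials with a known argmax
    t = np.arange(0, 200, 0.01)
    tau_r, tau_d = 2.0, 60.0
    y = (1 - np.exp(-t / tau_r)) * np.exp(-t / tau_d)
    t_max = tau_r * np.log(1 + tau_d / tau_r)  # dy/dt = 0
    feats = extract_features(_trace(t, y), (0.0, 200.0))
    assert abs(feats.peak_time_ms - t_max) <= 0.01  # within one sample
    assert feats.peak == pytest.approx(y.max())


def test_pure_leak_trace_is_ohmic(wt, solution_2mm):
    from dataclasses import replace

    silent = replace(wt, name="silent", g0=0.0)
    noise = NoiseSpec(g_leak=0.01, e_leak_mv=-20.0)
    protocol = build_amplitude_protocol()
    ts = simulate_protocol(silent, protocol, solution_2mm, noise=noise)
    sweep = protocol.sweeps[0]
    feats = extract_features(ts.sweeps[0], sweep.segment_bounds_ms(sweep.test_index))
    assert feats.peak == pytest.approx(0.01 * (50.0 - (-20.0)))


def test_window_outside_trace_raises_bounds_error():
    t = np.arange(0, 10, 0.1)
    with pytest.raises(BoundsError):
        extract_features(_trace(t, t), (5.0, 50.0))


# ---------------------------------------------------------------------------
# Recovery ratio
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("i2,expected", [(10.0, 1.0), (2.0, 0.0), (6.0, 0.5)])
def test_recovery_ratio_corrected_orientation(i2, expected):
    m = RecoveryMeasurement(i1_max=10.0, i1_min=2.0, i2_max=i2, delta_t_ms=100.0)
    assert recovery_ratio(m) == pytest.approx(expected)


def test_recovery_ratio_as_printed_is_reciprocal():
    m = RecoveryMeasurement(i1_max=10.0, i1_min=2.0, i2_max=6.0, delta_t_ms=100.0)
    assert recovery_ratio(m, "as_printed") == pytest.approx(2.0)


def test_recovery_ratio_degenerate_trace():
    m = RecoveryMeasurement(i1_max=5.0, i1_min=5.0, i2_max=5.0, delta_t_ms=100.0)
    with pytest.raises(DegenerateTraceError):
        recovery_ratio(m)


def test_recovery_curve_monotone_and_saturating(wt, solution_2mm):
    ts = simulate_protocol(wt, build_recovery_protocol(), solution_2mm, carry_state=True)
    points = recovery_curve(ts)
    ys = [p.y for p in points]
    assert all(b >= a for a, b in zip(ys, ys[1:]))
    assert 0.0 <= ys[0] < 0.2
    assert ys[-1] == pytest.approx(1.0, abs=5e-3)


# ---------------------------------------------------------------------------
# Mono-exponential fits
# ---------------------------------------------------------------------------


def test_monoexp_recovers_rising_time_constant_exactly():
    x = np.arange(20, 8020, 250.0)
    y = 1 - np.exp(-x / 800.0)
    fit = fit_monoexp((x, y), direction="rising")
    assert fit.tau1 == pytest.approx(800.0, rel=1e-6)


def test_monoexp_constant_data_unidentifiable():
    x = np.arange(0, 100, 10.0)
    with pytest.raises(FitError):
        fit_monoexp((x, np.ones_like(x)), direction="decaying")


def test_monoexp_requires_four_points():
    with pytest.raises(InsufficientDataError):
        fit_monoexp(([1.0, 2.0, 3.0], [1.0, 0.5, 0.2]), direction="decaying")


def test_recovery_tau_matches_preset(wt, solution_2mm):
    ts = simulate_protocol(wt, build_recovery_protocol(), solution_2mm, carry_state=True)
    fit = fit_monoexp(recovery_curve(ts), direction="rising")
    assert fit.tau1 == pytest.approx(wt.tau_rec_ref, rel=0.05)


# ---------------------------------------------------------------------------
# Bi-exponential fits (with independent grid+polish oracle)
# ---------------------------------------------------------------------------


def _biexp_oracle(x, y):
    """Coarse grid over (tau1, tau2) + linear amplitude solve, then polish."""

    def rss_for(logtaus):
        t1, t2 = np.exp(logtaus)
        design = np.column_stack([np.ones_like(x), np.exp(-x / t1), np.exp(-x / t2)])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = design @ coef - y
        return float(resid @ resid), coef

    grid = np.log(np.geomspace(1.0, 5000.0, 40))
    best = None
    for lt1 in grid:
        for lt2 in grid:
            if lt2 >= lt1:
                continue
            rss, _ = rss_for((lt1, lt2))
            if best is None or rss < best[1]:
                best = ((lt1, lt2), rss)
    sol = optimize.minimize(lambda p: rss_for(p)[0], best[0], method="Nelder-Mead")
    t1, t2 = np.exp(sol.x)
    _, coef = rss_for(sol.x)
    if t2 > t1:
        t1, t2 = t2, t1
        coef = coef[[0, 2, 1]]
    return t1, t2, coef


@pytest.mark.parametrize(
    "tau1,tau2,a1f",
    [(144.0, 50.0, 0.3), (136.0, 43.0, 0.3), (400.0, 30.0, 0.6)],
)
def test_biexp_recovers_exact_samples_within_one_percent(tau1, tau2, a1f):
    x = np.arange(0, 1000, 0.5)
    y = a1f * np.exp(-x / tau1) + (1 - a1f) * np.exp(-x / tau2)
    fit = fit_biexp((x, y))
    assert fit.tau1 == pytest.approx(tau1, rel=0.01)
    assert fit.tau2 == pytest.approx(tau2, rel=0.01)
    assert fit.a1_fraction == pytest.approx(a1f, abs=0.01)


@pytest.mark.parametrize("tau1,tau2,a1f,offset", [(144.0, 50.0, 0.3, 0.1), (250.0, 80.0, 0.3, 0.0)])
def test_biexp_agrees_with_grid_polish_oracle(tau1, tau2, a1f, offset):
    x = np.arange(0, 1200, 1.0)
    y = offset + a1f * np.exp(-x / tau1) + (1 - a1f) * np.exp(-x / tau2)
    fit = fit_biexp((x, y))
    o_t1, o_t2, _ = _biexp_oracle(x, y)
    assert fit.tau1 == pytest.approx(o_t1, rel=0.01)
    assert fit.tau2 == pytest.approx(o_t2, rel=0.01)


def test_biexp_collapses_on_monoexponential_data():
    x = np.arange(0, 1000, 1.0)
    y = np.exp(-x / 100.0)
    fit = fit_biexp((x, y))
    assert "mono_collapse" in fit.flags or "identifiability" in fit.flags
    dominant_tau = fit.tau1 if fit.a1_fraction > 0.5 else fit.tau2
    assert dominant_tau == pytest.approx(100.0, rel=0.01)


def test_biexp_requires_eight_points():
    x = np.arange(0, 7, 1.0)
    with pytest.raises(InsufficientDataError):
        fit_biexp((x, np.exp(-x / 2.0)))


# ---------------------------------------------------------------------------
# Boltzmann fits
# ---------------------------------------------------------------------------


def test_boltzmann_activation_self_consistency():
    v = np.arange(-70, 61, 10.0)
    y = 1.0 / (1.0 + np.exp((-5.0 - v) / 8.0))
    fit = fit_boltzmann((v, y), "activation")
    assert fit.v_half == pytest.approx(-5.0, abs=1e-4)
    assert fit.k == pytest.approx(8.0, abs=1e-4)
    # midpoint identity: the fitted curve evaluates to 0.5 at V1/2
    assert 1.0 / (1.0 + np.exp((fit.v_half - fit.v_half) / fit.k)) == 0.5


def test_boltzmann_inactivation_with_base():
    v = np.arange(-100, 31, 10.0)
    y = 0.1 + 0.9 / (1.0 + np.exp((v - (-35.0)) / 5.0))
    fit = fit_boltzmann((v, y), "inactivation")
    assert fit.v_half == pytest.approx(-35.0, abs=1e-3)
    assert fit.k == pytest.approx(5.0, abs=1e-3)
    assert fit.base == pytest.approx(0.1, abs=1e-3)


def test_boltzmann_flat_data_unidentifiable():
    v = np.arange(-70, 61, 10.0)
    with pytest.raises(FitError):
        fit_boltzmann((v, np.full_like(v, 0.7)), "activation")


# ---------------------------------------------------------------------------
# Curve families
# ---------------------------------------------------------------------------


def test_gv_curve_normalization_contract(wt, solution_2mm):
    ts = simulate_protocol(wt, build_gv_protocol(), solution_2mm)
    points = gv_curve(ts)
    assert max(p.y for p in points) == 1.0


def test_gv_curve_null_channel_degenerate(wt, solution_2mm):
    from dataclasses import replace

    silent = replace(wt, name="silent", g0=0.0)
    ts = simulate_protocol(silent, build_gv_protocol(), solution_2mm)
    with pytest.raises(DegenerateTraceError):
        gv_curve(ts)


def test_gv_curve_rejects_wrong_protocol(wt, solution_2mm):
    ts = simulate_protocol(wt, build_amplitude_protocol(), solution_2mm)
    with pytest.raises(ProtocolMismatchError):
        gv_curve(ts)


def test_gv_pipeline_recovers_activation_midpoint(wt, solution_2mm):
    ts = simulate_protocol(wt, build_gv_protocol(), solution_2mm)
    fit = fit_boltzmann(gv_curve(ts), "activation")
    assert fit.v_half == pytest.approx(wt.act_v_half, abs=1.0)


def test_inactivation_curve_contracts(wt, solution_2mm):
    ts = simulate_protocol(wt, build_inactivation_protocol(), solution_2mm)
    points = inactivation_curve(ts)
    assert max(p.y for p in points) == 1.0
    assert points[0].x == -100.0 and points[0].y == pytest.approx(1.0, abs=0.02)
    fit = fit_boltzmann(points, "inactivation")
    assert fit.v_half == pytest.approx(wt.inact_v_half_ref, abs=1.0)


def test_inactivation_midpoint_shifts_right_with_kex(e675k):
    fits = []
    for kex in (2.0, 8.0):
        ts = simulate_protocol(e675k, build_inactivation_protocol(), SolutionSpec(kex=kex))
        fits.append(fit_boltzmann(inactivation_curve(ts), "inactivation"))
    assert fits[1].v_half > fits[0].v_half


# ---------------------------------------------------------------------------
# Cumulative inactivation
# ---------------------------------------------------------------------------


def test_cumulative_inactivation_synthetic_decay_tau():
    # replace simulated amplitudes with a known exponential decay at 50 Hz
    protocol = build_train_protocol(50.0, 10.0)
    n = len(protocol.sweeps)
    period = 20.0
    sweeps = []
    for i in range(n):
        t = np.arange(0, protocol.sweeps[i].duration_ms, 0.1)
        amp = np.exp(-(i * period) / 500.0)
        sweeps.append(_trace(t, np.full_like(t, amp)))
    from kvclamp.simulate import TraceSet

    ts = TraceSet(protocol=protocol, solution=SolutionSpec(), preset_name="synthetic", sweeps=sweeps)
    result = cumulative_inactivation(ts)
    assert result.tau_first_2s_ms == pytest.approx(500.0, rel=0.02)
    assert result.frequency_hz == pytest.approx(50.0)


def test_cumulative_inactivation_identical_pulses_gives_unity():
    protocol = build_train_protocol(10.0, 10.0)
    sweeps = []
    for sweep in protocol.sweeps:
        t = np.arange(0, sweep.duration_ms, 0.1)
        sweeps.append(_trace(t, np.full_like(t, 2.0)))
    from kvclamp.simulate import TraceSet

    ts = TraceSet(protocol=protocol, solution=SolutionSpec(), preset_name="synthetic", sweeps=sweeps)
    result = cumulative_inactivation(ts)
    assert result.relative_current_10s == pytest.approx(1.0)


def test_cumulative_inactivation_tau_flagged_at_one_hertz(wt, solution_2mm):
    ts = simulate_protocol(
        wt, build_train_protocol(1.0, 10.0), solution_2mm, carry_state=True
    )
    result = cumulative_inactivation(ts)
    assert result.tau_first_2s_ms is None
    assert "tau_not_estimable" in result.flags


# ---------------------------------------------------------------------------
# Batch statistics
# ---------------------------------------------------------------------------


def test_normalize_batch_arithmetic():
    batch = [("wt", 2.0), ("wt", 4.0), ("mut", 1.8)]
    normalized = normalize_batch(batch, "wt")
    values = {(c, round(v, 3)) for c, v in normalized}
    assert values == {("wt", 0.667), ("wt", 1.333), ("mut", 0.6)}


def test_normalize_batch_reference_only_averages_to_one():
    normalized = normalize_batch([("wt", 1.0), ("wt", 3.0)], "wt")
    assert np.mean([v for _, v in normalized]) == pytest.approx(1.0)


def test_normalize_batch_missing_reference():
    with pytest.raises(InsufficientDataError):
        normalize_batch([("mut", 1.0)], "wt")


def test_summarize_identical_groups():
    s = summarize([1.0, 1.0, 1.0, 1.0], [1.0, 1.0, 1.0, 1.0])
    assert s.sem == 0.0
    assert s.p_value == pytest.approx(1.0)
    assert s.stars == "n.s."


def test_summarize_extreme_separation_is_three_stars():
    a = np.array([0.0, 0.1, -0.1, 0.05, -0.05] * 2)
    b = a + 10 * a.std(ddof=1)
    s = summarize(a, b)
    assert s.stars == "***"


def test_summarize_requires_two_observations():
    with pytest.raises(InsufficientDataError):
        summarize([1.0])


def test_stars_mapping_thresholds():
    assert stars_for_p(0.5) == "n.s."
    assert stars_for_p(0.04) == "*"
    assert stars_for_p(0.009) == "**"
    assert stars_for_p(0.0009) == "***"


def test_welch_test_type_one_error_is_calibrated():
    rng = np.random.default_rng(2026)
    hits = 0
    n_rep = 1000
    for _ in range(n_rep):
        a = rng.normal(0.0, 1.0, 10)
        b = rng.normal(0.0, 1.0, 10)
        if summarize(a, b).p_value < 0.05:
            hits += 1
    assert 0.03 <= hits / n_rep <= 0.07
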