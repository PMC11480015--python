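"""Trace analysis: feature extraction, curve construction and model fits.

Implements the standard analysis chain for two-electrode voltage-clamp
recordings of an inactivating Kv channel:

* per-sweep feature extraction (peak, end-of-step and tail-peak currents),
* the recovery-from-inactivation ratio
  I_rec = (I_2max − I_1min)/(I_1max − I_1min),
* Boltzmann fits of conductance–voltage (GV) and steady-state inactivation
  curves (midpoint V_1/2 and slope factor k),
* mono- and bi-exponential fits of decay/recovery time courses
  (τ1 > τ2 ordering convention; slow-component weight A1/(A1+A2)),
* cumulative-inactivation quantification under pulse trains (mono-exponential
  τ of the first 2 s; relative current after 10 s of pulsing),
* batch normalization of current amplitudes to a reference construct and
  mean ± s.e.m. summaries with Welch-test significance stars.

Conventions (configurable via keyword arguments): outward current is
positive; "end of step" means the mean over the final 5 % of a segment;
tail-peak searches skip a 2 ms capacitive-blank window after the voltage
jump and look within the first 50 ms of the tail.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .biophys import nernst_potential
from .errors import (
    BoundsError,
    DegenerateTraceError,
    FitError,
    InsufficientDataError,
    ProtocolMismatchError,
)
from .simulate import SweepTrace, TraceSet

END_OF_STEP_FRACTION = 0.05
TAIL_BLANK_MS = 2.0
TAIL_SEARCH_MS = 50.0


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Features:
    """Per-sweep current features (µA; times in ms)."""

    peak: float
    end_of_step: float
    peak_time_ms: float
    tail_peak: float | None = None


@dataclass(frozen=True)
class RecoveryMeasurement:
    """Currents entering the recovery ratio: peak and end-of-step of the
    first depolarization, peak of the second, and the recovery gap."""

    i1_max: float
    i1_min: float
    i2_max: float
    delta_t_ms: float


@dataclass(frozen=True)
class CurvePoint:
    x: float
    y: float


@dataclass(frozen=True)
class BoltzmannFit:
    v_half: float
    k: float
    direction: str  # "activation" | "inactivation"
    base: float
    rss: float
    n_points: int


@dataclass(frozen=True)
class ExpFit:
    """Mono- or bi-exponential fit; for bi-exponential fits τ1 > τ2."""

    tau1: float
    a1: float
    offset: float
    rss: float
    n_points: int
    tau2: float | None = None
    a2: float | None = None
    a1_fraction: float = 1.0
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class CumulativeResult:
    frequency_hz: float
    kex: float
    relative_currents: tuple[CurvePoint, ...]
    tau_first_2s_ms: float | None
    relative_current_10s: float
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class SummaryStats:
    mean: float
    sem: float
    n: int
    p_value: float | None = None
    stars: str | None = None


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------


def _window_slice(trace: SweepTrace, window: tuple[float, float]) -> np.ndarray:
    t0, t1 = window
    t = trace.time_ms
    if t0 < t[0] - 1e-9 or t1 > t[-1] + (t[1] - t[0]) + 1e-9 or t1 <= t0:
        raise BoundsError(f"window ({t0}, {t1}) ms outside trace [{t[0]}, {t[-1]}] ms")
    mask = (t >= t0 - 1e-9) & (t < t1 - 1e-9)
    if not mask.any():
        raise BoundsError(f"window ({t0}, {t1}) ms contains no samples")
    return mask


def extract_features(
    trace: SweepTrace,
    window: tuple[float, float],
    tail_window: tuple[float, float] | None = None,
    direction: int = 1,
    end_fraction: float = END_OF_STEP_FRACTION,
    tail_direction: int = 1,
    tail_blank_ms: float = TAIL_BLANK_MS,
    tail_search_ms: float = TAIL_SEARCH_MS,
) -> Features:
    """Extract (peak, end-of-step, peak time[, tail peak]) from one sweep.

    ``window`` bounds the analysed segment in sweep time (ms).  The peak is
    the extremum in the expected current direction (+1 outward, −1 inward);
    the end-of-step current is the mean over the final ``end_fraction`` of
    the window.  If ``tail_window`` is given, the tail peak is the extremum
    in ``tail_direction`` within the first ``tail_search_ms`` of the tail
    after a ``tail_blank_ms`` capacitive-blank interval.
    """
    mask = _window_slice(trace, window)
    current = trace.current_ua[mask]
    times = trace.time_ms[mask]
    idx = int(np.argmax(direction * current))
    peak = float(current[idx])
    peak_time = float(times[idx])
    n_tail = max(1, int(round(end_fraction * current.size)))
    end_of_step = float(current[-n_tail:].mean())

    tail_peak = None
    if tail_window is not None:
        t0, t1 = tail_window
        search = (t0 + tail_blank_ms, min(t1, t0 + tail_blank_ms + tail_search_ms))
        tmask = _window_slice(trace, search)
        tcur = trace.current_ua[tmask]
        tail_peak = float(tcur[np.argmax(tail_direction * tcur)])
    return Features(peak=peak, end_of_step=end_of_step, peak_time_ms=peak_time, tail_peak=tail_peak)


# ---------------------------------------------------------------------------
# Recovery from inactivation
# ---------------------------------------------------------------------------


def recovery_ratio(m: RecoveryMeasurement, orientation: str = "corrected") -> float:
    """Relative recovered current I_rec for one paired-pulse sweep.

    The default ``corrected`` orientation, (I_2max − I_1min)/(I_1max − I_1min),
    rises from 0 (no recovery) to 1 (full recovery) with the recovery gap.
    The reciprocal ``as_printed`` orientation is available for comparison
    with legacy analyses.
    """
    if m.i1_max <= m.i1_min:
        raise DegenerateTraceError(
            "first pulse shows no inactivation (I1max <= I1min); nothing to recover from"
        )
    if orientation == "corrected":
        return (m.i2_max - m.i1_min) / (m.i1_max - m.i1_min)
    if orientation == "as_printed":
        denom = m.i2_max - m.i1_min
        if denom == 0:
            raise DegenerateTraceError("as_printed orientation undefined at zero recovery")
        return (m.i1_max - m.i1_min) / denom
    raise ValueError(f"unknown orientation {orientation!r}")


def recovery_measurements(ts: TraceSet) -> list[RecoveryMeasurement]:
    """Per-sweep recovery measurements from a recovery-family trace set."""
    if ts.protocol.family != "recovery":
        raise ProtocolMismatchError(
            f"recovery analysis needs a recovery protocol, got {ts.protocol.family!r}"
        )
    out = []
    for sweep, trace in zip(ts.protocol.sweeps, ts.sweeps):
        first = sweep.label_segment_index
        p1 = sweep.segment_bounds_ms(first)
        p2 = sweep.segment_bounds_ms(first + 2)
        f1 = extract_features(trace, p1)
        f2 = extract_features(trace, p2)
        out.append(
            RecoveryMeasurement(
                i1_max=f1.peak,
                i1_min=f1.end_of_step,
                i2_max=f2.peak,
                delta_t_ms=float(sweep.recovery_interval_ms),
            )
        )
    return out


def recovery_curve(ts: TraceSet, orientation: str = "corrected") -> list[CurvePoint]:
    """Recovered-fraction versus recovery-gap curve (one point per sweep)."""
    return [
        CurvePoint(m.delta_t_ms, recovery_ratio(m, orientation))
        for m in recovery_measurements(ts)
    ]


# ---------------------------------------------------------------------------
# Fits
# ---------------------------------------------------------------------------


def _as_xy(points) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(points, tuple) and len(points) == 2:
        x, y = points
        return np.asarray(x, float), np.asarray(y, float)
    x = np.array([p.x for p in points], float)
    y = np.array([p.y for p in points], float)
    return x, y


def fit_monoexp(points, direction: str = "decaying") -> ExpFit:
    """Least-squares mono-exponential fit.

    ``decaying``: y = offset + a1·exp(−x/τ1); ``rising``: y = offset −
    a1·exp(−x/τ1), with a1 ≥ 0 and τ1 > 0 enforced by bounds.  ``points``
    is a list of :class:`CurvePoint` or an (x, y) pair of arrays.
    """
    x, y = _as_xy(points)
    if x.size < 4:
        raise InsufficientDataError(f"mono-exponential fit needs >= 4 points, got {x.size}")
    if np.any(np.diff(x) <= 0):
        raise ValueError("x values must be strictly increasing")
    if np.ptp(y) < 1e-12 * max(1.0, np.abs(y).max()):
        raise FitError("constant data: time constant unidentifiable")
    sign = {"decaying": 1.0, "rising": -1.0}[direction]
    span = x[-1] - x[0]

    def model(xv, tau, a, c):
        return c + sign * a * np.exp(-xv / tau)

    c0 = float(y[-1])
    a0 = max(abs(float(y[0]) - c0), 1e-12)
    best = None
    for scale in (0.3, 1.0, 3.0):
        try:
            popt, _ = optimize.curve_fit(
                model,
                x,
                y,
                p0=(span / 3.0 * scale, a0, c0),
                bounds=([1e-9, 0.0, -np.inf], [np.inf, np.inf, np.inf]),
                maxfev=20000,
            )
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((model(x, *popt) - y) ** 2))
        if best is None or rss < best[1]:
            best = (popt, rss)
    if best is None:
        raise FitError("mono-exponential fit did not converge")
    (tau, a, c), rss = best
    return ExpFit(tau1=float(tau), a1=float(a), offset=float(c), rss=rss, n_points=int(x.size))


def _biexp_model(x, tau1, tau2, a1, a2, c):
    return c + a1 * np.exp(-x / tau1) + a2 * np.exp(-x / tau2)


def _peel_init(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float, float]:
    """Log-linear peeling initial guess for a decaying bi-exponential."""
    c0 = float(y[-max(3, y.size // 20):].mean())
    z = y - c0
    pos = z > max(1e-12, 1e-6 * np.abs(z).max())
    # slow component from the latter part of the decay
    late = pos & (x > x[0] + 0.4 * (x[-1] - x[0]))
    if late.sum() >= 2:
        slope, intercept = np.polyfit(x[late], np.log(z[late]), 1)
        tau1 = -1.0 / slope if slope < 0 else (x[-1] - x[0])
        a1 = math.exp(intercept)
    else:
        tau1, a1 = (x[-1] - x[0]) / 2.0, max(z.max(), 1e-9)
    tau1 = min(max(tau1, 1e-6), 100 * (x[-1] - x[0]))
    resid = z - a1 * np.exp(-x / tau1)
    early = (resid > max(1e-12, 1e-6 * np.abs(z).max())) & (x < x[0] + 0.25 * (x[-1] - x[0]))
    if early.sum() >= 2:
        slope, intercept = np.polyfit(x[early], np.log(resid[early]), 1)
        tau2 = -1.0 / slope if slope < 0 else tau1 / 4.0
        a2 = math.exp(intercept)
    else:
        tau2, a2 = tau1 / 4.0, max(z.max() - a1, 1e-9)
    tau2 = min(max(tau2, 1e-6), tau1)
    return tau1, tau2, max(a1, 1e-12), max(a2, 1e-12), c0


def fit_biexp(points, n_starts: int = 8) -> ExpFit:
    """Least-squares bi-exponential decay fit y = c + a1·e^(−x/τ1) + a2·e^(−x/τ2).

    Initialized by log-linear peeling, polished by bounded least squares from
    ``n_starts`` perturbed starting points; τ1 > τ2 is enforced by a post-fit
    ordering swap and a1_fraction = a1/(a1+a2) refers to the slower
    component.  Near-equal time constants set an ``identifiability`` flag;
    a vanishing fast component sets ``mono_collapse``.
    """
    x, y = _as_xy(points)
    if x.size < 8:
        raise InsufficientDataError(f"bi-exponential fit needs >= 8 points, got {x.size}")
    if np.any(np.diff(x) <= 0):
        raise ValueError("x values must be strictly increasing")
    if np.ptp(y) < 1e-12 * max(1.0, np.abs(y).max()):
        raise FitError("constant data: time constants unidentifiable")
    tau1_0, tau2_0, a1_0, a2_0, c0 = _peel_init(x, y)

    def residuals(p):
        return _biexp_model(x, *p) - y

    lo = [1e-9, 1e-9, 0.0, 0.0, -np.inf]
    hi = [np.inf, np.inf, np.inf, np.inf, np.inf]
    rng_factors = [(1.0, 1.0), (2.0, 0.5), (0.5, 2.0), (4.0, 1.0), (1.0, 0.25),
                   (8.0, 0.5), (0.5, 0.125), (2.0, 2.0)]
    best = None
    for f1, f2 in rng_factors[:n_starts]:
        p0 = [tau1_0 * f1, tau2_0 * f2, a1_0, a2_0, c0]
        p0 = [min(max(v, l + 1e-12), 1e12) if i < 4 else v
              for i, (v, l) in enumerate(zip(p0, lo))]
        try:
            sol = optimize.least_squares(residuals, p0, bounds=(lo, hi), max_nfev=20000)
        except ValueError:
            continue
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[1]:
            best = (sol.x, rss)
    if best is None:
        raise FitError("bi-exponential fit did not converge")
    (tau1, tau2, a1, a2, c), rss = best
    if tau2 > tau1:  # ordering convention: tau1 is the slower constant
        tau1, tau2, a1, a2 = tau2, tau1, a2, a1
    flags: list[str] = []
    total = a1 + a2
    if total <= 0:
        raise FitError("bi-exponential fit degenerated to a constant")
    a1_fraction = a1 / total
    if min(a1, a2) < 1e-3 * total:
        flags.append("mono_collapse")
    if tau1 / max(tau2, 1e-12) < 1.2:
        flags.append("identifiability")
    return ExpFit(
        tau1=float(tau1),
        tau2=float(tau2),
        a1=float(a1),
        a2=float(a2),
        a1_fraction=float(a1_fraction),
        offset=float(c),
        rss=rss,
        n_points=int(x.size),
        flags=tuple(flags),
    )


def fit_boltzmann(points, direction: str = "activation") -> BoltzmannFit:
    """Boltzmann fit of a normalized GV or inactivation curve.

    activation:   y = 1/(1 + exp((V_1/2 − V)/k))
    inactivation: y = base + (1 − base)/(1 + exp((V − V_1/2)/k))

    Returns midpoint V_1/2 (mV) and slope factor k (mV, positive in both
    conventions).
    """
    x, y = _as_xy(points)
    if x.size < 4:
        raise InsufficientDataError(f"Boltzmann fit needs >= 4 points, got {x.size}")
    if np.ptp(y) < 1e-6:
        raise FitError("flat curve: midpoint unidentifiable")
    if direction not in ("activation", "inactivation"):
        raise ValueError(f"unknown direction {direction!r}")
    vh0 = float(x[np.argmin(np.abs(y - 0.5))])

    if direction == "activation":

        def model(v, vh, k):
            return 1.0 / (1.0 + np.exp((vh - v) / k))

        p0, (lo, hi) = (vh0, 8.0), ([-150.0, 0.1], [100.0, 100.0])
    else:

        def model(v, vh, k, base):
            return base + (1.0 - base) / (1.0 + np.exp((v - vh) / k))

        base0 = float(np.clip(y.min(), 0.0, 0.5))
        p0, (lo, hi) = (vh0, 8.0, base0), ([-150.0, 0.1, 0.0], [100.0, 100.0, 0.999])
    try:
        popt, _ = optimize.curve_fit(model, x, y, p0=p0, bounds=(lo, hi), maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"Boltzmann fit did not converge: {exc}") from exc
    rss = float(np.sum((model(x, *popt) - y) ** 2))
    base = float(popt[2]) if direction == "inactivation" else 0.0
    return BoltzmannFit(
        v_half=float(popt[0]),
        k=float(popt[1]),
        direction=direction,
        base=base,
        rss=rss,
        n_points=int(x.size),
    )


# ---------------------------------------------------------------------------
# Curve families
# ---------------------------------------------------------------------------


def _normalize_to_extremum(values: np.ndarray) -> np.ndarray:
    """Divide by the (signed) value of largest magnitude; its point maps to 1."""
    ref = values[np.argmax(np.abs(values))]
    if ref == 0:
        raise DegenerateTraceError("all current amplitudes are zero; cannot normalize")
    return values / ref


def gv_curve(ts: TraceSet) -> list[CurvePoint]:
    """Normalized tail-current GV curve from a GV-family trace set.

    The tail-peak amplitude after each test step is proportional to the open
    probability reached during the step; amplitudes are normalized to the
    largest tail current.  The expected tail direction follows the sign of
    the driving force at the tail potential.
    """
    if ts.protocol.family != "gv":
        raise ProtocolMismatchError(f"gv_curve needs a gv protocol, got {ts.protocol.family!r}")
    amplitudes, voltages = [], []
    for sweep, trace in zip(ts.protocol.sweeps, ts.sweeps):
        if sweep.tail_segment_index is None:
            raise ProtocolMismatchError("gv protocol sweep lacks a tail segment")
        tail_v = sweep.segments[sweep.tail_segment_index].voltage_mv
        e_k = nernst_potential(ts.solution.kin, ts.solution.kex, ts.solution.temperature_k)
        tail_dir = 1 if tail_v >= e_k else -1
        feats = extract_features(
            trace,
            sweep.segment_bounds_ms(sweep.test_index),
            tail_window=sweep.segment_bounds_ms(sweep.tail_segment_index),
            tail_direction=tail_dir,
        )
        amplitudes.append(feats.tail_peak)
        voltages.append(sweep.label_voltage_mv)
    normalized = _normalize_to_extremum(np.array(amplitudes, float))
    return [CurvePoint(v, float(y)) for v, y in zip(voltages, normalized)]


def inactivation_curve(ts: TraceSet) -> list[CurvePoint]:
    """Normalized availability curve from an inactivation-family trace set:
    peak current at the fixed test step versus conditioning voltage."""
    if ts.protocol.family != "inactivation":
        raise ProtocolMismatchError(
            f"inactivation_curve needs an inactivation protocol, got {ts.protocol.family!r}"
        )
    peaks, voltages = [], []
    for sweep, trace in zip(ts.protocol.sweeps, ts.sweeps):
        feats = extract_features(trace, sweep.segment_bounds_ms(sweep.test_index))
        peaks.append(feats.peak)
        voltages.append(sweep.label_voltage_mv)
    normalized = _normalize_to_extremum(np.array(peaks, float))
    return [CurvePoint(v, float(y)) for v, y in zip(voltages, normalized)]


def cumulative_inactivation(ts: TraceSet) -> CumulativeResult:
    """Quantify cumulative inactivation under a pulse train.

    Per pulse the end-of-step current is taken and normalized to the maximum
    over pulses (the first pulse for clean data).  The time constant of the
    first 2 s is a mono-exponential fit over pulses starting within 2 s of
    the first pulse (flagged not-estimable when fewer than four pulses fall
    in that window); the 10 s relative current is the normalized amplitude
    of the last pulse starting within 10 s.
    """
    if ts.protocol.family != "train":
        raise ProtocolMismatchError(
            f"cumulative_inactivation needs a train protocol, got {ts.protocol.family!r}"
        )
    starts = ts.protocol.sweep_start_times_ms()
    amps, times = [], []
    for sweep, trace, t0 in zip(ts.protocol.sweeps, ts.sweeps, starts):
        feats = extract_features(trace, sweep.segment_bounds_ms(sweep.label_segment_index))
        amps.append(feats.end_of_step)
        times.append(t0)
    times = np.array(times) - times[0]
    normalized = _normalize_to_extremum(np.array(amps, float))
    points = tuple(CurvePoint(float(t), float(y)) for t, y in zip(times, normalized))

    flags: list[str] = []
    early = [p for p in points if p.x <= 2000.0]
    if len(early) < 4:
        tau = None
        flags.append("tau_not_estimable")
    else:
        try:
            tau = fit_monoexp(early, direction="decaying").tau1
        except FitError:
            tau = None
            flags.append("tau_not_estimable")
    within_10s = [p for p in points if p.x <= 10000.0]
    rel_10s = within_10s[-1].y if within_10s else points[-1].y

    if ts.protocol.interval_dialect == "period":
        freq = 1000.0 / ts.protocol.inter_sweep_interval_ms
    else:
        period = ts.protocol.inter_sweep_interval_ms + ts.protocol.sweeps[0].duration_ms
        freq = 1000.0 / period
    return CumulativeResult(
        frequency_hz=freq,
        kex=ts.solution.kex,
        relative_currents=points,
        tau_first_2s_ms=tau,
        relative_current_10s=float(rel_10s),
        flags=tuple(flags),
    )


# ---------------------------------------------------------------------------
# Batch statistics
# ---------------------------------------------------------------------------


def normalize_batch(
    peaks: list[tuple[str, float]], reference: str
) -> list[tuple[str, float]]:
    """Divide every amplitude by the mean amplitude of ``reference`` within
    the batch, so the reference construct averages to 1."""
    ref_values = [v for c, v in peaks if c == reference]
    if not ref_values:
        raise InsufficientDataError(f"reference construct {reference!r} absent from batch")
    ref_mean = float(np.mean(ref_values))
    if ref_mean == 0:
        raise DegenerateTraceError(f"reference construct {reference!r} has zero mean amplitude")
    return [(c, v / ref_mean) for c, v in peaks]


def stars_for_p(p: float) -> str:
    """Significance-star convention: n.s. / * / ** / *** at 0.05/0.01/0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "n.s."


def summarize(values, comparison=None) -> SummaryStats:
    """Mean ± s.e.m. (sd/√n) and, given a comparison group, a Welch
    unequal-variance t-test with significance stars."""
    v = np.asarray(values, float)
    if v.size < 2:
        raise InsufficientDataError("s.e.m. needs at least two observations")
    mean = float(v.mean())
    sem = float(v.std(ddof=1) / math.sqrt(v.size))
    p_value = None
    stars = None
    if comparison is not None:
        w = np.asarray(comparison, float)
        if w.size < 2:
            raise InsufficientDataError("comparison group needs at least two observations")
        if np.ptp(v) == 0 and np.ptp(w) == 0:
            p_value = 1.0 if v.mean() == w.mean() else 0.0
        else:
            p_value = float(stats.ttest_ind(v, w, equal_var=False).pvalue)
        stars = stars_for_p(p_value)
    return SummaryStats(mean=mean, sem=sem, n=int(v.size), p_value=p_value, stars=stars)
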