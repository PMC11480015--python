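"""Voltage-clamp command protocols.

A protocol is an ordered list of sweeps, each sweep an ordered list of
piecewise-constant voltage segments, plus an inter-sweep interval and a
sampling rate.  The six builders below construct the standard two-electrode
voltage-clamp protocols used to characterize Kv3.3 channels:

=================  ==========================================================
``iv``             500 ms steps, −60..+80 mV in 20 mV increments
``gv``             25 ms steps, −70..+60 mV in 10 mV increments, 400 ms tail
``inactivation``   1 s (or 10 s) conditioning, −100..+30 mV, +50 mV test step
``recovery``       paired 200 ms pulses to +50 mV, gap 20 ms + 500 ms/sweep
``amplitude``      single 200 ms step to +50 mV
``train``          5 ms pulses to +40 mV at 1–100 Hz
=================  ==========================================================

All protocols hold at −80 mV.  The "inter-sweep time interval" of the train
protocol is interpreted as the pulse start-to-start *period* (the ``period``
dialect): the conventional listing 100 Hz = 10 ms is only consistent with a
5 ms pulse if the interval is the period rather than the gap.  A ``gap``
dialect (interval = holding time between pulses) is selectable but
non-default.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

from .errors import (
    InfeasibleFrequencyError,
    InvalidSolutionError,
    ProtocolError,
    SchemaError,
)

HOLDING_MV = -80.0
DEFAULT_SAMPLING_KHZ = 10.0
#: leading holding segment prepended to step-family sweeps so gates settle
DEFAULT_SETTLE_MS = 100.0
TRAIN_PULSE_MS = 5.0
TRAIN_PULSE_MV = 40.0

_VOLTAGE_LO, _VOLTAGE_HI = -150.0, 100.0


@dataclass(frozen=True)
class VoltageSegment:
    """A constant command voltage held for a duration."""

    duration_ms: float
    voltage_mv: float

    def __post_init__(self) -> None:
        if not self.duration_ms > 0:
            raise ProtocolError(f"segment duration must be > 0, got {self.duration_ms}")
        if not _VOLTAGE_LO <= self.voltage_mv <= _VOLTAGE_HI:
            raise ProtocolError(
                f"segment voltage {self.voltage_mv} mV outside sanity bound "
                f"[{_VOLTAGE_LO}, {_VOLTAGE_HI}] mV"
            )


@dataclass(frozen=True)
class Sweep:
    """One sweep: segments plus bookkeeping for the analysis stages.

    ``label_voltage_mv`` is the per-sweep x value of the curve families (the
    test potential of IV/GV sweeps, the conditioning potential of
    inactivation sweeps) and must equal the voltage of the designated
    ``label_segment_index``.  ``test_segment_index`` marks the segment whose
    current features are extracted (for IV/GV it coincides with the label
    segment); ``tail_segment_index`` marks the tail-current segment of GV
    sweeps.
    """

    segments: tuple[VoltageSegment, ...]
    label_voltage_mv: float
    label_segment_index: int = 0
    test_segment_index: int | None = None
    tail_segment_index: int | None = None
    recovery_interval_ms: float | None = None

    def __post_init__(self) -> None:
        if len(self.segments) < 1:
            raise ProtocolError("sweep needs at least one segment")
        if not 0 <= self.label_segment_index < len(self.segments):
            raise ProtocolError("label_segment_index out of range")
        seg_v = self.segments[self.label_segment_index].voltage_mv
        if seg_v != self.label_voltage_mv:
            raise ProtocolError(
                f"label voltage {self.label_voltage_mv} mV does not match "
                f"designated segment voltage {seg_v} mV"
            )
        if self.test_segment_index is not None and not (
            0 <= self.test_segment_index < len(self.segments)
        ):
            raise ProtocolError("test_segment_index out of range")
        if self.tail_segment_index is not None and not (
            0 <= self.tail_segment_index < len(self.segments)
        ):
            raise ProtocolError("tail_segment_index out of range")
        if self.recovery_interval_ms is not None and self.recovery_interval_ms <= 0:
            raise ProtocolError("recovery interval must be > 0 ms")

    @property
    def duration_ms(self) -> float:
        return sum(s.duration_ms for s in self.segments)

    @property
    def test_index(self) -> int:
        """Segment analysed for current features (defaults to label segment)."""
        return (
            self.test_segment_index
            if self.test_segment_index is not None
            else self.label_segment_index
        )

    def segment_bounds_ms(self, index: int) -> tuple[float, float]:
        """(start, end) time of segment ``index`` relative to sweep start."""
        if not 0 <= index < len(self.segments):
            raise ProtocolError(f"segment index {index} out of range")
        start = sum(s.duration_ms for s in self.segments[:index])
        return start, start + self.segments[index].duration_ms


@dataclass(frozen=True)
class VoltageProtocol:
    name: str
    family: str
    sweeps: tuple[Sweep, ...]
    inter_sweep_interval_ms: float
    holding_voltage_mv: float = HOLDING_MV
    sampling_khz: float = DEFAULT_SAMPLING_KHZ
    interval_dialect: str = "period"

    def __post_init__(self) -> None:
        if len(self.sweeps) < 1:
            raise ProtocolError("protocol needs at least one sweep")
        if self.inter_sweep_interval_ms < 0:
            raise ProtocolError("inter-sweep interval must be >= 0")
        if self.sampling_khz <= 0:
            raise ProtocolError("sampling rate must be > 0 kHz")
        if self.interval_dialect not in ("period", "gap"):
            raise ProtocolError(f"unknown interval dialect {self.interval_dialect!r}")

    def holding_gap_ms(self, sweep_index: int) -> float:
        """Time spent at holding between sweep ``sweep_index`` and the next.

        In the ``period`` dialect the inter-sweep interval is start-to-start,
        so the gap is the interval minus the sweep duration (clipped at 0);
        in the ``gap`` dialect it is the interval itself.
        """
        if self.interval_dialect == "gap":
            return self.inter_sweep_interval_ms
        return max(0.0, self.inter_sweep_interval_ms - self.sweeps[sweep_index].duration_ms)

    def sweep_start_times_ms(self) -> list[float]:
        """Start time of each sweep on the continuous experiment clock."""
        times: list[float] = []
        t = 0.0
        for i, sweep in enumerate(self.sweeps):
            times.append(t)
            t += sweep.duration_ms + self.holding_gap_ms(i)
        return times


def _settled(segments: list[VoltageSegment], settle_ms: float) -> list[VoltageSegment]:
    if settle_ms > 0:
        return [VoltageSegment(settle_ms, HOLDING_MV), *segments]
    return list(segments)


def build_iv_protocol(
    settle_ms: float = DEFAULT_SETTLE_MS, sampling_khz: float = DEFAULT_SAMPLING_KHZ
) -> VoltageProtocol:
    """Current–voltage protocol: 500 ms steps from −60 to +80 mV in 20 mV increments."""
    offset = 1 if settle_ms > 0 else 0
    sweeps = tuple(
        Sweep(
            segments=tuple(_settled([VoltageSegment(500.0, float(v))], settle_ms)),
            label_voltage_mv=float(v),
            label_segment_index=offset,
        )
        for v in range(-60, 81, 20)
    )
    return VoltageProtocol(
        name="iv",
        family="iv",
        sweeps=sweeps,
        inter_sweep_interval_ms=7000.0,
        sampling_khz=sampling_khz,
    )


def tail_voltage_for_kex(kex: float) -> float:
    """Tail-step voltage of the GV protocol, adjusted for [K+]ex.

    Raised [K+]ex shifts the K+ reversal potential toward 0 mV and shrinks
    tail amplitudes at the standard −40 mV step, so the tail voltage is moved:
    −25 mV at 1 mM, −15 mV at 8 mM, −40 mV at 98 mM.  All other
    concentrations use the standard −40 mV step.
    """
    if kex <= 0:
        raise InvalidSolutionError(f"[K+]ex must be > 0 mM, got {kex}")
    table = {1.0: -25.0, 8.0: -15.0, 98.0: -40.0}
    return table.get(float(kex), -40.0)


def build_gv_protocol(
    kex: float = 2.0,
    settle_ms: float = DEFAULT_SETTLE_MS,
    sampling_khz: float = DEFAULT_SAMPLING_KHZ,
) -> VoltageProtocol:
    """Conductance–voltage protocol: 25 ms steps −70..+60 mV, 400 ms tail."""
    if kex <= 0:
        raise InvalidSolutionError(f"[K+]ex must be > 0 mM, got {kex}")
    tail_mv = tail_voltage_for_kex(kex)
    offset = 1 if settle_ms > 0 else 0
    sweeps = tuple(
        Sweep(
            segments=tuple(
                _settled(
                    [VoltageSegment(25.0, float(v)), VoltageSegment(400.0, tail_mv)],
                    settle_ms,
                )
            ),
            label_voltage_mv=float(v),
            label_segment_index=offset,
            tail_segment_index=offset + 1,
        )
        for v in range(-70, 61, 10)
    )
    return VoltageProtocol(
        name=f"gv_kex{kex:g}",
        family="gv",
        sweeps=sweeps,
        inter_sweep_interval_ms=7000.0,
        sampling_khz=sampling_khz,
    )


def build_inactivation_protocol(
    long_steps: bool = False,
    settle_ms: float = DEFAULT_SETTLE_MS,
    sampling_khz: float = DEFAULT_SAMPLING_KHZ,
) -> VoltageProtocol:
    """Steady-state inactivation: 1 s (10 s for non-inactivating constructs)
    conditioning steps −100..+30 mV followed by a +50 mV, 400 ms test step."""
    cond_ms = 10000.0 if long_steps else 1000.0
    offset = 1 if settle_ms > 0 else 0
    sweeps = tuple(
        Sweep(
            segments=tuple(
                _settled(
                    [VoltageSegment(cond_ms, float(v)), VoltageSegment(400.0, 50.0)],
                    settle_ms,
                )
            ),
            label_voltage_mv=float(v),
            label_segment_index=offset,
            test_segment_index=offset + 1,
        )
        for v in range(-100, 31, 10)
    )
    return VoltageProtocol(
        name="inactivation_long" if long_steps else "inactivation",
        family="inactivation",
        sweeps=sweeps,
        inter_sweep_interval_ms=10000.0,
        sampling_khz=sampling_khz,
    )


def build_recovery_protocol(
    settle_ms: float = DEFAULT_SETTLE_MS, sampling_khz: float = DEFAULT_SAMPLING_KHZ
) -> VoltageProtocol:
    """Recovery from inactivation: paired 200 ms pulses to +50 mV.

    17 sweeps; the recovery gap at −80 mV is 20 ms in sweep 1 and grows by
    500 ms per sweep (the increment applies from sweep 2 onward).  The 30 s
    inter-sweep interval guarantees full recovery between sweeps.
    """
    offset = 1 if settle_ms > 0 else 0
    sweeps = []
    for i in range(17):
        gap_ms = 20.0 + i * 500.0
        sweeps.append(
            Sweep(
                segments=tuple(
                    _settled(
                        [
                            VoltageSegment(200.0, 50.0),
                            VoltageSegment(gap_ms, HOLDING_MV),
                            VoltageSegment(200.0, 50.0),
                        ],
                        settle_ms,
                    )
                ),
                label_voltage_mv=50.0,
                label_segment_index=offset,
                recovery_interval_ms=gap_ms,
            )
        )
    return VoltageProtocol(
        name="recovery",
        family="recovery",
        sweeps=tuple(sweeps),
        inter_sweep_interval_ms=30000.0,
        sampling_khz=sampling_khz,
    )


def build_amplitude_protocol(
    settle_ms: float = DEFAULT_SETTLE_MS, sampling_khz: float = DEFAULT_SAMPLING_KHZ
) -> VoltageProtocol:
    """Amplitude quantification: a single 200 ms step from −80 to +50 mV."""
    offset = 1 if settle_ms > 0 else 0
    sweep = Sweep(
        segments=tuple(_settled([VoltageSegment(200.0, 50.0)], settle_ms)),
        label_voltage_mv=50.0,
        label_segment_index=offset,
    )
    return VoltageProtocol(
        name="amplitude",
        family="amplitude",
        sweeps=(sweep,),
        inter_sweep_interval_ms=7000.0,
        sampling_khz=sampling_khz,
    )


def build_step_protocol(
    voltage_mv: float,
    duration_ms: float,
    settle_ms: float = DEFAULT_SETTLE_MS,
    sampling_khz: float = DEFAULT_SAMPLING_KHZ,
) -> VoltageProtocol:
    """A generic single-step protocol (e.g. the 1 s step to +50 mV used to
    quantify inactivation kinetics)."""
    offset = 1 if settle_ms > 0 else 0
    sweep = Sweep(
        segments=tuple(_settled([VoltageSegment(duration_ms, voltage_mv)], settle_ms)),
        label_voltage_mv=voltage_mv,
        label_segment_index=offset,
    )
    return VoltageProtocol(
        name=f"step_{voltage_mv:g}mV_{duration_ms:g}ms",
        family="step",
        sweeps=(sweep,),
        inter_sweep_interval_ms=7000.0,
        sampling_khz=sampling_khz,
    )


def build_train_protocol(
    frequency_hz: float,
    total_duration_s: float,
    dialect: str = "period",
    sampling_khz: float = DEFAULT_SAMPLING_KHZ,
) -> VoltageProtocol:
    """Pulse train: 5 ms pulses to +40 mV repeated at ``frequency_hz``.

    In the default ``period`` dialect the listed interval (1 Hz = 1000 ms,
    10 Hz = 100 ms, 50 Hz = 20 ms, 100 Hz = 10 ms) is the pulse start-to-start
    period; each sweep is a (period − 5 ms) holding segment followed by the
    pulse, so consecutive sweeps tile the train exactly.  The number of
    pulses is floor(total_duration · frequency).
    """
    if frequency_hz <= 0 or total_duration_s <= 0:
        raise ProtocolError("frequency and duration must be positive")
    if dialect not in ("period", "gap"):
        raise ProtocolError(f"unknown train dialect {dialect!r}")
    listed_ms = 1000.0 / frequency_hz
    if dialect == "period":
        period_ms = listed_ms
        if period_ms < TRAIN_PULSE_MS:
            raise InfeasibleFrequencyError(
                f"{frequency_hz:g} Hz period {period_ms:g} ms is shorter than "
                f"the {TRAIN_PULSE_MS:g} ms pulse"
            )
        gap_ms = period_ms - TRAIN_PULSE_MS
        n_pulses = math.floor(total_duration_s * frequency_hz)
    else:
        gap_ms = listed_ms
        period_ms = listed_ms + TRAIN_PULSE_MS
        n_pulses = math.floor(total_duration_s * 1000.0 / period_ms)
    if n_pulses < 1:
        raise ProtocolError("train too short for a single pulse")
    if gap_ms > 0:
        segments: tuple[VoltageSegment, ...] = (
            VoltageSegment(gap_ms, HOLDING_MV),
            VoltageSegment(TRAIN_PULSE_MS, TRAIN_PULSE_MV),
        )
        label_idx = 1
    else:  # back-to-back pulses (period == pulse width)
        segments = (VoltageSegment(TRAIN_PULSE_MS, TRAIN_PULSE_MV),)
        label_idx = 0
    sweep = Sweep(
        segments=segments, label_voltage_mv=TRAIN_PULSE_MV, label_segment_index=label_idx
    )
    return VoltageProtocol(
        name=f"train_{frequency_hz:g}Hz",
        family="train",
        sweeps=(sweep,) * n_pulses,
        inter_sweep_interval_ms=period_ms,
        sampling_khz=sampling_khz,
        interval_dialect="period",
    )


# ---------------------------------------------------------------------------
# JSON serialization.  The writer is canonical (sorted keys, fixed float
# precision) so serialized fixtures are diff-stable; deserialize(serialize(p))
# reproduces the protocol field-by-field.
# ---------------------------------------------------------------------------

_FLOAT_DECIMALS = 6


def _round(x: float) -> float:
    return round(float(x), _FLOAT_DECIMALS)


def protocol_to_dict(protocol: VoltageProtocol) -> dict:
    sweeps = []
    for sw in protocol.sweeps:
        entry: dict = {
            "segments": [
                {"ms": _round(s.duration_ms), "mV": _round(s.voltage_mv)}
                for s in sw.segments
            ],
            "label_mV": _round(sw.label_voltage_mv),
            "label_idx": sw.label_segment_index,
        }
        if sw.test_segment_index is not None:
            entry["test_idx"] = sw.test_segment_index
        if sw.tail_segment_index is not None:
            entry["tail_idx"] = sw.tail_segment_index
        if sw.recovery_interval_ms is not None:
            entry["recovery_ms"] = _round(sw.recovery_interval_ms)
        sweeps.append(entry)
    return {
        "name": protocol.name,
        "family": protocol.family,
        "holding_mV": _round(protocol.holding_voltage_mv),
        "sampling_kHz": _round(protocol.sampling_khz),
        "inter_sweep_ms": _round(protocol.inter_sweep_interval_ms),
        "dialect": protocol.interval_dialect,
        "sweeps": sweeps,
    }


def protocol_to_json(protocol: VoltageProtocol) -> str:
    return json.dumps(protocol_to_dict(protocol), sort_keys=True, indent=1)


def _require(mapping: dict, key: str, kind) -> object:
    if key not in mapping:
        raise SchemaError(f"protocol JSON missing required key {key!r}")
    value = mapping[key]
    if kind is float and isinstance(value, int):
        value = float(value)
    if not isinstance(value, kind):
        raise SchemaError(f"protocol JSON key {key!r} has wrong type {type(value).__name__}")
    return value


def protocol_from_dict(data: dict) -> VoltageProtocol:
    if not isinstance(data, dict):
        raise SchemaError("protocol JSON root must be an object")
    raw_sweeps = _require(data, "sweeps", list)
    sweeps = []
    for raw in raw_sweeps:
        if not isinstance(raw, dict):
            raise SchemaError("sweep entries must be objects")
        raw_segments = _require(raw, "segments", list)
        segments = tuple(
            VoltageSegment(
                duration_ms=float(_require(seg, "ms", (int, float))),
                voltage_mv=float(_require(seg, "mV", (int, float))),
            )
            for seg in raw_segments
        )
        sweeps.append(
            Sweep(
                segments=segments,
                label_voltage_mv=float(_require(raw, "label_mV", (int, float))),
                label_segment_index=int(raw.get("label_idx", 0)),
                test_segment_index=raw.get("test_idx"),
                tail_segment_index=raw.get("tail_idx"),
                recovery_interval_ms=raw.get("recovery_ms"),
            )
        )
    try:
        return VoltageProtocol(
            name=str(_require(data, "name", str)),
            family=str(_require(data, "family", str)),
            sweeps=tuple(sweeps),
            inter_sweep_interval_ms=float(_require(data, "inter_sweep_ms", (int, float))),
            holding_voltage_mv=float(_require(data, "holding_mV", (int, float))),
            sampling_khz=float(_require(data, "sampling_kHz", (int, float))),
            interval_dialect=str(data.get("dialect", "period")),
        )
    except ProtocolError as exc:
        raise SchemaError(f"protocol JSON violates invariants: {exc}") from exc


def protocol_from_json(text: str) -> VoltageProtocol:
    try:
        data = json.loads(text)
    except json.JSONDecodeError as exc:
        raise SchemaError(f"malformed protocol JSON: {exc}") from exc
    return protocol_from_dict(data)
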