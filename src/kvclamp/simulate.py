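"""Synthetic two-electrode voltage-clamp recordings.

The simulator renders a :class:`~kvclamp.protocols.VoltageProtocol` into
current traces for a parameterized channel construct.  The gating model is
Hodgkin–Huxley-style with a single activation gate ``a`` (exponent 1, so a
fitted GV directly recovers the preset's activation midpoint) and two
inactivation gates ``h1``/``h2`` (weights ``a1_frac`` / ``1 − a1_frac``)
whose weighted availability, together with a persistent open fraction,
produces bi-exponential macroscopic inactivation:

    P_open = a · (p + (1 − p)·(f·h1 + (1 − f)·h2)),
    I      = g0 · gain(kex) · expression · P_open · GHK(v) + g_leak·(v − E_leak) + noise.

Because command voltages are piecewise constant, every gate relaxes mono-
exponentially within each segment and the integrator uses the exact update
x(t) = x_inf + (x0 − x_inf)·exp(−t/τ) — noise-free runs are deterministic to
machine precision and an independent closed-form oracle can check any single
step.  A voltage threshold (default −40 mV) separates the inactivating
regime (h relaxes with τ_inact) from the recovering regime (h relaxes with
the K+-dependent recovery constant τ_rec(kex)); the activation gate uses
τ_act above and τ_deact below the same threshold.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import biophys
from .channels import NOISE_FREE, ChannelPreset, NoiseSpec, SolutionSpec
from .errors import SchemaError
from .protocols import VoltageProtocol, protocol_from_dict, protocol_to_dict

#: voltage separating inactivating from recovering kinetics, mV
V_KINETIC_THRESHOLD_MV = -40.0


def gate_steady_state(
    preset: ChannelPreset, v_mv: float, solution: SolutionSpec
) -> tuple[float, float]:
    """Steady-state activation and availability (a_inf, h_inf) at ``v_mv``.

    Both are Boltzmann functions of voltage; the inactivation midpoint is
    shifted by extracellular K+ (see :meth:`ChannelPreset.inact_v_half`).
    """
    a_inf = 1.0 / (1.0 + math.exp((preset.act_v_half - v_mv) / preset.act_k))
    vh = preset.inact_v_half(solution.kex)
    h_inf = preset.inact_floor + (1.0 - preset.inact_floor) / (
        1.0 + math.exp((v_mv - vh) / preset.inact_k)
    )
    return a_inf, h_inf


def ghk_open_channel_current(v_mv: float, solution: SolutionSpec) -> float:
    """GHK open-channel current per unit permeability (see :func:`biophys.ghk_flux`)."""
    return biophys.ghk_flux(v_mv, solution.kin, solution.kex, solution.temperature_k)


@dataclass
class SweepTrace:
    """One recorded sweep: uniform time grid, command voltage and current."""

    time_ms: np.ndarray
    voltage_mv: np.ndarray
    current_ua: np.ndarray
    gates: dict[str, np.ndarray] | None = None


@dataclass
class TraceSet:
    """A set of sweeps from one oocyte under one protocol and solution —
    the unit every analysis consumes."""

    protocol: VoltageProtocol
    solution: SolutionSpec
    preset_name: str
    sweeps: list[SweepTrace]
    metadata: dict = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        frames = []
        for i, sw in enumerate(self.sweeps):
            frames.append(
                pd.DataFrame(
                    {
                        "sweep_index": i,
                        "time_ms": sw.time_ms,
                        "voltage_mV": sw.voltage_mv,
                        "current_uA": sw.current_ua,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def to_csv(self, path: str | Path) -> None:
        """Write the long-format trace CSV plus a JSON sidecar.

        Floats are written at full repr precision so the round-trip
        read → analyze is equivalent to analyzing in memory.
        """
        path = Path(path)
        self.to_dataframe().to_csv(path, index=False, float_format="%.17g")
        sidecar = {
            "protocol": protocol_to_dict(self.protocol),
            "solution": {
                "kex": self.solution.kex,
                "kin": self.solution.kin,
                "temperature_k": self.solution.temperature_k,
            },
            "preset_name": self.preset_name,
            "metadata": self.metadata,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, sort_keys=True, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path) -> "TraceSet":
        path = Path(path)
        sidecar_path = path.with_suffix(".json")
        if not sidecar_path.exists():
            raise SchemaError(f"missing sidecar JSON for trace CSV: {sidecar_path}")
        try:
            sidecar = json.loads(sidecar_path.read_text())
        except json.JSONDecodeError as exc:
            raise SchemaError(f"malformed sidecar JSON: {exc}") from exc
        try:
            df = pd.read_csv(path, float_precision="round_trip")
        except (pd.errors.ParserError, OSError, ValueError) as exc:
            raise SchemaError(f"malformed trace CSV: {exc}") from exc
        required = {"sweep_index", "time_ms", "voltage_mV", "current_uA"}
        if not required.issubset(df.columns):
            raise SchemaError(f"trace CSV must have columns {sorted(required)}")
        protocol = protocol_from_dict(sidecar["protocol"])
        solution = SolutionSpec(**sidecar["solution"])
        sweeps = []
        for i in sorted(df["sweep_index"].unique()):
            chunk = df[df["sweep_index"] == i]
            sweeps.append(
                SweepTrace(
                    time_ms=chunk["time_ms"].to_numpy(float),
                    voltage_mv=chunk["voltage_mV"].to_numpy(float),
                    current_ua=chunk["current_uA"].to_numpy(float),
                )
            )
        return cls(
            protocol=protocol,
            solution=solution,
            preset_name=str(sidecar.get("preset_name", "")),
            sweeps=sweeps,
            metadata=dict(sidecar.get("metadata", {})),
        )


# ---------------------------------------------------------------------------
# Integrator
# ---------------------------------------------------------------------------


def _gate_targets_taus(
    preset: ChannelPreset,
    v_mv: float,
    solution: SolutionSpec,
    threshold_mv: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Steady-state targets and time constants of (a, h1, h2) at ``v_mv``."""
    a_inf, h_inf = gate_steady_state(preset, v_mv, solution)
    if v_mv >= threshold_mv:
        taus = np.array([preset.tau_act, preset.tau_inact_1, preset.tau_inact_2])
    else:
        tau_rec = preset.tau_rec(solution.kex)
        taus = np.array([preset.tau_deact, tau_rec, tau_rec])
    return np.array([a_inf, h_inf, h_inf]), taus


def _relax(state: np.ndarray, target: np.ndarray, taus: np.ndarray, dt_ms) -> np.ndarray:
    """Exact exponential relaxation of the gate vector over ``dt_ms``.

    ``dt_ms`` may be a scalar (state update) or a 1-D array of sample times
    (trace evaluation, returning shape (len(dt), 3))."""
    dt = np.asarray(dt_ms, dtype=float)
    decay = np.exp(-np.atleast_1d(dt)[:, None] / taus[None, :])
    out = target[None, :] + (state - target)[None, :] * decay
    return out[0] if np.ndim(dt_ms) == 0 else out


def _open_fraction(gates: np.ndarray, preset: ChannelPreset) -> np.ndarray:
    a = gates[..., 0]
    h_mix = preset.a1_frac * gates[..., 1] + (1.0 - preset.a1_frac) * gates[..., 2]
    p = preset.persistent_frac
    return a * (p + (1.0 - p) * h_mix)


def simulate_protocol(
    preset: ChannelPreset,
    protocol: VoltageProtocol,
    solution: SolutionSpec | None = None,
    noise: NoiseSpec | None = None,
    carry_state: bool = False,
    expression_factor: float = 1.0,
    rng: np.random.Generator | None = None,
    record_gates: bool = False,
    threshold_mv: float = V_KINETIC_THRESHOLD_MV,
) -> TraceSet:
    """Simulate ``protocol`` for one oocyte expressing ``preset``.

    With ``carry_state`` the gate state persists across sweeps, relaxing at
    the holding potential for the inter-sweep holding gap — required for the
    train and recovery protocol families, where incomplete recovery between
    depolarizations is the phenomenon of interest.  Without it each sweep
    starts from the steady state at holding.

    ``noise=None`` (or the all-zero default) gives a deterministic,
    noise-free and leak-free trace; otherwise Gaussian current noise and an
    ohmic leak are added and ``rng`` (default: seeded from ``noise.seed``)
    supplies the randomness.
    """
    solution = solution or SolutionSpec()
    noise = noise or NOISE_FREE
    if noise.current_sd > 0 and rng is None:
        rng = np.random.default_rng(noise.seed)

    fs = protocol.sampling_khz  # samples per ms
    dt = 1.0 / fs
    gain = preset.conductance_gain(solution.kex)
    scale = preset.g0 * gain * expression_factor

    holding_target, holding_taus = _gate_targets_taus(
        preset, protocol.holding_voltage_mv, solution, threshold_mv
    )
    state = holding_target.copy()

    sweeps: list[SweepTrace] = []
    for sweep_index, sweep in enumerate(protocol.sweeps):
        if not carry_state:
            state = holding_target.copy()
        elif sweep_index > 0:
            gap = protocol.holding_gap_ms(sweep_index - 1)
            if gap > 0:
                state = _relax(state, holding_target, holding_taus, gap)

        times: list[np.ndarray] = []
        volts: list[np.ndarray] = []
        currents: list[np.ndarray] = []
        gates_rec: list[np.ndarray] = []
        seg_start = 0.0
        for segment in sweep.segments:
            n = int(round(segment.duration_ms * fs))
            target, taus = _gate_targets_taus(preset, segment.voltage_mv, solution, threshold_mv)
            local_t = np.arange(n) * dt
            gates = _relax(state, target, taus, local_t)
            driving = ghk_open_channel_current(segment.voltage_mv, solution)
            times.append(seg_start + local_t)
            volts.append(np.full(n, segment.voltage_mv))
            currents.append(scale * _open_fraction(gates, preset) * driving)
            if record_gates:
                gates_rec.append(gates)
            # advance the state exactly to the segment end
            state = _relax(state, target, taus, segment.duration_ms)
            seg_start += segment.duration_ms

        time_ms = np.concatenate(times)
        voltage = np.concatenate(volts)
        current = np.concatenate(currents)
        if noise.g_leak > 0:
            current = current + noise.g_leak * (voltage - noise.e_leak_mv)
        if noise.current_sd > 0:
            current = current + rng.normal(0.0, noise.current_sd, size=current.shape)
        sweeps.append(
            SweepTrace(
                time_ms=time_ms,
                voltage_mv=voltage,
                current_ua=current,
                gates=(
                    {
                        "a": np.concatenate([g[:, 0] for g in gates_rec]),
                        "h1": np.concatenate([g[:, 1] for g in gates_rec]),
                        "h2": np.concatenate([g[:, 2] for g in gates_rec]),
                    }
                    if record_gates
                    else None
                ),
            )
        )

    return TraceSet(
        protocol=protocol,
        solution=solution,
        preset_name=preset.name,
        sweeps=sweeps,
        metadata={
            "carry_state": carry_state,
            "expression_factor": expression_factor,
            "threshold_mv": threshold_mv,
            "interval_dialect": protocol.interval_dialect,
            "noise": {
                "current_sd": noise.current_sd,
                "expression_cv": noise.expression_cv,
                "g_leak": noise.g_leak,
                "e_leak_mv": noise.e_leak_mv,
                "seed": noise.seed,
            },
        },
    )


def make_batch(
    preset: ChannelPreset,
    protocol: VoltageProtocol,
    solution: SolutionSpec,
    n_oocytes: int,
    noise: NoiseSpec,
    carry_state: bool = False,
) -> list[TraceSet]:
    """Simulate ``n_oocytes`` independent oocytes.

    Each oocyte draws a lognormal expression factor (mean 1, CV =
    ``noise.expression_cv``) and independent current noise from its own RNG
    stream ``default_rng([seed, oocyte_index])`` — derived by counter so the
    batch is fully reproducible and enlarging it never reshuffles earlier
    oocytes.
    """
    if n_oocytes < 1:
        raise ValueError("n_oocytes must be >= 1")
    sigma = math.sqrt(math.log(1.0 + noise.expression_cv**2))
    mu = -0.5 * sigma**2  # lognormal mean exactly 1
    out = []
    for i in range(n_oocytes):
        rng = np.random.default_rng([noise.seed, i])
        factor = float(rng.lognormal(mu, sigma)) if noise.expression_cv > 0 else 1.0
        ts = simulate_protocol(
            preset,
            protocol,
            solution,
            noise=noise,
            carry_state=carry_state,
            expression_factor=factor,
            rng=rng,
        )
        ts.metadata["oocyte_id"] = i
        out.append(ts)
    return out
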