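"""End-to-end experiments: simulate → analyze → compare → report.

An :class:`ExperimentConfig` names one of the experiment kinds below, the
presets and solutions to run, and the noise/replication settings; ``run_experiment``
executes the matching recipe and returns a JSON-serializable
:class:`ExperimentReport` that embeds the configuration, the seed and the
dialect flags needed to re-run itself exactly.

Experiment kinds
----------------
``amplitude_comparison``   peak amplitudes under the 200 ms step protocol,
                           batch-normalized to a reference construct
``coinjection``            homozygous / half-dose / co-injected mixtures,
                           including a dominant-negative binomial arm
``gv_family``              tail-current GV curves and Boltzmann fits
``inactivation_family``    steady-state inactivation curves and fits
``inactivation_kinetics``  bi-exponential fit of the decay during a 1 s step
``recovery``               paired-pulse recovery curves and τ_rec
``kex_titration``          GV/inactivation/recovery/peak currents across
                           [K+]ex plus GHK predictions and paradox indices
``train_family``           cumulative inactivation across a frequency × [K+]ex grid

Figure-style reproduction recipes (``fig2`` … ``fig9``) are configuration
data, not code: each maps to a list of experiment configs at desk scale.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .analysis import (
    cumulative_inactivation,
    extract_features,
    fit_biexp,
    fit_boltzmann,
    fit_monoexp,
    gv_curve,
    inactivation_curve,
    normalize_batch,
    recovery_curve,
    summarize,
)
from .biophys import GhkPrediction, paradox_index
from .channels import ChannelPreset, NoiseSpec, SolutionSpec, load_preset, mix_presets
from .errors import KvClampError
from .protocols import (
    build_amplitude_protocol,
    build_gv_protocol,
    build_inactivation_protocol,
    build_recovery_protocol,
    build_step_protocol,
    build_train_protocol,
)
from .simulate import make_batch, simulate_protocol

EXPERIMENTS = (
    "amplitude_comparison",
    "coinjection",
    "gv_family",
    "inactivation_family",
    "inactivation_kinetics",
    "recovery",
    "kex_titration",
    "train_family",
)

#: desk-scale default replication per group (typical panel n is 5–30)
DEFAULT_N_OOCYTES = 8
DEFAULT_NOISE = NoiseSpec(current_sd=0.02, expression_cv=0.3, g_leak=2e-4, e_leak_mv=-20.0)


@dataclass(frozen=True)
class ExperimentConfig:
    """Declarative description of one experiment run."""

    experiment: str
    presets: tuple[str, ...]
    kex_values: tuple[float, ...] = (2.0,)
    frequencies_hz: tuple[float, ...] = (1.0, 10.0, 50.0, 100.0)
    train_duration_s: float = 10.0
    n_oocytes: int = DEFAULT_N_OOCYTES
    noise_free: bool = False
    current_sd: float = DEFAULT_NOISE.current_sd
    expression_cv: float = DEFAULT_NOISE.expression_cv
    g_leak: float = DEFAULT_NOISE.g_leak
    e_leak_mv: float = DEFAULT_NOISE.e_leak_mv
    seed: int = 0
    long_steps: bool = False
    eq1_orientation: str = "corrected"
    train_dialect: str = "period"

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise KvClampError(
                f"unknown experiment {self.experiment!r}; choose from {EXPERIMENTS}"
            )
        if self.n_oocytes < 1:
            raise KvClampError("n_oocytes must be >= 1")
        if not self.presets:
            raise KvClampError("experiment needs at least one preset")

    @property
    def noise(self) -> NoiseSpec:
        if self.noise_free:
            return NoiseSpec(seed=self.seed)
        return NoiseSpec(
            current_sd=self.current_sd,
            expression_cv=self.expression_cv,
            g_leak=self.g_leak,
            e_leak_mv=self.e_leak_mv,
            seed=self.seed,
        )

    @property
    def effective_n(self) -> int:
        return 1 if self.noise_free else self.n_oocytes

    @classmethod
    def from_dict(cls, data: dict) -> "ExperimentConfig":
        kwargs = dict(data)
        for key in ("presets", "kex_values", "frequencies_hz"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class ExperimentReport:
    """Config echo plus per-group results; reproducible from (config, seed)."""

    config: ExperimentConfig
    results: dict
    version: str = ""
    results_key: str = ""

    def to_dict(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "experiment": self.config.experiment,
            "seed": self.config.seed,
            "version": self.version,
            "results": self.results,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=1)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


def _version() -> str:
    from . import __version__

    return __version__


def _solution(kex: float) -> SolutionSpec:
    return SolutionSpec(kex=kex)


def _peaks_for(
    preset: ChannelPreset, config: ExperimentConfig, kex: float, protocol=None
) -> list[float]:
    protocol = protocol or build_amplitude_protocol()
    batch = make_batch(preset, protocol, _solution(kex), config.effective_n, config.noise)
    peaks = []
    for ts in batch:
        sweep = ts.protocol.sweeps[0]
        trace = ts.sweeps[0]
        feats = extract_features(trace, sweep.segment_bounds_ms(sweep.test_index))
        peaks.append(feats.peak)
    return peaks


def _summary_dict(values, comparison=None) -> dict:
    s = summarize(values, comparison)
    out = {"mean": s.mean, "sem": s.sem, "n": s.n}
    if s.p_value is not None:
        out["p_value"] = s.p_value
        out["stars"] = s.stars
    return out


# ---------------------------------------------------------------------------
# Experiment implementations
# ---------------------------------------------------------------------------


def _run_amplitude_comparison(config: ExperimentConfig) -> dict:
    """Peak amplitudes normalized to the first (reference) construct."""
    kex = config.kex_values[0]
    reference = config.presets[0]
    labelled: list[tuple[str, float]] = []
    for name in config.presets:
        preset = load_preset(name)
        for peak in _peaks_for(preset, config, kex):
            labelled.append((name, peak))
    normalized = normalize_batch(labelled, reference)
    by_construct: dict[str, list[float]] = {}
    for construct, value in normalized:
        by_construct.setdefault(construct, []).append(value)
    ref_values = by_construct[reference]
    results: dict = {"reference": reference, "normalized_amplitudes": {}}
    for construct, values in by_construct.items():
        if len(values) >= 2:
            entry = _summary_dict(values, ref_values if construct != reference else None)
        else:
            entry = {"mean": float(np.mean(values)), "n": len(values)}
        results["normalized_amplitudes"][construct] = entry
    return results


def _run_coinjection(config: ExperimentConfig) -> dict:
    """Homozygous, half-dose and co-injection arms (peak amplitude analysis).

    Arms: the reference construct at full dose, at half dose, co-injected
    1:1 with the variant (independent populations), the dominant-negative
    construct alone, and the reference co-injected 1:1 with the
    dominant-negative (binomial tetramer poisoning).
    """
    kex = config.kex_values[0]
    wt = load_preset(config.presets[0])
    variant = load_preset(config.presets[1]) if len(config.presets) > 1 else None
    dn = load_preset(config.presets[2]) if len(config.presets) > 2 else None
    arms: list[tuple[str, ChannelPreset]] = [(wt.name, wt)]
    arms.append((f"{wt.name}_50pct", replace(wt, name=f"{wt.name}_50pct", g0=wt.g0 * 0.5)))
    if variant is not None:
        arms.append(
            (f"{wt.name}+{variant.name}", mix_presets([(wt, 0.5), (variant, 0.5)], "independent"))
        )
    if dn is not None:
        arms.append((dn.name, dn))
        arms.append((f"{wt.name}+{dn.name}", mix_presets([(wt, 0.5), (dn, 0.5)], "binomial_dn")))
    labelled: list[tuple[str, float]] = []
    for label, preset in arms:
        for peak in _peaks_for(preset, config, kex):
            labelled.append((label, peak))
    normalized = normalize_batch(labelled, wt.name)
    by_arm: dict[str, list[float]] = {}
    for label, value in normalized:
        by_arm.setdefault(label, []).append(value)
    results: dict = {"reference": wt.name, "normalized_amplitudes": {}}
    for label, values in by_arm.items():
        if len(values) >= 2:
            entry = _summary_dict(values, by_arm[wt.name] if label != wt.name else None)
        else:
            entry = {"mean": float(np.mean(values)), "n": len(values)}
        results["normalized_amplitudes"][label] = entry
    return results


def _gv_fit_for(preset: ChannelPreset, config: ExperimentConfig, kex: float) -> dict:
    protocol = build_gv_protocol(kex=kex)
    batch = make_batch(preset, protocol, _solution(kex), config.effective_n, config.noise)
    fits = [fit_boltzmann(gv_curve(ts), "activation") for ts in batch]
    v_halves = [f.v_half for f in fits]
    ks = [f.k for f in fits]
    if len(fits) >= 2:
        return {"v_half": _summary_dict(v_halves), "k": _summary_dict(ks)}
    return {
        "v_half": {"mean": v_halves[0], "n": 1},
        "k": {"mean": ks[0], "n": 1},
    }


def _run_gv_family(config: ExperimentConfig) -> dict:
    results: dict = {}
    for name in config.presets:
        preset = load_preset(name)
        results[name] = {
            f"kex_{kex:g}": _gv_fit_for(preset, config, kex) for kex in config.kex_values
        }
    return results


def _run_inactivation_family(config: ExperimentConfig) -> dict:
    results: dict = {}
    for name in config.presets:
        preset = load_preset(name)
        long_steps = config.long_steps or preset.persistent_frac > 0.9
        protocol = build_inactivation_protocol(long_steps=long_steps)
        per_kex = {}
        for kex in config.kex_values:
            batch = make_batch(preset, protocol, _solution(kex), config.effective_n, config.noise)
            fits = [fit_boltzmann(inactivation_curve(ts), "inactivation") for ts in batch]
            v_halves = [f.v_half for f in fits]
            ks = [f.k for f in fits]
            if len(fits) >= 2:
                per_kex[f"kex_{kex:g}"] = {
                    "v_half": _summary_dict(v_halves),
                    "k": _summary_dict(ks),
                }
            else:
                per_kex[f"kex_{kex:g}"] = {
                    "v_half": {"mean": v_halves[0], "n": 1},
                    "k": {"mean": ks[0], "n": 1},
                }
        results[name] = {"long_steps": long_steps, **per_kex}
    return results


def inactivation_kinetics_fit(
    preset: ChannelPreset,
    kex: float = 2.0,
    step_mv: float = 50.0,
    step_ms: float = 1000.0,
    noise: NoiseSpec | None = None,
):
    """Simulate a single depolarizing step and bi-exponentially fit the decay
    from the current peak onward.  Returns the :class:`~kvclamp.analysis.ExpFit`."""
    protocol = build_step_protocol(step_mv, step_ms)
    ts = simulate_protocol(preset, protocol, _solution(kex), noise=noise)
    sweep = ts.protocol.sweeps[0]
    trace = ts.sweeps[0]
    t0, t1 = sweep.segment_bounds_ms(sweep.test_index)
    feats = extract_features(trace, (t0, t1))
    mask = (trace.time_ms >= feats.peak_time_ms) & (trace.time_ms < t1 - 1e-9)
    x = trace.time_ms[mask] - feats.peak_time_ms
    y = trace.current_ua[mask]
    return fit_biexp((x, y))


def _run_inactivation_kinetics(config: ExperimentConfig) -> dict:
    results: dict = {}
    kex = config.kex_values[0]
    for name in config.presets:
        preset = load_preset(name)
        fit = inactivation_kinetics_fit(
            preset, kex=kex, noise=None if config.noise_free else config.noise
        )
        results[name] = {
            "tau1_ms": fit.tau1,
            "tau2_ms": fit.tau2,
            "a1_fraction": fit.a1_fraction,
            "offset": fit.offset,
            "rss": fit.rss,
            "n_points": fit.n_points,
            "flags": list(fit.flags),
        }
    return results


def _run_recovery(config: ExperimentConfig) -> dict:
    protocol = build_recovery_protocol()
    results: dict = {}
    for name in config.presets:
        preset = load_preset(name)
        per_kex = {}
        for kex in config.kex_values:
            batch = make_batch(
                preset, protocol, _solution(kex), config.effective_n, config.noise,
                carry_state=True,
            )
            taus = []
            for ts in batch:
                points = recovery_curve(ts, orientation=config.eq1_orientation)
                taus.append(fit_monoexp(points, direction="rising").tau1)
            if len(taus) >= 2:
                per_kex[f"kex_{kex:g}"] = {"tau_rec_ms": _summary_dict(taus)}
            else:
                per_kex[f"kex_{kex:g}"] = {"tau_rec_ms": {"mean": taus[0], "n": 1}}
        results[name] = per_kex
    return results


def _run_kex_titration(config: ExperimentConfig) -> dict:
    """[K+]ex dependence: GV midpoints, inactivation midpoints, recovery τ,
    +40 mV peak currents, and observed versus GHK-predicted current ratios."""
    reference_kex = 2.0
    step = build_step_protocol(40.0, 200.0)
    results: dict = {}
    for name in config.presets:
        preset = load_preset(name)
        entry: dict = {}
        ref_peak = None
        for kex in config.kex_values:
            gv = _gv_fit_for(preset, config, kex)
            inact_protocol = build_inactivation_protocol(
                long_steps=config.long_steps or preset.persistent_frac > 0.9
            )
            batch = make_batch(
                preset, inact_protocol, _solution(kex), config.effective_n, config.noise
            )
            inact_fits = [fit_boltzmann(inactivation_curve(ts), "inactivation") for ts in batch]
            rec_batch = make_batch(
                preset, build_recovery_protocol(), _solution(kex),
                config.effective_n, config.noise, carry_state=True,
            )
            rec_taus = [
                fit_monoexp(
                    recovery_curve(ts, orientation=config.eq1_orientation), "rising"
                ).tau1
                for ts in rec_batch
            ]
            peaks = _peaks_for(preset, config, kex, protocol=step)
            mean_peak = float(np.mean(peaks))
            if kex == reference_kex:
                ref_peak = mean_peak
            entry[f"kex_{kex:g}"] = {
                "gv": gv,
                "inact_v_half": float(np.mean([f.v_half for f in inact_fits])),
                "tau_rec_ms": float(np.mean(rec_taus)),
                "peak_at_40mV": mean_peak,
            }
        if ref_peak:
            for kex in config.kex_values:
                if kex == reference_kex:
                    continue
                observed = entry[f"kex_{kex:g}"]["peak_at_40mV"] / ref_peak
                predicted = GhkPrediction(c1_kex=kex, c2_kex=reference_kex, vm_mv=40.0)
                entry[f"kex_{kex:g}"]["observed_ratio_vs_2mM"] = observed
                entry[f"kex_{kex:g}"]["ghk_predicted_ratio"] = predicted.ratio
                entry[f"kex_{kex:g}"]["paradox_index"] = paradox_index(observed, predicted)
        results[name] = entry
    return results


def _run_train_family(config: ExperimentConfig) -> dict:
    results: dict = {}
    for name in config.presets:
        preset = load_preset(name)
        per_preset: dict = {}
        for kex in config.kex_values:
            per_kex: dict = {}
            for freq in config.frequencies_hz:
                protocol = build_train_protocol(
                    freq, config.train_duration_s, dialect=config.train_dialect
                )
                batch = make_batch(
                    preset, protocol, _solution(kex), config.effective_n, config.noise,
                    carry_state=True,
                )
                taus = [cumulative_inactivation(ts).tau_first_2s_ms for ts in batch]
                rels = [cumulative_inactivation(ts).relative_current_10s for ts in batch]
                valid_taus = [t for t in taus if t is not None]
                per_kex[f"{freq:g}Hz"] = {
                    "tau_first_2s_ms": float(np.mean(valid_taus)) if valid_taus else None,
                    "relative_current_10s": float(np.mean(rels)),
                    "n": len(batch),
                }
            per_preset[f"kex_{kex:g}"] = per_kex
        results[name] = per_preset
    return results


_RUNNERS = {
    "amplitude_comparison": _run_amplitude_comparison,
    "coinjection": _run_coinjection,
    "gv_family": _run_gv_family,
    "inactivation_family": _run_inactivation_family,
    "inactivation_kinetics": _run_inactivation_kinetics,
    "recovery": _run_recovery,
    "kex_titration": _run_kex_titration,
    "train_family": _run_train_family,
}


def run_experiment(config: ExperimentConfig) -> ExperimentReport:
    """Execute the recipe named by ``config.experiment`` (see module doc)."""
    results = _RUNNERS[config.experiment](config)
    return ExperimentReport(config=config, results=results, version=_version())


# ---------------------------------------------------------------------------
# Figure-style reproduction recipes (configuration data, not code)
# ---------------------------------------------------------------------------

RECIPES: dict[str, list[dict]] = {
    # voltage dependence of activation across channel backgrounds
    "fig2": [
        {"experiment": "gv_family", "presets": ["wt", "e675k", "m1i", "m77i"]},
    ],
    # steady-state inactivation and recovery from inactivation
    "fig3": [
        {"experiment": "inactivation_family", "presets": ["wt", "e675k", "m1i", "m77i"]},
        {"experiment": "recovery", "presets": ["wt", "e675k", "m77i"]},
    ],
    # inactivation kinetics with/without TBK1 inhibition (forced-long background)
    "fig4": [
        {
            "experiment": "inactivation_kinetics",
            "presets": ["m77i", "m77i_tbk1i", "m77i_e675k_tbk1i"],
        },
    ],
    # amplitude reduction and (non-)dominant-negative behaviour
    "fig5": [
        {"experiment": "amplitude_comparison", "presets": ["wt", "e675k"]},
        {"experiment": "coinjection", "presets": ["wt", "e675k", "r420h"]},
    ],
    # paradoxical activation by extracellular K+
    "fig7": [
        {
            "experiment": "kex_titration",
            "presets": ["wt", "e675k"],
            "kex_values": [1.0, 2.0, 4.0, 8.0, 98.0],
        },
    ],
    # K+-dependent destabilization of inactivation and cumulative inactivation
    "fig8": [
        {
            "experiment": "train_family",
            "presets": ["wt", "e675k"],
            "kex_values": [1.0, 2.0, 8.0, 98.0],
            "frequencies_hz": [1.0, 10.0, 50.0, 100.0],
        },
    ],
    # frequency-dependent accumulation of inactivation, wt vs variant
    "fig9": [
        {
            "experiment": "train_family",
            "presets": ["wt", "e675k"],
            "kex_values": [1.0, 8.0, 98.0],
            "frequencies_hz": [10.0, 50.0, 100.0],
        },
    ],
}


def run_recipe(
    name: str, noise_free: bool = False, seed: int = 0, n_oocytes: int = DEFAULT_N_OOCYTES
) -> list[ExperimentReport]:
    """Run a named figure-style recipe at desk scale."""
    if name not in RECIPES:
        raise KvClampError(f"unknown recipe {name!r}; choose from {sorted(RECIPES)}")
    reports = []
    for raw in RECIPES[name]:
        config = ExperimentConfig.from_dict(
            {**raw, "noise_free": noise_free, "seed": seed, "n_oocytes": n_oocytes}
        )
        reports.append(run_experiment(config))
    return reports
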