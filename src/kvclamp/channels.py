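"""Channel presets, recording solutions and noise specifications.

A :class:`ChannelPreset` collects every gating/permeation parameter of one
Kv3.3 construct for the Hodgkin–Huxley-style simulator: a single activation
gate ``a`` (Boltzmann steady state, exponential relaxation) and two
inactivation gates ``h1``/``h2`` whose weighted sum produces the
bi-exponential decay of macroscopic inactivation, plus a persistent
(non-inactivating) open fraction.  Extracellular K+ enters through three
phenomenological couplings:

* the inactivation midpoint shifts by ``k_shift_delta`` mV per doubling of
  [K+]ex (destabilized inactivation),
* recovery from inactivation speeds up as ``tau_rec_ref·(2/kex)^k_rec_gamma``,
* the conductance scale gains ``(1 + k_gain_alpha·ln(kex/2))`` (paradoxical
  activation by external K+).

Packaged presets (``wt``, ``e675k``, ``m1i``, ``m77i``, ``m77i_tbk1i``,
``m77i_e675k_tbk1i``, ``r420h``) live as JSON data files next to this module;
each parameter carries a ``source`` tag — ``"reported"`` when the value is a
published constant for that construct, ``"calibrated"`` when it is a model
choice tuned only to qualitative behaviour.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources

from .biophys import DEFAULT_TEMPERATURE_K, OOCYTE_KIN_MM
from .errors import InvalidSolutionError, PresetError, UnknownPresetError


@dataclass(frozen=True)
class SolutionSpec:
    """Recording solution: extracellular/intracellular K+ (mM) and temperature (K)."""

    kex: float = 2.0
    kin: float = OOCYTE_KIN_MM
    temperature_k: float = DEFAULT_TEMPERATURE_K

    def __post_init__(self) -> None:
        if self.kex <= 0 or self.kin <= 0:
            raise InvalidSolutionError(
                f"K+ concentrations must be > 0 mM (kex={self.kex}, kin={self.kin})"
            )
        if not 270.0 < self.temperature_k < 320.0:
            raise InvalidSolutionError(
                f"temperature {self.temperature_k} K outside plausible recording range"
            )


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement/expression noise: Gaussian current noise (µA), lognormal
    oocyte-to-oocyte conductance scatter, linear leak, and the root seed that
    reproducibly determines all randomness."""

    current_sd: float = 0.0
    expression_cv: float = 0.0
    g_leak: float = 0.0
    e_leak_mv: float = -20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.current_sd < 0 or self.expression_cv < 0 or self.g_leak < 0:
            raise PresetError("noise magnitudes must be non-negative")


NOISE_FREE = NoiseSpec()

#: [K+]ex at which the preset reference values are defined, mM
REFERENCE_KEX = 2.0


@dataclass(frozen=True)
class ChannelPreset:
    """All gating and permeation parameters of one channel construct."""

    name: str
    g0: float                   # conductance scale (µA per GHK flux unit)
    act_v_half: float           # activation midpoint, mV
    act_k: float                # activation slope factor, mV
    tau_act: float              # activation time constant, ms
    tau_deact: float            # deactivation time constant (v < threshold), ms
    inact_v_half_ref: float     # inactivation midpoint at 2 mM K+, mV
    inact_k: float              # inactivation slope factor, mV
    inact_floor: float          # residual availability at depolarized v
    tau_inact_1: float          # slower inactivation time constant, ms
    tau_inact_2: float          # faster inactivation time constant, ms
    a1_frac: float              # weight of the slower component, A1/(A1+A2)
    persistent_frac: float      # non-inactivating open fraction
    tau_rec_ref: float          # recovery time constant at 2 mM K+, ms
    k_shift_delta: float = 0.0  # inactivation V1/2 shift per doubling of kex, mV
    k_rec_gamma: float = 0.0    # recovery speed-up exponent in kex
    k_gain_alpha: float = 0.0   # conductance gain per ln-fold kex
    source: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.g0 < 0:
            raise PresetError(f"{self.name}: conductance scale must be >= 0")
        for attr in ("tau_act", "tau_deact", "tau_inact_1", "tau_inact_2", "tau_rec_ref"):
            if getattr(self, attr) <= 0:
                raise PresetError(f"{self.name}: {attr} must be > 0 ms")
        if self.act_k <= 0 or self.inact_k <= 0:
            raise PresetError(f"{self.name}: slope factors must be > 0 mV")
        if not 0.0 <= self.a1_frac <= 1.0:
            raise PresetError(f"{self.name}: a1_frac must lie in [0, 1]")
        if not 0.0 <= self.inact_floor < 1.0 or not 0.0 <= self.persistent_frac < 1.0:
            raise PresetError(f"{self.name}: fractions must lie in [0, 1)")
        if self.inact_floor + self.persistent_frac >= 1.0:
            raise PresetError(f"{self.name}: inact_floor + persistent_frac must be < 1")

    # ---- [K+]ex couplings ------------------------------------------------

    def inact_v_half(self, kex: float) -> float:
        """Inactivation midpoint at ``kex``: reference value plus
        ``k_shift_delta`` mV per doubling of [K+]ex."""
        return self.inact_v_half_ref + self.k_shift_delta * math.log2(kex / REFERENCE_KEX)

    def tau_rec(self, kex: float) -> float:
        """Recovery time constant at ``kex``: power-law speed-up with K+."""
        return self.tau_rec_ref * (REFERENCE_KEX / kex) ** self.k_rec_gamma

    def conductance_gain(self, kex: float) -> float:
        """Multiplicative conductance gain (1 + α·ln(kex/2)); must stay > 0."""
        gain = 1.0 + self.k_gain_alpha * math.log(kex / REFERENCE_KEX)
        if gain <= 0:
            raise PresetError(
                f"{self.name}: conductance gain non-positive at kex={kex} mM"
            )
        return gain


# ---------------------------------------------------------------------------
# Preset registry (packaged JSON files)
# ---------------------------------------------------------------------------

_REQUIRED_KEYS = {
    "name", "g0", "act_v_half", "act_k", "tau_act", "tau_deact",
    "inact_v_half_ref", "inact_k", "inact_floor", "tau_inact_1",
    "tau_inact_2", "a1_frac", "persistent_frac", "tau_rec_ref",
}
_OPTIONAL_KEYS = {"k_shift_delta", "k_rec_gamma", "k_gain_alpha", "source"}


def preset_from_dict(data: dict) -> ChannelPreset:
    """Build and validate a preset from a flat name→value mapping."""
    if not isinstance(data, dict):
        raise PresetError("preset JSON root must be an object")
    missing = _REQUIRED_KEYS - set(data)
    if missing:
        raise PresetError(f"preset missing keys: {sorted(missing)}")
    unknown = set(data) - _REQUIRED_KEYS - _OPTIONAL_KEYS
    if unknown:
        raise PresetError(f"preset has unknown keys: {sorted(unknown)}")
    return ChannelPreset(**data)


def preset_from_json(text: str) -> ChannelPreset:
    try:
        return preset_from_dict(json.loads(text))
    except json.JSONDecodeError as exc:
        raise PresetError(f"malformed preset JSON: {exc}") from exc


def list_presets() -> list[str]:
    """Names of the packaged channel presets."""
    root = resources.files(__package__) / "presets"
    return sorted(p.name[:-5] for p in root.iterdir() if p.name.endswith(".json"))


def load_preset(name: str) -> ChannelPreset:
    """Load a packaged preset by name (see :func:`list_presets`)."""
    root = resources.files(__package__) / "presets"
    path = root / f"{name}.json"
    try:
        text = path.read_text()
    except (FileNotFoundError, OSError) as exc:
        raise UnknownPresetError(
            f"unknown preset {name!r}; available: {list_presets()}"
        ) from exc
    preset = preset_from_json(text)
    if preset.name != name:
        raise PresetError(f"preset file {name}.json declares name {preset.name!r}")
    return preset


def mix_presets(
    components: list[tuple[ChannelPreset, float]],
    mode: str = "independent",
) -> ChannelPreset:
    """Effective preset for a mixture of co-expressed subunit pools.

    ``independent``: the populations conduct independently, so the effective
    conductance scale is the fraction-weighted sum of the component scales
    (all other gating parameters must agree).

    ``binomial_dn``: tetramers assemble binomially from the subunit pool and
    any tetramer containing at least one poisoning (dominant-negative)
    subunit is silent; only the all-functional tetramers conduct, so the
    effective scale is g0_functional · (functional fraction)^4.

    Mixing is an amplitude-level approximation used for co-injection
    comparisons: components must share the activation parameters that set the
    peak current, and the effective preset inherits all other kinetic
    parameters from the first (reference) component.
    """
    if not components:
        raise PresetError("mixture needs at least one component")
    fractions = [f for _, f in components]
    if any(f < 0 for f in fractions):
        raise PresetError("mixture fractions must be non-negative")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise PresetError(f"mixture fractions must sum to 1, got {sum(fractions)}")
    base = components[0][0]
    activation_fields = ("act_v_half", "act_k", "tau_act", "tau_deact")
    for preset, _ in components[1:]:
        for attr in activation_fields:
            if getattr(preset, attr) != getattr(base, attr):
                raise PresetError(
                    "mixture components must share gating parameters "
                    f"(differ in {attr}: {base.name} vs {preset.name})"
                )
    if mode == "independent":
        g0 = sum(f * p.g0 for p, f in components)
    elif mode == "binomial_dn":
        # conducting tetramers contain no poisoning (g0 == 0) subunit
        functional = [(p, f) for p, f in components if p.g0 > 0]
        f_ok = sum(f for _, f in functional)
        g_ref = functional[0][0].g0 if functional else 0.0
        g0 = g_ref * f_ok**4
    else:
        raise PresetError(f"unknown mixture mode {mode!r}")
    name = "+".join(f"{p.name}:{f:g}" for p, f in components) + f"[{mode}]"
    return replace(base, name=name, g0=g0, source=dict(base.source))
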