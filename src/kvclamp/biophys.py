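"""Closed-form electro-diffusion predictions.

Nernst reversal potential, the Goldman–Hodgkin–Katz (GHK) open-channel flux,
the GHK current ratio for two extracellular K+ concentrations at a fixed
membrane potential, and a "paradox index" comparing an observed current ratio
to the GHK-predicted one.

The current ratio for extracellular concentrations C1 and C2 at the same
membrane potential V_m is

    I_C1 / I_C2 = ([K+]_in − [K+]_ex^C1 · e^(−u)) / ([K+]_in − [K+]_ex^C2 · e^(−u)),

with u = V_m·F/(R·T).  The common GHK prefactor u/(1 − e^(−u)) cancels
because both currents are evaluated at the same V_m, so the ratio divides
flux numerators only.  An observed ratio larger than this prediction marks
K+-dependent channel activation beyond the change in driving force
("paradoxical" activation by raised extracellular K+).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import InvalidSolutionError, SingularRatioError

#: Faraday constant, C/mol
FARADAY = 96485.332
#: molar gas constant, J/(mol K)
GAS_CONSTANT = 8.314462
#: default recording temperature (22 °C in Kelvin; room temperature)
DEFAULT_TEMPERATURE_K = 295.15
#: intracellular K+ of a Xenopus laevis oocyte, mM
OOCYTE_KIN_MM = 108.6


def thermal_voltage_mv(temperature_k: float = DEFAULT_TEMPERATURE_K) -> float:
    """RT/F in millivolts."""
    return GAS_CONSTANT * temperature_k / FARADAY * 1000.0


def nernst_potential(
    kin: float, kex: float, temperature_k: float = DEFAULT_TEMPERATURE_K
) -> float:
    """K+ reversal potential (RT/F)·ln([K+]ex/[K+]in), in mV."""
    if kin <= 0 or kex <= 0:
        raise InvalidSolutionError(f"concentrations must be > 0 mM (kin={kin}, kex={kex})")
    return thermal_voltage_mv(temperature_k) * math.log(kex / kin)


def ghk_flux(
    v_mv: float,
    kin: float,
    kex: float,
    temperature_k: float = DEFAULT_TEMPERATURE_K,
) -> float:
    """GHK open-channel K+ current per unit permeability (arbitrary units).

    u·(kin − kex·e^(−u))/(1 − e^(−u)) with u = vF/RT; the analytic limit
    (kin − kex) is used for |u| below 1e−6.  Outward current is positive and
    the sign equals sign(v − E_K).
    """
    if kin <= 0 or kex <= 0:
        raise InvalidSolutionError(f"concentrations must be > 0 mM (kin={kin}, kex={kex})")
    u = v_mv / thermal_voltage_mv(temperature_k)
    if abs(u) < 1e-6:
        return kin - kex
    emu = math.exp(-u)
    return u * (kin - kex * emu) / (1.0 - emu)


@dataclass(frozen=True)
class GhkPrediction:
    """Theoretical current ratio I_C1/I_C2 of two extracellular K+ levels."""

    c1_kex: float
    c2_kex: float
    vm_mv: float
    kin: float = OOCYTE_KIN_MM
    temperature_k: float = DEFAULT_TEMPERATURE_K
    ratio: float = field(init=False)

    def __post_init__(self) -> None:
        if min(self.c1_kex, self.c2_kex, self.kin) <= 0:
            raise InvalidSolutionError("GHK prediction needs positive concentrations")
        object.__setattr__(
            self,
            "ratio",
            ghk_ratio(self.c1_kex, self.c2_kex, self.vm_mv, self.kin, self.temperature_k),
        )


def ghk_ratio(
    c1_kex: float,
    c2_kex: float,
    vm_mv: float,
    kin: float = OOCYTE_KIN_MM,
    temperature_k: float = DEFAULT_TEMPERATURE_K,
) -> float:
    """GHK-predicted current ratio at fixed membrane potential (see module doc)."""
    if min(c1_kex, c2_kex, kin) <= 0:
        raise InvalidSolutionError("concentrations must be > 0 mM")
    emu = math.exp(-vm_mv / thermal_voltage_mv(temperature_k))
    denominator = kin - c2_kex * emu
    if abs(denominator) < 1e-9 * kin:
        raise SingularRatioError(
            f"membrane potential {vm_mv} mV lies at the C2 reversal potential"
        )
    return (kin - c1_kex * emu) / denominator


def paradox_index(observed_ratio: float, predicted: GhkPrediction) -> float:
    """Observed/GHK-predicted current ratio.

    Values above 1 indicate current gain with raised [K+]ex beyond what the
    change in driving force allows — paradoxical K+ activation.
    """
    return observed_ratio / predicted.ratio
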