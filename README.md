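# kvclamp

Simulation and analysis of two-electrode voltage-clamp (TEVC) recordings of
Kv3.3 voltage-gated potassium channels, built for characterizing disease
variants (SCA13-associated constructs such as E675K, the forced-short M1I and
forced-long M77I alternative-translation-initiation backgrounds, and the
dominant-negative R420H) in *Xenopus laevis* oocytes.

The package is aimed at ion-channel electrophysiologists and modellers who
want the standard Kv3.3 characterization pipeline — protocols, feature
extraction, curve fits, driving-force predictions — as tested, scriptable
code, together with a synthetic oocyte simulator so every stage can be
exercised, validated and benchmarked without recorded data.

## What it computes

**Protocols** (`kvclamp.protocols`): the six standard voltage protocols as
data objects (IV, tail-current GV, steady-state inactivation, paired-pulse
recovery, amplitude quantification, 1–100 Hz pulse trains), serializable to
canonical JSON.

**Simulator** (`kvclamp.simulate`): a Hodgkin–Huxley-style model with one
activation gate *a* and two inactivation gates *h₁*, *h₂*,

    P_open = a · (p + (1 − p)·(f·h₁ + (1 − f)·h₂)),
    I      = g₀ · gain([K⁺]ₑₓ) · P_open · GHK(V) + g_leak·(V − E_leak) + ε,

with Boltzmann steady states, exact per-segment exponential gate relaxation,
GHK open-channel permeation, lognormal oocyte-to-oocyte expression scatter
and Gaussian current noise.  Extracellular K⁺ shifts the inactivation
midpoint, speeds recovery from inactivation and scales conductance —
reproducing the paradoxical activation of Kv3.3 by raised [K⁺]ₑₓ.

**Analysis** (`kvclamp.analysis`): peak/end-of-step/tail-current extraction;
Boltzmann fits `y = 1/(1+exp((V½−V)/k))` of GV and inactivation curves;
mono- and bi-exponential fits `y = c + A₁e^(−t/τ₁) + A₂e^(−t/τ₂)` (τ₁ > τ₂,
slow-component weight A₁/(A₁+A₂)); the recovery ratio
`I_rec = (I₂max − I₁min)/(I₁max − I₁min)`; cumulative-inactivation
quantification under pulse trains (τ of the first 2 s, relative current after
10 s); batch normalization and mean ± s.e.m. summaries with Welch-test
significance stars.

**Biophysics** (`kvclamp.biophys`): Nernst reversal potentials, the GHK
current ratio of two extracellular K⁺ concentrations at fixed membrane
potential,

    I_C1/I_C2 = ([K⁺]ᵢₙ − [K⁺]ₑₓ^C1·e^(−u)) / ([K⁺]ᵢₙ − [K⁺]ₑₓ^C2·e^(−u)),
    u = V_m·F/(R·T),

and a paradox index (observed/predicted ratio) that quantifies K⁺ activation
beyond the change in driving force.

**Pipelines and CLI** (`kvclamp.pipeline`, `kvclamp` command): figure-style
experiments (amplitude comparison, co-injection with dominant-negative
contrast, GV/inactivation families, recovery, [K⁺]ₑₓ titration, frequency ×
[K⁺]ₑₓ train grids) with fully reproducible JSON reports.

## Worked example

```python
from kvclamp import (load_preset, build_gv_protocol, simulate_protocol,
                     gv_curve, fit_boltzmann)
from kvclamp.pipeline import inactivation_kinetics_fit

for name in ("wt", "e675k", "m1i"):
    ts = simulate_protocol(load_preset(name), build_gv_protocol(kex=2.0))
    fit = fit_boltzmann(gv_curve(ts), "activation")
    print(f"{name:6s} V1/2 = {fit.v_half:6.2f} mV   k = {fit.k:.2f} mV")

fit = inactivation_kinetics_fit(load_preset("m77i_tbk1i"))
print(f"tau1 = {fit.tau1:.1f} ms  tau2 = {fit.tau2:.1f} ms  "
      f"A1/(A1+A2) = {fit.a1_fraction:.3f}")
```

prints

```
wt     V1/2 =   4.40 mV   k = 8.46 mV
e675k  V1/2 =   4.40 mV   k = 8.46 mV
m1i    V1/2 =   9.65 mV   k = 8.20 mV
tau1 = 145.2 ms  tau2 = 50.4 ms  A1/(A1+A2) = 0.307
```

The E675K variant leaves voltage dependence untouched (identical V½ and k to
wild-type; its defect is a ~30 % amplitude reduction plus deeper cumulative
inactivation), the forced-short M1I background shifts activation by about
+5 mV, and the bi-exponential fit of a noise-free 1 s step recovers the
TBK1-inhibited forced-long construct's inactivation constants (τ₁ = 144 ms,
τ₂ = 50 ms, A₁ fraction 0.3) to within 1 %.

The same analyses run from the shell:

```sh
kvclamp list-presets
kvclamp simulate --preset wt --protocol gv --n 3 --seed 7 --out traces/
kvclamp analyze traces/*.csv --analysis gv --out gv_report.json
kvclamp reproduce fig5 --noise-free --out reports/
```

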