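# Methods

## The channel model

The simulator is a phenomenological Hodgkin–Huxley-style model chosen to be
the *minimal* structure that generates the measured behaviour of Kv3.3:
sigmoidal voltage-dependent activation, bi-exponential N-type inactivation
with a persistent component, seconds-scale recovery from inactivation, and
[K⁺]ₑₓ-dependent modulation of all three.

State variables are one activation gate *a* and two inactivation gates
*h₁*, *h₂*.  Steady states are Boltzmann functions of voltage,

    a∞(V)  = 1 / (1 + exp((V½ᵃ − V)/kᵃ))
    h∞(V)  = floor + (1 − floor) / (1 + exp((V − V½ʰ([K⁺]ₑₓ))/kʰ)),

and the open probability combines them as

    P_open = a · (p + (1 − p)·(f·h₁ + (1 − f)·h₂)),

where *p* is the persistent (non-inactivating) fraction and *f* the
slow-component weight.  Design choices embedded here:

* **Activation exponent 1** (not the Hodgkin–Huxley n⁴): a fitted GV curve
  then directly recovers the preset's activation midpoint, which keeps
  simulation→fit round trips interpretable as parameter recovery.
* **Two inactivation gates plus a persistent fraction** are exactly what is
  needed for the bi-exponential decays observed during long depolarizations;
  with *p* → 1 the model degenerates to a non-inactivating channel, which is
  how the forced-short (ball-less) construct is represented.
* Permeation follows the GHK flux equation, so current amplitudes respond to
  [K⁺]ₑₓ/[K⁺]ᵢₙ and voltage with the correct reversal behaviour;
  `I ∝ u·([K⁺]ᵢₙ − [K⁺]ₑₓ·e^(−u))/(1 − e^(−u))`, `u = VF/RT`, with the
  analytic limit `[K⁺]ᵢₙ − [K⁺]ₑₓ` taken for |u| < 10⁻⁶.

### Kinetics and integration

Command protocols are piecewise-constant in voltage, so within each segment
every gate relaxes mono-exponentially toward its steady state.  The
integrator therefore uses the exact update
`x(t) = x∞ + (x₀ − x∞)e^(−t/τ)` per segment rather than a generic ODE
solver: noise-free runs are deterministic to machine precision, and any
single step can be checked against an independently coded closed-form
solution (the test suite does this to ≤ 10⁻⁶ relative error).

A fixed threshold of **−40 mV** separates kinetic regimes: above it *a*
relaxes with τ_act and *h₁*, *h₂* with their inactivation constants τ₁, τ₂;
below it *a* uses τ_deact and both *h* gates recover with the common
recovery constant τ_rec([K⁺]ₑₓ).  The threshold is a documented constant
(`kvclamp.simulate.V_KINETIC_THRESHOLD_MV`) and a keyword argument of the
simulator; no τ(V) curves are assumed beyond this two-regime split.

With `carry_state=True` (used for pulse trains and paired-pulse recovery)
the gate state persists across sweeps and relaxes at holding for the
inter-sweep holding gap; otherwise each sweep starts from the holding steady
state.

### Extracellular-potassium couplings

Three phenomenological couplings stand in for the K⁺-dependent behaviour of
the channel; their functional forms are model inventions calibrated only to
qualitative orderings, and their coefficients live in the preset JSON files
(tagged `calibrated` in the per-parameter `source` map), not in code:

| coupling | form | default (wt) |
|---|---|---|
| inactivation destabilization | V½ʰ = V½ʰ_ref + δ·log₂([K⁺]ₑₓ/2 mM) | δ = 6 mV/doubling |
| recovery speed-up | τ_rec = τ_rec_ref·(2 mM/[K⁺]ₑₓ)^γ | γ = 0.5 |
| conductance gain | g = g₀·(1 + α·ln([K⁺]ₑₓ/2 mM)) | α = 0.35 |

Together they reproduce the rightward shift of the inactivation curve, the
faster recovery, the reduced cumulative inactivation and the paradoxical
increase of outward current with raised [K⁺]ₑₓ (despite the smaller driving
force predicted by the GHK ratio).

### Presets

Packaged parameter sets: `wt`, `e675k` (conductance scale ×0.7, recovery
×1.5 slower, lower inactivation floor), `m1i` (persistent fraction 0.98,
activation +5 mV), `m77i` (activation +5 mV), `m77i_tbk1i` and
`m77i_e675k_tbk1i` (reported inactivation constants τ₁/τ₂/A₁-fraction of the
TBK1-inhibited forced-long constructs transcribed directly: 144/50/0.3 and
136/43/0.3), and `r420h` (g₀ = 0; used only as the poisoning subunit in
binomial dominant-negative mixtures).  Each parameter carries a `source` tag
distinguishing *reported* constants from *calibrated* model choices.

Reference gating values (wt): V½ᵃ = +5 mV, kᵃ = 8 mV, τ_act = 1 ms,
τ_deact = 3 ms — fast activation typical of the Kv3 family at strongly
depolarized potentials; V½ʰ = −35 mV, kʰ = 5 mV, floor 0.05, τ₁ = 250 ms,
τ₂ = 80 ms, f = 0.3, p = 0.05; τ_rec = 1000 ms at 2 mM K⁺, consistent with
recovery saturating over the 8 s span of the paired-pulse protocol.  No
absolute current scale is published for these constructs, so g₀ is arbitrary
(chosen to give µA-scale TEVC currents) and every quantitative analysis is
performed on normalized currents.

### Noise and replication

Oocyte-to-oocyte variability is a lognormal expression factor with mean 1
and configurable CV (default 0.3 in noisy pipelines — typical for batch
heterologous expression); measurement noise is additive Gaussian per sample;
leak is ohmic with configurable conductance and reversal.  Randomness
derives from one root seed; each oocyte uses the stream
`default_rng([seed, oocyte_index])`, so batches are reproducible and
extending a batch never reshuffles earlier oocytes.

## Protocols

All six protocol builders hold at −80 mV and match the standard TEVC
characterization sets (IV: 500 ms, −60..+80 mV/20 mV; GV: 25 ms, −70..+60
mV/10 mV with a 400 ms tail at −40 mV — moved to −25/−15 mV at 1/8 mM K⁺
because the shifted reversal potential shrinks tail amplitudes, and −40 mV
at 98 mM; inactivation: 1 s conditioning −100..+30 mV then +50 mV for 400 ms,
10 s conditioning for non-inactivating constructs; recovery: paired 200 ms
pulses to +50 mV with gaps 20 ms + 500 ms·(sweep − 1), 30 s between sweeps;
amplitude: one 200 ms step to +50 mV; trains: 5 ms pulses to +40 mV).

Two dialect decisions are recorded in every protocol object and report:

* **Train interval = period.**  The customary listing (1 Hz = 1000 ms …
  100 Hz = 10 ms) is only consistent with a 5 ms pulse if the interval is the
  pulse start-to-start period, not the gap; the `period` dialect is the
  default and a `gap` dialect is selectable.  Each train sweep carries a
  leading holding segment of (period − 5 ms) so sweeps tile the train
  exactly and the protocol still begins at holding.
* **First recovery gap = 20 ms**, with the 500 ms increment applied from
  sweep 2 onward.

A 100 ms holding segment is prepended to every step-family sweep so
simulated gates settle before the first jump (configurable; omitted for
trains, where it would break pulse timing).  The sampling rate defaults to
10 kHz (configurable; not dictated by the protocols themselves).

## Analysis conventions

* Outward current is positive; peaks are extrema in the expected direction.
* "End of step" is the mean over the final 5 % of a segment.
* Tail-peak searches skip a 2 ms capacitive-blank window after the jump and
  look within the first 50 ms of the tail.
* GV and inactivation curves are normalized to the amplitude of largest
  magnitude, so their maxima equal exactly 1 on clean data; leak subtraction
  is off by default.
* The recovery ratio is implemented in the *corrected* orientation
  (I₂max − I₁min)/(I₁max − I₁min), which rises from 0 to 1 with recovery
  time; the reciprocal as-printed orientation of legacy analyses is
  available behind `orientation="as_printed"`.
* Bi-exponential fits are initialized by log-linear peeling and polished by
  bounded least squares from eight perturbed starts; τ₁ > τ₂ is enforced by
  a post-fit swap, near-equal constants raise an identifiability flag, and a
  vanishing fast component raises a mono-collapse flag.  Fits report rss,
  point counts and flags.
* Inactivation-curve Boltzmann fits include a free baseline, which absorbs
  the persistent fraction and any uniform availability loss during the test
  step; activation fits are amplitude-fixed as is conventional for
  max-normalized GV data.
* Cumulative inactivation normalizes per-pulse end-of-step currents to the
  maximum over pulses; the τ of the first 2 s needs at least four pulses in
  the window (a mono-exponential fit is not identifiable below that), so at
  1 Hz it is reported as not estimable rather than as a number.
* Group statistics are mean ± s.e.m.; two-group comparisons use Welch's
  unequal-variance t-test mapped to the conventional star levels
  (p < 0.05/0.01/0.001).  The type-I error of this choice is verified by a
  seeded calibration simulation in the test suite.

## What the synthetic data do and do not show

The simulator reproduces the *structure* of TEVC recordings — gating,
permeation, expression scatter, leak, additive noise, state carry-over
across sweeps — and is calibrated so the packaged presets regenerate the
reported construct-level contrasts (amplitude ratio, GV shift, inactivation
constants, qualitative K⁺/frequency orderings).  It does not model
capacitive transients, series-resistance error, endogenous oocyte
conductances, C-type inactivation, temperature (Q10) effects, single-channel
stochasticity, or the TBK1/Hax-1 biochemistry (TBK1 inhibition is purely an
inactivation-kinetics preset; drugs would enter only as generic conductance
scalings).  Passing tests therefore demonstrate correctness of the analysis
chain and internal consistency of the model — not that real oocyte data are
free of the artifacts this generator omits.

## Numerical choices and scale

Physical constants: F = 96485.332 C/mol, R = 8.314462 J/(mol·K); default
temperature 295.15 K (midpoint of 20–22 °C room temperature); default
[K⁺]ᵢₙ = 108.6 mM, the accepted value for *Xenopus* oocytes.  The GHK ratio
raises a singular-ratio error within 10⁻⁹·[K⁺]ᵢₙ of the reference reversal.
Protocol JSON is written canonically (sorted keys, six-decimal floats);
trace CSVs are written at `%.17g` and read with round-trip float parsing, so
analyzing a written trace equals analyzing it in memory.  Desk-scale
defaults keep every pipeline in seconds on one CPU: 10 kHz sampling, eight
oocytes per noisy group, 10 s trains; these are package defaults, and all
are configurable.

## Known limitations

* Fitted GV midpoints carry a small (< 1 mV) systematic bias from the finite
  25 ms test step, the window current at the −40 mV tail and max-
  normalization of a not-fully-saturated Boltzmann; the bias largely cancels
  in construct differences (the +5 mV ATI shift is recovered to ~0.25 mV).
* Bi-exponential constants fitted from the current peak onward are biased by
  ≲ 1 % by the residual activation relaxation just after the peak; this is
  inherent to peak-onward fitting of a rising-times-decaying trace.
* The K⁺ couplings are log-linear/power-law conveniences; they are not
  mechanistic claims (candidate mechanisms such as relief of an external
  Na⁺ block are out of scope).
* Mixtures (`mix_presets`) are amplitude-level approximations: components
  must share activation parameters and the result inherits the first
  component's kinetics.
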