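# Methods

## The lung model

The test lung is a single compartment: one compliance `C` (mL/cmH₂O) and one
series resistance `R` (cmH₂O per mL/s, endotracheal tube plus airway),

    C · dP_alv/dt = (P_ao − P_alv) / R,        flow = (P_ao − P_alv) / R,

with time constant τ = RC and volume above baseline `V = C·(P_alv − P₀)`.
The circuit is leak-free (the scenario modelled is a cuffed tube into a
sealed test lung), so inspired and expired volume balance once the lung
returns to baseline. Numerically, `P_alv` is advanced one sample at a time
with the exact solution for an airway pressure that is linear within each
sample interval (a first-order-hold update). This makes the sampled state
exact for constant or ramp inputs and — unlike the zero-order-hold update —
leaves no half-sample bias in the sampled flow, so trapezoidal integration
of flow recovers the delivered volume to O(dt²). Consequences used by the
tests: a pressure step reproduces `V(t) = C·ΔP·(1 − e^(−t/τ))` essentially
to machine precision, and a fully equilibrated square breath delivers
exactly `C·(PIP − PEEP)`.

Defaults: `C = 1.44 mL/cmH₂O`, `R = 0.05 cmH₂O/(mL/s)` (τ = 72 ms). No
manufacturer mechanics are published for this class of newborn manikin, so
these are a bench calibration with one constraint per device: at the default
pressures, the T-piece median breath delivers ≈21 mL and the SIB median
squeeze ≈29 mL. Both constraints are consistent with the same `C` once the
measured pressures are taken at face value, which is why `C` is slightly
below the nominal 1.5 mL/cmH₂O of a 2.5 kg equivalent lung. τ must stay
well above the sampling interval; below ~8 samples the discretisation of a
squeeze can no longer be integrated accurately.

Sampling rate defaults to 200 Hz (acquisition hardware in this class of
bench study samples at 100–1000 Hz; the exact figure is rarely reported and
nothing downstream depends on it beyond resolution).

## Device waveforms

**T-piece.** Delivered airway pressure relaxes first-order toward the
per-breath PIP during inspiration and toward the set PEEP during
expiration, with circuit constant `circuit_tau = 0.08 s` — fast enough that
a ≥0.5 s inspiration reaches the dial pressure, as the measured PIP of a
pressure-limited device must. During an SLI the operator ramps onto the
target much more slowly (`sli_rise_tau = 0.4 s`); this single constant
reproduces both the measured time-to-plateau (~2.3 s under the attainment
rule below) and the near-ideal hold area (~196 of the ideal 200 cmH₂O·s).

**Self-inflating bag.** Each squeeze is a half-sine airway-pressure pulse of
width Ti, peak `min(target, pop-off)`, baseline 0 between breaths (no PEEP
valve); the pop-off (default 40 cmH₂O) caps every sample. The pulse shape is
a modelling convenience — the analyzers never assume it. An attempted SLI is
a quarter-sine rise (1.1 s to peak) followed by exponential pressure loss
with `sli_decay_tau = 1.9 s`: the bag cannot sustain the hold. The rise time
and decay constant are calibrated in closed form so the *measured* SLI
screen of an ideal-median operator lands on the study-scale values
(T Max ≈ 1.0 s after onset-detection and attainment-tolerance offsets,
AUPTC ≈ 60 cmH₂O·s including the rise-phase area).

## Operators

Each operator is a draw of (PIP, PEEP, Ti, RR, SLI target) from per-device
log-normal distributions parameterised by median and IQR
(σ = asinh(IQR/2m)/z₀.₇₅, which matches the interquartile range exactly).
Defaults are the study-scale medians/IQRs per device (T-piece
19.9/5.1 cmH₂O, Ti 1.0 s; SIB 21.1 cmH₂O, no PEEP, squeeze width 0.85 s —
chosen so the *flow-measured* inspiratory time of a half-sine squeeze is
0.5 s). Operators who draw a long Ti slow their rate so Ti never exceeds
60% of the breath period: hand ventilation requires expiratory time, and
without the cap a long-Ti draw at an independently drawn rate would produce
breaths with no exhalation. Per-breath PIP and Ti get multiplicative
log-normal jitter (cv 0.10 by default). A `knows_sli` flag carries the
subjects who cannot perform the maneuver and are excluded from the SLI
analysis.

The default cohort reproduces the emulated study's structure: 54 + 60
subjects, 3/1 acquisition failures, 13/13 SLI-unable per group, two devices
per subject in seed-randomised order, one 3-min ventilation epoch and one
10-s SLI per device.

## Analyzers

**Breath segmentation** works on flow alone: onset at a rising crossing of
+0.2 L/min, with hysteresis (a new onset requires the flow to have fallen
through −0.2 L/min, or to have stayed sub-threshold for ≥`min_ti` = 0.1 s);
inspiration ends at the first non-positive flow sample; candidates shorter
than `min_ti` are rejected as noise. Vt integrates only positive flow
(trapezoid, L/min → mL/s), so the sign convention of expiratory flow is
irrelevant. PIP is the segment maximum; PEEP the mean over the final 50 ms
of the segment (end-expiration, robust to noise). The per-subject reducer
is the arithmetic mean over breaths (median available); the group tables
then take medians of per-subject values, which is where the study-style
median(IQR) rows come from.

**SLI screen.** Onset = first sample exceeding the pre-maneuver baseline
(median of the first second) by 2 cmH₂O. The window is exactly 10 s from
onset. AUPTC is the trapezoidal integral over the window against *absolute
zero* pressure — the only baseline consistent with PMn ≡ AUPTC/window
matching the printed means — with linear interpolation at fractional window
edges, making a constant hold exact at any sampling rate. T Max is the time
to the first sample within 0.05 cmH₂O of the window maximum: "time to reach
the maximum" and "time to reach the target" coincide on plateau traces only
under such an attainment tolerance; an exact-argmax rule would report the
last sample of an asymptotic plateau.

## Statistics

Group summaries are median and Q₃−Q₁ with linear-interpolation quantiles.
Device comparisons use the two-sided Mann–Whitney U on per-subject values
(exact null distribution when n₁+n₂ ≤ 16 and untied, otherwise the tie- and
continuity-corrected normal approximation; a paired Wilcoxon is available
by flag since each subject used both devices). Welch's t (pooled by flag),
one-way ANOVA or tie-corrected Kruskal–Wallis with a Student–Newman–Keuls
stepwise range post-hoc (studentized-range critical values, harmonic-mean
n, classic non-testing shielding rule; the rank path applies the same
machinery to rank-transformed data), and χ² with Yates correction when all
expected counts exceed 5, otherwise two-sided Fisher. The sample-size solve
seeds statsmodels' power solver with the normal approximation
`n₀ = 2σ²(z₁₋α/₂ + z_power)²/δ²` and then verifies/adjusts the integer
answer against the exact noncentral-t power, which also covers corners
where the solver fails to converge.

## What the simulator does and does not emulate

It emulates: device physics that differ between T-piece and SIB (PEEP vs
none, pressure hold vs decay, pop-off), operator-level spread matching
published medians/IQRs, per-breath jitter, the exclusion structure, and
fully seeded reproducibility. It does **not** emulate face-mask leak (the
scenario is a cuffed tube), sensor noise or drift, within-epoch operator
fatigue or learning, correlation between a subject's behaviour on the two
devices, or gas-exchange physiology. Passing the cohort-level checks
therefore shows the analysis chain is correct and the device contrast is
robust at study scale — not that the generator is a physiological model of
any particular manikin.

Two quantitative caveats. The printed SIB mean-pressure value in the
emulated study (6.4 cmH₂O) is not consistent with its own printed AUPTC
(60.2/10 = 6.02) under the identity PMn = AUPTC/window that this package
enforces; the simulated SIB PMn sits ~6% below the printed figure and
cannot honestly match both. And the T-piece Ti median is the noisiest
reported quantity across seeds: an IQR of 0.9 s at a median of 1.0 s is a
heavy-tailed operator distribution, so the median of 110 draws carries a
~8% standard error.

## Problem sizes

The default acceptance run simulates the full 114-subject cohort — 220
three-minute epochs plus 168 SLI traces at 200 Hz — and completes in a few
seconds; waveforms are streamed per subject rather than retained. The test
suite's Monte-Carlo checks use 2,000 replicates (t-test power, SNK
family-wise error) and 10,000 draws (log-normal median recovery), sizes at
which the binomial margin of the assertion comfortably exceeds simulation
noise.
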