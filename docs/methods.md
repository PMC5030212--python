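# Methods

## The model system

Two organotypic spinal-cord slices cultured side by side on one MEA fuse into
a functional unit whose spontaneous activity, stabilized by disinhibition
(GABA_A and glycine receptor block), is organized in population bursts that
propagate between the slices. After a complete transection at the groove the
slices stay silent towards each other unless grafted cells differentiate into
neurons that **relay** activity across the lesion. The package's analysis
layer quantifies that relay function from extracellular multiunit recordings;
its generator simulates the system with the relay mechanism made explicit, so
every analysis output can be checked against a known hidden state.

## Event detection

Events are per-channel threshold crossings: `|v| > k·σ̂` with
`σ̂ = median(|v|)/0.6745` and a refractory dead time enforced in integer
samples. The median-based noise estimate is standard for extracellular data
because sparse spikes barely move the median of the rectified trace while
they inflate the plain SD. Defaults `k = 5`, refractory 1 ms; both
configurable. Polarity is ignored (threshold on `|v|`). A deflection staying
above threshold longer than the refractory period yields repeated events —
this matches a per-sample scan with dead time, which the test suite uses as
the independent oracle. Stimulation and LED-edge artifacts are blanked with
closed windows of ±2 ms (stimulation) and ±5 ms (light edges) by default.

## Burst detection and pairing

Events of each slice's selected electrodes are binned at 10 ms (half-open
bins; counts are conserved exactly). Candidate bursts are maximal runs of
bins with at least `onset_thresh = 3` events, merged across sub-threshold
gaps under 100 ms, and must last ≥30 ms while engaging ≥4 distinct
electrodes. Each candidate must additionally be flanked by ≥300 ms of
silence. The silence check is evaluated against neighbouring *candidates*
only: an isolated suprathreshold bin that itself fails the duration or
electrode criteria — a chance coincidence of a few background events — does
not void the silent period around a genuine burst. (With raw runs instead of
candidates, such blips discard ~4% of bursts at a 0.3 Hz/electrode
background and bias synchronization low.)

Burst onsets are reported as the time of the first event inside the burst
window rather than the first suprathreshold bin's start. Bin-start onsets
are uniformly early by up to one bin (−5 ms on average at 10 ms bins), which
cancels in onset-to-onset delay differences but directly biases the
graft-coupling delay, where a point-process (cell firing) is referenced to
the burst onset. First-event onsets carry only the ~1 ms first-spike latency
of the burst envelope.

Pairing is greedy and chronological within a 500 ms window (closed right
end) — generous relative to observed propagation delays up to ~170 ms but
far below the inter-burst interval, so mispairing is not a practical
concern. Simultaneous onsets are ordered by larger first-bin count, then
slice label; a burst claimed as a follower cannot lead. Synchronization is
directionless (propagated bursts in either direction over all leading
bursts) with a per-direction breakdown retained. Group comparison uses the
Kruskal–Wallis test (scipy) with tie correction; the fully degenerate
all-identical case is reported as H = 0, p = 1.

## Closed loop

The online detector emulates the acquisition-side trigger: one hand-picked
high-activity electrode per slice, 10 ms count windows, threshold
`5 × running SD` over a trailing 2 s burst-free history, with a floor of 3
events/bin. The floor stands in for the unspecified hardware discriminator:
burst-free count histories have SDs near 0.05, so a bare SD rule would
trigger on any isolated background event, and at a ~2 Hz trigger-electrode
background, two-event coincidences would still fire about once a minute —
each false pulse's lockout then leaves the next genuine burst unprotected.
Triggers are bin-end times (causal by construction); a zero-variance history
suppresses triggering with a warning. Pulses last 1 s, with a 5 s lockout
after pulse offset; the pulse delay is referenced to the online trigger for
spontaneous bursts and to the stimulation time for stimulated trials.

Block is quantified as `1 − (propagated fraction under light)/(propagated
fraction in control)`, clipped to [0, 1]. The block-vs-delay curve is made
monotone non-increasing by isotonic regression (weighted by trials per
delay) before the 50% point is read off by piecewise-linear interpolation;
monotone interpolation adds no functional-form assumption beyond the
physically required direction. Cultures with synchronization strictly below
50% (exactly 50% is kept) or with unreliable online detection are excluded.

## Intracellular analysis

Spikes are upward crossings of −20 mV with ≥30 mV amplitude above the
pre-spike baseline (median of 2–7 ms before the crossing); width is measured
at half amplitude. Cells with resting potentials above −45 mV are rejected
as damaged. Classification from depolarizing current steps: ≥5 spikes
sustained through the largest step → mature neuron; any spiking short of
that → immature neuron (the canonical immature signature being one or two
small (<40 mV), slow (>4 ms) spikes); no spikes with a passive quasi-linear
V–I response → glia. The numeric cutoffs encode qualitative descriptions and
are configurable. Light-evoked hyperpolarization is the median potential
over the 200 ms pre-pulse baseline minus the median over the last 50% of the
pulse (skipping the onset transient); medians make the measure invariant to
±1 mV additive noise at the ±0.5 mV level.

Graft-host coupling: for every burst of each slice the first graft event
within 300 ms after onset yields a delay; the input slice is the one whose
bursts capture the most coupled events.

## The generator

Study conditions (defaults, set once):

| parameter | default | rationale |
|---|---|---|
| electrodes per slice | 34 | standard two-group MEA layout |
| burst rate | 5 /min, min gap 8 s | disinhibited cultures burst quasi-rhythmically every ~10 s; gaps exceed pulse+lockout as in usable silencing experiments |
| background rate | 0.3 Hz/electrode | sparse inter-burst multiunit activity |
| burst envelope | double-exponential, rise 2 ms, decay 60 ms, peak 100 Hz/electrode | fast recruitment, few-hundred-ms bursts, ~200 events/burst/slice |
| electrode gains | U(0.5, 1.5); trigger electrode 6.0 | electrode-to-electrode variability; one "hot" electrode per slice as the online trigger |
| relay delay d_r | Normal(111, 20) ms | reported graft firing delay used as generative truth |
| follower delay d_d | Normal(170, 55) ms, truncated | reported propagation delay used as generative truth |
| propagation p | per experiment (0.076–0.80) | group means used as generative truth |
| intensity map | ΔV(I) = 12.6·I²/(I²+24.5²) mV | saturating; calibrated so ΔV(94%) = 11.8 mV |
| silencing threshold | 8 mV | hyperpolarizations below ~6 mV did not silence; 8 mV separates the silenced majority |
| raw mode | 10 kHz, noise SD 10 µV, spikes 80 µV | 8× SNR biphasic templates, resolvable at the 1 ms refractory |

`d_r` and `d_d` are drawn comonotonically (one shared standard-normal
quantile, truncated at ±3σ) with `d_r` clipped 1 ms below `d_d`. Independent
draws would put the relay after follower induction in ~16% of bursts, which
contradicts the relay mechanism; comonotone draws preserve both marginals to
within ~1 ms of their means (the clip removes ~0.75 ms from the relay mean).
Biologically this reads as slow propagation co-varying with slow relay
recruitment within a burst.

Mechanism: the relay starts firing at `d_r` (ISI 10 ms) and keeps firing
until the burst ends; the follower slice is induced at `d_d` iff an
unsilenced relay spike falls within the 25 ms induction window ending at
`d_d` *and* an independent Bernoulli(p) succeeds. Silencing (opsin present,
ΔV at pulse intensity ≥ threshold) removes relay spikes inside light pulses.
Consequently a pulse blocks propagation exactly when it covers the induction
time — delayed pulses block only while they precede follower induction, and
the half-block delay tracks the median of `d_d`. A pulse ending before
induction lets the relay recover.

Event rendering uses per-burst spawned random streams, so removing a
follower burst (silencing) never shifts the draws of unrelated bursts; an
opsin-negative session is bit-identical to its no-light control. Raw mode
renders biphasic templates plus Gaussian noise per channel; a streaming
variant (`generate_detected_raster`) renders and detects one channel at a
time so hour-long 68-channel sessions never exist in memory at once.

What the generator does **not** emulate: electrode drift, bursting-rate
nonstationarity, within-burst propagation waves across the electrode array,
spike-waveform diversity (one template), photoelectric light artifacts on
intracellular traces, and any spontaneous follower-slice activity not driven
by the relay (an optional rate exists, default 0). Passing tests therefore
demonstrate correctness of the analysis under the stated statistical
structure, not robustness to every pathology of real recordings.

## Problem sizes

The recovery checks use: synchronization — 2520 s sessions (tests; ≥200
bursts) and 7920 s (acceptance script; ~660 bursts) through the full
raw-trace path at 10 kHz; relay delay — 1500 s event-mode sessions with all
bursts leading from the graft's slice (~125 coupled bursts); follower
delay — ≥250 propagated bursts; hyperpolarization — 20 traces at 94%
intensity with 1 mV membrane noise; block — 1260 s closed-loop sessions
(~100 leading bursts) against a same-seed no-light control; half-block
delay — 16 delays × 200 stimulated trials per delay, tolerance twice the
binomial standard error of the 50% crossing.

## Known limitations

* Burst onset estimation inherits the first-spike latency of the envelope
  (~1 ms late); delays between onsets are unbiased but individually jittered
  by a few ms.
* The online detector assumes the trigger electrode participates early in
  every burst; real electrode selection is manual and can be worse, which is
  what the unreliable-detection exclusion models.
* The half-block extrapolation needs the measured curve to bracket 50%;
  outside that range it raises rather than extrapolating beyond the data.
* Kruskal–Wallis p-values use the chi-square approximation, adequate for the
  group sizes involved (≥8) but approximate below that.
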