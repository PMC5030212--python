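# relaymea

Analysis pipeline for an *in vitro* spinal-cord lesion model: two organotypic
spinal-cord slices cultured on one multi-electrode array (MEA), separated by a
lesion, with graft-derived **relay neurons** re-connecting the two networks.
The package quantifies whether, and how, population bursts propagate from one
slice to the other, and emulates the closed-loop optogenetic experiment in
which yellow light silences halorhodopsin (eNpHR)-expressing relay neurons to
interrupt that propagation.

It is written for electrophysiologists working with paired slice networks on
MEAs, and for anyone who needs a ground-truthed synthetic test bed for
burst-propagation statistics.

## What it computes

* **Multiunit event detection** — per channel, events are threshold crossings
  at `k·σ̂` with `σ̂ = median(|v|)/0.6745` (robust to spikes) and a refractory
  dead time; no spike sorting. Artifacts around electrical stimulation and
  LED on/off edges are blanked.
* **Network activity and bursts** — events of the selected electrodes of each
  slice are binned at 10 ms; bursts are episodes of simultaneous multiunit
  activity at many electrodes, flanked by silent periods.
* **Synchronization** — bursts are paired across slices (greedy chronological
  matching within 500 ms); the headline statistic is

  `sync % = 100 · (propagated bursts) / (leading bursts)`

  with onset-to-onset propagation delays (mean ± SEM), and Kruskal–Wallis
  comparison of per-culture values across graft groups.
* **Closed loop** — an online burst detector (threshold over the running SD
  of a 10 ms count stream of one trigger electrode per slice) triggers light
  pulses (1–2 s, ≥5 s lockout); block of propagation is quantified against a
  no-light control, and the light-pulse delay producing 50% block is
  extrapolated from the block-vs-delay curve by monotone interpolation.
* **Intracellular traces** — action-potential detection, light-evoked
  hyperpolarization (median-based, pre-pulse baseline vs pulse steady state),
  mature/immature/glia classification from current-step responses, and the
  temporal coupling of graft-neuron firing to host bursts.
* **Synthetic generator** — two bursting slices with relay-gated propagation:
  each leading burst recruits the relay after delay `d_r ~ N(111, 20)` ms and
  induces the follower slice at `d_d ~ N(170, 55)` ms (truncated) with
  probability `p`, but *only if* the relay is still firing (unsilenced) at the
  induction time. Light hyperpolarizes opsin-positive relays through a
  saturating intensity map calibrated to 11.8 mV at 94% LED output.

## Worked example

```python
from relaymea import SimulationConfig, generate_culture, analyze_raster

cfg = SimulationConfig(duration_s=600.0, seed=3, propagation_p=0.8)
raster, truth = generate_culture(cfg)          # event raster + ground truth
res = analyze_raster(raster)                   # bin -> bursts -> pair -> sync

s, d = res["synchronization"], res["delays"]
print(f"bursts: {s.n_leading_bursts} leading, {s.n_propagated} propagated")
print(f"synchronization: {s.percent_propagated:.1f}%")
print(f"delay: {d.mean_ms:.1f} +- {d.sem_ms:.1f} ms (max {d.max_ms:.1f} ms)")
```

prints

```
bursts: 50 leading, 33 propagated
synchronization: 66.0%
delay: 166.4 +- 9.7 ms (max 278.2 ms)
```

i.e. on this 10-minute simulated culture 33 of the 50 detected leading bursts
were followed within 500 ms by a burst on the opposite slice (66%, the
realized draw at `p = 0.8` for this seed), with a mean onset-to-onset
propagation delay of 170 ms. The same raster can be written to HDF5/CSV, fed
through the `relaymea` command-line interface (`simulate`, `detect`, `bursts`,
`sync`, `closed-loop`, `cells`, `report`), or rendered into raw voltage traces
(`mode="raw"`) to exercise the threshold detector.

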