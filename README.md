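# plasticity

Quantification pipeline for experiments that track how cortical neurons
remodel after a focal brain injury, built around three longitudinal
modalities:

* **Dendritic-spine turnover** from repeated two-photon imaging of the same
  dendritic stretches: per-interval elimination and formation rates as
  percentages of the previous session's spine total, spine density per µm,
  mushroom/thin/stubby morphology fractions, and the *persistence index* —
  the fraction of subsequent imaging sessions at which a spine remains
  present (its binary presence code averaged over the scored sessions).
* **Somatic calcium activity** from GCaMP recordings (30 Hz, 10 min
  sessions by default): ROI pixel averaging, zero-phase 10 Hz low-pass
  filtering, neuropil compensation
  `F_comp = F_roi − α·F_np + α·median(F_np)` with α = 0.7, transient
  detection as supra-threshold runs of ≥ 20 frames (~0.7 s), the
  ≥ 1 transient/min "high" vs "low" split, and an activity-fate taxonomy
  across baseline / mid / late sessions (persistently active, silent,
  regained, newly active).
* **Monosynaptic-tracing connectivity**: starter cells counted on a subset
  of sections are interpolated proportionally to the whole brain, and each
  region's *connectivity ratio* is its presynaptic cell count divided by the
  whole-brain starter count, summarized as mean ± SEM per group with
  group-vs-control comparisons.

Inference on fractions uses a nonparametric bootstrap (10,000 iterations,
95% percentile confidence intervals, units resampled with replacement), and
a small morphometry module covers lesion volume (Cavalieri rule over serial
section areas), cortical thickness, cell density and synaptic-pair density.
A synthetic-data module generates all three modalities with known ground
truth — a spine birth–death process with per-session hazards, Poisson event
trains convolved with a GCaMP-like kernel plus neuropil contamination
constructed so compensation is exactly invertible, and Poisson tracing
counts with binomially thinned starters — so every estimator can be tested
for parameter recovery without any raw imaging data.

## Worked example

```python
from plasticity.synthetic import SpineSimParams, simulate_spine_tracks
from plasticity import spines as sp

sessions = ["B1", "B2", "3d", "6d", "9d", "12d", "15d", "18d"]
params = SpineSimParams(
    n_dendrites=100, spines_per_dendrite_mean=100,
    elimination_prob_per_session={s: 0.12 for s in sessions[1:]},
    formation_rate_per_session={s: 0.05 for s in sessions[1:]},
    seed=1,
)
table, truth = simulate_spine_tracks(params)
rates = sp.turnover_rates(sp.classify_transitions(table, sessions))
print(round(rates["elimination_rate_pct"].mean(), 2),
      round(rates["formation_rate_pct"].mean(), 2))
```

prints `11.86 4.83`: with a true per-session elimination hazard of 12% and
a formation rate of 5% of the previous total, the estimated mean rates
recover both to within sampling error. The same round trip is available
from the shell:

```sh
plasticity simulate spines --seed 1 --out sim/
plasticity spines --tracks sim/spine_tracks.csv --out results/
```

which writes per-dendrite turnover, density and persistence CSVs plus a
mean ± SEM summary and a JSON run report.

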