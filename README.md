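# bundlescan

Automatic detection of **axon bundle activation thresholds** from
multi-electrode array (MEA) stimulation scans, for epiretinal
prosthesis calibration.

## The problem

An epiretinal prosthesis stimulates retinal ganglion cells (RGCs)
through a dense MEA. Current through one electrode can also activate
axons of far-away RGCs that merely pass by in the nerve fiber layer.
Those cells' somas lie off the array, their contribution to perception
cannot be mapped, and their activation produces distorted, arc-shaped
percepts. For each stimulating electrode `e_s` the *bundle threshold*
`b(e_s)` is the lowest current that evokes such off-array axonal
activation; keeping stimulation below it avoids the problem. Manual
identification of `b(e_s)` from recordings takes days per preparation —
this package automates it.

## The algorithm

Input: a single-electrode scan — voltages `V[e_s, a, r, e_r, t]`
recorded on all electrodes `e_r` after repeat `r` of stimulating
electrode `e_s` at amplitude `a` (typically 40 levels, +10% per step
over 0.1–4.1 μA, 25 repeats, 20 kHz). Per stimulating electrode:

1. `v ← V[a] − mean_r V[a_min]` — subtract the stimulation artifact,
   estimated as the mean recording at the lowest amplitude (the
   artifact is repeat-independent for a fixed pulse).
2. `t[a, r, e_r] ← argmin_t v` in the 0.3–2 ms window — extracellular
   spikes have negative peaks; the window skips the residual artifact.
3. Flag *signal electrodes*: spike-time variance across repeats below
   `σ₀² · Q_{χ²_{n−1}}(p) / (n−1)`, where σ₀² = (m²−1)/12 is the
   variance of times uniform over the window's m samples. Evoked spikes
   are time-locked; spontaneous spikes and noise are not. The level
   `p = 0.05` is the algorithm's only hyperparameter.
4. Prune: `Activated(a_j) = ⋂_{k≥j} Signal(a_k)` — evoked responses are
   monotone in current, chance flags are not.
5. `b(e_s)` = the lowest amplitude whose activated set touches ≥ 2
   borders of the rectangular array — the signature of a spike
   travelling bidirectionally along an axon bundle and leaving the
   array on both sides. If no amplitude qualifies: `NOT_FOUND`.

The package also provides a synthetic scan simulator implementing the
signal decomposition `y = x + i + s + n` (evoked, artifact,
spontaneous, noise) with per-electrode ground-truth thresholds, and the
validation metrics used to compare threshold sets (fraction within ±1
amplitude step = ±10%, exact fraction, Pearson r, permutation chance
baseline, repeat-subsampling curve, p-value sweep).

## Worked example

```python
import bundlescan as bs

config = bs.SimulationConfig.fixture(seed=7)   # 8x8 array, 12 levels, 10 repeats
sim = bs.SimulatedScan(config)

thresholds = bs.run_detection(sim, bs.DetectionConfig(p_value=0.05))
report = bs.compare_thresholds(
    thresholds, sim.ground_truth.to_thresholds(), config.amplitude_grid
)
print(f"within ±1 step: {report.fraction_within_one_step:.3f}, "
      f"exact: {report.fraction_exact:.3f}")
```

Output:

```
within ±1 step: 1.000, exact: 0.953
```

i.e. on this small moderate-noise synthetic scan every detected
threshold lies within one 10% amplitude step of the simulator's ground
truth, and 95.3% land exactly on it. `thresholds.to_frame()` gives one
row per stimulating electrode: the threshold in μA, its grid index, and
`detected`/`NOT_FOUND` status. The scripts in `examples/` walk through
each capability (detection, validation metrics, repeat subsampling,
p-value robustness, containers/CLI).

A thin command-line wrapper covers the file-based workflow:

```sh
bundlescan simulate --seed 7 --out scan.h5 --truth truth.csv
bundlescan detect --scan scan.h5 --out thresholds.csv
bundlescan validate --detected thresholds.csv --reference ref.csv \
    --grid-levels 12 --report report.json
```

Scans are stored in a single HDF5 container chunked per stimulating
electrode, so detection streams one electrode's block at a time and
full-array scans (512 electrodes × 40 amplitudes × 25 repeats) never
need to fit in memory.

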