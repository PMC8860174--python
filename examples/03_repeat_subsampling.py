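"""How many stimulation repeats does detection need?

Reruns detection on random subsets of the available repeats and tracks
agreement with ground truth as a function of subset size. Accuracy rises
sharply over the first few repeats and saturates well before the full
repeat count — useful for shortening calibration scans.
"""

import bundlescan as bs

config = bs.SimulationConfig.fixture(seed=19)
sim = bs.SimulatedScan(config)
reference = sim.ground_truth.to_thresholds()

curve = bs.repeats_curve(
    sim,
    bs.DetectionConfig(),
    repeat_counts=[2, 3, 5, 8, 10],
    n_draws=5,
    seed=0,
    reference=reference,
)
summary = bs.summarize_repeats_curve(curve)
print(summary.to_string(index=False))

# Each row: mean ± sd (over random subset draws) of the fraction of
# electrodes whose detected threshold lies within ±1 amplitude step of
# ground truth when only that many repeats are used.
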