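"""The five-step axon-bundle-activation detection algorithm.

For one stimulating electrode the algorithm proceeds:

1. **Subtract electrical artifact** — the mean over repeats of the
   recording at the lowest amplitude is subtracted from every higher
   amplitude's recording.  The artifact is repeat-independent for a fixed
   pulse, so this removes it up to its (mild) growth with amplitude; the
   estimate is deliberately not rescaled with amplitude.
2. **Extract spike times** — per (amplitude, repeat, recording
   electrode), the sample index of the minimum voltage inside the
   0.3–2 ms analysis window (extracellular spikes have negative peaks).
3. **Extract signal electrodes** — an electrode whose spike-time
   variance across repeats falls below a chi-squared cutoff is flagged
   as carrying evoked (time-locked) activity.  Under the null that spike
   times are uniform over the window's m samples, (n−1)·s²/σ₀² with
   σ₀² = (m²−1)/12 is modeled as χ²_{n−1}; the cutoff is its p-quantile.
4. **Prune signal electrodes** — evoked responses are monotone in
   current, so the activated set at an amplitude is the intersection of
   the signal sets at that amplitude and every higher one, computed
   iteratively from the top amplitude downward.
5. **Determine bundle threshold** — the lowest amplitude whose activated
   set touches at least two array borders (bidirectional axonal
   propagation exiting the array) is the bundle threshold; if no
   amplitude qualifies the result is NOT_FOUND.

All steps are independent across stimulating electrodes, so a scan is
processed by streaming one stimulating electrode's block at a time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Protocol, Sequence

import numpy as np
from scipy.stats import chi2

from .geometry import ElectrodeArray, satisfies_border_rule
from .scan_io import (
    NOT_FOUND_INDEX,
    AmplitudeGrid,
    BundleThresholds,
    DetectionConfig,
)


class ScanSource(Protocol):
    """Anything that can stream per-stimulating-electrode voltage blocks."""

    sampling_rate: float
    amplitude_grid: AmplitudeGrid
    array: ElectrodeArray

    @property
    def n_stim(self) -> int: ...

    @property
    def n_repeats(self) -> int: ...

    def get_block(self, es: int) -> np.ndarray: ...


class RepeatSubset:
    """View of a scan source restricted to a subset of repeats."""

    def __init__(self, source: ScanSource, repeats: Sequence[int]):
        repeats = np.asarray(repeats, dtype=int)
        if repeats.size < 2:
            raise ValueError("repeat subset must contain at least 2 repeats")
        if repeats.size != np.unique(repeats).size:
            raise ValueError("repeat subset contains duplicates")
        if repeats.min() < 0 or repeats.max() >= source.n_repeats:
            raise ValueError("repeat subset out of range")
        self._source = source
        self._repeats = repeats
        self.sampling_rate = source.sampling_rate
        self.amplitude_grid = source.amplitude_grid
        self.array = source.array

    @property
    def n_stim(self) -> int:
        return self._source.n_stim

    @property
    def n_repeats(self) -> int:
        return self._repeats.size

    def get_block(self, es: int) -> np.ndarray:
        return self._source.get_block(es)[:, self._repeats]


# ---------------------------------------------------------------------------
# step 1: artifact subtraction
# ---------------------------------------------------------------------------


@dataclass
class ArtifactCorrectedBlock:
    """Artifact-corrected voltages for one stimulating electrode.

    ``v`` has shape (n_amplitudes - 1, n_repeats, n_electrodes,
    n_samples): the amplitudes strictly above the artifact reference
    (the lowest amplitude), in grid order.  ``amplitude_indices`` maps
    axis 0 back to grid indices.
    """

    v: np.ndarray
    amplitude_indices: np.ndarray
    sampling_rate: float


def subtract_artifact(
    block: np.ndarray, sampling_rate: float, amin_index: int = 0
) -> ArtifactCorrectedBlock:
    """Subtract the mean lowest-amplitude recording from higher amplitudes.

    ``block`` is one stimulating electrode's (A, R, E, T) tensor.  The
    artifact estimate is the mean over repeats at ``amin_index``; it is
    applied unscaled to every higher amplitude.
    """
    block = np.asarray(block)
    if block.ndim != 4:
        raise ValueError(f"block must be (A, R, E, T), got shape {block.shape}")
    if amin_index != 0:
        raise ValueError("the artifact reference must be the lowest amplitude")
    artifact = block[amin_index].mean(axis=0)  # (E, T)
    above = np.arange(amin_index + 1, block.shape[0])
    v = block[above] - artifact[None, None]
    return ArtifactCorrectedBlock(
        v=v, amplitude_indices=above, sampling_rate=sampling_rate
    )


# ---------------------------------------------------------------------------
# step 2: spike times
# ---------------------------------------------------------------------------


@dataclass
class SpikeTimeTable:
    """Per-(amplitude, repeat, electrode) spike-time sample indices.

    ``times`` has shape (n_amplitudes_above_min, n_repeats,
    n_electrodes); values are absolute sample indices within
    [window[0], window[1]].
    """

    times: np.ndarray
    amplitude_indices: np.ndarray
    window: tuple[int, int]


def extract_spike_times(
    block: ArtifactCorrectedBlock, window: tuple[int, int]
) -> SpikeTimeTable:
    """Argmin of the corrected voltage inside the analysis window.

    The minimum is used because extracellular spikes have negative
    peaks; ties resolve to the earliest sample (numpy argmin).  The
    window is inclusive on both ends.
    """
    lo, hi = int(window[0]), int(window[1])
    n_t = block.v.shape[-1]
    if not (0 <= lo < hi < n_t):
        raise ValueError(
            f"window [{lo}, {hi}] not contained in trace of {n_t} samples"
        )
    times = lo + np.argmin(block.v[..., lo : hi + 1], axis=-1)
    return SpikeTimeTable(
        times=times, amplitude_indices=block.amplitude_indices, window=(lo, hi)
    )


# ---------------------------------------------------------------------------
# step 3: signal electrodes
# ---------------------------------------------------------------------------


def variance_cutoff(n_repeats: int, window_length: int, p_value: float) -> float:
    """Chi-squared cutoff on the spike-time sample variance.

    Under the null of spike times uniform over the window's
    ``window_length`` integer samples, the scaled sample variance
    (n−1)·s²/σ₀² is modeled as χ² with n−1 degrees of freedom, where
    σ₀² = (m²−1)/12 is the discrete-uniform variance.  Returns
    ``σ₀² · Q_{χ²_{n−1}}(p) / (n−1)`` in samples².
    """
    if n_repeats < 2:
        raise ValueError("need at least 2 repeats for a variance")
    if window_length < 2:
        raise ValueError("window must span at least 2 samples")
    if not 0 < p_value < 1:
        raise ValueError(f"p_value must lie in (0, 1), got {p_value}")
    sigma0_sq = (window_length**2 - 1) / 12.0
    return sigma0_sq * chi2.ppf(p_value, df=n_repeats - 1) / (n_repeats - 1)


def spike_time_variances(times: SpikeTimeTable) -> np.ndarray:
    """Across-repeat sample variance (ddof=1) per amplitude and electrode."""
    if times.times.shape[1] < 2:
        raise ValueError("need at least 2 repeats for a variance")
    return times.times.var(axis=1, ddof=1)


def extract_signal_electrodes(
    times: np.ndarray,
    cutoff: float,
    exclude: Iterable[int] = (),
) -> frozenset[int]:
    """Electrodes whose spike-time variance is strictly below the cutoff.

    ``times`` is the (n_repeats, n_electrodes) table for a single
    amplitude.  Equality with the cutoff excludes (strict inequality).
    """
    times = np.asarray(times)
    if times.ndim != 2 or times.shape[0] < 2:
        raise ValueError("times must be (n_repeats >= 2, n_electrodes)")
    variances = times.var(axis=0, ddof=1)
    flagged = set(np.flatnonzero(variances < cutoff).tolist())
    return frozenset(flagged - set(int(e) for e in exclude))


# ---------------------------------------------------------------------------
# step 4: pruning
# ---------------------------------------------------------------------------


def prune_signal_electrodes(
    signal_sets: Sequence[frozenset[int]],
) -> list[frozenset[int]]:
    """Intersect each amplitude's signal set with all higher amplitudes'.

    Computed incrementally from the highest amplitude downward:
    ``Activated(top) = Signal(top)`` and
    ``Activated(j) = Signal(j) ∩ Activated(j+1)``.  The result is nested:
    lower-amplitude activated sets are subsets of higher-amplitude ones,
    enforcing monotonicity of evoked responses with current.
    """
    if not signal_sets:
        return []
    activated = [frozenset(signal_sets[-1])]
    for s in reversed(signal_sets[:-1]):
        activated.append(frozenset(s) & activated[-1])
    activated.reverse()
    return activated


# ---------------------------------------------------------------------------
# step 5: threshold
# ---------------------------------------------------------------------------


def detect_bundle_threshold(
    activated_sets: Sequence[frozenset[int]],
    array: ElectrodeArray,
    grid: AmplitudeGrid,
    amplitude_indices: Sequence[int] | None = None,
    min_borders: int = 2,
    corner_rule: str = "literal",
) -> int:
    """Lowest amplitude whose activated set satisfies the border rule.

    Returns the grid index of the threshold, or ``NOT_FOUND_INDEX`` if no
    amplitude qualifies.  Because activated sets are nested, qualifying
    amplitudes form an upward-closed set and the first qualifying index
    in a linear scan is the threshold.
    """
    if amplitude_indices is None:
        amplitude_indices = range(len(activated_sets))
    amplitude_indices = list(amplitude_indices)
    if len(amplitude_indices) != len(activated_sets):
        raise ValueError("amplitude_indices must align with activated_sets")
    for idx, electrodes in zip(amplitude_indices, activated_sets):
        if satisfies_border_rule(electrodes, array, min_borders, corner_rule):
            if not 0 <= idx < grid.n_levels:
                raise ValueError(f"amplitude index {idx} outside the grid")
            return int(idx)
    return NOT_FOUND_INDEX


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------


def block_signal_sets(
    block: np.ndarray,
    sampling_rate: float,
    config: DetectionConfig,
) -> tuple[list[frozenset[int]], np.ndarray]:
    """Steps 1–3 for one stimulating electrode's raw block.

    Returns the per-amplitude signal sets (amplitudes above the
    reference, in grid order) and the corresponding grid indices.
    """
    corrected = subtract_artifact(block, sampling_rate)
    window = config.window_samples(sampling_rate)
    times = extract_spike_times(corrected, window)
    m = window[1] - window[0] + 1
    cutoff = variance_cutoff(times.times.shape[1], m, config.p_value)
    variances = spike_time_variances(times)  # (A-1, E)
    sets = []
    exclude = config.exclude_recording
    for a in range(variances.shape[0]):
        flagged = set(np.flatnonzero(variances[a] < cutoff).tolist())
        sets.append(frozenset(flagged - exclude))
    return sets, times.amplitude_indices


def detect_block(
    block: np.ndarray,
    sampling_rate: float,
    array: ElectrodeArray,
    grid: AmplitudeGrid,
    config: DetectionConfig,
) -> int:
    """Steps 1–5 for one stimulating electrode; returns a grid index."""
    signal_sets, amp_indices = block_signal_sets(block, sampling_rate, config)
    activated = prune_signal_electrodes(signal_sets)
    return detect_bundle_threshold(
        activated,
        array,
        grid,
        amplitude_indices=amp_indices,
        min_borders=config.min_borders,
        corner_rule=config.corner_rule,
    )


def run_detection(
    scan: ScanSource,
    config: DetectionConfig | None = None,
    progress: bool = False,
) -> BundleThresholds:
    """Run bundle detection on every stimulating electrode of a scan.

    Streams one stimulating electrode's block at a time, so memory stays
    bounded by a single block regardless of scan size.  Deterministic
    given the input.  The lowest amplitude serves as the artifact
    reference and is never a candidate threshold.
    """
    config = config or DetectionConfig()
    indices = np.empty(scan.n_stim, dtype=int)
    for es in range(scan.n_stim):
        try:
            indices[es] = detect_block(
                scan.get_block(es),
                scan.sampling_rate,
                scan.array,
                scan.amplitude_grid,
                config,
            )
        except Exception as exc:
            raise RuntimeError(
                f"bundle detection failed at stimulating electrode {es}"
            ) from exc
        if progress:
            status = indices[es] if indices[es] >= 0 else "NOT_FOUND"
            print(f"  es={es}: threshold index {status}")
    return BundleThresholds.from_indices(indices, scan.amplitude_grid)
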