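"""Validation metrics and experiments for bundle-threshold detection.

Agreement between two threshold sets (e.g. automatic vs manual, or
automatic vs simulator ground truth) is summarized by the fraction of
electrodes within ±1 amplitude-grid step, the fraction matching exactly,
and the Pearson correlation of threshold amplitudes.  On a grid that
increases 10% per step, ±1 step is the same as ±10% of threshold, so
agreement is computed in grid-index arithmetic (a literal amplitude-ratio
test would sit exactly on the float boundary at one step).

The module also provides the chance baseline (agreement after randomly
permuting the reference thresholds), the repeat-subsampling curve
(accuracy vs number of stimulation repeats used) and the p-value
robustness sweep.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .detection import (
    ScanSource,
    detect_block,
    detect_bundle_threshold,
    extract_spike_times,
    prune_signal_electrodes,
    spike_time_variances,
    subtract_artifact,
    variance_cutoff,
)
from .scan_io import (
    NOT_FOUND_INDEX,
    AmplitudeGrid,
    BundleThresholds,
    DetectionConfig,
)


@dataclass(frozen=True)
class AgreementReport:
    """Agreement between detected and reference threshold sets.

    Electrodes without a threshold (NOT_FOUND) in either set are
    excluded from the comparison and reported separately.
    ``pearson_r`` is None when fewer than two electrodes are jointly
    detected or when either side is constant.
    """

    n_compared: int
    fraction_within_one_step: float | None
    fraction_exact: float | None
    pearson_r: float | None
    n_detected_only: int
    n_reference_only: int
    n_neither: int

    def to_dict(self) -> dict:
        return {
            "n_compared": self.n_compared,
            "fraction_within_one_step": self.fraction_within_one_step,
            "fraction_exact": self.fraction_exact,
            "pearson_r": self.pearson_r,
            "n_detected_only": self.n_detected_only,
            "n_reference_only": self.n_reference_only,
            "n_neither": self.n_neither,
        }


def _index_agreement(
    detected_idx: np.ndarray, reference_idx: np.ndarray
) -> tuple[float | None, float | None, int]:
    both = (detected_idx != NOT_FOUND_INDEX) & (reference_idx != NOT_FOUND_INDEX)
    n = int(both.sum())
    if n == 0:
        return None, None, 0
    diff = np.abs(detected_idx[both] - reference_idx[both])
    return float((diff <= 1).mean()), float((diff == 0).mean()), n


def compare_thresholds(
    detected: BundleThresholds,
    reference: BundleThresholds,
    grid: AmplitudeGrid,
) -> AgreementReport:
    """Agreement metrics over jointly-detected stimulating electrodes.

    "Within tolerance" means |grid index difference| ≤ 1 (±10% on the
    standard 10%-per-step grid); "exact" means equal indices.  The
    Pearson correlation is computed on threshold amplitudes in μA.
    """
    if len(detected) != len(reference):
        raise ValueError(
            f"threshold sets cover different electrode counts: "
            f"{len(detected)} vs {len(reference)}"
        )
    d_idx, r_idx = detected.indices, reference.indices
    within, exact, n = _index_agreement(d_idx, r_idx)
    both = (d_idx != NOT_FOUND_INDEX) & (r_idx != NOT_FOUND_INDEX)
    pearson = None
    if n >= 2:
        a = detected.amplitudes_ua[both]
        b = reference.amplitudes_ua[both]
        if np.std(a) > 0 and np.std(b) > 0:
            pearson = float(np.corrcoef(a, b)[0, 1])
    return AgreementReport(
        n_compared=n,
        fraction_within_one_step=within,
        fraction_exact=exact,
        pearson_r=pearson,
        n_detected_only=int((detected.detected & ~reference.detected).sum()),
        n_reference_only=int((~detected.detected & reference.detected).sum()),
        n_neither=int((~detected.detected & ~reference.detected).sum()),
    )


def permutation_baseline(
    detected: BundleThresholds,
    reference: BundleThresholds,
    grid: AmplitudeGrid,
    n_perm: int = 1000,
    seed: int = 0,
    strata: Sequence[np.ndarray] | None = None,
) -> dict:
    """Chance level of the within-±1-step fraction.

    The reference thresholds are randomly permuted within each stratum
    (one stratum per scan/retina; a single stratum by default), results
    are pooled, and the within-tolerance fraction is recomputed per
    permutation.  Returns mean, sd and the per-permutation fractions.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    n = len(reference)
    if strata is None:
        strata = [np.arange(n)]
    fractions = np.empty(n_perm)
    ref_idx = reference.indices.copy()
    for k in range(n_perm):
        perm_idx = ref_idx.copy()
        for stratum in strata:
            stratum = np.asarray(stratum, dtype=int)
            perm_idx[stratum] = ref_idx[rng.permutation(stratum)]
        within, _, n_cmp = _index_agreement(detected.indices, perm_idx)
        fractions[k] = np.nan if within is None else within
    return {
        "mean": float(np.nanmean(fractions)),
        "sd": float(np.nanstd(fractions)),
        "fractions": fractions,
    }


# ---------------------------------------------------------------------------
# experiments
# ---------------------------------------------------------------------------


def repeats_curve(
    scan: ScanSource,
    config: DetectionConfig,
    repeat_counts: Sequence[int],
    n_draws: int,
    seed: int,
    reference: BundleThresholds,
) -> pd.DataFrame:
    """Detection accuracy as a function of the number of repeats used.

    For each repeat count, ``n_draws`` random subsets of the scan's
    repeats are drawn, detection is rerun on each subset, and the
    within-±1-step fraction against the reference is recorded.  Returns
    a tidy frame with one row per (repeat_count, draw).

    Each stimulating electrode's block is synthesized/loaded once and
    reused across all subsets, which is equivalent to rerunning full
    detection per subset because detection is independent across
    stimulating electrodes.
    """
    repeat_counts = [int(c) for c in repeat_counts]
    for c in repeat_counts:
        if c < 2:
            raise ValueError("repeat counts must be >= 2 (variance undefined)")
        if c > scan.n_repeats:
            raise ValueError(
                f"repeat count {c} exceeds scan repeats {scan.n_repeats}"
            )
    rng = np.random.default_rng(seed)
    subsets = {
        (c, d): np.sort(rng.choice(scan.n_repeats, size=c, replace=False))
        for c in repeat_counts
        for d in range(n_draws)
    }
    indices = {
        key: np.empty(scan.n_stim, dtype=int) for key in subsets
    }
    for es in range(scan.n_stim):
        block = scan.get_block(es)
        for key, rep in subsets.items():
            indices[key][es] = detect_block(
                block[:, rep],
                scan.sampling_rate,
                scan.array,
                scan.amplitude_grid,
                config,
            )
    rows = []
    for (c, d), idx in indices.items():
        det = BundleThresholds.from_indices(idx, scan.amplitude_grid)
        rep = compare_thresholds(det, reference, scan.amplitude_grid)
        rows.append(
            {
                "repeat_count": c,
                "draw": d,
                "fraction_within_one_step": rep.fraction_within_one_step,
                "fraction_exact": rep.fraction_exact,
                "n_compared": rep.n_compared,
            }
        )
    return pd.DataFrame(rows).sort_values(["repeat_count", "draw"]).reset_index(
        drop=True
    )


def summarize_repeats_curve(curve: pd.DataFrame) -> pd.DataFrame:
    """Mean ± sd of the within-tolerance fraction per repeat count."""
    return (
        curve.groupby("repeat_count")["fraction_within_one_step"]
        .agg(["mean", "std"])
        .reset_index()
    )


def pvalue_sweep(
    scan: ScanSource,
    config: DetectionConfig,
    pvalues: Sequence[float],
    reference: BundleThresholds,
) -> pd.DataFrame:
    """Detection accuracy across statistical-threshold (p-value) settings.

    Spike times and their across-repeat variances do not depend on the
    p-value, so they are computed once per stimulating electrode; each
    p-value then rethresholds the variances, reruns pruning and the
    border rule, and is compared to the reference.
    """
    pvalues = [float(p) for p in pvalues]
    for p in pvalues:
        if not 0 < p < 1:
            raise ValueError(f"p-values must lie in (0, 1), got {p}")
    window = config.window_samples(scan.sampling_rate)
    m = window[1] - window[0] + 1
    cutoffs = {p: variance_cutoff(scan.n_repeats, m, p) for p in pvalues}
    indices = {p: np.empty(scan.n_stim, dtype=int) for p in pvalues}
    for es in range(scan.n_stim):
        block = scan.get_block(es)
        corrected = subtract_artifact(block, scan.sampling_rate)
        times = extract_spike_times(corrected, window)
        variances = spike_time_variances(times)
        exclude = config.exclude_recording
        for p in pvalues:
            sets = [
                frozenset(
                    set(np.flatnonzero(variances[a] < cutoffs[p]).tolist())
                    - exclude
                )
                for a in range(variances.shape[0])
            ]
            activated = prune_signal_electrodes(sets)
            indices[p][es] = detect_bundle_threshold(
                activated,
                scan.array,
                scan.amplitude_grid,
                amplitude_indices=times.amplitude_indices,
                min_borders=config.min_borders,
                corner_rule=config.corner_rule,
            )
    rows = []
    for p in pvalues:
        det = BundleThresholds.from_indices(indices[p], scan.amplitude_grid)
        rep = compare_thresholds(det, reference, scan.amplitude_grid)
        rows.append(
            {
                "p_value": p,
                "fraction_within_one_step": rep.fraction_within_one_step,
                "fraction_exact": rep.fraction_exact,
                "n_compared": rep.n_compared,
            }
        )
    return pd.DataFrame(rows)


def recovery_experiment(
    scan: ScanSource,
    reference: BundleThresholds,
    config: DetectionConfig | None = None,
    subset_size: int | None = 15,
    n_subset_draws: int = 10,
    seed: int = 0,
) -> dict:
    """Full synthetic-recovery experiment in one streaming pass.

    Runs detection with all repeats and (optionally) on random repeat
    subsets, comparing each run to the reference thresholds.  Each
    stimulating electrode's block is obtained once and reused across the
    full run and every subset draw.  Returns the full-run
    :class:`AgreementReport` plus the per-draw subset fractions.
    """
    config = config or DetectionConfig()
    rng = np.random.default_rng(seed)
    draws = []
    if subset_size is not None:
        if not 2 <= subset_size <= scan.n_repeats:
            raise ValueError("subset_size must be in [2, n_repeats]")
        draws = [
            np.sort(rng.choice(scan.n_repeats, size=subset_size, replace=False))
            for _ in range(n_subset_draws)
        ]
    full_idx = np.empty(scan.n_stim, dtype=int)
    sub_idx = [np.empty(scan.n_stim, dtype=int) for _ in draws]
    for es in range(scan.n_stim):
        block = scan.get_block(es)
        full_idx[es] = detect_block(
            block, scan.sampling_rate, scan.array, scan.amplitude_grid, config
        )
        for d, rep in enumerate(draws):
            sub_idx[d][es] = detect_block(
                block[:, rep],
                scan.sampling_rate,
                scan.array,
                scan.amplitude_grid,
                config,
            )
    detected = BundleThresholds.from_indices(full_idx, scan.amplitude_grid)
    report = compare_thresholds(detected, reference, scan.amplitude_grid)
    subset_fractions = []
    for idx in sub_idx:
        det = BundleThresholds.from_indices(idx, scan.amplitude_grid)
        rep = compare_thresholds(det, reference, scan.amplitude_grid)
        subset_fractions.append(rep.fraction_within_one_step)
    result = {
        "detected": detected,
        "report": report,
        "subset_size": subset_size,
        "subset_fractions": subset_fractions,
    }
    if subset_fractions:
        arr = np.array(
            [np.nan if f is None else f for f in subset_fractions], dtype=float
        )
        result["subset_mean_fraction_within"] = float(np.nanmean(arr))
        result["subset_sd_fraction_within"] = float(np.nanstd(arr))
    return result
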