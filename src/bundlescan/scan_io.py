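"""Data model and on-disk container for single-electrode stimulation scans.

A scan is the raw material of bundle detection: every electrode of the
array is stimulated in turn at a ladder of current amplitudes, each
amplitude repeated many times, while voltages are recorded on the whole
array.  The in-memory model is a 5-D tensor ``V[es, a, r, er, t]``
(stimulating electrode, amplitude index, repeat, recording electrode,
sample).  On disk the tensor lives in a single HDF5 file chunked along
the stimulating-electrode axis so one electrode's block can stream
independently of the rest.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import h5py
import numpy as np
import pandas as pd

from .geometry import ElectrodeArray

#: Sentinel status for a stimulating electrode whose activated sets never
#: satisfy the border rule at any tested amplitude.  Deliberately not 0 and
#: not the maximum amplitude: "no bundle activation found in the tested
#: range" is a distinct outcome, not a threshold.
NOT_FOUND = "NOT_FOUND"

#: Integer sentinel used for threshold grid indices of undetected electrodes.
NOT_FOUND_INDEX = -1


# ---------------------------------------------------------------------------
# amplitude grid
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AmplitudeGrid:
    """Ordered ladder of stimulation current amplitudes in μA."""

    amplitudes: np.ndarray

    def __post_init__(self):
        amps = np.asarray(self.amplitudes, dtype=float)
        if amps.ndim != 1 or amps.size < 2:
            raise ValueError("amplitude grid must be a 1-D sequence of >= 2 levels")
        if not np.all(amps > 0):
            raise ValueError("all amplitudes must be positive")
        if not np.all(np.diff(amps) > 0):
            raise ValueError("amplitudes must be strictly increasing")
        object.__setattr__(self, "amplitudes", amps)

    @property
    def n_levels(self) -> int:
        return self.amplitudes.size

    @property
    def index_of_min(self) -> int:
        return 0

    def __len__(self) -> int:
        return self.n_levels

    def __getitem__(self, idx: int) -> float:
        return float(self.amplitudes[idx])

    @classmethod
    def geometric(
        cls, n_levels: int = 40, start: float = 0.1, ratio: float = 1.1
    ) -> "AmplitudeGrid":
        """Geometric ladder ``start * ratio**k``, k = 0..n_levels-1.

        The defaults reproduce the standard single-electrode scan
        protocol: 40 levels increasing by 10% per step from 0.1 μA, the
        last level rounding to 4.1 μA.
        """
        return cls(start * ratio ** np.arange(n_levels))


def default_scan_grid() -> AmplitudeGrid:
    """The 40-level, 10%-per-step, 0.1–4.1 μA scan grid."""
    return AmplitudeGrid.geometric()


# ---------------------------------------------------------------------------
# scan recording
# ---------------------------------------------------------------------------


@dataclass
class ScanRecording:
    """In-memory single-electrode stimulation scan.

    ``voltages`` has shape (n_stim, n_amplitudes, n_repeats,
    n_electrodes, n_samples) in μV.  Stimulating electrodes enumerate the
    array electrodes row-major, so axis 0 and axis 3 share the array's
    electrode indexing.
    """

    voltages: np.ndarray
    sampling_rate: float
    amplitude_grid: AmplitudeGrid
    array: ElectrodeArray
    stimulus_onset_sample: int = 0

    def __post_init__(self):
        self.voltages = np.asarray(self.voltages)
        self.validate()

    # scan-source protocol --------------------------------------------

    @property
    def n_stim(self) -> int:
        return self.voltages.shape[0]

    @property
    def n_repeats(self) -> int:
        return self.voltages.shape[2]

    @property
    def n_samples(self) -> int:
        return self.voltages.shape[4]

    def get_block(self, es: int) -> np.ndarray:
        """One stimulating electrode's (A, R, E, T) voltage block."""
        self.array.validate_indices([es])
        return self.voltages[es]

    # -----------------------------------------------------------------

    def validate(self) -> None:
        v = self.voltages
        if v.ndim != 5:
            raise ValueError(f"voltage tensor must be 5-D, got shape {v.shape}")
        n_stim, n_amp, n_rep, n_el, n_t = v.shape
        if n_rep < 1:
            raise ValueError("empty repeats axis")
        if n_amp != self.amplitude_grid.n_levels:
            raise ValueError(
                f"amplitude axis length {n_amp} does not match grid with "
                f"{self.amplitude_grid.n_levels} levels"
            )
        if n_el != self.array.n_electrodes or n_stim != self.array.n_electrodes:
            raise ValueError(
                f"tensor shape {v.shape} inconsistent with "
                f"{self.array.n_rows}x{self.array.n_cols} array "
                f"({self.array.n_electrodes} electrodes)"
            )
        if self.sampling_rate <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(v)):
            raise ValueError("voltage tensor contains non-finite values")


# ---------------------------------------------------------------------------
# detection configuration
# ---------------------------------------------------------------------------

_CORNER_RULES = ("literal", "two-electrode")


@dataclass(frozen=True)
class DetectionConfig:
    """Parameters of the bundle-detection algorithm.

    ``p_value`` is the algorithm's sole statistical hyperparameter: the
    level of the chi-squared test that separates time-locked (evoked)
    from random (spontaneous/noise) spike times.  The analysis window
    0.3–2 ms after the stimulus skips the large initial artifact while
    covering evoked latencies plus axonal propagation across the array.
    """

    p_value: float = 0.05
    window_start_ms: float = 0.3
    window_end_ms: float = 2.0
    min_borders: int = 2
    exclude_recording: frozenset[int] = frozenset()
    corner_rule: str = "literal"

    def __post_init__(self):
        if not 0 < self.p_value < 1:
            raise ValueError(f"p_value must lie in (0, 1), got {self.p_value}")
        if not self.window_start_ms < self.window_end_ms:
            raise ValueError("window_start_ms must be < window_end_ms")
        if self.min_borders < 2:
            raise ValueError("min_borders must be >= 2")
        if self.corner_rule not in _CORNER_RULES:
            raise ValueError(
                f"corner_rule must be one of {_CORNER_RULES}, got {self.corner_rule!r}"
            )
        object.__setattr__(
            self, "exclude_recording", frozenset(int(e) for e in self.exclude_recording)
        )

    def window_samples(self, sampling_rate: float) -> tuple[int, int]:
        """Inclusive (first, last) sample indices of the analysis window.

        ``[ceil(start*fs), floor(end*fs)]`` — e.g. samples 6..40 at
        20 kHz, i.e. 35 candidate spike-time samples.  A small epsilon
        guards against float round-off at exact sample boundaries.
        """
        lo = math.ceil(self.window_start_ms * 1e-3 * sampling_rate - 1e-9)
        hi = math.floor(self.window_end_ms * 1e-3 * sampling_rate + 1e-9)
        if hi <= lo:
            raise ValueError(
                f"analysis window [{self.window_start_ms}, {self.window_end_ms}] ms "
                f"contains fewer than 2 samples at {sampling_rate} Hz"
            )
        return lo, hi

    def to_dict(self) -> dict:
        return {
            "p_value": self.p_value,
            "window_start_ms": self.window_start_ms,
            "window_end_ms": self.window_end_ms,
            "min_borders": self.min_borders,
            "exclude_recording": sorted(self.exclude_recording),
            "corner_rule": self.corner_rule,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DetectionConfig":
        known = {
            "p_value",
            "window_start_ms",
            "window_end_ms",
            "min_borders",
            "exclude_recording",
            "corner_rule",
        }
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown detection config keys: {sorted(unknown)}")
        kwargs = dict(d)
        if "exclude_recording" in kwargs:
            kwargs["exclude_recording"] = frozenset(kwargs["exclude_recording"])
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# thresholds
# ---------------------------------------------------------------------------


@dataclass
class BundleThresholds:
    """Per-stimulating-electrode bundle activation thresholds.

    ``indices`` holds the grid index of the detected threshold, or
    ``NOT_FOUND_INDEX`` (-1) where no tested amplitude satisfied the
    border rule; ``amplitudes_ua`` holds the corresponding current in μA
    (NaN where not found).
    """

    electrodes: np.ndarray
    indices: np.ndarray
    amplitudes_ua: np.ndarray

    def __post_init__(self):
        self.electrodes = np.asarray(self.electrodes, dtype=int)
        self.indices = np.asarray(self.indices, dtype=int)
        self.amplitudes_ua = np.asarray(self.amplitudes_ua, dtype=float)
        if not (
            self.electrodes.shape == self.indices.shape == self.amplitudes_ua.shape
        ):
            raise ValueError("threshold arrays must share one shape")

    @classmethod
    def from_indices(
        cls, indices: Iterable[int], grid: AmplitudeGrid
    ) -> "BundleThresholds":
        idx = np.asarray(list(indices), dtype=int)
        amps = np.where(
            idx >= 0, grid.amplitudes[np.clip(idx, 0, grid.n_levels - 1)], np.nan
        )
        return cls(np.arange(idx.size), idx, amps)

    @property
    def detected(self) -> np.ndarray:
        return self.indices != NOT_FOUND_INDEX

    @property
    def n_detected(self) -> int:
        return int(self.detected.sum())

    def __len__(self) -> int:
        return self.electrodes.size

    def to_frame(self) -> pd.DataFrame:
        status = np.where(self.detected, "detected", NOT_FOUND)
        return pd.DataFrame(
            {
                "stim_electrode": self.electrodes,
                "threshold_uA": self.amplitudes_ua,
                "threshold_index": self.indices,
                "status": status,
            }
        )

    def summary(self) -> dict:
        return {
            "n_electrodes": int(len(self)),
            "n_detected": self.n_detected,
            "n_not_found": int(len(self)) - self.n_detected,
        }


def write_thresholds(
    thresholds: BundleThresholds,
    path: str | Path,
    summary_path: str | Path | None = None,
    extra_summary: dict | None = None,
) -> None:
    """Write a threshold table as CSV plus an optional JSON summary."""
    df = thresholds.to_frame()
    df.to_csv(path, index=False, float_format="%.10g")
    if summary_path is not None:
        payload = thresholds.summary()
        if extra_summary:
            payload.update(extra_summary)
        Path(summary_path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_thresholds(path: str | Path) -> BundleThresholds:
    df = pd.read_csv(path)
    required = {"stim_electrode", "threshold_uA", "threshold_index", "status"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"threshold table missing columns: {sorted(missing)}")
    return BundleThresholds(
        df["stim_electrode"].to_numpy(),
        df["threshold_index"].to_numpy(),
        df["threshold_uA"].to_numpy(),
    )


# ---------------------------------------------------------------------------
# HDF5 container
# ---------------------------------------------------------------------------


def write_scan(scan: ScanRecording, path: str | Path) -> None:
    """Write a scan to a single HDF5 container.

    Layout: dataset ``/voltages`` chunked along the stimulating-electrode
    axis (one chunk per stimulating electrode, so a block streams
    independently), dataset ``/amplitudes``, and root attributes
    ``sampling_rate``, ``stimulus_onset_sample`` and ``geometry`` (JSON).
    """
    scan.validate()
    v = scan.voltages
    chunk = (1,) + v.shape[1:]
    with h5py.File(path, "w") as f:
        f.create_dataset("voltages", data=v, chunks=chunk)
        f.create_dataset("amplitudes", data=scan.amplitude_grid.amplitudes)
        f.attrs["sampling_rate"] = float(scan.sampling_rate)
        f.attrs["stimulus_onset_sample"] = int(scan.stimulus_onset_sample)
        f.attrs["geometry"] = scan.array.to_json()


def read_scan(path: str | Path) -> ScanRecording:
    """Read a scan container written by :func:`write_scan`.

    Round-trips the voltage tensor bit-exactly at its stored precision.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"scan container not found: {path}")
    with h5py.File(path, "r") as f:
        for name in ("voltages", "amplitudes"):
            if name not in f:
                raise ValueError(f"scan container {path} is missing dataset /{name}")
        for attr in ("sampling_rate", "geometry"):
            if attr not in f.attrs:
                raise ValueError(f"scan container {path} is missing attribute {attr}")
        v = f["voltages"][...]
        grid = AmplitudeGrid(f["amplitudes"][...])
        array = ElectrodeArray.from_json(f.attrs["geometry"])
        if v.ndim != 5:
            raise ValueError(f"/voltages must be 5-D, got shape {v.shape}")
        if v.shape[2] == 0:
            raise ValueError("empty repeats axis")
        if v.shape[0] != array.n_electrodes or v.shape[3] != array.n_electrodes:
            raise ValueError(
                f"geometry descriptor ({array.n_rows}x{array.n_cols}, "
                f"{array.n_electrodes} electrodes) disagrees with voltage tensor "
                f"shape {v.shape}"
            )
        return ScanRecording(
            voltages=v,
            sampling_rate=float(f.attrs["sampling_rate"]),
            amplitude_grid=grid,
            array=array,
            stimulus_onset_sample=int(f.attrs["stimulus_onset_sample"]),
        )
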