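"""Synthetic single-electrode stimulation scans with ground truth.

The generator implements the additive decomposition of an extracellular
recording during epiretinal stimulation, ``y = x + i + s + n``:

* ``x`` — evoked axonal activity: each stimulating electrode owns a
  straight axon-bundle path through its site at a random orientation.
  A bundle spike propagates bidirectionally from the stimulation site,
  reaching every electrode within a capture radius of the path with
  latency = base latency + distance/velocity + sub-sample jitter, and
  appearing as a negative-peaked spike waveform.  Whether the bundle
  fires on a given repeat follows a sigmoidal activation probability in
  amplitude, with a monotone coupling (one uniform draw per repeat,
  shared across amplitudes) so that per-repeat activation is
  non-decreasing in current.
* ``i`` — stimulation artifact: a repeat-independent damped oscillatory
  transient, scaled linearly with current amplitude and spatially
  attenuated with distance from the stimulating electrode.
* ``s`` — spontaneous activity: per-electrode Poisson spikes at times
  unrelated to the stimulus.
* ``n`` — zero-mean Gaussian noise.

Every stimulating electrode's block is generated independently and
deterministically from (seed, electrode), so scans too large to hold in
memory stream one block at a time through :class:`SimulatedScan`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .geometry import ElectrodeArray, make_array
from .scan_io import (
    AmplitudeGrid,
    BundleThresholds,
    DetectionConfig,
    ScanRecording,
    default_scan_grid,
)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic scan generator.

    Defaults describe a moderate-fidelity healthy-retina preparation on
    a 16x16 patch of a 60 μm lattice sampled at 20 kHz: 40 amplitude
    levels (+10% per step from 0.1 μA), 25 repeats per level, ~0.05 ms
    evoked latency jitter, 5 μV recording noise and 5 Hz spontaneous
    firing.  The activation sigmoid is steep on the 10%-per-step grid
    (slope 0.12 index units), so the bundle goes from rarely to almost
    always firing within about one amplitude step.
    """

    n_rows: int = 16
    n_cols: int = 16
    pitch_um: float = 60.0
    amplitude_grid: AmplitudeGrid = field(default_factory=default_scan_grid)
    n_repeats: int = 25
    sampling_rate: float = 20000.0
    n_samples: int = 48
    # evoked component x
    spike_amplitude_uv: float = 90.0
    spike_width_ms: float = 0.05
    conduction_velocity_m_s: float = 1.0
    base_latency_ms: float = 0.5
    jitter_ms: float = 0.05
    activation_slope: float = 0.12
    activation_certainty: float = 0.95
    threshold_index_range: tuple[int, int] = (10, 30)
    capture_radius_um: float = 45.0
    # artifact component i
    artifact_amplitude_uv_per_ua: float = 2000.0
    artifact_tau_ms: float = 0.05
    artifact_freq_hz: float = 2000.0
    # spontaneous component s
    spontaneous_rate_hz: float = 5.0
    spontaneous_amplitude_uv: float = 70.0
    # noise component n
    noise_uv: float = 5.0
    # optional somatic (local, unidirectional) response
    somatic: bool = False
    somatic_radius_um: float = 90.0
    somatic_offset_steps: int = -6
    somatic_latency_ms: float = 0.45
    somatic_amplitude_uv: float = 150.0
    seed: int = 7

    def __post_init__(self):
        if self.jitter_ms < 0:
            raise ValueError("jitter must be non-negative")
        if self.activation_slope < 0:
            raise ValueError("activation slope must be non-negative")
        lo, hi = self.threshold_index_range
        if not (1 <= lo <= hi < self.amplitude_grid.n_levels):
            raise ValueError(
                "threshold_index_range must lie within [1, n_levels-1] "
                "(index 0 is the artifact reference amplitude)"
            )
        if not 0 < self.activation_certainty <= 1:
            raise ValueError("activation_certainty must lie in (0, 1]")

    @classmethod
    def clean(cls, **overrides) -> "SimulationConfig":
        """Small, effectively noiseless configuration.

        Step-function activation, zero jitter, no spontaneous spikes, no
        stimulation artifact, and a 0.5 μV noise floor (a strictly zero
        noise floor is degenerate: with constant traces every argmin
        ties, every electrode looks perfectly time-locked, and the
        variance test loses its null).  This isolates the evoked
        component ``x``; detection under the two-electrode corner rule
        recovers the ground-truth thresholds exactly.
        """
        defaults = dict(
            n_rows=8,
            n_cols=8,
            amplitude_grid=AmplitudeGrid.geometric(n_levels=12),
            n_repeats=10,
            threshold_index_range=(3, 9),
            jitter_ms=0.0,
            activation_slope=0.0,
            activation_certainty=1.0,
            spontaneous_rate_hz=0.0,
            artifact_amplitude_uv_per_ua=0.0,
            noise_uv=0.5,
        )
        defaults.update(overrides)
        return cls(**defaults)

    @classmethod
    def fixture(cls, seed: int = 7, **overrides) -> "SimulationConfig":
        """Small moderate-noise configuration for tests and demos."""
        defaults = dict(
            n_rows=8,
            n_cols=8,
            amplitude_grid=AmplitudeGrid.geometric(n_levels=12),
            n_repeats=10,
            threshold_index_range=(3, 9),
            seed=seed,
        )
        defaults.update(overrides)
        return cls(**defaults)


def validation_scan_config(seed: int = 7) -> SimulationConfig:
    """The packaged synthetic validation scan: default conditions, 16x16
    array, full 40-level grid, 25 repeats, moderate noise/jitter/
    spontaneous activity."""
    return SimulationConfig(seed=seed)


@dataclass
class GroundTruth:
    """Simulator ground truth for validating detection.

    ``threshold_indices[es]`` is the lowest grid index at which the
    bundle's activation probability reaches the configured certainty
    level; ``activation[es, a, r]`` records whether the bundle fired on
    that repeat (non-decreasing in ``a`` for fixed ``r`` by monotone
    coupling); ``path_electrodes[es]`` lists electrodes within the
    capture radius of the axon path.
    """

    threshold_indices: np.ndarray
    threshold_ua: np.ndarray
    orientations: np.ndarray
    activation_prob: np.ndarray
    activation: np.ndarray
    path_electrodes: list[np.ndarray]
    grid: AmplitudeGrid

    def to_thresholds(self) -> BundleThresholds:
        return BundleThresholds.from_indices(self.threshold_indices, self.grid)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stim_electrode": np.arange(self.threshold_indices.size),
                "true_threshold_uA": self.threshold_ua,
                "true_index": self.threshold_indices,
            }
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")


def _spike_template(amplitude_uv: float, width_ms: float, fs: float) -> tuple[np.ndarray, int]:
    """Biphasic extracellular spike waveform; returns (template, peak offset)."""
    w = max(1, round(width_ms * 1e-3 * fs))
    k = np.arange(-2 * w, 4 * w + 1, dtype=float)
    wave = -amplitude_uv * np.exp(-0.5 * (k / w) ** 2)
    wave += 0.3 * amplitude_uv * np.exp(-0.5 * ((k - 2.5 * w) / (1.5 * w)) ** 2)
    return wave.astype(np.float32), 2 * w


def _place_spikes(
    v: np.ndarray,
    a_idx: np.ndarray,
    r_idx: np.ndarray,
    e_idx: np.ndarray,
    times: np.ndarray,
    template: np.ndarray,
    peak_offset: int,
) -> None:
    """Add a spike template into v[a, r, e, t-peak .. t-peak+L] in place."""
    n_t = v.shape[-1]
    length = template.size
    start = times - peak_offset
    valid = (start >= 0) & (start + length <= n_t)
    if not np.any(valid):
        return
    a_idx, r_idx, e_idx, start = (x[valid] for x in (a_idx, r_idx, e_idx, start))
    cols = start[:, None] + np.arange(length)
    np.add.at(
        v,
        (a_idx[:, None], r_idx[:, None], e_idx[:, None], cols),
        template[None, :],
    )


class SimulatedScan:
    """Lazy scan source: per-stimulating-electrode blocks on demand.

    Satisfies the detection module's scan-source protocol without ever
    materializing the full 5-D tensor, so full-array scans (hundreds of
    stimulating electrodes) stay within desk memory.  Blocks are
    deterministic functions of (config.seed, stimulating electrode).
    """

    def __init__(self, config: SimulationConfig):
        self.config = config
        self.array: ElectrodeArray = make_array(
            config.n_rows, config.n_cols, config.pitch_um
        )
        self.amplitude_grid = config.amplitude_grid
        self.sampling_rate = config.sampling_rate
        lo, hi = DetectionConfig().window_samples(config.sampling_rate)
        if config.n_samples <= hi:
            raise ValueError(
                f"trace length {config.n_samples} does not cover the analysis "
                f"window upper bound (sample {hi})"
            )
        self.ground_truth = self._draw_ground_truth()

    # -- scan-source protocol -----------------------------------------

    @property
    def n_stim(self) -> int:
        return self.array.n_electrodes

    @property
    def n_repeats(self) -> int:
        return self.config.n_repeats

    @property
    def n_samples(self) -> int:
        return self.config.n_samples

    # -- ground truth --------------------------------------------------

    def _activation_prob(self, k_star: np.ndarray) -> np.ndarray:
        """(S, A) activation probability, sigmoidal in grid index."""
        idx = np.arange(self.amplitude_grid.n_levels, dtype=float)
        mid = k_star[:, None] - 0.5
        if self.config.activation_slope == 0:
            return (idx[None, :] >= k_star[:, None]).astype(float)
        return expit((idx[None, :] - mid) / self.config.activation_slope)

    def _draw_ground_truth(self) -> GroundTruth:
        cfg = self.config
        rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 1)))
        n = self.n_stim
        lo, hi = cfg.threshold_index_range
        k_star = rng.integers(lo, hi + 1, size=n)
        orientations = rng.uniform(0.0, np.pi, size=n)
        prob = self._activation_prob(k_star)
        # certainty-level definition must agree with the drawn index
        reached = prob >= cfg.activation_certainty
        implied = np.argmax(reached, axis=1)
        assert np.array_equal(implied, k_star), (
            "activation sigmoid too shallow for the certainty level: "
            "the implied threshold disagrees with the drawn one"
        )
        u = rng.random(size=(n, cfg.n_repeats))
        activation = u[:, None, :] < prob[:, :, None]  # (S, A, R)
        paths = [self._path_electrodes(es, orientations[es]) for es in range(n)]
        return GroundTruth(
            threshold_indices=k_star,
            threshold_ua=self.amplitude_grid.amplitudes[k_star],
            orientations=orientations,
            activation_prob=prob,
            activation=activation,
            path_electrodes=paths,
            grid=self.amplitude_grid,
        )

    def _path_geometry(self, es: int, theta: float) -> tuple[np.ndarray, np.ndarray]:
        """Signed along-path and perpendicular distances (μm) from the
        stimulation site, for all electrodes."""
        pos = self.array.positions
        rel = pos - pos[es]
        direction = np.array([np.cos(theta), np.sin(theta)])
        s_par = rel @ direction
        d_perp = np.abs(rel[:, 0] * direction[1] - rel[:, 1] * direction[0])
        return s_par, d_perp

    def _path_electrodes(self, es: int, theta: float) -> np.ndarray:
        _, d_perp = self._path_geometry(es, theta)
        return np.flatnonzero(d_perp <= self.config.capture_radius_um)

    def _evoked_latency_samples(self, es: int) -> np.ndarray:
        """Mean evoked arrival time (samples) for the path electrodes."""
        cfg = self.config
        theta = self.ground_truth.orientations[es]
        s_par, _ = self._path_geometry(es, theta)
        path = self.ground_truth.path_electrodes[es]
        um_per_ms = cfg.conduction_velocity_m_s * 1000.0
        latency_ms = cfg.base_latency_ms + np.abs(s_par[path]) / um_per_ms
        return latency_ms * 1e-3 * cfg.sampling_rate

    # -- block synthesis ----------------------------------------------

    def get_block(self, es: int) -> np.ndarray:
        """Synthesize the (A, R, E, T) voltage block for one stimulating
        electrode."""
        cfg = self.config
        self.array.validate_indices([es])
        rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 2, es)))
        n_a = self.amplitude_grid.n_levels
        n_r, n_e, n_t = cfg.n_repeats, self.array.n_electrodes, cfg.n_samples

        # n: recording noise
        v = rng.standard_normal((n_a, n_r, n_e, n_t), dtype=np.float32)
        v *= np.float32(cfg.noise_uv)

        # i: repeat-independent damped oscillatory artifact
        t_ms = np.arange(n_t) / cfg.sampling_rate * 1e3
        waveform = np.exp(-t_ms / cfg.artifact_tau_ms) * np.cos(
            2 * np.pi * cfg.artifact_freq_hz * t_ms * 1e-3
        )
        dist = np.linalg.norm(
            self.array.positions - self.array.positions[es], axis=1
        )
        atten = 1.0 / (1.0 + (dist / cfg.pitch_um) ** 2)
        artifact = (
            cfg.artifact_amplitude_uv_per_ua
            * self.amplitude_grid.amplitudes[:, None, None]
            * atten[None, :, None]
            * waveform[None, None, :]
        ).astype(np.float32)
        v += artifact[:, None, :, :]

        # s: spontaneous Poisson spikes (at most one per trace; the trace
        # is ~2.4 ms so multi-spike traces are vanishingly rare at
        # physiological rates)
        p_spont = cfg.spontaneous_rate_hz * (n_t / cfg.sampling_rate)
        if p_spont > 0:
            template, peak = _spike_template(
                cfg.spontaneous_amplitude_uv, cfg.spike_width_ms, cfg.sampling_rate
            )
            mask = rng.random((n_a, n_r, n_e)) < p_spont
            a_i, r_i, e_i = np.nonzero(mask)
            times = rng.integers(0, n_t, size=a_i.size)
            _place_spikes(v, a_i, r_i, e_i, times, template, peak)

        # x: evoked bidirectional axonal spikes
        self._add_evoked(v, es, rng)

        if cfg.somatic:
            self._add_somatic(v, es, rng)
        return v

    def _add_evoked(self, v: np.ndarray, es: int, rng: np.random.Generator) -> None:
        cfg = self.config
        path = self.ground_truth.path_electrodes[es]
        if path.size == 0:
            return
        template, peak = _spike_template(
            cfg.spike_amplitude_uv, cfg.spike_width_ms, cfg.sampling_rate
        )
        mean_t = self._evoked_latency_samples(es)  # (n_path,)
        active = self.ground_truth.activation[es]  # (A, R)
        a_i, r_i = np.nonzero(active)
        if a_i.size == 0:
            return
        jitter_samples = cfg.jitter_ms * 1e-3 * cfg.sampling_rate
        for j, e in enumerate(path):
            t = np.full(a_i.size, mean_t[j])
            if jitter_samples > 0:
                t = t + rng.normal(0.0, jitter_samples, size=a_i.size)
            times = np.rint(t).astype(int)
            _place_spikes(
                v, a_i, r_i, np.full(a_i.size, e), times, template, peak
            )

    def _add_somatic(self, v: np.ndarray, es: int, rng: np.random.Generator) -> None:
        """Local unidirectional somatic response near the stimulation
        site, activating a few steps below the bundle threshold."""
        cfg = self.config
        dist = np.linalg.norm(
            self.array.positions - self.array.positions[es], axis=1
        )
        local = np.flatnonzero(dist <= cfg.somatic_radius_um)
        k_som = max(1, int(self.ground_truth.threshold_indices[es]) + cfg.somatic_offset_steps)
        template, peak = _spike_template(
            cfg.somatic_amplitude_uv, cfg.spike_width_ms, cfg.sampling_rate
        )
        t0 = cfg.somatic_latency_ms * 1e-3 * cfg.sampling_rate
        jitter_samples = cfg.jitter_ms * 1e-3 * cfg.sampling_rate
        n_a, n_r = self.amplitude_grid.n_levels, cfg.n_repeats
        a_i, r_i = np.nonzero(
            np.arange(n_a)[:, None] >= np.full((1, n_r), k_som)
        )
        for e in local:
            t = np.full(a_i.size, t0)
            if jitter_samples > 0:
                t = t + rng.normal(0.0, jitter_samples, size=a_i.size)
            times = np.rint(t).astype(int)
            _place_spikes(
                v, a_i, r_i, np.full(a_i.size, e), times, template, peak
            )

    # -- fast timing path ----------------------------------------------

    def simulate_spike_times(
        self,
        es: int,
        a_index: int,
        window: tuple[int, int] | None = None,
    ) -> np.ndarray:
        """Per-repeat, per-electrode spike-time draws, no waveforms.

        Distributionally matches the timing model of the full synthesis:
        path electrodes with an activated bundle get the jittered
        propagation latency; every other (repeat, electrode) draws
        uniformly over the analysis window, the model of an argmin
        driven by noise or spontaneous spikes.  Used to test the
        statistical stages (signal extraction, pruning, thresholding)
        without waveform synthesis.
        """
        cfg = self.config
        self.array.validate_indices([es])
        if not 0 <= a_index < self.amplitude_grid.n_levels:
            raise IndexError(f"amplitude index {a_index} outside the grid")
        if window is None:
            window = DetectionConfig().window_samples(cfg.sampling_rate)
        lo, hi = window
        rng = np.random.default_rng(
            np.random.SeedSequence((cfg.seed, 3, es, a_index))
        )
        n_r, n_e = cfg.n_repeats, self.array.n_electrodes
        times = rng.integers(lo, hi + 1, size=(n_r, n_e))
        path = self.ground_truth.path_electrodes[es]
        if path.size:
            mean_t = self._evoked_latency_samples(es)
            active = self.ground_truth.activation[es, a_index]  # (R,)
            jitter_samples = cfg.jitter_ms * 1e-3 * cfg.sampling_rate
            t = np.broadcast_to(mean_t, (n_r, path.size)).astype(float)
            if jitter_samples > 0:
                t = t + rng.normal(0.0, jitter_samples, size=t.shape)
            locked = np.clip(np.rint(t).astype(int), lo, hi)
            times[:, path] = np.where(active[:, None], locked, times[:, path])
        return times


def simulate_scan(config: SimulationConfig) -> tuple[ScanRecording, GroundTruth]:
    """Materialize a full synthetic scan in memory.

    Suitable for small configurations (the in-memory tensor is
    S·A·R·E·T floats); large scans should use :class:`SimulatedScan`
    and stream blocks instead.
    """
    sim = SimulatedScan(config)
    n_bytes = (
        4.0
        * sim.n_stim
        * config.amplitude_grid.n_levels
        * config.n_repeats
        * sim.array.n_electrodes
        * config.n_samples
    )
    if n_bytes > 2e9:
        raise MemoryError(
            f"materializing this scan needs ~{n_bytes / 1e9:.1f} GB; "
            "use SimulatedScan to stream per-electrode blocks instead"
        )
    voltages = np.stack([sim.get_block(es) for es in range(sim.n_stim)])
    scan = ScanRecording(
        voltages=voltages,
        sampling_rate=config.sampling_rate,
        amplitude_grid=config.amplitude_grid,
        array=sim.array,
    )
    return scan, sim.ground_truth


def simulate_spike_times(
    config: SimulationConfig,
    es: int,
    a_index: int,
    window: tuple[int, int] | None = None,
) -> np.ndarray:
    """Module-level convenience wrapper; see
    :meth:`SimulatedScan.simulate_spike_times`."""
    return SimulatedScan(config).simulate_spike_times(es, a_index, window)
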