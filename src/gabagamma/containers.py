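"""Shared data containers for the MEG/PET pipeline.

Conventions: SI units throughout the MEG path (metres, tesla, volts, seconds,
time 0 = stimulus onset); PET concentrations are in arbitrary activity units
(the same for free, bound and B'max); windows are half-open ``[start, end)``;
grid indices are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class GeometryError(ValueError):
    """Invalid spatial configuration (empty ROI, source outside sphere, ...)."""


# --------------------------------------------------------------------------
# MEG sensor space
# --------------------------------------------------------------------------

@dataclass
class HeadModel:
    """Spherical conductor head model with point magnetometers.

    ``sensor_positions``/``sensor_orientations`` are ``(n, 3)`` in metres /
    unit vectors; all source points must lie strictly inside the sensor shell.
    """

    sphere_center: np.ndarray
    sensor_positions: np.ndarray
    sensor_orientations: np.ndarray

    def __post_init__(self):
        self.sphere_center = np.asarray(self.sphere_center, float)
        self.sensor_positions = np.atleast_2d(np.asarray(self.sensor_positions, float))
        ori = np.atleast_2d(np.asarray(self.sensor_orientations, float))
        norms = np.linalg.norm(ori, axis=1, keepdims=True)
        if np.any(norms == 0):
            raise GeometryError("sensor orientation with zero norm")
        self.sensor_orientations = ori / norms

    @property
    def n_sensors(self) -> int:
        return self.sensor_positions.shape[0]


@dataclass
class SourceGrid:
    """Volumetric source grid (metres) with the V1 patch marked by index."""

    points: np.ndarray
    v1_indices: np.ndarray
    spacing_mm: float = 6.0

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, float))
        self.v1_indices = np.asarray(self.v1_indices, int)
        if self.spacing_mm <= 0:
            raise GeometryError("grid spacing must be positive")
        if self.v1_indices.size and (
            self.v1_indices.min() < 0 or self.v1_indices.max() >= len(self.points)
        ):
            raise GeometryError("v1_indices out of range")

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


@dataclass
class TrialSet:
    """Multi-trial MEG sensor epochs with a single EOG channel.

    ``data``: (trials, sensors, samples) in tesla; ``eog``: (trials, samples)
    in volts.  Epochs run from ``t0`` for ``samples / srate`` seconds.
    """

    data: np.ndarray
    eog: np.ndarray
    srate: float = 600.0
    t0: float = -0.2
    n_rejected: int = 0

    def __post_init__(self):
        self.data = np.asarray(self.data, float)
        self.eog = np.asarray(self.eog, float)
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, sensors, samples)")
        if self.eog.shape != (self.data.shape[0], self.data.shape[2]):
            raise ValueError("eog must be (trials, samples)")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_sensors(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.srate


# --------------------------------------------------------------------------
# Time-frequency grids
# --------------------------------------------------------------------------

@dataclass
class FrequencyGrid:
    """Analysis frequencies in Hz (strictly increasing)."""

    freqs: np.ndarray

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, float)
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequencies must be strictly increasing")

    @classmethod
    def default(cls) -> "FrequencyGrid":
        """Three-range layout: 4-15 Hz @ 0.25, 15-30 @ 0.5, 36-104 @ 2."""
        low = np.arange(4.0, 15.0, 0.25)
        mid = np.arange(15.0, 30.0 + 1e-9, 0.5)
        high = np.arange(36.0, 104.0 + 1e-9, 2.0)
        return cls(np.concatenate([low, mid, high]))

    @classmethod
    def gamma_only(cls, step: float = 2.0) -> "FrequencyGrid":
        """Gamma-range grid 36-104 Hz used for reduced-scale runs."""
        return cls(np.arange(36.0, 104.0 + 1e-9, step))

    def band_mask(self, lo: float, hi: float) -> np.ndarray:
        """Inclusive band membership mask."""
        return (self.freqs >= lo - 1e-9) & (self.freqs <= hi + 1e-9)

    def __len__(self) -> int:
        return len(self.freqs)


@dataclass
class TimeGrid:
    """Uniformly spaced analysis instants in seconds.

    The default spans -200 to ~800 ms at 1/60 s steps (ten samples at the
    600 Hz sampling rate, i.e. the conventional "17 ms" time bin).
    """

    instants: np.ndarray

    def __post_init__(self):
        self.instants = np.asarray(self.instants, float)
        d = np.diff(self.instants)
        if len(d) and not np.allclose(d, d[0]):
            raise ValueError("time instants must be uniformly spaced")

    @classmethod
    def default(cls, t_start: float = -0.2, t_stop: float = 0.8,
                step: float = 1.0 / 60.0) -> "TimeGrid":
        n = int(np.floor((t_stop - t_start) / step + 1e-9))
        return cls(t_start + step * np.arange(n))

    @property
    def step(self) -> float:
        return float(self.instants[1] - self.instants[0])

    def baseline_mask(self) -> np.ndarray:
        """Bins in the half-open baseline window [-0.2, 0) s."""
        return (self.instants >= -0.2 - 1e-9) & (self.instants < -1e-9)

    def window_mask(self, lo: float, hi: float) -> np.ndarray:
        """Inclusive window membership mask (seconds)."""
        return (self.instants >= lo - 1e-9) & (self.instants <= hi + 1e-9)

    def __len__(self) -> int:
        return len(self.instants)


@dataclass
class CSDSeries:
    """Time- and frequency-resolved sensor cross-spectral density.

    ``csd``: (freq, time, sensors, sensors), complex Hermitian per matrix.
    ``valid_freq`` flags frequencies whose wavelet support fits in the epoch.
    """

    csd: np.ndarray
    fgrid: FrequencyGrid
    tgrid: TimeGrid
    wavelet_width: float
    n_trials_used: int
    valid_freq: np.ndarray = None

    def __post_init__(self):
        if self.valid_freq is None:
            self.valid_freq = np.ones(len(self.fgrid), bool)


@dataclass
class SourcePower:
    """Beamformed source power, (grid points, freq, time), non-negative."""

    power: np.ndarray
    fgrid: FrequencyGrid
    tgrid: TimeGrid
    lam: float = 0.05
    smoothed: bool = False
    band_averaged: bool = False


@dataclass
class ResponseArray:
    """Baseline-referenced, normalized modulation (points, freq, time)."""

    data: np.ndarray
    fgrid: FrequencyGrid
    tgrid: TimeGrid
    v1_indices: np.ndarray
    mode: str = "absolute"

    def v1_mean(self) -> np.ndarray:
        """Mean modulation over V1 grid points, shape (freq, time)."""
        return self.data[self.v1_indices].mean(axis=0)


# --------------------------------------------------------------------------
# PET
# --------------------------------------------------------------------------

@dataclass
class PETGeometry:
    """Regular PET voxel lattice; world coordinates in mm, origin at corner."""

    shape: tuple
    voxel_size: np.ndarray

    def __post_init__(self):
        self.shape = tuple(int(s) for s in self.shape)
        self.voxel_size = np.asarray(self.voxel_size, float)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def voxel_centers(self, indices: np.ndarray) -> np.ndarray:
        """World-coordinate centres (mm) of flat voxel indices."""
        ijk = np.column_stack(np.unravel_index(np.asarray(indices, int), self.shape))
        return (ijk + 0.5) * self.voxel_size

    def world_to_voxel(self, xyz_mm: np.ndarray) -> np.ndarray:
        """Nearest voxel (i, j, k) for world coordinates in mm."""
        ijk = np.floor(np.atleast_2d(xyz_mm) / self.voxel_size).astype(int)
        return np.clip(ijk, 0, np.asarray(self.shape) - 1)


@dataclass
class PETDynamic:
    """Dynamic PET acquisition: (frames, x, y, z) plus ROI voxel-index sets.

    ``frame_times`` are (start, end) pairs in minutes post-injection.  ROI
    sets (``roi_pons``, ``roi_occipital``, ``v1_voxels``) are flat voxel
    indices into the spatial volume and must be pairwise disjoint.
    """

    frames: np.ndarray
    frame_times: np.ndarray
    geometry: PETGeometry
    roi_pons: np.ndarray
    roi_occipital: np.ndarray
    v1_voxels: np.ndarray

    def __post_init__(self):
        self.frames = np.asarray(self.frames, float)
        self.frame_times = np.asarray(self.frame_times, float)
        for name in ("roi_pons", "roi_occipital", "v1_voxels"):
            setattr(self, name, np.asarray(getattr(self, name), int))
        if self.frames.ndim != 4:
            raise ValueError("frames must be (F, X, Y, Z)")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("non-finite PET intensities")
        pons, occ = set(self.roi_pons), set(self.roi_occipital)
        if pons & occ:
            raise GeometryError("pons and occipital ROIs overlap")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class StaticImage:
    """Summed late-frame PET volume (concentration x n_frames_summed)."""

    values: np.ndarray
    geometry: PETGeometry
    frames_summed: tuple  # 1-based inclusive frame labels, e.g. (8, 12)

    @property
    def n_frames_summed(self) -> int:
        return self.frames_summed[1] - self.frames_summed[0] + 1


@dataclass
class ScatchardFit:
    """Partial-saturation Scatchard calibration (per-frame concentration units)."""

    free_conc: float
    kd_app: float
    fit_r2: float

    def __post_init__(self):
        if not (self.free_conc > 0 and self.kd_app > 0):
            raise ValueError("free_conc and kd_app must be positive")


@dataclass
class BmaxMap:
    """Voxelwise GABA_A receptor density (B'max) parametric image."""

    values: np.ndarray
    geometry: PETGeometry
    smoothed: bool = False
    fwhm_mm: tuple = None
    n_clipped: int = 0
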