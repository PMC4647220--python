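"""Synthetic cohort generator with known GABA_A-gamma coupling.

Every downstream stage of the pipeline (beamforming, peak extraction, B'max
estimation, correlation statistics) is testable by parameter recovery against
the ground truth emitted here.  A cohort couples each subject's V1 gamma peak
frequency (positively) and gamma amplitude (negatively) to the subject's
total V1 GABA_A receptor density B'max, with configurable residual noise.

The MEG simulator produces multi-trial sensor epochs: a Gaussian-envelope
gamma burst at the subject's peak frequency (centred at the subject's
latency), ongoing alpha/beta rhythms attenuated post-stimulus, spatially
correlated pink sensor noise projected from random interior dipoles, and
blink-contaminated trials carrying a large EOG deflection plus a frontal
field artifact.

The PET simulator produces a 12-frame dynamic acquisition under an
instantaneous-equilibrium partial-saturation model: the free ligand
concentration decays over the early frames and plateaus over the late frames
(20-55 min), the bound concentration follows the saturation curve
``B = B'max * F / (F + Kd)``, pons voxels carry no specific binding, and the
occipital/V1 voxels carry the cohort's highest densities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .containers import GeometryError, HeadModel, PETDynamic, SourceGrid, TrialSet
from .forward import project_dipole, _tangential_basis
from .geometry import CohortGeometry

logger = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    pass


# population constants of the generator (concentration units are arbitrary
# but shared between free, bound, Kd and B'max)
BMAX_OCC_RANGE = (18.0, 42.0)   # per-voxel occipital/V1 B'max across subjects
BMAX_BACKGROUND = 12.0          # mean background (non-occipital) B'max
FREQ_CENTER = 65.0              # Hz, population centre of gamma peak frequency
AMP_CENTER = 1.0                # normalized gamma source amplitude
DIPOLE_MOMENT = 20e-9           # A m, total V1 source strength at amplitude 1


@dataclass
class CohortConfig:
    """Generative parameters of one synthetic cohort.

    ``coupling_freq``/``coupling_amp`` are the slopes of gamma peak frequency
    (Hz) and amplitude (normalized units) on total V1 B'max; the residual
    SDs set how far the truth-level correlations are from +/-1.
    """

    n_subjects: int = 10
    coupling_freq: float = 0.0
    coupling_amp: float = 0.0
    noise_sd_freq: float = 8.0
    noise_sd_amp: float = 0.22
    gamma_freq_range: tuple = (45.0, 85.0)
    blink_rate: float = 0.1
    seed: int = 0
    free_conc: float = 10.0
    kd_app: float = 10.0
    pet_noise_pct: float = 0.05

    def __post_init__(self):
        if self.n_subjects < 3:
            raise ConfigurationError("n_subjects must be >= 3")
        lo, hi = self.gamma_freq_range
        if not (40.0 <= lo < hi <= 100.0):
            raise ConfigurationError("gamma_freq_range must lie within [40, 100] Hz")
        if not 0.0 <= self.blink_rate <= 1.0:
            raise ConfigurationError("blink_rate must be in [0, 1]")

    @classmethod
    def calibrated(cls, geometry: CohortGeometry, target_pearson: float = 0.75,
                   freq_span: float = 34.0, amp_span: float = 0.8,
                   **kwargs) -> "CohortConfig":
        """Config whose truth-level feature-density correlation is ~``target_pearson``.

        The per-voxel occipital B'max is uniform over :data:`BMAX_OCC_RANGE`,
        so the coupled part of each feature spans ``freq_span`` Hz (resp.
        ``amp_span`` units); the residual SD is set from the target Pearson
        correlation of a signal-plus-independent-noise pair.
        """
        n_v1 = geometry.n_v1_pet
        width = (BMAX_OCC_RANGE[1] - BMAX_OCC_RANGE[0]) * n_v1  # span of totals
        noise_factor = np.sqrt(1.0 / target_pearson**2 - 1.0)
        return cls(
            coupling_freq=freq_span / width,
            coupling_amp=-amp_span / width,
            noise_sd_freq=freq_span / np.sqrt(12.0) * noise_factor,
            noise_sd_amp=amp_span / np.sqrt(12.0) * noise_factor,
            **kwargs,
        )


@dataclass
class SubjectTruth:
    """Latent generative parameters for one synthetic subject."""

    subject_id: str
    gamma_peak_freq: float      # Hz
    gamma_amp: float            # normalized units
    gamma_latency: float        # s post-stimulus
    alpha_supp: float
    beta_supp: float
    bmax_field: np.ndarray      # voxelwise true B'max, PET volume shape
    kd_app: float
    free_conc: float
    v1_surface_area: float      # mm^2
    gm_density: float           # fraction in [0, 1]

    @property
    def total_v1_bmax(self) -> float:
        raise AttributeError("use truth_total_v1_bmax(subject, geometry)")


def truth_total_v1_bmax(subject: SubjectTruth, geometry: CohortGeometry) -> float:
    """Ground-truth total B'max over the V1 PET voxel set."""
    return float(subject.bmax_field.ravel()[geometry.v1_pet].sum())


def _bmax_field(rng, geometry: CohortGeometry, bmax_occ: float) -> np.ndarray:
    """Background + occipital B'max volume; pons voxels carry no binding."""
    pet = geometry.pet
    rough = rng.standard_normal(pet.shape)
    smooth = ndimage.gaussian_filter(rough, 1.5)
    smooth /= max(smooth.std(), 1e-12)
    # background: cohort-level mean, small per-subject offset, smooth texture
    # (kept small so that smoothing-induced mixing of background into the V1
    # aggregate stays subdominant to the occipital density contrast)
    level = BMAX_BACKGROUND * (1.0 + 0.05 * rng.uniform(-1, 1))
    field = level * (1.0 + 0.08 * smooth)
    field = np.clip(field, 0.0, None).ravel()
    field[geometry.v1_pet] = bmax_occ
    field[geometry.roi_occipital] = bmax_occ
    field[geometry.roi_pons] = 0.0
    return field.reshape(pet.shape)


def make_cohort(config: CohortConfig, geometry: CohortGeometry) -> list:
    """Draw ``config.n_subjects`` ground-truth subjects (seeded, deterministic)."""
    rng = np.random.default_rng(config.seed)
    n_v1 = geometry.n_v1_pet
    mean_total = 0.5 * (BMAX_OCC_RANGE[0] + BMAX_OCC_RANGE[1]) * n_v1
    subjects = []
    for i in range(config.n_subjects):
        bmax_occ = rng.uniform(*BMAX_OCC_RANGE)
        total = bmax_occ * n_v1
        freq = (FREQ_CENTER + config.coupling_freq * (total - mean_total)
                + rng.normal(0.0, config.noise_sd_freq))
        freq = float(np.clip(freq, *config.gamma_freq_range))
        amp = (AMP_CENTER + config.coupling_amp * (total - mean_total)
               + rng.normal(0.0, config.noise_sd_amp))
        amp = float(np.clip(amp, 0.05, None))
        subjects.append(SubjectTruth(
            subject_id=f"S{i + 1:02d}",
            gamma_peak_freq=freq,
            gamma_amp=amp,
            gamma_latency=float(np.clip(rng.normal(0.30, 0.03), 0.20, 0.45)),
            alpha_supp=float(rng.uniform(0.3, 0.7)),
            beta_supp=float(rng.uniform(0.3, 0.7)),
            bmax_field=_bmax_field(rng, geometry, bmax_occ),
            kd_app=config.kd_app,
            free_conc=config.free_conc,
            v1_surface_area=float(rng.normal(2000.0, 250.0)),
            gm_density=float(rng.uniform(0.55, 0.80)),
        ))
    return subjects


# --------------------------------------------------------------------------
# MEG simulation
# --------------------------------------------------------------------------

def _pink_noise(rng, n_series: int, n_samples: int, srate: float) -> np.ndarray:
    """1/f-amplitude noise series, unit variance each."""
    n_fft = n_samples
    freqs = np.fft.rfftfreq(n_fft, 1.0 / srate)
    shaping = np.zeros_like(freqs)
    shaping[1:] = 1.0 / np.sqrt(freqs[1:])
    spec = (rng.standard_normal((n_series, len(freqs)))
            + 1j * rng.standard_normal((n_series, len(freqs)))) * shaping
    x = np.fft.irfft(spec, n=n_fft, axis=1)
    x /= x.std(axis=1, keepdims=True)
    return x


def _blink_waveform(times: np.ndarray, onset: float) -> np.ndarray:
    """Stereotyped ~300 ms biphasic blink, peak amplitude 1."""
    w = (np.exp(-((times - onset) ** 2) / (2 * 0.05**2))
         - 0.35 * np.exp(-((times - onset - 0.12) ** 2) / (2 * 0.07**2)))
    return w / np.abs(w).max()


def simulate_meg_recording(subject: SubjectTruth, head: HeadModel,
                           grid: SourceGrid, n_trials: int = 200,
                           rng=None, *, blink_rate: float = 0.1,
                           snr: float = 4.0, return_parts: bool = False):
    """Forward-project V1 oscillatory sources into noisy sensor epochs.

    ``snr`` is the ratio of the sensor-RMS of a unit-amplitude reference
    gamma burst to the sensor noise RMS; it is deliberately *not* scaled by
    the subject's own amplitude, so that inter-subject amplitude differences
    survive into the recordings.  Blink trials (fraction ``blink_rate``)
    carry an EOG deflection exceeding 150 uV plus a frontal field artifact.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if grid.v1_indices.size == 0:
        raise GeometryError("empty V1 index set")
    n_samples = round(1.0 * 600)
    srate = 600.0
    times = -0.2 + np.arange(n_samples) / srate

    # fixed tangential orientation per V1 point; combined patch topography
    topo = np.zeros(head.n_sensors)
    for idx in grid.v1_indices:
        p = grid.points[idx]
        e1, _ = _tangential_basis(p - head.sphere_center)
        topo += project_dipole(np.ones(1), e1, p, head)[:, 0]
    topo /= len(grid.v1_indices)

    # source time courses (A m)
    f_g, lat = subject.gamma_peak_freq, subject.gamma_latency
    env_gamma = np.exp(-((times - lat) ** 2) / (2 * 0.07**2))
    ramp_a = np.exp(-((times - 0.40) ** 2) / (2 * 0.15**2))
    ramp_b = np.exp(-((times - 0.35) ** 2) / (2 * 0.12**2))

    phases = rng.uniform(0, 2 * np.pi, size=(3, n_trials, 1))
    ref_burst = DIPOLE_MOMENT * env_gamma  # unit-amplitude reference envelope
    moments = DIPOLE_MOMENT * (
        subject.gamma_amp * env_gamma * np.cos(2 * np.pi * f_g * times + phases[0])
        + 0.8 * (1 - subject.alpha_supp * ramp_a) * np.cos(2 * np.pi * 10.5 * times + phases[1])
        + 0.5 * (1 - subject.beta_supp * ramp_b) * np.cos(2 * np.pi * 20.0 * times + phases[2])
    )                                           # (trials, samples)
    signal = topo[None, :, None] * moments[:, None, :]

    # spatially correlated pink noise from random interior dipoles
    n_noise = 30
    radii = 0.060 * rng.uniform(0.3, 1.0, n_noise) ** (1 / 3)
    dirs = rng.standard_normal((n_noise, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    noise_pos = radii[:, None] * dirs + head.sphere_center
    noise_topo = np.empty((n_noise, head.n_sensors))
    for i, p in enumerate(noise_pos):
        e1, e2 = _tangential_basis(p - head.sphere_center)
        ori = np.cos(a := rng.uniform(0, 2 * np.pi)) * e1 + np.sin(a) * e2
        noise_topo[i] = project_dipole(np.ones(1), ori, p, head)[:, 0]
    series = _pink_noise(rng, n_noise * n_trials, n_samples, srate)
    series = series.reshape(n_trials, n_noise, n_samples)
    noise = np.einsum("ns,tnm->tsm", noise_topo, series) * DIPOLE_MOMENT
    noise += 0.02 * noise.std() * rng.standard_normal(noise.shape)

    # scale noise to the requested reference SNR
    ref_rms = np.sqrt(np.mean((topo[:, None] * ref_burst[None, :]) ** 2) / 2.0)
    noise *= ref_rms / (snr * noise.std())

    # EOG channel and blink artifacts
    eog = 15e-6 * rng.standard_normal((n_trials, n_samples))
    blink_mask = rng.random(n_trials) < blink_rate
    frontal = project_dipole(np.ones(1), np.array([1.0, 0, 0]),
                             np.array([0.0, 0.06, 0.03]), head)[:, 0]
    data = signal + noise
    for t in np.nonzero(blink_mask)[0]:
        onset = rng.uniform(-0.1, 0.6)
        wave = _blink_waveform(times, onset)
        eog[t] += 250e-6 * wave
        data[t] += 3.0 * DIPOLE_MOMENT * frontal[:, None] * wave[None, :]

    trials = TrialSet(data, eog, srate=srate, t0=-0.2)
    if return_parts:
        return trials, signal, noise
    return trials


# --------------------------------------------------------------------------
# PET simulation
# --------------------------------------------------------------------------

# frame start/end times in minutes; frames 8-12 cover 20-55 min post-injection
FRAME_TIMES = np.array([
    (0, 2), (2, 4), (4, 7), (7, 10), (10, 13), (13, 16), (16, 20),
    (20, 27), (27, 34), (34, 41), (41, 48), (48, 55),
], dtype=float)


def free_ligand_curve(t_min: np.ndarray, free_conc: float) -> np.ndarray:
    """Free ligand concentration vs time: early decay, exact plateau >= 20 min."""
    t = np.asarray(t_min, float)
    return np.where(t < 20.0, free_conc * (1.0 + 2.0 * np.exp(-t / 5.0)), free_conc)


def simulate_pet_dynamic(subject: SubjectTruth, geometry: CohortGeometry,
                         rng=None, noise_pct: float = 0.05) -> PETDynamic:
    """Dynamic frames under instantaneous-equilibrium partial saturation.

    Per frame, voxel intensity is ``F_t + bmax * F_t / (F_t + Kd)`` plus
    Gaussian noise with SD ``noise_pct * free_conc``.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    pet = geometry.pet
    mids = FRAME_TIMES.mean(axis=1)
    F_t = free_ligand_curve(mids, subject.free_conc)
    bmax = subject.bmax_field
    frames = np.empty((len(F_t),) + pet.shape)
    for i, F in enumerate(F_t):
        bound = bmax * F / (F + subject.kd_app)
        frames[i] = F + bound
    if noise_pct > 0:
        frames += noise_pct * subject.free_conc * rng.standard_normal(frames.shape)
    return PETDynamic(frames, FRAME_TIMES, pet, geometry.roi_pons,
                      geometry.roi_occipital, geometry.v1_pet)


def simulate_gm_map(subject: SubjectTruth, geometry: CohortGeometry,
                    rng=None, noise_sd: float = 0.02) -> np.ndarray:
    """Gray-matter fraction volume with the subject's V1 mean density."""
    if rng is None:
        rng = np.random.default_rng(0)
    g = subject.gm_density + noise_sd * ndimage.gaussian_filter(
        rng.standard_normal(geometry.pet.shape), 1.0)
    return np.clip(g, 0.0, 1.0)
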