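"""Sensor-to-source chain: trial rejection, Morlet CSD, DICS beamformer,
temporal smoothing, gamma band averaging, baseline normalization."""

import numpy as np
import pytest
from scipy import stats

from gabagamma.containers import FrequencyGrid, TimeGrid, TrialSet
from gabagamma.forward import leadfield
from gabagamma.meg_source_power import (ArtifactRejectionError,
                                        band_average_high, dics_power,
                                        morlet_coefficients, morlet_csd,
                                        moving_average_shrink,
                                        normalize_and_modulate,
                                        reject_artifact_trials,
                                        temporal_smooth)
from gabagamma.synthetic_cohort import simulate_meg_recording

from conftest import make_tone_trials


# ------------------------------------------------------------------ rejection

def test_rejection_identity_on_clean_eog():
    tr = make_tone_trials(n_trials=5)
    kept = reject_artifact_trials(tr)
    assert kept.n_trials == 5 and kept.n_rejected == 0


def test_rejection_removes_spiking_trial():
    tr = make_tone_trials(n_trials=5)
    tr.eog[2, 100] = 200e-6
    kept = reject_artifact_trials(tr)
    assert kept.n_trials == 4 and kept.n_rejected == 1
    np.testing.assert_array_equal(kept.data, tr.data[[0, 1, 3, 4]])


def test_rejection_all_trials_is_hard_error():
    tr = make_tone_trials(n_trials=3)
    tr.eog += 1e-3
    with pytest.raises(ArtifactRejectionError, match="150"):
        reject_artifact_trials(tr)


def test_rejection_rate_matches_blink_rate(geom, cohort):
    _, subjects = cohort
    tr = simulate_meg_recording(subjects[1], geom.head, geom.grid,
                                n_trials=200, rng=np.random.default_rng(9),
                                blink_rate=0.2)
    kept = reject_artifact_trials(tr)
    lo, hi = stats.binom.ppf([0.005, 0.995], 200, 0.2)
    assert lo <= kept.n_rejected <= hi


# ------------------------------------------------------------------ CSD

@pytest.fixture(scope="module")
def gamma_grids():
    return FrequencyGrid.gamma_only(4.0), TimeGrid.default()


def test_csd_diagonal_peaks_at_tone_frequency(gamma_grids):
    fg, tg = gamma_grids
    csd = morlet_csd(make_tone_trials(freq=64.0, n_sensors=1), fg, tg)
    psd = np.real(csd.csd[:, len(tg) // 2, 0, 0])
    assert fg.freqs[np.argmax(psd)] == 64.0


def test_csd_hermitian(geom, cohort, gamma_grids):
    _, subjects = cohort
    fg, tg = gamma_grids
    tr = simulate_meg_recording(subjects[0], geom.head, geom.grid, n_trials=4,
                                rng=np.random.default_rng(1))
    csd = morlet_csd(tr, fg, tg)
    herm = np.conj(np.swapaxes(csd.csd, -1, -2))
    assert np.max(np.abs(csd.csd - herm)) == 0.0


def test_identical_sensors_have_unit_coherence(gamma_grids):
    fg, tg = gamma_grids
    rng = np.random.default_rng(0)
    x = 1e-13 * rng.standard_normal((8, 1, 600))
    tr = TrialSet(np.repeat(x, 2, axis=1), np.zeros((8, 600)))
    csd = morlet_csd(tr, fg, tg).csd
    coh = np.abs(csd[..., 0, 1]) ** 2 / (np.real(csd[..., 0, 0])
                                         * np.real(csd[..., 1, 1]))
    np.testing.assert_allclose(coh, 1.0, atol=1e-6)


def test_white_noise_coherence_vanishes_with_trials():
    """Off-diagonal coherence of independent channels -> 0 (|coh| < 0.1 at
    500 trials)."""
    fg = FrequencyGrid(np.array([48.0, 72.0]))
    tg = TimeGrid(np.array([0.1, 0.3, 0.5]))
    rng = np.random.default_rng(3)
    tr = TrialSet(1e-13 * rng.standard_normal((500, 2, 600)),
                  np.zeros((500, 600)))
    csd = morlet_csd(tr, fg, tg).csd
    coh = np.abs(csd[..., 0, 1]) / np.sqrt(np.real(csd[..., 0, 0])
                                           * np.real(csd[..., 1, 1]))
    assert coh.max() < 0.1


def test_low_frequency_bins_flagged_invalid():
    tr = make_tone_trials()
    fg = FrequencyGrid(np.array([4.0, 10.0, 64.0]))
    csd = morlet_csd(tr, fg, TimeGrid.default())
    # 6 sigma_t = 6*7/(2 pi f) exceeds the 1 s epoch only below ~6.7 Hz
    np.testing.assert_array_equal(csd.valid_freq, [False, True, True])


def test_amplitude_normalization_of_coefficients(gamma_grids):
    fg, tg = gamma_grids
    w = morlet_coefficients(make_tone_trials(freq=64.0, amp=3e-13), fg, tg)
    mid = np.abs(w[0, 0, np.argmin(np.abs(fg.freqs - 64.0)), len(tg) // 2])
    assert abs(mid - 3e-13) < 1e-15


# ------------------------------------------------------------------ DICS

def test_unit_gain_constraint(geom, lf, cohort, gamma_grids):
    _, subjects = cohort
    fg, tg = gamma_grids
    tr = simulate_meg_recording(subjects[0], geom.head, geom.grid, n_trials=6,
                                rng=np.random.default_rng(2))
    csd = morlet_csd(tr, fg, tg)
    # recompute the filters exactly as dics_power does, for one frequency
    n_s = lf.shape[1]
    C = np.real(csd.csd[3]).mean(axis=0)
    Cr = C + 0.05 * np.trace(C) / n_s * np.eye(n_s)
    Ci = np.linalg.inv(Cr)
    A = np.matmul(Ci, lf)
    M = np.matmul(np.transpose(lf, (0, 2, 1)), A)
    W = np.linalg.solve(M, np.transpose(A, (0, 2, 1)))
    WL = np.matmul(W, lf)
    np.testing.assert_allclose(WL, np.broadcast_to(np.eye(2), WL.shape),
                               atol=1e-10)


def test_power_nonnegative_and_filter_modes_agree_on_shape(geom, lf, cohort,
                                                           gamma_grids):
    _, subjects = cohort
    fg, tg = gamma_grids
    tr = simulate_meg_recording(subjects[0], geom.head, geom.grid, n_trials=6,
                                rng=np.random.default_rng(2))
    csd = morlet_csd(tr, fg, tg)
    for common in (True, False):
        p = dics_power(csd, lf, common_filter=common)
        assert p.power.shape == (geom.grid.n_points, len(fg), len(tg))
        assert np.all(p.power >= 0)


def test_single_source_localized_at_true_grid_point():
    """Noise-free single V1 source: the gamma-band modulation argmax over a
    volumetric grid is the true source point."""
    from gabagamma.geometry import make_head_model, posterior_box_grid
    from gabagamma.synthetic_cohort import CohortConfig, make_cohort
    from gabagamma.geometry import CohortGeometry

    head = make_head_model(24)
    grid = posterior_box_grid()
    true_idx = grid.v1_indices[:1]
    sub_grid = type(grid)(grid.points, true_idx, grid.spacing_mm)
    geom_full = CohortGeometry.reduced()
    subj = make_cohort(CohortConfig(seed=0), geom_full)[0]
    subj.gamma_peak_freq = 64.0
    subj.gamma_amp = 1.0
    tr = simulate_meg_recording(subj, head, sub_grid, n_trials=8,
                                rng=np.random.default_rng(5), blink_rate=0.0,
                                snr=50.0)
    fg = FrequencyGrid(np.array([60.0, 64.0, 68.0]))
    tg = TimeGrid.default()
    csd = morlet_csd(tr, fg, tg)
    power = dics_power(csd, leadfield(head, grid))
    active = power.tgrid.window_mask(0.15, 0.45)
    base = power.tgrid.baseline_mask()
    mod = (power.power[:, 1][:, active].mean(axis=1)
           - power.power[:, 1][:, base].mean(axis=1))
    assert np.argmax(mod) == true_idx[0]


def test_singular_csd_advises_larger_lambda(geom, lf):
    from gabagamma.containers import CSDSeries
    from gabagamma.meg_source_power import BeamformerError
    fg, tg = FrequencyGrid(np.array([64.0])), TimeGrid(np.array([0.0]))
    zero = CSDSeries(np.zeros((1, 1, lf.shape[1], lf.shape[1]), complex),
                     fg, tg, 7.0, 1)
    with pytest.raises(BeamformerError, match="lambda"):
        dics_power(zero, lf, lam=0.05)


# ------------------------------------------------------- smoothing/averaging

def test_smoothing_constant_unchanged(gamma_grids):
    fg, tg = gamma_grids
    from gabagamma.containers import SourcePower
    p = SourcePower(np.full((3, len(fg), len(tg)), 2.5), fg, tg)
    np.testing.assert_allclose(temporal_smooth(p).power, 2.5)


def test_smoothing_impulse_and_bruteforce(gamma_grids):
    fg, tg = gamma_grids
    from gabagamma.containers import SourcePower
    n_t = len(tg)
    arr = np.zeros((1, 1, n_t))
    arr[0, 0, 30] = 1.0
    p = SourcePower(arr, FrequencyGrid(np.array([64.0])), tg)
    sm = temporal_smooth(p).power[0, 0]
    assert abs(sm[30] - 1 / 13) < 1e-12
    # brute force on random arrays, including shrink-at-edge behaviour
    rng = np.random.default_rng(1)
    x = rng.random((2, 3, n_t))
    got = moving_average_shrink(x, 13, axis=-1)
    for t in range(n_t):
        lo, hi = max(0, t - 6), min(n_t, t + 7)
        np.testing.assert_allclose(got[..., t], x[..., lo:hi].mean(axis=-1))


def test_band_average_matches_direct_mean():
    fg = FrequencyGrid.gamma_only(2.0)
    tg = TimeGrid(np.array([0.0, 0.1]))
    from gabagamma.containers import SourcePower
    rng = np.random.default_rng(0)
    arr = rng.random((2, len(fg), 2))
    out = band_average_high(SourcePower(arr, fg, tg)).power
    i40 = np.argmin(np.abs(fg.freqs - 40.0))
    sel = np.abs(fg.freqs - 40.0) <= 4.0
    np.testing.assert_allclose(out[:, i40], arr[:, sel].mean(axis=1))
    # bins below 40 Hz untouched
    below = fg.freqs < 40.0
    np.testing.assert_array_equal(out[:, below], arr[:, below])


def test_band_average_window_support():
    fg = FrequencyGrid.gamma_only(2.0)
    tg = TimeGrid(np.array([0.0]))
    from gabagamma.containers import SourcePower
    arr = np.zeros((1, len(fg), 1))
    arr[0, np.argmin(np.abs(fg.freqs - 64.0)), 0] = 1.0
    out = band_average_high(SourcePower(arr, fg, tg)).power[0, :, 0]
    touched = fg.freqs[out > 0]
    assert touched.min() == 60.0 and touched.max() == 68.0


def test_flat_spectrum_unchanged_by_band_average():
    fg = FrequencyGrid.gamma_only(2.0)
    tg = TimeGrid(np.array([0.0]))
    from gabagamma.containers import SourcePower
    arr = np.full((2, len(fg), 1), 3.0)
    np.testing.assert_allclose(band_average_high(SourcePower(arr, fg, tg)).power,
                               3.0)


# ------------------------------------------------------------- normalization

def _power_fixture(geom, seed=0):
    from gabagamma.containers import SourcePower
    fg = FrequencyGrid.gamma_only(4.0)
    tg = TimeGrid.default()
    rng = np.random.default_rng(seed)
    arr = 1.0 + rng.random((geom.grid.n_points, len(fg), len(tg)))
    return SourcePower(arr, fg, tg)


def test_identical_pre_post_gives_zero_modulation(geom):
    from gabagamma.containers import SourcePower
    fg, tg = FrequencyGrid.gamma_only(4.0), TimeGrid.default()
    rng = np.random.default_rng(2)
    const_t = 1.0 + rng.random((geom.grid.n_points, len(fg), 1))
    p = SourcePower(np.repeat(const_t, len(tg), axis=2), fg, tg)
    for mode in ("absolute", "percent"):
        resp = normalize_and_modulate(p, geom.grid, mode=mode)
        np.testing.assert_allclose(resp.data, 0.0, atol=1e-9)


def test_absolute_mode_gain_invariance(geom):
    p = _power_fixture(geom)
    from gabagamma.containers import SourcePower
    r1 = normalize_and_modulate(p, geom.grid, "absolute").data
    p2 = SourcePower(2.0 * p.power, p.fgrid, p.tgrid)
    r2 = normalize_and_modulate(p2, geom.grid, "absolute").data
    np.testing.assert_allclose(r1, r2, rtol=1e-10)


def test_percent_mode_arithmetic(geom):
    from gabagamma.containers import SourcePower
    fg, tg = FrequencyGrid.gamma_only(4.0), TimeGrid.default()
    arr = np.full((geom.grid.n_points, len(fg), len(tg)), 3.0)
    arr[..., tg.baseline_mask()] = 2.0
    resp = normalize_and_modulate(SourcePower(arr, fg, tg), geom.grid,
                                  "percent")
    post = ~tg.baseline_mask()
    np.testing.assert_allclose(resp.data[..., post], 50.0)


def test_percent_mode_zero_baseline_errors(geom):
    from gabagamma.containers import SourcePower
    fg, tg = FrequencyGrid.gamma_only(4.0), TimeGrid.default()
    arr = np.zeros((geom.grid.n_points, len(fg), len(tg)))
    with pytest.raises(ZeroDivisionError):
        normalize_and_modulate(SourcePower(arr, fg, tg), geom.grid, "percent")
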