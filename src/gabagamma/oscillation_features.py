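"""Per-subject band peaks and group-level stimulation-effect maps.

Peak extraction finds, within a band's frequency range and the 0-600 ms
window, the frequency/time/amplitude of the largest modulation of the
V1-averaged response.  "Largest modulation" is signed: for alpha and beta the
response of interest is a suppression, so the extremum is the most negative
deflection; for gamma it is the largest increase.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .containers import ResponseArray

logger = logging.getLogger(__name__)


class NoModulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class BandDefinition:
    """Frequency band with peak-search and group-test ranges (Hz)."""

    name: str
    peak_range: tuple
    test_range: tuple
    sign: int  # +1 increase (gamma), -1 suppression (alpha/beta)

    def __post_init__(self):
        if self.sign not in (-1, 1):
            raise ValueError("sign must be -1 or +1")


ALPHA = BandDefinition("alpha", (7.0, 14.0), (8.0, 13.0), -1)
BETA = BandDefinition("beta", (15.0, 30.0), (15.0, 25.0), -1)
GAMMA = BandDefinition("gamma", (40.0, 100.0), (60.0, 90.0), +1)
#: theta is evaluated in group maps but has no peak-extraction default
THETA = BandDefinition("theta", (4.0, 7.0), (4.0, 7.0), -1)

BANDS = {"alpha": ALPHA, "beta": BETA, "gamma": GAMMA}

#: peak-search time window, seconds post-stimulus
PEAK_WINDOW = (0.0, 0.6)


@dataclass
class BandPeaks:
    """Peak frequency (Hz), timing (s) and signed amplitude of one band."""

    peak_freq: float
    peak_time: float
    peak_amp: float
    band: str


def extract_band_peaks(response: ResponseArray, band: BandDefinition) -> BandPeaks:
    """Locate the band's peak modulation in the V1-averaged response.

    Ties are broken toward the lower frequency and the earlier time instant
    (argmax of the first occurrence); a tie is logged at debug level.
    """
    v1 = response.v1_mean()                               # (F, T)
    fmask = response.fgrid.band_mask(*band.peak_range)
    tmask = response.tgrid.window_mask(*PEAK_WINDOW)
    if not fmask.any() or not tmask.any():
        raise ValueError(f"frequency/time grid does not cover the {band.name} band")
    sub = band.sign * v1[np.ix_(fmask, tmask)]
    if np.all(sub == 0):
        raise NoModulationError(f"no modulation in the {band.name} band")
    per_freq = sub.max(axis=1)
    if (per_freq == per_freq.max()).sum() > 1:
        logger.debug("peak-frequency tie in %s band; choosing lowest", band.name)
    fi = int(np.argmax(per_freq))
    row = sub[fi]
    if (row == row.max()).sum() > 1:
        logger.debug("peak-time tie in %s band; choosing earliest", band.name)
    ti = int(np.argmax(row))
    freqs = response.fgrid.freqs[fmask]
    times = response.tgrid.instants[tmask]
    amp = float(v1[np.ix_(fmask, tmask)][fi, ti])
    return BandPeaks(float(freqs[fi]), float(times[ti]), amp, band.name)


@dataclass
class SignificanceMap:
    """Group paired-t stimulation-effect map over grid points."""

    p_values: np.ndarray
    significant: np.ndarray
    undefined: np.ndarray
    alpha_level: float

    @property
    def flagged_fraction(self) -> float:
        ok = ~self.undefined
        return float(self.significant[ok].mean()) if ok.any() else float("nan")


def group_stimulation_map(powers: list, band: BandDefinition, fgrid, tgrid,
                          alpha_level: float = 0.005) -> SignificanceMap:
    """Paired t-test of post- vs pre-stimulus band power across subjects.

    ``powers`` is a list of per-subject (points, freq, time) arrays (or
    :class:`SourcePower`).  Per grid point, the subject-wise mean activity in
    the band's test range is compared between the baseline window
    ([-200, 0) ms) and the post-stimulus window ([0, 600] ms); the map flags
    points with two-sided ``p < alpha_level`` (uncorrected).  Points with
    zero across-subject variance of the paired difference are excluded.
    """
    arrays = [p.power if hasattr(p, "power") else np.asarray(p) for p in powers]
    if len(arrays) < 3:
        raise ValueError("group map needs at least 3 subjects")
    fmask = fgrid.band_mask(*band.test_range)
    pre_mask = tgrid.baseline_mask()
    post_mask = tgrid.window_mask(0.0, 0.6)
    pre = np.stack([a[:, fmask][:, :, pre_mask].mean(axis=(1, 2)) for a in arrays])
    post = np.stack([a[:, fmask][:, :, post_mask].mean(axis=(1, 2)) for a in arrays])
    diff = post - pre                                     # (subjects, points)
    undefined = diff.std(axis=0) == 0
    pvals = np.full(diff.shape[1], np.nan)
    ok = ~undefined
    if ok.any():
        res = stats.ttest_rel(post[:, ok], pre[:, ok], axis=0)
        pvals[ok] = res.pvalue
    significant = np.zeros(diff.shape[1], bool)
    significant[ok] = pvals[ok] < alpha_level
    return SignificanceMap(pvals, significant, undefined, alpha_level)
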