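"""Correlation statistics linking MEG gamma features to PET GABA_A density.

Implements the report machinery: Spearman's rho and Pearson's r with
two-sided p-values (t convention, df = n - 2), the default JZS Bayes factor
for a correlation, leave-2-out bootstrap confidence limits, linear confound
regression, and random-voxel-set specificity nulls.  All p-values are
uncorrected.

The JZS correlation Bayes factor contrasts a linear-association model with a
Jeffreys-Zellner-Siow prior (Cauchy on the standardized effect, Jeffreys on
the nuisance parameters) against the null of zero correlation:

    BF10 = integral over g of
        (1 + g)^((n - 2) / 2) * (1 + (1 - r^2) g)^(-(n - 1) / 2)
        * sqrt(n / 2) / Gamma(1/2) * g^(-3/2) * exp(-n / (2 g))

i.e. an expectation over an inverse-gamma(1/2, n/2) mixing density for the
Zellner g scale, evaluated here by adaptive quadrature.  BF10 > 1 favors the
presence of a correlation of any sign.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, special, stats

from .containers import BmaxMap, PETGeometry


class DegenerateSampleError(ValueError):
    pass


@dataclass
class PairedSample:
    """Per-subject (PET density, MEG feature) pairs."""

    x: np.ndarray
    y: np.ndarray
    labels: list = None

    def __post_init__(self):
        self.x = np.asarray(self.x, float)
        self.y = np.asarray(self.y, float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be equal-length vectors")
        if self.labels is None:
            self.labels = [f"S{i + 1:02d}" for i in range(len(self.x))]

    @property
    def n(self) -> int:
        return len(self.x)


def spearman(sample: PairedSample):
    """Spearman rank correlation with two-sided p (t approximation, df n-2)."""
    res = stats.spearmanr(sample.x, sample.y)
    return float(res.statistic), float(res.pvalue)


def spearman_exact_p(sample: PairedSample, n_perm: int = 100_000, seed: int = 0):
    """Permutation p-value for Spearman's rho (optional exact-style variant)."""
    rho, _ = spearman(sample)
    rng = np.random.default_rng(seed)
    rx = stats.rankdata(sample.x)
    ry = stats.rankdata(sample.y)
    rx = (rx - rx.mean()) / rx.std()
    ry = (ry - ry.mean()) / ry.std()
    # vectorized random permutations: argsort of uniforms
    order = np.argsort(rng.random((n_perm, len(ry))), axis=1)
    perm_rho = (ry[order] @ rx) / len(rx)
    count = int((np.abs(perm_rho) >= abs(rho) - 1e-12).sum())
    return rho, (count + 1) / (n_perm + 1)


def pearson_with_p(sample: PairedSample):
    """Pearson's r with two-sided p from ``t = r sqrt(n-2) / sqrt(1-r^2)``."""
    if sample.x.std() == 0 or sample.y.std() == 0:
        raise DegenerateSampleError("zero variance in x or y")
    r = float(np.corrcoef(sample.x, sample.y)[0, 1])
    p = pearson_p_from_r(r, sample.n)
    return r, p


def pearson_p_from_r(r: float, n: int) -> float:
    """Two-sided p for a given r and sample size (df = n - 2)."""
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def jzs_correlation_bf(r: float, n: int, atol: float = 1e-6) -> float:
    """Default JZS Bayes factor BF10 for a correlation coefficient.

    Symmetric in the sign of ``r``; > 1 favors a correlation.  Raises for
    |r| >= 1 (degenerate likelihood) or a non-convergent quadrature.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    if abs(r) >= 1.0:
        raise ValueError("|r| must be < 1: likelihood degenerate at |r| = 1")
    r2 = r * r
    const = (n / 2.0) ** 0.5 / special.gamma(0.5)

    def integrand(g):
        return ((1.0 + g) ** ((n - 2) / 2.0)
                * (1.0 + (1.0 - r2) * g) ** (-(n - 1) / 2.0)
                * const * g ** (-1.5) * np.exp(-n / (2.0 * g)))

    val, err = integrate.quad(integrand, 0.0, np.inf, epsabs=atol,
                              epsrel=1e-10, limit=400)
    if not np.isfinite(val) or err > max(atol, 1e-4 * abs(val)):
        raise RuntimeError(f"BF quadrature did not converge (estimate {val}, "
                           f"error {err}, tolerance {atol})")
    return float(val)


def bootstrap_ci(sample: PairedSample, n_resamples: int = 200,
                 leave_out: int = 2, seed: int = 0,
                 statistic=None):
    """Leave-``leave_out``-subjects-out bootstrap 95% limits for Spearman's rho.

    Each of the ``n_resamples`` draws removes ``leave_out`` distinct random
    subjects and recomputes the correlation; the CI is the 2.5th/97.5th
    percentile (linear interpolation) of the resulting distribution.
    """
    if sample.n - leave_out < 3:
        raise ValueError("too few subjects left after leave-out")
    if statistic is None:
        statistic = lambda x, y: stats.spearmanr(x, y).statistic
    rng = np.random.default_rng(seed)
    vals = np.empty(n_resamples)
    import warnings
    with warnings.catch_warnings():
        # a quantized feature may become constant in a resample; the
        # undefined correlation is dropped from the percentile computation
        warnings.simplefilter("ignore", stats.ConstantInputWarning)
        for i in range(n_resamples):
            drop = rng.choice(sample.n, size=leave_out, replace=False)
            keep = np.setdiff1d(np.arange(sample.n), drop)
            vals[i] = statistic(sample.x[keep], sample.y[keep])
    if np.isnan(vals).all():
        return float("nan"), float("nan")
    lo, hi = np.nanpercentile(vals, [2.5, 97.5])
    return float(lo), float(hi)


def regress_out(values: np.ndarray, confounds: np.ndarray) -> np.ndarray:
    """OLS residuals of ``values`` on ``confounds`` (intercept included)."""
    values = np.asarray(values, float)
    X = np.column_stack([np.ones(len(values)), np.atleast_2d(
        np.asarray(confounds, float).T).T])
    beta, *_ = np.linalg.lstsq(X, values, rcond=None)
    return values - X @ beta


def gm_density_confound(gm_fraction_map: np.ndarray,
                        v1_pet_voxels: np.ndarray) -> float:
    """Mean gray-matter fraction over the unique V1-PET voxel set."""
    v1 = np.asarray(v1_pet_voxels, int)
    if v1.size == 0:
        raise ValueError("empty V1 voxel set")
    return float(np.asarray(gm_fraction_map, float).ravel()[v1].mean())


@dataclass
class NullEnsemble:
    """Correlations for random voxel sets far from V1 (specificity control)."""

    correlations: np.ndarray  # 200 = 100 random + 100 contiguous
    set_sizes: np.ndarray
    min_distance_cm: float


def _eligible_pool(geometry: PETGeometry, v1_voxels: np.ndarray,
                   min_distance_cm: float) -> np.ndarray:
    all_idx = np.arange(geometry.n_voxels)
    centers = geometry.voxel_centers(all_idx)
    v1_centers = geometry.voxel_centers(v1_voxels)
    d = np.min(np.linalg.norm(
        centers[:, None, :] - v1_centers[None, :, :], axis=2), axis=1)
    return all_idx[d > min_distance_cm * 10.0]


def _grow_cluster(rng, start: int, pool_mask: np.ndarray, shape, k: int):
    """Seeded region-growing of a contiguous voxel set within the pool."""
    n = int(np.prod(shape))
    chosen = [start]
    in_set = np.zeros(n, bool)
    in_set[start] = True
    frontier = [start]
    strides = []
    for axis in range(3):
        step = np.ones(3, int)
        offs = np.zeros(3, int)
        offs[axis] = 1
        strides.append(offs)
    while len(chosen) < k and frontier:
        idx = frontier[int(rng.integers(len(frontier)))]
        ijk = np.array(np.unravel_index(idx, shape))
        neighbours = []
        for offs in strides:
            for sgn in (-1, 1):
                cand = ijk + sgn * offs
                if np.any(cand < 0) or np.any(cand >= np.array(shape)):
                    continue
                flat = int(np.ravel_multi_index(cand, shape))
                if pool_mask[flat] and not in_set[flat]:
                    neighbours.append(flat)
        if not neighbours:
            frontier.remove(idx)
            continue
        new = neighbours[int(rng.integers(len(neighbours)))]
        chosen.append(new)
        in_set[new] = True
        frontier.append(new)
    return np.array(chosen) if len(chosen) == k else None


def random_voxel_nulls(maps: list, v1_voxels: np.ndarray,
                       meg_feature: np.ndarray, geometry: PETGeometry,
                       n_each: int = 100, min_distance_cm: float = 4.0,
                       seed: int = 0) -> NullEnsemble:
    """Specificity null: correlations with densities of non-V1 voxel sets.

    Draws ``n_each`` fully random voxel sets and ``n_each`` contiguous
    region-grown sets, each of the V1 voxel count and entirely > 4 cm from
    V1, aggregates total density per subject per set, and correlates each
    set's densities with the MEG feature (Spearman).
    """
    v1_voxels = np.asarray(v1_voxels, int)
    k = len(v1_voxels)
    pool = _eligible_pool(geometry, v1_voxels, min_distance_cm)
    if len(pool) <= k:
        raise ValueError("eligible voxel pool (>4 cm from V1) smaller than V1 set")
    pool_mask = np.zeros(geometry.n_voxels, bool)
    pool_mask[pool] = True
    stacked = np.stack([m.values.ravel() if isinstance(m, BmaxMap)
                        else np.ravel(m) for m in maps])
    rng = np.random.default_rng(seed)
    sets = [rng.choice(pool, size=k, replace=False) for _ in range(n_each)]
    grown = 0
    while grown < n_each:
        start = int(pool[rng.integers(len(pool))])
        cluster = _grow_cluster(rng, start, pool_mask, geometry.shape, k)
        if cluster is not None:
            sets.append(cluster)
            grown += 1
    rhos = np.array([
        stats.spearmanr(stacked[:, s].sum(axis=1), meg_feature).statistic
        for s in sets])
    return NullEnsemble(rhos, np.full(len(sets), k), min_distance_cm)


# --------------------------------------------------------------------------
# Full report
# --------------------------------------------------------------------------

FEATURES = ("peak_freq_hz", "peak_amp", "peak_time_ms")
_FEATURE_SHORT = {"peak_freq_hz": "frequency", "peak_amp": "amplitude",
                  "peak_time_ms": "timing"}


def _result_row(name: str, sample: PairedSample, seed: int,
                n_boot: int = 200) -> dict:
    if sample.x.std() == 0 or sample.y.std() == 0:
        # a quantized feature can be constant across subjects; report NaNs
        nan = float("nan")
        return {"correlation_name": name, "spearman_rho": nan,
                "spearman_p": nan, "pearson_r": nan, "pearson_p": nan,
                "bf10": nan, "ci_low": nan, "ci_high": nan, "n": sample.n}
    rho, rho_p = spearman(sample)
    r, r_p = pearson_with_p(sample)
    bf = jzs_correlation_bf(r, sample.n) if abs(r) < 1.0 else float("inf")
    lo, hi = bootstrap_ci(sample, n_resamples=n_boot, seed=seed)
    return {"correlation_name": name, "spearman_rho": rho, "spearman_p": rho_p,
            "pearson_r": r, "pearson_p": r_p, "bf10": bf,
            "ci_low": lo, "ci_high": hi, "n": sample.n}


def run_full_analysis(features: pd.DataFrame, density: pd.DataFrame,
                      confounds: pd.DataFrame = None, n_boot: int = 200,
                      seed: int = 0):
    """Band x feature x density-variant correlation report (Table-1 style).

    ``features``: columns subject_id, band, peak_freq_hz, peak_time_ms,
    peak_amp.  ``density``: subject_id, total_v1_bmax and optionally
    total_brain_bmax.  ``confounds``: subject_id, v1_surface_area_mm2,
    gm_density (enables the confound-regressed variant).

    Returns ``(main, controls)`` DataFrames: the main report has one row per
    band x feature x {raw, regressed} density variant; controls hold the
    whole-brain-density and V1-size specificity rows for the gamma band.
    """
    bands = sorted(features["band"].unique())
    subj = sorted(density["subject_id"])
    for name, df in (("features", features), ("density", density),
                     ("confounds", confounds)):
        if df is None:
            continue
        missing = set(subj) ^ set(df["subject_id"].unique())
        if missing:
            raise ValueError(f"subject ids mismatch in {name}: {sorted(missing)}")
    density = density.sort_values("subject_id").reset_index(drop=True)
    dens = density["total_v1_bmax"].to_numpy()
    variants = {"raw": dens}
    conf = None
    if confounds is not None:
        conf = confounds.sort_values("subject_id").reset_index(drop=True)
        X = conf[["v1_surface_area_mm2", "gm_density"]].to_numpy()
        variants["regressed"] = regress_out(dens, X)

    rows = []
    rng = np.random.default_rng(seed)
    for band in bands:
        fb = features[features["band"] == band].sort_values("subject_id")
        for feat in FEATURES:
            y = fb[feat].to_numpy()
            for vname, x in variants.items():
                name = f"{band}_{_FEATURE_SHORT[feat]}_gabaa_{vname}"
                sample = PairedSample(x, y, labels=subj)
                rows.append(_result_row(name, sample, int(rng.integers(2**31)),
                                        n_boot))
    main = pd.DataFrame(rows)

    ctrl_rows = []
    gamma = features[features["band"] == "gamma"].sort_values("subject_id")
    if len(gamma):
        ctrl_vars = {}
        if "total_brain_bmax" in density:
            ctrl_vars["brain_density"] = density["total_brain_bmax"].to_numpy()
        if conf is not None:
            ctrl_vars["v1_surface_area"] = conf["v1_surface_area_mm2"].to_numpy()
        for feat in ("peak_freq_hz", "peak_amp"):
            y = gamma[feat].to_numpy()
            for vname, x in ctrl_vars.items():
                name = f"gamma_{_FEATURE_SHORT[feat]}_vs_{vname}"
                sample = PairedSample(x, y, labels=subj)
                ctrl_rows.append(_result_row(
                    name, sample, int(rng.integers(2**31)), n_boot))
    controls = pd.DataFrame(ctrl_rows)
    return main, controls
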