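"""Distributional QC and outlier screening.

Before modeling, columns are profiled by skewness and (non-excess)
kurtosis — for well-behaved variables kurtosis sits near 3, and strongly
leptokurtic columns betray samples with artifacts such as imperfect water
suppression.  Samples are screened by three independent rules: extreme
intensity inside high-kurtosis moment zones, Hotelling T2 / Q-residual
limits on a mean-centered PCA, and a low signal-to-noise floor.  Flags
propagate to whole subjects so replicate triplicates are removed together.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats

from .dataset import SpectraDataset
from .preprocess import RegionSet

DEFAULT_NOISE_REGIONS = ((0.2, 0.4), (6.6, 6.8))


@dataclasses.dataclass
class MomentProfile:
    """Per-column sample skewness and non-excess kurtosis.

    Zero-variance columns are recorded as NaN rather than raised.
    """

    skewness: np.ndarray
    kurtosis: np.ndarray


@dataclasses.dataclass
class OutlierReport:
    flagged_subjects: list[str]
    reasons: dict[str, set[str]]  # sample_id -> rule names
    thresholds: dict[str, float]

    def flagged_sample_mask(self, ds: SpectraDataset) -> np.ndarray:
        flagged = set(self.flagged_subjects)
        return ds.samples["subject_id"].isin(flagged).to_numpy()


def column_moments(ds: SpectraDataset | np.ndarray) -> MomentProfile:
    """Sample skewness (g1) and non-excess kurtosis per column."""
    X = ds.intensities if isinstance(ds, SpectraDataset) else np.asarray(ds)
    if X.shape[0] < 4:
        raise ValueError("moment profiling needs at least 4 samples")
    var = X.var(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        skew = stats.skew(X, axis=0, bias=True)
        kurt = stats.kurtosis(X, axis=0, fisher=False, bias=True)
    skew = np.where(var > 0, skew, np.nan)
    kurt = np.where(var > 0, kurt, np.nan)
    return MomentProfile(skewness=skew, kurtosis=kurt)


def _pca_limits(
    X: np.ndarray, n_components: int, limit_quantile: float
) -> tuple[np.ndarray, float, np.ndarray, float]:
    """Hotelling T2 and Q residuals with their conventional control limits
    (F approximation for T2; Box weighted-chi-square for Q)."""
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = n_components
    scores = U[:, :k] * s[:k]
    eig = s**2 / (n - 1)
    safe = np.where(eig[:k] > 0, eig[:k], 1.0)
    t2 = np.sum(np.where(eig[:k] > 0, scores**2 / safe, 0.0), axis=1)
    f_crit = stats.f.ppf(limit_quantile, k, n - k)
    t2_limit = k * (n**2 - 1) / (n * (n - k)) * f_crit

    resid = Xc - scores @ Vt[:k]
    q = np.sum(resid**2, axis=1)
    theta1 = eig[k:].sum()
    theta2 = (eig[k:] ** 2).sum()
    if theta1 <= 0 or theta2 <= 0:
        q_limit = np.inf
    else:
        g = theta2 / theta1
        h = theta1**2 / theta2
        q_limit = g * stats.chi2.ppf(limit_quantile, h)
    return t2, t2_limit, q, q_limit


def flag_outliers(
    ds: SpectraDataset,
    moment_zone_sd: float = 4.0,
    pca_components: int = 2,
    limit_quantile: float = 0.95,
    snr_floor: float = 5.0,
    kurtosis_limit: float = 10.0,
    zone_quantile: float = 0.995,
    min_zone_columns: int = 2,
    noise_regions=DEFAULT_NOISE_REGIONS,
) -> OutlierReport:
    """Screen samples by moment zones, PCA distance, and SNR.

    (a) moment zones: the zone is the set of columns whose kurtosis is both
    above ``kurtosis_limit`` and in the top ``1 - zone_quantile`` share of
    all column kurtoses; a sample is flagged when its intensity exceeds the
    zone mean + moment_zone_sd·sd in at least ``min_zone_columns`` zone
    columns (an artifact spans neighbouring points; single-point
    excursions are noise);
    (b) PCA: Hotelling T2 or Q residual beyond the ``limit_quantile`` control
    limit of a mean-centered PCA; (c) SNR: median intensity over the
    data-driven peak columns divided by the noise-region standard deviation
    below ``snr_floor``.  Any flagged replicate flags its whole subject.
    """
    X = ds.intensities
    n, p = X.shape
    if pca_components >= min(n, p):
        raise ValueError("pca_components must be < min(n_samples, n_variables)")

    reasons: dict[str, set[str]] = {sid: set() for sid in ds.samples["sample_id"]}
    sample_ids = ds.samples["sample_id"].to_numpy()

    # (a) moment zones
    profile = column_moments(ds)
    kurt = np.nan_to_num(profile.kurtosis, nan=0.0)
    zone = (kurt > kurtosis_limit) & (kurt >= np.quantile(kurt, zone_quantile))
    if zone.any():
        Z = X[:, zone]
        hi = Z.mean(axis=0) + moment_zone_sd * Z.std(axis=0)
        hit = (Z > hi).sum(axis=1) >= min(min_zone_columns, zone.sum())
        for sid in sample_ids[hit]:
            reasons[sid].add("moment_zone_contribution")

    # (b) PCA T2 / Q
    t2, t2_lim, q, q_lim = _pca_limits(X, pca_components, limit_quantile)
    for sid in sample_ids[t2 > t2_lim]:
        reasons[sid].add("pca_T2")
    for sid in sample_ids[q > q_lim]:
        reasons[sid].add("pca_Q")

    # (c) SNR floor
    noise_idx = np.flatnonzero(RegionSet.coerce(noise_regions).mask(ds.ppm))
    if noise_idx.size >= 3:
        median_spec = np.median(X, axis=0)
        peak_cols = median_spec >= np.quantile(median_spec, 0.98)
        noise_sd = X[:, noise_idx].std(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            snr = np.median(X[:, peak_cols], axis=1) / noise_sd
        snr = np.where(noise_sd > 0, snr, np.inf)
        for sid in sample_ids[snr < snr_floor]:
            reasons[sid].add("low_snr")

    # propagate to whole subjects
    flagged_samples = {sid for sid, r in reasons.items() if r}
    flagged_subjects = sorted(
        ds.samples.loc[
            ds.samples["sample_id"].isin(flagged_samples), "subject_id"
        ].unique()
    )
    subject_of = dict(zip(ds.samples["sample_id"], ds.samples["subject_id"]))
    for sid in sample_ids:
        if subject_of[sid] in flagged_subjects and not reasons[sid]:
            reasons[sid].add("replicate_of_flagged_subject")

    return OutlierReport(
        flagged_subjects=list(flagged_subjects),
        reasons={sid: r for sid, r in reasons.items() if r},
        thresholds={
            "moment_zone_sd": moment_zone_sd,
            "kurtosis_limit": kurtosis_limit,
            "t2_limit": float(t2_lim),
            "q_limit": float(q_lim),
            "snr_floor": snr_floor,
            "limit_quantile": limit_quantile,
        },
    )
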