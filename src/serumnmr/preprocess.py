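"""Spectral preprocessing: region exclusion, baseline, alignment, PQN.

The stages mirror standard serum-NMR practice: drop the residual-water
window and the signal-free spectrum edges, subtract a first-order baseline
fitted to peak-free anchor regions, align peaks by correlation-maximizing
rigid shifts (whole-spectrum first against the anomeric-glucose reference
zone, then per-interval), and remove dilution variation by probabilistic
quotient normalization.  Each stage exists both as a scikit-learn-style
transformer operating on intensity matrices and as a dataset-level function
that also maintains the processing log.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .dataset import SpectraDataset

#: default exclusion windows: residual water plus signal-free edges
DEFAULT_EXCLUDE = ((4.35, 5.0), (-np.inf, 0.17), (8.0, np.inf))
#: anomeric alpha-glucose doublet zone used as the whole-spectrum alignment
#: reference (doublet centered at 5.23 ppm beside the 5.27 ppm lipid line)
DEFAULT_ALIGN_REF = ((5.12, 5.19), (5.20, 5.35))
#: trouble zones that typically need a second, local alignment pass
DEFAULT_ALIGN_INTERVALS = ((1.16, 1.22), (3.62, 3.69))
#: peak-free zones of the synthetic library used as baseline anchors
DEFAULT_BASELINE_ANCHORS = ((0.2, 0.4), (6.6, 6.8), (9.5, 10.0))

DEFAULT_MAX_SHIFT = 50  # points


class RegionSet:
    """A set of closed ppm intervals."""

    def __init__(self, intervals: Sequence[tuple[float, float]]):
        self.intervals = [(float(lo), float(hi)) for lo, hi in intervals]
        for lo, hi in self.intervals:
            if not lo < hi:
                raise ValueError(f"degenerate interval ({lo}, {hi})")

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def mask(self, ppm: np.ndarray) -> np.ndarray:
        """Boolean mask of axis points lying inside any interval."""
        ppm = np.asarray(ppm)
        m = np.zeros(ppm.shape, dtype=bool)
        for lo, hi in self.intervals:
            m |= (ppm >= lo) & (ppm <= hi)
        return m

    @classmethod
    def coerce(cls, regions) -> "RegionSet":
        if isinstance(regions, RegionSet):
            return regions
        return cls(regions)


@dataclasses.dataclass
class BaselineModel:
    """Per-sample first-order baseline: intensity = slope·ppm + intercept."""

    slopes: np.ndarray
    intercepts: np.ndarray
    anchor_regions: RegionSet


@dataclasses.dataclass
class AlignmentResult:
    """Integer-point shifts applied per sample (and per interval)."""

    global_shifts: np.ndarray | None = None
    interval_shifts: dict[tuple[float, float], np.ndarray] | None = None
    target_spec: str = "median"
    iterations_run: int = 0


@dataclasses.dataclass
class NormalizationResult:
    """Per-sample dilution estimates from quotient normalization."""

    quotients: np.ndarray
    reference: str = "median_all"


# ----------------------------------------------------------------------
# vector utilities


def uniform_intervals(ppm: np.ndarray, n_points: int = 50) -> list[tuple[float, float]]:
    """Segment the axis into consecutive ~n_points-column intervals.

    The standard way to drive interval alignment over the whole spectrum:
    consecutive column blocks, expressed as closed ppm intervals on the
    stored axis (so they remain valid on a gap-bearing, post-exclusion
    axis).
    """
    ppm = np.asarray(ppm, dtype=float)
    if n_points < 2:
        raise ValueError("segments need at least 2 points")
    out = []
    for start in range(0, ppm.size, n_points):
        stop = min(start + n_points, ppm.size) - 1
        if stop > start:
            out.append((float(ppm[start]), float(ppm[stop])))
    return out


def pretreat_vector(x: np.ndarray, mode: str = "none") -> np.ndarray:
    """SNV or first-derivative pretreatment of a single spectrum segment.

    snv: (x − mean)/sd, giving mean 0 and unit sd.  derivative: central
    differences with one-sided endpoints (unit spacing).
    """
    x = np.asarray(x, dtype=float)
    if mode == "none":
        return x.copy()
    if mode == "snv":
        sd = x.std()
        if sd == 0:
            raise ValueError("SNV undefined for a constant vector")
        return (x - x.mean()) / sd
    if mode == "derivative":
        if x.size < 3:
            raise ValueError("derivative needs at least 3 points")
        return np.gradient(x)
    raise ValueError(f"unknown pretreatment {mode!r}")


def shift_vector(x: np.ndarray, lag: int) -> np.ndarray:
    """Rigid integer shift with edge-value fill (no wraparound).

    Positive lag moves the signal toward higher indices; vacated points
    repeat the edge value to avoid creating artificial baseline steps.
    """
    x = np.asarray(x)
    if lag == 0:
        return x.copy()
    out = np.empty_like(x)
    if lag > 0:
        out[lag:] = x[:-lag]
        out[:lag] = x[0]
    else:
        out[:lag] = x[-lag:]
        out[lag:] = x[-1]
    return out


def best_lag(
    x: np.ndarray, target: np.ndarray, region_idx: np.ndarray, max_shift: int
) -> int:
    """Integer lag in [−max_shift, max_shift] maximizing the correlation of
    the shifted spectrum with the target over the given columns.  Ties break
    toward the smaller |lag|."""
    lags = np.arange(-max_shift, max_shift + 1)
    scores = np.empty(lags.size)
    t = target[region_idx]
    for i, lag in enumerate(lags):
        scores[i] = float(t @ shift_vector(x, lag)[region_idx])
    order = np.lexsort((np.abs(lags), -scores))
    return int(lags[order[0]])


# ----------------------------------------------------------------------
# transformers


class RegionExcluder(BaseEstimator, TransformerMixin):
    """Drop axis columns falling inside any of the given ppm intervals."""

    def __init__(self, regions=DEFAULT_EXCLUDE, ppm=None):
        self.regions = regions
        self.ppm = ppm

    def fit(self, X=None, y=None):
        ppm = np.asarray(self.ppm, dtype=float)
        keep = ~RegionSet.coerce(self.regions).mask(ppm)
        if not keep.any():
            raise ValueError("exclusion regions remove every column")
        self.keep_mask_ = keep
        self.ppm_out_ = ppm[keep]
        return self

    def transform(self, X):
        return np.asarray(X)[:, self.keep_mask_]


class BaselineCorrector(BaseEstimator, TransformerMixin):
    """Subtract a per-sample least-squares line fitted over anchor regions."""

    def __init__(self, anchor_regions=DEFAULT_BASELINE_ANCHORS, ppm=None):
        self.anchor_regions = anchor_regions
        self.ppm = ppm

    def fit(self, X=None, y=None):
        ppm = np.asarray(self.ppm, dtype=float)
        idx = np.flatnonzero(RegionSet.coerce(self.anchor_regions).mask(ppm))
        if idx.size < 3:
            raise ValueError("anchor regions must contain at least 3 grid points")
        if np.ptp(ppm[idx]) == 0:
            raise ValueError("degenerate anchor set: all anchors at one ppm")
        self.anchor_idx_ = idx
        # design matrix for the per-row line fits, shared by all samples
        self._design = np.column_stack([ppm[idx], np.ones(idx.size)])
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        coef, *_ = np.linalg.lstsq(self._design, X[:, self.anchor_idx_].T, rcond=None)
        slopes, intercepts = coef
        ppm = np.asarray(self.ppm, dtype=float)
        self.slopes_ = slopes
        self.intercepts_ = intercepts
        return X - (slopes[:, None] * ppm[None, :] + intercepts[:, None])


class SpectrumAligner(BaseEstimator, TransformerMixin):
    """Correlation-maximizing rigid alignment, global or per-interval.

    In 'global' mode the whole spectrum is shifted by the lag maximizing
    cross-correlation with the target restricted to the reference regions,
    iterating ``n_iter`` times with the target recomputed (median spectrum)
    each round.  In 'interval' mode each interval is aligned independently;
    an SNV or derivative pretreatment may be applied to the segments for
    lag estimation only — the raw intensities are what get shifted.
    """

    def __init__(
        self,
        mode: str = "global",
        regions=DEFAULT_ALIGN_REF,
        n_iter: int = 4,
        max_shift: int = DEFAULT_MAX_SHIFT,
        pretreatment: str = "none",
        ppm=None,
    ):
        self.mode = mode
        self.regions = regions
        self.n_iter = n_iter
        self.max_shift = max_shift
        self.pretreatment = pretreatment
        self.ppm = ppm

    def _region_indices(self, ppm: np.ndarray) -> list[np.ndarray]:
        rs = RegionSet.coerce(self.regions)
        return [
            np.flatnonzero((ppm >= lo) & (ppm <= hi)) for lo, hi in rs
        ]

    def fit_transform(self, X, y=None):
        ppm = np.asarray(self.ppm, dtype=float)
        X = np.asarray(X, dtype=float).copy()
        if self.mode == "global":
            X, result = self._align_global(X, ppm)
        elif self.mode == "interval":
            X, result = self._align_intervals(X, ppm)
        else:
            raise ValueError(f"unknown alignment mode {self.mode!r}")
        self.result_ = result
        self.target_ = np.median(X, axis=0)
        return X

    def fit(self, X, y=None):
        self.fit_transform(X, y)
        return self

    def transform(self, X):
        """Align new spectra to the stored target in a single pass."""
        ppm = np.asarray(self.ppm, dtype=float)
        X = np.asarray(X, dtype=float).copy()
        if self.mode == "global":
            region_idx = np.concatenate(self._region_indices(ppm))
            for i in range(X.shape[0]):
                lag = best_lag(X[i], self.target_, region_idx, self.max_shift)
                X[i] = shift_vector(X[i], lag)
        else:
            for idx in self._region_indices(ppm):
                if idx.size == 0:
                    continue
                seg_t = self._pretreat_safe(self.target_[idx])
                for i in range(X.shape[0]):
                    seg = X[i, idx]
                    lag = best_lag(
                        self._pretreat_safe(seg),
                        seg_t,
                        np.arange(idx.size),
                        min(self.max_shift, idx.size - 1),
                    )
                    X[i, idx] = shift_vector(seg, lag)
        return X

    # -- internals ------------------------------------------------------
    def _align_global(self, X, ppm):
        if len(RegionSet.coerce(self.regions)) == 0:
            raise ValueError("global alignment needs at least one reference region")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        region_idx = np.concatenate(self._region_indices(ppm))
        if region_idx.size <= self.max_shift:
            raise ValueError("max_shift must be smaller than the reference width")
        total = np.zeros(X.shape[0], dtype=int)
        for _ in range(self.n_iter):
            target = np.median(X, axis=0)
            for i in range(X.shape[0]):
                lag = best_lag(X[i], target, region_idx, self.max_shift)
                if lag:
                    X[i] = shift_vector(X[i], lag)
                    total[i] += lag
        return X, AlignmentResult(
            global_shifts=total, target_spec="median", iterations_run=self.n_iter
        )

    def _pretreat_safe(self, seg):
        try:
            return pretreat_vector(seg, self.pretreatment)
        except ValueError:
            return np.asarray(seg, dtype=float)

    def _align_intervals(self, X, ppm):
        rs = RegionSet.coerce(self.regions)
        idx_sets = self._region_indices(ppm)
        # disjointness check on column membership
        seen = np.zeros(ppm.size, dtype=bool)
        for idx in idx_sets:
            if seen[idx].any():
                raise ValueError("intervals must be disjoint")
            seen[idx] = True
        shifts: dict[tuple[float, float], np.ndarray] = {}
        for (lo, hi), idx in zip(rs, idx_sets):
            lags = np.zeros(X.shape[0], dtype=int)
            if idx.size < 2:
                shifts[(lo, hi)] = lags
                continue
            max_shift = min(self.max_shift, idx.size - 1)
            target = self._pretreat_safe(np.median(X[:, idx], axis=0))
            local = np.arange(idx.size)
            for i in range(X.shape[0]):
                seg = X[i, idx]
                lag = best_lag(self._pretreat_safe(seg), target, local, max_shift)
                lags[i] = lag
                if lag:
                    X[i, idx] = shift_vector(seg, lag)
            shifts[(lo, hi)] = lags
        return X, AlignmentResult(
            interval_shifts=shifts, target_spec="median", iterations_run=1
        )


class PQNNormalizer(BaseEstimator, TransformerMixin):
    """Probabilistic quotient normalization.

    Integral (total-area) normalization first, then division by the median
    quotient against the column-median reference spectrum.  The per-sample
    product of area factor and median quotient is the dilution estimate
    stored in ``quotients_``.
    """

    def __init__(self, reference: str = "median_all", class_labels=None):
        self.reference = reference
        self.class_labels = class_labels

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.shape[0] < 2:
            raise ValueError("PQN needs at least 2 samples")
        areas = X.sum(axis=1)
        self.median_area_ = float(np.median(areas))
        X_int = X * (self.median_area_ / areas)[:, None]
        if self.reference == "median_control":
            if self.class_labels is None:
                raise ValueError("median_control reference requires class labels")
            mask = np.asarray(self.class_labels) == "Control"
            if not mask.any():
                raise ValueError("no Control samples for the reference")
            self.reference_spectrum_ = np.median(X_int[mask], axis=0)
        else:
            self.reference_spectrum_ = np.median(X_int, axis=0)
        ref = self.reference_spectrum_
        valid = ref > 0
        if not valid.any():
            raise ValueError("reference spectrum is non-positive everywhere")
        # quotients over the top-intensity half of the reference: noise-level
        # columns would dominate the median otherwise
        cutoff = np.median(ref[valid])
        self.quotient_columns_ = np.flatnonzero(valid & (ref >= cutoff))
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        areas = X.sum(axis=1)
        factors = areas / self.median_area_
        X_int = X / factors[:, None]
        cols = self.quotient_columns_
        ref = self.reference_spectrum_[cols]
        q = np.median(X_int[:, cols] / ref, axis=1)
        if np.any(q <= 0):
            raise ValueError("non-positive median quotient")
        self.quotients_ = factors * q
        return X_int / q[:, None]


# ----------------------------------------------------------------------
# dataset-level wrappers


def exclude_regions(
    ds: SpectraDataset, regions=DEFAULT_EXCLUDE
) -> SpectraDataset:
    """Remove axis columns inside the given ppm intervals (water, edges)."""
    rs = RegionSet.coerce(regions)
    if len(rs) == 0:
        out = ds.copy_with()
        out.log_step("exclude_regions", intervals=[])
        return out
    exc = RegionExcluder(regions=rs, ppm=ds.ppm).fit()
    out = ds.copy_with(ppm=exc.ppm_out_, intensities=exc.transform(ds.intensities))
    out.log_step("exclude_regions", intervals=rs.intervals)
    return out


def baseline_correct(
    ds: SpectraDataset, anchor_regions=DEFAULT_BASELINE_ANCHORS
) -> tuple[SpectraDataset, BaselineModel]:
    """First-order baseline fit over peak-free anchors, subtracted per sample."""
    rs = RegionSet.coerce(anchor_regions)
    bc = BaselineCorrector(anchor_regions=rs, ppm=ds.ppm).fit()
    corrected = bc.transform(ds.intensities)
    model = BaselineModel(
        slopes=bc.slopes_, intercepts=bc.intercepts_, anchor_regions=rs
    )
    out = ds.copy_with(intensities=corrected)
    out.log_step("baseline_correct", anchors=rs.intervals)
    return out, model


def global_align(
    ds: SpectraDataset,
    ref_regions=DEFAULT_ALIGN_REF,
    n_iter: int = 4,
    max_shift: int = DEFAULT_MAX_SHIFT,
) -> tuple[SpectraDataset, AlignmentResult]:
    """Whole-spectrum rigid alignment against the reference zone."""
    aligner = SpectrumAligner(
        mode="global", regions=ref_regions, n_iter=n_iter,
        max_shift=max_shift, ppm=ds.ppm,
    )
    aligned = aligner.fit_transform(ds.intensities)
    out = ds.copy_with(intensities=aligned)
    out.log_step("global_align", n_iter=n_iter, max_shift=max_shift)
    return out, aligner.result_


def interval_align(
    ds: SpectraDataset,
    intervals=DEFAULT_ALIGN_INTERVALS,
    pretreatment: str = "none",
    max_shift: int = DEFAULT_MAX_SHIFT,
) -> tuple[SpectraDataset, AlignmentResult]:
    """Independent per-interval alignment with optional SNV/derivative
    pretreatment used only for lag estimation."""
    rs = RegionSet.coerce(intervals)
    if len(rs) == 0:
        out = ds.copy_with()
        out.log_step("interval_align", intervals=[])
        return out, AlignmentResult(interval_shifts={}, iterations_run=0)
    aligner = SpectrumAligner(
        mode="interval", regions=rs, max_shift=max_shift,
        pretreatment=pretreatment, ppm=ds.ppm,
    )
    aligned = aligner.fit_transform(ds.intensities)
    out = ds.copy_with(intensities=aligned)
    out.log_step("interval_align", intervals=rs.intervals, pretreatment=pretreatment)
    return out, aligner.result_


def pqn_normalize(
    ds: SpectraDataset, reference: str = "median_all"
) -> tuple[SpectraDataset, NormalizationResult]:
    """Probabilistic quotient normalization; stores dilution estimates."""
    norm = PQNNormalizer(reference=reference, class_labels=ds.class_labels)
    normalized = norm.fit(ds.intensities).transform(ds.intensities)
    out = ds.copy_with(intensities=normalized)
    out.log_step("pqn_normalize", reference=reference)
    return out, NormalizationResult(quotients=norm.quotients_, reference=reference)
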