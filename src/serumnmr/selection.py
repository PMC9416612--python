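"""Discriminatory-variable ranking and metabolite annotation.

Two rankings over spectral variables are provided: variable importance in
projection (VIP), the per-variable share of the explained Y variance, and
the selectivity ratio — explained over residual variance per variable
under the target projection of the model's regression vector.  Contiguous
high-ranking variables are merged into ppm regions and annotated with the
library multiplets falling inside them.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .library import MetaboliteLibrary
from .models import OPLS


class EmptySelectionError(ValueError):
    """No variable exceeds the selection quantile."""


@dataclasses.dataclass
class VIPProfile:
    vip: np.ndarray


@dataclasses.dataclass
class SelectivityRatioProfile:
    sr: np.ndarray
    target_scores: np.ndarray


@dataclasses.dataclass
class MarkerReport:
    regions: pd.DataFrame  # low_ppm, high_ppm, peak_statistic, direction, metabolites
    statistic: str
    quantile: float
    tolerance: float


def vip_from_components(weights: np.ndarray, ssy: np.ndarray) -> np.ndarray:
    """VIP over PLS components: vip_i = sqrt(P Σ_a w_ia² SSY_a / Σ_a SSY_a).

    Weights are normalized per component; Σ vip² = P by construction.
    """
    W = np.atleast_2d(np.asarray(weights, dtype=float))
    if W.shape[0] < W.shape[1]:  # accept (A, P) or (P, A)
        W = W.T
    ssy = np.atleast_1d(np.asarray(ssy, dtype=float))
    if ssy.sum() <= 0:
        raise ValueError("total explained Y-variance is zero")
    W = W / np.linalg.norm(W, axis=0)
    p = W.shape[0]
    return np.sqrt(p * (W**2 @ ssy) / ssy.sum())


def vip(model: OPLS) -> VIPProfile:
    """VIP of the fitted model's predictive component(s).

    With a single predictive component the formula collapses to
    sqrt(P)·|w|.
    """
    ssy = np.array([(model.q_**2) * float(model.t_ @ model.t_)])
    return VIPProfile(vip=vip_from_components(model.w_[:, None], ssy))


def selectivity_ratio(model: OPLS, Xs: np.ndarray) -> SelectivityRatioProfile:
    """Explained/residual variance per variable under target projection.

    t_TP = Xs·b/‖b‖ and p_TP = Xs'·t_TP/(t_TP'·t_TP); for each variable the
    ratio of the variance captured by t_TP·p_TP to the residual variance.
    For centered columns this equals r²/(1−r²) with r = corr(Xs_i, t_TP).
    """
    Xs = np.asarray(Xs, dtype=float)
    b = model.b_
    nb = np.linalg.norm(b)
    if nb == 0:
        raise ValueError("zero regression vector")
    t = Xs @ (b / nb)
    p = Xs.T @ t / (t @ t)
    explained = (t @ t) * p**2
    resid = Xs - np.outer(t, p)
    residual = np.sum(resid**2, axis=0)
    tol = np.finfo(float).eps * max(1.0, float(explained.max()))
    with np.errstate(divide="ignore"):
        sr = np.where(residual > tol, explained / residual, np.inf)
    return SelectivityRatioProfile(sr=sr, target_scores=t)


def map_regions_to_metabolites(
    values: np.ndarray,
    ppm: np.ndarray,
    library: MetaboliteLibrary,
    quantile: float = 0.98,
    tolerance: float = 0.02,
    max_gap: int = 3,
    loadings: np.ndarray | None = None,
    statistic: str = "sr",
) -> MarkerReport:
    """Merge above-quantile variables into regions and annotate them.

    Variables strictly above the profile's ``quantile`` are merged into
    contiguous runs (gaps of up to ``max_gap`` grid points allowed), and
    each region is annotated with every library multiplet whose shift lies
    within the region ± ``tolerance`` ppm.  Direction of class association
    is the sign of the summed back-scaled loading over the region, when
    loadings are supplied.
    """
    values = np.asarray(values, dtype=float)
    ppm = np.asarray(ppm, dtype=float)
    if values.size != ppm.size:
        raise ValueError("profile is not aligned to the axis")
    threshold = np.quantile(values[np.isfinite(values)], quantile)
    selected = np.flatnonzero(values > threshold)
    if selected.size == 0:
        raise EmptySelectionError(
            f"no variable exceeds the {quantile:.3f} quantile"
        )

    runs: list[tuple[int, int]] = []
    start = prev = selected[0]
    for idx in selected[1:]:
        if idx - prev > max_gap:
            runs.append((start, prev))
            start = idx
        prev = idx
    runs.append((start, prev))

    rows = []
    for lo_i, hi_i in runs:
        lo, hi = float(ppm[lo_i]), float(ppm[hi_i])
        seg = slice(lo_i, hi_i + 1)
        matched = sorted(
            {
                e.metabolite_name
                for e in library.entries
                if lo - tolerance <= e.center_shift <= hi + tolerance
            }
        )
        if loadings is not None:
            direction = float(np.sign(np.sum(loadings[seg])))
        else:
            direction = float("nan")
        rows.append(
            {
                "low_ppm": lo,
                "high_ppm": hi,
                "peak_statistic": float(np.nanmax(values[seg])),
                "direction": direction,
                "metabolites": ";".join(matched),
            }
        )
    regions = pd.DataFrame(rows).sort_values(
        "peak_statistic", ascending=False, ignore_index=True
    )
    return MarkerReport(
        regions=regions, statistic=statistic, quantile=quantile, tolerance=tolerance
    )
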