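"""Shared test utilities: tiny dataset factory and an independent PLS1 oracle."""

import numpy as np

from serumnmr.dataset import SpectraDataset, make_sample_table


def toy_dataset(X, ppm=None, classes=None):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if ppm is None:
        ppm = np.linspace(0.0, 10.0, X.shape[1])
    if classes is None:
        classes = ["Control"] * n
    table = make_sample_table([f"s{i}" for i in range(n)], classes, 1)
    return SpectraDataset(ppm=ppm, intensities=X, samples=table)


def nipals_pls1_fitted(X, y, n_components):
    """Plain NIPALS PLS1 (fitted values), independent of the OPLS code path."""
    Xd = np.asarray(X, dtype=float).copy()
    y = np.asarray(y, dtype=float)
    yd = y - y.mean()
    fitted = np.full(y.shape, y.mean())
    for _ in range(n_components):
        w = Xd.T @ yd
        w /= np.linalg.norm(w)
        t = Xd @ w
        p = Xd.T @ t / (t @ t)
        q = yd @ t / (t @ t)
        Xd -= np.outer(t, p)
        yd = yd - q * t
        fitted = fitted + q * t
    return fitted
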