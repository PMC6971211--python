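"""Weighted functional connectome estimation.

A connectome is the symmetric matrix of Fisher-z transformed Pearson
correlations between ROI time series, with entries whose Benjamini-Hochberg
FDR-corrected p-value exceeds the chosen level set exactly to zero.  Graphs
are kept fully weighted (no density thresholding) and negative correlations
are stored with their sign; metric modules decide how to consume them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "Connectome",
    "pearson_matrix",
    "correlation_pvalues",
    "fisher_z",
    "build_connectome",
    "effective_samples_bandlimited",
    "write_connectome",
    "read_connectome",
    "edge_list",
]

#: correlations are clipped to this magnitude before atanh so that duplicated
#: columns yield a large finite weight instead of infinity
R_CLIP = 1.0 - 1e-7


@dataclass
class Connectome:
    """Symmetric n x n Fisher-z weight matrix with zero diagonal."""

    weights: np.ndarray
    atlas_name: Optional[str] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        W = np.asarray(self.weights, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("weights must be a square matrix")
        if not np.isfinite(W).all():
            raise ValueError("weights contain non-finite values")
        if not np.allclose(W, W.T, atol=1e-12):
            raise ValueError("weights must be symmetric")
        np.fill_diagonal(W, 0.0)
        self.weights = W

    @property
    def n_rois(self) -> int:
        return self.weights.shape[0]

    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, 1)))


def pearson_matrix(data: np.ndarray) -> np.ndarray:
    """Pearson correlation between columns of a T x n matrix.

    Cross-products of centered columns normalised by the product of their
    root sums of squares.  Zero-variance columns get zero correlation with
    every other column (with a warning) and a unit diagonal entry.
    """
    X = np.asarray(data, dtype=float)
    if X.ndim != 2 or X.shape[0] < 4:
        raise ValueError("need a T x n matrix with T >= 4")
    X = X - X.mean(axis=0, keepdims=True)
    norms = np.sqrt(np.sum(X**2, axis=0))
    degenerate = norms == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance column(s); their correlations set to 0",
            stacklevel=2,
        )
    safe = np.where(degenerate, 1.0, norms)
    r = (X.T @ X) / np.outer(safe, safe)
    r[degenerate, :] = 0.0
    r[:, degenerate] = 0.0
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)


def correlation_pvalues(r: np.ndarray, T: int) -> np.ndarray:
    """Two-sided p-values for Pearson correlations from T samples.

    Uses the exact null distribution of t = r * sqrt((T-2)/(1-r^2)) on T-2
    degrees of freedom; |r| = 1 maps to p = 0.  Diagonal entries are set to 0
    (self-correlations are never tested).
    """
    if T <= 3:
        raise ValueError("need T > 3")
    r = np.asarray(r, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((T - 2) / (1.0 - r**2))
    p = np.where(np.abs(r) >= 1.0, 0.0, 2.0 * stats.t.sf(np.abs(t), df=T - 2))
    if p.ndim == 2 and p.shape[0] == p.shape[1]:
        np.fill_diagonal(p, 0.0)
    return p


def fisher_z(r):
    """Fisher z-transform atanh(r), clipping |r| at 1 - 1e-7 to stay finite."""
    r = np.clip(np.asarray(r, dtype=float), -R_CLIP, R_CLIP)
    return np.arctanh(r)


def effective_samples_bandlimited(T: int, tr_seconds: float, low_hz: float, high_hz: float) -> int:
    """Independent-sample count of an ideally band-passed length-T series.

    A brick-wall filter keeps B Fourier bins, i.e. about 2B real degrees of
    freedom; correlation p-values computed on the nominal T are then
    anti-conservative.  Passing this count as ``effective_samples`` to
    :func:`build_connectome` restores the calibration of the FDR mask on
    band-limited data.
    """
    freqs = np.fft.rfftfreq(T, d=tr_seconds)
    bins = int(((freqs >= low_hz) & (freqs <= high_hz) & (freqs > 0)).sum())
    return max(4, 2 * bins)


def build_connectome(
    ts,
    q: float = 0.05,
    atlas_name: Optional[str] = None,
    effective_samples: Optional[int] = None,
) -> Connectome:
    """Estimate the FDR-masked Fisher-z connectome of one ROI time series.

    Benjamini-Hochberg is applied across the n(n-1)/2 distinct ROI pairs at
    level ``q``; surviving pairs carry atanh(r), the rest are exactly zero.
    ``ts`` may be an object with a ``data`` attribute or a bare T x n array.

    By default p-values use the number of scans T as the sample size.  For
    band-limited series, ``effective_samples`` substitutes a corrected
    degrees-of-freedom count (see :func:`effective_samples_bandlimited`).
    """
    data = getattr(ts, "data", ts)
    data = np.asarray(data, dtype=float)
    if data.shape[1] < 2:
        raise ValueError("need at least 2 ROIs")
    r = pearson_matrix(data)
    p = correlation_pvalues(r, T=effective_samples or data.shape[0])
    n = r.shape[0]
    iu = np.triu_indices(n, k=1)
    if q <= 0:
        keep = np.zeros(len(iu[0]), dtype=bool)
    else:
        keep, _, _, _ = multipletests(p[iu], alpha=q, method="fdr_bh")
    z_upper = np.where(keep, fisher_z(r[iu]), 0.0)
    Z = np.zeros((n, n))
    Z[iu] = z_upper
    Z = Z + Z.T
    meta = {}
    for key in ("subject_id", "run", "condition"):
        if hasattr(ts, key):
            meta[key] = getattr(ts, key)
    meta["fdr_q"] = q
    return Connectome(weights=Z, atlas_name=atlas_name, meta=meta)


def write_connectome(conn: Connectome, path) -> None:
    np.savetxt(Path(path), conn.weights, delimiter="\t")


def read_connectome(path, atlas_name: Optional[str] = None, meta: Optional[dict] = None) -> Connectome:
    W = np.loadtxt(Path(path), delimiter="\t")
    return Connectome(weights=W, atlas_name=atlas_name, meta=dict(meta or {}))


def edge_list(conn: Connectome) -> pd.DataFrame:
    """Non-zero upper-triangle edges as (roi_i, roi_j, weight), 1-based labels."""
    iu = np.triu_indices(conn.n_rois, k=1)
    w = conn.weights[iu]
    nz = w != 0
    return pd.DataFrame(
        {"roi_i": iu[0][nz] + 1, "roi_j": iu[1][nz] + 1, "weight": w[nz]}
    )
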