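"""Pearson correlation maps against representative signals.

Every scan pixel's working curve is correlated with each representative
signal S_k, giving n correlation maps over the scan grid.  For display,
each map is thresholded at its own median (values strictly below the
median are zeroed, suppressing weakly correlated regions), and up to
three thresholded maps are composed into an RGB image whose channels
are max-normalized so mixtures and gradients remain visible.

Correlations are computed on the normalized, resampled curves -- the
pipeline's working representation -- using the sample (n-1) covariance
convention.  Pixels excluded upstream (or with zero-variance curves)
carry NaN, flagged as missing rather than zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .preprocess import CurveMatrix
from .representatives import RepresentativeSignal
from .scattering_io import ScanGrid, flat_to_grid_index

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationMaps",
    "pearson",
    "correlation_maps",
    "threshold_median",
    "compose_rgb",
]


@dataclass
class CorrelationMaps:
    """Per-cluster correlation maps plus their thresholded versions."""

    rho: np.ndarray  # (n, ny, nx), values in [-1, 1] or NaN for missing
    cluster_ids: list[int]
    grid: ScanGrid
    thresholded: np.ndarray | None = None  # same shape, sub-median zeroed
    medians: np.ndarray | None = None  # (n,) per-map medians used

    def map_for(self, cluster_id: int, thresholded: bool = False) -> np.ndarray:
        arr = self.thresholded if thresholded else self.rho
        if arr is None:
            raise ValueError("maps have not been thresholded yet")
        return arr[self.cluster_ids.index(cluster_id)]


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson's correlation rho = cov(x, y) / (sigma_x sigma_y).

    Sample (n-1) convention throughout; the result lies in [-1, 1].
    Zero-variance input makes the coefficient undefined: NaN is returned
    (a flagged missing value, deliberately not 0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be 1-D arrays of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(xc @ xc)
    sy = np.sqrt(yc @ yc)
    if sx == 0 or sy == 0:
        return float("nan")
    return float(np.clip((xc @ yc) / (sx * sy), -1.0, 1.0))


def correlation_maps(
    curves: CurveMatrix,
    reps: list[RepresentativeSignal],
    grid: ScanGrid,
) -> CorrelationMaps:
    """Correlate every pixel's curve with each representative signal.

    The (vectorized) result equals a per-pixel :func:`pearson` loop.
    Excluded rows map to NaN.
    """
    if not reps:
        raise ValueError("need at least one representative signal")
    if curves.r != grid.n_pixels:
        raise ValueError("curve count does not match the scan grid")
    for s in reps:
        if not np.array_equal(s.q, curves.q_centers):
            raise ValueError("representatives must share the working q grid")

    X = curves.values - curves.values.mean(axis=1, keepdims=True)
    sx = np.linalg.norm(X, axis=1)
    S = np.array([s.curve for s in reps])
    S = S - S.mean(axis=1, keepdims=True)
    ss = np.linalg.norm(S, axis=1)
    if np.any(ss == 0):
        raise ValueError("a representative signal has zero variance")

    with np.errstate(invalid="ignore", divide="ignore"):
        rho_flat = (X @ S.T) / (sx[:, None] * ss[None, :])
    rho_flat = np.clip(rho_flat, -1.0, 1.0)
    rho_flat[sx == 0] = np.nan
    rho_flat[curves.excluded] = np.nan

    n = len(reps)
    rho = np.full((n, grid.ny, grid.nx), np.nan)
    for k in range(grid.n_pixels):
        row, col = flat_to_grid_index(k, grid)
        rho[:, row, col] = rho_flat[k]
    return CorrelationMaps(
        rho=rho, cluster_ids=[s.cluster_id for s in reps], grid=grid
    )


def threshold_median(maps: CorrelationMaps) -> CorrelationMaps:
    """Zero every entry strictly below its map's median; idempotent.

    The median is taken per cluster map over all finite pixels; entries
    equal to the median are retained.  Missing (NaN) pixels become 0 in
    the thresholded maps.
    """
    thr = np.zeros_like(maps.rho)
    medians = np.empty(maps.rho.shape[0])
    for k in range(maps.rho.shape[0]):
        finite = np.isfinite(maps.rho[k])
        if not finite.any():
            raise ValueError(f"correlation map {k} has no finite values")
        med = float(np.median(maps.rho[k][finite]))
        medians[k] = med
        keep = finite & (maps.rho[k] >= med)
        thr[k][keep] = maps.rho[k][keep]
    maps.thresholded = thr
    maps.medians = medians
    return maps


def compose_rgb(
    maps: CorrelationMaps, channel_assignment: tuple[int, int, int]
) -> np.ndarray:
    """Compose three thresholded maps into an (ny, nx, 3) RGB image.

    Each channel is one cluster's thresholded map with negatives clipped
    to 0 and divided by its own maximum, so relative spatial structure
    survives weak absolute correlations.  Missing values render as 0.
    """
    if len(set(channel_assignment)) != 3:
        raise ValueError(
            "need 3 distinct cluster ids for RGB; with fewer clusters "
            "render individual maps in grayscale instead"
        )
    if maps.thresholded is None:
        threshold_median(maps)
    rgb = np.zeros((maps.grid.ny, maps.grid.nx, 3))
    for ch, cid in enumerate(channel_assignment):
        plane = np.clip(maps.map_for(cid, thresholded=True), 0.0, None)
        plane = np.nan_to_num(plane, nan=0.0)
        peak = plane.max()
        if peak == 0:
            logger.warning("cluster %d: thresholded map is all zero", cid)
        else:
            plane = plane / peak
        rgb[:, :, ch] = plane
    return rgb
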