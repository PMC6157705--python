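"""Curve preprocessing: background subtraction, normalization, log-resampling.

The analysis operates on an r x c matrix M1 of scattering curves, one
row per scan pixel.  Each curve is normalized by its own mean intensity
over the measured q range, so that classification responds to curve
*shape* rather than magnitude (thickness or flux variations), and then
resampled onto a logarithmic q grid that reduces the number of q values
by a configurable factor (default 10), damping high-frequency counting
noise.  Normalization precedes resampling: the row mean is taken over
the measured range as acquired.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .scattering_io import ScatteringCurve

logger = logging.getLogger(__name__)

__all__ = [
    "CurveMatrix",
    "curves_to_matrix",
    "subtract_background",
    "normalize_transmission",
    "normalize_mean",
    "log_resample",
]


@dataclass
class CurveMatrix:
    """Stack of curves on a shared q grid, with preprocessing provenance.

    ``excluded`` flags rows that cannot be normalized (all-zero curves);
    they are carried along so the scan mapping stays intact but are left
    out of clustering and later rendered as unassigned pixels.
    """

    values: np.ndarray  # (r, c), nonnegative
    q_centers: np.ndarray  # (c,), strictly increasing, nm^-1
    normalized: bool = False
    resampled: bool = False
    background_subtracted: bool = False
    excluded: np.ndarray = field(default=None)  # (r,) bool

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.q_centers = np.asarray(self.q_centers, dtype=float)
        if self.values.shape[1] != self.q_centers.size:
            raise ValueError("column count must match the q grid")
        if np.any(np.diff(self.q_centers) <= 0) or np.any(self.q_centers <= 0):
            raise ValueError("q centers must be positive and strictly increasing")
        if self.excluded is None:
            self.excluded = np.zeros(self.values.shape[0], dtype=bool)
        else:
            self.excluded = np.asarray(self.excluded, dtype=bool)

    @property
    def r(self) -> int:
        return self.values.shape[0]

    @property
    def c(self) -> int:
        return self.values.shape[1]


def curves_to_matrix(curves: list[ScatteringCurve]) -> CurveMatrix:
    """Stack curves into a CurveMatrix; all must share one q grid exactly.

    Curves on differing grids are rejected rather than silently
    interpolated.
    """
    if not curves:
        raise ValueError("no curves given")
    q = curves[0].q
    for i, c in enumerate(curves):
        if not np.array_equal(c.q, q):
            raise ValueError(f"curve {i} is on a different q grid")
    return CurveMatrix(
        values=np.array([c.intensity for c in curves]), q_centers=q.copy()
    )


def subtract_background(
    matrix: CurveMatrix, background: ScatteringCurve
) -> CurveMatrix:
    """Subtract a common background curve, clipping negatives to zero.

    Intensities are photon counts, so negative residuals are treated as
    noise and clipped; the number of clipped samples is logged.
    """
    if not np.array_equal(background.q, matrix.q_centers):
        raise ValueError("background is on a different q grid")
    diff = matrix.values - background.intensity[None, :]
    n_clipped = int(np.sum(diff < 0))
    if n_clipped:
        logger.info("background subtraction clipped %d negative values", n_clipped)
    out = CurveMatrix(
        values=np.clip(diff, 0.0, None),
        q_centers=matrix.q_centers,
        normalized=matrix.normalized,
        resampled=matrix.resampled,
        background_subtracted=True,
        excluded=matrix.excluded.copy(),
    )
    empty = ~np.any(out.values > 0, axis=1)
    if empty.any():
        logger.info("%d curves are empty after background subtraction", empty.sum())
        out.excluded |= empty
    return out


def normalize_transmission(
    matrix: CurveMatrix, transmission: np.ndarray
) -> CurveMatrix:
    """Optional pre-step: divide each curve by its pixel's transmission.

    Off by default in the pipeline; shape-based classification uses the
    per-curve mean normalization instead.
    """
    t = np.asarray(transmission, dtype=float)
    if t.shape != (matrix.r,):
        raise ValueError("need one transmission value per curve")
    if np.any(t <= 0) or np.any(t > 1):
        raise ValueError("transmission values must lie in (0, 1]")
    return CurveMatrix(
        values=matrix.values / t[:, None],
        q_centers=matrix.q_centers,
        normalized=matrix.normalized,
        resampled=matrix.resampled,
        background_subtracted=matrix.background_subtracted,
        excluded=matrix.excluded.copy(),
    )


def normalize_mean(matrix: CurveMatrix) -> CurveMatrix:
    """Divide each curve by its mean intensity over the measured q range.

    Rows with zero mean (all-zero curves) cannot be normalized; they are
    flagged excluded and passed through as zeros so the scan mapping is
    preserved.
    """
    means = matrix.values.mean(axis=1)
    zero = means <= 0
    safe = np.where(zero, 1.0, means)
    values = matrix.values / safe[:, None]
    if zero.any():
        logger.info("%d all-zero curves excluded from normalization", zero.sum())
    return CurveMatrix(
        values=values,
        q_centers=matrix.q_centers,
        normalized=True,
        resampled=matrix.resampled,
        background_subtracted=matrix.background_subtracted,
        excluded=matrix.excluded | zero,
    )


def log_resample(matrix: CurveMatrix, reduction_factor: int = 10) -> CurveMatrix:
    """Rebin curves onto a logarithmic q grid, reducing c by the given factor.

    The target grid has ``c = ceil(c_raw / reduction_factor)`` bins with
    edges uniform in log q spanning [q_min, q_max].  Bin values are the
    arithmetic mean of member intensities (averaging, not decimation, so
    high-frequency noise is damped); bin centers are the geometric mean
    of the edges.  Empty bins are filled by linear interpolation from
    neighboring bins and logged.
    """
    if reduction_factor < 2:
        raise ValueError("reduction factor must be >= 2")
    c_raw = matrix.c
    if c_raw < 2 * reduction_factor:
        raise ValueError("too few q points for the requested reduction")
    q = matrix.q_centers
    if q[0] <= 0:
        raise ValueError("q must be positive for logarithmic resampling")

    c_new = int(np.ceil(c_raw / reduction_factor))
    edges = np.geomspace(q[0], q[-1], c_new + 1)
    centers = np.sqrt(edges[:-1] * edges[1:])

    # Right-open bins [e_i, e_{i+1}); the final point lands in the last bin.
    idx = np.clip(np.searchsorted(edges, q, side="right") - 1, 0, c_new - 1)
    counts = np.bincount(idx, minlength=c_new)
    sums = np.zeros((matrix.r, c_new))
    for b in range(c_new):
        members = idx == b
        if counts[b]:
            sums[:, b] = matrix.values[:, members].mean(axis=1)

    empty = counts == 0
    if empty.any():
        logger.info("%d empty log bins filled by interpolation", int(empty.sum()))
        filled = np.flatnonzero(~empty)
        for b in np.flatnonzero(empty):
            sums[:, b] = np.array(
                [
                    np.interp(centers[b], centers[filled], row[filled])
                    for row in sums
                ]
            )

    return CurveMatrix(
        values=sums,
        q_centers=centers,
        normalized=matrix.normalized,
        resampled=True,
        background_subtracted=matrix.background_subtracted,
        excluded=matrix.excluded.copy(),
    )
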