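"""Inflection-point feature extraction.

The classifier keys on the q positions where a curve's first or second
derivative vanishes: Bragg peaks place a first-derivative sign change at
the peak center and second-derivative sign changes at the flanks, while
slope variations of diffuse scattering show up as second-derivative sign
changes only.  Featureless curves (e.g. a pure power law) yield no
detections and become all-zero rows.

Derivatives are taken with respect to log q via Savitzky-Golay local
polynomial smoothing, since the working grid is logarithmically sampled
and slope features correspond to power-law exponents.  Per-curve
detections are pooled into a shared column set: the feature grid q_d is
the union of all detected bins, and each row holds its own normalized
intensity at the bins it detected, zero elsewhere.  This keeps the
feature matrix M2 a fixed r x d array with d < c.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .preprocess import CurveMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureMatrix",
    "smooth_and_differentiate",
    "find_inflections",
    "extract_features",
    "build_feature_matrix",
]


@dataclass
class FeatureMatrix:
    """Sparse r x d matrix of intensities at pooled inflection positions."""

    values: np.ndarray  # (r, d)
    feature_q: np.ndarray  # (d,) subset of the source q centers
    feature_bins: np.ndarray  # (d,) column indices into the source matrix
    source: CurveMatrix

    @property
    def d(self) -> int:
        return self.values.shape[1]


def smooth_and_differentiate(
    row: np.ndarray,
    log_q: np.ndarray,
    window: int = 7,
    polyorder: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """First and second derivative estimates of I with respect to log q.

    Uses Savitzky-Golay local least-squares polynomial fits on the
    (log-uniform) working grid; endpoints are handled by evaluating the
    one-sided boundary fits.  ``window`` must be odd and ``polyorder``
    at least 2 (a second derivative of a lower-order fit is identically
    zero) and smaller than the window.
    """
    row = np.asarray(row, dtype=float)
    log_q = np.asarray(log_q, dtype=float)
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be an odd integer >= 3")
    if window > row.size:
        raise ValueError("window larger than the curve")
    if not 2 <= polyorder < window:
        raise ValueError("polyorder must satisfy 2 <= polyorder < window")
    delta = np.diff(log_q)
    step = delta.mean()
    if np.any(np.abs(delta - step) > 1e-6 * step):
        logger.warning("q grid is not log-uniform; derivative spacing approximated")
    d1 = savgol_filter(row, window, polyorder, deriv=1, delta=step, mode="interp")
    d2 = savgol_filter(row, window, polyorder, deriv=2, delta=step, mode="interp")
    return d1, d2


def _sign_change_bins(v: np.ndarray, floor: float) -> set[int]:
    """Bins where v changes sign, with a lobe-prominence noise guard.

    Consecutive nonzero samples of opposite sign mark a zero crossing.
    Its two flanks are the same-sign lobes on either side; the crossing
    is kept only when both flanking lobes reach ``floor`` at their
    extremum (a noise blip inside a large lobe produces two crossings
    flanked by a tiny lobe, so both are discarded and the lobe
    effectively stays whole).  The bin nearer the linearly interpolated
    zero crossing is reported.
    """
    nz = np.flatnonzero(v)
    if nz.size < 2:
        return set()
    signs = np.sign(v[nz])
    change = np.flatnonzero(signs[:-1] != signs[1:])
    if change.size == 0:
        return set()
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change, [nz.size - 1]])
    lobe_max = np.array(
        [np.max(np.abs(v[nz[s] : nz[e] + 1])) for s, e in zip(starts, ends)]
    )
    bins: set[int] = set()
    for k, c in enumerate(change):
        if min(lobe_max[k], lobe_max[k + 1]) < floor:
            continue
        a, b = nz[c], nz[c + 1]
        zc = a + v[a] * (b - a) / (v[a] - v[b])
        bins.add(int(round(zc)))
    return bins


def find_inflections(
    d1: np.ndarray, d2: np.ndarray, prominence_floor: float = 0.2
) -> set[int]:
    """Bins where the first OR second derivative changes sign.

    ``prominence_floor`` is a noise guard expressed as a fraction of the
    row's maximum derivative magnitude (per derivative order): sign
    changes whose flanking magnitudes stay below the floor are judged
    noise and discarded.  An empty result is legitimate -- some curves
    have no inflection or peak in the measured range.  A bin where both
    derivatives change sign counts once.
    """
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    bins: set[int] = set()
    m1 = np.max(np.abs(d1)) if d1.size else 0.0
    m2 = np.max(np.abs(d2)) if d2.size else 0.0
    if m1 > 0:
        bins |= _sign_change_bins(d1, prominence_floor * m1)
    if m2 > 0:
        bins |= _sign_change_bins(d2, prominence_floor * m2)
    return bins


def extract_features(
    matrix: CurveMatrix,
    window: int = 7,
    polyorder: int = 2,
    prominence_floor: float = 0.2,
) -> FeatureMatrix:
    """Detect inflections per row and assemble the pooled feature matrix."""
    log_q = np.log(matrix.q_centers)
    per_row: list[set[int]] = []
    for i in range(matrix.r):
        if matrix.excluded[i]:
            per_row.append(set())
            continue
        d1, d2 = smooth_and_differentiate(
            matrix.values[i], log_q, window=window, polyorder=polyorder
        )
        per_row.append(find_inflections(d1, d2, prominence_floor))
    return build_feature_matrix(matrix, per_row)


def build_feature_matrix(
    matrix: CurveMatrix, inflections: list[set[int]]
) -> FeatureMatrix:
    """Pool per-row inflection bins into the shared r x d feature matrix.

    The column set is the union of all detected bins in increasing q
    order.  Entry (i, j) is row i's intensity at feature bin j when row
    i detected that bin, and 0 otherwise; rows with no detections stay
    all-zero but are retained so the scan mapping is unchanged.
    """
    if len(inflections) != matrix.r:
        raise ValueError("need one inflection set per row")
    union = sorted(set().union(*inflections)) if inflections else []
    if not union:
        raise ValueError(
            "no features: no curve has a detected inflection; "
            "lower prominence_floor or check preprocessing"
        )
    if any(b < 0 or b >= matrix.c for b in union):
        raise ValueError("inflection bin outside the curve grid")
    if len(union) >= matrix.c:
        logger.warning(
            "feature count d=%d is not smaller than c=%d; "
            "prominence floor may be too low",
            len(union),
            matrix.c,
        )
    col_of = {b: j for j, b in enumerate(union)}
    values = np.zeros((matrix.r, len(union)))
    for i, bins in enumerate(inflections):
        for b in bins:
            values[i, col_of[b]] = matrix.values[i, b]
    return FeatureMatrix(
        values=values,
        feature_q=matrix.q_centers[union],
        feature_bins=np.asarray(union, dtype=int),
        source=matrix,
    )
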