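"""Scoring helpers for phantom-validated runs.

These compare pipeline output against the ground truth carried by a
synthetic phantom: segmentation accuracy up to label permutation
(clusters are unordered, so predicted labels are matched to true phases
by the Hungarian algorithm on the confusion matrix) and the bijective
matching of representative signals to true phase spectra by Pearson
correlation.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment

from .corrmaps import pearson
from .preprocess import CurveMatrix, log_resample, normalize_mean
from .representatives import RepresentativeSignal
from .synthdata import PhantomTruth

__all__ = [
    "segmentation_accuracy",
    "processed_phase_curves",
    "representative_phase_correlations",
]


def segmentation_accuracy(
    predicted: np.ndarray,
    truth: PhantomTruth,
) -> float:
    """Fraction of non-mixed pixels labeled correctly up to permutation.

    Interface pixels where no phase reaches weight 0.5 are "mixed" --
    their curves are genuine blends with no single correct label -- and
    are excluded from scoring, as are pixels the pipeline left
    unassigned (label 0).
    """
    predicted = np.asarray(predicted, dtype=int)
    true_labels = truth.true_labels
    if predicted.shape != true_labels.shape:
        raise ValueError("predicted and true label maps must share one shape")
    keep = (~truth.mixed_mask) & (predicted > 0)
    pred = predicted[keep]
    true = true_labels[keep]
    n_pred = int(pred.max())
    n_true = int(true.max())
    k = max(n_pred, n_true)
    confusion = np.zeros((k, k))
    np.add.at(confusion, (pred - 1, true - 1), 1)
    rows, cols = linear_sum_assignment(-confusion)
    return float(confusion[rows, cols].sum() / keep.sum())


def processed_phase_curves(
    truth: PhantomTruth, reduction_factor: int = 10
) -> CurveMatrix:
    """True phase spectra pushed through the same normalize + log-resample
    preprocessing as the data, so they are comparable to working curves."""
    mat = CurveMatrix(
        values=truth.phase_curves(), q_centers=truth.spec.q_grid
    )
    return log_resample(normalize_mean(mat), reduction_factor)


def representative_phase_correlations(
    reps: list[RepresentativeSignal],
    truth: PhantomTruth,
    reduction_factor: int = 10,
) -> np.ndarray:
    """(n_reps, P) matrix of Pearson correlations between each
    representative signal and each preprocessed true phase spectrum."""
    phases = processed_phase_curves(truth, reduction_factor)
    out = np.empty((len(reps), phases.r))
    for i, rep in enumerate(reps):
        if not np.array_equal(rep.q, phases.q_centers):
            raise ValueError("representative is not on the working grid")
        for p in range(phases.r):
            out[i, p] = pearson(rep.curve, phases.values[p])
    return out
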