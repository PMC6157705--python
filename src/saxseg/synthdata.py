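"""Synthetic scanning SAXS/WAXS phantoms with known phase composition.

Real scanning measurements probe a heterogeneous sample with a focused
beam; every scan pixel records an azimuthally integrated curve I(q) to
which all phases along the beam path contribute additively.  This module
builds such datasets from first principles so that every downstream stage
(normalization, feature extraction, clustering, representative-signal
extraction, correlation mapping) can be validated against ground truth.

A phase is modelled as a sum of Gaussian Bragg lines on a power-law plus
constant background -- enough to exercise both feature families the
classification keys on: peak-type features (first derivative changes
sign) and slope-change features (second derivative changes sign).
Mixing is linear in intensity (incoherent addition of phases) and the
detector noise is Poisson, as appropriate for photon counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PhaseSpectrum",
    "PhantomSpec",
    "PhantomTruth",
    "evaluate_phase",
    "generate_phantom",
    "blob_weight_map",
    "quadrant_sites",
    "default_phantom_spec",
    "DEFAULT_PHASES",
]


@dataclass(frozen=True)
class PhaseSpectrum:
    """One pure phase: Gaussian Bragg lines on a power-law + flat background.

    Parameters
    ----------
    peaks
        Sequence of ``(center, sigma, amplitude)`` triples.  Centers and
        widths are in nm^-1, amplitudes in arbitrary counts.
    powerlaw_exponent
        Exponent p of the ``B * q**-p`` diffuse background, p >= 0.
    powerlaw_amplitude
        Amplitude B of the power-law term (counts at q = 1 nm^-1).
    flat_background
        Constant offset F >= 0 (counts).
    """

    peaks: tuple[tuple[float, float, float], ...] = ()
    powerlaw_exponent: float = 0.0
    powerlaw_amplitude: float = 0.0
    flat_background: float = 0.0

    def __post_init__(self) -> None:
        for mu, sigma, amp in self.peaks:
            if sigma <= 0:
                raise ValueError(f"peak width must be > 0, got {sigma}")
            if amp < 0:
                raise ValueError(f"peak amplitude must be >= 0, got {amp}")
        if self.powerlaw_exponent < 0:
            raise ValueError("power-law exponent must be >= 0")
        if self.powerlaw_amplitude < 0:
            raise ValueError("power-law amplitude must be >= 0")
        if self.flat_background < 0:
            raise ValueError("flat background must be >= 0")
        object.__setattr__(self, "peaks", tuple(tuple(p) for p in self.peaks))


def evaluate_phase(spectrum: PhaseSpectrum, q_grid: np.ndarray) -> np.ndarray:
    """Evaluate a phase spectrum on a strictly increasing positive q grid.

    I(q) = sum_peaks A exp(-(q - mu)^2 / (2 sigma^2)) + B q^-p + F.

    Raises
    ------
    ValueError
        If the grid contains non-positive values or is not strictly
        increasing (scattering-vector magnitudes are positive by
        construction).
    """
    q = np.asarray(q_grid, dtype=float)
    if q.ndim != 1 or q.size == 0:
        raise ValueError("q grid must be a non-empty 1-D array")
    if np.any(q <= 0):
        raise ValueError("q grid must be strictly positive")
    if np.any(np.diff(q) <= 0):
        raise ValueError("q grid must be strictly increasing")

    intensity = np.full_like(q, float(spectrum.flat_background))
    if spectrum.powerlaw_amplitude > 0:
        intensity = intensity + spectrum.powerlaw_amplitude * q ** (
            -spectrum.powerlaw_exponent
        )
    for mu, sigma, amp in spectrum.peaks:
        intensity = intensity + amp * np.exp(-((q - mu) ** 2) / (2.0 * sigma**2))
    return intensity


@dataclass
class PhantomSpec:
    """Full description of a synthetic scan: grid, phases, mixing, noise.

    ``weight_map`` has shape (ny, nx, P); per-pixel weights must sum to 1.
    ``counts_scale`` is the expected total number of detected photons per
    curve (summed over q); the Poisson draw is scaled accordingly.
    """

    q_grid: np.ndarray
    phases: list[PhaseSpectrum]
    weight_map: np.ndarray
    counts_scale: float = 1e5
    seed: int = 0

    def __post_init__(self) -> None:
        self.q_grid = np.asarray(self.q_grid, dtype=float)
        self.weight_map = np.asarray(self.weight_map, dtype=float)
        if np.any(self.q_grid <= 0) or np.any(np.diff(self.q_grid) <= 0):
            raise ValueError("q grid must be positive and strictly increasing")
        if len(self.phases) < 2:
            raise ValueError("need at least 2 phases")
        if self.weight_map.ndim != 3 or self.weight_map.shape[2] != len(self.phases):
            raise ValueError(
                "weight map must have shape (ny, nx, P) with P = number of phases"
            )
        ny, nx, P = self.weight_map.shape
        if ny * nx < 4 * P:
            raise ValueError("grid too small: need ny*nx >= 4*P pixels")
        if np.any(self.weight_map < 0):
            raise ValueError("mixing weights must be nonnegative")
        sums = self.weight_map.sum(axis=2)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("per-pixel mixing weights must sum to 1")
        if self.counts_scale < 0:
            raise ValueError("counts_scale must be >= 0")
        # Peak centers must lie inside the phantom q range so every phase
        # contributes detectable features.
        qlo, qhi = self.q_grid[0], self.q_grid[-1]
        for k, ph in enumerate(self.phases):
            for mu, _, _ in ph.peaks:
                if not (qlo <= mu <= qhi):
                    raise ValueError(
                        f"phase {k}: peak center {mu} outside q range [{qlo}, {qhi}]"
                    )

    @property
    def shape(self) -> tuple[int, int]:
        return self.weight_map.shape[:2]


@dataclass
class PhantomTruth:
    """Generated phantom plus everything needed to score the pipeline."""

    spec: PhantomSpec
    clean_curves: np.ndarray  # (ny*nx, c_raw), noise-free mixtures
    noisy_curves: np.ndarray  # (ny*nx, c_raw), Poisson realization
    true_labels: np.ndarray  # (ny, nx), argmax-weight phase per pixel, 1-based
    mixed_mask: np.ndarray = field(default=None)  # (ny, nx), True where no
    # phase dominates (max weight < 0.5); such interface pixels are
    # excluded from segmentation-accuracy scoring.

    def phase_curves(self) -> np.ndarray:
        """Pure-phase spectra on the raw grid, shape (P, c_raw)."""
        return np.array(
            [evaluate_phase(ph, self.spec.q_grid) for ph in self.spec.phases]
        )


def generate_phantom(spec: PhantomSpec) -> PhantomTruth:
    """Generate clean and Poisson-noisy curve stacks from a phantom spec.

    The clean curve at pixel (i, j) is the weight mixture of the phase
    spectra.  The noisy curve draws independent Poisson counts per q bin
    with mean proportional to the clean curve, scaled so the *expected*
    total over q equals ``counts_scale``.  Identical spec (including
    seed) gives bit-identical output.
    """
    ny, nx = spec.shape
    P = len(spec.phases)
    phase_mat = np.array([evaluate_phase(ph, spec.q_grid) for ph in spec.phases])
    weights = spec.weight_map.reshape(ny * nx, P)
    clean = weights @ phase_mat  # (r, c_raw)

    rng = np.random.default_rng(spec.seed)
    if spec.counts_scale == 0:
        noisy = np.zeros_like(clean)
    else:
        totals = clean.sum(axis=1, keepdims=True)
        lam = clean * (spec.counts_scale / totals)
        noisy = rng.poisson(lam).astype(float)

    labels = np.argmax(spec.weight_map, axis=2) + 1
    mixed = spec.weight_map.max(axis=2) < 0.5
    return PhantomTruth(
        spec=spec,
        clean_curves=clean,
        noisy_curves=noisy,
        true_labels=labels,
        mixed_mask=mixed,
    )


def blob_weight_map(
    ny: int,
    nx: int,
    P: int,
    mix_width: float = 0.0,
    seed: int = 0,
    sites: np.ndarray | None = None,
) -> np.ndarray:
    """Contiguous single-phase regions with linear cross-fade interfaces.

    Each phase owns the Voronoi cell of a site point; near a cell
    boundary the weight of the locally dominant phase fades linearly
    into the runner-up over a band of ``mix_width`` pixels, emulating
    the gradual mixed-phase transitions seen at real cluster interfaces.

    Parameters
    ----------
    sites
        Optional (P, 2) array of (row, col) site coordinates.  By default
        P sites are drawn uniformly at random (seeded), rejecting layouts
        where two sites collide.

    Returns
    -------
    (ny, nx, P) weight map; nonnegative, each pixel summing to 1.
    ``mix_width = 0`` gives a hard segmentation (one-hot weights).
    """
    if P < 2:
        raise ValueError("need at least 2 phases")
    if mix_width < 0:
        raise ValueError("mix_width must be >= 0")
    if mix_width >= min(ny, nx):
        raise ValueError("mix_width must be smaller than the shortest grid side")

    if sites is None:
        rng = np.random.default_rng(seed)
        for _ in range(100):
            cand = np.column_stack(
                [rng.uniform(0, ny - 1, P), rng.uniform(0, nx - 1, P)]
            )
            d = np.linalg.norm(cand[:, None] - cand[None, :], axis=2)
            if np.min(d[np.triu_indices(P, 1)]) > 1.0:
                sites = cand
                break
        else:  # pragma: no cover - vanishingly unlikely for sane grids
            raise RuntimeError("could not place distinct sites")
    sites = np.asarray(sites, dtype=float)
    if sites.shape != (P, 2):
        raise ValueError(f"sites must have shape ({P}, 2)")

    rows, cols = np.mgrid[0:ny, 0:nx]
    pix = np.stack([rows, cols], axis=-1).astype(float)  # (ny, nx, 2)
    dist = np.linalg.norm(pix[:, :, None, :] - sites[None, None, :, :], axis=3)

    order = np.argsort(dist, axis=2)
    nearest = order[:, :, 0]
    second = order[:, :, 1]
    d1 = np.take_along_axis(dist, nearest[:, :, None], axis=2)[:, :, 0]
    d2 = np.take_along_axis(dist, second[:, :, None], axis=2)[:, :, 0]

    weights = np.zeros((ny, nx, P))
    if mix_width == 0:
        np.put_along_axis(weights, nearest[:, :, None], 1.0, axis=2)
        return weights

    # Signed distance to the bisector between the two nearest sites is
    # (d2 - d1)/2; fade linearly across a band of total width mix_width.
    margin = (d2 - d1) / 2.0
    w_near = np.clip(0.5 + margin / mix_width, 0.0, 1.0)
    np.put_along_axis(weights, nearest[:, :, None], w_near[:, :, None], axis=2)
    cur = np.take_along_axis(weights, second[:, :, None], axis=2)
    np.put_along_axis(
        weights, second[:, :, None], cur + (1.0 - w_near)[:, :, None], axis=2
    )
    return weights


def quadrant_sites(ny: int, nx: int) -> np.ndarray:
    """Four site points at quadrant centers; Voronoi cells are the quadrants."""
    return np.array(
        [
            [ny / 4, nx / 4],
            [ny / 4, 3 * nx / 4],
            [3 * ny / 4, nx / 4],
            [3 * ny / 4, 3 * nx / 4],
        ]
    )


# Default four-phase phantom, loosely styled on a mineral mixture probed
# by WAXS (q = 1..30 nm^-1): three peak-rich crystalline phases with
# distinct Bragg lines plus one diffuse, power-law-dominated phase.
# Peak amplitudes dominate the diffuse background so the normalized
# curve *shapes* are well separated (pairwise correlation <= 0.5), and
# widths grow with q so every line survives tenfold logarithmic
# rebinning of a 1000-point grid (bin width ~3.5% of q).
DEFAULT_PHASES: tuple[PhaseSpectrum, ...] = (
    PhaseSpectrum(
        peaks=((8.5, 0.45, 30.0), (14.5, 0.7, 18.0), (21.0, 1.0, 12.0)),
        powerlaw_exponent=1.8,
        powerlaw_amplitude=8.0,
        flat_background=1.0,
    ),
    PhaseSpectrum(
        peaks=((12.0, 0.6, 25.0), (18.9, 0.9, 28.0), (26.0, 1.3, 12.0)),
        powerlaw_exponent=1.0,
        powerlaw_amplitude=3.0,
        flat_background=1.5,
    ),
    PhaseSpectrum(
        peaks=((6.2, 0.35, 15.0), (19.5, 1.0, 10.0), (28.5, 1.4, 20.0)),
        powerlaw_exponent=2.8,
        powerlaw_amplitude=15.0,
        flat_background=0.5,
    ),
    PhaseSpectrum(
        peaks=((10.3, 0.55, 8.0),),
        powerlaw_exponent=3.5,
        powerlaw_amplitude=60.0,
        flat_background=2.0,
    ),
)


def default_phantom_spec(
    ny: int = 32,
    nx: int = 32,
    counts_scale: float = 1e5,
    mix_width: float = 0.0,
    seed: int = 0,
    c_raw: int = 1000,
) -> PhantomSpec:
    """The documented reference phantom: four phases on quadrants.

    32x32 scan, 1000-point log-spaced q grid over 1..30 nm^-1, expected
    1e5 counts per curve, hard (well-separated) quadrant boundaries.
    Pass ``mix_width > 0`` for the mixed-interface variant with a linear
    cross-fade band at the boundaries.
    """
    q = np.geomspace(1.0, 30.0, c_raw)
    wmap = blob_weight_map(
        ny, nx, 4, mix_width=mix_width, seed=seed, sites=quadrant_sites(ny, nx)
    )
    return PhantomSpec(
        q_grid=q,
        phases=list(DEFAULT_PHASES),
        weight_map=wmap,
        counts_scale=counts_scale,
        seed=seed,
    )
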