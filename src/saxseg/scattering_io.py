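"""Readers and writers for curve stacks, label maps and signal tables.

Two curve-stack containers are supported: delimited text (one q column
followed by one intensity column per scan pixel, grid geometry in header
comments) and an HDF5 container with named arrays.  Label maps are
written as integer-valued PNG/TIFF images with a delimited-text sidecar
so that downstream tools never have to parse colors.

Conventions: scan-pixel indices are 0-based, cluster labels are 1-based
with 0 reserved for "unassigned/excluded".  Raster order maps the flat
curve index k to (row, col) = (k // nx, k % nx) for ``row_major``;
``snake`` additionally reverses the column order of odd rows, matching
continuous scans whose return lines run backwards.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile
from PIL import Image

__all__ = [
    "ScatteringCurve",
    "ScanGrid",
    "LabelMap",
    "FormatError",
    "read_curve_stack",
    "write_curve_stack",
    "write_label_map",
    "read_label_sidecar",
    "write_representatives",
    "read_representatives",
    "flat_to_grid_index",
    "grid_to_flat_index",
    "LABEL_PALETTE",
]


class FormatError(ValueError):
    """A file violated the curve-stack / label-map format contract."""


@dataclass
class ScatteringCurve:
    """One azimuthally integrated curve I(q) at one scan pixel."""

    q: np.ndarray
    intensity: np.ndarray
    pixel: tuple[int, int] | None = None
    transmission: float | None = None

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.q.size != self.intensity.size:
            raise FormatError("q and intensity must have equal length")
        if self.q.size < 8:
            raise FormatError("curve needs at least 8 points")
        if np.any(np.diff(self.q) <= 0) or np.any(self.q <= 0):
            raise FormatError("q must be strictly increasing and positive")
        if not np.all(np.isfinite(self.intensity)):
            raise FormatError("intensities must be finite")
        if self.transmission is not None and not (0 < self.transmission <= 1):
            raise FormatError("transmission must lie in (0, 1]")


@dataclass(frozen=True)
class ScanGrid:
    """Scan raster geometry: ny rows, nx columns, raster convention."""

    ny: int
    nx: int
    raster: str = "row_major"
    pixel_size: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.ny < 1 or self.nx < 1:
            raise ValueError("grid dimensions must be positive")
        if self.raster not in ("row_major", "snake"):
            raise ValueError(f"unknown raster order {self.raster!r}")

    @property
    def n_pixels(self) -> int:
        return self.ny * self.nx


def flat_to_grid_index(k: int, grid: ScanGrid) -> tuple[int, int]:
    """Map flat curve index k to (row, col) under the grid's raster order."""
    row, col = divmod(k, grid.nx)
    if grid.raster == "snake" and row % 2 == 1:
        col = grid.nx - 1 - col
    return row, col


def grid_to_flat_index(row: int, col: int, grid: ScanGrid) -> int:
    """Inverse of :func:`flat_to_grid_index`."""
    if grid.raster == "snake" and row % 2 == 1:
        col = grid.nx - 1 - col
    return row * grid.nx + col


@dataclass
class LabelMap:
    """Cluster label per scan pixel; 0 marks unassigned/excluded pixels."""

    labels: np.ndarray
    grid: ScanGrid

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (self.grid.ny, self.grid.nx):
            raise ValueError("label array shape must match the scan grid")
        if np.any(self.labels < 0):
            raise ValueError("labels must be >= 0")
        assigned = self.labels[self.labels > 0]
        if assigned.size:
            present = np.unique(assigned)
            if not np.array_equal(present, np.arange(1, present[-1] + 1)):
                raise ValueError("assigned labels must form a set {1..n}")

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max())


# Fixed categorical palette (RGB bytes), keyed by label 1..10; label 0
# renders black.  Colors follow the common matplotlib "tab10" cycle.
LABEL_PALETTE = np.array(
    [
        [0, 0, 0],
        [31, 119, 180],
        [255, 127, 14],
        [44, 160, 44],
        [214, 39, 40],
        [148, 103, 189],
        [140, 86, 75],
        [227, 119, 194],
        [127, 127, 127],
        [188, 189, 34],
        [23, 190, 207],
    ],
    dtype=np.uint8,
)


# ---------------------------------------------------------------------------
# curve stacks


def write_curve_stack(
    path: str | Path,
    q: np.ndarray,
    intensities: np.ndarray,
    grid: ScanGrid,
    fmt: str | None = None,
    transmission: np.ndarray | None = None,
) -> Path:
    """Write an (r, c) curve stack sharing one q grid.

    ``fmt`` is "text" (TSV: q column + r intensity columns, geometry in
    ``#`` header lines) or "hdf5"; inferred from the suffix when omitted
    (".h5"/".hdf5" -> hdf5, everything else text).
    """
    path = Path(path)
    q = np.asarray(q, dtype=float)
    intensities = np.atleast_2d(np.asarray(intensities, dtype=float))
    if intensities.shape[0] != grid.n_pixels:
        raise FormatError(
            f"{intensities.shape[0]} curves but grid has {grid.n_pixels} pixels"
        )
    if intensities.shape[1] != q.size:
        raise FormatError("intensity rows must match the q grid length")

    if fmt is None:
        fmt = "hdf5" if path.suffix.lower() in (".h5", ".hdf5") else "text"

    if fmt == "hdf5":
        with h5py.File(path, "w") as f:
            f.create_dataset("q", data=q)
            f.create_dataset("intensities", data=intensities)
            f.attrs["ny"] = grid.ny
            f.attrs["nx"] = grid.nx
            f.attrs["raster"] = grid.raster
            if transmission is not None:
                f.create_dataset("transmission", data=np.asarray(transmission))
    elif fmt == "text":
        with open(path, "w") as f:
            f.write(f"# ny={grid.ny} nx={grid.nx} raster={grid.raster}\n")
            if transmission is not None:
                tvals = " ".join(f"{t:.10g}" for t in np.asarray(transmission))
                f.write(f"# transmission={tvals}\n")
            header = "q\t" + "\t".join(
                f"I_{k:05d}" for k in range(intensities.shape[0])
            )
            f.write(header + "\n")
            np.savetxt(f, np.column_stack([q, intensities.T]), delimiter="\t")
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path


def read_curve_stack(
    path: str | Path, fmt: str | None = None
) -> tuple[list[ScatteringCurve], ScanGrid]:
    """Read a curve stack; returns curves in raster order plus the grid.

    All curves share one q grid (validated).  The k-th curve is bound to
    scan pixel ``flat_to_grid_index(k, grid)``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = "hdf5" if path.suffix.lower() in (".h5", ".hdf5") else "text"

    transmission = None
    if fmt == "hdf5":
        with h5py.File(path, "r") as f:
            q = f["q"][...]
            intensities = f["intensities"][...]
            grid = ScanGrid(
                ny=int(f.attrs["ny"]),
                nx=int(f.attrs["nx"]),
                raster=str(f.attrs["raster"]),
            )
            if "transmission" in f:
                transmission = f["transmission"][...]
    elif fmt == "text":
        meta: dict[str, str] = {}
        with open(path) as f:
            for line in f:
                if not line.startswith("#"):
                    break
                body = line[1:].strip()
                if body.startswith("transmission="):
                    # value is a whitespace-separated list; keep it whole
                    meta["transmission"] = body.split("=", 1)[1]
                    continue
                for tok in body.split():
                    if "=" in tok:
                        key, val = tok.split("=", 1)
                        meta[key] = val
        try:
            grid = ScanGrid(
                ny=int(meta["ny"]), nx=int(meta["nx"]), raster=meta.get("raster", "row_major")
            )
        except KeyError as exc:
            raise FormatError(f"{path}: missing grid geometry header") from exc
        data = np.loadtxt(path, delimiter="\t", skiprows=sum(1 for _ in _headers(path)))
        data = np.atleast_2d(data)
        q = data[:, 0]
        intensities = data[:, 1:].T
        if "transmission" in meta:
            transmission = np.array([float(t) for t in meta["transmission"].split()])
    else:
        raise ValueError(f"unknown format {fmt!r}")

    if np.any(np.diff(q) <= 0) or np.any(q <= 0):
        raise FormatError(f"{path}: q grid not strictly increasing and positive")
    r = intensities.shape[0]
    if r != grid.n_pixels:
        raise FormatError(
            f"{path}: {r} curves but grid declares {grid.n_pixels} pixels"
        )
    curves = []
    for k in range(r):
        curves.append(
            ScatteringCurve(
                q=q,
                intensity=intensities[k],
                pixel=flat_to_grid_index(k, grid),
                transmission=(
                    float(transmission[k]) if transmission is not None else None
                ),
            )
        )
    return curves, grid


def _headers(path: Path):
    """Yield leading comment + column-header lines of a text stack."""
    with open(path) as f:
        for line in f:
            if line.startswith("#") or line.startswith("q\t"):
                yield line
            else:
                return


# ---------------------------------------------------------------------------
# label maps


def write_label_map(label_map: LabelMap, path: str | Path) -> tuple[Path, Path]:
    """Write a label map as an image plus a (row, col, label) CSV sidecar.

    The image stores raw integer labels when the suffix is ".tif"/".tiff"
    and a palette-colored rendering for ".png".  Returns (image path,
    sidecar path).
    """
    path = Path(path)
    labels = label_map.labels
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, labels.astype(np.uint16))
    else:
        rgb = LABEL_PALETTE[labels % len(LABEL_PALETTE)]
        Image.fromarray(rgb, mode="RGB").save(path)
    sidecar = path.with_suffix(".csv")
    rows, cols = np.mgrid[0 : labels.shape[0], 0 : labels.shape[1]]
    pd.DataFrame(
        {"row": rows.ravel(), "col": cols.ravel(), "label": labels.ravel()}
    ).to_csv(sidecar, index=False)
    return path, sidecar


def read_label_sidecar(path: str | Path, grid: ScanGrid | None = None) -> LabelMap:
    """Rebuild a LabelMap from its CSV sidecar."""
    df = pd.read_csv(path)
    ny = int(df["row"].max()) + 1
    nx = int(df["col"].max()) + 1
    if grid is None:
        grid = ScanGrid(ny=ny, nx=nx)
    labels = np.zeros((grid.ny, grid.nx), dtype=int)
    labels[df["row"].to_numpy(), df["col"].to_numpy()] = df["label"].to_numpy()
    return LabelMap(labels=labels, grid=grid)


# ---------------------------------------------------------------------------
# representative-signal tables


def write_representatives(signals, path: str | Path) -> Path:
    """Write representative signals as a TSV: q column + one column per S_i.

    ``signals`` is a sequence of RepresentativeSignal-like objects with
    ``cluster_id``, ``curve``, ``method`` and a shared ``q`` grid.
    """
    signals = list(signals)
    if not signals:
        raise ValueError("no representative signals to write")
    path = Path(path)
    q = np.asarray(signals[0].q, dtype=float)
    for s in signals:
        if not np.array_equal(np.asarray(s.q), q):
            raise FormatError("representatives must share one q grid")
    cols = {"q": q}
    for s in signals:
        cols[f"S_{s.cluster_id}:{s.method}"] = np.asarray(s.curve, dtype=float)
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format="%.12g")
    return path


def read_representatives(path: str | Path) -> pd.DataFrame:
    """Read a representative-signal table back into a DataFrame."""
    return pd.read_csv(path, sep="\t")
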