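"""End-to-end orchestration: curves in, segmented maps and tables out.

``segment_curves`` runs the in-memory analysis chain --

    normalize -> log-resample -> inflection features -> PCA ->
    silhouette-selected k-means -> label map -> representative signals ->
    Pearson correlation maps -> RGB composite

-- and ``run_pipeline`` wraps it with file I/O: it reads a curve stack,
writes every stage's output into the bundle directory and records a
manifest (config values, seed, package versions, content hashes) that
suffices to reproduce the run.  One top-level seed feeds every stochastic
stage, so identical config + seed gives identical output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .cluster import ClusterModel, PCAModel, fit_pca, labels_to_map, select_n_and_fit
from .corrmaps import CorrelationMaps, compose_rgb, correlation_maps, threshold_median
from .features import FeatureMatrix, extract_features
from .preprocess import (
    CurveMatrix,
    curves_to_matrix,
    log_resample,
    normalize_mean,
    normalize_transmission,
    subtract_background,
)
from .representatives import (
    RepresentativeSignal,
    representative_centroid,
    representative_furthest,
)
from .scattering_io import (
    LabelMap,
    ScanGrid,
    read_curve_stack,
    write_curve_stack,
    write_label_map,
    write_representatives,
)
from .synthdata import PhantomTruth, default_phantom_spec, generate_phantom

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "segment_curves",
    "run_pipeline",
    "run_phantom_demo",
]


@dataclass
class PipelineConfig:
    """Flat, file-loadable configuration for one pipeline run."""

    input_path: str | None = None
    output_dir: str = "saxseg_out"
    raster: str = "row_major"
    background_path: str | None = None
    transmission_normalize: bool = False
    normalize: bool = True
    resample_factor: int = 10
    deriv_window: int = 7
    deriv_polyorder: int = 2
    prominence_floor: float = 0.2
    variance_threshold: float = 0.95
    n_min: int = 2
    n_max: int = 8
    kmeans_restarts: int = 20
    rep_method: str = "both"  # centroid | furthest | both
    rep_fraction: float = 0.10
    rgb_clusters: tuple[int, int, int] | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_min < 2 or self.n_max < self.n_min:
            raise ValueError(
                "cluster-count range invalid: need 2 <= n_min <= n_max "
                "(the silhouette criterion is undefined for one cluster)"
            )
        if self.rep_method not in ("centroid", "furthest", "both"):
            raise ValueError(f"unknown rep_method {self.rep_method!r}")
        if self.resample_factor < 2:
            raise ValueError("resample_factor must be >= 2")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Parse a flat ``key = value`` text config (# starts a comment)."""
        fields = {f.name: f for f in dataclasses.fields(cls)}
        kwargs: dict = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, val = (s.strip() for s in line.split("=", 1))
            if key not in fields:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            kwargs[key] = _coerce(val, fields[key].type)
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    def to_text(self) -> str:
        lines = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if v is None:
                continue
            if isinstance(v, tuple):
                v = ",".join(str(x) for x in v)
            lines.append(f"{f.name} = {v}")
        return "\n".join(lines) + "\n"


def _coerce(val: str, typ: str):
    if val.lower() in ("none", ""):
        return None
    if "bool" in typ:
        return val.lower() in ("1", "true", "yes", "on")
    if "tuple" in typ:
        return tuple(int(x) for x in val.replace(",", " ").split())
    if "int" in typ and "str" not in typ:
        return int(val)
    if "float" in typ:
        return float(val)
    return val


@dataclass
class PipelineResult:
    """Everything the analysis chain produced, stage by stage."""

    config: PipelineConfig
    grid: ScanGrid
    m1: CurveMatrix
    m2: FeatureMatrix
    pca: PCAModel
    clusters: ClusterModel
    label_map: LabelMap
    representatives: list[RepresentativeSignal]
    corr: CorrelationMaps
    rgb: np.ndarray | None
    excluded_rows: np.ndarray

    @property
    def n(self) -> int:
        return self.clusters.n


def segment_curves(
    values: np.ndarray,
    q: np.ndarray,
    grid: ScanGrid,
    config: PipelineConfig | None = None,
    background=None,
    transmission: np.ndarray | None = None,
) -> PipelineResult:
    """Run the full in-memory analysis on an (r, c_raw) curve stack."""
    cfg = config or PipelineConfig()
    cfg.validate()

    m1 = CurveMatrix(values=values, q_centers=q)
    if m1.r != grid.n_pixels:
        raise ValueError("curve count does not match the scan grid")
    if transmission is not None and cfg.transmission_normalize:
        m1 = normalize_transmission(m1, transmission)
    if background is not None:
        m1 = subtract_background(m1, background)
    if cfg.normalize:
        m1 = normalize_mean(m1)
    m1 = log_resample(m1, cfg.resample_factor)

    m2 = extract_features(
        m1,
        window=cfg.deriv_window,
        polyorder=cfg.deriv_polyorder,
        prominence_floor=cfg.prominence_floor,
    )

    keep = ~m1.excluded
    pca = fit_pca(m2.values[keep], variance_threshold=cfg.variance_threshold)
    clusters = select_n_and_fit(
        pca.selected_scores,
        n_candidates=(cfg.n_min, cfg.n_max),
        seed=cfg.seed,
        restarts=cfg.kmeans_restarts,
    )
    label_map = labels_to_map(
        clusters.labels, grid, excluded=np.flatnonzero(m1.excluded)
    )

    # Representatives and correlations operate on the kept rows only.
    kept_curves = CurveMatrix(
        values=m1.values[keep], q_centers=m1.q_centers, normalized=m1.normalized,
        resampled=m1.resampled,
    )
    reps: list[RepresentativeSignal] = []
    for cid in range(1, clusters.n + 1):
        if cfg.rep_method in ("centroid", "both"):
            reps.append(
                representative_centroid(
                    clusters, pca.selected_scores, kept_curves, cid
                )
            )
        if cfg.rep_method in ("furthest", "both"):
            reps.append(
                representative_furthest(
                    clusters,
                    pca.selected_scores,
                    kept_curves,
                    cid,
                    fraction=cfg.rep_fraction,
                )
            )

    # Correlation maps use one representative per cluster (furthest when
    # available: the less mixture-contaminated of the two rules).
    corr_reps = [
        next(
            r
            for r in reps
            if r.cluster_id == cid
            and (r.method == "furthest_mean" or cfg.rep_method == "centroid")
        )
        for cid in range(1, clusters.n + 1)
    ]
    corr = threshold_median(correlation_maps(m1, corr_reps, grid))

    rgb = None
    rgb_ids = cfg.rgb_clusters
    if rgb_ids is None and clusters.n >= 3:
        rgb_ids = (1, 2, 3)
    if rgb_ids is not None and clusters.n >= 3:
        rgb = compose_rgb(corr, rgb_ids)

    return PipelineResult(
        config=cfg,
        grid=grid,
        m1=m1,
        m2=m2,
        pca=pca,
        clusters=clusters,
        label_map=label_map,
        representatives=reps,
        corr=corr,
        rgb=rgb,
        excluded_rows=np.flatnonzero(m1.excluded),
    )


def run_pipeline(config: PipelineConfig) -> Path:
    """File-to-file run: read the input stack, analyze, write the bundle."""
    config.validate()
    if not config.input_path:
        raise ValueError("config has no input_path")
    if not Path(config.input_path).exists():
        raise FileNotFoundError(config.input_path)

    curves, grid = read_curve_stack(config.input_path)
    if config.raster != grid.raster:
        grid = ScanGrid(ny=grid.ny, nx=grid.nx, raster=config.raster)
    m = curves_to_matrix(curves)
    transmission = None
    if curves[0].transmission is not None:
        transmission = np.array([c.transmission for c in curves])
    background = None
    if config.background_path:
        from .scattering_io import ScatteringCurve

        bg = np.loadtxt(config.background_path, delimiter="\t")
        background = ScatteringCurve(q=bg[:, 0], intensity=bg[:, 1])

    result = segment_curves(
        m.values, m.q_centers, grid, config,
        background=background, transmission=transmission,
    )
    return write_bundle(result, Path(config.output_dir))


def write_bundle(result: PipelineResult, outdir: Path) -> Path:
    """Serialize every stage's output to the bundle directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = result.config

    # Working matrix M1 and sparse feature matrix M2.
    write_curve_stack(
        outdir / "m1_curves.tsv", result.m1.q_centers, result.m1.values, result.grid
    )
    pd.DataFrame(
        result.m2.values, columns=[f"q={q:.6g}" for q in result.m2.feature_q]
    ).to_csv(outdir / "m2_features.csv", index=False)

    # PCA L-curve table (explained-variance vs component count).
    ratio = result.pca.explained_ratio
    pd.DataFrame(
        {
            "component": np.arange(1, ratio.size + 1),
            "explained_ratio": ratio,
            "cumulative": np.cumsum(ratio),
        }
    ).to_csv(outdir / "pca_lcurve.csv", index=False)

    # Silhouette-vs-n table.
    sil = result.clusters.mean_silhouette
    pd.DataFrame(
        {"n": sorted(sil), "mean_silhouette": [sil[n] for n in sorted(sil)]}
    ).to_csv(outdir / "silhouette.csv", index=False)

    write_label_map(result.label_map, outdir / "labels.png")
    write_label_map(result.label_map, outdir / "labels.tiff")
    write_representatives(result.representatives, outdir / "representatives.tsv")

    for k, cid in enumerate(result.corr.cluster_ids):
        tifffile.imwrite(
            outdir / f"corr_S{cid}.tiff", result.corr.rho[k].astype(np.float32)
        )
    flat = result.corr.rho.reshape(len(result.corr.cluster_ids), -1).T
    pd.DataFrame(
        flat, columns=[f"rho_S{c}" for c in result.corr.cluster_ids]
    ).to_csv(outdir / "correlations.csv", index=False)

    if result.rgb is not None:
        from PIL import Image

        Image.fromarray(
            (np.clip(result.rgb, 0, 1) * 255).astype(np.uint8), mode="RGB"
        ).save(outdir / "rgb_composite.png")

    (outdir / "config.txt").write_text(cfg.to_text())
    manifest = {
        "saxseg_version": __version__,
        "seed": cfg.seed,
        "config_sha256": hashlib.sha256(cfg.to_text().encode()).hexdigest(),
        "selected_m": result.pca.m,
        "lcurve_knee": result.pca.knee,
        "selected_n": result.clusters.n,
        "mean_silhouette": {
            str(k): v for k, v in result.clusters.mean_silhouette.items()
        },
        "n_excluded": int(result.excluded_rows.size),
        "versions": _lib_versions(),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir


def _lib_versions() -> dict[str, str]:
    import scipy
    import sklearn

    return {
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "scikit-learn": sklearn.__version__,
        "pandas": pd.__version__,
    }


def run_phantom_demo(
    seed: int = 0,
    outdir: str | Path | None = None,
    counts_scale: float = 1e5,
    mix_width: float = 0.0,
    config: PipelineConfig | None = None,
) -> tuple[PipelineResult, PhantomTruth]:
    """Generate the documented default phantom and run the full pipeline.

    The reference phantom is a 32x32 scan of four phases arranged in
    quadrants with hard boundaries and an expected 1e5 counts per curve;
    pass ``mix_width > 0`` for the mixed-interface variant.  Returns the pipeline result together with the
    phantom ground truth so callers can score recovery.
    """
    spec = default_phantom_spec(
        counts_scale=counts_scale, mix_width=mix_width, seed=seed
    )
    truth = generate_phantom(spec)
    grid = ScanGrid(ny=spec.shape[0], nx=spec.shape[1])
    cfg = config or PipelineConfig(seed=seed)
    cfg.seed = seed
    result = segment_curves(truth.noisy_curves, spec.q_grid, grid, cfg)
    if outdir is not None:
        write_bundle(result, Path(outdir))
        truth_dir = Path(outdir)
        np.savetxt(
            truth_dir / "truth_labels.csv",
            truth.true_labels,
            fmt="%d",
            delimiter=",",
        )
        P = len(spec.phases)
        pd.DataFrame(
            truth.spec.weight_map.reshape(-1, P),
            columns=[f"w_phase{p + 1}" for p in range(P)],
        ).to_csv(truth_dir / "truth_weights.csv", index=False)
    return result, truth
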