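"""Pipeline orchestration: config, stage chaining, and report output.

The full chain per volume is: matrix band threshold → fill holes →
mask arithmetic (interior pores) → ball opening → label analysis →
per-pore morphometry and size distribution → distance transform /
skeleton / pore-throat network.  On a storage series the per-day
summaries are joined to the covariates and fed to the correlation and
moisture–porosity regression stage.

All constants with a printed provenance (segmentation bands, opening
radius, ROI side) are config defaults, never literals in stage code; a run
manifest echoes the full config so any run can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import difflib
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .morphometry import (
    DEFAULT_FERET_DIRECTIONS,
    DEFAULT_SIZE_BIN_EDGES_MM,
    MorphometrySummary,
    PoreStats,
    SizeDistribution,
    measure_labels,
    size_distribution,
    summarize,
)
from .phantom import (
    PhantomSpec,
    StorageTrend,
    covariate_table,
    generate_storage_series,
)
from .pore_network import (
    NetworkSummary,
    PoreNetwork,
    distance_transform,
    network_summary,
    skeleton_to_graph,
    skeletonize,
)
from .segmentation import (
    BinaryMask,
    band_threshold,
    binary_opening,
    fill_holes,
    label_components,
    mask_difference,
)
from .storage_stats import LinearFit, correlation_matrix, linear_fit
from .volume_io import VolumeMeta, VoxelVolume, load_volume, write_raw

log = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineConfig:
    """All knobs of the pipeline; every printed constant is a default here."""

    # input: either a RAW volume path (with sidecar) or a phantom series
    input_path: str | None = None
    phantom_days: int = 5
    volume_scale: float = 1.0
    trend: dict = dataclasses.field(default_factory=dict)
    phantom: dict = dataclasses.field(default_factory=dict)
    # segmentation
    matrix_band: tuple[int, int] = (-750, -250)
    pore_band: tuple[int, int] = (-1250, -1000)
    opening_radius_vox: float = 3.0  # ball RADIUS in voxels
    label_connectivity: int = 26
    fill_connectivity: int = 6
    # morphometry
    feret_directions: int = DEFAULT_FERET_DIRECTIONS
    size_bin_edges_mm: tuple[float, ...] = DEFAULT_SIZE_BIN_EDGES_MM
    include_border_pores: bool = True
    roi_side_vox: int = 45
    # network
    extract_network: bool = True
    prune_factor: float = 1.0
    # statistics
    stats_mode: str = "daily-means"
    moisture_column: str = "moisture_center_pct"
    # run
    output_dir: str = "crumbct_out"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for name in ("matrix_band", "pore_band"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name}: lo {lo} > hi {hi}")
        if self.opening_radius_vox <= 0:
            raise ValueError("opening_radius_vox must be > 0")
        if self.stats_mode not in ("daily-means", "per-sample"):
            raise ValueError("stats_mode must be 'daily-means' or 'per-sample'")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        valid = {f.name for f in dataclasses.fields(cls)}
        clean = {}
        for key, value in data.items():
            if key not in valid:
                hint = difflib.get_close_matches(key, valid, n=1)
                suggestion = f"; did you mean {hint[0]!r}?" if hint else ""
                raise ValueError(f"unknown config key {key!r}{suggestion}")
            if isinstance(value, list):
                value = tuple(value)
            clean[key] = value
        return cls(**clean)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key, value in d.items():
            if isinstance(value, tuple):
                d[key] = list(value)
        return d


@dataclasses.dataclass
class VolumeAnalysis:
    """All stage outputs for one volume."""

    summary: MorphometrySummary
    pore_stats: list[PoreStats]
    size_dist: SizeDistribution
    network: PoreNetwork | None
    net_summary: NetworkSummary | None
    matrix_mask: BinaryMask
    filled_mask: BinaryMask
    pore_mask: BinaryMask
    opened_mask: BinaryMask
    n_labels: int


def analyze_volume(volume: VoxelVolume, config: PipelineConfig) -> VolumeAnalysis:
    """Run the segmentation → morphometry → network chain on one volume."""
    matrix = band_threshold(volume, *config.matrix_band)
    log.info("matrix band %s: %d voxels", config.matrix_band, matrix.count)
    filled = fill_holes(matrix, background_connectivity=config.fill_connectivity)
    log.info("fill holes: %d voxels", filled.count)
    pores = mask_difference(filled, matrix)
    log.info("mask arithmetic (pores): %d voxels", pores.count)
    opened = binary_opening(pores, ball_radius_vox=config.opening_radius_vox)
    log.info("opening r=%.1f: %d voxels", config.opening_radius_vox, opened.count)
    labels = label_components(opened, connectivity=config.label_connectivity)
    log.info("label analysis: %d pores", labels.n_labels)
    stats = measure_labels(labels, n_directions=config.feret_directions)
    summary = summarize(
        stats, pores, filled, include_border=config.include_border_pores
    )
    dist = size_distribution(stats, bin_edges_mm=config.size_bin_edges_mm)
    net = netsum = None
    if config.extract_network:
        dmap = distance_transform(pores)
        skel = skeletonize(pores)
        net = skeleton_to_graph(skel, dmap, prune_factor=config.prune_factor)
        netsum = network_summary(net)
        log.info("network: %d nodes, %d segments", netsum.n_nodes, netsum.n_segments)
    return VolumeAnalysis(
        summary=summary,
        pore_stats=stats,
        size_dist=dist,
        network=net,
        net_summary=netsum,
        matrix_mask=matrix,
        filled_mask=filled,
        pore_mask=pores,
        opened_mask=opened,
        n_labels=labels.n_labels,
    )


# ---------------------------------------------------------------- tables


def pore_table(stats: list[PoreStats]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "label": [s.label for s in stats],
            "volume_mm3": [s.volume_mm3 for s in stats],
            "area_mm2": [s.area_mm2 for s in stats],
            "eq_diameter_mm": [s.eq_diameter_mm for s in stats],
            "length_mm": [s.length_mm for s in stats],
            "width_mm": [s.width_mm for s in stats],
            "centroid_x_mm": [s.centroid_mm[0] for s in stats],
            "centroid_y_mm": [s.centroid_mm[1] for s in stats],
            "centroid_z_mm": [s.centroid_mm[2] for s in stats],
            "touches_border": [s.touches_border for s in stats],
        }
    )


def size_table(dist: SizeDistribution) -> pd.DataFrame:
    edges = dist.bin_edges_mm
    return pd.DataFrame(
        {
            "bin_lo_mm": edges[:-1],
            "bin_hi_mm": edges[1:],
            "count": dist.counts,
            "percentage": dist.percentages,
        }
    )


def network_tables(net: PoreNetwork) -> tuple[pd.DataFrame, pd.DataFrame]:
    nodes = pd.DataFrame(
        {
            "id": range(len(net.nodes)),
            "x_mm": [n.position_mm[0] for n in net.nodes],
            "y_mm": [n.position_mm[1] for n in net.nodes],
            "z_mm": [n.position_mm[2] for n in net.nodes],
            "radius_mm": [n.radius_mm for n in net.nodes],
            "degree": [n.degree for n in net.nodes],
        }
    )
    edges = pd.DataFrame(
        {
            "id": range(len(net.segments)),
            "node_a": [s.node_a for s in net.segments],
            "node_b": [s.node_b for s in net.segments],
            "length_mm": [s.length_mm for s in net.segments],
            "min_radius_mm": [s.min_radius_mm for s in net.segments],
            "mean_radius_mm": [s.mean_radius_mm for s in net.segments],
        }
    )
    return nodes, edges


def summary_row(summary: MorphometrySummary) -> dict:
    return {
        "volume_mm3": summary.mean_volume_mm3,
        "area_mm2": summary.mean_area_mm2,
        "length_mm": summary.mean_length_mm,
        "width_mm": summary.mean_width_mm,
        "porosity_pct": summary.porosity_pct,
        "sample_volume_mL": summary.sample_volume_mL,
        "pore_count": summary.pore_count,
    }


# ---------------------------------------------------------------- masks on disk


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    """Persist a mask as an 8-bit multi-page TIFF (z pages of xy slices)."""
    tifffile.imwrite(str(path), mask.grid.transpose(2, 1, 0).astype(np.uint8))


def read_mask(path: str | Path, spacing_mm=(0.16, 0.16, 0.16)) -> BinaryMask:
    arr = tifffile.imread(str(path))
    grid = (arr > 0).transpose(2, 1, 0)
    return BinaryMask(grid=grid, meta=VolumeMeta(shape=grid.shape, spacing_mm=spacing_mm))


# ---------------------------------------------------------------- full runs


@dataclasses.dataclass
class PipelineResult:
    config: PipelineConfig
    analyses: list[VolumeAnalysis]
    feature_table: pd.DataFrame | None
    correlations: pd.DataFrame | None
    moisture_fit: LinearFit | None
    output_dir: Path


def _storage_trend(config: PipelineConfig) -> StorageTrend:
    return StorageTrend(**{k: tuple(v) if isinstance(v, list) else v
                           for k, v in config.trend.items()})


def _phantom_spec(config: PipelineConfig) -> PhantomSpec:
    return PhantomSpec(**{k: tuple(v) if isinstance(v, list) else v
                          for k, v in config.phantom.items()})


def build_feature_table(records, analyses, moisture_column="moisture_center_pct"):
    """Join per-day covariates with per-day morphometry summaries."""
    cov = covariate_table(records)
    morph = pd.DataFrame([summary_row(a.summary) for a in analyses])
    table = pd.concat([cov.reset_index(drop=True), morph], axis=1)
    features = table[
        ["day", "hardness_N", "flexibility_mm", moisture_column,
         "volume_mm3", "area_mm2", "porosity_pct", "length_mm", "width_mm"]
    ].set_index("day")
    return table, features


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the configured run end to end and write the report bundle.

    Phantom-series runs additionally execute the statistics stage
    (correlation matrix over covariates and morphometry, moisture–porosity
    OLS fit).  Same config + seed → identical outputs.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    timings: dict[str, float] = {}

    analyses: list[VolumeAnalysis] = []
    feature = corr = None
    fit = None

    if config.input_path:
        volume = load_volume(config.input_path)
        analyses.append(analyze_volume(volume, config))
        _write_day_outputs(out, 0, analyses[0])
        pd.DataFrame([summary_row(analyses[0].summary)]).to_csv(
            out / "summary.csv", index=False
        )
        timings["analysis"] = time.time() - t0
    else:
        series = generate_storage_series(
            base=_phantom_spec(config),
            days=config.phantom_days,
            trend=_storage_trend(config),
            seed=config.seed,
            volume_scale=config.volume_scale,
        )
        timings["phantom"] = time.time() - t0
        records = []
        truths = []
        for volume, truth, record in series:
            t1 = time.time()
            analysis = analyze_volume(volume, config)
            record.morphometry = analysis.summary
            analyses.append(analysis)
            records.append(record)
            truths.append(truth)
            _write_day_outputs(out, record.day, analysis)
            timings[f"day{record.day}"] = time.time() - t1
        table, feature = build_feature_table(
            records, analyses, moisture_column=config.moisture_column
        )
        table["true_porosity_pct"] = [t.true_porosity_pct for t in truths]
        table["true_body_volume_mL"] = [t.true_body_volume_mL for t in truths]
        table.to_csv(out / "storage_series.csv", index=False)
        corr = correlation_matrix(feature)
        corr.to_csv(out / "correlation_matrix.csv")
        fit = linear_fit(
            feature["porosity_pct"].to_numpy(),
            feature[config.moisture_column].to_numpy(),
        )
        (out / "moisture_porosity_fit.yaml").write_text(
            yaml.safe_dump(dataclasses.asdict(fit), sort_keys=False)
        )

    manifest = {
        "package": "crumbct",
        "version": __version__,
        "config": config.to_dict(),
        "seed": config.seed,
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "total_s": round(time.time() - t0, 3),
    }
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
    return PipelineResult(
        config=config,
        analyses=analyses,
        feature_table=feature,
        correlations=corr,
        moisture_fit=fit,
        output_dir=out,
    )


def _write_day_outputs(out: Path, day: int, analysis: VolumeAnalysis) -> None:
    tag = f"day{day}" if day else "volume"
    pore_table(analysis.pore_stats).to_csv(out / f"pores_{tag}.csv", index=False)
    size_table(analysis.size_dist).to_csv(out / f"size_distribution_{tag}.csv", index=False)
    if analysis.network is not None:
        nodes, edges = network_tables(analysis.network)
        nodes.to_csv(out / f"network_nodes_{tag}.csv", index=False)
        edges.to_csv(out / f"network_edges_{tag}.csv", index=False)


def write_series_summaries(result: PipelineResult, path: str | Path) -> None:
    rows = [summary_row(a.summary) for a in result.analyses]
    pd.DataFrame(rows).to_csv(path, index=False)


def save_phantom_series(
    out_dir: str | Path,
    days: int = 5,
    seed: int = 0,
    volume_scale: float = 1.0,
    trend: StorageTrend | None = None,
    base: PhantomSpec | None = None,
) -> list[Path]:
    """Generate a storage series and persist it (RAW + sidecars + tables)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    series = generate_storage_series(
        base=base or PhantomSpec(),
        days=days,
        trend=trend or StorageTrend(),
        seed=seed,
        volume_scale=volume_scale,
    )
    paths = []
    truth_rows = []
    for volume, truth, record in series:
        raw = out / f"day{record.day}.raw"
        write_raw(volume, raw)
        paths.append(raw)
        truth_rows.append(
            {
                "day": record.day,
                "true_porosity_pct": truth.true_porosity_pct,
                "true_body_volume_mL": truth.true_body_volume_mL,
                "n_pores_placed": len(truth.pore_spheres),
            }
        )
    covariate_table([r for _, _, r in series]).to_csv(out / "covariates.csv", index=False)
    pd.DataFrame(truth_rows).to_csv(out / "ground_truth.csv", index=False)
    return paths
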