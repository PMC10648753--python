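"""Synthetic CT phantoms of a porous bun, with ground truth.

Real scan data for stored steamed bread is not publicly deposited, so the
package carries a seeded generator that emulates the imaging situation the
analysis chain is built for: an ellipsoidal solid matrix whose GSVs sit in
the −750..−250 band, spherical pores (and exterior air) near −1100 GSV,
160 µm voxels, and a five-day storage series along which total porosity
grows while the sample shrinks, accompanied by covariates (hardness,
flexibility, regional moisture) with the trends reported for aging bread.

Every phantom carries exact ground truth — a per-voxel phase grid and the
generating sphere list — so parameter-recovery tests can compare pipeline
output against truth rather than against another implementation.

Exterior air deliberately shares the pore-phase GSV distribution (both are
air), which is what forces the segmentation chain to use hole filling plus
mask arithmetic rather than a single threshold.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np
import pandas as pd

from .volume_io import GSV_MAX, GSV_MIN, VolumeMeta, VoxelVolume

log = logging.getLogger(__name__)

PHASE_EXTERIOR = 0
PHASE_MATRIX = 1
PHASE_PORE = 2


@dataclasses.dataclass(frozen=True)
class Delamination:
    """Planar air gap (skin/crumb separation) clipped to the body.

    ``z_mm`` is the slab center along z measured from the body center;
    ``thickness_mm`` its full thickness.
    """

    z_mm: float
    thickness_mm: float


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one bun phantom.

    ``pore_count`` spheres are placed (rejection-sampled to lie fully
    inside the body, keeping at least ``wall_clearance_mm`` of matrix
    between any pore and the exterior so interior pores stay enclosed;
    overlaps allowed, as merging pores are part of the aging process being
    emulated).  If ``target_porosity_pct`` is set it overrides
    ``pore_count``: spheres are added until the phase-grid porosity
    reaches the target.

    GSV distributions default to matrix −500 ± 80 and pore/air −1100 ± 40,
    so the two printed segmentation bands (−750..−250 and −1250..−1000)
    are the natural per-phase bands.
    """

    body_semi_axes_mm: tuple[float, float, float] = (12.0, 10.0, 8.0)
    pore_count: int = 150
    target_porosity_pct: float | None = None
    pore_radius_median_mm: float = 0.9
    pore_radius_log_sd: float = 0.3
    matrix_gsv: tuple[float, float] = (-500.0, 80.0)
    pore_gsv: tuple[float, float] = (-1100.0, 40.0)
    delamination: Delamination | None = None
    spacing_mm: tuple[float, float, float] = (0.16, 0.16, 0.16)
    wall_clearance_mm: float = 0.5
    margin_vox: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.body_semi_axes_mm):
            raise ValueError("body semi-axes must be positive")
        if self.pore_count < 0:
            raise ValueError("pore_count must be >= 0")
        if self.pore_radius_median_mm <= 0:
            raise ValueError("pore radius median must be positive")
        if self.target_porosity_pct is not None and not (
            0 <= self.target_porosity_pct < 100
        ):
            raise ValueError("target_porosity_pct must be in [0, 100)")
        m_mean, m_sd = self.matrix_gsv
        p_mean, p_sd = self.pore_gsv
        if m_sd <= 0 or p_sd <= 0:
            raise ValueError("GSV standard deviations must be positive")
        # the two phase distributions must separate at +-3 sd, otherwise
        # the fixed segmentation bands cannot distinguish them
        lo_hi = sorted([(m_mean, m_sd), (p_mean, p_sd)])
        if lo_hi[0][0] + 3 * lo_hi[0][1] >= lo_hi[1][0] - 3 * lo_hi[1][1]:
            raise ValueError("matrix and pore GSV bands overlap at +-3 sd")


@dataclasses.dataclass
class GroundTruth:
    """Exact per-voxel truth of a generated phantom."""

    pore_spheres: list[tuple[tuple[float, float, float], float]]
    phase_grid: np.ndarray  # uint8, same shape as the volume
    true_porosity_pct: float
    true_body_volume_mL: float

    @classmethod
    def from_phase_grid(cls, phase_grid, pore_spheres, voxel_volume_mm3):
        pore = int((phase_grid == PHASE_PORE).sum())
        body = int((phase_grid != PHASE_EXTERIOR).sum())
        porosity = 100.0 * pore / body if body else 0.0
        return cls(
            pore_spheres=list(pore_spheres),
            phase_grid=phase_grid,
            true_porosity_pct=porosity,
            true_body_volume_mL=body * voxel_volume_mm3 / 1000.0,
        )


@dataclasses.dataclass
class StorageRecord:
    """Covariates of one storage day (morphometry attached after analysis)."""

    day: int
    hardness_N: float
    flexibility_mm: float
    moisture_pct: tuple[float, float, float]  # (center, crumb, skin)
    nominal_porosity_pct: float
    nominal_body_volume_mL: float
    morphometry: object | None = None

    def __post_init__(self) -> None:
        c, r, s = self.moisture_pct
        if not (c >= r >= s):
            raise ValueError("moisture must satisfy center >= crumb >= skin")
        if self.hardness_N <= 0:
            raise ValueError("hardness must be positive")


def _grid_coords(shape, spacing, center_mm):
    axes = [
        (np.arange(n) + 0.5) * s - c
        for n, s, c in zip(shape, spacing, center_mm)
    ]
    return np.meshgrid(*axes, indexing="ij", sparse=True)


def generate_bun_phantom(spec: PhantomSpec) -> tuple[VoxelVolume, GroundTruth]:
    """Generate one bun phantom and its ground truth.

    Deterministic for a fixed spec (the seed is part of the spec).  Voxel
    phase is pore if inside any sphere or the delamination slab, matrix if
    inside the ellipsoid otherwise, exterior elsewhere.  GSVs are drawn
    per phase and clipped to the int16 range.

    Raises ``RuntimeError`` if the placement budget (100 attempts per
    requested pore) is exhausted, reporting the achieved count.
    """
    rng = np.random.default_rng(spec.seed)
    sx, sy, sz = spec.spacing_mm
    a, b, c = spec.body_semi_axes_mm
    shape = tuple(
        int(math.ceil(2 * ax / sp)) + 2 * spec.margin_vox
        for ax, sp in zip((a, b, c), (sx, sy, sz))
    )
    center = tuple(n * sp / 2.0 for n, sp in zip(shape, (sx, sy, sz)))
    X, Y, Z = _grid_coords(shape, (sx, sy, sz), center)

    phase = np.zeros(shape, dtype=np.uint8)
    body = (X / a) ** 2 + (Y / b) ** 2 + (Z / c) ** 2 <= 1.0
    phase[body] = PHASE_MATRIX

    body_count = int(body.sum())
    mu = math.log(spec.pore_radius_median_mm)

    spheres: list[tuple[tuple[float, float, float], float]] = []
    pore_voxels = 0
    want_count = spec.pore_count if spec.target_porosity_pct is None else None
    budget = 100 * max(spec.pore_count, 1000 if want_count is None else 1)
    attempts = 0

    def done() -> bool:
        if want_count is not None:
            return len(spheres) >= want_count
        return 100.0 * pore_voxels / body_count >= spec.target_porosity_pct

    while not done():
        if attempts >= budget:
            raise RuntimeError(
                f"pore placement budget ({budget} attempts) exhausted after "
                f"{len(spheres)} pores (porosity "
                f"{100.0 * pore_voxels / body_count:.2f}%)"
            )
        attempts += 1
        r = float(np.exp(mu + spec.pore_radius_log_sd * rng.standard_normal()))
        cx = float(rng.uniform(-a, a))
        cy = float(rng.uniform(-b, b))
        cz = float(rng.uniform(-c, c))
        # sufficient condition for the sphere to lie fully inside the body
        # with a matrix wall of at least wall_clearance_mm around it
        rr = r + spec.wall_clearance_mm
        if rr >= min(a, b, c):
            continue
        if (cx / (a - rr)) ** 2 + (cy / (b - rr)) ** 2 + (cz / (c - rr)) ** 2 > 1.0:
            continue
        # rasterize into the local bounding box only
        lo = [
            max(0, int((cc + off - r) / sp) - 1)
            for cc, off, sp in zip((cx, cy, cz), center, (sx, sy, sz))
        ]
        hi = [
            min(n, int((cc + off + r) / sp) + 2)
            for cc, off, sp, n in zip((cx, cy, cz), center, (sx, sy, sz), shape)
        ]
        sub = (
            (X[lo[0] : hi[0]] - cx) ** 2
            + (Y[:, lo[1] : hi[1]] - cy) ** 2
            + (Z[:, :, lo[2] : hi[2]] - cz) ** 2
        ) <= r * r
        box = phase[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
        newly = sub & (box == PHASE_MATRIX)
        pore_voxels += int(newly.sum())
        box[newly] = PHASE_PORE
        spheres.append(((cx, cy, cz), r))

    if spec.delamination is not None:
        d = spec.delamination
        w = spec.wall_clearance_mm
        inner = (X / (a - w)) ** 2 + (Y / (b - w)) ** 2 + (Z / (c - w)) ** 2 <= 1.0
        slab = (
            (np.abs(Z - d.z_mm) <= d.thickness_mm / 2.0)
            & inner
            & (phase == PHASE_MATRIX)
        )
        phase[slab] = PHASE_PORE

    gsv = np.empty(shape, dtype=np.float64)
    air = phase != PHASE_MATRIX  # exterior air and pores share a distribution
    p_mean, p_sd = spec.pore_gsv
    m_mean, m_sd = spec.matrix_gsv
    noise = rng.standard_normal(shape)
    gsv[air] = p_mean + p_sd * noise[air]
    gsv[~air] = m_mean + m_sd * noise[~air]
    values = np.clip(np.rint(gsv), GSV_MIN, GSV_MAX).astype(np.int16)

    meta = VolumeMeta(shape=shape, spacing_mm=spec.spacing_mm)
    volume = VoxelVolume(meta=meta, values=values)
    truth = GroundTruth.from_phase_grid(phase, spheres, meta.voxel_volume_mm3)
    return volume, truth


@dataclasses.dataclass(frozen=True)
class StorageTrend:
    """Day-1 → day-5 endpoints of the storage series.

    Porosity and sample-volume endpoints are the reported day-1/day-5
    values for stored buns (23.5→28.8 % and 165→126 mL); hardness is an
    affine function of center moisture calibrated so the reported 10.1 N →
    40.4 N range maps onto the default moisture trajectory, plus Gaussian
    noise.  Moisture noise defaults to the level at which the population
    moisture–porosity R² equals ``moisture_target_r2`` (0.94); pass an
    explicit ``moisture_noise_sd_pct`` (e.g. 0.0) to override.
    """

    porosity_pct: tuple[float, float] = (23.5, 28.8)
    body_volume_mL: tuple[float, float] = (165.0, 126.0)
    pore_radius_median_mm: tuple[float, float] = (0.85, 1.15)
    moisture_center_pct: tuple[float, float] = (45.0, 42.0)
    moisture_crumb_pct: tuple[float, float] = (43.5, 39.5)
    moisture_skin_pct: tuple[float, float] = (41.0, 35.0)
    hardness_intercept_N: float = 464.6
    hardness_slope_N_per_pct: float = 10.1  # hardness = a - b * moisture_center
    hardness_noise_sd_N: float = 1.0
    flexibility_mm: tuple[float, float] = (6.5, 6.0)
    flexibility_noise_sd_mm: float = 0.05
    moisture_target_r2: float = 0.94
    moisture_noise_sd_pct: float | None = None


def _interp(endpoints: tuple[float, float], t: float) -> float:
    return endpoints[0] + (endpoints[1] - endpoints[0]) * t


def moisture_noise_sd_for_r2(signal: np.ndarray, target_r2: float) -> float:
    """Noise sd such that the population R² of signal + noise vs the signal's
    regressor equals ``target_r2`` (signal variance taken over the design)."""
    if not (0 < target_r2 <= 1):
        raise ValueError("target_r2 must be in (0, 1]")
    var = float(np.var(np.asarray(signal, dtype=float)))
    return math.sqrt(var * (1.0 - target_r2) / target_r2)


def generate_storage_covariates(
    trend: StorageTrend = StorageTrend(), days: int = 5, seed: int = 0
) -> list[StorageRecord]:
    """Covariates of a storage series, without voxel phantoms.

    Light enough for Monte-Carlo studies of the downstream statistics.
    Moisture ordering (center >= crumb >= skin) is enforced by sorting the
    three noisy values; with default noise levels this almost never
    rearranges them.
    """
    if days < 2:
        raise ValueError("a storage series needs at least 2 days")
    rng = np.random.default_rng(seed)
    ts = np.linspace(0.0, 1.0, days)
    if trend.moisture_noise_sd_pct is not None:
        m_sd = trend.moisture_noise_sd_pct
    else:
        signal = np.array([_interp(trend.moisture_center_pct, t) for t in ts])
        m_sd = moisture_noise_sd_for_r2(signal, trend.moisture_target_r2)
    if trend.porosity_pct[1] <= trend.porosity_pct[0]:
        log.warning("storage trend: porosity endpoints are non-increasing")
    if trend.body_volume_mL[1] >= trend.body_volume_mL[0]:
        log.warning("storage trend: body volume endpoints are non-decreasing")

    records = []
    for day, t in enumerate(ts, start=1):
        center = _interp(trend.moisture_center_pct, t) + m_sd * rng.standard_normal()
        crumb = _interp(trend.moisture_crumb_pct, t) + m_sd * rng.standard_normal()
        skin = _interp(trend.moisture_skin_pct, t) + m_sd * rng.standard_normal()
        center, crumb, skin = sorted((center, crumb, skin), reverse=True)
        hardness = (
            trend.hardness_intercept_N
            - trend.hardness_slope_N_per_pct * center
            + trend.hardness_noise_sd_N * rng.standard_normal()
        )
        flexibility = _interp(
            trend.flexibility_mm, t
        ) + trend.flexibility_noise_sd_mm * rng.standard_normal()
        records.append(
            StorageRecord(
                day=day,
                hardness_N=max(hardness, 1e-6),
                flexibility_mm=flexibility,
                moisture_pct=(center, crumb, skin),
                nominal_porosity_pct=_interp(trend.porosity_pct, t),
                nominal_body_volume_mL=_interp(trend.body_volume_mL, t),
            )
        )
    return records


def generate_storage_series(
    base: PhantomSpec = PhantomSpec(),
    days: int = 5,
    trend: StorageTrend = StorageTrend(),
    seed: int = 0,
    volume_scale: float = 1.0,
) -> list[tuple[VoxelVolume, GroundTruth, StorageRecord]]:
    """Per-day phantoms plus covariates for a storage series.

    Each day's body semi-axes are rescaled (keeping the base aspect ratio)
    so the ellipsoid volume equals ``volume_scale`` times the day's nominal
    sample volume, and spheres are placed until the day's nominal porosity
    is reached.  ``volume_scale < 1`` runs the same study at a smaller
    grid size; porosity, being a ratio, is scale-free.
    """
    if volume_scale <= 0:
        raise ValueError("volume_scale must be positive")
    records = generate_storage_covariates(trend=trend, days=days, seed=seed)
    day_seeds = np.random.SeedSequence(seed).generate_state(days) % (2**31)
    a0, b0, c0 = base.body_semi_axes_mm
    base_vol = 4.0 / 3.0 * math.pi * a0 * b0 * c0
    out = []
    for rec, day_seed in zip(records, day_seeds):
        t = (rec.day - 1) / (days - 1)
        target_vol_mm3 = volume_scale * rec.nominal_body_volume_mL * 1000.0
        f = (target_vol_mm3 / base_vol) ** (1.0 / 3.0)
        spec = dataclasses.replace(
            base,
            body_semi_axes_mm=(a0 * f, b0 * f, c0 * f),
            target_porosity_pct=rec.nominal_porosity_pct,
            pore_radius_median_mm=_interp(trend.pore_radius_median_mm, t),
            seed=int(day_seed),
        )
        volume, truth = generate_bun_phantom(spec)
        out.append((volume, truth, rec))
    return out


def covariate_table(records: list[StorageRecord]) -> pd.DataFrame:
    """Delimited-text-ready table of the series covariates."""
    return pd.DataFrame(
        {
            "day": [r.day for r in records],
            "hardness_N": [r.hardness_N for r in records],
            "flexibility_mm": [r.flexibility_mm for r in records],
            "moisture_center_pct": [r.moisture_pct[0] for r in records],
            "moisture_crumb_pct": [r.moisture_pct[1] for r in records],
            "moisture_skin_pct": [r.moisture_pct[2] for r in records],
            "nominal_porosity_pct": [r.nominal_porosity_pct for r in records],
            "nominal_body_volume_mL": [r.nominal_body_volume_mL for r in records],
        }
    )
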