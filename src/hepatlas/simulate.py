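"""Synthetic data generators with known ground truth.

Three generators stand in for the pipeline's real-world inputs:

* :func:`simulate_sc` — cell-type-structured negative-binomial count
  matrices with planted marker genes (single-cell RNA-seq surrogate).
* :func:`simulate_cohort` — a bulk expression cohort whose survival hazard
  is tied to a planted signature-gene burden (TCGA-like surrogate).
* :func:`simulate_fish` — multi-channel FISH-like micrographs with exact
  nucleus/spot/tumor geometry.

Every generator takes an explicit seed and is bit-for-bit reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .containers import BulkCohort, FishScene, LabeledExpression


# ---------------------------------------------------------------------------
# single-cell counts
# ---------------------------------------------------------------------------

@dataclass
class ScSimConfig:
    """Parameters of the structured negative-binomial count simulator.

    The NB is parameterized by mean/dispersion with
    ``variance = mu + mu**2 / nb_dispersion``.  Marker genes of a type have
    their mean multiplied by ``2**marker_log2fc`` in cells of that type.
    Per-cell library-size factors are log-normal with sigma=0.3.
    """

    n_types: int = 4
    cells_per_type: int = 200
    n_genes: int = 1000
    markers_per_type: int = 10
    marker_log2fc: float = 3.0
    nb_dispersion: float = 0.5
    mean_library_size: float = 2000.0
    mito_fraction_range: tuple[float, float] = (0.01, 0.08)
    library_sigma: float = 0.3  # sd of the log-normal library-size factor
    stage: str = "healthy"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_types < 1 or self.cells_per_type < 1 or self.n_genes < 1:
            raise ValueError("n_types, cells_per_type and n_genes must be >= 1")
        if self.markers_per_type * self.n_types > self.n_genes:
            raise ValueError(
                "markers_per_type * n_types must not exceed n_genes "
                f"({self.markers_per_type} * {self.n_types} > {self.n_genes})"
            )
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        lo, hi = self.mito_fraction_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("mito_fraction_range must satisfy 0 <= lo <= hi <= 1")


def type_names(config: ScSimConfig) -> list[str]:
    return [f"type{k}" for k in range(config.n_types)]


def planted_markers(config: ScSimConfig) -> dict[str, list[str]]:
    """Ground-truth marker gene lists, disjoint by construction.

    Type ``k`` owns genes ``k*markers_per_type .. (k+1)*markers_per_type``.
    """
    m = config.markers_per_type
    return {
        f"type{k}": [f"gene{m * k + j:05d}" for j in range(m)]
        for k in range(config.n_types)
    }


def simulate_sc(config: ScSimConfig) -> LabeledExpression:
    """Draw a labeled genes x cells NB count matrix with planted markers."""
    rng = np.random.default_rng(config.seed)
    n_genes, k_types = config.n_genes, config.n_types
    n_cells = k_types * config.cells_per_type

    # relative gene weights -> base means scaled to the target library size
    weights = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    base_mean = weights / weights.sum() * config.mean_library_size

    fold = 2.0 ** config.marker_log2fc
    marker_idx = np.arange(k_types * config.markers_per_type).reshape(
        k_types, config.markers_per_type
    )
    # markers are off-state genes: low baseline outside their own type, so
    # detection fractions behave like real subtype markers; the planted
    # within-type mean is exactly 2**marker_log2fc times this baseline
    base_mean[marker_idx.ravel()] = rng.uniform(0.4, 0.7, size=marker_idx.size)

    lib = (
        rng.lognormal(mean=0.0, sigma=config.library_sigma, size=n_cells)
        if config.library_sigma > 0
        else np.ones(n_cells)
    )
    theta = config.nb_dispersion
    counts = np.empty((n_genes, n_cells), dtype=np.int64)
    labels = np.empty(n_cells, dtype=object)
    for k in range(k_types):
        mean_k = base_mean.copy()
        mean_k[marker_idx[k]] *= fold
        sl = slice(k * config.cells_per_type, (k + 1) * config.cells_per_type)
        mu = np.outer(mean_k, lib[sl])
        lam = rng.gamma(shape=theta, scale=mu / theta)
        counts[:, sl] = rng.poisson(lam)
        labels[sl] = f"type{k}"

    mito_lo, mito_hi = config.mito_fraction_range
    cell_meta = pd.DataFrame(
        {
            "stage": config.stage,
            "subtype": labels,
            "mito_fraction": rng.uniform(mito_lo, mito_hi, size=n_cells),
            "n_detected_genes": (counts > 0).sum(axis=0),
        },
        index=pd.Index([f"cell{i:05d}" for i in range(n_cells)], name="barcode"),
    )
    gene_ids = pd.Index([f"gene{i:05d}" for i in range(n_genes)], name="gene")
    return LabeledExpression(counts=counts, gene_ids=gene_ids, cell_meta=cell_meta)


def simulate_cell_labels(
    stage_compositions: dict[str, dict[str, float]],
    cells_per_stage: int | dict[str, int],
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a cell metadata table with planted per-stage type compositions.

    ``stage_compositions`` maps stage -> {cell type -> probability}; type
    probabilities must sum to 1 per stage.  Used to exercise composition
    inference without materializing counts.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for stage, comp in stage_compositions.items():
        probs = np.array(list(comp.values()), dtype=float)
        if not np.isclose(probs.sum(), 1.0):
            raise ValueError(f"type probabilities for stage {stage!r} must sum to 1")
        n = cells_per_stage[stage] if isinstance(cells_per_stage, dict) else cells_per_stage
        types = rng.choice(list(comp.keys()), size=n, p=probs / probs.sum())
        rows.append(pd.DataFrame({"stage": stage, "subtype": types}))
    meta = pd.concat(rows, ignore_index=True)
    meta["mito_fraction"] = 0.0
    meta["n_detected_genes"] = 1
    meta.index = pd.Index([f"cell{i:05d}" for i in range(len(meta))], name="barcode")
    return meta


# ---------------------------------------------------------------------------
# survival cohort
# ---------------------------------------------------------------------------

@dataclass
class CohortSimConfig:
    """Bulk cohort with a planted signature burden driving survival.

    Expression is on a log-like continuous scale: gene baselines ~ N(5, 2),
    per-sample noise N(0, 1); signature genes are shifted by
    ``signature_effect_sd * z_i`` where ``z_i`` is the standardized planted
    burden.  Survival times are exponential with
    ``hazard_i = baseline_hazard * planted_hazard_ratio ** z_i`` and
    independent exponential censoring tuned to ``censor_fraction``.
    """

    n_samples: int = 300
    n_genes: int = 2000
    signature_genes: tuple[str, ...] = ()
    planted_hazard_ratio: float = 2.0
    baseline_hazard: float = 0.05
    censor_fraction: float = 0.3
    age_range: tuple[int, int] = (40, 80)
    signature_effect_sd: float = 1.0
    n_normal: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.signature_genes:
            raise ValueError("signature_genes must be non-empty")
        if self.planted_hazard_ratio <= 0 or self.baseline_hazard <= 0:
            raise ValueError("hazard parameters must be > 0")
        if not 0 <= self.censor_fraction < 1:
            raise ValueError("censor_fraction must be in [0, 1)")
        universe = {f"g{i:05d}" for i in range(self.n_genes)}
        missing = set(self.signature_genes) - universe
        if missing:
            raise ValueError(
                f"signature genes outside the g00000..g{self.n_genes - 1:05d} "
                f"universe: {sorted(missing)[:5]}"
            )


def cohort_gene_ids(config: CohortSimConfig) -> pd.Index:
    return pd.Index([f"g{i:05d}" for i in range(config.n_genes)], name="gene")


def _censor_rate(lam: np.ndarray, censor_fraction: float) -> float:
    """Exponential censoring rate mu with mean P(censor) = censor_fraction.

    For event rate lam_i and independent Exp(mu) censoring,
    P(censored_i) = mu / (lam_i + mu); solve the cohort average for mu.
    """
    def gap(mu: float) -> float:
        return float(np.mean(mu / (lam + mu))) - censor_fraction

    hi = float(lam.max()) * 1e6 + 1.0
    return brentq(gap, 1e-12, hi)


def simulate_cohort(config: CohortSimConfig) -> BulkCohort:
    """Simulate a bulk cohort; ground-truth burden stored as clinical.true_z."""
    rng = np.random.default_rng(config.seed)
    genes = cohort_gene_ids(config)
    n_tumor = config.n_samples
    n = n_tumor + config.n_normal

    burden = rng.normal(0.0, 1.0, size=n_tumor)
    z = (burden - burden.mean()) / burden.std(ddof=0)
    if config.n_normal:
        # normal tissue carries a depleted signature burden
        z_normal = rng.normal(-2.0, 0.5, size=config.n_normal)
        z = np.concatenate([z, z_normal])

    base = rng.normal(5.0, 2.0, size=config.n_genes)
    expr = base[:, None] + rng.normal(0.0, 1.0, size=(config.n_genes, n))
    sig_idx = genes.get_indexer(list(config.signature_genes))
    expr[sig_idx, :] += config.signature_effect_sd * z[None, :]

    lam = config.baseline_hazard * config.planted_hazard_ratio ** z
    event_time = rng.exponential(1.0 / lam)
    if config.censor_fraction > 0:
        mu = _censor_rate(lam, config.censor_fraction)
        censor_time = rng.exponential(1.0 / mu, size=n)
        time = np.minimum(event_time, censor_time)
        event = (event_time <= censor_time).astype(int)
    else:
        time, event = event_time, np.ones(n, dtype=int)

    lo, hi = config.age_range
    samples = pd.Index(
        [f"sample{i:04d}" for i in range(n)], name="sample"
    )
    clinical = pd.DataFrame(
        {
            "OS_time": np.maximum(time, 1e-9),
            "event": event,
            "age": rng.integers(lo, hi + 1, size=n),
            "group": ["tumor"] * n_tumor + ["normal"] * config.n_normal,
            "true_z": z,
        },
        index=samples,
    )
    expression = pd.DataFrame(expr, index=genes, columns=samples)
    return BulkCohort(expression=expression, clinical=clinical)


# ---------------------------------------------------------------------------
# FISH-like micrographs
# ---------------------------------------------------------------------------

@dataclass
class FishSimConfig:
    """Geometry-first FISH scene: nuclei, marker spots, tumor cells.

    ``nuclei`` is a list of (x_px, y_px, true_type); ``spot_offsets`` is a
    per-nucleus list of (channel, dx_um, dy_um) placing marker spots
    relative to the nucleus centre; ``tumor_centroids`` are (x_px, y_px).
    Spots and nuclei are rendered as filled discs; Gaussian pixel noise of
    sd ``noise_level`` (intensity units, max intensity 1.0) is added.
    """

    image_size: tuple[int, int] = (512, 512)  # (height, width) px
    pixel_size_um: float = 1.0
    nuclei: tuple = ()
    spot_offsets: tuple = ()  # one list of (channel, dx_um, dy_um) per nucleus
    tumor_centroids: tuple = ()
    spot_radius_px: int = 2
    nucleus_radius_px: int = 4
    tumor_radius_px: int = 5
    noise_level: float = 0.0
    channel_map: dict[str, str] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if not 0 <= self.noise_level <= 1:
            raise ValueError("noise_level must be in [0, 1]")
        if self.spot_offsets and len(self.spot_offsets) != len(self.nuclei):
            raise ValueError("spot_offsets must have one entry per nucleus")
        h, w = self.image_size
        for x, y, _ in self.nuclei:
            if not (0 <= x < w and 0 <= y < h):
                raise ValueError(f"nucleus at ({x}, {y}) outside image {w}x{h}")
        for x, y in self.tumor_centroids:
            if not (0 <= x < w and 0 <= y < h):
                raise ValueError(f"tumor centroid ({x}, {y}) outside image")
        for i, offsets in enumerate(self.spot_offsets):
            nx, ny, _ = self.nuclei[i]
            for channel, dx, dy in offsets:
                sx = nx + dx / self.pixel_size_um
                sy = ny + dy / self.pixel_size_um
                if not (0 <= sx < w and 0 <= sy < h):
                    raise ValueError(
                        f"spot for nucleus {i} channel {channel!r} at "
                        f"({sx:.1f}, {sy:.1f}) px falls outside the image"
                    )


def _disc(image: np.ndarray, x: float, y: float, radius: int) -> None:
    from skimage.draw import disk

    rr, cc = disk((y, x), radius, shape=image.shape)
    image[rr, cc] = 1.0


def simulate_fish(config: FishSimConfig) -> tuple[FishScene, pd.DataFrame]:
    """Render the scene and emit an analytically exact ground-truth table.

    Returns (scene, truth) where truth has one row per nucleus with its
    planted type and exact Euclidean nearest-tumor distance in um.
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.image_size
    channel_names = {ch for offsets in config.spot_offsets for ch, _, _ in offsets}
    channel_names |= {ch for ch in config.channel_map if ch not in ("DAPI", "tumor")}
    channels: dict[str, np.ndarray] = {
        "DAPI": np.zeros((h, w)),
        "tumor": np.zeros((h, w)),
        **{ch: np.zeros((h, w)) for ch in sorted(channel_names)},
    }

    for x, y, _ in config.nuclei:
        _disc(channels["DAPI"], x, y, config.nucleus_radius_px)
    for x, y in config.tumor_centroids:
        _disc(channels["tumor"], x, y, config.tumor_radius_px)
    for i, offsets in enumerate(config.spot_offsets):
        nx, ny, _ = config.nuclei[i]
        for channel, dx, dy in offsets:
            _disc(
                channels[channel],
                nx + dx / config.pixel_size_um,
                ny + dy / config.pixel_size_um,
                config.spot_radius_px,
            )

    if config.noise_level > 0:
        for name in channels:
            noisy = channels[name] + rng.normal(0, config.noise_level, size=(h, w))
            channels[name] = np.clip(noisy, 0.0, 1.0)

    channel_map = dict(config.channel_map) or {ch: ch for ch in sorted(channel_names)}
    scene = FishScene(
        channels=channels, pixel_size_um=config.pixel_size_um, channel_map=channel_map
    )

    tumors = np.asarray(config.tumor_centroids, dtype=float).reshape(-1, 2)
    rows = []
    for i, (x, y, true_type) in enumerate(config.nuclei):
        if len(tumors):
            d = np.hypot(tumors[:, 0] - x, tumors[:, 1] - y).min()
            nearest_um = d * config.pixel_size_um
        else:
            nearest_um = np.nan
        rows.append(
            {
                "nucleus_id": i,
                "x_px": float(x),
                "y_px": float(y),
                "true_type": true_type,
                "nearest_tumor_um": nearest_um,
            }
        )
    truth = pd.DataFrame(rows)
    if truth.empty:
        warnings.warn("scene contains no nuclei", stacklevel=2)
    return scene, truth


def example_fish_config(
    seed: int = 0,
    n_mac: int = 8,
    n_t: int = 8,
    n_tumor: int = 10,
    image_size: tuple[int, int] = (400, 400),
    pixel_size_um: float = 1.0,
    noise_level: float = 0.0,
) -> FishSimConfig:
    """A realistic HCC-like scene: SPP1+ macrophages hug tumor cells,
    Klf2+ cytotoxic T cells sit farther out.

    Each macrophage nucleus is placed 6-10 px from a tumor centroid with a
    Spp1 subtype spot and a Clec4f lineage spot inside the 10 um typing
    radius; each T nucleus is placed uniformly with Klf2 and Cd3 spots
    inside the 5 um radius.  Nuclei keep a 25 px minimum separation so
    typing is unambiguous and segmentation never merges components.
    """
    rng = np.random.default_rng(seed)
    h, w = image_size
    margin = 30

    def sample_point(existing, min_sep):
        for _ in range(10_000):
            p = rng.uniform(margin, (w - margin, h - margin))
            if all((p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 >= min_sep ** 2
                   for q in existing):
                return (float(p[0]), float(p[1]))
        raise RuntimeError("could not place a point; image too crowded")

    tumors: list[tuple[float, float]] = []
    for _ in range(n_tumor):
        tumors.append(sample_point(tumors, 30))

    nuclei: list[tuple[float, float, str]] = []
    placed: list[tuple[float, float]] = []
    offsets: list[list[tuple[str, float, float]]] = []
    for i in range(n_mac):
        tx, ty = tumors[i % n_tumor]
        for _ in range(10_000):
            ang = rng.uniform(0, 2 * np.pi)
            r = rng.uniform(6, 10)
            p = (tx + r * np.cos(ang), ty + r * np.sin(ang))
            in_bounds = margin <= p[0] <= w - margin and margin <= p[1] <= h - margin
            if in_bounds and all((p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 >= 25 ** 2
                                 for q in placed):
                break
        else:
            raise RuntimeError("could not place a macrophage nucleus")
        placed.append(p)
        nuclei.append((p[0], p[1], "Spp1+ Mac"))
        a1, a2 = rng.uniform(0, 2 * np.pi, 2)
        offsets.append([
            ("Spp1", 4.0 * pixel_size_um * np.cos(a1), 4.0 * pixel_size_um * np.sin(a1)),
            ("Clec4f", 4.0 * pixel_size_um * np.cos(a2), 4.0 * pixel_size_um * np.sin(a2)),
        ])
    for _ in range(n_t):
        p = sample_point(placed, 25)
        placed.append(p)
        nuclei.append((p[0], p[1], "Klf2+ T"))
        a1, a2 = rng.uniform(0, 2 * np.pi, 2)
        offsets.append([
            ("Klf2", 2.0 * pixel_size_um * np.cos(a1), 2.0 * pixel_size_um * np.sin(a1)),
            ("Cd3", 2.0 * pixel_size_um * np.cos(a2), 2.0 * pixel_size_um * np.sin(a2)),
        ])

    return FishSimConfig(
        image_size=image_size,
        pixel_size_um=pixel_size_um,
        nuclei=tuple(nuclei),
        spot_offsets=tuple(offsets),
        tumor_centroids=tuple(tumors),
        noise_level=noise_level,
        seed=seed,
    )
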