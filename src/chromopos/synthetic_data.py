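"""Synthetic gene maps, paired expression tables and 3D nucleus stacks.

Every downstream stage of the pipeline is exercised against data with
known ground truth: gene maps with realistic density, paired expression
tables with planted misexpressed probesets / genomic clusters /
per-chromosome enrichment, and multi-channel confocal-like nucleus stacks
with planted territories and FISH signals at analytically known
distances.  All draws come from one seeded generator per call, so a fixed
seed reproduces every output bit for bit.

The expression model is multiplicative log-normal noise on intensities:
each probeset has a latent control intensity, planted probesets carry a
+/- ``effect_log2fc`` shift in the mutant channel, and the two
"normalization variant" tables share a common noise component so that
their per-probeset fold changes correlate at ``normalization_corr`` --
the minimal structure the dual-normalization intersection assumes.

The image model is a filled DAPI ellipsoid, a thin lamin shell at its
boundary, and Gaussian-blurred solid spheres for territories and FISH
spots, with Poisson-Gaussian noise at a stated SNR.  It makes no attempt
at chromatin texture, photobleaching or microscope-specific optics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import minimize

from .fish3d import DEFAULT_VOXEL_SIZE, VoxelGrid
from .genemap_io import ALLOWED_CHROMOSOMES, ChipUniverse, GeneAnnotation

__all__ = [
    "ExpressionTruth",
    "NucleusTruth",
    "make_gene_map",
    "plan_expression_truth",
    "make_expression",
    "make_nucleus_truth",
    "make_nucleus_stack",
    "rasterize_truth",
    "point_to_ellipsoid_edge",
]


# -- gene maps -----------------------------------------------------------


def make_gene_map(
    n_chromosomes: int,
    chrom_lengths: int | Sequence[int],
    genes_per_mb: float,
    seed: int,
    probesets_per_gene_extra: float = 0.15,
) -> ChipUniverse:
    """Random chip universe with uniform gene starts.

    Gene start positions are uniform over each chromosome; gene lengths
    are exponential with mean 20 kb (clipped into the chromosome, minimum
    200 bp).  A fraction ``probesets_per_gene_extra`` of genes receives a
    second probeset at the same locus, emulating redundant chip coverage.
    """
    if n_chromosomes < 1:
        raise ValueError("need at least one chromosome")
    if genes_per_mb <= 0:
        raise ValueError("genes_per_mb must be positive")
    if isinstance(chrom_lengths, (int, np.integer)):
        chrom_lengths = [int(chrom_lengths)] * n_chromosomes
    if len(chrom_lengths) != n_chromosomes:
        raise ValueError("chrom_lengths length must match n_chromosomes")
    if min(chrom_lengths) <= 0:
        raise ValueError("chromosome lengths must be positive")
    if n_chromosomes > len(ALLOWED_CHROMOSOMES):
        raise ValueError(f"at most {len(ALLOWED_CHROMOSOMES)} chromosomes supported")
    rng = np.random.default_rng(seed)
    annotations: list[GeneAnnotation] = []
    sizes: dict[str, int] = {}
    gene_no = 0
    for ci in range(n_chromosomes):
        chrom = ALLOWED_CHROMOSOMES[ci]
        length = int(chrom_lengths[ci])
        sizes[chrom] = length
        n_genes = rng.poisson(genes_per_mb * length / 1e6)
        starts = np.sort(rng.integers(0, max(length - 200, 1), size=n_genes))
        lens = np.maximum(rng.exponential(20_000, size=n_genes), 200).astype(int)
        for s, ln in zip(starts, lens):
            gene_no += 1
            symbol = f"G{gene_no:05d}"
            end = min(int(s) + int(ln), length)
            n_probes = 2 if rng.random() < probesets_per_gene_extra else 1
            for k in range(n_probes):
                annotations.append(
                    GeneAnnotation(
                        chromosome=chrom,
                        start=int(s),
                        end=end,
                        probeset_id=f"{gene_no:05d}_{'s' if k else 'x'}_at",
                        gene_symbol=symbol,
                    )
                )
    return ChipUniverse(annotations, sizes)


# -- expression ----------------------------------------------------------


@dataclass
class ExpressionTruth:
    """Ground truth behind one pair of synthetic expression tables."""

    planted_de_probesets: set[str]
    planted_clusters: list[tuple[str, int, int, tuple[str, ...]]]
    planted_chrom_enrichment: dict[str, float]
    effect_log2fc: float
    noise_sd: float
    normalization_corr: float
    seed: int
    planted_directions: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.effect_log2fc <= 0:
            raise ValueError("effect_log2fc must be positive")
        if not (0.0 < self.normalization_corr <= 1.0):
            raise ValueError("normalization_corr must be in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def validate_against(self, universe: ChipUniverse) -> None:
        missing = [p for p in self.planted_de_probesets if p not in universe]
        if missing:
            raise ValueError(f"planted probesets absent from universe: {missing[:5]}")
        for chrom, start, end, members in self.planted_clusters:
            for p in members:
                if p not in self.planted_de_probesets:
                    raise ValueError(
                        f"cluster member {p} not in planted_de_probesets"
                    )


def plan_expression_truth(
    universe: ChipUniverse,
    n_de_genes: int,
    effect_log2fc: float = 2.0,
    noise_sd: float = 0.25,
    normalization_corr: float = 0.9,
    chrom_excess: Mapping[str, float] | None = None,
    n_clusters: int = 0,
    genes_per_cluster: int = 3,
    cluster_span_bp: int = 400_000,
    frac_over: float = 0.5,
    seed: int = 0,
    recover_window_bp: int = 500_000,
    recover_slide_bp: int = 100_000,
    recover_density_ratio: float = 0.75,
) -> ExpressionTruth:
    """Choose which probesets to misexpress, with optional structure.

    ``n_clusters`` runs of ``genes_per_cluster`` genomically consecutive
    genes (total anchor span <= ``cluster_span_bp``) are planted first;
    then genes are drawn uniformly per chromosome at the background rate
    implied by ``n_de_genes``, raised by ``chrom_excess`` (a map
    chromosome -> excess DE *fraction* of that chromosome's genes) where
    given.  All probesets of a chosen gene are planted, with one random
    direction per gene.

    Planted runs are only accepted at *recoverable* positions: some
    window on the ``recover_window_bp``/``recover_slide_bp`` scan grid
    must contain the whole run at a DE density >= the
    ``recover_density_ratio`` threshold, and runs keep more than one
    window length of clearance from each other, so that in the noiseless
    limit every planted cluster is detected and no two merge.
    """
    rng = np.random.default_rng(seed)
    genes: dict[str, list[GeneAnnotation]] = {}
    for ann in universe.annotations:
        genes.setdefault(ann.gene_symbol, []).append(ann)
    by_chrom: dict[str, list[str]] = {}
    anchor = {g: min(a.start for a in anns) for g, anns in genes.items()}
    for g, anns in genes.items():
        by_chrom.setdefault(anns[0].chromosome, []).append(g)
    for chrom in by_chrom:
        by_chrom[chrom].sort(key=lambda g: (anchor[g], g))

    de_genes: set[str] = set()
    clusters: list[tuple[str, int, int, tuple[str, ...]]] = []
    placed_spans: dict[str, list[tuple[int, int]]] = {}
    chroms = sorted(by_chrom, key=lambda c: -len(by_chrom[c]))

    def recoverable(chrom: str, run: list[str]) -> bool:
        """Some grid window holds the whole run at qualifying density."""
        lo, hi = anchor[run[0]], anchor[run[-1]]
        pos = np.array([anchor[g] for g in by_chrom[chrom]])
        first = max(0, (hi - recover_window_bp) // recover_slide_bp + 1)
        start = first * recover_slide_bp
        while start <= lo:
            in_win = ((pos >= start) & (pos < start + recover_window_bp)).sum()
            if in_win > 0 and genes_per_cluster / in_win >= recover_density_ratio:
                return True
            start += recover_slide_bp
        return False

    attempts = 0
    while len(clusters) < n_clusters:
        attempts += 1
        if attempts > 20_000:
            raise ValueError(
                "could not place requested clusters; map too sparse/dense for "
                f"span {cluster_span_bp} bp at the requested window density"
            )
        chrom = chroms[rng.integers(0, len(chroms))]
        order = by_chrom[chrom]
        if len(order) < genes_per_cluster:
            continue
        i = int(rng.integers(0, len(order) - genes_per_cluster + 1))
        run = order[i : i + genes_per_cluster]
        span = anchor[run[-1]] - anchor[run[0]]
        if span > cluster_span_bp or any(g in de_genes for g in run):
            continue
        lo, hi = anchor[run[0]], anchor[run[-1]]
        near = any(
            lo - 2 * recover_window_bp < e and hi + 2 * recover_window_bp > s
            for s, e in placed_spans.get(chrom, [])
        )
        if near or not recoverable(chrom, run):
            continue
        members = tuple(
            sorted(a.probeset_id for g in run for a in genes[g])
        )
        clusters.append((chrom, lo, hi + 1, members))
        placed_spans.setdefault(chrom, []).append((lo, hi))
        de_genes.update(run)

    # background (optionally chromosome-enriched) singleton DE genes
    n_background = max(n_de_genes - len(de_genes), 0)
    base_rate = n_background / max(universe.n_genes(), 1)
    chrom_excess = dict(chrom_excess or {})
    for chrom, order in by_chrom.items():
        rate = base_rate + chrom_excess.get(chrom, 0.0)
        avail = [g for g in order if g not in de_genes]
        n_pick = min(int(round(rate * len(order))), len(avail))
        if n_pick > 0:
            picks = rng.choice(len(avail), size=n_pick, replace=False)
            de_genes.update(avail[i] for i in picks)

    planted = set()
    directions: dict[str, int] = {}
    for g in sorted(de_genes):
        sign = 1 if rng.random() < frac_over else -1
        for a in genes[g]:
            planted.add(a.probeset_id)
            directions[a.probeset_id] = sign
    truth = ExpressionTruth(
        planted_de_probesets=planted,
        planted_clusters=clusters,
        planted_chrom_enrichment=chrom_excess,
        effect_log2fc=effect_log2fc,
        noise_sd=noise_sd,
        normalization_corr=normalization_corr,
        seed=seed,
        planted_directions=directions,
    )
    truth.validate_against(universe)
    return truth


def make_expression(
    universe: ChipUniverse, truth: ExpressionTruth
) -> tuple[pd.DataFrame, pd.DataFrame, ExpressionTruth]:
    """Two paired expression tables (normalization variants "A" and "B").

    Each table has columns ``probeset_id``, ``mutant``, ``control``
    (positive linear intensities).  Per probeset, variant v's log2 fold
    change is ``delta + noise_v`` with ``delta`` the planted signed
    effect (0 for unplanted probesets) and ``noise_v`` split into a
    shared and an independent part so that
    ``corr(noise_A, noise_B) = normalization_corr``.
    """
    truth.validate_against(universe)
    rng = np.random.default_rng(truth.seed)
    ids = universe.probeset_ids
    n = len(ids)
    log2_control = rng.normal(8.0, 1.5, size=n)
    delta = np.array(
        [
            truth.planted_directions.get(p, 0) * truth.effect_log2fc
            if p in truth.planted_de_probesets
            else 0.0
            for p in ids
        ]
    )
    rho = truth.normalization_corr
    shared = rng.normal(0.0, truth.noise_sd, size=n)
    indep_a = rng.normal(0.0, truth.noise_sd, size=n)
    indep_b = rng.normal(0.0, truth.noise_sd, size=n)
    noise_a = math.sqrt(rho) * shared + math.sqrt(1.0 - rho) * indep_a
    noise_b = math.sqrt(rho) * shared + math.sqrt(1.0 - rho) * indep_b
    tables = []
    for noise in (noise_a, noise_b):
        tables.append(
            pd.DataFrame(
                {
                    "probeset_id": ids,
                    "mutant": 2.0 ** (log2_control + delta + noise),
                    "control": 2.0 ** log2_control,
                }
            )
        )
    return tables[0], tables[1], truth


# -- nuclei --------------------------------------------------------------


def point_to_ellipsoid_edge(
    point: Sequence[float], semi_axes: Sequence[float]
) -> float:
    """Shortest distance from an interior point to an axis-aligned
    ellipsoid surface centered at the origin.

    Exact ``R - |p|`` for a sphere; otherwise a multi-start smooth
    minimization over the spherically parameterized surface (the
    closest-point problem can have several stationary points, so starts
    cover the axis directions and the direction of the point itself).
    """
    p = np.asarray(point, dtype=float)
    a = np.asarray(semi_axes, dtype=float)
    if (a <= 0).any():
        raise ValueError("semi-axes must be positive")
    if (p**2 / a**2).sum() > 1.0 + 1e-9:
        raise ValueError("point lies outside the ellipsoid")
    if np.allclose(a, a[0]):
        return float(a[0] - np.linalg.norm(p))

    def surface(angles: np.ndarray) -> np.ndarray:
        th, ph = angles
        return a * np.array(
            [np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)]
        )

    def objective(angles: np.ndarray) -> float:
        return float(((surface(angles) - p) ** 2).sum())

    starts = [
        (np.pi / 2, 0.0), (np.pi / 2, np.pi / 2), (np.pi / 2, np.pi),
        (np.pi / 2, 3 * np.pi / 2), (1e-3, 0.0), (np.pi - 1e-3, 0.0),
    ]
    if np.linalg.norm(p) > 0:
        u = p / np.linalg.norm(p)
        starts.append((float(np.arccos(np.clip(u[2], -1, 1))),
                       float(np.arctan2(u[1], u[0]))))
    best = np.inf
    for s in starts:
        res = minimize(objective, np.asarray(s), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-14})
        best = min(best, float(res.fun))
    return float(np.sqrt(best))


@dataclass
class NucleusTruth:
    """Ground truth for one synthetic nucleus.

    Geometry is in um relative to the nucleus center.  Territory offsets
    should lie in the equatorial (z = 0) plane or on the y = 0 plane so
    that the slice-based two-plane edge-distance protocol attains the
    true 3D minimum in one of its passes.
    """

    semi_axes_um: tuple[float, float, float]  # (ax, ay, az)
    territory_specs: list[tuple[tuple[float, float, float], float]] = field(
        default_factory=list
    )  # (center offset (x, y, z) um, radius um)
    signal_positions: list[tuple[float, float, float, str]] = field(
        default_factory=list
    )  # (x, y, z, channel)
    lamina_shell_thickness_um: float = 0.2
    snr: float | None = 20.0
    seed: int = 0
    # derived, filled on construction
    true_min_edge_distances_um: list[float] = field(default_factory=list)
    true_pair_distance_um: float | None = None
    true_volume_ratios: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        ax = np.asarray(self.semi_axes_um, dtype=float)
        if (ax <= 0).any():
            raise ValueError("semi-axes must be positive")
        self.true_min_edge_distances_um = []
        self.true_volume_ratios = []
        nuc_vol = 4.0 / 3.0 * math.pi * float(np.prod(ax))
        for center, radius in self.territory_specs:
            if radius <= 0:
                raise ValueError("territory radius must be positive")
            edge = point_to_ellipsoid_edge(center, ax) - radius
            if edge < -1e-9:
                raise ValueError(
                    f"territory at {center} with radius {radius} um does not fit "
                    "inside the nucleus"
                )
            self.true_min_edge_distances_um.append(max(edge, 0.0))
            self.true_volume_ratios.append(4.0 / 3.0 * math.pi * radius**3 / nuc_vol)
        for x, y, z, _ in self.signal_positions:
            if (np.array([x, y, z]) ** 2 / ax**2).sum() > 1.0 + 1e-9:
                raise ValueError(f"signal at {(x, y, z)} lies outside the nucleus")
        if len(self.signal_positions) >= 2:
            p1 = np.array(self.signal_positions[0][:3])
            p2 = np.array(self.signal_positions[1][:3])
            self.true_pair_distance_um = float(np.linalg.norm(p1 - p2))


def make_nucleus_truth(
    seed: int,
    radius_um: tuple[float, float] = (3.0, 4.5),
    n_territories: int = 1,
    territory_radius_um: tuple[float, float] = (0.8, 1.2),
    n_signals: int = 2,
    snr: float | None = 20.0,
) -> NucleusTruth:
    """Random spherical-nucleus truth with equatorial-plane territories.

    Territory offsets are drawn in the z = 0 plane (so the x-y pass of the
    two-plane protocol sees the true minimum); signals are drawn anywhere
    in the inner 70% of the nucleus.
    """
    rng = np.random.default_rng(seed)
    r = float(rng.uniform(*radius_um))
    semi = (r, r, r)
    specs = []
    for _ in range(n_territories):
        tr = float(rng.uniform(*territory_radius_um))
        max_off = r - tr
        rho = float(rng.uniform(0.0, 0.9 * max_off))
        theta = float(rng.uniform(0.0, 2 * math.pi))
        specs.append(((rho * math.cos(theta), rho * math.sin(theta), 0.0), tr))
    signals = []
    for i in range(n_signals):
        while True:
            p = rng.uniform(-0.7 * r, 0.7 * r, size=3)
            if (p**2).sum() <= (0.7 * r) ** 2:
                break
        signals.append((float(p[0]), float(p[1]), float(p[2]), f"signal_{i + 1}"))
    return NucleusTruth(
        semi_axes_um=semi,
        territory_specs=specs,
        signal_positions=signals,
        snr=snr,
        seed=seed,
    )


def _grid_coords(
    semi_axes: tuple[float, float, float],
    voxel_size: tuple[float, float, float],
    margin_um: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, tuple[int, int, int]]:
    dx, dy, dz = voxel_size
    ax, ay, az = semi_axes
    nx = int(math.ceil(2 * (ax + margin_um) / dx))
    ny = int(math.ceil(2 * (ay + margin_um) / dy))
    nz = int(math.ceil(2 * (az + margin_um) / dz))
    # physical coordinate of each voxel center, relative to nucleus center
    xs = (np.arange(nx) - (nx - 1) / 2.0) * dx
    ys = (np.arange(ny) - (ny - 1) / 2.0) * dy
    zs = (np.arange(nz) - (nz - 1) / 2.0) * dz
    return xs, ys, zs, (nz, ny, nx)


def rasterize_truth(
    truth: NucleusTruth,
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE,
    margin_um: float = 0.6,
) -> dict[str, np.ndarray]:
    """Analytic binary masks of the planted geometry (no optics, no noise).

    Returns masks keyed ``nucleus``, ``lamin``, ``territory_<i>`` and the
    signal channel names; the nucleus is centered in the grid.
    """
    xs, ys, zs, shape = _grid_coords(truth.semi_axes_um, voxel_size, margin_um)
    ax, ay, az = truth.semi_axes_um
    Z, Y, X = np.meshgrid(zs, ys, xs, indexing="ij")
    rho2 = (X / ax) ** 2 + (Y / ay) ** 2 + (Z / az) ** 2
    masks: dict[str, np.ndarray] = {"nucleus": rho2 <= 1.0}
    t_rel = truth.lamina_shell_thickness_um / min(truth.semi_axes_um)
    masks["lamin"] = (rho2 <= 1.0) & (rho2 >= (1.0 - t_rel) ** 2)
    for i, ((cx, cy, cz), r) in enumerate(truth.territory_specs, start=1):
        masks[f"territory_{i}"] = (X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2 <= r**2
    for (sx, sy, sz, label) in truth.signal_positions:
        r = 0.25  # FISH spot radius um
        masks[label] = (X - sx) ** 2 + (Y - sy) ** 2 + (Z - sz) ** 2 <= r**2
    return masks


def make_nucleus_stack(
    truth: NucleusTruth,
    voxel_size_xy: float = DEFAULT_VOXEL_SIZE[0],
    voxel_size_z: float = DEFAULT_VOXEL_SIZE[2],
    psf_sigma_um: float = 0.08,
    margin_um: float = 0.6,
) -> tuple[VoxelGrid, NucleusTruth]:
    """Render a multi-channel stack for one nucleus truth.

    Channels: ``dapi`` (filled ellipsoid), ``lamin`` (thin boundary
    shell), ``territory_<i>`` (solid spheres) and one channel per planted
    FISH signal.  Every channel is blurred with an isotropic Gaussian PSF
    of ``psf_sigma_um`` and, when ``truth.snr`` is set, corrupted with
    Poisson-Gaussian noise scaled so that a unit-intensity voxel has the
    stated signal-to-noise ratio.
    """
    if voxel_size_xy <= 0 or voxel_size_z <= 0:
        raise ValueError("voxel sizes must be positive")
    voxel_size = (voxel_size_xy, voxel_size_xy, voxel_size_z)
    masks = rasterize_truth(truth, voxel_size, margin_um)
    rng = np.random.default_rng(truth.seed)
    sigma_vox = (
        psf_sigma_um / voxel_size_z,
        psf_sigma_um / voxel_size_xy,
        psf_sigma_um / voxel_size_xy,
    )
    channels: dict[str, np.ndarray] = {}
    for label, mask in masks.items():
        if label == "nucleus":
            label_out = "dapi"
        else:
            label_out = label
        img = ndimage.gaussian_filter(mask.astype(float), sigma=sigma_vox)
        if truth.snr is not None:
            photons = rng.poisson(np.clip(img, 0.0, None) * truth.snr**2)
            img = photons / truth.snr**2 + rng.normal(
                0.0, 0.5 / truth.snr, size=img.shape
            )
        channels[label_out] = img.astype(np.float32)
    return VoxelGrid(channels=channels, voxel_size=voxel_size), truth
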