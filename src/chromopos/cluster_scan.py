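"""Sliding-window genomic clusters of misexpressed genes and their null.

A 500 kb window slides along each chromosome in 100 kb steps.  Within a
window the chip defines the local gene universe; the window *qualifies*
when misexpressed genes make up at least 75% of the chip genes anchored
there and there are at least two of them.  Overlapping or abutting
qualifying windows merge into maximal *genomic clusters*.  Significance of
the observed cluster count comes from an empirical null: many random
probeset lists of the same size are drawn from the chip, collapsed to
genes, and scanned identically; the upper-tail empirical p-value uses the
plus-one convention ``(b + 1)/(n_sims + 1)`` so that zero exceedances over
1000 simulations reports "<0.001".

Counting is by deduplicated gene symbol, each gene anchored at its lowest
probeset start coordinate (see :mod:`chromopos.genemap_io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .de_ranking import DEGeneSet, collapse_to_genes
from .genemap_io import ChipUniverse

__all__ = [
    "ScanConfig",
    "Window",
    "GenomicCluster",
    "NullClusterDistribution",
    "EmpiricalPReport",
    "scan_windows",
    "merge_windows",
    "count_clusters",
    "null_cluster_distribution",
    "empirical_p",
    "clusters_to_frame",
    "clusters_to_bed",
]


@dataclass(frozen=True)
class ScanConfig:
    """Window-scan parameters.

    Defaults are the published protocol: 500 kb window, 100 kb slide,
    misexpressed-gene density >= 75% of local chip-gene density, and more
    than one misexpressed gene per window.
    """

    window_bp: int = 500_000
    slide_bp: int = 100_000
    density_ratio_min: float = 0.75
    min_de_genes: int = 2

    def __post_init__(self) -> None:
        if self.slide_bp <= 0 or self.window_bp <= 0:
            raise ValueError("window_bp and slide_bp must be positive")
        if self.slide_bp > self.window_bp:
            raise ValueError("slide_bp must not exceed window_bp")
        if not (0.0 < self.density_ratio_min <= 1.0):
            raise ValueError("density_ratio_min must be in (0, 1]")
        if self.min_de_genes < 2:
            raise ValueError("min_de_genes must be >= 2")


@dataclass(frozen=True)
class Window:
    """One qualifying window position."""

    chromosome: str
    start: int
    end: int
    n_chip_genes: int
    n_de_genes: int
    de_genes: tuple[str, ...]

    @property
    def density_ratio(self) -> float:
        return self.n_de_genes / self.n_chip_genes


@dataclass(frozen=True)
class GenomicCluster:
    """A maximal run of merged qualifying windows on one chromosome."""

    chromosome: str
    start: int
    end: int
    member_de_genes: tuple[str, ...]
    n_chip_genes: int
    peak_density_ratio: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("cluster start must precede end")


class _ScanIndex:
    """Per-chromosome window geometry precomputed once per (universe, config).

    Genes (unique symbols) are anchored at their minimum probeset start and
    sorted; every window's chip-gene span reduces to a pair of searchsorted
    indices, so a scan over any DE gene set is two cumulative sums.
    """

    def __init__(self, universe: ChipUniverse, config: ScanConfig):
        if len(universe) == 0:
            raise ValueError("empty universe")
        self.config = config
        anchors: dict[str, dict[str, int]] = {}
        for ann in universe.annotations:
            per = anchors.setdefault(ann.chromosome, {})
            cur = per.get(ann.gene_symbol)
            per[ann.gene_symbol] = ann.start if cur is None else min(cur, ann.start)
        self.chroms: list[str] = [c for c in universe.chromosomes]
        self.gene_names: dict[str, np.ndarray] = {}
        self.gene_anchors: dict[str, np.ndarray] = {}
        self.window_starts: dict[str, np.ndarray] = {}
        self.window_ends: dict[str, np.ndarray] = {}
        self.lo: dict[str, np.ndarray] = {}
        self.hi: dict[str, np.ndarray] = {}
        self.n_chip: dict[str, np.ndarray] = {}
        for chrom in self.chroms:
            per = anchors[chrom]
            names = np.array(sorted(per, key=lambda g: (per[g], g)))
            pos = np.array([per[g] for g in names], dtype=np.int64)
            size = universe.chrom_sizes[chrom]
            starts = np.arange(0, size, config.slide_bp, dtype=np.int64)
            ends = np.minimum(starts + config.window_bp, size)
            lo = np.searchsorted(pos, starts, side="left")
            hi = np.searchsorted(pos, starts + config.window_bp, side="left")
            self.gene_names[chrom] = names
            self.gene_anchors[chrom] = pos
            self.window_starts[chrom] = starts
            self.window_ends[chrom] = ends
            self.lo[chrom] = lo
            self.hi[chrom] = hi
            self.n_chip[chrom] = (hi - lo).astype(np.int64)

    def de_indicator(self, chrom: str, de_genes: set[str]) -> np.ndarray:
        return np.isin(self.gene_names[chrom], list(de_genes)) if de_genes else np.zeros(
            len(self.gene_names[chrom]), dtype=bool
        )


def _scan_with_index(index: _ScanIndex, de_genes: set[str]) -> list[Window]:
    cfg = index.config
    out: list[Window] = []
    for chrom in index.chroms:
        ind = index.de_indicator(chrom, de_genes).astype(np.int64)
        csum = np.concatenate(([0], np.cumsum(ind)))
        n_de = csum[index.hi[chrom]] - csum[index.lo[chrom]]
        n_chip = index.n_chip[chrom]
        with np.errstate(divide="ignore", invalid="ignore"):
            ok = (
                (n_chip > 0)
                & (n_de >= cfg.min_de_genes)
                & (n_de >= cfg.density_ratio_min * n_chip)
            )
        for w in np.nonzero(ok)[0]:
            members = index.gene_names[chrom][index.lo[chrom][w] : index.hi[chrom][w]]
            members = tuple(sorted(m for m in members if m in de_genes))
            out.append(
                Window(
                    chromosome=chrom,
                    start=int(index.window_starts[chrom][w]),
                    end=int(index.window_ends[chrom][w]),
                    n_chip_genes=int(n_chip[w]),
                    n_de_genes=int(n_de[w]),
                    de_genes=members,
                )
            )
    return out


def scan_windows(
    universe: ChipUniverse,
    de_set: DEGeneSet | Iterable[str],
    config: ScanConfig = ScanConfig(),
    _index: _ScanIndex | None = None,
) -> list[Window]:
    """All qualifying windows over every chromosome.

    ``de_set`` is a :class:`~chromopos.de_ranking.DEGeneSet` (its gene
    symbols are used) or a bare iterable of gene symbols.  The window grid
    starts at coordinate 0 on each chromosome and the final partial window
    is scanned.  A window qualifies when it holds at least one chip gene,
    the misexpressed fraction of its chip genes is >= ``density_ratio_min``
    and it holds >= ``min_de_genes`` misexpressed genes.
    """
    de_genes = set(de_set.gene_symbols if isinstance(de_set, DEGeneSet) else de_set)
    index = _index if _index is not None else _ScanIndex(universe, config)
    return _scan_with_index(index, de_genes)


def merge_windows(windows: Sequence[Window]) -> list[GenomicCluster]:
    """Merge overlapping/abutting qualifying windows into maximal clusters.

    Windows on different chromosomes never merge.  Member genes are the
    union over merged windows; ``peak_density_ratio`` is the maximum
    single-window ratio within the cluster.
    """
    by_chrom: dict[str, list[Window]] = {}
    for w in windows:
        by_chrom.setdefault(w.chromosome, []).append(w)
    clusters: list[GenomicCluster] = []
    for chrom in sorted(by_chrom, key=lambda c: (len(c), c)):
        ws = sorted(by_chrom[chrom], key=lambda w: w.start)
        cur: list[Window] = [ws[0]]
        cur_end = ws[0].end
        for w in ws[1:]:
            if w.start <= cur_end:  # overlap or abut
                cur.append(w)
                cur_end = max(cur_end, w.end)
            else:
                clusters.append(_make_cluster(chrom, cur))
                cur = [w]
                cur_end = w.end
        clusters.append(_make_cluster(chrom, cur))
    return clusters


def _make_cluster(chrom: str, windows: list[Window]) -> GenomicCluster:
    genes = sorted(set().union(*(w.de_genes for w in windows)))
    return GenomicCluster(
        chromosome=chrom,
        start=min(w.start for w in windows),
        end=max(w.end for w in windows),
        member_de_genes=tuple(genes),
        n_chip_genes=max(w.n_chip_genes for w in windows),
        peak_density_ratio=max(w.density_ratio for w in windows),
    )


def count_clusters(
    universe: ChipUniverse,
    de_set: DEGeneSet | Iterable[str],
    config: ScanConfig = ScanConfig(),
    _index: _ScanIndex | None = None,
) -> int:
    """Number of merged genomic clusters for one DE gene set."""
    windows = scan_windows(universe, de_set, config, _index=_index)
    return len(merge_windows(windows)) if windows else 0


@dataclass
class NullClusterDistribution:
    """Cluster counts over random probeset lists of fixed size."""

    n_sims: int
    list_size: int
    counts: list[int]
    seed: int
    config: ScanConfig = field(default_factory=ScanConfig)

    def __post_init__(self) -> None:
        if len(self.counts) != self.n_sims:
            raise ValueError("counts length must equal n_sims")

    @property
    def mean(self) -> float:
        return float(np.mean(self.counts))

    @property
    def min(self) -> int:
        return int(np.min(self.counts))

    @property
    def max(self) -> int:
        return int(np.max(self.counts))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sim": np.arange(len(self.counts)), "cluster_count": self.counts}
        )


def null_cluster_distribution(
    universe: ChipUniverse,
    list_size: int,
    n_sims: int = 1000,
    config: ScanConfig = ScanConfig(),
    seed: int = 0,
) -> NullClusterDistribution:
    """Empirical null over uniformly drawn probeset lists.

    Each simulation draws ``list_size`` probesets without replacement from
    the chip, collapses them to unique genes (mirroring the real pipeline,
    where randomization is at probeset level), scans and merges, and
    records the cluster count.
    """
    if list_size > len(universe):
        raise ValueError(
            f"list_size {list_size} exceeds universe size {len(universe)}"
        )
    if list_size < 1 or n_sims < 1:
        raise ValueError("list_size and n_sims must be >= 1")
    rng = np.random.default_rng(seed)
    index = _ScanIndex(universe, config)
    probesets = np.array(universe.probeset_ids)
    gene_of = {a.probeset_id: a.gene_symbol for a in universe.annotations}
    counts: list[int] = []
    for _ in range(n_sims):
        drawn = probesets[rng.choice(len(probesets), size=list_size, replace=False)]
        genes = {gene_of[p] for p in drawn}
        counts.append(len(merge_windows(_scan_with_index(index, genes))) if genes else 0)
    return NullClusterDistribution(
        n_sims=n_sims, list_size=list_size, counts=counts, seed=seed, config=config
    )


@dataclass(frozen=True)
class EmpiricalPReport:
    """Upper-tail empirical p-value against a simulated null."""

    observed: int
    n_exceedances: int
    n_sims: int
    p: float
    rendered: str


def empirical_p(observed_count: int, null: NullClusterDistribution) -> EmpiricalPReport:
    """Plus-one empirical p-value ``(b + 1)/(n_sims + 1)``.

    ``b`` counts simulations with a cluster count >= the observed count
    (one-sided upper tail).  When ``b == 0`` the rendered form additionally
    reports the conventional bound ``< 1/n_sims`` (e.g. "<0.001" for 1000
    simulations).
    """
    counts = np.asarray(null.counts)
    b = int((counts >= observed_count).sum())
    p = (b + 1) / (null.n_sims + 1)
    if b == 0:
        rendered = f"<{1 / null.n_sims:g}"
    else:
        rendered = f"{p:.4g}"
    return EmpiricalPReport(
        observed=observed_count, n_exceedances=b, n_sims=null.n_sims, p=p, rendered=rendered
    )


def clusters_to_frame(clusters: Sequence[GenomicCluster]) -> pd.DataFrame:
    rows = [
        {
            "chromosome": c.chromosome,
            "start": c.start,
            "end": c.end,
            "genes": ",".join(c.member_de_genes),
            "n_de_genes": len(c.member_de_genes),
            "n_chip_genes": c.n_chip_genes,
            "peak_density_ratio": c.peak_density_ratio,
        }
        for c in clusters
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "chromosome",
            "start",
            "end",
            "genes",
            "n_de_genes",
            "n_chip_genes",
            "peak_density_ratio",
        ],
    )


def clusters_to_bed(clusters: Sequence[GenomicCluster], path) -> None:
    with open(path, "w") as fh:
        for c in clusters:
            fh.write(
                f"chr{c.chromosome}\t{c.start}\t{c.end}\t{'|'.join(c.member_de_genes)}\n"
            )
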