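"""Per-chromosome misexpression enrichment and cross-tissue shared genes.

If misexpression were blind to genomic position, each chromosome would
carry the genome-wide misexpressed fraction of its chip genes.  This
module computes the per-chromosome percentages, tests uniformity with a
plain chi-square goodness-of-fit against chip-composition expectations
(24 autosome+sex categories when all are on the chip, hence df = 23), and
intersects two tissues' gene-level calls to find shared misexpressed
genes and their chromosomal distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .de_ranking import DEGeneSet
from .genemap_io import ChipUniverse, normalize_chromosome

__all__ = [
    "ChromEnrichmentResult",
    "SharedGeneResult",
    "chromosome_fractions",
    "chi_square_uniformity",
    "shared_genes",
]

logger = logging.getLogger(__name__)

CountMode = Literal["gene", "probeset"]


@dataclass
class ChromEnrichmentResult:
    """Per-chromosome misexpression table plus genome-wide summary.

    ``per_chromosome`` columns: ``n_chip``, ``n_de``, ``percent`` (raw
    float, 100 * n_de / n_chip); chromosomes with no chip genes are
    excluded (and logged).  Chi-square fields are filled by
    :func:`chi_square_uniformity`.
    """

    per_chromosome: pd.DataFrame
    genomewide_percent: float
    n_de_total: int
    n_chip_total: int
    mode: str = "gene"
    chi2: float | None = None
    df: int | None = None
    p: float | None = None

    def to_frame(self) -> pd.DataFrame:
        """Report table with expected counts and chi-square contributions."""
        tab = self.per_chromosome.copy()
        frac = self.n_de_total / self.n_chip_total
        tab["expected"] = tab["n_chip"] * frac
        tab["chi2_contribution"] = (tab["n_de"] - tab["expected"]) ** 2 / tab["expected"]
        return tab


def chromosome_fractions(
    universe: ChipUniverse,
    de_set: DEGeneSet,
    mode: CountMode = "gene",
) -> ChromEnrichmentResult:
    """Misexpressed percentage of chip genes, per chromosome and genome-wide.

    ``mode="gene"`` (default) counts deduplicated gene symbols; the
    probeset mode counts probesets instead.  Rounding is left to the
    report layer -- all percentages here are raw floats.
    """
    if mode not in ("gene", "probeset"):
        raise ValueError(f"mode must be 'gene' or 'probeset', got {mode!r}")
    rows = {}
    if mode == "gene":
        de_by_chrom: dict[str, int] = {}
        for call in de_set.genes.values():
            de_by_chrom[call.chromosome] = de_by_chrom.get(call.chromosome, 0) + 1
        n_de_total = de_set.n_genes
        for chrom in universe.chromosomes:
            rows[chrom] = (universe.n_genes(chrom), de_by_chrom.get(chrom, 0))
    else:
        de_probesets = de_set.over_probesets | de_set.under_probesets
        de_by_chrom = {}
        for p in de_probesets:
            chrom = universe.annotation(p).chromosome
            de_by_chrom[chrom] = de_by_chrom.get(chrom, 0) + 1
        n_de_total = len(de_probesets)
        for chrom in universe.chromosomes:
            rows[chrom] = (universe.n_probesets(chrom), de_by_chrom.get(chrom, 0))
    dropped = [c for c, (n_chip, _) in rows.items() if n_chip == 0]
    if dropped:
        logger.warning("chromosomes with no chip genes excluded: %s", dropped)
    rows = {c: v for c, v in rows.items() if v[0] > 0}
    n_chip_total = sum(v[0] for v in rows.values())
    tab = pd.DataFrame(
        {
            "n_chip": [rows[c][0] for c in rows],
            "n_de": [rows[c][1] for c in rows],
        },
        index=pd.Index(list(rows), name="chromosome"),
    )
    tab["percent"] = 100.0 * tab["n_de"] / tab["n_chip"]
    return ChromEnrichmentResult(
        per_chromosome=tab,
        genomewide_percent=100.0 * n_de_total / n_chip_total,
        n_de_total=n_de_total,
        n_chip_total=n_chip_total,
        mode=mode,
    )


def chi_square_uniformity(
    result: ChromEnrichmentResult,
) -> tuple[float, int, float]:
    """Chi-square goodness-of-fit of DE counts against chip composition.

    Expected count for chromosome c is ``n_chip_c`` times the genome-wide
    misexpressed fraction, so the test asks whether misexpressed genes are
    spread over chromosomes in proportion to chip-gene content.
    df = (number of chromosomes with chip genes) - 1; no continuity
    correction.  The result object is updated in place and the
    ``(chi2, df, p)`` triple returned.
    """
    tab = result.per_chromosome
    if len(tab) < 2:
        raise ValueError("need at least 2 chromosome categories")
    observed = tab["n_de"].to_numpy(float)
    expected = tab["n_chip"].to_numpy(float) * (result.n_de_total / result.n_chip_total)
    if (expected <= 0).any():
        raise ValueError("all expected counts must be positive")
    chi2, p = stats.chisquare(observed, expected)
    df = len(tab) - 1
    result.chi2, result.df, result.p = float(chi2), df, float(p)
    return float(chi2), df, float(p)


@dataclass
class SharedGeneResult:
    """Genes misexpressed in both of two tissue contrasts."""

    shared: set[str]
    per_chromosome: pd.DataFrame  # columns: n_shared, n_chip, percent_of_chip

    @property
    def n_shared(self) -> int:
        return len(self.shared)

    def n_on(self, chromosome: str) -> int:
        chrom = normalize_chromosome(chromosome)
        if chrom not in self.per_chromosome.index:
            return 0
        return int(self.per_chromosome.loc[chrom, "n_shared"])

    def percent_of_chip(self, chromosome: str) -> float:
        chrom = normalize_chromosome(chromosome)
        return float(self.per_chromosome.loc[chrom, "percent_of_chip"])


def shared_genes(
    de_set_a: DEGeneSet, de_set_b: DEGeneSet, universe: ChipUniverse
) -> SharedGeneResult:
    """Gene-symbol intersection of two tissues' calls, by chromosome.

    The per-chromosome shared fraction is quoted against the chip's gene
    content of that chromosome (``100 * shared_on_chrom / n_chip_on_chrom``).
    """
    shared = de_set_a.gene_symbols & de_set_b.gene_symbols
    by_chrom: dict[str, int] = {}
    for sym in shared:
        chrom = de_set_a.genes[sym].chromosome
        by_chrom[chrom] = by_chrom.get(chrom, 0) + 1
    chroms = universe.chromosomes
    tab = pd.DataFrame(
        {
            "n_shared": [by_chrom.get(c, 0) for c in chroms],
            "n_chip": [universe.n_genes(c) for c in chroms],
        },
        index=pd.Index(chroms, name="chromosome"),
    )
    tab = tab[tab["n_chip"] > 0]
    tab["percent_of_chip"] = 100.0 * tab["n_shared"] / tab["n_chip"]
    return SharedGeneResult(shared=shared, per_chromosome=tab)
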