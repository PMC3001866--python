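"""Fold changes, rank-products ranking and dual-normalization intersection.

With a single mutant/control pair per tissue, moderated statistics are not
available; the robust alternative used here is to rank probesets by fold
change with the rank-products statistic under each of two independent
normalization variants, keep the top-K over- and under-expressed lists from
each variant, and call differentially expressed (DE) only the probesets in
the intersection of the two variants' lists.  Probeset calls are then
collapsed to unique gene symbols, with a ``discordant`` direction for genes
whose member probesets disagree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .genemap_io import ChipUniverse

__all__ = [
    "Direction",
    "FoldChange",
    "GeneCall",
    "DEGeneSet",
    "fold_change",
    "fold_change_table",
    "rank_products",
    "intersect_top_k",
    "collapse_to_genes",
    "call_de_probesets",
]

Direction = Literal["over", "under"]


@dataclass(frozen=True)
class FoldChange:
    """Signed fold change of one probeset.

    ``fc_signed`` follows the microarray reporting convention: the ratio
    mutant/control when >= 1, else the negated reciprocal (so a halving is
    -2.0, never 0.5).  ``log2fc`` is the plain log2 ratio; a ratio of
    exactly 1 is reported as +1.0 / 0.0.
    """

    probeset_id: str
    fc_signed: float
    log2fc: float

    def __post_init__(self) -> None:
        if abs(self.fc_signed) < 1.0 - 1e-12:
            raise ValueError(f"|fc_signed| must be >= 1, got {self.fc_signed}")
        sign_fc = 1.0 if self.fc_signed >= 0 else -1.0
        sign_log = 1.0 if self.log2fc >= 0 else -1.0
        if sign_fc != sign_log:
            raise ValueError("fc_signed and log2fc must agree in sign")


def fold_change(mutant: float, control: float, probeset_id: str = "") -> FoldChange:
    """Signed fold change of ``mutant`` relative to ``control``.

    Both intensities must be strictly positive.
    """
    if mutant <= 0 or control <= 0:
        raise ValueError(
            f"intensities must be positive, got mutant={mutant}, control={control}"
        )
    r = mutant / control
    fc_signed = r if r >= 1.0 else -1.0 / r
    return FoldChange(probeset_id=probeset_id, fc_signed=fc_signed, log2fc=math.log2(r))


def fold_change_table(expression: pd.DataFrame) -> pd.Series:
    """log2 fold changes for a two-column expression table.

    ``expression`` must have columns ``probeset_id``, ``mutant``,
    ``control`` (intensities, linear scale).  Returns a Series of log2
    fold changes indexed by probeset id.
    """
    for col in ("probeset_id", "mutant", "control"):
        if col not in expression.columns:
            raise ValueError(f"expression table missing column {col!r}")
    mut = expression["mutant"].to_numpy(float)
    ctl = expression["control"].to_numpy(float)
    if (mut <= 0).any() or (ctl <= 0).any():
        raise ValueError("expression intensities must be positive")
    return pd.Series(
        np.log2(mut / ctl), index=pd.Index(expression["probeset_id"], name="probeset_id")
    )


def rank_products(
    fold_change_lists: Sequence[Mapping[str, float]] | Sequence[pd.Series],
    direction: Direction,
) -> pd.Series:
    """Rank probesets by the rank-products statistic over >= 1 comparisons.

    Each element of ``fold_change_lists`` maps probeset id -> log2 fold
    change for one comparison; all comparisons must cover the same
    universe.  Within each comparison probesets are ranked 1..N with rank 1
    the most extreme in ``direction`` ("over": largest log2fc; "under":
    smallest).  The rank product is the geometric mean of a probeset's
    ranks across comparisons.

    Returns a Series of RP scores indexed by probeset id, sorted ascending
    (best first); ties in both the within-comparison ranks and the final
    ordering are broken by probeset id, lexicographically, so the output is
    fully deterministic.
    """
    if direction not in ("over", "under"):
        raise ValueError(f"direction must be 'over' or 'under', got {direction!r}")
    if len(fold_change_lists) == 0:
        raise ValueError("need at least one comparison")
    series = [pd.Series(fc, dtype=float) for fc in fold_change_lists]
    universe = set(series[0].index)
    for s in series[1:]:
        if set(s.index) != universe:
            raise ValueError("fold-change lists cover different probeset universes")
    ids = sorted(universe)
    n = len(ids)
    log_rp = np.zeros(n)
    for s in series:
        vals = s.loc[ids].to_numpy(float)
        key = -vals if direction == "over" else vals
        # lexsort: primary key extremeness, secondary probeset id (ids sorted)
        order = np.lexsort((np.arange(n), key))
        ranks = np.empty(n, dtype=float)
        ranks[order] = np.arange(1, n + 1)
        log_rp += np.log(ranks)
    rp = np.exp(log_rp / len(series))
    out = pd.Series(rp, index=pd.Index(ids, name="probeset_id"), name="rank_product")
    return out.sort_values(kind="stable")  # index already id-sorted -> det. ties


def intersect_top_k(
    ranking_a: pd.Series | Sequence[str],
    ranking_b: pd.Series | Sequence[str],
    k: int,
) -> set[str]:
    """Intersection of the first ``k`` probesets of two rankings."""
    ids_a = list(ranking_a.index) if isinstance(ranking_a, pd.Series) else list(ranking_a)
    ids_b = list(ranking_b.index) if isinstance(ranking_b, pd.Series) else list(ranking_b)
    if set(ids_a) != set(ids_b):
        raise ValueError("rankings cover different probeset universes")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(ids_a):
        raise ValueError(f"k={k} exceeds universe size {len(ids_a)}")
    return set(ids_a[:k]) & set(ids_b[:k])


@dataclass(frozen=True)
class GeneCall:
    """Direction call for one gene, with its member DE probesets."""

    gene_symbol: str
    direction: str  # over | under | discordant
    probesets: tuple[str, ...]
    chromosome: str


@dataclass
class DEGeneSet:
    """Probeset- and gene-level misexpression calls.

    ``over_probesets`` and ``under_probesets`` are disjoint; ``genes`` maps
    each unique gene symbol to its direction call.
    """

    over_probesets: set[str]
    under_probesets: set[str]
    genes: dict[str, GeneCall]

    def __post_init__(self) -> None:
        clash = self.over_probesets & self.under_probesets
        if clash:
            raise ValueError(f"probesets called both over and under: {sorted(clash)[:5]}")
        for sym, call in self.genes.items():
            if not call.probesets:
                raise ValueError(f"gene {sym} has no member probesets")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_over(self) -> int:
        return sum(1 for g in self.genes.values() if g.direction == "over")

    @property
    def n_under(self) -> int:
        return sum(1 for g in self.genes.values() if g.direction == "under")

    @property
    def n_discordant(self) -> int:
        return sum(1 for g in self.genes.values() if g.direction == "discordant")

    @property
    def gene_symbols(self) -> set[str]:
        return set(self.genes)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "gene_symbol": g.gene_symbol,
                "chromosome": g.chromosome,
                "direction": g.direction,
                "probesets": ",".join(g.probesets),
            }
            for g in sorted(self.genes.values(), key=lambda g: g.gene_symbol)
        ]
        return pd.DataFrame(rows, columns=["gene_symbol", "chromosome", "direction", "probesets"])


def collapse_to_genes(
    over: Iterable[str], under: Iterable[str], universe: ChipUniverse
) -> DEGeneSet:
    """Collapse probeset-level DE calls to unique genes.

    A gene is counted once; its direction is ``over``/``under`` when all of
    its member DE probesets agree and ``discordant`` otherwise.  Probesets
    absent from the universe are a hard error (listed in the message).
    """
    over = set(over)
    under = set(under)
    missing = sorted(p for p in over | under if p not in universe)
    if missing:
        raise ValueError(f"probesets absent from universe: {missing}")
    per_gene: dict[str, dict[str, set[str]]] = {}
    for pset, drctn in [(p, "over") for p in over] + [(p, "under") for p in under]:
        ann = universe.annotation(pset)
        per_gene.setdefault(ann.gene_symbol, {"over": set(), "under": set()})[
            drctn
        ].add(pset)
    genes: dict[str, GeneCall] = {}
    for sym, d in per_gene.items():
        if d["over"] and d["under"]:
            direction = "discordant"
        elif d["over"]:
            direction = "over"
        else:
            direction = "under"
        members = tuple(sorted(d["over"] | d["under"]))
        genes[sym] = GeneCall(
            gene_symbol=sym,
            direction=direction,
            probesets=members,
            chromosome=universe.annotation(members[0]).chromosome,
        )
    return DEGeneSet(over_probesets=over, under_probesets=under, genes=genes)


def call_de_probesets(
    expression_a: pd.DataFrame,
    expression_b: pd.DataFrame,
    k: int,
    universe: ChipUniverse | None = None,
) -> tuple[set[str], set[str]] | DEGeneSet:
    """Full DE pipeline for one tissue contrast.

    Ranks both normalization variants' tables by rank products in each
    direction, intersects the two top-``k`` over lists and the two top-``k``
    under lists, and (when a universe is given) collapses the calls to
    genes.  A probeset landing in both the over- and the under-intersection
    cannot occur for ``k <= N/2`` with consistent rankings but is guarded
    against by dropping it from both sets.
    """
    fc_a = fold_change_table(expression_a)
    fc_b = fold_change_table(expression_b)
    over = intersect_top_k(
        rank_products([fc_a], "over"), rank_products([fc_b], "over"), k
    )
    under = intersect_top_k(
        rank_products([fc_a], "under"), rank_products([fc_b], "under"), k
    )
    clash = over & under
    over -= clash
    under -= clash
    if universe is None:
        return over, under
    return collapse_to_genes(over, under, universe)
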