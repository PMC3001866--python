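"""Probeset/gene annotation universe and genomic-interval arithmetic.

A microarray chip measures a fixed set of probesets, each mapped to a gene
symbol and a genomic locus.  This module holds that measurement universe
(:class:`ChipUniverse`), reads and writes it as a plain annotation TSV, and
provides the interval queries the sliding-window cluster scan is built on.

Coordinate conventions
----------------------
Input annotation TSVs carry 1-based fully-closed coordinates (UCSC browser
style).  Internally every interval is 0-based half-open ``[start, end)``;
conversion happens once, on read.  For window-membership queries a gene is
anchored at a single point -- its lower (start) coordinate -- regardless of
strand, so that a long gene can never be counted in two disjoint windows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

__all__ = [
    "ALLOWED_CHROMOSOMES",
    "GeneAnnotation",
    "ChipUniverse",
    "normalize_chromosome",
    "read_gene_map",
    "write_gene_map",
    "write_bed",
    "genes_in_interval",
    "locus_separation_mb",
]

#: Human chromosome labels accepted on input (bare form; "chr" prefix stripped).
ALLOWED_CHROMOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23)) + ("X", "Y")

_REQUIRED_COLUMNS = ("probeset_id", "gene_symbol", "chromosome", "start", "end")


def normalize_chromosome(label: str) -> str:
    """Map ``"chr13"``/``"13"``/``"x"`` synonyms onto the bare stored label.

    Raises ``ValueError`` for anything outside chromosomes 1-22, X and Y.
    """
    lab = str(label).strip()
    if lab.lower().startswith("chr"):
        lab = lab[3:]
    lab = lab.upper()
    if lab not in ALLOWED_CHROMOSOMES:
        raise ValueError(f"unknown chromosome label: {label!r}")
    return lab


@dataclass(frozen=True, order=True)
class GeneAnnotation:
    """One probeset mapped to a gene symbol and a genomic interval.

    ``start``/``end`` are 0-based half-open.  The anchor used for all
    window-membership queries is ``start``.
    """

    chromosome: str
    start: int
    end: int
    probeset_id: str
    gene_symbol: str
    strand: str | None = None

    def __post_init__(self) -> None:
        if not self.probeset_id:
            raise ValueError("probeset_id must be non-empty")
        if self.chromosome not in ALLOWED_CHROMOSOMES:
            raise ValueError(f"unknown chromosome label: {self.chromosome!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) for {self.probeset_id}"
            )
        if self.strand not in (None, "+", "-"):
            raise ValueError(f"strand must be '+', '-' or None, got {self.strand!r}")

    @property
    def anchor(self) -> int:
        return self.start


@dataclass
class ChipUniverse:
    """The full annotated probeset universe of one chip design.

    Parameters
    ----------
    annotations
        All probeset annotations; probeset ids must be unique.
    chrom_sizes
        Chromosome lengths in bp.  When omitted, each chromosome's size is
        inferred as the maximum annotated end coordinate.
    """

    annotations: list[GeneAnnotation]
    chrom_sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for ann in self.annotations:
            if ann.probeset_id in seen:
                raise ValueError(f"duplicate probeset_id: {ann.probeset_id!r}")
            seen.add(ann.probeset_id)
        if not self.chrom_sizes:
            sizes: dict[str, int] = {}
            for ann in self.annotations:
                sizes[ann.chromosome] = max(sizes.get(ann.chromosome, 0), ann.end)
            self.chrom_sizes = sizes
        else:
            self.chrom_sizes = {
                normalize_chromosome(c): int(n) for c, n in self.chrom_sizes.items()
            }
            for ann in self.annotations:
                size = self.chrom_sizes.get(ann.chromosome)
                if size is None:
                    raise ValueError(
                        f"annotation {ann.probeset_id} on chromosome {ann.chromosome} "
                        "absent from chrom_sizes"
                    )
                if ann.end > size:
                    raise ValueError(
                        f"annotation {ann.probeset_id} ends at {ann.end} beyond "
                        f"chromosome {ann.chromosome} length {size}"
                    )
        self._by_probeset = {a.probeset_id: a for a in self.annotations}

    # -- lookups ---------------------------------------------------------

    def __len__(self) -> int:
        return len(self.annotations)

    def __contains__(self, probeset_id: str) -> bool:
        return probeset_id in self._by_probeset

    def annotation(self, probeset_id: str) -> GeneAnnotation:
        try:
            return self._by_probeset[probeset_id]
        except KeyError:
            raise KeyError(f"probeset {probeset_id!r} not in universe") from None

    @property
    def probeset_ids(self) -> list[str]:
        return [a.probeset_id for a in self.annotations]

    @property
    def chromosomes(self) -> list[str]:
        """Chromosomes carrying at least one annotation, in karyotype order."""
        present = {a.chromosome for a in self.annotations}
        return [c for c in ALLOWED_CHROMOSOMES if c in present]

    def n_probesets(self, chromosome: str | None = None) -> int:
        if chromosome is None:
            return len(self.annotations)
        chrom = normalize_chromosome(chromosome)
        return sum(1 for a in self.annotations if a.chromosome == chrom)

    def n_genes(self, chromosome: str | None = None) -> int:
        """Deduplicated gene-symbol count, genome-wide or per chromosome."""
        if chromosome is None:
            return len({a.gene_symbol for a in self.annotations})
        chrom = normalize_chromosome(chromosome)
        return len({a.gene_symbol for a in self.annotations if a.chromosome == chrom})

    def gene_chromosome(self, gene_symbol: str) -> str:
        for a in self.annotations:
            if a.gene_symbol == gene_symbol:
                return a.chromosome
        raise KeyError(f"gene {gene_symbol!r} not in universe")


# -- I/O -----------------------------------------------------------------


def read_gene_map(
    path: str | Path,
    chrom_sizes: Mapping[str, int] | None = None,
) -> ChipUniverse:
    """Read an annotation TSV into a validated :class:`ChipUniverse`.

    The TSV must have a header row with columns ``probeset_id``,
    ``gene_symbol``, ``chromosome``, ``start``, ``end`` (``strand``
    optional).  Coordinates in the file are 1-based fully-closed and are
    converted to the internal 0-based half-open representation.

    Raises
    ------
    ValueError
        On a duplicated probeset id (named in the message) or a malformed
        coordinate (reported with its line number).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    annotations: list[GeneAnnotation] = []
    for idx, row in enumerate(df.itertuples(index=False)):
        line_no = idx + 2  # header is line 1
        try:
            start1 = int(getattr(row, "start"))
            end1 = int(getattr(row, "end"))
        except (TypeError, ValueError):
            raise ValueError(
                f"{path}:{line_no}: malformed coordinate "
                f"({getattr(row, 'start')!r}, {getattr(row, 'end')!r})"
            ) from None
        if start1 < 1 or end1 <= start1:
            raise ValueError(
                f"{path}:{line_no}: invalid 1-based interval {start1}..{end1}"
            )
        strand = getattr(row, "strand", None)
        if isinstance(strand, float) and math.isnan(strand):
            strand = None
        try:
            ann = GeneAnnotation(
                chromosome=normalize_chromosome(getattr(row, "chromosome")),
                start=start1 - 1,
                end=end1,
                probeset_id=str(getattr(row, "probeset_id")),
                gene_symbol=str(getattr(row, "gene_symbol")),
                strand=strand if strand in ("+", "-") else None,
            )
        except ValueError as exc:
            raise ValueError(f"{path}:{line_no}: {exc}") from None
        annotations.append(ann)
    return ChipUniverse(annotations, dict(chrom_sizes) if chrom_sizes else {})


def write_gene_map(universe: ChipUniverse, path: str | Path) -> None:
    """Write the universe back as an annotation TSV (1-based closed coords)."""
    rows = [
        {
            "probeset_id": a.probeset_id,
            "gene_symbol": a.gene_symbol,
            "chromosome": a.chromosome,
            "start": a.start + 1,
            "end": a.end,
            "strand": a.strand if a.strand else "",
        }
        for a in universe.annotations
    ]
    pd.DataFrame(rows, columns=list(_REQUIRED_COLUMNS) + ["strand"]).to_csv(
        path, sep="\t", index=False
    )


def write_bed(universe: ChipUniverse, path: str | Path) -> None:
    """Export as BED6 (0-based half-open; name column = probeset id)."""
    with open(path, "w") as fh:
        for a in universe.annotations:
            strand = a.strand if a.strand else "."
            fh.write(
                f"chr{a.chromosome}\t{a.start}\t{a.end}\t{a.probeset_id}\t0\t{strand}\n"
            )


# -- interval queries ----------------------------------------------------


def genes_in_interval(
    universe: ChipUniverse, chromosome: str, start: int, end: int
) -> list[GeneAnnotation]:
    """Annotations whose anchor (start coordinate) lies in ``[start, end)``.

    The result is stably ordered by anchor coordinate, then probeset id.
    """
    if start >= end:
        raise ValueError(f"empty interval [{start}, {end})")
    chrom = normalize_chromosome(chromosome)
    if chrom not in universe.chrom_sizes:
        raise ValueError(f"chromosome {chromosome!r} not present in universe")
    hits = [
        a
        for a in universe.annotations
        if a.chromosome == chrom and start <= a.anchor < end
    ]
    hits.sort(key=lambda a: (a.anchor, a.probeset_id))
    return hits


def locus_separation_mb(start_a: int, start_b: int) -> tuple[float, int]:
    """Genomic separation of two loci in megabases.

    Returns ``(mb, mb_truncated)`` where ``mb = |start_b - start_a| / 1e6``
    and the integer form is truncated toward zero -- the convention used
    when quoting separations like "21 Mb apart" from browser coordinates.
    """
    if start_a < 0 or start_b < 0:
        raise ValueError("coordinates must be non-negative")
    mb = abs(start_b - start_a) / 1e6
    return mb, int(mb)
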