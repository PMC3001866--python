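"""Two-sample tests and report assembly.

Group comparisons throughout the pipeline are plain two-sample t-tests.
Because published group summaries arrive as ``mean +/- SEM`` with an n,
the Welch test is implemented directly from summary statistics as well as
from raw data; binary lamina-contact scores are compared with the same
t-test applied to the 0/1 values.  Rounding happens only in the report
layer -- every stored value keeps full precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SummaryStat",
    "TTestResult",
    "welch_t_from_summary",
    "pooled_t_from_summary",
    "contact_fraction_test",
    "render_report",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SummaryStat:
    """Group summary: mean, standard error of the mean, and sample size.

    Published ``+/-`` values are interpreted as SEMs; this is the reading
    under which the published p-values are reproducible (see the methods
    note for the SD-vs-SEM ambiguity).
    """

    mean: float
    sem: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.sem < 0:
            raise ValueError("sem must be >= 0")

    @classmethod
    def from_data(cls, values: Sequence[float]) -> "SummaryStat":
        arr = np.asarray(values, dtype=float)
        if arr.size < 2:
            raise ValueError("need at least 2 observations")
        return cls(
            mean=float(arr.mean()),
            sem=float(arr.std(ddof=1) / np.sqrt(arr.size)),
            n=int(arr.size),
        )


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    degenerate: bool = False


def welch_t_from_summary(a: SummaryStat, b: SummaryStat) -> TTestResult:
    """Two-sided Welch t-test from two mean/SEM/n triples.

    ``t = (mean_a - mean_b) / sqrt(sem_a^2 + sem_b^2)`` with
    Welch-Satterthwaite degrees of freedom.  Degenerate zero-variance
    inputs follow the stated conventions: equal means -> p = 1, unequal
    means -> p = 0 (flagged).
    """
    se2 = a.sem**2 + b.sem**2
    if se2 == 0.0:
        if a.mean == b.mean:
            return TTestResult(t=0.0, df=float(a.n + b.n - 2), p=1.0, degenerate=True)
        return TTestResult(
            t=float("inf") if a.mean > b.mean else float("-inf"),
            df=float(a.n + b.n - 2),
            p=0.0,
            degenerate=True,
        )
    t = (a.mean - b.mean) / np.sqrt(se2)
    df = se2**2 / (a.sem**4 / (a.n - 1) + b.sem**4 / (b.n - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return TTestResult(t=float(t), df=float(df), p=float(p))


def pooled_t_from_summary(a: SummaryStat, b: SummaryStat) -> TTestResult:
    """Classical equal-variance (pooled) two-sample t-test from summaries."""
    var_a = a.sem**2 * a.n
    var_b = b.sem**2 * b.n
    df = a.n + b.n - 2
    sp2 = ((a.n - 1) * var_a + (b.n - 1) * var_b) / df
    se = np.sqrt(sp2 * (1.0 / a.n + 1.0 / b.n))
    if se == 0.0:
        if a.mean == b.mean:
            return TTestResult(t=0.0, df=float(df), p=1.0, degenerate=True)
        return TTestResult(
            t=float("inf") if a.mean > b.mean else float("-inf"),
            df=float(df),
            p=0.0,
            degenerate=True,
        )
    t = (a.mean - b.mean) / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return TTestResult(t=float(t), df=float(df), p=float(p))


def contact_fraction_test(
    contacts_a: Sequence[int], contacts_b: Sequence[int]
) -> tuple[tuple[float, float], float, float]:
    """Compare two groups of binary lamina-contact scores.

    Returns ``((fraction_a, fraction_b), t, p)`` where the p-value comes
    from a two-sided Welch t-test applied directly to the 0/1 values.
    """
    a = np.asarray(contacts_a, dtype=float)
    b = np.asarray(contacts_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each contact list needs at least 2 entries")
    if not (np.isin(a, (0, 1)).all() and np.isin(b, (0, 1)).all()):
        raise ValueError("contact scores must be 0 or 1")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return (float(a.mean()), float(b.mean())), float(t), float(p)


# -- report assembly -----------------------------------------------------


def _percent(n: int, total: int, decimals: int = 0) -> str:
    pct = 100.0 * n / total
    return f"{pct:.{decimals}f}%" if decimals else f"{round(pct):d}%"


def render_report(results: Mapping[str, object], decimals: int = 1) -> dict:
    """Assemble a machine- and human-readable result bundle.

    ``results`` may contain any of the keys ``de`` (a DEGeneSet),
    ``clusters`` (list of GenomicCluster), ``null`` (a
    NullClusterDistribution), ``empirical_p`` (EmpiricalPReport),
    ``enrichment`` (ChromEnrichmentResult), ``shared``
    (SharedGeneResult) and ``fish`` (DataFrame of per-nucleus
    measurements).  Missing sections are skipped with a warning.  Returns
    a dict with a ``summary`` mapping, per-section DataFrames, and a
    rendered text block; rounding is applied here only.
    """
    from .chrom_enrich import ChromEnrichmentResult, SharedGeneResult
    from .cluster_scan import EmpiricalPReport, NullClusterDistribution, clusters_to_frame
    from .de_ranking import DEGeneSet

    sections: dict[str, pd.DataFrame] = {}
    summary: dict[str, object] = {}
    lines: list[str] = []

    de = results.get("de")
    if isinstance(de, DEGeneSet):
        sections["de_genes"] = de.to_frame()
        summary.update(
            n_de_genes=de.n_genes,
            n_over=de.n_over,
            n_under=de.n_under,
            n_discordant=de.n_discordant,
        )
        lines.append(
            f"Misexpressed genes: {de.n_genes} "
            f"({de.n_over} over, {de.n_under} under, {de.n_discordant} discordant)"
        )
    else:
        logger.warning("report: no DE section")

    clusters = results.get("clusters")
    if clusters is not None:
        sections["clusters"] = clusters_to_frame(clusters)
        summary["n_clusters"] = len(clusters)
        lines.append(f"Genomic clusters: {len(clusters)}")
    else:
        logger.warning("report: no cluster section")

    null = results.get("null")
    if isinstance(null, NullClusterDistribution):
        sections["null"] = null.to_frame()
        summary.update(
            null_mean=round(null.mean, 1), null_min=null.min, null_max=null.max
        )
        lines.append(
            f"Null clusters over {null.n_sims} lists of {null.list_size} probesets: "
            f"mean {null.mean:.1f}, range {null.min} to {null.max}"
        )
    ep = results.get("empirical_p")
    if isinstance(ep, EmpiricalPReport):
        summary["empirical_p"] = ep.p
        summary["empirical_p_rendered"] = ep.rendered
        lines.append(f"Empirical P {ep.rendered} ({ep.n_exceedances}/{ep.n_sims} exceedances)")

    enr = results.get("enrichment")
    if isinstance(enr, ChromEnrichmentResult):
        sections["enrichment"] = enr.to_frame()
        summary["genomewide_percent"] = _percent(enr.n_de_total, enr.n_chip_total)
        lines.append(
            f"Genome-wide misexpressed: {_percent(enr.n_de_total, enr.n_chip_total)} "
            f"({enr.n_de_total}/{enr.n_chip_total})"
        )
        if enr.chi2 is not None:
            summary.update(chi2=round(enr.chi2, 1), chi2_df=enr.df, chi2_p=round(enr.p, 3))
            lines.append(
                f"Chi-square vs uniform: chi2={enr.chi2:.1f}, df={enr.df}, p={enr.p:.3f}"
            )

    shared = results.get("shared")
    if isinstance(shared, SharedGeneResult):
        sections["shared_genes"] = shared.per_chromosome.reset_index()
        summary["n_shared_genes"] = shared.n_shared
        lines.append(f"Shared misexpressed genes: {shared.n_shared}")

    fish = results.get("fish")
    if isinstance(fish, pd.DataFrame):
        sections["fish"] = fish
        lines.append(f"FISH measurements: {len(fish)} rows")
    if not sections:
        logger.warning("report: empty pipeline, nothing to render")
    return {"summary": summary, "sections": sections, "text": "\n".join(lines)}
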