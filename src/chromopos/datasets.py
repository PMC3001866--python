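"""Published reference inputs for the LMNA E161K contrasts.

Small tables and counts reported for the E161K mutant-vs-normal heart and
fibroblast comparisons, shipped so worked examples and the acceptance
script can be recomputed without external downloads.  These are *inputs*
(gene lists, printed coordinates, group summaries), not expected outputs:
everything derived from them is computed at run time by the pipeline.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .stats_report import SummaryStat

__all__ = [
    "load_shared_gene_table",
    "CLUSTER_13A_START_HG17",
    "CLUSTER_13B_START_HG17",
    "CHIP_TOTAL_GENES",
    "CHIP_CHR13_GENES",
    "HEART_DE_GENES",
    "HEART_DE_GENES_CHR13",
    "FIBROBLAST_DE_GENES",
    "PAIR_DISTANCE_E161K",
    "PAIR_DISTANCE_NORMAL",
    "KI67_POSITIVE_DISTANCE",
    "KI67_NEGATIVE_DISTANCE",
    "CONTACT_13A_NORMAL",
    "CONTACT_13A_E161K",
]

#: hg17 browser start coordinates of the two chromosome-13 gene clusters
#: selected for 3D FISH (cluster 13A holds LMO7/KCTD12; 13B holds
#: MBNL2/RAP2A).
CLUSTER_13A_START_HG17 = 75_092_571
CLUSTER_13B_START_HG17 = 96_672_575

#: HGU133 Plus 2.0 chip composition (unique annotated genes).
CHIP_TOTAL_GENES = 18_350
CHIP_CHR13_GENES = 340

#: Unique misexpressed genes per tissue contrast, and the chr13 share of
#: the heart list.
HEART_DE_GENES = 583
HEART_DE_GENES_CHR13 = 20
FIBROBLAST_DE_GENES = 468

#: Inter-cluster (13A-13B) FISH pair distances, mean +/- SEM over nuclei.
PAIR_DISTANCE_E161K = SummaryStat(mean=1.778, sem=0.0957, n=56)
PAIR_DISTANCE_NORMAL = SummaryStat(mean=1.401, sem=0.0750, n=94)

#: Chromosome 13 territory edge distance by Ki-67 status in normal cells.
KI67_POSITIVE_DISTANCE = SummaryStat(mean=0.794, sem=0.162, n=34)
KI67_NEGATIVE_DISTANCE = SummaryStat(mean=0.524, sem=0.203, n=21)

#: Cluster 13A lamina-contact counts: (signals in contact, nuclei scored).
CONTACT_13A_NORMAL = (80, 98)
CONTACT_13A_E161K = (38, 64)


def load_shared_gene_table() -> pd.DataFrame:
    """The 36 genes misexpressed in both E161K heart and fibroblasts.

    Columns: ``gene_symbol``, ``chromosome``, ``heart_fold_change``,
    ``fibroblast_fold_change``.  Fold changes are signed strings as
    reported (DCN's fibroblast entry is discordant across probesets,
    "-2.4/+2.5").
    """
    with resources.files("chromopos").joinpath(
        "data/shared_misexpressed_genes_e161k.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t", dtype=str)
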