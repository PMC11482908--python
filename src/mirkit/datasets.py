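"""Small published reference inputs bundled with the package.

These are printed summary tables and counts from the miR-317 testis study
the toolkit was built around; they serve as worked-example inputs, not as
test fixtures for the algorithms.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: Predominant mature miR-317 species (miR-317-3p), 5'→3'.
MIR317_MATURE_SEQUENCE = "UGAACACAGUGCUAAAUGAAAGA"

#: Published per-database prediction-list sizes for miR-317 and the overlap
#: structure consistent with their union of 1030 (76 genes multi-source).
PREDICTION_LIST_SIZES = {"microRNA.org": 975, "TargetScanFly": 102, "MinoTar": 31}

#: Site prevalence among dysregulated testis lncRNAs:
#: (with site, group size) for up- and downregulated genes.
LNCRNA_PREVALENCE_UP = (38, 140)
LNCRNA_PREVALENCE_DOWN = (18, 52)


def mir317_testis_candidates() -> pd.DataFrame:
    """The 15 predicted miR-317 targets upregulated in mutant testes.

    Columns: gene_id (FlyBase), gene_name, log2fc, padj, biotype.  These
    rows all satisfy padj < 0.05 and log2FC > 0.5 and are the worked input
    for :func:`mirkit.target_integration.filter_candidates`.
    """
    ref = resources.files("mirkit.data").joinpath("mir317_testis_candidates.tsv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")
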