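"""Packaged reference data for the cross-condition stage.

``reference_score_matrix`` is a published 20-miRNA x 7-pathway grid of
common-core-miRNA enrichment scores from a COPD/NSCLC comparison (zeros
encode non-membership); ``reference_pathway_nes`` carries the matching
per-contrast normalized enrichment scores of the seven shared pathways.
Together they exercise every aggregation and selection rule of the
cross-disease module against known printed values.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .cross_disease import ScoreMatrix


def _read_packaged(name: str) -> pd.DataFrame:
    ref = resources.files("mirpathsea").joinpath("data", name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", index_col=0)


def reference_score_matrix() -> ScoreMatrix:
    """The packaged common-core-miRNA score grid (20 rows x 7 pathways)."""
    df = _read_packaged("common_core_scores.tsv").astype(float)
    return ScoreMatrix(df)


def reference_pathway_nes() -> pd.DataFrame:
    """Per-contrast NES of the seven shared pathways (columns NES_A, NES_B)."""
    return _read_packaged("common_pathway_nes.tsv").astype(float)
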