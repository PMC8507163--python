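"""Cross-condition comparison of two enrichment runs.

Given per-pathway enrichment results from two phenotype contrasts (e.g. a
COPD-vs-control and an NSCLC-vs-normal study), this module

1. finds pathways significant in both contrasts, optionally requiring
   opposite regulation (down in one, up in the other);
2. builds the common-core-miRNA score matrix: rows are miRNAs that are
   core (leading-edge) members of a pathway in *both* contrasts for at
   least ``min_pathways`` pathways; each nonzero cell is the mean of the
   miRNA's two per-contrast scores, and a zero encodes "not a common core
   miRNA of this pathway";
3. aggregates the matrix — nonzero row/column means, per-pathway core
   counts, pairwise shared-miRNA counts (the comparison network's edge
   weights) — and selects the most significant pathways and miRNAs.

The per-contrast cell score is the miRNA's differential weighted score in
that pathway's ranked list, rescaled by the list's maximum absolute score
so cells live in [-1, 1]; the choice is isolated in the enrichment stage
(``core_scores``) so alternatives remain pluggable, and every aggregation
here works on any score convention.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import DataError
from .enrichment import PathwayEnrichment

log = logging.getLogger(__name__)

#: magnitude used to keep a genuine score of exactly zero distinguishable
#: from the zero that encodes non-membership
ZERO_NUDGE = 1e-12


@dataclass
class ScoreMatrix:
    """Common-core-miRNA x common-pathway score grid (zeros = absence)."""

    scores: pd.DataFrame
    provenance: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.scores.index)

    @property
    def pathway_ids(self) -> list[str]:
        return list(self.scores.columns)


@dataclass
class CommonPathway:
    pathway_id: str
    nes_a: float
    nes_b: float
    q_a: float
    q_b: float
    direction_a: str
    direction_b: str

    def to_jsonable(self) -> dict:
        return self.__dict__.copy()


@dataclass
class CrossDiseaseReport:
    common_pathways: list[CommonPathway]
    score_matrix: ScoreMatrix
    selected_pathways: list[str]
    selected_mirnas: list[tuple[str, float]]
    core_count: dict[str, int]
    pairwise_overlap: dict[tuple[str, str], int]

    def to_jsonable(self) -> dict:
        return {
            "common_pathways": [c.to_jsonable() for c in self.common_pathways],
            "selected_pathways": self.selected_pathways,
            "selected_mirnas": [[m, s] for m, s in self.selected_mirnas],
            "core_count": self.core_count,
            "pairwise_overlap": {f"{a}|{b}": v for (a, b), v in self.pairwise_overlap.items()},
        }


def _by_id(enr: Sequence[PathwayEnrichment]) -> dict[str, PathwayEnrichment]:
    return {e.pathway_id: e for e in enr}


def common_pathways(
    enr_a: Sequence[PathwayEnrichment],
    enr_b: Sequence[PathwayEnrichment],
    qmax: float = 0.25,
    require_opposite: bool = True,
) -> list[CommonPathway]:
    """Pathways significant (q <= qmax) in both contrasts.

    With ``require_opposite`` the regulation direction must differ between
    the contrasts (the cross-disease signature of interest).
    """
    a, b = _by_id(enr_a), _by_id(enr_b)
    out = []
    for pw in a:
        if pw not in b:
            continue
        ea, eb = a[pw], b[pw]
        if ea.fdr_q > qmax or eb.fdr_q > qmax:
            continue
        if require_opposite and ea.direction == eb.direction:
            continue
        out.append(
            CommonPathway(pw, ea.nes, eb.nes, ea.fdr_q, eb.fdr_q, ea.direction, eb.direction)
        )
    return out


def build_score_matrix(
    enr_a: Sequence[PathwayEnrichment],
    enr_b: Sequence[PathwayEnrichment],
    pathways: Sequence[str],
    min_pathways: int = 2,
) -> ScoreMatrix:
    """Score grid over miRNAs that are core in both contrasts.

    A cell is the arithmetic mean of the miRNA's per-contrast scores when
    the miRNA is a core member of the pathway in both contrasts, else 0.
    Rows nonzero in fewer than ``min_pathways`` columns are dropped.
    """
    a, b = _by_id(enr_a), _by_id(enr_b)
    missing = [pw for pw in pathways if pw not in a or pw not in b]
    if missing:
        raise DataError(f"pathways missing from an enrichment run: {missing}")
    cells: dict[tuple[str, str], tuple[float, float]] = {}
    mirnas: list[str] = []
    for pw in pathways:
        core_a, core_b = a[pw].core_scores, b[pw].core_scores
        for mir in core_a.keys() & core_b.keys():
            cells[(mir, pw)] = (core_a[mir], core_b[mir])
            if mir not in mirnas:
                mirnas.append(mir)

    df = pd.DataFrame(0.0, index=sorted(mirnas), columns=list(pathways))
    for (mir, pw), (sa, sb) in cells.items():
        val = (sa + sb) / 2.0
        if val == 0.0:
            log.warning(
                "common core miRNA %s scored exactly 0 in pathway %s; "
                "nudging to keep it distinguishable from absence", mir, pw
            )
            val = ZERO_NUDGE
        df.at[mir, pw] = val
    nonzero = (df != 0.0).sum(axis=1)
    df = df.loc[nonzero >= min_pathways]
    return ScoreMatrix(df, cells)


def row_mean_score(row: Sequence[float]) -> float:
    """Mean over the strictly nonzero entries; NaN for an all-zero row."""
    vals = [v for v in row if v != 0.0]
    if not vals:
        return math.nan
    return sum(vals) / len(vals)


def col_mean_score(column: Sequence[float]) -> float:
    """Mean over the strictly nonzero entries; NaN for an all-zero column."""
    return row_mean_score(column)


def mean_scores(sm: ScoreMatrix) -> tuple[pd.Series, pd.Series]:
    """(per-miRNA row means, per-pathway column means), zeros excluded."""
    rows = pd.Series(
        {m: row_mean_score(sm.scores.loc[m]) for m in sm.mirna_ids}, name="mean_score"
    )
    cols = pd.Series(
        {p: col_mean_score(sm.scores[p]) for p in sm.pathway_ids}, name="mean_score"
    )
    return rows, cols


def core_counts(sm: ScoreMatrix) -> dict[str, int]:
    """Per-pathway count of common core miRNAs (nonzero cells)."""
    return {p: int((sm.scores[p] != 0.0).sum()) for p in sm.pathway_ids}


def pairwise_overlap(sm: ScoreMatrix) -> dict[tuple[str, str], int]:
    """Shared common-core-miRNA count for every unordered pathway pair."""
    nz = sm.scores != 0.0
    out: dict[tuple[str, str], int] = {}
    for p1, p2 in itertools.combinations(sm.pathway_ids, 2):
        out[(p1, p2)] = int((nz[p1] & nz[p2]).sum())
    return out


def select_pathways(
    sm: ScoreMatrix,
    nes_a: Mapping[str, float] | None = None,
    nes_bound: float | None = -2.0,
    top_k: int = 3,
) -> list[str]:
    """Most significant common pathways.

    Candidates passing the first-contrast NES bound (``NES_A <= nes_bound``,
    disabled with ``nes_bound=None``) are ranked by |nonzero column mean|
    descending, then common-core count descending, then pathway id.
    """
    _, col_means = mean_scores(sm)
    counts = core_counts(sm)
    candidates = list(sm.pathway_ids)
    if nes_bound is not None and nes_a is not None:
        candidates = [p for p in candidates if nes_a.get(p, 0.0) <= nes_bound]
    ranked = sorted(
        candidates,
        key=lambda p: (-abs(col_means[p]) if not math.isnan(col_means[p]) else 0.0,
                       -counts[p], p),
    )
    return ranked[:top_k]


def select_mirnas(
    sm: ScoreMatrix, selected_pathways: Sequence[str], top_k: int = 5
) -> list[tuple[str, float]]:
    """miRNAs core in every selected pathway, ranked by nonzero row mean."""
    if not selected_pathways:
        raise DataError("at least one selected pathway required")
    nz = sm.scores != 0.0
    in_all = nz[list(selected_pathways)].all(axis=1)
    candidates = list(sm.scores.index[in_all])
    if not candidates:
        log.warning("no miRNA is a common core member of every selected pathway")
        return []
    scored = [(m, row_mean_score(sm.scores.loc[m])) for m in candidates]
    scored.sort(key=lambda t: (-t[1], t[0]))
    return scored[:top_k]


def compare(
    enr_a: Sequence[PathwayEnrichment],
    enr_b: Sequence[PathwayEnrichment],
    qmax: float = 0.25,
    require_opposite: bool = True,
    min_pathways: int = 2,
    nes_bound: float | None = -2.0,
    top_k_pathways: int = 3,
    top_k_mirnas: int = 5,
) -> CrossDiseaseReport:
    """Full cross-condition stage: common pathways, score matrix, selections."""
    common = common_pathways(enr_a, enr_b, qmax=qmax, require_opposite=require_opposite)
    ids = [c.pathway_id for c in common]
    sm = build_score_matrix(enr_a, enr_b, ids, min_pathways=min_pathways)
    if sm.scores.empty or not ids:
        return CrossDiseaseReport(common, sm, [], [], core_counts(sm), {})
    nes_a = {c.pathway_id: c.nes_a for c in common}
    selected = select_pathways(sm, nes_a, nes_bound=nes_bound, top_k=top_k_pathways)
    mirnas = select_mirnas(sm, selected, top_k=top_k_mirnas) if selected else []
    return CrossDiseaseReport(
        common_pathways=common,
        score_matrix=sm,
        selected_pathways=selected,
        selected_mirnas=mirnas,
        core_count=core_counts(sm),
        pairwise_overlap=pairwise_overlap(sm),
    )


def edge_list(sm: ScoreMatrix) -> pd.DataFrame:
    """Pathway-pathway shared-core-miRNA counts as a network edge list."""
    rows = [
        (a, b, c) for (a, b), c in pairwise_overlap(sm).items() if c > 0
    ]
    return pd.DataFrame(rows, columns=["pathway_a", "pathway_b", "shared_core_mirnas"])
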