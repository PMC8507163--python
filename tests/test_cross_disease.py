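import math

import numpy as np
import pandas as pd
import pytest

from mirpathsea import (
    build_score_matrix,
    common_pathways,
    core_counts,
    pairwise_overlap,
    reference_pathway_nes,
    reference_score_matrix,
    select_mirnas,
    select_pathways,
)
from mirpathsea.cross_disease import (
    ScoreMatrix,
    col_mean_score,
    edge_list,
    mean_scores,
    row_mean_score,
)
from mirpathsea.enrichment import PathwayEnrichment


def _enr(pathway, es, q, core_scores):
    return PathwayEnrichment(
        pathway_id=pathway,
        size=len(core_scores) + 2,
        es=es,
        nes=2.0 * es,
        p_nominal=q / 2,
        fdr_q=q,
        peak_rank=3,
        running_profile=np.zeros(4),
        core_mirnas=list(core_scores),
        core_scores=core_scores,
        direction="up" if es >= 0 else "down",
    )


class TestMeanScores:
    @pytest.mark.parametrize(
        "row,expected",
        [
            ([0.0495, 0.1025, 0.067, 0, 0, 0, 0.1145], 0.083375),
            ([0.076, 0, 0.085, 0, 0, 0, 0.121], 0.094),
        ],
    )
    def test_nonzero_row_mean(self, row, expected):
        assert row_mean_score(row) == pytest.approx(expected, abs=1e-12)

    def test_all_zero_row_is_null_not_zero(self):
        assert math.isnan(row_mean_score([0.0] * 7))

    def test_single_nonzero_column(self):
        assert col_mean_score([0, 0, 0.42, 0]) == pytest.approx(0.42)


class TestReferenceGridAggregation:
    def test_grid_shape_and_cells(self):
        sm = reference_score_matrix()
        assert sm.scores.shape == (20, 7)
        assert sm.scores.at["hsa-miR-106a", "KEGG_CELL_CYCLE"] == pytest.approx(0.0495)
        assert sm.scores.at["hsa-miR-15b", "KEGG_ERBB_SIGNALING"] == 0.0

    def test_overlap_bounded_by_core_counts(self):
        sm = reference_score_matrix()
        counts = core_counts(sm)
        for (a, b), shared in pairwise_overlap(sm).items():
            assert shared <= min(counts[a], counts[b])

    def test_aggregates_invariant_under_row_permutation(self):
        sm = reference_score_matrix()
        rng = np.random.default_rng(0)
        perm = rng.permutation(sm.scores.index)
        shuffled = ScoreMatrix(sm.scores.loc[perm])
        assert core_counts(shuffled) == core_counts(sm)
        assert pairwise_overlap(shuffled) == pairwise_overlap(sm)
        _, cols = mean_scores(sm)
        _, cols2 = mean_scores(shuffled)
        assert np.allclose(cols, cols2)

    def test_edge_list_matches_overlaps(self):
        sm = reference_score_matrix()
        edges = edge_list(sm)
        lookup = {(r.pathway_a, r.pathway_b): r.shared_core_mirnas
                  for r in edges.itertuples()}
        assert lookup[("KEGG_CELL_CYCLE", "KEGG_P53_SIGNALING")] == 12


class TestCommonPathways:
    def test_disjoint_significant_sets_empty(self):
        enr_a = [_enr("P1", -0.5, 0.01, {"m": -0.1})]
        enr_b = [_enr("P2", 0.5, 0.01, {"m": 0.1})]
        assert common_pathways(enr_a, enr_b, qmax=0.25) == []

    def test_opposite_direction_pathway_included(self):
        enr_a = [_enr("P1", -0.6, 0.01, {"m": -0.1})]
        enr_b = [_enr("P1", 0.4, 0.02, {"m": 0.1})]
        (cp,) = common_pathways(enr_a, enr_b, qmax=0.25)
        assert cp.pathway_id == "P1"
        assert (cp.direction_a, cp.direction_b) == ("down", "up")

    def test_same_direction_excluded_when_opposite_required(self):
        enr_a = [_enr("P1", 0.6, 0.01, {"m": 0.1})]
        enr_b = [_enr("P1", 0.4, 0.02, {"m": 0.1})]
        assert common_pathways(enr_a, enr_b, qmax=0.25) == []
        assert len(common_pathways(enr_a, enr_b, qmax=0.25, require_opposite=False)) == 1

    def test_insignificant_pathway_excluded(self):
        enr_a = [_enr("P1", -0.6, 0.5, {"m": -0.1})]
        enr_b = [_enr("P1", 0.4, 0.02, {"m": 0.1})]
        assert common_pathways(enr_a, enr_b, qmax=0.25) == []


class TestBuildScoreMatrix:
    def test_cell_rules(self):
        enr_a = [
            _enr("P1", -0.5, 0.01, {"mA": 0.05, "mBoth": 0.05, "mDrop": 0.03}),
            _enr("P2", -0.4, 0.01, {"mBoth": 0.07}),
        ]
        enr_b = [
            _enr("P1", 0.5, 0.01, {"mBoth": 0.049, "mOnlyB": 0.2}),
            _enr("P2", 0.4, 0.01, {"mBoth": 0.049}),
        ]
        sm = build_score_matrix(enr_a, enr_b, ["P1", "P2"], min_pathways=2)
        # core in A only -> zero cell; core in one pathway only -> row dropped
        assert "mA" not in sm.mirna_ids and "mDrop" not in sm.mirna_ids
        assert sm.scores.at["mBoth", "P1"] == pytest.approx((0.05 + 0.049) / 2)
        assert core_counts(sm) == {"P1": 1, "P2": 1}

    def test_min_pathways_one_keeps_single_column_rows(self):
        enr_a = [_enr("P1", -0.5, 0.01, {"m1": 0.1})]
        enr_b = [_enr("P1", 0.5, 0.01, {"m1": 0.2})]
        sm = build_score_matrix(enr_a, enr_b, ["P1"], min_pathways=1)
        assert sm.scores.at["m1", "P1"] == pytest.approx(0.15)


class TestSelection:
    def test_reference_selection_reproduced(self):
        sm = reference_score_matrix()
        nes_a = reference_pathway_nes()["NES_A"].to_dict()
        selected = select_pathways(sm, nes_a, nes_bound=-2.0, top_k=3)
        assert set(selected) == {
            "KEGG_CELL_CYCLE",
            "KEGG_P53_SIGNALING",
            "KEGG_NON_SMALL_CELL_LUNG_CANCER",
        }

    def test_top_k_larger_than_candidates(self):
        sm = reference_score_matrix()
        selected = select_pathways(sm, None, nes_bound=None, top_k=99)
        assert len(selected) == 7

    def test_nes_bound_filters(self):
        sm = reference_score_matrix()
        nes_a = {p: -1.0 for p in sm.pathway_ids}  # nothing passes -2 bound
        assert select_pathways(sm, nes_a, nes_bound=-2.0, top_k=3) == []

    def test_mirna_selection_requires_presence_in_all(self):
        sm = reference_score_matrix()
        picks = select_mirnas(
            sm,
            ["KEGG_CELL_CYCLE", "KEGG_P53_SIGNALING", "KEGG_NON_SMALL_CELL_LUNG_CANCER"],
            top_k=99,
        )
        names = [m for m, _ in picks]
        # hsa-miR-203 is core in cell cycle and NSCLC but not p53
        assert "hsa-miR-203" not in names
        assert len(names) == 7

    def test_top_one(self):
        sm = reference_score_matrix()
        picks = select_mirnas(sm, ["KEGG_CELL_CYCLE"], top_k=1)
        assert len(picks) == 1
        assert picks[0][0] == "hsa-miR-15b"
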