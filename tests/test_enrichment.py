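import numpy as np
import pandas as pd
import pytest

from mirpathsea import (
    DataError,
    GeneSetCollection,
    build_weight_matrix,
    differential_scores,
    enrich,
    leading_edge,
    mirscore,
    rank_list,
    running_es,
)
from mirpathsea.enrichment import RankedMiRNAList, _normalize
from mirpathsea.preprocess import preprocess
from mirpathsea.weights import WeightMatrix

from conftest import make_expr


def brute_force_es(scores, member_mask, weight_exp=1.0):
    """Independent prefix-by-prefix evaluation of the running statistic."""
    n = len(scores)
    n_h = sum(member_mask)
    n_r = sum(abs(s) ** weight_exp for s, h in zip(scores, member_mask) if h)
    run, best, best_abs, peak = 0.0, 0.0, -1.0, 0
    profile = []
    for i, (s, h) in enumerate(zip(scores, member_mask)):
        if h:
            run += (abs(s) ** weight_exp) / n_r if n_r > 0 else 1.0 / n_h
        else:
            run -= 1.0 / (n - n_h)
        profile.append(run)
        if abs(run) > best_abs + 1e-12:
            best_abs, best, peak = abs(run), run, i + 1
    return best, peak, profile


class TestDifferentialScores:
    def test_identical_groups_score_zero(self, two_group_labels):
        expr = make_expr(
            np.tile([[1.0, 2.0, 3.0, 4.0]], (3, 2)),
            samples=two_group_labels.sample_ids,
            log_scale=True,
        )
        de = differential_scores(expr, two_group_labels)
        assert np.allclose(de, 0.0)

    def test_sigma_floor_applied(self, two_group_labels):
        expr = make_expr(
            [[2.0] * 4 + [1.0] * 4],
            samples=two_group_labels.sample_ids,
            log_scale=True,
        )
        de = differential_scores(expr, two_group_labels)
        # constant groups: floored sigmas 0.2*2 and 0.2*1
        assert de.iloc[0] == pytest.approx((2 - 1) / (0.4 + 0.2))

    def test_label_swap_negates(self, two_group_labels):
        rng = np.random.default_rng(0)
        expr = make_expr(
            rng.normal(5, 1, (6, 8)),
            samples=two_group_labels.sample_ids,
            log_scale=True,
        )
        de = differential_scores(expr, two_group_labels)
        swapped = type(two_group_labels)(
            two_group_labels.sample_ids,
            two_group_labels.group,
            ("control", "case"),
        )
        assert np.allclose(differential_scores(expr, swapped), -de)

    def test_single_sample_group_rejected(self):
        from mirpathsea import PhenotypeLabels

        expr = make_expr([[1.0, 2.0, 3.0]], log_scale=True)
        labels = PhenotypeLabels(["s1", "s2", "s3"], ["case", "control", "control"],
                                 ("case", "control"))
        with pytest.raises(DataError, match="miRNA-permutation"):
            differential_scores(expr, labels)


class TestMirScore:
    @pytest.mark.parametrize(
        "w,de,expected",
        [(0.5, 2.0, 3.0), (0.0, -1.2, -1.2), (1 - 1205 / 4845, 1.5, 2.626935)],
    )
    def test_values(self, w, de, expected):
        assert mirscore(w, de) == pytest.approx(expected, abs=5e-7)

    def test_weight_bounds(self):
        with pytest.raises(ValueError):
            mirscore(1.5, 1.0)


def _wm_from_weights(w_df: pd.DataFrame) -> WeightMatrix:
    shape = w_df.shape
    return WeightMatrix(
        W=w_df,
        p=1.0 - w_df,
        r=(w_df > 0).astype(int),
        membership=w_df > 0,
        m=100,
        t=pd.Series(10, index=w_df.columns),
        n=pd.Series(5, index=w_df.index),
    )


class TestRankList:
    def test_zero_weights_rank_by_de(self):
        de = pd.Series([0.5, 2.0, -1.0], index=["a", "b", "c"])
        wm = _wm_from_weights(pd.DataFrame(0.0, index=de.index, columns=["PW"]))
        ranked = rank_list(de, wm, pathway="PW")
        assert ranked.mirna_ids == ["b", "a", "c"]

    def test_ties_broken_lexicographically(self):
        de = pd.Series([1.0, 1.0, 1.0], index=["zeta", "alpha", "mid"])
        wm = _wm_from_weights(pd.DataFrame(0.0, index=de.index, columns=["PW"]))
        ranked = rank_list(de, wm, pathway="PW")
        assert ranked.mirna_ids == ["alpha", "mid", "zeta"]

    def test_pathway_weight_reorders(self):
        de = pd.Series([1.0, 0.9], index=["a", "b"])
        w = pd.DataFrame({"PW": [0.0, 0.5]}, index=de.index)
        ranked = rank_list(de, _wm_from_weights(w), pathway="PW")
        # b: (1+0.5)*0.9 = 1.35 beats a: 1.0
        assert ranked.mirna_ids == ["b", "a"]
        assert ranked.scores[0] == pytest.approx(1.35)

    def test_global_mode_uses_max_weight(self):
        de = pd.Series([1.0, 0.9], index=["a", "b"])
        w = pd.DataFrame({"P1": [0.0, 0.5], "P2": [0.0, 0.8]}, index=de.index)
        ranked = rank_list(de, _wm_from_weights(w), pathway=None)
        assert ranked.scores[0] == pytest.approx(1.8 * 0.9)


def _ranked(scores, ids=None):
    ids = ids or [f"m{i:02d}" for i in range(len(scores))]
    return RankedMiRNAList(ids, np.asarray(scores, float), np.asarray(scores, float))


class TestRunningEs:
    def test_worked_example(self):
        ranked = _ranked([5, 4, 3, 2, 1])
        members = {ranked.mirna_ids[0], ranked.mirna_ids[4]}
        es, peak, profile = running_es(ranked, members, weight_exp=1.0)
        assert np.allclose(profile, [5 / 6, 0.5, 1 / 6, -1 / 6, 0.0], atol=1e-12)
        assert es == pytest.approx(5 / 6)
        assert peak == 1

    def test_members_heading_list_reach_unity(self):
        ranked = _ranked([9, 8, 7, 1, 0.5])
        es, peak, _ = running_es(ranked, set(ranked.mirna_ids[:3]))
        assert es == pytest.approx(1.0)
        assert peak == 3

    def test_members_at_bottom_give_negative_es(self):
        ranked = _ranked([9, 8, 7, 1, 0.5])
        es, _, _ = running_es(ranked, set(ranked.mirna_ids[3:]))
        assert es < 0

    def test_unweighted_profile_returns_to_zero(self):
        rng = np.random.default_rng(5)
        ranked = _ranked(sorted(rng.normal(size=12), reverse=True))
        es, _, profile = running_es(ranked, set(ranked.mirna_ids[::3]), weight_exp=0.0)
        assert profile[-1] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("n", [4, 6, 8])
    def test_matches_brute_force_all_placements(self, n):
        rng = np.random.default_rng(n)
        scores = np.sort(rng.normal(scale=2, size=n))[::-1]
        ranked = _ranked(scores)
        for mask_bits in range(1, 2**n - 1):
            mask = [(mask_bits >> i) & 1 == 1 for i in range(n)]
            members = {m for m, h in zip(ranked.mirna_ids, mask) if h}
            es, peak, profile = running_es(ranked, members)
            b_es, b_peak, b_profile = brute_force_es(scores, mask)
            assert es == pytest.approx(b_es, abs=1e-12)
            assert peak == b_peak
            assert np.allclose(profile, b_profile, atol=1e-12)

    def test_degenerate_member_sets_rejected(self):
        ranked = _ranked([3, 2, 1])
        with pytest.raises(DataError):
            running_es(ranked, set())
        with pytest.raises(DataError):
            running_es(ranked, set(ranked.mirna_ids))


class TestLeadingEdge:
    def test_worked_example_statistics(self):
        ranked = _ranked([5, 4, 3, 2, 1])
        members = {ranked.mirna_ids[0], ranked.mirna_ids[4]}
        es, peak, _ = running_es(ranked, members)
        core, mir_pct, tag_pct, signal = leading_edge(es, peak, ranked, members)
        assert core == [ranked.mirna_ids[0]]
        assert mir_pct == pytest.approx(0.2)
        assert tag_pct == pytest.approx(0.5)
        assert signal == pytest.approx(0.5 * 0.8 * 5 / 3)

    def test_all_members_before_peak(self):
        ranked = _ranked([9, 8, 7, 1, 0.5])
        es, peak, _ = running_es(ranked, set(ranked.mirna_ids[:3]))
        core, _, tag_pct, _ = leading_edge(es, peak, ranked, set(ranked.mirna_ids[:3]))
        assert tag_pct == 1.0

    def test_peak_at_list_end_boundary(self):
        core, mir_pct, tag_pct, signal = leading_edge(
            0.2, 5, _ranked([5, 4, 3, 2, 1]), {"m04"}
        )
        assert mir_pct == 1.0
        assert signal == 0.0

    def test_negative_es_core_from_tail(self):
        ranked = _ranked([5, 4, 3, 2, 1])
        members = {ranked.mirna_ids[3], ranked.mirna_ids[4]}
        es, peak, _ = running_es(ranked, members)
        assert es < 0
        core, mir_pct, _, _ = leading_edge(es, peak, ranked, members)
        assert set(core) == members
        assert mir_pct == pytest.approx((5 - peak + 1) / 5)


class TestNormalization:
    def test_degenerate_null_self_normalizes(self):
        profile = np.array([0.3])
        kept = [dict(pathway="PW", size=3, es=0.42, peak=1, profile=profile,
                     ranked=None, core=["m"], mir_pct=0.1, tag_pct=0.5,
                     signal=0.4, core_scores={"m": 1.0})]
        nulls = {"PW": np.full(50, 0.42)}
        (res,) = _normalize(kept, nulls)
        assert res.nes == pytest.approx(1.0)
        assert res.p_nominal == pytest.approx(1.0)


@pytest.fixture(scope="module")
def small_enrichment(request):
    study = request.getfixturevalue("small_study")
    wm = build_weight_matrix(study.targets, study.pathways)
    con = study.contrasts["A"]
    norm, _ = preprocess(con.expr)
    labels = con.labels.reorder(norm.sample_ids)
    res = enrich(norm, labels, wm, n_perm=100, seed=3)
    return study, wm, norm, labels, res


class TestEnrich:
    def test_reproducible_for_same_seed(self, small_enrichment):
        study, wm, norm, labels, res = small_enrichment
        res2 = enrich(norm, labels, wm, n_perm=100, seed=3)
        for a, b in zip(res, res2):
            assert a.pathway_id == b.pathway_id
            assert a.es == b.es and a.nes == b.nes
            assert a.p_nominal == b.p_nominal and a.fdr_q == b.fdr_q

    def test_planted_pathways_have_expected_sign(self, small_enrichment):
        study, _, _, _, res = small_enrichment
        by_id = {e.pathway_id: e for e in res}
        assert by_id["PW_0001"].es < 0  # planted down in contrast A
        assert by_id["PW_0002"].es > 0  # planted up in contrast A

    def test_label_swap_flips_every_es(self, small_enrichment):
        study, wm, norm, labels, res = small_enrichment
        from mirpathsea import PhenotypeLabels

        swapped = PhenotypeLabels(labels.sample_ids, labels.group,
                                  (labels.group_names[1], labels.group_names[0]))
        res_swapped = enrich(norm, swapped, wm, n_perm=100, seed=3)
        for a, b in zip(res, res_swapped):
            assert a.es == pytest.approx(-b.es, abs=1e-10)
            assert a.direction != b.direction

    def test_core_mirnas_are_members(self, small_enrichment):
        study, wm, norm, _, res = small_enrichment
        for e in res:
            members = set(wm.members(e.pathway_id))
            assert set(e.core_mirnas) <= members
            assert -1.0 <= e.es <= 1.0
            assert 0.0 <= e.mir_pct <= 1.0
            assert 0.0 <= e.p_nominal <= 1.0 and 0.0 <= e.fdr_q <= 1.0

    def test_small_groups_fall_back_to_mirna_mode(self, small_study, caplog):
        wm = build_weight_matrix(small_study.targets, small_study.pathways)
        con = small_study.contrasts["A"]
        norm, _ = preprocess(con.expr)
        labels = con.labels.reorder(norm.sample_ids)
        sub_samples = labels.case_samples[:4] + labels.control_samples[:4]
        sub = make_expr(
            norm.values[sub_samples].to_numpy(),
            mirnas=list(norm.values.index),
            samples=sub_samples,
            log_scale=True,
        )
        sub_labels = labels.reorder(sub_samples)
        with caplog.at_level("WARNING"):
            res = enrich(sub, sub_labels, wm, n_perm=50, seed=1)
        assert "miRNA-identity" in caplog.text
        assert res

    def test_too_few_permutations_rejected(self, small_enrichment):
        _, wm, norm, labels, _ = small_enrichment
        with pytest.raises(ValueError):
            enrich(norm, labels, wm, n_perm=5, seed=0)
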