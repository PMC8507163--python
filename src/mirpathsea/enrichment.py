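"""Weighted running-sum enrichment of pathway miRNA sets.

The analysis ranks miRNAs by a differential weighted score and asks, for
each pathway's miRNA set, whether its members concentrate at the top or
bottom of the ranked list (a weighted Kolmogorov-Smirnov running sum, as
in gene set enrichment analysis but at miRNA level):

1. ``DE_i`` — differential expression of miRNA *i* between the two
   phenotype groups (signal-to-noise by default, Welch t optional).
2. ``miRScore_ij = (1 + W_ij) * DE_i`` — the differential score boosted by
   the miRNA's target-overlap weight with the pathway.
3. The running sum increments by ``|score|^p / N_R`` at each member
   ("hit") and decrements by ``1/(N - N_H)`` at each non-member; the
   enrichment score ES is the signed maximum deviation, and the member
   miRNAs on the peak side form the core (leading-edge) subset.
4. Significance comes from phenotype-label permutations: the null ES
   distribution yields a normalized score NES = ES / mean(|same-sign null
   ES|), a nominal p, and a same-sign pooled-null FDR q. With fewer than
   seven samples per group the null switches to miRNA-identity
   permutation over the fixed observed ranking.

Positive ES/NES means enrichment at the top of the list, i.e. members
up-regulated in the case group (the group named first in the phenotype
labels).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import DataError, ExpressionMatrix, PhenotypeLabels
from .weights import WeightMatrix

log = logging.getLogger(__name__)

#: s2n standard deviations are floored at this fraction of |mean|
SIGMA_FLOOR_FRACTION = 0.2


@dataclass
class RankedMiRNAList:
    """miRNAs ordered by decreasing ranking score (ties: lexicographic id)."""

    mirna_ids: list[str]
    scores: np.ndarray
    de: np.ndarray

    def __len__(self) -> int:
        return len(self.mirna_ids)

    def rank_of(self, mirna_id: str) -> int:
        """1-based rank."""
        return self.mirna_ids.index(mirna_id) + 1


@dataclass
class PathwayEnrichment:
    pathway_id: str
    size: int
    es: float
    nes: float
    p_nominal: float
    fdr_q: float
    peak_rank: int
    running_profile: np.ndarray
    core_mirnas: list[str]
    core_scores: dict[str, float] = field(default_factory=dict)
    mir_pct: float = 0.0
    tag_pct: float = 0.0
    signal: float = 0.0
    direction: str = "up"

    def to_jsonable(self) -> dict:
        return {
            "pathway": self.pathway_id,
            "SIZE": self.size,
            "ES": self.es,
            "NES": self.nes,
            "p": self.p_nominal,
            "FDR": self.fdr_q,
            "peak_rank": self.peak_rank,
            "core_mirnas": self.core_mirnas,
            "core_scores": self.core_scores,
            "MirPct": self.mir_pct,
            "TagPct": self.tag_pct,
            "Signal": self.signal,
            "direction": self.direction,
        }


def differential_scores(
    expr: ExpressionMatrix, labels: PhenotypeLabels, method: str = "s2n"
) -> pd.Series:
    """Per-miRNA differential expression between case and control.

    ``s2n``: (mu_case - mu_control) / (sigma_case + sigma_control) with
    each group's sigma floored at ``0.2 * |mu|`` of that group; identical
    constant groups score 0. ``tstat``: Welch's t statistic.
    """
    if not expr.log_scale:
        raise DataError("differential scores expect a log2-scale matrix")
    lab = labels.reorder(expr.sample_ids)
    case = expr.values[lab.case_samples].to_numpy(dtype=float)
    ctrl = expr.values[lab.control_samples].to_numpy(dtype=float)
    if case.shape[1] < 2 or ctrl.shape[1] < 2:
        raise DataError(
            "each group needs >= 2 samples for a differential score; "
            "use miRNA-permutation mode for smaller designs"
        )
    if method == "s2n":
        mu_c, mu_k = case.mean(axis=1), ctrl.mean(axis=1)
        sd_c, sd_k = case.std(axis=1, ddof=1), ctrl.std(axis=1, ddof=1)
        sd_c = np.maximum(sd_c, SIGMA_FLOOR_FRACTION * np.abs(mu_c))
        sd_k = np.maximum(sd_k, SIGMA_FLOOR_FRACTION * np.abs(mu_k))
        denom = sd_c + sd_k
        num = mu_c - mu_k
        out = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    elif method == "tstat":
        out = stats.ttest_ind(case, ctrl, axis=1, equal_var=False).statistic
        out = np.nan_to_num(out, nan=0.0)
    else:
        raise ValueError(f"unknown differential method {method!r}")
    return pd.Series(out, index=expr.values.index, name="DE")


def mirscore(w: float, de: float) -> float:
    """Differential weighted score ``(1 + W) * DE`` for one miRNA-pathway."""
    if not 0.0 <= w <= 1.0:
        raise ValueError(f"weight must be in [0, 1], got {w}")
    return (1.0 + w) * de


def _ordered(ids: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Indices sorting scores descending, ties by lexicographic id."""
    return np.lexsort((ids, -scores))


def rank_list(
    de: pd.Series, wm: WeightMatrix, pathway: str | None = None
) -> RankedMiRNAList:
    """Rank miRNAs by decreasing differential weighted score.

    With a pathway given, the score is that pathway's ``(1+W_ij)*DE_i``;
    without one, the pathway-independent score uses each miRNA's maximum
    weight over all pathways.
    """
    ids = np.asarray(de.index, dtype=object)
    if pathway is not None:
        w = wm.W.loc[de.index, pathway].to_numpy(dtype=float)
    else:
        w = wm.W.loc[de.index].max(axis=1).to_numpy(dtype=float)
    scores = (1.0 + w) * de.to_numpy(dtype=float)
    order = _ordered(ids, scores)
    return RankedMiRNAList(
        mirna_ids=list(ids[order]),
        scores=scores[order],
        de=de.to_numpy(dtype=float)[order],
    )


def _running_sum(
    abs_scores: np.ndarray, hits: np.ndarray, weight_exp: float
) -> np.ndarray:
    """Running deviation profile(s); inputs are already in rank order.

    ``abs_scores`` and ``hits`` are (N,) or (N, K) for K score columns
    sharing one membership layout per column.
    """
    absw = abs_scores**weight_exp
    hit_w = np.where(hits, absw, 0.0)
    n_r = hit_w.sum(axis=0)
    n_h = hits.sum(axis=0)
    n = hits.shape[0]
    # degenerate all-zero hit weights: fall back to the unweighted statistic
    n_r_safe = np.where(n_r > 0, n_r, 1.0)
    uniform = np.where(hits, 1.0 / np.maximum(n_h, 1), 0.0)
    inc = np.where(n_r > 0, hit_w / n_r_safe, uniform)
    dec = np.where(hits, 0.0, 1.0 / (n - n_h))
    return np.cumsum(inc - dec, axis=0)


#: ties in |running deviation| within this tolerance resolve to the
#: earliest rank, so float dust cannot flip the peak (or the ES sign)
_PEAK_TIE_TOL = 1e-12


def _es_from_profile(profile: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Signed maximum deviation and its earliest 0-based position, per column."""
    absp = np.abs(profile)
    peak = np.argmax(absp >= absp.max(axis=0) - _PEAK_TIE_TOL, axis=0)
    if profile.ndim == 1:
        return profile[peak], peak
    cols = np.arange(profile.shape[1])
    return profile[peak, cols], peak


def running_es(
    ranked: RankedMiRNAList, members: set[str], weight_exp: float = 1.0
) -> tuple[float, int, np.ndarray]:
    """Enrichment score of a member set over a ranked list.

    Returns ``(ES, peak_rank, profile)`` where ``peak_rank`` is 1-based
    and the earliest position on ties of the maximum |deviation|.
    """
    n = len(ranked)
    members = set(members)
    unknown = members - set(ranked.mirna_ids)
    if unknown:
        raise DataError(f"member miRNAs absent from ranked list: {sorted(unknown)[:5]}")
    if not members or len(members) >= n:
        raise DataError("member set must be non-empty and a proper subset of the list")
    hits = np.array([m in members for m in ranked.mirna_ids], dtype=bool)
    profile = _running_sum(np.abs(ranked.scores), hits, weight_exp)
    es, peak = _es_from_profile(profile)
    return float(es), int(peak) + 1, profile


def leading_edge(
    es: float,
    peak_rank: int,
    ranked: RankedMiRNAList,
    members: set[str],
) -> tuple[list[str], float, float, float]:
    """Core (leading-edge) miRNAs and the derived summary statistics.

    For non-negative ES the core is the members at or before the peak and
    ``mir_pct = peak/N``; for negative ES the members at or after the peak
    with ``mir_pct = (N - peak + 1)/N``. ``signal`` combines tag and list
    fractions: ``tag_pct * (1 - mir_pct) * N / (N - N_H)``.
    """
    n = len(ranked)
    n_h = len(members)
    if es >= 0:
        core = [m for m in ranked.mirna_ids[:peak_rank] if m in members]
        mir_pct = peak_rank / n
    else:
        core = [m for m in ranked.mirna_ids[peak_rank - 1 :] if m in members]
        mir_pct = (n - peak_rank + 1) / n
    tag_pct = len(core) / n_h if n_h else 0.0
    signal = tag_pct * (1.0 - mir_pct) * n / (n - n_h) if n > n_h else 0.0
    return core, mir_pct, tag_pct, signal


def _permutation_masks(
    n_samples: int, n_case: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """(n_samples, n_perm) boolean case-assignment masks."""
    masks = np.zeros((n_samples, n_perm), dtype=bool)
    for k in range(n_perm):
        masks[rng.permutation(n_samples)[:n_case], k] = True
    return masks


def _null_de_s2n(X: np.ndarray, masks: np.ndarray) -> np.ndarray:
    """Signal-to-noise DE for every permuted case assignment, vectorized."""
    n_case = masks[:, 0].sum()
    n_ctrl = masks.shape[0] - n_case
    B = masks.astype(float)
    tot = X.sum(axis=1, keepdims=True)
    tot2 = (X**2).sum(axis=1, keepdims=True)
    s_c = X @ B
    q_c = (X**2) @ B
    s_k = tot - s_c
    q_k = tot2 - q_c
    mu_c, mu_k = s_c / n_case, s_k / n_ctrl
    var_c = np.maximum(q_c - n_case * mu_c**2, 0.0) / (n_case - 1)
    var_k = np.maximum(q_k - n_ctrl * mu_k**2, 0.0) / (n_ctrl - 1)
    sd_c = np.maximum(np.sqrt(var_c), SIGMA_FLOOR_FRACTION * np.abs(mu_c))
    sd_k = np.maximum(np.sqrt(var_k), SIGMA_FLOOR_FRACTION * np.abs(mu_k))
    denom = sd_c + sd_k
    return np.where(denom > 0, (mu_c - mu_k) / np.where(denom > 0, denom, 1.0), 0.0)


def _null_de_tstat(X: np.ndarray, masks: np.ndarray) -> np.ndarray:
    n_case = masks[:, 0].sum()
    n_ctrl = masks.shape[0] - n_case
    B = masks.astype(float)
    tot = X.sum(axis=1, keepdims=True)
    tot2 = (X**2).sum(axis=1, keepdims=True)
    s_c = X @ B
    q_c = (X**2) @ B
    mu_c, mu_k = s_c / n_case, (tot - s_c) / n_ctrl
    var_c = np.maximum(q_c - n_case * mu_c**2, 0.0) / (n_case - 1)
    var_k = np.maximum((tot2 - q_c) - n_ctrl * mu_k**2, 0.0) / (n_ctrl - 1)
    se = np.sqrt(var_c / n_case + var_k / n_ctrl)
    return np.where(se > 0, (mu_c - mu_k) / np.where(se > 0, se, 1.0), 0.0)


def _column_es(
    ids: np.ndarray, scores: np.ndarray, member_mask: np.ndarray, weight_exp: float
) -> np.ndarray:
    """ES for each score column against one fixed member mask."""
    order = np.argsort(-scores, axis=0, kind="stable")
    hits = member_mask[order]
    absord = np.abs(np.take_along_axis(scores, order, axis=0))
    profile = _running_sum(absord, hits, weight_exp)
    es, _ = _es_from_profile(profile)
    return es


def _dem_gate(
    expr: ExpressionMatrix, labels: PhenotypeLabels, dem_fdr: float
) -> ExpressionMatrix:
    """Optional differential-expression pre-filter (BH-adjusted Welch p).

    The default threshold of 1.0 admits every miRNA and skips the test.
    """
    if dem_fdr >= 1.0:
        return expr
    lab = labels.reorder(expr.sample_ids)
    case = expr.values[lab.case_samples].to_numpy(dtype=float)
    ctrl = expr.values[lab.control_samples].to_numpy(dtype=float)
    pvals = stats.ttest_ind(case, ctrl, axis=1, equal_var=False).pvalue
    pvals = np.nan_to_num(pvals, nan=1.0)
    order = np.argsort(pvals)
    ranked_p = pvals[order] * len(pvals) / (np.arange(len(pvals)) + 1)
    qvals = np.empty_like(pvals)
    qvals[order] = np.minimum.accumulate(ranked_p[::-1])[::-1]
    keep = expr.values.index[qvals < dem_fdr]
    if len(keep) == 0:
        raise DataError(f"no miRNA passes the DEM gate at FDR < {dem_fdr}")
    log.info("DEM gate FDR < %g keeps %d/%d miRNAs", dem_fdr, len(keep), len(pvals))
    return ExpressionMatrix(expr.values.loc[keep], expr.log_scale)


def enrich(
    expr: ExpressionMatrix,
    labels: PhenotypeLabels,
    wm: WeightMatrix,
    n_perm: int = 1000,
    seed: int | None = None,
    mode: str = "phenotype",
    weight_exp: float = 1.0,
    de_method: str = "s2n",
    ranking: str = "per-pathway",
    min_size: int = 3,
    max_size: int = 500,
    dem_fdr: float = 1.0,
) -> list[PathwayEnrichment]:
    """Permutation-based miRNA set enrichment over every eligible pathway.

    ``mode='phenotype'`` permutes sample labels (recomputing DE, scores
    and the ranking each time); with fewer than 7 samples in a group it
    falls back, with a warning, to ``mode='mirna'`` which permutes miRNA
    identities over the fixed observed ranking. Results are reproducible
    for identical ``(seed, n_perm, mode)``.
    """
    if n_perm < 10:
        raise ValueError(f"n_perm must be >= 10, got {n_perm}")
    if mode not in {"phenotype", "mirna"}:
        raise ValueError(f"unknown permutation mode {mode!r}")
    if ranking not in {"per-pathway", "global"}:
        raise ValueError(f"unknown ranking mode {ranking!r}")
    rng = np.random.default_rng(seed)

    expr = _dem_gate(expr, labels, dem_fdr)
    # canonical row order (sorted ids) makes stable sorts break ties
    # lexicographically without a second key
    df = expr.values.sort_index()
    expr = ExpressionMatrix(df, expr.log_scale)
    lab = labels.reorder(expr.sample_ids)
    n_case = len(lab.case_samples)
    n_ctrl = len(lab.control_samples)
    if mode == "phenotype" and min(n_case, n_ctrl) < 7:
        log.warning(
            "group sizes %d vs %d too small for phenotype permutation; "
            "switching to miRNA-identity permutation",
            n_case,
            n_ctrl,
        )
        mode = "mirna"

    wsub = wm.reindex_mirnas(list(df.index))
    ids = np.asarray(df.index, dtype=object)
    n = len(ids)
    de_obs = differential_scores(expr, lab, method=de_method).to_numpy(dtype=float)

    # case columns first, control columns after: permutation masks apply
    # to this fixed layout
    X = df[lab.case_samples + lab.control_samples].to_numpy(dtype=float)
    if mode == "phenotype":
        masks = _permutation_masks(n_case + n_ctrl, n_case, n_perm, rng)
        null_de = _null_de_s2n(X, masks) if de_method == "s2n" else _null_de_tstat(X, masks)

    w_all = wsub.W.to_numpy(dtype=float)
    w_global = w_all.max(axis=1)
    member_all = wsub.membership.to_numpy(dtype=bool)

    kept: list[dict] = []
    null_es: dict[str, np.ndarray] = {}
    for j, pw in enumerate(wsub.pathway_ids):
        mask = member_all[:, j]
        size = int(mask.sum())
        if size < min_size or size > max_size or size >= n:
            log.info("skipping pathway %s (miRNA-set size %d outside [%d, %d])",
                     pw, size, min_size, max_size)
            continue
        w_j = w_all[:, j] if ranking == "per-pathway" else w_global
        scores_obs = (1.0 + w_j) * de_obs
        order = np.lexsort((ids, -scores_obs))
        hits = mask[order]
        profile = _running_sum(np.abs(scores_obs[order]), hits, weight_exp)
        es_arr, peak_arr = _es_from_profile(profile)
        es, peak = float(es_arr), int(peak_arr) + 1
        ranked = RankedMiRNAList(list(ids[order]), scores_obs[order], de_obs[order])
        members = set(ids[mask])
        core, mir_pct, tag_pct, signal = leading_edge(es, peak, ranked, members)
        max_abs = np.max(np.abs(scores_obs))
        norm = max_abs if max_abs > 0 else 1.0
        score_by_id = dict(zip(ids, scores_obs / norm))
        kept.append(
            dict(
                pathway=pw, size=size, es=es, peak=peak, profile=profile,
                ranked=ranked, core=core, mir_pct=mir_pct, tag_pct=tag_pct,
                signal=signal, core_scores={m: float(score_by_id[m]) for m in core},
            )
        )
        if mode == "phenotype":
            s_null = (1.0 + w_j)[:, None] * null_de
            null_es[pw] = _column_es(ids, s_null, mask, weight_exp)
        else:
            hitmat = np.zeros((n, n_perm), dtype=bool)
            for k in range(n_perm):
                hitmat[rng.permutation(n)[:size], k] = True
            absord = np.abs(scores_obs[order])[:, None]
            prof = _running_sum(np.broadcast_to(absord, (n, n_perm)).copy(),
                                hitmat[order], weight_exp)
            es_null, _ = _es_from_profile(prof)
            null_es[pw] = es_null

    return _normalize(kept, null_es)


#: alias matching the statistical operation's conventional name
permutation_test = enrich


def _normalize(kept: list[dict], null_es: dict[str, np.ndarray]) -> list[PathwayEnrichment]:
    """NES, nominal p and pooled same-sign FDR q from the null ES sets."""
    nes_obs: dict[str, float] = {}
    p_nom: dict[str, float] = {}
    null_nes_pool: list[np.ndarray] = []
    for rec in kept:
        pw, es = rec["pathway"], rec["es"]
        nulls = null_es[pw]
        pos = nulls[nulls >= 0]
        neg = nulls[nulls < 0]
        mean_pos = pos.mean() if pos.size else np.nan
        mean_neg = np.abs(neg).mean() if neg.size else np.nan
        scaled = np.concatenate(
            [
                pos / mean_pos if pos.size and mean_pos > 0 else pos[:0],
                neg / mean_neg if neg.size and mean_neg > 0 else neg[:0],
            ]
        )
        null_nes_pool.append(scaled)
        if es >= 0:
            same = pos
            denom_mean = mean_pos
        else:
            same = np.abs(neg)
            denom_mean = mean_neg
        if same.size == 0 or not denom_mean > 0:
            log.warning("pathway %s: no same-sign null ES; NES undefined", pw)
            nes_obs[pw] = 0.0
            p_nom[pw] = 1.0
            continue
        nes_obs[pw] = es / denom_mean
        p_nom[pw] = (1.0 + np.sum(same >= abs(es))) / (1.0 + same.size)

    pool = np.concatenate(null_nes_pool) if null_nes_pool else np.empty(0)
    obs = np.array([nes_obs[rec["pathway"]] for rec in kept])
    results = []
    for rec in kept:
        pw = rec["pathway"]
        nes = nes_obs[pw]
        if nes >= 0:
            n_null_sign = np.sum(pool >= 0)
            n_null_ge = np.sum(pool >= nes)
            n_obs_sign = np.sum(obs >= 0)
            n_obs_ge = np.sum(obs >= nes)
        else:
            n_null_sign = np.sum(pool < 0)
            n_null_ge = np.sum(pool <= nes)
            n_obs_sign = np.sum(obs < 0)
            n_obs_ge = np.sum(obs <= nes)
        if n_null_sign == 0 or n_obs_ge == 0:
            q = 1.0
        else:
            num = n_null_ge / n_null_sign
            den = n_obs_ge / max(n_obs_sign, 1)
            q = min(1.0, num / den) if den > 0 else 1.0
        results.append(
            PathwayEnrichment(
                pathway_id=pw,
                size=rec["size"],
                es=rec["es"],
                nes=float(nes),
                p_nominal=float(p_nom[pw]),
                fdr_q=float(q),
                peak_rank=rec["peak"],
                running_profile=rec["profile"],
                core_mirnas=rec["core"],
                core_scores=rec["core_scores"],
                mir_pct=rec["mir_pct"],
                tag_pct=rec["tag_pct"],
                signal=rec["signal"],
                direction="up" if rec["es"] >= 0 else "down",
            )
        )
    return results
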