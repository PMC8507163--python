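"""miRNA-pathway association weights from target/gene-set overlaps.

For miRNA *i* with *n* target genes and pathway *j* with *t* member genes
drawn from a genome of *m* genes, the association weight is

    W_ij = 1 - p_ij,      p_ij = P(X >= r_ij),  X ~ Hypergeometric(m, t, n),

where r_ij is the observed number of the miRNA's targets inside the
pathway. p_ij is the upper tail of the hypergeometric distribution; a
miRNA with no targets in a pathway has p = 1 and weight 0. A miRNA
belongs to a pathway's miRNA set when its overlap reaches ``min_overlap``
(default one shared gene).

The genome size m defaults to the union of all pathway genes and all
target genes, since no fixed universe is mandated by the inputs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .containers import DataError, GeneSetCollection, TargetMap, target_universe

log = logging.getLogger(__name__)

#: above this genome size the vectorised float path replaces exact integers
_EXACT_LIMIT = 100_000


def hypergeom_tail(m: int, t: int, n: int, r: int, method: str = "auto") -> float:
    """Upper-tail hypergeometric probability P(X >= r).

    Exact integer arithmetic (method ``"exact"``) evaluates
    sum_{x=r}^{n} C(t,x) C(m-t,n-x) / C(m,n) with out-of-range terms zero,
    so the result is correct to full float precision; ``"float"`` uses the
    scipy survival function. ``"auto"`` picks exact for any genome a
    pathway analysis will meet.
    """
    if not (0 <= t <= m and 0 <= n <= m):
        raise ValueError(f"need 0 <= t,n <= m; got m={m}, t={t}, n={n}")
    if not (0 <= r <= min(n, t)):
        raise ValueError(f"need 0 <= r <= min(n,t)={min(n, t)}; got r={r}")
    if r == 0:
        return 1.0
    if method == "auto":
        method = "exact" if m <= _EXACT_LIMIT else "float"
    if method == "float":
        return float(hypergeom.sf(r - 1, m, t, n))
    if method != "exact":
        raise ValueError(f"unknown method {method!r}")
    numer = 0
    for x in range(r, min(n, t) + 1):
        if n - x > m - t:
            continue
        numer += math.comb(t, x) * math.comb(m - t, n - x)
    return numer / math.comb(m, n)


@dataclass
class WeightMatrix:
    """All per-(miRNA, pathway) association quantities, aligned DataFrames."""

    W: pd.DataFrame            # weight 1 - p, in [0, 1]
    p: pd.DataFrame            # hypergeometric upper-tail probability
    r: pd.DataFrame            # integer overlap counts
    membership: pd.DataFrame   # bool: miRNA in pathway's miRNA set
    m: int                     # genome size
    t: pd.Series               # pathway gene counts
    n: pd.Series               # miRNA target counts (within genome)

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.W.index)

    @property
    def pathway_ids(self) -> list[str]:
        return list(self.W.columns)

    def members(self, pathway_id: str) -> list[str]:
        col = self.membership[pathway_id]
        return list(col.index[col])

    def reindex_mirnas(self, mirna_ids: list[str]) -> "WeightMatrix":
        """Restrict to the miRNAs present in an expression matrix."""
        missing = [m_ for m_ in mirna_ids if m_ not in self.W.index]
        if missing:
            raise DataError(f"miRNAs absent from weight matrix: {missing[:5]}...")
        return WeightMatrix(
            self.W.loc[mirna_ids],
            self.p.loc[mirna_ids],
            self.r.loc[mirna_ids],
            self.membership.loc[mirna_ids],
            self.m,
            self.t,
            self.n.loc[mirna_ids],
        )


def build_weight_matrix(
    targets: TargetMap,
    pathways: GeneSetCollection,
    genome: frozenset[str] | set[str] | None = None,
    min_overlap: int = 1,
    p_max: float | None = None,
) -> WeightMatrix:
    """Hypergeometric weights for every (miRNA, pathway) pair.

    Target genes outside the genome are dropped (with a warning) and do
    not count toward a miRNA's ``n``. Membership additionally requires
    ``p <= p_max`` when that filter is enabled.
    """
    if genome is None:
        genome = pathways.gene_universe() | target_universe(targets)
    genome = frozenset(genome)
    if not genome:
        raise DataError("empty gene universe")
    outside = pathways.gene_universe() - genome
    if outside:
        raise DataError(f"pathway genes outside the genome: {sorted(outside)[:5]}...")

    gene_index = {g: k for k, g in enumerate(sorted(genome))}
    m = len(genome)
    mirna_ids = list(targets)
    pathway_ids = pathways.pathway_ids

    T = np.zeros((len(mirna_ids), m), dtype=bool)
    n_dropped = 0
    for i, mir in enumerate(mirna_ids):
        for g in targets[mir]:
            k = gene_index.get(g)
            if k is None:
                n_dropped += 1
            else:
                T[i, k] = True
    if n_dropped:
        log.warning("%d target genes outside the genome were dropped", n_dropped)
    P = np.zeros((len(pathway_ids), m), dtype=bool)
    for j, pw in enumerate(pathway_ids):
        for g in pathways[pw]:
            P[j, gene_index[g]] = True

    r = T.astype(np.int64) @ P.T.astype(np.int64)
    n_vec = T.sum(axis=1).astype(np.int64)
    t_vec = P.sum(axis=1).astype(np.int64)

    # scipy broadcasts; sf(r-1) is the inclusive upper tail P(X >= r)
    p = hypergeom.sf(r - 1, m, t_vec[None, :], n_vec[:, None])
    p = np.clip(p, 0.0, 1.0)
    p[r == 0] = 1.0
    W = 1.0 - p

    member = r >= min_overlap
    if p_max is not None:
        member &= p <= p_max

    idx = pd.Index(mirna_ids, name="mirna")
    cols = pd.Index(pathway_ids, name="pathway")
    return WeightMatrix(
        W=pd.DataFrame(W, index=idx, columns=cols),
        p=pd.DataFrame(p, index=idx, columns=cols),
        r=pd.DataFrame(r, index=idx, columns=cols),
        membership=pd.DataFrame(member, index=idx, columns=cols),
        m=m,
        t=pd.Series(t_vec, index=cols),
        n=pd.Series(n_vec, index=idx),
    )


def weight_table(wm: WeightMatrix) -> pd.DataFrame:
    """Long-format (mirna, pathway, r, p, W, member) table for export."""
    records = []
    for mir in wm.mirna_ids:
        for pw in wm.pathway_ids:
            records.append(
                (
                    mir,
                    pw,
                    int(wm.r.at[mir, pw]),
                    float(wm.p.at[mir, pw]),
                    float(wm.W.at[mir, pw]),
                    bool(wm.membership.at[mir, pw]),
                )
            )
    return pd.DataFrame(records, columns=["mirna", "pathway", "r", "p", "W", "member"])
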