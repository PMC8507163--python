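"""Mapping selected miRNAs' target genes into selected pathways.

The final reporting step: for each significant miRNA, which of its
(validated) target genes sit inside each selected pathway's gene set.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import pandas as pd

from .containers import DataError, GeneSetCollection, TargetMap

log = logging.getLogger(__name__)

#: pathway_id -> (mirna_id -> frozenset of in-pathway target genes)
PathwayTargetMap = dict[str, dict[str, frozenset]]


def read_target_table(path: str | Path, evidence: Sequence[str] | None = None) -> dict:
    """Read a (mirna, gene[, evidence]) table, optionally filtering rows.

    When ``evidence`` is given, only rows whose third column matches one of
    the listed values are kept; tables without a third column pass through
    unfiltered. Defaults to accepting all rows.
    """
    path = Path(path)
    out: dict[str, set] = {}
    keep = set(evidence) if evidence else None
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise DataError(f"{path}:{lineno}: expected at least (mirna, gene)")
            if lineno == 1 and fields[0].lower() in {"mirna", "mirna_id"}:
                continue
            if keep is not None and len(fields) >= 3 and fields[2].strip() not in keep:
                continue
            out.setdefault(fields[0].strip(), set()).add(fields[1].strip())
    return {m: frozenset(g) for m, g in out.items()}


def map_targets(
    mirnas: Sequence[str],
    targets: TargetMap,
    pathways: GeneSetCollection,
    selected: Sequence[str],
) -> PathwayTargetMap:
    """Intersect each miRNA's targets with each selected pathway's genes.

    Empty intersections are kept as empty entries; a miRNA absent from the
    target map gets an empty entry with a warning.
    """
    bad = [pw for pw in selected if pw not in pathways]
    if bad:
        raise DataError(f"selected pathways not in the collection: {bad}")
    out: PathwayTargetMap = {}
    for pw in selected:
        genes = pathways[pw]
        per_mir: dict[str, frozenset] = {}
        for mir in mirnas:
            if mir not in targets:
                log.warning("miRNA %s has no entry in the target map", mir)
                per_mir[mir] = frozenset()
            else:
                per_mir[mir] = frozenset(targets[mir]) & genes
        out[pw] = per_mir
    return out


def mapping_table(ptm: PathwayTargetMap) -> pd.DataFrame:
    """Long-format (pathway, mirna, gene) rows, deterministically sorted."""
    rows = [
        (pw, mir, gene)
        for pw in sorted(ptm)
        for mir in sorted(ptm[pw])
        for gene in sorted(ptm[pw][mir])
    ]
    return pd.DataFrame(rows, columns=["pathway", "mirna", "gene"])


def export_mapping(ptm: PathwayTargetMap, path: str | Path) -> None:
    """Write the mapping as a sorted long-format TSV (header always present)."""
    mapping_table(ptm).to_csv(path, sep="\t", index=False)
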