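"""Readers and writers for the pipeline's external formats.

Canonical delimiter is the tab (GEO-style exports); CSV is accepted via an
explicit ``dialect`` argument. Missing values are spelled ``NA`` on disk
and become NaN in memory; only the preprocessing filters are allowed to
handle them. Phenotype labels are read either from a 3-line CLS-like file
(counts line, ``#``-prefixed names line, labels line) or from a two-column
``sample<TAB>group`` table.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path
from typing import Any, Sequence

import pandas as pd

from .containers import DataError, ExpressionMatrix, GeneSetCollection, PhenotypeLabels

log = logging.getLogger(__name__)

_DELIMS = {"tsv": "\t", "csv": ","}

#: significant digits used when rendering floats to text
FLOAT_DIGITS = 6


def _delimiter(dialect: str) -> str:
    try:
        return _DELIMS[dialect]
    except KeyError:
        raise ValueError(f"unknown dialect {dialect!r}; expected 'tsv' or 'csv'") from None


def read_expression(path: str | Path, dialect: str = "tsv") -> ExpressionMatrix:
    """Read a miRNA x sample matrix (first row samples, first column miRNAs).

    Row and column order are preserved from the file. The returned matrix
    is flagged as raw scale (``log_scale=False``).
    """
    path = Path(path)
    sep = _delimiter(dialect)
    with path.open() as fh:
        header = fh.readline()
        if not header.strip():
            raise DataError(f"{path}: empty file")
        sample_ids = [c.strip() for c in header.rstrip("\n").split(sep)[1:]]
        rows: list[list[str]] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split(sep)
            if len(fields) != len(sample_ids) + 1:
                raise DataError(
                    f"{path}:{lineno}: expected {len(sample_ids) + 1} fields, got {len(fields)}"
                )
            rows.append(fields)
    if not rows:
        raise DataError(f"{path}: no data rows")

    mirna_ids = [r[0].strip() for r in rows]
    for ids, what in ((mirna_ids, "miRNA"), (sample_ids, "sample")):
        seen: set[str] = set()
        for x in ids:
            if x in seen:
                raise DataError(f"{path}: duplicate {what} identifier {x!r}")
            seen.add(x)

    data = []
    for i, r in enumerate(rows):
        vals = []
        for j, cell in enumerate(r[1:]):
            cell = cell.strip()
            if cell == "NA" or cell == "":
                vals.append(math.nan)
                continue
            try:
                vals.append(float(cell))
            except ValueError:
                raise DataError(
                    f"{path}: non-numeric value {cell!r} at miRNA {mirna_ids[i]!r}, "
                    f"sample {sample_ids[j]!r}"
                ) from None
        data.append(vals)
    df = pd.DataFrame(data, index=mirna_ids, columns=sample_ids, dtype=float)
    return ExpressionMatrix(df, log_scale=False)


def write_expression(expr: ExpressionMatrix, path: str | Path, dialect: str = "tsv") -> None:
    sep = _delimiter(dialect)
    df = expr.values.map(lambda v: "NA" if pd.isna(v) else f"{v:.{FLOAT_DIGITS}g}")
    df.to_csv(path, sep=sep, index_label="miRNA")


def read_phenotype(path: str | Path, group_names: tuple[str, str] | None = None) -> PhenotypeLabels:
    """Read phenotype labels from a CLS-like file or a two-column table.

    CLS-like layout::

        27 2 1
        # COPD control
        COPD COPD ... control

    The first name on the ``#`` line is the case group. A CLS file carries
    no sample identifiers; positional ids ``s1..sN`` are assigned and should
    be re-aligned to an expression matrix with :meth:`PhenotypeLabels.reorder`
    only when the file ordering matches the matrix columns (use
    :func:`attach_samples`).
    """
    path = Path(path)
    lines = [ln.rstrip("\n") for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise DataError(f"{path}: empty phenotype file")
    first = lines[0].split()
    if len(lines) >= 3 and all(tok.lstrip("-").isdigit() for tok in first):
        n, k, _ = (int(tok) for tok in first[:3])
        if k != 2:
            raise DataError(f"{path}: exactly two phenotype classes required, got {k}")
        names_line = lines[1].split()
        if names_line[0] != "#":
            raise DataError(f"{path}: second CLS line must start with '#'")
        names = tuple(names_line[1:3])
        labels = lines[2].split()
        if len(labels) != n:
            raise DataError(f"{path}: counts line promises {n} samples, labels line has {len(labels)}")
        # numeric labels index into the names line
        if set(labels) <= {"0", "1"}:
            labels = [names[int(tok)] for tok in labels]
        ids = [f"s{i + 1}" for i in range(n)]
        return PhenotypeLabels(ids, labels, (names[0], names[1]))

    # two-column TSV: sample <TAB> group, optional header
    ids, labels = [], []
    for lineno, ln in enumerate(lines, start=1):
        fields = ln.split("\t")
        if len(fields) < 2:
            raise DataError(f"{path}:{lineno}: expected 2 tab-separated fields")
        if lineno == 1 and fields[0].lower() in {"sample", "sample_id"}:
            continue
        ids.append(fields[0].strip())
        labels.append(fields[1].strip())
    if group_names is None:
        ordered = list(dict.fromkeys(labels))
        if len(ordered) != 2:
            raise DataError(f"{path}: expected exactly two groups, found {ordered}")
        group_names = (ordered[0], ordered[1])
    return PhenotypeLabels(ids, labels, group_names)


def attach_samples(labels: PhenotypeLabels, sample_ids: Sequence[str]) -> PhenotypeLabels:
    """Replace positional CLS sample ids with the matrix's column ids."""
    if len(sample_ids) != len(labels.sample_ids):
        raise DataError(
            f"label count {len(labels.sample_ids)} != sample count {len(sample_ids)}"
        )
    return PhenotypeLabels(list(sample_ids), list(labels.group), labels.group_names)


def write_phenotype(labels: PhenotypeLabels, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("sample\tgroup\n")
        for s, g in zip(labels.sample_ids, labels.group):
            fh.write(f"{s}\t{g}\n")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: ``name TAB description TAB gene1 TAB gene2 ...``."""
    path = Path(path)
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise DataError(f"{path}:{lineno}: GMT line needs >=3 tab-separated fields")
            name, desc, *genes = fields
            genes = [g.strip() for g in genes if g.strip()]
            if name in sets:
                raise DataError(f"{path}:{lineno}: duplicate pathway id {name!r}")
            unique = list(dict.fromkeys(genes))
            if len(unique) != len(genes):
                log.warning("%s:%d: duplicate genes within set %s deduplicated", path, lineno, name)
            sets[name] = frozenset(unique)
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(pathways: GeneSetCollection, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for name in pathways.pathway_ids:
            desc = pathways.descriptions.get(name, "na")
            genes = sorted(pathways[name])
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_target_map(path: str | Path) -> dict[str, frozenset[str]]:
    """Read a two-column (miRNA, gene) TSV into a target map.

    Extra columns (e.g. an evidence annotation) are ignored here; duplicate
    pairs collapse. An empty file yields an empty map.
    """
    path = Path(path)
    out: dict[str, set[str]] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                raise DataError(f"{path}:{lineno}: expected (mirna, gene) tab-separated pair")
            if lineno == 1 and fields[0].lower() in {"mirna", "mirna_id"}:
                continue
            out.setdefault(fields[0].strip(), set()).add(fields[1].strip())
    return {m: frozenset(g) for m, g in out.items()}


def write_target_map(targets: dict[str, frozenset[str]], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("mirna\tgene\n")
        for m in sorted(targets):
            for g in sorted(targets[m]):
                fh.write(f"{m}\t{g}\n")


def _fmt(v: Any) -> str:
    if isinstance(v, float):
        if math.isnan(v):
            return "NA"
        return f"{v:.{FLOAT_DIGITS}g}"
    return str(v)


#: column layout of the per-pathway enrichment report
ENRICHMENT_COLUMNS = ["pathway", "SIZE", "ES", "NES", "p", "FDR", "MirPct", "Signal"]


def write_report(result: Any, path: str | Path, format: str = "tsv") -> None:
    """Serialize a pipeline product with deterministic field order.

    Accepts a list of :class:`~mirpathsea.enrichment.PathwayEnrichment`
    (written in the standard SIZE/ES/NES/Mir%/Signal table layout), a
    DataFrame, or any JSON-serializable mapping.
    """
    path = Path(path)
    if format == "json":
        with path.open("w") as fh:
            json.dump(_jsonable(result), fh, indent=2, sort_keys=True)
            fh.write("\n")
        return
    if format != "tsv":
        raise ValueError(f"unknown report format {format!r}")

    if isinstance(result, pd.DataFrame):
        out = result.map(_fmt) if len(result) else result
        out.to_csv(path, sep="\t")
        return
    rows = list(result) if not isinstance(result, (list, tuple)) else result
    with path.open("w") as fh:
        fh.write("\t".join(ENRICHMENT_COLUMNS) + "\n")
        for enr in rows:
            fh.write(
                "\t".join(
                    _fmt(v)
                    for v in (
                        enr.pathway_id,
                        enr.size,
                        enr.es,
                        enr.nes,
                        enr.p_nominal,
                        enr.fdr_q,
                        enr.mir_pct,
                        enr.signal,
                    )
                )
                + "\n"
            )


def _jsonable(obj: Any) -> Any:
    if hasattr(obj, "to_jsonable"):
        return obj.to_jsonable()
    if isinstance(obj, pd.DataFrame):
        return {c: obj[c].tolist() for c in obj.columns}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, float):
        return None if math.isnan(obj) else round(obj, 10)
    if hasattr(obj, "item"):  # numpy scalar
        return obj.item()
    return obj
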