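"""Core in-memory containers shared across the pipeline.

Expression data lives in a pandas DataFrame (miRNA rows, sample columns);
the thin wrappers here enforce the identifier-uniqueness and shape
invariants the downstream stages rely on, and track whether the matrix has
been log2-transformed so the transform cannot be applied twice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd


class MirpathseaError(Exception):
    """Base class for all pipeline errors."""


class DataError(MirpathseaError):
    """Malformed or inconsistent input data."""


@dataclass
class ExpressionMatrix:
    """A miRNA x sample abundance matrix.

    Parameters
    ----------
    values
        DataFrame with miRNA identifiers as the index and sample
        identifiers as columns. Row/column order is meaningful and
        preserved through every operation.
    log_scale
        True once a log2 transform has been applied (exactly once).
    """

    values: pd.DataFrame
    log_scale: bool = False

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        dup_rows = idx[idx.duplicated()].unique().tolist()
        if dup_rows:
            raise DataError(f"duplicate miRNA identifier(s): {dup_rows}")
        dup_cols = cols[cols.duplicated()].unique().tolist()
        if dup_cols:
            raise DataError(f"duplicate sample identifier(s): {dup_cols}")

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), self.log_scale)


@dataclass
class PhenotypeLabels:
    """Two-group sample labels for one contrast.

    ``group_names`` is ordered (case, control); the case group listed
    first defines the sign convention of every differential score
    downstream (positive = up in case).
    """

    sample_ids: list[str]
    group: list[str]
    group_names: tuple[str, str]

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.group):
            raise DataError("sample_ids and group labels differ in length")
        case, control = self.group_names
        if case == control:
            raise DataError("the two group names must differ")
        extra = set(self.group) - {case, control}
        if extra:
            raise DataError(f"unknown group label(s): {sorted(extra)}")
        if case not in self.group or control not in self.group:
            raise DataError("both groups must be non-empty")

    @property
    def case_samples(self) -> list[str]:
        case = self.group_names[0]
        return [s for s, g in zip(self.sample_ids, self.group) if g == case]

    @property
    def control_samples(self) -> list[str]:
        control = self.group_names[1]
        return [s for s, g in zip(self.sample_ids, self.group) if g == control]

    def reorder(self, sample_ids: Iterable[str]) -> "PhenotypeLabels":
        """Labels restricted to and ordered like ``sample_ids``."""
        lookup = dict(zip(self.sample_ids, self.group))
        missing = [s for s in sample_ids if s not in lookup]
        if missing:
            raise DataError(f"samples without phenotype label: {missing}")
        ids = list(sample_ids)
        return PhenotypeLabels(ids, [lookup[s] for s in ids], self.group_names)


@dataclass
class GeneSetCollection:
    """Named gene sets (pathways) with optional free-text descriptions."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise DataError(f"gene set {name!r} is empty")

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    @property
    def pathway_ids(self) -> list[str]:
        return list(self.sets)

    def gene_universe(self) -> frozenset[str]:
        out: set[str] = set()
        for genes in self.sets.values():
            out |= genes
        return frozenset(out)


#: miRNA identifier -> set of target gene identifiers.
TargetMap = Mapping[str, frozenset]


def target_universe(targets: TargetMap) -> frozenset:
    out: set = set()
    for genes in targets.values():
        out |= set(genes)
    return frozenset(out)
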