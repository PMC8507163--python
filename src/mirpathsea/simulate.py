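"""Synthetic two-contrast miRNA expression studies with planted structure.

The generator emulates the shape of a pair of public two-group miRNA
microarray studies — contrast A with 1308 miRNAs over 19 case vs 8
control samples, contrast B with 1145 miRNAs over 20 vs 20 — together
with a pathway gene-set collection and a miRNA-target table, so the whole
pipeline can run without any download.

Structure is planted at the *target* level: each planted pathway gets a
set of "driver" miRNAs whose target genes are concentrated (a
configurable majority) inside that pathway's gene set, which makes their
hypergeometric weights and pathway membership high by construction. The
drivers then receive a mean log2 shift in the case group of the stated
contrast, so the pathway's miRNA set is genuinely enriched at one end of
the ranked list. Baseline expression is drawn on raw intensity scale
(2 to the power of a Normal log2 value) so the preprocessing chain is
exercised on the path real data would take.

Everything derives from one seeded NumPy generator: identical config and
seed give bitwise-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import (
    DataError,
    ExpressionMatrix,
    GeneSetCollection,
    PhenotypeLabels,
)

#: (pathway_id, direction in {up, down}, contrast in {A, B, both})
PlantedPathway = tuple[str, str, str]


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults mirror the emulated studies."""

    n_mirnas: tuple[int, int] = (1308, 1145)       # per-contrast panel sizes
    n_genes: int = 20000                            # genome size m (~human protein-coding)
    n_pathways: int = 40
    pathway_size_range: tuple[int, int] = (30, 120)
    targets_per_mirna_range: tuple[int, int] = (10, 60)
    samples: dict = field(default_factory=lambda: {"A": (19, 8), "B": (20, 20)})
    planted_pathways: list[PlantedPathway] | None = None
    effect_size: float = 2.0                        # case-group log2 shift
    noise_sd: float = 0.5                           # log2 units
    baseline_log2: float = 6.0
    drivers_per_pathway: int = 6
    driver_target_fraction: float = 0.75            # of a driver's targets in-pathway
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.n_mirnas, int):
            self.n_mirnas = (self.n_mirnas, self.n_mirnas)
        counts = [*self.n_mirnas, self.n_genes, self.n_pathways,
                  *self.pathway_size_range, *self.targets_per_mirna_range]
        for contrast, (n_case, n_control) in self.samples.items():
            counts += [n_case, n_control]
        if any(c <= 0 for c in counts):
            raise ValueError("all counts must be positive")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.pathway_size_range[1] > self.n_genes:
            raise ValueError("pathway sizes cannot exceed the genome size")
        if self.n_pathways * self.pathway_size_range[1] > self.n_genes:
            raise ValueError(
                "genome too small for disjoint pathway gene sets "
                f"({self.n_pathways} pathways x up to {self.pathway_size_range[1]} "
                f"genes > {self.n_genes})"
            )
        if not 0.5 <= self.driver_target_fraction <= 1.0:
            raise ValueError("driver_target_fraction must be in [0.5, 1]")


@dataclass
class TruthRecord:
    """What was planted: drivers per pathway and direction per contrast."""

    drivers: dict[str, list[str]]
    directions: dict[tuple[str, str], str]   # (pathway, contrast) -> up|down

    @property
    def planted_pathways(self) -> list[str]:
        return list(self.drivers)

    def to_jsonable(self) -> dict:
        return {
            "drivers": self.drivers,
            "directions": {f"{pw}|{c}": d for (pw, c), d in self.directions.items()},
        }


@dataclass
class Contrast:
    expr: ExpressionMatrix
    labels: PhenotypeLabels


@dataclass
class SimulatedStudy:
    contrasts: dict[str, Contrast]
    pathways: GeneSetCollection
    targets: dict[str, frozenset[str]]
    truth: TruthRecord


def _default_planted(pathway_ids: list[str]) -> list[PlantedPathway]:
    """Balanced default: three signature pathways shifted down in contrast A
    and up in contrast B, plus three shifted the opposite way, so each
    contrast carries regulation in both directions (as real two-group
    comparisons do)."""
    out: list[PlantedPathway] = []
    for pw in pathway_ids[:3]:
        out.append((pw, "down", "A"))
        out.append((pw, "up", "B"))
    for pw in pathway_ids[3:6]:
        out.append((pw, "up", "A"))
        out.append((pw, "down", "B"))
    return out


def simulate(config: SimulationConfig) -> SimulatedStudy:
    """Draw a full synthetic study from a seeded generator."""
    rng = np.random.default_rng(config.seed)
    genes = np.array([f"G{k + 1:05d}" for k in range(config.n_genes)], dtype=object)
    pathway_ids = [f"PW_{j + 1:04d}" for j in range(config.n_pathways)]
    lo, hi = config.pathway_size_range
    # gene sets are drawn disjointly so that planted target structure is
    # attributable to exactly one pathway (real collections overlap; see docs)
    sets: dict[str, frozenset[str]] = {}
    unused = list(genes)
    rng.shuffle(unused)
    cursor = 0
    for pw in pathway_ids:
        size = int(rng.integers(lo, hi + 1))
        sets[pw] = frozenset(unused[cursor : cursor + size])
        cursor += size
    pathways = GeneSetCollection(sets, {pw: "synthetic pathway" for pw in pathway_ids})

    planted = config.planted_pathways
    if planted is None:
        planted = _default_planted(pathway_ids)
    entries: list[tuple[str, str, str]] = []
    for pw, direction, contrast in planted:
        if pw not in sets:
            raise DataError(f"planted pathway {pw!r} is not among the generated pathways")
        if direction not in {"up", "down"}:
            raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
        if contrast not in {"A", "B", "both"}:
            raise ValueError(f"contrast must be 'A', 'B' or 'both', got {contrast!r}")
        targets_c = ["A", "B"] if contrast == "both" else [contrast]
        for c in targets_c:
            if c not in config.samples:
                raise DataError(f"planted contrast {c!r} has no sample sizes configured")
            entries.append((pw, direction, c))

    n_universe = max(config.n_mirnas)
    mirna_ids = np.array(
        [f"syn-miR-{i + 1:04d}" for i in range(n_universe)], dtype=object
    )

    planted_ids = list(dict.fromkeys(pw for pw, _, _ in entries))
    drivers: dict[str, list[str]] = {}
    pool = list(range(n_universe))
    rng.shuffle(pool)
    cursor = 0
    for pw in planted_ids:
        take = pool[cursor : cursor + config.drivers_per_pathway]
        if len(take) < 1:
            raise DataError("not enough miRNAs to assign drivers")
        drivers[pw] = sorted(mirna_ids[i] for i in take)
        cursor += config.drivers_per_pathway
    driver_of = {mir: pw for pw, mirs in drivers.items() for mir in mirs}

    t_lo, t_hi = config.targets_per_mirna_range
    gene_set_arrays = {pw: np.array(sorted(sets[pw]), dtype=object) for pw in pathway_ids}
    in_any_pathway = frozenset().union(*sets.values())
    # drivers' off-pathway targets avoid every gene set so the planted
    # signal stays attributable to its pathway alone
    nonpathway_pool = np.array(sorted(set(genes) - in_any_pathway), dtype=object)
    targets: dict[str, frozenset[str]] = {}
    for mir in mirna_ids:
        n_t = int(rng.integers(t_lo, t_hi + 1))
        pw = driver_of.get(mir)
        if pw is None:
            chosen = rng.choice(genes, size=n_t, replace=False)
        else:
            inside_pool = gene_set_arrays[pw]
            k = min(max(1, math.ceil(config.driver_target_fraction * n_t)),
                    len(inside_pool))
            inside = rng.choice(inside_pool, size=k, replace=False)
            n_out = min(n_t - k, len(nonpathway_pool))
            outside = rng.choice(nonpathway_pool, size=n_out, replace=False) if n_out else []
            chosen = np.concatenate([inside, np.asarray(outside, dtype=object)])
        targets[str(mir)] = frozenset(str(g) for g in chosen)

    directions = {(pw, c): d for pw, d, c in entries}
    truth = TruthRecord(drivers=drivers, directions=directions)

    contrasts: dict[str, Contrast] = {}
    for contrast_name in sorted(config.samples):
        n_case, n_control = config.samples[contrast_name]
        panel_size = config.n_mirnas[0] if contrast_name == "A" else config.n_mirnas[1]
        driver_idx = np.array(
            sorted({np.where(mirna_ids == m)[0][0] for m in driver_of}), dtype=int
        ) if driver_of else np.array([], dtype=int)
        if panel_size >= n_universe:
            panel = np.arange(n_universe)
        elif panel_size < len(driver_idx):
            raise DataError("panel smaller than the planted driver set")
        else:
            rest = np.setdiff1d(np.arange(n_universe), driver_idx)
            extra = rng.choice(rest, size=panel_size - len(driver_idx), replace=False)
            panel = np.sort(np.concatenate([driver_idx, extra]))
        panel_ids = mirna_ids[panel]

        n_samp = n_case + n_control
        log2 = rng.normal(config.baseline_log2, config.noise_sd,
                          size=(len(panel), n_samp))
        for (pw, c), direction in directions.items():
            if c != contrast_name:
                continue
            sign = 1.0 if direction == "up" else -1.0
            rows = np.isin(panel_ids, drivers[pw])
            log2[np.ix_(rows, np.arange(n_case))] += sign * config.effect_size
        raw = np.power(2.0, log2)
        sample_ids = [f"{contrast_name}_case_{i + 1:02d}" for i in range(n_case)] + [
            f"{contrast_name}_ctrl_{i + 1:02d}" for i in range(n_control)
        ]
        group = ["case"] * n_case + ["control"] * n_control
        expr = ExpressionMatrix(
            pd.DataFrame(raw, index=list(panel_ids), columns=sample_ids),
            log_scale=False,
        )
        labels = PhenotypeLabels(sample_ids, group, ("case", "control"))
        contrasts[contrast_name] = Contrast(expr, labels)

    return SimulatedStudy(contrasts, pathways, targets, truth)


def null_config(**overrides) -> SimulationConfig:
    """A no-effect configuration (effect_size 0) for calibration checks."""
    cfg = SimulationConfig(effect_size=0.0, planted_pathways=[])
    return replace(cfg, **overrides) if overrides else cfg
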