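"""End-to-end pipeline driver: simulate/load -> preprocess -> weights ->
enrich (per contrast) -> cross-disease comparison -> target mapping.

One :class:`RunConfig` holds every stage parameter; a single seed governs
all stochastic stages. ``run_all`` writes each intermediate artifact plus
a manifest (effective parameters, package version, seed, input digests)
sufficient to reproduce the run bit-for-bit from the same inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .containers import DataError, ExpressionMatrix, GeneSetCollection, PhenotypeLabels
from .cross_disease import CrossDiseaseReport, compare, edge_list, mean_scores
from .enrichment import PathwayEnrichment, enrich
from .io import (
    attach_samples,
    read_expression,
    read_gmt,
    read_phenotype,
    read_target_map,
    write_expression,
    write_report,
)
from .preprocess import preprocess
from .simulate import SimulationConfig, simulate
from .targets import export_mapping, map_targets
from .weights import build_weight_matrix, weight_table

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Declarative description of a full run.

    Either ``simulation`` is set (synthetic study) or ``inputs`` maps each
    contrast name to ``{"expression": path, "phenotype": path}`` alongside
    ``pathways_gmt`` and ``targets_tsv``.
    """

    outdir: str = "mirpathsea_run"
    seed: int = 0
    simulation: dict | None = None
    inputs: dict[str, dict[str, str]] | None = None
    pathways_gmt: str | None = None
    targets_tsv: str | None = None
    pseudocount: float = 1.0
    quantile: bool = True
    min_overlap: int = 1
    n_perm: int = 200
    mode: str = "phenotype"
    weight_exp: float = 1.0
    de_method: str = "s2n"
    ranking: str = "per-pathway"
    min_size: int = 3
    max_size: int = 500
    dem_fdr: float = 1.0
    qmax: float = 0.25
    require_opposite: bool = True
    min_pathways: int = 2
    nes_bound: float | None = -2.0
    top_k_pathways: int = 3
    top_k_mirnas: int = 5

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_jsonable(self) -> dict:
        return dataclasses.asdict(self)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _frame_digest(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.to_csv().encode()).hexdigest()


def enrichment_to_json(results: list[PathwayEnrichment], path: Path) -> None:
    payload = [r.to_jsonable() | {"running_profile": r.running_profile.tolist()}
               for r in results]
    path.write_text(json.dumps(payload, indent=1) + "\n")


def enrichment_from_json(path: Path) -> list[PathwayEnrichment]:
    out = []
    for rec in json.loads(Path(path).read_text()):
        out.append(
            PathwayEnrichment(
                pathway_id=rec["pathway"],
                size=rec["SIZE"],
                es=rec["ES"],
                nes=rec["NES"],
                p_nominal=rec["p"],
                fdr_q=rec["FDR"],
                peak_rank=rec["peak_rank"],
                running_profile=np.asarray(rec["running_profile"], dtype=float),
                core_mirnas=rec["core_mirnas"],
                core_scores=rec["core_scores"],
                mir_pct=rec["MirPct"],
                tag_pct=rec["TagPct"],
                signal=rec["Signal"],
                direction=rec["direction"],
            )
        )
    return out


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            log.info("[%s] starting", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise DataError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


def _load_inputs(
    config: RunConfig,
) -> tuple[dict[str, tuple[ExpressionMatrix, PhenotypeLabels]], GeneSetCollection, dict, dict]:
    digests: dict[str, str] = {}
    contrasts: dict[str, tuple[ExpressionMatrix, PhenotypeLabels]] = {}
    if config.simulation is not None:
        sim_cfg = SimulationConfig(**{**config.simulation, "seed": config.seed})
        study = simulate(sim_cfg)
        for name, con in study.contrasts.items():
            contrasts[name] = (con.expr, con.labels)
            digests[f"expression_{name}"] = _frame_digest(con.expr.values)
        return contrasts, study.pathways, dict(study.targets), digests

    if not (config.inputs and config.pathways_gmt and config.targets_tsv):
        raise DataError(
            "config needs either 'simulation' or all of 'inputs', "
            "'pathways_gmt' and 'targets_tsv'"
        )
    for name, paths in config.inputs.items():
        expr = read_expression(paths["expression"])
        labels = read_phenotype(paths["phenotype"])
        if labels.sample_ids and labels.sample_ids[0].startswith("s") and \
                set(labels.sample_ids) != set(expr.sample_ids):
            labels = attach_samples(labels, expr.sample_ids)
        contrasts[name] = (expr, labels)
        digests[f"expression_{name}"] = _digest(Path(paths["expression"]))
        digests[f"phenotype_{name}"] = _digest(Path(paths["phenotype"]))
    pathways = read_gmt(config.pathways_gmt)
    targets = read_target_map(config.targets_tsv)
    digests["pathways"] = _digest(Path(config.pathways_gmt))
    digests["targets"] = _digest(Path(config.targets_tsv))
    return contrasts, pathways, targets, digests


def run_all(config: RunConfig) -> CrossDiseaseReport:
    """Execute every stage in fixed order and write all artifacts."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    contrasts, pathways, targets, digests = _stage("load")(_load_inputs)(config)
    if len(contrasts) != 2:
        raise DataError(f"exactly two contrasts required, got {sorted(contrasts)}")

    processed: dict[str, tuple[ExpressionMatrix, PhenotypeLabels]] = {}
    for name, (expr, labels) in contrasts.items():
        norm, report = _stage("preprocess")(preprocess)(
            expr, pseudocount=config.pseudocount, quantile=config.quantile
        )
        labels = labels.reorder(norm.sample_ids)
        processed[name] = (norm, labels)
        write_expression(norm, outdir / f"expression_{name}.normalized.tsv")
        write_report(report, outdir / f"filter_report_{name}.json", format="json")
        log.info("[preprocess:%s] kept %d miRNAs x %d samples",
                 name, report.kept_mirnas, report.kept_samples)

    wm = _stage("weights")(build_weight_matrix)(
        targets, pathways, min_overlap=config.min_overlap
    )
    weight_table(wm).to_csv(outdir / "weights.tsv", sep="\t", index=False)

    enriched: dict[str, list[PathwayEnrichment]] = {}
    for name, (norm, labels) in sorted(processed.items()):
        res = _stage("enrich")(enrich)(
            norm,
            labels,
            wm,
            n_perm=config.n_perm,
            seed=config.seed,
            mode=config.mode,
            weight_exp=config.weight_exp,
            de_method=config.de_method,
            ranking=config.ranking,
            min_size=config.min_size,
            max_size=config.max_size,
            dem_fdr=config.dem_fdr,
        )
        enriched[name] = res
        write_report(res, outdir / f"enrichment_{name}.tsv")
        enrichment_to_json(res, outdir / f"enrichment_{name}.json")

    name_a, name_b = sorted(enriched)
    report = _stage("compare")(compare)(
        enriched[name_a],
        enriched[name_b],
        qmax=config.qmax,
        require_opposite=config.require_opposite,
        min_pathways=config.min_pathways,
        nes_bound=config.nes_bound,
        top_k_pathways=config.top_k_pathways,
        top_k_mirnas=config.top_k_mirnas,
    )
    sm = report.score_matrix
    if not sm.scores.empty:
        row_means, _ = mean_scores(sm)
        out = sm.scores.copy()
        out["Mean_Score"] = row_means
        write_report(out, outdir / "score_matrix.tsv")
        edge_list(sm).to_csv(outdir / "pathway_network_edges.tsv", sep="\t", index=False)
    write_report(report, outdir / "report.json", format="json")

    selected_mirnas = [m for m, _ in report.selected_mirnas]
    ptm = _stage("map-targets")(map_targets)(
        selected_mirnas, targets, pathways, report.selected_pathways
    )
    export_mapping(ptm, outdir / "target_mapping.tsv")

    manifest = {
        "package": "mirpathsea",
        "version": __version__,
        "seed": config.seed,
        "parameters": config.to_jsonable(),
        "input_digests": digests,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return report
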