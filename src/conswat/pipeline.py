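"""End-to-end pipeline: label -> featurize -> evaluate -> compare.

Each stage writes its TSV into the output directory; a JSON manifest
records the stages run, the configuration hash, the seed and the package
version so a report bundle is self-describing.  No stage mutates its
inputs, and identical configuration + seed yields byte-identical outputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from . import __version__
from .config import RunConfig
from .features import PropensityTable, featurize_model
from .labeling import label_waters, labeled_sites_frame
from .ml_eval import (
    combination_table,
    compare_models,
    best_model,
    evaluate_combinations,
    select_best_combination,
)
from .structure_io import StructureModel, parse_pdb, write_report


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


def _stage(name: str, inputs: str):
    class _ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage {name!r} failed on {inputs}: {exc}") from exc
            return False

    return _ctx()


def run_pipeline(
    reference: StructureModel | str | Path,
    homolog: StructureModel | str | Path,
    out_dir: str | Path,
    config: RunConfig | None = None,
    ligand_selector: str | None = None,
    propensities: PropensityTable | None = None,
) -> dict:
    """Label a homolog pair, featurize, and benchmark models on the result.

    Returns a manifest dict (also written to ``manifest.json``) listing the
    stages run and the produced files.  Structures may be given as parsed
    models or PDB paths (paths require *ligand_selector*).
    """
    config = config or RunConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table = propensities or PropensityTable.default_table()
    cfg_hash = config.content_hash()
    files: dict[str, str] = {}
    stages: list[str] = []

    with _stage("parse", str(reference)):
        if not isinstance(reference, StructureModel):
            reference = parse_pdb(reference, ligand_selector=ligand_selector)
        if not isinstance(homolog, StructureModel):
            homolog = parse_pdb(homolog, ligand_selector=None)

    with _stage("label", reference.structure_id):
        sites = label_waters(reference, homolog, config.labeling)
        labels = labeled_sites_frame(sites)
        labels.insert(0, "config_hash", cfg_hash)
        write_report(labels, out_dir / "labels.tsv", config.float_precision)
        files["labels"] = "labels.tsv"
        stages.append("label")

    with _stage("featurize", reference.structure_id):
        pocket_sites = [s for s in sites if s.in_pocket]
        feats = featurize_model(reference, sites=pocket_sites, table=table, config=config.features)
        feats.insert(0, "config_hash", cfg_hash)
        write_report(feats, out_dir / "features.tsv", config.float_precision)
        files["features"] = "features.tsv"
        stages.append("featurize")

    labeled = feats[feats["label"].isin(["CWM", "FWM"])]
    counts = labeled["label"].value_counts()
    can_cv = len(counts) == 2 and counts.min() >= 5

    if can_cv:
        with _stage("evaluate", reference.structure_id):
            reports = evaluate_combinations(labeled, seed=config.seed, families=config.families)
            winner, _ = select_best_combination(reports, tolerance=config.tolerance)
            table2 = combination_table(reports)
            table2.insert(0, "config_hash", cfg_hash)
            write_report(table2, out_dir / "combinations.tsv", config.float_precision)
            files["combinations"] = "combinations.tsv"
            stages.append("evaluate")

        with _stage("compare", reference.structure_id):
            comparison = compare_models(labeled, combination=winner, seed=config.seed, families=config.families)
            comparison.insert(0, "config_hash", cfg_hash)
            write_report(comparison, out_dir / "models.tsv", config.float_precision)
            files["models"] = "models.tsv"
            stages.append("compare")
            selected = best_model(comparison)
    else:
        winner = None
        selected = None

    manifest = {
        "config_hash": cfg_hash,
        "config": config.to_dict(),
        "seed": config.seed,
        "version": __version__,
        "stages": stages,
        "files": files,
        "best_combination": winner,
        "best_model": selected,
    }
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
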