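"""YAML-driven pipeline entry points used by the command line."""

from __future__ import annotations

import logging
import shutil
from pathlib import Path
from typing import Dict, Optional

import yaml

from .errors import CbcDelimError, ConfigError
from .model import CbcDelimitation, CbcDelimitationResults
from .simulate import (DeletionSpec, PlantedEvent, SimulationConfig,
                       TemplateParams, simulate_alignment, study_scale_config,
                       write_simulation)

logger = logging.getLogger(__name__)


def run_pipeline(config_path, outdir=None) -> CbcDelimitationResults:
    """Run analyse stages from a YAML config; write the report files.

    Config keys: ``alignment`` (aligned FASTA), ``structures`` (list of
    ``{vienna: path, region: label}``), optional ``tree`` (newick),
    optional ``template_id``, optional ``out`` (overridden by ``outdir``).
    On any stage error, partial outputs are removed and the error re-raised
    with the stage name.
    """
    config_path = Path(config_path)
    cfg = yaml.safe_load(config_path.read_text())
    if not isinstance(cfg, dict) or "alignment" not in cfg or "structures" not in cfg:
        raise ConfigError(f"{config_path}: config must define alignment and structures")
    base = config_path.parent

    def resolve(p):
        p = Path(p)
        return p if p.is_absolute() else base / p

    structures = [(resolve(s["vienna"]), s["region"]) for s in cfg["structures"]]
    out = Path(outdir) if outdir else (resolve(cfg["out"]) if "out" in cfg else None)

    stage = "input"
    try:
        model = CbcDelimitation.from_files(
            resolve(cfg["alignment"]), structures,
            tree_path=resolve(cfg["tree"]) if cfg.get("tree") else None,
            template_id=cfg.get("template_id"),
        )
        stage = "fit"
        logger.info("fitting: %d taxa, %d regions, tree=%s",
                    len(model.alignment), len(structures),
                    "yes" if model.tree is not None else "no")
        results = model.fit()
        if out is not None:
            stage = "write"
            results.save(out)
            logger.info("report written to %s", out)
    except CbcDelimError:
        if out is not None and out.exists() and stage == "write":
            shutil.rmtree(out, ignore_errors=True)
        logger.error("pipeline failed at stage %r", stage)
        raise
    return results


def simulate_command(config_path=None, outdir=None, preset_seed: Optional[int] = None):
    """Run the simulator from YAML (or the study-scale preset) and write files."""
    if preset_seed is not None:
        cfg = study_scale_config(preset_seed)
    else:
        raw = yaml.safe_load(Path(config_path).read_text())
        cfg = config_from_dict(raw)
    aln, tree, log = simulate_alignment(cfg)
    if outdir is not None:
        write_simulation(outdir, aln, tree, log)
    return aln, tree, log


def config_from_dict(raw: Dict) -> SimulationConfig:
    """Build a SimulationConfig from plain YAML data."""
    if not isinstance(raw, dict) or "seed" not in raw:
        raise ConfigError("simulation config must at least define a seed")
    regions = tuple(
        (label, TemplateParams(**params))
        for label, params in raw.get(
            "regions", {"ITS1": {}, "ITS2": {}}
        ).items()
    )
    planted = tuple(
        PlantedEvent(
            category=p["category"], region=p["region"],
            clade=frozenset(p["clade"]), count=p.get("count", 1),
            helix_label=p.get("helix"), pair_index=p.get("pair_index"),
        )
        for p in raw.get("planted", [])
    )
    deletions = tuple(
        DeletionSpec(region=d["region"], helix_label=d["helix"],
                     n_pairs=d["n_pairs"], taxa=frozenset(d["taxa"]))
        for d in raw.get("deletions", [])
    )
    return SimulationConfig(
        seed=int(raw["seed"]),
        n_taxa=int(raw.get("n_taxa", 8)),
        tree_shape=raw.get("tree_shape", "random-yule"),
        newick=raw.get("newick"),
        taxon_names=tuple(raw["taxon_names"]) if raw.get("taxon_names") else None,
        regions=regions, planted=planted, deletions=deletions,
        background_sub_rate=float(raw.get("background_sub_rate", 0.0)),
        spacer_len=int(raw.get("spacer_len", 12)),
    )
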