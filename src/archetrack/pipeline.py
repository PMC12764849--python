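"""End-to-end orchestration with provenance.

One configuration (YAML or dict) drives QC, log-normalization, ssGSEA
scoring, temporal modeling, archetype discovery on malignant cells, and the
ploidy-rescue classifier. Every output file is listed in a JSON manifest
with its SHA-256 content hash; re-running with the same config and seed
reproduces the hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from ._exceptions import ConfigError
from . import io as atio
from .archetypes import (
    ConsensusConfig,
    archetype_proportions,
    cluster_to_k,
    consensus_select_k,
    dpe_wilcoxon,
    reduce_svd,
    remove_batch_component,
)
from .classify import reclassify_undefined, train_reference_classifier
from .containers import QcConfig
from .preprocess import lognormalize, qc_filter
from .scoring import SsgseaConfig, ssgsea_scores
from .simulate import SimConfig, generate_cohort, write_cohort
from .temporal import fit_temporal_linear, volcano_table

logger = logging.getLogger(__name__)

STAGES = ("input", "qc", "score", "temporal", "archetypes", "classify")


@dataclass
class RunConfig:
    """Pipeline configuration; exactly one of ``input_paths``/``simulate``."""

    outdir: str = "archetrack_run"
    seed: int = 0
    input_paths: dict | None = None  # matrix, genes, cells, metadata, gene_sets
    simulate: dict | None = None  # SimConfig overrides
    qc: dict = field(default_factory=dict)
    ssgsea: dict = field(default_factory=dict)
    temporal: dict = field(default_factory=dict)
    consensus: dict = field(default_factory=dict)
    graph: dict = field(default_factory=dict)
    classifier: dict = field(default_factory=dict)
    batch_correct: bool = True

    def __post_init__(self) -> None:
        if (self.input_paths is None) == (self.simulate is None):
            raise ConfigError("exactly one of input_paths / simulate must be set")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_seed(seed: int, stage: str) -> int:
    child = np.random.SeedSequence(seed, spawn_key=(STAGES.index(stage),))
    return int(child.generate_state(1)[0] % (2**31))


def run_all(cfg: RunConfig) -> dict:
    """Execute the full workflow; returns the manifest dict.

    On a stage failure the exception is re-raised with the stage name and a
    partial manifest is still written.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg.seed, "stages": {}, "files": {}}
    manifest_path = out / "manifest.json"

    def record(stage: str, name: str, path: Path) -> None:
        manifest["files"][name] = {
            "path": str(path),
            "stage": stage,
            "sha256": _sha256(path),
        }

    stage = "input"
    try:
        if cfg.simulate is not None:
            sim_cfg = SimConfig(**{"seed": _stage_seed(cfg.seed, "input"), **cfg.simulate})
            bundle = generate_cohort(sim_cfg)
            expr, meta, gene_sets, _truth = bundle
            paths = write_cohort(bundle, out / "cohort", overwrite=True)
            for name, p in paths.items():
                record(stage, f"cohort/{name}", Path(p))
        else:
            ip = cfg.input_paths
            for key in ("matrix", "genes", "cells", "metadata", "gene_sets"):
                if key not in ip or not Path(ip[key]).exists():
                    raise ConfigError(f"input path {key!r} missing or nonexistent")
            expr = atio.read_counts(ip["matrix"], ip["genes"], ip["cells"])
            meta = atio.read_metadata(ip["metadata"])
            gene_sets = atio.read_gmt(ip["gene_sets"])
        manifest["stages"][stage] = "ok"

        stage = "qc"
        expr, meta, qc_report = qc_filter(expr, meta, QcConfig(**cfg.qc))
        (out / "qc_report.json").write_text(json.dumps(qc_report, indent=1))
        record(stage, "qc_report", out / "qc_report.json")
        lognorm = lognormalize(expr)
        manifest["stages"][stage] = "ok"

        stage = "score"
        scores = ssgsea_scores(lognorm, gene_sets, SsgseaConfig(**cfg.ssgsea))
        atio.write_table(
            scores.scores, out / "scores.tsv",
            header_lines=[f"seed={cfg.seed}", f"config={json.dumps(scores.config)}"],
            index=True,
        )
        record(stage, "scores", out / "scores.tsv")
        manifest["stages"][stage] = "ok"

        stage = "temporal"
        fits = fit_temporal_linear(scores, meta, **cfg.temporal)
        volcano = volcano_table(fits)
        atio.write_table(volcano, out / "temporal_pathways.tsv",
                         header_lines=[f"seed={cfg.seed}"])
        record(stage, "temporal_pathways", out / "temporal_pathways.tsv")
        manifest["stages"][stage] = "ok"

        stage = "classify"
        model = train_reference_classifier(
            lognorm, meta, seed=_stage_seed(cfg.seed, "classify"), **cfg.classifier
        )
        meta = reclassify_undefined(model, lognorm, meta)
        summary = {
            "cv_auc": model.cv_auc,
            "gate_threshold": model.gate_threshold,
            "accepted": model.accepted,
            "n_panel_genes": len(model.panel),
            "n_rescued": int(meta["ploidy_rescued"].sum()),
        }
        (out / "classifier.json").write_text(json.dumps(summary, indent=1))
        record(stage, "classifier", out / "classifier.json")
        atio.write_metadata(meta, out / "metadata_final.tsv")
        record(stage, "metadata_final", out / "metadata_final.tsv")
        manifest["stages"][stage] = "ok"

        stage = "archetypes"
        malignant = meta["ploidy"].eq("aneuploid").to_numpy()
        cancer_scores = scores.scores.loc[malignant]
        emb = reduce_svd(cancer_scores)
        patients = meta.loc[malignant, "patient"].to_numpy()
        if cfg.batch_correct and np.unique(patients).size > 1:
            emb = remove_batch_component(emb, patients)
        atio.write_table(emb.coordinates, out / "embedding.tsv", index=True,
                         header_lines=[f"removed_component={emb.removed_component_index}"])
        record(stage, "embedding", out / "embedding.tsv")

        consensus = consensus_select_k(
            emb, ConsensusConfig(**{"seed": _stage_seed(cfg.seed, "archetypes"),
                                    **cfg.consensus})
        )
        atio.write_table(consensus.as_frame(), out / "stability.tsv")
        record(stage, "stability", out / "stability.tsv")

        assignment = cluster_to_k(emb, consensus.selected_k, **cfg.graph)
        labels_df = assignment.labels.rename("archetype").rename_axis("cell_id").reset_index()
        atio.write_table(labels_df, out / "archetype_labels.tsv")
        record(stage, "archetype_labels", out / "archetype_labels.tsv")

        profiles = dpe_wilcoxon(scores.scores.loc[malignant], assignment.labels)
        atio.write_table(profiles, out / "archetype_profiles.tsv")
        record(stage, "archetype_profiles", out / "archetype_profiles.tsv")

        proportions = archetype_proportions(assignment.labels, meta)
        atio.write_table(proportions, out / "archetype_proportions.tsv")
        record(stage, "archetype_proportions", out / "archetype_proportions.tsv")
        manifest["stages"][stage] = "ok"
    except Exception as exc:
        manifest["stages"][stage] = f"failed: {exc}"
        manifest_path.write_text(json.dumps(manifest, indent=1))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest
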