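"""End-to-end orchestration: reduce -> describe -> featurize -> ROC -> classify.

One declarative :class:`RunConfig` (loadable from YAML/JSON) drives all
stages in fixed order.  Every stage writes its table into the output
directory and a single ``manifest.json`` records parameters, seeds,
scale names and row counts before/after each filter, so a run is fully
self-describing and reruns with the same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .classify import ClassifierSpec, evaluate_classifiers, write_reports
from .physchem import descriptor_table, write_descriptor_table
from .pseaac import PseAACConfig, featurize_dataset, write_feature_matrix
from .redundancy import greedy_reduce, write_cluster_table
from .roc_stats import ACCEPTABILITY_CUTOFF, feature_table_roc, write_roc_report
from .seq_io import LabeledDataset, ResiduePolicy, build_dataset, read_fasta, write_fasta
from .synthetic_data import SyntheticConfig, generate, write_manifest as _write_syn_manifest

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Declarative configuration of one full run."""

    fasta_a: str | None = None
    fasta_b: str | None = None
    label_a: str = "bacterial"
    label_b: str = "fungal"
    synthetic: SyntheticConfig | None = None
    residue_policy: str = "drop_record"
    redundancy_cutoff: float = 0.95
    skip_redundancy: bool = False
    pseaac_lambda: int = 5
    pseaac_weight: float = 0.05
    roc_accuracy_cutoff: float = ACCEPTABILITY_CUTOFF
    classifiers: list[ClassifierSpec] = field(
        default_factory=lambda: [
            ClassifierSpec("oet_knn"),
            ClassifierSpec("covariance_discriminant"),
            ClassifierSpec("svm"),
            ClassifierSpec("random_forest"),
        ]
    )
    cv_folds: int = 5
    seed: int = 17
    output_dir: str = "aspasep_run"

    def validate(self) -> None:
        from_files = self.fasta_a is not None and self.fasta_b is not None
        if not from_files and self.synthetic is None:
            raise ValueError("config needs either two FASTA paths or a synthetic block")
        if from_files:
            for p in (self.fasta_a, self.fasta_b):
                if not Path(p).exists():
                    raise FileNotFoundError(p)
        if self.label_a == self.label_b:
            raise ValueError("class labels must differ")


def load_run_config(path: str | Path) -> RunConfig:
    """Read a YAML (or JSON — a YAML subset) run configuration."""
    from .synthetic_data import ClassProfile

    raw = yaml.safe_load(Path(path).read_text()) or {}
    syn = raw.pop("synthetic", None)
    classifiers = raw.pop("classifiers", None)
    cfg = RunConfig(**raw)
    if syn is not None:
        profiles = [
            ClassProfile(**p) for p in (syn.pop("profile_a"), syn.pop("profile_b"))
        ]
        cfg.synthetic = SyntheticConfig(
            profile_a=profiles[0], profile_b=profiles[1], **syn
        )
    if classifiers is not None:
        cfg.classifiers = [
            ClassifierSpec(c["name"], c.get("params", {})) for c in classifiers
        ]
    return cfg


@dataclass
class RunReport:
    """Handles to everything a run produced."""

    output_dir: Path
    dataset: LabeledDataset
    descriptor_frame: pd.DataFrame
    pseaac_frame: pd.DataFrame
    descriptor_roc: list
    pseaac_roc: list
    classifier_reports: list
    manifest: dict


def _json_default(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run(config: RunConfig) -> RunReport:
    """Execute every stage in order and bundle the outputs."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "tool_version": __version__,
        "seed": config.seed,
        "residue_policy": config.residue_policy,
        "redundancy_cutoff": None if config.skip_redundancy else config.redundancy_cutoff,
        "pseaac": {"lambda": config.pseaac_lambda, "weight": config.pseaac_weight,
                   "scales": ["chou_hydrophobicity", "chou_hydrophilicity", "side_chain_mass"]},
        "roc_accuracy_cutoff": config.roc_accuracy_cutoff,
        "roc_accuracy_definition": "best single-threshold accuracy over both orientations",
        "cv_folds": config.cv_folds,
        "classifiers": [{"name": c.name, "params": c.params} for c in config.classifiers],
        "stages": {},
    }

    # -- input stage ------------------------------------------------------
    try:
        if config.synthetic is not None:
            dataset, syn_manifest = generate(config.synthetic)
            _write_syn_manifest(syn_manifest, outdir / "synthetic_manifest.json")
            groups = {
                name: list(dataset.subset(name)) for name in dataset.class_names
            }
            for name, records in groups.items():
                write_fasta(records, outdir / f"input_{name}.fasta")
            manifest["stages"]["input"] = {
                "source": "synthetic",
                "counts": dataset.counts,
            }
        else:
            a = read_fasta(config.fasta_a, label=config.label_a,
                           residue_policy=ResiduePolicy(config.residue_policy))
            b = read_fasta(config.fasta_b, label=config.label_b,
                           residue_policy=ResiduePolicy(config.residue_policy))
            dataset = build_dataset(a, b)
            groups = {config.label_a: a, config.label_b: b}
            manifest["stages"]["input"] = {
                "source": {"fasta_a": str(config.fasta_a), "fasta_b": str(config.fasta_b)},
                "counts": dataset.counts,
            }
    except Exception as exc:
        raise StageError("input", str(exc)) from exc

    # -- redundancy reduction (per class, as in the source workflow) ------
    try:
        if config.skip_redundancy:
            manifest["stages"]["redundancy"] = {"skipped": True}
        else:
            reduced = {}
            stage_info = {}
            for name, records in groups.items():
                reps, clusters = greedy_reduce(records, cutoff=config.redundancy_cutoff)
                write_fasta(reps, outdir / f"representatives_{name}.fasta")
                write_cluster_table(clusters, outdir / f"clusters_{name}.tsv")
                stage_info[name] = {"before": len(records), "after": len(reps)}
                reduced[name] = reps
            dataset = build_dataset(*reduced.values())
            manifest["stages"]["redundancy"] = {
                "cutoff": config.redundancy_cutoff, "counts": stage_info,
            }
    except Exception as exc:
        raise StageError("redundancy", str(exc)) from exc

    # -- physicochemical descriptors --------------------------------------
    try:
        desc = descriptor_table(dataset)
        write_descriptor_table(desc, outdir / "descriptors.tsv")
        manifest["stages"]["physchem"] = {"rows": len(desc)}
    except Exception as exc:
        raise StageError("physchem", str(exc)) from exc

    # -- PseAAC featurization ---------------------------------------------
    try:
        pcfg = PseAACConfig(lambda_=config.pseaac_lambda, weight=config.pseaac_weight,
                            on_short="drop")
        feats = featurize_dataset(dataset, pcfg)
        write_feature_matrix(feats, outdir / "pseaac.tsv", pcfg)
        manifest["stages"]["pseaac"] = {
            "rows": len(feats), "dropped_short": len(dataset) - len(feats),
            **pcfg.metadata(),
        }
    except Exception as exc:
        raise StageError("pseaac", str(exc)) from exc

    # -- per-feature ROC ---------------------------------------------------
    try:
        desc_roc = feature_table_roc(desc, accuracy_cutoff=config.roc_accuracy_cutoff)
        write_roc_report(desc_roc, outdir / "roc_descriptors.tsv",
                         outdir / "roc_descriptors.json",
                         accuracy_cutoff=config.roc_accuracy_cutoff)
        pse_roc = feature_table_roc(feats, accuracy_cutoff=config.roc_accuracy_cutoff)
        write_roc_report(pse_roc, outdir / "roc_pseaac.tsv", outdir / "roc_pseaac.json",
                         accuracy_cutoff=config.roc_accuracy_cutoff)
        manifest["stages"]["roc"] = {
            "descriptor_features": len(desc_roc),
            "descriptor_discriminative": [r.feature_name for r in desc_roc if r.discriminative],
            "pseaac_features": len(pse_roc),
        }
    except Exception as exc:
        raise StageError("roc", str(exc)) from exc

    # -- cross-validated classification -----------------------------------
    try:
        reports = evaluate_classifiers(
            feats, config.classifiers, folds=config.cv_folds, seed=config.seed
        )
        write_reports(reports, outdir / "classifiers.tsv", outdir / "classifiers.json")
        manifest["stages"]["classify"] = {
            r.classifier_name: {"acc": r.acc, "mcc": r.mcc} for r in reports
        }
    except Exception as exc:
        raise StageError("classify", str(exc)) from exc

    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=_json_default) + "\n"
    )
    return RunReport(
        output_dir=outdir,
        dataset=dataset,
        descriptor_frame=desc,
        pseaac_frame=feats,
        descriptor_roc=desc_roc,
        pseaac_roc=pse_roc,
        classifier_reports=reports,
        manifest=manifest,
    )
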