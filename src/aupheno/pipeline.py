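"""End-to-end orchestration: ingest -> QC -> features -> classifier ->
clinical validation -> report, with a run manifest for reproducibility.

Each stage writes its artifacts before the next starts, so stages are
independently re-runnable; the manifest records the config hash, the
master seed, per-file checksums and stage timestamps.  Two runs with the
same configuration and seed produce byte-identical stage outputs.
"""

from __future__ import annotations

import dataclasses
import glob
import hashlib
import json
import logging
import os
import time

import pandas as pd
import yaml

from . import ingest, simulate, validate
from .classify import CVConfig, NestedCVClassifier
from .features import FeatureMatrix, build_feature_matrix
from .report import plot_correlation_heatmap, render_report

log = logging.getLogger("aupheno")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")


@dataclasses.dataclass
class PipelineConfig:
    out_dir: str = "aupheno_out"
    input_dir: str | None = None
    simulate: bool = False
    seed: int = 0
    cohort: simulate.CohortConfig | None = None
    frame_confidence: float = ingest.DEFAULT_FRAME_CONFIDENCE
    valid_fraction: float = ingest.DEFAULT_VALID_FRACTION
    cv: CVConfig | None = None
    covariates: list[str] | None = None
    make_figures: bool = True
    overwrite: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.frame_confidence <= 1.0:
            raise ValueError("frame_confidence must be in (0, 1]")
        if not 0.0 < self.valid_fraction <= 1.0:
            raise ValueError("valid_fraction must be in (0, 1]")
        if self.cohort is None:
            self.cohort = simulate.CohortConfig(seed=self.seed)
        if self.cv is None:
            self.cv = CVConfig(seed=self.seed)

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        cohort = raw.pop("cohort", None)
        cv = raw.pop("cv", None)
        cfg = cls(**raw)
        if cohort:
            cfg.cohort = simulate.CohortConfig(seed=cfg.seed, **cohort)
        if cv:
            cfg.cv = CVConfig(seed=cfg.seed, **cv)
        return cfg

    def semantic_hash(self) -> str:
        """Config hash over analysis-relevant fields; paths excluded."""
        d = dataclasses.asdict(self)
        d.pop("out_dir")
        d.pop("input_dir")
        d["cohort"] = simulate.config_hash(self.cohort)
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclasses.dataclass
class RunManifest:
    config_hash: str
    seed: int
    stages: dict[str, dict] = dataclasses.field(default_factory=dict)
    checksums: dict[str, str] = dataclasses.field(default_factory=dict)
    failed_stage: str | None = None

    def record(self, stage: str, out_dir: str, files: list[str]) -> None:
        for rel in files:
            self.checksums[rel] = _sha256(os.path.join(out_dir, rel))
        self.stages[stage] = {"files": files, "completed_at": time.time()}

    def write(self, out_dir: str) -> None:
        payload = dataclasses.asdict(self)
        if self.failed_stage is not None:
            payload["status"] = "FAILED"
        with open(os.path.join(out_dir, "run_manifest.json"), "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)


def load_input(config: PipelineConfig) -> tuple[list, pd.DataFrame]:
    """Read OpenFace CSVs and the clinical table from the input directory."""
    root = config.input_dir
    clinical_path = os.path.join(root, "clinical.csv")
    if not os.path.exists(clinical_path):
        raise FileNotFoundError(f"clinical file not found: {clinical_path}")
    clinical = validate.read_clinical_csv(clinical_path)
    frames_dir = os.path.join(root, "frames")
    paths = sorted(glob.glob(os.path.join(frames_dir, "*.csv")))
    if not paths:
        raise FileNotFoundError(f"no frame CSVs under {frames_dir}")
    sequences = [ingest.read_openface_csv(p) for p in paths]
    return sequences, clinical


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Run every stage in order; abort (with FAILED marker) on error."""
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    manifest = RunManifest(config_hash=config.semantic_hash(), seed=config.seed)
    stage = "init"
    try:
        # --- simulate / ingest -------------------------------------------
        if config.simulate:
            stage = "simulate"
            cohort_dir = os.path.join(out, "cohort")
            cohort = simulate.generate_cohort(config.cohort)
            simulate.write_cohort(cohort, cohort_dir, config.cohort, overwrite=config.overwrite)
            sequences = [p.sequence for p in cohort]
            clinical = simulate.clinical_frame(cohort)
            log.info("stage=simulate participants=%d", len(cohort))
            manifest.record(
                stage, out, ["cohort/manifest.json", "cohort/clinical.csv"]
            )
        else:
            stage = "ingest"
            if not config.input_dir:
                raise ValueError("input_dir required when simulate=False")
            sequences, clinical = load_input(config)
            log.info("stage=ingest participants=%d", len(sequences))

        # --- QC -----------------------------------------------------------
        stage = "qc"
        filtered, entries = [], []
        for seq in sequences:
            f, e = ingest.filter_low_confidence(seq, config.frame_confidence)
            filtered.append(f)
            entries.append(e)
        qc = ingest.assess_validity(entries, config.valid_fraction)
        qc.to_frame().to_csv(os.path.join(out, "qc_report.csv"), index=False)
        kept = [s for s in filtered if s.participant_id not in set(qc.excluded)]
        pose = ingest.pose_nuisance_correlations(kept)
        pose.to_csv(os.path.join(out, "pose_nuisance.csv"), index=False)
        log.info("stage=qc excluded=%d", len(qc.excluded))
        manifest.record(stage, out, ["qc_report.csv", "pose_nuisance.csv"])

        # --- features -----------------------------------------------------
        stage = "features"
        labels = clinical.set_index("id")["group"]
        matrix = build_feature_matrix(filtered, qc, labels)
        matrix.to_csv(os.path.join(out, "features.csv"))
        log.info("stage=features rows=%d cols=%d", *matrix.X.shape)
        manifest.record(stage, out, ["features.csv"])

        # --- classifier ---------------------------------------------------
        stage = "classify"
        clf = NestedCVClassifier(matrix, config.cv)
        results = clf.fit()
        if config.cv.n_permutations > 0:
            clf.permutation_test(results)
        results.to_json(os.path.join(out, "cv_summary.json"))
        results.metrics_frame.to_csv(os.path.join(out, "fold_results.csv"), index=False)
        results.selection_frequencies().to_csv(os.path.join(out, "selection_frequencies.csv"))
        log.info(
            "stage=classify folds=%d permutations=%d",
            len(results.fold_results),
            0 if results.permutation is None else results.permutation.n_permutations,
        )
        manifest.record(
            stage, out, ["cv_summary.json", "fold_results.csv", "selection_frequencies.csv"]
        )

        # --- clinical validation -----------------------------------------
        stage = "validate"
        val = validate.ExpressivityValidation(matrix, clinical).fit(config.covariates)
        val_files = []
        vdir = os.path.join(out, "validation")
        os.makedirs(vdir, exist_ok=True)
        val.primary.to_csv(os.path.join(vdir, "primary.csv"), index=False)
        validate.correlation_table_wide(val.primary).to_csv(os.path.join(vdir, "primary_wide_r.csv"))
        val_files += ["validation/primary.csv", "validation/primary_wide_r.csv"]
        for name, fam in val.exploratory.items():
            rel = f"validation/exploratory_{name}.csv"
            fam.to_csv(os.path.join(out, rel), index=False)
            val_files.append(rel)
        val.group_tests.to_csv(os.path.join(vdir, "group_tests.csv"), index=False)
        val_files.append("validation/group_tests.csv")
        if val.ap is not None:
            val.ap["stage1"].to_csv(os.path.join(vdir, "ap_stage1.csv"), index=False)
            val.ap["stage2"].to_csv(os.path.join(vdir, "ap_stage2.csv"), index=False)
            val_files += ["validation/ap_stage1.csv", "validation/ap_stage2.csv"]
        n_tests = val.primary.attrs["family_size"] + sum(
            f.attrs["family_size"] for f in val.exploratory.values()
        )
        log.info("stage=validate corrected_tests=%d", n_tests)
        manifest.record(stage, out, val_files)

        # --- report -------------------------------------------------------
        stage = "report"
        fig_files = []
        if config.make_figures:
            fdir = os.path.join(out, "figures")
            os.makedirs(fdir, exist_ok=True)
            plot_correlation_heatmap(
                val.primary, os.path.join(fdir, "primary_heatmap.png"), "AU metrics vs facial affect"
            )
            fig_files.append("figures/primary_heatmap.png")
        render_report(
            {
                "qc": {"report": qc, "frame_threshold": config.frame_confidence},
                "cv_results": results,
                "validation": val,
            },
            out,
        )
        log.info("stage=report sections=5")
        manifest.record(stage, out, ["report.md", "report.json"] + fig_files)
    except Exception as exc:
        manifest.failed_stage = stage
        manifest.write(out)
        if isinstance(exc, (PipelineError, FileNotFoundError)):
            raise
        raise PipelineError(stage, str(exc)) from exc

    manifest.write(out)
    return manifest
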