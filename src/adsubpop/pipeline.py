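"""End-to-end pipeline orchestration and reporting.

Runs simulate → preprocess → embed+cluster → profile → mine → overlay in a
fixed order with a single master seed, writing every intermediate artifact
and a consolidated machine-readable report.  Per-stage seeds are derived
deterministically from the master seed so one integer reproduces the whole
run, labels and rules included.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering, embedding, profiles, rules
from .cohort import CohortTable, load_cohort, preprocess
from .lexicon import DrugLexicon
from .synthetic import SyntheticSpec, generate_cohort, generate_medications

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "cluster", "profile", "mine")


@dataclass
class PipelineConfig:
    """Everything a run needs; round-trips losslessly through YAML."""

    cohort_csv: str | None = None          # None -> simulate
    medication_csv: str | None = None
    out_dir: str = "out"
    seed: int = 0
    # preprocessing
    diagnosis_filter: list[str] = field(default_factory=lambda: ["AD"])
    missingness_threshold: float = 0.20
    knn_k: int = 5
    deskew_enabled: bool = True
    exclude_features: list[str] = field(default_factory=list)
    # embedding + clustering
    reduce: str = "tsne"                   # {"none", "pca", "tsne"}
    clusterer: str = "kmeans"              # {"kmeans", "dbscan"}
    k: int | None = None                   # None -> use selected_k
    k_range: list[int] = field(default_factory=lambda: [2, 12])
    perplexity: float = 30.0
    tsne_iters: int = 1000
    dbscan_eps: float = 0.5
    dbscan_min_samples: int = 5
    # profiling
    alpha: float = 0.05
    top_n_features: int = 10
    # mining
    mining_enabled: bool = True
    min_support: float = 0.001
    min_confidence: float = 0.7
    min_lift: float = 1.0
    synthetic: dict = field(default_factory=dict)  # SyntheticSpec overrides

    def validate(self) -> None:
        if self.reduce not in ("none", "pca", "tsne"):
            raise ValueError(f"unknown reduce {self.reduce!r}")
        if self.clusterer not in ("kmeans", "dbscan"):
            raise ValueError(f"unknown clusterer {self.clusterer!r}")
        if len(self.k_range) != 2 or self.k_range[0] > self.k_range[1]:
            raise ValueError(f"invalid k_range {self.k_range}")
        if self.k_range[0] < 2:
            raise ValueError("k_range minimum must be >= 2")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.__dict__, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**data)
        cfg.validate()
        return cfg


@dataclass
class RunReport:
    """Consolidated record of one pipeline run."""

    config: dict
    stages: list[dict] = field(default_factory=list)
    quality: dict | None = None
    severity: dict | None = None
    orderings: dict | None = None
    overlay: dict | None = None
    warnings: list[str] = field(default_factory=list)
    n_rules: int | None = None
    selected_k: int | None = None

    def add_stage(self, name: str, seconds: float, **info) -> None:
        self.stages.append({"stage": name, "seconds": round(seconds, 3), **info})

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "stages": self.stages,
            "selected_k": self.selected_k,
            "quality": self.quality,
            "severity": self.severity,
            "severity_orderings": self.orderings,
            "n_rules": self.n_rules,
            "overlay": self.overlay,
            "warnings": self.warnings,
        }


def stage_seeds(master_seed: int, n: int = len(STAGES)) -> dict[str, int]:
    """Derive one independent 31-bit seed per stage from the master seed."""
    ss = np.random.SeedSequence(master_seed)
    children = ss.generate_state(n) % (2**31)
    return dict(zip(STAGES, (int(c) for c in children)))


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig) -> RunReport:
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    report = RunReport(config=dict(config.__dict__))

    class _Capture(logging.Handler):
        def emit(self, record):
            if record.levelno >= logging.WARNING:
                report.warnings.append(record.getMessage())
    capture = _Capture()
    logging.getLogger("adsubpop").addHandler(capture)

    try:
        # -- simulate / load ---------------------------------------------
        t0 = time.perf_counter()
        stage = "simulate"
        try:
            if config.cohort_csv is None:
                spec = SyntheticSpec(**config.synthetic) if config.synthetic \
                    else SyntheticSpec()
                cohort, truth = generate_cohort(spec, seed=seeds["simulate"])
                med_log = generate_medications(truth, spec, seed=seeds["simulate"])
                cohort.to_csv(out / "cohort.csv")
                med_log.to_csv(out / "medications.csv", index=False)
                (out / "truth.json").write_text(json.dumps({
                    "subpop": {p: int(s) for p, s
                               in zip(truth.patient_ids, truth.subpop)},
                    "diagnosis": dict(zip(truth.patient_ids, truth.diagnosis)),
                }, indent=1))
                (out / "synthetic_spec.yaml").write_text(
                    yaml.safe_dump(spec.to_dict(), sort_keys=True))
            else:
                cohort = load_cohort(config.cohort_csv)
                med_log = (pd.read_csv(config.medication_csv, dtype=str)
                           if config.medication_csv else None)
                truth = None
            report.add_stage(stage, time.perf_counter() - t0,
                             n_rows=cohort.n_rows)
        except Exception as e:
            raise StageError(stage, e)

        # -- preprocess ---------------------------------------------------
        t0 = time.perf_counter()
        stage = "preprocess"
        try:
            filtered = cohort
            if config.diagnosis_filter:
                from .cohort import filter_diagnosis
                filtered = filter_diagnosis(cohort, config.diagnosis_filter)
            matrix, prep = preprocess(
                filtered,
                missingness_threshold=config.missingness_threshold,
                knn_k=config.knn_k, deskew_enabled=config.deskew_enabled,
                exclude_features=config.exclude_features)
            matrix.to_csv(out / "analysis_matrix.csv", index=False)
            (out / "preprocess_report.json").write_text(
                json.dumps(prep.to_dict(), indent=1))
            report.add_stage(stage, time.perf_counter() - t0,
                             n_features=matrix.shape[1],
                             n_imputed=prep.n_imputed_cells)
        except Exception as e:
            raise StageError(stage, e)

        # -- embed + cluster ---------------------------------------------
        t0 = time.perf_counter()
        stage = "cluster"
        try:
            emb_cfg = embedding.EmbeddingConfig(
                method=config.reduce, perplexity=config.perplexity,
                tsne_iters=config.tsne_iters, seed=seeds["cluster"])
            emb = embedding.reduce_matrix(matrix.to_numpy(), emb_cfg)
            coords = emb.coords
            pd.DataFrame(coords, columns=[f"dim{i+1}" for i
                                          in range(coords.shape[1])]
                         ).to_csv(out / "embedding.csv", index=False)
            if config.clusterer == "kmeans":
                quality = clustering.select_k(
                    coords, range(config.k_range[0], config.k_range[1] + 1),
                    seeds=[seeds["cluster"]])
                k = config.k or quality.selected_k
                fit = clustering.kmeans(coords, k, seed=seeds["cluster"])
                report.quality = quality.to_dict()
                report.selected_k = quality.selected_k
            else:
                fit = clustering.dbscan(coords, eps=config.dbscan_eps,
                                        min_samples=config.dbscan_min_samples)
                report.selected_k = fit.k
            labels = fit.labels
            pd.DataFrame({"PTID": filtered.frame["PTID"],
                          "VISCODE": filtered.frame.get("VISCODE", "bl"),
                          "cluster": labels}).to_csv(out / "labels.csv",
                                                     index=False)
            if report.quality is not None:
                (out / "quality.json").write_text(json.dumps(report.quality,
                                                             indent=1))
            report.add_stage(stage, time.perf_counter() - t0, k=int(fit.k))
        except Exception as e:
            raise StageError(stage, e)

        # -- profile ------------------------------------------------------
        t0 = time.perf_counter()
        stage = "profile"
        try:
            raw = filtered.frame.copy()
            cont = [s.name for s in filtered.feature_specs
                    if s.kind == "continuous" and s.name in matrix.columns]
            from .cohort import strip_inequalities
            for cname in cont:
                raw[cname] = [strip_inequalities(v)[0] for v in raw[cname]]
            fold = profiles.FoldChangeTable.compute(
                raw, labels, filtered.feature_specs, features=cont)
            tests = []
            for f in cont:
                vals = raw[f].to_numpy(dtype=float)
                for c in sorted(set(int(x) for x in labels if x >= 0)):
                    try:
                        r = profiles.cluster_feature_ttest(vals, labels, c)
                    except ValueError as err:
                        # e.g. a tiny cluster with <2 observed values
                        logger.warning("profile: skipping %s / cluster %s (%s)",
                                       f, c, err)
                        continue
                    r.feature = f
                    tests.append(r)
            profiles.familywise_adjust(tests, alpha=config.alpha)
            axis_feats = {s.name for s in filtered.feature_specs
                          if s.group in ("cognition", "volume")}
            axis_fold = profiles.FoldChangeTable(
                fold.entries[fold.entries["feature"].isin(axis_feats)]
                .reset_index(drop=True))
            summary = profiles.severity_summary(axis_fold,
                                                filtered.feature_specs)
            orders = profiles.rank_clusters(summary)
            fold.entries.to_csv(out / "fold_changes.csv", index=False)
            (out / "severity.json").write_text(json.dumps(
                {"summary": summary.to_dict(), "orderings": orders}, indent=1))
            report.severity = summary.to_dict()
            report.orderings = orders
            report.add_stage(stage, time.perf_counter() - t0,
                             n_tests=len(tests))
        except Exception as e:
            raise StageError(stage, e)

        # -- mine + overlay ----------------------------------------------
        if config.mining_enabled and med_log is not None:
            t0 = time.perf_counter()
            stage = "mine"
            try:
                label_frame = pd.DataFrame({
                    "PTID": filtered.frame["PTID"],
                    "VISCODE": filtered.frame.get("VISCODE", "bl"),
                    "DX": filtered.frame["DX"],
                    "cluster": labels,
                })
                keep = set(map(tuple,
                               label_frame[["PTID", "VISCODE"]]
                               .itertuples(index=False)))
                med_kept = med_log[[
                    (p, v) in keep for p, v in
                    zip(med_log["PTID"], med_log["VISCODE"])]]
                transactions = rules.build_transactions(med_kept, label_frame,
                                                        DrugLexicon())
                itemsets, mined = rules.mine(
                    transactions, min_support=config.min_support,
                    min_confidence=config.min_confidence,
                    min_lift=config.min_lift)
                overlay = rules.overlay_clusters(mined, transactions)
                rules.itemsets_frame(itemsets).to_csv(out / "itemsets.csv",
                                                      index=False)
                rules.rules_frame(mined).to_csv(out / "rules.csv", index=False)
                (out / "overlay.json").write_text(
                    json.dumps(overlay.to_dict(), indent=1))
                report.n_rules = len(mined)
                report.overlay = overlay.to_dict()
                report.add_stage(stage, time.perf_counter() - t0,
                                 n_rules=len(mined))
            except Exception as e:
                raise StageError(stage, e)
    finally:
        logging.getLogger("adsubpop").removeHandler(capture)

    (out / "run_report.json").write_text(render_report(report)[1])
    return report


def render_report(report: RunReport) -> tuple[str, str]:
    """Render a run report as (human-readable text, machine JSON).

    Rendering is deterministic: the same report yields identical bytes.
    """
    data = report.to_dict()
    machine = json.dumps(data, indent=1, sort_keys=True, default=str)

    lines = ["== run summary =="]
    if report.selected_k is not None:
        lines.append(f"selected number of clusters: {report.selected_k}")
    if report.severity:
        lines.append("severity summary (direction-standardized mean fold "
                     "change %, positive = less severe):")
        for c in report.severity["clusters"]:
            cog = report.severity["cognition"][c]
            vol = report.severity["volume"][c]
            lines.append(f"  cluster {c}: cognition {cog['mean']:+.1f} "
                         f"± {cog['sd']:.1f}, volume {vol['mean']:+.1f} "
                         f"± {vol['sd']:.1f}")
    if report.orderings:
        lines.append(f"severity order (combined mean, least→most severe): "
                     f"{report.orderings['combined_mean']}")
        lines.append(f"severity order (volume-weighted): "
                     f"{report.orderings['volume_weighted']}")
    if report.overlay is not None:
        lines.append(f"association rules passing thresholds: {report.n_rules}")
        for c, val in report.overlay.items():
            if isinstance(val, str):
                lines.append(f"  cluster {c}: no associated substances")
            else:
                ants = sorted({r['antecedent'] for r in val})
                lines.append(f"  cluster {c}: {', '.join(ants)}")
    if report.warnings:
        lines.append(f"warnings: {len(report.warnings)}")
    return "\n".join(lines) + "\n", machine
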