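"""End-to-end orchestration: QC -> normalization -> differential signal
-> trends -> tissue signatures -> risk model -> performance report.

``run_pipeline`` runs every stage on either file inputs named in the
:class:`~cfrna.io.AnalysisConfig` or a synthetic cohort simulated from a
:class:`~cfrna.simulate.SimulationDesign`, writes TSV tables plus a JSON
run manifest (seed, config hash, thresholds used) to the output
directory, and is deterministic given the seed. Stages that lack their
inputs (no QC metric table, no reference atlas, a single cohort) are
skipped with a logged notice rather than failing the run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classifier as clf
from . import degs, metrics, normalize, profiles, qc, simulate, trends
from .io import (
    ANTENATAL_WINDOWS,
    AnalysisConfig,
    CountMatrix,
    OUTCOME_PE,
    WINDOWS,
    read_counts,
    read_metadata,
)

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineResult:
    """In-memory view of everything the pipeline wrote to disk."""

    qc_table: pd.DataFrame | None
    normalized: CountMatrix
    kept_genes: pd.Index
    deg_table: pd.DataFrame
    fold_changes: pd.DataFrame
    trend_model: trends.TrendModel | None
    enrichment: pd.DataFrame | None
    trajectories: pd.DataFrame | None
    model: clf.ClassifierModel | None
    predictions: pd.DataFrame | None
    performance: dict | None
    manifest: dict = field(default_factory=dict)


def _demo_design(seed: int) -> simulate.SimulationDesign:
    # scaled-down two-cohort demo so an end-to-end run stays interactive
    return simulate.SimulationDesign(
        cohorts={"discovery": (24, 12), "validation": (14, 7)},
        n_genes=1500,
        seed=seed,
    )


def run_pipeline(
    config: AnalysisConfig,
    design: simulate.SimulationDesign | None = None,
) -> PipelineResult:
    """Run every analysis stage and write the result bundle to disk."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "stages": {},
        "skipped": [],
    }

    # ---- inputs ---------------------------------------------------------
    stage = "inputs"
    try:
        truth = None
        qc_metrics = None
        atlas = None
        if config.counts_path:
            cm = read_counts(config.counts_path)
            meta = read_metadata(config.metadata_path, counts=cm)
            if config.atlas_path:
                atlas = profiles.read_atlas(config.atlas_path)
        else:
            if design is None:
                design = _demo_design(config.seed)
            cm, meta, truth = simulate.simulate_cohort(design)
            qc_metrics, _ = simulate.simulate_qc_tables(design)
            atlas, _ = simulate.simulate_reference_atlas(
                planted=truth.category_profiles,
                background_noise=0.05,
                seed=design.seed,
            )
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    # ---- QC -------------------------------------------------------------
    stage = "qc"
    qc_table = None
    try:
        if qc_metrics is not None:
            records = [
                qc.QCRecord(
                    sample_id=r["sample_id"],
                    degradation_fraction=r["degradation_fraction"],
                    reads_assigned=int(r["reads_assigned"]),
                    intron_exon_ratio=r["intron_exon_ratio"],
                )
                for _, r in qc_metrics.iterrows()
            ]
            flagged = qc.flag_outliers(records, percentile=config.qc_percentile)
            qc_table = qc.records_to_frame(flagged)
            qc_table.to_csv(out / "qc_table.tsv", sep="\t", index=False)
            outlier_ids = set(qc_table.loc[qc_table["outlier"], "sample_id"])
            keep = ~meta["sample_id"].isin(outlier_ids)
            manifest["stages"]["qc"] = {
                "n_outliers": int(len(outlier_ids)),
                "percentile": config.qc_percentile,
            }
            meta = meta[keep].reset_index(drop=True)
            cm = cm.subset(samples=meta["sample_id"].tolist())
        else:
            manifest["skipped"].append("qc: no per-sample metric table supplied")
            logger.info("QC metric table absent; skipping outlier exclusion")
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    # ---- normalization --------------------------------------------------
    stage = "normalization"
    try:
        discovery = meta["cohort"].iloc[0]
        disc_samples = meta.loc[meta["cohort"] == discovery, "sample_id"]
        kept = normalize.filter_genes(
            cm, disc_samples, min_cpm=config.min_cpm,
            min_fraction=config.min_detect_fraction,
        )
        cm = cm.subset(genes=kept)
        factors = normalize.tmm_factors(
            cm, trim_m=config.tmm_trim_m, trim_a=config.tmm_trim_a
        )
        cm = normalize.logcpm(cm, factors, prior_count=config.prior_count)
        batch = meta.set_index("sample_id")["batch"]
        adjusted = normalize.regress_out_batch(cm.logcpm, batch)
        cm = CountMatrix(counts=cm.counts, logcpm=adjusted)
        factors.to_frame().to_csv(out / "normalization_factors.tsv", sep="\t", index=False)
        pd.Series(kept, name="gene").to_csv(out / "kept_genes.tsv", sep="\t", index=False)
        manifest["stages"]["normalization"] = {
            "n_genes_kept": int(len(kept)),
            "min_cpm": config.min_cpm,
            "min_detect_fraction": config.min_detect_fraction,
        }
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    # ---- differential signal -------------------------------------------
    stage = "differential"
    try:
        disc_meta = meta[meta["cohort"] == discovery]
        early = _early_first_samples(disc_meta, config.ga_max_predict)
        early_meta = disc_meta.set_index("sample_id").loc[early]
        pe = early[(early_meta["outcome"] == OUTCOME_PE).to_numpy()]
        nt = early[(early_meta["outcome"] != OUTCOME_PE).to_numpy()]
        deg_table = degs.rank_test_degs(
            cm.logcpm, pe, nt, alternative="two-sided", alpha=config.bh_alpha
        )
        fold_changes = degs.window_fold_changes(
            cm.logcpm, disc_meta, WINDOWS,
            n_boot=config.n_boot, level=config.boot_level, seed=config.seed,
        )
        deg_table.rename_axis("gene").to_csv(out / "deg_table.tsv", sep="\t")
        fold_changes.to_csv(out / "fold_changes.tsv", sep="\t", index=False)
        manifest["stages"]["differential"] = {
            "n_significant": int(deg_table["significant"].sum()),
            "bh_alpha": config.bh_alpha,
        }
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    # ---- longitudinal trends -------------------------------------------
    stage = "trends"
    trend_model = None
    try:
        sig = deg_table.index[deg_table["significant"]]
        fc_mat = fold_changes.pivot(index="gene", columns="window", values="log2fc")
        fc_mat = fc_mat.reindex(columns=[w for w in WINDOWS if w in fc_mat.columns])
        fc_mat = fc_mat.loc[fc_mat.index.intersection(sig)]
        if len(fc_mat.dropna()) >= 2:
            trend_model = trends.fit_trends(
                fc_mat, k_max=config.k_max, seed=config.seed, n_boot=config.n_boot
            )
            trend_model.assignments.rename_axis("gene").to_csv(
                out / "trend_assignments.tsv", sep="\t"
            )
            trend_model.cluster_profiles.to_csv(
                out / "trend_profiles.tsv", sep="\t", index=False
            )
            manifest["stages"]["trends"] = {"k": trend_model.k}
        else:
            manifest["skipped"].append("trends: fewer than 2 significant genes")
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    # ---- profiles, enrichment, signatures ------------------------------
    stage = "signatures"
    enrichment = trajectories = None
    try:
        if atlas is not None:
            prof = profiles.build_tissue_profiles(atlas, gini_cut=config.tissue_gini_cut)
            prof.to_csv(out / "profile_reference.tsv", sep="\t", index=False)
            sig = deg_table.index[deg_table["significant"]]
            enrichment = profiles.enrichment_test(
                sig, prof, universe=cm.genes, alpha=config.bh_alpha
            )
            enrichment.to_csv(out / "enrichment.tsv", sep="\t", index=False)
            scores = profiles.signature_scores(
                cm.logcpm, prof, meta, min_genes=config.min_profile_genes
            )
            trajectories = profiles.signature_trajectories(
                scores, n_boot=config.n_boot, seed=config.seed
            )
            scores.to_csv(out / "signature_scores.tsv", sep="\t", index=False)
            trajectories.to_csv(out / "signature_trajectories.tsv", sep="\t", index=False)
            manifest["stages"]["signatures"] = {
                "n_profile_genes": int(len(prof)),
                "n_categories_scored": int(trajectories["category"].nunique()),
            }
        else:
            manifest["skipped"].append("signatures: no reference atlas supplied")
            logger.info("reference atlas absent; enrichment/signature stages skipped")
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    # ---- risk classifier ------------------------------------------------
    stage = "classifier"
    model = predictions = performance = None
    try:
        candidates = deg_table.index[deg_table["significant"]].tolist()
        if candidates:
            scheme = clf.fit_normalization(
                cm.logcpm,
                meta.set_index("sample_id")["cohort"],
                discovery,
                deg_table["bh_adjusted_p"],
                control_adj_p=config.control_adj_p,
            )
            normalized = clf.apply_normalization(
                scheme, cm.logcpm, meta.set_index("sample_id")["cohort"]
            )
            early_disc = _early_first_samples(disc_meta, config.ga_max_predict)
            x_disc = normalized[early_disc].T
            y = meta.set_index("sample_id")["outcome"].eq(OUTCOME_PE)
            parts = meta.set_index("sample_id")["participant_id"]
            model = clf.train(
                x_disc, y.loc[early_disc], parts.loc[early_disc], candidates,
                seed=config.seed,
            )
            clf.tune_threshold(
                model, x_disc, y.loc[early_disc],
                fpr_target=config.fpr_target, grain=config.threshold_grain,
            )
            other = meta[meta["cohort"] != discovery]
            eval_meta = other if len(other) else disc_meta
            eval_samples = _early_first_samples(eval_meta, config.ga_max_predict)
            predictions = clf.predict(model, normalized[eval_samples].T, meta)
            predictions["truth"] = y.loc[predictions["sample_id"]].to_numpy()
            predictions["ga_collection"] = (
                meta.set_index("sample_id")
                .loc[predictions["sample_id"], "ga_collection"].to_numpy()
            )
            predictions.to_csv(out / "predictions.tsv", sep="\t", index=False)
            _write_model(model, scheme, out / "model.json")
            manifest["stages"]["classifier"] = {
                "n_panel_genes": len(model.panel),
                "threshold": model.threshold,
                "hyperparameters": model.hyperparameters,
            }

            cmx = metrics.ConfusionMatrix.from_labels(
                predictions["truth"], predictions["predicted"]
            )
            perf = metrics.confusion_metrics(cmx)
            auc = metrics.auroc(predictions["probability"], predictions["truth"])
            performance = {
                name: m.__dict__ for name, m in {**perf, "AUROC": auc}.items()
            }
            with open(out / "performance.json", "w") as fh:
                json.dump(performance, fh, indent=1)
        else:
            manifest["skipped"].append("classifier: no significant candidate genes")
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    manifest_path = out / "run_manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    logger.info("pipeline complete; manifest at %s", manifest_path)
    return PipelineResult(
        qc_table=qc_table,
        normalized=cm,
        kept_genes=cm.genes,
        deg_table=deg_table,
        fold_changes=fold_changes,
        trend_model=trend_model,
        enrichment=enrichment,
        trajectories=trajectories,
        model=model,
        predictions=predictions,
        performance=performance,
        manifest=manifest,
    )


def _early_first_samples(meta: pd.DataFrame, ga_max: float) -> pd.Index:
    """Earliest eligible sample (ga in [5, ga_max], antenatal) per participant."""
    sub = meta[
        (~meta["postpartum"])
        & (meta["ga_collection"] >= clf.GA_MIN)
        & (meta["ga_collection"] <= ga_max)
    ]
    sub = sub.sort_values(["participant_id", "ga_collection", "sample_id"])
    return pd.Index(sub.groupby("participant_id").head(1)["sample_id"].tolist())


def _write_model(model: clf.ClassifierModel, scheme: clf.NormalizationScheme, path) -> None:
    payload = {
        "genes": model.genes,
        "coefficients": model.coefficients.to_dict(),
        "intercept": float(model.estimator.intercept_[0]),
        "hyperparameters": model.hyperparameters,
        "threshold": model.threshold,
        "seed": model.seed,
        "control_genes": scheme.control_genes,
        "scale": scheme.scale.to_dict(),
        "center": {c: scheme.center[c].to_dict() for c in scheme.center.columns},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)
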