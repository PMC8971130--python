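"""Early-gestation preeclampsia risk model.

The model consumes samples collected between 5 and 16 weeks of
gestation. Its bespoke normalization mimics RT-qPCR practice: per-gene
centering by the cohort median logCPM, scaling by the discovery-cohort
interquartile range, then a per-sample shift by the median normalized
value of internal-control (housekeeping) genes — genes whose levels do
not change between outcomes (differential-stage adjusted p > 0.99) —
excluding controls with raw logCPM of 0 (likely technical dropout).

Feature pre-selection keeps candidate genes by fold-change magnitude and
stability (|log2FC| >= fc_cut, CV <= cv_cut, both measured on the 80%
discovery split), and an elastic-net logistic regression is tuned by
5-fold grouped, stratified cross-validated AUROC on the 80% split; the
selected hyperparameter point maximizes the worse of the 80%-split CV
AUROC and the 20%-split AUROC. The probability threshold is then tuned
on the full discovery cohort at a 10% false-positive-rate target and
rounded to the nearest 0.05; a sample is called at risk when
P(PE) >= threshold.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedGroupKFold

from .degs import bootstrap_fold_change
from .io import ValidationError

logger = logging.getLogger(__name__)

FC_CUT_GRID = (0.0, 0.25, 0.5, 0.75, 1.0)
CV_CUT_GRID = (0.25, 0.5, 0.75, 1.0)
C_GRID = tuple(np.logspace(-2, 3, 6))
L1_RATIO_GRID = (0.1, 0.5, 0.9)

GA_MIN, GA_MAX = 5.0, 16.0


@dataclass
class NormalizationScheme:
    """Centering/scaling parameters and the internal-control gene set."""

    center: pd.DataFrame  # genes x cohorts: per-cohort median logCPM
    scale: pd.Series  # gene -> discovery IQR (zero-IQR genes dropped)
    control_genes: list[str]

    def __post_init__(self) -> None:
        if (self.scale <= 0).any():
            raise ValidationError("scheme retains zero-IQR genes")
        missing = set(self.control_genes) - set(self.scale.index)
        if missing:
            raise ValidationError(f"control genes outside analysis universe: {sorted(missing)}")


def fit_normalization(
    logcpm: pd.DataFrame,
    cohorts: pd.Series,
    discovery_cohort: str,
    adj_p: pd.Series,
    control_adj_p: float = 0.99,
) -> NormalizationScheme:
    """Fit per-cohort centering, discovery-IQR scaling and the control set.

    ``cohorts`` maps sample -> cohort label; ``adj_p`` carries the
    differential-stage BH-adjusted p per gene (controls are genes with
    adjusted p > ``control_adj_p``).
    """
    cohorts = cohorts.loc[logcpm.columns]
    if discovery_cohort not in set(cohorts):
        raise ValidationError(f"discovery cohort {discovery_cohort!r} absent")
    center = pd.DataFrame(
        {c: logcpm.loc[:, (cohorts == c).to_numpy()].median(axis=1)
         for c in pd.unique(cohorts)}
    )
    disc = logcpm.loc[:, (cohorts == discovery_cohort).to_numpy()]
    q75 = disc.quantile(0.75, axis=1)
    q25 = disc.quantile(0.25, axis=1)
    scale = q75 - q25
    kept = scale[scale > 0].index
    dropped = len(scale) - len(kept)
    if dropped:
        logger.info("dropped %d zero-IQR gene(s) from the normalization scheme", dropped)
    controls = [
        g for g in kept
        if g in adj_p.index and np.isfinite(adj_p[g]) and adj_p[g] > control_adj_p
    ]
    if not controls:
        raise ValidationError(
            "no gene passes the internal-control criterion (adjusted p > "
            f"{control_adj_p}); the dataset must contain null genes"
        )
    return NormalizationScheme(
        center=center.loc[kept], scale=scale.loc[kept], control_genes=controls
    )


def apply_normalization(
    scheme: NormalizationScheme, logcpm: pd.DataFrame, cohorts: pd.Series
) -> pd.DataFrame:
    """Centre, scale and control-shift a logCPM matrix (genes x samples).

    Controls with raw logCPM exactly 0 in a sample are excluded from that
    sample's median shift; if every control is 0 the sample is left
    unshifted with a warning.
    """
    cohorts = cohorts.loc[logcpm.columns]
    unknown = set(cohorts) - set(scheme.center.columns)
    if unknown:
        raise ValidationError(f"cohort(s) without fitted centering: {sorted(unknown)}")
    genes = scheme.scale.index
    x = logcpm.loc[genes]
    centered = x.sub(scheme.center.loc[genes, cohorts].to_numpy(), axis=0)
    normalized = centered.div(scheme.scale, axis=0)
    ctrl = [g for g in scheme.control_genes if g in normalized.index]
    raw_ctrl = logcpm.loc[ctrl]
    norm_ctrl = normalized.loc[ctrl]
    shifts = []
    for s in normalized.columns:
        usable = raw_ctrl[s] != 0
        if not usable.any():
            logger.warning("sample %s: all control genes have 0 logCPM; no shift applied", s)
            shifts.append(0.0)
        else:
            shifts.append(float(norm_ctrl.loc[usable.to_numpy(), s].median()))
    return normalized.sub(pd.Series(shifts, index=normalized.columns), axis=1)


def preselect_features(
    fc_records: pd.DataFrame, fc_cut: float, cv_cut: float
) -> pd.Index:
    """Genes with |log2FC| >= fc_cut and defined CV <= cv_cut."""
    ok = (
        (fc_records["log2fc"].abs() >= fc_cut)
        & fc_records["cv"].notna()
        & (fc_records["cv"] <= cv_cut)
    )
    return fc_records.index[ok]


@dataclass
class ClassifierModel:
    """Fitted elastic-net logistic model plus its tuned decision rule."""

    genes: list[str]
    estimator: LogisticRegression
    hyperparameters: dict
    threshold: float | None = None
    seed: int = 0
    grid_scores: pd.DataFrame = field(default_factory=pd.DataFrame, repr=False)

    @property
    def coefficients(self) -> pd.Series:
        return pd.Series(self.estimator.coef_.ravel(), index=self.genes)

    @property
    def panel(self) -> list[str]:
        """Genes with nonzero coefficient in the fitted model."""
        coef = self.coefficients
        return coef.index[coef != 0].tolist()

    def predict_proba(self, x: pd.DataFrame) -> pd.Series:
        """P(case) for samples x genes input (genes reindexed to the model)."""
        mat = x.reindex(columns=self.genes)
        if mat.isna().any().any():
            raise ValidationError("input missing model genes")
        return pd.Series(
            self.estimator.predict_proba(mat.to_numpy())[:, 1], index=x.index
        )


def _split_participants(
    participants: pd.Series, y: pd.Series, train_fraction: float, rng
) -> tuple[np.ndarray, np.ndarray]:
    """80/20 participant-level split, stratified by outcome."""
    by_part = pd.DataFrame({"participant": participants, "y": y}).groupby(
        "participant"
    )["y"].any()
    train_parts: list = []
    for label in (False, True):
        parts = by_part.index[by_part == label].to_numpy()
        rng.shuffle(parts)
        n_train = max(1, int(round(train_fraction * len(parts))))
        train_parts.extend(parts[:n_train])
    in_train = participants.isin(train_parts).to_numpy()
    return in_train, ~in_train


def split_fold_changes(
    x: pd.DataFrame,
    y: pd.Series,
    participants: pd.Series,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Fold change and CV per gene over a sample split (samples x genes).

    One sample per participant is not re-enforced here: callers pass
    early-gestation matrices where each participant's earliest eligible
    sample has already been chosen.
    """
    logcpm_like = x.T  # genes x samples
    pe = x.index[y.to_numpy()]
    nt = x.index[~y.to_numpy()]
    return bootstrap_fold_change(logcpm_like, pe, nt, n_boot=n_boot, seed=seed)


def train(
    x: pd.DataFrame,
    y: pd.Series,
    participants: pd.Series,
    candidate_genes,
    seed: int = 0,
    fc_cut_grid=FC_CUT_GRID,
    cv_cut_grid=CV_CUT_GRID,
    c_grid=C_GRID,
    l1_ratio_grid=L1_RATIO_GRID,
    n_folds: int = 5,
    n_boot: int = 200,
    train_fraction: float = 0.8,
) -> ClassifierModel:
    """Tune and fit the elastic-net logistic risk model on discovery data.

    ``x`` is samples x genes (bespoke-normalized logCPM, early-gestation
    samples only); ``participants`` keeps repeat samples of one mother on
    the same side of every split. The discovery cohort is split 80/20 by
    participant; fold-change/CV pre-selection cuts, penalty strength and
    mixing ratio are tuned by 5-fold grouped stratified CV AUROC on the
    80% split, and the hyperparameter point maximizing
    min(CV AUROC, 20%-split AUROC) wins. The returned estimator is the
    winning model fitted on the 80% split (no refit on full discovery).
    """
    candidate_genes = [g for g in candidate_genes if g in x.columns]
    if not candidate_genes:
        raise ValidationError("no candidate gene present in the feature matrix")
    y = y.loc[x.index].astype(bool)
    participants = participants.loc[x.index]
    rng = np.random.default_rng(seed)
    in_train, in_sel = _split_participants(participants, y, train_fraction, rng)
    if y[in_train].nunique() < 2 or y[in_sel].nunique() < 2:
        raise ValidationError("both outcome classes required in each split")
    x80, y80 = x.loc[in_train, candidate_genes], y[in_train]
    x20, y20 = x.loc[in_sel, candidate_genes], y[in_sel]
    groups80 = participants[in_train]

    fc80 = split_fold_changes(x80, y80, groups80, n_boot=n_boot, seed=seed)
    gene_sets: dict[tuple, list[str]] = {}
    for fc_cut in fc_cut_grid:
        for cv_cut in cv_cut_grid:
            genes = preselect_features(fc80, fc_cut, cv_cut).tolist()
            if genes:  # an empty set is an invalid hyperparameter point
                gene_sets[(fc_cut, cv_cut)] = genes

    if not gene_sets:
        raise ValidationError("every pre-selection cut produced an empty gene set")

    n_folds_eff = min(n_folds, int(y80.sum()), int((~y80).sum()))
    cv = StratifiedGroupKFold(n_splits=n_folds_eff, shuffle=True, random_state=seed)

    # evaluate each distinct gene set once per (C, l1_ratio)
    results = []
    cache: dict[tuple, tuple[float, float, LogisticRegression]] = {}
    for (fc_cut, cv_cut), genes in gene_sets.items():
        key_genes = tuple(sorted(genes))
        for c in c_grid:
            for l1 in l1_ratio_grid:
                cache_key = (key_genes, c, l1)
                if cache_key not in cache:
                    xg = x80[genes].to_numpy()
                    aucs = []
                    for tr, te in cv.split(xg, y80, groups=groups80):
                        if y80.iloc[te].nunique() < 2:
                            continue
                        est = _make_estimator(c, l1, seed)
                        est.fit(xg[tr], y80.iloc[tr])
                        aucs.append(
                            roc_auc_score(y80.iloc[te], est.predict_proba(xg[te])[:, 1])
                        )
                    cv_auc = float(np.mean(aucs)) if aucs else float("nan")
                    est = _make_estimator(c, l1, seed)
                    est.fit(xg, y80)
                    sel_auc = float(
                        roc_auc_score(y20, est.predict_proba(x20[genes].to_numpy())[:, 1])
                    )
                    cache[cache_key] = (cv_auc, sel_auc, est)
                cv_auc, sel_auc, est = cache[cache_key]
                results.append(
                    {
                        "fc_cut": fc_cut,
                        "cv_cut": cv_cut,
                        "C": c,
                        "l1_ratio": l1,
                        "n_genes": len(genes),
                        "cv_auroc": cv_auc,
                        "selection_auroc": sel_auc,
                        "score": min(cv_auc, sel_auc),
                        "_genes": genes,
                        "_est": est,
                    }
                )
    grid = pd.DataFrame(results)
    # ties on the selection score are resolved toward the larger gene set:
    # a broader panel is more robust to single-gene dropout
    best_score = grid["score"].max()
    tied = grid[grid["score"] >= best_score - 1e-9]
    best = tied.loc[tied["n_genes"].idxmax()]
    model = ClassifierModel(
        genes=list(best["_genes"]),
        estimator=best["_est"],
        hyperparameters={
            "fc_cut": float(best["fc_cut"]),
            "cv_cut": float(best["cv_cut"]),
            "C": float(best["C"]),
            "l1_ratio": float(best["l1_ratio"]),
            "cv_auroc": float(best["cv_auroc"]),
            "selection_auroc": float(best["selection_auroc"]),
        },
        seed=seed,
        grid_scores=grid.drop(columns=["_genes", "_est"]),
    )
    return model


def _make_estimator(c: float, l1_ratio: float, seed: int) -> LogisticRegression:
    # elastic net: l1_ratio in (0, 1) with the saga solver
    return LogisticRegression(
        solver="saga",
        C=c,
        l1_ratio=l1_ratio,
        max_iter=2000,
        tol=1e-3,
        random_state=seed,
    )


def round_threshold(value: float, grain: float = 0.05) -> float:
    """Round a probability threshold to the nearest multiple of ``grain``.

    Halves round away from zero (0.425 -> 0.45 at grain 0.05); the result
    is reported at the grain's precision, e.g. 0.37 -> 0.35.
    """
    steps = round(value / grain, 9)
    rounded = math.floor(steps + 0.5) * grain
    decimals = max(0, -int(math.floor(math.log10(grain))) + 1)
    return round(rounded, decimals)


def tune_threshold(
    model: ClassifierModel,
    x: pd.DataFrame,
    y: pd.Series,
    fpr_target: float = 0.10,
    grain: float = 0.05,
) -> float:
    """Tune the at-risk probability threshold at an FPR target.

    From the ROC over the full discovery predictions, the smallest
    threshold with FPR <= target is taken (maximizing sensitivity under
    the constraint) and rounded to the nearest ``grain``. If no threshold
    attains the target, the one with FPR closest from above is used with
    a warning. The classification rule is positive iff P(case) >= threshold.
    """
    probs = model.predict_proba(x)
    y = y.loc[x.index].astype(bool)
    fpr, _, thresholds = roc_curve(y, probs)
    ok = fpr <= fpr_target
    if ok.any():
        raw = float(thresholds[ok][-1])  # largest admissible FPR -> smallest threshold
    else:
        raw = float(thresholds[int(np.argmin(fpr - fpr_target))])
        logger.warning("no threshold attains FPR <= %.2f; using closest from above",
                       fpr_target)
    raw = min(max(raw, 0.0), 1.0)
    threshold = round_threshold(raw, grain)
    model.threshold = threshold
    return threshold


def predict(
    model: ClassifierModel,
    x: pd.DataFrame,
    meta: pd.DataFrame | None = None,
    ga_range: tuple[float, float] = (GA_MIN, GA_MAX),
) -> pd.DataFrame:
    """Per-sample risk probabilities and threshold calls (5-16 week samples).

    When ``meta`` is provided, samples outside the gestational window are
    excluded with a notice. Returns sample_id, probability, predicted
    (P >= threshold) and, with metadata, the participant for aggregation.
    """
    if model.threshold is None:
        raise ValidationError("threshold not tuned; call tune_threshold first")
    idx = x.index
    part = None
    if meta is not None:
        m = meta.set_index("sample_id").loc[idx.intersection(meta["sample_id"])]
        in_window = (m["ga_collection"] >= ga_range[0]) & (
            m["ga_collection"] <= ga_range[1]
        ) & ~m["postpartum"]
        excluded = int((~in_window).sum())
        if excluded:
            logger.info("excluded %d sample(s) outside %.0f-%.0f weeks", excluded,
                        *ga_range)
        idx = m.index[in_window.to_numpy()]
        part = m.loc[idx, "participant_id"]
    probs = model.predict_proba(x.loc[idx])
    out = pd.DataFrame(
        {
            "sample_id": idx,
            "probability": probs.to_numpy(),
            "predicted": (probs >= model.threshold).to_numpy(),
        }
    )
    if part is not None:
        out["participant_id"] = part.to_numpy()
    return out


def aggregate_by_participant(predictions: pd.DataFrame) -> pd.DataFrame:
    """Participant-level call: maximum probability across eligible samples."""
    if "participant_id" not in predictions.columns:
        raise ValidationError("predictions lack participant_id")
    agg = predictions.groupby("participant_id").agg(
        probability=("probability", "max"), predicted=("predicted", "any")
    )
    return agg.reset_index()


def feature_subset_sweep(
    panel: list[str],
    x_train: pd.DataFrame,
    y_train: pd.Series,
    groups_train: pd.Series,
    x_test: pd.DataFrame,
    y_test: pd.Series,
    n_per_size: int = 3,
    sizes=None,
    seed: int = 0,
    c_grid=C_GRID,
    l1_ratio_grid=L1_RATIO_GRID,
    n_folds: int = 5,
) -> pd.DataFrame:
    """Retrain on sampled gene subsets and report test AUROC per subset.

    For each subset size a seeded sampler draws ``n_per_size`` subsets
    (the full panel is always included); hyperparameters (C, l1_ratio)
    are re-tuned by grouped stratified CV on the training data, no
    pre-selection. A subset is flagged weakly predictive when its test
    AUROC exceeds 0.5.
    """
    if not panel:
        raise ValidationError("empty gene panel")
    rng = np.random.default_rng(seed)
    sizes = sizes if sizes is not None else range(1, len(panel) + 1)
    subsets: list[tuple[str, ...]] = []
    for size in sizes:
        if size == len(panel):
            subsets.append(tuple(panel))
            continue
        seen = set()
        for _ in range(n_per_size):
            sub = tuple(sorted(rng.choice(panel, size=size, replace=False)))
            if sub not in seen:
                seen.add(sub)
                subsets.append(sub)
    n_folds_eff = min(n_folds, int(y_train.sum()), int((~y_train).sum()))
    cv = StratifiedGroupKFold(n_splits=n_folds_eff, shuffle=True, random_state=seed)
    rows = []
    for sub in subsets:
        genes = list(sub)
        xg = x_train[genes].to_numpy()
        best_auc, best_params = -np.inf, None
        for c in c_grid:
            for l1 in l1_ratio_grid:
                aucs = []
                for tr, te in cv.split(xg, y_train, groups=groups_train):
                    if y_train.iloc[te].nunique() < 2:
                        continue
                    est = _make_estimator(c, l1, seed)
                    est.fit(xg[tr], y_train.iloc[tr])
                    aucs.append(
                        roc_auc_score(y_train.iloc[te], est.predict_proba(xg[te])[:, 1])
                    )
                if aucs and np.mean(aucs) > best_auc:
                    best_auc, best_params = float(np.mean(aucs)), (c, l1)
        est = _make_estimator(*best_params, seed)
        est.fit(xg, y_train)
        test_auc = float(
            roc_auc_score(y_test, est.predict_proba(x_test[genes].to_numpy())[:, 1])
        )
        rows.append(
            {
                "n_genes": len(genes),
                "genes": ";".join(genes),
                "cv_auroc": best_auc,
                "test_auroc": test_auc,
                "weakly_predictive": test_auc > 0.5,
            }
        )
    return pd.DataFrame(rows)
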