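"""Longitudinal trend clustering of per-window fold-change profiles.

Each differential gene is summarized as a vector of per-window log2 fold
changes (N genes x 4 time points). k-means clustering over k = 1..16
groups genes by longitudinal shape; the cluster count is picked at the
knee of the inertia curve (discrete kneedle on the convex decreasing
curve), with near-ties resolved toward the simpler model. A within-gene
column-permutation control scrambles time structure while preserving the
marginal distribution; real longitudinal trends flatten under it.

Also hosts the heatmap-segregation analysis: for one collection window,
genes passing fold-change and stability cuts are z-scored and samples
hierarchically clustered (average linkage, Euclidean); cutting the
sample tree into two clusters yields a label-free case/control split
whose sensitivity and specificity are reported.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans

from .io import OUTCOME_NT, OUTCOME_PE, WINDOW_MID, ValidationError
from .degs import first_sample_per_participant

logger = logging.getLogger(__name__)


@dataclass
class TrendModel:
    """k-means trend assignment over per-window fold-change profiles."""

    assignments: pd.Series  # gene -> cluster label (0-based)
    k: int
    inertia: dict[int, float]  # candidate k -> within-cluster sum of squares
    cluster_profiles: pd.DataFrame  # cluster, window, median, ci_low, ci_high
    seed: int


def select_k(inertia: dict[int, float] | list[float], sensitivity: float = 1.0,
             near_tie: float = 0.01) -> int:
    """Discrete kneedle knee of a convex decreasing inertia curve.

    Near-ties (relative inertia difference below ``near_tie``) are
    resolved toward smaller k — the simpler model. A curve with no knee
    (e.g. linear decay) falls back to the smallest k allowed by the
    near-tie rule.
    """
    if isinstance(inertia, dict):
        ks = sorted(inertia)
        y = np.array([inertia[k] for k in ks], dtype=float)
    else:
        y = np.asarray(inertia, dtype=float)
        ks = list(range(1, len(y) + 1))
    if len(ks) < 3:
        raise ValidationError("need >= 3 candidate k values")
    if np.any(np.diff(y) > 1e-12 * max(1.0, np.abs(y).max())):
        warnings.warn("inertia curve not nonincreasing; smoothing with running minimum")
        y = np.minimum.accumulate(y)
    if y[0] - y[-1] <= 0:
        k_sel = ks[0]
    else:
        x_n = (np.array(ks, dtype=float) - ks[0]) / (ks[-1] - ks[0])
        y_n = (y - y[-1]) / (y[0] - y[-1])
        y_diff = (1.0 - y_n) - x_n
        threshold = sensitivity * np.mean(np.diff(x_n))
        if y_diff.max() > threshold:
            k_sel = ks[int(np.argmax(y_diff))]
        else:
            k_sel = ks[0]
    # prefer a simpler model when the inertia gain is negligible
    pos = ks.index(k_sel)
    while pos > 0:
        lo, hi = y[pos - 1], y[pos]
        denom = abs(lo) if lo != 0 else 1.0
        if (lo - hi) / denom < near_tie:
            pos -= 1
        else:
            break
    return ks[pos]


def _cluster_summary(
    mat: pd.DataFrame, labels: np.ndarray, n_boot: int, level: float, rng
) -> pd.DataFrame:
    rows = []
    alpha = (1.0 - level) / 2.0
    for c in np.unique(labels):
        sub = mat.to_numpy(dtype=float)[labels == c]
        med = np.median(sub, axis=0)
        if sub.shape[0] > 1:
            idx = rng.integers(0, sub.shape[0], size=(n_boot, sub.shape[0]))
            boot = np.median(sub[idx], axis=1)  # n_boot x windows
            lo = np.quantile(boot, alpha, axis=0)
            hi = np.quantile(boot, 1.0 - alpha, axis=0)
        else:
            lo = hi = med
        for j, w in enumerate(mat.columns):
            rows.append(
                {"cluster": int(c), "window": w, "median_log2fc": med[j],
                 "ci_low": lo[j], "ci_high": hi[j]}
            )
    return pd.DataFrame(rows)


def fit_trends(
    fc_matrix: pd.DataFrame,
    k_max: int = 16,
    seed: int = 0,
    n_restarts: int = 25,
    k_override: int | None = None,
    n_boot: int = 1000,
    ci_level: float = 0.95,
) -> TrendModel:
    """Cluster genes by longitudinal fold-change shape.

    ``fc_matrix`` is genes x windows; rows with any missing value are
    dropped with a notice. k-means runs with ``n_restarts`` restarts for
    each k up to ``k_max``; the knee of the inertia curve picks k unless
    ``k_override`` is given (mirrors a visual override of the locator).
    Cluster medians per window carry a bootstrap CI over genes.
    """
    mat = fc_matrix.dropna(axis=0)
    dropped = len(fc_matrix) - len(mat)
    if dropped:
        logger.warning("dropped %d gene(s) with undefined window fold changes", dropped)
    if len(mat) < 2:
        raise ValidationError("need >= 2 genes with complete profiles")
    mat = mat.sort_index()  # assignment invariant to input gene order
    k_hi = min(k_max, len(mat))
    x = mat.to_numpy(dtype=float)
    inertia: dict[int, float] = {}
    fits: dict[int, np.ndarray] = {}
    for k in range(1, k_hi + 1):
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
        labels = km.fit_predict(x)
        inertia[k] = float(km.inertia_)
        fits[k] = labels
    k_sel = k_override if k_override is not None else select_k(inertia)
    labels = fits[k_sel]
    rng = np.random.default_rng(seed)
    profiles = _cluster_summary(mat, labels, n_boot=n_boot, level=ci_level, rng=rng)
    return TrendModel(
        assignments=pd.Series(labels, index=mat.index, name="cluster"),
        k=k_sel,
        inertia=inertia,
        cluster_profiles=profiles,
        seed=seed,
    )


@dataclass
class PermutationControl:
    model: TrendModel
    observed_range: pd.Series  # per-cluster cross-window range of the unpermuted fit
    permuted_range: pd.Series  # per-cluster cross-window range after permutation


def permutation_control(
    fc_matrix: pd.DataFrame, seed: int = 0, **fit_kwargs
) -> PermutationControl:
    """Refit trends after independently permuting each gene's window values.

    Permutation scrambles time structure while preserving each gene's
    marginal fold-change distribution. The flatness summary holds the
    unpermuted gene-to-cluster assignment fixed and recomputes per-cluster
    per-window medians on the permuted values: genuine longitudinal trends
    collapse to nearly flat profiles. (A k-means refit on permuted data is
    also returned for inspection, but refitting rediscovers artifact
    clusters — rows grouped by where their large values happened to land —
    so the refit medians are not the flatness yardstick.)
    """
    rng = np.random.default_rng(seed)
    mat = fc_matrix.dropna(axis=0)
    observed = fit_trends(mat, seed=seed, **fit_kwargs)
    permuted_values = rng.permuted(mat.to_numpy(dtype=float), axis=1)
    permuted = pd.DataFrame(permuted_values, index=mat.index, columns=mat.columns)
    model = fit_trends(permuted, seed=seed, **fit_kwargs)

    def _ranges(m: pd.DataFrame, labels: np.ndarray) -> pd.Series:
        out = {}
        for c in np.unique(labels):
            med = np.median(m.to_numpy(dtype=float)[labels == c], axis=0)
            out[int(c)] = float(med.max() - med.min())
        return pd.Series(out)

    labels = observed.assignments.loc[mat.sort_index().index].to_numpy()
    sorted_obs = mat.sort_index()
    sorted_perm = permuted.loc[sorted_obs.index]
    return PermutationControl(
        model=model,
        observed_range=_ranges(sorted_obs, labels),
        permuted_range=_ranges(sorted_perm, labels),
    )


@dataclass
class SegregationResult:
    genes: pd.Index
    cv_cut_used: float
    sample_linkage: np.ndarray
    gene_linkage: np.ndarray
    cluster_labels: pd.Series  # sample -> {1, 2}
    pe_cluster: int
    sensitivity: float
    specificity: float


def heatmap_segregation(
    logcpm: pd.DataFrame,
    meta: pd.DataFrame,
    window: str,
    fc_records: pd.DataFrame,
    fc_cut: float = 1.0,
    cv_cut: float | None = None,
) -> SegregationResult:
    """Two-cluster sample segregation on stable, large-fold-change genes.

    Gene selection: |log2FC| >= ``fc_cut`` and CV < ``cv_cut`` within the
    window (default cut 0.4 for the 13-20 week window, 0.5 otherwise).
    The gene count is kept at or below the window's sample count by
    tightening the CV cut in 0.05 steps. Samples are clustered on
    per-gene z-scores (average linkage, Euclidean) and the tree cut at
    two clusters; the majority-case cluster is called the case cluster
    and the split's sensitivity/specificity against outcome reported.
    """
    if cv_cut is None:
        cv_cut = 0.4 if window == WINDOW_MID else 0.5
    chosen = first_sample_per_participant(meta, window)
    if len(chosen) < 4:
        raise ValidationError("too few samples in window")
    rec = fc_records[fc_records["window"] == window].set_index("gene")

    def _select(cut: float) -> pd.Index:
        ok = (rec["log2fc"].abs() >= fc_cut) & (rec["cv"] < cut) & rec["cv"].notna()
        return rec.index[ok]

    genes = _select(cv_cut)
    while len(genes) > len(chosen) and cv_cut > 0.05:
        cv_cut = round(cv_cut - 0.05, 10)
        genes = _select(cv_cut)
    if len(genes) < 2:
        raise ValidationError("fewer than 2 genes pass the thresholds")
    x = logcpm.loc[genes, chosen].to_numpy(dtype=float)
    sd = x.std(axis=1, ddof=0)
    if np.all(sd == 0):
        raise ValidationError("all selected genes constant across samples")
    sd[sd == 0] = 1.0
    z = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
    sample_link = hierarchy.linkage(pdist(z.T, metric="euclidean"), method="average")
    gene_link = hierarchy.linkage(pdist(z, metric="euclidean"), method="average")
    labels = hierarchy.fcluster(sample_link, t=2, criterion="maxclust")
    labels = pd.Series(labels, index=chosen, name="cluster")
    outcome = meta.set_index("sample_id").loc[chosen, "outcome"]
    is_pe = (outcome == OUTCOME_PE).to_numpy()
    pe_frac = {c: is_pe[(labels == c).to_numpy()].mean() for c in (1, 2)}
    pe_cluster = max(pe_frac, key=pe_frac.get)
    pred_pe = (labels == pe_cluster).to_numpy()
    tp = int(np.sum(pred_pe & is_pe))
    fn = int(np.sum(~pred_pe & is_pe))
    tn = int(np.sum(~pred_pe & ~is_pe))
    fp = int(np.sum(pred_pe & ~is_pe))
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    return SegregationResult(
        genes=genes,
        cv_cut_used=cv_cut,
        sample_linkage=sample_link,
        gene_linkage=gene_link,
        cluster_labels=labels,
        pe_cluster=int(pe_cluster),
        sensitivity=sens,
        specificity=spec,
    )
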