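"""Gini-based tissue / cell-type gene profiles, enrichment tests and
relative signature scores.

A gene's specificity across a reference atlas (categories x mean
expression) is measured with the Gini coefficient

    G(x) = sum_ij |x_i - x_j| / (2 * T * sum_i x_i)

which is 0 for uniform expression and (T-1)/T for a one-hot vector over
T categories. A gene is assigned to the category of its maximum
expression when its Gini passes the source cutoff (0.6 for tissue
atlases, 0.8 for cell-type atlases). A "strict" tissue reference
additionally requires an enriched/enhanced annotation, guaranteeing
single-category specificity for trajectory tracking.

Differential gene sets are tested for category enrichment with a
one-sided hypergeometric test over the profile-annotated universe, and
per-sample signature scores are sums of logCPM over profile genes,
anchored to each participant's post-partum sample and scaled by the
category's interquartile range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import OUTCOME_PE, WINDOW_POSTPARTUM, ValidationError

logger = logging.getLogger(__name__)

SOURCE_TISSUE = "tissue-atlas"
SOURCE_CELL = "cell-atlas"
SOURCE_INDIVIDUAL = "individual-atlas"

PROFILE_COLUMNS = ("gene", "category", "gini", "source", "strict")


def read_atlas(path) -> pd.DataFrame:
    """Read a long-format reference atlas TSV (category, gene, mean_expression).

    Returns a genes x categories mean-expression matrix. An optional
    ``annotation`` column (HPA-style enriched/enhanced labels) is ignored
    here; read it separately for strict-mode profile building.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"category", "gene", "mean_expression"}
    if not required.issubset(df.columns):
        raise ValidationError(f"atlas needs columns {sorted(required)}")
    return df.pivot_table(
        index="gene", columns="category", values="mean_expression", fill_value=0.0
    )


def write_atlas(atlas: pd.DataFrame, path) -> None:
    """Write a genes x categories matrix as the long-format atlas TSV."""
    long = atlas.stack().rename("mean_expression").reset_index()
    long.columns = ["gene", "category", "mean_expression"]
    long[["category", "gene", "mean_expression"]].to_csv(path, sep="\t", index=False)


def gini_coefficient(x) -> float:
    """Gini inequality of a nonnegative expression vector across categories.

    Raises on negative entries; an all-zero vector is undefined and
    raises. Scale-invariant: G(c*x) = G(x) for any c > 0.
    """
    x = np.asarray(x, dtype=float)
    if (x < 0).any():
        raise ValidationError("expression values must be nonnegative")
    total = x.sum()
    if total == 0:
        raise ValidationError("all-zero expression vector: Gini undefined")
    t = x.size
    # mean absolute difference via the sorted-vector identity
    xs = np.sort(x)
    i = np.arange(1, t + 1)
    mad_sum = 2.0 * np.sum((2 * i - t - 1) * xs)  # == sum_ij |x_i - x_j|
    g = mad_sum / (2.0 * t * total)
    return 0.0 if abs(g) < 1e-12 else float(g)  # snap accumulation dust


def gini_per_gene(atlas: pd.DataFrame) -> pd.Series:
    """Gini of each gene (row) across atlas categories (columns)."""
    x = atlas.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValidationError("atlas expression must be nonnegative")
    t = x.shape[1]
    xs = np.sort(x, axis=1)
    i = np.arange(1, t + 1)
    mad_sum = 2.0 * (xs * (2 * i - t - 1)).sum(axis=1)
    total = x.sum(axis=1)
    out = np.full(x.shape[0], np.nan)
    nz = total > 0
    g = mad_sum[nz] / (2.0 * t * total[nz])
    out[nz] = np.where(np.abs(g) < 1e-12, 0.0, g)
    return pd.Series(out, index=atlas.index, name="gini")


def build_tissue_profiles(
    atlas: pd.DataFrame,
    gini_cut: float = 0.6,
    strict: bool = False,
    annotation: pd.Series | None = None,
) -> pd.DataFrame:
    """Assign genes to tissues: Gini >= cut and maximum expression in that tissue.

    ``atlas`` is genes x tissues (mean expression). In strict mode a gene
    must additionally carry a 'Tissue-enriched' or 'Tissue-enhanced'
    annotation (``annotation``: gene -> label), which restricts the
    reference to single-tissue genes.
    """
    if atlas.shape[1] < 2:
        raise ValidationError("atlas needs >= 2 categories")
    if strict and annotation is None:
        raise ValidationError("strict mode requires the enriched/enhanced annotation")
    gini = gini_per_gene(atlas)
    argmax = atlas.idxmax(axis=1)
    keep = gini >= gini_cut
    if strict:
        ann = annotation.reindex(atlas.index)
        keep &= ann.isin(["Tissue-enriched", "Tissue-enhanced"])
    out = pd.DataFrame(
        {
            "gene": atlas.index[keep],
            "category": argmax[keep].to_numpy(),
            "gini": gini[keep].to_numpy(),
            "source": SOURCE_TISSUE,
            "strict": strict,
        }
    )
    return out.reset_index(drop=True)


def build_celltype_profiles(
    cell_atlas: pd.DataFrame,
    gini_cut: float = 0.8,
    subtype_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Assign genes to cell types: Gini >= cut and max mean expression there.

    ``subtype_map`` merges subtype columns into parent categories (e.g.
    neutrophil subsets into 'neutrophil') by pooling (averaging) their
    mean expression before the Gini computation.
    """
    atlas = cell_atlas
    if subtype_map:
        parents = {c: subtype_map.get(c, c) for c in atlas.columns}
        atlas = atlas.T.groupby(atlas.columns.map(parents)).mean().T
    prof = build_tissue_profiles(atlas, gini_cut=gini_cut, strict=False)
    prof["source"] = SOURCE_CELL
    return prof


def merge_references(
    base_profiles: pd.DataFrame,
    individual_profiles: pd.DataFrame,
    tissue_gini: pd.Series | None = None,
    tissue_gini_cut: float = 0.6,
) -> pd.DataFrame:
    """Union of a whole-body reference with individual-atlas annotations.

    On per-gene conflict the individual-atlas label wins (individual
    atlases cover tissues the whole-body reference misses). When
    ``tissue_gini`` is supplied, individual-atlas genes must also be
    tissue-specific (Gini >= ``tissue_gini_cut``); others are dropped.
    """
    ind = individual_profiles.copy()
    ind["source"] = SOURCE_INDIVIDUAL
    if tissue_gini is not None:
        ok = ind["gene"].map(tissue_gini).fillna(0.0) >= tissue_gini_cut
        dropped = int((~ok).sum())
        if dropped:
            logger.info("dropped %d individual-atlas gene(s) failing tissue specificity",
                        dropped)
        ind = ind[ok]
    base = base_profiles[~base_profiles["gene"].isin(ind["gene"])]
    return pd.concat([base, ind], ignore_index=True)


@dataclass
class EnrichmentTest:
    """One category's hypergeometric enrichment result.

    M: universe genes specific to any category; n: specific to this
    category; N: differential genes specific to any category; k:
    differential genes specific to this category.
    """

    category: str
    M: int
    n: int
    N: int
    k: int
    p_value: float
    bh_adjusted_p: float = float("nan")

    def __post_init__(self) -> None:
        if self.k > min(self.n, self.N) or self.N > self.M or self.n > self.M:
            raise ValidationError("hypergeometric counts violate containment")


def enrichment_test(
    deg_set,
    profiles: pd.DataFrame,
    universe,
    alpha: float = 0.05,
    min_k: int = 2,
) -> pd.DataFrame:
    """One-sided hypergeometric category enrichment of a differential gene set.

    Only categories with at least ``min_k`` differential genes specific to
    them are tested; p = hypergeometric survival function at k-1, i.e.
    P(X >= k). BH correction runs across the tested categories.
    """
    universe = set(universe)
    deg_set = set(deg_set) & universe
    prof = profiles[profiles["gene"].isin(universe)]
    specific = prof.drop_duplicates("gene").set_index("gene")["category"]
    M = len(specific)
    deg_specific = specific[specific.index.isin(deg_set)]
    N = len(deg_specific)
    rows = []
    for cat, n_cat in specific.value_counts().items():
        k = int((deg_specific == cat).sum())
        if k < min_k:
            continue
        p = float(stats.hypergeom.sf(k - 1, M, int(n_cat), N))
        rows.append(EnrichmentTest(category=cat, M=M, n=int(n_cat), N=N, k=k, p_value=p))
    if not rows:
        return pd.DataFrame(columns=["category", "M", "n", "N", "k", "p_value",
                                     "bh_adjusted_p", "significant"])
    df = pd.DataFrame([r.__dict__ for r in rows]).drop(columns="bh_adjusted_p")
    _, p_adj, _, _ = multipletests(df["p_value"], alpha=alpha, method="fdr_bh")
    df["bh_adjusted_p"] = p_adj
    df["significant"] = p_adj <= alpha
    return df.sort_values("p_value").reset_index(drop=True)


def signature_scores(
    logcpm: pd.DataFrame,
    profiles: pd.DataFrame,
    meta: pd.DataFrame,
    min_genes: int = 5,
) -> pd.DataFrame:
    """Absolute, relative and IQR-scaled signature scores per sample.

    Score = sum of logCPM over the category's profile genes present in
    the matrix; categories with fewer than ``min_genes`` such genes are
    skipped. The relative score anchors each participant to their
    post-partum sample (participants without one are excluded with a
    notice), so every post-partum sample scores exactly 0. Scaling
    divides by the category's IQR of relative scores across all included
    samples — no median centering, preserving the zero post-partum
    baseline.
    """
    meta_idx = meta.set_index("sample_id")
    pp = meta[meta["window"] == WINDOW_POSTPARTUM]
    pp_by_participant = (
        pp.sort_values(["ga_collection", "sample_id"]).groupby("participant_id").head(1)
    ).set_index("participant_id")["sample_id"]
    eligible = meta[meta["participant_id"].isin(pp_by_participant.index)]
    skipped = meta.loc[~meta["participant_id"].isin(pp_by_participant.index),
                       "participant_id"].nunique()
    if skipped:
        logger.info("excluded %d participant(s) without a post-partum sample", skipped)
    rows = []
    for cat, grp in profiles.groupby("category"):
        genes = [g for g in pd.unique(grp["gene"]) if g in logcpm.index]
        if len(genes) < min_genes:
            logger.info("category %s skipped: %d profile gene(s) < %d",
                        cat, len(genes), min_genes)
            continue
        score = logcpm.loc[genes, eligible["sample_id"]].sum(axis=0)
        for _, m in eligible.iterrows():
            sid = m["sample_id"]
            baseline = score[pp_by_participant[m["participant_id"]]]
            rows.append(
                {
                    "sample_id": sid,
                    "participant_id": m["participant_id"],
                    "category": cat,
                    "window": m["window"],
                    "outcome": m["outcome"],
                    "score": float(score[sid]),
                    "relative_score": float(score[sid] - baseline),
                }
            )
    if not rows:
        raise ValidationError("no category passed the minimum profile size")
    df = pd.DataFrame(rows)
    iqr = df.groupby("category")["relative_score"].transform(
        lambda s: stats.iqr(s) if stats.iqr(s) > 0 else 1.0
    )
    df["scaled_score"] = df["relative_score"] / iqr
    return df


def signature_trajectories(
    scores: pd.DataFrame,
    n_boot: int = 1000,
    level: float = 0.75,
    seed: int = 0,
) -> pd.DataFrame:
    """Median scaled score per (category, outcome, window) with bootstrap CI.

    The 75% bootstrap interval (1,000 iterations by default) is a
    non-parametric analogue of a standard-deviation band.
    """
    rng = np.random.default_rng(seed)
    alpha = (1.0 - level) / 2.0
    rows = []
    for (cat, outcome, window), grp in scores.groupby(
        ["category", "outcome", "window"]
    ):
        vals = grp["scaled_score"].to_numpy(dtype=float)
        med = float(np.median(vals))
        if vals.size > 1:
            idx = rng.integers(0, vals.size, size=(n_boot, vals.size))
            boot = np.median(vals[idx], axis=1)
            lo, hi = np.quantile(boot, [alpha, 1.0 - alpha])
        else:
            lo = hi = med
        rows.append(
            {"category": cat, "outcome": outcome, "window": window,
             "median_scaled_score": med, "ci_low": float(lo), "ci_high": float(hi),
             "n_samples": int(vals.size)}
        )
    return pd.DataFrame(rows)
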