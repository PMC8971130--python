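"""Rank-test differential signal, per-window log2 fold change and the
bootstrap CV stability statistic.

For a collection window, the log2 fold change of a gene is the
difference of group median logCPM (case minus control), computed over at
most one sample per participant (the earliest in the window) to avoid
shrinking within-group variance through autocorrelated repeat samples.

The stability statistic divides a one-sided bootstrap error bound by the
fold-change magnitude: for a positive log2(FC) the bound is the distance
to the bootstrap 5th percentile, for a negative one the distance to the
95th percentile. CV = 1 means the bound touches zero fold change; CV > 1
means the bootstrap interval crosses zero and the sign itself is
uncertain. Participants (not samples) are the resampling unit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import OUTCOME_NT, OUTCOME_PE, ValidationError

logger = logging.getLogger(__name__)


def first_sample_per_participant(meta: pd.DataFrame, window: str) -> pd.Index:
    """Earliest sample (by gestational age, then sample_id) per participant in a window."""
    sub = meta[meta["window"] == window]
    if sub.empty:
        return pd.Index([], dtype=object)
    sub = sub.sort_values(["participant_id", "ga_collection", "sample_id"])
    picked = sub.groupby("participant_id", sort=True).head(1)
    return pd.Index(picked["sample_id"].tolist())


def log2_fold_change(
    logcpm: pd.DataFrame, pe_samples, nt_samples
) -> pd.Series:
    """median(case logCPM) - median(control logCPM), per gene."""
    pe_samples, nt_samples = list(pe_samples), list(nt_samples)
    if not pe_samples or not nt_samples:
        raise ValidationError("both groups must be nonempty")
    return logcpm[pe_samples].median(axis=1) - logcpm[nt_samples].median(axis=1)


def bootstrap_fold_change(
    logcpm: pd.DataFrame,
    pe_samples,
    nt_samples,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Per-gene log2(FC) with one-sided bootstrap error bound and CV.

    Returns a frame indexed by gene with columns ``log2fc``, ``delta``,
    ``cv``, ``n_pe``, ``n_nt``. ``cv`` is NaN where log2fc == 0 (the
    statistic is undefined there). ``delta`` is clipped at 0 so the bound
    is never negative.
    """
    pe_samples, nt_samples = list(pe_samples), list(nt_samples)
    if not pe_samples or not nt_samples:
        raise ValidationError("both groups must be nonempty")
    if n_boot < 100:
        raise ValidationError("n_boot must be >= 100")
    rng = np.random.default_rng(seed)
    x_pe = logcpm[pe_samples].to_numpy(dtype=float)
    x_nt = logcpm[nt_samples].to_numpy(dtype=float)
    fc = np.median(x_pe, axis=1) - np.median(x_nt, axis=1)

    n_pe, n_nt = x_pe.shape[1], x_nt.shape[1]
    idx_pe = rng.integers(0, n_pe, size=(n_boot, n_pe))
    idx_nt = rng.integers(0, n_nt, size=(n_boot, n_nt))
    # boot medians: genes x n_boot
    boot_pe = np.median(x_pe[:, idx_pe], axis=2)
    boot_nt = np.median(x_nt[:, idx_nt], axis=2)
    boot_fc = boot_pe - boot_nt
    alpha = 1.0 - level
    q_lo = np.quantile(boot_fc, alpha, axis=1)
    q_hi = np.quantile(boot_fc, level, axis=1)
    delta = np.where(fc >= 0, fc - q_lo, q_hi - fc)
    delta = np.maximum(delta, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(fc != 0, delta / np.abs(fc), np.nan)
    return pd.DataFrame(
        {
            "log2fc": fc,
            "delta": delta,
            "cv": cv,
            "n_pe": n_pe,
            "n_nt": n_nt,
        },
        index=logcpm.index,
    )


def bootstrap_cv(
    logcpm_row: pd.Series,
    pe_samples,
    nt_samples,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Single-gene convenience wrapper; returns ``(delta, cv)``."""
    row = bootstrap_fold_change(
        logcpm_row.to_frame().T, pe_samples, nt_samples, n_boot, level, seed
    ).iloc[0]
    return float(row["delta"]), float(row["cv"])


def window_fold_changes(
    logcpm: pd.DataFrame,
    meta: pd.DataFrame,
    windows,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> pd.DataFrame:
    """Long-format fold-change table across collection windows.

    First-sample-per-participant selection and case/control splitting are
    applied per window; windows with an empty group are skipped with a
    notice.
    """
    frames = []
    for i, window in enumerate(windows):
        chosen = first_sample_per_participant(meta, window)
        sub = meta.set_index("sample_id").loc[chosen]
        pe = chosen[(sub["outcome"] == OUTCOME_PE).to_numpy()]
        nt = chosen[(sub["outcome"] == OUTCOME_NT).to_numpy()]
        if len(pe) == 0 or len(nt) == 0:
            logger.warning("window %s skipped: empty case or control group", window)
            continue
        fc = bootstrap_fold_change(
            logcpm, pe, nt, n_boot=n_boot, level=level, seed=seed + i
        )
        fc.insert(0, "window", window)
        fc.insert(0, "gene", fc.index)
        frames.append(fc.reset_index(drop=True))
    if not frames:
        raise ValidationError("no window had both groups populated")
    return pd.concat(frames, ignore_index=True)


def rank_test_degs(
    logcpm: pd.DataFrame,
    pe_samples,
    nt_samples,
    alternative: str = "two-sided",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene Mann-Whitney rank test with Benjamini-Hochberg correction.

    ``alternative='greater'`` tests case > control. The exact null
    distribution is enumerated when both groups have <= 8 samples and no
    ties; otherwise the normal approximation with tie correction is used.
    Returns a frame with ``p_value``, ``bh_adjusted_p``, ``direction``
    and ``significant`` (BH-adjusted p <= alpha).
    """
    pe_samples, nt_samples = list(pe_samples), list(nt_samples)
    if not pe_samples or not nt_samples:
        raise ValidationError("both groups must be nonempty")
    alt = {"two-sided": "two-sided", "greater": "greater", "less": "less"}[alternative]
    x = logcpm[pe_samples].to_numpy(dtype=float)
    y = logcpm[nt_samples].to_numpy(dtype=float)
    res = stats.mannwhitneyu(x, y, alternative=alt, method="auto", axis=1)
    u = np.atleast_1d(res.statistic)
    p = np.atleast_1d(res.pvalue)
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    direction = np.where(
        u >= x.shape[1] * y.shape[1] / 2.0, "up-in-PE", "down-in-PE"
    )
    return pd.DataFrame(
        {
            "u_statistic": u,
            "p_value": p,
            "bh_adjusted_p": p_adj,
            "direction": direction,
            "significant": p_adj <= alpha,
        },
        index=logcpm.index,
    )


@dataclass
class ConcordanceStats:
    sign_agreement: float
    spearman_rho: float
    n_genes: int


def concordance_stats(fc_a: pd.Series, fc_b: pd.Series) -> ConcordanceStats:
    """Cross-cohort agreement of fold changes on matched genes.

    Sign agreement is computed over genes with nonzero fold change in both
    cohorts; the Spearman correlation over all matched genes.
    """
    common = fc_a.index.intersection(fc_b.index)
    if len(common) < 3:
        raise ValidationError("need >= 3 matched genes")
    a, b = fc_a.loc[common], fc_b.loc[common]
    nz = (a != 0) & (b != 0)
    agreement = float((np.sign(a[nz]) == np.sign(b[nz])).mean()) if nz.any() else float("nan")
    rho = float(stats.spearmanr(a, b).statistic)
    return ConcordanceStats(sign_agreement=agreement, spearman_rho=rho, n_genes=len(common))


def severity_slope(fc_without_severe: pd.Series, fc_with_severe: pd.Series) -> float:
    """OLS slope of with-severe vs without-severe fold changes.

    A slope of 1 means symptom severity does not scale the fold-change
    magnitude; 0 means no relationship (e.g. after permutation).
    """
    common = fc_without_severe.index.intersection(fc_with_severe.index)
    if len(common) < 3:
        raise ValidationError("need >= 3 matched genes")
    x = fc_without_severe.loc[common].to_numpy(dtype=float)
    y = fc_with_severe.loc[common].to_numpy(dtype=float)
    if np.var(x) == 0:
        raise ValidationError("zero variance in x")
    return float(stats.linregress(x, y).slope)
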