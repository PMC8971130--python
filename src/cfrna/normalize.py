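"""Library-size normalization to log2-CPM with TMM factors.

TMM (trimmed mean of M-values) corrects for composition bias between
libraries: for each sample a scaling factor is computed as the doubly
trimmed, precision-weighted mean of gene-wise log-ratios (M-values)
against a reference sample, then all factors are rescaled to geometric
mean one. The moderated log2-CPM transform adds a library-size-scaled
prior count so that zeros map to a finite floor and the transform stays
monotone in the raw count.

Gene detection filtering (CPM >= `min_cpm` in >= `min_fraction` of
reference samples) is computed on raw-library-size CPM, since detection
precedes normalization in the analysis order; pass TMM-effective sizes
explicitly if scaled CPM is wanted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import CountMatrix, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class NormalizationFactors:
    """Per-sample library sizes and TMM scaling factors.

    ``effective_size = library_size * tmm_factor``; factors are rescaled so
    their geometric mean is 1.
    """

    sample_id: pd.Index
    library_size: pd.Series
    tmm_factor: pd.Series

    def __post_init__(self) -> None:
        if (self.tmm_factor <= 0).any():
            raise ValidationError("TMM factors must be positive")

    @property
    def effective_size(self) -> pd.Series:
        return self.library_size * self.tmm_factor

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_id,
                "library_size": self.library_size.to_numpy(),
                "tmm_factor": self.tmm_factor.to_numpy(),
                "effective_size": self.effective_size.to_numpy(),
            }
        )


def _upper_quartile_depth(counts: np.ndarray, lib_size: np.ndarray) -> np.ndarray:
    # 75th percentile of depth-scaled counts per sample
    return np.quantile(counts / lib_size, 0.75, axis=0)


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    """TMM factor of one observed library against the reference library."""
    with np.errstate(divide="ignore", invalid="ignore"):
        p_obs = obs / n_obs
        p_ref = ref / n_ref
        log_r = np.log2(p_obs / p_ref)  # M-values
        abs_e = (np.log2(p_obs) + np.log2(p_ref)) / 2.0  # A-values
        # delta-method asymptotic variance of each M-value
        v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    keep = np.isfinite(log_r) & np.isfinite(abs_e) & (abs_e > -1e10)
    log_r, abs_e, v = log_r[keep], abs_e[keep], v[keep]
    if log_r.size == 0 or np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    n = log_r.size
    lo_l = np.floor(n * trim_m) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * trim_a) + 1
    hi_s = n + 1 - lo_s
    rank_m = rankdata(log_r)
    rank_a = rankdata(abs_e)
    sel = (rank_m >= lo_l) & (rank_m <= hi_l) & (rank_a >= lo_s) & (rank_a <= hi_s)
    if not sel.any():
        return 1.0
    f = np.sum(log_r[sel] / v[sel]) / np.sum(1.0 / v[sel])
    if not np.isfinite(f):
        f = 0.0
    return float(2.0**f)


def tmm_factors(
    cm: CountMatrix, trim_m: float = 0.30, trim_a: float = 0.05
) -> NormalizationFactors:
    """Compute TMM scaling factors for every sample of a count matrix.

    The reference sample is the one whose upper-quartile depth-scaled
    count is closest to the mean upper quartile across samples. ``trim_m``
    and ``trim_a`` are the two-sided trim fractions on the M-values and
    A-values respectively.
    """
    counts = cm.counts.to_numpy(dtype=float)
    if counts.shape[1] < 2:
        raise ValidationError("TMM requires at least 2 samples")
    lib = counts.sum(axis=0)
    if (lib == 0).any():
        bad = cm.samples[lib == 0].tolist()
        raise ValidationError(f"all-zero sample(s): {bad}")
    uq = _upper_quartile_depth(counts, lib)
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    ref = counts[:, ref_idx]
    f = np.array(
        [
            _tmm_pair(counts[:, s], ref, lib[s], lib[ref_idx], trim_m, trim_a)
            for s in range(counts.shape[1])
        ]
    )
    f = f / np.exp(np.mean(np.log(f)))  # geometric mean 1
    return NormalizationFactors(
        sample_id=cm.samples,
        library_size=pd.Series(lib, index=cm.samples),
        tmm_factor=pd.Series(f, index=cm.samples),
    )


def logcpm(
    cm: CountMatrix,
    factors: NormalizationFactors | None = None,
    prior_count: float = 0.5,
) -> CountMatrix:
    """Return a new :class:`CountMatrix` carrying moderated log2-CPM values.

    The prior count is scaled per sample in proportion to its effective
    library size relative to the mean, and the library size is offset by
    twice the scaled prior — the standard moderated-CPM convention, which
    keeps the transform monotone and depth-scale invariant.
    """
    if factors is None:
        factors = tmm_factors(cm)
    missing = cm.samples.difference(factors.sample_id)
    if len(missing):
        raise ValidationError(f"factors missing for samples: {list(missing)}")
    counts = cm.counts.to_numpy(dtype=float)
    eff = factors.effective_size.loc[cm.samples].to_numpy(dtype=float)
    if (eff <= 0).any():
        raise ValidationError("nonpositive effective library size")
    prior_scaled = eff / eff.mean() * prior_count
    denom = (eff + 2.0 * prior_scaled) * 1e-6
    lc = np.log2((counts + prior_scaled[None, :]) / denom[None, :])
    return CountMatrix(
        counts=cm.counts,
        logcpm=pd.DataFrame(lc, index=cm.genes, columns=cm.samples),
    )


def cpm(cm: CountMatrix, effective_size: pd.Series | None = None) -> pd.DataFrame:
    """Plain (non-log) counts per million; raw library sizes by default."""
    counts = cm.counts.to_numpy(dtype=float)
    size = counts.sum(axis=0) if effective_size is None else (
        effective_size.loc[cm.samples].to_numpy(dtype=float)
    )
    return pd.DataFrame(counts / size[None, :] * 1e6, index=cm.genes, columns=cm.samples)


def filter_genes(
    cm: CountMatrix,
    reference_samples,
    min_cpm: float = 0.5,
    min_fraction: float = 0.75,
) -> pd.Index:
    """Genes detected at >= ``min_cpm`` CPM in >= ``min_fraction`` of reference samples.

    ``reference_samples`` should be the outlier-free discovery samples.
    The fraction cut is strict in the sense that a gene detected in 74% of
    samples fails a 75% requirement.
    """
    reference_samples = list(reference_samples)
    if not reference_samples:
        raise ValidationError("empty reference sample set")
    sub = cm.subset(samples=reference_samples)
    c = cpm(sub)
    frac = (c >= min_cpm).mean(axis=1)
    kept = cm.genes[(frac >= min_fraction).to_numpy()]
    logger.info("gene filter kept %d / %d genes", len(kept), len(cm.genes))
    return kept


def regress_out_batch(logcpm_df: pd.DataFrame, batch: pd.Series) -> pd.DataFrame:
    """Remove additive per-batch offsets from a logCPM matrix.

    Per gene, batch coefficients are estimated by least squares under
    sum-to-zero coding and subtracted; the overall gene mean is preserved.
    With a single batch the matrix is returned unchanged. Outcome labels
    are deliberately not protected: the adjustment is used after the
    model-based differential stage, for fold-change estimation and display.
    """
    batch = batch.loc[logcpm_df.columns]
    levels = pd.unique(batch)
    if len(levels) < 2:
        return logcpm_df.copy()
    singletons = [lv for lv in levels if (batch == lv).sum() == 1]
    if singletons:
        logger.warning("batch level(s) with a single sample: %s", singletons)
    x = logcpm_df.to_numpy(dtype=float)
    grand = x.mean(axis=1, keepdims=True)
    out = x.copy()
    # Sum-to-zero least squares on a balanced one-way layout reduces to
    # per-batch mean-centering around the weighted overall batch-mean mean.
    batch_means = np.column_stack(
        [x[:, (batch == lv).to_numpy()].mean(axis=1) for lv in levels]
    )
    mean_of_means = batch_means.mean(axis=1, keepdims=True)
    for j, lv in enumerate(levels):
        cols = (batch == lv).to_numpy()
        offset = batch_means[:, [j]] - mean_of_means
        out[:, cols] = x[:, cols] - offset
    # preserve each gene's overall mean exactly
    out += grand - out.mean(axis=1, keepdims=True)
    return pd.DataFrame(out, index=logcpm_df.index, columns=logcpm_df.columns)
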