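"""Per-sample quality metrics and the empirical-percentile exclusion rule.

Three metrics summarize plasma cfRNA sample quality:

* **RNA degradation** — the fraction of detected genes whose reads all
  fall in the gene's 3'-most exon. Degraded cfRNA is sequenced from the
  poly-A end, so heavy 3' bias marks a degraded library.
* **DNA contamination** — the ratio of intronic to exonic reads; genomic
  DNA contributes intron-mapping fragments that cfRNA should not.
* **Reads assigned** — total reads quantified to genes; zero means the
  library carries no usable signal.

A sample is excluded when degradation or contamination reaches the
pooled empirical 95th-percentile bound (value >= bound fails) or when no
reads were assigned to genes. Bounds are recomputed per dataset by
default; fixed bounds may be supplied for cross-study reuse.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA

from .io import CountMatrix, ValidationError

logger = logging.getLogger(__name__)

METRIC_DEGRADATION = "degradation"
METRIC_CONTAMINATION = "contamination"
METRIC_NO_READS = "no_reads"


@dataclass
class QCRecord:
    """Quality metrics and the outlier decision for one sample."""

    sample_id: str
    degradation_fraction: float  # NaN when no genes detected
    reads_assigned: int
    intron_exon_ratio: float  # NaN when exonic reads == 0
    outlier: bool = False
    failing_metrics: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if np.isfinite(self.degradation_fraction) and not (
            0.0 <= self.degradation_fraction <= 1.0
        ):
            raise ValidationError(
                f"degradation_fraction out of [0,1]: {self.degradation_fraction}"
            )
        if self.reads_assigned < 0:
            raise ValidationError("reads_assigned must be >= 0")


def degradation_fraction(exon_counts: pd.DataFrame) -> float:
    """Fraction of detected genes whose reads lie only in their 3'-most exon.

    Parameters
    ----------
    exon_counts
        Long table with columns ``gene``, ``exon_index`` (transcript
        orientation, so a gene's 3'-most exon has the maximum index) and
        ``count``.

    Returns
    -------
    float
        NaN when no gene has any reads (signalled distinctly; feeds the
        no-reads exclusion rule).
    """
    required = {"gene", "exon_index", "count"}
    if not required.issubset(exon_counts.columns):
        raise ValidationError(f"exon table needs columns {sorted(required)}")
    detected = 0
    last_exon_only = 0
    for gene, grp in exon_counts.groupby("gene", sort=False):
        total = grp["count"].sum()
        if total <= 0:
            continue
        detected += 1
        last = grp["exon_index"].max()
        if grp.loc[grp["exon_index"] != last, "count"].sum() == 0:
            last_exon_only += 1
    if detected == 0:
        return float("nan")
    return last_exon_only / detected


def intron_exon_ratio(intronic_reads: int, exonic_reads: int) -> float:
    """Intronic / exonic read ratio; NaN when there are no exonic reads."""
    if intronic_reads < 0 or exonic_reads < 0:
        raise ValidationError("read counts must be >= 0")
    if exonic_reads == 0:
        return float("nan")
    return intronic_reads / exonic_reads


def _percentile_bound(values: np.ndarray, percentile: float) -> float:
    """Linear-interpolation empirical percentile over defined values."""
    vals = values[np.isfinite(values)]
    if vals.size == 0:
        return float("inf")
    return float(np.percentile(vals, percentile, method="linear"))


def flag_outliers(
    records: list[QCRecord],
    percentile: float = 95.0,
    fixed_bounds: dict[str, float] | None = None,
) -> list[QCRecord]:
    """Apply the percentile exclusion rule across a pooled sample collection.

    A sample fails a metric when its value is **greater than or equal to**
    the bound. Undefined contamination (no exonic reads) is treated as
    failing: such a sample carries no usable signal. ``fixed_bounds`` maps
    metric name to a precomputed bound, overriding the empirical one.
    """
    if not records:
        raise ValidationError("empty QC record collection")
    deg = np.array([r.degradation_fraction for r in records])
    ratio = np.array([r.intron_exon_ratio for r in records])
    if percentile >= 100.0:
        # the maximum would always sit at its own bound under the >= rule;
        # percentile 100 therefore means "no empirical exclusion"
        bounds = {METRIC_DEGRADATION: float("inf"),
                  METRIC_CONTAMINATION: float("inf")}
    else:
        bounds = {
            METRIC_DEGRADATION: _percentile_bound(deg, percentile),
            METRIC_CONTAMINATION: _percentile_bound(ratio, percentile),
        }
    if fixed_bounds:
        bounds.update(fixed_bounds)
    out = []
    for r in records:
        failing = []
        if np.isfinite(r.degradation_fraction) and r.degradation_fraction >= bounds[
            METRIC_DEGRADATION
        ]:
            failing.append(METRIC_DEGRADATION)
        if not np.isfinite(r.intron_exon_ratio) or r.intron_exon_ratio >= bounds[
            METRIC_CONTAMINATION
        ]:
            failing.append(METRIC_CONTAMINATION)
        if r.reads_assigned == 0:
            failing.append(METRIC_NO_READS)
        out.append(
            QCRecord(
                sample_id=r.sample_id,
                degradation_fraction=r.degradation_fraction,
                reads_assigned=r.reads_assigned,
                intron_exon_ratio=r.intron_exon_ratio,
                outlier=bool(failing),
                failing_metrics=tuple(failing),
            )
        )
    return out


def records_to_frame(records: list[QCRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "degradation_fraction": [r.degradation_fraction for r in records],
            "reads_assigned": [r.reads_assigned for r in records],
            "intron_exon_ratio": [r.intron_exon_ratio for r in records],
            "outlier": [r.outlier for r in records],
            "failing_metrics": [";".join(r.failing_metrics) for r in records],
        }
    )


@dataclass
class QCDiagnostics:
    """Reporting bundle: sample dendrogram + principal components, outlier-annotated."""

    linkage: np.ndarray | None
    sample_order: list[str]
    pca_coordinates: pd.DataFrame | None
    explained_variance_ratio: np.ndarray | None
    outlier: pd.Series
    notice: str | None = None


def qc_diagnostics(cm: CountMatrix, records: list[QCRecord]) -> QCDiagnostics:
    """Average-linkage Euclidean clustering and PCA of samples, outlier-annotated.

    Purely a reporting aid: shows whether flagged low-quality samples
    cluster apart or drive the leading principal components.
    """
    if cm.logcpm is None:
        raise ValidationError("qc_diagnostics needs a normalized (logcpm) matrix")
    if cm.shape[1] < 3:
        raise ValidationError("need at least 3 samples")
    flags = pd.Series(
        {r.sample_id: r.outlier for r in records}, name="outlier"
    ).reindex(cm.samples, fill_value=False)
    x = cm.logcpm.to_numpy(dtype=float).T  # samples x genes
    link = hierarchy.linkage(pdist(x, metric="euclidean"), method="average")
    order = [cm.samples[i] for i in hierarchy.leaves_list(link)]
    if np.allclose(x.var(axis=0), 0.0):
        return QCDiagnostics(
            linkage=link,
            sample_order=order,
            pca_coordinates=None,
            explained_variance_ratio=None,
            outlier=flags,
            notice="zero-variance matrix; PCA skipped",
        )
    n_comp = min(10, x.shape[0] - 1, x.shape[1])
    pca = PCA(n_components=n_comp, random_state=0)
    coords = pca.fit_transform(x - x.mean(axis=0, keepdims=True))
    pcs = pd.DataFrame(
        coords, index=cm.samples, columns=[f"PC{i + 1}" for i in range(n_comp)]
    )
    return QCDiagnostics(
        linkage=link,
        sample_order=order,
        pca_coordinates=pcs,
        explained_variance_ratio=pca.explained_variance_ratio_,
        outlier=flags,
    )
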