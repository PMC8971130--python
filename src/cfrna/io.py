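"""Domain containers and file I/O shared by every analysis stage.

The two core objects are :class:`CountMatrix` (genes x samples raw counts
plus, after normalization, a matching log2-CPM matrix) and the sample
metadata table, a validated :class:`pandas.DataFrame` with one row per
plasma sample carrying the participant, gestational age at collection,
collection window, pregnancy outcome and batch/cohort labels.

Collection windows follow the study design: three antenatal windows
(<=12 weeks, 13-20 weeks, >=23 weeks of gestation) and a post-partum
sample. Gestational ages falling between the defined windows (21 to <23
weeks, or the sliver just above 12.99) are labelled ``unassigned`` and
excluded from window-based statistics rather than silently merged.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

# Canonical window labels, in gestational order.
WINDOW_EARLY = "<=12"
WINDOW_MID = "13-20"
WINDOW_LATE = ">=23"
WINDOW_POSTPARTUM = "post-partum"
WINDOW_UNASSIGNED = "unassigned"
WINDOWS = (WINDOW_EARLY, WINDOW_MID, WINDOW_LATE, WINDOW_POSTPARTUM)
ANTENATAL_WINDOWS = (WINDOW_EARLY, WINDOW_MID, WINDOW_LATE)

OUTCOME_NT = "normotensive"
OUTCOME_PE = "PE"
SEVERITY_LEVELS = ("none", "without-severe", "severe")

METADATA_COLUMNS = (
    "sample_id",
    "participant_id",
    "ga_collection",
    "window",
    "outcome",
    "severity",
    "ga_onset_or_delivery",
    "cohort",
    "batch",
    "postpartum",
)
#: Columns that must be present in a metadata file; ``window`` may be
#: derived from ``ga_collection`` and ``postpartum`` when absent.
REQUIRED_METADATA_COLUMNS = (
    "sample_id",
    "participant_id",
    "ga_collection",
    "outcome",
    "cohort",
    "batch",
    "postpartum",
)


class ValidationError(ValueError):
    """Raised when an input table violates a domain invariant."""


def assign_window(ga_collection: float, postpartum: bool = False) -> str:
    """Map a gestational age at collection (weeks) to a collection window.

    Post-partum samples are identified by the ``postpartum`` flag, not by
    gestational age. Ages in the gap between the defined antenatal windows
    return :data:`WINDOW_UNASSIGNED`.
    """
    if postpartum:
        return WINDOW_POSTPARTUM
    if ga_collection <= 12.99:
        return WINDOW_EARLY
    if 13.0 <= ga_collection < 21.0:
        return WINDOW_MID
    if ga_collection >= 23.0:
        return WINDOW_LATE
    return WINDOW_UNASSIGNED


@dataclass
class CountMatrix:
    """Gene x sample count matrix with an optional log2-CPM companion.

    Parameters
    ----------
    counts
        Non-negative integer matrix; index = gene identifiers,
        columns = sample identifiers. Identifiers are opaque strings.
    logcpm
        Optional matrix of log2-transformed counts per million on
        identical axes; present only after normalization.
    """

    counts: pd.DataFrame
    logcpm: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            dups = sorted(c.index[c.index.duplicated()].unique())
            raise ValidationError(f"duplicate gene identifiers: {dups}")
        if c.columns.has_duplicates:
            dups = sorted(c.columns[c.columns.duplicated()].unique())
            raise ValidationError(f"duplicate sample identifiers: {dups}")
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("counts must be numeric")
        if (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative count at gene {c.index[g]!r}, sample {c.columns[s]!r}"
            )
        if self.logcpm is not None:
            if not self.logcpm.index.equals(c.index) or not self.logcpm.columns.equals(
                c.columns
            ):
                raise ValidationError("logcpm axes do not match counts axes")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def subset(self, genes=None, samples=None) -> "CountMatrix":
        """Return a new matrix restricted to the given genes/samples (order kept)."""
        counts = self.counts
        logcpm = self.logcpm
        if genes is not None:
            counts = counts.loc[list(genes)]
            logcpm = None if logcpm is None else logcpm.loc[list(genes)]
        if samples is not None:
            counts = counts[list(samples)]
            logcpm = None if logcpm is None else logcpm[list(samples)]
        return CountMatrix(counts=counts, logcpm=logcpm)


def _sep_for(path: Path, fmt: str | None) -> str:
    if fmt is None:
        fmt = "csv" if Path(path).suffix.lower() == ".csv" else "tsv"
    if fmt not in ("tsv", "csv"):
        raise ValueError(f"unknown format {fmt!r}")
    return "\t" if fmt == "tsv" else ","


def read_counts(path, fmt: str | None = None) -> CountMatrix:
    """Read a genes x samples count table (first column = gene IDs).

    Raises
    ------
    ValidationError
        On duplicate gene/sample identifiers or negative values.
    ValueError
        On non-numeric body cells, reported with their location.
    """
    path = Path(path)
    sep = _sep_for(path, fmt)
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    bad = df.columns[[not pd.api.types.is_numeric_dtype(df[c]) for c in df.columns]]
    if len(bad):
        col = bad[0]
        row = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
        raise ValueError(f"non-numeric count at gene {row!r}, sample {col!r}")
    return CountMatrix(counts=df)


def write_counts(cm: CountMatrix, path, fmt: str | None = None) -> None:
    path = Path(path)
    sep = _sep_for(path, fmt)
    cm.counts.to_csv(path, sep=sep, index_label="gene")


def validate_metadata(meta: pd.DataFrame, counts: CountMatrix | None = None) -> pd.DataFrame:
    """Validate (and lightly coerce) a sample metadata table.

    Enforces: unique sample IDs, window/postpartum consistency,
    severity/outcome consistency and (optionally) that every sample has a
    column in the paired count matrix.
    """
    meta = meta.copy()
    missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValidationError(f"metadata missing required columns: {missing}")
    meta["sample_id"] = meta["sample_id"].astype(str)
    meta["participant_id"] = meta["participant_id"].astype(str)
    meta["postpartum"] = meta["postpartum"].astype(bool)
    if meta["sample_id"].duplicated().any():
        dups = sorted(meta.loc[meta["sample_id"].duplicated(), "sample_id"])
        raise ValidationError(f"duplicate sample_id entries: {dups}")
    if "severity" not in meta.columns:
        meta["severity"] = np.where(meta["outcome"] == OUTCOME_PE, "without-severe", "none")
    if "ga_onset_or_delivery" not in meta.columns:
        meta["ga_onset_or_delivery"] = np.nan
    if "window" not in meta.columns or meta["window"].isna().any():
        derived = [
            assign_window(ga, pp)
            for ga, pp in zip(meta["ga_collection"], meta["postpartum"])
        ]
        if "window" not in meta.columns:
            meta["window"] = derived
        else:
            meta["window"] = meta["window"].where(meta["window"].notna(), derived)
    bad_pp = (meta["window"] == WINDOW_POSTPARTUM) != meta["postpartum"]
    if bad_pp.any():
        rows = meta.loc[bad_pp, "sample_id"].tolist()
        raise ValidationError(f"postpartum flag inconsistent with window for: {rows}")
    bad_sev = (meta["severity"] == "none") != (meta["outcome"] == OUTCOME_NT)
    if bad_sev.any():
        rows = meta.loc[bad_sev, "sample_id"].tolist()
        raise ValidationError(f"severity inconsistent with outcome for: {rows}")
    n_unassigned = int((meta["window"] == WINDOW_UNASSIGNED).sum())
    if n_unassigned:
        logger.warning(
            "%d sample(s) fall outside the defined collection windows; "
            "flagged 'unassigned' and excluded from window-based statistics",
            n_unassigned,
        )
    if counts is not None:
        absent = set(meta["sample_id"]) - set(counts.samples.astype(str))
        if absent:
            raise ValidationError(
                f"metadata samples missing from count matrix: {sorted(absent)}"
            )
    return meta.reset_index(drop=True)


def read_metadata(path, counts: CountMatrix | None = None) -> pd.DataFrame:
    """Read and validate a sample metadata CSV (see module docstring for schema)."""
    meta = pd.read_csv(path)
    return validate_metadata(meta, counts=counts)


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, index=False)


@dataclass
class AnalysisConfig:
    """All tunable thresholds of the pipeline, in one place.

    Defaults are the analysis defaults used throughout the package; every
    value can be overridden from a YAML file via :meth:`from_yaml`.
    """

    seed: int = 0
    # detection filter
    min_cpm: float = 0.5
    min_detect_fraction: float = 0.75
    # QC
    qc_percentile: float = 95.0
    # differential signal
    bh_alpha: float = 0.05
    n_boot: int = 1000
    boot_level: float = 0.95
    # normalization
    tmm_trim_m: float = 0.30
    tmm_trim_a: float = 0.05
    prior_count: float = 0.5
    # trend clustering
    k_max: int = 16
    # profiles / signatures
    tissue_gini_cut: float = 0.6
    celltype_gini_cut: float = 0.8
    min_profile_genes: int = 5
    # heatmap segregation
    heatmap_fc_cut: float = 1.0
    # classifier
    fpr_target: float = 0.10
    threshold_grain: float = 0.05
    control_adj_p: float = 0.99
    ga_max_predict: float = 16.0
    # file paths (optional; the pipeline can also run on in-memory inputs)
    counts_path: str | None = None
    metadata_path: str | None = None
    atlas_path: str | None = None
    output_dir: str = "results"

    def __post_init__(self) -> None:
        for name in ("min_detect_fraction", "bh_alpha", "fpr_target", "control_adj_p",
                     "boot_level"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.n_boot < 1:
            raise ValidationError("n_boot must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        """Stable hash of the full configuration, recorded in every output."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
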