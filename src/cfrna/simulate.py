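"""Synthetic cfRNA cohort generation.

Emulates the statistical structure of a longitudinal plasma cfRNA
case/control study so every downstream stage is testable without
sequencing data: negative-binomial gene counts with gamma-distributed
per-gene dispersions and log-normal library sizes; participants sampled
in three antenatal windows (<=12, 13-20, >=23 weeks) and post-partum;
planted case effects following two longitudinal trend shapes — a
V-shaped decrease bottoming at mid-gestation ("group 1", attenuated
toward no effect post-partum, mimicking a placental contribution) and an
early-gestation increase that wanes late ("group 2"); multiplicative
per-batch composition offsets; a designated set of null housekeeping
genes; per-sample QC metrics with a small planted-outlier fraction; and
a category x gene reference atlas with known profile genes.

Default magnitudes follow the case/control differences the analysis is
designed to detect: trend peaks near +0.8 and -0.6 log2 units, cohort
sizes near 50 controls / 25 cases, ~6,000 genes with ~7.5% planted
differential genes and 66 housekeeping genes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    CountMatrix,
    OUTCOME_NT,
    OUTCOME_PE,
    ValidationError,
    WINDOW_EARLY,
    WINDOW_LATE,
    WINDOW_MID,
    WINDOW_POSTPARTUM,
    validate_metadata,
)

logger = logging.getLogger(__name__)

GROUP1 = "group1-V"
GROUP2 = "group2-early-peak"

#: Per-window planted log2 fold-change targets for the two trend shapes.
#: Group 1 falls across gestation with a minimum at 13-20 weeks and
#: attenuates toward 0 post-partum; group 2 peaks before 20 weeks.
DEFAULT_TREND_SHAPES = {
    GROUP1: {
        WINDOW_EARLY: -0.38,
        WINDOW_MID: -0.585,
        WINDOW_LATE: -0.38,
        WINDOW_POSTPARTUM: -0.05,
    },
    GROUP2: {
        WINDOW_EARLY: 0.8,
        WINDOW_MID: 0.8,
        WINDOW_LATE: 0.38,
        WINDOW_POSTPARTUM: 0.38,
    },
}

#: Gestational-age sampling ranges (weeks) per collection window.
GA_RANGES = {
    WINDOW_EARLY: (8.0, 12.5),
    WINDOW_MID: (13.0, 20.5),
    WINDOW_LATE: (23.0, 34.0),
}


@dataclass
class SimulationDesign:
    """Parameters of a synthetic cohort.

    ``cohorts`` maps cohort label -> (n normotensive, n preeclampsia)
    participants; every cohort receives ``n_batches`` sequencing batches.
    ``frac_deg`` is the fraction of genes planted as differential, split
    ``group1_fraction`` : (1 - ``group1_fraction``) between the two trend
    shapes.
    """

    cohorts: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {"discovery": (49, 24)}
    )
    windows: tuple[str, ...] = (
        WINDOW_EARLY, WINDOW_MID, WINDOW_LATE, WINDOW_POSTPARTUM
    )
    n_genes: int = 6000
    frac_deg: float = 0.075
    group1_fraction: float = 0.4
    trend_shapes: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_TREND_SHAPES.items()}
    )
    n_housekeeping: int = 66
    dispersion_shape: float = 2.0
    dispersion_mean: float = 0.2
    library_size_median: float = 2.0e6
    library_size_sigma: float = 0.3
    n_batches: int = 2
    batch_sd: float = 0.15  # per-batch per-gene log2 offset spread
    qc_outlier_fraction: float = 0.04
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_deg", "group1_fraction", "qc_outlier_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        n_deg = int(round(self.frac_deg * self.n_genes))
        if n_deg + self.n_housekeeping > self.n_genes:
            raise ValidationError("planted DEG + housekeeping fractions exceed the genome")
        for shape, targets in self.trend_shapes.items():
            if not all(np.isfinite(list(targets.values()))):
                raise ValidationError(f"non-finite log2FC target in {shape}")


@dataclass
class GroundTruth:
    """Planted structure of a simulated cohort, for recovery checks."""

    deg_trends: dict[str, str]  # gene -> trend shape label
    informative_genes: list[str]  # |early log2FC| >= 0.8 planted genes
    housekeeping_genes: list[str]
    category_profiles: dict[str, list[str]]  # atlas category -> profile genes
    qc_outlier_samples: list[str]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1)


def _participant_table(design: SimulationDesign, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for cohort, (n_nt, n_pe) in design.cohorts.items():
        for arm, n, outcome in ((OUTCOME_NT, n_nt, OUTCOME_NT), (OUTCOME_PE, n_pe, OUTCOME_PE)):
            for i in range(n):
                pid = f"{cohort[:4].upper()}-{'NT' if outcome == OUTCOME_NT else 'PE'}-{i + 1:03d}"
                if outcome == OUTCOME_NT:
                    onset = rng.uniform(37.0, 41.5)
                    severity = "none"
                else:
                    onset = rng.uniform(32.0, 40.0)
                    severity = "without-severe" if i % 2 == 0 else "severe"
                rows.append(
                    {
                        "participant_id": pid,
                        "cohort": cohort,
                        "outcome": outcome,
                        "severity": severity,
                        "ga_onset_or_delivery": round(onset, 2),
                        "batch": f"{cohort}-b{rng.integers(design.n_batches) + 1}",
                    }
                )
    return pd.DataFrame(rows)


def _sample_table(design: SimulationDesign, rng: np.random.Generator) -> pd.DataFrame:
    parts = _participant_table(design, rng)
    rows = []
    for _, p in parts.iterrows():
        for w_idx, window in enumerate(design.windows):
            postpartum = window == WINDOW_POSTPARTUM
            if postpartum:
                ga = p["ga_onset_or_delivery"] + rng.uniform(4.0, 8.0)
            else:
                lo, hi = GA_RANGES[window]
                ga = rng.uniform(lo, hi)
            rows.append(
                {
                    "sample_id": f"{p['participant_id']}-w{w_idx + 1}",
                    "participant_id": p["participant_id"],
                    "ga_collection": round(float(ga), 2),
                    "window": window,
                    "outcome": p["outcome"],
                    "severity": p["severity"],
                    "ga_onset_or_delivery": p["ga_onset_or_delivery"],
                    "cohort": p["cohort"],
                    "batch": p["batch"],
                    "postpartum": postpartum,
                }
            )
    return pd.DataFrame(rows)


def simulate_cohort(
    design: SimulationDesign,
) -> tuple[CountMatrix, pd.DataFrame, GroundTruth]:
    """Draw a full synthetic cohort from a design.

    Counts are negative binomial with mean
    ``library_size x relative_abundance x 2^(batch offset) x 2^(planted
    log2FC if a case sample in that window)``; housekeeping genes carry no
    planted effect in any contrast. Deterministic given ``design.seed``.
    """
    rng = np.random.default_rng(design.seed)
    meta = _sample_table(design, rng)

    genes = np.array([f"GENE{i + 1:05d}" for i in range(design.n_genes)])
    n_deg = int(round(design.frac_deg * design.n_genes))
    n_g1 = int(round(design.group1_fraction * n_deg))
    order = rng.permutation(design.n_genes)
    g1 = genes[order[:n_g1]]
    g2 = genes[order[n_g1:n_deg]]
    housekeeping = genes[order[n_deg:n_deg + design.n_housekeeping]]
    deg_trends = {g: GROUP1 for g in g1}
    deg_trends.update({g: GROUP2 for g in g2})
    informative = [
        g for g, shape in deg_trends.items()
        if abs(design.trend_shapes[shape][WINDOW_EARLY]) >= 0.8
    ]

    # per-gene baseline abundance (log-normal) and NB dispersion (gamma)
    baseline = rng.lognormal(mean=1.0, sigma=1.2, size=design.n_genes)
    dispersion = rng.gamma(
        shape=design.dispersion_shape,
        scale=design.dispersion_mean / design.dispersion_shape,
        size=design.n_genes,
    )
    batches = pd.unique(meta["batch"])
    batch_offset = {
        b: rng.normal(0.0, design.batch_sd, size=design.n_genes) for b in batches
    }
    lib_size = rng.lognormal(
        mean=np.log(design.library_size_median),
        sigma=design.library_size_sigma,
        size=len(meta),
    )

    fc_matrix = np.zeros((design.n_genes, len(meta)))
    gene_pos = {g: i for i, g in enumerate(genes)}
    is_pe = (meta["outcome"] == OUTCOME_PE).to_numpy()
    for shape_name, members in ((GROUP1, g1), (GROUP2, g2)):
        targets = design.trend_shapes[shape_name]
        rows = [gene_pos[g] for g in members]
        for s, (window, pe) in enumerate(zip(meta["window"], is_pe)):
            if pe and window in targets:
                fc_matrix[rows, s] = targets[window]

    counts = np.empty((design.n_genes, len(meta)), dtype=np.int64)
    for s in range(len(meta)):
        rel = baseline * 2.0 ** (batch_offset[meta["batch"].iloc[s]] + fc_matrix[:, s])
        rel = rel / rel.sum()
        mu = lib_size[s] * rel
        # NB parameterized by mean and size r = 1/dispersion
        r = 1.0 / np.maximum(dispersion, 1e-8)
        p = r / (r + mu)
        counts[:, s] = rng.negative_binomial(r, p)

    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=meta["sample_id"].tolist())
    )
    meta = validate_metadata(meta, counts=cm)

    # atlas alignment: one category owns planted group-2 genes (elevated in
    # cases early in gestation), remaining categories own null genes
    profile_size = 20
    null_pool = [g for g in genes[order[n_deg + design.n_housekeeping:]]]
    category_profiles = {}
    if len(g2) >= 5:
        category_profiles["cat01"] = list(g2[:profile_size])
    for c in range(2, 6):
        start = (c - 2) * profile_size
        category_profiles[f"cat{c:02d}"] = list(null_pool[start:start + profile_size])

    qc_outliers = _planted_outliers(meta, design, rng)
    truth = GroundTruth(
        deg_trends=deg_trends,
        informative_genes=informative,
        housekeeping_genes=list(housekeeping),
        category_profiles=category_profiles,
        qc_outlier_samples=qc_outliers,
    )
    return cm, meta, truth


def _planted_outliers(
    meta: pd.DataFrame, design: SimulationDesign, rng: np.random.Generator
) -> list[str]:
    n_out = int(round(design.qc_outlier_fraction * len(meta)))
    if n_out == 0:
        return []
    picked = rng.choice(meta["sample_id"].to_numpy(), size=n_out, replace=False)
    return sorted(picked)


def simulate_qc_tables(
    design: SimulationDesign,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample QC metric table plus a small exon-level count fixture.

    Clean degradation fractions are beta-distributed and contamination
    ratios log-normal; the design's outlier fraction of samples is pushed
    beyond the empirical 95th percentile of the clean draw on both
    metrics. The exon fixture is a genes x exons long table for
    formula-level testing of the degradation metric.
    """
    rng = np.random.default_rng(design.seed)
    meta = _sample_table(design, rng)
    n = len(meta)
    degradation = rng.beta(2.0, 18.0, size=n)
    ratio = rng.lognormal(mean=np.log(0.3), sigma=0.35, size=n)
    reads = rng.lognormal(
        mean=np.log(design.library_size_median), sigma=design.library_size_sigma, size=n
    ).astype(np.int64)
    qc = pd.DataFrame(
        {
            "sample_id": meta["sample_id"],
            "degradation_fraction": degradation,
            "reads_assigned": reads,
            "intron_exon_ratio": ratio,
            "planted_outlier": False,
        }
    )
    outliers = _planted_outliers(meta, design, np.random.default_rng(design.seed))
    if outliers:
        q_deg = np.quantile(degradation, 0.95)
        q_rat = np.quantile(ratio, 0.95)
        sel = qc["sample_id"].isin(outliers)
        qc.loc[sel, "degradation_fraction"] = np.minimum(q_deg * 1.5, 0.99)
        qc.loc[sel, "intron_exon_ratio"] = q_rat * 1.5
        qc.loc[sel, "planted_outlier"] = True

    # exon fixture: 20 genes with randomized read placement over <=5 exons;
    # the first gene's reads sit only in its 3'-most exon
    rows = []
    for g in range(20):
        n_exons = int(rng.integers(2, 6))
        placements = rng.integers(0, 40, size=n_exons)
        if g == 0:
            placements[:] = 0
            placements[-1] = 25
        for e, cnt in enumerate(placements, start=1):
            rows.append({"gene": f"FIXG{g + 1:03d}", "exon_index": e, "count": int(cnt)})
    exon_fixture = pd.DataFrame(rows)
    return qc, exon_fixture


def simulate_reference_atlas(
    n_categories: int = 10,
    genes_per_category: int = 20,
    background_noise: float = 0.0,
    n_background_genes: int = 100,
    expression_level: float = 100.0,
    seed: int = 0,
    planted: dict[str, list[str]] | None = None,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Category x gene mean-expression atlas with known profile genes.

    Each category owns ``genes_per_category`` genes expressed at
    ``expression_level`` in it and at ``background_noise x level x U(0,1)``
    elsewhere; background genes are expressed uniformly everywhere.
    ``planted`` optionally names the profile genes per category (e.g. to
    align the atlas with a simulated cohort's differential genes).
    Returns (genes x categories table, category -> profile genes).
    """
    if n_categories < 2:
        raise ValidationError("need >= 2 categories")
    rng = np.random.default_rng(seed)
    if planted is None:
        categories = [f"cat{i + 1:02d}" for i in range(n_categories)]
        planted = {
            c: [f"{c}-g{j + 1:02d}" for j in range(genes_per_category)]
            for c in categories
        }
    categories = list(planted)
    profile_genes = [g for genes in planted.values() for g in genes]
    background = [f"bg-g{j + 1:03d}" for j in range(n_background_genes)]
    all_genes = profile_genes + background
    x = background_noise * expression_level * rng.random((len(all_genes), len(categories)))
    atlas = pd.DataFrame(x, index=all_genes, columns=categories)
    for c, genes in planted.items():
        atlas.loc[genes, c] = expression_level
    atlas.loc[background, :] = expression_level * 0.5
    return atlas, {c: list(g) for c, g in planted.items()}
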