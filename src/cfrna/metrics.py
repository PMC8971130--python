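"""Diagnostic performance with Jeffreys binomial intervals and a
binormal-approximation AUROC CI.

Confusion-matrix proportions (sensitivity, specificity, PPV, NPV) carry
90% Jeffreys intervals — quantiles of Beta(x + 1/2, n - x + 1/2), with
the conventional exact endpoints at x = 0 and x = n. AUROC is the
rank-statistic (ties counted half) with a Hanley-McNeil
binormal-exponential standard error by default; a nonparametric
bootstrap CI is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ValidationError


@dataclass
class ConfusionMatrix:
    tn: int
    fp: int
    fn: int
    tp: int

    def __post_init__(self) -> None:
        if min(self.tn, self.fp, self.fn, self.tp) < 0:
            raise ValidationError("confusion-matrix entries must be >= 0")

    @property
    def total(self) -> int:
        return self.tn + self.fp + self.fn + self.tp

    @classmethod
    def from_labels(cls, truth, predicted) -> "ConfusionMatrix":
        truth = np.asarray(truth, dtype=bool)
        predicted = np.asarray(predicted, dtype=bool)
        return cls(
            tn=int(np.sum(~truth & ~predicted)),
            fp=int(np.sum(~truth & predicted)),
            fn=int(np.sum(truth & ~predicted)),
            tp=int(np.sum(truth & predicted)),
        )


@dataclass
class MetricWithCI:
    name: str
    estimate: float  # NaN when the denominator is zero (undefined, not 0)
    ci_low: float
    ci_high: float
    level: float = 0.90
    n: int = 0

    def as_percent(self) -> tuple[int, int, int]:
        """(estimate, low, high) rounded half-away-from-zero to whole percent."""

        def pct(v: float) -> int:
            return int(np.floor(v * 100.0 + 0.5))

        return pct(self.estimate), pct(self.ci_low), pct(self.ci_high)


def jeffreys_interval(successes: int, trials: int, level: float = 0.90) -> tuple[float, float]:
    """Jeffreys (Beta(x+1/2, n-x+1/2)) binomial interval.

    Endpoint convention: the lower bound is exactly 0 when x = 0 and the
    upper exactly 1 when x = n.
    """
    if trials < 1 or not 0 <= successes <= trials:
        raise ValidationError(f"invalid counts: {successes}/{trials}")
    alpha = 1.0 - level
    a, b = successes + 0.5, trials - successes + 0.5
    low = 0.0 if successes == 0 else float(stats.beta.ppf(alpha / 2.0, a, b))
    high = 1.0 if successes == trials else float(stats.beta.ppf(1.0 - alpha / 2.0, a, b))
    return max(0.0, low), min(1.0, high)


def _proportion_metric(name: str, num: int, den: int, level: float) -> MetricWithCI:
    if den == 0:
        return MetricWithCI(name=name, estimate=float("nan"), ci_low=float("nan"),
                            ci_high=float("nan"), level=level, n=0)
    lo, hi = jeffreys_interval(num, den, level=level)
    return MetricWithCI(name=name, estimate=num / den, ci_low=lo, ci_high=hi,
                        level=level, n=den)


def confusion_metrics(cm: ConfusionMatrix, level: float = 0.90) -> dict[str, MetricWithCI]:
    """Sensitivity, specificity, PPV and NPV with Jeffreys intervals."""
    return {
        "sensitivity": _proportion_metric("sensitivity", cm.tp, cm.tp + cm.fn, level),
        "specificity": _proportion_metric("specificity", cm.tn, cm.tn + cm.fp, level),
        "PPV": _proportion_metric("PPV", cm.tp, cm.tp + cm.fp, level),
        "NPV": _proportion_metric("NPV", cm.tn, cm.tn + cm.fn, level),
    }


def auroc(
    scores,
    labels,
    level: float = 0.90,
    method: str = "hanley-mcneil",
    n_boot: int = 2000,
    seed: int = 0,
) -> MetricWithCI:
    """AUROC by the rank statistic (ties half) with a parametric CI.

    ``method='hanley-mcneil'`` uses the binormal-exponential
    approximation Q1 = A/(2-A), Q2 = 2A^2/(1+A); ``method='bootstrap'``
    resamples samples with replacement. Bounds are clipped to [0, 1].
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("AUROC needs both classes")
    ranks = stats.rankdata(scores)
    a = (ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    z = stats.norm.ppf(1.0 - (1.0 - level) / 2.0)
    if method == "hanley-mcneil":
        q1 = a / (2.0 - a)
        q2 = 2.0 * a * a / (1.0 + a)
        var = (
            a * (1.0 - a) + (n_pos - 1) * (q1 - a * a) + (n_neg - 1) * (q2 - a * a)
        ) / (n_pos * n_neg)
        se = float(np.sqrt(max(var, 0.0)))
        lo, hi = a - z * se, a + z * se
    elif method == "bootstrap":
        rng = np.random.default_rng(seed)
        n = scores.size
        boots = []
        while len(boots) < n_boot:
            idx = rng.integers(0, n, size=n)
            lb = labels[idx]
            if lb.all() or not lb.any():
                continue
            r = stats.rankdata(scores[idx])
            np_, nn_ = int(lb.sum()), int((~lb).sum())
            boots.append((r[lb].sum() - np_ * (np_ + 1) / 2.0) / (np_ * nn_))
        alpha = (1.0 - level) / 2.0
        lo, hi = np.quantile(boots, [alpha, 1.0 - alpha])
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return MetricWithCI(
        name="AUROC", estimate=float(a), ci_low=float(max(0.0, lo)),
        ci_high=float(min(1.0, hi)), level=level, n=n_pos + n_neg,
    )


def misclassification_summary(
    predictions: pd.DataFrame,
    group_column: str | None = None,
    ga_restrict: float | None = None,
) -> dict:
    """Collection-timing and subgroup composition of misclassified samples.

    ``predictions`` needs columns ``truth`` (bool, case), ``predicted``
    (bool), ``ga_collection``; optionally a subgroup column. Reports mean
    and sd of gestational age at collection for false negatives vs true
    positives (rows marked n/a when empty), subgroup misclassification
    fractions vs cohort composition, and, when ``ga_restrict`` is given,
    the evaluated-sample count under the restricted window.
    """
    df = predictions
    out: dict = {}
    if ga_restrict is not None:
        df = df[df["ga_collection"] < ga_restrict]
        out["ga_restrict"] = ga_restrict
        out["n_evaluated"] = int(len(df))
    fn = df[df["truth"] & ~df["predicted"]]
    tp = df[df["truth"] & df["predicted"]]

    def _ga(sub: pd.DataFrame):
        if sub.empty:
            return {"n": 0, "mean_ga": None, "sd_ga": None}
        return {
            "n": int(len(sub)),
            "mean_ga": float(sub["ga_collection"].mean()),
            "sd_ga": float(sub["ga_collection"].std(ddof=1)) if len(sub) > 1 else 0.0,
        }

    out["false_negatives"] = _ga(fn)
    out["true_positives"] = _ga(tp)
    if group_column is not None and group_column in df.columns:
        mis = df[df["truth"] != df["predicted"]]
        out["group_composition"] = {
            "cohort": df[group_column].value_counts(normalize=True).to_dict(),
            "misclassified": (
                mis[group_column].value_counts(normalize=True).to_dict()
                if len(mis) else {}
            ),
        }
    return out


def probability_by_group(probabilities, groups) -> pd.DataFrame:
    """Mean and sd of predicted probability per group label."""
    df = pd.DataFrame({"probability": np.asarray(probabilities, dtype=float),
                       "group": list(groups)})
    if df.empty:
        raise ValidationError("empty predictions")
    agg = df.groupby("group")["probability"].agg(
        mean="mean", sd=lambda s: s.std(ddof=1) if len(s) > 1 else 0.0, n="size"
    )
    return agg.reset_index()
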