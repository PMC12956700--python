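"""Per-indicator group-difference testing and model-input selection.

Each indicator is compared between the high- and low-stress groups with a
two-sided two-sample t-test.  Student's pooled-variance test is used only
when both groups look normal (Shapiro-Wilk) and the variances are
homogeneous (Levene, mean-centred); otherwise Welch's unequal-variance
test is used.  Effect size is Cohen's d with the pooled SD in either case;
for equal group sizes this gives the identity d = t·√(2/n).  Indicators
with p < 0.05 are selected as classifier inputs; no multiple-testing
correction is applied (a deliberate, documented caveat).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .features import INDICATORS

logger = logging.getLogger("aerostress")

STUDENT_T = "student_t"
WELCH_T = "welch_t"

SIGNIFICANT = "significant"
MARGINAL = "marginal"
NOT_SIGNIFICANT = "not_significant"


@dataclass
class ScreeningRecord:
    indicator: str
    test_used: str
    t_stat: float
    p_value: float
    cohens_d: float
    mean_high: float
    mean_low: float
    verdict: str
    selected: bool

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def choose_test(group_a: np.ndarray, group_b: np.ndarray, alpha: float = 0.05) -> str:
    """Pick Student's or Welch's t-test from normality and homogeneity gates."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("need at least 3 values per group")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        logger.warning("constant group encountered; defaulting to Welch's t")
        return WELCH_T
    for g in (a, b):
        if stats.shapiro(g).pvalue < alpha:
            return WELCH_T
    if stats.levene(a, b, center="mean").pvalue < alpha:
        return WELCH_T
    return STUDENT_T


def pooled_cohens_d(high: np.ndarray, low: np.ndarray) -> float:
    """(mean_high − mean_low) / pooled SD, sample-variance pooling."""
    n1, n2 = high.size, low.size
    s2 = ((n1 - 1) * np.var(high, ddof=1) + (n2 - 1) * np.var(low, ddof=1)) / (
        n1 + n2 - 2
    )
    if s2 == 0:
        return 0.0
    return float((np.mean(high) - np.mean(low)) / math.sqrt(s2))


def cohens_d_from_t(t: float, n1: int, n2: int) -> float:
    """Recover pooled-SD Cohen's d from a t statistic and group sizes."""
    return t * math.sqrt(1.0 / n1 + 1.0 / n2)


def run_screening(
    features: pd.DataFrame,
    alpha: float = 0.05,
    marginal_alpha: float = 0.1,
) -> list[ScreeningRecord]:
    """Test every indicator's high-vs-low difference.

    Missing values are dropped per indicator with a logged count.
    """
    labels = set(features["label"])
    if not {"high", "low"} <= labels:
        raise ValueError("feature table must contain both high and low labels")
    records = []
    for ind in INDICATORS:
        high = features.loc[features["label"] == "high", ind].to_numpy(dtype=float)
        low = features.loc[features["label"] == "low", ind].to_numpy(dtype=float)
        n_missing = int(np.isnan(high).sum() + np.isnan(low).sum())
        if n_missing:
            logger.info("%s: dropped %d missing value(s)", ind, n_missing)
        high, low = high[~np.isnan(high)], low[~np.isnan(low)]
        test = choose_test(high, low, alpha=alpha)
        res = stats.ttest_ind(high, low, equal_var=(test == STUDENT_T))
        p = float(res.pvalue)
        verdict = (
            SIGNIFICANT if p < alpha
            else MARGINAL if p < marginal_alpha
            else NOT_SIGNIFICANT
        )
        records.append(
            ScreeningRecord(
                indicator=ind,
                test_used=test,
                t_stat=float(res.statistic),
                p_value=p,
                cohens_d=pooled_cohens_d(high, low),
                mean_high=float(np.mean(high)),
                mean_low=float(np.mean(low)),
                verdict=verdict,
                selected=p < alpha,
            )
        )
    return records


def select_features(records: list[ScreeningRecord]) -> list[str]:
    """Significant indicators in canonical order; marginal ones excluded."""
    order = {name: i for i, name in enumerate(INDICATORS)}
    selected = sorted(
        (r.indicator for r in records if r.selected), key=order.__getitem__
    )
    if not selected:
        raise ValueError(
            "no indicator reached significance; consider a larger study"
        )
    return selected


def screening_table(records: list[ScreeningRecord]) -> pd.DataFrame:
    """CSV-ready report mirroring the indicator/test/t/p/d column layout."""
    return pd.DataFrame([r.to_dict() for r in records])
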