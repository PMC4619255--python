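"""Paired high/low comparisons: means, H/L fold ratios and paired t-tests.

Summaries follow the matched-pair conventions of the study design: a pair
with a flagged (invalid) measurement in either member is excluded entirely
from that feature's summary; fold change is the ratio of the high-emitter
mean to the low-emitter mean over the remaining pairs; inference is a
two-sided paired t-test on within-pair (high - low) differences.
P values are reported unadjusted by design (exploratory screening);
Benjamini-Hochberg adjusted values are available as an additive column.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .panel import AnimalPanel

__all__ = [
    "PairedSummary",
    "PairedTestResult",
    "paired_summary",
    "paired_t_test",
    "compare_features",
]


@dataclass(frozen=True)
class PairedSummary:
    feature_id: str
    mean_low: float
    mean_high: float
    ratio_hl: float | None  # None when mean_low == 0 (undefined, never inf)
    n_pairs_used: int
    excluded_pairs: tuple[str, ...] = ()


@dataclass(frozen=True)
class PairedTestResult:
    feature_id: str
    t: float
    df: int
    p: float | None  # None when the differences are degenerate
    degenerate: bool = False


def _usable_pairs(
    values: Mapping[str, float],
    panel: AnimalPanel,
    flags: set[str] | None,
) -> tuple[list[tuple[float, float]], list[str], list[str]]:
    """Per-pair (low, high) values after pairwise deletion of flagged pairs."""
    flagged = set(flags) if flags is not None else set()
    flagged |= panel.flagged_animals()
    pairs, used, excluded = [], [], []
    for pair_id in panel.pair_ids:
        low = panel.member(pair_id, "low")["animal_id"]
        high = panel.member(pair_id, "high")["animal_id"]
        if (
            low in flagged
            or high in flagged
            or low not in values
            or high not in values
            or pd.isna(values[low])
            or pd.isna(values[high])
        ):
            excluded.append(pair_id)
            continue
        pairs.append((float(values[low]), float(values[high])))
        used.append(pair_id)
    return pairs, used, excluded


def paired_summary(
    values: Mapping[str, float],
    panel: AnimalPanel,
    flags: set[str] | None = None,
    feature_id: str = "",
) -> PairedSummary:
    """Low/high means and H/L ratio with flagged-pair exclusion.

    ``values`` maps animal_id to the measured value.  A pair with either
    member flagged (or missing) is dropped from both means.  The ratio is
    undefined (None) when the low mean is zero.
    """
    pairs, used, excluded = _usable_pairs(values, panel, flags)
    if not pairs:
        raise ValueError(f"no usable pairs for feature {feature_id!r}")
    lows = np.array([p[0] for p in pairs])
    highs = np.array([p[1] for p in pairs])
    mean_low = float(lows.mean())
    mean_high = float(highs.mean())
    ratio = mean_high / mean_low if mean_low > 0 else None
    return PairedSummary(
        feature_id=feature_id,
        mean_low=mean_low,
        mean_high=mean_high,
        ratio_hl=ratio,
        n_pairs_used=len(pairs),
        excluded_pairs=tuple(excluded),
    )


def paired_t_test(
    values: Mapping[str, float],
    panel: AnimalPanel,
    flags: set[str] | None = None,
    feature_id: str = "",
) -> PairedTestResult:
    """Two-sided paired t-test on (high - low) differences; df = pairs - 1."""
    pairs, used, _ = _usable_pairs(values, panel, flags)
    if len(pairs) < 2:
        raise ValueError("paired t-test needs at least 2 usable pairs")
    diffs = np.array([h - l for l, h in pairs])
    if np.allclose(diffs.std(ddof=1), 0.0):
        return PairedTestResult(feature_id, float("nan"), len(pairs) - 1, None, True)
    res = stats.ttest_rel([p[1] for p in pairs], [p[0] for p in pairs])
    return PairedTestResult(
        feature_id=feature_id,
        t=float(res.statistic),
        df=len(pairs) - 1,
        p=float(res.pvalue),
    )


def compare_features(
    matrix: pd.DataFrame,
    panel: AnimalPanel,
    flags: set[str] | None = None,
    bh_adjust: bool = False,
) -> pd.DataFrame:
    """Paired summary + t-test per column of an animals x features matrix.

    Rows of ``matrix`` are indexed by animal_id.  Returns one row per
    feature: mean_low, mean_high, ratio_hl, n_pairs_used, t, df, p — and,
    only when ``bh_adjust`` is set, an additional ``p_bh`` column (the
    unadjusted p column is never altered).
    """
    rows = []
    for feature in matrix.columns:
        values = matrix[feature].to_dict()
        summ = paired_summary(values, panel, flags, feature_id=str(feature))
        if summ.n_pairs_used >= 2:
            test = paired_t_test(values, panel, flags, feature_id=str(feature))
        else:
            test = PairedTestResult(str(feature), float("nan"), 0, None, True)
        rows.append(
            {
                "feature_id": str(feature),
                "mean_low": summ.mean_low,
                "mean_high": summ.mean_high,
                "ratio_hl": summ.ratio_hl if summ.ratio_hl is not None else np.nan,
                "n_pairs_used": summ.n_pairs_used,
                "t": test.t,
                "df": test.df,
                "p": test.p if test.p is not None else np.nan,
            }
        )
    out = pd.DataFrame(rows).set_index("feature_id")
    if bh_adjust:
        from statsmodels.stats.multitest import multipletests

        mask = out["p"].notna()
        p_bh = pd.Series(np.nan, index=out.index)
        if mask.any():
            p_bh[mask] = multipletests(out.loc[mask, "p"], method="fdr_bh")[1]
        out["p_bh"] = p_bh
    return out
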