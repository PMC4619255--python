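"""Alpha-diversity summaries on genus count tables.

Shannon index (natural log) for richness-and-evenness, Chao1 for estimated
total richness.  Both operate on raw integer counts; Shannon is invariant
to uniform scaling but Chao1 is not (it depends on singletons/doubletons),
so tables must carry counts, not percentages.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .abundance import AbundanceTable

__all__ = ["DiversityResult", "shannon", "chao1", "diversity_result", "write_diversity"]


def _as_counts(counts) -> np.ndarray:
    if isinstance(counts, Mapping):
        arr = np.asarray(list(counts.values()), dtype=float)
    else:
        arr = np.asarray(pd.Series(counts).to_numpy(), dtype=float)
    if arr.size == 0 or not (arr > 0).any():
        raise ValueError("diversity needs at least one positive count")
    if (arr < 0).any():
        raise ValueError("negative counts")
    return arr


def shannon(counts) -> float:
    """Shannon index H = -sum p_i ln p_i in nats, over positive counts."""
    arr = _as_counts(counts)
    arr = arr[arr > 0]
    p = arr / arr.sum()
    return float(-(p * np.log(p)).sum())


def chao1(counts) -> float:
    """Chao1 richness: S_obs + F1^2/(2 F2), bias-corrected when F2 = 0.

    F1/F2 are the singleton/doubleton counts.  With no doubletons the
    classic form divides by zero; the standard bias-corrected fallback
    S_obs + F1(F1-1)/(2(F2+1)) is used, which reduces to S_obs when F1 <= 1.
    """
    arr = _as_counts(counts)
    arr = arr[arr > 0]
    s_obs = arr.size
    f1 = int((arr == 1).sum())
    f2 = int((arr == 2).sum())
    if f2 > 0:
        return float(s_obs + f1 * f1 / (2.0 * f2))
    return float(s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1)))


@dataclass(frozen=True)
class DiversityResult:
    sample_id: str
    shannon: float
    chao1: float
    s_obs: int
    f1: int
    f2: int


def diversity_result(table: AbundanceTable) -> DiversityResult:
    arr = _as_counts(table.counts)
    arr = arr[arr > 0]
    return DiversityResult(
        sample_id=table.sample_id,
        shannon=shannon(table.counts),
        chao1=chao1(table.counts),
        s_obs=int(arr.size),
        f1=int((arr == 1).sum()),
        f2=int((arr == 2).sum()),
    )


def write_diversity(results: list[DiversityResult], path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in results],
            "shannon": [r.shannon for r in results],
            "chao1": [r.chao1 for r in results],
            "s_obs": [r.s_obs for r in results],
            "f1": [r.f1 for r in results],
            "f2": [r.f2 for r in results],
        }
    ).to_csv(path, sep="\t", index=False)
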