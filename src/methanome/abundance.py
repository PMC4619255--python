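"""Sample-level abundance tables (counts and percentages at a stated rank).

A table records integer counts per taxon (or per KEGG orthologue), the
denominator they are normalised against, and — crucially for the archaeal
reporting conventions — *which* denominator that is, since archaeal genera
are conventionally expressed relative to the bacterial read count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from .taxonomy import Lineage

__all__ = ["AbundanceTable", "read_abundance_table", "write_abundance_tables"]


@dataclass
class AbundanceTable:
    """Counts per taxon/KO for one sample at one level.

    ``level`` is a rank name ("kingdom", ..., "genus") or "KO".
    ``denominator`` is the count the percentages are computed against; when
    it differs from ``sum(counts)`` (e.g. archaeal genera over the bacterial
    read count) percentages need not sum to 100.
    ``lineages`` optionally maps each taxon label to its full lineage.
    """

    sample_id: str
    level: str
    counts: "pd.Series[int]"
    denominator: int
    denominator_label: str = "level_total"
    lineages: dict[str, Lineage] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.counts = pd.Series(self.counts, dtype="int64")
        self.counts.index = self.counts.index.astype(str)
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        if self.denominator < 0:
            raise ValueError("negative denominator")

    @property
    def percent(self) -> "pd.Series[float]":
        if self.denominator == 0:
            return pd.Series(dtype=float, index=self.counts.index)
        return 100.0 * self.counts / self.denominator

    def get_percent(self, taxon: str) -> float:
        if self.denominator == 0:
            raise ZeroDivisionError("denominator is 0")
        return 100.0 * int(self.counts.get(taxon, 0)) / self.denominator

    def to_frame(self) -> pd.DataFrame:
        pct = self.percent
        return pd.DataFrame(
            {
                "sample_id": self.sample_id,
                "level": self.level,
                "taxon": self.counts.index,
                "count": self.counts.values,
                "percent": [pct[t] for t in self.counts.index],
                "denominator": self.denominator,
                "denominator_label": self.denominator_label,
            }
        )


def write_abundance_tables(tables: list[AbundanceTable], path: str | Path) -> None:
    frames = [t.to_frame() for t in tables]
    out = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(
            columns=[
                "sample_id", "level", "taxon", "count",
                "percent", "denominator", "denominator_label",
            ]
        )
    )
    out.to_csv(path, sep="\t", index=False)


def read_abundance_table(path: str | Path) -> list[AbundanceTable]:
    """Read back a TSV written by :func:`write_abundance_tables`."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "taxon": str})
    tables = []
    for (sample, level, denom_label), grp in df.groupby(
        ["sample_id", "level", "denominator_label"], sort=False
    ):
        denominator = int(grp["denominator"].iloc[0])
        counts = pd.Series(grp["count"].values, index=grp["taxon"].values)
        tables.append(
            AbundanceTable(
                sample_id=str(sample),
                level=str(level),
                counts=counts,
                denominator=denominator,
                denominator_label=str(denom_label),
            )
        )
    return tables
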