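"""Paired animal panel: metadata and methane phenotype.

The design is a matched-pair one: each pair holds one high- and one
low-methane-emitting animal of the same breed and diet.  The phenotype is
methane yield in g CH4 per kg dry-matter intake (DMI).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = ["AnimalPanel", "read_panel"]

BREEDS = ("AA", "L")  # Aberdeen-Angus cross, Limousin cross
DIETS = ("Conc", "Med")  # high-concentrate, medium (forage:concentrate) diet
CLASSES = ("low", "high")

PANEL_COLUMNS = [
    "animal_id", "pair_id", "breed", "diet", "emitter_class", "ch4_g_per_kg_dmi",
]


@dataclass
class AnimalPanel:
    """Animal metadata table with pair-structure validation.

    ``animals`` columns: animal_id, pair_id, breed, diet, emitter_class,
    ch4_g_per_kg_dmi, and optionally dmi_kg_d and flagged (boolean mark for
    an invalid measurement on that animal).
    """

    animals: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.animals.copy()
        missing = [c for c in PANEL_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"panel missing columns {missing}")
        df["animal_id"] = df["animal_id"].astype(str)
        df["pair_id"] = df["pair_id"].astype(str)
        if "flagged" not in df.columns:
            df["flagged"] = False
        df["flagged"] = df["flagged"].astype(bool)
        if df["animal_id"].duplicated().any():
            raise ValueError("duplicate animal_id in panel")
        bad_class = set(df["emitter_class"]) - set(CLASSES)
        if bad_class:
            raise ValueError(f"unknown emitter_class values {sorted(bad_class)}")
        for pair_id, grp in df.groupby("pair_id"):
            if sorted(grp["emitter_class"]) != ["high", "low"]:
                raise ValueError(
                    f"pair {pair_id!r} must have exactly one high and one low animal"
                )
            if grp["breed"].nunique() != 1 or grp["diet"].nunique() != 1:
                raise ValueError(f"pair {pair_id!r} mixes breeds or diets")
        self.animals = df.reset_index(drop=True)

    @property
    def animal_ids(self) -> list[str]:
        return list(self.animals["animal_id"])

    @property
    def pair_ids(self) -> list[str]:
        return list(dict.fromkeys(self.animals["pair_id"]))

    @property
    def n_pairs(self) -> int:
        return len(self.pair_ids)

    def member(self, pair_id: str, emitter_class: str) -> pd.Series:
        df = self.animals
        row = df[(df["pair_id"] == pair_id) & (df["emitter_class"] == emitter_class)]
        return row.iloc[0]

    def ch4(self) -> pd.Series:
        return pd.Series(
            self.animals["ch4_g_per_kg_dmi"].values,
            index=self.animals["animal_id"].values,
            name="ch4_g_per_kg_dmi",
        )

    def indicator(self, column: str, value) -> pd.Series:
        """0/1 indicator for column == value, indexed by animal_id."""
        return pd.Series(
            (self.animals[column] == value).astype(float).values,
            index=self.animals["animal_id"].values,
            name=f"{column}_{value}",
        )

    def flagged_animals(self) -> set[str]:
        return set(self.animals.loc[self.animals["flagged"], "animal_id"])

    def write(self, path: str | Path) -> None:
        self.animals.to_csv(path, sep="\t", index=False)


def read_panel(path: str | Path) -> AnimalPanel:
    return AnimalPanel(pd.read_csv(path, sep="\t"))
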