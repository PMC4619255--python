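"""Published per-pair summary values from the beef-steer methane study.

These are the printed worked-example inputs: four breed/diet-matched pairs
of steers (Aberdeen-Angus or Limousin cross; high-concentrate or mixed
diet), each pair holding the highest and lowest methane emitter of its
group.  Values are as printed (2 dp for percentages), so statistics
recomputed from them agree with the published ones only to rounding.

``qpcr`` rows are 16S rRNA gene copies/ng DNA; ``metagenome_pct`` rows are
percentages of mapped 16S reads (domain rows of the whole community,
genus/phylum rows of the bacterial count for archaeal taxa — the
published convention).
"""

from __future__ import annotations

import pandas as pd

from .panel import AnimalPanel

__all__ = ["PAIR_LABELS", "ch4_g_per_kg_dmi", "qpcr", "metagenome_pct", "study_panel"]

PAIR_LABELS = ("AA_Conc", "L_Conc", "AA_Med", "L_Med")

#: g CH4 / kg DM intake, (low, high) per pair
ch4_g_per_kg_dmi = {
    "AA_Conc": (7.63, 18.14),
    "L_Conc": (9.29, 20.13),
    "AA_Med": (17.41, 32.42),
    "L_Med": (19.37, 30.37),
}

#: qPCR 16S rRNA abundances, copies/ng DNA, (low, high) per pair
qpcr = {
    "Bacteria": {
        "AA_Conc": (923503, 1026155),
        "L_Conc": (964081, 572312),
        "AA_Med": (891432, 575574),
        "L_Med": (563798, 595201),
    },
    "Archaea": {
        "AA_Conc": (23269, 72076),
        "L_Conc": (21459, 40242),
        "AA_Med": (19662, 54880),
        "L_Med": (37006, 75912),
    },
}

#: 16S-read percentages from the metagenome, (low, high) per pair
metagenome_pct = {
    "Bacteria": {  # domain, % of mapped reads
        "AA_Conc": (98.84, 97.72),
        "L_Conc": (99.24, 95.08),
        "AA_Med": (98.82, 96.60),
        "L_Med": (97.07, 95.60),
    },
    "Archaea": {  # domain, % relative to bacteria
        "AA_Conc": (1.16, 2.28),
        "L_Conc": (0.76, 4.92),
        "AA_Med": (1.18, 3.40),
        "L_Med": (2.93, 4.40),
    },
    "Firmicutes": {
        "AA_Conc": (45.25, 43.11),
        "L_Conc": (48.81, 40.47),
        "AA_Med": (43.93, 46.31),
        "L_Med": (39.50, 52.74),
    },
    "Bacteroidetes": {
        "AA_Conc": (36.21, 40.06),
        "L_Conc": (25.70, 45.33),
        "AA_Med": (34.53, 36.47),
        "L_Med": (49.98, 31.64),
    },
    "Proteobacteria": {
        "AA_Conc": (11.93, 3.71),
        "L_Conc": (17.15, 4.44),
        "AA_Med": (13.17, 1.92),
        "L_Med": (2.56, 0.83),
    },
    "Methanobrevibacter": {  # genus, % relative to bacteria
        "AA_Conc": (2.27, 4.93),
        "L_Conc": (1.88, 8.40),
        "AA_Med": (2.73, 7.49),
        "L_Med": (5.62, 11.00),
    },
    "Methanosphaera": {  # genus, % relative to bacteria
        "AA_Conc": (0.01, 0.04),
        "L_Conc": (0.01, 0.05),
        "AA_Med": (0.06, 0.08),
        "L_Med": (0.07, 0.13),
    },
    "Megasphaera": {
        "AA_Conc": (0.82, 0.05),
        "L_Conc": (0.46, 0.06),
        "AA_Med": (0.70, 0.05),
        "L_Med": (0.01, 0.00),
    },
}


def study_panel() -> AnimalPanel:
    """The eight-animal paired panel with its printed methane phenotypes."""
    rows = []
    for pair in PAIR_LABELS:
        breed, diet = pair.split("_")
        low, high = ch4_g_per_kg_dmi[pair]
        rows.append((f"{pair}_low", pair, breed, diet, "low", low))
        rows.append((f"{pair}_high", pair, breed, diet, "high", high))
    return AnimalPanel(
        pd.DataFrame(
            rows,
            columns=[
                "animal_id", "pair_id", "breed", "diet",
                "emitter_class", "ch4_g_per_kg_dmi",
            ],
        )
    )


def as_animal_values(per_pair: dict[str, tuple[float, float]]) -> dict[str, float]:
    """Spread a per-pair (low, high) dict onto the study panel's animal ids."""
    values: dict[str, float] = {}
    for pair, (low, high) in per_pair.items():
        values[f"{pair}_low"] = low
        values[f"{pair}_high"] = high
    return values
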