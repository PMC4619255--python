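import numpy as np
import pandas as pd
import pytest

from methanome.panel import AnimalPanel
from methanome.study_tables import study_panel
from methanome.taxonomy import Lineage, ReferenceRecord


@pytest.fixture
def panel8() -> AnimalPanel:
    """The published eight-animal paired panel (four pairs, two breeds/diets)."""
    return study_panel()


@pytest.fixture
def small_reference() -> list[ReferenceRecord]:
    """A hand-built reference taxonomy spanning both kingdoms."""
    L = Lineage.from_labels
    return [
        ReferenceRecord("ref_succinivibrio", L("Bacteria", "Proteobacteria", "Gammaproteobacteria", "Aeromonadales", "Succinivibrionaceae", "Succinivibrio")),
        ReferenceRecord("ref_anaerobiospirillum", L("Bacteria", "Proteobacteria", "Gammaproteobacteria", "Aeromonadales", "Succinivibrionaceae", "Anaerobiospirillum")),
        ReferenceRecord("ref_prevotella", L("Bacteria", "Bacteroidetes", "Bacteroidia", "Bacteroidales", "Prevotellaceae", "Prevotella")),
        ReferenceRecord("ref_mbb1", L("Archaea", "Euryarchaeota", "Methanobacteria", "Methanobacteriales", "Methanobacteriaceae", "Methanobrevibacter")),
        ReferenceRecord("ref_mbb2", L("Archaea", "Euryarchaeota", "Methanobacteria", "Methanobacteriales", "Methanobacteriaceae", "Methanobrevibacter")),
        ReferenceRecord("ref_msp", L("Archaea", "Euryarchaeota", "Methanobacteria", "Methanobacteriales", "Methanobacteriaceae", "Methanosphaera")),
        ReferenceRecord("ref_family_only", L("Archaea", "Euryarchaeota", "Methanobacteria")),
    ]


def random_lineages(rng: np.random.Generator, n_taxa: int = 30) -> list[Lineage]:
    """A random consistent taxonomy: labels nest properly within parents."""
    lineages = []
    for _ in range(n_taxa):
        kingdom = f"K{rng.integers(2)}"
        labels = [kingdom]
        for depth in range(1, 6):
            # branch narrowly so lineages share prefixes often
            labels.append(f"{labels[-1]}.{rng.integers(2)}")
        depth = int(rng.integers(1, 7))  # allow truncated lineages
        labels = labels[:depth] + [""] * (6 - depth)
        lineages.append(Lineage(tuple(labels)))
    return lineages


def brute_force_lca(lineages):
    """Independent oracle: rank-by-rank top-down label-set intersection."""
    labels = []
    agreed = None
    for r in range(6):
        level = {l.labels[r] for l in lineages}
        if len(level) == 1 and "" not in level:
            labels.append(next(iter(level)))
            agreed = r
        else:
            break
    labels += [""] * (6 - len(labels))
    return tuple(labels), agreed
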