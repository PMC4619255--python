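"""Synthetic data with the statistical structure the analysis assumes.

Generators for every input the pipeline consumes: a ranked reference
taxonomy, read-level alignment hit tables with controllable multi-hit
ambiguity, KO-annotated hit tables, and a paired animal panel with taxon
and KO abundance matrices carrying planted high/low-emitter effects.

The default parameters are the study conditions: four matched pairs across
two breeds and two diets; methane yields centred at 13.43 (low) and 25.26
(high) g CH4/kg DMI; a rumen-like community (Firmicutes ~44 %,
Bacteroidetes ~40 %, Proteobacteria ~11 % in low emitters, archaea ~1.5 %)
with archaea 2.5x and Proteobacteria 0.24x planted high/low multipliers;
and methanogenesis-gene abundances 2.82x (SD 0.27) higher in high emitters.
Methane couples to total archaeal abundance, reflecting the mechanism that
archaeal biomass yield is proportional to methane formed.  Abundance noise
is multiplicative lognormal, matching the ratio-scale reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .panel import AnimalPanel
from .taxonomy import KOMap, Lineage, Rank, ReferenceRecord

__all__ = [
    "TaxonSpec",
    "PanelSpec",
    "CommunitySpec",
    "KOEffectSpec",
    "SimulatedPanel",
    "default_community",
    "make_taxonomy",
    "simulate_hits",
    "simulate_ko_hits",
    "simulate_panel",
]

#: methanogenesis-pathway KEGG orthologues carrying the planted effect
METHANOGENESIS_KOS = (
    "K00399", "K00401", "K00200", "K00201", "K03388", "K14126", "K02117", "K02118",
)


@dataclass(frozen=True)
class TaxonSpec:
    genus: str
    kingdom: str
    phylum: str
    class_: str
    order: str
    family: str
    baseline: float           # low-emitter relative abundance (fraction)
    hl_multiplier: float = 1.0  # planted high/low fold effect

    @property
    def lineage(self) -> Lineage:
        return Lineage.from_labels(
            self.kingdom, self.phylum, self.class_, self.order, self.family, self.genus
        )


def default_community() -> list[TaxonSpec]:
    """Rumen-like community template (low-emitter baselines sum to 1)."""
    B = "Bacteria"
    A = "Archaea"
    taxa = [
        # Bacteroidetes ~ 40 %
        TaxonSpec("Prevotella", B, "Bacteroidetes", "Bacteroidia", "Bacteroidales", "Prevotellaceae", 0.34),
        TaxonSpec("Bacteroides", B, "Bacteroidetes", "Bacteroidia", "Bacteroidales", "Bacteroidaceae", 0.06),
        # Firmicutes ~ 44 %
        TaxonSpec("Butyrivibrio", B, "Firmicutes", "Clostridia", "Clostridiales", "Lachnospiraceae", 0.10),
        TaxonSpec("Coprococcus", B, "Firmicutes", "Clostridia", "Clostridiales", "Lachnospiraceae", 0.05),
        TaxonSpec("Ruminococcus", B, "Firmicutes", "Clostridia", "Clostridiales", "Ruminococcaceae", 0.09),
        TaxonSpec("Succiniclasticum", B, "Firmicutes", "Clostridia", "Clostridiales", "Veillonellaceae", 0.13),
        TaxonSpec("Megasphaera", B, "Firmicutes", "Clostridia", "Clostridiales", "Veillonellaceae", 0.005, 0.08),
        TaxonSpec("Bulleidia", B, "Firmicutes", "Erysipelotrichi", "Erysipelotrichales", "Erysipelotrichaceae", 0.0685),
        # Proteobacteria ~ 11 % low, planted 0.24x in high emitters
        TaxonSpec("Succinivibrio", B, "Proteobacteria", "Gammaproteobacteria", "Aeromonadales", "Succinivibrionaceae", 0.092, 0.24),
        TaxonSpec("Ruminobacter", B, "Proteobacteria", "Gammaproteobacteria", "Aeromonadales", "Succinivibrionaceae", 0.02, 0.24),
        # minor phyla
        TaxonSpec("Bifidobacterium", B, "Actinobacteria", "Actinobacteria", "Bifidobacteriales", "Bifidobacteriaceae", 0.013),
        TaxonSpec("Treponema", B, "Spirochaetes", "Spirochaetes", "Spirochaetales", "Spirochaetaceae", 0.016),
        # archaea ~ 1.5 % low, planted 2.5x in high emitters
        TaxonSpec("Methanobrevibacter", A, "Euryarchaeota", "Methanobacteria", "Methanobacteriales", "Methanobacteriaceae", 0.014, 2.5),
        TaxonSpec("Methanosphaera", A, "Euryarchaeota", "Methanobacteria", "Methanobacteriales", "Methanobacteriaceae", 0.0015, 2.5),
    ]
    total = sum(t.baseline for t in taxa)
    assert abs(total - 1.0) < 1e-9, total
    return taxa


@dataclass(frozen=True)
class PanelSpec:
    n_pairs: int = 4
    ch4_mean_low: float = 13.43    # g CH4 / kg DMI
    ch4_mean_high: float = 25.26
    ch4_noise_sd: float = 2.0
    diet_half_effect: float = 5.0  # Med diet raises yield, Conc lowers it
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if self.ch4_noise_sd < 0:
            raise ValueError("ch4_noise_sd must be >= 0")


@dataclass(frozen=True)
class CommunitySpec:
    taxa: tuple[TaxonSpec, ...] = field(default_factory=lambda: tuple(default_community()))
    noise_sd: float = 0.3          # lognormal sigma on abundances
    dirichlet_concentration: float | None = None  # optional composition noise
    seed: int | None = None

    def __post_init__(self) -> None:
        total = sum(t.baseline for t in self.taxa)
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"baseline proportions sum to {total}, not 1")
        if any(t.hl_multiplier <= 0 for t in self.taxa):
            raise ValueError("multipliers must be > 0")
        genera = [t.genus for t in self.taxa]
        if len(set(genera)) != len(genera):
            raise ValueError("duplicate genus in community spec")

    def archaeal_genera(self) -> list[str]:
        return [t.genus for t in self.taxa if t.kingdom == "Archaea"]


@dataclass(frozen=True)
class KOEffectSpec:
    methanogenesis_kos: tuple[str, ...] = METHANOGENESIS_KOS
    multiplier_mean: float = 2.82
    multiplier_sd: float = 0.27
    n_null_kos: int = 100
    noise_sd: float = 0.3
    ch4_coupling: float = 100.0    # g CH4/kg DMI per unit archaeal abundance
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.multiplier_mean <= 0:
            raise ValueError("multiplier_mean must be > 0")
        if self.multiplier_sd < 0:
            raise ValueError("multiplier_sd must be >= 0")


def null_specs() -> tuple[PanelSpec, CommunitySpec, KOEffectSpec]:
    """Specs with every planted effect removed (for calibration runs)."""
    community = CommunitySpec(
        taxa=tuple(replace(t, hl_multiplier=1.0) for t in default_community())
    )
    kos = KOEffectSpec(multiplier_mean=1.0, multiplier_sd=0.0, ch4_coupling=0.0)
    return PanelSpec(), community, kos


# ---------------------------------------------------------------------------
# Taxonomy generation


def make_taxonomy(
    spec: CommunitySpec,
    seed: int | None = None,
    refs_per_genus: int = 2,
    decoys_per_family: int = 1,
) -> list[ReferenceRecord]:
    """A consistent six-rank reference taxonomy for the community.

    Each genus receives ``refs_per_genus`` reference entries (so multi-hit
    reads can be ambiguous *within* a genus), and each family receives
    ``decoys_per_family`` sibling decoy genera (so ambiguity can force the
    LCA up to family and beyond).  Deterministic for a given seed.
    """
    del seed  # construction is deterministic; kept for interface symmetry
    records: list[ReferenceRecord] = []
    ref_counter = 0

    def add(lineage: Lineage, n: int) -> None:
        nonlocal ref_counter
        for _ in range(n):
            ref_counter += 1
            records.append(ReferenceRecord(f"R{ref_counter:05d}", lineage))

    for taxon in spec.taxa:
        add(taxon.lineage, refs_per_genus)
    seen_families: set[tuple[str, ...]] = set()
    for taxon in spec.taxa:
        key = (taxon.kingdom, taxon.phylum, taxon.class_, taxon.order, taxon.family)
        if key in seen_families:
            continue
        seen_families.add(key)
        for d in range(decoys_per_family):
            decoy = Lineage.from_labels(
                taxon.kingdom, taxon.phylum, taxon.class_, taxon.order,
                taxon.family, f"{taxon.family}_decoy{d + 1}",
            )
            add(decoy, 1)
    lineage_by_genus: dict[str, Lineage] = {}
    for rec in records:
        genus = rec.lineage.label_at(Rank.GENUS)
        if lineage_by_genus.setdefault(genus, rec.lineage) != rec.lineage:
            raise ValueError(f"genus {genus!r} generated with two different lineages")
    return records


# ---------------------------------------------------------------------------
# Hit-table simulation


def simulate_hits(
    composition: Mapping[str, float],
    records: Sequence[ReferenceRecord],
    n_reads: int,
    ambiguity_rate: float = 0.1,
    ambiguity_rank: Rank = Rank.FAMILY,
    overcap_rate: float = 0.0,
    fragment_length: int = 200,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate a per-sample alignment hit table.

    Each fragment draws a source genus from ``composition`` and emits one
    hit, or — with probability ``ambiguity_rate`` — several equal-score hits
    whose lowest common taxon is at ``ambiguity_rank``.  A fraction
    ``overcap_rate`` of fragments get more than 10 % mismatches across the
    fragment and is therefore removed by downstream filtering.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be > 0")
    if not 0.0 <= ambiguity_rate <= 1.0:
        raise ValueError("ambiguity_rate must be in [0, 1]")
    genera = list(composition)
    probs = np.asarray([composition[g] for g in genera], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-6:
        raise ValueError("composition must sum to 1")

    by_genus: dict[str, list[ReferenceRecord]] = {}
    for rec in records:
        by_genus.setdefault(rec.lineage.label_at(Rank.GENUS), []).append(rec)
    unknown = [g for g in genera if g not in by_genus]
    if unknown:
        raise ValueError(f"composition genera missing from taxonomy: {unknown}")
    # partner refs for forcing an LCA exactly at ambiguity_rank: a reference
    # agreeing with the source through ambiguity_rank but differing below it
    def partners(genus: str) -> list[ReferenceRecord]:
        src = by_genus[genus][0].lineage
        if ambiguity_rank == Rank.GENUS:
            return by_genus[genus][1:]
        out = []
        for rec in records:
            lin = rec.lineage
            if (
                all(
                    lin.labels[r] == src.labels[r] and lin.labels[r] != ""
                    for r in Rank
                    if r <= ambiguity_rank
                )
                and lin.labels[ambiguity_rank + 1] != src.labels[ambiguity_rank + 1]
            ):
                out.append(rec)
        return out

    partner_cache = {g: partners(g) for g in genera}
    rng = np.random.default_rng(seed)
    cap = int(np.floor(0.10 * fragment_length))
    rows = []
    for i in range(n_reads):
        read_id = f"read{i:07d}"
        genus = genera[rng.choice(len(genera), p=probs)]
        if rng.random() < overcap_rate:
            mismatches = int(rng.integers(cap + 1, fragment_length // 2 + cap + 2))
        else:
            mismatches = int(min(rng.binomial(fragment_length, 0.02), cap))
        score = fragment_length - mismatches
        hits = [by_genus[genus][0]]
        if rng.random() < ambiguity_rate and partner_cache[genus]:
            extra = partner_cache[genus]
            hits.append(extra[rng.integers(len(extra))])
        for rec in hits:
            rows.append((read_id, rec.ref_id, score, mismatches, fragment_length))
    return pd.DataFrame(
        rows, columns=["read_id", "ref_id", "score", "mismatches", "fragment_length"]
    )


def simulate_ko_hits(
    ko_weights: Mapping[str, float],
    n_reads: int,
    ambiguity_rate: float = 0.1,
    no_annotation_rate: float = 0.05,
    fragment_length: int = 200,
    seed: int | None = None,
) -> tuple[pd.DataFrame, KOMap]:
    """Simulate a KO-annotated hit table plus its gene->KO map.

    Each KO gets two synthetic gene entries; an ambiguous fragment hits
    genes of two different KOs at equal score (and is therefore ignored by
    unique-KO resolution), and a ``no_annotation_rate`` fraction hits a gene
    absent from the KO map.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be > 0")
    kos = list(ko_weights)
    probs = np.asarray([ko_weights[k] for k in kos], dtype=float)
    probs = probs / probs.sum()
    komap = KOMap()
    for ko in kos:
        komap.add(f"{ko}_gene1", ko)
        komap.add(f"{ko}_gene2", ko)
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_reads):
        read_id = f"koread{i:07d}"
        mismatches = int(min(rng.binomial(fragment_length, 0.02), fragment_length // 10))
        score = fragment_length - mismatches
        ko = kos[rng.choice(len(kos), p=probs)]
        u = rng.random()
        if u < no_annotation_rate:
            genes = [f"unannotated_gene{i}"]
        elif u < no_annotation_rate + ambiguity_rate and len(kos) > 1:
            other = kos[rng.integers(len(kos) - 1)]
            if other == ko:
                other = kos[-1]
            genes = [f"{ko}_gene1", f"{other}_gene1"]
        else:
            genes = [f"{ko}_gene{rng.integers(1, 3)}"]
        for g in genes:
            rows.append((read_id, g, score, mismatches, fragment_length, g))
    df = pd.DataFrame(
        rows,
        columns=["read_id", "ref_id", "score", "mismatches", "fragment_length", "gene_id"],
    )
    return df, komap


# ---------------------------------------------------------------------------
# Panel simulation


@dataclass
class SimulatedPanel:
    panel: AnimalPanel
    taxon_abundance: pd.DataFrame   # animals x genera, relative units
    ko_abundance: pd.DataFrame      # animals x KOs, relative units
    composition: pd.DataFrame       # animals x genera, rows sum to 1
    ko_multipliers: pd.Series       # planted per-KO high/low multipliers


def _lognormal_noise(rng: np.random.Generator, sd: float, size) -> np.ndarray:
    if sd == 0:
        return np.ones(size)
    # mean-one lognormal so planted fold effects are unbiased
    return np.exp(rng.normal(0.0, sd, size=size) - 0.5 * sd * sd)


def simulate_panel(
    panel_spec: PanelSpec | None = None,
    community_spec: CommunitySpec | None = None,
    ko_spec: KOEffectSpec | None = None,
    seed: int | None = None,
) -> SimulatedPanel:
    """Generate a paired panel with planted taxon and KO high/low effects.

    Abundances are baseline x planted multiplier (high emitters only)
    x mean-one lognormal noise.  Methane yield is the emitter-class mean,
    plus a diet offset, plus ``ch4_coupling`` times the animal's deviation
    in total archaeal abundance from its class expectation, plus Gaussian
    noise — so within a class, methane tracks archaea.
    """
    panel_spec = panel_spec or PanelSpec()
    community_spec = community_spec or CommunitySpec()
    ko_spec = ko_spec or KOEffectSpec()
    if seed is None:
        seed = panel_spec.seed
    rng = np.random.default_rng(seed)

    combos = [("AA", "Conc"), ("L", "Conc"), ("AA", "Med"), ("L", "Med")]
    rows = []
    for p in range(panel_spec.n_pairs):
        breed, diet = combos[p % len(combos)]
        pair_id = f"P{p + 1:02d}"
        for cls in ("low", "high"):
            rows.append((f"{pair_id}_{cls}", pair_id, breed, diet, cls, np.nan))
    meta = pd.DataFrame(
        rows,
        columns=["animal_id", "pair_id", "breed", "diet", "emitter_class", "ch4_g_per_kg_dmi"],
    )
    n_animals = len(meta)
    is_high = (meta["emitter_class"] == "high").to_numpy()

    # taxon abundances
    genera = [t.genus for t in community_spec.taxa]
    baseline = np.array([t.baseline for t in community_spec.taxa])
    mult = np.array([t.hl_multiplier for t in community_spec.taxa])
    expected = np.where(is_high[:, None], baseline * mult, baseline)
    noise = _lognormal_noise(rng, community_spec.noise_sd, expected.shape)
    taxon_abund = pd.DataFrame(
        expected * noise, index=meta["animal_id"].values, columns=genera
    )

    # per-animal composition for read simulation
    comp_raw = taxon_abund.to_numpy()
    comp = comp_raw / comp_raw.sum(axis=1, keepdims=True)
    if community_spec.dirichlet_concentration is not None:
        conc = community_spec.dirichlet_concentration
        comp = np.vstack([rng.dirichlet(conc * row) for row in comp])
    composition = pd.DataFrame(comp, index=taxon_abund.index, columns=genera)

    # KO abundances
    n_meth = len(ko_spec.methanogenesis_kos)
    ko_mult = rng.normal(ko_spec.multiplier_mean, ko_spec.multiplier_sd, n_meth)
    ko_mult = np.clip(ko_mult, 0.05, None)
    null_kos = [f"K9{j:04d}" for j in range(ko_spec.n_null_kos)]
    ko_names = list(ko_spec.methanogenesis_kos) + null_kos
    ko_expected = np.ones((n_animals, len(ko_names)))
    ko_expected[:, :n_meth] = np.where(is_high[:, None], ko_mult, 1.0)
    ko_noise = _lognormal_noise(rng, ko_spec.noise_sd, ko_expected.shape)
    ko_abund = pd.DataFrame(
        ko_expected * ko_noise, index=meta["animal_id"].values, columns=ko_names
    )

    # methane phenotype
    arch_idx = [genera.index(g) for g in community_spec.archaeal_genera()]
    archaea = taxon_abund.to_numpy()[:, arch_idx].sum(axis=1)
    expected_archaea = expected[:, arch_idx].sum(axis=1)
    class_mean = np.where(is_high, panel_spec.ch4_mean_high, panel_spec.ch4_mean_low)
    diet_dev = np.where(
        meta["diet"].to_numpy() == "Med",
        panel_spec.diet_half_effect,
        -panel_spec.diet_half_effect,
    )
    ch4 = (
        class_mean
        + diet_dev
        + ko_spec.ch4_coupling * (archaea - expected_archaea)
        + (rng.normal(0.0, panel_spec.ch4_noise_sd, n_animals)
           if panel_spec.ch4_noise_sd > 0 else 0.0)
    )
    meta["ch4_g_per_kg_dmi"] = np.maximum(ch4, 0.1)

    return SimulatedPanel(
        panel=AnimalPanel(meta),
        taxon_abundance=taxon_abund,
        ko_abundance=ko_abund,
        composition=composition,
        ko_multipliers=pd.Series(ko_mult, index=list(ko_spec.methanogenesis_kos)),
    )
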