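"""Synthetic-data generators: determinism, planted effects, round-trips."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from methanome.hits import assign_kos, assign_taxa, filter_hits, tabulate_taxa
from methanome.simulate import (
    METHANOGENESIS_KOS,
    CommunitySpec,
    KOEffectSpec,
    PanelSpec,
    default_community,
    make_taxonomy,
    null_specs,
    simulate_hits,
    simulate_ko_hits,
    simulate_panel,
)
from methanome.taxonomy import Rank, parse_taxonomy, write_taxonomy


@pytest.fixture(scope="module")
def community():
    return CommunitySpec()


@pytest.fixture(scope="module")
def records(community):
    return make_taxonomy(community, seed=0)


class TestMakeTaxonomy:
    def test_deterministic(self, community):
        a = make_taxonomy(community, seed=1)
        b = make_taxonomy(community, seed=1)
        assert a == b

    def test_all_lineages_root_in_two_kingdoms(self, records):
        kingdoms = {r.lineage.label_at(Rank.KINGDOM) for r in records}
        assert kingdoms == {"Bacteria", "Archaea"}

    def test_every_spec_genus_present_distinct(self, community, records):
        genera = {r.lineage.label_at(Rank.GENUS) for r in records}
        wanted = {t.genus for t in community.taxa}
        assert wanted <= genera

    def test_round_trips_through_parser(self, records, tmp_path):
        path = tmp_path / "tax.tsv"
        write_taxonomy(records, path)
        assert parse_taxonomy(path) == records


class TestSimulateHits:
    def test_composition_recovered_without_ambiguity(self, community, records):
        composition = {t.genus: t.baseline for t in community.taxa}
        hits = simulate_hits(composition, records, n_reads=100_000,
                             ambiguity_rate=0.0, seed=5)
        assignments = assign_taxa(filter_hits(hits),
                                  {r.ref_id: r.lineage for r in records})
        table = tabulate_taxa(assignments, Rank.GENUS)
        for genus, expected in composition.items():
            observed = table.counts.get(genus, 0) / table.denominator
            se = np.sqrt(expected * (1 - expected) / table.denominator)
            assert abs(observed - expected) < max(5 * se, 5e-4), genus

    def test_full_family_ambiguity_empties_genus_table(self, community, records):
        composition = {t.genus: t.baseline for t in community.taxa}
        hits = simulate_hits(composition, records, n_reads=2000,
                             ambiguity_rate=1.0, ambiguity_rank=Rank.FAMILY, seed=6)
        assignments = assign_taxa(filter_hits(hits),
                                  {r.ref_id: r.lineage for r in records})
        assert all(a.assigned_rank == Rank.FAMILY for a in assignments)
        assert tabulate_taxa(assignments, Rank.GENUS).denominator == 0
        assert tabulate_taxa(assignments, Rank.FAMILY).denominator == len(assignments)

    def test_overcap_reads_absent_downstream(self, community, records):
        composition = {t.genus: t.baseline for t in community.taxa}
        hits = simulate_hits(composition, records, n_reads=5000,
                             ambiguity_rate=0.0, overcap_rate=0.2, seed=7)
        surviving = filter_hits(hits)["read_id"].nunique()
        assert surviving < 5000
        # binomial check on the 20 % drop rate
        assert abs(surviving / 5000 - 0.8) < 0.02

    def test_deterministic(self, community, records):
        composition = {t.genus: t.baseline for t in community.taxa}
        a = simulate_hits(composition, records, 500, seed=3)
        b = simulate_hits(composition, records, 500, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_inputs_rejected(self, community, records):
        composition = {t.genus: t.baseline for t in community.taxa}
        with pytest.raises(ValueError):
            simulate_hits(composition, records, n_reads=0)
        bad = dict(composition)
        bad["Prevotella"] = 0.9
        with pytest.raises(ValueError):
            simulate_hits(bad, records, n_reads=10)


class TestSimulateKOHits:
    def test_ambiguous_fraction_never_assigned(self):
        weights = {ko: 1.0 for ko in METHANOGENESIS_KOS}
        hits, komap = simulate_ko_hits(weights, n_reads=4000, ambiguity_rate=0.3,
                                       no_annotation_rate=0.1, seed=9)
        assignments = assign_kos(filter_hits(hits), komap)
        unassigned = sum(a.ko_id is None for a in assignments)
        assert len(assignments) == 4000
        # ~40 % should be unassigned (ambiguous + unannotated)
        assert abs(unassigned / 4000 - 0.4) < 0.03


class TestSimulatePanel:
    def test_zero_noise_ratio_exact(self):
        sim = simulate_panel(
            PanelSpec(ch4_noise_sd=0.0),
            CommunitySpec(noise_sd=0.0),
            KOEffectSpec(noise_sd=0.0, multiplier_sd=0.0),
            seed=1,
        )
        high = (sim.panel.animals["emitter_class"] == "high").to_numpy()
        arch = sim.taxon_abundance[["Methanobrevibacter", "Methanosphaera"]].sum(axis=1)
        ratio = arch[high].mean() / arch[~high].mean()
        assert ratio == pytest.approx(2.5, abs=1e-12)
        meth = sim.ko_abundance[list(METHANOGENESIS_KOS)]
        ko_ratio = meth[high].mean() / meth[~high].mean()
        assert np.allclose(ko_ratio, 2.82)

    def test_mean_archaea_ratio_across_seeds(self):
        ratios = []
        for seed in range(100):
            sim = simulate_panel(seed=seed)
            high = (sim.panel.animals["emitter_class"] == "high").to_numpy()
            arch = sim.taxon_abundance[["Methanobrevibacter", "Methanosphaera"]].sum(axis=1)
            ratios.append(arch[high].mean() / arch[~high].mean())
        mean = np.mean(ratios)
        mc_half_width = 3 * np.std(ratios) / np.sqrt(len(ratios))
        assert abs(mean - 2.5) < max(mc_half_width, 0.05)

    def test_same_seed_bit_identical(self):
        a = simulate_panel(seed=42)
        b = simulate_panel(seed=42)
        pd.testing.assert_frame_equal(a.taxon_abundance, b.taxon_abundance)
        pd.testing.assert_frame_equal(a.ko_abundance, b.ko_abundance)
        pd.testing.assert_frame_equal(a.panel.animals, b.panel.animals)

    def test_ch4_tracks_archaea_within_class(self):
        sim = simulate_panel(PanelSpec(n_pairs=40, ch4_noise_sd=0.5), seed=12)
        df = sim.panel.animals.set_index("animal_id")
        arch = sim.taxon_abundance[["Methanobrevibacter", "Methanosphaera"]].sum(axis=1)
        low = df["emitter_class"] == "low"
        corr = np.corrcoef(arch[low.values], df.loc[low, "ch4_g_per_kg_dmi"])[0, 1]
        assert corr > 0.3

    def test_null_specs_have_no_planted_effects(self):
        panel_spec, community, kos = null_specs()
        assert all(t.hl_multiplier == 1.0 for t in community.taxa)
        assert kos.multiplier_mean == 1.0 and kos.ch4_coupling == 0.0

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            PanelSpec(n_pairs=0)
        with pytest.raises(ValueError):
            KOEffectSpec(multiplier_mean=-1.0)
        taxa = default_community()
        with pytest.raises(ValueError, match="sum"):
            CommunitySpec(taxa=tuple(replace(t, baseline=t.baseline * 2) for t in taxa))
        with pytest.raises(ValueError, match="duplicate"):
            CommunitySpec(taxa=(replace(taxa[0], baseline=0.5),) * 2)
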