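"""Equal-best hit filtering, LCA/KO read assignment and tabulation."""

import numpy as np
import pandas as pd
import pytest

from methanome.hits import (
    archaea_to_bacteria_ratio,
    assign_kos,
    assign_taxa,
    filter_hits,
    relative_to_bacteria,
    tabulate_kos,
    tabulate_taxa,
)
from methanome.taxonomy import KOMap, Lineage, Rank, lowest_common_taxon

from conftest import brute_force_lca, random_lineages


def hit_frame(rows):
    cols = ["read_id", "ref_id", "score", "mismatches", "fragment_length"]
    if rows and len(rows[0]) == 6:
        cols.append("gene_id")
    return pd.DataFrame(rows, columns=cols)


class TestFilterHits:
    def test_mismatch_cap_is_ten_percent_of_fragment(self):
        hits = hit_frame([
            ("r1", "a", 90, 11, 100),   # 11 % -> removed
            ("r2", "a", 90, 10, 100),   # exactly 10 % -> kept
        ])
        out = filter_hits(hits)
        assert list(out["read_id"]) == ["r2"]

    def test_single_passing_hit_kept_unchanged(self):
        hits = hit_frame([("r1", "a", 55, 0, 100)])
        out = filter_hits(hits)
        pd.testing.assert_frame_equal(out.reset_index(drop=True), hits)

    def test_equal_best_retention(self):
        hits = hit_frame([
            ("r1", "a", 50, 1, 100),
            ("r1", "b", 50, 2, 100),
            ("r1", "c", 49, 0, 100),
        ])
        out = filter_hits(hits)
        assert sorted(out["ref_id"]) == ["a", "b"]

    def test_best_over_cap_does_not_mask_admissible_hits(self):
        # the cap applies before the equal-best comparison
        hits = hit_frame([
            ("r1", "a", 90, 30, 100),
            ("r1", "b", 60, 2, 100),
        ])
        out = filter_hits(hits)
        assert list(out["ref_id"]) == ["b"]

    def test_idempotent_and_worse_hit_invariant(self):
        hits = hit_frame([
            ("r1", "a", 50, 1, 100),
            ("r1", "b", 50, 2, 100),
            ("r2", "c", 40, 0, 200),
        ])
        once = filter_hits(hits)
        pd.testing.assert_frame_equal(filter_hits(once).reset_index(drop=True),
                                      once.reset_index(drop=True))
        worse = pd.concat([hits, hit_frame([("r1", "z", 10, 0, 100)])])
        pd.testing.assert_frame_equal(
            filter_hits(worse).reset_index(drop=True), once.reset_index(drop=True)
        )

    def test_negative_score_rejected(self):
        with pytest.raises(ValueError):
            filter_hits(hit_frame([("r1", "a", -1, 0, 100)]))


class TestAssignTaxa:
    def test_single_hit_takes_full_lineage(self, small_reference):
        hits = hit_frame([("r1", "ref_succinivibrio", 50, 0, 100)])
        (a,) = assign_taxa(hits, small_reference)
        assert a.assigned_rank == Rank.GENUS
        assert a.lineage.label_at(Rank.GENUS) == "Succinivibrio"

    def test_two_entries_same_genus_resolve_to_genus(self, small_reference):
        hits = hit_frame([
            ("r1", "ref_mbb1", 50, 0, 100),
            ("r1", "ref_mbb2", 50, 0, 100),
        ])
        (a,) = assign_taxa(hits, small_reference)
        assert a.assigned_rank == Rank.GENUS
        assert a.lineage.label_at(Rank.GENUS) == "Methanobrevibacter"

    def test_sibling_genera_resolve_to_family(self, small_reference):
        hits = hit_frame([
            ("r1", "ref_succinivibrio", 50, 0, 100),
            ("r1", "ref_anaerobiospirillum", 50, 0, 100),
        ])
        (a,) = assign_taxa(hits, small_reference)
        assert a.assigned_rank == Rank.FAMILY
        assert a.lineage.label_at(Rank.FAMILY) == "Succinivibrionaceae"

    def test_kingdom_split_gives_rank_none(self, small_reference):
        hits = hit_frame([
            ("r1", "ref_prevotella", 50, 0, 100),
            ("r1", "ref_mbb1", 50, 0, 100),
        ])
        (a,) = assign_taxa(hits, small_reference)
        assert a.assigned_rank is None

    def test_unknown_ref_strict_raises_lenient_drops(self, small_reference):
        hits = hit_frame([("r1", "mystery", 50, 0, 100),
                          ("r2", "ref_prevotella", 50, 0, 100)])
        with pytest.raises(KeyError, match="mystery"):
            assign_taxa(hits, small_reference, strict=True)
        out = assign_taxa(hits, small_reference, strict=False)
        assert [a.read_id for a in out] == ["r2"]

    def test_random_multihit_reads_match_lca_oracle(self):
        rng = np.random.default_rng(11)
        pool = random_lineages(rng, n_taxa=20)
        reference = {f"ref{i}": lin for i, lin in enumerate(pool)}
        rows = []
        expected = {}
        for r in range(300):
            k = int(rng.integers(1, 5))
            refs = [f"ref{i}" for i in rng.integers(0, len(pool), size=k)]
            for ref in refs:
                rows.append((f"r{r:04d}", ref, 40, 0, 100))
            expected[f"r{r:04d}"] = brute_force_lca(
                [reference[ref] for ref in refs]
            )
        out = assign_taxa(hit_frame(rows), reference)
        assert len(out) == 300
        for a in out:
            exp_labels, exp_rank = expected[a.read_id]
            assert a.lineage.labels == exp_labels
            assert (a.assigned_rank if a.assigned_rank is None else int(a.assigned_rank)) == exp_rank


class TestTabulate:
    def test_kingdom_percentages(self, small_reference):
        rows = [(f"b{i}", "ref_prevotella", 50, 0, 100) for i in range(6)]
        rows += [(f"a{i}", "ref_mbb1", 50, 0, 100) for i in range(2)]
        assignments = assign_taxa(hit_frame(rows), small_reference)
        table = tabulate_taxa(assignments, Rank.KINGDOM, sample_id="s")
        assert table.counts.to_dict() == {"Archaea": 2, "Bacteria": 6}
        assert table.get_percent("Bacteria") == 75.0
        assert table.percent.sum() == pytest.approx(100.0)

    def test_family_level_read_excluded_from_genus_denominator(self, small_reference):
        rows = [
            ("r1", "ref_succinivibrio", 50, 0, 100),
            ("r2", "ref_succinivibrio", 50, 0, 100),
            ("r2", "ref_anaerobiospirillum", 50, 0, 100),  # family-level LCA
        ]
        assignments = assign_taxa(hit_frame(rows), small_reference)
        genus = tabulate_taxa(assignments, Rank.GENUS)
        family = tabulate_taxa(assignments, Rank.FAMILY)
        assert genus.denominator == 1
        assert family.denominator == 2
        assert genus.counts.to_dict() == {"Succinivibrio": 1}

    def test_reads_counted_once_and_totals_bounded(self, small_reference):
        rng = np.random.default_rng(5)
        refs = [r.ref_id for r in small_reference]
        rows = []
        for i in range(200):
            for ref in set(rng.choice(refs, size=rng.integers(1, 4))):
                rows.append((f"r{i:03d}", ref, 50, 0, 100))
        assignments = assign_taxa(filter_hits(hit_frame(rows)), small_reference)
        n_reads = len({a.read_id for a in assignments})
        for rank in Rank:
            table = tabulate_taxa(assignments, rank)
            assert table.counts.sum() <= n_reads
            assert table.counts.sum() == table.denominator

    def test_zero_reads_gives_empty_table(self):
        table = tabulate_taxa([], Rank.GENUS)
        assert table.denominator == 0
        assert len(table.counts) == 0
        assert table.percent.empty


class TestRatios:
    def test_ab_ratio_zero_archaea(self):
        assert archaea_to_bacteria_ratio(0, 1000) == 0.0

    def test_ab_ratio_zero_bacteria_flagged(self):
        with pytest.raises(ZeroDivisionError):
            archaea_to_bacteria_ratio(10, 0)

    def test_relative_to_bacteria_recount(self, small_reference):
        rows = [(f"b{i}", "ref_prevotella", 50, 0, 100) for i in range(100)]
        rows += [(f"a{i}", "ref_mbb1", 50, 0, 100) for i in range(5)]
        assignments = assign_taxa(hit_frame(rows), small_reference)
        genus = tabulate_taxa(assignments, Rank.GENUS, sample_id="s")
        kingdom = tabulate_taxa(assignments, Rank.KINGDOM, sample_id="s")
        rel = relative_to_bacteria(genus, kingdom)
        assert rel.counts.to_dict() == {"Methanobrevibacter": 5}
        assert rel.get_percent("Methanobrevibacter") == pytest.approx(5.0)
        assert rel.denominator_label == "bacteria_total"

    def test_relative_to_bacteria_no_archaea_is_empty(self, small_reference):
        rows = [("b0", "ref_prevotella", 50, 0, 100)]
        assignments = assign_taxa(hit_frame(rows), small_reference)
        rel = relative_to_bacteria(
            tabulate_taxa(assignments, Rank.GENUS),
            tabulate_taxa(assignments, Rank.KINGDOM),
        )
        assert len(rel.counts) == 0


class TestKOAssignment:
    @pytest.fixture
    def komap(self):
        komap = KOMap()
        komap.add("geneA", "K00399")
        komap.add("geneA2", "K00399")
        komap.add("geneB", "K00401")
        komap.add("geneC", "K00201")
        return komap

    def test_unique_ko_assigned(self, komap):
        hits = hit_frame([
            ("r1", "x", 50, 0, 100, "geneA"),
            ("r1", "y", 50, 0, 100, "geneA2"),
        ])
        (a,) = assign_kos(hits, komap)
        assert a.ko_id == "K00399"

    def test_ambiguous_ko_ignored(self, komap):
        hits = hit_frame([
            ("r1", "x", 50, 0, 100, "geneA"),
            ("r1", "y", 50, 0, 100, "geneB"),
        ])
        (a,) = assign_kos(hits, komap)
        assert a.ko_id is None

    def test_unannotated_hits_dropped_before_resolution(self, komap):
        hits = hit_frame([
            ("r1", "x", 50, 0, 100, "geneA"),
            ("r1", "y", 50, 0, 100, "unknown_gene"),
            ("r2", "z", 50, 0, 100, "unknown_gene"),
        ])
        out = {a.read_id: a.ko_id for a in assign_kos(hits, komap)}
        assert out == {"r1": "K00399", "r2": None}

    def test_tabulate_kos_percentages(self, komap):
        hits = hit_frame(
            [(f"r{i}", "x", 50, 0, 100, "geneA") for i in range(3)]
            + [("r9", "x", 50, 0, 100, "geneC")]
        )
        table = tabulate_kos(assign_kos(hits, komap), sample_id="s")
        assert table.counts.to_dict() == {"K00201": 1, "K00399": 3}
        assert table.get_percent("K00399") == pytest.approx(75.0)
        assert table.percent.sum() == pytest.approx(100.0)

    def test_count_conservation_assigned_plus_unassigned(self, komap):
        rng = np.random.default_rng(3)
        genes = ["geneA", "geneA2", "geneB", "geneC", "nope"]
        rows = []
        for i in range(500):
            for g in set(rng.choice(genes, size=rng.integers(1, 4))):
                rows.append((f"r{i:03d}", g, 50, 0, 100, g))
        filtered = filter_hits(hit_frame(rows))
        assignments = assign_kos(filtered, komap)
        surviving = filtered["read_id"].nunique()
        assigned = sum(a.ko_id is not None for a in assignments)
        unassigned = sum(a.ko_id is None for a in assignments)
        assert assigned + unassigned == surviving
        table = tabulate_kos(assignments)
        assert table.counts.sum() == assigned
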