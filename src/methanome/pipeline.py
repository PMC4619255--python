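"""End-to-end orchestration: simulate -> profile -> diversity -> compare -> select.

``run_pipeline`` executes the stages in order on synthetic data (paper-like
or null preset) or on user-supplied tables, writes every stage output as a
TSV under the output directory, and produces a machine-readable JSON report
(seed, thresholds, config hash, per-stage counts).  Stage outputs are pure
functions of config + seed: rerunning the same configuration reproduces
byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .abundance import write_abundance_tables
from .compare import compare_features
from .diversity import diversity_result, write_diversity
from .hits import (
    archaea_to_bacteria_ratio,
    assign_taxa,
    filter_hits,
    read_hit_table,
    relative_to_bacteria,
    tabulate_taxa,
    write_hit_table,
)
from .panel import AnimalPanel, read_panel
from .screen import select_genes
from .simulate import (
    CommunitySpec,
    KOEffectSpec,
    PanelSpec,
    make_taxonomy,
    null_specs,
    simulate_hits,
    simulate_panel,
)
from .taxonomy import Rank, parse_taxonomy, write_taxonomy

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    out_dir: str
    seed: int = 0
    preset: str | None = "paper"      # "paper" | "null" | None (user data)
    n_pairs: int = 4
    reads_per_animal: int = 20000
    ambiguity_rate: float = 0.1
    ranks: tuple[str, ...] = ("kingdom", "phylum", "genus")
    screen_threshold: float = 0.1
    vip_cutoff: float = 0.8
    factor_policy: str = "auto"       # "auto" or an integer as text
    strict: bool = True
    # user-data inputs (used when preset is None)
    taxonomy_path: str | None = None
    panel_path: str | None = None
    hits_paths: tuple[str, ...] = ()  # one hit table per animal, ordered as panel
    ko_matrix_path: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.screen_threshold < 1:
            raise ValueError("screen_threshold must be in (0, 1)")
        if self.vip_cutoff <= 0:
            raise ValueError("vip_cutoff must be > 0")
        if self.preset not in ("paper", "null", None):
            raise ValueError(f"unknown preset {self.preset!r}")
        if self.preset is None:
            for name in ("taxonomy_path", "panel_path"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"{name} missing or not found: {p}")
            for p in self.hits_paths:
                if not Path(p).exists():
                    raise FileNotFoundError(f"hit table not found: {p}")

    @property
    def n_factors(self) -> int | str:
        return "auto" if self.factor_policy == "auto" else int(self.factor_policy)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _simulate_inputs(config: RunConfig, out: Path) -> dict:
    if config.preset == "null":
        panel_spec, community, kos = null_specs()
        panel_spec = dataclasses.replace(panel_spec, n_pairs=config.n_pairs)
    else:
        panel_spec = PanelSpec(n_pairs=config.n_pairs)
        community, kos = CommunitySpec(), KOEffectSpec()
    sim = simulate_panel(panel_spec, community, kos, seed=config.seed)
    records = make_taxonomy(community, seed=config.seed)
    inputs = out / "inputs"
    inputs.mkdir(parents=True, exist_ok=True)
    write_taxonomy(records, inputs / "taxonomy.tsv")
    sim.panel.write(inputs / "panel.tsv")
    sim.ko_abundance.to_csv(inputs / "ko_abundance.tsv", sep="\t")
    sim.taxon_abundance.to_csv(inputs / "taxon_abundance.tsv", sep="\t")
    hits_paths = []
    rng_seeds = np.random.default_rng(config.seed).integers(
        0, 2**31 - 1, size=len(sim.panel.animal_ids)
    )
    for animal, sub_seed in zip(sim.panel.animal_ids, rng_seeds):
        hits = simulate_hits(
            sim.composition.loc[animal].to_dict(),
            records,
            n_reads=config.reads_per_animal,
            ambiguity_rate=config.ambiguity_rate,
            seed=int(sub_seed),
        )
        path = inputs / f"hits_{animal}.tsv"
        write_hit_table(hits, path)
        hits_paths.append(str(path))
    return {
        "panel": sim.panel,
        "records": records,
        "hits_paths": hits_paths,
        "ko_matrix": sim.ko_abundance,
        "planted_kos": list(kos.methanogenesis_kos) if config.preset == "paper" else [],
    }


def _load_inputs(config: RunConfig) -> dict:
    panel = read_panel(config.panel_path)
    records = parse_taxonomy(config.taxonomy_path)
    ko_matrix = None
    if config.ko_matrix_path:
        ko_matrix = pd.read_csv(config.ko_matrix_path, sep="\t", index_col=0)
        ko_matrix.index = ko_matrix.index.astype(str)
    return {
        "panel": panel,
        "records": records,
        "hits_paths": list(config.hits_paths),
        "ko_matrix": ko_matrix,
        "planted_kos": [],
    }


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; returns (and writes) the run report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "preset": config.preset,
        "thresholds": {
            "screen_p": config.screen_threshold,
            "vip": config.vip_cutoff,
            "factor_policy": config.factor_policy,
        },
        "stages": {},
    }

    data = _simulate_inputs(config, out) if config.preset else _load_inputs(config)
    panel: AnimalPanel = data["panel"]
    report["stages"]["inputs"] = {
        "n_animals": len(panel.animal_ids),
        "n_pairs": panel.n_pairs,
        "n_reference_records": len(data["records"]),
        "n_hit_tables": len(data["hits_paths"]),
    }

    # ---- profile: per-animal rank tables from hit tables
    ranks = [Rank.from_name(r) for r in config.ranks]
    reference = {rec.ref_id: rec.lineage for rec in data["records"]}
    all_tables = []
    genus_counts: dict[str, pd.Series] = {}
    genus_pct_rel_bacteria: dict[str, dict[str, float]] = {}
    ab_ratio: dict[str, float] = {}
    n_surviving = {}
    for animal, path in zip(panel.animal_ids, data["hits_paths"]):
        hits = filter_hits(read_hit_table(path))
        assignments = assign_taxa(hits, reference, strict=config.strict)
        n_surviving[animal] = len(assignments)
        kingdom_table = None
        for rank in ranks:
            table = tabulate_taxa(assignments, rank, sample_id=animal)
            all_tables.append(table)
            if rank == Rank.KINGDOM:
                kingdom_table = table
            if rank == Rank.GENUS:
                genus_counts[animal] = table.counts
                if kingdom_table is not None and kingdom_table.counts.get("Bacteria", 0) > 0:
                    rel = relative_to_bacteria(table, kingdom_table)
                    all_tables.append(rel)
                    genus_pct_rel_bacteria[animal] = rel.percent.to_dict()
        if kingdom_table is not None:
            bacteria = float(kingdom_table.counts.get("Bacteria", 0))
            archaea = float(kingdom_table.counts.get("Archaea", 0))
            if bacteria > 0:
                ab_ratio[animal] = archaea_to_bacteria_ratio(archaea, bacteria)
    write_abundance_tables(all_tables, out / "abundance.tsv")
    report["stages"]["profile"] = {
        "reads_assigned": n_surviving,
        "n_tables": len(all_tables),
    }

    # ---- diversity on genus counts
    genus_tables = [t for t in all_tables
                    if t.level == "genus" and t.denominator_label == "level_total"]
    diversity = [diversity_result(t) for t in genus_tables if t.denominator > 0]
    write_diversity(diversity, out / "diversity.tsv")
    report["stages"]["diversity"] = {
        "n_samples": len(diversity),
        "mean_shannon": float(np.mean([d.shannon for d in diversity])) if diversity else None,
        "mean_chao1": float(np.mean([d.chao1 for d in diversity])) if diversity else None,
    }

    # ---- paired comparison of genus percentages (relative to bacteria for
    # archaeal genera via the dedicated tables) plus the A:B ratio
    genus_pct = pd.DataFrame(
        {
            a: (100.0 * genus_counts[a] / genus_counts[a].sum())
            for a in genus_counts
            if genus_counts[a].sum() > 0
        }
    ).T.fillna(0.0)
    features = genus_pct.copy()
    if ab_ratio:
        features["A:B_ratio_pct"] = pd.Series(ab_ratio)
    comparison = compare_features(features, panel)
    comparison.to_csv(out / "comparison.tsv", sep="\t")
    report["stages"]["compare"] = {
        "n_features": int(len(comparison)),
        "n_significant_p05": int((comparison["p"] < 0.05).sum()),
    }

    # ---- gene selection on the KO matrix
    if data["ko_matrix"] is not None:
        selection = select_genes(
            data["ko_matrix"],
            panel,
            screen_threshold=config.screen_threshold,
            vip_cutoff=config.vip_cutoff,
            n_factors=config.n_factors,
        )
        selection.selection_frame().to_csv(out / "selection.tsv", sep="\t")
        planted = set(data["planted_kos"])
        retained = set(selection.retained)
        report["stages"]["select_genes"] = {
            "n_screened": len(selection.screen),
            "n_passed_screen": sum(r.passed for r in selection.screen),
            "n_retained": len(retained),
            "n_factors": selection.final_model.n_factors if selection.final_model else None,
            "planted_kos": sorted(planted),
            "planted_recovered": sorted(planted & retained),
        }

    with (out / "report.json").open("w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
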