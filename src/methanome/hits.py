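"""Read-level assignment rules for alignment hit tables.

The profiling conventions implemented here:

* equal-best-hit retention — for each sequenced fragment, keep every hit
  whose alignment score equals the per-fragment maximum, after discarding
  hits with more than 10 % mismatches across the fragment;
* taxon assignment — a fragment with a single surviving hit takes that
  reference's full lineage; a fragment with several takes their lowest
  common taxon;
* KO assignment — a fragment is assigned a KEGG orthologue only when its
  equal-best hits resolve to exactly one KO; otherwise it is ignored;
* rank-wise tabulation — counts at a rank are over fragments annotated at
  that rank, and percentages are normalised to that per-rank total, with
  archaeal genera additionally expressible against the bacterial count.

Hit tables are pandas DataFrames with columns
``read_id, ref_id, score, mismatches, fragment_length`` and optionally
``gene_id``; one row per hit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .abundance import AbundanceTable
from .taxonomy import KOMap, Lineage, Rank, ReferenceRecord, lowest_common_taxon

logger = logging.getLogger(__name__)

__all__ = [
    "HIT_COLUMNS",
    "MAX_MISMATCH_FRACTION",
    "ReadTaxonAssignment",
    "KOAssignment",
    "read_hit_table",
    "write_hit_table",
    "filter_hits",
    "assign_taxa",
    "assign_kos",
    "tabulate_taxa",
    "tabulate_kos",
    "archaea_to_bacteria_ratio",
    "relative_to_bacteria",
]

HIT_COLUMNS = ["read_id", "ref_id", "score", "mismatches", "fragment_length"]

#: mismatch cap: up to 10 % mismatches across the sequenced fragment
MAX_MISMATCH_FRACTION = 0.10


@dataclass(frozen=True)
class ReadTaxonAssignment:
    read_id: str
    lineage: Lineage
    assigned_rank: Rank | None


@dataclass(frozen=True)
class KOAssignment:
    read_id: str
    ko_id: str | None  # None = unassigned (zero or ambiguous KO)


def read_hit_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"read_id": str, "ref_id": str})
    missing = [c for c in HIT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: hit table missing columns {missing}")
    if "gene_id" in df.columns:
        df["gene_id"] = df["gene_id"].astype("string")
    return df


def write_hit_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def _validate_hits(hits: pd.DataFrame) -> None:
    missing = [c for c in HIT_COLUMNS if c not in hits.columns]
    if missing:
        raise ValueError(f"hit table missing columns {missing}")
    if len(hits) == 0:
        return
    if (hits["score"] < 0).any():
        raise ValueError("negative alignment score")
    if (hits["mismatches"] < 0).any():
        raise ValueError("negative mismatch count")
    if (hits["fragment_length"] <= 0).any():
        raise ValueError("non-positive fragment length")
    if (hits["mismatches"] > hits["fragment_length"]).any():
        raise ValueError("more mismatches than fragment positions")


def filter_hits(
    hits: pd.DataFrame, max_mismatch_fraction: float = MAX_MISMATCH_FRACTION
) -> pd.DataFrame:
    """Equal-best retention with the fragment-mismatch cap.

    Hits above the mismatch cap are discarded first; among the survivors of
    each fragment, only hits whose score equals the per-fragment maximum are
    kept (exact score equality — scores are integral in the supported
    dialects).  Fragments with no surviving hit disappear.
    """
    _validate_hits(hits)
    if len(hits) == 0:
        return hits.copy()
    admissible = hits[
        hits["mismatches"] <= max_mismatch_fraction * hits["fragment_length"]
    ]
    if len(admissible) == 0:
        return admissible.copy()
    best = admissible.groupby("read_id")["score"].transform("max")
    return admissible[admissible["score"] == best].copy()


def assign_taxa(
    filtered_hits: pd.DataFrame,
    reference: Mapping[str, Lineage] | Iterable[ReferenceRecord],
    strict: bool = True,
) -> list[ReadTaxonAssignment]:
    """One taxon assignment per surviving fragment.

    Single-hit fragments take the reference lineage verbatim; multi-hit
    fragments take the lowest common taxon of their hit lineages.  Unknown
    ``ref_id``s raise (strict, default) or drop the offending hit with a
    logged count (lenient); a fragment whose hits are all unknown is dropped.
    """
    if not isinstance(reference, Mapping):
        reference = {rec.ref_id: rec.lineage for rec in reference}
    assignments: list[ReadTaxonAssignment] = []
    n_unknown = 0
    for read_id, grp in filtered_hits.groupby("read_id", sort=True):
        lineages = []
        for ref_id in grp["ref_id"]:
            lin = reference.get(ref_id)
            if lin is None:
                if strict:
                    raise KeyError(f"unknown ref_id {ref_id!r} for read {read_id!r}")
                n_unknown += 1
                continue
            lineages.append(lin)
        if not lineages:
            continue
        if len(lineages) == 1:
            lineage, rank = lineages[0], lineages[0].depth
        else:
            lineage, rank = lowest_common_taxon(lineages)
        assignments.append(ReadTaxonAssignment(str(read_id), lineage, rank))
    if n_unknown:
        logger.warning("dropped %d hits with unknown ref_id", n_unknown)
    return assignments


def assign_kos(filtered_hits: pd.DataFrame, ko_map: KOMap) -> list[KOAssignment]:
    """Unique-KO resolution over each fragment's equal-best hits.

    Hits without a KO annotation are set aside first; if the remaining
    equal-best hits map to exactly one distinct KO the fragment is assigned
    it, otherwise (zero or >= 2 KOs) the fragment is left unassigned.
    """
    if "gene_id" not in filtered_hits.columns:
        raise ValueError("hit table has no gene_id column; cannot assign KOs")
    out: list[KOAssignment] = []
    for read_id, grp in filtered_hits.groupby("read_id", sort=True):
        kos = set()
        for gene_id in grp["gene_id"]:
            if pd.isna(gene_id) or gene_id == "":
                continue
            ko = ko_map.get(str(gene_id))
            if ko is not None:
                kos.add(ko)
        out.append(KOAssignment(str(read_id), kos.pop() if len(kos) == 1 else None))
    return out


def tabulate_taxa(
    assignments: Iterable[ReadTaxonAssignment],
    rank: Rank,
    sample_id: str = "",
) -> AbundanceTable:
    """Count fragments per taxon at ``rank``.

    A fragment contributes iff its lineage is annotated at ``rank`` (its
    assigned rank is at least that deep); the denominator is the number of
    contributing fragments, so percentages at each rank sum to 100.
    """
    counts: dict[str, int] = {}
    lineages: dict[str, Lineage] = {}
    for a in assignments:
        if a.assigned_rank is None or a.assigned_rank < rank:
            continue
        label = a.lineage.label_at(rank)
        counts[label] = counts.get(label, 0) + 1
        lineages.setdefault(label, a.lineage.truncate(rank))
    series = pd.Series(counts, dtype="int64").sort_index()
    return AbundanceTable(
        sample_id=sample_id,
        level=rank.name.lower(),
        counts=series,
        denominator=int(series.sum()),
        denominator_label="level_total",
        lineages=lineages,
    )


def tabulate_kos(
    ko_assignments: Iterable[KOAssignment], sample_id: str = ""
) -> AbundanceTable:
    """Count fragments per KO; denominator = number of KO-assigned fragments."""
    counts: dict[str, int] = {}
    for a in ko_assignments:
        if a.ko_id is None:
            continue
        counts[a.ko_id] = counts.get(a.ko_id, 0) + 1
    series = pd.Series(counts, dtype="int64").sort_index()
    return AbundanceTable(
        sample_id=sample_id,
        level="KO",
        counts=series,
        denominator=int(series.sum()),
        denominator_label="ko_total",
    )


def archaea_to_bacteria_ratio(archaea: float, bacteria: float) -> float:
    """A:B ratio as a percentage: 100 x archaeal / bacterial abundance.

    Accepts read counts or qPCR copies/ng alike.  Zero archaea gives 0;
    zero bacteria is undefined and raises.
    """
    if bacteria <= 0:
        raise ZeroDivisionError("A:B ratio undefined: bacterial abundance is 0")
    if archaea < 0:
        raise ValueError("negative archaeal abundance")
    return 100.0 * archaea / bacteria


def relative_to_bacteria(
    genus_table: AbundanceTable,
    kingdom_table: AbundanceTable,
    kingdom: str = "Archaea",
    bacteria_label: str = "Bacteria",
) -> AbundanceTable:
    """Re-express archaeal genus counts against the bacterial read count.

    The archaeal-genus reporting convention: percentages are of reads
    assigned to ``Bacteria`` at kingdom level, not of genus-level totals.
    Requires ``genus_table.lineages`` (populated by :func:`tabulate_taxa`).
    """
    bacterial = int(kingdom_table.counts.get(bacteria_label, 0))
    if bacterial <= 0:
        raise ZeroDivisionError("no bacterial reads to normalise against")
    keep = [
        taxon
        for taxon in genus_table.counts.index
        if genus_table.lineages.get(taxon) is not None
        and genus_table.lineages[taxon].label_at(Rank.KINGDOM) == kingdom
    ]
    series = genus_table.counts.loc[keep]
    return AbundanceTable(
        sample_id=genus_table.sample_id,
        level=genus_table.level,
        counts=series,
        denominator=bacterial,
        denominator_label="bacteria_total",
        lineages={t: genus_table.lineages[t] for t in keep},
    )
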