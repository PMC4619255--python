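"""Candidate-protein selection per KO group and identity/conservation tallies.

Predicted proteins are screened against a KO group's reference profile:
a candidate must carry the same ordered Pfam-domain-accession sequence
(configurably an unordered multiset) and be at least as long as the
shortest known member of the group.  Candidates are then classified by
their best database match: "identical at theta" when best-match percent
identity >= theta, "conserved at theta" when percent positives >= theta,
for theta in {100, 90}, with full-query alignment coverage required by
default so that an exact match cannot be claimed from a partial alignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "PredictedProtein",
    "KOProfile",
    "NoveltyCounts",
    "select_candidates",
    "classify_matches",
    "read_protein_table",
    "read_match_table",
    "read_profiles",
    "write_novelty_counts",
]

MATCH_COLUMNS = ["qseqid", "sseqid", "pident", "ppos", "length", "qlen"]


@dataclass(frozen=True)
class PredictedProtein:
    protein_id: str
    length: int  # amino acids
    domains: tuple[str, ...]  # ordered Pfam accessions

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"protein {self.protein_id!r}: non-positive length")


@dataclass(frozen=True)
class KOProfile:
    ko_id: str
    domains: tuple[str, ...]
    min_length: int

    def __post_init__(self) -> None:
        if not self.domains:
            raise ValueError(f"profile {self.ko_id!r}: empty domain structure")
        if self.min_length <= 0:
            raise ValueError(f"profile {self.ko_id!r}: non-positive minimum length")


@dataclass(frozen=True)
class NoveltyCounts:
    ko_id: str
    n_candidates: int
    n_identical_100: int
    n_conserved_100: int
    n_identical_90: int
    n_conserved_90: int


def select_candidates(
    proteins: Iterable[PredictedProtein],
    profile: KOProfile,
    ordered: bool = True,
) -> list[PredictedProtein]:
    """Keep proteins matching the profile's domain structure and length floor.

    ``ordered=True`` (default) compares the domain accession sequence
    exactly; ``ordered=False`` compares as an unordered multiset.
    """
    def structure(domains: tuple[str, ...]):
        return domains if ordered else tuple(sorted(domains))

    want = structure(profile.domains)
    return [
        p
        for p in proteins
        if structure(p.domains) == want and p.length >= profile.min_length
    ]


def classify_matches(
    candidates: Sequence[PredictedProtein],
    matches: pd.DataFrame,
    ko_id: str = "",
    full_coverage_100: bool = True,
    full_coverage_90: bool = True,
) -> NoveltyCounts:
    """Tally identity/conservation categories over candidates' best matches.

    The best match per candidate is the row with highest percent identity,
    ties broken by highest percent positives.  A candidate without any match
    counts in no category.  Coverage rule: a match only qualifies for the
    theta categories when alignment_length >= query_length (switchable per
    threshold band).
    """
    missing = [c for c in MATCH_COLUMNS if c not in matches.columns]
    if missing:
        raise ValueError(f"match table missing columns {missing}")
    if len(matches) and (matches["pident"] > matches["ppos"] + 1e-9).any():
        raise ValueError("percent identity exceeds percent positives")

    by_query: dict[str, pd.Series] = {}
    for _, row in matches.iterrows():
        q = str(row["qseqid"])
        best = by_query.get(q)
        if (
            best is None
            or row["pident"] > best["pident"]
            or (row["pident"] == best["pident"] and row["ppos"] > best["ppos"])
        ):
            by_query[q] = row

    n_id100 = n_co100 = n_id90 = n_co90 = 0
    for cand in candidates:
        best = by_query.get(cand.protein_id)
        if best is None:
            continue
        covered = best["length"] >= best["qlen"]
        ok100 = covered or not full_coverage_100
        ok90 = covered or not full_coverage_90
        if ok100 and best["pident"] >= 100.0:
            n_id100 += 1
        if ok100 and best["ppos"] >= 100.0:
            n_co100 += 1
        if ok90 and best["pident"] >= 90.0:
            n_id90 += 1
        if ok90 and best["ppos"] >= 90.0:
            n_co90 += 1
    return NoveltyCounts(
        ko_id=ko_id,
        n_candidates=len(candidates),
        n_identical_100=n_id100,
        n_conserved_100=n_co100,
        n_identical_90=n_id90,
        n_conserved_90=n_co90,
    )


# ---------------------------------------------------------------------------
# TSV interfaces


def read_protein_table(path: str | Path) -> list[PredictedProtein]:
    """protein_id TAB length TAB semicolon-joined domain accessions."""
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "domains": str})
    out = []
    for _, row in df.iterrows():
        domains = tuple(
            d.strip() for d in str(row.get("domains", "")).split(";") if d.strip()
        )
        out.append(PredictedProtein(str(row["protein_id"]), int(row["length"]), domains))
    return out


def read_match_table(path: str | Path) -> pd.DataFrame:
    """BLAST outfmt-6-like TSV extended with ppos and qlen; header required."""
    df = pd.read_csv(path, sep="\t", dtype={"qseqid": str, "sseqid": str})
    missing = [c for c in MATCH_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: match table missing columns {missing}")
    return df


def read_profiles(path: str | Path) -> list[KOProfile]:
    """ko_id TAB semicolon-joined domains TAB min_length."""
    df = pd.read_csv(path, sep="\t", dtype={"ko_id": str, "domains": str})
    return [
        KOProfile(
            str(row["ko_id"]),
            tuple(d.strip() for d in str(row["domains"]).split(";") if d.strip()),
            int(row["min_length"]),
        )
        for _, row in df.iterrows()
    ]


def write_novelty_counts(counts: list[NoveltyCounts], path: str | Path) -> None:
    pd.DataFrame(
        {
            "ko_id": [c.ko_id for c in counts],
            "n_candidates": [c.n_candidates for c in counts],
            "n_identical_100": [c.n_identical_100 for c in counts],
            "n_conserved_100": [c.n_conserved_100 for c in counts],
            "n_identical_90": [c.n_identical_90 for c in counts],
            "n_conserved_90": [c.n_conserved_90 for c in counts],
        }
    ).to_csv(path, sep="\t", index=False)
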