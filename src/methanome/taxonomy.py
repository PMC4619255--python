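"""Ranked reference taxonomy: lineages, Greengenes-style parsing, lowest common taxon.

The taxonomy model is a fixed six-rank hierarchy (kingdom through genus).
Lineage labels may be empty from some rank downward (a *prefix* property):
once a rank is unannotated, all deeper ranks are unannotated too.  An empty
label never "agrees" with anything, including another empty label, so the
lowest common taxon of a set of lineages can be shallower than any input's
annotated depth.
"""

from __future__ import annotations

import enum
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "Rank",
    "Lineage",
    "ReferenceRecord",
    "KOMap",
    "TaxonomyError",
    "parse_taxonomy",
    "parse_taxonomy_lines",
    "write_taxonomy",
    "parse_ko_map",
    "lowest_common_taxon",
]


class TaxonomyError(ValueError):
    """Raised for malformed taxonomy or KO-map input."""


class Rank(enum.IntEnum):
    """The six ranks, totally ordered from kingdom (shallowest) to genus."""

    KINGDOM = 0
    PHYLUM = 1
    CLASS = 2
    ORDER = 3
    FAMILY = 4
    GENUS = 5

    @property
    def prefix(self) -> str:
        return _PREFIXES[self.value]

    @classmethod
    def from_name(cls, name: str) -> "Rank":
        try:
            return cls[name.upper()]
        except KeyError:
            raise TaxonomyError(f"unknown rank name: {name!r}") from None


_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__")
N_RANKS = len(Rank)


@dataclass(frozen=True)
class Lineage:
    """One label per rank; labels are empty from some rank downward.

    ``labels`` always has exactly six entries.  ``Lineage.empty()`` (all
    labels blank) is the degenerate result of a kingdom-level disagreement;
    lineages read from a reference file always have a non-empty kingdom.
    """

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != N_RANKS:
            raise TaxonomyError(
                f"lineage needs {N_RANKS} labels, got {len(self.labels)}"
            )
        seen_empty = False
        for lab in self.labels:
            if lab != lab.strip():
                raise TaxonomyError(f"untrimmed label {lab!r}")
            if lab == "":
                seen_empty = True
            elif seen_empty:
                raise TaxonomyError(
                    f"non-empty label below an empty rank in {self.labels!r}"
                )

    @classmethod
    def empty(cls) -> "Lineage":
        return cls(("",) * N_RANKS)

    @classmethod
    def from_labels(cls, *labels: str) -> "Lineage":
        padded = tuple(lab.strip() for lab in labels) + ("",) * (N_RANKS - len(labels))
        return cls(padded)

    @classmethod
    def from_string(cls, text: str) -> "Lineage":
        """Parse a Greengenes-style lineage string (``k__X; p__Y; ...``).

        Rank prefixes must appear in order.  A species payload (``s__``),
        if present, is discarded with a warning — this model stops at genus.
        """
        parts = [p.strip() for p in text.split(";") if p.strip() != ""]
        labels = [""] * N_RANKS
        next_rank = 0
        for part in parts:
            if part.startswith("s__"):
                if part != "s__":
                    logger.warning("discarding species payload %r", part)
                continue
            matched = False
            for r in range(next_rank, N_RANKS):
                if part.startswith(_PREFIXES[r]):
                    labels[r] = part[len(_PREFIXES[r]):].strip()
                    next_rank = r + 1
                    matched = True
                    break
            if not matched:
                raise TaxonomyError(
                    f"out-of-order or unknown rank prefix in segment {part!r}"
                )
        # empty payloads below a set rank truncate; enforce prefix property
        truncated = False
        out = []
        for lab in labels:
            if lab == "":
                truncated = True
            out.append("" if truncated else lab)
        return cls(tuple(out))

    def to_string(self) -> str:
        return "; ".join(p + lab for p, lab in zip(_PREFIXES, self.labels))

    @property
    def depth(self) -> Rank | None:
        """Deepest annotated rank, or None for the empty lineage."""
        deepest = None
        for r in Rank:
            if self.labels[r] != "":
                deepest = r
        return deepest

    def label_at(self, rank: Rank) -> str:
        return self.labels[rank]

    def is_annotated_at(self, rank: Rank) -> bool:
        return self.labels[rank] != ""

    def truncate(self, rank: Rank) -> "Lineage":
        """Keep labels down to ``rank`` inclusive, blank below."""
        return Lineage(
            tuple(lab if r <= rank else "" for r, lab in enumerate(self.labels))
        )


@dataclass(frozen=True)
class ReferenceRecord:
    ref_id: str
    lineage: Lineage


def lowest_common_taxon(
    lineages: Iterable[Lineage],
) -> tuple[Lineage, Rank | None]:
    """Longest common prefix of a non-empty set of lineages.

    Returns the common lineage and the deepest rank at which every lineage
    carries the same non-empty label.  A disagreement (or any empty label)
    at the kingdom level yields ``(Lineage.empty(), None)``.
    """
    lins = list(lineages)
    if not lins:
        raise TaxonomyError("lowest_common_taxon needs at least one lineage")
    labels = []
    agreed_rank: Rank | None = None
    for r in Rank:
        cand = lins[0].labels[r]
        if cand != "" and all(l.labels[r] == cand for l in lins[1:]):
            labels.append(cand)
            agreed_rank = r
        else:
            break
    labels += [""] * (N_RANKS - len(labels))
    return Lineage(tuple(labels)), agreed_rank


# ---------------------------------------------------------------------------
# Parsers / writers


def parse_taxonomy_lines(
    lines: Iterable[str], source: str = "<memory>"
) -> list[ReferenceRecord]:
    records: list[ReferenceRecord] = []
    seen: set[str] = set()
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if line.strip() == "" or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise TaxonomyError(
                f"{source}:{lineno}: expected 'ref_id<TAB>lineage', got {len(fields)} fields"
            )
        ref_id = fields[0].strip()
        if ref_id == "":
            raise TaxonomyError(f"{source}:{lineno}: empty ref_id")
        if ref_id in seen:
            raise TaxonomyError(f"{source}:{lineno}: duplicate ref_id {ref_id!r}")
        seen.add(ref_id)
        try:
            lineage = Lineage.from_string(fields[1])
        except TaxonomyError as exc:
            raise TaxonomyError(f"{source}:{lineno}: {exc}") from None
        if not lineage.is_annotated_at(Rank.KINGDOM):
            raise TaxonomyError(f"{source}:{lineno}: kingdom label is empty")
        records.append(ReferenceRecord(ref_id, lineage))
    return records


def parse_taxonomy(path: str | Path) -> list[ReferenceRecord]:
    """Read a Greengenes-style taxonomy TSV (ref_id TAB lineage string)."""
    path = Path(path)
    with path.open() as fh:
        return parse_taxonomy_lines(fh, source=str(path))


def write_taxonomy(records: Sequence[ReferenceRecord], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for rec in records:
            fh.write(f"{rec.ref_id}\t{rec.lineage.to_string()}\n")


_KO_RE = re.compile(r"^K\d{5}$")


@dataclass
class KOMap:
    """gene_id -> KEGG orthologue id, plus KO descriptions."""

    gene_to_ko: dict[str, str] = field(default_factory=dict)
    ko_description: dict[str, str] = field(default_factory=dict)

    def add(self, gene_id: str, ko_id: str, description: str = "") -> None:
        if not _KO_RE.match(ko_id):
            raise TaxonomyError(f"malformed KO id {ko_id!r} (expected K#####)")
        if gene_id in self.gene_to_ko and self.gene_to_ko[gene_id] != ko_id:
            raise TaxonomyError(
                f"gene {gene_id!r} maps to both {self.gene_to_ko[gene_id]!r} and {ko_id!r}"
            )
        self.gene_to_ko[gene_id] = ko_id
        if description:
            self.ko_description[ko_id] = description

    def get(self, gene_id: str) -> str | None:
        return self.gene_to_ko.get(gene_id)

    def __len__(self) -> int:
        return len(self.gene_to_ko)

    def write(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            for gene, ko in self.gene_to_ko.items():
                fh.write(f"{gene}\t{ko}\t{self.ko_description.get(ko, '')}\n")


def parse_ko_map(path: str | Path) -> KOMap:
    """Read a KO map TSV: gene_id TAB ko_id [TAB description]."""
    path = Path(path)
    komap = KOMap()
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if line.strip() == "" or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise TaxonomyError(
                    f"{path}:{lineno}: expected 'gene_id<TAB>ko_id[<TAB>description]'"
                )
            desc = fields[2] if len(fields) > 2 else ""
            try:
                komap.add(fields[0].strip(), fields[1].strip(), desc)
            except TaxonomyError as exc:
                raise TaxonomyError(f"{path}:{lineno}: {exc}") from None
    return komap
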