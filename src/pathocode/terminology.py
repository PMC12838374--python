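"""Concept tables for the three clinical terminologies.

Each concept carries a code, a preferred label, synonyms, and a group tag:
a hierarchy root for SNOMED CT-style tables, a class designation for
LOINC-style tables, and a chapter for ICD-11-style tables.  Licensed
terminology content is never bundled; the package reads schema-compatible
TSV/JSON tables, and the synthetic module generates fixtures in the same
schema.  Codes are opaque strings (no checksum validation).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

from .corpus_io import TERMINOLOGIES

_TSV_COLUMNS = ["terminology", "code", "label", "synonyms", "group", "parent"]


class TerminologyError(ValueError):
    """Malformed concept table content."""


@dataclass
class Concept:
    terminology: str
    code: str
    label: str
    synonyms: list[str] = field(default_factory=list)
    group: str = ""
    parent: str | None = None

    def validate(self) -> None:
        if self.terminology not in TERMINOLOGIES:
            raise TerminologyError(f"unknown terminology tag {self.terminology!r}")
        if not self.code:
            raise TerminologyError("concept code must be non-empty")
        if not self.label:
            raise TerminologyError(f"concept {self.code}: label must be non-empty")


@dataclass
class ConceptTable:
    terminology: str
    concepts: dict[str, Concept] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.concepts)

    def __contains__(self, code: str) -> bool:
        return code in self.concepts

    def __getitem__(self, code: str) -> Concept:
        return self.concepts[code]

    def add(self, concept: Concept) -> None:
        concept.validate()
        if concept.terminology != self.terminology:
            raise TerminologyError(
                f"concept {concept.code} tagged {concept.terminology}, "
                f"table is {self.terminology}"
            )
        if concept.code in self.concepts:
            raise TerminologyError(f"duplicate code {concept.code!r}")
        self.concepts[concept.code] = concept

    def validate(self) -> None:
        for concept in self.concepts.values():
            if concept.parent and concept.parent not in self.concepts:
                raise TerminologyError(
                    f"concept {concept.code}: dangling parent {concept.parent!r}"
                )

    def groups(self) -> set[str]:
        return {c.group for c in self.concepts.values()}


def from_concepts(terminology: str, concepts: Iterable[Concept]) -> ConceptTable:
    table = ConceptTable(terminology)
    for concept in concepts:
        table.add(concept)
    table.validate()
    return table


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_concepts(path: str | Path) -> ConceptTable:
    """Load a concept table from TSV (synonyms pipe-separated)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise TerminologyError(f"missing columns: {sorted(missing)}")
    terminologies = df["terminology"].unique().tolist()
    if len(terminologies) != 1:
        raise TerminologyError(f"expected one terminology per file, got {terminologies}")
    table = ConceptTable(terminologies[0])
    for row in df.itertuples(index=False):
        table.add(
            Concept(
                terminology=row.terminology,
                code=row.code,
                label=row.label,
                synonyms=[s for s in row.synonyms.split("|") if s],
                group=row.group,
                parent=row.parent or None,
            )
        )
    table.validate()
    return table


def write_concepts(table: ConceptTable, path: str | Path) -> None:
    rows = [
        {
            "terminology": c.terminology,
            "code": c.code,
            "label": c.label,
            "synonyms": "|".join(c.synonyms),
            "group": c.group,
            "parent": c.parent or "",
        }
        for c in table.concepts.values()
    ]
    pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def to_json(table: ConceptTable) -> str:
    objs = [
        {
            "terminology": c.terminology,
            "code": c.code,
            "label": c.label,
            "synonyms": c.synonyms,
            "group": c.group,
            "parent": c.parent,
        }
        for c in table.concepts.values()
    ]
    return json.dumps(objs, ensure_ascii=False, indent=1)


def from_json(text: str) -> ConceptTable:
    objs = json.loads(text)
    if not objs:
        raise TerminologyError("empty concept list")
    table = ConceptTable(objs[0]["terminology"])
    for obj in objs:
        table.add(Concept(**obj))
    table.validate()
    return table


# ---------------------------------------------------------------------------
# Subsetting and entry expansion
# ---------------------------------------------------------------------------

def select_subset(table: ConceptTable, groups: set[str]) -> ConceptTable:
    """Concepts whose group is in *groups*.

    For SNOMED CT-style tables, the subset additionally closes over parent
    links: every descendant of a selected concept is included even when it
    carries a different group tag, mirroring hierarchy-based subsetting.
    LOINC/ICD-11 style tables subset flat on the group tag.
    """
    selected = {c.code for c in table.concepts.values() if c.group in groups}
    if table.terminology == "SNOMEDCT":
        children: dict[str, list[str]] = {}
        for c in table.concepts.values():
            if c.parent:
                children.setdefault(c.parent, []).append(c.code)
        frontier = list(selected)
        while frontier:
            code = frontier.pop()
            for child in children.get(code, ()):
                if child not in selected:
                    selected.add(child)
                    frontier.append(child)
    result = ConceptTable(table.terminology)
    for code in table.concepts:  # preserve input order
        if code in selected:
            concept = table.concepts[code]
            parent = concept.parent if concept.parent in selected else None
            result.add(
                Concept(
                    concept.terminology,
                    concept.code,
                    concept.label,
                    list(concept.synonyms),
                    concept.group,
                    parent,
                )
            )
    if not result.concepts:
        import warnings

        warnings.warn(f"subset selection over {sorted(groups)} produced an empty table")
    return result


def text_entries(table: ConceptTable) -> list[tuple[str, str]]:
    """Indexable (entry_text, code) pairs: one per label and per synonym."""
    entries: list[tuple[str, str]] = []
    for code in table.concepts:
        concept = table.concepts[code]
        entries.append((concept.label, code))
        for syn in concept.synonyms:
            entries.append((syn, code))
    return entries
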