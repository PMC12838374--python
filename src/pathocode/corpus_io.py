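"""Data model and serialization for annotated pathology reports.

Reports carry raw text plus character-offset entity annotations for three
entity types (sample type, test performed, finding).  This module owns the
JSONL on-disk format, word tokenization, BIO tag conversion in both
directions, and the alignment of word-level labels onto subword sequences
with the conventional ``-100`` ignore value.

Offsets are 0-based half-open throughout; annotation files store offsets,
never tokenized text, so tokenizers can vary without re-annotation.
"""

from __future__ import annotations

import json
import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

ENTITY_TYPES = ("SAMPLE_TYPE", "TEST_PERFORMED", "FINDING")
TERMINOLOGIES = ("SNOMEDCT", "LOINC", "ICD11")

#: BIO label inventory: O plus B-/I- for each of the three entity types.
BIO_LABELS = ("O",) + tuple(
    f"{prefix}-{etype}" for etype in ENTITY_TYPES for prefix in ("B", "I")
)
LABEL_TO_ID = {label: i for i, label in enumerate(BIO_LABELS)}
ID_TO_LABEL = dict(enumerate(BIO_LABELS))

#: Label value excluded from loss and metrics (filler / special positions).
IGNORE_INDEX = -100

# Unicode-aware: runs of word characters, or single non-space punctuation.
_TOKEN_RE = re.compile(r"\w+|[^\w\s]", re.UNICODE)


class CorpusError(ValueError):
    """Malformed corpus content (bad JSON, invalid spans, overlaps)."""


@dataclass(frozen=True)
class Token:
    text: str
    start: int
    end: int


def word_tokenize(text: str, offset: int = 0) -> list[Token]:
    """Split *text* into word/punctuation tokens with character offsets.

    ``offset`` shifts the reported spans, so sentence-local text can be
    tokenized while keeping report-global coordinates.
    """
    return [
        Token(m.group(), m.start() + offset, m.end() + offset)
        for m in _TOKEN_RE.finditer(text)
    ]


@dataclass
class EntityMention:
    """One annotated span: ``[start, end)`` in the parent report's text."""

    start: int
    end: int
    entity_type: str
    surface: str
    codes: dict[str, str] = field(default_factory=dict)

    def validate(self, text: str, report_id: str = "?") -> None:
        if not (0 <= self.start < self.end <= len(text)):
            raise CorpusError(
                f"report {report_id}: entity span [{self.start}, {self.end}) "
                f"outside text of length {len(text)}"
            )
        if self.entity_type not in ENTITY_TYPES:
            raise CorpusError(
                f"report {report_id}: unknown entity type {self.entity_type!r}"
            )
        if self.surface != text[self.start : self.end]:
            raise CorpusError(
                f"report {report_id}: surface {self.surface!r} does not match "
                f"text slice {text[self.start:self.end]!r}"
            )
        bad = set(self.codes) - set(TERMINOLOGIES)
        if bad:
            raise CorpusError(f"report {report_id}: unknown terminologies {sorted(bad)}")


@dataclass
class Report:
    report_id: str
    text: str
    language: str = "fr"
    sentences: list[tuple[int, int]] = field(default_factory=list)
    entities: list[EntityMention] = field(default_factory=list)

    def validate(self) -> None:
        prev_end = 0
        for start, end in self.sentences:
            if not (0 <= start < end <= len(self.text)):
                raise CorpusError(
                    f"report {self.report_id}: sentence span [{start}, {end}) "
                    f"outside text bounds"
                )
            if start < prev_end:
                raise CorpusError(
                    f"report {self.report_id}: overlapping or unsorted sentence spans"
                )
            prev_end = end
        for ent in self.entities:
            ent.validate(self.text, self.report_id)
        # Gold entities must be pairwise non-overlapping: the three entity
        # types are disjoint by annotation design.
        spans = sorted((e.start, e.end) for e in self.entities)
        for (s1, e1), (s2, _) in zip(spans, spans[1:]):
            if s2 < e1:
                raise CorpusError(
                    f"report {self.report_id}: overlapping gold entities at "
                    f"offsets {s1}..{e1} and {s2}.."
                )


@dataclass
class TaggedSequence:
    """Word tokens and their BIO tags (parallel lists)."""

    tokens: list[str]
    tags: list[str]

    def __post_init__(self) -> None:
        if len(self.tokens) != len(self.tags):
            raise CorpusError("tokens and tags must have equal length")
        unknown = set(self.tags) - set(BIO_LABELS)
        if unknown:
            raise CorpusError(f"unknown BIO tags: {sorted(unknown)}")


@dataclass
class AlignedExample:
    """Subword sequence with per-position source word index and label id.

    Positions whose ``word_index`` is None (special or filler tokens) always
    carry label id ``-100`` and are invisible to loss and metrics.
    """

    subword_tokens: list[str]
    word_index: list[int | None]
    label_ids: list[int]

    def __post_init__(self) -> None:
        if not (len(self.subword_tokens) == len(self.word_index) == len(self.label_ids)):
            raise CorpusError("aligned example sequences must have equal length")
        for wi, lid in zip(self.word_index, self.label_ids):
            if wi is None and lid != IGNORE_INDEX:
                raise CorpusError("special position must carry the ignore label")


# ---------------------------------------------------------------------------
# JSONL serialization
# ---------------------------------------------------------------------------

def _report_to_obj(report: Report) -> dict:
    return {
        "report_id": report.report_id,
        "text": report.text,
        "language": report.language,
        "sentences": [[s, e] for s, e in report.sentences],
        "entities": [
            {
                "start": ent.start,
                "end": ent.end,
                "type": ent.entity_type,
                "codes": dict(ent.codes),
            }
            for ent in report.entities
        ],
    }


def _report_from_obj(obj: dict) -> Report:
    text = obj["text"]
    entities = [
        EntityMention(
            start=e["start"],
            end=e["end"],
            entity_type=e["type"],
            surface=text[e["start"] : e["end"]] if 0 <= e["start"] <= e["end"] <= len(text) else "",
            codes=dict(e.get("codes") or {}),
        )
        for e in obj.get("entities", [])
    ]
    report = Report(
        report_id=obj["report_id"],
        text=text,
        language=obj.get("language", "fr"),
        sentences=[(int(s), int(e)) for s, e in obj.get("sentences", [])],
        entities=entities,
    )
    report.validate()
    return report


def read_reports(path: str | Path, normalize: bool = True) -> list[Report]:
    """Read a JSONL report file; one report object per line.

    Text is NFC-normalized at load by default (French diacritics are
    preserved; only the byte representation is canonicalized).  Offsets in
    the file must refer to the NFC form.
    """
    reports: list[Report] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusError(f"line {lineno}: malformed JSON ({exc.msg})") from exc
            if normalize:
                obj["text"] = unicodedata.normalize("NFC", obj["text"])
            reports.append(_report_from_obj(obj))
    return reports


def write_reports(reports: Iterable[Report], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for report in reports:
            report.validate()
            fh.write(json.dumps(_report_to_obj(report), ensure_ascii=False) + "\n")


# ---------------------------------------------------------------------------
# BIO conversion
# ---------------------------------------------------------------------------

def sentence_tokens(report: Report, sentence: tuple[int, int]) -> list[Token]:
    """Tokens of one sentence span, with report-global offsets."""
    start, end = sentence
    return word_tokenize(report.text[start:end], offset=start)


def spans_to_bio(report: Report, sentence: tuple[int, int]) -> TaggedSequence:
    """BIO tags for one sentence: first overlapping word gets B-, rest I-.

    A word overlapping an entity by any character counts as inside it;
    entities are clipped to the sentence.
    """
    tokens = sentence_tokens(report, sentence)
    tags = ["O"] * len(tokens)
    s_start, s_end = sentence
    for ent in sorted(report.entities, key=lambda e: e.start):
        if ent.end <= s_start or ent.start >= s_end:
            continue
        first = True
        for i, tok in enumerate(tokens):
            if tok.start < ent.end and tok.end > ent.start:  # any-char overlap
                tags[i] = f"{'B' if first else 'I'}-{ent.entity_type}"
                first = False
    return TaggedSequence([t.text for t in tokens], tags)


def bio_to_spans(
    tagged: TaggedSequence, char_offsets: Sequence[tuple[int, int]], text: str | None = None
) -> list[EntityMention]:
    """Decode BIO tags into entity mentions.

    Repairs illegal sequences: an ``I-t`` following ``O``, the sequence
    start, or a tag of a different type is read as ``B-t``.
    """
    if len(char_offsets) != len(tagged.tokens):
        raise CorpusError("char_offsets length must match token count")
    mentions: list[EntityMention] = []
    current: list[int] | None = None  # [start_idx, end_idx] in token space
    current_type: str | None = None

    def flush() -> None:
        nonlocal current, current_type
        if current is not None:
            start = char_offsets[current[0]][0]
            end = char_offsets[current[1]][1]
            surface = text[start:end] if text is not None else ""
            mentions.append(EntityMention(start, end, current_type, surface))
        current, current_type = None, None

    for i, tag in enumerate(tagged.tags):
        if tag == "O":
            flush()
            continue
        prefix, etype = tag.split("-", 1)
        if prefix == "I" and current_type == etype:
            current[1] = i
        else:  # B-, or repaired I- after O / different type
            flush()
            current, current_type = [i, i], etype
    flush()
    return mentions


def align_labels(
    tagged: TaggedSequence,
    subword_map: Sequence[tuple[str, int | None]],
    strategy: str = "first",
) -> AlignedExample:
    """Align word-level BIO labels onto a subword sequence.

    ``subword_map`` lists, per subword, the subword string and its source
    word index (None for special/filler tokens).  Default strategy labels
    only the first subword of each word; continuations get ``-100``.  The
    ``all`` strategy labels continuations with the word's I- variant.
    """
    if strategy not in ("first", "all"):
        raise ValueError(f"unknown alignment strategy {strategy!r}")
    subwords: list[str] = []
    word_idx: list[int | None] = []
    label_ids: list[int] = []
    prev_word: int | None = None
    for sw, wi in subword_map:
        subwords.append(sw)
        word_idx.append(wi)
        if wi is None:
            label_ids.append(IGNORE_INDEX)
        else:
            if not (0 <= wi < len(tagged.tags)):
                raise CorpusError(f"word index {wi} out of range")
            tag = tagged.tags[wi]
            if wi != prev_word:  # first subword of the word
                label_ids.append(LABEL_TO_ID[tag])
            elif strategy == "all":
                inside = tag if tag == "O" else f"I-{tag.split('-', 1)[1]}"
                label_ids.append(LABEL_TO_ID[inside])
            else:
                label_ids.append(IGNORE_INDEX)
        prev_word = wi
    return AlignedExample(subwords, word_idx, label_ids)


def to_conll(report: Report) -> str:
    """CoNLL-style export: ``token<TAB>tag`` lines, blank line between sentences."""
    blocks = []
    sentences = report.sentences or [(0, len(report.text))]
    for sent in sentences:
        tagged = spans_to_bio(report, sent)
        blocks.append("\n".join(f"{tok}\t{tag}" for tok, tag in zip(tagged.tokens, tagged.tags)))
    return "\n\n".join(blocks) + "\n"
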