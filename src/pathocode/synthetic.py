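"""Seeded generator of terminology fixtures and annotated report corpora.

Emulates an anatomopathology corpus: short template sentences (French or
English report boilerplate) each embedding one mention of one entity type,
with gold character spans and gold codes in the routed terminologies.
Concept usage follows a Zipf law, mention surfaces vary over synonyms and
abbreviations, and configurable character-level noise reproduces the
error sources real reports exhibit (typos, abbreviated technique names,
case drift).  A configurable fraction of each concept pool can be held
out of the training segment entirely, so the retrieval-fallback path for
codes never seen by a classifier is exercised.

All output is deterministic per seed.  The prose is synthetic fixture
material, not clinical text.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .corpus_io import EntityMention, Report
from .normalization import route_terminologies
from .terminology import Concept, ConceptTable

# ---------------------------------------------------------------------------
# Lexicon (pathology-flavored, seeded by annotation-guideline vocabulary)
# ---------------------------------------------------------------------------

_SITES = [
    "thyroid", "prostate", "bone", "skin", "breast", "colon", "lung", "liver",
    "kidney", "bladder", "stomach", "esophagus", "pancreas", "ovary", "uterus",
    "cervix", "larynx", "tonsil", "lymph node", "bone marrow", "pleura",
    "salivary gland", "appendix", "gallbladder",
]

_SPECIMEN_FIXED = [
    ("bronchoalveolar lavage fluid specimen", ["bronchoalveolar lavage", "BAL fluid"]),
    ("bone marrow sample", ["bone marrow aspirate"]),
]
_SPECIMEN_PATTERNS = [
    ("biopsy of {site}", ["{site} biopsy", "{site} needle biopsy"]),
    ("resection of {site}", ["{site} resection specimen"]),
    ("curettage of {site}", ["{site} curettage material"]),
]

_TESTS = [
    ("immunohistochemistry", ["immunostaining", "IHC"]),
    ("hematoxylin and eosin", ["H&E", "HE stain"]),
    ("periodic acid-Schiff", ["PAS stain", "PAS"]),
    ("Masson's trichrome", ["trichrome stain"]),
    ("Ziehl-Neelsen stain", ["ZN stain", "acid-fast stain"]),
    ("Congo red stain", ["congo red"]),
    ("Giemsa stain", ["giemsa"]),
    ("fluorescence in situ hybridization", ["FISH"]),
    ("polymerase chain reaction", ["PCR"]),
    ("flow cytometry", ["FCM"]),
    ("frozen section examination", ["frozen section"]),
    ("electron microscopy", ["EM"]),
    ("gram stain", ["gram staining"]),
    ("reticulin stain", ["reticulin"]),
    ("alcian blue stain", ["alcian blue"]),
    ("toluidine blue stain", ["toluidine blue"]),
    ("von Kossa stain", ["von Kossa"]),
    ("oil red O stain", ["oil red O"]),
    ("Grocott methenamine silver stain", ["GMS stain"]),
    ("direct immunofluorescence", ["DIF"]),
    ("in situ hybridization", ["ISH"]),
    ("molecular profiling", ["molecular analysis"]),
    ("cytogenetic analysis", ["karyotyping"]),
    ("immunophenotyping", ["immune phenotyping"]),
    ("Perls Prussian blue stain", ["Perls stain"]),
]
_TEST_MARKERS = [
    "CD20", "CD3", "S100", "Ki-67", "p53", "CK7", "CK20", "TTF-1", "PSA",
    "CD45", "CD30", "ALK", "HER2", "ER", "PR", "CD117", "DOG1", "WT1",
    "calretinin", "chromogranin", "synaptophysin", "desmin", "vimentin", "EMA",
]
_TEST_PATTERNS = [
    ("immunohistochemistry for {site}", ["{site} immunostain"]),
]

_FINDING_FIXED = [
    ("osteosarcoma", ["osteogenic sarcoma"]),
    ("mesothelioma", ["malignant mesothelioma"]),
    ("melanoma in situ", ["in situ melanoma"]),
    ("Hashimoto's thyroiditis", ["chronic lymphocytic thyroiditis"]),
    ("lipoma", ["benign lipomatous tumor"]),
    ("fibroadenoma", ["fibroadenomatous nodule"]),
    ("amyloidosis", ["amyloid deposition"]),
    ("sarcoidosis", ["sarcoid granulomatosis"]),
]
_FINDING_PATTERNS = [
    ("adenocarcinoma of {site}", ["{site} adenocarcinoma"]),
    ("squamous cell carcinoma of {site}", ["{site} squamous carcinoma"]),
    ("chronic inflammation of {site}", ["chronic {site} inflammation"]),
    ("papillary carcinoma of {site}", ["{site} papillary carcinoma"]),
    ("lymphoma of {site}", ["{site} lymphoma"]),
]

#: Full form -> abbreviated form, applied by the abbreviation corruption.
ABBREVIATIONS = {
    "hematoxylin and eosin": "H&E",
    "immunohistochemistry": "IHC",
    "polymerase chain reaction": "PCR",
    "fluorescence in situ hybridization": "FISH",
    "bronchoalveolar lavage": "BAL",
    "electron microscopy": "EM",
    "direct immunofluorescence": "DIF",
    "in situ hybridization": "ISH",
}

_TEMPLATES = {
    ("fr", "SAMPLE_TYPE"): [
        "Prélèvement reçu : {m}.",
        "Nature du prélèvement : {m}.",
        "Matériel adressé : {m}.",
    ],
    ("fr", "TEST_PERFORMED"): [
        "Technique réalisée : {m}.",
        "Examen effectué : {m}.",
        "Coloration : {m}.",
    ],
    ("fr", "FINDING"): [
        "Conclusion : {m}.",
        "Aspect morphologique en faveur de {m}.",
        "Diagnostic retenu : {m}.",
    ],
    ("en", "SAMPLE_TYPE"): [
        "Specimen received: {m}.",
        "Material submitted: {m}.",
    ],
    ("en", "TEST_PERFORMED"): [
        "Technique performed: {m}.",
        "The test performed was {m}.",
    ],
    ("en", "FINDING"): [
        "Findings are consistent with {m}.",
        "Final diagnosis: {m}.",
    ],
}

_ENTITY_CYCLE = ("SAMPLE_TYPE", "TEST_PERFORMED", "FINDING")


@dataclass
class NoiseConfig:
    synonym_rate: float = 0.5  # chance of using a synonym instead of the label
    abbreviation_rate: float = 0.1
    typo_rate: float = 0.05
    case_rate: float = 0.05

    def __post_init__(self) -> None:
        for name in ("synonym_rate", "abbreviation_rate", "typo_rate", "case_rate"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")

    @classmethod
    def none(cls) -> "NoiseConfig":
        """Exact-surface generation: every mention is a verbatim entry."""
        return cls(synonym_rate=0.5, abbreviation_rate=0.0, typo_rate=0.0, case_rate=0.0)


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic corpus.

    Defaults mirror a 560-report single-site corpus with a long-tailed
    (Zipf, exponent 1.1) concept usage over 25 concepts per terminology.
    ``unseen_fraction`` reserves that fraction of each concept pool for
    the test segment (the last 1 - train_fraction of report indices), so
    those codes never occur in classifier training under an in-order
    split.
    """

    n_reports: int = 560
    n_concepts: int = 25
    max_synonyms: int = 3
    zipf_s: float = 1.1
    noise: NoiseConfig | None = None
    french_fraction: float = 0.7
    unseen_fraction: float = 0.0
    train_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reports < 1:
            raise ValueError("n_reports must be at least 1")
        if self.zipf_s <= 0:
            raise ValueError("zipf exponent must be positive")
        if not (0.0 <= self.unseen_fraction < 1.0):
            raise ValueError("unseen_fraction must lie in [0, 1)")
        if self.noise is None:
            self.noise = NoiseConfig()


# ---------------------------------------------------------------------------
# Concept pools and terminology tables
# ---------------------------------------------------------------------------

def _expand(fixed, patterns, n: int, max_synonyms: int, rng: np.random.Generator,
            sites: list[str] = _SITES):
    """Deterministically materialize n (label, synonyms) concepts."""
    pool = [(label, list(syns)) for label, syns in fixed]
    combos = [(p, s) for p, _ in patterns for s in sites]
    order = rng.permutation(len(combos))
    pattern_syns = {p: syns for p, syns in patterns}
    for idx in order:
        if len(pool) >= n:
            break
        pattern, site = combos[idx]
        label = pattern.format(site=site)
        syns = [s.format(site=site) for s in pattern_syns[pattern]]
        pool.append((label, syns))
    if len(pool) < n:
        raise ValueError(f"lexicon supports at most {len(pool)} concepts, {n} requested")
    return [(label, syns[:max_synonyms]) for label, syns in pool[:n]]


def _pools(cfg: GeneratorConfig):
    """The three concept pools (specimens, tests, findings), seed-stable."""
    rng = np.random.default_rng(cfg.seed + 1)
    specimens = _expand(_SPECIMEN_FIXED, _SPECIMEN_PATTERNS, cfg.n_concepts,
                        cfg.max_synonyms, rng)
    if cfg.n_concepts <= len(_TESTS):
        tests = [(l, s[: cfg.max_synonyms]) for l, s in _TESTS[: cfg.n_concepts]]
    else:
        extra_rng = np.random.default_rng(cfg.seed + 2)
        tests = _expand(_TESTS, _TEST_PATTERNS, cfg.n_concepts, cfg.max_synonyms,
                        extra_rng, sites=_TEST_MARKERS)
    findings = _expand(_FINDING_FIXED, _FINDING_PATTERNS, cfg.n_concepts,
                       cfg.max_synonyms, rng)
    return specimens, tests, findings


def _unique_codes(rng: np.random.Generator, n: int, style: str) -> list[str]:
    codes: list[str] = []
    seen: set[str] = set()
    while len(codes) < n:
        if style == "SNOMEDCT":
            code = str(int(rng.integers(10_000_000, 100_000_000)))
        elif style == "LOINC":
            code = f"{int(rng.integers(1000, 100_000))}-{int(rng.integers(0, 10))}"
        else:  # ICD11-like: digit, letter, two digits, dot, digit
            code = (
                f"{int(rng.integers(1, 10))}"
                f"{chr(int(rng.integers(ord('A'), ord('Z') + 1)))}"
                f"{int(rng.integers(10, 100))}.{int(rng.integers(0, 10))}"
            )
        if code not in seen:
            seen.add(code)
            codes.append(code)
    return codes


def generate_terminology(cfg: GeneratorConfig, terminology: str) -> ConceptTable:
    """Synthetic concept table in the given terminology's code style.

    SNOMED CT-style tables get two hierarchy roots (specimen, clinical
    finding) with all concepts as children, so parent-closure subsetting is
    exercised; LOINC-style tables carry a class designation; ICD-11-style
    tables a chapter.  Finding concepts are shared (by label) between the
    SNOMED CT and ICD-11 tables, mirroring dual coding of diagnoses.
    """
    if cfg.n_concepts < 2:
        raise ValueError("n_concepts must be at least 2")
    specimens, tests, findings = _pools(cfg)
    term_offset = {"SNOMEDCT": 11, "LOINC": 13, "ICD11": 17}.get(terminology, 19)
    rng = np.random.default_rng(cfg.seed + term_offset)
    table = ConceptTable(terminology)
    if terminology == "SNOMEDCT":
        codes = _unique_codes(rng, 2 + len(specimens) + len(findings), "SNOMEDCT")
        spec_root, find_root = codes[0], codes[1]
        table.add(Concept(terminology, spec_root, "Specimen", [], "specimen", None))
        table.add(Concept(terminology, find_root, "Clinical finding", [],
                          "clinical_finding", None))
        for code, (label, syns) in zip(codes[2 : 2 + len(specimens)], specimens):
            table.add(Concept(terminology, code, label, syns, "specimen", spec_root))
        for code, (label, syns) in zip(codes[2 + len(specimens) :], findings):
            table.add(Concept(terminology, code, label, syns, "clinical_finding",
                              find_root))
    elif terminology == "LOINC":
        codes = _unique_codes(rng, len(tests), "LOINC")
        for code, (label, syns) in zip(codes, tests):
            table.add(Concept(terminology, code, label, syns, "PATH", None))
    elif terminology == "ICD11":
        codes = _unique_codes(rng, len(findings), "ICD11")
        for code, (label, syns) in zip(codes, findings):
            table.add(Concept(terminology, code, label, syns, "02", None))
    else:
        raise ValueError(f"unknown terminology {terminology!r}")
    table.validate()
    return table


def generate_terminologies(cfg: GeneratorConfig) -> dict[str, ConceptTable]:
    return {t: generate_terminology(cfg, t) for t in ("SNOMEDCT", "LOINC", "ICD11")}


# ---------------------------------------------------------------------------
# Surface corruption
# ---------------------------------------------------------------------------

def _edit_word(word: str, rng: np.random.Generator) -> str:
    """One character edit (insert / delete / swap) inside a word."""
    op = rng.integers(3)
    i = int(rng.integers(len(word)))
    if op == 0 and len(word) > 2:  # delete
        return word[:i] + word[i + 1 :]
    if op == 1:  # insert
        ch = chr(ord("a") + int(rng.integers(26)))
        return word[:i] + ch + word[i:]
    if len(word) > 1:  # swap adjacent
        if i == len(word) - 1:
            i -= 1
        return word[:i] + word[i + 1] + word[i] + word[i + 2 :]
    return word


def corrupt_surface(text: str, noise: NoiseConfig, rng: np.random.Generator) -> str:
    """Apply abbreviation substitution, per-word character edits, and case
    perturbation, each with its configured probability.

    ``typo_rate`` is a per-word probability; each corrupted word receives
    exactly one character edit, so the output is within Levenshtein
    distance word-count of the input.
    """
    if rng.random() < noise.abbreviation_rate:
        lowered = text.lower()
        for full in sorted(ABBREVIATIONS, key=len, reverse=True):
            pos = lowered.find(full)
            if pos >= 0:
                text = text[:pos] + ABBREVIATIONS[full] + text[pos + len(full) :]
                break
    if noise.typo_rate > 0:
        words = text.split(" ")
        words = [
            _edit_word(w, rng) if w and rng.random() < noise.typo_rate else w
            for w in words
        ]
        text = " ".join(words)
    if rng.random() < noise.case_rate:
        text = text.upper() if rng.random() < 0.5 else text.lower()
    return text


# ---------------------------------------------------------------------------
# Report generation
# ---------------------------------------------------------------------------

def _zipf_probs(n: int, s: float) -> np.ndarray:
    weights = (np.arange(1, n + 1, dtype=float)) ** (-s)
    return weights / weights.sum()


def _mention_pools(tables: dict[str, ConceptTable]):
    """Rebuild (label, synonyms, codes-per-terminology) pools from tables."""
    snomed = tables["SNOMEDCT"]
    icd_by_label = {c.label: c.code for c in tables["ICD11"].concepts.values()}
    pools: dict[str, list[tuple[str, list[str], dict[str, str]]]] = {
        "SAMPLE_TYPE": [], "TEST_PERFORMED": [], "FINDING": [],
    }
    for c in snomed.concepts.values():
        if c.parent is None:
            continue  # hierarchy roots are not mention concepts
        if c.group == "specimen":
            pools["SAMPLE_TYPE"].append((c.label, c.synonyms, {"SNOMEDCT": c.code}))
        elif c.group == "clinical_finding":
            codes = {"SNOMEDCT": c.code}
            if c.label in icd_by_label:
                codes["ICD11"] = icd_by_label[c.label]
            pools["FINDING"].append((c.label, c.synonyms, codes))
    for c in tables["LOINC"].concepts.values():
        pools["TEST_PERFORMED"].append((c.label, c.synonyms, {"LOINC": c.code}))
    for etype, pool in pools.items():
        if not pool:
            raise ValueError(f"no concepts available for entity type {etype}")
    return pools


def generate_reports(
    cfg: GeneratorConfig, tables: dict[str, ConceptTable] | None = None
) -> list[Report]:
    """Generate the annotated corpus.

    Each report holds 1-5 template sentences; sentence i embeds one mention
    whose entity type cycles sample / test / finding.  Concept choice is
    Zipf-distributed over each pool in pool order (rank 1 = most frequent).
    With ``unseen_fraction`` > 0, the rarest concepts of each pool appear
    only in reports belonging to the test segment, where they are
    oversampled (probability 1/4 per mention slot) to exercise the
    unseen-code path at a realistic rare-code share of test mentions.
    """
    if tables is None:
        tables = generate_terminologies(cfg)
    if any(len(t) == 0 for t in tables.values()):
        raise ValueError("empty concept tables")
    pools = _mention_pools(tables)
    rng = np.random.default_rng(cfg.seed)
    train_cut = int(round(cfg.train_fraction * cfg.n_reports))

    head_probs: dict[str, np.ndarray] = {}
    tails: dict[str, np.ndarray] = {}
    for etype, pool in pools.items():
        n = len(pool)
        n_tail = math.ceil(cfg.unseen_fraction * n) if cfg.unseen_fraction > 0 else 0
        n_head = n - n_tail
        if n_head < 2:
            raise ValueError("unseen_fraction leaves fewer than 2 training concepts")
        head_probs[etype] = _zipf_probs(n_head, cfg.zipf_s)
        tails[etype] = np.arange(n_head, n)

    reports: list[Report] = []
    for r in range(cfg.n_reports):
        in_test = r >= train_cut
        language = "fr" if rng.random() < cfg.french_fraction else "en"
        n_sent = int(rng.integers(1, 6))
        text_parts: list[str] = []
        sentences: list[tuple[int, int]] = []
        entities: list[EntityMention] = []
        cursor = 0
        for si in range(n_sent):
            etype = _ENTITY_CYCLE[si % 3]
            pool = pools[etype]
            tail = tails[etype]
            if in_test and tail.size and rng.random() < 0.25:
                ci = int(tail[rng.integers(tail.size)])
            else:
                ci = int(rng.choice(len(head_probs[etype]), p=head_probs[etype]))
            label, syns, codes = pool[ci]
            surface = label
            if syns and rng.random() < cfg.noise.synonym_rate:
                surface = syns[int(rng.integers(len(syns)))]
            surface = corrupt_surface(surface, cfg.noise, rng)
            template = _TEMPLATES[(language, etype)]
            sentence = template[int(rng.integers(len(template)))]
            prefix, suffix = sentence.split("{m}")
            if si > 0:
                text_parts.append(" ")
                cursor += 1
            s_start = cursor
            m_start = cursor + len(prefix)
            m_end = m_start + len(surface)
            text_parts.extend([prefix, surface, suffix])
            cursor = m_end + len(suffix)
            sentences.append((s_start, cursor))
            entities.append(EntityMention(m_start, m_end, etype, surface, codes))
        report = Report(
            report_id=f"R{r:04d}",
            text="".join(text_parts),
            language=language,
            sentences=sentences,
            entities=entities,
        )
        report.validate()
        reports.append(report)
    return reports


def mention_examples(
    reports: Sequence[Report], terminology: str
) -> tuple[list[str], list[str]]:
    """(surface, gold code) training pairs for one terminology's classifier."""
    texts, codes = [], []
    for report in reports:
        for mention in report.entities:
            if terminology in mention.codes and terminology in route_terminologies(
                mention.entity_type
            ):
                texts.append(mention.surface)
                codes.append(mention.codes[terminology])
    return texts, codes
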