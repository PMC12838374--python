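"""End-to-end pipeline: corpus -> split -> tagger -> indices -> coders ->
fusion -> normalization -> evaluation.

The pipeline is a pure function of its (schema-validated) config: every
stage seed derives from the one global seed, and the resulting
``report.json`` is bit-identical across re-runs.  Comparison protocol:
the fusion weights are optimized once with the dense retrieval channel
(the proposed system); the classifier-only and BM25 ablations are the
degenerate corner (w=1, tau=0) and the same learned config with the
sparse channel swapped in.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Literal, Sequence

from pydantic import BaseModel, ConfigDict

from . import corpus_io
from .corpus_io import ENTITY_TYPES, Report, TERMINOLOGIES
from .encoders import HashingEncoder
from .evaluation import (
    ConfusionMatrix,
    compare_systems,
    evaluate_predictions,
    prf,
)
from .ner import NERConfig, SplitSpec, split_reports, token_predictions, train_tagger
from .normalization import (
    CoderConfig,
    classifier_candidates,
    fit_code_classifier,
    fuse,
    optimize_fusion,
    route_terminologies,
)
from .retrieval import build_dense_index, build_sparse_index, dense_search, sparse_search
from .synthetic import GeneratorConfig, NoiseConfig, generate_reports, generate_terminologies
from .terminology import write_concepts


class CorpusSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    reports_path: str | None = None  # load instead of simulate
    n_reports: int = 560
    n_concepts: int = 25
    zipf_s: float = 1.1
    synonym_rate: float = 0.5
    abbreviation_rate: float = 0.1
    typo_rate: float = 0.05
    case_rate: float = 0.05
    french_fraction: float = 0.7
    unseen_fraction: float = 0.0


class EncoderSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    type: Literal["hashing", "external"] = "hashing"
    dim: int = 256
    model_id: str | None = None


class NERSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    epochs: int = 3
    learning_rate: float = 0.05
    batch_size: int = 8
    weight_decay: float = 0.01
    window: int = 2
    encoder_dim: int = 96


class CoderSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    epochs: int = 10
    learning_rate: float = 0.05
    batch_size: int = 8
    weight_decay: float = 0.01
    val_fraction: float = 0.1
    patience: int = 2


class FusionSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    k: int = 5
    grid_w: list[float] | None = None
    grid_tau: list[float] | None = None


class SplitSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    train_fraction: float = 0.8
    shuffle: bool = True


class EvalSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_perm: int = 10_000
    n_boot: int = 10_000


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    corpus: CorpusSection = CorpusSection()
    encoder: EncoderSection = EncoderSection()
    ner: NERSection = NERSection()
    coder: CoderSection = CoderSection()
    fusion: FusionSection = FusionSection()
    split: SplitSection = SplitSection()
    evaluation: EvalSection = EvalSection()


def config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(config.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _generator_config(config: PipelineConfig) -> GeneratorConfig:
    c = config.corpus
    return GeneratorConfig(
        n_reports=c.n_reports,
        n_concepts=c.n_concepts,
        zipf_s=c.zipf_s,
        noise=NoiseConfig(
            synonym_rate=c.synonym_rate,
            abbreviation_rate=c.abbreviation_rate,
            typo_rate=c.typo_rate,
            case_rate=c.case_rate,
        ),
        french_fraction=c.french_fraction,
        unseen_fraction=c.unseen_fraction,
        train_fraction=config.split.train_fraction,
        seed=config.seed,
    )


# ---------------------------------------------------------------------------
# Token-level NER metrics (entity-class view)
# ---------------------------------------------------------------------------

def ner_token_report(gold_tags: Sequence[str], pred_tags: Sequence[str]) -> dict:
    """Token-level metrics with BIO prefixes collapsed to entity classes.

    Per-class P/R/F1 over the three entity types, plus a micro average over
    entity (non-O) tokens: TP = entity tokens tagged with their gold class,
    FP = predicted-entity tokens that are wrong, FN = gold-entity tokens
    that are missed or mislabeled.
    """

    def collapse(tag: str) -> str:
        return tag if tag == "O" else tag.split("-", 1)[1]

    gold = [collapse(t) for t in gold_tags]
    pred = [collapse(t) for t in pred_tags]
    labels = ["O", *ENTITY_TYPES]
    cm = ConfusionMatrix.from_pairs(gold, pred, labels=labels)
    report = prf(cm)
    tp = sum(1 for g, p in zip(gold, pred) if g != "O" and g == p)
    fp = sum(1 for g, p in zip(gold, pred) if p != "O" and g != p)
    fn = sum(1 for g, p in zip(gold, pred) if g != "O" and g != p)
    micro_p = tp / (tp + fp) if tp + fp else 0.0
    micro_r = tp / (tp + fn) if tp + fn else 0.0
    micro_f1 = 2 * micro_p * micro_r / (micro_p + micro_r) if micro_p + micro_r else 0.0
    per_entity = {
        etype: {
            "precision": report.precision[etype],
            "recall": report.recall[etype],
            "f1": report.f1[etype],
            "support": report.support[etype],
        }
        for etype in ENTITY_TYPES
    }
    return {
        "per_entity": per_entity,
        "micro_precision": micro_p,
        "micro_recall": micro_r,
        "micro_f1": micro_f1,
        "token_accuracy": cm.accuracy(),
    }


# ---------------------------------------------------------------------------
# Coding stage
# ---------------------------------------------------------------------------

def _mention_pairs(reports: Sequence[Report], terminology: str):
    texts, codes = [], []
    for report in reports:
        for m in report.entities:
            if terminology in route_terminologies(m.entity_type) and terminology in m.codes:
                texts.append(m.surface)
                codes.append(m.codes[terminology])
    return texts, codes


def run_coding_stage(
    train: Sequence[Report],
    test: Sequence[Report],
    tables: dict,
    config: PipelineConfig,
) -> dict:
    """Train coders, learn fusion, evaluate the three system variants."""
    encoder = HashingEncoder(dim=config.encoder.dim, seed=config.seed)
    out: dict = {}
    for term in TERMINOLOGIES:
        train_texts, train_codes = _mention_pairs(train, term)
        test_texts, test_codes = _mention_pairs(test, term)
        if not test_texts or len(set(train_codes)) < 2:
            continue
        table = tables[term]
        dense = build_dense_index(table, encoder)
        sparse = build_sparse_index(table)
        coder_cfg = CoderConfig(
            epochs=config.coder.epochs,
            learning_rate=config.coder.learning_rate,
            batch_size=config.coder.batch_size,
            weight_decay=config.coder.weight_decay,
            val_fraction=config.coder.val_fraction,
            patience=config.coder.patience,
            seed=config.seed,
        )
        clf = fit_code_classifier(train_texts, train_codes, term, encoder,
                                  table=table, config=coder_cfg)
        fusion_cfg = optimize_fusion(
            train_texts, train_codes, term, table, encoder, dense,
            grid_w=config.fusion.grid_w, grid_tau=config.fusion.grid_tau,
            k=config.fusion.k, seed=config.seed, coder_config=coder_cfg,
        )
        k = config.fusion.k
        preds = {"classifier_only": [], "fusion_dense": [], "fusion_sparse": []}
        for text in test_texts:
            clf_cs = classifier_candidates(clf, text, k)
            dense_cs = dense_search(dense, text, k, encoder)
            sparse_cs = sparse_search(sparse, text, k)
            preds["classifier_only"].append(clf_cs.top().code)
            preds["fusion_dense"].append(fuse(clf_cs, dense_cs, fusion_cfg)[0])
            preds["fusion_sparse"].append(fuse(clf_cs, sparse_cs, fusion_cfg)[0])
        systems = {
            name: evaluate_predictions(test_codes, p) for name, p in preds.items()
        }
        comparisons = {
            "classifier_vs_fusion": compare_systems(
                test_codes, preds["classifier_only"], preds["fusion_dense"],
                n_perm=config.evaluation.n_perm, seed=config.seed,
            ),
            "sparse_vs_fusion": compare_systems(
                test_codes, preds["fusion_sparse"], preds["fusion_dense"],
                n_perm=config.evaluation.n_perm, seed=config.seed,
            ),
        }
        out[term] = {
            "n_test_mentions": len(test_texts),
            "n_train_mentions": len(train_texts),
            "n_train_codes": len(set(train_codes)),
            "unseen_code_fraction": (
                sum(1 for c in test_codes if c not in set(train_codes)) / len(test_codes)
            ),
            "fusion_config": asdict(fusion_cfg),
            "systems": {
                name: {
                    "accuracy": r.accuracy,
                    "macro_precision": r.macro_precision,
                    "macro_recall": r.macro_recall,
                    "macro_f1": r.macro_f1,
                    "kappa": r.kappa,
                    "mcc": r.mcc,
                }
                for name, r in systems.items()
            },
            "comparisons": {
                name: {
                    "accuracy_a": c.accuracy_a,
                    "accuracy_b": c.accuracy_b,
                    "accuracy_difference": c.accuracy_difference,
                    "mcnemar_b": c.mcnemar_b,
                    "mcnemar_c": c.mcnemar_c,
                    "mcnemar_p": c.mcnemar_p,
                    "permutation_p": c.permutation_p,
                }
                for name, c in comparisons.items()
            },
        }
    return out


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Execute every stage and return (and optionally write) the report."""
    gen_cfg = _generator_config(config)
    tables = generate_terminologies(gen_cfg)
    if config.corpus.reports_path:
        # externally supplied corpus: gold codes must reference the same
        # concept tables (e.g. a corpus written by an earlier simulate run)
        reports = corpus_io.read_reports(config.corpus.reports_path)
    else:
        reports = generate_reports(gen_cfg, tables)
    split_spec = SplitSpec(
        train_fraction=config.split.train_fraction,
        seed=config.seed,
        shuffle=config.split.shuffle,
    )
    train, test = split_reports(reports, split_spec)

    ner_cfg = NERConfig(
        epochs=config.ner.epochs,
        learning_rate=config.ner.learning_rate,
        batch_size=config.ner.batch_size,
        weight_decay=config.ner.weight_decay,
        window=config.ner.window,
        encoder_dim=config.ner.encoder_dim,
        seed=config.seed,
    )
    tagger = train_tagger(train, ner_cfg)
    gold_tags, pred_tags = token_predictions(tagger, test)
    ner_report = ner_token_report(gold_tags, pred_tags)

    coding = run_coding_stage(train, test, tables, config)

    report = {
        "config_hash": config_hash(config),
        "seed": config.seed,
        "n_reports": len(reports),
        "n_train": len(train),
        "n_test": len(test),
        "ner": ner_report,
        "coding": coding,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
        corpus_io.write_reports(reports, out_dir / "reports.jsonl")
        for term, table in tables.items():
            write_concepts(table, out_dir / f"kb_{term.lower()}.tsv")
        (out_dir / "manifest.json").write_text(
            json.dumps({"seed": config.seed, "config": config.model_dump()}, indent=1)
        )
    return report
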