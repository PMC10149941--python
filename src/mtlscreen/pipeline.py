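"""End-to-end experiment orchestration.

One experiment run executes the full chain deterministically from a single
seed: (synthetic or file) corpora -> cleaning and minimum-token filtering ->
risk-label collapsing and control balancing -> cross-task alignment ->
vocabulary + sequence encoding (+ optional lexicon auxiliary features with
train-fitted scaling) -> five stratified shuffle splits -> per-split training
-> probability-averaging ensemble -> evaluation on the held-out test pair,
plus any extra test corpora evaluated with the already-trained ensemble (no
retraining).

Metric keys follow the reporting vocabulary of the study this pipeline
reproduces the shape of: Ps/Pm (macro precision, suicide / mental-disorder
task), Rs/Rm (recall), F1s/F1m (macro F1), ACCs/ACCm (accuracy, in percent),
AUCs/AUCm (macro ROC AUC).
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import numpy as np

from .corpus import (
    AlignedPairDataset,
    SplitSpec,
    TASKS,
    align_tasks,
    balance_with_controls,
    build_vocabulary,
    collapse_risk,
    encode_documents,
    split_by_label,
    stratified_shuffle_splits,
    suggest_max_len,
)
from .evaluation import MetricsReport, evaluate_task, majority_baseline_accuracy
from .lexicon import FeatureScaler, Lexicon, load_preset, score_many
from .mtl_model import ModelConfig
from .preprocess import CleaningConfig, UserDocument, documents_from_records, filter_min_tokens
from .synthetic_data import GeneratorConfig, SyntheticCorpusPair, generate_corpus_pair
from .training import (
    EncodedPairs,
    TrainConfig,
    derive_seeds,
    predict_ensemble,
    predict_single_task_ensemble,
    train_ensemble,
    train_single_task_ensemble,
)

log = logging.getLogger("mtlscreen")


@dataclass
class ExperimentConfig:
    task: str = "flagged"
    generator: Optional[GeneratorConfig] = None
    corpus_a_path: Optional[str] = None
    corpus_b_path: Optional[str] = None
    lexicon_path: Optional[str] = None
    aux_preset: Optional[str] = None
    normalize_aux: bool = True
    vocab_max_size: int = 20_000
    max_len: Optional[int] = None
    model_overrides: dict = field(default_factory=dict)
    split: SplitSpec = field(default_factory=SplitSpec)
    train: TrainConfig = field(default_factory=TrainConfig)
    extra_test_sets: list[str] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.task not in ("flagged", "urgent"):
            raise ValueError("task must be 'flagged' or 'urgent'")
        if self.generator is None and not (self.corpus_a_path and self.corpus_b_path):
            raise ValueError("either a generator config or both corpus paths are required")
        if self.aux_preset is not None and self.generator is None and self.lexicon_path is None:
            raise ValueError("aux_preset requires a lexicon (path or generated)")


@dataclass
class AssembledData:
    """Everything the trainers need, frozen after assembly."""

    train_pairs: EncodedPairs
    splits: list[tuple[np.ndarray, np.ndarray]]
    test_pairs: EncodedPairs
    extra_tests: list[EncodedPairs]
    vocab_size: int
    max_len: int
    n_aux_features: Optional[int]
    manifest: dict


def _split_records(records: Sequence[dict]) -> tuple[list[dict], list[dict]]:
    train = [r for r in records if r.get("split", "train") == "train"]
    test = [r for r in records if r.get("split") == "test"]
    return train, test


def _documents(records: Sequence[dict], cleaning: CleaningConfig) -> list[UserDocument]:
    return filter_min_tokens(documents_from_records(records, cleaning), cleaning.min_tokens)


def _binary_labels(docs: Sequence[UserDocument], task_name: str) -> np.ndarray:
    spec = TASKS[task_name]
    return np.array([collapse_risk(d.label, spec) for d in docs], dtype=np.int64)


def assemble_experiment(cfg: ExperimentConfig) -> AssembledData:
    """Run the data half of the pipeline (everything before training)."""
    seeds = derive_seeds(cfg.seed, 6)
    gen_seed, bal_a_seed, bal_b_seed, align_seed, split_seed, _ = seeds

    lexicon: Optional[Lexicon] = None
    if cfg.generator is not None:
        gen_cfg = GeneratorConfig(**{**asdict(cfg.generator), "seed": gen_seed, "task": cfg.task})
        pair: SyntheticCorpusPair = generate_corpus_pair(gen_cfg)
        records_a, records_b = pair.users_a, pair.users_b
        lexicon = pair.lexicon
        min_tokens = gen_cfg.min_tokens
    else:
        with open(cfg.corpus_a_path) as fh:
            records_a = [json.loads(l) for l in fh if l.strip()]
        with open(cfg.corpus_b_path) as fh:
            records_b = [json.loads(l) for l in fh if l.strip()]
        min_tokens = 50
    if cfg.lexicon_path is not None:
        lexicon = Lexicon.from_json(cfg.lexicon_path)

    cleaning = CleaningConfig.for_platform("synthetic", min_tokens=min_tokens)
    train_a_recs, test_a_recs = _split_records(records_a)
    train_b_recs, test_b_recs = _split_records(records_b)
    log.info("assembling task=%s: %d/%d train users, %d/%d test users",
             cfg.task, len(train_a_recs), len(train_b_recs), len(test_a_recs), len(test_b_recs))

    train_a = _documents(train_a_recs, cleaning)
    train_b = _documents(train_b_recs, cleaning)
    test_a = _documents(test_a_recs, cleaning)
    test_b = _documents(test_b_recs, cleaning)

    # collapse + balance + align
    task_spec = TASKS[cfg.task]
    pos_a, neg_a, pool_a = split_by_label(train_a, task_spec)
    bal_a = balance_with_controls(pos_a, neg_a, pool_a, seed=bal_a_seed)
    pos_b, neg_b, pool_b = split_by_label(train_b, TASKS["disorder"])
    bal_b = balance_with_controls(pos_b, neg_b, pool_b, seed=bal_b_seed)
    aligned: AlignedPairDataset = align_tasks(bal_a, bal_b, seed=align_seed)

    docs_a = [r.doc_a for r in aligned.rows]
    docs_b = [r.doc_b for r in aligned.rows]
    vocab = build_vocabulary(docs_a, docs_b, max_size=cfg.vocab_max_size)
    max_len = cfg.max_len or suggest_max_len(docs_a + docs_b)

    X_a = encode_documents(docs_a, vocab, max_len)
    X_b = encode_documents(docs_b, vocab, max_len)
    y = aligned.labels

    aux_a = aux_m = None
    scaler_a = scaler_b = None
    n_aux = None
    sub_lexicon = None
    if cfg.aux_preset is not None:
        if lexicon is None:
            raise ValueError("aux_preset set but no lexicon available")
        preset = load_preset(cfg.aux_preset)
        sub_lexicon = lexicon.subset([c for c in preset.categories if c in lexicon.categories])
        n_aux = len(sub_lexicon.categories)
        feats_a = score_many(docs_a, sub_lexicon, cfg.normalize_aux)
        feats_b = score_many(docs_b, sub_lexicon, cfg.normalize_aux)
        scaler_a = FeatureScaler().fit(feats_a)
        scaler_b = FeatureScaler().fit(feats_b)
        aux_a = scaler_a.transform(feats_a)
        aux_m = scaler_b.transform(feats_b)

    train_pairs = EncodedPairs(X_s=X_a, X_m=X_b, y_s=y, y_m=y, aux_s=aux_a, aux_m=aux_m)
    splits = stratified_shuffle_splits(
        aligned, SplitSpec(cfg.split.n_splits, cfg.split.train_fraction, split_seed)
    )

    def encode_test(docs_s: list[UserDocument], docs_m: list[UserDocument]) -> EncodedPairs:
        if len(docs_s) != len(docs_m):
            # pair by tiling the disorder side; its labels are then only
            # meaningful when the sizes match
            reps = -(-len(docs_s) // max(len(docs_m), 1))
            docs_m = (docs_m * reps)[: len(docs_s)]
        Xs = encode_documents(docs_s, vocab, max_len)
        Xm = encode_documents(docs_m, vocab, max_len)
        ys = _binary_labels(docs_s, cfg.task)
        ym = _binary_labels(docs_m, "disorder")
        a_s = a_m = None
        if sub_lexicon is not None:
            a_s = scaler_a.transform(score_many(docs_s, sub_lexicon, cfg.normalize_aux))
            a_m = scaler_b.transform(score_many(docs_m, sub_lexicon, cfg.normalize_aux))
        return EncodedPairs(X_s=Xs, X_m=Xm, y_s=ys, y_m=ym, aux_s=a_s, aux_m=a_m)

    test_pairs = encode_test(test_a, test_b)
    extra_tests = []
    for path in cfg.extra_test_sets:
        with open(path) as fh:
            recs = [json.loads(l) for l in fh if l.strip()]
        docs = _documents(recs, cleaning)
        extra_tests.append(encode_test(docs, test_b))

    manifest = {
        "seed": cfg.seed,
        "derived_seeds": seeds[:5],
        "task": cfg.task,
        "n_train_rows": len(train_pairs),
        "n_test_rows": len(test_pairs),
        "sampled_control_ids_a": bal_a.sampled_control_ids,
        "sampled_control_ids_b": bal_b.sampled_control_ids,
        "vocab_size": len(vocab),
        "max_len": max_len,
        "splits": [
            {"train": tr.tolist(), "val": va.tolist()} for tr, va in splits
        ],
    }
    return AssembledData(
        train_pairs=train_pairs,
        splits=splits,
        test_pairs=test_pairs,
        extra_tests=extra_tests,
        vocab_size=len(vocab),
        max_len=max_len,
        n_aux_features=n_aux,
        manifest=manifest,
    )


def _model_config(cfg: ExperimentConfig, assembled: AssembledData) -> ModelConfig:
    kwargs = dict(
        vocab_size=assembled.vocab_size,
        max_len=assembled.max_len,
    )
    if assembled.n_aux_features is not None:
        kwargs["aux_units"] = 8
        kwargs["n_aux_features"] = assembled.n_aux_features
    kwargs.update(cfg.model_overrides)
    return ModelConfig(**kwargs)


def _report_to_paper_keys(rep_s: MetricsReport, rep_m: MetricsReport) -> dict[str, float]:
    return {
        "Ps": rep_s.macro_precision, "Pm": rep_m.macro_precision,
        "Rs": rep_s.macro_recall, "Rm": rep_m.macro_recall,
        "F1s": rep_s.macro_f1, "F1m": rep_m.macro_f1,
        "ACCs": 100.0 * rep_s.accuracy, "ACCm": 100.0 * rep_m.accuracy,
        "AUCs": rep_s.macro_auc, "AUCm": rep_m.macro_auc,
    }


@dataclass
class ExperimentResult:
    metrics: dict[str, dict[str, float]]
    manifest: dict
    models: list
    histories: list

    def write(self, directory) -> None:
        os.makedirs(directory, exist_ok=True)
        with open(os.path.join(directory, "results.json"), "w") as fh:
            json.dump(self.metrics, fh, indent=1)
        with open(os.path.join(directory, "manifest.json"), "w") as fh:
            json.dump(self.manifest, fh, indent=1)


def run_experiment(cfg: ExperimentConfig, assembled: AssembledData | None = None) -> ExperimentResult:
    """Train the multi-task ensemble and evaluate on all test sets."""
    if assembled is None:
        assembled = assemble_experiment(cfg)
    model_cfg = _model_config(cfg, assembled)
    train_cfg = TrainConfig(**{**vars(cfg.train), "seed": derive_seeds(cfg.seed, 6)[5]})
    models, histories = train_ensemble(model_cfg, assembled.train_pairs, assembled.splits, train_cfg)

    metrics: dict[str, dict[str, float]] = {}
    for name, pairs in [("test", assembled.test_pairs)] + [
        (f"extra_{i}", t) for i, t in enumerate(assembled.extra_tests)
    ]:
        pred = predict_ensemble(models, pairs.X_s, pairs.X_m, pairs.aux_s, pairs.aux_m)
        rep_s = evaluate_task(pairs.y_s, pred["labels_suicide"], pred["probs_suicide"][:, 1])
        rep_m = evaluate_task(pairs.y_m, pred["labels_disorder"], pred["probs_disorder"][:, 1])
        metrics[name] = _report_to_paper_keys(rep_s, rep_m)
    manifest = dict(assembled.manifest)
    manifest["model_config"] = asdict(model_cfg)
    manifest["train_config"] = vars(train_cfg)
    manifest["best_epochs"] = [h.best_epoch for h in histories]
    return ExperimentResult(metrics=metrics, manifest=manifest, models=models, histories=histories)


def run_baselines(cfg: ExperimentConfig, assembled: AssembledData | None = None) -> dict:
    """Single-task baselines on the same splits, plus majority-class accuracy."""
    if assembled is None:
        assembled = assemble_experiment(cfg)
    base_cfg = _model_config(cfg, assembled)
    # the baseline reads no auxiliary input
    model_cfg = ModelConfig(**{**asdict(base_cfg), "aux_units": None, "n_aux_features": None,
                               "kernel_sizes": tuple(base_cfg.kernel_sizes)})
    train_cfg = TrainConfig(**{**vars(cfg.train), "seed": derive_seeds(cfg.seed, 6)[5]})
    tp = assembled.train_pairs
    out: dict = {"per_split": {}}
    for side, X, y, Xt, yt in (
        ("suicide", tp.X_s, tp.y_s, assembled.test_pairs.X_s, assembled.test_pairs.y_s),
        ("disorder", tp.X_m, tp.y_m, assembled.test_pairs.X_m, assembled.test_pairs.y_m),
    ):
        models, _ = train_single_task_ensemble(model_cfg, X, y, assembled.splits, train_cfg)
        pred = predict_single_task_ensemble(models, Xt)
        rep = evaluate_task(yt, pred["labels"], pred["probs"][:, 1])
        out[side] = rep.to_dict()
        per_split = []
        for m in models:
            p = m.forward(Xt, train=False)
            per_split.append(evaluate_task(yt, p.argmax(axis=1), p[:, 1]).macro_f1)
        out["per_split"][side] = per_split
        out[f"majority_accuracy_{side}"] = majority_baseline_accuracy(yt)
    return out
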