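"""Dataset assembly: risk-label collapsing, control balancing, cross-task
pairing, stratified splitting, vocabulary construction and sequence encoding.

The suicide-risk side of the data carries a 4-level taxonomy (none / low /
moderate / severe) plus a separate control pool.  Two binary screening tasks
collapse it:

* ``flagged``: any risk (low, moderate, severe) vs none — "does this user show
  suicide ideation at all?"
* ``urgent``: moderate or severe vs none/low — "does this user need urgent
  attention?"

The disorder side is already binary (self-reported diagnosis vs control).
Because the multi-task network consumes one user from each task per row, the
two balanced datasets are aligned class-with-class: positives pair with
positives, controls with controls, via a seeded permutation.  Batches formed
from the aligned rows must never be shuffled row-internally, otherwise the
soft-parameter-sharing penalty would compare representations of mismatched
classes.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedShuffleSplit

from .preprocess import UserDocument

RISK_LEVELS = ("none", "low", "moderate", "severe", "control")

#: Reserved vocabulary indices.
PAD_INDEX = 0
OOV_INDEX = 1


@dataclass(frozen=True)
class BinaryTaskSpec:
    """How a 4-level risk label (or a binary flag) collapses to one bit."""

    name: str
    positive_set: frozenset[str]

    def __post_init__(self) -> None:
        if not self.positive_set:
            raise ValueError("positive_set must be nonempty")


TASK_FLAGGED = BinaryTaskSpec("flagged", frozenset({"low", "moderate", "severe"}))
TASK_URGENT = BinaryTaskSpec("urgent", frozenset({"moderate", "severe"}))
#: Disorder-side corpora carry their own 0/1 flag; "1" is the positive class.
TASK_DISORDER = BinaryTaskSpec("disorder", frozenset({"1"}))

TASKS = {t.name: t for t in (TASK_FLAGGED, TASK_URGENT, TASK_DISORDER)}


def collapse_risk(label: object, task: BinaryTaskSpec) -> int:
    """Collapse a risk label to the task's binary class (1 positive, 0 negative)."""
    key = str(label).lower()
    if task.name == "disorder":
        if key in ("1", "true"):
            return 1
        if key in ("0", "false", "control", "none"):
            return 0
        raise ValueError(f"unknown disorder label: {label!r}")
    if key not in RISK_LEVELS:
        raise ValueError(f"unknown risk label: {label!r}")
    return int(key in task.positive_set)


@dataclass
class BalancedTaskData:
    """A class-balanced single-task dataset.

    ``rows`` lists positives first, then negatives (original negatives followed
    by the sampled control top-up); ``sampled_control_ids`` records the top-up
    for the reproducibility manifest.
    """

    positives: list[UserDocument]
    negatives: list[UserDocument]
    sampled_control_ids: list[str]

    def __post_init__(self) -> None:
        if len(self.positives) != len(self.negatives):
            raise AssertionError(
                f"balance violated: {len(self.positives)} positives vs "
                f"{len(self.negatives)} negatives"
            )

    @property
    def n_rows(self) -> int:
        return 2 * len(self.positives)


def balance_with_controls(
    positives: Sequence[UserDocument],
    negatives: Sequence[UserDocument],
    control_pool: Sequence[UserDocument],
    seed: int,
) -> BalancedTaskData:
    """Top up the negative class with controls sampled without replacement.

    Mirrors the corpus-assembly step in which e.g. 369 any-risk positives face
    only 127 no-risk users, so 242 random controls are drawn to balance the
    classes (or 319 vs 177 with a 142-user top-up for the urgent task).
    """
    if len(positives) < len(negatives):
        raise ValueError(
            f"expected |positives| >= |negatives|, got {len(positives)} < {len(negatives)}"
        )
    neg_ids = {d.user_id for d in negatives}
    pool = [d for d in control_pool if d.user_id not in neg_ids]
    if len(pool) != len(control_pool):
        raise ValueError("control_pool overlaps the negative class")
    deficit = len(positives) - len(negatives)
    if deficit > len(pool):
        raise ValueError(
            f"control pool too small: need {deficit}, have {len(pool)}"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=deficit, replace=False) if deficit else []
    sampled = [pool[i] for i in sorted(idx)]
    return BalancedTaskData(
        positives=list(positives),
        negatives=list(negatives) + sampled,
        sampled_control_ids=[d.user_id for d in sampled],
    )


@dataclass
class PairRow:
    """One aligned row: a task-A user and a task-B user of the same class."""

    doc_a: UserDocument
    doc_b: UserDocument
    label: int  # shared by construction: label_a == label_b

    @property
    def label_a(self) -> int:
        return self.label

    @property
    def label_b(self) -> int:
        return self.label


@dataclass
class AlignedPairDataset:
    rows: list[PairRow]

    def __post_init__(self) -> None:
        # label-homogeneity is the core invariant of task alignment
        for i, row in enumerate(self.rows):
            if row.label_a != row.label_b:
                raise AssertionError(f"row {i} pairs mismatched classes")

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.rows], dtype=np.int64)


def align_tasks(
    ds_a: BalancedTaskData,
    ds_b: BalancedTaskData,
    seed: int,
    identity: bool = False,
) -> AlignedPairDataset:
    """Pair task-A users with task-B users, positives-with-positives.

    Within each class the pairing is a seeded uniform permutation of the B side
    (``identity=True`` keeps stored order, for tests).  Both datasets must have
    identical per-class counts.
    """
    if len(ds_a.positives) != len(ds_b.positives) or len(ds_a.negatives) != len(ds_b.negatives):
        raise ValueError(
            "class-count mismatch: "
            f"A has {len(ds_a.positives)}+/{len(ds_a.negatives)}-, "
            f"B has {len(ds_b.positives)}+/{len(ds_b.negatives)}-"
        )
    rng = np.random.default_rng(seed)
    rows: list[PairRow] = []
    for label, docs_a, docs_b in (
        (1, ds_a.positives, ds_b.positives),
        (0, ds_a.negatives, ds_b.negatives),
    ):
        perm = np.arange(len(docs_b)) if identity else rng.permutation(len(docs_b))
        rows.extend(
            PairRow(doc_a=a, doc_b=docs_b[j], label=label)
            for a, j in zip(docs_a, perm)
        )
    return AlignedPairDataset(rows=rows)


@dataclass(frozen=True)
class SplitSpec:
    n_splits: int = 5
    train_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_splits < 1:
            raise ValueError("n_splits must be >= 1")


def stratified_shuffle_splits(
    ds: AlignedPairDataset, spec: SplitSpec
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded stratified shuffle splits over pair rows.

    Rows (not individual users) are the sampling unit: labels agree within a
    row, so stratifying on the shared label preserves both tasks' class ratios
    simultaneously.  Returns ``n_splits`` (train_idx, val_idx) pairs.
    """
    if len(ds) == 0:
        raise ValueError("dataset is empty")
    y = ds.labels
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present for stratification")
    splitter = StratifiedShuffleSplit(
        n_splits=spec.n_splits,
        train_size=spec.train_fraction,
        random_state=spec.seed,
    )
    return [(tr.copy(), va.copy()) for tr, va in splitter.split(np.zeros(len(y)), y)]


@dataclass
class Vocabulary:
    """Token -> index map with reserved indices 0 (padding) and 1 (OOV)."""

    index: dict[str, int]
    max_size: int

    def __len__(self) -> int:
        return len(self.index) + 2

    def encode_token(self, token: str) -> int:
        return self.index.get(token, OOV_INDEX)

    def decode(self, indices: Sequence[int]) -> list[str]:
        rev = {i: t for t, i in self.index.items()}
        out = []
        for i in indices:
            if i == PAD_INDEX:
                break
            out.append(rev.get(int(i), "<oov>"))
        return out


def build_vocabulary(
    train_docs_a: Sequence[UserDocument],
    train_docs_b: Sequence[UserDocument],
    max_size: int = 20_000,
) -> Vocabulary:
    """Frequency-ranked vocabulary over the pooled training text of both tasks.

    Pooling the two tasks' training tokens gives the branches a common index
    space, which is what lets the shared representation converge.  Ties in
    frequency break lexicographically; the top ``max_size - 2`` tokens receive
    indices from 2 upward.
    """
    if max_size < 3:
        raise ValueError("max_size must be >= 3")
    counts: Counter[str] = Counter()
    for doc in list(train_docs_a) + list(train_docs_b):
        counts.update(doc.tokens)
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    kept = ranked[: max_size - 2]
    return Vocabulary(index={tok: i + 2 for i, (tok, _) in enumerate(kept)}, max_size=max_size)


def encode_and_pad(
    doc: UserDocument | Sequence[str],
    vocab: Vocabulary,
    max_len: int,
    truncate: str = "head",
) -> np.ndarray:
    """Map tokens to indices, truncate/pad to exactly ``max_len``.

    Truncation keeps the chronological head by default (earliest tokens);
    padding uses index 0 on the right, unseen tokens map to index 1.
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    tokens = doc.tokens if isinstance(doc, UserDocument) else list(doc)
    if len(tokens) > max_len:
        tokens = tokens[:max_len] if truncate == "head" else tokens[-max_len:]
    out = np.full(max_len, PAD_INDEX, dtype=np.int64)
    for i, tok in enumerate(tokens):
        out[i] = vocab.encode_token(tok)
    return out


def encode_documents(
    docs: Sequence[UserDocument], vocab: Vocabulary, max_len: int
) -> np.ndarray:
    """Stack encodings of many documents into an (n, max_len) int array."""
    if not docs:
        return np.zeros((0, max_len), dtype=np.int64)
    return np.stack([encode_and_pad(d, vocab, max_len) for d in docs])


def suggest_max_len(
    docs: Sequence[UserDocument], percentile: float = 95.0, cap: int = 2000
) -> int:
    """Default sequence length: 95th percentile of training token counts, capped."""
    if not docs:
        return cap
    q = int(np.ceil(np.percentile([d.n_tokens for d in docs], percentile)))
    return max(1, min(q, cap))


def split_by_label(
    docs: Sequence[UserDocument], task: BinaryTaskSpec
) -> tuple[list[UserDocument], list[UserDocument], list[UserDocument]]:
    """Partition documents into (positives, negatives, control_pool) for a task.

    Users labelled ``control`` form the top-up pool; every other label is
    collapsed through the task spec.
    """
    pos: list[UserDocument] = []
    neg: list[UserDocument] = []
    pool: list[UserDocument] = []
    for d in docs:
        if str(d.label).lower() == "control" and task.name != "disorder":
            pool.append(d)
        elif collapse_risk(d.label, task) == 1:
            pos.append(d)
        else:
            neg.append(d)
    return pos, neg, pool
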