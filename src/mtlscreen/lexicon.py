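"""Lexicon-category scoring of user documents for auxiliary model inputs.

A lexicon maps named semantic categories (e.g. "sadness", "medical_emergency")
to term lists, in the style of the EMPATH tool.  A document's feature vector
is the per-category count of matching tokens, optionally normalized by
document length; features are min-max scaled on the training split before
entering the network's auxiliary dense layer.

Three presets name the category lists used for the two same-platform screening
tasks and the cross-platform variant.  Term inventories are user-supplied data
files (the category *names* are fixed; "suicide_topw" in particular is a
custom category whose terms the user provides).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.preprocessing import MinMaxScaler, StandardScaler

from .preprocess import UserDocument

PRESETS: dict[str, tuple[str, ...]] = {
    # 14 categories shared between suicide-ideation and disorder positives
    "flagged14": (
        "health", "medical_emergency", "sadness", "nervousness", "fear",
        "contentment", "domestic_work", "horror", "torment", "suicide_topw",
        "neglect", "shame", "suffering", "sexual",
    ),
    # 6 categories for the urgent-attention task
    "urgent6": ("neglect", "anger", "sadness", "torment", "emotional", "shame"),
    # 10 categories for cross-platform (Reddit + Twitter) experiments
    "crossplatform10": (
        "health", "medical_emergency", "crime", "horror", "war",
        "sadness", "fear", "suffering", "aggression", "neglect",
    ),
}


@dataclass(frozen=True)
class CategoryPreset:
    name: str
    categories: tuple[str, ...]


def load_preset(name: str) -> CategoryPreset:
    """Return the fixed category-name list for a preset, in printed order."""
    try:
        return CategoryPreset(name=name, categories=PRESETS[name])
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}") from None


@dataclass
class Lexicon:
    """category name -> set of terms.  Multi-word terms match token bigrams."""

    categories: dict[str, set[str]]
    name: str = "lexicon"

    def __post_init__(self) -> None:
        for cat, terms in self.categories.items():
            if not terms:
                raise ValueError(f"category {cat!r} has no terms")

    @property
    def category_order(self) -> list[str]:
        return list(self.categories)

    def subset(self, names: Sequence[str]) -> "Lexicon":
        missing = [n for n in names if n not in self.categories]
        if missing:
            raise ValueError(f"lexicon {self.name!r} lacks categories: {missing}")
        return Lexicon({n: self.categories[n] for n in names}, name=self.name)

    @classmethod
    def from_json(cls, path) -> "Lexicon":
        with open(path, encoding="utf-8") as fh:
            obj = json.load(fh)
        return cls(
            categories={k: set(v) for k, v in obj["categories"].items()},
            name=obj.get("name", "lexicon"),
        )

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {"name": self.name,
                 "categories": {k: sorted(v) for k, v in self.categories.items()}},
                fh, indent=1,
            )


@dataclass
class FeatureVector:
    values: np.ndarray
    order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.order and len(self.values) != len(self.order):
            raise ValueError("values/order length mismatch")


def score_categories(
    doc: UserDocument | Sequence[str], lexicon: Lexicon, normalize: bool = True
) -> FeatureVector:
    """Count category-term occurrences in a document.

    Single-word terms match tokens; terms containing a space match adjacent
    token bigrams.  With ``normalize`` the counts are divided by the document
    token count (0/0 defined as 0 for empty documents).
    """
    tokens = doc.tokens if isinstance(doc, UserDocument) else list(doc)
    n = len(tokens)
    bigrams = None
    values = np.zeros(len(lexicon.categories), dtype=np.float64)
    for j, (cat, terms) in enumerate(lexicon.categories.items()):
        unigrams = {t for t in terms if " " not in t}
        phrases = [t for t in terms if " " in t]
        count = sum(1 for t in tokens if t in unigrams)
        if phrases:
            if bigrams is None:
                bigrams = [f"{a} {b}" for a, b in zip(tokens, tokens[1:])]
            phrase_set = set(phrases)
            count += sum(1 for bg in bigrams if bg in phrase_set)
        values[j] = count
    if normalize and n > 0:
        values /= n
    return FeatureVector(values=values, order=lexicon.category_order)


def score_many(
    docs: Sequence[UserDocument], lexicon: Lexicon, normalize: bool = True
) -> np.ndarray:
    """(n_docs, n_categories) matrix of category scores."""
    if not docs:
        return np.zeros((0, len(lexicon.categories)))
    return np.stack([score_categories(d, lexicon, normalize).values for d in docs])


class FeatureScaler:
    """Train-fitted per-dimension scaler for auxiliary features.

    ``minmax`` (default) maps the training min to 0 and max to 1 and clips
    transformed values into [0, 1]; constant training dimensions map to 0.
    ``zscore`` standardizes instead (no clipping), for ablations.
    """

    def __init__(self, kind: str = "minmax"):
        if kind not in ("minmax", "zscore"):
            raise ValueError(f"unknown scaler kind {kind!r}")
        self.kind = kind
        self._impl = MinMaxScaler(clip=True) if kind == "minmax" else StandardScaler()
        self.n_features_: int | None = None

    def fit(self, train_features: np.ndarray) -> "FeatureScaler":
        train_features = np.asarray(train_features, dtype=np.float64)
        if train_features.ndim != 2 or train_features.shape[0] == 0:
            raise ValueError("train_features must be a nonempty 2-D array")
        self._impl.fit(train_features)
        self.n_features_ = train_features.shape[1]
        return self

    def transform(self, features: np.ndarray) -> np.ndarray:
        features = np.atleast_2d(np.asarray(features, dtype=np.float64))
        if self.n_features_ is None:
            raise RuntimeError("scaler is not fitted")
        if features.shape[1] != self.n_features_:
            raise ValueError(
                f"dimension mismatch: fitted {self.n_features_}, got {features.shape[1]}"
            )
        return self._impl.transform(features)

    def inverse_transform(self, features: np.ndarray) -> np.ndarray:
        return self._impl.inverse_transform(np.atleast_2d(features))


def fit_scaler(train_features: Sequence[FeatureVector] | np.ndarray, kind: str = "minmax") -> FeatureScaler:
    if not isinstance(train_features, np.ndarray):
        train_features = np.stack([fv.values for fv in train_features])
    return FeatureScaler(kind).fit(train_features)


def apply_scaler(scaler: FeatureScaler, fv: FeatureVector | np.ndarray) -> FeatureVector:
    values = fv.values if isinstance(fv, FeatureVector) else np.asarray(fv)
    order = fv.order if isinstance(fv, FeatureVector) else []
    return FeatureVector(values=scaler.transform(values)[0], order=order)
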