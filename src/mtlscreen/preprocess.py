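"""Deterministic cleaning and per-user assembly of social-media posts.

Raw posts are noisy: URLs, @mentions, #hashtags, retweet markers, emoji,
emoticons, digit runs and punctuation carry little generalizable signal for
user-level screening, so they are stripped before tokenization.  Stopwords are
removed *except* personal pronouns — elevated first-person-singular usage is a
known linguistic marker of depression, so pronouns must survive cleaning.

The cleaning order matters and is fixed:

    URL/mention/hashtag/RT/emoji/emoticon/number removal
    -> lowercase -> contraction expansion -> punctuation removal
    -> whitespace collapse

Contraction expansion needs apostrophes, hence it precedes punctuation
stripping.  ``clean_text`` is idempotent: cleaning already-clean text is a
no-op (property-tested).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Iterator, Literal, Optional, Sequence

Platform = Literal["reddit", "twitter", "synthetic"]
TokenizerKind = Literal["tweet_rules", "generic_rules"]

#: Personal pronouns (subject/object/possessive/reflexive, all three persons)
#: that are exempt from stopword removal.
PRONOUNS: frozenset[str] = frozenset(
    """i me my mine myself we us our ours ourselves
       you your yours yourself yourselves
       he him his himself she her hers herself it its itself
       they them their theirs themselves""".split()
)

_URL_RE = re.compile(r"(?:https?://\S+|www\.\S+)")
_MENTION_RE = re.compile(r"@\w+")
_HASHTAG_RE = re.compile(r"#\w+")
# Retweet marker: uppercase "RT" at the start of the post or directly before a
# mention.  Matching the raw-case marker only keeps clean_text idempotent
# (clean output is lowercase, so a second pass cannot re-trigger this rule).
_RT_RE = re.compile(r"(?:\A\s*RT\b|\bRT\b(?=\s*@))")
# Standalone digit runs (optionally with decimal/thousand separators); digits
# embedded in words ("t00042") are kept.
_NUMBER_RE = re.compile(r"(?<!\w)\d+(?:[.,]\d+)*(?!\w)")
# ASCII emoticons such as :-) ;P =D x( <3, delimited by whitespace.
_EMOTICON_RE = re.compile(
    r"(?:(?<=\s)|\A)(?:[<>]?[:;=8xX][\-o'^]?[()\[\]dDpPoO/\\|@*{}3]+|<3+|</3)"
    r"(?=\s|\Z)"
)
# Major emoji blocks plus variation selectors, ZWJ and skin-tone modifiers.
_EMOJI_RE = re.compile(
    "["
    "\U0001F1E6-\U0001F1FF"  # regional indicators (flags)
    "\U0001F300-\U0001F5FF"  # symbols & pictographs
    "\U0001F600-\U0001F64F"  # emoticons
    "\U0001F680-\U0001F6FF"  # transport & map
    "\U0001F700-\U0001F77F"
    "\U0001F780-\U0001F8FF"
    "\U0001F900-\U0001F9FF"  # supplemental symbols
    "\U0001FA00-\U0001FAFF"
    "☀-➿"          # misc symbols + dingbats
    "⬀-⯿"
    "︀-️"          # variation selectors
    "‍"                 # zero-width joiner
    "\U0001F3FB-\U0001F3FF"  # skin tones
    "]+"
)
# Apostrophes vanish (so unknown contractions just lose the quote); all other
# punctuation/symbols become spaces.
_APOSTROPHE_RE = re.compile(r"[’']")
_PUNCT_RE = re.compile(r"[^\w\s]")
_WS_RE = re.compile(r"\s+")


def _load_default_stopwords() -> frozenset[str]:
    text = resources.files("mtlscreen.data").joinpath("stopwords.txt").read_text()
    return frozenset(
        line.strip()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    )


def _load_default_contractions() -> dict[str, str]:
    text = resources.files("mtlscreen.data").joinpath("contractions.json").read_text()
    return json.loads(text)


@dataclass(frozen=True)
class CleaningConfig:
    """Parameters of the cleaning pipeline.

    ``min_tokens`` is the user-level survival threshold applied *after*
    cleaning and stopword removal (i.e. on the token count the model actually
    sees): 50 for long-form (Reddit-style) corpora, 20 for tweet-style ones.
    """

    stopword_list: frozenset[str] = field(default_factory=_load_default_stopwords)
    pronouns_kept: frozenset[str] = PRONOUNS
    contraction_table: dict[str, str] = field(default_factory=_load_default_contractions)
    min_tokens: int = 50
    tokenizer_kind: TokenizerKind = "generic_rules"

    def __post_init__(self) -> None:
        if self.min_tokens < 1:
            raise ValueError("min_tokens must be >= 1")

    @property
    def removal_set(self) -> frozenset[str]:
        """Stopwords actually removed: the list minus the pronoun exemption."""
        return self.stopword_list - self.pronouns_kept

    @classmethod
    def for_platform(cls, platform: Platform, **kwargs) -> "CleaningConfig":
        defaults = {"reddit": 50, "twitter": 20, "synthetic": 50}
        kwargs.setdefault("min_tokens", defaults[platform])
        kwargs.setdefault(
            "tokenizer_kind",
            "tweet_rules" if platform == "twitter" else "generic_rules",
        )
        return cls(**kwargs)


@dataclass(frozen=True)
class RawPost:
    user_id: str
    timestamp: float | int | str
    text: str
    platform: Platform = "synthetic"


@dataclass
class UserDocument:
    """One user's chronologically concatenated, cleaned token sequence."""

    user_id: str
    tokens: list[str]
    platform: Platform = "synthetic"
    label: Optional[object] = None

    @property
    def n_tokens(self) -> int:
        return len(self.tokens)


def _expand_contractions(text: str, table: dict[str, str]) -> str:
    if not table or "'" not in text and "’" not in text:
        return text
    text = text.replace("’", "'")
    keys = sorted(table, key=len, reverse=True)
    pattern = re.compile(r"\b(?:" + "|".join(re.escape(k) for k in keys) + r")\b")
    return pattern.sub(lambda m: table[m.group(0)], text)


def clean_text(text: str, config: CleaningConfig | None = None) -> str:
    """Clean one post; always returns a (possibly empty) lowercase string."""
    config = config or _DEFAULT_CONFIG
    text = _URL_RE.sub(" ", text)
    text = _RT_RE.sub(" ", text)
    text = _MENTION_RE.sub(" ", text)
    text = _HASHTAG_RE.sub(" ", text)
    text = _EMOJI_RE.sub(" ", text)
    text = _EMOTICON_RE.sub(" ", text)
    text = _NUMBER_RE.sub(" ", text)
    text = text.lower()
    text = _expand_contractions(text, config.contraction_table)
    text = _APOSTROPHE_RE.sub("", text)
    text = _PUNCT_RE.sub(" ", text)
    return _WS_RE.sub(" ", text).strip()


def tokenize(text: str, tokenizer_kind: TokenizerKind = "generic_rules") -> list[str]:
    """Split cleaned text into tokens.

    After the aggressive cleaning above, both dialects reduce to whitespace
    splitting (tweet-specific apostrophe handling has already happened during
    contraction expansion); the enum is kept so a softer cleaning profile can
    diverge later.
    """
    if tokenizer_kind not in ("tweet_rules", "generic_rules"):
        raise ValueError(f"unknown tokenizer_kind: {tokenizer_kind!r}")
    return text.split()


def remove_stopwords(tokens: Sequence[str], config: CleaningConfig | None = None) -> list[str]:
    """Drop stopwords, keeping personal pronouns; order preserved."""
    config = config or _DEFAULT_CONFIG
    removal = config.removal_set
    return [t for t in tokens if t not in removal]


def build_user_document(
    posts: Sequence[RawPost], config: CleaningConfig | None = None
) -> UserDocument:
    """Concatenate a user's posts in timestamp order into one token sequence.

    Posts cleaning to the empty string are dropped.  An empty post list yields
    a zero-token document (the caller filters via :func:`filter_min_tokens`).
    """
    config = config or _DEFAULT_CONFIG
    if posts:
        ids = {p.user_id for p in posts}
        if len(ids) > 1:
            raise ValueError(f"posts span multiple users: {sorted(ids)}")
        user_id = posts[0].user_id
        platform = posts[0].platform
    else:
        user_id, platform = "", "synthetic"
    tokens: list[str] = []
    for post in sorted(posts, key=lambda p: p.timestamp):
        cleaned = clean_text(post.text, config)
        if not cleaned:
            continue
        tokens.extend(remove_stopwords(tokenize(cleaned, config.tokenizer_kind), config))
    return UserDocument(user_id=user_id, tokens=tokens, platform=platform)


def filter_min_tokens(
    users: Iterable[UserDocument], min_tokens: int
) -> list[UserDocument]:
    """Keep exactly the users with ``n_tokens >= min_tokens`` (order preserved)."""
    return [u for u in users if u.n_tokens >= min_tokens]


# ---------------------------------------------------------------------------
# Line-delimited JSON corpus IO
# ---------------------------------------------------------------------------

def read_corpus_jsonl(path) -> list[dict]:
    """Read a raw corpus: one JSON object per line, one object per user."""
    users = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                users.append(json.loads(line))
    return users


def documents_from_records(
    records: Iterable[dict], config: CleaningConfig
) -> Iterator[UserDocument]:
    """Turn raw user records ({"user_id", "platform", "label", "posts"}) into
    cleaned :class:`UserDocument` objects (unfiltered)."""
    for rec in records:
        posts = [
            RawPost(
                user_id=rec["user_id"],
                timestamp=p["t"],
                text=p["text"],
                platform=rec.get("platform", "synthetic"),
            )
            for p in rec.get("posts", [])
        ]
        doc = build_user_document(posts, config)
        doc.user_id = rec["user_id"]
        doc.platform = rec.get("platform", "synthetic")
        doc.label = rec.get("label")
        yield doc


def write_documents_jsonl(docs: Iterable[UserDocument], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for d in docs:
            fh.write(
                json.dumps(
                    {
                        "user_id": d.user_id,
                        "platform": d.platform,
                        "label": d.label,
                        "tokens": d.tokens,
                    }
                )
                + "\n"
            )


def read_documents_jsonl(path) -> list[UserDocument]:
    docs = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            docs.append(
                UserDocument(
                    user_id=rec["user_id"],
                    tokens=list(rec["tokens"]),
                    platform=rec.get("platform", "synthetic"),
                    label=rec.get("label"),
                )
            )
    return docs


def preprocess_corpus(
    in_path, out_path, config: CleaningConfig, min_tokens: int | None = None
) -> int:
    """Clean a raw corpus file end to end; returns the number of users kept."""
    docs = documents_from_records(read_corpus_jsonl(in_path), config)
    kept = filter_min_tokens(docs, min_tokens if min_tokens is not None else config.min_tokens)
    write_documents_jsonl(kept, out_path)
    return len(kept)


_DEFAULT_CONFIG = CleaningConfig()
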