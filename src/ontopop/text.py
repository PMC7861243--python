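"""Label and corpus preprocessing.

The pipeline applies, in order: lower-case conversion, synonym mapping,
punctuation stripping, white-space stripping, numeric stripping, stop-word
removal, short-word stripping, and lemmatization.  The whole chain is
deterministic and idempotent.
"""

from __future__ import annotations

import logging
import unicodedata
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, FrozenSet, List, Mapping, Set

__all__ = [
    "PipelineConfig",
    "TokenizedLabel",
    "default_stopwords",
    "preprocess",
    "tokenize_labels",
    "lemmatize_noun",
    "vocabulary",
    "read_token_file",
]

log = logging.getLogger(__name__)


def _strip_punct(text: str) -> str:
    """Replace punctuation/symbol characters with spaces (Unicode-aware)."""
    out = []
    for ch in text:
        cat = unicodedata.category(ch)
        out.append(" " if cat[0] in "PS" else ch)
    return "".join(out)


def _strip_digits(text: str) -> str:
    return "".join(ch for ch in text if unicodedata.category(ch)[0] != "N")


def default_stopwords() -> FrozenSet[str]:
    """Standard English stop-word list shipped with the package."""
    text = resources.files("ontopop").joinpath("data/stopwords_en.txt").read_text("utf-8")
    return frozenset(w for w in text.split("\n") if w)


# Suffix detachment rules for a dictionary-free noun lemmatizer, longest
# suffix first.  Chosen so a lemma is a fixed point of the rule set.
_NOUN_RULES = (
    ("ches", "ch"),
    ("shes", "sh"),
    ("ses", "s"),
    ("xes", "x"),
    ("zes", "z"),
    ("ies", "y"),
    ("men", "man"),
    ("s", ""),
)


def lemmatize_noun(token: str, min_len: int = 1) -> str:
    """Rule-based singularization with noun preference.

    Lemmas that would fall below ``min_len`` characters, or words that end in
    ``ss``/``us``/``is`` (mass/Latin endings), are returned unchanged.
    """
    if token.endswith(("ss", "us", "is")):
        return token
    for suffix, repl in _NOUN_RULES:
        if token.endswith(suffix) and len(token) > len(suffix):
            lemma = token[: -len(suffix)] + repl
            if len(lemma) >= min_len:
                return lemma
            return token
    return token


@dataclass(frozen=True)
class PipelineConfig:
    synonym_map: Mapping[str, str] = field(default_factory=dict)
    stopword_list: FrozenSet[str] = field(default_factory=default_stopwords)
    min_token_len: int = 3
    lemmatize: bool = True

    def __post_init__(self) -> None:
        if self.min_token_len < 1:
            raise ValueError("min_token_len must be positive")
        for src, dst in self.synonym_map.items():
            if self.synonym_map.get(dst, dst) != dst:
                raise ValueError(f"synonym map chains: {src!r} -> {dst!r} -> {self.synonym_map[dst]!r}")


@dataclass(frozen=True)
class TokenizedLabel:
    source_id: str
    raw: str
    tokens: tuple


def preprocess(text: str, config: PipelineConfig | None = None) -> List[str]:
    """Normalize ``text`` into a (possibly empty) list of clean tokens."""
    if config is None:
        config = PipelineConfig()
    tokens = text.lower().split()
    tokens = [config.synonym_map.get(t, t) for t in tokens]
    # punctuation becomes whitespace so "food/(product)" splits cleanly
    tokens = [p for t in tokens for p in _strip_punct(t).split()]
    tokens = [t.strip() for t in tokens]
    tokens = [_strip_digits(t) for t in tokens]
    tokens = [t for t in tokens if t]
    tokens = [t for t in tokens if t not in config.stopword_list]
    tokens = [t for t in tokens if len(t) >= config.min_token_len]
    if config.lemmatize:
        tokens = [lemmatize_noun(t, min_len=config.min_token_len) for t in tokens]
        # a lemma may land on a stop-word (e.g. a spurious plural of one);
        # re-filter so output invariants hold and the pipeline stays idempotent
        tokens = [t for t in tokens if t not in config.stopword_list and len(t) >= config.min_token_len]
    return tokens


def tokenize_labels(ontology, config: PipelineConfig | None = None) -> Dict[str, TokenizedLabel]:
    """Preprocess every class and instance label of an ontology.

    Labels that reduce to an empty token list are kept (with empty tokens) and
    reported via a warning, not an error.
    """
    if config is None:
        config = PipelineConfig()
    out: Dict[str, TokenizedLabel] = {}
    n_empty = 0
    for xid, label in ontology.labels().items():
        tokens = tuple(preprocess(label, config))
        if not tokens:
            n_empty += 1
        out[xid] = TokenizedLabel(source_id=xid, raw=label, tokens=tokens)
    if n_empty:
        log.warning("%d label(s) preprocessed to empty token lists", n_empty)
    return out


def vocabulary(tokenized: Mapping[str, TokenizedLabel]) -> Set[str]:
    """Set of unique tokens across all tokenized labels."""
    out: Set[str] = set()
    for tl in tokenized.values():
        out.update(tl.tokens)
    return out


def read_token_file(path) -> List[List[str]]:
    """Read one document per line, tokens space-separated."""
    docs: List[List[str]] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                docs.append(line.split(" "))
    return docs
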