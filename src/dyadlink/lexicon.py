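"""Dictionary-based word-category features and first-person word bigrams.

The shipped lexicon is a minimal open dictionary covering the pronoun and
non-fluency categories used in the analysis (first/second/third person
pronouns and filler words).  Frequencies are expressed as a percentage of
the speaker's total word count, and a natural-log transform with a small
offset handles zero frequencies.  Users with a licensed psycholinguistic
dictionary can load their own category→word-list JSON instead.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .errors import EmptyStreamError, InsufficientLengthError
from .transcript import Owner, Role, TokenStream

DEFAULT_EPSILON = 0.01  # percentage points added before taking logs

DEFAULT_CATEGORIES: dict[str, tuple[str, ...]] = {
    "i": ("i", "i'm", "i've", "i'll", "i'd", "me", "my", "mine", "myself"),
    "we": ("we", "we're", "we've", "we'll", "we'd", "our", "ours", "us", "let's"),
    "you": ("you", "you're", "you've", "you'll", "you'd", "your", "yours",
            "yourself", "yourselves"),
    "shehe": ("she", "she's", "she'll", "she'd", "her", "hers", "herself",
              "he", "he's", "he'll", "he'd", "him", "his", "himself"),
    "they": ("they", "they're", "they've", "they'll", "they'd", "them",
             "their", "theirs", "themselves"),
    "nonfluent": ("uh", "uhh", "um", "umm", "er", "err", "hm", "hmm",
                  "mm", "mmm", "eh", "ehh", "ehhh", "huh"),
}


@dataclass(frozen=True)
class Lexicon:
    """Category name → lowercase word set; exact whole-token matching only."""

    categories: Mapping[str, frozenset[str]]
    version: str = "dyadlink-open-1"

    def __post_init__(self):
        for name, words in self.categories.items():
            for w in words:
                if w != w.lower():
                    raise ValueError(f"lexicon entry {w!r} in {name!r} is not lowercase")

    @classmethod
    def default(cls) -> "Lexicon":
        return cls({k: frozenset(v) for k, v in DEFAULT_CATEGORIES.items()})

    @classmethod
    def from_json(cls, path: str | Path) -> "Lexicon":
        data = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls({k: frozenset(str(w).lower() for w in v) for k, v in data.items()},
                   version=str(path))

    def to_json(self, path: str | Path) -> None:
        data = {k: sorted(v) for k, v in sorted(self.categories.items())}
        Path(path).write_text(json.dumps(data, indent=1), encoding="utf-8")


@dataclass(frozen=True)
class FeatureValue:
    dyad_id: str
    speaker_role: str
    name: str
    percent: float
    log_value: float


def category_percents(stream: TokenStream, lex: Lexicon) -> dict[str, float]:
    """Percent of the stream's tokens falling in each lexicon category.

    Counts are case-insensitive exact token matches; the denominator is the
    stream's total token count, so duplicating a stream leaves every percent
    unchanged.
    """
    if len(stream) == 0:
        raise EmptyStreamError("cannot compute category percents on an empty stream")
    total = len(stream)
    counts = {name: 0 for name in lex.categories}
    members = {name: words for name, words in lex.categories.items()}
    for tok, _, _ in stream.items:
        for name, words in members.items():
            if tok in words:
                counts[name] += 1
    return {name: 100.0 * c / total for name, c in counts.items()}


def log_transform(percent: float, epsilon: float = DEFAULT_EPSILON) -> float:
    """Natural log of (percent + epsilon); strictly increasing in percent."""
    if percent < 0:
        raise ValueError(f"percent must be non-negative, got {percent}")
    if epsilon <= 0:
        raise ValueError(f"epsilon must be positive, got {epsilon}")
    return math.log(percent + epsilon)


def pronoun_bigrams(
    stream: TokenStream, anchors: Iterable[str] = ("i", "we")
) -> dict[str, float]:
    """Frequency of contiguous word pairs containing a first-person anchor.

    Every within-speaker adjacent token pair is a bigram; pairs crossing a
    speaker change (possible when the stream owner is ``dialogue``) are not
    formed and do not enter the denominator.  Returned values are fractions
    of the total bigram count.
    """
    if len(stream) < 2:
        raise InsufficientLengthError("need at least 2 tokens for word bigrams")
    anchors = frozenset(anchors)
    counts: dict[str, int] = {}
    total = 0
    for (w1, r1, _), (w2, r2, _) in zip(stream.items, stream.items[1:]):
        if r1 != r2:
            continue
        total += 1
        if w1 in anchors or w2 in anchors:
            key = f"{w1} {w2}"
            counts[key] = counts.get(key, 0) + 1
    if total == 0:
        raise InsufficientLengthError("no within-speaker bigrams in stream")
    return {k: c / total for k, c in sorted(counts.items())}


def feature_values(
    stream: TokenStream,
    lex: Lexicon,
    dyad_id: str,
    role: Role | str,
    epsilon: float = DEFAULT_EPSILON,
) -> list[FeatureValue]:
    """Named per-role feature values (percent and log scale) for one stream."""
    role = Role(role).value
    out = []
    for name, pct in category_percents(stream, lex).items():
        out.append(
            FeatureValue(dyad_id, role, f"{role}_{name}", pct, log_transform(pct, epsilon))
        )
    return sorted(out, key=lambda fv: fv.name)
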