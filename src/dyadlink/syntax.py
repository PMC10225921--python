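"""POS tagging (pluggable), POS-bigram transition matrices, and
interjection-adjacent non-fluency features.

Tags use the 17-tag universal POS inventory.  Any callable mapping a token
sequence to an equal-length UPOS tag sequence can serve as a tagger; the
built-in :class:`RuleTagger` is a deterministic closed-lexicon tagger with
suffix fallbacks and a filler-"like" context rule, intended for synthetic
and lightly structured conversational text.  Adapters for external neural
taggers plug in behind the same callable interface.

Transition features normalise tag-pair counts either jointly (count of the
pair over all of that speaker's pairs) or conditionally (row-normalised by
the first tag's outgoing count).  Pair attribution is either per-speaker
(pairs over each speaker's concatenated token sequence) or by the speaker
of the first token of each pair in the full dialogue sequence, which lets a
cross-speaker talk-turn pair (patient "…i can" → therapist "yeah") count
toward the patient.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientLengthError
from .transcript import Role, TokenStream

UPOS_TAGS: tuple[str, ...] = (
    "ADJ", "ADP", "ADV", "AUX", "CCONJ", "DET", "INTJ", "NOUN", "NUM",
    "PART", "PRON", "PROPN", "PUNCT", "SCONJ", "SYM", "VERB", "X",
)
_TAG_INDEX = {t: i for i, t in enumerate(UPOS_TAGS)}

Tagger = Callable[[Sequence[str]], Sequence[str]]

_RULE_LEXICON: dict[str, str] = {}
for _tag, _words in {
    "PRON": (
        "i me my mine myself we us our ours ourselves you your yours yourself "
        "yourselves he him his himself she her hers herself it its itself they "
        "them their theirs themselves this these those what who whom which "
        "something anything nothing everything someone anyone everyone "
        "i'm i've i'll i'd we're we've we'll we'd you're you've you'll you'd "
        "he's he'll he'd she's she'll she'd it's they're they've they'll they'd "
        "that's there's what's who's"
    ),
    "AUX": (
        "am is are was were be been being do does did have has had will would "
        "can could shall should may might must "
        "don't didn't doesn't can't won't isn't wasn't aren't weren't couldn't "
        "wouldn't shouldn't haven't hasn't hadn't ain't"
    ),
    "VERB": (
        "go goes going went gone think thought know knew feel felt say said says "
        "talk talked tell told want wanted get got give gave make made see saw "
        "try tried understand understood brought bring figure deal lose keep kept "
        "suppose take took come came look looked mean meant need needed remind "
        "worry worrying accommodate let's gonna wanna gotta happen happened help"
    ),
    "DET": "the a an any some every each no all both another",
    "INTJ": (
        "uh uhh um umm er err hm hmm mm mmm eh ehh ehhh huh oh ooh ah aw wow "
        "hey yeah yep yup nope okay ok alright yes"
    ),
    "ADV": (
        "really just very so too now then here there always never often maybe "
        "again still almost nearly pretty quite kind sort more most less well "
        "better worse away back down up out how why where sometimes"
    ),
    "ADP": (
        "in on at with about of for from to into through over under after "
        "before between during without within toward towards like"
    ),
    "SCONJ": "because cause if when while although though since unless that whether",
    "CCONJ": "and but or nor",
    "PART": "not n't",
    "NUM": "one two three four five six seven eight nine ten zero",
    "NOUN": (
        "therapy week work day family sleep job thing time feeling session "
        "stress home people way life year month night medication medications "
        "frustration frustrations snowstorm pay conditions"
    ),
    "ADJ": "good hard anxious tired better worse difficult fine okay dangerous honest",
}.items():
    for _w in _words.split():
        _RULE_LEXICON.setdefault(_w, _tag)

_SUFFIX_RULES: tuple[tuple[str, str], ...] = (
    ("n't", "AUX"),
    ("ly", "ADV"),
    ("ing", "VERB"),
    ("ed", "VERB"),
    ("tion", "NOUN"),
    ("sion", "NOUN"),
    ("ness", "NOUN"),
    ("ment", "NOUN"),
    ("ity", "NOUN"),
    ("ous", "ADJ"),
    ("ful", "ADJ"),
    ("able", "ADJ"),
    ("ible", "ADJ"),
    ("ive", "ADJ"),
    ("s", "NOUN"),
)


class RuleTagger:
    """Deterministic closed-lexicon UPOS tagger with suffix fallbacks.

    A token absent from the word lexicon falls through the suffix rules
    (digit tokens become NUM); with no match it is tagged X, never raising.
    Filler "like" is retagged INTJ when the previous token's tag is AUX or
    ADV ("was like", "just like"); otherwise it keeps its lexical ADP tag.
    """

    #: tags that license a following filler-"like" interjection reading
    FILLER_LIKE_CONTEXT = frozenset({"AUX", "ADV"})

    def __init__(self, extra_lexicon: dict[str, str] | None = None):
        self.lexicon = dict(_RULE_LEXICON)
        if extra_lexicon:
            for w, t in extra_lexicon.items():
                if t not in _TAG_INDEX:
                    raise ValueError(f"unknown UPOS tag {t!r} for {w!r}")
                self.lexicon[w.lower()] = t

    def _base_tag(self, token: str) -> str:
        tag = self.lexicon.get(token)
        if tag is not None:
            return tag
        if any(ch.isdigit() for ch in token):
            return "NUM"
        for suffix, tag in _SUFFIX_RULES:
            if len(token) > len(suffix) + 1 and token.endswith(suffix):
                return tag
        return "X"

    def __call__(self, tokens: Sequence[str]) -> list[str]:
        tags: list[str] = []
        for tok in tokens:
            tag = self._base_tag(tok)
            if tok == "like" and tags and tags[-1] in self.FILLER_LIKE_CONTEXT:
                tag = "INTJ"
            tags.append(tag)
        return tags


@dataclass
class TaggedSequence:
    """Equal-length pairing of a token stream with UPOS tags."""

    items: list[tuple[str, str, Role, int]]  # (token, tag, role, utterance_index)
    tagset: tuple[str, ...] = UPOS_TAGS

    def __len__(self) -> int:
        return len(self.items)

    @property
    def tags(self) -> list[str]:
        return [t for _, t, _, _ in self.items]


def tag(stream: TokenStream, tagger: Tagger | None = None) -> TaggedSequence:
    """Apply a tagger to a stream, validating length and tag inventory."""
    if len(stream) == 0:
        raise InsufficientLengthError("cannot tag an empty stream")
    tagger = tagger or RuleTagger()
    tags = list(tagger(stream.tokens))
    if len(tags) != len(stream):
        raise ValueError(
            f"tagger returned {len(tags)} tags for {len(stream)} tokens"
        )
    for t in tags:
        if t not in _TAG_INDEX:
            raise ValueError(f"tag {t!r} not in the universal tagset")
    items = [
        (tok, tg, role, idx)
        for (tok, role, idx), tg in zip(stream.items, tags)
    ]
    return TaggedSequence(items=items)


def gold_tagged_sequence(
    tokens_with_roles: Sequence[tuple[str, str, Role, int]]
) -> TaggedSequence:
    """Wrap pre-tagged (gold) items, e.g. from the synthetic generator."""
    items = []
    for tok, tg, role, idx in tokens_with_roles:
        if tg not in _TAG_INDEX:
            raise ValueError(f"gold tag {tg!r} not in the universal tagset")
        items.append((tok, tg, Role(role), idx))
    return TaggedSequence(items=items)


@dataclass
class TransitionMatrix:
    """Per-speaker POS-bigram counts and probabilities over the fixed tagset."""

    counts: np.ndarray
    total_bigrams: int
    mode: str  # "joint" | "conditional"
    owner: Role
    attribution: str  # "per_speaker" | "dialogue_first_token"
    tagset: tuple[str, ...] = UPOS_TAGS

    @property
    def probabilities(self) -> np.ndarray:
        c = self.counts.astype(float)
        if self.mode == "joint":
            return c / self.total_bigrams if self.total_bigrams else c
        rows = c.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(rows > 0, c / rows, 0.0)
        return p

    def probability(self, first: str, second: str) -> float:
        return float(self.probabilities[_TAG_INDEX[first], _TAG_INDEX[second]])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.probabilities, index=self.tagset, columns=self.tagset)


def transition_matrix(
    seq: TaggedSequence,
    owner: Role | str,
    mode: str = "joint",
    attribution: str = "per_speaker",
) -> TransitionMatrix:
    """Count contiguous tag pairs for one speaker under the chosen attribution.

    per_speaker: pairs over the role-concatenated sequence, so pairs may span
    that speaker's consecutive utterances.  dialogue_first_token: pairs over
    the full dialogue sequence, each attributed to its first token's speaker.
    """
    if mode not in ("joint", "conditional"):
        raise ValueError(f"unknown mode {mode!r}")
    if attribution not in ("per_speaker", "dialogue_first_token"):
        raise ValueError(f"unknown attribution {attribution!r}")
    owner = Role(owner)
    counts = np.zeros((len(UPOS_TAGS), len(UPOS_TAGS)), dtype=np.int64)
    if attribution == "per_speaker":
        tags = [t for _, t, r, _ in seq.items if r == owner]
        if len(tags) < 2:
            raise InsufficientLengthError(
                f"need >= 2 tokens for role {owner.value!r}, got {len(tags)}"
            )
        for a, b in zip(tags, tags[1:]):
            counts[_TAG_INDEX[a], _TAG_INDEX[b]] += 1
    else:
        if len(seq) < 2:
            raise InsufficientLengthError("need a dialogue of >= 2 tokens")
        n_owner = 0
        for (_, a, r1, _), (_, b, _, _) in zip(seq.items, seq.items[1:]):
            if r1 != owner:
                continue
            n_owner += 1
            counts[_TAG_INDEX[a], _TAG_INDEX[b]] += 1
        if n_owner == 0:
            raise InsufficientLengthError(
                f"role {owner.value!r} starts no bigram in the dialogue"
            )
    return TransitionMatrix(
        counts=counts,
        total_bigrams=int(counts.sum()),
        mode=mode,
        owner=owner,
        attribution=attribution,
    )


def interjection_features(m: TransitionMatrix) -> dict[str, float]:
    """All X-INTJ and INTJ-Y transition probabilities as named features.

    Transitions that start or end with an interjection serve as multi-word
    non-fluency metrics; absent transitions are reported as 0.
    """
    p = m.probabilities
    j = _TAG_INDEX["INTJ"]
    role = m.owner.value
    out: dict[str, float] = {}
    for tag in m.tagset:
        i = _TAG_INDEX[tag]
        out[f"{role}_{tag}-INTJ"] = float(p[i, j])
        out[f"{role}_INTJ-{tag}"] = float(p[j, i])
    return out
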