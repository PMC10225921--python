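"""Parsing, cleaning, and streaming of two-speaker session transcripts.

A session is an ordered sequence of utterances, each attributed to the
``patient`` or ``therapist`` role.  Cleaning lowercases the text, strips
punctuation (keeping apostrophes internal to a token so contractions such
as ``let's`` and ``i'm`` survive as single tokens), and removes bracketed
redaction placeholders like ``[NAME]`` left by de-identification.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

from .errors import EmptyInputError, EmptyStreamError, TranscriptParseError


class Role(str, Enum):
    PATIENT = "patient"
    THERAPIST = "therapist"


class Owner(str, Enum):
    PATIENT = "patient"
    THERAPIST = "therapist"
    DIALOGUE = "dialogue"


DEFAULT_LABELS: Mapping[str, Role] = {
    "PATIENT": Role.PATIENT,
    "THERAPIST": Role.THERAPIST,
}

#: bracketed spans are de-identification placeholders and are dropped
_REDACTION = re.compile(r"\[[^\]]*\]")
#: anything that is not a lowercase letter, digit or apostrophe becomes a separator
_NON_TOKEN = re.compile(r"[^a-z0-9']+")
_APOSTROPHES = {0x2019: 0x27, 0x02BC: 0x27, 0x2018: 0x27}


@dataclass
class Utterance:
    speaker_role: Role
    index: int
    raw_text: str
    tokens: tuple[str, ...] = ()


@dataclass
class Transcript:
    dyad_id: str
    utterances: list[Utterance] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def token_count(self, role: Role) -> int:
        return sum(len(u.tokens) for u in self.utterances if u.speaker_role == role)


@dataclass
class TokenStream:
    """Ordered tokens with role and utterance provenance.

    ``items`` holds ``(token, speaker_role, utterance_index)`` triples in
    session order; for per-role owners all triples carry that role.
    """

    owner: Owner
    items: list[tuple[str, Role, int]] = field(default_factory=list)

    @property
    def tokens(self) -> list[str]:
        return [tok for tok, _, _ in self.items]

    def __len__(self) -> int:
        return len(self.items)


def clean_text_to_tokens(text: str) -> tuple[str, ...]:
    """Lowercase, strip punctuation and redactions, split on whitespace.

    Apostrophes internal to a token are kept (``let's`` stays one token);
    leading/trailing apostrophes are trimmed.  Numerals are kept: they count
    toward a speaker's total word count.
    """
    text = _REDACTION.sub(" ", text)
    text = text.lower().translate(_APOSTROPHES)
    text = _NON_TOKEN.sub(" ", text)
    out = []
    for tok in text.split():
        tok = tok.strip("'")
        if tok:
            out.append(tok)
    return tuple(out)


def parse_transcript(
    source: str,
    dialect: str = "prefixed_lines",
    dyad_id: str | None = None,
    labels: Mapping[str, Role] = DEFAULT_LABELS,
) -> Transcript:
    """Parse raw transcript text in either supported dialect.

    ``prefixed_lines``: one utterance per line, ``ROLE: text`` with the role
    label matched case-insensitively against ``labels``.  ``json_records``:
    a JSON array of ``{"speaker": ..., "text": ...}`` objects.
    """
    if not source or not source.strip():
        raise EmptyInputError("transcript source is empty")
    label_map = {k.upper(): v for k, v in labels.items()}
    utterances: list[Utterance] = []
    if dialect == "prefixed_lines":
        for line_no, line in enumerate(source.splitlines(), start=1):
            if not line.strip():
                continue
            head, sep, text = line.partition(":")
            if not sep:
                raise TranscriptParseError("missing 'ROLE:' prefix", line_no)
            label = head.strip().upper()
            if label not in label_map:
                raise TranscriptParseError(
                    f"unrecognized speaker label {head.strip()!r}", line_no
                )
            utterances.append(
                Utterance(label_map[label], len(utterances), text.strip())
            )
    elif dialect == "json_records":
        try:
            records = json.loads(source)
        except json.JSONDecodeError as exc:
            raise TranscriptParseError(f"invalid JSON: {exc}") from exc
        if not isinstance(records, list) or not records:
            raise EmptyInputError("json_records source holds no records")
        for i, rec in enumerate(records):
            label = str(rec.get("speaker", "")).strip().upper()
            if label not in label_map:
                raise TranscriptParseError(
                    f"unrecognized speaker label {rec.get('speaker')!r}", i + 1
                )
            utterances.append(
                Utterance(label_map[label], i, str(rec.get("text", "")).strip())
            )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if not utterances:
        raise EmptyInputError("transcript source holds no utterances")
    return Transcript(dyad_id=dyad_id or "dyad", utterances=utterances)


def read_transcript(path: str | Path, dialect: str | None = None, **kwargs) -> Transcript:
    """Read a transcript file; the dyad id defaults to the filename stem."""
    path = Path(path)
    if dialect is None:
        dialect = "json_records" if path.suffix == ".json" else "prefixed_lines"
    kwargs.setdefault("dyad_id", path.stem)
    return parse_transcript(path.read_text(encoding="utf-8"), dialect=dialect, **kwargs)


def preprocess(t: Transcript) -> Transcript:
    """Populate cleaned token sequences for every utterance.

    Idempotent: raw text is untouched and tokens are always recomputed from it.
    """
    cleaned = [replace(u, tokens=clean_text_to_tokens(u.raw_text)) for u in t.utterances]
    return Transcript(t.dyad_id, cleaned, dict(t.metadata))


def token_stream(t: Transcript, owner: Owner | str) -> TokenStream:
    """Concatenate a role's tokens in session order, or interleave the dialogue."""
    owner = Owner(owner)
    items: list[tuple[str, Role, int]] = []
    for u in t.utterances:
        if owner != Owner.DIALOGUE and u.speaker_role.value != owner.value:
            continue
        items.extend((tok, u.speaker_role, u.index) for tok in u.tokens)
    if not items:
        raise EmptyStreamError(f"no tokens for owner {owner.value!r} in {t.dyad_id!r}")
    return TokenStream(owner=owner, items=items)


def to_prefixed_lines(t: Transcript, cleaned: bool = True, labels: Mapping[Role, str] | None = None) -> str:
    """Serialize to the prefixed_lines dialect (deterministic for fixed input)."""
    labels = labels or {Role.PATIENT: "PATIENT", Role.THERAPIST: "THERAPIST"}
    lines = []
    for u in t.utterances:
        text = " ".join(u.tokens) if cleaned and u.tokens else u.raw_text
        lines.append(f"{labels[u.speaker_role]}: {text}")
    return "\n".join(lines) + "\n"


def to_json_records(t: Transcript, cleaned: bool = True) -> str:
    records = [
        {
            "speaker": u.speaker_role.value,
            "text": " ".join(u.tokens) if cleaned and u.tokens else u.raw_text,
        }
        for u in t.utterances
    ]
    return json.dumps(records, indent=1, sort_keys=True)
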