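"""Reading and normalizing letter-fluency transcripts.

Two input dialects are supported: plain one-word-per-line lists, and a
minimal subset of the TalkBank CHAT format (participant ``*PAR:`` tiers,
terminators, ``[x N]`` repetition marks). Full CHAT grammar — overlaps,
retracing codes, timing — is deliberately out of scope.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

__all__ = [
    "TokenAnnotation",
    "ParticipantMeta",
    "FluencySession",
    "normalize_token",
    "read_chat_session",
    "read_plain_list",
    "annotate_errors",
    "count_correct_words",
    "read_demographics",
]

# strip leading/trailing punctuation; keep internal hyphens/apostrophes
# so items like "fire-fly" survive normalization.
_EDGE_PUNCT = re.compile(r"^[^\w]+|[^\w]+$", re.UNICODE)


def normalize_token(raw: str) -> str:
    """Lowercase and strip edge punctuation from a transcribed token.

    Idempotent: ``normalize_token(normalize_token(s)) == normalize_token(s)``.
    """
    return _EDGE_PUNCT.sub("", raw.strip().lower())


@dataclass
class TokenAnnotation:
    """One produced word with its normalized form and scoring flags."""

    raw: str
    norm: str
    is_repetition: bool = False
    is_error: bool = False


@dataclass
class ParticipantMeta:
    """Optional demographics; any field may be missing (None)."""

    age: Optional[float] = None
    education: Optional[float] = None
    mmse: Optional[int] = None

    def __post_init__(self) -> None:
        if self.mmse is not None and not (0 <= self.mmse <= 30):
            raise ValueError(f"mmse must lie in [0, 30], got {self.mmse}")


@dataclass
class FluencySession:
    """One participant's ordered token sequence plus metadata."""

    participant_id: str
    tokens: list[TokenAnnotation] = field(default_factory=list)
    target_letter: str = "f"
    duration_s: float = 60.0
    meta: ParticipantMeta = field(default_factory=ParticipantMeta)

    def __post_init__(self) -> None:
        if not (len(self.target_letter) == 1 and self.target_letter.isalpha()):
            raise ValueError("target_letter must be a single alphabetic character")
        self.target_letter = self.target_letter.lower()
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")

    @property
    def norms(self) -> list[str]:
        return [t.norm for t in self.tokens]

    def to_record(self) -> dict:
        """JSON-serializable record (one line of a JSON-lines cohort file)."""
        return {
            "participant_id": self.participant_id,
            "target_letter": self.target_letter,
            "duration_s": self.duration_s,
            "tokens": [
                {
                    "raw": t.raw,
                    "norm": t.norm,
                    "is_repetition": t.is_repetition,
                    "is_error": t.is_error,
                }
                for t in self.tokens
            ],
            "meta": {
                "age": self.meta.age,
                "education": self.meta.education,
                "mmse": self.meta.mmse,
            },
        }

    @classmethod
    def from_record(cls, rec: dict) -> "FluencySession":
        meta = rec.get("meta") or {}
        return cls(
            participant_id=rec["participant_id"],
            tokens=[TokenAnnotation(**t) for t in rec.get("tokens", [])],
            target_letter=rec.get("target_letter", "f"),
            duration_s=rec.get("duration_s", 60.0),
            meta=ParticipantMeta(
                age=meta.get("age"),
                education=meta.get("education"),
                mmse=meta.get("mmse"),
            ),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_record(), sort_keys=True)


def _flag_repetitions(tokens: list[TokenAnnotation]) -> None:
    """is_repetition is true iff an earlier token has the identical norm."""
    seen: set[str] = set()
    for tok in tokens:
        tok.is_repetition = tok.norm in seen
        seen.add(tok.norm)


def _build_tokens(raws: Iterable[str]) -> list[TokenAnnotation]:
    tokens = []
    for raw in raws:
        norm = normalize_token(raw)
        if norm:
            tokens.append(TokenAnnotation(raw=raw, norm=norm))
    _flag_repetitions(tokens)
    return tokens


def read_plain_list(
    path: str | Path,
    target_letter: str = "f",
    participant_id: Optional[str] = None,
) -> FluencySession:
    """Read a one-token-per-line word list; blank lines ignored."""
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    tokens = _build_tokens(ln for ln in lines if ln.strip())
    return FluencySession(
        participant_id=participant_id or path.stem,
        tokens=tokens,
        target_letter=target_letter,
    )


# --- minimal CHAT dialect -------------------------------------------------

_TIER_RE = re.compile(r"^([*%@])([A-Za-z0-9]*):?\s?(.*)$")
_REPEAT_MARK = re.compile(r"\[x\s*(\d+)\]")
_BRACKET_GROUP = re.compile(r"\[[^\]]*\]")
_PAREN_GROUP = re.compile(r"\([^)]*\)")
# CHAT codes that are never lexical material in this minimal dialect
_NONLEX = re.compile(r"^(?:&\S*|\+\S*|#\S*|<|>|xxx|www|yyy|0\S*)$")


def _chat_tier_lines(text: str) -> list[str]:
    """Collect ``*PAR:`` main-tier contents, joining tab continuations."""
    out: list[str] = []
    in_par = False
    for line in text.splitlines():
        if line.startswith(("\t", " ")) and in_par and out:
            out[-1] += " " + line.strip()
            continue
        m = _TIER_RE.match(line)
        in_par = bool(m and m.group(1) == "*" and m.group(2).upper() == "PAR")
        if in_par:
            out.append(m.group(3).strip())
    return out


def _chat_tokens(tier: str) -> list[str]:
    # expand [x N] repetition marks on the preceding word, drop other
    # bracketed and parenthesized material, then filter CHAT codes.
    raws: list[str] = []
    pos = 0
    pieces: list[tuple[str, int]] = []  # (word-ish chunk, repeat count)
    # tokenize keeping bracket groups intact
    chunks = re.findall(r"\[[^\]]*\]|\S+", tier)
    for chunk in chunks:
        if chunk.startswith("["):
            m = _REPEAT_MARK.fullmatch(chunk)
            if m and pieces:
                word, n = pieces[-1]
                pieces[-1] = (word, n * int(m.group(1)))
            # any other [...] group (errors codes, comments) is dropped
            continue
        word = _PAREN_GROUP.sub("", chunk)
        word = word.strip("<>")
        if not word or _NONLEX.match(word):
            continue
        if normalize_token(word):
            pieces.append((word, 1))
    for word, n in pieces:
        raws.extend([word] * n)
    del pos
    return raws


def read_chat_session(
    path: str | Path,
    target_letter: str = "f",
    participant_id: Optional[str] = None,
) -> FluencySession:
    """Read the participant tiers of a CHAT (.cha) transcript.

    Investigator (``*INV:``) and dependent (``%``) tiers are ignored. A file
    with no participant tier yields an empty session rather than an error.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    raws: list[str] = []
    for tier in _chat_tier_lines(text):
        raws.extend(_chat_tokens(tier))
    tokens = _build_tokens(raws)
    return FluencySession(
        participant_id=participant_id or path.stem,
        tokens=tokens,
        target_letter=target_letter,
    )


def annotate_errors(session: FluencySession) -> FluencySession:
    """Flag tokens whose normalized form does not start with the target letter.

    The flagging is idempotent and returns a new session object.
    """
    tokens = [
        replace(t, is_error=not t.norm.startswith(session.target_letter))
        for t in session.tokens
    ]
    _flag_repetitions(tokens)
    return replace(session, tokens=tokens)


def count_correct_words(session: FluencySession) -> int:
    """Number of correct words: tokens that are neither errors nor repetitions."""
    return sum(1 for t in session.tokens if not t.is_error and not t.is_repetition)


def read_demographics(path: str | Path) -> dict[str, ParticipantMeta]:
    """Read a demographics CSV (participant_id, age, education, mmse)."""
    df = pd.read_csv(path, dtype={"participant_id": str}, comment="#")
    out: dict[str, ParticipantMeta] = {}
    for _, row in df.iterrows():
        def _num(key: str):
            v = row.get(key)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                return None
            return float(v)

        mmse = _num("mmse")
        out[row["participant_id"]] = ParticipantMeta(
            age=_num("age"),
            education=_num("education"),
            mmse=int(mmse) if mmse is not None else None,
        )
    return out
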