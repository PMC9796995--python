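"""Phonological strategy scoring: clusters and switches.

Consecutive words form a cluster when each adjacent pair is related by
any of four pronunciation rules: shared first two phonemes, rhyme,
single-vowel difference, or homonymy. A cluster of k words has size
k − 1, so singletons score 0. Switches are the transitions between
consecutive clusters. Errors and repetitions participate in clusters and
switches; they are excluded only from the correct-word count.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence

from fluencylab.sessions import FluencySession, count_correct_words

logger = logging.getLogger(__name__)

__all__ = [
    "ARPABET_PHONES",
    "ARPABET_VOWELS",
    "Pronunciation",
    "PronLexicon",
    "RelationTag",
    "ClusterSpan",
    "PhonologicalIndices",
    "load_pron_lexicon",
    "pair_relation",
    "find_clusters",
    "mean_cluster_size",
    "count_switches",
    "score_phonological",
]

ARPABET_VOWELS = frozenset(
    "AA AE AH AO AW AY EH ER EY IH IY OW OY UH UW".split()
)
ARPABET_CONSONANTS = frozenset(
    "B CH D DH F G HH JH K L M N NG P R S SH T TH V W Y Z ZH".split()
)
ARPABET_PHONES = ARPABET_VOWELS | ARPABET_CONSONANTS


def _strip_stress(phone: str) -> str:
    return phone.rstrip("012")


def _is_vowel(phone: str) -> bool:
    return _strip_stress(phone) in ARPABET_VOWELS


@dataclass(frozen=True)
class Pronunciation:
    """A word's ARPABET phone sequence (stress digits on vowels)."""

    word: str
    phones: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.phones:
            raise ValueError(f"empty phone sequence for {self.word!r}")
        for ph in self.phones:
            if _strip_stress(ph) not in ARPABET_PHONES:
                raise ValueError(f"invalid ARPABET phone {ph!r} in {self.word!r}")

    @property
    def segments(self) -> tuple[str, ...]:
        """Phones with stress digits removed."""
        return tuple(_strip_stress(p) for p in self.phones)

    @property
    def rime(self) -> tuple[str, ...]:
        """Stress-stripped phones from the last stressed vowel to the end.

        Falls back to the last secondary-stressed vowel, then the last
        vowel of any kind, for entries without a primary stress mark.
        """
        idx = None
        for digit in ("1", "2"):
            for i in range(len(self.phones) - 1, -1, -1):
                if self.phones[i].endswith(digit):
                    idx = i
                    break
            if idx is not None:
                break
        if idx is None:
            for i in range(len(self.phones) - 1, -1, -1):
                if _is_vowel(self.phones[i]):
                    idx = i
                    break
        if idx is None:
            idx = len(self.phones) - 1
        return self.segments[idx:]


class PronLexicon:
    """Case-insensitive word → pronunciation(s) lookup (CMUdict style)."""

    def __init__(self, entries: Optional[dict[str, list[Pronunciation]]] = None):
        self._entries: dict[str, list[Pronunciation]] = {}
        if entries:
            for word, prons in entries.items():
                for p in prons:
                    self.add(word, p.phones)

    def add(self, word: str, phones: Sequence[str]) -> None:
        key = word.lower()
        self._entries.setdefault(key, []).append(
            Pronunciation(word=key, phones=tuple(phones))
        )

    def get(self, word: str) -> list[Pronunciation]:
        return self._entries.get(word.lower(), [])

    def __contains__(self, word: str) -> bool:
        return word.lower() in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def words(self) -> list[str]:
        return sorted(self._entries)

    def save(self, path: str | Path) -> None:
        """Write in CMU Pronouncing Dictionary text format."""
        lines = []
        for word in sorted(self._entries):
            for i, pron in enumerate(self._entries[word]):
                key = word.upper() if i == 0 else f"{word.upper()}({i})"
                lines.append(f"{key}  {' '.join(pron.phones)}")
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "PronLexicon":
        lex = cls()
        n_bad = 0
        with open(path, encoding="latin-1") as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(";;;"):
                    continue
                parts = line.split()
                if len(parts) < 2:
                    n_bad += 1
                    logger.warning("skipping malformed lexicon line %d: %r", lineno, line)
                    continue
                word = parts[0]
                # variant suffix WORD(2)
                if word.endswith(")") and "(" in word:
                    word = word[: word.index("(")]
                try:
                    lex.add(word, parts[1:])
                except ValueError as exc:
                    n_bad += 1
                    logger.warning("skipping lexicon line %d: %s", lineno, exc)
        if len(lex) == 0:
            raise ValueError(f"no valid pronunciation entries in {path}")
        if n_bad:
            logger.warning("%d malformed lexicon lines skipped", n_bad)
        return lex


def load_pron_lexicon(path: str | Path) -> PronLexicon:
    """Load a pronunciation lexicon in CMUdict text format."""
    return PronLexicon.load(path)


def bundled_lexicon() -> PronLexicon:
    """The small CMUdict excerpt shipped with the package (letter-f words)."""
    return PronLexicon.load(Path(__file__).parent / "data" / "cmudict_f.txt")


class RelationTag(str, Enum):
    HOMONYM = "homonym"
    FIRST_TWO_PHONEMES = "first_two_phonemes"
    RHYME = "rhyme"
    VOWEL_SWAP = "vowel_swap"
    NONE = "none"


# precedence used when several rules hold for one pair; membership in a
# cluster depends only on whether ANY rule holds, never on the tag.
_PRECEDENCE = (
    RelationTag.HOMONYM,
    RelationTag.FIRST_TWO_PHONEMES,
    RelationTag.RHYME,
    RelationTag.VOWEL_SWAP,
)


def _vowel_swap(a: tuple[str, ...], b: tuple[str, ...]) -> bool:
    """Identical consonant frames with exactly one differing vowel position."""
    if len(a) != len(b):
        return False
    diffs = 0
    for pa, pb in zip(a, b):
        va, vb = pa in ARPABET_VOWELS, pb in ARPABET_VOWELS
        if va != vb:
            return False
        if pa != pb:
            if not va:
                return False  # consonant mismatch
            diffs += 1
    return diffs == 1


def _relations_for_pair(p1: Pronunciation, p2: Pronunciation,
                        spelled_differently: bool) -> set[RelationTag]:
    a, b = p1.segments, p2.segments
    tags: set[RelationTag] = set()
    if a == b and spelled_differently:
        tags.add(RelationTag.HOMONYM)
    if len(a) >= 2 and len(b) >= 2 and a[:2] == b[:2]:
        tags.add(RelationTag.FIRST_TWO_PHONEMES)
    if p1.rime == p2.rime:
        tags.add(RelationTag.RHYME)
    if _vowel_swap(a, b):
        tags.add(RelationTag.VOWEL_SWAP)
    return tags


def pair_relation(
    w1: str,
    w2: str,
    lex: PronLexicon,
    grapheme_fallback: bool = True,
) -> RelationTag:
    """Classify the phonological relation between two words.

    All pronunciation-variant pairs are tried; when several rules match,
    the reported tag follows the precedence homonym > first-two-phonemes >
    rhyme > vowel-swap. Words missing from the lexicon use a grapheme
    fallback (first two letters stand in for the first two phonemes) when
    enabled, otherwise they relate to nothing.
    """
    n1, n2 = w1.lower(), w2.lower()
    prons1, prons2 = lex.get(n1), lex.get(n2)
    spelled_differently = n1 != n2
    if prons1 and prons2:
        tags: set[RelationTag] = set()
        for p1 in prons1:
            for p2 in prons2:
                tags |= _relations_for_pair(p1, p2, spelled_differently)
        for tag in _PRECEDENCE:
            if tag in tags:
                return tag
        return RelationTag.NONE
    if not grapheme_fallback:
        return RelationTag.NONE
    # grapheme fallback: only the first-two-phonemes rule has an
    # orthographic stand-in; rhyme/vowel-swap/homonymy need phones.
    if len(n1) >= 2 and len(n2) >= 2 and n1[:2] == n2[:2]:
        logger.debug("grapheme fallback related %r ~ %r", n1, n2)
        return RelationTag.FIRST_TWO_PHONEMES
    return RelationTag.NONE


@dataclass(frozen=True)
class ClusterSpan:
    """A maximal run of related consecutive tokens; indices inclusive."""

    start_index: int
    end_index: int

    def __post_init__(self) -> None:
        if self.end_index < self.start_index:
            raise ValueError("end_index before start_index")

    @property
    def size(self) -> int:
        """Cluster size: word count minus one (singleton = 0)."""
        return self.end_index - self.start_index


@dataclass
class PhonologicalIndices:
    """Per-participant phonological strategy summary."""

    mean_cluster_size: Optional[float]
    num_switches: int
    spans: list[ClusterSpan] = field(default_factory=list)
    relation_tags: list[RelationTag] = field(default_factory=list)


def find_clusters(
    tokens: Sequence[str],
    lex: PronLexicon,
    grapheme_fallback: bool = True,
) -> list[ClusterSpan]:
    """Partition a token sequence into maximal related runs.

    Adjacent-pair chaining: a run extends while each consecutive pair is
    related by any rule. The spans cover every index exactly once.
    """
    n = len(tokens)
    if n == 0:
        return []
    spans: list[ClusterSpan] = []
    start = 0
    for i in range(1, n):
        rel = pair_relation(tokens[i - 1], tokens[i], lex, grapheme_fallback)
        if rel is RelationTag.NONE:
            spans.append(ClusterSpan(start, i - 1))
            start = i
    spans.append(ClusterSpan(start, n - 1))
    return spans


def mean_cluster_size(spans: Sequence[ClusterSpan]) -> Optional[float]:
    """Total cluster size divided by the number of clusters.

    Singletons (size 0) count in the denominator. Undefined (None) for an
    empty span list.
    """
    if not spans:
        return None
    return sum(s.size for s in spans) / len(spans)


def count_switches(spans: Sequence[ClusterSpan]) -> int:
    """Transitions between consecutive clusters."""
    return max(len(spans) - 1, 0)


def score_phonological(
    session: FluencySession,
    lex: PronLexicon,
    grapheme_fallback: bool = True,
) -> PhonologicalIndices:
    """Score one session: MCS, NoS, spans, and per-adjacent-pair tags.

    All tokens participate — errors and repetitions included.
    """
    words = session.norms
    spans = find_clusters(words, lex, grapheme_fallback)
    tags = [
        pair_relation(words[i - 1], words[i], lex, grapheme_fallback)
        for i in range(1, len(words))
    ]
    mcs = mean_cluster_size(spans)
    return PhonologicalIndices(
        mean_cluster_size=mcs,
        num_switches=count_switches(spans),
        spans=spans,
        relation_tags=tags,
    )
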