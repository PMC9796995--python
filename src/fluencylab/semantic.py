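"""Semantic strategy scoring via embedding-angle persistence length.

Consecutive word vectors define a sequence of turning angles (arccos of
cosine similarity, in degrees). Viewed as the bending of a discrete
unit-segment chain, the decay of directional correlation along the chain
gives a persistence length Lp, and the bounded semantic-relatedness
index SR = exp(-1/Lp) — equivalently the mean adjacent cosine, floored
at zero. Larger SR means successive words stay semantically closer.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "EmbeddingLexicon",
    "AngleSequence",
    "Chain2D",
    "PersistenceEstimate",
    "SemanticIndex",
    "InsufficientDataError",
    "load_embeddings",
    "turning_angles",
    "build_chain",
    "estimate_persistence_length",
    "semantic_relatedness",
]

MIN_WORDS_SEMANTIC = 4  # fewer words -> too few angles to estimate Lp
_LAG_MAX = 5


class InsufficientDataError(ValueError):
    """Raised when a session has too few in-vocabulary words/angles."""


class EmbeddingLexicon:
    """Case-insensitive word → dense vector lookup of uniform dimension."""

    def __init__(self, vectors: Optional[dict[str, np.ndarray]] = None):
        self._vectors: dict[str, np.ndarray] = {}
        self.dim: Optional[int] = None
        if vectors:
            for word, vec in vectors.items():
                self.add(word, vec)

    def add(self, word: str, vector: Sequence[float]) -> None:
        vec = np.asarray(vector, dtype=float)
        if vec.ndim != 1:
            raise ValueError("vector must be one-dimensional")
        if self.dim is None:
            if vec.size < 2:
                raise ValueError("embedding dimension must be >= 2")
            self.dim = vec.size
        elif vec.size != self.dim:
            raise ValueError(
                f"inconsistent dimension for {word!r}: {vec.size} != {self.dim}"
            )
        if not np.any(vec):
            raise ValueError(f"zero vector for {word!r}")
        key = word.lower()
        if key in self._vectors:
            logger.warning("duplicate embedding for %r; keeping first", word)
            return
        self._vectors[key] = vec

    def get(self, word: str) -> Optional[np.ndarray]:
        return self._vectors.get(word.lower())

    def __contains__(self, word: str) -> bool:
        return word.lower() in self._vectors

    def __len__(self) -> int:
        return len(self._vectors)

    def words(self) -> list[str]:
        return sorted(self._vectors)

    def save(self, path: str | Path, header: bool = True) -> None:
        """Write word2vec-style plain text (word then floats per line)."""
        with open(path, "w", encoding="utf-8") as fh:
            if header:
                fh.write(f"{len(self._vectors)} {self.dim}\n")
            for word in sorted(self._vectors):
                vals = " ".join(f"{x:.6f}" for x in self._vectors[word])
                fh.write(f"{word} {vals}\n")

    @classmethod
    def load(cls, path: str | Path) -> "EmbeddingLexicon":
        lex = cls()
        with open(path, encoding="utf-8") as fh:
            first = fh.readline()
            parts = first.split()
            is_header = len(parts) == 2 and all(p.isdigit() for p in parts)
            if not is_header and parts:
                cls._add_line(lex, parts, 1)
            for lineno, line in enumerate(fh, 2):
                parts = line.split()
                if parts:
                    cls._add_line(lex, parts, lineno)
        if len(lex) == 0:
            raise ValueError(f"no embedding vectors in {path}")
        return lex

    @staticmethod
    def _add_line(lex: "EmbeddingLexicon", parts: list[str], lineno: int) -> None:
        word, vals = parts[0], parts[1:]
        try:
            vec = np.array([float(v) for v in vals])
        except ValueError as exc:
            raise ValueError(f"malformed embedding line {lineno}: {exc}") from exc
        try:
            lex.add(word, vec)
        except ValueError as exc:
            if "zero vector" in str(exc):
                logger.warning("skipping %s", exc)
            else:
                raise


def load_embeddings(path: str | Path) -> EmbeddingLexicon:
    """Load a word2vec/GloVe plain-text embedding table."""
    return EmbeddingLexicon.load(path)


def bundled_embeddings() -> EmbeddingLexicon:
    """Pretrained vectors shipped with the package.

    Extracted from spaCy ``en_core_web_lg`` 3.8.0 (300-d GloVe-derived
    vectors) for a small set of letter-f words, in word2vec text format.
    """
    return EmbeddingLexicon.load(
        Path(__file__).parent / "data" / "embeddings_f.txt"
    )


@dataclass
class AngleSequence:
    """Ordered turning angles (degrees, in [0, 180]) between word vectors."""

    angles_deg: list[float]

    def __post_init__(self) -> None:
        for a in self.angles_deg:
            if not (0.0 <= a <= 180.0):
                raise ValueError(f"angle {a} outside [0, 180]")

    def __len__(self) -> int:
        return len(self.angles_deg)

    @property
    def cosines(self) -> np.ndarray:
        return np.cos(np.radians(self.angles_deg))


def angle_between(u: np.ndarray, v: np.ndarray) -> float:
    """Angle in degrees between two vectors; cosine clipped to [-1, 1]."""
    c = float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def turning_angles(
    words: Sequence[str], emb: EmbeddingLexicon
) -> tuple[AngleSequence, list[str]]:
    """Angles between consecutive in-vocabulary word vectors.

    Out-of-vocabulary words are dropped (and returned for diagnostics);
    the chain then connects the surviving neighbours.

    Raises :class:`InsufficientDataError` with fewer than two
    in-vocabulary words.
    """
    oov = [w for w in words if w not in emb]
    vecs = [emb.get(w) for w in words if w in emb]
    if oov:
        logger.info("dropping %d out-of-vocabulary words: %s", len(oov), oov)
    if len(vecs) < 2:
        raise InsufficientDataError(
            f"need >=2 in-vocabulary words, got {len(vecs)}"
        )
    angles = [angle_between(vecs[i], vecs[i + 1]) for i in range(len(vecs) - 1)]
    return AngleSequence(angles), oov


@dataclass
class Chain2D:
    """Unit-segment planar chain whose joint angles match an AngleSequence."""

    vertices: np.ndarray  # shape (n_angles + 2, 2)


def build_chain(
    angles: AngleSequence,
    sign_rule: str = "positive",
    seed: Optional[int] = None,
) -> Chain2D:
    """Lay out the angle sequence as a planar chain for plotting.

    The chain starts at the origin heading along +x; each joint bends by
    the corresponding angle magnitude with a sign chosen by ``sign_rule``
    ("positive", "alternating", or "random"). SR and Lp never depend on
    the sign rule — it exists purely for visualization.
    """
    n = len(angles)
    if sign_rule == "positive":
        signs = np.ones(n)
    elif sign_rule == "alternating":
        signs = np.array([1.0 if i % 2 == 0 else -1.0 for i in range(n)])
    elif sign_rule == "random":
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=n)
    else:
        raise ValueError(f"unknown sign_rule {sign_rule!r}")
    heading = 0.0
    pts = [np.zeros(2), np.array([1.0, 0.0])]
    for ang, s in zip(angles.angles_deg, signs):
        heading += s * math.radians(ang)
        step = np.array([math.cos(heading), math.sin(heading)])
        pts.append(pts[-1] + step)
    return Chain2D(vertices=np.vstack(pts))


@dataclass
class PersistenceEstimate:
    """Persistence length in segment units, with estimator provenance."""

    lp_segments: float  # may be math.inf
    estimator: str
    n_angles: int

    @property
    def is_infinite(self) -> bool:
        return math.isinf(self.lp_segments)


def _lag_correlations(cosines: np.ndarray, max_lag: int) -> dict[int, float]:
    """Mean directional correlation at each lag.

    The correlation over a window is the product of the adjacent cosines
    inside it — the expected cosine of the cumulative heading change when
    bend signs are independent and symmetric, which keeps the estimator
    free of the (unobservable) turn signs.
    """
    out = {}
    n = len(cosines)
    for s in range(1, max_lag + 1):
        if n - s + 1 <= 0:
            break
        windows = [float(np.prod(cosines[i : i + s])) for i in range(n - s + 1)]
        out[s] = float(np.mean(windows))
    return out


def estimate_persistence_length(
    angles: AngleSequence, estimator: str = "adjacent_cosine"
) -> PersistenceEstimate:
    """Estimate Lp from turning angles.

    ``adjacent_cosine``: Lp = -1/ln(cbar) with cbar the mean adjacent
    cosine; cbar <= 0 gives Lp = 0, cbar >= 1 is flagged infinite.

    ``lag_decay_fit``: zero-intercept least squares of ln<cos(s)> on the
    lag s over s = 1..min(5, n-1); the slope is -1/Lp.

    Raises :class:`InsufficientDataError` with fewer than 3 angles.
    """
    n = len(angles)
    if n < 3:
        raise InsufficientDataError(f"need >=3 angles, got {n}")
    cosines = angles.cosines
    if estimator == "adjacent_cosine":
        cbar = float(np.mean(cosines))
        lp = _lp_from_cbar(cbar)
    elif estimator == "lag_decay_fit":
        corr = _lag_correlations(cosines, min(_LAG_MAX, n - 1))
        lags = np.array([s for s, c in corr.items() if c > 0], dtype=float)
        logs = np.array([math.log(corr[int(s)]) for s in lags])
        if lags.size == 0:
            lp = 0.0
        elif np.allclose(logs, 0.0):
            lp = math.inf
        else:
            slope = float(np.dot(lags, logs) / np.dot(lags, lags))
            lp = math.inf if slope >= 0 else -1.0 / slope
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    return PersistenceEstimate(lp_segments=lp, estimator=estimator, n_angles=n)


def _lp_from_cbar(cbar: float) -> float:
    if cbar >= 1.0:
        return math.inf
    if cbar <= 0.0:
        return 0.0
    return -1.0 / math.log(cbar)


@dataclass
class SemanticIndex:
    """Per-participant semantic strategy summary."""

    sr: float  # in [0, 1]
    lp: PersistenceEstimate
    oov_words: list[str] = field(default_factory=list)
    n_words_used: int = 0


def semantic_relatedness(
    words: Sequence[str],
    emb: EmbeddingLexicon,
    estimator: str = "adjacent_cosine",
) -> SemanticIndex:
    """Compute the bounded semantic-relatedness index SR for a session.

    SR is the mean adjacent cosine floored at zero; under the
    adjacent-cosine estimator this equals exp(-1/Lp). Repetitions stay in
    the sequence (identical vectors contribute 0-degree angles).

    Raises :class:`InsufficientDataError` with fewer than four
    in-vocabulary words — too few angles for a meaningful estimate.
    """
    in_vocab = [w for w in words if w in emb]
    if len(in_vocab) < MIN_WORDS_SEMANTIC:
        raise InsufficientDataError(
            f"need >={MIN_WORDS_SEMANTIC} in-vocabulary words, got {len(in_vocab)}"
        )
    angles, oov = turning_angles(words, emb)
    cbar = float(np.mean(angles.cosines))
    sr = max(0.0, cbar)
    lp = estimate_persistence_length(angles, estimator=estimator)
    return SemanticIndex(
        sr=sr, lp=lp, oov_words=oov, n_words_used=len(in_vocab)
    )
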