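"""Synthetic lexicons, participants, and cohorts with known ground truth.

Every pipeline stage is testable without restricted clinical data: the
generator plants pronunciation relations of all four kinds in a
CMUdict-style lexicon, draws word sequences with a controllable
clustering probability, and assigns embedding vectors so that the
realized turning angles follow a worm-like-chain law with a known
persistence length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from fluencylab.phonological import PronLexicon, RelationTag, pair_relation
from fluencylab.semantic import AngleSequence, EmbeddingLexicon
from fluencylab.sessions import FluencySession, TokenAnnotation, annotate_errors

__all__ = [
    "SynthConfig",
    "SynthTruth",
    "SynthLexicon",
    "SynthCohort",
    "make_synthetic_lexicon",
    "simulate_wlc_angles",
    "simulate_participant",
    "simulate_cohort",
    "write_cohort",
]


@dataclass(frozen=True)
class SynthConfig:
    n_participants: int = 47
    lexicon_size: int = 25
    embedding_dim: int = 50
    cluster_prob: float = 0.3
    lp_range: tuple[float, float] = (2.0, 10.0)
    length_mean: float = 8.0
    length_min: int = 1
    length_max: int = 20
    error_rate: float = 0.02
    repetition_rate: float = 0.03
    target_letter: str = "f"
    preset: Optional[str] = None  # None or "phonological"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("cluster_prob", "error_rate", "repetition_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.lp_range[0] <= 0 or self.lp_range[1] < self.lp_range[0]:
            raise ValueError("lp_range must be a positive interval")
        if self.embedding_dim < 2:
            raise ValueError("embedding_dim must be >= 2")


@dataclass
class SynthTruth:
    """Ground-truth generative parameters for one simulated participant."""

    participant_id: str
    true_lp: float
    true_cluster_prob: float
    planted_cluster_spans: list[tuple[int, int]] = field(default_factory=list)
    length: int = 0
    unambiguous: bool = True  # False if sampling had to break the plan

    @property
    def target_sr(self) -> float:
        return math.exp(-1.0 / self.true_lp)


@dataclass
class SynthLexicon:
    """A generated lexicon with its exhaustive phonological relation graph."""

    pron: PronLexicon
    emb: EmbeddingLexicon
    relation_graph: dict[str, set[str]]
    planted_pairs: dict[RelationTag, list[tuple[str, str]]]
    words: list[str] = field(default_factory=list)


# phone inventory for generated words (all begin with F)
_VOWELS = "AA1 AE1 AH1 AO1 AY1 EH1 ER1 EY1 IH1 IY1 OW1 UW1".split()
_CODAS = ["B", "D", "G", "K", "M", "N", "P", "S", "T", "SH", "Z"]
_SPELL = {
    "F": "f", "R": "r", "L": "l", "B": "b", "D": "d", "G": "g", "K": "k",
    "M": "m", "N": "n", "P": "p", "S": "s", "T": "t", "SH": "sh", "Z": "z",
    "AA": "o", "AE": "a", "AH": "u", "AO": "aw", "AY": "y", "EH": "e",
    "ER": "ir", "EY": "ay", "IH": "i", "IY": "ee", "OW": "oh", "UW": "oo",
}


def _spell(phones: Sequence[str]) -> str:
    return "".join(_SPELL[p.rstrip("012")] for p in phones)


def _unit(rng: np.random.Generator, dim: int) -> np.ndarray:
    v = rng.standard_normal(dim)
    return v / np.linalg.norm(v)


def make_synthetic_lexicon(
    config: SynthConfig,
    rng: Optional[np.random.Generator] = None,
    namespace: str = "",
) -> SynthLexicon:
    """Generate a lexicon of letter-f words with planted relations.

    At least three word pairs per relation type (homonym, shared first
    two phonemes, rhyme, vowel swap) are planted, each detectable by
    :func:`fluencylab.phonological.pair_relation` with exactly that tag.
    Every word receives a unit-norm embedding vector. ``namespace`` is a
    spelling suffix that keeps words from different participants
    distinct without touching their phonology.
    """
    if config.lexicon_size < 20:
        raise ValueError("lexicon_size must be >= 20 to plant all relation types")
    if config.lexicon_size > 120:
        raise ValueError("phone inventory too small for lexicon_size > 120")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    pron = PronLexicon()
    spellings: set[str] = set()
    phone_sigs: set[tuple[str, ...]] = set()
    planted: dict[RelationTag, list[tuple[str, str]]] = {
        RelationTag.HOMONYM: [],
        RelationTag.FIRST_TWO_PHONEMES: [],
        RelationTag.RHYME: [],
        RelationTag.VOWEL_SWAP: [],
    }

    def register(phones: list[str], spelling: Optional[str] = None) -> str:
        word = (spelling or _spell(phones)) + namespace
        base = word
        bump = 0
        while word in spellings:
            bump += 1
            word = base + "x" * bump
        spellings.add(word)
        phone_sigs.add(tuple(p.rstrip("012") for p in phones))
        pron.add(word, phones)
        return word

    def fresh_phones(onset: list[str], max_tries: int = 200) -> list[str]:
        for _ in range(max_tries):
            v = _VOWELS[rng.integers(len(_VOWELS))]
            c = _CODAS[rng.integers(len(_CODAS))]
            phones = ["F", *onset, v, c]
            if tuple(p.rstrip("012") for p in phones) not in phone_sigs:
                return phones
        raise ValueError("phone inventory exhausted")

    # homonyms: same phones, two spellings
    for _ in range(3):
        phones = fresh_phones([])
        w1 = register(phones)
        w2 = register(phones, _spell(phones) + "e")
        planted[RelationTag.HOMONYM].append((w1, w2))
    # rhymes: F R V C vs F L V C — same rime, different first two phones
    for _ in range(3):
        phones = fresh_phones(["R"])
        w1 = register(phones)
        w2 = register(["F", "L", *phones[2:]])
        planted[RelationTag.RHYME].append((w1, w2))
    # vowel swaps: F V1 C vs F V2 C — one vowel differs, frame identical
    for _ in range(3):
        phones = fresh_phones([])
        alt = [v for v in _VOWELS if v != phones[1]][rng.integers(len(_VOWELS) - 1)]
        w1 = register(phones)
        w2 = register(["F", alt, phones[2]])
        planted[RelationTag.VOWEL_SWAP].append((w1, w2))
    # first two phonemes: F V C1 vs F V C2 — shared F+vowel start
    for _ in range(3):
        phones = fresh_phones([])
        alt = [c for c in _CODAS if c != phones[2]][rng.integers(len(_CODAS) - 1)]
        w1 = register(phones)
        w2 = register(["F", phones[1], alt])
        planted[RelationTag.FIRST_TWO_PHONEMES].append((w1, w2))
    # filler words up to the requested size
    while len(pron) < config.lexicon_size:
        register(fresh_phones([]))

    words = pron.words()
    emb = EmbeddingLexicon()
    for w in words:
        emb.add(w, _unit(rng, config.embedding_dim))

    graph: dict[str, set[str]] = {w: set() for w in words}
    for i, a in enumerate(words):
        for b in words[i + 1 :]:
            if pair_relation(a, b, pron, grapheme_fallback=False) is not RelationTag.NONE:
                graph[a].add(b)
                graph[b].add(a)
    for tag, pairs in planted.items():
        for a, b in pairs:
            got = pair_relation(a, b, pron, grapheme_fallback=False)
            if got is not tag:
                raise AssertionError(f"planted {tag} pair ({a},{b}) detected as {got}")
    return SynthLexicon(
        pron=pron, emb=emb, relation_graph=graph, planted_pairs=planted, words=words
    )


def simulate_wlc_angles(
    true_lp: float,
    n_angles: int,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> AngleSequence:
    """Draw i.i.d. turning angles with mean cosine exp(-1/true_lp).

    Heading increments are Gaussian with variance 2/true_lp, wrapped to
    (-pi, pi]; since the cosine is periodic, E[cos] = exp(-1/true_lp)
    holds exactly. Magnitudes are reported in [0, 180] degrees.
    """
    if true_lp <= 0:
        raise ValueError("true_lp must be positive")
    if n_angles < 1:
        raise ValueError("n_angles must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(seed)
    sigma = math.sqrt(2.0 / true_lp)
    delta = rng.normal(0.0, sigma, size=n_angles)
    wrapped = np.mod(delta + np.pi, 2 * np.pi) - np.pi
    return AngleSequence(list(np.degrees(np.abs(wrapped))))


_ERROR_WORDS = ["dog", "cat", "sun", "tree", "bird", "moon"]


def simulate_participant(
    truth: SynthTruth,
    lexicon: SynthLexicon,
    config: SynthConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[FluencySession, dict[str, np.ndarray]]:
    """Simulate one participant's session.

    Words are drawn without replacement; with probability
    ``true_cluster_prob`` the next word is a phonological relative of the
    current one, otherwise a word unrelated to it (resampled against the
    relation graph so planted cluster boundaries stay unambiguous).
    Embedding vectors for the words used are then re-assigned along a
    worm-like-chain trajectory with persistence length ``true_lp``, and
    returned as a per-session overlay. Errors (non-target-letter words,
    out of embedding vocabulary) and immediate repetitions are injected
    at the configured rates.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    graph = lexicon.relation_graph
    words = lexicon.words
    L = truth.length or _trunc_poisson(rng, config.length_mean,
                                       config.length_min, config.length_max)
    truth.length = L

    used: list[str] = []
    used_set: set[str] = set()
    boundaries: list[bool] = []  # True where a switch was intended
    unambiguous = True
    cur = words[rng.integers(len(words))]
    used.append(cur)
    used_set.add(cur)
    while len(used) < L:
        want_cluster = rng.random() < truth.true_cluster_prob
        if want_cluster:
            cands = sorted(graph[cur] - used_set)
            if not cands:
                want_cluster = False
        if not want_cluster:
            cands = sorted(set(words) - used_set - graph[cur] - {cur})
            if not cands:  # forced to break the plan
                cands = sorted(set(words) - used_set)
                if not cands:
                    break
                unambiguous = False
        nxt = cands[rng.integers(len(cands))]
        boundaries.append(not want_cluster)
        used.append(nxt)
        used_set.add(nxt)
        cur = nxt

    # planted spans from the draw decisions
    spans: list[tuple[int, int]] = []
    start = 0
    for i, is_switch in enumerate(boundaries, start=1):
        if is_switch:
            spans.append((start, i - 1))
            start = i
    spans.append((start, len(used) - 1))
    truth.planted_cluster_spans = spans
    truth.unambiguous = unambiguous

    # embedding overlay: worm-like-chain trajectory over the session words
    dim = lexicon.emb.dim or config.embedding_dim
    overlay: dict[str, np.ndarray] = {}
    v = _unit(rng, dim)
    overlay[used[0]] = v
    if len(used) > 1:
        angles = simulate_wlc_angles(truth.true_lp, len(used) - 1, rng=rng)
        for word, ang in zip(used[1:], angles.angles_deg):
            theta = math.radians(ang)
            u = _unit(rng, dim)
            u = u - np.dot(u, v) * v
            u /= np.linalg.norm(u)
            v = math.cos(theta) * v + math.sin(theta) * u
            v /= np.linalg.norm(v)
            overlay[word] = v

    # inject immediate repetitions and errors
    final: list[str] = []
    for i, w in enumerate(used):
        final.append(w)
        if i > 0 and rng.random() < config.repetition_rate:
            final.append(w)
        if rng.random() < config.error_rate:
            final.append(_ERROR_WORDS[rng.integers(len(_ERROR_WORDS))])

    tokens = [TokenAnnotation(raw=w, norm=w) for w in final]
    session = FluencySession(
        participant_id=truth.participant_id,
        tokens=tokens,
        target_letter=config.target_letter,
    )
    session = annotate_errors(session)
    return session, overlay


@dataclass
class SynthCohort:
    sessions: list[FluencySession]
    truths: list[SynthTruth]
    pron: PronLexicon
    emb: EmbeddingLexicon
    demographics: pd.DataFrame
    config: SynthConfig


def _trunc_poisson(rng: np.random.Generator, lam: float, lo: int, hi: int) -> int:
    for _ in range(200):
        x = int(rng.poisson(lam))
        if lo <= x <= hi:
            return x
    return int(min(max(round(lam), lo), hi))


def _alpha_suffix(i: int) -> str:
    # purely alphabetic per-participant namespace: qa, qb, ..., qaa, ...
    letters = ""
    i += 1
    while i:
        i, r = divmod(i - 1, 26)
        letters = chr(ord("a") + r) + letters
    return "q" + letters


def simulate_cohort(config: SynthConfig) -> SynthCohort:
    """Simulate a full cohort with per-participant ground truth.

    Each participant gets a private sub-lexicon (namespaced spellings, so
    the cohort-wide pronunciation and embedding tables stay consistent).
    The ``"phonological"`` preset couples the generative parameters the
    way a phonologically driven cohort would behave: participants with
    high semantic-relatedness targets produce shorter sequences, which
    yields the expected positive r(NoCW, NoS) and negative r(NoCW, SR)
    downstream.
    """
    rng = np.random.default_rng(config.seed)
    sessions: list[FluencySession] = []
    truths: list[SynthTruth] = []
    pron_union = PronLexicon()
    emb_union = EmbeddingLexicon()
    demo_rows = []
    for i in range(config.n_participants):
        pid = f"synth{i:03d}"
        sub_rng = np.random.default_rng(rng.integers(2**63))
        if config.preset == "phonological":
            c = float(sub_rng.uniform(0.40, 0.78))
            true_lp = -1.0 / math.log(c)
            p_cluster = float(sub_rng.uniform(0.05, 0.45))
            lam = 2.0 + 16.0 * (0.78 - c) / 0.38
        elif config.preset is None:
            true_lp = float(sub_rng.uniform(*config.lp_range))
            p_cluster = config.cluster_prob
            lam = config.length_mean
        else:
            raise ValueError(f"unknown preset {config.preset!r}")
        length = _trunc_poisson(sub_rng, lam, config.length_min, config.length_max)
        truth = SynthTruth(
            participant_id=pid,
            true_lp=true_lp,
            true_cluster_prob=p_cluster,
            length=length,
        )
        lexicon = make_synthetic_lexicon(config, rng=sub_rng,
                                         namespace=_alpha_suffix(i))
        session, overlay = simulate_participant(truth, lexicon, config, rng=sub_rng)
        for w in lexicon.words:
            for p in lexicon.pron.get(w):
                pron_union.add(w, p.phones)
            vec = overlay.get(w, lexicon.emb.get(w))
            emb_union.add(w, vec)
        age = float(np.clip(sub_rng.normal(72.3, 8.6), 55, 90))
        edu = float(np.clip(sub_rng.normal(11.8, 2.7), 6, 20))
        mmse = int(np.clip(round(10 + 0.8 * lam + sub_rng.normal(0, 2.5)), 0, 30))
        demo_rows.append(
            {"participant_id": pid, "age": round(age, 1),
             "education": round(edu, 1), "mmse": mmse}
        )
        session.meta.age = round(age, 1)
        session.meta.education = round(edu, 1)
        session.meta.mmse = mmse
        sessions.append(session)
        truths.append(truth)
    demographics = pd.DataFrame(
        demo_rows, columns=["participant_id", "age", "education", "mmse"]
    )
    return SynthCohort(
        sessions=sessions, truths=truths, pron=pron_union, emb=emb_union,
        demographics=demographics, config=config,
    )


def write_cohort(cohort: SynthCohort, outdir: str | Path) -> Path:
    """Write a cohort in the exact formats the pipeline reads.

    Layout: ``transcripts/<pid>.txt`` word lists, ``lexicon.txt``
    (CMUdict format), ``embeddings.txt`` (word2vec text),
    ``demographics.csv``, and ``truth.csv``.
    """
    outdir = Path(outdir)
    (outdir / "transcripts").mkdir(parents=True, exist_ok=True)
    for session in cohort.sessions:
        path = outdir / "transcripts" / f"{session.participant_id}.txt"
        path.write_text("\n".join(t.raw for t in session.tokens) + "\n",
                        encoding="utf-8")
    cohort.pron.save(outdir / "lexicon.txt")
    cohort.emb.save(outdir / "embeddings.txt")
    cohort.demographics.to_csv(outdir / "demographics.csv", index=False)
    truth_df = pd.DataFrame(
        [
            {
                "participant_id": t.participant_id,
                "true_lp": t.true_lp,
                "target_sr": t.target_sr,
                "true_cluster_prob": t.true_cluster_prob,
                "length": t.length,
                "unambiguous": t.unambiguous,
            }
            for t in cohort.truths
        ]
    )
    truth_df.to_csv(outdir / "truth.csv", index=False)
    return outdir
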