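"""End-to-end orchestration: transcripts in, cohort statistics out."""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

from fluencylab import cohort as cohort_stats
from fluencylab.phonological import load_pron_lexicon, score_phonological
from fluencylab.semantic import (
    InsufficientDataError,
    load_embeddings,
    semantic_relatedness,
)
from fluencylab.sessions import (
    FluencySession,
    annotate_errors,
    count_correct_words,
    read_chat_session,
    read_demographics,
    read_plain_list,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "score_session", "score_cohort"]


@dataclass
class PipelineConfig:
    transcripts_dir: str
    lexicon_path: str
    embeddings_path: str
    output_dir: str
    demographics_path: Optional[str] = None
    target_letter: str = "f"
    min_words: int = 4
    sd_threshold: float = 3.0
    outlier_measures: tuple[str, ...] = ("mcs", "sr")
    p_enter: float = 0.05
    p_remove: float = 0.10
    estimator: str = "adjacent_cosine"
    sign_rule: str = "positive"
    grapheme_fallback: bool = True
    seed: int = 0

    def config_hash(self) -> str:
        keys = {k: v for k, v in asdict(self).items() if k != "output_dir"}
        blob = json.dumps(keys, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def score_session(session: FluencySession, pron, emb,
                  estimator: str = "adjacent_cosine",
                  grapheme_fallback: bool = True) -> dict:
    """Score one annotated session into a flat indices record."""
    session = annotate_errors(session)
    phon = score_phonological(session, pron, grapheme_fallback)
    row = {
        "participant_id": session.participant_id,
        "n_tokens": len(session.tokens),
        "nocw": count_correct_words(session),
        "mcs": phon.mean_cluster_size,
        "nos": phon.num_switches,
        "sr": float("nan"),
        "lp_segments": float("nan"),
        "n_angles": 0,
        "n_oov": 0,
    }
    try:
        sem = semantic_relatedness(session.norms, emb, estimator=estimator)
        row.update(
            sr=sem.sr,
            lp_segments=sem.lp.lp_segments,
            n_angles=sem.lp.n_angles,
            n_oov=len(sem.oov_words),
        )
    except InsufficientDataError as exc:
        logger.info("semantic index unavailable for %s: %s",
                    session.participant_id, exc)
    return row


def _load_sessions(config: PipelineConfig) -> list[FluencySession]:
    tdir = Path(config.transcripts_dir)
    sessions = []
    for path in sorted(tdir.iterdir()):
        if path.suffix == ".cha":
            sessions.append(read_chat_session(path, config.target_letter))
        elif path.suffix in (".txt", ".list"):
            sessions.append(read_plain_list(path, config.target_letter))
    return sessions


def score_cohort(sessions: list[FluencySession], pron, emb,
                 config: PipelineConfig,
                 demographics: Optional[dict] = None) -> pd.DataFrame:
    rows = []
    for session in sessions:
        try:
            row = score_session(session, pron, emb,
                                estimator=config.estimator,
                                grapheme_fallback=config.grapheme_fallback)
        except Exception:
            logger.exception("failed to score %s; skipping",
                             session.participant_id)
            continue
        meta = None
        if demographics is not None:
            meta = demographics.get(session.participant_id)
        if meta is None:
            meta = session.meta
        row["age"] = meta.age if meta.age is not None else float("nan")
        row["education"] = (meta.education if meta.education is not None
                            else float("nan"))
        row["mmse"] = meta.mmse if meta.mmse is not None else float("nan")
        rows.append(row)
    cols = ["participant_id", "n_tokens", "nocw", "mcs", "nos", "sr",
            "lp_segments", "n_angles", "n_oov", "age", "education", "mmse"]
    return pd.DataFrame(rows, columns=cols)


def _write_csv(df: pd.DataFrame, path: Path, config_hash: str,
               index: bool = False) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# config_hash: {config_hash}\n")
        df.to_csv(fh, index=index)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the full analysis and write all artifacts to the output dir.

    Artifacts: ``indices.csv``, ``exclusions.csv``, ``descriptives.csv``,
    ``correlations.csv`` (with significance stars), ``regression.json``,
    ``regression.txt``, plus the verbatim ``config.json``. Every artifact
    names the config hash that produced it.
    """
    for name in ("transcripts_dir", "lexicon_path", "embeddings_path"):
        p = Path(getattr(config, name))
        if not p.exists():
            raise FileNotFoundError(f"{name} does not exist: {p}")
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    (outdir / "config.json").write_text(
        json.dumps({"config_hash": chash, **asdict(config)}, indent=2),
        encoding="utf-8",
    )
    pron = load_pron_lexicon(config.lexicon_path)
    emb = load_embeddings(config.embeddings_path)
    demographics = (read_demographics(config.demographics_path)
                    if config.demographics_path else None)
    sessions = _load_sessions(config)
    logger.info("loaded %d sessions, %d pronunciations, %d vectors",
                len(sessions), len(pron), len(emb))

    indices = score_cohort(sessions, pron, emb, config, demographics)
    _write_csv(indices, outdir / "indices.csv", chash)

    retained, exclusions = cohort_stats.apply_exclusions(
        indices,
        min_words=config.min_words,
        sd_threshold=config.sd_threshold,
        outlier_measures=config.outlier_measures,
    )
    _write_csv(exclusions, outdir / "exclusions.csv", chash)
    logger.info("retained %d of %d participants", len(retained), len(indices))

    if retained.empty:
        for name in ("descriptives.csv", "correlations.csv"):
            _write_csv(pd.DataFrame(), outdir / name, chash)
        report = {"config_hash": chash, "note": "empty retained cohort"}
        (outdir / "regression.json").write_text(json.dumps(report, indent=2))
        (outdir / "regression.txt").write_text(
            f"# config_hash: {chash}\nempty retained cohort\n")
        return outdir

    desc = cohort_stats.describe_cohort(retained)
    _write_csv(desc, outdir / "descriptives.csv", chash, index=True)

    corr = cohort_stats.pearson_matrix(retained)
    _write_csv(corr.stars(), outdir / "correlations.csv", chash, index=True)

    reg = cohort_stats.stepwise_regression(
        retained, p_enter=config.p_enter, p_remove=config.p_remove
    )
    payload = {"config_hash": chash, **_jsonable(reg.to_dict())}
    (outdir / "regression.json").write_text(json.dumps(payload, indent=2),
                                            encoding="utf-8")
    (outdir / "regression.txt").write_text(_format_regression(reg, chash),
                                           encoding="utf-8")
    return outdir


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float) and not math.isfinite(obj):
        return str(obj)
    return obj


def _format_regression(reg, chash: str) -> str:
    lines = [f"# config_hash: {chash}",
             f"Stepwise regression for {reg.outcome} (n = {reg.n})"]
    if not reg.predictors:
        lines.append("No candidate entered the model; R^2 = 0.")
        return "\n".join(lines) + "\n"
    lines.append(
        f"F({reg.df_model}, {reg.df_resid}) = {reg.f_statistic:.3f}, "
        f"R^2 = {reg.r_squared:.3f}"
    )
    for p in reg.predictors:
        lines.append(
            f"  {p}: b = {reg.coefficients[p]:.3f}, p = {reg.pvalues[p]:.4g}, "
            f"tolerance = {reg.tolerance[p]:.3f}, VIF = {reg.vif[p]:.3f}"
        )
    lines.append("Step trace:")
    for step in reg.steps:
        lines.append(
            f"  {step['action']} {step['predictor']} "
            f"(p = {step['p']:.4g}, R^2 = {step['r_squared']:.3f})"
        )
    return "\n".join(lines) + "\n"
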