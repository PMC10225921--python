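"""End-to-end orchestration: transcripts → feature table → analysis report.

`run_features` turns a set of transcripts (from disk or a synthetic cohort)
into one row per dyad: lexicon category percents with log transforms,
interjection-adjacent POS-transition probabilities, first-person word-bigram
frequencies, and per-role token totals.  `run_analysis` joins the feature
table with per-dyad outcomes and reproduces the analysis structure:
mass-univariate feature~alliance F-regressions with FDR control, role
comparisons, trust-game correlations, duration-partialled correlations,
dependent-correlation (subscore) comparisons, and mediation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import lexicon as lx
from . import syntax as sx
from .errors import DyadlinkError, EmptyInputError, JoinError
from .stats import (
    StatsConfig,
    correlation,
    fdr_adjust,
    kruskal_wallis,
    mediate,
    paired_t,
    partial_correlation,
    steiger_z,
    univariate_f_regression,
    wilcoxon_paired,
)
from .synthetic import Cohort, CohortSpec, generate_cohort
from .transcript import Owner, Role, preprocess, read_transcript, token_stream

ROLES = ("patient", "therapist")


@dataclass
class RunConfig:
    """Configuration for a pipeline run; all randomness flows from ``seed``."""

    seed: int = 0
    lexicon_path: str | None = None
    tagger: str = "rule"                 # "rule" | "gold" (synthetic cohorts only)
    transition_mode: str = "joint"       # "joint" | "conditional"
    attribution: str = "per_speaker"     # | "dialogue_first_token"
    epsilon: float = lx.DEFAULT_EPSILON
    n_bigrams_per_role: int = 10
    stats: StatsConfig = field(default_factory=StatsConfig)
    mediation_exposures: tuple[str, ...] = ("log_therapist_i", "log_therapist_we")
    partial_features: tuple[str, ...] = ("patient_AUX-INTJ",)
    steiger_features: tuple[str, ...] = (
        "log_patient_i", "log_therapist_i", "log_therapist_we",
    )
    outcome_column: str = "alliance_patient"
    rf_column: str = "patient_mean_RF"
    duration_column: str = "log_treatment_duration"

    def lexicon(self) -> lx.Lexicon:
        if self.lexicon_path:
            return lx.Lexicon.from_json(self.lexicon_path)
        return lx.Lexicon.default()

    def fingerprint(self) -> dict:
        return {
            "seed": self.seed,
            "alpha": self.stats.alpha,
            "fdr_method": self.stats.fdr_method,
            "mediation_iterations": self.stats.mediation_iterations,
            "transition_mode": self.transition_mode,
            "attribution": self.attribution,
            "epsilon": self.epsilon,
            "tagger": self.tagger,
            "lexicon": self.lexicon_path or "builtin",
        }


def _dyad_features(transcript, cfg: RunConfig, gold=None) -> dict[str, float]:
    lex = cfg.lexicon()
    row: dict[str, float] = {}
    bigrams: dict[str, dict[str, float]] = {}
    if cfg.tagger == "gold":
        if gold is None:
            raise DyadlinkError("gold tagger requested but no gold tags available")
        tagged_dialogue = gold
    else:
        tagged_dialogue = sx.tag(token_stream(transcript, Owner.DIALOGUE), sx.RuleTagger())
    for role in ROLES:
        stream = token_stream(transcript, role)
        row[f"{role}_total_tokens"] = float(len(stream))
        for cat, pct in lx.category_percents(stream, lex).items():
            row[f"{role}_{cat}"] = pct
            row[f"log_{role}_{cat}"] = lx.log_transform(pct, cfg.epsilon)
        m = sx.transition_matrix(
            tagged_dialogue, role, mode=cfg.transition_mode, attribution=cfg.attribution
        )
        row.update(sx.interjection_features(m))
        try:
            bigrams[role] = lx.pronoun_bigrams(stream)
        except DyadlinkError:
            bigrams[role] = {}
    row["_bigrams"] = bigrams  # type: ignore[assignment]
    return row


def _select_bigram_columns(rows: list[dict], n_per_role: int) -> pd.DataFrame:
    """Keep the most frequent anchored word bigrams per role across the cohort.

    Ranked by summed frequency, ties broken alphabetically so column choice
    is deterministic.
    """
    table: dict[str, dict[int, float]] = {}
    for i, row in enumerate(rows):
        for role, bg in row["_bigrams"].items():
            for name, freq in bg.items():
                col = f"{role}_bigram_{name.replace(' ', '_')}"
                table.setdefault(col, {})[i] = freq
    keep: list[str] = []
    for role in ROLES:
        cols = [c for c in table if c.startswith(f"{role}_bigram_")]
        cols.sort(key=lambda c: (-sum(table[c].values()), c))
        keep.extend(cols[:n_per_role])
    out = pd.DataFrame(index=range(len(rows)))
    for col in keep:
        out[col] = [table[col].get(i, 0.0) for i in range(len(rows))]
    return out


def run_features(
    source: str | Path | Cohort,
    cfg: RunConfig,
) -> tuple[pd.DataFrame, list[dict]]:
    """Feature table (one row per dyad) plus a per-file error log.

    ``source`` is a directory of ``*.txt`` / ``*.json`` transcripts or a
    synthetic :class:`Cohort` (which also enables the gold-tag path).  A
    transcript that fails to parse is recorded in the error log and skipped.
    """
    errors: list[dict] = []
    rows: list[dict] = []
    ids: list[str] = []
    if isinstance(source, Cohort):
        for d in source.dyads:
            rows.append(_dyad_features(d.transcript, cfg, gold=d.gold))
            ids.append(d.dyad_id)
    else:
        paths = sorted(
            p for p in Path(source).iterdir() if p.suffix in (".txt", ".json")
        )
        if not paths:
            raise EmptyInputError(f"no transcripts found under {source}")
        for path in paths:
            try:
                t = preprocess(read_transcript(path))
                rows.append(_dyad_features(t, cfg))
                ids.append(t.dyad_id)
            except DyadlinkError as exc:
                errors.append({"file": str(path), "error": str(exc)})
    if not rows:
        raise EmptyInputError("no transcript could be parsed")
    bigram_df = _select_bigram_columns(rows, cfg.n_bigrams_per_role)
    for row in rows:
        row.pop("_bigrams")
    df = pd.DataFrame(rows, index=ids)
    df.index.name = "dyad_id"
    bigram_df.index = df.index
    df = pd.concat([df, bigram_df], axis=1)
    return df.reindex(sorted(df.columns), axis=1), errors


def _regression_features(features: pd.DataFrame) -> list[str]:
    """Feature columns entering the mass-univariate regression family:
    log lexicon percents, transition probabilities, and word bigrams."""
    cols = []
    for c in features.columns:
        if c.startswith("log_") or "-INTJ" in c or "INTJ-" in c or "_bigram_" in c:
            cols.append(c)
    return sorted(cols)


def run_analysis(
    features: pd.DataFrame,
    outcomes: pd.DataFrame,
    cfg: RunConfig,
) -> dict:
    """Full analysis report as a JSON-serializable dictionary."""
    missing_f = sorted(set(outcomes.index) - set(features.index))
    missing_o = sorted(set(features.index) - set(outcomes.index))
    if missing_f or missing_o:
        raise JoinError(
            f"unmatched dyad_ids (features-only: {missing_o}, outcomes-only: {missing_f})",
            offenders=missing_f + missing_o,
        )
    outcomes = outcomes.loc[features.index]
    y = outcomes[cfg.outcome_column].to_numpy(dtype=float)
    rf = outcomes[cfg.rf_column].to_numpy(dtype=float)
    alpha = cfg.stats.alpha

    # (i) mass-univariate regressions with one BH family
    reg_cols = _regression_features(features)
    regressions = []
    for col in reg_cols:
        x = features[col].to_numpy(dtype=float)
        if np.std(x) == 0:
            continue
        regressions.append(univariate_f_regression(x, y, name=col, alpha=alpha))
    qs = fdr_adjust([r.p for r in regressions], method=cfg.stats.fdr_method)
    for r, q in zip(regressions, qs):
        r.q = float(q)

    # (ii) role comparisons: paired t on log lexicon, signed-rank on transitions
    comparisons = []
    for cat in sorted(cfg.lexicon().categories):
        pc, tc = f"log_patient_{cat}", f"log_therapist_{cat}"
        if pc in features and tc in features:
            comparisons.append(
                paired_t(features[pc], features[tc], name=f"{cat} (patient-therapist)")
            )
    for suffix in sorted({c.split("_", 1)[1] for c in features.columns if "INTJ" in c}):
        pc, tc = f"patient_{suffix}", f"therapist_{suffix}"
        if pc in features and tc in features:
            pv = features[pc].to_numpy(dtype=float)
            tv = features[tc].to_numpy(dtype=float)
            if np.any(pv != tv):
                comparisons.append(
                    wilcoxon_paired(pv, tv, name=f"{suffix} (patient-therapist)")
                )

    # (iii) correlations with the trust game
    game_corr = []
    for cat in sorted(cfg.lexicon().categories):
        for role in ROLES:
            col = f"log_{role}_{cat}"
            if col in features and np.std(features[col]) > 0:
                game_corr.append(
                    correlation(features[col], rf, method="pearson",
                                name=f"{col} ~ mean_RF", alpha=alpha)
                )
    for col in sorted(c for c in features.columns if "AUX-INTJ" in c):
        if np.std(features[col]) > 0:
            game_corr.append(
                correlation(features[col], rf, method="spearman",
                            name=f"{col} ~ mean_RF", alpha=alpha)
            )
    game_corr.append(
        correlation(rf, y, method="pearson", name="mean_RF ~ alliance", alpha=alpha)
    )

    # (iv) duration-partialled correlations
    partials = []
    if cfg.duration_column in outcomes:
        z = outcomes[cfg.duration_column].to_numpy(dtype=float)
        for col in cfg.partial_features:
            if col in features and np.std(features[col]) > 0:
                partials.append(
                    partial_correlation(
                        features[col], y, z, method="spearman",
                        name=f"{col} ~ alliance | duration", alpha=alpha,
                    )
                )

    # (v) dependent-correlation comparisons across alliance subscores
    steiger = []
    sub_cols = [c for c in ("goal", "task", "bond") if c in outcomes]
    n = len(features)
    for col in cfg.steiger_features:
        if col not in features or np.std(features[col]) == 0:
            continue
        x = features[col].to_numpy(dtype=float)
        rs = {s: correlation(x, outcomes[s], method="pearson").estimate for s in sub_cols}
        for s1, s2 in [("goal", "task"), ("goal", "bond"), ("task", "bond")]:
            if s1 in rs and s2 in rs:
                r_kh = correlation(outcomes[s1], outcomes[s2], method="pearson").estimate
                steiger.append(
                    steiger_z(rs[s1], rs[s2], r_kh, n, name=f"{col}: {s1} vs {s2}")
                )

    # (vi) Kruskal-Wallis across categorical clinical variables
    kw = []
    for cat_col in ("clinic", "diagnosis"):
        if cat_col in outcomes and outcomes[cat_col].nunique() > 1:
            kw.append(
                kruskal_wallis(y, outcomes[cat_col].to_numpy(), name=f"alliance ~ {cat_col}")
            )

    # (vii) mediation: exposure → mean RF → alliance
    mediations = []
    med_cfg = StatsConfig(
        alpha=alpha, fdr_method=cfg.stats.fdr_method,
        mediation_iterations=cfg.stats.mediation_iterations,
        seed=cfg.seed,
    )
    for col in cfg.mediation_exposures:
        if col in features and np.std(features[col]) > 0:
            mediations.append(
                mediate(features[col], rf, y, med_cfg,
                        exposure=col, mediator=cfg.rf_column, outcome=cfg.outcome_column)
            )

    return {
        "config": cfg.fingerprint(),
        "n_dyads": int(len(features)),
        "regressions": [r.to_dict() for r in regressions],
        "role_comparisons": [r.to_dict() for r in comparisons],
        "game_correlations": [r.to_dict() for r in game_corr],
        "partial_correlations": [r.to_dict() for r in partials],
        "steiger": [r.to_dict() for r in steiger],
        "kruskal_wallis": [r.to_dict() for r in kw],
        "mediation": [m.to_dict() for m in mediations],
    }


def _denan(obj):
    """Replace NaN/inf with None so the report is strict JSON."""
    if isinstance(obj, dict):
        return {k: _denan(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_denan(v) for v in obj]
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def report_to_frame(report: dict) -> pd.DataFrame:
    """Flatten a report into one row per (section, test) for CSV export."""
    rows = []
    for section in ("regressions", "role_comparisons", "game_correlations",
                    "partial_correlations", "steiger", "kruskal_wallis"):
        for rec in report[section]:
            rows.append({"section": section, **rec})
    for rec in report["mediation"]:
        rows.append(
            {
                "section": "mediation",
                "name": f"{rec['exposure']} -> {rec['mediator']} -> {rec['outcome']}",
                "method": "quasi_bayesian_mediation",
                "estimate": rec["indirect"],
                "p": rec["p_indirect"],
                "ci_low": rec["ci_low"],
                "ci_high": rec["ci_high"],
                "n": None,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(
    cfg: RunConfig,
    out_dir: str | Path,
    cohort_spec: CohortSpec | None = None,
    transcript_dir: str | Path | None = None,
    outcomes_path: str | Path | None = None,
) -> dict:
    """simulate (optional) → extract → analyze → write a report bundle.

    Writes features.csv, outcomes.csv, report.json, report.csv and
    manifest.json under ``out_dir``; byte-reproducible for a fixed seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if cohort_spec is not None:
        spec = cohort_spec
        cohort = generate_cohort(spec, seed=cfg.seed)
        cohort.save(out / "cohort")
        features, errors = run_features(cohort, cfg)
        outcomes = cohort.outcomes
    else:
        if transcript_dir is None or outcomes_path is None:
            raise DyadlinkError("need either a cohort spec or transcripts + outcomes")
        features, errors = run_features(transcript_dir, cfg)
        outcomes = pd.read_csv(outcomes_path, index_col="dyad_id")
    features.to_csv(out / "features.csv", float_format="%.12g")
    outcomes.to_csv(out / "outcomes.csv", float_format="%.12g")
    report = run_analysis(features, outcomes, cfg)
    report["feature_extraction_errors"] = errors
    (out / "report.json").write_text(
        json.dumps(_denan(report), indent=1, sort_keys=True), encoding="utf-8"
    )
    report_to_frame(report).to_csv(out / "report.csv", index=False, float_format="%.12g")
    manifest = {"config": cfg.fingerprint(), "n_dyads": report["n_dyads"]}
    if cohort_spec is not None:
        manifest["cohort_fingerprint"] = cohort_spec.fingerprint()
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True), encoding="utf-8"
    )
    return report
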