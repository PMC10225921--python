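"""Synthetic dyad cohorts with known planted structure.

Every downstream stage — lexicon features, POS transitions, trust game,
regressions, mediation — can be validated against ground truth recorded at
generation time.  Transcripts are emitted from a template-free token-level
grammar: at each position a word-category draw (first/second/third-person
pronouns, filler words) competes with a small first-order Markov chain over
content part-of-speech tags; a filler "like" can follow an auxiliary or
adverb, planting AUX-INTJ / ADV-INTJ transition structure.  Gold UPOS tags
are recorded at emission time.

Outcomes are planted linearly on log-features: the working-alliance total
(bounded 12..84, with goal/task/bond subscores) depends on the planted
slopes plus Gaussian noise, and a mediation chain routes part of the
therapist first-person-singular effect through the patient's mean trust-game
repayment fraction.  Default rates mirror the cohort means the study design
targets (e.g. patient "i" 10.3%, therapist "i" 3.3%).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import SpecError
from .lexicon import DEFAULT_EPSILON, Lexicon, log_transform
from .syntax import UPOS_TAGS, TaggedSequence, gold_tagged_sequence
from .transcript import Role, Transcript, Utterance, preprocess
from .trustgame import (
    FractionTrustee,
    InvestorReference,
    KNNInvestor,
    TrustGameSession,
    play_session,
)

# words emitted per category (weights favour the high-frequency members)
CATEGORY_WORDS: dict[str, tuple[tuple[str, float], ...]] = {
    "i": (("i", 0.55), ("my", 0.12), ("me", 0.12), ("i'm", 0.08),
          ("myself", 0.04), ("i've", 0.04), ("i'll", 0.03), ("mine", 0.02)),
    "we": (("we", 0.45), ("our", 0.15), ("us", 0.15), ("let's", 0.10),
           ("we're", 0.10), ("we've", 0.05)),
    "you": (("you", 0.60), ("your", 0.20), ("you're", 0.12), ("yourself", 0.08)),
    "shehe": (("she", 0.30), ("he", 0.30), ("her", 0.20), ("him", 0.10), ("his", 0.10)),
    "they": (("they", 0.50), ("them", 0.25), ("their", 0.25)),
    "nonfluent": (("um", 0.35), ("uh", 0.25), ("hmm", 0.15), ("umm", 0.10),
                  ("uhh", 0.08), ("er", 0.04), ("mm", 0.03)),
}
CATEGORY_TAGS = {"i": "PRON", "we": "PRON", "you": "PRON", "shehe": "PRON",
                 "they": "PRON", "nonfluent": "INTJ"}

# content vocabulary per tag; deliberately disjoint from every lexicon
# category and from the filler "like"
CONTENT_WORDS: dict[str, tuple[str, ...]] = {
    "NOUN": ("therapy", "week", "work", "day", "family", "sleep", "job",
             "thing", "time", "feeling", "session", "stress", "home"),
    "VERB": ("went", "feel", "think", "know", "talked", "said", "want",
             "tried", "happened", "worry", "started"),
    "AUX": ("was", "is", "been", "are", "do", "did", "have", "can",
            "would", "could"),
    "DET": ("the", "a", "this"),
    "ADJ": ("good", "hard", "anxious", "tired", "better", "difficult"),
    "ADV": ("really", "just", "very", "so", "then", "maybe", "again"),
    "ADP": ("in", "on", "with", "about", "at", "for"),
    "SCONJ": ("because", "if", "when", "that"),
    "CCONJ": ("and", "but", "or"),
    "PART": ("not", "to"),
    "NUM": ("two", "three", "five"),
    "INTJ": ("yeah", "oh", "okay"),
}
CONTENT_TAGS = tuple(CONTENT_WORDS)

# first-order Markov weights over content tags (row: previous tag; START for
# the utterance opening).  INTJ rows plant INTJ-PRON / INTJ-SCONJ structure
# via the follow-up category draw and SCONJ weight.
_CHAIN_ROWS: dict[str, dict[str, float]] = {
    "START": {"INTJ": 2, "ADV": 2, "SCONJ": 1, "DET": 2, "AUX": 1, "VERB": 1,
              "NOUN": 1, "CCONJ": 1},
    "NOUN": {"AUX": 4, "VERB": 3, "ADP": 2, "CCONJ": 2, "SCONJ": 1, "ADV": 1},
    "VERB": {"DET": 3, "ADP": 2, "ADV": 2, "NOUN": 2, "PART": 1, "SCONJ": 1},
    "AUX": {"VERB": 3, "ADV": 2, "ADJ": 2, "PART": 1, "DET": 1},
    "DET": {"NOUN": 6, "ADJ": 2},
    "ADJ": {"NOUN": 3, "CCONJ": 1, "SCONJ": 1, "ADP": 1},
    "ADV": {"ADJ": 2, "VERB": 2, "AUX": 1, "ADV": 1, "ADP": 1},
    "ADP": {"DET": 3, "NOUN": 3, "NUM": 1},
    "SCONJ": {"DET": 2, "NOUN": 2, "AUX": 1, "ADV": 1},
    "CCONJ": {"DET": 2, "NOUN": 2, "VERB": 2, "ADV": 1},
    "PART": {"VERB": 4, "ADJ": 1},
    "NUM": {"NOUN": 4},
    "INTJ": {"SCONJ": 2, "DET": 2, "NOUN": 2, "AUX": 1, "ADV": 1},
    "PRON": {"AUX": 4, "VERB": 3, "ADV": 1},
}


def _normalized_chain() -> dict[str, tuple[np.ndarray, np.ndarray]]:
    out = {}
    for state, row in _CHAIN_ROWS.items():
        tags = np.array(sorted(row), dtype=object)
        w = np.array([row[t] for t in tags], dtype=float)
        out[state] = (tags, w / w.sum())
    return out


_CHAIN = _normalized_chain()


@dataclass
class CohortSpec:
    """Study-condition parameters for a synthetic cohort.

    Category rates are percentages of each speaker's total word count; the
    planted slopes act on the natural-log features used downstream.
    """

    n_dyads: int = 28
    seed: int = 0
    tokens_mean: Mapping[str, int] = field(
        default_factory=lambda: {"patient": 4500, "therapist": 2500}
    )
    tokens_dispersion: float = 0.15          # lognormal sigma on session length
    utterance_mean_tokens: float = 14.0
    category_rates: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "patient": {"i": 10.3, "we": 0.517, "you": 1.6, "shehe": 1.2,
                        "they": 1.0, "nonfluent": 2.12},
            "therapist": {"i": 3.30, "we": 0.994, "you": 3.0, "shehe": 0.8,
                          "they": 0.7, "nonfluent": 2.79},
        }
    )
    rate_jitter_cv: float = 0.15             # inter-dyad lognormal spread of rates
    like_rate: Mapping[str, float] = field(   # P(filler "like" | prev tag AUX/ADV)
        default_factory=lambda: {"patient": 0.08, "therapist": 0.05}
    )
    # alliance plant: intercept + sum slope * log-feature + noise, clip 12..84
    alliance_intercept: float = 72.0
    planted_slopes: Mapping[str, float] = field(
        default_factory=lambda: {
            "log_therapist_i": -5.0,
            "log_therapist_we": -2.0,
            "log_patient_i": -4.0,
            "log_patient_nonfluent": 3.0,
        }
    )
    alliance_noise_sd: float = 6.0
    # mediation plant: mean_RF = rf_intercept + a * log_therapist_i + noise
    mediation_exposure: str = "log_therapist_i"
    rf_intercept: float = 0.95
    rf_slope_a: float = -0.40
    rf_noise_sd: float = 0.10
    rf_alliance_slope_b: float = 30.0
    # subscores: near-equal thirds, with a bond-vs-goal tilt on one feature
    subscore_tilt_feature: str = "log_patient_i"
    subscore_tilt: float = -1.0
    subscore_noise_sd: float = 0.8
    # covariates
    duration_median: float = 14.5
    duration_log_sd: float = 1.0
    duration_confounder_rho: float = 0.4     # corr(log duration, patient AUX-INTJ)
    duration_alliance_slope: float = 2.0     # per log-session unit
    epsilon: float = DEFAULT_EPSILON
    trust_k: int = 5

    def validate(self) -> None:
        if self.n_dyads < 4:
            raise SpecError("need at least 4 dyads")
        if self.alliance_noise_sd < 0 or self.rf_noise_sd < 0:
            raise SpecError("noise sd must be non-negative")
        for role, rates in self.category_rates.items():
            for cat, r in rates.items():
                if not 0 <= r <= 100:
                    raise SpecError(f"{role} {cat} rate {r} outside [0, 100]")
            if sum(rates.values()) > 100:
                raise SpecError(f"{role} category rates sum above 100%")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["tokens_mean"] = dict(self.tokens_mean)
        d["category_rates"] = {r: dict(v) for r, v in self.category_rates.items()}
        d["like_rate"] = dict(self.like_rate)
        d["planted_slopes"] = dict(self.planted_slopes)
        return d

    def fingerprint(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class SyntheticDyad:
    dyad_id: str
    transcript: Transcript
    gold: TaggedSequence
    true_features: dict[str, float]
    covariates: dict


def _draw_word(pairs, rng: np.random.Generator) -> str:
    words = [w for w, _ in pairs]
    probs = np.array([p for _, p in pairs])
    return words[rng.choice(len(words), p=probs / probs.sum())]


def generate_transcript(
    spec: CohortSpec,
    dyad_id: str,
    rng: np.random.Generator,
    rates: Mapping[str, Mapping[str, float]] | None = None,
    like_rate: Mapping[str, float] | None = None,
) -> SyntheticDyad:
    """Emit one dyad's alternating-utterance transcript with gold tags.

    ``rates`` and ``like_rate`` default to the spec targets; the cohort
    generator passes per-dyad jittered values.  True feature values are the
    emission-time category and tag-bigram counts.
    """
    spec.validate()
    rates = rates or spec.category_rates
    like_rate = like_rate or spec.like_rate
    n_target = {
        role: max(10, int(round(spec.tokens_mean[role]
                                * rng.lognormal(0.0, spec.tokens_dispersion))))
        for role in ("patient", "therapist")
    }
    cats = sorted(CATEGORY_WORDS)
    cat_probs = {
        role: np.array([rates[role].get(c, 0.0) / 100.0 for c in cats])
        for role in ("patient", "therapist")
    }
    emitted = {role: 0 for role in n_target}
    utterances: list[Utterance] = []
    gold_items: list[tuple[str, str, str, int]] = []
    cat_counts = {role: {c: 0 for c in cats} for role in n_target}
    prev_tag_by_role: dict[str, str | None] = {"patient": None, "therapist": None}
    role_cycle = ("patient", "therapist")
    turn = 0
    while any(emitted[r] < n_target[r] for r in n_target):
        role = role_cycle[turn % 2]
        turn += 1
        if emitted[role] >= n_target[role]:
            continue
        n_utt = min(
            1 + rng.poisson(spec.utterance_mean_tokens - 1),
            n_target[role] - emitted[role],
        )
        words: list[str] = []
        chain_state = "START"
        prev_tag: str | None = None
        idx = len(utterances)
        for _ in range(n_utt):
            p = cat_probs[role]
            if prev_tag in ("AUX", "ADV") and rng.random() < like_rate[role]:
                word, tag_ = "like", "INTJ"
            else:
                u = rng.random()
                cum = np.cumsum(p)
                pick = int(np.searchsorted(cum, u))
                if pick < len(cats) and u < cum[-1]:
                    cat = cats[pick]
                    word = _draw_word(CATEGORY_WORDS[cat], rng)
                    tag_ = CATEGORY_TAGS[cat]
                    cat_counts[role][cat] += 1
                else:
                    tags_, probs_ = _CHAIN[chain_state]
                    tag_ = str(tags_[rng.choice(len(tags_), p=probs_)])
                    wlist = CONTENT_WORDS[tag_]
                    word = wlist[rng.integers(0, len(wlist))]
            words.append(word)
            gold_items.append((word, tag_, role, idx))
            chain_state = tag_ if tag_ in _CHAIN else "START"
            prev_tag = tag_
        emitted[role] += n_utt
        utterances.append(Utterance(Role(role), idx, " ".join(words)))
    transcript = preprocess(Transcript(dyad_id, utterances))
    gold = gold_tagged_sequence(gold_items)
    true_features = _truth_from_emission(cat_counts, gold_items, spec.epsilon)
    return SyntheticDyad(dyad_id, transcript, gold, true_features, covariates={})


def _truth_from_emission(cat_counts, gold_items, epsilon: float) -> dict[str, float]:
    """Ground-truth features from emission-time counts (naive counting,
    independent of the extraction modules)."""
    out: dict[str, float] = {}
    totals = {"patient": 0, "therapist": 0}
    for _, _, role, _ in gold_items:
        totals[role] += 1
    for role, counts in cat_counts.items():
        for cat, c in sorted(counts.items()):
            pct = 100.0 * c / totals[role] if totals[role] else 0.0
            out[f"{role}_{cat}"] = pct
            out[f"log_{role}_{cat}"] = log_transform(pct, epsilon)
    # per-speaker joint tag-bigram probabilities over concatenated sequences
    for role in ("patient", "therapist"):
        tags = [t for _, t, r, _ in gold_items if r == role]
        pairs: dict[tuple[str, str], int] = {}
        for a, b in zip(tags, tags[1:]):
            pairs[(a, b)] = pairs.get((a, b), 0) + 1
        total = max(1, len(tags) - 1)
        for t_ in UPOS_TAGS:
            out[f"{role}_{t_}-INTJ"] = pairs.get((t_, "INTJ"), 0) / total
            out[f"{role}_INTJ-{t_}"] = pairs.get(("INTJ", t_), 0) / total
    out["patient_total_tokens"] = float(totals["patient"])
    out["therapist_total_tokens"] = float(totals["therapist"])
    return out


def _jittered_rates(spec: CohortSpec, rng: np.random.Generator):
    cv = spec.rate_jitter_cv
    rates = {}
    for role, base in spec.category_rates.items():
        row = {}
        for cat, r in sorted(base.items()):
            if cv > 0 and r > 0:
                # mean-preserving lognormal multiplier
                mult = rng.lognormal(-0.5 * np.log(1 + cv**2), np.sqrt(np.log(1 + cv**2)))
                row[cat] = min(100.0, r * mult)
            else:
                row[cat] = r
        # keep the draw feasible
        s = sum(row.values())
        if s > 100:
            row = {c: v * 100.0 / s for c, v in row.items()}
        rates[role] = row
    like = {
        role: float(np.clip(lr * rng.lognormal(-0.5 * np.log(1.25), np.sqrt(np.log(1.25))), 0, 1))
        if spec.rate_jitter_cv > 0 else lr
        for role, lr in sorted(spec.like_rate.items())
    }
    return rates, like


@dataclass
class Cohort:
    spec: CohortSpec
    dyads: list[SyntheticDyad]
    features: pd.DataFrame       # ground-truth feature table, dyad_id index
    outcomes: pd.DataFrame       # alliance, subscores, mean RF, covariates
    sessions: dict[str, dict[str, TrustGameSession]]
    manifest: dict

    def save(self, out_dir: str | Path) -> None:
        from .transcript import to_prefixed_lines

        out = Path(out_dir)
        (out / "transcripts").mkdir(parents=True, exist_ok=True)
        for d in self.dyads:
            (out / "transcripts" / f"{d.dyad_id}.txt").write_text(
                to_prefixed_lines(d.transcript), encoding="utf-8"
            )
            tags = pd.DataFrame(
                [(tok, tg, r, i) for tok, tg, r, i in d.gold.items],
                columns=["token", "tag", "role", "utterance"],
            )
            tags.to_csv(out / "transcripts" / f"{d.dyad_id}.tags.csv", index=False)
        self.features.to_csv(out / "features_truth.csv")
        self.outcomes.to_csv(out / "outcomes.csv")
        (out / "manifest.json").write_text(
            json.dumps(self.manifest, indent=1, sort_keys=True), encoding="utf-8"
        )


def plant_outcomes(
    features: pd.DataFrame, spec: CohortSpec, rng: np.random.Generator
) -> pd.DataFrame:
    """Plant alliance and trust-game outcomes on an extracted feature table.

    mean_RF follows the mediation chain (exposure → RF), alliance combines
    the planted log-feature slopes, the RF→alliance path, the duration
    covariate, and Gaussian noise, then is clipped to the instrument range
    12..84.  Subscores split the total into near-thirds with a planted
    bond-vs-goal tilt.  Values are kept continuous so noiseless slope
    recovery is exact.
    """
    spec.validate()
    n = len(features)
    idx = features.index
    exposure = features[spec.mediation_exposure].to_numpy(dtype=float)
    mean_rf_target = np.clip(
        spec.rf_intercept + spec.rf_slope_a * exposure
        + rng.normal(0.0, spec.rf_noise_sd, size=n),
        0.02, 0.98,
    )
    # duration confounded with the patient AUX-INTJ transition feature
    aux = features.get("patient_AUX-INTJ")
    if aux is not None and np.std(aux.to_numpy()) > 0:
        zaux = (aux - aux.mean()) / aux.std()
        latent = (spec.duration_confounder_rho * zaux.to_numpy()
                  + np.sqrt(max(0.0, 1 - spec.duration_confounder_rho**2))
                  * rng.normal(size=n))
    else:
        latent = rng.normal(size=n)
    log_duration = np.log(spec.duration_median) + spec.duration_log_sd * latent
    duration = np.clip(np.rint(np.exp(log_duration)), 1, 300).astype(int)

    alliance = np.full(n, spec.alliance_intercept, dtype=float)
    for feat, slope in sorted(spec.planted_slopes.items()):
        if feat not in features.columns:
            raise SpecError(f"planted slope names unknown feature {feat!r}")
        alliance = alliance + slope * features[feat].to_numpy(dtype=float)
    alliance = alliance + spec.rf_alliance_slope_b * (mean_rf_target - mean_rf_target.mean())
    alliance = alliance + spec.duration_alliance_slope * (log_duration - log_duration.mean())
    alliance = alliance + rng.normal(0.0, spec.alliance_noise_sd, size=n)
    alliance = np.clip(alliance, 12.0, 84.0)

    base = alliance / 3.0
    tilt_feat = features.get(spec.subscore_tilt_feature)
    if tilt_feat is not None and np.std(tilt_feat.to_numpy()) > 0:
        zt = ((tilt_feat - tilt_feat.mean()) / tilt_feat.std()).to_numpy()
    else:
        zt = np.zeros(n)
    delta = spec.subscore_tilt * zt + rng.normal(0.0, spec.subscore_noise_sd, size=n)
    eps2 = rng.normal(0.0, spec.subscore_noise_sd, size=n)
    bond = np.clip(base + delta, 4.0, 28.0)
    goal = np.clip(base - delta + eps2, 4.0, 28.0)
    task = np.clip(alliance - bond - goal, 4.0, 28.0)

    therapist_alliance = np.clip(
        0.6 * alliance + 0.4 * alliance.mean() + rng.normal(0.0, 5.0, size=n),
        12.0, 84.0,
    )
    therapist_rf = np.clip(0.55 + rng.normal(0.0, 0.12, size=n), 0.02, 0.98)

    clinic = np.where(rng.random(n) < 0.21, "personality_specialized", "general")
    diagnosis = rng.choice(
        np.array(["personality", "mood", "anxiety_trauma"], dtype=object),
        size=n, p=[0.54, 0.25, 0.21],
    )
    return pd.DataFrame(
        {
            "alliance_patient": alliance,
            "goal": goal,
            "task": task,
            "bond": bond,
            "alliance_therapist": therapist_alliance,
            "patient_mean_RF_target": mean_rf_target,
            "therapist_mean_RF_target": therapist_rf,
            "treatment_duration": duration,
            "log_treatment_duration": log_duration,
            "clinic": clinic,
            "diagnosis": diagnosis,
        },
        index=idx,
    )


def generate_cohort(spec: CohortSpec, seed: int | None = None) -> Cohort:
    """Generate the full cohort bundle: transcripts, truth, outcomes, games."""
    spec.validate()
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    dyads: list[SyntheticDyad] = []
    rows = []
    for i in range(spec.n_dyads):
        rates, like = _jittered_rates(spec, rng)
        dyad = generate_transcript(spec, f"dyad{i:03d}", rng, rates=rates, like_rate=like)
        dyads.append(dyad)
        rows.append(dyad.true_features)
    features = pd.DataFrame(rows, index=[d.dyad_id for d in dyads])
    features.index.name = "dyad_id"
    outcomes = plant_outcomes(features, spec, rng)

    ref = InvestorReference.synthetic(rng, k=spec.trust_k)
    sessions: dict[str, dict[str, TrustGameSession]] = {}
    realized = {"patient": [], "therapist": []}
    for d in dyads:
        sessions[d.dyad_id] = {}
        for role, col in (("patient", "patient_mean_RF_target"),
                          ("therapist", "therapist_mean_RF_target")):
            target = float(outcomes.loc[d.dyad_id, col])
            s = play_session(
                KNNInvestor(ref), FractionTrustee(target), rng,
                dyad_id=d.dyad_id, player_role=role,
            )
            sessions[d.dyad_id][role] = s
            realized[role].append(s.mean_rf)
    outcomes["patient_mean_RF"] = realized["patient"]
    outcomes["therapist_mean_RF"] = realized["therapist"]
    manifest = {
        "seed": seed,
        "n_dyads": spec.n_dyads,
        "spec": spec.to_dict(),
        "spec_fingerprint": spec.fingerprint(),
    }
    return Cohort(spec, dyads, features, outcomes, sessions, manifest)
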