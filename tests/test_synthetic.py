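"""Synthetic cohort generator: determinism, fidelity, self-consistency."""

import numpy as np
import pytest

from dyadlink import (
    CohortSpec,
    RunConfig,
    SpecError,
    generate_cohort,
    generate_transcript,
    plant_outcomes,
    run_features,
    univariate_f_regression,
)
from dyadlink.synthetic import _jittered_rates


def small_spec(**kw):
    base = dict(
        n_dyads=8,
        tokens_mean={"patient": 600, "therapist": 400},
        seed=11,
    )
    base.update(kw)
    return CohortSpec(**base)


class TestGenerateTranscript:
    def test_degenerate_full_i_rate(self, rng, lexicon):
        spec = small_spec(
            category_rates={
                "patient": {"i": 100.0},
                "therapist": {"i": 100.0},
            },
            rate_jitter_cv=0.0,
            like_rate={"patient": 0.0, "therapist": 0.0},
        )
        d = generate_transcript(spec, "d0", rng)
        i_words = lexicon.categories["i"]
        for u in d.transcript.utterances:
            assert all(tok in i_words for tok in u.tokens)

    def test_rate_within_binomial_se(self, lexicon):
        spec = small_spec(
            tokens_mean={"patient": 10_000, "therapist": 10},
            category_rates={
                "patient": {"nonfluent": 20.0},
                "therapist": {"nonfluent": 20.0},
            },
            rate_jitter_cv=0.0,
        )
        d = generate_transcript(spec, "d0", np.random.default_rng(3))
        toks = [tok for u in d.transcript.utterances
                if u.speaker_role.value == "patient" for tok in u.tokens]
        hits = sum(t in lexicon.categories["nonfluent"] for t in toks)
        rate = hits / len(toks)
        se = np.sqrt(0.2 * 0.8 / len(toks))
        assert abs(rate - 0.2) <= 3 * se

    def test_same_seed_identical(self):
        spec = small_spec()
        a = generate_transcript(spec, "d0", np.random.default_rng(5))
        b = generate_transcript(spec, "d0", np.random.default_rng(5))
        assert [u.tokens for u in a.transcript.utterances] == [
            u.tokens for u in b.transcript.utterances
        ]
        assert a.gold.items == b.gold.items

    def test_infeasible_rates_rejected(self, rng):
        spec = small_spec(
            category_rates={"patient": {"i": 70.0, "we": 40.0}, "therapist": {"i": 1.0}}
        )
        with pytest.raises(SpecError):
            generate_transcript(spec, "d0", rng)

    def test_utterance_indices_strictly_increasing(self, rng):
        d = generate_transcript(small_spec(), "d0", rng)
        idx = [u.index for u in d.transcript.utterances]
        assert idx == sorted(set(idx))


class TestPlantOutcomes:
    def feature_frame(self, seed=1, n=40):
        spec = small_spec(n_dyads=n, seed=seed)
        return generate_cohort(spec).features, spec

    def test_zero_slopes_zero_noise_constant(self):
        features, spec = self.feature_frame()
        spec.planted_slopes = {}
        spec.alliance_noise_sd = 0.0
        spec.rf_alliance_slope_b = 0.0
        spec.duration_alliance_slope = 0.0
        out = plant_outcomes(features, spec, np.random.default_rng(0))
        assert out["alliance_patient"].nunique() == 1

    def test_noiseless_slope_recovered_exactly(self):
        features, spec = self.feature_frame()
        spec.planted_slopes = {"log_therapist_i": -5.0}
        spec.alliance_noise_sd = 0.0
        spec.rf_alliance_slope_b = 0.0
        spec.duration_alliance_slope = 0.0
        out = plant_outcomes(features, spec, np.random.default_rng(0))
        fit = univariate_f_regression(
            features["log_therapist_i"], out["alliance_patient"]
        )
        assert fit.estimate == pytest.approx(-5.0, abs=1e-9)

    def test_planted_correlation_recovered_on_average(self):
        # noise sd chosen so that corr(log feature, alliance) targets -0.6
        features, spec = self.feature_frame(n=28)
        spec.planted_slopes = {"log_therapist_i": -5.0}
        spec.rf_alliance_slope_b = 0.0
        spec.duration_alliance_slope = 0.0
        x = features["log_therapist_i"].to_numpy()
        target_r = -0.6
        spec.alliance_noise_sd = float(
            5.0 * x.std() * np.sqrt(1 / target_r**2 - 1)
        )
        rng = np.random.default_rng(7)
        rs = []
        for _ in range(100):
            out = plant_outcomes(features, spec, rng)
            rs.append(np.corrcoef(x, out["alliance_patient"])[0, 1])
        assert abs(np.mean(rs) - target_r) < 0.1

    def test_negative_noise_rejected(self):
        features, spec = self.feature_frame()
        spec.alliance_noise_sd = -1.0
        with pytest.raises(SpecError):
            plant_outcomes(features, spec, np.random.default_rng(0))

    def test_alliance_within_instrument_range(self):
        features, spec = self.feature_frame()
        out = plant_outcomes(features, spec, np.random.default_rng(0))
        assert out["alliance_patient"].between(12, 84).all()
        for s in ("goal", "task", "bond"):
            assert out[s].between(4, 28).all()


class TestGenerateCohort:
    def test_cohort_shape_and_manifest(self):
        spec = small_spec(n_dyads=28)
        cohort = generate_cohort(spec)
        assert len(cohort.dyads) == 28
        assert cohort.features.shape[0] == 28
        assert cohort.manifest["spec_fingerprint"] == spec.fingerprint()

    def test_seeded_determinism_bundle(self, tmp_path):
        spec = small_spec()
        a, b = generate_cohort(spec), generate_cohort(spec)
        assert a.features.equals(b.features)
        assert a.outcomes.equals(b.outcomes)
        (tmp_path / "a").mkdir(), (tmp_path / "b").mkdir()
        a.save(tmp_path / "a"), b.save(tmp_path / "b")
        for p in sorted((tmp_path / "a").rglob("*")):
            if p.is_file():
                q = tmp_path / "b" / p.relative_to(tmp_path / "a")
                assert p.read_bytes() == q.read_bytes()

    def test_extracted_features_equal_truth(self):
        cohort = generate_cohort(small_spec())
        feats, errors = run_features(cohort, RunConfig(tagger="gold"))
        assert not errors
        common = [c for c in cohort.features.columns if c in feats.columns]
        assert len(common) > 40
        diff = (cohort.features[common] - feats[common]).abs().to_numpy().max()
        assert diff == 0.0

    def test_realized_mean_rf_tracks_target(self):
        cohort = generate_cohort(small_spec(n_dyads=20))
        out = cohort.outcomes
        err = (out["patient_mean_RF"] - out["patient_mean_RF_target"]).abs()
        # integer repayments of offers up to 20 round RF to within ~1/6 per round
        assert err.max() < 0.05

    def test_distributional_fidelity_across_cohort(self):
        spec = small_spec(n_dyads=200, seed=2)
        cohort = generate_cohort(spec)
        for role in ("patient", "therapist"):
            for cat, target in spec.category_rates[role].items():
                vals = cohort.features[f"{role}_{cat}"]
                se = vals.std() / np.sqrt(len(vals))
                assert abs(vals.mean() - target) <= 3 * se + 1e-9


def test_jittered_rates_feasible(rng):
    spec = small_spec(rate_jitter_cv=0.8)
    for _ in range(50):
        rates, like = _jittered_rates(spec, rng)
        for role, row in rates.items():
            assert sum(row.values()) <= 100.0 + 1e-9
            assert all(0 <= v <= 100 for v in row.values())
        assert all(0 <= v <= 1 for v in like.values())
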