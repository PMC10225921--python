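# dyadlink

Dyadic language features, trust-game behavior, and therapeutic-alliance
analysis.

Psychotherapy outcomes depend on the working alliance between patient and
therapist, yet alliance is usually measured only by post-session
questionnaires.  `dyadlink` implements a reproducible pipeline for an
alternative, computational view of the dyad: it extracts interpretable
speech markers from two-speaker session transcripts — first-person pronoun
frequencies ("i", "we" word categories as percent of each speaker's
words), filler-word non-fluency rates, and part-of-speech bigram
transition probabilities that start or end with an interjection
(AUX-INTJ, INTJ-PRON, ...) — scores a ten-round trustee-role trust game
with a k-nearest-neighbour simulated investor (repayment fraction
RF_t = R_t / 3·I_t, averaged over rounds), and relates all of it to
alliance ratings (total and goal/task/bond subscores).

The statistical layer covers the full analysis structure:

- mass-univariate OLS with F(1, n−2) tests and Benjamini–Hochberg FDR,
  on ln(percent + ε) transformed features;
- Pearson/Spearman correlations, duration-partialled correlations, and
  Steiger's Z for dependent correlations sharing a variable;
- paired t, exact tie-aware Wilcoxon signed-rank, rank-sum, and
  Kruskal–Wallis comparisons;
- quasi-Bayesian mediation: OLS fits of m ~ x and y ~ x + m, 1,000 draws
  from the asymptotic coefficient distributions, percentile CI on a·b, and
  a three-part significance rule (indirect CI excludes 0, total effect
  significant, direct effect not).

Real transcripts of this kind are protected data, so the package ships a
synthetic cohort generator with planted structure — controlled per-role
category rates, POS transition skeletons with filler insertion, alliance
outcomes with known slopes, and a planted language → trust → alliance
mediation chain — giving every pipeline stage a ground truth to be tested
against.

## Worked example

```bash
python examples/full_pipeline.py
```

simulates the default 28-dyad cohort, extracts 112 feature columns, and
prints:

```
28 dyads, 112 feature columns
strongest feature ~ alliance regressions (by FDR q):
  patient_NUM-INTJ               slope=-15267.77  F=   9.7  p=0.004  q=0.125
  patient_bigram_i_would         slope=-6111.27  F=   9.4  p=0.005  q=0.125
  therapist_bigram_i_was         slope=-8898.65  F=  10.7  p=0.003  q=0.125
  therapist_bigram_i_would       slope=-5522.79  F=   8.4  p=0.008  q=0.139
  log_therapist_i                slope=  -17.59  F=   4.0  p=0.056  q=0.519
  patient_CCONJ-INTJ             slope=+4961.27  F=   4.3  p=0.049  q=0.519
mediation log_therapist_i -> mean RF -> alliance: a*b=-12.97 CI [-27.18, -1.80] significant=False
mediation log_therapist_we -> mean RF -> alliance: a*b=-4.03 CI [-13.23, +4.26] significant=False
```

The slopes are alliance points per unit feature (per log-percent for
lexicon features, per transition-probability unit for POS features —
hence the large magnitudes on probabilities of order 0.005).  The planted
first-person effects are negative, and the indirect (trust-mediated)
therapist-i path has a CI excluding zero; at 28 dyads the FDR-corrected
family is underpowered, so borderline q-values are the expected picture.

Other examples: `examples/extract_features.py` (feature extraction on a
tiny transcript), `examples/trust_game.py` (one simulated session),
`examples/mediation.py` (mediation on a planted chain).

A thin CLI wraps the same library calls:

```bash
dyadlink pipeline --seed 1 --n-dyads 28 --out runs/demo
dyadlink trustgame --seed 4 --k 5
dyadlink features --transcripts my_transcripts/ --out features.csv
```

Transcripts are plain text, one utterance per line (`PATIENT: ...` /
`THERAPIST: ...`), or JSON arrays of `{speaker, text}` records.

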