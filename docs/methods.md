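# Methods

`dyadlink` links interpretable conversational markers extracted from
two-speaker psychotherapy-style session transcripts to working-alliance
ratings and to trust-game behavior, and tests whether the behavioral
measure mediates the language–alliance association.  Because real session
transcripts of this kind are protected data, the package pairs the analysis
pipeline with a synthetic cohort generator with planted, known structure;
every stage of the pipeline can therefore be validated against ground
truth.

## Transcript processing

A session is an ordered list of utterances attributed to the `patient` or
`therapist` role, read either from `ROLE: text` lines or JSON records.
Cleaning lowercases text, removes bracketed spans (de-identification
placeholders such as `[NAME]`), and strips punctuation while keeping
apostrophes internal to a token, so contractions (`let's`, `i'm`) remain
single tokens that dictionary categories can match.  Tokenization is
whitespace splitting after stripping; numerals are kept and count toward a
speaker's total word count.  These two choices (contraction preservation,
numeral inclusion) are conventions of this package: dictionary-based text
analysis tools vary here and we document rather than infer any particular
tool's behavior.  Cleaning is idempotent and token streams conserve counts
(patient + therapist = dialogue).

## Lexicon features

Word-category frequencies are percent of the speaker's total words that
fall in a category, with case-insensitive exact whole-token matching (no
stemming or wildcards — deterministic and easily audited).  The shipped
open lexicon covers first-person singular (`i`, `i'm`, `me`, `my`, ...),
first-person plural (`we`, `our`, `us`, `let's`, ...), second/third-person
pronouns, and a non-fluency category of fillers (`um`, `uh`, `hmm`, ...).
Proprietary psycholinguistic dictionaries cannot be redistributed; users
holding a license can load their own category→word-list JSON and everything
downstream is unchanged.

Percentages are transformed as ln(percent + ε) before parametric analysis,
with ε = 0.01 percentage points.  The smallest plausible nonzero frequency
in a ~2,000-word speech sample is about 0.05%, so ε is an order of
magnitude smaller: it separates "absent" from "rare" without distorting
observed frequencies.

First-person word bigrams count each adjacent within-speaker word pair
containing `i` or `we`, scaled by the speaker's total bigram count.  Pairs
never straddle a speaker change.

## Syntactic non-fluency features

Tokens are tagged with the 17-tag universal POS inventory.  The tagger is a
pluggable callable; the built-in rule tagger uses a closed word lexicon
with suffix fallbacks (unknown tokens become `X`, never an error) and a
context rule that reads `like` as a filler interjection after an auxiliary
or adverb ("was like", "just like").  The rule tagger is a deterministic,
dependency-free tagger adequate for synthetic and lightly structured
conversational text; adapters for neural taggers plug in behind the same
interface, and gold tags from the synthetic generator pass through
unchanged.

POS-bigram transition matrices count contiguous tag pairs per speaker.  Two
normalizations are available: **joint** (pair count over all of that
speaker's pairs; the default, consistent with transition features whose
cohort means sit in the 0.005–0.01 range) and **conditional**
(row-normalized by the first tag's outgoing count).  Two attribution rules
are available: **per_speaker** (pairs over each speaker's concatenated
token sequence, so pairs span that speaker's consecutive utterances) and
**dialogue_first_token** (pairs over the interleaved dialogue, attributed
to the speaker of the pair's first token, so a talk-turn pair like patient
"…i can" → therapist "yeah" counts toward the patient).  Both choices are
recorded in output metadata.  Features that start or end with an
interjection (`AUX-INTJ`, `ADV-INTJ`, `INTJ-PRON`, `INTJ-SCONJ`, and all
other X-INTJ / INTJ-Y cells) serve as multi-word non-fluency metrics.

## Trust game

The ten-round trustee-role game: the simulated investor offers an integer
share of a 20-unit endowment, the offer is tripled, and the trustee repays
an integer amount from the tripled sum.  The repayment fraction divides the
repayment by the amount received; the default denominator is the tripled
offer 3·I (that is what the trustee holds), with the un-tripled reading
available by flag.  The session statistic is the mean over rounds with a
nonzero offer; zero-offer rounds are missing, not zero.

The investor policy samples later offers from a reference table of other
players' choices in the same round: the k records nearest in previous-round
repayment fraction (k = 5 by default, clamped to availability; distance
ties broken uniformly at random) are located and one offer is drawn
uniformly.  The one-dimensional repayment-fraction history is the minimal
state that makes the investor responsive; the shipped reference table is
synthetic (a seeded reciprocal-investor population) and is labelled as
such.  With k covering all records the policy reduces to uniform sampling
of that round's offers — a property used as a test.  Conservation holds
exactly in every session: units kept + units repaid = tripled offers.

## Statistical layer

All tests are two-sided at α = 0.05.

- **Mass-univariate regression**: each feature is regressed on the alliance
  total by OLS with intercept; F = (regression SS)/(residual SS/(n−2)) on
  F(1, n−2), equal to the squared slope t.  The family of feature p-values
  is adjusted by Benjamini–Hochberg step-up FDR (the method is recorded in
  the report; other step-up variants can be selected).
- **Correlations**: Pearson on log-transformed lexicon features, Spearman
  for the zero-skewed transition features; Fisher-z confidence intervals.
- **Partial correlation** residualizes both variables on the covariate
  (midranks first for Spearman) and tests the residual correlation on n−3
  degrees of freedom; used for treatment-duration-confounded features.
- **Role comparisons**: paired t on log lexicon features; Wilcoxon
  signed-rank on transition features.  The signed-rank p is exact for up to
  25 non-zero pairs via a dynamic program over midrank sums (correct under
  ties, where textbook exact tables do not apply); above that a
  tie-corrected normal approximation is used.  Effect size r = |Z|/√n.  A
  two-sample rank-sum variant is also provided and selectable.
- **Steiger's Z** compares two dependent correlations sharing one variable
  (feature vs two alliance subscores), using Fisher transforms and the
  dependent-correlation covariance evaluated at the back-transformed
  average correlation.
- **Kruskal–Wallis** (tie-corrected) compares alliance across categorical
  clinical covariates.
- **Mediation** (quasi-Bayesian): fit m ~ x and y ~ x + m by OLS, draw
  1,000 coefficient vectors from each fit's asymptotic normal, and
  summarize the a·b draws by percentile CI and a sign-share p (draws at
  exactly 0 count in both shares).  The point estimate is exactly a·b from
  the fits.  The mediation is declared significant only when the indirect
  CI excludes zero **and** the total effect c is significant **and** the
  direct effect c′ is not, once the mediator is controlled.  Fixed seed ⇒
  bit-reproducible.

Dyads sharing a therapist are treated as independent rows; no mixed-effects
correction is attempted (a known limitation, flagged in reports of real
data).

## Synthetic cohorts

The generator emits alternating utterances token by token: a category draw
(per-role target rates, as percent) competes with a small first-order
Markov chain over content POS tags, and a filler `like` (gold tag INTJ) can
follow an auxiliary or adverb, planting AUX-INTJ / ADV-INTJ mass without
touching the filler-word category rate.  Gold tags are recorded at
emission, and ground-truth features are computed by naive counting at
emission time — independent of the extraction modules, which must reproduce
them exactly (a standing test).

Default study conditions: 28 dyads; mean tokens per session 4,500 (patient)
and 2,500 (therapist), lognormal dispersion 0.15; per-role category rates
patient i 10.3%, we 0.517%, nonfluent 2.12% and therapist i 3.30%, we
0.994%, nonfluent 2.79% (second/third-person rates set to plausible
conversational values: therapists address "you" more, patients narrate
more third-person content); inter-dyad rate jitter is a mean-preserving
lognormal with CV 0.15.  Alliance totals are intercept 72 plus planted
negative slopes on log therapist-i/we and patient-i, a positive slope on
patient non-fluency, a positive trust path, a log-duration term, and
Gaussian noise (sd 6), clipped to the instrument range 12..84.  Totals are
kept continuous (not rounded to item sums) so that noiseless planted-slope
recovery is exact to machine precision.  Goal/task/bond subscores split the
total into near-thirds with a planted bond-vs-goal tilt on patient-i;
clipping to 4..28 can break the exact partition in extreme draws.
Treatment duration is lognormal (median 14.5 sessions, log-sd 1.0),
correlated ρ = 0.4 with the patient AUX-INTJ feature so the
partial-correlation path is exercised.  The mediation plant routes the
therapist-i effect through the patient's mean repayment fraction
(a = −0.40 per log-unit, RF noise 0.10, b = 30 alliance points per RF
unit); the trust-game module then synthesizes round-level sessions whose
realized mean repayment matches the planted value up to integer rounding,
and the realized value is what enters the outcome table.

What the generator does **not** emulate: real semantic content, topical
coherence, diagnosis-specific language, therapist nesting, item-level
(integer) alliance scoring, and session-to-session dynamics.  Passing tests
therefore demonstrate the correctness and calibration of the pipeline, not
clinical validity on real recordings.

## Numerical and design choices

- Degenerate inputs raise typed errors (constant predictor, zero-variance
  correlate, all-zero paired differences, all-zero-offer sessions) rather
  than returning NaN.
- A perfectly flat response in the F-regression returns F = 0, p = 1; a
  perfect fit reports p at the machine floor.
- Correlation triples outside the positive-definite region are rejected by
  Steiger's Z with a clear message.
- All randomness flows from a single integer seed (`numpy` Generator);
  reports and cohort bundles are byte-reproducible, and iteration order
  never depends on hash randomization.
- Problem sizes used in validation: oracle equivalence on 100 random
  instances per primitive; null calibration with 2,000 univariate
  simulations at n = 200 and 200 mediation replicates at n = 100; power
  checks with 50 replicates at n = 200; the end-to-end determinism check
  runs the full 28-dyad default cohort twice.
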