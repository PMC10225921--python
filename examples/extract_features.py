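"""Extract lexicon and syntactic non-fluency features from a tiny session.

Builds a short two-speaker transcript, cleans it, and prints the per-role
pronoun/filler percentages, the first-person word bigrams, and the
interjection-adjacent POS-transition probabilities.
"""

from dyadlink import (
    Lexicon,
    category_percents,
    interjection_features,
    parse_transcript,
    preprocess,
    pronoun_bigrams,
    tag,
    token_stream,
    transition_matrix,
)

TEXT = """\
PATIENT: I was like, um, I don't know if I can keep doing this.
THERAPIST: let's talk about that. I do understand the frustration.
PATIENT: when I talk about work I just, uh, freeze up.
THERAPIST: yeah. what do you think is behind that?
"""

t = preprocess(parse_transcript(TEXT, dyad_id="demo"))
lex = Lexicon.default()

for role in ("patient", "therapist"):
    stream = token_stream(t, role)
    pct = category_percents(stream, lex)
    print(f"{role}: {len(stream)} tokens, "
          f"i={pct['i']:.1f}%  we={pct['we']:.1f}%  nonfluent={pct['nonfluent']:.1f}%")
    # percent of this speaker's words in each dictionary category

dialogue = tag(token_stream(t, "dialogue"))
for role in ("patient", "therapist"):
    m = transition_matrix(dialogue, role, mode="joint", attribution="per_speaker")
    feats = {k: v for k, v in interjection_features(m).items() if v > 0}
    print(f"{role} interjection transitions (joint prob):", feats)

print("patient first-person bigrams:",
      pronoun_bigrams(token_stream(t, "patient")))
# fractions of the speaker's adjacent word pairs that contain "i" or "we"
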