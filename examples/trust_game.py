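"""Simulate one ten-round trustee session against the k-NN investor.

The investor's first offer is uniform on 0..20; later offers are sampled
from a synthetic reference population of reciprocal investors, matched on
the trustee's previous-round repayment fraction.  The trustee here repays
about 40% of the tripled amount received.
"""

import numpy as np

from dyadlink import FractionTrustee, InvestorReference, KNNInvestor, play_session

rng = np.random.default_rng(7)
ref = InvestorReference.synthetic(rng, k=5)
session = play_session(KNNInvestor(ref), FractionTrustee(0.4, jitter_sd=0.05), rng)

print(session.to_frame().to_string(index=False))
# I_t: offer; received = 3*I_t; RF_t = repayment / received
print(f"mean repayment fraction: {session.mean_rf:.3f}")
print(f"units kept by trustee:   {session.kept_total}")
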