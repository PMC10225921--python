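"""Ten-round trustee-role trust game with a k-nearest-neighbour investor.

In each round the (simulated) investor offers an integer share of a
20-unit endowment; the offer is tripled on its way to the trustee, who
chooses an integer repayment out of that tripled amount.  The repayment
fraction RF_t divides the repayment by the amount received — by default the
tripled offer 3·I_t, since that is what the trustee actually holds; a config
switch exposes the un-tripled reading RF_t = R_t / I_t.  The session-level
statistic is the mean of the defined round fractions.

The investor's first offer is uniform on 0..20; later offers are sampled
from a reference table of other players' choices in the same round, taking
the k records nearest in previous-round repayment fraction and drawing one
uniformly.  A small seeded synthetic reference table (a reciprocal investor:
larger offers after generous repayments) ships with the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DegenerateInputError, InvariantViolationError

ENDOWMENT = 20
MULTIPLIER = 3
N_ROUNDS = 10

#: previous-round repayment fraction assumed when the last offer was 0
#: (no information), a neutral mid-scale value
NEUTRAL_RF = 0.5


@dataclass
class TrustGameRound:
    t: int
    offer: int            # I_t, investor's offer in 0..20
    repayment: int        # R_t, trustee's repayment in 0..3*I_t

    def __post_init__(self):
        if not 0 <= self.offer <= ENDOWMENT:
            raise InvariantViolationError(f"offer {self.offer} outside 0..{ENDOWMENT}")
        if not 0 <= self.repayment <= MULTIPLIER * self.offer:
            raise InvariantViolationError(
                f"repayment {self.repayment} outside 0..{MULTIPLIER * self.offer}"
            )

    @property
    def received(self) -> int:
        return MULTIPLIER * self.offer

    @property
    def rf(self) -> float | None:
        return repayment_fraction(self)


def repayment_fraction(r: TrustGameRound, tripled: bool = True) -> float | None:
    """RF_t = R_t / amount received; None (missing) when the offer was 0.

    ``tripled=True`` divides by 3·I_t (the amount the trustee holds);
    ``tripled=False`` divides by the bare offer I_t.
    """
    if r.offer == 0:
        return None
    denom = r.received if tripled else r.offer
    return r.repayment / denom


@dataclass
class TrustGameSession:
    dyad_id: str
    player_role: str
    rounds: list[TrustGameRound]
    tripled_denominator: bool = True

    def __post_init__(self):
        if len(self.rounds) != N_ROUNDS:
            raise InvariantViolationError(
                f"a session has {N_ROUNDS} rounds, got {len(self.rounds)}"
            )

    @property
    def kept_total(self) -> int:
        return sum(r.received - r.repayment for r in self.rounds)

    @property
    def mean_rf(self) -> float:
        return mean_repayment(self)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "t": r.t,
                "I_t": r.offer,
                "received": r.received,
                "R_t": r.repayment,
                "RF_t": repayment_fraction(r, self.tripled_denominator),
            }
            for r in self.rounds
        ]
        return pd.DataFrame(rows)


def mean_repayment(session: TrustGameSession) -> float:
    """Mean of the defined round repayment fractions (zero-offer rounds excluded)."""
    rfs = [
        repayment_fraction(r, session.tripled_denominator)
        for r in session.rounds
    ]
    rfs = [x for x in rfs if x is not None]
    if not rfs:
        raise DegenerateInputError("all rounds had a zero offer; mean RF undefined")
    return sum(rfs) / len(rfs)


@dataclass
class InvestorReference:
    """Reference table of (round, previous-round RF, offer) from other players."""

    rounds: np.ndarray    # int round index, 1-based
    prev_rf: np.ndarray   # float, NaN for round-1 records
    offers: np.ndarray    # int offers in 0..20
    k: int = 5

    def __post_init__(self):
        self.rounds = np.asarray(self.rounds, dtype=int)
        self.prev_rf = np.asarray(self.prev_rf, dtype=float)
        self.offers = np.asarray(self.offers, dtype=int)
        if not (len(self.rounds) == len(self.prev_rf) == len(self.offers)):
            raise ConfigurationError("reference columns have unequal lengths")
        if self.offers.size and (self.offers.min() < 0 or self.offers.max() > ENDOWMENT):
            raise ConfigurationError("reference offers outside 0..20")

    @classmethod
    def synthetic(cls, rng: np.random.Generator, n_per_round: int = 40, k: int = 5) -> "InvestorReference":
        """Seeded stand-in reference table (synthetic; no behavioral dataset).

        Emulates a reciprocal investor population: offers increase with the
        trustee's previous-round repayment fraction, with individual scatter.
        """
        rounds, prev, offers = [], [], []
        for t in range(1, N_ROUNDS + 1):
            rf = rng.beta(2.0, 2.0, size=n_per_round)
            base = 4.0 + 14.0 * rf + rng.normal(0.0, 2.5, size=n_per_round)
            off = np.clip(np.rint(base), 0, ENDOWMENT).astype(int)
            rounds.extend([t] * n_per_round)
            prev.extend([math.nan] * n_per_round if t == 1 else rf.tolist())
            offers.extend(off.tolist())
        return cls(np.array(rounds), np.array(prev), np.array(offers), k=k)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"round": self.rounds, "prev_rf": self.prev_rf, "offer": self.offers})


def investor_offer(
    history: Sequence[TrustGameRound],
    ref: InvestorReference,
    rng: np.random.Generator,
    k: int | None = None,
) -> int:
    """Next offer: uniform 0..20 in round 1, k-NN sampled thereafter.

    Later rounds take the reference records for the same round index, rank
    them by |previous RF − observed RF_{t−1}| (ties broken uniformly at
    random), and sample one of the k nearest offers uniformly.  k is clamped
    to the number of available records.
    """
    t = len(history) + 1
    if t == 1:
        return int(rng.integers(0, ENDOWMENT + 1))
    k = ref.k if k is None else k
    mask = ref.rounds == t
    if not mask.any():
        raise ConfigurationError(f"investor reference has no records for round {t}")
    last = history[-1]
    observed = repayment_fraction(last)
    if observed is None:
        observed = NEUTRAL_RF
    prev = ref.prev_rf[mask]
    offers = ref.offers[mask]
    dist = np.abs(np.where(np.isnan(prev), NEUTRAL_RF, prev) - observed)
    kk = min(max(1, k), dist.size)
    tiebreak = rng.permutation(dist.size)
    order = np.lexsort((tiebreak, dist))
    neighbors = offers[order[:kk]]
    return int(neighbors[rng.integers(0, kk)])


class KNNInvestor:
    """Investor policy closing over a reference table and neighbour count."""

    def __init__(self, ref: InvestorReference, k: int | None = None):
        self.ref = ref
        self.k = k

    def __call__(self, history, rng):
        return investor_offer(history, self.ref, rng, k=self.k)


class FractionTrustee:
    """Trustee repaying a (possibly jittered) fixed fraction of the amount received."""

    def __init__(self, target_rf: float, jitter_sd: float = 0.0):
        if not 0.0 <= target_rf <= 1.0:
            raise ConfigurationError(f"target_rf {target_rf} outside [0, 1]")
        self.target_rf = target_rf
        self.jitter_sd = jitter_sd

    def __call__(self, received: int, history, rng) -> int:
        f = self.target_rf
        if self.jitter_sd > 0:
            f = float(np.clip(f + rng.normal(0.0, self.jitter_sd), 0.0, 1.0))
        return int(np.clip(round(f * received), 0, received))


def play_session(
    investor: Callable,
    trustee: Callable,
    rng: np.random.Generator,
    dyad_id: str = "sim",
    player_role: str = "patient",
    n_rounds: int = N_ROUNDS,
) -> TrustGameSession:
    """Play the rounds sequentially; out-of-range policy values raise."""
    history: list[TrustGameRound] = []
    for t in range(1, n_rounds + 1):
        offer = int(investor(history, rng))
        if not 0 <= offer <= ENDOWMENT:
            raise InvariantViolationError(f"investor offered {offer} in round {t}")
        received = MULTIPLIER * offer
        repayment = int(trustee(received, history, rng))
        if not 0 <= repayment <= received:
            raise InvariantViolationError(f"trustee repaid {repayment} of {received}")
        history.append(TrustGameRound(t=t, offer=offer, repayment=repayment))
    return TrustGameSession(dyad_id=dyad_id, player_role=player_role, rounds=history)
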