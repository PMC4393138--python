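"""Gap-analysis apparent extirpation and colonization rates.

Operates on a species' trimmed range — the samples strictly between its
first and last appearance in the longest per-core window — so that the
interior presence/absence gaps alone carry the occupancy-turnover
signal.  For a trimmed series like X X 0 0 0 X 0 X X (X = present):
t = 8 intervals, z = 4 zero samples, ε = 2 extirpation (X→0) events,
i = 2 colonization (0→X) events, and both rates equal 2/4 = 0.5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from paleosel.core_data import AbundanceSeries


@dataclass(frozen=True)
class TransitionSummary:
    """Presence/absence transition counts of a trimmed series."""

    t: int  # interval count = samples − 1
    z: int  # zero-sample count
    eps: int  # extirpation events: positive → zero transitions
    i_col: int  # colonization events: zero → positive transitions
    n_t: int  # count value of the final sample

    def __post_init__(self) -> None:
        if self.eps > self.t or self.i_col > self.t:
            raise ValueError("more events than intervals")
        if self.z > self.t + 1:
            raise ValueError("more zeros than samples")
        if abs(self.eps - self.i_col) > 1:
            raise ValueError("extirpation and colonization counts differ by more than 1")


def summarize_transitions(trimmed: AbundanceSeries) -> TransitionSummary:
    """Count zeros and presence/absence transitions along a trimmed series."""
    v = trimmed.values
    if len(v) < 2:
        raise ValueError("transition summary requires at least 2 samples")
    present = [x > 0 for x in v]
    return TransitionSummary(
        t=len(v) - 1,
        z=sum(1 for p in present if not p),
        eps=sum(1 for a, b in zip(present, present[1:]) if a and not b),
        i_col=sum(1 for a, b in zip(present, present[1:]) if not a and b),
        n_t=v[-1],
    )


def extirpation_rate(s: TransitionSummary) -> float:
    """Apparent extirpation rate E(t).

    E = ε/(t+1−z) if the series ends absent, else ε/(t−z): extirpation
    events per sample at which the species was present (with a
    final-state correction).  NaN when the denominator is zero — the
    species then carries no defined rate and is dropped from models
    using this predictor.
    """
    denom = s.t + 1 - s.z if s.n_t == 0 else s.t - s.z
    if denom <= 0:
        return math.nan
    return s.eps / denom


def colonization_rate(s: TransitionSummary) -> float:
    """Apparent colonization rate I(t).

    I = i/(z−1) if the series ends absent, else i/z: colonization
    events per zero sample (with a final-state correction).  NaN when
    there is no zero sample to colonize from.
    """
    denom = s.z - 1 if s.n_t == 0 else s.z
    if denom <= 0:
        return math.nan
    return s.i_col / denom
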