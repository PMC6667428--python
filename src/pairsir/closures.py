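"""Moment closures for [ASI]-type triples on regular networks.

The unclosed pairwise SIR system contains the triples [SSI] and [ISI].  A
closure expresses such triples through pairs and singles.  Four variants are
provided:

``unclustered``
    The classical regular-network closure
    [ASI] = ((n-1)/n) [AS][SI]/[S], exact in spirit for tree-like contact
    structure.

``simple``
    Keeling's clustered closure: the unclustered estimate multiplied by
    (1 - phi) + phi * C_AI, where C_AI is the pair correlation factor.  It
    does not preserve the pair-level conservation sum_A [ASI] = (n-1)[SI]
    when phi > 0.

``improved_full``
    The renormalised closure in which the clustered part is normalised over
    all three states {S, I, R} so that the conservation identity holds
    exactly.

``compact_improved``
    The improved closure restricted to {S, I} in its normalisation, dropping
    R-class pairs from the clustered correction.  Conservation over {S, I}
    holds exactly, and the closure yields a self-contained five-equation
    system.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

from .params import DegenerateStateError, ModelParams, PairwiseState

__all__ = [
    "TripleEstimate",
    "Correlations",
    "closure_unclustered",
    "closure_simple",
    "closure_improved_full",
    "closure_compact_improved",
    "correlations",
]

StateLabel = Literal["S", "I", "R"]


@dataclass(frozen=True)
class TripleEstimate:
    """An estimated expected triple count [ASI] with its provenance."""

    value: float
    kind: str  # e.g. "[SSI]" or "[ISI]"
    closure: str

    def __float__(self) -> float:
        return self.value


@dataclass(frozen=True)
class Correlations:
    """Pair correlation factors C_AB = N [AB] / (n [A] [B]).

    C_AB = 1 under random labelling; C_SI <= 1, C_II >= 1 and C_SS >= 1 are
    expected during an epidemic (neighbouring states are correlated).
    """

    C_SI: float
    C_II: float
    C_SS: float


def _pair_AS(state: PairwiseState, A: StateLabel, SR: Optional[float] = None) -> float:
    if A == "S":
        return state.SS
    if A == "I":
        return state.SI
    if SR is None:
        raise DegenerateStateError("closure for A=R requires the [SR] pair count")
    return SR


def _pair_IA(state: PairwiseState, A: StateLabel, IR: Optional[float] = None) -> float:
    if A == "S":
        return state.SI
    if A == "I":
        return state.II
    if IR is None:
        raise DegenerateStateError("closure for A=R requires the [IR] pair count")
    return IR


def correlations(state: PairwiseState, params: ModelParams) -> Correlations:
    """Compute the correlation factors C_SI, C_II, C_SS at a state."""
    if state.S <= 0 or state.I <= 0:
        raise DegenerateStateError("correlation factors require S > 0 and I > 0")
    n, N = params.n, params.N
    return Correlations(
        C_SI=N * state.SI / (n * state.S * state.I),
        C_II=N * state.II / (n * state.I**2),
        C_SS=N * state.SS / (n * state.S**2),
    )


def closure_unclustered(state: PairwiseState, params: ModelParams, A: StateLabel) -> TripleEstimate:
    """Tree-like closure [ASI] = ((n-1)/n) [AS][SI]/[S] with A in {S, I}."""
    if A not in ("S", "I"):
        raise ValueError(f"A must be 'S' or 'I', got {A!r}")
    if state.S <= 0:
        raise DegenerateStateError("unclustered closure requires S > 0")
    value = params.xi * _pair_AS(state, A) * state.SI / state.S
    return TripleEstimate(value=value, kind=f"[{A}SI]", closure="unclustered")


def closure_simple(state: PairwiseState, params: ModelParams, A: StateLabel) -> TripleEstimate:
    """Keeling's clustered closure.

    [ASI] = ((n-1)/n) ([AS][SI]/[S]) ((1-phi) + phi N [AI]/(n [A][I])).
    """
    if A not in ("S", "I"):
        raise ValueError(f"A must be 'S' or 'I', got {A!r}")
    if state.S <= 0 or state.I <= 0:
        raise DegenerateStateError("simple clustered closure requires S > 0 and I > 0")
    singles_A = state.S if A == "S" else state.I
    if singles_A <= 0:
        raise DegenerateStateError(f"simple clustered closure requires [{A}] > 0")
    n, N, phi = params.n, params.N, params.phi
    C_AI = N * _pair_IA(state, A) / (n * singles_A * state.I)
    value = params.xi * _pair_AS(state, A) * state.SI / state.S * ((1.0 - phi) + phi * C_AI)
    return TripleEstimate(value=value, kind=f"[{A}SI]", closure="simple")


def closure_improved_full(
    state: PairwiseState,
    params: ModelParams,
    A: StateLabel,
    R: Optional[float] = None,
    SR: Optional[float] = None,
    IR: Optional[float] = None,
) -> TripleEstimate:
    """Fully renormalised clustered closure over the states {S, I, R}.

    [ASI] = (n-1) ( (1-phi) [AS][SI]/(n[S])
                    + phi [AS][SI][IA] / ([A] sum_a [aS][aI]/[a]) ),

    with a ranging over {S, I, R}.  When the R-class counts are omitted they
    are filled in by complement: R = N - S - I, SR = nS - SS - SI and
    IR = nI - SI - II (stub conservation on a regular network).

    This closure satisfies sum_A [ASI] = (n-1)[SI] exactly.  It is provided
    for conservation analysis and is not wired into an ODE system; the closed
    improved system used here is the compact variant.
    """
    n, N, phi = params.n, params.N, params.phi
    if R is None:
        R = N - state.S - state.I
    if SR is None:
        SR = n * state.S - state.SS - state.SI
    if IR is None:
        IR = n * state.I - state.SI - state.II
    if state.S <= 0 or state.I <= 0 or R <= 0:
        raise DegenerateStateError("improved closure requires S > 0, I > 0 and R > 0")
    denom = state.SS * state.SI / state.S + state.SI * state.II / state.I + SR * IR / R
    if denom <= 0:
        raise DegenerateStateError("improved closure: sum_a [aS][aI]/[a] vanishes")
    singles = {"S": state.S, "I": state.I, "R": R}[A]
    pair_AS = _pair_AS(state, A, SR)
    pair_IA = _pair_IA(state, A, IR)
    value = (n - 1.0) * (
        (1.0 - phi) * pair_AS * state.SI / (n * state.S)
        + phi * pair_AS * state.SI * pair_IA / (singles * denom)
    )
    return TripleEstimate(value=value, kind=f"[{A}SI]", closure="improved_full")


def closure_compact_improved(state: PairwiseState, params: ModelParams, A: StateLabel) -> TripleEstimate:
    """Compact improved closure (clustered part normalised over {S, I} only).

    [ASI] = (n-1) ( (1-phi) [AS][SI]/(n[S])
                    + phi [AS][SI][IA] / ([A] ([SS][SI]/[S] + [SI][II]/[I])) ).

    The bracketed denominator is the {S, I} part of the improved closure's
    normalisation, so sum over A in {S, I} recovers (n-1)[SI] exactly.  When
    the clustered numerator vanishes together with the denominator the term is
    defined as 0 (the continuous limit); a vanishing denominator against a
    non-zero numerator is a genuine degeneracy.
    """
    if A not in ("S", "I"):
        raise ValueError(f"A must be 'S' or 'I', got {A!r}")
    if state.S <= 0 or state.I <= 0:
        raise DegenerateStateError("compact improved closure requires S > 0 and I > 0")
    n, phi = params.n, params.phi
    singles = state.S if A == "S" else state.I
    pair_AS = _pair_AS(state, A)
    pair_IA = _pair_IA(state, A)
    unclustered = (1.0 - phi) * pair_AS * state.SI / (n * state.S)
    numerator = pair_AS * state.SI * pair_IA
    denom = singles * (state.SS * state.SI / state.S + state.SI * state.II / state.I)
    if denom == 0.0:
        if numerator == 0.0:
            clustered = 0.0
        else:
            raise DegenerateStateError("compact improved closure: zero denominator with non-zero numerator")
    else:
        clustered = numerator / denom
    value = (n - 1.0) * (unclustered + phi * clustered)
    return TripleEstimate(value=value, kind=f"[{A}SI]", closure="compact_improved")
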