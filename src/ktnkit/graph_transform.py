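"""Partial graph transformation (pGT): exact state elimination preserving
mean first-passage statistics.

The network is recast in branching probabilities and waiting times:

    P[i, j] = K[i, j] / D[j, j]    (probability that a jump out of j goes to i)
    tau_j   = 1 / D[j, j]          (mean waiting time in j)
    eps_j   = direct escape probability into the absorbing sink,

with the invariant sum_i P[i, j] + eps_j = 1 per column.  Eliminating a
state x reroutes its flux through its neighbors,

    P'[i, j] = P[i, j] + P[i, x] P[x, j] / (1 - P[x, x])
    eps'_j   = eps_j   + eps_x   P[x, j] / (1 - P[x, x])
    tau'_j   = tau_j   + tau_x   P[x, j] / (1 - P[x, x]),

which leaves every source-to-sink mean first-passage time of the retained
states exactly unchanged.  The denominator 1 - P[x, x] is never formed by
subtraction: it equals sum_{i != x} P[i, x] + eps_x, a sum of small
positives, so the recursion keeps full relative precision even when a
state returns almost all of its flux — the reason graph transformation
remains accurate where naive rate-matrix elimination and dense
eigendecomposition lose the slow eigenvalues.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .rate_theory import RateMatrices

logger = logging.getLogger(__name__)


class TrappedStateError(RuntimeError):
    """1 - P[x, x] vanished even as a stable sum: elimination impossible."""


@dataclass
class BranchingRepresentation:
    """Branching probabilities, waiting times and sink-escape fractions.

    Columns of ``P`` (self-loop included) plus ``eps`` sum to 1; ``eps`` is
    the direct sink escape fraction per state.  ``ids`` maps matrix
    position to minimum id.
    """

    P: np.ndarray
    tau: np.ndarray
    eps: np.ndarray
    ids: list[int]
    _pos: dict[int, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._pos:
            self._pos = {mid: i for i, mid in enumerate(self.ids)}

    @property
    def n(self) -> int:
        return len(self.ids)

    def position(self, min_id: int) -> int:
        return self._pos[min_id]

    def sink_fraction(self) -> np.ndarray:
        """Per-state probability that the next jump goes straight to the sink."""
        return self.eps.copy()

    def escape_denominator(self, ix: int) -> float:
        """1 - P[x, x] as a cancellation-free sum of exit probabilities.

        Summing only the off-diagonal column entries (never subtracting the
        self-loop from a total that contains it) keeps full relative
        precision when P[x, x] is within machine epsilon of 1.
        """
        col = self.P[:, ix]
        mask = np.ones(len(col), dtype=bool)
        mask[ix] = False
        return float(col[mask].sum() + self.eps[ix])


def to_branching(
    rates: RateMatrices, sink: set[int] | frozenset[int] = frozenset()
) -> BranchingRepresentation:
    """Convert a rate matrix to the branching representation.

    Sink states are treated as an external absorber: their columns and rows
    are dropped and the rates into them become the ``eps`` fractions.  A
    pGT-reduced input contributes its stored ``sink_rates`` the same way.
    A retained state with zero total escape rate is isolated and rejected.
    """
    sink = set(sink)
    retained = [mid for mid in rates.ids if mid not in sink]
    rpos = [rates.position(mid) for mid in retained]
    K = rates.K[np.ix_(rpos, rpos)]
    into_sink = np.zeros(len(retained))
    if sink:
        spos = [rates.position(mid) for mid in sink]
        into_sink += rates.K[np.ix_(spos, rpos)].sum(axis=0)
    if rates.sink_rates is not None:
        into_sink += rates.sink_rates[rpos]
    escape = K.sum(axis=0) + into_sink
    dead = [retained[i] for i in np.nonzero(escape <= 0)[0]]
    if dead:
        raise ValueError(f"isolated states with zero escape rate: {dead}")
    P = K / escape[None, :]
    np.fill_diagonal(P, 0.0)
    return BranchingRepresentation(
        P=P, tau=1.0 / escape, eps=into_sink / escape, ids=list(retained)
    )


def to_rates(rep: BranchingRepresentation) -> RateMatrices:
    """Convert back to rates, resumming accumulated self-loops.

    A self-loop probability a = P[j, j] renormalizes column j by 1/(1 - a),
    the geometric series of immediate returns, with 1 - a formed as the
    stable exit-probability sum.  K[i, j] = P'[i, j] / tau'_j; sink escape
    lands in ``sink_rates`` and the escape diagonal.
    """
    n = rep.n
    P = rep.P.copy()
    tau = rep.tau.copy()
    eps = rep.eps.copy()
    denom = np.array([rep.escape_denominator(j) for j in range(n)])
    stuck = np.nonzero(denom < 1e-300)[0]
    if stuck.size:
        raise TrappedStateError(
            f"states {[rep.ids[i] for i in stuck]} have no escape path"
        )
    renorm = 1.0 / denom
    P = P * renorm[None, :]
    np.fill_diagonal(P, 0.0)
    tau = tau * renorm
    eps = eps * renorm
    K = P / tau[None, :]
    sink_rates = eps / tau
    D = np.diag(K.sum(axis=0) + sink_rates)
    return RateMatrices(K=K, D=D, Q=K - D, ids=list(rep.ids),
                        sink_rates=sink_rates)


def eliminate_state(
    rep: BranchingRepresentation, x: int
) -> BranchingRepresentation:
    """Eliminate one state (by minimum id), rerouting its flux exactly."""
    ix = rep.position(x)
    denom = rep.escape_denominator(ix)
    if denom < 1e-300:
        raise TrappedStateError(
            f"state {x} is numerically trapped (1 - P_xx ~ {denom:.3g}); "
            "try a different elimination order"
        )
    keep = [i for i in range(rep.n) if i != ix]
    inv = 1.0 / denom
    P_out = rep.P[keep, ix]          # x -> retained
    P_in = rep.P[ix, keep]           # retained -> x
    P_new = rep.P[np.ix_(keep, keep)] + np.outer(P_out, P_in) * inv
    tau_new = rep.tau[keep] + P_in * rep.tau[ix] * inv
    eps_new = rep.eps[keep] + P_in * rep.eps[ix] * inv
    return BranchingRepresentation(
        P=P_new, tau=tau_new, eps=eps_new, ids=[rep.ids[i] for i in keep]
    )


def gt_mfpt(
    rates: RateMatrices,
    source: int,
    sink: set[int] | frozenset[int] = frozenset(),
) -> float:
    """Source-to-sink MFPT computed entirely by graph transformation.

    Eliminates every state except the source; the surviving state's waiting
    time divided by its sink-escape probability is the MFPT.  Every step is
    an addition or multiplication of positive quantities, so the result
    keeps full relative precision on networks where the float linear solve
    of the reduced master equation is hopelessly ill-conditioned.
    """
    rep = to_branching(rates, sink=sink)
    if source not in rep.ids:
        raise ValueError(f"source {source} not among the live states")
    for mid in [m for m in rep.ids if m != source]:
        rep = eliminate_state(rep, mid)
    denom = rep.escape_denominator(0)
    return float(rep.tau[0] / denom)


def pgt_reduce(
    rates: RateMatrices,
    retain: set[int] | frozenset[int],
    sink: set[int] | frozenset[int] = frozenset(),
    order: list[int] | None = None,
) -> RateMatrices:
    """Reduce the network to the retained states, preserving MFPTs exactly.

    All states outside ``retain`` and ``sink`` are eliminated, by default in
    min-degree order (fewest current nonzero branching partners first, ties
    by id) to limit fill-in; ``order`` overrides for testing.  The result is
    a :class:`RateMatrices` over the retained states whose ``sink_rates``
    hold direct escape into the sink, ready for
    :func:`~ktnkit.fpt_kinetics.absorbing_reduction` or a further
    :func:`to_branching` round.
    """
    retain = set(retain)
    sink = set(sink)
    if not retain:
        raise ValueError("retain set must be nonempty")
    if retain & sink:
        raise ValueError("retain and sink sets overlap")
    rep = to_branching(rates, sink=sink)
    to_remove = [mid for mid in rep.ids if mid not in retain]
    if order is not None:
        if set(order) != set(to_remove):
            raise ValueError("order must be a permutation of the removable states")
        for mid in order:
            rep = eliminate_state(rep, mid)
    else:
        remaining = set(to_remove)
        while remaining:
            # min-degree heuristic on the current branching graph
            best, best_deg = None, None
            for mid in sorted(remaining):
                j = rep.position(mid)
                deg = int(np.count_nonzero(rep.P[:, j]) +
                          np.count_nonzero(rep.P[j, :]))
                if best_deg is None or deg < best_deg:
                    best, best_deg = mid, deg
            rep = eliminate_state(rep, best)
            remaining.discard(best)
    return to_rates(rep)
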