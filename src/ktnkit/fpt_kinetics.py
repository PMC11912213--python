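"""First-passage-time distributions by eigendecomposition of the reduced
master equation.

Making a set of minima absorbing ("the sink") and deleting their rows and
columns leaves a reduced transition matrix Q~ on the surviving states whose
diagonal still contains the escape rates INTO the sink; probability that
reaches the sink never returns.  Decomposing Q~ into eigenmodes
(lambda_l, x_l, y_l) writes the first-passage-time density from an initial
occupation p0 as

    p(t) = sum_l A_l |lambda_l| exp(lambda_l t),   A_l = (1 . x_l)(y_l . p0),

and in log time y = ln t the transformed density p~(y) = e^y p(e^y) gives
each mode a peak of height A_l / e at y* = -ln|lambda_l|.  Because rates are
exponentially sensitive to barriers, well-separated barriers appear as
separate peaks in p~(y), and the right-eigenvector components of each mode
identify which minima set its time scale.

Detailed balance of harmonic TST rates makes Q~ symmetrizable: the similarity
transform with the square root of the Boltzmann weights turns it into the
symmetric matrix S with S_ij = sqrt(K_ij K_ji), which is solved with a
symmetric eigensolver.  This guarantees a real spectrum and is dramatically
better conditioned than a general dense eigensolve — the geometric-mean
entries of S stay bounded even when the Boltzmann weights span hundreds of
orders of magnitude.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .rate_theory import RateMatrices

logger = logging.getLogger(__name__)


class UnreachableSinkError(ValueError):
    """The sink cannot absorb probability from (part of) the source."""


class ConditioningError(RuntimeError):
    """Eigendecomposition produced an invalid (non-negative) eigenvalue."""


@dataclass
class SinkReduction:
    """Reduced master equation on the surviving state space.

    ``retained_ids`` lists minimum ids in matrix order; ``Q_tilde`` has the
    inter-state rates of the survivors with sink escape kept inside the
    diagonal; ``p0`` is the initial occupation (sums to 1).
    """

    retained_ids: list[int]
    Q_tilde: np.ndarray
    p0: np.ndarray

    @property
    def n(self) -> int:
        return len(self.retained_ids)

    def position(self, min_id: int) -> int:
        return self.retained_ids.index(min_id)


@dataclass
class EigenmodeSet:
    """Eigenmodes of Q~, sorted ascending in |lambda| (slowest first)."""

    eigenvalues: np.ndarray          # (L,), all < 0, units 1/time
    right_vectors: np.ndarray        # (n, L), columns x_l
    left_vectors: np.ndarray         # (L, n), rows y_l
    amplitudes: np.ndarray           # (L,)
    retained_ids: list[int]

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)


@dataclass
class FPTDistribution:
    """FPT density on a log-time grid with analytic and empirical peaks.

    ``mode_peaks`` lists (mode index, y*, A_l/e) for every mode;
    ``empirical_peaks`` lists (y, p~(y)) at local maxima of the summed
    density, which is what one reads off a plotted distribution when modes
    overlap.
    """

    modes: EigenmodeSet
    y: np.ndarray
    p_y: np.ndarray
    mode_peaks: list[tuple[int, float, float]]
    empirical_peaks: list[tuple[float, float]]

    def p_t(self, t: np.ndarray) -> np.ndarray:
        """Evaluate the density in linear time."""
        lam = self.modes.eigenvalues
        A = self.modes.amplitudes
        return np.einsum("l,lk->k", A * np.abs(lam),
                         np.exp(np.outer(lam, np.asarray(t))))


# ---------------------------------------------------------------------------
# Reduction
# ---------------------------------------------------------------------------

def reduce_to_sink(
    rates: RateMatrices,
    sink: set[int] | frozenset[int],
    source: set[int] | frozenset[int],
    source_weights: dict[int, float] | None = None,
) -> SinkReduction:
    """Remove the sink states, keeping their absorption inside the diagonal.

    ``p0`` is uniform over the source unless ``source_weights`` is given.
    Raises :class:`UnreachableSinkError` (naming the disconnected sources) if
    some source state cannot reach the sink through retained states.
    """
    sink = set(sink)
    source = set(source)
    if not sink or not source:
        raise ValueError("sink and source must be nonempty")
    if sink & source:
        raise ValueError(f"sink and source overlap: {sorted(sink & source)}")
    missing = (sink | source) - set(rates.ids)
    if missing:
        raise ValueError(f"unknown minimum ids: {sorted(missing)}")

    retained = [mid for mid in rates.ids if mid not in sink]
    rpos = [rates.position(mid) for mid in retained]
    Q_tilde = rates.Q[np.ix_(rpos, rpos)].copy()

    # reachability: BFS backwards from states adjacent to the sink
    n = len(retained)
    K_within = Q_tilde - np.diag(np.diag(Q_tilde))
    sink_adjacent = np.zeros(n, dtype=bool)
    spos = [rates.position(mid) for mid in sink]
    for i, mid in enumerate(retained):
        j = rates.position(mid)
        if rates.K[spos, j].sum() > 0:
            sink_adjacent[i] = True
        if rates.sink_rates is not None and rates.sink_rates[j] > 0:
            sink_adjacent[i] = True
    reach = sink_adjacent.copy()
    frontier = list(np.nonzero(reach)[0])
    while frontier:
        nxt = []
        for i in frontier:
            # j can reach the sink if it has a rate into i (K[i, j] > 0)
            feeders = np.nonzero(K_within[i, :] > 0)[0]
            for j in feeders:
                if not reach[j]:
                    reach[j] = True
                    nxt.append(j)
        frontier = nxt
    bad = [mid for i, mid in enumerate(retained) if mid in source and not reach[i]]
    if bad:
        raise UnreachableSinkError(
            f"sink unreachable from source minima {sorted(bad)}"
        )

    p0 = np.zeros(n)
    if source_weights is None:
        for mid in source:
            p0[retained.index(mid)] = 1.0 / len(source)
    else:
        for mid, w in source_weights.items():
            p0[retained.index(mid)] = w
        p0 /= p0.sum()
    return SinkReduction(retained_ids=retained, Q_tilde=Q_tilde, p0=p0)


def absorbing_reduction(
    rates: RateMatrices,
    source: set[int] | frozenset[int],
    source_weights: dict[int, float] | None = None,
) -> SinkReduction:
    """Build a :class:`SinkReduction` from an already-absorbing network.

    Used for graph-transformation-reduced networks, whose ``sink_rates``
    carry the direct escape into a sink that is no longer part of the state
    space; Q already has that escape inside its diagonal.
    """
    if rates.sink_rates is None or not np.any(rates.sink_rates > 0):
        raise ValueError(
            "network carries no sink escape; use reduce_to_sink with an "
            "explicit sink set"
        )
    source = set(source)
    missing = source - set(rates.ids)
    if missing:
        raise ValueError(f"unknown minimum ids: {sorted(missing)}")
    p0 = np.zeros(rates.n)
    if source_weights is None:
        for mid in source:
            p0[rates.position(mid)] = 1.0 / len(source)
    else:
        for mid, w in source_weights.items():
            p0[rates.position(mid)] = w
        p0 /= p0.sum()
    return SinkReduction(
        retained_ids=list(rates.ids), Q_tilde=rates.Q.copy(), p0=p0
    )


# ---------------------------------------------------------------------------
# Eigendecomposition
# ---------------------------------------------------------------------------

def _log_boltzmann_weights(Q_tilde: np.ndarray) -> np.ndarray:
    """Log equilibrium weights inferred from detailed balance.

    For a reversible chain K_ij pi_j = K_ji pi_i, so log pi differences along
    any edge are log(K_ij / K_ji); a BFS over each connected block propagates
    them (log space avoids overflow for deep traps).
    """
    n = Q_tilde.shape[0]
    K = Q_tilde - np.diag(np.diag(Q_tilde))
    lp = np.full(n, np.nan)
    for start in range(n):
        if not np.isnan(lp[start]):
            continue
        lp[start] = 0.0
        frontier = [start]
        while frontier:
            nxt = []
            for j in frontier:
                neighbors = np.nonzero((K[:, j] > 0) | (K[j, :] > 0))[0]
                for i in neighbors:
                    if np.isnan(lp[i]) and K[i, j] > 0 and K[j, i] > 0:
                        lp[i] = lp[j] + np.log(K[i, j]) - np.log(K[j, i])
                        nxt.append(i)
            frontier = nxt
        # one-way edges (no reverse rate) cannot occur for TST rates; any
        # state still unreached via reversible edges gets weight 1
    lp[np.isnan(lp)] = 0.0
    return lp - lp.max()


def eigenmodes(reduction: SinkReduction) -> EigenmodeSet:
    """Solve the symmetrized eigenproblem of Q~ and form FPT amplitudes.

    Off-diagonal entries of the symmetrized matrix are geometric means
    sqrt(K_ij K_ji); eigenvectors are transformed back with the square-root
    Boltzmann weights.  Modes are sorted slowest first.  A non-negative
    eigenvalue beyond 1e-12 * max|lambda| raises :class:`ConditioningError`
    (advising graph-transformation reduction).
    """
    Q = reduction.Q_tilde
    n = Q.shape[0]
    K = Q - np.diag(np.diag(Q))
    S = np.sqrt(K * K.T)
    np.fill_diagonal(S, np.diag(Q))
    asym = np.abs(S - S.T).max()
    scale = np.abs(S).max() or 1.0
    if asym > 1e-8 * scale:
        logger.warning(
            "reduced matrix not symmetrizable to %.2g (detailed-balance "
            "violation?); proceeding with (S+S^T)/2", asym / scale,
        )
    S = 0.5 * (S + S.T)
    w, U = scipy.linalg.eigh(S)

    lp = _log_boltzmann_weights(Q)
    half = np.exp(0.5 * lp)
    X = half[:, None] * U          # right eigenvectors as columns
    Y = (U / half[:, None]).T      # left eigenvectors as rows; Y @ X = I

    lam_max = np.abs(w).max() or 1.0
    if np.any(w > 1e-12 * lam_max):
        raise ConditioningError(
            f"non-negative eigenvalue {w.max():.3g} (max|lambda| {lam_max:.3g}); "
            "the sink may be unreachable or the matrix ill-conditioned — "
            "consider pgt_reduce to retain only the slow states"
        )
    w = np.minimum(w, -0.0)

    order = np.argsort(np.abs(w))
    w, X, Y = w[order], X[:, order], Y[order, :]
    A = (X.sum(axis=0)) * (Y @ reduction.p0)
    # tiny negative amplitudes are round-off; larger ones are legitimate
    A[(A < 0) & (A > -1e-10)] = 0.0
    return EigenmodeSet(
        eigenvalues=w, right_vectors=X, left_vectors=Y,
        amplitudes=A, retained_ids=list(reduction.retained_ids),
    )


# ---------------------------------------------------------------------------
# Distributions and moments
# ---------------------------------------------------------------------------

def fpt_distribution(
    modes: EigenmodeSet,
    y_range: tuple[float, float] | None = None,
    n_grid: int = 2048,
) -> FPTDistribution:
    """Evaluate p~(y) on a log-time grid and locate the peaks.

    The default grid spans 5 log-units beyond the extreme per-mode peak
    positions y* = -ln|lambda|; a user grid that does not cover that span is
    extended with a warning.
    """
    lam = modes.eigenvalues
    A = modes.amplitudes
    live = np.abs(lam) > 0
    ystars = -np.log(np.abs(lam[live]))
    lo, hi = ystars.min() - 5.0, ystars.max() + 5.0
    if y_range is not None:
        if y_range[0] > lo or y_range[1] < hi:
            logger.warning(
                "grid [%.3g, %.3g] does not cover the mode peaks; extended",
                *y_range,
            )
            lo, hi = min(lo, y_range[0]), max(hi, y_range[1])
        else:
            lo, hi = y_range
    y = np.linspace(lo, hi, n_grid)
    t = np.exp(y)
    # p~(y) = e^y sum_l A_l |lambda_l| exp(lambda_l e^y), evaluated in log
    # space per mode to dodge overflow for extreme grids
    log_terms = (
        y[None, :]
        + np.log(np.abs(lam[live]))[:, None]
        + lam[live][:, None] * t[None, :]
    )
    p_y = np.einsum("l,lk->k", A[live], np.exp(log_terms))

    mode_peaks = [
        (int(l), float(-np.log(np.abs(lam[l]))), float(A[l] / np.e))
        for l in range(modes.n_modes)
        if np.abs(lam[l]) > 0
    ]
    interior = (p_y[1:-1] > p_y[:-2]) & (p_y[1:-1] >= p_y[2:])
    idx = np.nonzero(interior)[0] + 1
    empirical = [(float(y[i]), float(p_y[i])) for i in idx if p_y[i] > 0]
    return FPTDistribution(
        modes=modes, y=y, p_y=p_y,
        mode_peaks=mode_peaks, empirical_peaks=empirical,
    )


def mfpt(reduction: SinkReduction) -> float:
    """Mean first passage time by direct linear solve.

    Solves Q~^T tau = -1 and returns tau . p0 — an eigendecomposition-free
    route that serves as the independent cross-check of the eigenmode sum
    sum_l A_l / |lambda_l| (see :func:`mfpt_from_modes`).
    """
    n = reduction.n
    try:
        tau = scipy.linalg.solve(reduction.Q_tilde.T, -np.ones(n))
    except scipy.linalg.LinAlgError as exc:
        raise UnreachableSinkError(
            "singular reduced matrix: sink unreachable from part of the network"
        ) from exc
    return float(tau @ reduction.p0)


def mfpt_from_modes(modes: EigenmodeSet) -> float:
    """First moment of the eigenmode expansion, sum_l A_l / |lambda_l|."""
    lam = np.abs(modes.eigenvalues)
    if np.any(lam == 0):
        raise UnreachableSinkError("zero eigenvalue: sink unreachable")
    return float(np.sum(modes.amplitudes / lam))


def mode_attribution(
    modes: EigenmodeSet, mode_id: int, top_k: int | None = None
) -> list[tuple[int, float]]:
    """Rank minima by their contribution to one eigenmode's time scale.

    Weights are |x_l| components normalized to sum 1 — the right-eigenvector
    reading that assigns FPT peaks to sets of minima.
    """
    x = np.abs(modes.right_vectors[:, mode_id])
    w = x / x.sum()
    ranked = sorted(
        zip(modes.retained_ids, w), key=lambda p: (-p[1], p[0])
    )
    return [(mid, float(wt)) for mid, wt in (ranked[:top_k] if top_k else ranked)]


def dominant_modes(modes: EigenmodeSet, cutoff: float = 0.01) -> list[int]:
    """Indices of modes with |A_l| above the cutoff (the few that matter)."""
    return [l for l in range(modes.n_modes)
            if abs(modes.amplitudes[l]) >= cutoff]
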