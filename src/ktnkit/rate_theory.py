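"""Harmonic transition-state-theory rates and master-equation matrices.

Under the uniform-frequency approximation every minimum and transition state
is assigned the same average frequency factor nu_av, so the harmonic TST
prefactor collapses to nu_av and the rate from minimum j over a transition
state of energy V_ts is

    k(j -> i) = nu_av * exp(-(V_ts - V_j) / (k_B T)).

All times are reported in reduced units of 1/nu_av (nu_av = 1 by default);
``RateModel.to_seconds`` converts given a physical nu_av.

Matrix convention (a classic source of transposition bugs, so stated
prominently): ``K[i, j]`` is the rate FROM minimum j TO minimum i, i.e.
columns index the departing state.  The escape-rate diagonal is
``D[j, j] = sum_i K[i, j]`` and the transition matrix is ``Q = K - D``,
whose columns sum to zero on a closed network.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .ktn_io import KTN, connected_components

logger = logging.getLogger(__name__)

#: Boltzmann constant in kcal/(mol K)
BOLTZMANN_KCAL = 0.0019872041


@dataclass(frozen=True)
class RateModel:
    """Physical parameters of the rate calculation.

    temperature in K; nu_av is the average frequency factor in 1/s (1 keeps
    reduced time units); kappa, the count of vibrational degrees of freedom,
    cancels under uniform frequencies and is carried for documentation only.
    """

    temperature: float = 300.0
    k_B: float = BOLTZMANN_KCAL
    nu_av: float = 1.0
    kappa: int | None = None

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.nu_av <= 0:
            raise ValueError("nu_av must be positive")

    @property
    def kT(self) -> float:
        return self.k_B * self.temperature

    def to_seconds(self, reduced_time: float) -> float:
        """Convert a time in reduced 1/nu_av units to seconds."""
        return reduced_time / self.nu_av


@dataclass
class RateMatrices:
    """Assembled master-equation matrices for one connected component.

    ``index_map`` maps matrix position -> minimum id; ``ids`` is that map as
    a list.  ``sink_rates`` holds, for reduced networks produced by graph
    transformation, the direct escape rate from each retained state to the
    absorbing sink (zero for a closed network).
    """

    K: np.ndarray
    D: np.ndarray
    Q: np.ndarray
    ids: list[int]
    sink_rates: np.ndarray | None = None
    _pos: dict[int, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._pos:
            self._pos = {mid: i for i, mid in enumerate(self.ids)}

    @property
    def n(self) -> int:
        return len(self.ids)

    def position(self, min_id: int) -> int:
        return self._pos[min_id]


def harmonic_rate(V_ts: float, V_min: float, model: RateModel) -> float:
    """Harmonic TST rate over a barrier, in units of nu_av.

    Zero barrier gives rate 1 (the bare frequency factor).  Rates too small
    to represent in double precision are floored to 0 with a warning.
    """
    barrier = V_ts - V_min
    if barrier < 0:
        raise ValueError(
            f"negative barrier {barrier:.6g} kcal/mol (V_ts < V_min); "
            "validate the network with the clamp policy first"
        )
    exponent = -barrier / model.kT
    if exponent < -700.0:  # exp underflows double precision near e^-745
        logger.warning(
            "barrier %.3g kcal/mol underflows at T=%.1f K; rate floored to 0",
            barrier, model.temperature,
        )
        return 0.0
    return math.exp(exponent)


def build_rate_matrices(ktn: KTN, model: RateModel | None = None) -> RateMatrices:
    """Assemble K, D and Q = K - D for a kinetic transition network.

    Every transition state contributes a forward and a backward rate;
    parallel transition states between the same pair of minima sum.  The
    network should be a single connected component (a warning is logged
    otherwise; disconnected minima simply carry no flux).
    """
    if model is None:
        model = RateModel()
    if ktn.n_minima == 0:
        raise ValueError("empty network")
    comps = connected_components(ktn)
    if len(comps) > 1:
        logger.warning(
            "network has %d connected components; rates computed on all minima",
            len(comps),
        )
    ids = sorted(ktn.minima)
    pos = {mid: i for i, mid in enumerate(ids)}
    n = len(ids)
    K = np.zeros((n, n))
    for ts in ktn.transition_states:
        a, b = ts.min1, ts.min2
        K[pos[b], pos[a]] += harmonic_rate(ts.energy, ktn.energy(a), model)
        K[pos[a], pos[b]] += harmonic_rate(ts.energy, ktn.energy(b), model)
    D = np.diag(K.sum(axis=0))
    Q = K - D
    return RateMatrices(K=K, D=D, Q=Q, ids=ids)


def equilibrium_distribution(ktn: KTN, model: RateModel | None = None) -> np.ndarray:
    """Boltzmann occupation probabilities over the minima.

    pi_j proportional to exp(-E_j / kT), normalized to sum 1; the minimum
    energy is subtracted before exponentiation to avoid overflow.  Indexing
    follows sorted minimum ids, matching :func:`build_rate_matrices`.
    """
    if model is None:
        model = RateModel()
    ids = sorted(ktn.minima)
    E = np.array([ktn.energy(mid) for mid in ids])
    w = np.exp(-(E - E.min()) / model.kT)
    return w / w.sum()
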