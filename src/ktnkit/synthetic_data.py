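"""Synthetic landscapes, toy peptide ensembles and labelled solubility
datasets with known ground truth.

Real coarse-grained landscape databases for amyloid monomers run to
thousands of minima and are produced by extensive basin-hopping / discrete
path sampling; none are needed to exercise the machinery.  These generators
plant the structure the analyses are supposed to recover:

* multi-funnel kinetic transition networks where each funnel is a random
  tree of minima with energies rising away from its bottom, intra-funnel
  barriers drawn from a stated range, and funnels joined through high
  inter-funnel barriers — so threshold clustering has an exact planted
  partition and the funnel bottoms are the planted representatives;
* toy C-alpha/C-beta peptide geometries (ideal helix: 1.5 A rise and 100
  degrees of twist per residue; extended chain; self-avoiding random coil
  with 3.8 A virtual bonds) with optional Gaussian jitter;
* random peptide contact graphs whose solubility label is a sigmoid of a
  planted additive per-residue contribution (hydrophobic residues
  depressing solubility) plus clipped Gaussian noise.

Energy scales follow the real use case (barriers of a few to ~20 kcal/mol,
clustering thresholds of 5–14 kcal/mol) so numerical behavior matches.
All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gcn_solubility import ProteinGraph, node_features_for
from .ktn_io import KTN, Minimum, TransitionState, validate_ktn
from .structure_metrics import (
    HYDROPHOBIC,
    Structure,
    StructureEnsemble,
)

AA20 = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# Kinetic transition networks
# ---------------------------------------------------------------------------

@dataclass
class FunnelSpec:
    """Blueprint for a planted multi-funnel landscape.

    ``inter_funnel_barrier`` is measured above the higher of the two funnel
    bottoms it joins and must exceed every intra-funnel barrier, otherwise
    the planted partition is not recoverable and the spec is rejected.
    """

    n_funnels: int = 2
    minima_per_funnel: int = 10
    bottom_energies: tuple[float, ...] | None = None   # kcal/mol
    intra_barrier_range: tuple[float, float] = (1.0, 5.0)
    inter_funnel_barrier: float = 20.0
    energy_spread: float = 3.0       # max rise of minima above their bottom
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.intra_barrier_range
        if not (0 < lo <= hi):
            raise ValueError("intra-funnel barriers must be positive")
        if self.inter_funnel_barrier <= hi + self.energy_spread:
            raise ValueError(
                "inter-funnel barrier must exceed intra-funnel barriers plus "
                "the energy spread for the planted partition to be recoverable"
            )
        if self.n_funnels < 1 or self.minima_per_funnel < 1:
            raise ValueError("need at least one funnel and one minimum")


def generate_funnel_ktn(
    spec: FunnelSpec,
) -> tuple[KTN, dict[int, int], list[int]]:
    """Planted multi-funnel KTN.

    Returns (ktn, assignment, representatives): ``assignment`` maps minimum
    id -> planted funnel index, ``representatives`` lists the funnel-bottom
    ids (lowest minimum of each funnel).  Each funnel is a random tree so
    the minimax barrier between any two of its minima stays below the
    intra-funnel maximum, and inter-funnel edges sit at the planted barrier.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.bottom_energies is None:
        bottoms = -50.0 + 2.0 * np.arange(spec.n_funnels, dtype=float)
    else:
        if len(spec.bottom_energies) != spec.n_funnels:
            raise ValueError("need one bottom energy per funnel")
        bottoms = np.array(spec.bottom_energies, dtype=float)

    minima: list[Minimum] = []
    ts: list[TransitionState] = []
    assignment: dict[int, int] = {}
    reps: list[int] = []
    lo, hi = spec.intra_barrier_range

    for f in range(spec.n_funnels):
        ids = []
        for k in range(spec.minima_per_funnel):
            mid = len(minima) + 1
            if k == 0:
                energy = bottoms[f]
                reps.append(mid)
            else:
                energy = bottoms[f] + rng.uniform(0.1, spec.energy_spread)
            minima.append(Minimum(id=mid, energy=energy))
            assignment[mid] = f
            ids.append(mid)
        # random tree: each later minimum attaches to an earlier one
        for k in range(1, len(ids)):
            a = ids[int(rng.integers(0, k))]
            b = ids[k]
            base = max(minima[a - 1].energy, minima[b - 1].energy)
            ts.append(TransitionState(
                id=len(ts) + 1, energy=base + rng.uniform(lo, hi),
                min1=a, min2=b,
            ))

    # join funnels in a chain bottom-to-bottom at the planted barrier
    for f in range(1, spec.n_funnels):
        a, b = reps[f - 1], reps[f]
        base = max(minima[a - 1].energy, minima[b - 1].energy)
        ts.append(TransitionState(
            id=len(ts) + 1, energy=base + spec.inter_funnel_barrier,
            min1=a, min2=b,
        ))
    ktn = validate_ktn(minima, ts, policy="strict")
    return ktn, assignment, reps


def generate_two_state(
    barrier_forward: float, barrier_backward: float
) -> KTN:
    """Two minima joined by one transition state realizing the barriers.

    ``barrier_forward`` is the barrier out of minimum 1 (the higher-energy
    reactant side when forward > backward is not required); energies are
    placed so the shared transition state realizes both.
    """
    if barrier_forward <= 0 or barrier_backward <= 0:
        raise ValueError("barriers must be positive")
    e1 = 0.0
    e_ts = e1 + barrier_forward
    e2 = e_ts - barrier_backward
    minima = [Minimum(id=1, energy=e1), Minimum(id=2, energy=e2)]
    ts = [TransitionState(id=1, energy=e_ts, min1=1, min2=2)]
    return validate_ktn(minima, ts, policy="strict")


def generate_chain_ktn(
    n: int, barrier: float = 3.0, tilt: float = 0.0, seed: int = 0
) -> KTN:
    """1-D chain of n minima with uniform barriers (optionally tilted)."""
    minima = [Minimum(id=i + 1, energy=-10.0 + tilt * i) for i in range(n)]
    ts = [
        TransitionState(
            id=i + 1,
            energy=max(minima[i].energy, minima[i + 1].energy) + barrier,
            min1=i + 1, min2=i + 2,
        )
        for i in range(n - 1)
    ]
    return validate_ktn(minima, ts, policy="strict")


def generate_random_ktn(
    n: int, extra_edges: int = 0, barrier_range=(1.0, 6.0),
    energy_range=(-20.0, -10.0), seed: int = 0,
) -> KTN:
    """Connected random KTN (random spanning tree plus extra edges)."""
    rng = np.random.default_rng(seed)
    energies = rng.uniform(*energy_range, size=n)
    minima = [Minimum(id=i + 1, energy=float(e)) for i, e in enumerate(energies)]
    ts: list[TransitionState] = []
    for k in range(1, n):
        a = int(rng.integers(0, k)) + 1
        b = k + 1
        base = max(energies[a - 1], energies[b - 1])
        ts.append(TransitionState(
            id=len(ts) + 1, energy=float(base + rng.uniform(*barrier_range)),
            min1=a, min2=b,
        ))
    for _ in range(extra_edges):
        a, b = rng.choice(n, size=2, replace=False) + 1
        base = max(energies[a - 1], energies[b - 1])
        ts.append(TransitionState(
            id=len(ts) + 1, energy=float(base + rng.uniform(*barrier_range)),
            min1=int(a), min2=int(b),
        ))
    return validate_ktn(minima, ts, policy="strict")


# ---------------------------------------------------------------------------
# Toy peptide ensembles
# ---------------------------------------------------------------------------

@dataclass
class ToyPeptideSpec:
    """Blueprint for C-alpha/C-beta pseudo-atom peptide ensembles."""

    n_residues: int = 28
    geometry: str = "helix"          # "helix" | "extended" | "coil"
    jitter: float = 0.0              # Gaussian sigma, Angstrom
    n_models: int = 1
    sequence: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.geometry not in ("helix", "extended", "coil"):
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if self.n_residues < 2:
            raise ValueError("need at least 2 residues")
        if self.jitter < 0:
            raise ValueError("jitter must be nonnegative")


def _ca_trace(spec: ToyPeptideSpec, rng: np.random.Generator) -> np.ndarray:
    n = spec.n_residues
    if spec.geometry == "helix":
        # ideal alpha-helix: 1.5 A rise, 100 deg/residue, 2.3 A radius
        i = np.arange(n)
        theta = np.deg2rad(100.0) * i
        return np.stack([
            2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * i
        ], axis=1)
    if spec.geometry == "extended":
        i = np.arange(n)
        return np.stack([3.5 * i, np.zeros(n), np.zeros(n)], axis=1)
    # self-avoiding-ish random coil with 3.8 A virtual bonds
    coords = [np.zeros(3)]
    while len(coords) < n:
        step = rng.normal(size=3)
        step *= 3.8 / np.linalg.norm(step)
        cand = coords[-1] + step
        if all(np.linalg.norm(cand - c) > 3.0 for c in coords[:-1]):
            coords.append(cand)
    return np.array(coords)


def generate_toy_peptides(spec: ToyPeptideSpec) -> StructureEnsemble:
    """Ensemble of jittered toy structures with CA and CB pseudo-atoms.

    CB sits 1.53 A from CA, pointing away from the local chain direction
    (glycine gets no CB).  Helix geometry puts (i, i+4) CA distances near
    6.2 A, inside the 8 A contact cutoff.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.sequence is None:
        seq = "".join(rng.choice(list(AA20)) for _ in range(spec.n_residues))
    else:
        seq = spec.sequence
        if len(seq) != spec.n_residues:
            raise ValueError("sequence length does not match n_residues")

    base_ca = _ca_trace(spec, rng)
    members = []
    for _ in range(spec.n_models):
        ca = base_ca + (
            rng.normal(scale=spec.jitter, size=base_ca.shape)
            if spec.jitter > 0 else 0.0
        )
        names, resix, elems, coords = [], [], [], []
        for i in range(spec.n_residues):
            names.append("CA")
            resix.append(i + 1)
            elems.append("C")
            coords.append(ca[i])
            if seq[i] != "G":
                lo = ca[max(i - 1, 0)]
                hi = ca[min(i + 1, spec.n_residues - 1)]
                away = ca[i] - 0.5 * (lo + hi)
                nrm = np.linalg.norm(away)
                direction = away / nrm if nrm > 1e-9 else np.array([0.0, 0.0, 1.0])
                names.append("CB")
                resix.append(i + 1)
                elems.append("C")
                coords.append(ca[i] + 1.53 * direction)
        members.append(Structure(
            atom_names=names, residue_index=np.array(resix), sequence=seq,
            elements=elems, coords=np.array(coords),
        ))
    return StructureEnsemble(members=members)


# ---------------------------------------------------------------------------
# Solubility datasets
# ---------------------------------------------------------------------------

#: Planted per-residue solubility contributions: hydrophobic residues
#: depress the label, polar residues raise it.
PLANTED_HYDROPHOBIC_CONTRIB = -0.25
PLANTED_POLAR_CONTRIB = 0.12


def planted_contribution(aa: str) -> float:
    return (PLANTED_HYDROPHOBIC_CONTRIB if aa in HYDROPHOBIC
            else PLANTED_POLAR_CONTRIB)


def generate_solubility_dataset(
    n_graphs: int = 500,
    length_range: tuple[int, int] = (15, 30),
    noise_sigma: float = 0.05,
    seed: int = 0,
    contribution_fn=None,
) -> tuple[list[tuple[ProteinGraph, float]], list[np.ndarray]]:
    """Labelled random peptide graphs with a planted additive label.

    Labels are sigmoid(sum_i c(aa_i)) + clipped Gaussian noise, truncated to
    [0, 1]; ``contribution_fn`` overrides the planted per-residue function.
    Adjacency is a chain band (|i-j| <= 2) plus a few random long-range
    contacts, symmetric with unit diagonal.  Returns the dataset and the
    per-graph ground-truth contribution vectors.
    """
    rng = np.random.default_rng(seed)
    contrib = contribution_fn or planted_contribution
    dataset: list[tuple[ProteinGraph, float]] = []
    truths: list[np.ndarray] = []
    for _ in range(n_graphs):
        n = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = "".join(rng.choice(list(AA20)) for _ in range(n))
        A = np.zeros((n, n), dtype=int)
        for i in range(n):
            for j in range(max(0, i - 2), min(n, i + 3)):
                A[i, j] = 1
        for _ in range(int(rng.integers(0, n // 3 + 1))):
            i, j = rng.choice(n, size=2, replace=False)
            A[i, j] = A[j, i] = 1
        sasa = rng.uniform(0.0, 150.0, size=n)
        ss = [str(rng.choice(["H", "E", "C"])) for _ in range(n)]
        H = node_features_for(seq, sasa_per_residue=sasa, ss_labels=ss)
        graph = ProteinGraph(sequence=seq, node_features=H, A=A)
        c = np.array([contrib(aa) for aa in seq])
        label = 1.0 / (1.0 + np.exp(-c.sum()))
        if noise_sigma > 0:
            label = float(np.clip(label + rng.normal(scale=noise_sigma), 0, 1))
        dataset.append((graph, float(label)))
        truths.append(c)
    return dataset, truths
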