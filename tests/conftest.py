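"""Shared fixtures: small analytic networks and toy ensembles."""

import numpy as np
import pytest

import ktnkit as kk


@pytest.fixture
def two_state_ktn():
    """Two minima (0.0, -1.5) joined by a TS at +3.0 (barriers 3.0 / 4.5)."""
    return kk.generate_two_state(3.0, 4.5)


@pytest.fixture
def model300():
    return kk.RateModel(temperature=300.0)


@pytest.fixture
def chain3():
    """Three-minimum chain with uniform 2 kcal/mol barriers, flat energies."""
    return kk.generate_chain_ktn(3, barrier=2.0)


@pytest.fixture
def funnel2():
    """Two planted funnels of 8 minima, inter-funnel barrier 15 kcal/mol."""
    spec = kk.FunnelSpec(
        n_funnels=2, minima_per_funnel=8, intra_barrier_range=(1.0, 4.0),
        inter_funnel_barrier=15.0, energy_spread=3.0, seed=42,
    )
    return kk.generate_funnel_ktn(spec)


@pytest.fixture
def helix_ensemble():
    return kk.generate_toy_peptides(kk.ToyPeptideSpec(
        n_residues=16, geometry="helix", jitter=0.2, n_models=4, seed=7,
    ))


def exact_mfpt_oracle(rates, sink, source):
    """Exact-rational MFPT: build Q~ from K in Fractions and solve exactly.

    This sidesteps the float cancellation of forming Q = K - D in double
    precision, so it is trustworthy even for deep-trap networks.
    """
    from fractions import Fraction

    ids = rates.ids
    pos = {m: i for i, m in enumerate(ids)}
    ret = [m for m in ids if m not in sink]
    n = len(ret)
    Kf = rates.K
    Q = [[Fraction(Kf[pos[ret[i]], pos[ret[j]]]) for j in range(n)]
         for i in range(n)]
    for j in range(n):
        colsum = sum(Fraction(Kf[pos[g], pos[ret[j]]]) for g in ids)
        if rates.sink_rates is not None:
            colsum += Fraction(rates.sink_rates[pos[ret[j]]])
        Q[j][j] -= colsum
    # solve Q^T tau = -1 by exact Gaussian elimination
    A = [[Q[j][i] for j in range(n)] for i in range(n)]
    b = [Fraction(-1)] * n
    for c in range(n):
        piv = max(range(c, n), key=lambda r: abs(A[r][c]))
        A[c], A[piv] = A[piv], A[c]
        b[c], b[piv] = b[piv], b[c]
        for r in range(c + 1, n):
            f = A[r][c] / A[c][c]
            for k in range(c, n):
                A[r][k] -= f * A[c][k]
            b[r] -= f * b[c]
    tau = [None] * n
    for r in range(n - 1, -1, -1):
        s = b[r] - sum(A[r][k] * tau[k] for k in range(r + 1, n))
        tau[r] = s / A[r][r]
    src = sorted(source)
    return float(sum(tau[ret.index(m)] for m in src)) / len(src)


def minimax_barrier_matrix(ktn):
    """All-pairs minimax (widest-path) TS energies by Floyd-Warshall."""
    ids = sorted(ktn.minima)
    pos = {m: i for i, m in enumerate(ids)}
    n = len(ids)
    B = np.full((n, n), np.inf)
    np.fill_diagonal(B, -np.inf)
    for ts in ktn.transition_states:
        i, j = pos[ts.min1], pos[ts.min2]
        B[i, j] = B[j, i] = min(B[i, j], ts.energy)
    for k in range(n):
        B = np.minimum(B, np.maximum(B[:, k:k + 1], B[k:k + 1, :]))
    return ids, B
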