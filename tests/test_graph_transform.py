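"""Graph transformation: branching bookkeeping, exact MFPT preservation,
and conditioning rescue of slow eigenvalues on deep-trap networks."""

from fractions import Fraction

import numpy as np
import pytest

import ktnkit as kk
from ktnkit.graph_transform import to_branching, to_rates, eliminate_state
from conftest import exact_mfpt_oracle


def deep_trap_network():
    """Three funnels with 20 kcal/mol inter-funnel barriers: rate ratios of
    ~1e15 defeat double-precision dense linear algebra on the full matrix."""
    spec = kk.FunnelSpec(
        n_funnels=3, minima_per_funnel=8, intra_barrier_range=(1.0, 5.0),
        inter_funnel_barrier=20.0, seed=3,
    )
    return kk.generate_funnel_ktn(spec)


class TestBranching:
    def test_two_exit_branching_and_waiting(self):
        # state 1 with exits at rates 1 and 3 (built directly; small return
        # rates keep the other states alive)
        K = np.array([[0.0, 0.5, 0.5], [1.0, 0.0, 0.0], [3.0, 0.0, 0.0]])
        D = np.diag(K.sum(axis=0))
        rates = kk.RateMatrices(K=K, D=D, Q=K - D, ids=[1, 2, 3])
        rep = to_branching(rates)
        j = rep.position(1)
        assert rep.P[rep.position(2), j] == pytest.approx(0.25)
        assert rep.P[rep.position(3), j] == pytest.approx(0.75)
        assert rep.tau[j] == pytest.approx(0.25)

    def test_sink_adjacent_deficit(self):
        K = np.array([[0.0, 0.0], [2.0, 0.0]])
        D = np.diag(K.sum(axis=0))
        rates = kk.RateMatrices(K=K, D=D, Q=K - D, ids=[1, 2])
        rep = to_branching(rates, sink={2})
        assert rep.n == 1
        assert rep.eps[0] == pytest.approx(1.0)
        assert rep.tau[0] == pytest.approx(0.5)

    def test_round_trip_identity(self, funnel2):
        ktn, _, _ = funnel2
        rates = kk.build_rate_matrices(ktn)
        back = to_rates(to_branching(rates))
        np.testing.assert_allclose(back.K, rates.K, rtol=1e-12)
        np.testing.assert_allclose(np.diag(back.D), np.diag(rates.D),
                                   rtol=1e-12)

    def test_isolated_state_rejected(self):
        K = np.zeros((2, 2))
        K[1, 0] = 1.0
        D = np.diag(K.sum(axis=0))
        rates = kk.RateMatrices(K=K, D=D, Q=K - D, ids=[1, 2])
        with pytest.raises(ValueError, match="2"):
            to_branching(rates)


class TestEliminateState:
    def test_linear_chain_exact_reroute(self):
        # 1 -> 2 -> 3 at rate k each, no reverse: eliminating 2 gives
        # P(3|1) = 1 and tau_1 = 2/k, preserving the MFPT exactly
        k = 0.7
        K = np.zeros((3, 3))
        K[1, 0] = k
        K[2, 1] = k
        D = np.diag(K.sum(axis=0))
        rates = kk.RateMatrices(K=K, D=D, Q=K - D, ids=[1, 2, 3])
        rep = to_branching(rates, sink={3})
        rep2 = eliminate_state(rep, 2)
        assert rep2.ids == [1]
        assert rep2.eps[0] == pytest.approx(1.0)
        assert rep2.tau[0] == pytest.approx(2.0 / k, rel=1e-14)

    def test_unconnected_elimination_leaves_column_unchanged(self, funnel2):
        ktn, _, _ = funnel2
        rates = kk.build_rate_matrices(ktn)
        rep = to_branching(rates, sink={16})
        # minimum 8 (funnel 1 leaf) has no TS to minimum 9's column unless
        # adjacent; pick x, j with P[x, j] = 0
        P = rep.P
        x_i, j_i = None, None
        for a in range(rep.n):
            for b in range(rep.n):
                if a != b and P[a, b] == 0 and P[b, a] == 0:
                    x_i, j_i = a, b
                    break
            if x_i is not None:
                break
        x, j = rep.ids[x_i], rep.ids[j_i]
        rep2 = eliminate_state(rep, x)
        jj = rep2.position(j)
        before = np.delete(P[:, j_i], x_i)
        np.testing.assert_array_equal(rep2.P[:, jj], before)
        assert rep2.tau[jj] == rep.tau[j_i]

    def test_dead_end_elimination_renormalizes_neighbors(self):
        # dead-end state 3 hangs off state 1; eliminating it only stretches
        # the waiting time of 1 (flux in must come back)
        minima = [kk.Minimum(1, -10.0), kk.Minimum(2, -9.0),
                  kk.Minimum(3, -9.5)]
        ts = [kk.TransitionState(1, -7.0, 1, 2),
              kk.TransitionState(2, -8.0, 1, 3)]
        ktn = kk.validate_ktn(minima, ts, policy="strict")
        rates = kk.build_rate_matrices(ktn)
        red_full = kk.reduce_to_sink(rates, sink={2}, source={1})
        m_full = kk.mfpt(red_full)
        reduced = kk.pgt_reduce(rates, retain={1}, sink={2})
        sr = kk.absorbing_reduction(reduced, source={1})
        assert kk.mfpt(sr) == pytest.approx(m_full, rel=1e-12)


class TestPgtReduce:
    def test_retain_everything_is_identity(self, funnel2):
        ktn, _, _ = funnel2
        rates = kk.build_rate_matrices(ktn)
        red = kk.pgt_reduce(rates, retain=set(rates.ids[:-1]),
                            sink={rates.ids[-1]})
        keep = rates.ids[:-1]
        pos = [rates.position(m) for m in keep]
        np.testing.assert_allclose(
            red.K, rates.K[np.ix_(pos, pos)], rtol=1e-12
        )

    def test_three_state_chain_single_effective_rate(self, chain3):
        rates = kk.build_rate_matrices(chain3)
        full = kk.reduce_to_sink(rates, sink={3}, source={1})
        red = kk.pgt_reduce(rates, retain={1}, sink={3})
        assert red.n == 1
        assert 1.0 / red.sink_rates[0] == pytest.approx(
            kk.mfpt(full), rel=1e-12
        )

    def test_two_funnel_bottoms_preserve_mfpt(self):
        spec = kk.FunnelSpec(n_funnels=2, minima_per_funnel=25,
                             intra_barrier_range=(1.0, 4.0),
                             inter_funnel_barrier=10.0, seed=8)
        ktn, _, reps = kk.generate_funnel_ktn(spec)
        rates = kk.build_rate_matrices(ktn)
        sink_id = [m for m in rates.ids
                   if m != reps[1] and m > reps[1]][-1]   # a funnel-2 leaf
        exact = exact_mfpt_oracle(rates, {sink_id}, {reps[0]})
        red = kk.pgt_reduce(rates, retain=set(reps), sink={sink_id})
        sr = kk.absorbing_reduction(red, source={reps[0]})
        assert kk.mfpt(sr) == pytest.approx(exact, rel=1e-8)

    def test_mfpt_invariant_under_random_elimination_subsets(self):
        """Eliminating any random subset of intervening states leaves the
        source-to-sink MFPT unchanged (50 networks x 4 subsets)."""
        rng = np.random.default_rng(23)
        trials = 0
        for net in range(50):
            n = int(rng.integers(8, 30))
            ktn = kk.generate_random_ktn(
                n, extra_edges=int(rng.integers(0, n // 2)),
                barrier_range=(1.0, 5.0), seed=1000 + net,
            )
            rates = kk.build_rate_matrices(ktn)
            source, sink = 1, n
            # exact-rational reference: the float linear solve itself is
            # only ~1e-8-accurate on the harder draws
            m_full = exact_mfpt_oracle(rates, {sink}, {source})
            middle = [m for m in rates.ids if m not in (source, sink)]
            for _ in range(4):
                keep_mask = rng.random(len(middle)) > rng.uniform(0.2, 0.8)
                retain = {source} | {m for m, k in zip(middle, keep_mask) if k}
                red = kk.pgt_reduce(rates, retain=retain, sink={sink})
                # MFPT of the reduced network, evaluated stably within the
                # branching representation
                assert kk.gt_mfpt(red, source) == pytest.approx(
                    m_full, rel=1e-8
                )
                trials += 1
        assert trials == 200

    def test_elimination_order_independence(self):
        ktn = kk.generate_random_ktn(12, extra_edges=6, seed=6)
        rates = kk.build_rate_matrices(ktn)
        middle = [m for m in rates.ids if m not in (1, 12)]
        rng = np.random.default_rng(0)
        results = []
        for _ in range(4):
            order = list(middle)
            rng.shuffle(order)
            red = kk.pgt_reduce(rates, retain={1}, sink={12}, order=order)
            results.append((red.K.copy(), red.sink_rates.copy()))
        for K2, s2 in results[1:]:
            np.testing.assert_allclose(K2, results[0][0], rtol=1e-10)
            np.testing.assert_allclose(s2, results[0][1], rtol=1e-10)

    def test_absorption_probability_conserved(self):
        ktn = kk.generate_random_ktn(15, extra_edges=5, seed=2)
        rates = kk.build_rate_matrices(ktn)
        red = kk.pgt_reduce(rates, retain={1, 2, 3}, sink={15})
        rep = to_branching(red)
        # from any retained state, total absorption probability is 1:
        # solve (I - P^T) a = eps  => a = 1 for all states
        a = np.linalg.solve(np.eye(rep.n) - rep.P.T, rep.eps)
        np.testing.assert_allclose(a, 1.0, atol=1e-10)


class TestConditioningRescue:
    def _rational_slow_eigenvalue(self, rates, sink):
        """Extended-precision slow eigenvalue of the reduced transition
        matrix by exact-rational inverse power iteration (the matrix is
        assembled from K in Fractions, never through the float Q)."""
        ids = rates.ids
        pos = {m: i for i, m in enumerate(ids)}
        ret = [m for m in ids if m not in sink]
        n = len(ret)
        Q = [[Fraction(rates.K[pos[ret[i]], pos[ret[j]]]) for j in range(n)]
             for i in range(n)]
        for j in range(n):
            colsum = sum(Fraction(rates.K[pos[g], pos[ret[j]]]) for g in ids)
            Q[j][j] -= colsum

        def solve(A, b):
            A = [row[:] for row in A]
            b = b[:]
            for c in range(n):
                piv = max(range(c, n), key=lambda r: abs(A[r][c]))
                A[c], A[piv] = A[piv], A[c]
                b[c], b[piv] = b[piv], b[c]
                for r in range(c + 1, n):
                    f = A[r][c] / A[c][c]
                    for k in range(c, n):
                        A[r][k] -= f * A[c][k]
                    b[r] -= f * b[c]
            x = [None] * n
            for r in range(n - 1, -1, -1):
                s = b[r] - sum(A[r][k] * x[k] for k in range(r + 1, n))
                x[r] = s / A[r][r]
            return x

        x = [Fraction(1)] * n
        for _ in range(3):
            x = solve(Q, x)
            big = max(x, key=abs)
            x = [v / big for v in x]
        Qx = [sum(Q[i][j] * x[j] for j in range(n)) for i in range(n)]
        i = max(range(n), key=lambda i: abs(x[i]))
        return float(Qx[i] / x[i])

    def test_pgt_recovers_slow_eigenvalue_where_dense_solve_fails(self):
        ktn, _, reps = deep_trap_network()
        rates = kk.build_rate_matrices(ktn)
        sink = {reps[2]}
        lam_exact = self._rational_slow_eigenvalue(rates, sink)

        # direct double-precision route on the full reduced matrix
        full = kk.reduce_to_sink(rates, sink=sink, source={reps[0]})
        lam_dense = kk.eigenmodes(full).eigenvalues[0]
        dense_err = abs(lam_dense - lam_exact) / abs(lam_exact)
        assert dense_err > 1e-3   # the full-matrix route has broken down

        # pGT route: retain the two competing funnel bottoms
        red = kk.pgt_reduce(rates, retain=set(reps[:2]), sink=sink)
        sr = kk.absorbing_reduction(red, source={reps[0]})
        lam_pgt = kk.eigenmodes(sr).eigenvalues[0]
        assert lam_pgt == pytest.approx(lam_exact, rel=1e-6)

    def test_pgt_mfpt_matches_exact_oracle_on_deep_trap(self):
        ktn, _, reps = deep_trap_network()
        rates = kk.build_rate_matrices(ktn)
        exact = exact_mfpt_oracle(rates, {reps[2]}, {reps[0]})
        red = kk.pgt_reduce(rates, retain={reps[0]}, sink={reps[2]})
        sr = kk.absorbing_reduction(red, source={reps[0]})
        assert kk.mfpt(sr) == pytest.approx(exact, rel=1e-10)
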