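"""First-passage-time machinery: reduction, eigenmodes, distributions,
mean first passage times and per-state attribution."""

import numpy as np
import pytest
import scipy.integrate

import ktnkit as kk
from conftest import exact_mfpt_oracle


def _two_state_reduction(barrier=3.0):
    ktn = kk.generate_two_state(barrier, 4.5)
    rates = kk.build_rate_matrices(ktn)
    k_f = rates.K[1, 0]
    return kk.reduce_to_sink(rates, sink={2}, source={1}), k_f


class TestReduceToSink:
    def test_two_state_absorbing_boundary(self):
        red, k_f = _two_state_reduction()
        assert red.Q_tilde.shape == (1, 1)
        assert red.Q_tilde[0, 0] == pytest.approx(-k_f, rel=1e-14)

    def test_chain_column_sums(self, chain3):
        rates = kk.build_rate_matrices(chain3)
        red = kk.reduce_to_sink(rates, sink={3}, source={1})
        sums = red.Q_tilde.sum(axis=0)
        assert sums[0] == pytest.approx(0.0, abs=1e-15)   # state 1: closed
        assert sums[1] < 0                                 # state 2 leaks to sink

    def test_ring_sink_adjacent_columns_strict(self):
        minima = [kk.Minimum(i, -10.0) for i in range(1, 6)]
        ts = [kk.TransitionState(i, -7.0, i, i % 5 + 1) for i in range(1, 6)]
        ktn = kk.validate_ktn(minima, ts)
        rates = kk.build_rate_matrices(ktn)
        red = kk.reduce_to_sink(rates, sink={3}, source={1})
        sums = red.Q_tilde.sum(axis=0)
        assert np.all(sums <= 1e-15)
        strict = [red.retained_ids[i] for i in np.nonzero(sums < -1e-12)[0]]
        assert sorted(strict) == [2, 4]   # the two sink neighbors on the ring

    def test_unreachable_source_named(self):
        minima = [kk.Minimum(i, -10.0) for i in (1, 2, 3)]
        ts = [kk.TransitionState(1, -7.0, 1, 2)]
        ktn = kk.validate_ktn(minima, ts)
        rates = kk.build_rate_matrices(ktn)
        with pytest.raises(kk.UnreachableSinkError, match="3"):
            kk.reduce_to_sink(rates, sink={2}, source={3})


class TestEigenmodes:
    def test_single_state_mode(self):
        red, k_f = _two_state_reduction()
        modes = kk.eigenmodes(red)
        assert modes.eigenvalues[0] == pytest.approx(-k_f, rel=1e-12)
        assert modes.amplitudes[0] == pytest.approx(1.0, rel=1e-12)

    def test_amplitudes_sum_to_one(self, funnel2):
        ktn, _, reps = funnel2
        rates = kk.build_rate_matrices(ktn)
        red = kk.reduce_to_sink(rates, sink={reps[1]}, source={reps[0]})
        modes = kk.eigenmodes(red)
        assert np.all(modes.eigenvalues < 0)
        assert modes.amplitudes.sum() == pytest.approx(1.0, abs=1e-8)

    def test_biorthogonality(self, funnel2):
        ktn, _, reps = funnel2
        rates = kk.build_rate_matrices(ktn)
        red = kk.reduce_to_sink(rates, sink={reps[1]}, source={reps[0]})
        modes = kk.eigenmodes(red)
        G = modes.left_vectors @ modes.right_vectors
        np.testing.assert_allclose(G, np.eye(red.n), atol=1e-8)

    def test_agrees_with_dense_general_solver(self):
        ktn = kk.generate_random_ktn(20, extra_edges=8, seed=9)
        rates = kk.build_rate_matrices(ktn)
        red = kk.reduce_to_sink(rates, sink={20}, source={1})
        modes = kk.eigenmodes(red)
        ref = np.sort(np.real(scipy.linalg.eigvals(red.Q_tilde)))
        got = np.sort(modes.eigenvalues)
        np.testing.assert_allclose(got, ref, rtol=1e-8)


class TestFptDistribution:
    def test_single_mode_exponential_peak(self):
        red, k_f = _two_state_reduction()
        dist = kk.fpt_distribution(kk.eigenmodes(red))
        (mode_id, ystar, height), = dist.mode_peaks
        assert ystar == pytest.approx(np.log(1.0 / k_f), rel=1e-12)
        assert height == pytest.approx(1.0 / np.e, rel=1e-12)
        # empirical maximum coincides for a single mode
        y_emp, p_emp = max(dist.empirical_peaks, key=lambda t: t[1])
        assert y_emp == pytest.approx(ystar, abs=0.02)
        assert p_emp == pytest.approx(1.0 / np.e, rel=1e-3)

    def test_two_separated_modes_superpose(self):
        modes = kk.EigenmodeSet(
            eigenvalues=np.array([-1e-6, -1.0]),
            right_vectors=np.eye(2), left_vectors=np.eye(2),
            amplitudes=np.array([0.5, 0.5]), retained_ids=[1, 2],
        )
        dist = kk.fpt_distribution(modes)
        heights = sorted(h for _, _, h in dist.mode_peaks)
        assert np.allclose(heights, 0.5 / np.e)
        assert len(dist.empirical_peaks) == 2
        for _, p in dist.empirical_peaks:
            assert p == pytest.approx(0.5 / np.e, rel=1e-2)

    def test_density_normalized_on_grid(self, funnel2):
        ktn, _, reps = funnel2
        rates = kk.build_rate_matrices(ktn)
        red = kk.reduce_to_sink(rates, sink={reps[1]}, source={reps[0]})
        dist = kk.fpt_distribution(kk.eigenmodes(red))
        assert np.trapezoid(dist.p_y, dist.y) == pytest.approx(1.0, abs=1e-6)

    def test_mfpt_from_grid_matches_linear_solve(self, chain3):
        rates = kk.build_rate_matrices(chain3)
        red = kk.reduce_to_sink(rates, sink={3}, source={1})
        dist = kk.fpt_distribution(kk.eigenmodes(red))
        t = np.exp(dist.y)
        mfpt_grid = np.trapezoid(t * dist.p_y, dist.y)
        assert mfpt_grid == pytest.approx(kk.mfpt(red), rel=1e-4)

    def test_barrier_raise_shifts_peak_right(self):
        ys = []
        for barrier in (2.0, 4.0, 6.0):
            red, _ = _two_state_reduction(barrier)
            dist = kk.fpt_distribution(kk.eigenmodes(red))
            ys.append(dist.mode_peaks[0][1])
        assert ys[0] < ys[1] < ys[2]


class TestMfpt:
    def test_single_state_inverse_rate(self):
        red, k_f = _two_state_reduction()
        assert kk.mfpt(red) == pytest.approx(1.0 / k_f, rel=1e-12)

    def test_uniform_chain_lattice_formula(self):
        # uniform forward/backward rate k, sink at one end, source at the
        # other: MFPT = n(n+1)/2 / k for n retained states
        for n in (1, 2, 5, 10):
            ktn = kk.generate_chain_ktn(n + 1, barrier=2.0)
            rates = kk.build_rate_matrices(ktn)
            k = rates.K[1, 0]
            red = kk.reduce_to_sink(rates, sink={n + 1}, source={1})
            assert kk.mfpt(red) == pytest.approx(
                n * (n + 1) / 2.0 / k, rel=1e-10
            )

    def test_eigenmode_sum_equals_linear_solve_on_random_networks(self):
        # moderate barrier spread keeps both routes in the well-conditioned
        # regime where 1e-8 agreement is meaningful; the ill-conditioned
        # regime is exercised by the graph-transformation tests
        rng = np.random.default_rng(17)
        for trial in range(30):
            n = int(rng.integers(5, 60))
            ktn = kk.generate_random_ktn(
                n, extra_edges=int(rng.integers(0, n)),
                barrier_range=(1.0, 4.0), energy_range=(-15.0, -10.0),
                seed=trial,
            )
            rates = kk.build_rate_matrices(ktn)
            sink = int(rng.integers(1, n + 1))
            source = int(rng.integers(1, n + 1))
            if source == sink:
                continue
            red = kk.reduce_to_sink(rates, sink={sink}, source={source})
            modes = kk.eigenmodes(red)
            assert kk.mfpt_from_modes(modes) == pytest.approx(
                kk.mfpt(red), rel=1e-8
            )

    def test_matches_exact_rational_oracle(self, funnel2):
        ktn, _, reps = funnel2
        rates = kk.build_rate_matrices(ktn)
        red = kk.reduce_to_sink(rates, sink={reps[1]}, source={reps[0]})
        exact = exact_mfpt_oracle(rates, {reps[1]}, {reps[0]})
        assert kk.mfpt(red) == pytest.approx(exact, rel=1e-6)


class TestOdePropagationOracle:
    def test_density_matches_stiff_integration(self):
        """p(t) from eigenmodes equals -dS/dt from direct integration of the
        reduced master equation (S the survival probability)."""
        ktn = kk.generate_random_ktn(25, extra_edges=10, seed=3)
        rates = kk.build_rate_matrices(ktn)
        red = kk.reduce_to_sink(rates, sink={25}, source={1})
        modes = kk.eigenmodes(red)
        dist = kk.fpt_distribution(modes)
        mfpt = kk.mfpt(red)
        ts = mfpt * np.array([0.05, 0.2, 0.5, 1.0, 2.0, 4.0])
        sol = scipy.integrate.solve_ivp(
            lambda t, p: red.Q_tilde @ p, (0.0, ts[-1]), red.p0,
            method="Radau", t_eval=ts, rtol=1e-10, atol=1e-14, jac=red.Q_tilde,
        )
        # -dS/dt = -1^T Q~ p(t)
        p_ode = -(np.ones(red.n) @ red.Q_tilde @ sol.y)
        p_modes = dist.p_t(ts)
        np.testing.assert_allclose(p_modes, p_ode, rtol=1e-5)


class TestModeAttribution:
    def test_single_state_full_weight(self):
        red, _ = _two_state_reduction()
        attr = kk.mode_attribution(kk.eigenmodes(red), 0)
        assert attr == [(1, 1.0)]

    def test_slow_mode_concentrates_on_trapping_basin(self):
        # two basins: a deep trap (ids 1-3) and a shallow pass (ids 4-5)
        # next to the sink; the slow mode lives on the trap
        minima = [
            kk.Minimum(1, -60.0), kk.Minimum(2, -58.0), kk.Minimum(3, -57.0),
            kk.Minimum(4, -47.0), kk.Minimum(5, -46.0), kk.Minimum(6, -50.0),
        ]
        ts = [
            kk.TransitionState(1, -55.0, 1, 2),
            kk.TransitionState(2, -54.0, 2, 3),
            kk.TransitionState(3, -42.0, 3, 4),   # trap exit: 15+ barrier
            kk.TransitionState(4, -44.0, 4, 5),
            kk.TransitionState(5, -43.0, 5, 6),
        ]
        ktn = kk.validate_ktn(minima, ts, policy="strict")
        rates = kk.build_rate_matrices(ktn)
        red = kk.reduce_to_sink(rates, sink={6}, source={1})
        modes = kk.eigenmodes(red)
        attr = dict(kk.mode_attribution(modes, 0))
        assert attr[1] + attr[2] + attr[3] > 0.99

    def test_weights_invariant_under_relabeling(self, funnel2):
        ktn, _, reps = funnel2
        rates = kk.build_rate_matrices(ktn)
        red = kk.reduce_to_sink(rates, sink={reps[1]}, source={reps[0]})
        attr = dict(kk.mode_attribution(kk.eigenmodes(red), 0))

        # relabel ids by reversing the order
        n = ktn.n_minima
        relabel = {mid: n + 1 - mid for mid in ktn.minima}
        minima = [kk.Minimum(relabel[m.id], m.energy)
                  for m in ktn.minima.values()]
        ts = [kk.TransitionState(t.id, t.energy, relabel[t.min1],
                                 relabel[t.min2])
              for t in ktn.transition_states]
        ktn2 = kk.validate_ktn(minima, ts)
        rates2 = kk.build_rate_matrices(ktn2)
        red2 = kk.reduce_to_sink(
            rates2, sink={relabel[reps[1]]}, source={relabel[reps[0]]}
        )
        attr2 = dict(kk.mode_attribution(kk.eigenmodes(red2), 0))
        for mid, w in attr.items():
            assert attr2[relabel[mid]] == pytest.approx(w, rel=1e-8)

    def test_dominant_mode_cutoff(self, funnel2):
        ktn, _, reps = funnel2
        rates = kk.build_rate_matrices(ktn)
        red = kk.reduce_to_sink(rates, sink={reps[1]}, source={reps[0]})
        modes = kk.eigenmodes(red)
        dom = kk.dominant_modes(modes, cutoff=0.01)
        assert all(abs(modes.amplitudes[l]) >= 0.01 for l in dom)
        assert modes.amplitudes[dom].sum() == pytest.approx(1.0, abs=0.1)


class TestMultiFunnelSignature:
    def test_two_funnel_with_trap_is_multi_peaked(self):
        """A source next to the inter-funnel pass either crosses quickly or
        falls into its funnel's trap first: the FPT distribution to the
        other funnel's bottom has at least two modes with amplitude > 0.05
        and two empirical peaks."""
        minima = [
            kk.Minimum(1, -50.0),   # trap bottom, funnel 1
            kk.Minimum(2, -44.0),   # source, high in funnel 1
            kk.Minimum(3, -45.0),   # pass-side minimum, funnel 2
            kk.Minimum(4, -52.0),   # sink: funnel 2 bottom
        ]
        ts = [
            kk.TransitionState(1, -42.0, 1, 2),   # into the trap: barrier 2
            kk.TransitionState(2, -41.5, 2, 3),   # pass: barrier 2.5
            kk.TransitionState(3, -41.0, 3, 4),
        ]
        ktn = kk.validate_ktn(minima, ts, policy="strict")
        rates = kk.build_rate_matrices(ktn)
        red = kk.reduce_to_sink(rates, sink={4}, source={2})
        modes = kk.eigenmodes(red)
        big = [a for a in modes.amplitudes if a > 0.05]
        assert len(big) >= 2
        dist = kk.fpt_distribution(modes)
        tall = [p for _, p in dist.empirical_peaks if p > 0.05 / np.e]
        assert len(tall) >= 2
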