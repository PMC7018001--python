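"""Simulated annealer, exhaustive solver, and the sampler contract."""

import numpy as np
import pytest

import qubomod as qm
from qubomod.anneal import AnnealSchedule, SamplerContractError, check_sampler_output
from qubomod.qubo import QUBOProblem


def single_var_problem(h):
    return QUBOProblem(
        n=1, k=1, linear=np.array([float(h)]),
        rows=np.empty(0, dtype=np.int64), cols=np.empty(0, dtype=np.int64),
        vals=np.empty(0), offset=2.0, beta=1.0, gamma=np.array([1.0]),
    )


def two_var_problem(q11, q22, q12):
    return QUBOProblem(
        n=2, k=1, linear=np.array([q11, q22], dtype=float),
        rows=np.array([0]), cols=np.array([1]), vals=np.array([float(q12)]),
        offset=0.0, beta=1.0, gamma=np.array([1.0, 1.0]),
    )


class TestSimulatedAnneal:
    def test_single_variable_positive_linear_stays_off(self):
        prob = single_var_problem(+5.0)
        ss = qm.simulated_anneal(prob, num_reads=20, seed=0)
        bits, e = ss.best()
        assert bits.tolist() == [0]
        assert e == pytest.approx(prob.offset)

    def test_single_variable_negative_linear_turns_on(self):
        prob = single_var_problem(-5.0)
        bits, e = qm.simulated_anneal(prob, num_reads=20, seed=0).best()
        assert bits.tolist() == [1]
        assert e == pytest.approx(prob.offset - 5.0)

    def test_seeded_determinism(self, triangle):
        M = qm.modularity_matrix(triangle)
        prob = qm.build_kconcurrent_qubo(M, k=2, gamma=3.0)
        a = qm.simulated_anneal(prob, num_reads=50, seed=99)
        b = qm.simulated_anneal(prob, num_reads=50, seed=99)
        np.testing.assert_array_equal(a.bits, b.bits)
        np.testing.assert_array_equal(a.energies, b.energies)
        np.testing.assert_array_equal(a.counts, b.counts)
        c = qm.simulated_anneal(prob, num_reads=50, seed=100)
        assert not (
            a.bits.shape == c.bits.shape and np.array_equal(a.bits, c.bits)
        )

    def test_energies_consistent_with_qubo_energy(self, triangle):
        M = qm.modularity_matrix(triangle)
        prob = qm.build_kconcurrent_qubo(M, k=2, gamma=3.0)
        ss = qm.simulated_anneal(prob, num_reads=30, seed=5)
        for bits, e, _ in ss:
            assert e == pytest.approx(qm.energy(prob, bits), abs=1e-9)
        assert np.all(np.diff(ss.energies) >= 0)  # sorted ascending

    def test_finds_exhaustive_minimum_on_triangle_k2(self, triangle):
        M = qm.modularity_matrix(triangle)
        prob = qm.build_kconcurrent_qubo(M, k=2, gamma=3.0)
        _, exact = qm.exhaustive_solve(prob).best()
        _, sa = qm.simulated_anneal(prob, num_reads=100, seed=3).best()
        assert sa == pytest.approx(exact, abs=1e-9)

    def test_mean_best_energy_non_increasing_in_num_reads(self, zachary_B):
        """More reads can only improve the best-of-reads energy (statistically)."""
        prob = qm.build_kconcurrent_qubo(zachary_B, k=2, gamma=5.0)
        sched = AnnealSchedule(sweeps=100)
        means = []
        for reads in (1, 8, 64):
            bests = [
                qm.simulated_anneal(prob, num_reads=reads, schedule=sched,
                                    seed=s).best()[1]
                for s in range(12)
            ]
            means.append(np.mean(bests))
        assert means[0] >= means[1] >= means[2]

    def test_num_reads_validation(self, triangle):
        M = qm.modularity_matrix(triangle)
        prob = qm.build_kconcurrent_qubo(M, k=2, gamma=3.0)
        with pytest.raises(ValueError, match="num_reads"):
            qm.simulated_anneal(prob, num_reads=0)


class TestSchedule:
    def test_validation(self):
        with pytest.raises(ValueError, match="sweeps"):
            AnnealSchedule(sweeps=0)
        with pytest.raises(ValueError, match="beta_range"):
            AnnealSchedule(beta_range=(2.0, 1.0))

    def test_geometric_interpolation(self, triangle):
        M = qm.modularity_matrix(triangle)
        prob = qm.build_kconcurrent_qubo(M, k=2, gamma=3.0)
        betas = AnnealSchedule(sweeps=5, beta_range=(0.1, 10.0)).resolve(prob)
        np.testing.assert_allclose(betas, 0.1 * 100 ** (np.arange(5) / 4))

    def test_auto_range_is_ordered_and_positive(self, zachary_B):
        prob = qm.build_kconcurrent_qubo(zachary_B, k=4, gamma=5.0)
        betas = AnnealSchedule().resolve(prob)
        assert 0 < betas[0] < betas[-1]


class TestExhaustive:
    def test_empty_qubo_ties_at_offset(self):
        prob = QUBOProblem(
            n=2, k=1, linear=np.zeros(2),
            rows=np.empty(0, dtype=np.int64), cols=np.empty(0, dtype=np.int64),
            vals=np.empty(0), offset=1.5, beta=1.0, gamma=np.array([1.0, 1.0]),
        )
        ss = qm.exhaustive_solve(prob)
        assert len(ss) == 4  # every assignment is a ground state
        np.testing.assert_allclose(ss.energies, 1.5)

    def test_hand_enumerated_two_variable_problem(self):
        # q11 = q22 = -1, q12 = +3: minimum is exactly one bit set
        ss = qm.exhaustive_solve(two_var_problem(-1.0, -1.0, 3.0))
        ground = {tuple(b) for b, e, _ in ss if e == ss.energies[0]}
        assert ground == {(0, 1), (1, 0)}
        assert ss.energies[0] == pytest.approx(-1.0)

    def test_cap_enforced(self):
        prob = QUBOProblem(
            n=23, k=1, linear=np.zeros(23),
            rows=np.empty(0, dtype=np.int64), cols=np.empty(0, dtype=np.int64),
            vals=np.empty(0), offset=0.0, beta=1.0, gamma=np.ones(23),
        )
        with pytest.raises(ValueError, match="capped"):
            qm.exhaustive_solve(prob)

    @pytest.mark.parametrize("seed", range(4))
    def test_sa_reaches_exhaustive_ground_state_on_small_problems(self, seed):
        """Best-of-reads SA energy matches the exact minimum on <=16-var QUBOs."""
        rng = np.random.default_rng(seed)
        n, k = 5, 3  # 15 variables
        A = np.zeros((n, n))
        iu = np.triu_indices(n, k=1)
        draw = rng.random(iu[0].size) < 0.7
        A[iu[0][draw], iu[1][draw]] = 1.0
        A += A.T
        if A.sum() == 0:
            A[0, 1] = A[1, 0] = 1.0
        g = qm.Graph(tuple(map(str, range(n))), A)
        prob = qm.build_kconcurrent_qubo(qm.modularity_matrix(g), k=k)
        _, exact = qm.exhaustive_solve(prob).best()
        sched = AnnealSchedule(sweeps=2000)
        _, sa = qm.simulated_anneal(prob, num_reads=50, schedule=sched,
                                    seed=seed).best()
        assert sa == pytest.approx(exact, abs=1e-9)


class TestSamplerContract:
    def test_builtin_samplers_satisfy_contract(self, triangle):
        M = qm.modularity_matrix(triangle)
        prob = qm.build_kconcurrent_qubo(M, k=2, gamma=3.0)
        for sampler in (qm.SimulatedAnnealingSampler(num_reads=10, seed=1),
                        qm.ExhaustiveSampler()):
            assert isinstance(sampler, qm.Sampler)
            check_sampler_output(prob, sampler(prob))

    def test_wrong_bitstring_length_rejected(self, triangle):
        M = qm.modularity_matrix(triangle)
        prob = qm.build_kconcurrent_qubo(M, k=2, gamma=3.0)
        bad = qm.SampleSet.from_reads(
            np.zeros((1, 4), dtype=np.uint8), np.zeros(1)
        )
        with pytest.raises(SamplerContractError, match="length"):
            check_sampler_output(prob, bad)

    def test_inconsistent_energies_rejected(self, triangle):
        M = qm.modularity_matrix(triangle)
        prob = qm.build_kconcurrent_qubo(M, k=2, gamma=3.0)
        bits = np.zeros((1, prob.num_vars), dtype=np.uint8)
        bad = qm.SampleSet.from_reads(bits, np.array([prob.offset + 1.0]))
        with pytest.raises(SamplerContractError, match="energies"):
            check_sampler_output(prob, bad)
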