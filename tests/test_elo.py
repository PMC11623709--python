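import itertools

import numpy as np
import pytest

import impelo
from impelo.elo import (
    ELOConfig,
    block_sparsity,
    bomp,
    elo_greedy,
    select_candidate_block,
)
from impelo.solvers import SolverConfig, build_l2_system
from oracles import nnls_bruteforce, orthonormal_block_instance, toy_problem

TIGHT = SolverConfig(tol=1e-9, admm_max_iter=4000)


class TestBlockSparsity:
    def test_zero_vector(self):
        blocks = [np.array([0, 1]), np.array([2, 3, 4])]
        assert block_sparsity(np.zeros(5), blocks) == 0

    def test_single_active_block(self):
        blocks = [np.arange(0, 2), np.arange(2, 4), np.arange(4, 6)]
        x = np.zeros(6)
        x[5] = 0.3
        assert block_sparsity(x, blocks) == 1

    def test_matches_bruteforce_count(self):
        rng = np.random.default_rng(0)
        blocks = [np.arange(0, 3), np.arange(3, 4), np.arange(4, 8),
                  np.arange(8, 10)]
        for _ in range(10):
            x = rng.random(10) * (rng.random(10) < 0.4)
            expected = sum(1 for c in blocks if np.any(x[c] != 0))
            assert block_sparsity(x, blocks) == expected

    def test_partition_mismatch_rejected(self):
        with pytest.raises(ValueError, match="partition"):
            block_sparsity(np.zeros(5), [np.array([0, 1])])


class TestCandidateSelection:
    def test_orthogonal_target_selects_spanning_block(self):
        # block 1 spans rows 4..7; b lives there, other correlations vanish
        A = np.zeros((12, 6))
        blocks = [np.array([0, 1]), np.array([2, 3]), np.array([4, 5])]
        rng = np.random.default_rng(1)
        for bi, c in enumerate(blocks):
            A[bi * 4:(bi + 1) * 4, c] = rng.random((4, 2))
        b = np.zeros(12)
        b[4:8] = A[4:8, 2:4] @ np.array([1.0, 0.5])
        from scipy import sparse
        assert select_candidate_block(sparse.csr_matrix(A), blocks, b) == 1

    def test_exact_tie_returns_lowest_index(self):
        from scipy import sparse
        A = np.zeros((4, 4))
        A[0, 0] = A[0, 1] = 1.0   # block 0
        A[1, 2] = A[1, 3] = 1.0   # block 1, same score by symmetry
        blocks = [np.array([0, 1]), np.array([2, 3])]
        r = np.array([1.0, 1.0, 0.0, 0.0])
        assert select_candidate_block(sparse.csr_matrix(A), blocks, r) == 0

    def test_excluded_blocks_are_skipped(self):
        from scipy import sparse
        A = np.eye(4)
        blocks = [np.array([0, 1]), np.array([2, 3])]
        r = np.array([2.0, 0, 1.0, 0])
        assert select_candidate_block(sparse.csr_matrix(A), blocks, r,
                                      excluded={0}) == 1
        with pytest.raises(ValueError, match="excluded"):
            select_candidate_block(sparse.csr_matrix(A), blocks, r,
                                   excluded={0, 1})


class TestBOMP:
    def test_single_block_target_recovered_in_one_step(self):
        rng = np.random.default_rng(2)
        A, blocks, _ = orthonormal_block_instance(rng, ne=4, cols_per_block=2,
                                                  m=24)
        z = np.zeros(8)
        z[4:6] = [1.0, 0.7]       # block 2 only
        infl, spec, structures = toy_problem(A, blocks)
        system = build_l2_system(infl, spec, structures)
        system.b = A @ z
        x, support = bomp(system, 1)
        assert support == [2]
        assert np.linalg.norm(A @ x - system.b) < 1e-8

    def test_full_budget_matches_unrestricted_nnls(self):
        rng = np.random.default_rng(3)
        A = rng.random((20, 6)) * (rng.random((20, 6)) < 0.7)
        A[0] += 0.1
        blocks = [np.array([0, 1]), np.array([2, 3]), np.array([4, 5])]
        infl, spec, structures = toy_problem(A, blocks)
        system = build_l2_system(infl, spec, structures)
        x, _ = bomp(system, 3)
        _, f_ref = nnls_bruteforce(A, system.b)
        f = float(np.sum((A @ x - system.b) ** 2))
        assert f == pytest.approx(f_ref, rel=1e-8, abs=1e-10)

    def test_residual_norms_non_increasing(self):
        rng = np.random.default_rng(4)
        A = rng.random((25, 8))
        blocks = list(np.array_split(np.arange(8), 4))
        infl, spec, structures = toy_problem(A, blocks)
        system = build_l2_system(infl, spec, structures)
        x = np.zeros(8)
        support = []
        norms = [np.linalg.norm(system.b)]
        for _ in range(4):
            r = system.b - system.A @ x
            j = select_candidate_block(system.A, blocks, r, excluded=support)
            support.append(j)
            x = impelo.solve_l2_support(system, support)
            norms.append(np.linalg.norm(system.b - system.A @ x))
        assert all(b <= a + 1e-10 for a, b in zip(norms, norms[1:]))


class TestGreedyELO:
    def _run(self, A, blocks, n, gmin=0.0):
        infl, spec, structures = toy_problem(A, blocks)
        cfg = ELOConfig(n_energies=n, gmin=gmin, solver=TIGHT)
        return elo_greedy(infl, spec, structures, cfg), infl, spec, structures

    def test_budget_saturation_single_dominant_block(self):
        rng = np.random.default_rng(5)
        A, blocks, b = orthonormal_block_instance(rng, 4, 2, 24)
        res, infl, *_ = self._run(A, blocks, 1)
        assert res.n_active == 1
        assert block_sparsity(res.x, infl.blocks) <= 1

    def test_accepted_objective_strictly_decreases(self):
        rng = np.random.default_rng(6)
        A = rng.random((30, 10))
        blocks = list(np.array_split(np.arange(10), 5))
        res, *_ = self._run(A, blocks, 3)
        fs = [h["f_candidate"] for h in res.history if h["accepted"]]
        assert len(fs) >= 1
        assert all(b < a for a, b in zip(fs, fs[1:]))

    def test_toy_matches_exhaustive_under_orthogonality(self):
        """With orthonormal blocks and a target in the nonnegative cone the
        greedy support attains the exhaustive best-support objective."""
        rng = np.random.default_rng(7)
        for _ in range(5):
            A, blocks, b_unused = orthonormal_block_instance(rng, 4, 2, 24)
            infl, spec, structures = toy_problem(A, blocks)
            cfg = ELOConfig(n_energies=2, solver=TIGHT)
            res = elo_greedy(infl, spec, structures, cfg)
            best = np.inf
            b = np.ones(A.shape[0])
            for supp in itertools.combinations(range(4), 2):
                cols = np.concatenate([blocks[j] for j in supp])
                _, f = nnls_bruteforce(A[:, cols], b)
                best = min(best, f)
            assert res.f == pytest.approx(best, rel=1e-6, abs=1e-9)

    def test_s2_is_subset_of_s1_and_budget_respected(self):
        rng = np.random.default_rng(8)
        A = rng.random((30, 12)) * (rng.random((30, 12)) < 0.5)
        A[0] += 0.05
        blocks = list(np.array_split(np.arange(12), 6))
        res, infl, *_ = self._run(A, blocks, 3, gmin=0.2)
        s1 = {h["candidate_block"] for h in res.history}
        assert set(res.support) <= s1
        assert block_sparsity(res.x, infl.blocks) <= 3
        assert np.all((res.x == 0.0) | (res.x >= 0.2))

    def test_reduces_to_bomp_without_dvh_and_mmu(self):
        """With a single L2 term and Gmin = 0 the greedy selection follows
        the matching-pursuit candidate stream."""
        rng = np.random.default_rng(9)
        A = rng.random((25, 8)) + 0.05
        blocks = list(np.array_split(np.arange(8), 4))
        infl, spec, structures = toy_problem(A, blocks)
        system = build_l2_system(infl, spec, structures)
        _, bomp_support = bomp(system, 3)
        cfg = ELOConfig(n_energies=3, solver=TIGHT)
        res = elo_greedy(infl, spec, structures, cfg)
        assert [h["candidate_block"] for h in res.history][:3] == bomp_support

    def test_under_budget_flag_when_iterations_exhausted(self):
        rng = np.random.default_rng(10)
        A = rng.random((20, 8))
        blocks = list(np.array_split(np.arange(8), 4))
        infl, spec, structures = toy_problem(A, blocks)
        cfg = ELOConfig(n_energies=3, itr=1, solver=TIGHT)
        res = elo_greedy(infl, spec, structures, cfg)
        assert res.n_active <= 1
        assert res.under_budget

    def test_invalid_budget_rejected(self):
        rng = np.random.default_rng(11)
        A = rng.random((10, 4))
        blocks = [np.arange(0, 2), np.arange(2, 4)]
        infl, spec, structures = toy_problem(A, blocks)
        for n in (0, 2, 5):
            with pytest.raises(ValueError, match="N"):
                elo_greedy(infl, spec, structures, ELOConfig(n_energies=n))

    def test_final_plan_is_mmu_feasible_and_sparse(self, abdomen_setup):
        setup = abdomen_setup
        cfg = ELOConfig(n_energies=6, gmin=setup.gmin)
        res = elo_greedy(setup.influence, setup.objectives,
                         setup.case.structures, cfg)
        assert block_sparsity(res.x, setup.influence.blocks) <= 6
        assert np.all((res.x == 0.0) | (res.x >= setup.gmin))
        fs = [h["f_candidate"] for h in res.history if h["accepted"]]
        assert all(b < a for a, b in zip(fs, fs[1:]))
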