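"""Greedy energy-layer selection under a hard layer budget.

The number of energy layers a scanned proton plan uses dominates its
delivery time, so the planning problem is solved under the block-sparsity
constraint ``||x||_BS <= N``: at most N of the (beam, energy) column blocks
of the influence matrix may carry nonzero spot weights.

Two algorithms are provided:

* :func:`bomp` - block orthogonal matching pursuit on the pure least-squares
  objective: repeatedly select the block whose columns correlate most with
  the current residual, then re-project onto the enlarged support.
* :func:`elo_greedy` - the modified greedy selection for the full planning
  problem.  The matching-pursuit track (x1, S1) supplies the stream of
  candidate blocks from the L2 residual; each candidate is tentatively added
  to the accepted-plan track (x2, S2) and the DVH + MMU problem is re-solved
  on that support.  The candidate is kept only if the objective strictly
  decreases, so the accepted objective sequence is strictly decreasing; the
  loop stops once N blocks are active.

Candidates rejected from S2 remain in S1, so the residual-driven stream
moves past unhelpful blocks instead of re-proposing them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dose_engine import InfluenceMatrix
from .objectives import ObjectiveSpec, evaluate_objective, update_violation_sets
from .phantoms import StructureSet
from .solvers import (
    L2System,
    MMUConstraint,
    SolveResult,
    SolverConfig,
    build_l2_system,
    solve_fixed_support_dvh,
    solve_l2_support,
)

__all__ = [
    "ELOConfig",
    "EloResult",
    "block_sparsity",
    "select_candidate_block",
    "bomp",
    "elo_greedy",
]


@dataclass
class ELOConfig:
    n_energies: int                   # hard budget N (< number of blocks)
    itr: int | None = None            # max iterations, defaults to NE
    gmin: float = 0.0                 # MMU threshold [MU]
    solver: SolverConfig = field(default_factory=SolverConfig)

    def validate(self, n_blocks: int) -> None:
        if not (1 <= self.n_energies < n_blocks):
            raise ValueError(
                f"energy budget N={self.n_energies} must satisfy "
                f"1 <= N < NE={n_blocks}"
            )
        if self.itr is not None and not (1 <= self.itr <= n_blocks):
            raise ValueError(f"Itr must lie in [1, NE={n_blocks}]")


@dataclass
class EloResult:
    x: np.ndarray                     # accepted plan weights (MMU-feasible)
    support: list[int]                # accepted blocks S2, selection order
    f: float                          # objective of the accepted plan
    history: list[dict]               # per-iteration records
    n_active: int                     # CE, number of accepted blocks
    under_budget: bool                # stopped with CE < N


def block_sparsity(x: np.ndarray, blocks) -> int:
    """Number of blocks of x containing any nonzero entry."""
    x = np.asarray(x)
    cols = [np.asarray(getattr(b, "cols", b)) for b in blocks]
    covered = np.sort(np.concatenate(cols)) if cols else np.array([], dtype=int)
    if not np.array_equal(covered, np.arange(x.size)):
        raise ValueError("block map does not partition the weight vector")
    return int(sum(bool(np.any(x[c] != 0)) for c in cols))


def select_candidate_block(
    A,
    blocks: list[np.ndarray],
    residual: np.ndarray,
    excluded=(),
) -> int:
    """argmax over non-excluded blocks j of ||A_j^T r||_2; ties -> lowest j."""
    excluded = set(excluded)
    if len(excluded) >= len(blocks):
        raise ValueError("all blocks are excluded")
    corr = np.asarray(A.T @ residual).ravel()
    best_j, best_score = -1, -1.0
    for j, cols in enumerate(blocks):
        if j in excluded:
            continue
        score = float(np.linalg.norm(corr[cols]))
        if score > best_score:  # strict: first maximizer wins ties
            best_j, best_score = j, score
    return best_j


def bomp(system: L2System, n: int) -> tuple[np.ndarray, list[int]]:
    """Block orthogonal matching pursuit with nonnegative re-projection."""
    if not (1 <= n <= system.n_blocks):
        raise ValueError(f"N must lie in [1, {system.n_blocks}]")
    x = np.zeros(system.A.shape[1])
    support: list[int] = []
    for _ in range(n):
        r = system.b - system.A @ x
        j = select_candidate_block(system.A, system.blocks, r, excluded=support)
        support.append(j)
        x = solve_l2_support(system, support)
    return x, support


def elo_greedy(
    influence: InfluenceMatrix,
    spec: ObjectiveSpec,
    structures: StructureSet,
    config: ELOConfig,
) -> EloResult:
    """Greedy layer selection with DVH/MMU inner solves and acceptance test."""
    ne = influence.n_blocks
    config.validate(ne)
    itr = ne if config.itr is None else config.itr
    mmu = MMUConstraint(gmin=config.gmin)
    system = build_l2_system(influence, spec, structures)
    blocks = system.blocks

    n_cols = influence.D.shape[1]
    x1 = np.zeros(n_cols)
    x2 = np.zeros(n_cols)
    s1: list[int] = []
    s2: list[int] = []
    ce = 0
    d0 = np.zeros(influence.D.shape[0])
    f_best = evaluate_objective(
        d0, spec, structures, update_violation_sets(d0, spec, structures)
    )
    history: list[dict] = []

    for k in range(itr):
        if len(s1) >= ne:
            break
        ce += 1
        r = system.b - system.A @ x1
        j = select_candidate_block(system.A, blocks, r, excluded=s1)
        s1.append(j)
        x1 = solve_l2_support(system, s1)
        trial = s2 + [j]
        res: SolveResult = solve_fixed_support_dvh(
            influence, spec, structures, trial, mmu, config.solver, x0=x2
        )
        accepted = res.f < f_best
        blk = influence.blocks[j]
        history.append(
            {
                "k": k,
                "candidate_block": j,
                "beam": blk.beam,
                "energy_mev": blk.energy_mev,
                "f_candidate": res.f,
                "accepted": bool(accepted),
                "ce": ce if accepted else ce - 1,
            }
        )
        if accepted:
            s2 = trial
            x2 = res.x
            f_best = res.f
        else:
            ce -= 1
        if ce == config.n_energies:
            break

    return EloResult(
        x=x2,
        support=s2,
        f=f_best,
        history=history,
        n_active=ce,
        under_budget=ce < config.n_energies,
    )
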