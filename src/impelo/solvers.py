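"""Restricted planning solves on a fixed set of energy-layer blocks.

Two solvers back the greedy layer-selection loop:

* :func:`solve_l2_support` - nonnegative least squares over the selected
  blocks (the matching-pursuit re-projection step),
* :func:`solve_fixed_support_dvh` - the full DVH-weighted quadratic with the
  minimum-monitor-unit (MMU) set constraint ``x_j in {0} u [Gmin, inf)``,
  solved by iterative convex relaxation (freeze the DVH violator sets, solve
  the resulting convex quadratic, refresh the sets) with an ADMM inner loop
  whose z-update is the exact Euclidean projection onto the MMU set.

The ADMM split is the canonical one for set constraints:
``min f(x) + I_M(z) s.t. x = z``; the x-update is a dense Cholesky solve of
the support-restricted normal system (support sizes stay in the low
thousands), the z-update is :func:`mmu_project` coordinatewise, followed by a
scaled dual update with residual-balancing penalty adaptation.  The returned
weights are taken from z, so MMU feasibility holds exactly (set membership,
no tolerance).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import lsq_linear

from .dose_engine import InfluenceMatrix
from .objectives import (
    ObjectiveSpec,
    ViolationIndex,
    evaluate_objective,
    update_violation_sets,
)
from .phantoms import StructureSet

__all__ = [
    "L2System",
    "MMUConstraint",
    "SolverConfig",
    "SolveResult",
    "build_l2_system",
    "solve_l2_support",
    "mmu_project",
    "solve_fixed_support_dvh",
]


@dataclass
class L2System:
    """sqrt(weight)-scaled L2 rows of D and the matching target vector.

    ``A`` inherits the block column decomposition of the influence matrix.
    """

    A: sparse.csr_matrix
    b: np.ndarray
    blocks: list[np.ndarray]    # column index arrays, one per block

    def __post_init__(self):
        ncols = sum(c.size for c in self.blocks)
        if ncols != self.A.shape[1]:
            raise ValueError("block map does not cover the columns of A")

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)


@dataclass
class MMUConstraint:
    gmin: float = 0.0

    def __post_init__(self):
        if self.gmin < 0:
            raise ValueError("Gmin must be >= 0")


@dataclass
class SolverConfig:
    rho: float = 1.0              # ADMM penalty, in units of mean diag(H)
    admm_max_iter: int = 600
    tol: float = 1e-7             # ADMM residual tolerance (relative)
    icr_iters: int = 5            # outer violation-set refreshes
    nnls_tol: float = 1e-10
    seed: int = 0

    def __post_init__(self):
        if self.rho <= 0 or self.tol <= 0:
            raise ValueError("rho and tol must be positive")
        if self.admm_max_iter < 1 or self.icr_iters < 1:
            raise ValueError("iteration counts must be >= 1")


@dataclass
class SolveResult:
    x: np.ndarray                 # full-length weights, MMU-feasible
    f: float                      # objective with the final violator sets
    omega: ViolationIndex | None
    converged: bool
    n_admm_iters: int
    trace: list[dict] = field(default_factory=list)


def build_l2_system(
    influence: InfluenceMatrix,
    spec: ObjectiveSpec,
    structures: StructureSet,
) -> L2System:
    """Stack sqrt(w)-scaled rows of D over all L2-term voxels."""
    rows, targets = [], []
    csr = influence.csr
    for term in spec.terms:
        if term.kind != "l2":
            continue
        idx = np.flatnonzero(structures[term.roi].ravel())
        sw = np.sqrt(term.weight)
        rows.append(csr[idx] * sw)
        targets.append(np.full(idx.size, sw * term.dose))
    A = sparse.vstack(rows, format="csr")
    return L2System(
        A=A,
        b=np.concatenate(targets),
        blocks=[blk.cols for blk in influence.blocks],
    )


def _support_cols(blocks: list[np.ndarray], support) -> np.ndarray:
    support = list(support)
    if not support:
        raise ValueError("support must be non-empty")
    return np.concatenate([blocks[j] for j in support])


def solve_l2_support(system: L2System, support) -> np.ndarray:
    """min ||A z - b||^2 over z >= 0 supported on the given blocks."""
    cols = _support_cols(system.blocks, support)
    As = system.A[:, cols]
    n = As.shape[1]
    if n <= 400:
        res = lsq_linear(As.toarray(), system.b, bounds=(0.0, np.inf),
                         method="bvls", tol=1e-12)
    else:
        res = lsq_linear(As, system.b, bounds=(0.0, np.inf), method="trf",
                         tol=1e-10, lsmr_tol="auto", max_iter=60)
    x = np.zeros(system.A.shape[1])
    x[cols] = np.clip(res.x, 0.0, None)
    return x


def mmu_project(v, gmin: float):
    """Nearest point of {0} u [Gmin, inf): 0 if v <= Gmin/2, else max(v, Gmin)."""
    if gmin < 0:
        raise ValueError("Gmin must be >= 0")
    v = np.asarray(v, dtype=float)
    out = np.where(v <= 0.5 * gmin, 0.0, np.maximum(v, gmin))
    return out if out.ndim else float(out)


def _admm_quadratic_mmu(
    H: np.ndarray,
    q: np.ndarray,
    gmin: float,
    config: SolverConfig,
    x0: np.ndarray,
):
    """min 0.5 x'Hx - q'x  s.t.  x in ({0} u [Gmin, inf))^n.

    Returns the best feasible iterate found (by quadratic value), its
    convergence flag and iteration count.
    """
    n = q.size
    scale = max(float(np.trace(H)) / n, 1e-12)
    rho = config.rho * scale
    eye = np.eye(n)
    fac = cho_factor(H + rho * eye, lower=True)
    z = mmu_project(x0, gmin)
    u = np.zeros(n)

    def quad(v):
        return 0.5 * float(v @ (H @ v)) - float(q @ v)

    best_z, best_val = z.copy(), quad(z)
    converged = False
    it = 0
    for it in range(1, config.admm_max_iter + 1):
        x = cho_solve(fac, q + rho * (z - u))
        z_old = z
        z = mmu_project(x + u, gmin)
        u = u + x - z
        r = float(np.linalg.norm(x - z))
        s = rho * float(np.linalg.norm(z - z_old))
        if it % 5 == 0 or it == config.admm_max_iter:
            val = quad(z)
            if val < best_val:
                best_val, best_z = val, z.copy()
        eps = config.tol * np.sqrt(n) * max(
            1.0, float(np.linalg.norm(x)), float(np.linalg.norm(z))
        )
        if r < eps and s < eps:
            converged = True
            break
        if it % 25 == 0:  # residual balancing (Boyd et al. scheme)
            if r > 10.0 * s:
                rho *= 2.0
                u *= 0.5
                fac = cho_factor(H + rho * eye, lower=True)
            elif s > 10.0 * r:
                rho *= 0.5
                u *= 2.0
                fac = cho_factor(H + rho * eye, lower=True)
    val = quad(z)
    if val < best_val:
        best_val, best_z = val, z
    return best_z, converged, it


def _quadratic_pieces(
    csr: sparse.csr_matrix,
    cols: np.ndarray,
    spec: ObjectiveSpec,
    omega: ViolationIndex,
):
    """Dense normal matrix H and linear term q of f restricted to ``cols``."""
    mats, tgts = [], []
    for term, idx in zip(spec.terms, omega.active):
        if idx.size == 0:
            continue
        sw = np.sqrt(term.weight)
        mats.append(csr[idx][:, cols] * sw)
        tgts.append(np.full(idx.size, sw * term.dose))
    if not mats:
        n = cols.size
        return np.zeros((n, n)), np.zeros(n)
    B = sparse.vstack(mats, format="csr")
    c = np.concatenate(tgts)
    H = 2.0 * (B.T @ B).toarray()
    q = 2.0 * np.asarray(B.T @ c).ravel()
    return H, q


def solve_fixed_support_dvh(
    influence: InfluenceMatrix,
    spec: ObjectiveSpec,
    structures: StructureSet,
    support,
    mmu: MMUConstraint,
    config: SolverConfig | None = None,
    x0: np.ndarray | None = None,
) -> SolveResult:
    """Full DVH + MMU solve restricted to the given blocks.

    Outer loop: freeze the violator sets Omega at the current feasible
    iterate, solve the convex quadratic with ADMM, refresh Omega; stop when
    the sets no longer change.  The returned objective is evaluated with a
    final Omega refresh at the final feasible x.  Never raises on
    non-convergence; the flag on the result reports it.
    """
    config = config or SolverConfig()
    blocks = [blk.cols for blk in influence.blocks]
    cols = _support_cols(blocks, support)
    csr = influence.csr
    n_full = influence.D.shape[1]
    Ds = csr[:, cols].tocsc()

    xs = np.zeros(cols.size) if x0 is None else np.asarray(x0, float)[cols]
    xs = mmu_project(xs, mmu.gmin)
    omega_prev = None
    converged = True
    iters = 0
    trace: list[dict] = []
    for outer in range(config.icr_iters):
        d = np.zeros(influence.D.shape[0])
        d += Ds @ xs
        omega = update_violation_sets(d, spec, structures)
        if omega_prev is not None and omega == omega_prev:
            break
        H, q = _quadratic_pieces(csr, cols, spec, omega)
        xs, ok, it = _admm_quadratic_mmu(H, q, mmu.gmin, config, xs)
        converged = converged and ok
        iters += it
        trace.append(
            {"outer": outer, "admm_iters": it, "admm_converged": ok,
             "omega_sizes": omega.sizes()}
        )
        omega_prev = omega

    d = Ds @ xs
    omega_final = update_violation_sets(d, spec, structures)
    f = evaluate_objective(d, spec, structures, omega_final)
    x_full = np.zeros(n_full)
    x_full[cols] = xs
    return SolveResult(
        x=x_full,
        f=f,
        omega=omega_final,
        converged=converged,
        n_admm_iters=iters,
        trace=trace,
    )
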