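"""Independent reference implementations used as test oracles.

Everything here is deliberately brute force (enumeration, fine-step
integration, exhaustive search) and shares no code path with the package.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import sparse
from scipy.interpolate import RegularGridInterpolator

from impelo.dose_engine import Block, GridSpec, InfluenceMatrix
from impelo.objectives import ObjectiveSpec, ObjectiveTerm
from impelo.phantoms import StructureSet


def nnls_bruteforce(A: np.ndarray, b: np.ndarray):
    """Global nonnegative least squares by enumerating all active sets.

    Exact for small column counts: the NNLS optimum is the least-squares
    solution on some subset of columns with all coefficients nonnegative.
    """
    A = np.asarray(A, dtype=float)
    b = np.asarray(b, dtype=float)
    n = A.shape[1]
    best_x = np.zeros(n)
    best_f = float(b @ b)
    for r in range(1, n + 1):
        for subset in itertools.combinations(range(n), r):
            cols = list(subset)
            sol, *_ = np.linalg.lstsq(A[:, cols], b, rcond=None)
            if np.any(sol < -1e-9):
                continue
            x = np.zeros(n)
            x[cols] = np.clip(sol, 0.0, None)
            resid = A @ x - b
            f = float(resid @ resid)
            if f < best_f - 1e-15:
                best_f, best_x = f, x
    return best_x, best_f


def toy_problem(A: np.ndarray, block_cols: list[np.ndarray], level: float = 1.0):
    """Wrap a dense nonnegative matrix as an influence matrix + single-L2
    objective with target vector ``level * ones`` (grid shape (m, 1, 1))."""
    A = np.asarray(A, dtype=float)
    if np.any(A < 0):
        raise ValueError("influence entries must be nonnegative")
    m, n = A.shape
    blocks = [
        Block(beam=0, energy_index=i, energy_mev=100.0 + i,
              cols=np.asarray(c, dtype=int))
        for i, c in enumerate(block_cols)
    ]
    grid = GridSpec(shape=(m, 1, 1), spacing=np.ones(3), origin=np.zeros(3))
    infl = InfluenceMatrix(D=sparse.csc_matrix(A), blocks=blocks, grid=grid)
    mask = np.ones((m, 1, 1), dtype=bool)
    structures = StructureSet(masks={"body": mask, "ctv": mask})
    spec = ObjectiveSpec(
        terms=[ObjectiveTerm("l2", "ctv", level, 1.0)], prescription=level
    )
    return infl, spec, structures


def orthonormal_block_instance(rng: np.random.Generator, ne: int,
                               cols_per_block: int, m: int):
    """Nonnegative matrix with orthonormal columns (disjoint row supports)
    and a target in the nonnegative cone of the columns."""
    n = ne * cols_per_block
    assert m >= n
    perm = rng.permutation(m)
    A = np.zeros((m, n))
    rows_per_col = m // n
    for j in range(n):
        rows = perm[j * rows_per_col:(j + 1) * rows_per_col]
        v = rng.uniform(0.2, 1.0, size=rows.size)
        A[rows, j] = v / np.linalg.norm(v)
    x_true = rng.uniform(0.0, 2.0, size=n) * (rng.random(n) < 0.7)
    b = A @ x_true
    blocks = [np.arange(i * cols_per_block, (i + 1) * cols_per_block)
              for i in range(ne)]
    return A, blocks, b


def wepl_fine_integration(phantom, calibration, p0, p1, step: float = 0.01):
    """Midpoint-rule line integral of relative density at ``step`` mm."""
    from impelo.beam_model import hu_to_density

    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    length = float(np.linalg.norm(p1 - p0))
    u = (p1 - p0) / length
    ns = int(np.ceil(length / step))
    s = (np.arange(ns) + 0.5) * (length / ns)
    pts = p0[None, :] + s[:, None] * u[None, :]
    lower = phantom.lower_corner
    idx = np.floor((pts - lower[None, :]) / phantom.spacing[None, :]).astype(int)
    inside = np.all(
        (idx >= 0) & (idx < np.array(phantom.shape)[None, :]), axis=1
    )
    dens = np.zeros(ns)
    if inside.any():
        hu = phantom.hu[idx[inside, 0], idx[inside, 1], idx[inside, 2]]
        dens[inside] = hu_to_density(calibration, hu)
    return float(dens.sum() * (length / ns))


def gamma_pass_rate_bruteforce(ref: np.ndarray, ev: np.ndarray, spacing,
                               dd_pct: float, dta: float,
                               threshold: float = 0.1,
                               step: float = 0.2) -> float:
    """Exhaustive gamma pass rate with a fine (``step`` mm) search lattice.

    A voxel passes iff some evaluated sample within DTA satisfies
    (dd/DD)^2 + (dr/DTA)^2 <= 1; offsets beyond DTA cannot help.
    Out-of-grid samples clamp to the nearest edge (per axis), matching the
    nearest-mode interpolation convention.
    """
    ref = np.asarray(ref, dtype=float)
    ev = np.asarray(ev, dtype=float)
    spacing = np.asarray(spacing, dtype=float)
    gmax = ref.max()
    dd_abs = dd_pct / 100.0 * gmax
    axes = [spacing[a] * np.arange(ref.shape[a]) for a in range(3)]
    interp = RegularGridInterpolator(axes, ev, bounds_error=False)
    include = ref >= threshold * gmax
    pts = np.argwhere(include) * spacing[None, :]
    ref_vals = ref[include]

    k = int(np.floor(dta / step))
    o1 = step * np.arange(-k, k + 1)
    ox, oy, oz = np.meshgrid(o1, o1, o1, indexing="ij")
    offs = np.stack([ox.ravel(), oy.ravel(), oz.ravel()], axis=1)
    r2 = (offs**2).sum(axis=1)
    offs, r2 = offs[r2 <= dta**2 + 1e-12], r2[r2 <= dta**2 + 1e-12]

    passed = np.zeros(pts.shape[0], dtype=bool)
    hi = np.array([ax[-1] for ax in axes])
    for off, rr in zip(offs, r2):
        todo = ~passed
        if not todo.any():
            break
        sample = np.clip(pts[todo] + off[None, :], 0.0, hi[None, :])
        vals = interp(sample)
        g2 = ((vals - ref_vals[todo]) / dd_abs) ** 2 + rr / dta**2
        passed[np.flatnonzero(todo)[g2 <= 1.0 + 1e-12]] = True
    return 100.0 * float(passed.mean())
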