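"""Pencil-beam dose engine: ray tracing, spot placement, influence matrix.

The dose of one scanned proton spot is modelled as the product of the layer's
integrated depth dose (evaluated at the water-equivalent depth along the spot
axis) and two independent lateral Gaussians whose widths combine the
divergence-scaled in-air spot size with multiple-scattering growth in the
medium.  Water-equivalent depth is computed once along each spot's central
axis by exact Siddon-style voxel traversal and reused laterally - the
standard pencil-beam approximation and its main fidelity limit in strongly
heterogeneous geometry.

The per-spot dose columns are assembled into a sparse nonnegative influence
matrix ``D`` (voxels x spots) whose columns are grouped into *blocks*, one
per (beam, energy layer).  The ordered block map is the partition the
energy-layer selection algorithms operate on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .beam_model import BeamModel, CTCalibrationCurve, IDD_TAIL_MM, \
    hu_to_density, sigma_mcs
from .phantoms import Phantom

__all__ = [
    "BeamGeometry",
    "Spot",
    "Block",
    "SpotSet",
    "GridSpec",
    "InfluenceMatrix",
    "DoseDistribution",
    "wepl_along_ray",
    "place_spots",
    "spot_dose",
    "assemble_influence",
    "dose_from_weights",
]


@dataclass
class BeamGeometry:
    """One treatment field: gantry angle in the axial plane + isocenter."""

    gantry_angle_deg: float
    iso: np.ndarray
    sad_x: float = 1900.0
    sad_y: float = 2300.0

    def __post_init__(self):
        self.iso = np.asarray(self.iso, dtype=float).reshape(3)

    @property
    def u0(self) -> np.ndarray:
        """Central beam direction (unit); angle 0 deg enters along -y."""
        th = np.deg2rad(self.gantry_angle_deg)
        return -np.array([np.sin(th), np.cos(th), 0.0])

    @property
    def ey(self) -> np.ndarray:
        """Scanning-y direction = patient z (couch axis)."""
        return np.array([0.0, 0.0, 1.0])

    @property
    def ex(self) -> np.ndarray:
        """Scanning-x direction, in the axial plane, right-handed with u0."""
        return np.cross(self.ey, self.u0)

    def spot_axis(self, x: float, y: float) -> tuple[np.ndarray, np.ndarray]:
        """Point at isocenter plane and unit direction of the (x, y) spot axis.

        Each scanning axis diverges from its own virtual source (sad_x /
        sad_y upstream of isocenter), so the axis direction tilts with the
        spot's lateral position.
        """
        p0 = self.iso + x * self.ex + y * self.ey
        d = self.u0 + (x / self.sad_x) * self.ex + (y / self.sad_y) * self.ey
        return p0, d / np.linalg.norm(d)


@dataclass
class Spot:
    beam: int
    energy_index: int
    energy_mev: float
    x: float            # lateral position at isocenter plane [mm]
    y: float
    weight: float = 0.0  # MU

    def __post_init__(self):
        if self.weight < 0:
            raise ValueError("spot weight must be >= 0")


@dataclass
class Block:
    """One (beam, energy layer) group of influence-matrix columns."""

    beam: int
    energy_index: int
    energy_mev: float
    cols: np.ndarray    # column indices into D, contiguous, ascending


@dataclass
class SpotSet:
    spots: list[Spot]
    blocks: list[Block]
    geometries: list[BeamGeometry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.spots)

    def validate_partition(self) -> None:
        """Blocks must partition [0, n) exactly and be non-empty."""
        all_cols = np.concatenate([b.cols for b in self.blocks]) if self.blocks else \
            np.array([], dtype=int)
        if any(b.cols.size == 0 for b in self.blocks):
            raise ValueError("empty block in partition")
        if not np.array_equal(np.sort(all_cols), np.arange(len(self.spots))):
            raise ValueError("block map does not partition the spot indices")

    @property
    def weights(self) -> np.ndarray:
        return np.array([s.weight for s in self.spots])

    def with_weights(self, w: np.ndarray) -> "SpotSet":
        w = np.asarray(w, dtype=float)
        if w.shape != (len(self.spots),):
            raise ValueError("weight vector length mismatch")
        spots = [
            Spot(s.beam, s.energy_index, s.energy_mev, s.x, s.y, float(wi))
            for s, wi in zip(self.spots, w)
        ]
        return SpotSet(spots=spots, blocks=self.blocks, geometries=self.geometries)


@dataclass
class GridSpec:
    shape: tuple[int, int, int]
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self):
        self.shape = tuple(int(s) for s in self.shape)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)

    @classmethod
    def from_phantom(cls, ph: Phantom) -> "GridSpec":
        return cls(shape=ph.shape, spacing=ph.spacing.copy(), origin=ph.origin.copy())

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))


@dataclass
class InfluenceMatrix:
    """Nonnegative sparse (voxels x spots) dose-per-MU matrix with block map."""

    D: sparse.csc_matrix
    blocks: list[Block]
    grid: GridSpec
    spot_set: SpotSet | None = None

    _csr_cache: sparse.csr_matrix | None = field(default=None, repr=False)

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def csr(self) -> sparse.csr_matrix:
        if self._csr_cache is None:
            self._csr_cache = self.D.tocsr()
        return self._csr_cache


@dataclass
class DoseDistribution:
    """Per-voxel dose (percent of prescription), flat ordering = C order."""

    values: np.ndarray
    grid: GridSpec

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size != self.grid.n_voxels:
            raise ValueError("dose vector does not match grid size")

    def as_array(self) -> np.ndarray:
        return self.values.reshape(self.grid.shape)


# ---------------------------------------------------------------------------
# ray tracing

def _ray_cumulative_wepl(density: np.ndarray, spacing, lower, p0, u, length):
    """Siddon-style exact traversal: breakpoints s_i and cumulative WEPL.

    Returns (s, cum) with s ascending in [0, length], cum[i] = WEPL from the
    start of the segment to s[i].  Voxels outside the grid contribute zero.
    """
    shape = density.shape
    ts = [np.array([0.0, length])]
    for a in range(3):
        if abs(u[a]) > 1e-12:
            planes = lower[a] + spacing[a] * np.arange(shape[a] + 1)
            t = (planes - p0[a]) / u[a]
            ts.append(t[(t > 0.0) & (t < length)])
    s = np.unique(np.concatenate(ts))
    mids = 0.5 * (s[:-1] + s[1:])
    pts = p0[None, :] + mids[:, None] * u[None, :]
    idx = np.floor((pts - lower[None, :]) / spacing[None, :]).astype(int)
    inside = np.all((idx >= 0) & (idx < np.array(shape)[None, :]), axis=1)
    dens = np.zeros(mids.size)
    if inside.any():
        ii = idx[inside]
        dens[inside] = density[ii[:, 0], ii[:, 1], ii[:, 2]]
    cum = np.concatenate([[0.0], np.cumsum(dens * np.diff(s))])
    return s, cum, idx, inside


def wepl_along_ray(
    phantom: Phantom,
    calibration: CTCalibrationCurve,
    source,
    target,
) -> float:
    """Water-equivalent path length [mm] of the segment source -> target."""
    source = np.asarray(source, dtype=float)
    target = np.asarray(target, dtype=float)
    seg = target - source
    length = float(np.linalg.norm(seg))
    if length <= 0:
        raise ValueError("degenerate zero-length ray")
    density = hu_to_density(calibration, phantom.hu)
    _, cum, _, _ = _ray_cumulative_wepl(
        density, phantom.spacing, phantom.lower_corner, source, seg / length, length
    )
    return float(cum[-1])


def _box_entry_exit(lower, upper, p0, u):
    """Slab intersection of line p0 + t*u with the grid box; (t_in, t_out)."""
    t_in, t_out = -np.inf, np.inf
    for a in range(3):
        if abs(u[a]) > 1e-12:
            t1 = (lower[a] - p0[a]) / u[a]
            t2 = (upper[a] - p0[a]) / u[a]
            t_in = max(t_in, min(t1, t2))
            t_out = min(t_out, max(t1, t2))
        elif not (lower[a] <= p0[a] <= upper[a]):
            return None
    if t_out <= t_in:
        return None
    return t_in, t_out


# ---------------------------------------------------------------------------
# spot placement

def place_spots(
    phantom: Phantom,
    calibration: CTCalibrationCurve,
    ctv_mask: np.ndarray,
    geometries: list[BeamGeometry],
    model: BeamModel,
    lateral_spacing: float | None = None,
    margin: float = 5.0,
) -> SpotSet:
    """Energy layers and lateral spot lattice covering the target.

    Per beam, candidate spot axes form a regular lattice (spacing defaults to
    the in-air sigma of the model's middle layer) over the target's projection
    onto the isocenter plane, expanded by ``margin`` mm.  Energy layers are
    those whose distal range r80 falls inside the target's water-equivalent
    depth interval [min - margin, max + margin]; each layer keeps the lattice
    nodes whose own WEPL interval (+- margin) contains the layer's r80.

    Blocks are ordered (beam ascending, energy descending: distal first);
    spots run row-major in the lattice.
    """
    if not ctv_mask.any():
        raise ValueError("target mask is empty")
    if lateral_spacing is None:
        lateral_spacing = model.layers[len(model.layers) // 2].sigma_air
    density = hu_to_density(calibration, phantom.hu)
    lower, upper = phantom.lower_corner, phantom.upper_corner
    ctv_idx = np.argwhere(ctv_mask)
    ctv_pts = phantom.origin[None, :] + ctv_idx * phantom.spacing[None, :]

    spots: list[Spot] = []
    blocks: list[Block] = []
    ranges = model.ranges
    col = 0
    for bi, geom in enumerate(geometries):
        rel = ctv_pts - geom.iso[None, :]
        zeta = rel @ geom.u0
        px = (rel @ geom.ex) * geom.sad_x / (geom.sad_x + zeta)
        py = (rel @ geom.ey) * geom.sad_y / (geom.sad_y + zeta)
        xs = np.arange(px.min() - margin, px.max() + margin + 1e-9, lateral_spacing)
        ys = np.arange(py.min() - margin, py.max() + margin + 1e-9, lateral_spacing)

        nodes = []  # (x, y, w_entry, w_exit) for axes crossing the target
        for y in ys:               # row-major: y outer, x inner
            for x in xs:
                p0, u = geom.spot_axis(x, y)
                hit = _box_entry_exit(lower, upper, p0, u)
                if hit is None:
                    continue
                t_in, t_out = hit
                entry = p0 + t_in * u
                s, cum, idx, inside = _ray_cumulative_wepl(
                    density, phantom.spacing, lower, entry, u, t_out - t_in
                )
                in_ctv = np.zeros(inside.size, dtype=bool)
                if inside.any():
                    ii = idx[inside]
                    in_ctv[inside] = ctv_mask[ii[:, 0], ii[:, 1], ii[:, 2]]
                if not in_ctv.any():
                    continue
                segs = np.nonzero(in_ctv)[0]
                w_entry = float(cum[segs[0]])
                w_exit = float(cum[segs[-1] + 1])
                nodes.append((float(x), float(y), w_entry, w_exit))
        if not nodes:
            raise ValueError(
                f"beam {bi} (gantry {geom.gantry_angle_deg} deg): no spot axis "
                "intersects the target"
            )
        w_entries = np.array([n[2] for n in nodes])
        w_exits = np.array([n[3] for n in nodes])
        if w_exits.max() > model.max_range:
            raise ValueError(
                f"target WEPL {w_exits.max():.1f} mm exceeds the maximum beam "
                f"range r80 = {model.max_range:.1f} mm"
            )
        wmin, wmax = w_entries.min() - margin, w_exits.max() + margin
        layer_ids = [i for i in range(len(ranges)) if wmin <= ranges[i] <= wmax]
        if not layer_ids:
            raise ValueError(
                f"beam {bi}: no energy layer with r80 in [{wmin:.1f}, {wmax:.1f}] mm"
            )
        for li in sorted(layer_ids, key=lambda i: -ranges[i]):  # distal first
            r80 = ranges[li]
            layer_spots = [
                Spot(bi, li, model.layers[li].nominal_energy, x, y)
                for (x, y, we, wx) in nodes
                if we - margin <= r80 <= wx + margin
            ]
            if not layer_spots:
                continue
            cols = np.arange(col, col + len(layer_spots))
            col += len(layer_spots)
            spots.extend(layer_spots)
            blocks.append(
                Block(bi, li, model.layers[li].nominal_energy, cols)
            )
    ss = SpotSet(spots=spots, blocks=blocks, geometries=list(geometries))
    ss.validate_partition()
    return ss


# ---------------------------------------------------------------------------
# per-spot dose

def spot_dose(
    phantom: Phantom,
    calibration: CTCalibrationCurve,
    spot: Spot,
    geom: BeamGeometry,
    model: BeamModel,
    cutoff: float = 1e-4,
    _density: np.ndarray | None = None,
    _trace=None,
):
    """Sparse dose column of one spot per MU: (flat voxel indices, values).

    dose(v) = IDD(wepl(v)) * G(dx; sigma_x) * G(dy; sigma_y), lateral offsets
    measured from the diverging spot axis; entries below cutoff * max dropped.
    """
    layer = model.layers[spot.energy_index]
    density = _density if _density is not None else hu_to_density(
        calibration, phantom.hu
    )
    lower, upper = phantom.lower_corner, phantom.upper_corner

    if _trace is None:
        p0, u = geom.spot_axis(spot.x, spot.y)
        hit = _box_entry_exit(lower, upper, p0, u)
        if hit is None:
            return np.array([], dtype=int), np.array([])
        t_in, t_out = hit
        entry = p0 + t_in * u
        s, cum, _, _ = _ray_cumulative_wepl(
            density, phantom.spacing, lower, entry, u, t_out - t_in
        )
    else:
        entry, u, s, cum = _trace

    w_max = layer.r80 + IDD_TAIL_MM
    if cum[-1] >= w_max:
        s_end = float(np.interp(w_max, cum, s))
    else:
        s_end = float(s[-1])
    if s_end <= 0:
        return np.array([], dtype=int), np.array([])

    # transverse basis perpendicular to the spot axis
    ey = geom.ey - (geom.ey @ u) * u
    ey /= np.linalg.norm(ey)
    ex = np.cross(ey, u)

    sa = layer.sigma_air
    r_lat = 3.5 * np.sqrt((1.2 * sa) ** 2 + (0.025 * layer.r80) ** 2) + float(
        phantom.spacing.max()
    )
    pa, pb = entry, entry + s_end * u
    lo_pt = np.minimum(pa, pb) - r_lat
    hi_pt = np.maximum(pa, pb) + r_lat
    lo = np.maximum(np.floor((lo_pt - lower) / phantom.spacing).astype(int), 0)
    hi = np.minimum(
        np.ceil((hi_pt - lower) / phantom.spacing).astype(int),
        np.array(phantom.shape),
    )
    if np.any(hi <= lo):
        return np.array([], dtype=int), np.array([])

    ax = [phantom.axis_coords(a)[lo[a]:hi[a]] for a in range(3)]
    X = ax[0][:, None, None]
    Y = ax[1][None, :, None]
    Z = ax[2][None, None, :]
    rx, ry, rz = X - entry[0], Y - entry[1], Z - entry[2]
    sv = rx * u[0] + ry * u[1] + rz * u[2]
    w = np.interp(sv, s, cum)
    idd = layer.idd_at(w)
    valid = (sv >= 0) & (sv <= s_end) & (idd > 0)
    if not valid.any():
        return np.array([], dtype=int), np.array([])

    lx = rx * ex[0] + ry * ex[1] + rz * ex[2]
    ly = rx * ey[0] + ry * ey[1] + rz * ey[2]
    zeta = (
        (X - geom.iso[0]) * geom.u0[0]
        + (Y - geom.iso[1]) * geom.u0[1]
        + (Z - geom.iso[2]) * geom.u0[2]
    )
    mag_x = np.clip((geom.sad_x + zeta) / geom.sad_x, 0.1, None)
    mag_y = np.clip((geom.sad_y + zeta) / geom.sad_y, 0.1, None)
    smcs = sigma_mcs(layer, np.clip(w, 0.0, None))
    sx = np.sqrt((sa * mag_x) ** 2 + smcs**2)
    sy = np.sqrt((sa * mag_y) ** 2 + smcs**2)
    val = np.zeros_like(idd)
    val[valid] = (
        idd[valid]
        * np.exp(-0.5 * (lx[valid] / sx[valid]) ** 2
                 - 0.5 * (ly[valid] / sy[valid]) ** 2)
        / (2.0 * np.pi * sx[valid] * sy[valid])
    )
    vmax = val.max()
    if vmax <= 0:
        return np.array([], dtype=int), np.array([])
    keep = val > cutoff * vmax if cutoff > 0 else val > 0
    ki, kj, kk = np.nonzero(keep)
    flat = np.ravel_multi_index(
        (ki + lo[0], kj + lo[1], kk + lo[2]), phantom.shape
    )
    return flat, val[keep]


def assemble_influence(
    phantom: Phantom,
    calibration: CTCalibrationCurve,
    spot_set: SpotSet,
    model: BeamModel,
    cutoff: float = 1e-4,
    nnz_budget: float = 2e8,
) -> InfluenceMatrix:
    """Dose-influence matrix with columns in block-map order.

    Raises before computing anything if a rough upper bound on the stored
    nonzeros exceeds ``nnz_budget``.
    """
    if not spot_set.spots:
        raise ValueError("spot set is empty")
    spot_set.validate_partition()
    n = len(spot_set.spots)
    est = n * min(phantom.n_voxels, 40_000)
    if est > nnz_budget:
        raise MemoryError(
            f"estimated nonzeros {est:.2e} exceed budget {nnz_budget:.2e}; "
            "coarsen the grid, raise the cutoff, or raise nnz_budget"
        )
    density = hu_to_density(calibration, phantom.hu)
    lower, upper = phantom.lower_corner, phantom.upper_corner

    trace_cache: dict[tuple, tuple] = {}
    rows, cols, vals = [], [], []
    for j, spot in enumerate(spot_set.spots):
        geom = spot_set.geometries[spot.beam]
        key = (spot.beam, spot.x, spot.y)
        tr = trace_cache.get(key)
        if tr is None:
            p0, u = geom.spot_axis(spot.x, spot.y)
            hit = _box_entry_exit(lower, upper, p0, u)
            if hit is None:
                tr = False
            else:
                t_in, t_out = hit
                entry = p0 + t_in * u
                s, cum, _, _ = _ray_cumulative_wepl(
                    density, phantom.spacing, lower, entry, u, t_out - t_in
                )
                tr = (entry, u, s, cum)
            trace_cache[key] = tr
        if tr is False:
            continue
        r, v = spot_dose(
            phantom, calibration, spot, geom, model,
            cutoff=cutoff, _density=density, _trace=tr,
        )
        rows.append(r)
        cols.append(np.full(r.size, j, dtype=int))
        vals.append(v)
    m = phantom.n_voxels
    D = sparse.csc_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(m, n),
    )
    return InfluenceMatrix(
        D=D,
        blocks=spot_set.blocks,
        grid=GridSpec.from_phantom(phantom),
        spot_set=spot_set,
    )


def dose_from_weights(influence: InfluenceMatrix, x: np.ndarray) -> DoseDistribution:
    """d = D x."""
    x = np.asarray(x, dtype=float).ravel()
    if x.size != influence.D.shape[1]:
        raise ValueError(
            f"weight vector length {x.size} != number of spots {influence.D.shape[1]}"
        )
    return DoseDistribution(values=influence.D @ x, grid=influence.grid)
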