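"""Synthetic voxel phantoms and structure sets for end-to-end planning tests.

Provides a uniform water tank plus three anatomy-flavoured presets (abdomen,
brain, lung) with the clinically-typical beam-angle sets.  Geometry is
deliberately simple (ellipsoidal target, capsule-like organs at risk, an
optional low-density shell for the lung) - enough to give each beam a
realistic depth spread and OAR adjacency without any patient data.

Axis convention (used package-wide): array index (i, j, k) maps to patient
(x, y, z) in mm, voxel-center coordinates, 0-based, right-handed.  Gantry
angle 0 deg means the beam enters along -y (from the "anterior" +y side) and
rotates in the axial (x, y) plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Phantom",
    "StructureSet",
    "CasePreset",
    "SyntheticCase",
    "make_water_phantom",
    "make_synthetic_case",
    "PRESET_ANGLES",
]

PRESET_ANGLES = {
    "abdomen": [90.0, 180.0, 270.0],
    "brain": [45.0, 135.0, 225.0, 315.0],
    "lung": [0.0, 60.0, 90.0, 330.0],
    "waterbox": [0.0],
}


@dataclass
class Phantom:
    """HU grid with spacing and origin (mm, voxel-center of index 0)."""

    hu: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self):
        self.hu = np.asarray(self.hu, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive on all axes")
        if not np.all(np.isfinite(self.hu)):
            raise ValueError("HU values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.hu.shape

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.hu.shape))

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def axis_coords(self, axis: int) -> np.ndarray:
        """Voxel-center coordinates along one axis [mm]."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    def coordinate_grids(self):
        """Broadcastable (X, Y, Z) voxel-center coordinate arrays."""
        x = self.axis_coords(0)[:, None, None]
        y = self.axis_coords(1)[None, :, None]
        z = self.axis_coords(2)[None, None, :]
        return x, y, z

    @property
    def lower_corner(self) -> np.ndarray:
        """Outer corner of voxel (0,0,0) [mm]."""
        return self.origin - 0.5 * self.spacing

    @property
    def upper_corner(self) -> np.ndarray:
        return self.lower_corner + self.spacing * np.array(self.shape)


@dataclass
class StructureSet:
    """Named boolean masks on the phantom grid; 'body' and 'ctv' mandatory."""

    masks: dict[str, np.ndarray]

    def __post_init__(self):
        for key in ("body", "ctv"):
            if key not in self.masks:
                raise ValueError(f"structure set must contain a '{key}' mask")
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) != 1:
            raise ValueError("all masks must share one grid shape")
        if np.any(self.masks["ctv"] & ~self.masks["body"]):
            raise ValueError("ctv must be a subset of body")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    @property
    def names(self) -> list[str]:
        return list(self.masks)

    @property
    def oar_names(self) -> list[str]:
        return [n for n in self.masks if n not in ("body", "ctv")]


@dataclass
class CasePreset:
    """Parameters of one synthetic scenario."""

    name: str
    seed: int = 0
    spacing: float = 2.0          # mm, isotropic
    beam_angles: list[float] = field(default_factory=list)
    heterogeneity: bool = False

    def __post_init__(self):
        if self.name not in PRESET_ANGLES:
            raise ValueError(
                f"unknown preset {self.name!r}; choose from {sorted(PRESET_ANGLES)}"
            )
        if not self.beam_angles:
            self.beam_angles = list(PRESET_ANGLES[self.name])
        if any(not (0 <= a < 360) for a in self.beam_angles):
            raise ValueError("gantry angles must lie in [0, 360)")
        if self.name == "lung":
            self.heterogeneity = True


@dataclass
class SyntheticCase:
    phantom: Phantom
    structures: StructureSet
    beam_angles: list[float]
    preset: CasePreset


def make_water_phantom(side: float, spacing: float) -> Phantom:
    """Uniform HU = 0 cube of edge ``side`` mm; grid size floor(side/spacing)."""
    if side <= 0 or spacing <= 0:
        raise ValueError("side and spacing must be positive")
    n = int(side // spacing)
    if n < 1:
        raise ValueError("side smaller than one voxel")
    sp = np.array([spacing] * 3)
    return Phantom(hu=np.zeros((n, n, n)), spacing=sp, origin=0.5 * sp)


def _centered_phantom(extent_mm, spacing: float, hu_value: float = -1000.0) -> Phantom:
    shape = tuple(int(round(e / spacing)) for e in extent_mm)
    sp = np.array([spacing] * 3)
    origin = -0.5 * (np.array(shape) - 1) * sp  # grid centered on (0,0,0)
    return Phantom(hu=np.full(shape, hu_value), spacing=sp, origin=origin)


def _ellipsoid(ph: Phantom, center, semi) -> np.ndarray:
    x, y, z = ph.coordinate_grids()
    c, s = np.asarray(center, float), np.asarray(semi, float)
    return (
        ((x - c[0]) / s[0]) ** 2 + ((y - c[1]) / s[1]) ** 2 + ((z - c[2]) / s[2]) ** 2
    ) <= 1.0


def _zcylinder(ph: Phantom, center_xy, radius, z_range=None) -> np.ndarray:
    x, y, z = ph.coordinate_grids()
    m = ((x - center_xy[0]) ** 2 + (y - center_xy[1]) ** 2) <= radius**2
    m = np.broadcast_to(m, ph.shape).copy()
    if z_range is not None:
        m &= (z >= z_range[0]) & (z <= z_range[1])
    return m


def make_synthetic_case(preset: CasePreset) -> SyntheticCase:
    """Deterministic phantom + structures + beam angles for one preset/seed.

    Target and OAR centers/sizes carry a small seeded jitter so different
    seeds give geometrically distinct but equally valid cases.
    """
    rng = np.random.default_rng(preset.seed)
    jc = rng.uniform(-3.0, 3.0, size=3)        # center jitter [mm]
    js = rng.uniform(-1.5, 1.5, size=3)        # semi-axis jitter [mm]
    sp = preset.spacing

    if preset.name == "waterbox":
        ph = make_water_phantom(100.0, sp)
        mid = ph.origin + 0.5 * sp * (np.array(ph.shape) - 1)
        ctv = _ellipsoid(ph, mid + jc, np.array([12.0, 12.0, 12.0]) + js)
        body = np.ones(ph.shape, dtype=bool)
        masks = {"body": body, "ctv": ctv}

    elif preset.name == "abdomen":
        ph = _centered_phantom((116, 96, 72), sp)
        x, y, z = ph.coordinate_grids()
        body = np.broadcast_to(
            ((x / 52.0) ** 2 + (y / 42.0) ** 2) <= 1.0, ph.shape
        ).copy()
        ph.hu[body] = 30.0
        ctv = _ellipsoid(ph, jc + np.array([0.0, 4.0, 0.0]),
                         np.array([12.0, 10.0, 11.0]) + js)
        kidney = _ellipsoid(ph, np.array([30.0, -8.0, 0.0]) + 0.5 * jc,
                            np.array([9.0, 8.0, 12.0]))
        masks = {"body": body, "ctv": ctv & body, "kidney": kidney & body}

    elif preset.name == "brain":
        ph = _centered_phantom((100, 100, 100), sp)
        skull_outer = _ellipsoid(ph, (0, 0, 0), (46, 46, 46))
        skull_inner = _ellipsoid(ph, (0, 0, 0), (42, 42, 42))
        ph.hu[skull_outer] = 700.0          # bone shell
        ph.hu[skull_inner] = 25.0           # brain tissue
        body = skull_outer
        ctv = _ellipsoid(ph, np.array([12.0, 8.0, 0.0]) + jc,
                         np.array([11.0, 9.0, 10.0]) + js)
        brainstem = _zcylinder(ph, (-6.0 + 0.5 * jc[0], -8.0), 6.0,
                               z_range=(-20.0, 20.0)) & skull_inner
        masks = {"body": body, "ctv": ctv & body, "brainstem": brainstem}

    elif preset.name == "lung":
        ph = _centered_phantom((140, 120, 80), sp)
        x, y, z = ph.coordinate_grids()
        body = np.broadcast_to(
            ((x / 64.0) ** 2 + (y / 54.0) ** 2) <= 1.0, ph.shape
        ).copy()
        ph.hu[body] = 30.0
        c_ctv = np.array([-20.0, -4.0, 0.0]) + jc
        s_ctv = np.array([10.0, 9.0, 10.0]) + js
        ctv = _ellipsoid(ph, c_ctv, s_ctv)
        shell = _ellipsoid(ph, c_ctv, s_ctv + 13.0) & ~_ellipsoid(
            ph, c_ctv, s_ctv + 3.0
        ) & body
        ph.hu[shell] = -700.0               # low-density lung tissue
        esophagus = _zcylinder(ph, (8.0, -8.0), 5.0) & body
        masks = {"body": body, "ctv": ctv & body, "esophagus": esophagus}

    else:  # pragma: no cover - guarded by CasePreset
        raise ValueError(f"unknown preset {preset.name!r}")

    if not masks["ctv"].any():
        raise RuntimeError("preset produced an empty CTV")
    return SyntheticCase(
        phantom=ph,
        structures=StructureSet(masks=masks),
        beam_angles=list(preset.beam_angles),
        preset=preset,
    )
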