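"""Machine beam model: energy grid, depth-dose curves, spot widths, CT calibration.

The clinical base data behind a proton pencil-beam-scanning machine (integrated
depth dose per energy, distal range, spot size in air and in water) are
machine-specific.  This module synthesizes a physically plausible stand-in from
an analytic range-energy power law ``R = alpha * E**p`` with a Bohr-style range
straggling width, so that every downstream stage (spot placement, influence
matrix, energy-layer selection) can be exercised on a self-contained model.

Conventions
-----------
* energies in MeV, depths and ranges in mm of water, spot sigmas in mm
* an *energy layer* is one nominal energy; its IDD is the laterally integrated
  dose of a single spot versus water-equivalent depth, per monitor unit (MU)
* ``r80`` is the distal depth at which the IDD falls to 80 % of its peak; by
  construction it equals ``alpha * E**p`` for the synthetic curves
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "EnergyLayer",
    "BeamModel",
    "CTCalibrationCurve",
    "energy_grid",
    "proton_range",
    "synthesize_bragg_idd",
    "sigma_mcs",
    "sigma_at_depth",
    "hu_to_density",
    "default_beam_model",
    "default_calibration",
]

#: range-energy power law R[mm] = RANGE_ALPHA_MM * E[MeV] ** RANGE_EXPONENT
RANGE_ALPHA_MM = 0.022
RANGE_EXPONENT = 1.77

#: Bohr-style range straggling sigma [mm] as a function of range [mm]
STRAGGLING_COEFF = 0.012
STRAGGLING_EXPONENT = 0.935

#: multiple-scattering sigma at end of range, as a fraction of r80
MCS_END_FRACTION = 0.025

#: IDD peak value at the reference energy, in dose*mm^2 per MU (dose in % of
#: a nominal prescription); one global scale, the shape per energy is analytic
IDD_PEAK_REFERENCE = 20.0
IDD_REFERENCE_ENERGY = 150.0

#: IDD support ends where the curve falls below 0.1 % of peak; guaranteed
#: within this many mm past r80
IDD_TAIL_MM = 30.0


def energy_grid(e_min: float, e_max: float, step: float) -> np.ndarray:
    """Inclusive arithmetic grid of nominal energies [MeV]."""
    if step <= 0:
        raise ValueError(f"energy step must be positive, got {step}")
    if e_max < e_min:
        raise ValueError(f"e_max ({e_max}) < e_min ({e_min})")
    n = int(round((e_max - e_min) / step)) + 1
    grid = e_min + step * np.arange(n)
    return grid[grid <= e_max + 1e-9]


def proton_range(energy, alpha: float = RANGE_ALPHA_MM, p: float = RANGE_EXPONENT):
    """Continuous-slowing-down range in water [mm] from the power law."""
    return alpha * np.asarray(energy, dtype=float) ** p


def _sigma_air_default(energy: float) -> float:
    """Spot sigma in air at isocenter [mm]; decreases with energy (2.6-7 mm)."""
    return 2.0 + 5.0 * (70.0 / energy) ** 1.8


@dataclass
class EnergyLayer:
    """One nominal beam energy with its sampled depth-dose curve."""

    nominal_energy: float           # MeV
    depths: np.ndarray              # water-equivalent depth grid [mm]
    idd: np.ndarray                 # integrated depth dose [dose*mm^2 / MU]
    r80: float                      # distal 80 % range [mm]
    peak_depth: float               # depth of IDD maximum [mm]
    sigma_air: float                # initial lateral sigma at isocenter [mm]

    def idd_at(self, depth):
        """IDD interpolated at water-equivalent depth(s); zero outside support."""
        return np.interp(depth, self.depths, self.idd, left=0.0, right=0.0)

    def to_dict(self) -> dict:
        return {
            "nominal_energy": self.nominal_energy,
            "depths": self.depths.tolist(),
            "idd": self.idd.tolist(),
            "r80": self.r80,
            "peak_depth": self.peak_depth,
            "sigma_air": self.sigma_air,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EnergyLayer":
        return cls(
            nominal_energy=float(d["nominal_energy"]),
            depths=np.asarray(d["depths"], dtype=float),
            idd=np.asarray(d["idd"], dtype=float),
            r80=float(d["r80"]),
            peak_depth=float(d["peak_depth"]),
            sigma_air=float(d["sigma_air"]),
        )


def _distal_crossing(depths: np.ndarray, idd: np.ndarray, level: float) -> float:
    """Distal depth where idd crosses ``level`` (linear interpolation)."""
    ipk = int(np.argmax(idd))
    tail_d, tail_v = depths[ipk:], idd[ipk:]
    below = np.nonzero(tail_v < level)[0]
    if below.size == 0:
        return float(tail_d[-1])
    i = below[0]
    if i == 0:
        return float(tail_d[0])
    d0, d1 = tail_d[i - 1], tail_d[i]
    v0, v1 = tail_v[i - 1], tail_v[i]
    return float(d0 + (v0 - level) * (d1 - d0) / (v0 - v1))


def synthesize_bragg_idd(
    energy: float,
    depth_step: float = 1.0,
    e_bounds: tuple[float, float] = (70.0, 225.0),
    alpha: float = RANGE_ALPHA_MM,
    p: float = RANGE_EXPONENT,
    sigma_air: float | None = None,
) -> EnergyLayer:
    """Analytic Bragg curve for one energy, sampled at ``depth_step`` [mm].

    The raw power-law depth dose ``(R - z)**(1/p - 1)`` is convolved with a
    Gaussian range-straggling kernel and the depth axis is rescaled so that
    the distal 80 % point of the smeared curve equals ``alpha * E**p``
    exactly.  A single global factor scales the family so the peak at
    150 MeV is ``IDD_PEAK_REFERENCE``.
    """
    if not (e_bounds[0] - 1e-9 <= energy <= e_bounds[1] + 1e-9):
        raise ValueError(
            f"energy {energy} MeV outside configured bounds {e_bounds}"
        )
    r = float(proton_range(energy, alpha, p))
    fine = 0.1  # internal sampling [mm]
    zmax = r + IDD_TAIL_MM + 10.0
    z = np.arange(0.0, zmax + fine, fine)
    dz = np.clip(r - z, 1e-6, None)
    raw = np.where(z < r, dz ** (1.0 / p - 1.0), 0.0)
    sig = STRAGGLING_COEFF * r ** STRAGGLING_EXPONENT
    smeared = gaussian_filter1d(raw, sig / fine, mode="nearest")
    # rescale depth axis so the distal 80 % point lands exactly on r
    r80_fine = _distal_crossing(z, smeared, 0.8 * float(smeared.max()))
    z_scaled = z * (r / r80_fine)
    depths = np.arange(0.0, r + IDD_TAIL_MM + depth_step, depth_step)
    idd = np.interp(depths, z_scaled, smeared)
    idd[idd < 1e-12] = 0.0
    # one global amplitude for the whole family
    scale = IDD_PEAK_REFERENCE / _reference_peak(alpha, p)
    idd = idd * scale
    peak_depth = float(depths[int(np.argmax(idd))])
    r80 = _distal_crossing(depths, idd, 0.8 * float(idd.max()))
    if sigma_air is None:
        sigma_air = _sigma_air_default(energy)
    return EnergyLayer(
        nominal_energy=float(energy),
        depths=depths,
        idd=idd,
        r80=r80,
        peak_depth=peak_depth,
        sigma_air=float(sigma_air),
    )


@lru_cache(maxsize=8)
def _reference_peak(alpha: float, p: float) -> float:
    """Unscaled smeared-curve peak at the reference energy (amplitude anchor)."""
    r = float(proton_range(IDD_REFERENCE_ENERGY, alpha, p))
    fine = 0.1
    z = np.arange(0.0, r + IDD_TAIL_MM + 10.0 + fine, fine)
    dz = np.clip(r - z, 1e-6, None)
    raw = np.where(z < r, dz ** (1.0 / p - 1.0), 0.0)
    sig = STRAGGLING_COEFF * r ** STRAGGLING_EXPONENT
    return float(gaussian_filter1d(raw, sig / fine, mode="nearest").max())


def sigma_mcs(layer: EnergyLayer, depth):
    """Multiple-scattering lateral growth [mm] at water depth(s) [mm].

    Monotone cubic in t = depth/r80 reaching ``MCS_END_FRACTION * r80`` at
    the end of range, constant beyond.
    """
    t = np.clip(np.asarray(depth, dtype=float) / layer.r80, 0.0, 1.0)
    end = MCS_END_FRACTION * layer.r80
    return end * (1.5 * t**2 - 0.5 * t**3)


def sigma_at_depth(layer: EnergyLayer, depth, sigma_air: float | None = None):
    """Total lateral spot sigma [mm] at water depth(s): quadrature of the
    (divergence-scaled) in-air width and the multiple-scattering growth."""
    d = np.asarray(depth, dtype=float)
    if np.any(d < 0):
        raise ValueError("depth must be >= 0")
    sa = layer.sigma_air if sigma_air is None else sigma_air
    return np.sqrt(sa**2 + sigma_mcs(layer, d) ** 2)


@dataclass
class CTCalibrationCurve:
    """Piecewise-linear HU -> relative electron density calibration."""

    hu: np.ndarray
    density: np.ndarray

    def __post_init__(self):
        self.hu = np.asarray(self.hu, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.hu.size < 2:
            raise ValueError("calibration curve needs at least 2 control points")
        if np.any(np.diff(self.hu) <= 0):
            raise ValueError("calibration HU control points must be increasing")
        if np.any(np.diff(self.density) < 0):
            raise ValueError("calibration curve must be monotone non-decreasing")

    @classmethod
    def from_csv(cls, path) -> "CTCalibrationCurve":
        arr = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        return cls(arr[:, 0], arr[:, 1])

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("hu,density\n")
            for h, d in zip(self.hu, self.density):
                fh.write(f"{float(h)!r},{float(d)!r}\n")


def default_calibration() -> CTCalibrationCurve:
    """Generic water-anchored calibration (air, water, bone-like)."""
    return CTCalibrationCurve(
        hu=[-1000.0, 0.0, 1000.0, 3000.0],
        density=[0.001, 1.0, 1.52, 2.83],
    )


def hu_to_density(curve: CTCalibrationCurve, hu):
    """Relative electron density at HU value(s); clamped at the curve ends."""
    return np.interp(hu, curve.hu, curve.density)


@dataclass
class BeamModel:
    """Ordered set of energy layers plus machine geometry (two virtual SADs)."""

    layers: list[EnergyLayer] = field(default_factory=list)
    sad_x: float = 1900.0   # mm, scanning-x virtual source to isocenter
    sad_y: float = 2300.0   # mm, scanning-y virtual source to isocenter

    def __post_init__(self):
        e = self.energies
        if e.size and np.any(np.diff(e) <= 0):
            raise ValueError("layer energies must be strictly increasing")

    @property
    def energies(self) -> np.ndarray:
        return np.array([l.nominal_energy for l in self.layers])

    @property
    def ranges(self) -> np.ndarray:
        return np.array([l.r80 for l in self.layers])

    @property
    def max_range(self) -> float:
        return float(self.ranges.max())

    def to_dict(self) -> dict:
        return {
            "sad_x": self.sad_x,
            "sad_y": self.sad_y,
            "layers": [l.to_dict() for l in self.layers],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BeamModel":
        return cls(
            layers=[EnergyLayer.from_dict(x) for x in d["layers"]],
            sad_x=float(d["sad_x"]),
            sad_y=float(d["sad_y"]),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "BeamModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@lru_cache(maxsize=4)
def default_beam_model(
    e_min: float = 70.0,
    e_max: float = 225.0,
    step: float = 2.5,
    depth_step: float = 1.0,
    sad_x: float = 1900.0,
    sad_y: float = 2300.0,
) -> BeamModel:
    """Full synthetic machine model on the default 70-225 MeV / 2.5 MeV grid."""
    layers = [
        synthesize_bragg_idd(e, depth_step=depth_step, e_bounds=(e_min, e_max))
        for e in energy_grid(e_min, e_max, step)
    ]
    return BeamModel(layers=layers, sad_x=sad_x, sad_y=sad_y)
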