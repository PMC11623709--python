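"""File formats: spot CSV, NIfTI grids, Matrix Market influence matrices,
YAML planning configs.

The spot CSV is the interchange format for delivering a plan: one row per
spot with the fixed header ``beam_id,gantry_angle_deg,energy_MeV,x_mm,y_mm,mu``
written at full float precision so a write/read round trip is lossless.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml
from scipy import io as sio
from scipy import sparse

from .dose_engine import (
    Block,
    BeamGeometry,
    DoseDistribution,
    GridSpec,
    InfluenceMatrix,
    Spot,
    SpotSet,
)
from .phantoms import Phantom, StructureSet

__all__ = [
    "SPOT_CSV_HEADER",
    "write_spot_csv",
    "read_spot_csv",
    "save_nifti",
    "load_nifti",
    "save_phantom",
    "load_phantom",
    "save_structures",
    "load_structures",
    "save_dose",
    "load_dose",
    "save_influence",
    "load_influence",
    "load_config",
]

SPOT_CSV_HEADER = ["beam_id", "gantry_angle_deg", "energy_MeV", "x_mm", "y_mm", "mu"]


def write_spot_csv(spot_set: SpotSet, path) -> None:
    """One row per spot, block order, full float precision."""
    angles = {i: g.gantry_angle_deg for i, g in enumerate(spot_set.geometries)}
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(SPOT_CSV_HEADER)
        for blk in spot_set.blocks:
            for c in blk.cols:
                s = spot_set.spots[c]
                w.writerow(
                    [s.beam, repr(float(angles.get(s.beam, 0.0))),
                     repr(float(s.energy_mev)), repr(float(s.x)),
                     repr(float(s.y)), repr(float(s.weight))]
                )


def read_spot_csv(path) -> SpotSet:
    """Parse a spot CSV back into a SpotSet (blocks grouped per beam/energy,
    in file order).  Malformed or negative-MU rows fail with the line number."""
    spots: list[Spot] = []
    angle_by_beam: dict[int, float] = {}
    block_order: list[tuple[int, float]] = []
    by_block: dict[tuple[int, float], list[int]] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != SPOT_CSV_HEADER:
            raise ValueError(f"unexpected spot CSV header: {header}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                beam = int(row[0])
                angle = float(row[1])
                energy = float(row[2])
                x, y, mu = float(row[3]), float(row[4]), float(row[5])
            except (ValueError, IndexError) as exc:
                raise ValueError(f"malformed spot row at line {lineno}: {row}") from exc
            if mu < 0:
                raise ValueError(f"negative MU at line {lineno}: {mu}")
            angle_by_beam.setdefault(beam, angle)
            key = (beam, energy)
            if key not in by_block:
                block_order.append(key)
                by_block[key] = []
            by_block[key].append(len(spots))
            spots.append(Spot(beam, -1, energy, x, y, mu))
    blocks = [
        Block(beam=k[0], energy_index=-1, energy_mev=k[1],
              cols=np.array(by_block[k], dtype=int))
        for k in block_order
    ]
    geoms = [
        BeamGeometry(gantry_angle_deg=angle_by_beam[b], iso=np.zeros(3))
        for b in sorted(angle_by_beam)
    ]
    return SpotSet(spots=spots, blocks=blocks, geometries=geoms)


# ---------------------------------------------------------------------------
# NIfTI grids

def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    aff[:3, 3] = origin
    return aff


def save_nifti(array, spacing, origin, path) -> None:
    img = nib.Nifti1Image(np.asarray(array, dtype=np.float32), _affine(spacing, origin))
    nib.save(img, str(path))


def load_nifti(path):
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    aff = img.affine
    spacing = np.array([aff[0, 0], aff[1, 1], aff[2, 2]])
    origin = aff[:3, 3].copy()
    return data, spacing, origin


def save_phantom(phantom: Phantom, path) -> None:
    save_nifti(phantom.hu, phantom.spacing, phantom.origin, path)


def load_phantom(path) -> Phantom:
    data, spacing, origin = load_nifti(path)
    return Phantom(hu=data, spacing=spacing, origin=origin)


def save_structures(structures: StructureSet, phantom: Phantom, directory) -> None:
    """One NIfTI mask file per structure, on the phantom grid."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, mask in structures.masks.items():
        save_nifti(mask.astype(np.float32), phantom.spacing, phantom.origin,
                   directory / f"{name}.nii.gz")


def load_structures(directory) -> StructureSet:
    directory = Path(directory)
    masks = {}
    for path in sorted(directory.glob("*.nii.gz")):
        name = path.name[: -len(".nii.gz")]
        data, _, _ = load_nifti(path)
        masks[name] = data > 0.5
    return StructureSet(masks=masks)


def save_dose(dose: DoseDistribution, path) -> None:
    save_nifti(dose.as_array(), dose.grid.spacing, dose.grid.origin, path)


def load_dose(path) -> DoseDistribution:
    data, spacing, origin = load_nifti(path)
    grid = GridSpec(shape=data.shape, spacing=spacing, origin=origin)
    return DoseDistribution(values=data.ravel(), grid=grid)


# ---------------------------------------------------------------------------
# influence matrix interchange

def save_influence(influence: InfluenceMatrix, mtx_path, blockmap_path) -> None:
    """Matrix Market matrix + JSON block-map sidecar."""
    sio.mmwrite(str(mtx_path), influence.D)
    blockmap = {
        "grid": {
            "shape": list(influence.grid.shape),
            "spacing": influence.grid.spacing.tolist(),
            "origin": influence.grid.origin.tolist(),
        },
        "blocks": [
            {
                "block_id": i,
                "beam": blk.beam,
                "energy_MeV": blk.energy_mev,
                "columns": blk.cols.tolist(),
            }
            for i, blk in enumerate(influence.blocks)
        ],
    }
    with open(blockmap_path, "w") as fh:
        json.dump(blockmap, fh)


def load_influence(mtx_path, blockmap_path) -> InfluenceMatrix:
    D = sparse.csc_matrix(sio.mmread(str(mtx_path)))
    with open(blockmap_path) as fh:
        bm = json.load(fh)
    blocks = [
        Block(
            beam=int(b["beam"]),
            energy_index=-1,
            energy_mev=float(b["energy_MeV"]),
            cols=np.asarray(b["columns"], dtype=int),
        )
        for b in bm["blocks"]
    ]
    grid = GridSpec(
        shape=tuple(bm["grid"]["shape"]),
        spacing=np.asarray(bm["grid"]["spacing"]),
        origin=np.asarray(bm["grid"]["origin"]),
    )
    return InfluenceMatrix(D=D, blocks=blocks, grid=grid)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("planning config must be a YAML mapping")
    return cfg
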