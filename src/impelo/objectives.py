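"""DVH-based quadratic plan objective and its violating-voxel sets.

The plan objective is a weighted sum of squared dose deviations:

    f(d, Omega) =  sum_i w1_i ||d_ROI - p||^2            (L2 terms)
                 + sum_i w2_i ||d_Omega2 - b2_i||^2       (DVH-max terms)
                 + sum_i w3_i ||d_Omega3 - b3_i||^2       (DVH-min terms)

where each DVH term only penalizes the subset Omega of its ROI that
currently violates the dose-volume constraint.  For a DVH-max term with
bound D_b and allowed hot-volume fraction v on an ROI of K voxels, the
floor(v*K) hottest voxels are exempt and the remaining voxels above D_b are
penalized; the DVH-min rule is the mirror image (the coldest floor((1-v)*K)
voxels are exempt, the remaining voxels below the bound are penalized).
Holding Omega fixed makes f a convex quadratic in d; alternating
Omega-updates with convex solves is the iterative convex relaxation used by
the inner solver.

All doses are percent of the prescription (100 == prescribed dose).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phantoms import StructureSet

__all__ = [
    "ObjectiveTerm",
    "ObjectiveSpec",
    "ViolationIndex",
    "update_violation_sets",
    "evaluate_objective",
    "objective_gradient",
    "default_objectives",
]

_KINDS = ("l2", "dvh_max", "dvh_min")


@dataclass
class ObjectiveTerm:
    kind: str                 # 'l2' | 'dvh_max' | 'dvh_min'
    roi: str                  # structure name
    dose: float               # level [% of prescription]
    weight: float             # positive
    volume: float | None = None  # DVH volume fraction in [0, 1]

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown objective kind {self.kind!r}")
        if self.weight <= 0:
            raise ValueError("objective weight must be positive")
        if self.kind != "l2":
            if self.volume is None or not (0.0 <= self.volume <= 1.0):
                raise ValueError("DVH terms need a volume fraction in [0, 1]")

    def to_dict(self) -> dict:
        d = {"kind": self.kind, "roi": self.roi, "dose": self.dose,
             "weight": self.weight}
        if self.volume is not None:
            d["volume"] = self.volume
        return d


@dataclass
class ObjectiveSpec:
    terms: list[ObjectiveTerm]
    prescription: float = 100.0

    def __post_init__(self):
        if not any(t.kind == "l2" for t in self.terms):
            raise ValueError("objective needs at least one l2 term on the target")

    @classmethod
    def from_dict(cls, d: dict) -> "ObjectiveSpec":
        terms = [ObjectiveTerm(**t) for t in d["terms"]]
        return cls(terms=terms, prescription=float(d.get("prescription", 100.0)))

    def to_dict(self) -> dict:
        return {
            "prescription": self.prescription,
            "terms": [t.to_dict() for t in self.terms],
        }

    def roi_indices(self, structures: StructureSet) -> list[np.ndarray]:
        """Flat voxel indices per term (C order on the grid)."""
        out = []
        for t in self.terms:
            idx = np.flatnonzero(structures[t.roi].ravel())
            if idx.size == 0:
                raise ValueError(f"ROI {t.roi!r} is empty")
            out.append(idx)
        return out


@dataclass
class ViolationIndex:
    """Per-term active voxel sets (flat indices); whole ROI for l2 terms."""

    active: list[np.ndarray] = field(default_factory=list)

    def sizes(self) -> list[int]:
        return [a.size for a in self.active]

    def __eq__(self, other) -> bool:
        if not isinstance(other, ViolationIndex):
            return NotImplemented
        return len(self.active) == len(other.active) and all(
            np.array_equal(a, b) for a, b in zip(self.active, other.active)
        )


def update_violation_sets(
    d: np.ndarray,
    spec: ObjectiveSpec,
    structures: StructureSet,
) -> ViolationIndex:
    """Violating-voxel sets at the current dose (sorted-exemption rule).

    Ties in the dose sort are broken by voxel index ascending (stable sort),
    exempt counts use floor.
    """
    d = np.asarray(d, dtype=float).ravel()
    active: list[np.ndarray] = []
    for term, idx in zip(spec.terms, spec.roi_indices(structures)):
        if term.kind == "l2":
            active.append(idx)
            continue
        dr = d[idx]
        k = idx.size
        if term.kind == "dvh_max":
            n_exempt = int(np.floor(term.volume * k))
            order = np.argsort(-dr, kind="stable")   # hottest first
            rest = order[n_exempt:]
            viol = rest[dr[rest] > term.dose]
        else:  # dvh_min
            n_exempt = int(np.floor((1.0 - term.volume) * k))
            order = np.argsort(dr, kind="stable")    # coldest first
            rest = order[n_exempt:]
            viol = rest[dr[rest] < term.dose]
        active.append(np.sort(idx[viol]))
    return ViolationIndex(active=active)


def evaluate_objective(
    d: np.ndarray,
    spec: ObjectiveSpec,
    structures: StructureSet,
    omega: ViolationIndex,
) -> float:
    """f(d, Omega) >= 0."""
    d = np.asarray(d, dtype=float).ravel()
    if len(omega.active) != len(spec.terms):
        raise ValueError("violation index does not match the objective terms")
    f = 0.0
    for term, idx in zip(spec.terms, omega.active):
        if idx.size:
            diff = d[idx] - term.dose
            f += term.weight * float(diff @ diff)
    return f


def objective_gradient(
    d: np.ndarray,
    spec: ObjectiveSpec,
    structures: StructureSet,
    omega: ViolationIndex,
) -> np.ndarray:
    """df/dd as a full per-voxel vector (zero outside all active sets)."""
    d = np.asarray(d, dtype=float).ravel()
    g = np.zeros_like(d)
    for term, idx in zip(spec.terms, omega.active):
        if idx.size:
            np.add.at(g, idx, 2.0 * term.weight * (d[idx] - term.dose))
    return g


def default_objectives(structures: StructureSet, prescription: float = 100.0,
                       ) -> ObjectiveSpec:
    """Clinically-shaped default: uniform target dose, target coverage,
    body hot-spot control, and a max-dose-volume limit per OAR.

    Weights are scaled by 1/K_roi so ROIs of different size contribute on a
    comparable per-voxel scale.
    """
    k = {n: max(int(structures[n].sum()), 1) for n in structures.names}
    terms = [
        ObjectiveTerm("l2", "ctv", prescription, 1.0 / k["ctv"]),
        ObjectiveTerm("dvh_min", "ctv", 0.98 * prescription, 1.0 / k["ctv"],
                      volume=0.95),
        ObjectiveTerm("dvh_max", "body", 1.10 * prescription, 0.5 / k["body"],
                      volume=0.02),
    ]
    for name in structures.oar_names:
        terms.append(
            ObjectiveTerm("dvh_max", name, 0.5 * prescription, 0.3 / k[name],
                          volume=0.3)
        )
    return ObjectiveSpec(terms=terms, prescription=prescription)
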