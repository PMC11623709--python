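"""Plan evaluation: DVH, D95 normalization, conformity index, 3D gamma,
delivery-time estimate.

Doses are percent of prescription throughout; plans are conventionally
normalized so D95 of the target equals 100 % before metrics are compared.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .dose_engine import DoseDistribution, SpotSet

__all__ = [
    "DVHCurve",
    "GammaParams",
    "GammaResult",
    "DeliveryTimeModel",
    "NormalizedPlan",
    "dvh_curve",
    "dvh_quantile",
    "normalize_d95",
    "conformity_index",
    "gamma_index_3d",
    "estimate_delivery_time",
    "plan_metrics",
]


@dataclass
class DVHCurve:
    """Cumulative DVH: volume(dose >= D) as a fraction of the ROI volume."""

    dose: np.ndarray      # ascending, starts at 0
    volume: np.ndarray    # non-increasing, volume[0] == 1

    def __post_init__(self):
        self.dose = np.asarray(self.dose, dtype=float)
        self.volume = np.asarray(self.volume, dtype=float)


def dvh_curve(d, mask) -> DVHCurve:
    """Empirical cumulative DVH of the masked voxels."""
    d = np.asarray(d, dtype=float).ravel()
    mask = np.asarray(mask, dtype=bool).ravel()
    if not mask.any():
        raise ValueError("empty ROI mask")
    vals = d[mask]
    levels = np.unique(np.concatenate([[0.0], vals]))
    volume = (vals[None, :] >= levels[:, None]).mean(axis=1)
    return DVHCurve(dose=levels, volume=volume)


def dvh_quantile(curve: DVHCurve, q: float) -> float:
    """D_q: largest dose D with volume(dose >= D) >= q (q a fraction)."""
    ok = curve.volume >= q - 1e-12
    if not ok.any():
        return 0.0
    return float(curve.dose[ok].max())


@dataclass
class NormalizedPlan:
    dose: DoseDistribution
    weights: np.ndarray | None
    scale: float
    mmu_broken: bool      # any scaled weight fell strictly inside (0, Gmin)


def normalize_d95(
    dose: DoseDistribution,
    ctv_mask,
    weights: np.ndarray | None = None,
    gmin: float | None = None,
) -> NormalizedPlan:
    """Scale the plan so D95 of the target equals 100 %.  Idempotent.

    Scaling can push previously feasible weights into the forbidden MMU gap
    (0, Gmin); the returned flag reports that.
    """
    d95 = dvh_quantile(dvh_curve(dose.values, ctv_mask), 0.95)
    if d95 <= 0:
        raise ValueError("target D95 is zero; cannot normalize")
    s = 100.0 / d95
    new_dose = DoseDistribution(values=dose.values * s, grid=dose.grid)
    new_w = None
    broken = False
    if weights is not None:
        new_w = np.asarray(weights, dtype=float) * s
        if gmin is not None and gmin > 0:
            broken = bool(np.any((new_w > 0) & (new_w < gmin)))
    return NormalizedPlan(dose=new_dose, weights=new_w, scale=s, mmu_broken=broken)


def conformity_index(d, ctv_mask, body_mask, level: float = 100.0) -> float:
    """CI = V100,CTV^2 / (V_CTV * V100); 1 when the prescription isodose
    exactly conforms to the target.  V100 = 0 gives 0 by convention."""
    d = np.asarray(d, dtype=float).ravel()
    ctv = np.asarray(ctv_mask, dtype=bool).ravel()
    body = np.asarray(body_mask, dtype=bool).ravel()
    if not ctv.any():
        raise ValueError("empty CTV mask")
    hot = (d >= level) & body
    v100 = int(hot.sum())
    if v100 == 0:
        return 0.0
    v100_ctv = int((hot & ctv).sum())
    return v100_ctv**2 / (int(ctv.sum()) * v100)


@dataclass
class GammaParams:
    dose_diff_pct: float = 2.0      # % of the global reference maximum
    dta_mm: float = 2.0             # distance to agreement
    threshold: float = 0.1          # low-dose cutoff, fraction of ref max
    search_radius_mm: float | None = None  # default 3 * DTA
    step_fraction: float = 0.1      # search step as a fraction of DTA

    def __post_init__(self):
        if self.dose_diff_pct <= 0 or self.dta_mm <= 0:
            raise ValueError("gamma criteria must be positive")
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie in (0, 1)")
        if self.search_radius_mm is None:
            self.search_radius_mm = 3.0 * self.dta_mm


@dataclass
class GammaResult:
    pass_rate: float        # percent of included voxels with gamma <= 1
    gamma: np.ndarray       # per included voxel (capped by the search radius)
    n_included: int


def gamma_index_3d(
    reference: DoseDistribution,
    evaluated: DoseDistribution,
    params: GammaParams | None = None,
) -> GammaResult:
    """Global 3D gamma: min over nearby evaluated points of
    sqrt(dd^2/DD^2 + dr^2/DTA^2), dose difference normalized to the global
    reference maximum; voxels below the low-dose threshold are excluded.

    The evaluated distribution is sampled on a discrete offset neighborhood
    (trilinear interpolation, step = step_fraction * DTA, radius =
    search_radius_mm) with early termination once no voxel can improve.
    """
    params = params or GammaParams()
    if reference.grid.shape != evaluated.grid.shape or not np.allclose(
        reference.grid.spacing, evaluated.grid.spacing
    ):
        raise ValueError("reference and evaluated must share one grid")
    ref = reference.as_array()
    ev = evaluated.as_array()
    gmax = float(ref.max())
    if gmax <= 0:
        raise ValueError("reference distribution is empty")
    include = ref >= params.threshold * gmax
    if not include.any():
        raise ValueError("no voxels above the low-dose threshold")
    dd_abs = params.dose_diff_pct / 100.0 * gmax
    dta = params.dta_mm
    spacing = reference.grid.spacing

    step = params.step_fraction * dta
    radius = params.search_radius_mm
    k = int(np.floor(radius / step))
    off1 = step * np.arange(-k, k + 1)
    ox, oy, oz = np.meshgrid(off1, off1, off1, indexing="ij")
    offs = np.stack([ox.ravel(), oy.ravel(), oz.ravel()], axis=1)
    r2 = (offs**2).sum(axis=1)
    keep = r2 <= radius**2 + 1e-9
    offs, r2 = offs[keep], r2[keep]
    order = np.argsort(r2, kind="stable")
    offs, r2 = offs[order], r2[order]

    pts = np.argwhere(include).astype(float)       # voxel-index coordinates
    ref_vals = ref[include]
    ncand = pts.shape[0]
    gmin2 = np.full(ncand, np.inf)
    active = np.arange(ncand)
    for off, rr in zip(offs, r2):
        dr2 = rr / dta**2
        still = gmin2[active] > dr2
        active = active[still]
        if active.size == 0:
            break
        coords = (pts[active] + (off / spacing)[None, :]).T
        ev_vals = map_coordinates(ev, coords, order=1, mode="nearest")
        g2 = ((ev_vals - ref_vals[active]) / dd_abs) ** 2 + dr2
        np.minimum.at(gmin2, active, g2)
    gamma = np.sqrt(np.minimum(gmin2, (radius / dta) ** 2 + (10.0) ** 2))
    pass_rate = 100.0 * float(np.mean(gmin2 <= 1.0 + 1e-12))
    return GammaResult(pass_rate=pass_rate, gamma=gamma, n_included=ncand)


@dataclass
class DeliveryTimeModel:
    """Additive delivery-time decomposition: layer switching + spot travel
    + beam-on time.  Defaults give clinically-shaped orders of magnitude;
    they are not fitted to any particular machine."""

    elst_s: float = 1.5             # energy-layer switch time [s]
    scan_speed_mm_s: float = 1000.0  # inter-spot transit speed
    dose_rate_mu_s: float = 400.0    # MU per second

    def __post_init__(self):
        if min(self.elst_s, self.scan_speed_mm_s, self.dose_rate_mu_s) <= 0:
            raise ValueError("all delivery-time parameters must be positive")


def estimate_delivery_time(spot_set: SpotSet, model: DeliveryTimeModel) -> float:
    """Seconds: (layer switches) * ELST + travel/speed + total MU / dose rate.

    Only delivered spots count (weight > 0), and only layers containing at
    least one delivered spot; layer switches = delivered layers - beams.
    """
    switches = 0
    travel = 0.0
    total_mu = 0.0
    beams = set()
    delivered_layers = 0
    for blk in spot_set.blocks:
        spots = [spot_set.spots[c] for c in blk.cols if spot_set.spots[c].weight > 0]
        if not spots:
            continue
        delivered_layers += 1
        beams.add(blk.beam)
        total_mu += sum(s.weight for s in spots)
        for a, b in zip(spots[:-1], spots[1:]):
            travel += float(np.hypot(b.x - a.x, b.y - a.y))
    if delivered_layers == 0:
        return 0.0
    switches = delivered_layers - len(beams)
    return (
        switches * model.elst_s
        + travel / model.scan_speed_mm_s
        + total_mu / model.dose_rate_mu_s
    )


def plan_metrics(
    dose: DoseDistribution,
    structures,
    spot_set: SpotSet | None = None,
    time_model: DeliveryTimeModel | None = None,
) -> dict:
    """Summary metrics of one plan (doses in % of prescription)."""
    d = dose.values
    ctv = structures["ctv"]
    body = structures["body"]
    curve = dvh_curve(d, ctv)
    out = {
        "d95_ctv": dvh_quantile(curve, 0.95),
        "dmax_ctv": float(d[ctv.ravel()].max()),
        "dmean_ctv": float(d[ctv.ravel()].mean()),
        "ci": conformity_index(d, ctv, body),
    }
    for name in structures.oar_names:
        m = structures[name].ravel()
        out[f"dmax_{name}"] = float(d[m].max())
        out[f"dmean_{name}"] = float(d[m].mean())
    if spot_set is not None:
        tm = time_model or DeliveryTimeModel()
        out["delivery_time_s"] = estimate_delivery_time(spot_set, tm)
        out["n_delivered_layers"] = int(
            sum(
                any(spot_set.spots[c].weight > 0 for c in blk.cols)
                for blk in spot_set.blocks
            )
        )
        out["n_delivered_spots"] = int(sum(s.weight > 0 for s in spot_set.spots))
    return out
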