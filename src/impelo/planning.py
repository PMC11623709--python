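"""High-level planning pipeline: case -> spots -> influence -> optimized plan.

Thin orchestration over the library modules, shared by the CLI and the
acceptance/benchmark scripts.  A *CONV* plan optimizes spot weights over all
placed energy layers; an *ELO* plan additionally hard-constrains the number
of active layers via the greedy selection loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .beam_model import BeamModel, CTCalibrationCurve, default_beam_model, \
    default_calibration
from .dose_engine import (
    BeamGeometry,
    DoseDistribution,
    InfluenceMatrix,
    SpotSet,
    assemble_influence,
    dose_from_weights,
    place_spots,
)
from .elo import ELOConfig, EloResult, elo_greedy
from .evaluation import DeliveryTimeModel, normalize_d95, plan_metrics
from .objectives import ObjectiveSpec, default_objectives
from .phantoms import CasePreset, SyntheticCase, make_synthetic_case
from .solvers import MMUConstraint, SolverConfig, solve_fixed_support_dvh

__all__ = ["PlanSetup", "PlanResult", "build_setup", "plan_conv", "plan_elo"]


@dataclass
class PlanSetup:
    case: SyntheticCase
    model: BeamModel
    calibration: CTCalibrationCurve
    geometries: list[BeamGeometry]
    spot_set: SpotSet
    influence: InfluenceMatrix
    objectives: ObjectiveSpec
    gmin: float


@dataclass
class PlanResult:
    weights: np.ndarray           # normalized (D95 = 100 %) weights
    dose: DoseDistribution        # normalized dose
    spot_set: SpotSet             # with the normalized weights attached
    f: float                      # objective before normalization
    metrics: dict
    elo: EloResult | None = None


def build_setup(
    preset_name: str,
    seed: int = 0,
    spacing: float = 2.0,
    model: BeamModel | None = None,
    objectives: ObjectiveSpec | None = None,
    gmin: float = 2.0,
    lateral_spacing: float | None = None,
    margin: float = 5.0,
    cutoff: float = 1e-4,
) -> PlanSetup:
    """Generate a synthetic case and assemble its influence matrix."""
    case = make_synthetic_case(CasePreset(name=preset_name, seed=seed,
                                          spacing=spacing))
    model = model or default_beam_model()
    cal = default_calibration()
    ctv = case.structures["ctv"]
    idx = np.argwhere(ctv)
    iso = case.phantom.origin + idx.mean(axis=0) * case.phantom.spacing
    geoms = [
        BeamGeometry(gantry_angle_deg=a, iso=iso, sad_x=model.sad_x,
                     sad_y=model.sad_y)
        for a in case.beam_angles
    ]
    spot_set = place_spots(
        case.phantom, cal, ctv, geoms, model,
        lateral_spacing=lateral_spacing, margin=margin,
    )
    influence = assemble_influence(case.phantom, cal, spot_set, model,
                                   cutoff=cutoff)
    spec = objectives or default_objectives(case.structures)
    return PlanSetup(
        case=case, model=model, calibration=cal, geometries=geoms,
        spot_set=spot_set, influence=influence, objectives=spec, gmin=gmin,
    )


def _finalize(setup: PlanSetup, x: np.ndarray, f: float,
              elo: EloResult | None = None,
              time_model: DeliveryTimeModel | None = None) -> PlanResult:
    dose = dose_from_weights(setup.influence, x)
    norm = normalize_d95(dose, setup.case.structures["ctv"], weights=x,
                         gmin=setup.gmin)
    spot_set = setup.spot_set.with_weights(norm.weights)
    metrics = plan_metrics(norm.dose, setup.case.structures, spot_set,
                           time_model)
    metrics["objective"] = f
    metrics["d95_scale"] = norm.scale
    metrics["mmu_broken_by_normalization"] = norm.mmu_broken
    return PlanResult(
        weights=norm.weights, dose=norm.dose, spot_set=spot_set, f=f,
        metrics=metrics, elo=elo,
    )


def plan_conv(setup: PlanSetup, solver: SolverConfig | None = None,
              time_model: DeliveryTimeModel | None = None) -> PlanResult:
    """Optimize all placed energy layers (no layer budget)."""
    res = solve_fixed_support_dvh(
        setup.influence, setup.objectives, setup.case.structures,
        support=range(setup.influence.n_blocks),
        mmu=MMUConstraint(gmin=setup.gmin),
        config=solver or SolverConfig(),
    )
    return _finalize(setup, res.x, res.f, time_model=time_model)


def plan_elo(setup: PlanSetup, n_energies: int,
             solver: SolverConfig | None = None,
             itr: int | None = None,
             time_model: DeliveryTimeModel | None = None) -> PlanResult:
    """Greedy layer-budgeted plan with at most ``n_energies`` active blocks."""
    cfg = ELOConfig(n_energies=n_energies, itr=itr, gmin=setup.gmin,
                    solver=solver or SolverConfig())
    res = elo_greedy(setup.influence, setup.objectives, setup.case.structures,
                     cfg)
    return _finalize(setup, res.x, res.f, elo=res, time_model=time_model)
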