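"""Shared fixtures.

The solver fixtures use a desk-scale phantom (1.2 mm voxels, 6 mm condyle
radius) so that full 3 ms explicit impact events run in seconds; the
physics checks they feed are scale-free (energy balance, symmetry,
directional comparisons).
"""

import numpy as np
import pytest

from condylefe.config import RunConfig
from condylefe.densitymap import scale_moduli
from condylefe.pipeline import build_model
from condylefe.solver_impact import ImpactLoadCase, run_impact
from condylefe.solver_static import StaticLoadCase, solve_static

SMALL_PHANTOM = dict(
    voxel_spacing=1.2, shaft_length=16.0, condyle_radius=6.0,
    condyle_separation=5.5, ridge_half_width=1.4, cortical_thickness=1.5)


def small_config(**over) -> RunConfig:
    cfg = RunConfig.model_validate({
        "phantom": SMALL_PHANTOM,
        "meshing": {"coarsening": 1},
        "analysis": {"slice_offset": 3.0},
        "seed": 7})
    for key, sub in over.items():
        section = getattr(cfg, key)
        for k, v in sub.items():
            setattr(section, k, v)
    return cfg


@pytest.fixture(scope="session")
def small_cfg() -> RunConfig:
    return small_config()


@pytest.fixture(scope="session")
def healthy_model(small_cfg):
    """(mesh, materials, counterbody mesh, counterbody materials, volume)."""
    return build_model(small_cfg, "healthy")


@pytest.fixture(scope="session")
def sym_impact():
    """Frictionless central impact of an exactly symmetric phantom."""
    cfg = small_config(phantom={"trabecular_density_sd": 0.0,
                                "joint_angle": 180.0})
    mesh, mats, cmesh, cmats, _ = build_model(cfg, "healthy")
    case = ImpactLoadCase(friction_mu=0.0)
    hist = run_impact(mesh, mats, case, cmesh, cmats)
    return {"cfg": cfg, "mesh": mesh, "mats": mats, "cmesh": cmesh,
            "cmats": cmats, "case": case, "hist": hist}


@pytest.fixture(scope="session")
def impact_pair(small_cfg):
    """Healthy and OA impact runs under the study's impact constants."""
    out = {}
    case = ImpactLoadCase(**small_cfg.impact.model_dump())
    for variant in ("healthy", "oa"):
        mesh, mats, cmesh, cmats, _ = build_model(small_cfg, variant)
        hist = run_impact(mesh, mats, case, cmesh, cmats)
        vm_pf = np.asarray(hist.von_mises[
            int(np.argmax(hist.total_contact_force))])
        out[variant] = {"mesh": mesh, "mats": mats, "cmesh": cmesh,
                        "cmats": cmats, "hist": hist, "vm_peak": vm_pf}
    out["case"] = case
    return out


@pytest.fixture(scope="session")
def sensitivity_run(small_cfg, impact_pair):
    """The healthy impact model re-run with 1.5x moduli."""
    h = impact_pair["healthy"]
    mats15 = scale_moduli(h["mats"], 1.5)
    hist = run_impact(h["mesh"], mats15, impact_pair["case"],
                      h["cmesh"], h["cmats"])
    return {"hist": hist,
            "vm_peak": np.asarray(hist.von_mises[
                int(np.argmax(hist.total_contact_force))]),
            "mats": mats15}


@pytest.fixture(scope="session")
def default_scale_pair():
    """Palmar-slice regional tables for impact vs midstance on the
    study-scale (default) phantom, where the two load cases produce
    comparable stress magnitudes."""
    from condylefe.analysis import (make_sampling_grid, regional_summary,
                                    sample_field)

    cfg = RunConfig()
    cfg.seed = 7
    mesh, mats, cmesh, cmats, _ = build_model(cfg, "healthy")
    case = ImpactLoadCase(**cfg.impact.model_dump())
    hist = run_impact(mesh, mats, case, cmesh, cmats)
    vm_impact = np.asarray(hist.von_mises[
        int(np.argmax(hist.total_contact_force))])
    sol = solve_static(mesh, mats, StaticLoadCase(
        {"dorsal_patch": cfg.static.pressure_MPa,
         "palmar_patch": cfg.static.pressure_MPa}, cfg.static.fixed_set))
    out = {}
    for case_name, vm in (("impact", vm_impact),
                          ("static", sol.von_mises)):
        out[case_name] = {}
        for sl in ("dorsal", "palmar"):
            grid = make_sampling_grid(mesh, "slice", slice_name=sl)
            out[case_name][sl] = regional_summary(
                sample_field(grid, vm, mesh), grid,
                {"load_case": case_name, "slice": sl})
    return out


@pytest.fixture(scope="session")
def static_solution(impact_pair, small_cfg):
    """Midstance solve on the healthy mesh (dorsal + palmar patches)."""
    h = impact_pair["healthy"]
    case = StaticLoadCase(
        {"dorsal_patch": small_cfg.static.pressure_MPa,
         "palmar_patch": small_cfg.static.pressure_MPa},
        small_cfg.static.fixed_set)
    return solve_static(h["mesh"], h["mats"], case)
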