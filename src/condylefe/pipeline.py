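"""End-to-end orchestration: phantom -> materials -> mesh -> solve -> tables.

``run_pipeline`` executes the configured variants (healthy and/or ``oa``)
and load cases (``impact`` and/or ``static``), writing volumes, meshes,
regional tables and a checksum manifest under the output directory.  Each
stage failure aborts with a stage-tagged error; partial outputs are kept.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .analysis import (compare_variants, make_sampling_grid,
                       regional_summary, sample_field)
from .config import RunConfig
from .densitymap import (HUCalibration, add_proximal_mass,
                         assign_element_materials, hu_to_apparent_density,
                         model_mass_kg, scale_moduli)
from .meshing import build_voxel_mesh, label_regions, mark_fixed_end, \
    segment_volume
from .phantom import PhantomSpec, density_to_hu, generate_condyle_volume, \
    generate_counterbody
from .solver_impact import ImpactLoadCase, contact_summary, run_impact
from .solver_static import StaticLoadCase, solve_static

log = logging.getLogger(__name__)


def _spec_from_config(cfg: RunConfig, variant: str) -> PhantomSpec:
    kw = cfg.phantom.model_dump()
    kw["rng_seed"] = cfg.seed
    if variant == "oa":
        return PhantomSpec.oa_default(**kw)
    if variant != "healthy":
        raise ValueError(f"unknown variant {variant!r}")
    return PhantomSpec(**kw)


def build_model(cfg: RunConfig, variant: str = "healthy"):
    """Phantom -> HU -> density -> mesh -> materials for one variant.

    Returns (condyle mesh, condyle materials, counterbody mesh,
    counterbody materials, density volume).  The density volume is pushed
    through the HU round trip so the material chain exercises the same
    calibration path a real CT volume would.
    """
    spec = _spec_from_config(cfg, variant)
    cal = HUCalibration(**cfg.calibration.model_dump())
    vol = generate_condyle_volume(spec)
    vol = hu_to_apparent_density(density_to_hu(vol, cal), cal)
    mask = segment_volume(vol, cfg.meshing.threshold)
    mesh = build_voxel_mesh(mask, cfg.meshing.coarsening,
                            cfg.meshing.element_type)
    label_regions(mesh, spec,
                  articular_z_fraction=cfg.analysis.articular_z_fraction,
                  slice_offset=cfg.analysis.slice_offset)
    mats = assign_element_materials(vol, mesh, nu=cfg.materials.poisson_ratio)
    if cfg.materials.augment_mass:
        mats = add_proximal_mass(mesh, mats, cfg.materials.target_mass_kg)
    if cfg.materials.modulus_scale != 1.0:
        mats = scale_moduli(mats, cfg.materials.modulus_scale)

    cvol = generate_counterbody(spec)
    cmask = segment_volume(cvol, cfg.meshing.threshold, fill_holes=False)
    cmesh = build_voxel_mesh(cmask, cfg.meshing.coarsening)
    mark_fixed_end(cmesh, end="distal")
    cmats = assign_element_materials(cvol, cmesh,
                                     nu=cfg.materials.poisson_ratio)
    return mesh, mats, cmesh, cmats, vol


def analyze_solution(mesh, von_mises_values, cfg: RunConfig, meta: dict):
    """Regional von Mises tables for the two mediolateral slices."""
    tables = {}
    for sl in ("dorsal", "palmar"):
        grid = make_sampling_grid(
            mesh, "slice", (cfg.analysis.grid_rows, cfg.analysis.grid_cols),
            slice_name=sl)
        samples = sample_field(grid, von_mises_values, mesh)
        tables[sl] = regional_summary(
            samples, grid, dict(meta, slice=sl))
    return tables


def run_pipeline(cfg: RunConfig, out_dir) -> Path:
    """Run all configured variants/load cases; returns the run directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")
    manifest = {"seed": cfg.seed, "stages": [], "files": {}}
    results = {}

    for variant in cfg.variants:
        vdir = out / variant
        vdir.mkdir(exist_ok=True)
        stage = f"{variant}/build"
        t0 = time.time()
        try:
            mesh, mats, cmesh, cmats, vol = build_model(cfg, variant)
        except Exception as exc:
            _write_manifest(out, manifest)
            raise RuntimeError(f"stage {stage} failed: {exc}") from exc
        log.info("%s: %d elements, mass %.3f kg (%.1f s)", stage,
                 mesh.n_elements, model_mass_kg(mesh, mats),
                 time.time() - t0)
        manifest["stages"].append({"stage": stage,
                                   "elements": mesh.n_elements,
                                   "seconds": time.time() - t0})
        cio.write_volume(vol, vdir / "condyle.mhd")
        cio.write_mesh(mesh, vdir / "condyle.vtk",
                       cell_data={"E_MPa": mats.E, "rho_gcm3": mats.rho})
        cio.write_material_csv(mesh, mats, vdir / "materials.csv")

        for case_name in cfg.load_cases:
            stage = f"{variant}/{case_name}"
            t0 = time.time()
            try:
                if case_name == "impact":
                    case = ImpactLoadCase(**cfg.impact.model_dump())
                    hist = run_impact(mesh, mats, case, cmesh, cmats)
                    # stresses at the instant of peak total contact force
                    vm_peak = np.asarray(hist.von_mises[
                        int(np.argmax(hist.total_contact_force))])
                    csum = contact_summary(hist, mesh)
                    csum.to_csv(vdir / "contact_pressure.csv")
                    pd.DataFrame({
                        "time_ms": hist.times_ms,
                        **{k: v for k, v in hist.energies.items()},
                        "total_contact_force_N": hist.total_contact_force,
                    }).to_csv(vdir / "impact_energies.csv", index=False)
                elif case_name == "static":
                    case = StaticLoadCase(
                        {"dorsal_patch": cfg.static.pressure_MPa,
                         "palmar_patch": cfg.static.pressure_MPa},
                        cfg.static.fixed_set)
                    sol = solve_static(mesh, mats, case)
                    vm_peak = sol.von_mises
                else:
                    raise ValueError(f"unknown load case {case_name!r}")
                tables = analyze_solution(
                    mesh, vm_peak, cfg,
                    {"variant": variant, "load_case": case_name})
                for sl, tab in tables.items():
                    tab.table.to_csv(vdir / f"{case_name}_vm_{sl}.csv")
                results[(variant, case_name)] = tables
            except Exception as exc:
                _write_manifest(out, manifest)
                raise RuntimeError(f"stage {stage} failed: {exc}") from exc
            manifest["stages"].append({
                "stage": stage, "seconds": time.time() - t0})

    if {"healthy", "oa"} <= set(cfg.variants):
        for case_name in cfg.load_cases:
            for sl in ("dorsal", "palmar"):
                diff = compare_variants(
                    results[("healthy", case_name)][sl],
                    results[("oa", case_name)][sl])
                diff.to_csv(out / f"healthy_vs_oa_{case_name}_{sl}.csv")

    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest["files"][str(p.relative_to(out))] = hashlib.sha256(
                p.read_bytes()).hexdigest()
    _write_manifest(out, manifest)
    return out


def _write_manifest(out: Path, manifest: dict):
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
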