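"""Robustness harnesses: mesh convergence and stiffness sensitivity.

These reproduce the study's model-robustness procedures on the phantom:

* convergence — the same model meshed at three densities (coarse, moderate,
  fine), solved under identical loading; regional average von Mises from
  the dorsal slice compared coarse-vs-fine and moderate-vs-fine against the
  ±5% criterion.
* sensitivity — the impact model re-run with every modulus multiplied by
  1.5 (the stiffening bone exhibits at impact strain rates); per-region
  ratios and the per-point change distribution reported.
"""

from __future__ import annotations

import logging

import numpy as np

from .analysis import (convergence_check, make_sampling_grid,
                       regional_summary, sample_field, sensitivity_compare)
from .config import RunConfig
from .densitymap import scale_moduli
from .pipeline import build_model
from .solver_impact import ImpactLoadCase, run_impact
from .solver_static import StaticLoadCase, solve_static

log = logging.getLogger(__name__)


def _dorsal_slice_table(mesh, vm, cfg, meta):
    grid = make_sampling_grid(
        mesh, "slice", (cfg.analysis.grid_rows, cfg.analysis.grid_cols),
        slice_name="dorsal")
    samples = sample_field(grid, vm, mesh)
    return regional_summary(samples, grid, meta), samples


def convergence_harness(cfg: RunConfig, coarsenings=(4, 3, 2),
                        criterion: float = 0.05):
    """Three mesh densities under the static load case; ±5% criterion.

    ``coarsenings`` ordered coarse -> fine.  Returns (tables, report
    DataFrame) where the report carries coarse-vs-fine and
    moderate-vs-fine regional differences and converged flags.
    """
    if len(coarsenings) < 2:
        raise ValueError("need at least two mesh densities")
    tables = []
    for c in coarsenings:
        ccfg = cfg.model_copy(deep=True)
        ccfg.meshing.coarsening = int(c)
        mesh, mats, *_ = build_model(ccfg, "healthy")
        case = StaticLoadCase(
            {"dorsal_patch": cfg.static.pressure_MPa,
             "palmar_patch": cfg.static.pressure_MPa},
            cfg.static.fixed_set)
        sol = solve_static(mesh, mats, case)
        tab, _ = _dorsal_slice_table(
            mesh, sol.von_mises, ccfg,
            {"coarsening": int(c), "load_case": "static"})
        log.info("convergence: coarsening %d -> %d elements", c,
                 mesh.n_elements)
        tables.append(tab)
    report = convergence_check(tables, criterion)
    return tables, report


def sensitivity_harness(cfg: RunConfig, factor: float = 1.5):
    """Impact model vs the same model with moduli scaled by ``factor``.

    Returns the :func:`~condylefe.analysis.sensitivity_compare` report
    (per-region ratios; per-point change fractions from the dorsal-slice
    samples of the event-peak von Mises field).
    """
    mesh, mats, cmesh, cmats, _ = build_model(cfg, "healthy")
    case = ImpactLoadCase(**cfg.impact.model_dump())
    out = {}
    samples = {}
    for name, m in (("base", mats), ("scaled", scale_moduli(mats, factor))):
        hist = run_impact(mesh, m, case, cmesh, cmats)
        vm_peak = np.asarray(hist.von_mises[
            int(np.argmax(hist.total_contact_force))])
        out[name], samples[name] = _dorsal_slice_table(
            mesh, vm_peak, cfg, {"variant": name, "load_case": "impact"})
    report = sensitivity_compare(out["base"], out["scaled"],
                                 samples["base"], samples["scaled"])
    report["factor"] = factor
    return out, report
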