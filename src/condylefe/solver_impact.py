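"""Explicit-dynamic impact solver.

Central-difference (leapfrog) time integration with a lumped (equal-split)
mass matrix and linear-elastic internal forces, modelling the primary-impact
transient: the condyle, carrying a distally-directed initial nodal velocity,
strikes the stationary counterbody whose far end is fully constrained.

Contact is node-to-facet penalty contact with the linear pressure–overclosure
law the study prescribes (contact pressure = stiffness x interpenetration,
default 12 MPa/mm) and Coulomb friction (default mu = 0.007, the synovial
friction coefficient).  Friction uses an elastic-predictor / slip return
mapping: a tangential penalty spring anchored at first touch supplies the
trial force, capped at mu*N with the excess released as slip (dissipated
energy is tracked).  Contact facets come from the counterbody surface facing
the condyle; because meshes are voxel-based these facets are axis-aligned
rectangles and point location is an O(1) column lookup.

The stable time step comes from the CFL condition on the dilatational wave
speed, further limited by the contact-spring frequency; the 0.25 ms interval
the study names is the *output/recording* interval — it is orders of
magnitude above any stable explicit step at these element sizes.

The counterbody may be replaced by an analytic rigid plane for verification
problems (e.g. the elastic-rod impact, whose plateau stress rho*c*v0 is a
closed-form oracle).

All solver math runs in mm / MPa / tonne / s units.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .densitymap import MaterialField
from .meshing import FEMesh
from .solver_static import (assemble_lumped_mass, assemble_system,
                            element_stresses, von_mises)
from .units import (density_gcm3_to_solver, time_ms_to_solver,
                    velocity_ms_to_solver)

log = logging.getLogger(__name__)


@dataclass
class ImpactLoadCase:
    """Primary-impact load case (study defaults).

    ``velocity_ms`` is the initial speed (m/s) of every condyle node,
    directed distally (+z); ``contact_stiffness`` the linear
    pressure–overclosure slope (MPa/mm); ``duration_ms`` the simulated
    event; ``output_interval_ms`` the recording interval.
    ``rigid_plane_z`` switches to an analytic rigid wall at that z (mm).
    """

    velocity_ms: float = 3.55
    contact_stiffness: float = 12.0
    friction_mu: float = 0.007
    duration_ms: float = 3.0
    output_interval_ms: float = 0.25
    safety: float = 0.8
    max_overclosure_factor: float = 10.0
    rigid_plane_z: Optional[float] = None

    def validate(self) -> None:
        if self.velocity_ms <= 0:
            raise ValueError("velocity must be > 0")
        if self.contact_stiffness <= 0:
            raise ValueError("contact stiffness must be > 0")
        if self.friction_mu < 0:
            raise ValueError("friction coefficient must be >= 0")
        if self.duration_ms <= 0:
            raise ValueError("duration must be > 0")
        if not 0 < self.output_interval_ms <= self.duration_ms:
            raise ValueError("output_interval must lie in (0, duration]")
        if not 0 < self.safety <= 1:
            raise ValueError("safety factor must lie in (0, 1]")


@dataclass
class ImpactHistory:
    """Recorded impact time series (one entry per output interval).

    ``contact_pressure`` rows align with ``articular_facets`` (facet ids on
    the condyle mesh); energies are in mJ (N*mm).
    """

    times_ms: np.ndarray
    displacements: list
    velocities: list
    von_mises: list
    contact_pressure: list
    articular_facets: np.ndarray
    energies: dict
    total_contact_force: np.ndarray
    meta: dict = field(default_factory=dict)


def stable_timestep(mesh: FEMesh, materials: MaterialField,
                    safety: float = 0.8) -> float:
    """CFL-stable explicit step (s): safety * min_e (h_e / c_e) with
    c = sqrt(E(1-nu) / (rho (1+nu)(1-2nu))) the dilatational wave speed."""
    en = mesh.nodes[mesh.elements]
    h = (en.max(axis=1) - en.min(axis=1)).min(axis=1)
    E, nu = materials.E, materials.nu
    rho = density_gcm3_to_solver(materials.rho)
    live = E > 0
    if np.any(live & (rho <= 0)):
        raise ValueError("element with stiffness but zero mass density")
    if not live.any():
        raise ValueError("no elements with positive stiffness")
    c = np.sqrt(E[live] * (1 - nu[live])
                / (rho[live] * (1 + nu[live]) * (1 - 2 * nu[live])))
    return float(safety * np.min(h[live] / c))


# ---------------------------------------------------------------------------
# contact geometry helpers
# ---------------------------------------------------------------------------

def _slave_surface(mesh: FEMesh):
    """Slave nodes and tributary areas from the condyle articular surface
    (falls back to all distally-facing boundary facets)."""
    if "distal_articular_surface" in mesh.facet_sets:
        fids = np.asarray(mesh.facet_sets["distal_articular_surface"])
    else:
        fids = np.flatnonzero(mesh.facet_normals[:, 2] > 0.5)
    if fids.size == 0:
        raise ValueError("no candidate contact surface on the moving body")
    areas = mesh.facet_areas()[fids]
    quads = mesh.boundary_facets[fids]
    node_area = np.zeros(mesh.n_nodes)
    np.add.at(node_area, quads.ravel(), np.repeat(areas / 4.0, 4))
    slave = np.flatnonzero(node_area > 0)
    return slave, node_area[slave], fids


def _stencil_slots(xy: np.ndarray, origin, h, shape):
    """Bilinear-interpolation stencil: 4 (column-index, weight,
    weight-gradient) slots per point, over the column-center grid.
    Weights are continuous in (x, y), which keeps the lookup
    mirror-symmetric (a point on a boundary weights both neighbours
    equally); the analytic weight gradients support the conservative
    tangential component of the contact force on sloped surfaces."""
    uf = (np.atleast_2d(xy) - (origin + 0.5 * h)) / h
    i0 = np.clip(np.floor(uf).astype(int), 0, np.array(shape) - 2)
    inside = (uf - i0 > 0.0) & (uf - i0 < 1.0)
    frac = np.clip(uf - i0, 0.0, 1.0)
    dfrac = np.where(inside, 1.0 / h, 0.0)      # d(frac)/d(x,y)
    for di, dj in ((0, 0), (1, 0), (0, 1), (1, 1)):
        wx = frac[:, 0] if di else 1 - frac[:, 0]
        wy = frac[:, 1] if dj else 1 - frac[:, 1]
        dwx = dfrac[:, 0] * (1 if di else -1)
        dwy = dfrac[:, 1] * (1 if dj else -1)
        yield (i0[:, 0] + di, i0[:, 1] + dj, wx * wy,
               dwx * wy, wx * dwy)


def _master_columns(mesh: FEMesh, slave_xyz: np.ndarray):
    """One candidate master facet per (x, y) grid column of the counterbody.

    Node-to-facet contact along z is only meaningful against the portion of
    the counterbody surface directly *above* the condyle, so per column we
    keep the lowest facet facing the condyle (normal -z) that starts above
    every slave node whose interpolation stencil can reach that column;
    side-wall and bottom-rim facets of the concave cup — and near-vertical
    cliffs such as the end walls of the sagittal-ridge groove — are thereby
    excluded from the z-penalty.
    """
    fids = np.flatnonzero(mesh.facet_normals[:, 2] < -0.5)
    if fids.size == 0:
        raise ValueError("counterbody has no facets facing the condyle")
    cent = mesh.facet_centroids()[fids]
    g = mesh.metadata["grid"]
    origin = np.asarray(g["origin"])[:2]
    h = np.asarray(g["spacing"])[:2]
    shape = tuple(g["shape"][:2])

    slave_top = np.full(shape, -np.inf)
    for ii, jj, *_ in _stencil_slots(slave_xyz[:, :2], origin, h, shape):
        np.maximum.at(slave_top, (ii, jj), slave_xyz[:, 2])

    ij = np.floor((cent[:, :2] - origin) / h).astype(int)
    col = np.full(shape, -1, dtype=np.int64)
    colz = np.full(shape, np.inf)
    for n, (i, j) in enumerate(ij):
        if not (0 <= i < shape[0] and 0 <= j < shape[1]):
            continue
        if cent[n, 2] <= slave_top[i, j] + 1e-9:
            continue          # facet not above the condyle surface here
        if cent[n, 2] < colz[i, j]:
            colz[i, j] = cent[n, 2]
            col[i, j] = fids[n]

    # fill columns with no admissible facet from their lowest valid
    # neighbour (synchronously, so the fill is mirror-symmetric): the
    # interpolated height field is then continuous everywhere, which keeps
    # the penalty potential free of artificial jumps at patch borders
    while (col < 0).any():
        best_z = np.full(shape, np.inf)
        best_f = np.full(shape, -1, dtype=np.int64)
        for ax, d in ((0, 1), (0, -1), (1, 1), (1, -1)):
            nz = np.full(shape, np.inf)
            nf = np.full(shape, -1, dtype=np.int64)
            src = (slice(None, -1), slice(None)) if (ax, d) == (0, 1) else \
                  (slice(1, None), slice(None)) if (ax, d) == (0, -1) else \
                  (slice(None), slice(None, -1)) if (ax, d) == (1, 1) else \
                  (slice(None), slice(1, None))
            dst = (slice(1, None), slice(None)) if (ax, d) == (0, 1) else \
                  (slice(None, -1), slice(None)) if (ax, d) == (0, -1) else \
                  (slice(None), slice(1, None)) if (ax, d) == (1, 1) else \
                  (slice(None), slice(None, -1))
            nz[dst] = colz[src]
            nf[dst] = col[src]
            take = (col < 0) & (nf >= 0) & (nz < best_z)
            best_z[take] = nz[take]
            best_f[take] = nf[take]
        grow = best_f >= 0
        if not grow.any():
            break
        col[grow] = best_f[grow]
        colz[grow] = best_z[grow]
    return col, colz, origin, h


# ---------------------------------------------------------------------------
# the solver
# ---------------------------------------------------------------------------

def run_impact(mesh_a: FEMesh, materials_a: MaterialField,
               case: ImpactLoadCase,
               mesh_b: FEMesh | None = None,
               materials_b: MaterialField | None = None) -> ImpactHistory:
    """Run the explicit impact simulation.

    ``mesh_a`` is the moving condyle (every node starts at the impact
    velocity, +z); ``mesh_b`` the stationary counterbody with a ``fixed``
    node set at its distal end (created if missing), or None when
    ``case.rigid_plane_z`` is set.  Returns the recorded history.

    The solver is deterministic: identical inputs produce bit-identical
    histories.  It aborts with a diagnostic if the total energy exceeds
    10x the initial kinetic energy (instability) or the overclosure passes
    ``max_overclosure_factor`` element edges.
    """
    case.validate()
    rigid = case.rigid_plane_z is not None
    if not rigid and (mesh_b is None or materials_b is None):
        raise ValueError("mesh_b/materials_b required without a rigid plane")

    Ka = assemble_system(mesh_a, materials_a)
    ma = assemble_lumped_mass(mesh_a, density_gcm3_to_solver(materials_a.rho))
    ma3 = np.repeat(ma, 3)
    dt = stable_timestep(mesh_a, materials_a, case.safety)

    slave, s_area, art_fids = _slave_surface(mesh_a)
    k = case.contact_stiffness
    # contact-spring frequency can govern stability for stiff walls; keep
    # ~25 steps per contact period so the penalty spring stays conservative
    w_max = np.sqrt(k * s_area.max() / ma[slave].min())
    dt = min(dt, 0.25 * 2.0 / w_max)

    if rigid:
        plane_z = float(case.rigid_plane_z)
    else:
        Kb = assemble_system(mesh_b, materials_b)
        mb = assemble_lumped_mass(
            mesh_b, density_gcm3_to_solver(materials_b.rho))
        mb3 = np.repeat(mb, 3)
        dt = min(dt, stable_timestep(mesh_b, materials_b, case.safety))
        if "fixed" not in mesh_b.node_sets:
            from .meshing import mark_fixed_end
            mark_fixed_end(mesh_b, end="distal")
        fixed_b = np.asarray(mesh_b.node_sets["fixed"])
        fixed_dofs_b = (3 * fixed_b[:, None] + np.arange(3)).ravel()
        col, colz, col_origin, col_h = _master_columns(
            mesh_b, mesh_a.nodes[slave])
        # surface slope raises the tangential contact stiffness; bound it
        # from the initial column heights and tighten the contact dt cap
        slope2 = 0.0
        for ax in (0, 1):
            a = colz[:-1, :] if ax == 0 else colz[:, :-1]
            b = colz[1:, :] if ax == 0 else colz[:, 1:]
            both = np.isfinite(a) & np.isfinite(b)
            if both.any():
                slope2 = max(slope2, float(
                    ((np.abs(a[both] - b[both]) / col_h[ax]) ** 2).max()))
        dt = min(dt, 0.25 * 2.0 / (w_max * np.sqrt(1.0 + slope2)))
        Xb = mesh_b.nodes
        ub = np.zeros(3 * mesh_b.n_nodes)
        vb = np.zeros(3 * mesh_b.n_nodes)

    Xa = mesh_a.nodes
    ua = np.zeros(3 * mesh_a.n_nodes)
    va = np.zeros(3 * mesh_a.n_nodes)
    v0 = velocity_ms_to_solver(case.velocity_ms)
    va[2::3] = v0

    h_edge = float(np.min(mesh_a.nodes[mesh_a.elements].max(axis=1)
                          - mesh_a.nodes[mesh_a.elements].min(axis=1)))
    max_g = case.max_overclosure_factor * h_edge

    duration = time_ms_to_solver(case.duration_ms)
    out_dt = time_ms_to_solver(case.output_interval_ms)
    n_steps = int(np.ceil(duration / dt))
    record_every = max(1, int(round(out_dt / dt)))
    ke0 = 0.5 * float(ma3 @ va ** 2)

    # friction state: tangential rest position relative to the master
    # surface (NaN while a slave node is out of contact)
    anchor = np.full((slave.size, 2), np.nan)
    rest_clearance = None
    e_fric = 0.0
    touched = False

    sdof = (3 * slave[:, None] + np.arange(3))   # (ns, 3)
    art_quads = mesh_a.boundary_facets[art_fids]
    node_to_slave = np.full(mesh_a.n_nodes, -1)
    node_to_slave[slave] = np.arange(slave.size)

    times, disps, vels, vms, cps, energies_rows, tot_force = \
        [], [], [], [], [], [], []

    def record(t, node_p, e_kin, e_str, e_con):
        times.append(t / time_ms_to_solver(1.0))
        disps.append(ua.reshape(-1, 3).copy())
        vels.append(va.reshape(-1, 3).copy())
        if touched:
            vms.append(von_mises(element_stresses(mesh_a, materials_a, ua)))
        else:
            vms.append(np.zeros(mesh_a.n_elements))
        sl = node_to_slave[art_quads]
        pq = np.where(sl >= 0, node_p[np.clip(sl, 0, None)], 0.0)
        cps.append(pq.mean(axis=1))
        energies_rows.append((e_kin, e_str, e_con, e_fric))
        tot_force.append(float(np.sum(node_p * s_area)))

    step = 0
    t = 0.0
    next_record = 0.0
    while t < duration - 0.5 * dt:
        # --- forces at time t ---------------------------------------------
        if touched:
            fint_a = Ka @ ua
            fa = -fint_a
            if not rigid:
                fint_b = Kb @ ub
                fb = -fint_b
        else:
            # exact free flight: internal forces of a rigid translation
            # vanish analytically; skip the (noisy) matvec until first touch
            fint_a = np.zeros_like(ua)
            fa = np.zeros_like(ua)
            if not rigid:
                fint_b = np.zeros_like(ub)
                fb = np.zeros_like(ub)

        ps = Xa[slave] + ua.reshape(-1, 3)[slave]
        if rigid:
            gap = ps[:, 2] - plane_z
            active = gap > 0
            slot_data = None
            wsum = None
        else:
            # continuous master surface: bilinear interpolation of the
            # per-column cup height (initial geometry + deformation) in
            # (x, y).  A piecewise-constant staircase surface injects
            # O(voxel) overclosure jumps into sliding nodes and pumps
            # energy; the interpolated height field is smooth, symmetric
            # and keeps the penalty spring conservative.
            ub3 = ub.reshape(-1, 3)
            n_s = len(ps)
            num = np.zeros(n_s)                 # sum w * z_surface
            num_g = np.zeros((n_s, 2))          # sum dw * z_surface
            Wxy = np.zeros((n_s, 2))
            wsum = np.zeros(n_s)
            wsum_g = np.zeros((n_s, 2))
            slot_data = []
            for ii, jj, w, dwx, dwy in _stencil_slots(
                    ps[:, :2], col_origin, col_h, col.shape):
                fid = col[ii, jj]
                ok = fid >= 0
                w = np.where(ok, w, 0.0)
                dw = np.where(ok[:, None], np.stack([dwx, dwy], 1), 0.0)
                q = mesh_b.boundary_facets[np.clip(fid, 0, None)]
                zsurf = np.where(
                    ok, (Xb[q][:, :, 2] + ub3[q][:, :, 2]).mean(axis=1),
                    0.0)
                num += w * zsurf
                num_g += dw * zsurf[:, None]
                Wxy += w[:, None] * np.where(
                    ok[:, None], ub3[q][:, :, :2].mean(axis=1), 0.0)
                wsum += w
                wsum_g += dw
                slot_data.append((w, q))
            valid = wsum > 1e-12
            wnorm = np.where(valid, wsum, 1.0)
            H = num / wnorm
            # surface slope dH/d(x,y) of the normalized interpolant
            Hgrad = (num_g - H[:, None] * wsum_g) / wnorm[:, None]
            Wxy = Wxy / wnorm[:, None]
            if rest_clearance is None:
                # voxelization and height-field smoothing leave some nodes
                # nominally "inside" the counterbody at t=0 (the bodies are
                # separated by the congruency gap in the continuum
                # geometry); calibrate the rest clearance once so contact
                # measures advance relative to the initial configuration
                rest_clearance = np.where(
                    valid, np.maximum(ps[:, 2] - H, 0.0), 0.0)
            gap = np.where(valid, ps[:, 2] - H - rest_clearance, -1.0)
            active = valid & (gap > 0)

        node_p = np.zeros(slave.size)
        if active.any():
            touched = True
            g_act = gap[active]
            if g_act.max() > max_g:
                raise RuntimeError(
                    f"interpenetration {g_act.max():.2f} mm exceeds "
                    f"{case.max_overclosure_factor:g} element edges at "
                    f"t={t * 1e3:.3f} ms")
            node_p[active] = k * g_act
            fN = node_p * s_area                      # N, +z on master

            def distribute(vals, comp):
                """Spread master-side reactions over the interpolation
                stencil's facet nodes (consistent with the height field,
                so the contact spring has a well-defined potential)."""
                view = fb.reshape(-1, 3)[:, comp]
                for w, q in slot_data:
                    sel = active & (w > 0)
                    if sel.any():
                        share = (vals * w / wnorm / 4.0)[sel]
                        np.add.at(view, q[sel].ravel(),
                                  np.repeat(share, 4))

            fa[sdof[:, 2]] -= fN
            if not rigid:
                # conservative tangential component on sloped surfaces:
                # F_slave = -dU/d(x,y,z) with U = 1/2 k A (z - H(x,y))^2
                fa[sdof[:, 0]] += fN * Hgrad[:, 0]
                fa[sdof[:, 1]] += fN * Hgrad[:, 1]
                distribute(fN, 2)

            # Coulomb friction: tangential penalty with slip return mapping
            if case.friction_mu > 0:
                newly = active & np.isnan(anchor[:, 0])
                rel = ps[:, :2] - Wxy if not rigid else ps[:, :2].copy()
                anchor[newly] = rel[newly]
                trial = -k * s_area[:, None] * (rel - anchor)
                tmag = np.linalg.norm(trial, axis=1)
                cap = case.friction_mu * fN
                slide = active & (tmag > cap) & (tmag > 0)
                if slide.any():
                    scale = cap[slide] / tmag[slide]
                    slip = (1 - scale[:, None]) * (rel - anchor)[slide]
                    e_fric += float(np.sum(
                        cap[slide] * np.linalg.norm(slip, axis=1)))
                    anchor[slide] += slip
                    trial[slide] *= scale[:, None]
                ft = np.where(active[:, None], trial, 0.0)
                fa[sdof[:, 0]] += ft[:, 0]
                fa[sdof[:, 1]] += ft[:, 1]
                if not rigid:
                    distribute(-ft[:, 0], 0)
                    distribute(-ft[:, 1], 1)
        anchor[~active] = np.nan

        # --- integrate velocities ----------------------------------------
        va_new = va + dt * fa / ma3
        if not rigid:
            fb[fixed_dofs_b] = 0.0
            vb_new = vb + dt * fb / mb3
            vb_new[fixed_dofs_b] = 0.0

        # --- energy audit at time t (displacements not yet advanced) ------
        if step % record_every == 0 or step == n_steps - 1:
            v_mid = 0.5 * (va + va_new)
            e_kin = 0.5 * float(ma3 @ v_mid ** 2)
            e_str = 0.5 * float(ua @ fint_a)
            if not rigid:
                vb_mid = 0.5 * (vb + vb_new)
                e_kin += 0.5 * float(mb3 @ vb_mid ** 2)
                e_str += 0.5 * float(ub @ fint_b)
            e_con = 0.5 * float(np.sum(k * s_area * gap ** 2 * active))
            if case.friction_mu > 0 and active.any():
                dev = np.where(active[:, None], rel - anchor, 0.0)
                e_con += 0.5 * float(np.sum(k * s_area * (dev ** 2).sum(1)))
            if e_kin + e_str + e_con > 10.0 * ke0:
                raise RuntimeError(
                    f"instability: total energy {e_kin + e_str + e_con:.3g} "
                    f"mJ exceeds 10x initial KE ({ke0:.3g} mJ) at "
                    f"t={t * 1e3:.3f} ms")
            if t >= next_record - 0.5 * dt:
                record(t, node_p, e_kin, e_str, e_con)
                next_record += out_dt

        # --- advance displacements ---------------------------------------
        va = va_new
        ua = ua + dt * va
        if not rigid:
            vb = vb_new
            ub = ub + dt * vb
        t += dt
        step += 1

    en = np.array(energies_rows)
    hist = ImpactHistory(
        times_ms=np.asarray(times),
        displacements=disps, velocities=vels, von_mises=vms,
        contact_pressure=cps, articular_facets=art_fids,
        energies={"kinetic": en[:, 0], "strain": en[:, 1],
                  "contact": en[:, 2], "friction_dissipated": en[:, 3]},
        total_contact_force=np.asarray(tot_force),
        meta={"dt_s": dt, "n_steps": step, "initial_ke_mJ": ke0,
              "case": vars(case).copy(), "rigid_plane": rigid})
    log.info("run_impact: %d steps, dt=%.3e s, peak force %.1f N",
             step, dt, hist.total_contact_force.max(initial=0.0))
    return hist


def contact_summary(history: ImpactHistory, mesh: FEMesh):
    """Per-region contact-pressure summary table.

    For each labelled articular region: the event maximum of the
    facet-area-weighted mean pressure, the pointwise peak pressure, and the
    contact area (facets with positive pressure) at the instant of peak
    total contact force.  Regions that never see contact report zeros
    (with a warning).
    """
    import pandas as pd

    from .meshing import REGION_LABELS

    art = history.articular_facets
    pos = {fid: i for i, fid in enumerate(art)}
    areas = mesh.facet_areas()
    P = np.asarray(history.contact_pressure)      # (t, n_art)
    if P.size == 0 or P.max() <= 0:
        import warnings
        warnings.warn("no contact occurred during the event", stacklevel=2)
    t_peak = int(np.argmax(history.total_contact_force))

    rows = []
    for name in REGION_LABELS:
        if name not in mesh.facet_sets:
            continue
        fids = np.asarray(mesh.facet_sets[name])
        idx = np.array([pos[f] for f in fids if f in pos], dtype=int)
        if idx.size == 0:
            continue
        a = areas[fids]
        mean_t = (P[:, idx] * a).sum(axis=1) / a.sum()
        p_at_peak = P[t_peak, idx]
        rows.append({
            "region": name,
            "avg_pressure_MPa": float(mean_t.max()),
            "peak_pressure_MPa": float(P[:, idx].max()),
            "contact_area_mm2": float(a[p_at_peak > 0].sum()),
            "n_facets": int(idx.size)})
    return pd.DataFrame(rows).set_index("region")
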