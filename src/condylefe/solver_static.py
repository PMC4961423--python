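"""Small-strain isotropic linear-elastic FE core and static solver.

Hex8 (trilinear) elements with full 2x2x2 Gauss integration — no reduced
integration, hence no hourglass control.  Stresses are evaluated at the
element centroid from the centroid strain and the element's isotropic
material law.  The voxel meshes this package builds consist of congruent
axis-aligned boxes, which the element-matrix code exploits: one reference
stiffness per (element size, Poisson ratio), scaled by each element's
modulus.

The midstance load case applies known static surface pressures (default
19.5 MPa, the middle of the 19–20 MPa range reported for ex vivo joint
pressures at midstance) on the dorsal and palmar contact patches of the
distal articular surface, with the proximal cut end fully constrained.

Units: mm / MPa / N (see :mod:`condylefe.units`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .densitymap import MaterialField
from .meshing import FEMesh

log = logging.getLogger(__name__)

#: Default midstance contact-patch pressure, MPa.
DEFAULT_STATIC_PRESSURE = 19.5

#: Above this many DOF the solver switches from sparse LU to Jacobi-CG.
DIRECT_SOLVE_DOF_LIMIT = 150_000

_GP = np.array([-1.0, 1.0]) / np.sqrt(3.0)


@dataclass
class StaticLoadCase:
    """Surface-pressure loading with full fixation of one node set.

    ``pressure_patches`` maps facet-set names to pressures (MPa), applied
    along the inward facet normal; ``fixed_set`` names the node set
    constrained in all directions.
    """

    pressure_patches: dict[str, float] = field(default_factory=lambda: {
        "dorsal_patch": DEFAULT_STATIC_PRESSURE,
        "palmar_patch": DEFAULT_STATIC_PRESSURE})
    fixed_set: str = "proximal_end"

    def validate(self, mesh: FEMesh) -> None:
        if not self.pressure_patches:
            raise ValueError("no pressure patches")
        for name, p in self.pressure_patches.items():
            if p < 0:
                raise ValueError(f"negative pressure on {name!r}")
            if name not in mesh.facet_sets:
                raise ValueError(f"facet set {name!r} not on mesh")
        nset = mesh.node_sets.get(self.fixed_set)
        if nset is None or len(nset) == 0:
            raise ValueError(f"fixed node set {self.fixed_set!r} empty")


@dataclass
class SolutionField:
    """Nodal displacements (mm) and per-element centroid stresses (MPa).

    ``stress`` components are ordered (xx, yy, zz, xy, yz, zx).
    """

    displacements: np.ndarray
    stress: np.ndarray
    von_mises: np.ndarray
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# element matrices
# ---------------------------------------------------------------------------

def isotropic_D(E: float, nu: float) -> np.ndarray:
    """6x6 isotropic elasticity matrix, engineering shear strains."""
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    D = np.zeros((6, 6))
    D[:3, :3] = lam
    D[np.arange(3), np.arange(3)] += 2 * mu
    D[3:, 3:] = np.eye(3) * mu
    return D


def _shape_gradients(xi, eta, zeta, h):
    """Physical shape-function gradients of a [0,h]^3 box hex8 at a
    natural-coordinate point; returns (8, 3)."""
    from .meshing import _HEX_OFFSETS
    signs = _HEX_OFFSETS * 2 - 1            # (8,3) in {-1,+1}
    nat = np.array([xi, eta, zeta])
    grads = np.empty((8, 3))
    for a in range(8):
        s = signs[a]
        for d in range(3):
            terms = [(1 + s[j] * nat[j]) / 2 for j in range(3) if j != d]
            grads[a, d] = (s[d] / 2) * terms[0] * terms[1] * (2.0 / h[d])
    return grads


def _B_matrix(grads: np.ndarray) -> np.ndarray:
    """6x24 strain-displacement matrix from (8,3) shape gradients."""
    B = np.zeros((6, 24))
    for a in range(8):
        gx, gy, gz = grads[a]
        c = 3 * a
        B[0, c] = gx
        B[1, c + 1] = gy
        B[2, c + 2] = gz
        B[3, c] = gy
        B[3, c + 1] = gx
        B[4, c + 1] = gz
        B[4, c + 2] = gy
        B[5, c] = gz
        B[5, c + 2] = gx
    return B


def element_stiffness(h, E: float, nu: float) -> np.ndarray:
    """24x24 hex8 stiffness of an axis-aligned box with edges ``h``."""
    h = np.broadcast_to(np.asarray(h, float), (3,))
    D = isotropic_D(E, nu)
    detJ = np.prod(h) / 8.0
    Ke = np.zeros((24, 24))
    for xi in _GP:
        for eta in _GP:
            for zeta in _GP:
                B = _B_matrix(_shape_gradients(xi, eta, zeta, h))
                Ke += B.T @ D @ B * detJ
    return Ke


def _element_edges(mesh: FEMesh) -> np.ndarray:
    en = mesh.nodes[mesh.elements]
    return en.max(axis=1) - en.min(axis=1)


def assemble_system(mesh: FEMesh, materials: MaterialField) -> sp.csr_matrix:
    """Assemble the global stiffness matrix (3 DOF per node, node-major).

    Symmetric positive semi-definite with exactly the 6 rigid-body
    zero-energy modes before constraints are applied.
    """
    if mesh.element_type != "hex8":
        raise ValueError("solver supports hex8 meshes")
    if materials.n_elements != mesh.n_elements:
        raise ValueError("materials not aligned with mesh elements")
    mesh.element_volumes()          # raises on inverted elements
    edges = _element_edges(mesh)
    h = edges[0]
    if not np.allclose(edges, h, rtol=1e-9):
        raise ValueError("assemble_system expects congruent voxel elements")

    dof = (3 * mesh.elements[:, :, None] +
           np.arange(3)[None, None, :]).reshape(mesh.n_elements, 24)
    rows = np.repeat(dof, 24, axis=1).ravel()
    cols = np.tile(dof, (1, 24)).ravel()

    data = np.empty((mesh.n_elements, 24, 24))
    for nu in np.unique(materials.nu):
        sel = materials.nu == nu
        Ke1 = element_stiffness(h, 1.0, nu)
        data[sel] = materials.E[sel, None, None] * Ke1
    K = sp.coo_matrix(
        (data.ravel(), (rows, cols)),
        shape=(3 * mesh.n_nodes, 3 * mesh.n_nodes)).tocsr()
    return K


def assemble_lumped_mass(mesh: FEMesh, rho_solver: np.ndarray) -> np.ndarray:
    """Row-sum (here: equal-split) lumped nodal masses, shape (n_nodes,).

    ``rho_solver`` is per-element density in tonne/mm^3; returns tonnes.
    """
    vols = mesh.element_volumes()
    m_el = rho_solver * vols / 8.0
    mass = np.zeros(mesh.n_nodes)
    np.add.at(mass, mesh.elements.ravel(),
              np.repeat(m_el, 8))
    return mass


def pressure_forces(mesh: FEMesh, patches: dict[str, float]) -> np.ndarray:
    """Consistent nodal forces (N) for uniform pressures on facet sets,
    directed along the inward facet normal."""
    f = np.zeros((mesh.n_nodes, 3))
    areas = mesh.facet_areas()
    for name, p in patches.items():
        idx = np.asarray(mesh.facet_sets[name])
        fvec = -p * areas[idx, None] * mesh.facet_normals[idx] / 4.0
        for corner in range(4):
            np.add.at(f, mesh.boundary_facets[idx, corner], fvec)
    return f.ravel()


# ---------------------------------------------------------------------------
# solves
# ---------------------------------------------------------------------------

def solve_dirichlet(K: sp.csr_matrix, f: np.ndarray,
                    fixed_dofs: np.ndarray,
                    fixed_values: np.ndarray | None = None,
                    rtol: float = 1e-8) -> tuple[np.ndarray, float]:
    """Solve K u = f with prescribed DOF values; returns (u, rel residual)."""
    n = K.shape[0]
    fixed_dofs = np.asarray(fixed_dofs)
    if fixed_dofs.size == 0:
        raise ValueError("under-constrained system: no fixed DOFs")
    u = np.zeros(n)
    if fixed_values is not None:
        u[fixed_dofs] = fixed_values
    free = np.ones(n, bool)
    free[fixed_dofs] = False
    free_idx = np.flatnonzero(free)

    rhs = f[free_idx] - K[free_idx][:, fixed_dofs] @ u[fixed_dofs]
    Kff = K[free_idx][:, free_idx].tocsc()
    if Kff.shape[0] <= DIRECT_SOLVE_DOF_LIMIT:
        uf = spla.spsolve(Kff, rhs)
    else:
        d = Kff.diagonal()
        M = spla.LinearOperator(Kff.shape, lambda x: x / d)
        uf, info = spla.cg(Kff, rhs, M=M, rtol=rtol * 1e-2, maxiter=20_000)
        if info != 0:
            raise RuntimeError(f"CG failed to converge (info={info})")
    u[free_idx] = uf
    ref = np.linalg.norm(rhs)
    res = np.linalg.norm(Kff @ uf - rhs) / ref if ref > 0 else \
        np.linalg.norm(Kff @ uf)
    return u, float(res)


def element_stresses(mesh: FEMesh, materials: MaterialField,
                     u: np.ndarray) -> np.ndarray:
    """Centroid stress tensors (m, 6) from a nodal displacement vector."""
    h = _element_edges(mesh)[0]
    B0 = _B_matrix(_shape_gradients(0.0, 0.0, 0.0, h))
    ue = u.reshape(-1, 3)[mesh.elements].reshape(mesh.n_elements, 24)
    strain = ue @ B0.T                     # (m, 6) engineering strains
    stress = np.empty_like(strain)
    for nu in np.unique(materials.nu):
        sel = materials.nu == nu
        D1 = isotropic_D(1.0, nu)
        stress[sel] = (strain[sel] @ D1.T) * materials.E[sel, None]
    return stress


def von_mises(stress: np.ndarray) -> np.ndarray:
    """Von Mises stress from (…, 6) tensors ordered (xx,yy,zz,xy,yz,zx)."""
    s = np.asarray(stress, float)
    sxx, syy, szz, sxy, syz, szx = (s[..., i] for i in range(6))
    return np.sqrt(0.5 * ((sxx - syy) ** 2 + (syy - szz) ** 2
                          + (szz - sxx) ** 2)
                   + 3.0 * (sxy ** 2 + syz ** 2 + szx ** 2))


def solve_static(mesh: FEMesh, materials: MaterialField,
                 case: StaticLoadCase | None = None) -> SolutionField:
    """Linear static equilibrium under the midstance surface pressures."""
    case = case or StaticLoadCase()
    case.validate(mesh)
    K = assemble_system(mesh, materials)
    f = pressure_forces(mesh, case.pressure_patches)
    fixed_nodes = np.asarray(mesh.node_sets[case.fixed_set])
    fixed_dofs = (3 * fixed_nodes[:, None] + np.arange(3)).ravel()
    u, res = solve_dirichlet(K, f, fixed_dofs)
    if res > 1e-8:
        raise RuntimeError(f"static solve residual {res:.2e} exceeds 1e-8")
    stress = element_stresses(mesh, materials, u)
    vm = von_mises(stress)
    # global equilibrium audit: reactions balance the applied load
    reactions = (K @ u - f)[fixed_dofs]
    total_applied = f.reshape(-1, 3).sum(axis=0)
    balance = reactions.reshape(-1, 3).sum(axis=0) + total_applied
    log.info("solve_static: residual %.2e, equilibrium gap %s N", res,
             np.array2string(balance, precision=3))
    return SolutionField(
        displacements=u.reshape(-1, 3), stress=stress, von_mises=vm,
        meta={"residual": res,
              "equilibrium_gap_N": balance,
              "case": {"pressure_patches": dict(case.pressure_patches),
                       "fixed_set": case.fixed_set}})
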