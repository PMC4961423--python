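"""File formats: volumes, meshes, material tables, solver decks.

Volumes go through SimpleITK (MetaImage ``.mhd``/``.mha`` and NIfTI
``.nii``/``.nii.gz``), with the package's (x, y, z) axis order mapped
to/from SimpleITK's (z, y, x) array layout and a JSON sidecar carrying
provenance metadata.  Meshes are written as VTK legacy-ASCII unstructured
grids (with optional cell/point data arrays) plus a JSON sidecar for the
named node/facet/element sets, and as Abaqus-style ``.inp`` decks with one
element set and ``*SOLID SECTION`` per material bin.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .meshing import FEMesh
from .volume import VoxelVolume

_VOLUME_EXTS = (".mhd", ".mha", ".nii", ".nii.gz")


def _sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".meta.json")


def write_volume(volume: VoxelVolume, path) -> Path:
    """Write a volume (MetaImage or NIfTI by extension) + metadata sidecar."""
    import SimpleITK as sitk

    path = Path(path)
    if not str(path).endswith(_VOLUME_EXTS):
        raise ValueError(
            f"unsupported volume extension {path.suffix!r}; "
            f"supported: {', '.join(_VOLUME_EXTS)}")
    img = sitk.GetImageFromArray(
        np.ascontiguousarray(volume.data.astype(np.float64).T))
    img.SetSpacing(tuple(volume.spacing))
    img.SetOrigin(tuple(volume.origin))
    sitk.WriteImage(img, str(path))
    meta = {"value_kind": volume.value_kind, "units": "mm",
            **volume.meta}
    _sidecar(path).write_text(json.dumps(_jsonable(meta), indent=1))
    return path


def read_volume(path) -> VoxelVolume:
    """Read a MetaImage/NIfTI volume; restores value_kind from the sidecar
    (defaults to ``hu`` when no sidecar is present)."""
    import SimpleITK as sitk

    path = Path(path)
    if not str(path).endswith(_VOLUME_EXTS):
        raise ValueError(
            f"unsupported volume extension {path.suffix!r}; "
            f"supported: {', '.join(_VOLUME_EXTS)}")
    img = sitk.ReadImage(str(path))
    data = sitk.GetArrayFromImage(img).T
    meta = {}
    sc = _sidecar(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
    kind = meta.pop("value_kind", "hu")
    meta.pop("units", None)
    return VoxelVolume(data=np.asarray(data, float),
                       spacing=tuple(img.GetSpacing()),
                       origin=np.asarray(img.GetOrigin()),
                       value_kind=kind, meta=meta)


# ---------------------------------------------------------------------------
# VTK legacy ASCII unstructured grid
# ---------------------------------------------------------------------------

_VTK_CELL = {"hex8": 12, "tet4": 10}
_CELL_VTK = {12: ("hex8", 8), 10: ("tet4", 4)}


def write_mesh(mesh: FEMesh, path, cell_data: dict | None = None,
               point_data: dict | None = None) -> Path:
    """Write a mesh as a VTK legacy ASCII unstructured grid.

    ``cell_data``/``point_data`` map array names to per-element/per-node
    scalar or vector arrays.  Named sets go to a ``.sets.json`` sidecar.
    """
    path = Path(path)
    npts, ncell = mesh.n_nodes, mesh.n_elements
    nn = mesh.elements.shape[1]
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\ncondylefe mesh\nASCII\n")
        f.write("DATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {npts} double\n")
        for p in mesh.nodes:
            f.write("%.17g %.17g %.17g\n" % tuple(p))
        f.write(f"CELLS {ncell} {ncell * (nn + 1)}\n")
        for el in mesh.elements:
            f.write(str(nn) + " " + " ".join(map(str, el)) + "\n")
        f.write(f"CELL_TYPES {ncell}\n")
        ct = _VTK_CELL[mesh.element_type]
        f.write("\n".join([str(ct)] * ncell) + "\n")
        for tag, data, n in (("CELL_DATA", cell_data, ncell),
                             ("POINT_DATA", point_data, npts)):
            if not data:
                continue
            f.write(f"{tag} {n}\n")
            for name, arr in data.items():
                arr = np.asarray(arr)
                if arr.ndim == 1:
                    f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE "
                            "default\n")
                    f.write("\n".join("%.17g" % v for v in arr) + "\n")
                else:
                    f.write(f"VECTORS {name} double\n")
                    for row in arr:
                        f.write("%.17g %.17g %.17g\n" % tuple(row))
    sets = {
        "element_type": mesh.element_type,
        "node_sets": {k: np.asarray(v).tolist()
                      for k, v in mesh.node_sets.items()},
        "facet_sets": {k: np.asarray(v).tolist()
                       for k, v in mesh.facet_sets.items()},
        "element_sets": {k: np.asarray(v).tolist()
                         for k, v in mesh.element_sets.items()},
    }
    path.with_name(path.name + ".sets.json").write_text(json.dumps(sets))
    return path


def read_mesh(path) -> FEMesh:
    """Read a VTK legacy ASCII unstructured grid written by
    :func:`write_mesh` (sets restored from the sidecar when present).

    Boundary facets and the point-location grid are not serialized; meshes
    intended for further solving should be rebuilt from the volume.
    """
    path = Path(path)
    if path.suffix.lower() != ".vtk":
        raise ValueError(f"unsupported mesh extension {path.suffix!r}; "
                         "supported: .vtk")
    tokens = path.read_text().split()

    def find(word):
        for i, t in enumerate(tokens):
            if t == word:
                return i
        raise ValueError(f"malformed VTK file: missing {word}")

    ip = find("POINTS")
    npts = int(tokens[ip + 1])
    pts = np.array(tokens[ip + 3: ip + 3 + 3 * npts],
                   float).reshape(npts, 3)
    ic = find("CELLS")
    ncell = int(tokens[ic + 1])
    total = int(tokens[ic + 2])
    raw = np.array(tokens[ic + 3: ic + 3 + total], int)
    nn = raw[0]
    cells = raw.reshape(ncell, nn + 1)[:, 1:]
    itype = find("CELL_TYPES")
    etype = _CELL_VTK[int(tokens[itype + 2])][0]
    mesh = FEMesh(nodes=pts, elements=cells, element_type=etype)
    sc = path.with_name(path.name + ".sets.json")
    if sc.exists():
        sets = json.loads(sc.read_text())
        mesh.node_sets = {k: np.asarray(v, int)
                          for k, v in sets["node_sets"].items()}
        mesh.facet_sets = {k: np.asarray(v, int)
                           for k, v in sets["facet_sets"].items()}
        mesh.element_sets = {k: np.asarray(v, int)
                             for k, v in sets["element_sets"].items()}
    return mesh


# ---------------------------------------------------------------------------
# Abaqus-style deck export
# ---------------------------------------------------------------------------

def write_inp(mesh: FEMesh, materials, path, n_bins: int = 200) -> Path:
    """Write an Abaqus-style ``.inp`` deck (write-only interchange format).

    Moduli are grouped into at most ``n_bins`` bins; each bin becomes an
    ELSET with its own ``*SOLID SECTION`` and ``*MATERIAL``.  Node/element
    ids are 1-based per the format.  Named node sets become ``*NSET`` cards.
    """
    path = Path(path)
    eltype = {"hex8": "C3D8", "tet4": "C3D4"}[mesh.element_type]
    E = np.asarray(materials.E)
    edges = np.linspace(E.min(), E.max() + 1e-9, min(n_bins, max(
        1, len(np.unique(E)))) + 1)
    bins = np.clip(np.digitize(E, edges) - 1, 0, len(edges) - 2)
    with open(path, "w") as f:
        f.write("*HEADING\ncondylefe voxel mesh export\n")
        f.write("*NODE\n")
        for i, p in enumerate(mesh.nodes, start=1):
            f.write("%d, %.9g, %.9g, %.9g\n" % (i, *p))
        f.write(f"*ELEMENT, TYPE={eltype}\n")
        for i, el in enumerate(mesh.elements, start=1):
            f.write(str(i) + ", " + ", ".join(str(v + 1) for v in el)
                    + "\n")
        for b in np.unique(bins):
            sel = np.flatnonzero(bins == b) + 1
            name = f"MATBIN{b}"
            f.write(f"*ELSET, ELSET={name}\n")
            for i in range(0, len(sel), 8):
                f.write(", ".join(map(str, sel[i:i + 8])) + "\n")
            Eb = float(E[bins == b].mean())
            nub = float(np.asarray(materials.nu)[bins == b].mean())
            rhob = float(np.asarray(materials.rho)[bins == b].mean())
            f.write(f"*SOLID SECTION, ELSET={name}, MATERIAL={name}\n")
            f.write(f"*MATERIAL, NAME={name}\n*ELASTIC\n"
                    f"{Eb:.6g}, {nub:.4g}\n*DENSITY\n{rhob * 1e-9:.6g}\n")
        for name, nodes in mesh.node_sets.items():
            f.write(f"*NSET, NSET={name.upper()}\n")
            arr = np.asarray(nodes) + 1
            for i in range(0, len(arr), 8):
                f.write(", ".join(map(str, arr[i:i + 8])) + "\n")
    return path


def write_material_csv(mesh: FEMesh, materials, path) -> Path:
    """Per-element material table (id, E, nu, rho, volume)."""
    import pandas as pd

    df = pd.DataFrame({
        "element": np.arange(mesh.n_elements),
        "E_MPa": materials.E, "nu": materials.nu,
        "rho_gcm3": materials.rho,
        "volume_mm3": mesh.element_volumes()})
    df.to_csv(path, index=False)
    return Path(path)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
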