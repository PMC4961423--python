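"""Regional stress post-processing.

Mirrors the study's data analysis: a uniform sampling grid of 160
equidistant points (8 rows x 20 columns, matching the condylar aspect
ratio) is superimposed either over the distal articular surface (for
contact pressures) or over a mediolateral slice a fixed offset dorsal or
palmar to the transverse ridge (for von Mises stress), scaled to the
domain's bounding rectangle.  Sampled values are grouped by anatomical
region and reduced to per-region averages and peaks; companion routines
implement the mesh-convergence report (±5% criterion on regional
averages), the stiffness-sensitivity report (1.5x modulus scaling) and
healthy-vs-OA / impact-vs-midstance difference tables.

Sampling is piecewise-constant: each point takes the centroid value of its
containing element, consistent with per-element stress output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .meshing import FEMesh

log = logging.getLogger(__name__)

DEFAULT_LAYOUT = (8, 20)

#: Mediolateral slice band labels, lateral -> medial.
SLICE_BANDS = ("LateralCondyle", "LateralPSG", "SR", "MedialPSG",
               "MedialCondyle")


@dataclass
class SamplingGrid:
    """A rows x cols grid of sample points with per-point region labels.

    ``points`` are mm coordinates (n_rows*n_cols, 3); ``labels`` the region
    of each point; ``n_projected`` counts points that fell outside the bone
    outline and were projected to the nearest interior location.
    """

    points: np.ndarray
    labels: np.ndarray
    layout: tuple[int, int]
    domain: dict
    n_projected: int = 0

    @property
    def n_points(self) -> int:
        return len(self.points)


@dataclass
class RegionalStressTable:
    """Per-region average/peak values — the shape of the study's tables."""

    table: pd.DataFrame          # index: region; columns: average, peak, n
    metadata: dict = field(default_factory=dict)

    def region(self, name: str) -> pd.Series:
        return self.table.loc[name]

    @property
    def regions(self):
        return list(self.table.index)


def _corner_anchored(lo: float, hi: float, n: int) -> np.ndarray:
    """n equidistant points spanning [lo, hi] inclusive of both ends."""
    return np.linspace(lo, hi, n)


def make_sampling_grid(mesh: FEMesh, domain: str = "surface",
                       layout: tuple[int, int] = DEFAULT_LAYOUT,
                       slice_name: str | None = None) -> SamplingGrid:
    """Build the sampling grid over a surface or slice domain.

    ``domain="surface"``: grid in the (x, y) footprint of the distal
    articular surface; each point takes the z and region label of the
    nearest articular facet, and points whose nearest facet is farther than
    one element edge in-plane count as projected.

    ``domain="slice"`` with ``slice_name`` "dorsal" or "palmar": grid in
    the (x, z) rectangle of the elements cut by that mediolateral slice
    plane (recorded by region labelling); labels are the five mediolateral
    bands (condyle/PSG/SR) projected into the section.
    """
    nrow, ncol = layout
    if nrow < 1 or ncol < 1:
        raise ValueError("layout must be at least 1x1")
    reg = mesh.metadata.get("regions")
    if reg is None:
        raise ValueError("mesh has no region labelling; run label_regions")
    h = float(np.max(mesh.metadata["grid"]["spacing"]))

    if domain == "surface":
        art = np.asarray(mesh.facet_sets["distal_articular_surface"])
        cent = mesh.facet_centroids()[art]
        labels_f = _facet_labels(mesh, art)
        lo, hi = cent[:, :2].min(0), cent[:, :2].max(0)
        gx = _corner_anchored(lo[0], hi[0], ncol)
        gy = _corner_anchored(lo[1], hi[1], nrow)
        GX, GY = np.meshgrid(gx, gy)
        pts2 = np.stack([GX.ravel(), GY.ravel()], axis=1)
        from scipy.spatial import cKDTree
        d, idx = cKDTree(cent[:, :2]).query(pts2)
        outside = d > h
        pts = np.column_stack([pts2, cent[idx, 2]])
        pts[outside, :2] = cent[idx[outside], :2]
        labels = labels_f[idx]
        n_proj = int(outside.sum())
        dom = {"kind": "surface",
               "bounds": [lo.tolist(), hi.tolist()]}
    elif domain == "slice":
        if slice_name not in ("dorsal", "palmar"):
            raise ValueError("slice_name must be 'dorsal' or 'palmar'")
        y0 = reg["slice_planes"][slice_name]
        ec = mesh.element_centroids()
        cut = np.abs(ec[:, 1] - y0) <= 0.5 * h
        if not cut.any():
            raise ValueError(
                f"slice plane y={y0:g} mm cuts no elements (degenerate "
                "domain)")
        exz = ec[cut][:, [0, 2]]
        lo, hi = exz.min(0), exz.max(0)
        if np.any(hi - lo <= 0):
            raise ValueError("degenerate slice domain")
        gx = _corner_anchored(lo[0], hi[0], ncol)
        gz = _corner_anchored(lo[1], hi[1], nrow)
        GX, GZ = np.meshgrid(gx, gz)
        pts = np.column_stack(
            [GX.ravel(), np.full(GX.size, y0), GZ.ravel()])
        # outside the bone outline = inside no element
        outside = mesh.locate_points(pts) < 0
        if outside.any():
            from scipy.spatial import cKDTree
            _, idx = cKDTree(exz).query(pts[np.ix_(outside, [0, 2])])
            pts[outside, 0] = exz[idx, 0]
            pts[outside, 2] = exz[idx, 1]
        n_proj = int(outside.sum())
        labels = _band_labels(pts[:, 0], reg)
        dom = {"kind": "slice", "slice": slice_name, "y": float(y0),
               "bounds": [lo.tolist(), hi.tolist()]}
    else:
        raise ValueError(f"unknown domain {domain!r}")

    if n_proj:
        log.info("make_sampling_grid: %d/%d points projected to the bone "
                 "outline", n_proj, pts.shape[0])
    return SamplingGrid(points=pts, labels=np.asarray(labels, dtype=object),
                        layout=(nrow, ncol), domain=dom,
                        n_projected=n_proj)


def _facet_labels(mesh: FEMesh, art: np.ndarray) -> np.ndarray:
    from .meshing import REGION_LABELS
    lab = np.empty(len(art), dtype=object)
    pos = {f: i for i, f in enumerate(art)}
    for name in REGION_LABELS:
        for f in mesh.facet_sets.get(name, ()):
            lab[pos[f]] = name
    return lab


def _band_labels(x: np.ndarray, reg: dict) -> np.ndarray:
    """Mediolateral band label per x coordinate (ties go to SR)."""
    dx = x - reg["x_mid"]
    lab = np.empty(len(x), dtype=object)
    sr = np.abs(dx) <= reg["sr_half_width"]
    psg = ~sr & (np.abs(dx) <= reg["psg_outer"])
    lab[sr] = "SR"
    lab[psg & (dx > 0)] = "MedialPSG"
    lab[psg & (dx < 0)] = "LateralPSG"
    lab[~sr & ~psg & (dx > 0)] = "MedialCondyle"
    lab[~sr & ~psg & (dx < 0)] = "LateralCondyle"
    return lab


def sample_field(grid: SamplingGrid, element_values: np.ndarray,
                 mesh: FEMesh) -> np.ndarray:
    """Per-point values: the containing element's centroid value
    (piecewise-constant); points in no element take the nearest element's
    value (logged)."""
    element_values = np.asarray(element_values)
    if element_values.shape[0] != mesh.n_elements:
        raise ValueError("element_values must have one entry per element")
    eid = mesh.locate_points(grid.points)
    missing = eid < 0
    if missing.any():
        from scipy.spatial import cKDTree
        ec = mesh.element_centroids()
        _, near = cKDTree(ec).query(grid.points[missing])
        eid[missing] = near
        log.info("sample_field: %d/%d points outside the mesh took the "
                 "nearest element value", int(missing.sum()), len(eid))
    return element_values[eid]


def regional_summary(samples: np.ndarray, grid: SamplingGrid,
                     metadata: dict | None = None) -> RegionalStressTable:
    """Arithmetic mean and max of the sampled values per region.

    Regions with no sample points are absent from the table (not zero).
    """
    samples = np.asarray(samples, float)
    if samples.shape[0] != grid.n_points:
        raise ValueError("samples must align with grid points")
    rows = {}
    for name in pd.unique(grid.labels):
        sel = grid.labels == name
        rows[name] = {"average": float(samples[sel].mean()),
                      "peak": float(samples[sel].max()),
                      "n": int(sel.sum())}
    table = pd.DataFrame(rows).T[["average", "peak", "n"]]
    table.index.name = "region"
    return RegionalStressTable(table=table, metadata=dict(metadata or {}))


def convergence_check(tables: list[RegionalStressTable],
                      criterion: float = 0.05) -> pd.DataFrame:
    """Compare coarser meshes' regional averages against the finest.

    ``tables`` ordered coarse -> fine; for each coarser table and region:
    absolute difference (coarse - fine, MPa), relative difference, and a
    converged flag at ``criterion`` (default the ±5% rule).
    """
    if len(tables) < 2:
        raise ValueError("need at least two tables")
    fine = tables[-1].table
    rows = []
    for level, tab in enumerate(tables[:-1]):
        t = tab.table
        if set(t.index) != set(fine.index):
            raise ValueError("tables report different regions")
        for region in fine.index:
            a, f = t.loc[region, "average"], fine.loc[region, "average"]
            diff = a - f
            rel = diff / f if f != 0 else np.inf * np.sign(diff) if diff \
                else 0.0
            rows.append({
                "comparison": f"level{level}-vs-fine",
                "region": region,
                "diff_MPa": diff,
                "rel_diff": rel,
                "converged": bool(abs(rel) <= criterion)})
    return pd.DataFrame(rows)


def sensitivity_compare(base: RegionalStressTable,
                        scaled: RegionalStressTable,
                        base_samples: np.ndarray | None = None,
                        scaled_samples: np.ndarray | None = None,
                        change_tol: float = 1e-3) -> dict:
    """Stiffness-sensitivity report: scaled/base regional ratios.

    Returns a dict with a per-region DataFrame (ratio and percent change)
    and, when per-point samples are supplied, the fraction of points whose
    value changed by more than ``change_tol`` (relative) plus the largest
    single-point percent change.
    """
    b, s = base.table, scaled.table
    if set(b.index) != set(s.index):
        raise ValueError("tables report different regions")
    ratio = s["average"] / b["average"]
    per_region = pd.DataFrame({
        "base_avg": b["average"], "scaled_avg": s["average"],
        "ratio": ratio, "percent_change": 100.0 * (ratio - 1.0)})
    out = {"per_region": per_region}
    if base_samples is not None and scaled_samples is not None:
        bs, ss = np.asarray(base_samples, float), np.asarray(
            scaled_samples, float)
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.where(bs != 0, (ss - bs) / bs, np.where(ss != 0,
                                                             np.inf, 0.0))
        changed = np.abs(rel) > change_tol
        out["points"] = {
            "n_changed": int(changed.sum()),
            "fraction_changed": float(changed.mean()),
            "max_percent_increase": float(100.0 * np.max(rel, initial=0.0)),
        }
    return out


def compare_variants(a: RegionalStressTable,
                     b: RegionalStressTable) -> pd.DataFrame:
    """Signed per-region differences b - a (absolute MPa and percent).

    Used for healthy-vs-OA and impact-vs-midstance reports; antisymmetric
    under swapping the arguments.
    """
    ta, tb = a.table, b.table
    if set(ta.index) != set(tb.index):
        raise ValueError("tables report different regions")
    la = a.metadata.get("load_case")
    lb = b.metadata.get("load_case")
    if la is not None and lb is not None and la != lb:
        raise ValueError(
            f"incompatible load cases: {la!r} vs {lb!r}")
    diff = tb["average"] - ta["average"]
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(ta["average"] != 0,
                       100.0 * diff / ta["average"], np.nan)
    return pd.DataFrame({
        "a_avg": ta["average"], "b_avg": tb["average"],
        "diff_MPa": diff, "percent": pct,
        "peak_diff_MPa": tb["peak"] - ta["peak"]})
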