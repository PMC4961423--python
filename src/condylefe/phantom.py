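"""Synthetic CT-like condyle phantoms.

The study this package supports models the distal condyle of the equine
third metacarpal (MC3) impacting the proximal phalanx (P1).  The original
micro-CT scans were never deposited, so the pipeline is driven by a
constructive-solid-geometry (CSG) phantom instead: a cylindrical shaft
capped by a bi-lobed condylar surface (two partially overlapping spheres)
with an optional central sagittal ridge, a cortical shell over a noisy
trabecular core, and an optional focal subchondral sclerotic lesion for the
osteoarthritic (OA) variant.

CSG rather than an anatomical mesh is deliberate: the shapes admit
closed-form volumes and exact mirror symmetry, which the test-suite uses as
independent oracles.  Densities are apparent densities in g/cm^3, clipped to
the 0–2.47 g/cm^3 range observed for dense equine subchondral bone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np

from .volume import VoxelVolume

#: Apparent-density ceiling (g/cm^3) applied to every phantom voxel.
DENSITY_MAX = 2.47


@dataclass
class PhantomSpec:
    """Geometry, density architecture and pose of a synthetic condyle.

    Lengths in mm, densities in g/cm^3, angles in degrees.  The condyle is
    built from two spheres of radius ``condyle_radius`` whose centers sit on
    the distal shaft-end plane, offset by ``condyle_separation`` along the
    lateral–medial (x) axis; the shaft is the inscribing cylinder of radius
    ``condyle_separation/2 + condyle_radius``.  ``ridge_height > 0`` adds a
    sagittal ridge (an elliptical prism along y) protruding past the lobes.

    ``joint_angle`` poses the counterbody relative to the shaft axis
    (180 deg = collinear; the physiological range at first ground contact is
    about 165–175 deg).
    """

    voxel_spacing: float = 0.8
    shaft_length: float = 40.0
    condyle_radius: float = 11.0
    condyle_separation: float = 10.0
    ridge_height: float = 1.2
    ridge_half_width: float = 2.5
    cortical_thickness: float = 1.6
    cortical_density: float = 1.8
    trabecular_density_mean: float = 0.6
    trabecular_density_sd: float = 0.15
    lesion_center: Optional[tuple[float, float, float]] = None
    lesion_radius: float = 0.0
    lesion_density_delta: float = 0.0
    joint_angle: float = 170.0
    congruency_gap: float = 0.5
    counterbody_depth: float = 6.0
    rng_seed: int = 0

    # -- derived geometry -------------------------------------------------

    @property
    def shaft_radius(self) -> float:
        return 0.5 * self.condyle_separation + self.condyle_radius

    @property
    def condyle_plane_z(self) -> float:
        """z of the distal shaft-end plane carrying the sphere centers."""
        return self.shaft_length

    @property
    def lobe_centers(self) -> np.ndarray:
        s = 0.5 * self.condyle_separation
        L = self.shaft_length
        return np.array([[-s, 0.0, L], [s, 0.0, L]])

    def validate(self) -> None:
        positive = {
            "voxel_spacing": self.voxel_spacing,
            "shaft_length": self.shaft_length,
            "condyle_radius": self.condyle_radius,
            "condyle_separation": self.condyle_separation,
            "ridge_half_width": self.ridge_half_width,
            "cortical_thickness": self.cortical_thickness,
            "congruency_gap": self.congruency_gap,
            "counterbody_depth": self.counterbody_depth,
        }
        for name, val in positive.items():
            if val <= 0:
                raise ValueError(f"{name} must be > 0, got {val}")
        if self.ridge_height < 0:
            raise ValueError("ridge_height must be >= 0")
        if self.condyle_separation >= 2 * self.condyle_radius:
            raise ValueError("condyle lobes must overlap "
                             "(condyle_separation < 2*condyle_radius)")
        for name, val in (
            ("cortical_density", self.cortical_density),
            ("trabecular_density_mean", self.trabecular_density_mean),
        ):
            if not 0 <= val <= DENSITY_MAX:
                raise ValueError(
                    f"{name} must lie in [0, {DENSITY_MAX}] g/cm^3, got {val}")
        if self.trabecular_density_sd < 0:
            raise ValueError("trabecular_density_sd must be >= 0")
        if self.lesion_radius < 0:
            raise ValueError("lesion_radius must be >= 0")
        if not 90 < self.joint_angle <= 180:
            raise ValueError("joint_angle must lie in (90, 180] degrees")

    @classmethod
    def oa_default(cls, **overrides) -> "PhantomSpec":
        """Default OA variant: focal sclerosis under the palmar-medial
        condylar surface (the site of subchondral bone change in advanced
        OA), modelled as a +0.5 g/cm^3 focal density increase."""
        spec = cls(**overrides)
        if spec.lesion_center is None:
            r, s, L = spec.condyle_radius, 0.5 * spec.condyle_separation, \
                spec.shaft_length
            spec.lesion_center = (s, -0.55 * r, L + 0.55 * r)
        if spec.lesion_radius == 0.0:
            spec.lesion_radius = 0.35 * spec.condyle_radius
        if spec.lesion_density_delta == 0.0:
            spec.lesion_density_delta = 0.5
        return spec

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["lesion_center"] is not None:
            d["lesion_center"] = list(d["lesion_center"])
        return d


# ---------------------------------------------------------------------------
# implicit solid
# ---------------------------------------------------------------------------

def _solid_mask(spec: PhantomSpec, x, y, z) -> np.ndarray:
    """Membership of voxel centers in the condyle CSG solid (broadcasts)."""
    L = spec.condyle_plane_z
    R = spec.shaft_radius
    r = spec.condyle_radius
    s2 = 0.5 * spec.condyle_separation

    rho2 = x * x + y * y
    shaft = (z >= 0) & (z <= L) & (rho2 <= R * R)
    sph = np.zeros(np.broadcast_shapes(x.shape, y.shape, z.shape), bool)
    for sx in (-s2, s2):
        sph |= (x - sx) ** 2 + y * y + (z - L) ** 2 <= r * r
    solid = shaft | sph
    if spec.ridge_height > 0:
        a = spec.ridge_half_width
        b = r + spec.ridge_height
        ycap = 0.8 * r
        ridge = ((x / a) ** 2 + ((z - L) / b) ** 2 <= 1.0) \
            & (np.abs(y) <= ycap) & (z >= 0)
        solid |= ridge
    return solid


def _distance_to_solid(spec: PhantomSpec, pts: np.ndarray) -> np.ndarray:
    """Outside distance (mm) from points to the condyle solid surface.

    Exact for the sphere and finite-cylinder primitives; first-order
    normalized for the ridge prism.  Points inside the solid get <= 0.
    """
    x, y, z = pts[..., 0], pts[..., 1], pts[..., 2]
    L = spec.condyle_plane_z
    R = spec.shaft_radius
    r = spec.condyle_radius
    s2 = 0.5 * spec.condyle_separation

    d = np.full(x.shape, np.inf)
    for sx in (-s2, s2):
        d = np.minimum(
            d, np.sqrt((x - sx) ** 2 + y * y + (z - L) ** 2) - r)

    # finite cylinder z in [0, L], radius R (distance to its surface/solid)
    rho = np.sqrt(x * x + y * y)
    dr = rho - R                      # >0 outside laterally
    dz = np.maximum(z - L, -z)        # >0 beyond either cap
    outside = np.sqrt(np.maximum(dr, 0) ** 2 + np.maximum(dz, 0) ** 2)
    inside = np.maximum(dr, dz)       # <=0 when inside
    d_cyl = np.where((dr > 0) | (dz > 0), outside, inside)
    d = np.minimum(d, d_cyl)

    if spec.ridge_height > 0:
        a = spec.ridge_half_width
        b = r + spec.ridge_height
        ycap = 0.8 * r
        zz = z - L
        f = np.sqrt((x / a) ** 2 + (zz / b) ** 2)
        grad = np.sqrt((x / a ** 2) ** 2 + (zz / b ** 2) ** 2)
        with np.errstate(invalid="ignore", divide="ignore"):
            d_ell = np.where(grad > 0, (f - 1.0) * f / grad, -min(a, b))
        dy = np.abs(y) - ycap
        ex, ey = np.maximum(d_ell, 0), np.maximum(dy, 0)
        d_ridge = np.where((d_ell > 0) | (dy > 0),
                           np.sqrt(ex * ex + ey * ey),
                           np.maximum(d_ell, dy))
        d = np.minimum(d, d_ridge)
    return d


def analytic_solid_volume(spec: PhantomSpec) -> float:
    """Closed-form volume (mm^3) of the CSG solid for ``ridge_height == 0``.

    cylinder + two spheres - their lens intersection; valid because the
    sphere centers lie on the distal cap plane and the shaft radius
    inscribes the lobes exactly, so each sphere's proximal half is inside
    the cylinder.
    """
    if spec.ridge_height != 0:
        raise NotImplementedError(
            "closed-form volume is only available for ridge_height == 0")
    r = spec.condyle_radius
    s = spec.condyle_separation
    R = spec.shaft_radius
    L = spec.shaft_length
    v_cyl = np.pi * R * R * L
    v_sph = 4.0 / 3.0 * np.pi * r ** 3
    v_lens = np.pi * (4 * r + s) * (2 * r - s) ** 2 / 12.0
    return v_cyl + v_sph - 0.5 * v_lens


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def _make_grid(spec: PhantomSpec, lo: np.ndarray, hi: np.ndarray):
    h = spec.voxel_spacing
    lo = np.asarray(lo, float) - 1.5 * h
    hi = np.asarray(hi, float) + 1.5 * h
    n = np.maximum(np.ceil((hi - lo) / h).astype(int), 1)
    # axes symmetric about the box center: mirror-image voxel centers are
    # exact FP negations of each other, so symmetric specs voxelize to
    # exactly mirror-symmetric masks
    center = 0.5 * (lo + hi)
    axes = [center[a] + h * (np.arange(n[a]) - 0.5 * (n[a] - 1))
            for a in range(3)]
    origin = np.array([ax[0] for ax in axes])
    return origin, n, axes


def generate_condyle_volume(spec: PhantomSpec) -> VoxelVolume:
    """Generate the density-valued condyle volume for a spec.

    Voxels within ``cortical_thickness`` of the solid surface get
    ``cortical_density``; the interior gets i.i.d. normal trabecular noise
    (one RNG stream seeded by ``rng_seed``); an optional spherical lesion
    adds ``lesion_density_delta``.  All densities are clipped to
    ``[0, 2.47]`` g/cm^3; background is 0.
    """
    from scipy import ndimage

    spec.validate()
    r, R, L = spec.condyle_radius, spec.shaft_radius, spec.shaft_length
    top = L + r + spec.ridge_height
    origin, n, axes = _make_grid(
        spec, [-R, -R, 0.0], [R, R, top])
    X = axes[0][:, None, None]
    Y = axes[1][None, :, None]
    Z = axes[2][None, None, :]
    mask = _solid_mask(spec, X, Y, Z)

    h = spec.voxel_spacing
    # depth (mm) of each bone voxel below the surface
    depth = ndimage.distance_transform_edt(mask, sampling=(h, h, h))
    interior = depth > spec.cortical_thickness

    rng = np.random.default_rng(spec.rng_seed)
    data = np.zeros(mask.shape, dtype=np.float64)
    data[mask] = spec.cortical_density
    n_int = int(interior.sum())
    if spec.trabecular_density_sd > 0:
        trab = rng.normal(spec.trabecular_density_mean,
                          spec.trabecular_density_sd, size=n_int)
    else:
        trab = np.full(n_int, spec.trabecular_density_mean)
    data[interior] = trab

    if spec.lesion_center is not None and spec.lesion_radius > 0:
        c = np.asarray(spec.lesion_center, float)
        inside_solid = bool(_solid_mask(
            spec, np.array(c[0]), np.array(c[1]), np.array(c[2])))
        if not inside_solid:
            warnings.warn(
                f"lesion_center {tuple(c)} lies outside the bone envelope; "
                "proceeding", stacklevel=2)
        lesion = ((X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2
                  <= spec.lesion_radius ** 2) & mask
        data[lesion] += spec.lesion_density_delta

    np.clip(data, 0.0, DENSITY_MAX, out=data)

    return VoxelVolume(
        data=data, spacing=(h, h, h), origin=origin, value_kind="density",
        meta={"phantom_spec": spec.to_dict(), "rng_seed": spec.rng_seed,
              "body": "condyle"})


def _pose_rotation(spec: PhantomSpec):
    """Rotation (about +x through the condyle center) posing the counterbody.

    ``joint_angle == 180`` is the identity; smaller angles tip the
    counterbody axis dorsally (+y) away from the shaft axis.
    """
    # the tip direction narrows the dorsal-side clearance: at first ground
    # contact the slightly-extended joint loads the dorsal aspect of the
    # condyle, so joint angles below 180 deg shift contact dorsally
    theta = np.deg2rad(180.0 - spec.joint_angle)
    c, s = np.cos(theta), np.sin(theta)
    Rm = np.array([[1, 0, 0], [0, c, -s], [0, s, c]], float)
    pivot = np.array([0.0, 0.0, spec.condyle_plane_z])
    return Rm, pivot


def generate_counterbody(spec: PhantomSpec) -> VoxelVolume:
    """Generate the concave articular counterbody (P1 stand-in).

    The body is the negative imprint of the condylar profile offset by
    ``congruency_gap``: a distal slab carved where the distance to the
    condyle solid is below the gap, of uniform ``cortical_density``, posed
    at ``joint_angle`` to the shaft axis by rotation about the condyle
    center.
    """
    spec.validate()
    r, R, L = spec.condyle_radius, spec.shaft_radius, spec.shaft_length
    gap = spec.congruency_gap
    z_lo = L - 0.25 * r
    z_hi = L + r + spec.ridge_height + gap + spec.counterbody_depth
    r_lat = R + 1.0

    Rm, pivot = _pose_rotation(spec)

    # world-frame bounding box of the rotated aligned-frame slab
    corners = np.array([[sx, sy, sz]
                        for sx in (-r_lat, r_lat)
                        for sy in (-r_lat, r_lat)
                        for sz in (z_lo, z_hi)])
    world = (corners - pivot) @ Rm.T + pivot
    origin, n, axes = _make_grid(spec, world.min(0), world.max(0))

    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([X, Y, Z], axis=-1)
    # map world voxel centers back to the aligned frame
    pal = (pts.reshape(-1, 3) - pivot) @ Rm + pivot
    pal = pal.reshape(pts.shape)
    xa, ya, za = pal[..., 0], pal[..., 1], pal[..., 2]

    slab = (za >= z_lo) & (za <= z_hi) & (xa * xa + ya * ya <= r_lat ** 2)
    dist = _distance_to_solid(spec, pal)
    mask = slab & (dist >= gap)

    data = np.zeros(mask.shape)
    data[mask] = spec.cortical_density
    h = spec.voxel_spacing
    return VoxelVolume(
        data=data, spacing=(h, h, h), origin=origin, value_kind="density",
        meta={"phantom_spec": spec.to_dict(), "rng_seed": spec.rng_seed,
              "body": "counterbody", "joint_angle": spec.joint_angle})


def density_to_hu(volume: VoxelVolume, calibration) -> VoxelVolume:
    """Map a density volume to Hounsfield units — the exact inverse of the
    mapper's HU -> ash -> apparent chain under the same calibration
    (supports round-trip testing)."""
    volume.require_kind("density")
    ash = volume.data * calibration.ash_to_apparent_ratio
    hu = (ash - calibration.intercept) / calibration.slope
    out = volume.copy(data=hu, value_kind="hu")
    out.meta["calibration"] = {
        "slope": calibration.slope,
        "intercept": calibration.intercept,
        "ash_to_apparent_ratio": calibration.ash_to_apparent_ratio,
    }
    return out
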