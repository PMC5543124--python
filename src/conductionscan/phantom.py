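"""Synthetic voxel phantoms with known ground truth.

The contrast micro-CT appearance being emulated: after iodine staining, fat,
working myocardium, paranodal tissue, sinus-node tissue and connective tissue
show strictly decreasing attenuation, so tissue classes separate as intensity
bands.  The default phantom is a simplified two-chamber heart on an isotropic
grid: a truncated-ellipsoid ventricular shell with a transmural helical fiber
field, an ellipsoidal atrial shell, a sinus-node body in the atrial wall with
paranodal projections of intermediate intensity, an insulating connective
base crossed only by a conduction axis, and a branching Purkinje tree on the
ventricular endocardium with one free-running chord.

Every voxel's intensity is its class mean plus independent Gaussian noise;
true labels, the true fiber field, the cardiac frame and landmark points are
returned alongside, so segmentation, orientation, morphometry and activation
modelling can all be scored against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .volumes import LabelVolume, Volume

__all__ = [
    "LABELS",
    "TISSUE_CLASS_OF_LABEL",
    "PhantomSpec",
    "ShellSpec",
    "PhantomGroundTruth",
    "generate_phantom",
    "generate_fiber_test_volume",
    "generate_shell_phantom",
]

# structure labels (0 = background)
LABELS = {
    1: "fat",
    2: "atrial_myocardium",
    3: "ventricular_myocardium",
    4: "paranodal",
    5: "node",
    6: "connective",
    7: "axis",
    8: "purkinje",
}

# attenuation class each structure belongs to (axis and Purkinje tissue are
# specialised conduction tissue and share the nodal band)
TISSUE_CLASS_OF_LABEL = {
    0: "background",
    1: "fat",
    2: "working_myocardium",
    3: "working_myocardium",
    4: "paranodal",
    5: "node",
    6: "connective",
    7: "node",
    8: "node",
}

_CLASS_ORDER = ["fat", "working_myocardium", "paranodal", "node", "connective"]


@dataclass
class PhantomSpec:
    """Parameters of the default two-chamber phantom.

    Geometry is expressed in millimetres and is independent of the grid
    resolution, so the same physical phantom can be generated at any pitch.
    Class mean intensities follow the attenuation ordering
    fat > working myocardium > paranodal > node > connective, with the
    paranodal mean between myocardium and node.
    """

    shape: tuple[int, int, int] = (64, 64, 88)
    voxel_pitch_um: float = 300.0
    class_means: dict[str, float] = field(default_factory=lambda: {
        "fat": 100.0,
        "working_myocardium": 80.0,
        "paranodal": 65.0,
        "node": 50.0,
        "connective": 30.0,
        "background": 10.0,
    })
    noise_sd: float = 3.5

    # ventricle: ellipsoid truncated at the basal plane
    ventricular_centre_mm: tuple[float, float, float] = (9.6, 9.6, 11.5)
    ventricular_outer_semiaxes_mm: tuple[float, float, float] = (8.0, 8.0, 10.5)
    ventricular_wall_mm: float = 2.4
    basal_plane_mm: float = 13.0

    # atrium: ellipsoid clipped above the insulating base
    atrial_centre_mm: tuple[float, float, float] = (9.6, 9.6, 19.0)
    atrial_semiaxes_mm: tuple[float, float, float] = (8.0, 8.0, 5.2)
    atrial_wall_mm: float = 1.8
    atrial_floor_mm: float = 14.2

    # sinus node: ellipsoid at the atrial mid-wall, long axis along z
    node_semiaxes_mm: tuple[float, float, float] = (0.8, 0.8, 2.0)
    paranodal_count: int = 3
    paranodal_radius_mm: float = 0.5
    paranodal_length_mm: float = 3.4

    # conduction axis tube through the connective base
    axis_radius_mm: float = 0.6

    # Purkinje tree on the ventricular endocardium
    purkinje_depth: int = 4
    purkinje_segment_mm: float = 5.0
    purkinje_decay: float = 0.8
    purkinje_branch_angle_deg: float = 28.0
    purkinje_radius_mm: float = 0.35

    # transmural fiber rule for the ventricular shell
    helix_endo_deg: float = 60.0
    helix_epi_deg: float = -60.0

    seed: int = 42

    def validate(self) -> None:
        m = self.class_means
        for hi, lo in zip(_CLASS_ORDER, _CLASS_ORDER[1:]):
            if not m[hi] > m[lo]:
                raise ValueError(f"class mean ordering violated: {hi} <= {lo}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for a in (self.helix_endo_deg, self.helix_epi_deg):
            if not -90.0 <= a <= 90.0:
                raise ValueError("helix angles must lie in [-90, 90] degrees")
        if self.ventricular_wall_mm <= 0 or self.atrial_wall_mm <= 0:
            raise ValueError("wall thickness must be positive")
        extent = np.asarray(self.shape) * self.voxel_pitch_um / 1000.0
        c = np.asarray(self.ventricular_centre_mm)
        a = np.asarray(self.ventricular_outer_semiaxes_mm)
        if np.any(c - a < -1e-6) or np.any(c[:2] + a[:2] > extent[:2] + 1e-6):
            raise ValueError("ventricular geometry exceeds the grid")

    def coarse(self) -> "PhantomSpec":
        """Same physical phantom on a ~half-resolution grid (fast tests)."""
        f = 1.6
        shape = tuple(int(round(s / f)) for s in self.shape)
        return replace(self, shape=shape, voxel_pitch_um=self.voxel_pitch_um * f)


@dataclass
class PhantomGroundTruth:
    """True labels, fiber field and geometry of a generated phantom."""

    labels: LabelVolume
    fibers: np.ndarray                 # (nx, ny, nz, 3); NaN where undefined
    fiber_mask: np.ndarray             # voxels with a defined fiber
    long_axis: tuple[float, float, float]
    centre_mm: tuple[float, float, float]
    landmarks: dict[str, np.ndarray]   # name -> (k, 3) world points in mm
    helix_deg: np.ndarray | None = None  # true helix angle where defined

    def mask(self, name: str) -> np.ndarray:
        return self.labels.mask(name)


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _world_grid(shape, pitch_mm):
    ax = [np.arange(n) * pitch_mm for n in shape]
    return np.meshgrid(*ax, indexing="ij")


def _ellipsoid_level(X, Y, Z, centre, semiaxes):
    cx, cy, cz = centre
    ax, ay, az = semiaxes
    return ((X - cx) / ax) ** 2 + ((Y - cy) / ay) ** 2 + ((Z - cz) / az) ** 2


def _paint_tube(labelled, dirs, p0, p1, radius_mm, pitch_mm, value, clip=None):
    """Rasterize a capsule from p0 to p1; record the segment direction."""
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    d = p1 - p0
    length = np.linalg.norm(d)
    u = d / length if length > 0 else np.array([0.0, 0.0, 1.0])
    lo = np.maximum(np.floor((np.minimum(p0, p1) - radius_mm) / pitch_mm).astype(int), 0)
    hi = np.minimum(np.ceil((np.maximum(p0, p1) + radius_mm) / pitch_mm).astype(int) + 1,
                    labelled.shape)
    if np.any(hi <= lo):
        return
    sub = tuple(slice(a, b) for a, b in zip(lo, hi))
    X, Y, Z = np.meshgrid(*[np.arange(a, b) * pitch_mm for a, b in zip(lo, hi)],
                          indexing="ij")
    rel = np.stack([X - p0[0], Y - p0[1], Z - p0[2]], axis=-1)
    t = np.clip(rel @ u, 0.0, length)
    closest = t[..., None] * u
    dist = np.linalg.norm(rel - closest, axis=-1)
    inside = dist <= radius_mm
    if clip is not None:
        inside &= clip[sub]
    region = labelled[sub]
    region[inside] = value
    for k in range(3):
        dirs[k][sub][inside] = u[k]


def _unit(v):
    v = np.asarray(v, float)
    return v / np.linalg.norm(v)


def _tangent_frame(normals, long_axis):
    """Local circumferential/longitudinal unit vectors in the wall-tangent
    plane; ill-defined (near-polar) voxels fall back to an arbitrary tangent."""
    la = _unit(long_axis)
    c = np.cross(np.broadcast_to(la, normals.shape), normals)
    cn = np.linalg.norm(c, axis=-1, keepdims=True)
    bad = cn[..., 0] < 1e-3
    if np.any(bad):
        alt = np.cross(normals[bad], np.array([1.0, 0.0, 0.0]))
        alt_n = np.linalg.norm(alt, axis=-1, keepdims=True)
        alt_n[alt_n == 0] = 1.0
        c[bad] = alt / alt_n
        cn[bad] = 1.0
    c = c / np.maximum(cn, 1e-12)
    l = np.broadcast_to(la, normals.shape) - (normals @ la)[..., None] * normals
    ln = np.linalg.norm(l, axis=-1, keepdims=True)
    l = np.where(ln > 1e-6, l / np.maximum(ln, 1e-12), np.cross(normals, c))
    return c, l


def transmural_depth(wall_mask: np.ndarray, inner_region: np.ndarray,
                     outer_region: np.ndarray) -> np.ndarray:
    """Normalized transmural depth: 0 at the endocardial (inner) surface,
    1 at the epicardial (outer) surface, via Euclidean distance transforms."""
    d_in = ndimage.distance_transform_edt(~inner_region)
    d_out = ndimage.distance_transform_edt(~outer_region)
    denom = d_in + d_out
    denom[denom == 0] = 1.0
    t = np.where(wall_mask, d_in / denom, np.nan)
    return t


# ---------------------------------------------------------------------------
# main phantom
# ---------------------------------------------------------------------------

def generate_phantom(spec: PhantomSpec | None = None):
    """Build the default two-chamber phantom.

    Returns ``(Volume, PhantomGroundTruth)``.  Deterministic given
    ``spec.seed``; the label geometry is independent of the noise level.
    """
    spec = spec or PhantomSpec()
    spec.validate()
    pitch = spec.voxel_pitch_um / 1000.0
    shape = tuple(spec.shape)
    X, Y, Z = _world_grid(shape, pitch)

    cv = spec.ventricular_centre_mm
    av_out = np.asarray(spec.ventricular_outer_semiaxes_mm)
    av_in = av_out - spec.ventricular_wall_mm
    ca = spec.atrial_centre_mm
    aa_out = np.asarray(spec.atrial_semiaxes_mm)
    aa_in = aa_out - spec.atrial_wall_mm

    Lv_out = _ellipsoid_level(X, Y, Z, cv, av_out)
    Lv_in = _ellipsoid_level(X, Y, Z, cv, av_in)
    La_out = _ellipsoid_level(X, Y, Z, ca, aa_out)
    La_in = _ellipsoid_level(X, Y, Z, ca, aa_in)

    below_base = Z <= spec.basal_plane_mm
    above_floor = Z >= spec.atrial_floor_mm
    vent_solid = (Lv_out <= 1.0) & below_base
    vent_wall = vent_solid & (Lv_in > 1.0)
    vent_cavity = vent_solid & ~vent_wall
    atr_solid = (La_out <= 1.0) & above_floor
    atr_wall = atr_solid & (La_in > 1.0)

    labels = np.zeros(shape, dtype=np.int32)
    dirs = [np.full(shape, np.nan) for _ in range(3)]
    labels[vent_wall] = 3
    labels[atr_wall] = 2

    # insulating connective base between the chambers
    base = ((Z > spec.basal_plane_mm) & (Z < spec.atrial_floor_mm)
            & ((X - cv[0]) ** 2 + (Y - cv[1]) ** 2 <= (av_out[0] + 0.6) ** 2))
    labels[base] = 6

    # sinus node at the atrial mid-wall on the +x side, long axis along z
    mid_r = 0.5 * (aa_in[0] + aa_out[0])
    node_c = (ca[0] + mid_r, ca[1], ca[2])
    Ln = _ellipsoid_level(X, Y, Z, node_c, spec.node_semiaxes_mm)
    node = (Ln <= 1.0) & atr_wall
    labels[node] = 5
    # node fibers along its long axis
    dirs[0][node], dirs[1][node], dirs[2][node] = 0.0, 0.0, 1.0

    # paranodal projections: tangential tubes leaving the node body
    proj_dirs = [np.array([-0.15, 1.0, 0.25]), np.array([-0.15, -1.0, 0.25]),
                 np.array([-0.35, 0.15, 1.0]), np.array([-0.35, -0.15, -1.0])]
    para = np.zeros(shape, dtype=bool)
    for k in range(spec.paranodal_count):
        d = _unit(proj_dirs[k % len(proj_dirs)])
        p0 = np.asarray(node_c)
        p1 = p0 + d * spec.paranodal_length_mm
        tube = np.zeros(shape, dtype=np.int32)
        _paint_tube(tube, dirs, p0, p1, spec.paranodal_radius_mm, pitch, 1,
                    clip=atr_wall)
        para |= (tube == 1) & ~node
    labels[para & (labels != 5)] = 4

    # conduction axis: atrial floor -> ventricular basal wall
    ax_p0 = np.array([ca[0] + 1.2, ca[1], spec.atrial_floor_mm + 0.4])
    ax_p1 = np.array([cv[0] + 6.0, cv[1], spec.basal_plane_mm - 0.6])
    axis_lab = np.zeros(shape, dtype=np.int32)
    _paint_tube(axis_lab, dirs, ax_p0, ax_p1, spec.axis_radius_mm, pitch, 1)
    axis_mask = (axis_lab == 1) & ~node & ~(labels == 4)
    labels[axis_mask] = 7

    # Purkinje tree on the ventricular endocardial surface
    purk = np.zeros(shape, dtype=np.int32)
    surf = av_in * 1.04  # just inside the wall
    b = surf[2]

    def surf_point(theta, phi):
        return np.array([
            cv[0] + surf[0] * np.sin(phi) * np.cos(theta),
            cv[1] + surf[1] * np.sin(phi) * np.sin(theta),
            cv[2] - b * np.cos(phi),
        ])

    # root where the axis meets the endocardium
    rel = ax_p1 - np.asarray(cv)
    theta0 = np.arctan2(rel[1], rel[0])
    # polar angle (from the apex) of the basal ring, where the tree starts
    phi0 = np.arccos(np.clip(-(spec.basal_plane_mm - cv[2]) / b, -1.0, 1.0))
    _paint_tube(purk, dirs, ax_p1, surf_point(theta0, phi0),
                spec.purkinje_radius_mm, pitch, 1)

    ang = np.deg2rad(spec.purkinje_branch_angle_deg)
    mean_r = 0.5 * (surf[0] + b)

    def grow(theta, phi, heading, length_mm, depth):
        # heading measured from the apexward direction in the (theta, phi) chart
        if depth == 0 or phi < 0.25:
            return
        dphi = -length_mm * np.cos(heading) / mean_r
        dtheta = length_mm * np.sin(heading) / max(mean_r * np.sin(phi), 0.3)
        t2, p2 = theta + dtheta, max(phi + dphi, 0.12)
        a, bpt = surf_point(theta, phi), surf_point(t2, p2)
        steps = max(int(np.linalg.norm(bpt - a) / (0.5 * pitch)), 2)
        prev = a
        for s in range(1, steps + 1):
            f = s / steps
            th, ph = theta + f * dtheta, max(phi + f * dphi, 0.12)
            cur = surf_point(th, ph)
            _paint_tube(purk, dirs, prev, cur, spec.purkinje_radius_mm, pitch, 1)
            prev = cur
        grow(t2, p2, heading - ang, length_mm * spec.purkinje_decay, depth - 1)
        grow(t2, p2, heading + ang, length_mm * spec.purkinje_decay, depth - 1)

    grow(theta0, phi0, 0.0, spec.purkinje_segment_mm, spec.purkinje_depth)
    # one free-running chord across the cavity
    _paint_tube(purk, dirs, surf_point(theta0 + 1.1, np.pi / 2.4),
                surf_point(theta0 - 1.1, np.pi / 2.4),
                spec.purkinje_radius_mm, pitch, 1)
    purk_mask = (purk == 1) & (vent_solid | vent_cavity) & ~axis_mask
    labels[purk_mask & ~np.isin(labels, (5, 4, 7))] = 8

    # epicardial fat pads (outside all tissue)
    fat = np.zeros(shape, dtype=bool)
    for c, s in (((ca[0], ca[1] - aa_out[1] - 0.6, ca[2] + 0.5), (1.6, 1.1, 1.6)),
                 ((cv[0] - av_out[0] - 0.5, cv[1], cv[2] - 2.0), (1.2, 1.6, 2.0))):
        fat |= _ellipsoid_level(X, Y, Z, c, s) <= 1.0
    labels[fat & (labels == 0)] = 1

    # ------------------------------------------------------------------ fibers
    fibers = np.full(shape + (3,), np.nan)
    helix = np.full(shape, np.nan)

    # ventricular shell: linear transmural helix ramp
    grads = np.stack([2 * (X - cv[0]) / av_out[0] ** 2,
                      2 * (Y - cv[1]) / av_out[1] ** 2,
                      2 * (Z - cv[2]) / av_out[2] ** 2], axis=-1)
    n_hat = grads / np.maximum(np.linalg.norm(grads, axis=-1, keepdims=True), 1e-12)
    outside = ~vent_solid & ~base & (Z <= spec.atrial_floor_mm)
    t = transmural_depth(vent_wall, vent_cavity, outside)
    c_hat, l_hat = _tangent_frame(n_hat, (0.0, 0.0, 1.0))
    alpha = np.deg2rad(spec.helix_endo_deg
                       + (spec.helix_epi_deg - spec.helix_endo_deg) * t)
    f_v = np.cos(alpha)[..., None] * c_hat + np.sin(alpha)[..., None] * l_hat
    vm = labels == 3
    fibers[vm] = f_v[vm]
    helix[vm] = np.rad2deg(alpha[vm])

    # atrial shell: circumferential around its own surface normal
    grads_a = np.stack([2 * (X - ca[0]) / aa_out[0] ** 2,
                        2 * (Y - ca[1]) / aa_out[1] ** 2,
                        2 * (Z - ca[2]) / aa_out[2] ** 2], axis=-1)
    na = grads_a / np.maximum(np.linalg.norm(grads_a, axis=-1, keepdims=True), 1e-12)
    c_a, _ = _tangent_frame(na, (0.0, 0.0, 1.0))
    am = labels == 2
    fibers[am] = c_a[am]
    helix[am] = 0.0

    # tube structures carry their rasterized segment direction
    tube_dir = np.stack(dirs, axis=-1)
    tube_ok = np.all(np.isfinite(tube_dir), axis=-1) & np.isin(labels, (4, 5, 7, 8))
    fibers[tube_ok] = tube_dir[tube_ok]

    fiber_mask = np.all(np.isfinite(fibers), axis=-1)
    nrm = np.linalg.norm(fibers[fiber_mask], axis=-1, keepdims=True)
    fibers[fiber_mask] = fibers[fiber_mask] / nrm

    # ------------------------------------------------------------ intensities
    means = spec.class_means
    intensity = np.full(shape, means["background"], dtype=np.float64)
    for lab, cls in TISSUE_CLASS_OF_LABEL.items():
        if lab == 0:
            continue
        intensity[labels == lab] = means[cls]
    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, spec.noise_sd, size=shape)

    volume = Volume(intensity, spec.voxel_pitch_um)
    legend = dict(LABELS)
    lv = LabelVolume(labels, legend, spec.voxel_pitch_um)

    hinge_r = 0.5 * (av_in[0] + av_out[0])
    hinges = np.array([[cv[0] + hinge_r * np.cos(t_), cv[1] + hinge_r * np.sin(t_),
                        spec.basal_plane_mm] for t_ in np.deg2rad([90, 210, 330])])
    landmarks = {
        "valve_hinge": hinges,
        "node_centre": np.array([node_c]),
        "axis_entry": np.array([ax_p0]),
    }
    gt = PhantomGroundTruth(lv, fibers, fiber_mask, (0.0, 0.0, 1.0),
                            tuple(cv), landmarks, helix)
    return volume, gt


# ---------------------------------------------------------------------------
# orientation test fixtures
# ---------------------------------------------------------------------------

def generate_fiber_test_volume(
    pattern: str,
    axis,
    period_um: float,
    noise_sd: float = 0.0,
    shape: tuple[int, int, int] = (64, 64, 64),
    voxel_pitch_um: float = 28.0,
    seed: int = 0,
):
    """A volume whose texture is elongated along ``axis`` everywhere.

    ``parallel_cylinders``: a smoothed random cross-sectional pattern swept
    along the axis (fiber-bundle-like).  ``sinusoidal_grating``: a product of
    cosines in the two transverse directions (periodic, used for coherence /
    noise studies).  The true orientation is the unit ``axis`` at every voxel.
    Intensity contrast is ~1 (unit amplitude); noise_sd is in the same units.
    """
    axis = _unit(axis)
    pitch = voxel_pitch_um / 1000.0
    period_vox = period_um / voxel_pitch_um
    if period_vox < 4:
        raise ValueError(f"period {period_um} µm is below 4 voxels ({4 * voxel_pitch_um} µm)")
    # transverse orthonormal basis
    e = np.eye(3)[int(np.argmin(np.abs(axis)))]
    p = _unit(np.cross(axis, e))
    q = np.cross(axis, p)
    X, Y, Z = _world_grid(shape, pitch)
    U = (X * p[0] + Y * p[1] + Z * p[2]) / pitch   # transverse coords, voxels
    W = (X * q[0] + Y * q[1] + Z * q[2]) / pitch
    rng = np.random.default_rng(seed)
    if pattern == "parallel_cylinders":
        n2 = int(2 * max(shape) + 8)
        noise2d = rng.standard_normal((n2, n2))
        blob = ndimage.gaussian_filter(noise2d, period_vox / 3.0, mode="wrap")
        blob /= blob.std()
        off = n2 / 2.0
        tex = ndimage.map_coordinates(blob, [(U + off) % n2, (W + off) % n2],
                                      order=1, mode="wrap")
    elif pattern == "sinusoidal_grating":
        tex = np.cos(2 * np.pi * U / period_vox) * np.cos(2 * np.pi * W / period_vox)
    else:
        raise ValueError(f"unknown pattern {pattern!r}")
    if noise_sd > 0:
        tex = tex + rng.normal(0.0, noise_sd, size=tex.shape)
    return Volume(tex, voxel_pitch_um), axis


# ---------------------------------------------------------------------------
# helical shell phantom
# ---------------------------------------------------------------------------

@dataclass
class ShellSpec:
    """A fiber-textured myocardial shell with a linear transmural helix ramp.

    The default cylindrical shell is ~48 voxels thick so the helix ramp is
    a few degrees per voxel, comparable (in per-voxel terms) to a human
    ventricular wall imaged at tens of micrometres.
    """

    geometry: str = "cylinder"            # or "ellipsoid"
    shape: tuple[int, int, int] = (168, 168, 64)
    voxel_pitch_um: float = 28.0
    inner_radius_mm: float = 0.90         # cylinder; wall = outer - inner
    outer_radius_mm: float = 2.24
    z_margin_vox: int = 8                 # wall kept clear of the z faces
    semiaxes_mm: tuple[float, float, float] = (2.2, 2.2, 1.3)  # ellipsoid outer
    wall_mm: float = 0.9
    helix_endo_deg: float = 60.0
    helix_epi_deg: float = -60.0
    texture_corr_vox: float = 1.5         # in-plane texture correlation length
    lic_steps: int = 6
    noise_sd: float = 0.2                 # relative to unit texture contrast
    seed: int = 7


def _swept_helix_texture(spec: ShellSpec, R, Z, TH, wall, rng) -> np.ndarray:
    """Cylinder-shell texture exactly constant along the local helix.

    Within each one-voxel radial shell (frozen radius r_k and helix angle
    a_k) the intensity is a random 1D profile of the helical invariant
    ``xi = z cos(a) - r theta sin(a)``, whose gradient is perpendicular to
    the fiber; radial shells are mutually independent.  Two angular charts
    with complementary seams are blended to remove the theta wrap seam, and
    the texture continues ~10 voxels past the wall with clamped helix angle
    so the wall boundary itself carries no spurious oriented gradient.
    """
    pitch = spec.voxel_pitch_um / 1000.0
    ri, ro = spec.inner_radius_mm, spec.outer_radius_mm
    ext = 10 * pitch
    n_r = int(np.ceil((ro - ri + 2 * ext) / pitch)) + 2
    n_xi = 4096
    k = np.clip(np.round((R - (ri - ext)) / pitch), 0, n_r - 1)
    r_k = (ri - ext) + k * pitch
    a_k = np.deg2rad(spec.helix_endo_deg
                     + (spec.helix_epi_deg - spec.helix_endo_deg)
                     * np.clip((r_k - ri) / (ro - ri), 0.0, 1.0))

    def make_profile():
        p = rng.standard_normal((n_r, n_xi))
        p = ndimage.gaussian_filter1d(p, spec.texture_corr_vox, axis=1, mode="wrap")
        return p / p.std()

    P1, P2 = make_profile(), make_profile()

    def sample(P, theta):
        xi = (Z * np.cos(a_k) - np.maximum(r_k, 0.05) * theta * np.sin(a_k)) / pitch
        return ndimage.map_coordinates(P, [k, xi % n_xi], order=1, mode="wrap")

    th_a = TH
    th_b = np.where(TH < 0, TH + 2 * np.pi, TH)
    w = 0.5 * (1 + np.cos(th_a))
    tex = np.sqrt(w) * sample(P1, th_a) + np.sqrt(1 - w) * sample(P2, th_b)
    return tex / tex[wall].std()


def generate_shell_phantom(spec: ShellSpec | None = None):
    """Shell with fibers following a linear transmural helix ramp.

    For the cylindrical geometry the intensity texture is exactly invariant
    along the local fiber (see :func:`_swept_helix_texture`); for the
    ellipsoidal geometry it is built by repeated line-integral smoothing of
    white noise along the fiber field (weaker anisotropy, adequate for
    qualitative maps).  Returns ``(Volume, PhantomGroundTruth)`` with the
    true helix-angle field attached.
    """
    spec = spec or ShellSpec()
    for a in (spec.helix_endo_deg, spec.helix_epi_deg):
        if not -90.0 <= a <= 90.0:
            raise ValueError("helix angles must lie in [-90, 90] degrees")
    pitch = spec.voxel_pitch_um / 1000.0
    shape = tuple(spec.shape)
    X, Y, Z = _world_grid(shape, pitch)
    centre = (np.asarray(shape) - 1) * pitch / 2.0

    if spec.geometry == "cylinder":
        wall_vox = (spec.outer_radius_mm - spec.inner_radius_mm) / pitch
        if wall_vox < 6:
            raise ValueError("wall thinner than 6 voxels: helix ramp unresolvable")
        R = np.sqrt((X - centre[0]) ** 2 + (Y - centre[1]) ** 2)
        wall = (R >= spec.inner_radius_mm) & (R <= spec.outer_radius_mm)
        # keep the wall clear of the volume z faces; the texture continues
        # past the wall ends, so truncation adds no oriented boundary signal
        zi = np.arange(shape[2])[None, None, :]
        m = int(spec.z_margin_vox)
        if m > 0 and shape[2] > 2 * m + 6:
            wall &= (zi >= m) & (zi < shape[2] - m)
        t = (R - spec.inner_radius_mm) / (spec.outer_radius_mm - spec.inner_radius_mm)
        Rs = np.maximum(R, 1e-9)
        n_hat = np.stack([(X - centre[0]) / Rs, (Y - centre[1]) / Rs,
                          np.zeros_like(R)], axis=-1)
    elif spec.geometry == "ellipsoid":
        ao = np.asarray(spec.semiaxes_mm)
        ai = ao - spec.wall_mm
        if spec.wall_mm / pitch < 6:
            raise ValueError("wall thinner than 6 voxels: helix ramp unresolvable")
        Lo = _ellipsoid_level(X, Y, Z, centre, ao)
        Li = _ellipsoid_level(X, Y, Z, centre, ai)
        wall = (Lo <= 1.0) & (Li > 1.0)
        inner = Lo <= 1.0
        t = transmural_depth(wall, inner & (Li <= 1.0), ~inner)
        g = np.stack([2 * (X - centre[0]) / ao[0] ** 2,
                      2 * (Y - centre[1]) / ao[1] ** 2,
                      2 * (Z - centre[2]) / ao[2] ** 2], axis=-1)
        n_hat = g / np.maximum(np.linalg.norm(g, axis=-1, keepdims=True), 1e-12)
    else:
        raise ValueError(f"unknown geometry {spec.geometry!r}")

    c_hat, l_hat = _tangent_frame(n_hat, (0.0, 0.0, 1.0))
    t_cl = np.clip(np.nan_to_num(t, nan=0.5), 0.0, 1.0)
    alpha = np.deg2rad(spec.helix_endo_deg
                       + (spec.helix_epi_deg - spec.helix_endo_deg) * t_cl)
    fib = np.cos(alpha)[..., None] * c_hat + np.sin(alpha)[..., None] * l_hat

    rng = np.random.default_rng(spec.seed)
    if spec.geometry == "cylinder":
        TH = np.arctan2(Y - centre[1], X - centre[0])
        tex = _swept_helix_texture(spec, R, Z, TH, wall, rng)
    else:
        # line-integral smoothing of white noise along the fiber field, two
        # passes so the streamline follows the fiber curvature
        base = ndimage.gaussian_filter(rng.standard_normal(shape), 0.7)
        base /= base.std()
        idx = np.stack(np.meshgrid(*[np.arange(n, dtype=float) for n in shape],
                                   indexing="ij"), axis=-1)
        L = spec.lic_steps
        tex = base
        for _ in range(2):
            acc = np.zeros(shape)
            wsum = 0.0
            for k in range(-L, L + 1):
                w = np.exp(-0.5 * (k / max(L / 1.5, 1.0)) ** 2)
                pos = idx + k * fib  # one-voxel steps along the fiber
                acc += w * ndimage.map_coordinates(tex, [pos[..., 0], pos[..., 1],
                                                         pos[..., 2]], order=1,
                                                   mode="nearest")
                wsum += w
            tex = acc / wsum
        tex /= tex[wall].std() if wall.any() else 1.0
    if spec.noise_sd > 0:
        tex = tex + rng.normal(0.0, spec.noise_sd, size=shape)

    labels = np.where(wall, 3, 0).astype(np.int32)
    fibers = np.full(shape + (3,), np.nan)
    fibers[wall] = fib[wall]
    helix = np.where(wall, np.rad2deg(alpha), np.nan)
    lv = LabelVolume(labels, {3: "ventricular_myocardium"}, spec.voxel_pitch_um)
    gt = PhantomGroundTruth(lv, fibers, wall, (0.0, 0.0, 1.0), tuple(centre),
                            {"centre": np.array([centre])}, helix)
    return Volume(tex, spec.voxel_pitch_um), gt
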