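"""Procedural potted-plant point clouds with analytic ground truth.

A synthetic plant is a curved stem tube (cubic Bezier spine), elliptical
leaf patches attached along and atop the stem, and a pot disc below the
stem base.  Surfaces are sampled uniformly by area, Gaussian sensor noise
and uniform box outliers are added after labeling, and every point carries
an organ label and a leaf instance id.  Leaves are ellipses (optionally
bent isometrically around a cylinder) so that length, width and area have
closed forms:

    length (flat)  = 2a                 width = 2b        area = pi*a*b
    length (bent)  = 2R*sin(a/R)  (tip-to-tip chord; arc stays 2a and the
                                   bend preserves area exactly)

The generator is deterministic given the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .cloud import LEAF, NOISE, STEM, PointCloud


@dataclass(frozen=True)
class LeafSpec:
    """One elliptical leaf patch.

    ``attach_frac`` places the attachment along the stem (0 = base,
    1 = apex); ``azimuth``/``pitch`` orient the length axis (radians,
    pitch measured up from horizontal); ``bend_radius`` of ``None`` means
    a flat leaf; ``split_gap`` removes a strip across the blade to emulate
    a fragmented reconstruction.
    """

    attach_frac: float
    azimuth: float
    semi_a: float = 0.05
    semi_b: float = 0.02
    pitch: float = 0.35
    bend_radius: float | None = None
    petiole: float = 0.006
    split_gap: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.attach_frac <= 1.0:
            raise ValueError("attach_frac must lie in [0, 1]")
        if self.semi_a <= 0 or self.semi_b <= 0 or self.petiole < 0:
            raise ValueError("leaf dimensions must be positive")
        if self.bend_radius is not None and self.bend_radius < 2 * self.semi_a / np.pi:
            raise ValueError("bend_radius too tight: leaf would curl past a half circle")

    # ---- closed-form traits -------------------------------------------------
    @property
    def length(self) -> float:
        """Tip-to-tip extent (what a max-pairwise measurement sees)."""
        if self.bend_radius is None:
            return 2 * self.semi_a
        return 2 * self.bend_radius * np.sin(self.semi_a / self.bend_radius)

    @property
    def length_arc(self) -> float:
        """Geodesic length along the blade (2a, bend-invariant)."""
        return 2 * self.semi_a

    @property
    def width(self) -> float:
        return 2 * self.semi_b

    @property
    def area(self) -> float:
        """pi*a*b; isometric bending preserves surface area exactly."""
        return np.pi * self.semi_a * self.semi_b


@dataclass(frozen=True)
class SyntheticPlantSpec:
    """Parametric ground truth for one potted plant."""

    stem_control: np.ndarray = None  # type: ignore[assignment]  # (4,3) Bezier
    stem_radius: float = 0.006
    height: float = 0.25             # stem apex z (control points scale to this)
    leaves: tuple[LeafSpec, ...] = ()
    pot_radius: float = 0.06
    pot_height: float = 0.05
    pot_gap: float = 0.004           # vertical clearance between pot rim and stem base
    density: float = 2.0e6           # sampling density, points per m^2
    noise_sigma: float = 0.0005      # isotropic Gaussian sensor noise (m)
    outlier_fraction: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stem_control is None:
            ctrl = np.array([[0, 0, 0], [0, 0, self.height / 3],
                             [0, 0, 2 * self.height / 3], [0, 0, self.height]], float)
            object.__setattr__(self, "stem_control", ctrl)
        ctrl = np.asarray(self.stem_control, float).reshape(4, 3)
        object.__setattr__(self, "stem_control", ctrl)
        if self.stem_radius <= 0 or self.height <= 0 or self.density <= 0:
            raise ValueError("stem_radius, height and density must be positive")
        if not 0 <= self.outlier_fraction < 1:
            raise ValueError("outlier_fraction must lie in [0, 1)")
        area_leaf = min((lf.area for lf in self.leaves), default=None)
        if area_leaf is not None and self.density * area_leaf < 100:
            raise ValueError("density too low: expected points per leaf < 100")


@dataclass
class GroundTruth:
    """Per-point labels plus the closed-form traits of the generating spec."""

    organ: np.ndarray
    leaf_id: np.ndarray
    plant_height: float
    stem_diameter: float
    leaf_traits: list[dict]          # leaf_id, length, length_arc, width, area
    spec: SyntheticPlantSpec = field(repr=False, default=None)  # type: ignore


# ---------------------------------------------------------------------------
# stem spine helpers
# ---------------------------------------------------------------------------

def _bezier(ctrl: np.ndarray, t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, float)[:, None]
    return ((1 - t) ** 3 * ctrl[0] + 3 * (1 - t) ** 2 * t * ctrl[1]
            + 3 * (1 - t) * t ** 2 * ctrl[2] + t ** 3 * ctrl[3])


def _bezier_tangent(ctrl: np.ndarray, t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, float)[:, None]
    d = (3 * (1 - t) ** 2 * (ctrl[1] - ctrl[0])
         + 6 * (1 - t) * t * (ctrl[2] - ctrl[1])
         + 3 * t ** 2 * (ctrl[3] - ctrl[2]))
    return d / np.linalg.norm(d, axis=1, keepdims=True)


def stem_arc_length(spec: SyntheticPlantSpec, n: int = 2048) -> float:
    """Arc length of the stem spine (dense polyline quadrature)."""
    pts = _bezier(spec.stem_control, np.linspace(0, 1, n))
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def _arc_length_param(ctrl: np.ndarray, n: int = 2048):
    """Map uniform arc-length fractions to curve parameters t."""
    ts = np.linspace(0, 1, n)
    pts = _bezier(ctrl, ts)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0], np.cumsum(seg)])
    s /= s[-1]

    def to_t(frac: np.ndarray) -> np.ndarray:
        return np.interp(frac, s, ts)

    return to_t


def _stem_frame(ctrl: np.ndarray, t: np.ndarray):
    """Tangent + a stable normal/binormal pair along the (mostly vertical) spine."""
    tangent = _bezier_tangent(ctrl, t)
    ref = np.array([1.0, 0.0, 0.0])
    normal = ref - tangent * (tangent @ ref)[:, None]
    bad = np.linalg.norm(normal, axis=1) < 1e-8
    if bad.any():
        normal[bad] = np.array([0.0, 1.0, 0.0]) - tangent[bad] * tangent[bad][:, 2:3]
    normal /= np.linalg.norm(normal, axis=1, keepdims=True)
    binormal = np.cross(tangent, normal)
    return tangent, normal, binormal


# ---------------------------------------------------------------------------
# leaf geometry
# ---------------------------------------------------------------------------

def _leaf_frame(leaf: LeafSpec):
    cphi, sphi = np.cos(leaf.azimuth), np.sin(leaf.azimuth)
    cpsi, spsi = np.cos(leaf.pitch), np.sin(leaf.pitch)
    u_hat = np.array([cpsi * cphi, cpsi * sphi, spsi])      # length direction
    v_hat = np.array([-sphi, cphi, 0.0])                    # width direction
    n_hat = np.cross(u_hat, v_hat)
    return u_hat, v_hat, n_hat


def _leaf_local(leaf: LeafSpec, u: np.ndarray, v: np.ndarray):
    """Blade coordinates -> (along-length offset x, width v, normal offset zn)."""
    if leaf.bend_radius is None:
        return u, v, np.zeros_like(u)
    r = leaf.bend_radius
    return r * np.sin(u / r), v, r * (1 - np.cos(u / r))


def _leaf_base(spec: SyntheticPlantSpec, leaf: LeafSpec) -> np.ndarray:
    to_t = _arc_length_param(spec.stem_control)
    t = to_t(np.array([leaf.attach_frac]))
    center = _bezier(spec.stem_control, t)[0]
    radial = np.array([np.cos(leaf.azimuth), np.sin(leaf.azimuth), 0.0])
    return center + spec.stem_radius * radial


def _leaf_shift(leaf: LeafSpec) -> float:
    """Along-u shift putting the u=-a blade edge at the petiole gap."""
    if leaf.bend_radius is None:
        inner = -leaf.semi_a
    else:
        inner = -leaf.bend_radius * np.sin(leaf.semi_a / leaf.bend_radius)
    return leaf.petiole - inner


def leaf_point(spec: SyntheticPlantSpec, leaf: LeafSpec,
               u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """World coordinates of blade points (u in [-a, a], v across the blade)."""
    base = _leaf_base(spec, leaf)
    u_hat, v_hat, n_hat = _leaf_frame(leaf)
    x, vv, zn = _leaf_local(leaf, np.asarray(u, float), np.asarray(v, float))
    shift = _leaf_shift(leaf)
    return base + np.outer(x + shift, u_hat) + np.outer(vv, v_hat) + np.outer(zn, n_hat)


def _analytic_height(spec: SyntheticPlantSpec) -> float:
    """max z - min z over the noiseless plant surfaces (pot excluded).

    Stem contributes its spine extremes +- radius in z where the tangent is
    horizontal-adjacent; evaluated on a fine parameter grid.  Each leaf is a
    1D family in u at v = +-b ellipse boundary; z is independent of v except
    through the ellipse domain, so extremes are found on a fine (u, v-edge)
    grid.  Dense-grid evaluation of closed-form curves: exact to ~1e-6 m.
    """
    ts = np.linspace(0, 1, 4001)
    spine = _bezier(spec.stem_control, ts)
    tangent, normal, binormal = _stem_frame(spec.stem_control, ts)
    ring_amp = spec.stem_radius * np.sqrt(normal[:, 2] ** 2 + binormal[:, 2] ** 2)
    z_max = float((spine[:, 2] + ring_amp).max())
    z_min = float((spine[:, 2] - ring_amp).min())
    for leaf in spec.leaves:
        u = np.linspace(-leaf.semi_a, leaf.semi_a, 4001)
        half_w = leaf.semi_b * np.sqrt(np.clip(1 - (u / leaf.semi_a) ** 2, 0, None))
        for v in (half_w, -half_w, np.zeros_like(u)):
            z = leaf_point(spec, leaf, u, v)[:, 2]
            z_max = max(z_max, float(z.max()))
            z_min = min(z_min, float(z.min()))
    return z_max - z_min


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _sample_count(rng: np.random.Generator, area: float, density: float) -> int:
    return max(int(round(area * density)), 1)


def generate_plant(spec: SyntheticPlantSpec) -> tuple[PointCloud, GroundTruth]:
    """Sample the plant surfaces; label first, then perturb with noise.

    Returns the noisy cloud and the ground truth (labels aligned with the
    cloud, closed-form traits of the generating spec).
    """
    rng = np.random.default_rng(spec.seed)
    chunks: list[np.ndarray] = []
    organs: list[np.ndarray] = []
    leaf_ids: list[np.ndarray] = []

    # stem tube, uniform by area via arc-length parameterization
    arc = stem_arc_length(spec)
    n_stem = _sample_count(rng, 2 * np.pi * spec.stem_radius * arc, spec.density)
    to_t = _arc_length_param(spec.stem_control)
    t = to_t(rng.uniform(0, 1, n_stem))
    center = _bezier(spec.stem_control, t)
    _, normal, binormal = _stem_frame(spec.stem_control, t)
    theta = rng.uniform(0, 2 * np.pi, n_stem)
    stem_pts = center + spec.stem_radius * (normal * np.cos(theta)[:, None]
                                            + binormal * np.sin(theta)[:, None])
    chunks.append(stem_pts)
    organs.append(np.full(n_stem, STEM))
    leaf_ids.append(np.full(n_stem, -1))

    # leaves: uniform in the ellipse (area-preserving map of the unit disc)
    for lid, leaf in enumerate(spec.leaves):
        n_leaf = _sample_count(rng, leaf.area, spec.density)
        r = np.sqrt(rng.uniform(0, 1, n_leaf))
        ang = rng.uniform(0, 2 * np.pi, n_leaf)
        u = leaf.semi_a * r * np.cos(ang)
        v = leaf.semi_b * r * np.sin(ang)
        if leaf.split_gap > 0:
            keep = np.abs(u) > leaf.split_gap / 2
            u, v = u[keep], v[keep]
        pts = leaf_point(spec, leaf, u, v)
        chunks.append(pts)
        organs.append(np.full(len(pts), LEAF))
        leaf_ids.append(np.full(len(pts), lid))

    # pot: top disc plus side wall, below the stem base, labeled noise
    base_z = float(spec.stem_control[0, 2])
    rim_z = base_z - spec.pot_gap
    n_disc = _sample_count(rng, np.pi * spec.pot_radius ** 2, spec.density / 4)
    rr = spec.pot_radius * np.sqrt(rng.uniform(0, 1, n_disc))
    aa = rng.uniform(0, 2 * np.pi, n_disc)
    disc = np.column_stack([rr * np.cos(aa), rr * np.sin(aa), np.full(n_disc, rim_z)])
    n_side = _sample_count(rng, 2 * np.pi * spec.pot_radius * spec.pot_height,
                           spec.density / 4)
    aa = rng.uniform(0, 2 * np.pi, n_side)
    zz = rng.uniform(rim_z - spec.pot_height, rim_z, n_side)
    side = np.column_stack([spec.pot_radius * np.cos(aa),
                            spec.pot_radius * np.sin(aa), zz])
    chunks.append(disc)
    chunks.append(side)
    organs.append(np.full(n_disc + n_side, NOISE))
    leaf_ids.append(np.full(n_disc + n_side, -1))

    points = np.vstack(chunks)
    organ = np.concatenate(organs).astype(np.int32)
    leaf_id = np.concatenate(leaf_ids).astype(np.int32)

    if spec.noise_sigma > 0:
        points = points + rng.normal(0, spec.noise_sigma, points.shape)

    if spec.outlier_fraction > 0:
        n_out = rng.binomial(len(points), spec.outlier_fraction)
        lo, hi = points.min(axis=0), points.max(axis=0)
        pad = 0.1 * (hi - lo + 1e-6)
        outliers = rng.uniform(lo - pad, hi + pad, (n_out, 3))
        points = np.vstack([points, outliers])
        organ = np.concatenate([organ, np.full(n_out, NOISE, dtype=np.int32)])
        leaf_id = np.concatenate([leaf_id, np.full(n_out, -1, dtype=np.int32)])

    truth = GroundTruth(
        organ=organ,
        leaf_id=leaf_id,
        plant_height=_analytic_height(spec),
        stem_diameter=2 * spec.stem_radius,
        leaf_traits=[{"leaf_id": i, "length": lf.length, "length_arc": lf.length_arc,
                      "width": lf.width, "area": lf.area}
                     for i, lf in enumerate(spec.leaves)],
        spec=spec,
    )
    cloud = PointCloud(points, source=f"synthetic(seed={spec.seed})")
    return cloud, truth


# ---------------------------------------------------------------------------
# canonical fixtures
# ---------------------------------------------------------------------------

def _curved_control(height: float, sway: float) -> np.ndarray:
    """Control points of a stem curving away near the top.

    The lower stem rises vertically from the soil (so the thickness
    measurement site is an upright tube); the curvature concentrates in
    the upper third, where potted stems actually lean toward the light.
    ``sway`` around 0.06 m on a 0.25 m stem gives chord/arc ~0.97.
    """
    return np.array([[0, 0, 0],
                     [0, 0, height / 3],
                     [0, 0, 2 * height / 3],
                     [sway, 0.8 * sway, height]], float)


def straight_3leaf_spec(seed: int = 7) -> SyntheticPlantSpec:
    leaves = (
        LeafSpec(0.45, 0.0, 0.05, 0.02, pitch=0.30),
        LeafSpec(0.65, 2.1, 0.05, 0.02, pitch=0.35),
        LeafSpec(1.00, 4.2, 0.045, 0.018, pitch=1.15),  # apical leaf caps the stem
    )
    return SyntheticPlantSpec(leaves=leaves, seed=seed)


def curved_5leaf_spec(seed: int = 11) -> SyntheticPlantSpec:
    leaves = (
        LeafSpec(0.35, 0.3, 0.055, 0.022, pitch=0.25, bend_radius=0.14),
        LeafSpec(0.50, 1.9, 0.050, 0.020, pitch=0.30),
        LeafSpec(0.65, 3.6, 0.050, 0.020, pitch=0.40, bend_radius=0.13),
        LeafSpec(0.80, 5.1, 0.045, 0.018, pitch=0.45),
        LeafSpec(1.00, 2.7, 0.040, 0.016, pitch=1.20),
    )
    return SyntheticPlantSpec(stem_control=_curved_control(0.25, 0.06),
                              leaves=leaves, seed=seed)


def touching_leaves_spec(seed: int = 13) -> SyntheticPlantSpec:
    """Two apical leaves closer than typical clustering radii (crassula-like)."""
    leaves = (
        LeafSpec(0.97, 0.0, 0.04, 0.018, pitch=0.55),
        LeafSpec(0.99, 0.035, 0.04, 0.018, pitch=0.55),
    )
    return SyntheticPlantSpec(leaves=leaves, seed=seed)


def stem_only_spec(seed: int = 17) -> SyntheticPlantSpec:
    return SyntheticPlantSpec(leaves=(), seed=seed)


def split_leaf_spec(seed: int = 19) -> SyntheticPlantSpec:
    """One leaf fragmented by a missing strip across the blade."""
    leaves = (LeafSpec(0.8, 0.5, 0.05, 0.02, pitch=0.35, split_gap=0.004),)
    return SyntheticPlantSpec(leaves=leaves, seed=seed)


def fixture_suite(seed: int = 0) -> dict[str, tuple[PointCloud, GroundTruth]]:
    """Canonical named fixtures; seeds are offset from the suite seed."""
    specs = {
        "straight_3leaf": straight_3leaf_spec(seed + 7),
        "curved_5leaf": curved_5leaf_spec(seed + 11),
        "touching_leaves": touching_leaves_spec(seed + 13),
        "stem_only": stem_only_spec(seed + 17),
        "split_leaf": split_leaf_spec(seed + 19),
    }
    return {name: generate_plant(sp) for name, sp in specs.items()}


def random_population(n_plants: int, seed: int = 0,
                      noise_sigma: float = 0.0005) -> list[SyntheticPlantSpec]:
    """Randomized specs spanning realistic potted-plant trait ranges."""
    rng = np.random.default_rng(seed)
    specs = []
    for i in range(n_plants):
        height = rng.uniform(0.18, 0.32)
        radius = rng.uniform(0.0045, 0.0075)
        sway = rng.uniform(0.0, 0.055)
        n_leaves = int(rng.integers(3, 6))
        fracs = np.sort(rng.uniform(0.35, 0.88, n_leaves - 1))
        azim = rng.uniform(0, 2 * np.pi)
        leaves = []
        for j, frac in enumerate(fracs):
            a = rng.uniform(0.038, 0.058)
            leaves.append(LeafSpec(
                attach_frac=float(frac),
                azimuth=float((azim + j * 2.39996) % (2 * np.pi)),  # golden angle
                semi_a=a,
                semi_b=float(a * rng.uniform(0.36, 0.46)),
                pitch=float(rng.uniform(0.2, 0.5)),
                bend_radius=float(rng.uniform(2.6, 4.0) * a) if rng.random() < 0.5 else None,
            ))
        a = rng.uniform(0.034, 0.046)
        leaves.append(LeafSpec(1.0, float(rng.uniform(0, 2 * np.pi)), a,
                               float(a * 0.4), pitch=1.15))
        specs.append(SyntheticPlantSpec(
            stem_control=_curved_control(height, sway),
            stem_radius=radius, height=height, leaves=tuple(leaves),
            noise_sigma=noise_sigma, seed=int(rng.integers(0, 2 ** 31 - 1))))
    return specs


def suggested_config(spec: SyntheticPlantSpec, base=None):
    """Pipeline configuration scaled to a spec's geometry.

    The backtracking range must cover the longest leaf's geodesic extent
    (blade arc + petiole) in voxel hops; tree hops on an 18-connected
    voxel graph have median length ~1.4x the voxel size.
    """
    from .config import RunConfig
    base = base or RunConfig()
    max_reach = max((1.1 * (lf.length_arc + lf.petiole) for lf in spec.leaves),
                    default=1.4 * base.voxel_size)
    hop = 1.4 * base.voxel_size
    k_retrace = max(int(np.ceil(max_reach / hop)) + 2, 1)
    rim_z = float(spec.stem_control[0, 2]) - spec.pot_gap
    return base.replace(k_retrace=k_retrace,
                        z_min=rim_z + spec.pot_gap / 2,
                        z_max=float(spec.stem_control[0, 2]) + 2 * spec.height)
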