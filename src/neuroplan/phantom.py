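"""Synthetic head phantom and participant-cohort simulator.

The study case this package models — a single parasagittal tumor under a
gently curved scalp patch — is represented by an analytic three-layer
phantom: ellipsoidal scalp and outer-skull surfaces and an ellipsoidal
tumor, all in mm. The default tumor's in-plane semi-axes (31.2, 27.72 mm)
are fixed so the projected silhouette area is pi*a*b ~= 2,717 mm², the
reference tumor area used by all coverage metrics; the depth semi-axis
(20 mm) is unconstrained by any metric.

Two generation paths exist, mirroring a real imaging pipeline:

* analytic: :func:`build_phantom` produces watertight ellipsoid meshes;
* volumetric: :func:`voxelize` samples a labeled voxel volume (a synthetic
  stand-in for a segmented scan) and :func:`extract_surface` recovers a
  surface mesh from it by marching cubes.

The cohort simulator replaces the study's undeposited participant drawings.
A :class:`SkillProfile` specifies error distributions for the four drawing
tasks; :func:`simulate_annotation` turns one profile draw into a full
annotation set by *construction*, so that each downstream metric equals the
sampled error parameter exactly (painted region = silhouette translated and
scaled; incision = chord at the sampled offset from the epicenter;
craniotomy = quadrilateral whose per-edge signed margins equal the sampled
values). Default profiles are calibrated to the reference cohort summaries
in :data:`REFERENCE_SUMMARIES`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Mapping

import numpy as np
import shapely.affinity
import trimesh
from scipy import stats as sps
from scipy.ndimage import gaussian_filter
from shapely.geometry import LineString
from skimage.measure import marching_cubes

from . import projection as proj
from .distributions import (
    CoverageTarget,
    GammaFromMoments,
    Normal,
    PointMass,
    ScaledBeta,
)
from .errors import (
    InvalidSpecError,
    LabelNotFoundError,
    ReproducibilityError,
    ResolutionError,
)
from .metrics import AnnotationSet
from .projection import AssessmentPlane, Quad2D

__all__ = [
    "LABELS",
    "REFERENCE_SUMMARIES",
    "PhantomSpec",
    "LabelVolume",
    "PhantomModel",
    "SkillProfile",
    "CohortSpec",
    "ParticipantRecord",
    "build_phantom",
    "voxelize",
    "extract_surface",
    "simulate_annotation",
    "simulate_cohort",
    "calibrated_profiles",
    "default_cohort_spec",
]

#: Voxel labels of the synthetic volume.
LABELS = {"background": 0, "scalp": 1, "skull": 2, "brain": 3, "tumor": 4}

#: Reference cohort summaries the default skill profiles emulate:
#: (mean, SD) of each continuous metric at the pre-3D-model (AA1) and
#: post-3D-model (AA2) assessments. Incision deviations are stratified:
#: only residents improve after 3D-model training.
REFERENCE_SUMMARIES = {
    "percent_coverage_pct": {"AA1": (66.4, 26.2), "AA2": (77.2, 17.4)},
    "painted_area_mm2": {"AA1": (4036.0, 1611.0), "AA2": (3760.0, 1081.0)},
    "margin_deviation_sum_mm": {"AA1": (57.3, 24.0), "AA2": (47.2, 19.8)},
    "incision_deviation_mm": {
        "resident": {"AA1": (16.3, 9.6), "AA2": (8.3, 7.9)},
        "intern": {"AA1": (16.3, 9.6), "AA2": (16.3, 9.6)},
    },
}

#: Reference tumor silhouette area, mm² (pi * 31.2 * 27.72).
REFERENCE_TUMOR_AREA = float(np.pi * 31.2 * 27.72)

# E|N(0,s)| = s*sqrt(2/pi): converts a target mean |margin - standard| sum
# over 4 edges into the per-edge margin SD.
_FOLD = np.sqrt(2.0 / np.pi)


# ---------------------------------------------------------------------------
# phantom geometry


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of the layered head phantom (all lengths mm).

    The scalp and outer skull are concentric ellipsoids; the inner skull
    surface lies ``skull_thickness`` further inward. ``tumor_semiaxes``
    lists the two in-plane (projection-normal) semi-axes first, then depth.
    """

    scalp_semiaxes: tuple = (90.0, 75.0, 80.0)
    skull_offset: float = 6.0
    skull_thickness: float = 6.0
    tumor_semiaxes: tuple = (31.2, 27.72, 20.0)
    tumor_center: tuple = (0.0, 0.0, 40.0)
    projection_axis: tuple = (0.0, 0.0, 1.0)
    voxel_pitch: float = 1.0
    mesh_subdivisions: int = 4

    def __post_init__(self) -> None:
        scalp = np.asarray(self.scalp_semiaxes, dtype=float)
        tumor = np.asarray(self.tumor_semiaxes, dtype=float)
        if scalp.shape != (3,) or tumor.shape != (3,):
            raise InvalidSpecError("semiaxes must be length-3")
        if np.any(scalp <= 0) or np.any(tumor <= 0):
            raise InvalidSpecError("all semiaxes must be positive")
        if self.skull_offset <= 0 or self.skull_thickness <= 0:
            raise InvalidSpecError("skull offset and thickness must be positive")
        if np.any(self.inner_skull_semiaxes <= 0):
            raise InvalidSpecError("skull shell thicker than the scalp ellipsoid")
        if self.voxel_pitch <= 0:
            raise InvalidSpecError("voxel pitch must be positive")
        axis = np.asarray(self.projection_axis, dtype=float)
        if np.linalg.norm(axis) == 0:
            raise InvalidSpecError("projection axis must be nonzero")
        if not self._tumor_inside_inner_skull():
            raise InvalidSpecError("tumor not fully inside the inner skull surface")

    @property
    def skull_semiaxes(self) -> np.ndarray:
        return np.asarray(self.scalp_semiaxes, dtype=float) - self.skull_offset

    @property
    def inner_skull_semiaxes(self) -> np.ndarray:
        return self.skull_semiaxes - self.skull_thickness

    @property
    def axis_unit(self) -> np.ndarray:
        a = np.asarray(self.projection_axis, dtype=float)
        return a / np.linalg.norm(a)

    def _tumor_inside_inner_skull(self, n: int = 512) -> bool:
        # sample the tumor surface; all points must satisfy the inner-skull
        # implicit inequality strictly
        rng = np.random.default_rng(0)
        v = rng.standard_normal((n, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        pts = np.asarray(self.tumor_center) + v * np.asarray(self.tumor_semiaxes)
        q = (pts / self.inner_skull_semiaxes) ** 2
        return bool(np.all(q.sum(axis=1) < 1.0))


@dataclass
class LabelVolume:
    """Integer label volume (synthetic stand-in for a segmented scan)."""

    labels: np.ndarray  # (nx, ny, nz) int8
    pitch: float  # mm, isotropic
    origin: np.ndarray  # mm, world coordinate of voxel (0,0,0) center

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.pitch <= 0:
            raise InvalidSpecError("voxel pitch must be positive")
        bad = set(np.unique(self.labels)) - set(LABELS.values())
        if bad:
            raise InvalidSpecError(f"unknown labels in volume: {sorted(bad)}")

    def count(self, label: int) -> int:
        return int(np.count_nonzero(self.labels == label))

    def volume_of(self, label: int) -> float:
        """Voxel-count volume estimate for one label, mm³."""
        return self.count(label) * self.pitch**3


@dataclass(eq=False)
class PhantomModel:
    """Layered head model: watertight scalp, skull and tumor meshes (mm)."""

    scalp_mesh: trimesh.Trimesh
    skull_mesh: trimesh.Trimesh
    tumor_mesh: trimesh.Trimesh
    spec: PhantomSpec

    @cached_property
    def plane(self) -> AssessmentPlane:
        """Assessment plane: through the tumor center, normal = projection axis."""
        return AssessmentPlane(origin=np.asarray(self.spec.tumor_center), axis=self.spec.axis_unit)

    @cached_property
    def _silhouette(self):
        return proj.project_silhouette(self.tumor_mesh, self.plane)

    def silhouette(self):
        """Projected tumor silhouette on the assessment plane (Region2D)."""
        return self._silhouette


def _ellipsoid_mesh(semiaxes, center=(0, 0, 0), subdivisions: int = 4) -> trimesh.Trimesh:
    mesh = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    mesh.apply_scale(np.asarray(semiaxes, dtype=float))
    mesh.apply_translation(np.asarray(center, dtype=float))
    return mesh


def build_phantom(spec: PhantomSpec | None = None) -> PhantomModel:
    """Analytic-mesh phantom: watertight ellipsoid surfaces for each layer.

    The skull layer is represented by its outer surface; the shell interior
    exists only in the voxel path, where layer thickness matters.
    """
    spec = spec or PhantomSpec()
    sub = spec.mesh_subdivisions
    return PhantomModel(
        scalp_mesh=_ellipsoid_mesh(spec.scalp_semiaxes, subdivisions=sub),
        skull_mesh=_ellipsoid_mesh(spec.skull_semiaxes, subdivisions=sub),
        tumor_mesh=_ellipsoid_mesh(spec.tumor_semiaxes, spec.tumor_center, subdivisions=sub),
        spec=spec,
    )


def voxelize(spec: PhantomSpec | None = None, pitch: float | None = None) -> LabelVolume:
    """Sample the phantom onto an isotropic voxel grid.

    Labels overwrite in priority order scalp < skull < brain < tumor, so the
    tumor is never masked by an enclosing shell. The pitch must resolve the
    tumor with at least 8 voxels per axis.
    """
    spec = spec or PhantomSpec()
    pitch = float(pitch if pitch is not None else spec.voxel_pitch)
    if pitch <= 0:
        raise ResolutionError("voxel pitch must be positive")
    if 2.0 * min(spec.tumor_semiaxes) / pitch < 8.0:
        raise ResolutionError(
            f"pitch {pitch} mm too coarse: tumor must span >= 8 voxels per axis"
        )
    scalp = np.asarray(spec.scalp_semiaxes)
    lo = -(scalp + pitch)
    hi = scalp + pitch
    axes = [np.arange(lo[i] + pitch / 2, hi[i], pitch) for i in range(3)]
    x, y, z = np.meshgrid(*axes, indexing="ij", sparse=True)

    def inside(semiaxes, center=(0.0, 0.0, 0.0)):
        cx, cy, cz = center
        a, b, c = semiaxes
        return ((x - cx) / a) ** 2 + ((y - cy) / b) ** 2 + ((z - cz) / c) ** 2 <= 1.0

    labels = np.zeros((len(axes[0]), len(axes[1]), len(axes[2])), dtype=np.int8)
    labels[inside(spec.scalp_semiaxes)] = LABELS["scalp"]
    labels[inside(spec.skull_semiaxes)] = LABELS["skull"]
    labels[inside(spec.inner_skull_semiaxes)] = LABELS["brain"]
    labels[inside(spec.tumor_semiaxes, spec.tumor_center)] = LABELS["tumor"]
    if not np.any(labels == LABELS["tumor"]):
        raise ResolutionError("no tumor voxels at this pitch")
    origin = np.array([a[0] for a in axes])
    return LabelVolume(labels=labels, pitch=pitch, origin=origin)


def extract_surface(volume: LabelVolume, label: int, smooth_sigma: float = 1.0) -> trimesh.Trimesh:
    """Marching-cubes surface of one label, in mm world coordinates.

    The binary mask is smoothed with a Gaussian of ``smooth_sigma`` voxels
    before contouring at 0.5: the staircase bias of contouring a raw binary
    mask inflates surface area by several percent and does not vanish with
    finer pitch, while the smoothed field converges to the true surface.
    """
    mask = volume.labels == label
    if not np.any(mask):
        raise LabelNotFoundError(f"label {label} absent from volume")
    pad = max(2, int(np.ceil(3 * smooth_sigma)) + 1)
    padded = np.pad(mask.astype(np.float32), pad)
    if smooth_sigma > 0:
        padded = gaussian_filter(padded, smooth_sigma)
    verts, faces, _, _ = marching_cubes(padded, level=0.5, spacing=(1.0, 1.0, 1.0))
    verts = (verts - pad) * volume.pitch + volume.origin
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    trimesh.repair.fix_winding(mesh)
    if mesh.volume < 0:
        mesh.invert()
    return mesh


# ---------------------------------------------------------------------------
# skill profiles and annotation simulation


@dataclass(frozen=True)
class SkillProfile:
    """Error-distribution profile for one group at one assessment.

    ``paint_shift`` is either an explicit distribution of painted-region
    displacement magnitudes (mm) or a :class:`CoverageTarget` wrapping a
    distribution of target coverage percentages, inverted through the
    phantom's displacement->coverage map at simulation time.
    ``paint_area_factor`` scales the painted area relative to the true
    silhouette; ``incision_offset`` is the linear-incision distance from the
    epicenter (mm); ``edge_margin`` is the signed per-edge craniotomy margin
    (mm), sampled independently for the four edges.
    """

    paint_shift: object = field(default_factory=lambda: PointMass(0.0))
    paint_area_factor: object = field(default_factory=lambda: PointMass(1.0))
    incision_offset: object = field(default_factory=lambda: PointMass(0.0))
    edge_margin: object = field(default_factory=lambda: PointMass(10.0))
    name: str = "zero-error"

    @classmethod
    def zero_error(cls) -> "SkillProfile":
        """All mass at zero displacement, unit area factor, 10 mm margins."""
        return cls()


@dataclass(frozen=True)
class CohortSpec:
    """Cohort composition and per-group pre/post skill profiles.

    Defaults mirror the reference cohort: 38 participants, 14 neurosurgical
    residents and 24 interns. ``ability_rho`` is the within-participant
    correlation (Gaussian copula) between pre- and post-assessment error
    draws; paired designs on the same participant are correlated, and with
    independent draws the paired tests the pipeline runs would be badly
    underpowered relative to the reference results.
    """

    n_residents: int = 14
    n_interns: int = 24
    profiles: Mapping[str, tuple] = None  # type: ignore[assignment]  # group -> (pre, post)
    seed: int = 0
    ability_rho: float = 0.8

    def __post_init__(self) -> None:
        if self.n_residents < 0 or self.n_interns < 0:
            raise InvalidSpecError("cohort counts must be >= 0")
        if not -1.0 < self.ability_rho < 1.0:
            raise InvalidSpecError("ability_rho must be in (-1, 1)")
        if self.profiles is not None:
            for g, pair in self.profiles.items():
                if len(pair) != 2:
                    raise InvalidSpecError(f"group {g!r} needs (pre, post) profiles")


@dataclass
class ParticipantRecord:
    """Pre (AA1) and post (AA2) annotation sets for one participant."""

    participant_id: str
    group: str  # resident | intern
    substream_seed: int
    pre: AnnotationSet
    post: AnnotationSet


def _boundary_distance(silhouette, c, direction):
    return proj._ray_boundary_distance(np.asarray(c), np.asarray(direction, dtype=float), silhouette)


def _solve_shift_for_coverage(silhouette, scaled, direction, target_pct: float) -> float:
    """Displacement (mm) of ``scaled`` along ``direction`` giving the target coverage."""
    ref_area = silhouette.area
    d = np.asarray(direction, dtype=float)

    def coverage(s: float) -> float:
        moved = shapely.affinity.translate(scaled, *(s * d))
        return 100.0 * moved.intersection(silhouette).area / ref_area

    lo, hi = 0.0, 1.0
    if coverage(0.0) <= target_pct:
        return 0.0
    # expand until coverage drops below target, then bisect
    while coverage(hi) > target_pct:
        lo, hi = hi, hi * 2.0
        if hi > 1e4:
            return hi
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if coverage(mid) > target_pct:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-6:
            break
    return 0.5 * (lo + hi)


def _craniotomy_for_margins(silhouette, targets: np.ndarray, max_iter: int = 60) -> Quad2D:
    """Axis-aligned quadrilateral whose four midpoint-ray margins equal ``targets``.

    Offsets along +x, +y, -x, -y from the centroid are initialized at
    boundary-distance + target and refined by fixed point iteration, because
    a margin is measured along the centroid ray through the *midpoint* of an
    edge, which moves as the other edges move.
    """
    c = proj.centroid(silhouette)
    dirs = np.array([[1.0, 0.0], [0.0, 1.0], [-1.0, 0.0], [0.0, -1.0]])
    r_b = np.array([_boundary_distance(silhouette, c, d) for d in dirs])
    targets = np.maximum(targets, 3.0 - r_b)  # keep the quad simple and off-center
    offsets = np.maximum(r_b + targets, 0.5)

    def quad_from(o):
        xp, yp, xm, ym = c[0] + o[0], c[1] + o[1], c[0] - o[2], c[1] - o[3]
        return Quad2D(np.array([[xp, ym], [xp, yp], [xm, yp], [xm, ym]]))

    quad = quad_from(offsets)
    for _ in range(max_iter):
        measured = proj.quad_margins(quad, silhouette)
        err = targets - measured
        if np.max(np.abs(err)) < 1e-9:
            break
        offsets = np.maximum(offsets + err, 0.5)
        quad = quad_from(offsets)
    return quad


def _annotation_from_uniforms(
    model: PhantomModel,
    profile: SkillProfile,
    assessment: str,
    u_err: np.ndarray,
    u_angle: np.ndarray,
    meta: dict | None = None,
) -> AnnotationSet:
    """Deterministic annotation construction from 7 error and 2 angle uniforms.

    ``u_err`` drives, in order: area factor, paint shift (or coverage
    target), incision offset, and the four edge margins. Each metric of the
    result equals the sampled parameter by construction.
    """
    silhouette = model.silhouette()
    c = proj.centroid(silhouette)

    factor = float(np.maximum(profile.paint_area_factor.ppf(u_err[0]), 0.05))
    scaled = shapely.affinity.scale(silhouette, np.sqrt(factor), np.sqrt(factor), origin=(c[0], c[1]))
    theta = 2.0 * np.pi * u_angle[0]
    direction = np.array([np.cos(theta), np.sin(theta)])
    if isinstance(profile.paint_shift, CoverageTarget):
        # invert the monotone shift -> coverage map for this sampled factor
        target = float(profile.paint_shift.ppf(u_err[1]))
        target = float(np.clip(target, 0.5, min(100.0, 100.0 * factor) - 1e-6))
        shift = _solve_shift_for_coverage(silhouette, scaled, direction, target)
    else:
        shift = float(np.abs(profile.paint_shift.ppf(u_err[1])))
    painted = shapely.affinity.translate(scaled, *(shift * direction))

    offset = float(np.abs(profile.incision_offset.ppf(u_err[2])))
    phi = 2.0 * np.pi * u_angle[1]
    normal = np.array([np.cos(phi), np.sin(phi)])
    tangent = np.array([-np.sin(phi), np.cos(phi)])
    foot = c + offset * normal
    half = 40.0  # incision half-length, mm
    incision = LineString([foot - half * tangent, foot + half * tangent])

    margins = np.asarray(profile.edge_margin.ppf(u_err[3:7]), dtype=float)
    craniotomy = _craniotomy_for_margins(silhouette, margins)
    v = craniotomy.vertices
    # U-incision: three craniotomy edges, base (v3 -> v0) left open
    u_incision = LineString([v[0], v[1], v[2], v[3]])
    burr_holes = v.copy()

    return AnnotationSet(
        painted=painted,
        linear_incision=incision,
        u_incision=u_incision,
        burr_holes=burr_holes,
        craniotomy=craniotomy,
        assessment=assessment,
        meta=dict(meta or {}),
    )


def _check_rng(rng) -> np.random.Generator:
    if isinstance(rng, (int, np.integer)):
        return np.random.default_rng(int(rng))
    if isinstance(rng, np.random.Generator):
        return rng
    raise ReproducibilityError("simulate_* requires a seed or a seeded numpy Generator")


def simulate_annotation(
    model: PhantomModel, profile: SkillProfile, assessment: str = "AA1", rng=None
) -> AnnotationSet:
    """One simulated annotation set from a skill profile.

    ``rng`` must be an integer seed or a seeded ``numpy.random.Generator``;
    passing nothing is a reproducibility error by design.
    """
    gen = _check_rng(rng)
    u_err = gen.random(7)
    u_angle = gen.random(2)
    return _annotation_from_uniforms(model, profile, assessment, u_err, u_angle)


def simulate_cohort(model: PhantomModel, cohort: CohortSpec | None = None) -> list[ParticipantRecord]:
    """Simulate pre/post annotation sets for a full cohort.

    Each participant has an independent RNG substream (seed XOR participant
    index). Pre/post error draws are coupled through a Gaussian copula with
    correlation ``cohort.ability_rho``, modeling stable per-participant
    ability; drawing angles are independent between assessments.
    """
    if cohort is None:
        cohort = default_cohort_spec(model)
    profiles = cohort.profiles if cohort.profiles is not None else _calibrated_profile_map(model)
    groups = ["resident"] * cohort.n_residents + ["intern"] * cohort.n_interns
    rho = cohort.ability_rho
    records = []
    for i, group in enumerate(groups):
        sub_seed = int(cohort.seed) ^ i
        gen = np.random.default_rng(sub_seed)
        z_shared = gen.standard_normal(7)
        z_pre = gen.standard_normal(7)
        z_post = gen.standard_normal(7)
        u_pre = sps.norm.cdf(rho * z_shared + np.sqrt(1 - rho**2) * z_pre)
        u_post = sps.norm.cdf(rho * z_shared + np.sqrt(1 - rho**2) * z_post)
        angles = gen.random(4)
        pre_prof, post_prof = profiles[group]
        meta = {"substream_seed": sub_seed, "group": group}
        pre = _annotation_from_uniforms(model, pre_prof, "AA1", u_pre, angles[:2], meta)
        post = _annotation_from_uniforms(model, post_prof, "AA2", u_post, angles[2:], meta)
        records.append(
            ParticipantRecord(
                participant_id=f"P{i + 1:02d}",
                group=group,
                substream_seed=sub_seed,
                pre=pre,
                post=post,
            )
        )
    return records


# ---------------------------------------------------------------------------
# calibrated default profiles


def _margin_sigma(target_sum_mean: float) -> float:
    # E sum |N(10, s) - 10| over 4 edges = 4 * s * sqrt(2/pi)
    return target_sum_mean / (4.0 * _FOLD)


def calibrated_profiles(group: str, assessment: str) -> SkillProfile:
    """Skill profile reproducing the reference cohort summaries.

    Coverage targets are Beta-distributed on [0, 100] (moment-matched);
    painted-area factors and incision offsets are Gamma (moment-matched,
    nonnegative); per-edge margins are Normal around the 10 mm standard with
    SD set so the expected margin-deviation sum matches the reference mean.
    """
    ref = REFERENCE_SUMMARIES
    cov_m, cov_s = ref["percent_coverage_pct"][assessment]
    area_m, area_s = ref["painted_area_mm2"][assessment]
    sum_m, _ = ref["margin_deviation_sum_mm"][assessment]
    inc_m, inc_s = ref["incision_deviation_mm"][group][assessment]
    return SkillProfile(
        paint_shift=CoverageTarget(ScaledBeta(cov_m, cov_s, 0.0, 100.0)),
        paint_area_factor=GammaFromMoments(area_m / REFERENCE_TUMOR_AREA, area_s / REFERENCE_TUMOR_AREA),
        incision_offset=GammaFromMoments(inc_m, inc_s),
        edge_margin=Normal(10.0, _margin_sigma(sum_m)),
        name=f"{group}-{assessment}",
    )


def _calibrated_profile_map(model: PhantomModel) -> dict:
    return {
        g: (calibrated_profiles(g, "AA1"), calibrated_profiles(g, "AA2"))
        for g in ("resident", "intern")
    }


def default_cohort_spec(model: PhantomModel, seed: int = 0, **overrides) -> CohortSpec:
    """Reference cohort: 14 residents + 24 interns with calibrated profiles."""
    kwargs = dict(profiles=_calibrated_profile_map(model), seed=seed)
    kwargs.update(overrides)
    return CohortSpec(**kwargs)
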