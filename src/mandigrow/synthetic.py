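"""Synthetic longitudinal studies of a growing mandible-like surface.

The generator emulates the design of a year-long monthly CBCT monitoring
study: a cohort of subjects, each with T (default 12) four-week
timepoints, a closed bilaterally symmetric mandible-like mesh per
subject-timepoint, and ground-truth trajectories for all 17 landmarks.

Growth model
------------
A template mesh (the T1 anatomy) is deformed by a smooth, region- and
direction-weighted expansion about the volume centroid:

    x'_a = x_a * (1 + c(t) * g_a(x))        a in {AP, ML, SI}

where ``g_a`` is a partition-of-unity blend of per-region rates (ramus,
body, anterior, condyle, coronoid) and ``c(t)`` is a saturating-
exponential time curve with c(T1) = 0 and c(T12) = 1, calibrated so that
half the total change has accrued by month 4. Region weights are smooth
plateau fields (soft masks), so meshes stay crack-free and watertight;
every landmark neighbourhood sits on a weight plateau, which makes the
deformation locally an exact diagonal affine map there and keeps the
automatic detectors stable across timepoints.

With defaults the ramus/condyle/coronoid unit grows fastest
superoinferiorly and anteroposteriorly and every region grows least
mediolaterally, reproducing the qualitative anisotropy of real mandibular
growth (ramus faster than body; SI/AP faster than ML).

Measurement noise is applied to landmark coordinates (the manual-landmark
channel), never to mesh topology; a small smooth left-right perturbation
models biological asymmetry.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .landmarks import (
    MANUAL_CODES,
    LandmarkSet,
    default_rois,
    detect_all,
    landmark_table,
)
from .mesh import TriangleMesh, mesh_volume, nearest_point_on_surface, voxelize

__all__ = [
    "GrowthModel",
    "MandibleShape",
    "StudyDataset",
    "default_growth_model",
    "generate_study",
    "generate_template_mesh",
    "grow_mesh",
    "icosphere",
    "random_blob",
    "voxelize_and_reconstruct",
]


# ----- implicit-surface primitives ------------------------------------------


def _smooth_union(a: np.ndarray, b: np.ndarray, k: float) -> np.ndarray:
    """Polynomial smooth minimum of two distance fields (blend width k, mm)."""
    h = np.clip(0.5 + 0.5 * (b - a) / k, 0.0, 1.0)
    return b + (a - b) * h - k * h * (1.0 - h)


def _sd_sphere(p: np.ndarray, center, radius: float) -> np.ndarray:
    return np.linalg.norm(p - np.asarray(center), axis=1) - radius


def _sd_ellipsoid(p: np.ndarray, center, axes) -> np.ndarray:
    # scaled distance bound; exact zero level, adequate gradients for MC
    q = (p - np.asarray(center)) / np.asarray(axes)
    k = np.linalg.norm(q, axis=1)
    return (k - 1.0) * min(axes)

def _rot_y(deg: float) -> np.ndarray:
    b = np.deg2rad(deg)
    c, s = np.cos(b), np.sin(b)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _sd_rounded_box(p: np.ndarray, center, half, rot: np.ndarray, round_r: float) -> np.ndarray:
    local = (p - np.asarray(center)) @ rot  # rot columns = local axes in world
    q = np.abs(local) - (np.asarray(half) - round_r)
    outside = np.linalg.norm(np.maximum(q, 0.0), axis=1)
    inside = np.minimum(q.max(axis=1), 0.0)
    return outside + inside - round_r


def _sd_round_cone(p: np.ndarray, a, b, r1: float, r2: float) -> np.ndarray:
    """Rounded cone between sphere (a, r1) and sphere (b, r2)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    ba = b - a
    l2 = ba @ ba
    rr = r1 - r2
    a2 = l2 - rr * rr
    il2 = 1.0 / l2
    pa = p - a
    y = pa @ ba
    z = y - l2
    q = pa * l2 - np.outer(y, ba)
    x2 = np.einsum("ij,ij->i", q, q)
    y2 = y * y * l2
    z2 = z * z * l2
    k = np.sign(rr) * rr * rr * x2
    res = (np.sqrt(x2 * a2 * il2) + y * rr) * il2 - r1
    res = np.where(np.sign(z) * a2 * z2 > k, np.sqrt(x2 + z2) * il2 - r2, res)
    res = np.where(np.sign(y) * a2 * y2 < k, np.sqrt(x2 + y2) * il2 - r1, res)
    return res


def _sd_parabolic_tube(
    p: np.ndarray, tip_x: float, end_x: float, halfwidth: float,
    r_h: float, r_v: float, n_samples: int = 160,
) -> np.ndarray:
    """Tube with elliptical cross-section swept along x = tip_x - c*y^2.

    Evaluated at folded |y|, so the field is exactly bilaterally
    symmetric. Distance is a running minimum over centreline samples with
    the cross-section anisotropy absorbed into an elliptical norm; the
    zero level is accurate to well under the mesh pitch.
    """
    c_par = (tip_x - end_x) / halfwidth**2
    ya = np.abs(p[:, 1])
    ts = np.linspace(0.0, halfwidth, n_samples)
    best = np.full(len(p), np.inf)
    r_min = min(r_h, r_v)
    for t in ts:
        cx = tip_x - c_par * t * t
        dx = p[:, 0] - cx
        dy = ya - t
        dz = p[:, 2]
        q = np.sqrt((dx * dx + dy * dy) / (r_h * r_h) + (dz * dz) / (r_v * r_v))
        np.minimum(best, q, out=best)
    return (best - 1.0) * r_min


# ----- shape parameters -----------------------------------------------------


@dataclass(frozen=True)
class MandibleShape:
    """Size/curvature controls of the template, in mm (T1 scale).

    The default values give a miniature-pig-like mandible roughly 9 cm
    long and 7 cm wide: a horseshoe body, two tilted ramus plates with a
    condylar knob and a pointed coronoid process, rounded gonial corners,
    and a genial-tubercle bump on the lingual midline.
    """

    scale: float = 1.0
    body_tip_x: float = 45.0
    body_end_x: float = -25.0
    body_halfwidth: float = 27.0
    body_r_h: float = 6.5
    body_r_v: float = 9.0
    slab_center: tuple = (-25.0, 26.5, 12.0)
    slab_half: tuple = (11.0, 5.0, 17.0)
    slab_tilt_deg: float = 18.0
    slab_round: float = 1.5
    condyle_center: tuple = (-30.9, 26.5, 30.5)
    condyle_axes: tuple = (4.2, 7.5, 4.5)
    coronoid_base: tuple = (-22.0, 26.5, 29.0)
    coronoid_tip: tuple = (-21.5, 26.5, 41.0)
    coronoid_r_base: float = 4.0
    coronoid_r_tip: float = 0.5
    gt_center: tuple = (36.5, 0.0, -2.0)
    gt_radius: float = 3.5
    blend_k: float = 1.5
    # manual-landmark seed positions: |y| of the body-arm parameter
    amf_y: float = 6.25
    mmf_y: float = 12.3
    pmf_y: float = 18.0
    no_y: float = 25.0


def _template_field(points: np.ndarray, shape: MandibleShape) -> np.ndarray:
    """Signed distance-like field of the template (negative inside)."""
    s = shape.scale
    p = points / s  # evaluate in unit-scale design frame
    folded = p.copy()
    folded[:, 1] = np.abs(folded[:, 1])

    rot = _rot_y(-shape.slab_tilt_deg)
    d = _sd_parabolic_tube(
        folded, shape.body_tip_x, shape.body_end_x, shape.body_halfwidth,
        shape.body_r_h, shape.body_r_v,
    )
    d = _smooth_union(
        d,
        _sd_rounded_box(folded, shape.slab_center, shape.slab_half, rot, shape.slab_round),
        shape.blend_k,
    )
    d = _smooth_union(
        d, _sd_ellipsoid(folded, shape.condyle_center, shape.condyle_axes), shape.blend_k
    )
    d = _smooth_union(
        d,
        _sd_round_cone(
            folded, shape.coronoid_base, shape.coronoid_tip,
            shape.coronoid_r_base, shape.coronoid_r_tip,
        ),
        shape.blend_k,
    )
    d = _smooth_union(
        d, _sd_sphere(folded, shape.gt_center, shape.gt_radius), shape.blend_k
    )
    return d * s


def _design_anchors(shape: MandibleShape) -> dict:
    """Landmark seeds and region geometry in the (uncentred) design frame."""
    s = shape.scale
    c_par = (shape.body_tip_x - shape.body_end_x) / shape.body_halfwidth**2
    rot = _rot_y(-shape.slab_tilt_deg)
    up = rot[:, 2]  # local superior axis of the ramus slab, world coords

    def arm_point(y0: float, side_sign: float) -> np.ndarray:
        xc = shape.body_tip_x - c_par * y0 * y0
        t = np.array([-2.0 * c_par * y0, 1.0])
        t /= np.linalg.norm(t)
        n = np.array([t[1], -t[0]])  # outward (buccal) in-plane normal
        return np.array(
            [xc + shape.body_r_h * n[0], side_sign * (y0 + shape.body_r_h * n[1]), 0.0]
        )

    anchors: dict = {"shape": shape}
    for side, sign in (("L", 1.0), ("R", -1.0)):
        mirror = np.array([1.0, sign, 1.0])
        anchors[f"condyle_center_{side}"] = np.asarray(shape.condyle_center) * mirror * s
        anchors[f"coronoid_base_{side}"] = np.asarray(shape.coronoid_base) * mirror * s
        anchors[f"coronoid_tip_{side}"] = np.asarray(shape.coronoid_tip) * mirror * s
        anchors[f"slab_center_{side}"] = np.asarray(shape.slab_center) * mirror * s
        anchors[f"AMF_{side}"] = arm_point(shape.amf_y, sign) * s
        anchors[f"MMF_{side}"] = arm_point(shape.mmf_y, sign) * s
        anchors[f"PMF_{side}"] = arm_point(shape.pmf_y, sign) * s
        xc = shape.body_tip_x - c_par * shape.no_y**2
        anchors[f"NO_{side}"] = np.array([xc, sign * shape.no_y, -shape.body_r_v]) * s
    anchors["anterior_center"] = np.array([40.0, 0.0, 0.0]) * s
    anchors["slab_half"] = np.asarray(shape.slab_half) * s
    anchors["slab_rot"] = rot
    anchors["slab_round"] = shape.slab_round * s
    return anchors


def _symmetrize_y(verts: np.ndarray, tol: float = 0.1) -> np.ndarray:
    """Make a nearly mirror-symmetric vertex set exactly symmetric in y.

    Marching cubes emits float32 coordinates, leaving micron-scale
    left-right discrepancies; each vertex is averaged with its mirrored
    partner so the vertex set maps onto itself to machine precision.
    """
    from scipy.spatial import cKDTree

    mirrored = verts * np.array([1.0, -1.0, 1.0])
    dist, partner = cKDTree(verts).query(mirrored, k=1)
    if dist.max() > tol:
        return verts  # not a symmetric mesh; leave untouched
    out = 0.5 * (verts + mirrored[partner])
    out[:, 1] = 0.5 * (verts[:, 1] - verts[partner, 1])
    near_mid = np.abs(out[:, 1]) < 1e-9
    out[near_mid, 1] = 0.0
    return out


def generate_template_mesh(
    shape: MandibleShape | None = None,
    resolution: int = 40000,
) -> TriangleMesh:
    """Build the watertight, bilaterally symmetric template mandible.

    ``resolution`` is the approximate target vertex count; it sets the
    marching-cubes pitch. The mesh is returned in the canonical frame
    (+x anterior, +y left, +z superior, origin at the volume centroid)
    with ground-truth anchor metadata attached (``mesh._cache['anchors']``).
    """
    shape = shape or MandibleShape()
    if resolution < 500:
        raise ValueError("resolution must be at least 500 vertices")
    pitch = float(np.sqrt(16400.0 / resolution)) * shape.scale
    if pitch > 2.2 * shape.scale:
        raise ValueError(
            f"resolution {resolution} is unmeetable: pitch {pitch:.2f} mm is too "
            "coarse to resolve the coronoid and gonial features"
        )

    s = shape.scale
    lo = np.array([-46.0, -40.0, -14.0]) * s
    hi = np.array([56.0, 40.0, 47.0]) * s
    xs = np.arange(lo[0], hi[0] + pitch, pitch)
    zs = np.arange(lo[2], hi[2] + pitch, pitch)
    ny = int(np.ceil(hi[1] / pitch))
    ys = (np.arange(-ny, ny + 1)) * pitch  # exactly symmetric, includes 0

    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    f = _template_field(pts, shape).reshape(gx.shape)
    eps = 1e-4 * pitch
    f = np.where(np.abs(f) < eps, eps, f)  # keep MC away from exact zeros

    from skimage.measure import marching_cubes

    verts, faces, _, _ = marching_cubes(
        f, level=0.0, spacing=(pitch, pitch, pitch), allow_degenerate=False
    )
    verts = verts.astype(np.float64) + np.array([xs[0], ys[0], zs[0]])
    verts = _symmetrize_y(verts)
    mesh = TriangleMesh(verts, faces.astype(np.int64), fix_orientation=True)

    # centre the canonical frame on the volume centroid (kept on y=0 so
    # bilateral symmetry is preserved bitwise)
    tri = mesh.triangles
    vols = np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])) / 6.0
    centroid = (tri.sum(axis=1) / 4.0 * vols[:, None]).sum(axis=0) / vols.sum()
    centroid[1] = 0.0
    mesh.vertices -= centroid
    mesh._cache.clear()

    anchors = _design_anchors(shape)
    for key, val in anchors.items():
        if isinstance(val, np.ndarray) and val.shape == (3,) and key != "slab_half":
            anchors[key] = val - centroid
    anchors["centroid_offset"] = centroid
    mesh._cache["anchors"] = anchors
    return mesh


# ----- growth model ---------------------------------------------------------

_REGIONS = ("ramus", "body", "anterior", "condyle", "coronoid")
_AXES = ("AP", "ML", "SI")  # maps to (x, y, z)


def _solve_half_growth_rate(t_half: float = 3.9, t_final: float = 12.0) -> float:
    """Rate constant k (1/month) with half the saturating change by t_half.

    Calibrated slightly before month 4 so the fourth measurement robustly
    clears the 50% mark (half the overall growth "around the 4th month").
    """

    def f(k):
        return (1 - np.exp(-k * (t_half - 1))) - 0.5 * (1 - np.exp(-k * (t_final - 1)))

    return float(brentq(f, 1e-4, 3.0))


_DEFAULT_K = None


def default_time_constant() -> float:
    global _DEFAULT_K
    if _DEFAULT_K is None:
        _DEFAULT_K = _solve_half_growth_rate()
    return _DEFAULT_K


@dataclass(frozen=True)
class GrowthModel:
    """Region- and direction-resolved growth rates plus noise settings.

    region_rates maps region -> (AP, ML, SI) total fractional growth
    (unitless; the amount accrued at T12 under the default time curve).
    ``time_constant`` is the saturating-exponential rate in 1/month.
    ``noise_sd`` (mm) jitters the manual-landmark measurement channel;
    ``asymmetry_sd`` (mm) drives a smooth left-right shape perturbation.
    """

    region_rates: dict = field(
        default_factory=lambda: {
            "ramus": (1.65, 0.60, 1.60),
            "body": (1.00, 0.50, 0.60),
            "anterior": (1.20, 0.42, 0.60),
            "condyle": (1.45, 0.66, 1.45),
            "coronoid": (1.65, 0.60, 1.60),
        }
    )
    time_constant: float | None = None
    n_timepoints: int = 12
    noise_sd: float = 0.15
    asymmetry_sd: float = 0.1
    seed: int = 0
    asymmetry_vector: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        for region, rates in self.region_rates.items():
            if region not in _REGIONS:
                raise ValueError(f"unknown region {region!r}")
            if len(rates) != 3 or any(r < 0 for r in rates):
                raise ValueError(f"rates for {region} must be 3 non-negative values")
        missing = set(_REGIONS) - set(self.region_rates)
        if missing:
            raise ValueError(f"region_rates missing regions: {sorted(missing)}")

    @property
    def k(self) -> float:
        return self.time_constant if self.time_constant is not None else default_time_constant()

    def time_curve(self, t) -> np.ndarray:
        """Saturating growth fraction: 0 at T1, 1 at the final timepoint."""
        t = np.asarray(t, dtype=float)
        k = self.k
        tf = self.n_timepoints
        return (1.0 - np.exp(-k * (t - 1.0))) / (1.0 - np.exp(-k * (tf - 1.0)))


def default_growth_model(seed: int = 0, **overrides) -> GrowthModel:
    return dataclasses.replace(GrowthModel(), seed=seed, **overrides)


def _smooth_plateau(d: np.ndarray, inner: float, outer: float) -> np.ndarray:
    """1 inside ``inner``, 0 beyond ``outer``, smooth cubic ramp between."""
    t = np.clip((d - inner) / (outer - inner), 0.0, 1.0)
    return 1.0 - t * t * (3.0 - 2.0 * t)


def _point_segment_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ab = b - a
    t = np.clip(((p - a) @ ab) / (ab @ ab), 0.0, 1.0)
    return np.linalg.norm(p - (a + t[:, None] * ab), axis=1)


def _region_weights(points: np.ndarray, anchors: dict) -> dict:
    """Partition-of-unity region weights (plateau soft masks).

    The ramus/condyle/coronoid plateaus cover every automatic-landmark
    neighbourhood, so the growth field is locally constant there.
    """
    shape: MandibleShape = anchors["shape"]
    s = shape.scale
    raw = {r: np.zeros(len(points)) for r in _REGIONS}
    rot = anchors["slab_rot"]
    for side in ("L", "R"):
        d_slab = _sd_rounded_box(
            points, anchors[f"slab_center_{side}"], anchors["slab_half"],
            rot, anchors["slab_round"],
        )
        raw["ramus"] = np.maximum(raw["ramus"], _smooth_plateau(d_slab, 8.0 * s, 17.0 * s))
        d_cond = np.linalg.norm(points - anchors[f"condyle_center_{side}"], axis=1)
        raw["condyle"] = np.maximum(raw["condyle"], _smooth_plateau(d_cond, 9.0 * s, 13.0 * s))
        d_cor = _point_segment_distance(
            points, anchors[f"coronoid_base_{side}"], anchors[f"coronoid_tip_{side}"]
        )
        raw["coronoid"] = np.maximum(raw["coronoid"], _smooth_plateau(d_cor, 6.5 * s, 10.0 * s))
    d_ant = np.linalg.norm(points - anchors["anterior_center"], axis=1)
    raw["anterior"] = _smooth_plateau(d_ant, 12.0 * s, 20.0 * s)
    covered = np.maximum.reduce([raw[r] for r in ("ramus", "condyle", "coronoid", "anterior")])
    raw["body"] = 1.0 - covered  # complement, so plateaus are not diluted
    total = sum(raw.values())
    return {r: w / total for r, w in raw.items()}


def _growth_field(points: np.ndarray, model: GrowthModel, anchors: dict) -> np.ndarray:
    """Per-point (AP, ML, SI) total fractional growth g_a(x)."""
    w = _region_weights(points, anchors)
    g = np.zeros((len(points), 3))
    for region in _REGIONS:
        g += w[region][:, None] * np.asarray(model.region_rates[region])
    return g


def _deform_points(
    points: np.ndarray, model: GrowthModel, anchors: dict, t: float
) -> np.ndarray:
    c = float(model.time_curve(t))
    g = _growth_field(points, model, anchors)
    out = points * (1.0 + c * g)
    asym = np.asarray(model.asymmetry_vector, float)
    if np.any(asym != 0.0):
        shape: MandibleShape = anchors["shape"]
        out = out + c * np.tanh(points[:, 1:2] / (10.0 * shape.scale)) * asym
    return out


def _truth_landmarks(template: TriangleMesh) -> LandmarkSet:
    """Ground-truth landmark set of the template (= T1 anatomy).

    Automatic codes come from the detectors themselves (truth and
    detection coincide at T1 by construction); manual codes come from the
    analytic body-arm seeds snapped to the surface.
    """
    anchors = template._cache["anchors"]
    truth = detect_all(template, default_rois(template))
    for (code, side), lm in truth.entries.items():
        lm.source = "truth"
    for code in MANUAL_CODES:
        for side in ("L", "R"):
            seed_pt = anchors[f"{code}_{side}"]
            snapped, dist = nearest_point_on_surface(template, seed_pt[None, :])
            if dist[0] > 2.0 * anchors["shape"].scale:
                raise RuntimeError(
                    f"manual seed {code}_{side} is {dist[0]:.2f} mm off surface; "
                    "template shape parameters are inconsistent"
                )
            truth.add(code, side, snapped[0], "truth")
    return truth


def grow_mesh(
    template: TriangleMesh, model: GrowthModel, t: int
) -> tuple[TriangleMesh, LandmarkSet]:
    """Deform the template (and its ground-truth landmarks) to timepoint t.

    At t = 1 the mesh equals the template. The returned landmark set is
    the transported ground truth, re-snapped onto the deformed surface.
    Raises if the deformation folds the surface (flipped face normals).
    """
    if "anchors" not in template._cache:
        raise ValueError("template lacks anchor metadata; use generate_template_mesh")
    if not (1 <= t <= model.n_timepoints):
        raise ValueError(f"timepoint {t} outside 1..{model.n_timepoints}")
    anchors = template._cache["anchors"]
    if "truth" not in template._cache:
        template._cache["truth"] = _truth_landmarks(template)
    truth_t1: LandmarkSet = template._cache["truth"]

    new_v = _deform_points(template.vertices, model, anchors, t)
    mesh = TriangleMesh(new_v, template.faces.copy(), validate=False)

    tri_old, tri_new = template.triangles, mesh.triangles
    n_old = np.cross(tri_old[:, 1] - tri_old[:, 0], tri_old[:, 2] - tri_old[:, 0])
    n_new = np.cross(tri_new[:, 1] - tri_new[:, 0], tri_new[:, 2] - tri_new[:, 0])
    if (np.einsum("ij,ij->i", n_old, n_new) <= 0).any():
        bad = int(np.argmin(np.einsum("ij,ij->i", n_old, n_new)))
        raise RuntimeError(
            f"growth deformation folds the surface (face {bad} flipped); "
            "reduce region-rate contrast or time step"
        )

    out = LandmarkSet(truth_t1.subject, int(t))
    keys = sorted(truth_t1.entries)
    pts = np.array([truth_t1.entries[k].point for k in keys])
    moved = _deform_points(pts, model, anchors, t)
    snapped, _ = nearest_point_on_surface(mesh, moved)
    for key, p in zip(keys, snapped):
        out.add(key[0], key[1], p, "truth")
    return mesh, out


# ----- study dataset --------------------------------------------------------


@dataclass
class StudyDataset:
    """A generated longitudinal study, regenerable mesh-by-mesh.

    Meshes are produced on demand (``mesh(subject, t)``) from the stored
    per-subject templates and growth models, so a full study never has to
    be resident in memory; ``write`` materialises PLY meshes, landmark
    CSVs and a JSON manifest.
    """

    subjects: list
    timepoints: list
    templates: dict  # subject -> TriangleMesh (with anchors + truth cached)
    models: dict  # subject -> GrowthModel (per-subject jittered)
    truth: pd.DataFrame  # landmark table, source == "truth"
    manual: pd.DataFrame  # noisy manual-channel table, source == "manual"
    volumes: pd.DataFrame  # subject, timepoint, volume_cm3
    seed: int

    def mesh(self, subject: str, t: int) -> TriangleMesh:
        # one-slot cache: pipeline stages visit (subject, t) in the same order
        cached = getattr(self, "_mesh_cache", None)
        if cached is not None and cached[0] == (subject, t):
            return cached[1]
        m, _ = grow_mesh(self.templates[subject], self.models[subject], t)
        self._mesh_cache = ((subject, t), m)
        return m

    def landmarks_truth(self, subject: str, t: int) -> LandmarkSet:
        sub = self.truth[(self.truth.subject == subject) & (self.truth.timepoint == t)]
        out = LandmarkSet(subject, t)
        for _, row in sub.iterrows():
            out.add(row["code"], row["side"], [row.x_mm, row.y_mm, row.z_mm], "truth")
        return out

    def write(self, out_dir, overwrite: bool = False) -> Path:
        from .mesh import write_mesh

        out = Path(out_dir)
        if out.exists() and any(out.iterdir()) and not overwrite:
            raise FileExistsError(
                f"output directory {out} exists and is not empty (pass overwrite=True)"
            )
        (out / "meshes").mkdir(parents=True, exist_ok=True)
        files = []
        for subj in self.subjects:
            for t in self.timepoints:
                path = out / "meshes" / f"{subj}_T{t:02d}.ply"
                write_mesh(self.mesh(subj, t), path)
                files.append(str(path.relative_to(out)))
        self.truth.to_csv(out / "landmarks_truth.csv", index=False, float_format="%.9f")
        self.manual.to_csv(out / "landmarks_manual.csv", index=False, float_format="%.9f")
        self.volumes.to_csv(out / "volumes_truth.csv", index=False, float_format="%.9f")
        subj0 = self.subjects[0]
        manifest = {
            "seed": self.seed,
            "subjects": self.subjects,
            "timepoints": self.timepoints,
            "files": files,
            "model": {
                "region_rates": {
                    r: list(v) for r, v in self.models[subj0].region_rates.items()
                },
                "time_constant": self.models[subj0].k,
                "noise_sd": self.models[subj0].noise_sd,
                "asymmetry_sd": self.models[subj0].asymmetry_sd,
            },
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
            fh.write("\n")
        return out


def generate_study(
    n_subjects: int,
    n_timepoints: int,
    model: GrowthModel | None = None,
    resolution: int = 20000,
    shape: MandibleShape | None = None,
    subject_rate_sd: float = 0.04,
    region_rate_sd: float = 0.015,
    subject_scale_sd: float = 0.03,
    out_dir=None,
    overwrite: bool = False,
) -> StudyDataset:
    """Generate a longitudinal cohort with known ground truth.

    Between-subject variation (all seeded from ``model.seed``): the
    template is scaled by a per-subject size factor; growth rates get a
    shared per-axis anisotropy factor (SD ``subject_rate_sd``) plus a
    small per-region factor (SD ``region_rate_sd``, clipped to +/-3%).
    The per-region factor is kept small because strong region-to-region
    rate contrast folds the surface at the region transitions.
    Manual-channel landmark coordinates get i.i.d. Gaussian noise of SD
    ``model.noise_sd`` mm; set it to 0 for a noise-free study.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if n_timepoints < 2:
        raise ValueError("n_timepoints must be >= 2")
    model = model or default_growth_model()
    model = dataclasses.replace(model, n_timepoints=n_timepoints)
    shape = shape or MandibleShape()
    rng = np.random.default_rng(model.seed)

    subjects = [f"S{i+1}" for i in range(n_subjects)]
    timepoints = list(range(1, n_timepoints + 1))
    templates: dict = {}
    models: dict = {}
    truth_sets = []
    manual_rows = []
    vol_rows = []
    for subj in subjects:
        scale_f = float(np.clip(1.0 + rng.normal(0.0, subject_scale_sd), 0.8, 1.2))
        # shared per-axis anisotropy jitter; identical jitter for ramus and
        # coronoid keeps the growth field locally constant at the coronoid
        # apex (detector stability)
        axis_f = 1.0 + np.clip(rng.normal(0.0, subject_rate_sd, size=3), -0.10, 0.10)
        region_f = {}
        for region in ("ramus", "condyle", "body", "anterior"):
            region_f[region] = 1.0 + float(
                np.clip(rng.normal(0.0, region_rate_sd), -0.03, 0.03)
            )
        region_f["coronoid"] = region_f["ramus"]
        rates = {
            r: tuple(
                np.maximum(
                    np.asarray(model.region_rates[r]) * axis_f * region_f[r], 0.0
                )
            )
            for r in _REGIONS
        }
        asym = tuple(rng.normal(0.0, model.asymmetry_sd, size=3))
        sub_shape = dataclasses.replace(shape, scale=shape.scale * scale_f)
        sub_model = dataclasses.replace(
            model, region_rates=rates, asymmetry_vector=asym,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        template = generate_template_mesh(sub_shape, resolution=resolution)
        templates[subj] = template
        models[subj] = sub_model

        for t in timepoints:
            mesh_t, lm_t = grow_mesh(template, sub_model, t)
            lm_t.subject = subj
            truth_sets.append(lm_t)
            vol_rows.append(
                {"subject": subj, "timepoint": t, "volume_cm3": mesh_volume(mesh_t)}
            )
            for code in MANUAL_CODES:
                for side in ("L", "R"):
                    p = lm_t.get(code, side) + rng.normal(0.0, model.noise_sd, 3)
                    manual_rows.append(
                        {
                            "subject": subj, "timepoint": t, "code": code,
                            "side": side, "x_mm": p[0], "y_mm": p[1],
                            "z_mm": p[2], "source": "manual",
                        }
                    )

    dataset = StudyDataset(
        subjects=subjects,
        timepoints=timepoints,
        templates=templates,
        models=models,
        truth=landmark_table(truth_sets),
        manual=pd.DataFrame(manual_rows),
        volumes=pd.DataFrame(vol_rows),
        seed=model.seed,
    )
    if out_dir is not None:
        dataset.write(out_dir, overwrite=overwrite)
    return dataset


# ----- voxel round trip -----------------------------------------------------


def voxelize_and_reconstruct(mesh: TriangleMesh, voxel_size: float) -> TriangleMesh:
    """Emulate the CT segment-then-mesh path: occupancy grid + isosurface.

    The mesh is voxelized at the given isotropic spacing (0.25 mm emulates
    the CBCT protocol), the binary occupancy is lightly smoothed, and the
    0.5 isosurface is re-extracted with marching cubes.
    """
    occ, origin, h = voxelize(mesh, voxel_size)
    if not occ.any():
        raise ValueError("voxelization produced an empty grid")
    if mesh.is_watertight:
        thickness_proxy = 3.0 * mesh.signed_volume_mm3 / mesh.area
        if voxel_size > 0.5 * thickness_proxy:
            warnings.warn(
                f"voxel size {voxel_size} mm exceeds half the mean thickness "
                f"({thickness_proxy:.1f} mm); reconstruction may lose features",
                stacklevel=2,
            )
    from scipy.ndimage import gaussian_filter
    from skimage.measure import marching_cubes

    vol = gaussian_filter(occ.astype(float), sigma=0.5)
    verts, faces, _, _ = marching_cubes(
        vol, level=0.5, spacing=(h, h, h), allow_degenerate=False
    )
    verts = verts + origin + 0.5 * h
    return TriangleMesh(verts, faces.astype(np.int64), fix_orientation=True)


# ----- simple analytic fixtures ---------------------------------------------


def icosphere(radius: float = 1.0, subdivisions: int = 3) -> TriangleMesh:
    """Regular sphere tessellation (subdivided icosahedron)."""
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    v = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=float,
    )
    f = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ]
    )
    for _ in range(subdivisions):
        cache: dict = {}
        new_faces = []
        verts = list(map(tuple, v))

        def midpoint(i, j):
            key = (min(i, j), max(i, j))
            if key not in cache:
                m = (np.array(verts[i]) + np.array(verts[j])) / 2.0
                verts.append(tuple(m))
                cache[key] = len(verts) - 1
            return cache[key]

        for a, b, c in f:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]
        v = np.array(verts)
        f = np.array(new_faces)
    v = v / np.linalg.norm(v, axis=1, keepdims=True) * radius
    return TriangleMesh(v, f, fix_orientation=True)


def random_blob(seed: int = 0, radius: float = 6.0, bumpiness: float = 0.25,
                subdivisions: int = 4) -> TriangleMesh:
    """Smooth star-shaped random blob (for volume-oracle tests)."""
    rng = np.random.default_rng(seed)
    base = icosphere(1.0, subdivisions)
    d = base.vertices
    r = np.ones(len(d))
    for _ in range(6):
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        freq = rng.uniform(1.0, 2.5)
        phase = rng.uniform(0, 2 * np.pi)
        amp = rng.uniform(0.2, 1.0) * bumpiness / 2.0
        r += amp * np.sin(freq * np.pi * (d @ axis) + phase)
    v = d * (radius * r)[:, None]
    return TriangleMesh(v, base.faces, fix_orientation=True)
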