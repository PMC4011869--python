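"""Anatomical landmark detection and ingestion.

Nine landmark codes are tracked, 17 points in total (8 bilateral codes
plus the midline genial tubercle):

====  =========================================================
LP    lateral pole of the condyle (most lateral condyle point)
MP    medial pole of the condyle (most medial condyle point)
CP    coronoid process (largest-curvature point on the coronoid)
GO    gonion, via the three-plane construction (see detect_gonion)
GT    genial tubercle (most posterior point of the tubercle)
AMF   anterior edge of the mental foramen (manual)
MMF   middle edge of the mental foramen (manual)
PMF   posterior edge of the mental foramen (manual)
NO    notch of the groove for the external maxillary artery (manual)
====  =========================================================

LP, MP, CP, GT and GO are detected automatically from mesh geometry
within coarse regions of interest (the machine stand-in for a human
indicating the gross position); AMF, MMF, PMF and NO are ingested from a
CSV of manually placed points and snapped to the surface.

The canonical anatomical frame is +x anterior, +y subject-left,
+z superior; side "L" means subject-left (y > 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import TOL
from .mesh import (
    Plane,
    RegionOfInterest,
    TriangleMesh,
    bisecting_plane,
    discrete_curvature,
    extremal_point,
    nearest_point_on_surface,
    plane_line,
    plane_surface_intersection,
    support_plane,
)

AUTO_CODES = ("LP", "MP", "CP", "GO", "GT")
MANUAL_CODES = ("AMF", "MMF", "PMF", "NO")
ALL_CODES = ("LP", "MP", "CP", "GO", "AMF", "MMF", "PMF", "NO", "GT")
BILATERAL_CODES = tuple(c for c in ALL_CODES if c != "GT")
SIDES = ("L", "R", "M")

#: (code, side) keys of a complete 17-landmark set
COMPLETE_KEYS = tuple(
    [(c, s) for c in BILATERAL_CODES for s in ("L", "R")] + [("GT", "M")]
)


@dataclass
class Landmark:
    point: np.ndarray
    source: str = "auto"  # auto | manual | truth

    def __post_init__(self):
        self.point = np.asarray(self.point, dtype=float).reshape(3)


@dataclass
class LandmarkSet:
    """Named landmark points of one subject at one timepoint."""

    subject: str
    timepoint: int
    entries: dict = field(default_factory=dict)  # (code, side) -> Landmark

    def add(self, code: str, side: str, point, source: str = "auto") -> None:
        if code not in ALL_CODES:
            raise ValueError(f"unknown landmark code {code!r}")
        if side not in SIDES:
            raise ValueError(f"unknown side {side!r}")
        if code == "GT" and side != "M":
            raise ValueError("GT is a midline landmark (side M)")
        self.entries[(code, side)] = Landmark(point, source)

    def get(self, code: str, side: str) -> np.ndarray:
        try:
            return self.entries[(code, side)].point
        except KeyError:
            raise KeyError(f"landmark ({code}, {side}) missing from set") from None

    def __contains__(self, key) -> bool:
        return key in self.entries

    @property
    def is_complete(self) -> bool:
        return all(k in self.entries for k in COMPLETE_KEYS)

    def merge(self, other: "LandmarkSet") -> "LandmarkSet":
        merged = LandmarkSet(self.subject, self.timepoint, dict(self.entries))
        merged.entries.update(other.entries)
        return merged

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "subject": self.subject,
                "timepoint": self.timepoint,
                "code": code,
                "side": side,
                "x_mm": lm.point[0],
                "y_mm": lm.point[1],
                "z_mm": lm.point[2],
                "source": lm.source,
            }
            for (code, side), lm in sorted(self.entries.items())
        ]
        return pd.DataFrame(rows)


LANDMARK_CSV_COLUMNS = [
    "subject", "timepoint", "code", "side", "x_mm", "y_mm", "z_mm", "source",
]


def landmark_table(sets) -> pd.DataFrame:
    """Long-format table of many landmark sets (the CSV schema)."""
    frames = [s.to_frame() for s in sets]
    return pd.concat(frames, ignore_index=True)[LANDMARK_CSV_COLUMNS]


# ----- default regions of interest ------------------------------------------


def default_rois(mesh: TriangleMesh) -> dict:
    """Procedural ROIs in the canonical frame, scaled to the mesh bounds.

    These encode the coarse "gross position" a human would indicate and
    are tuned to the synthetic mandible family; override them (YAML box
    definitions) for other anatomies.
    """
    lo, hi = mesh.bounds
    span = hi - lo

    def frac(v, axis):
        return (v[:, axis] - lo[axis]) / span[axis]

    def side_mask(v, side):
        return v[:, 1] >= 2.0 if side == "L" else v[:, 1] <= -2.0

    half_y = span[1] / 2.0

    rois: dict = {}
    for side in ("L", "R"):
        rois[f"condyle_{side}"] = RegionOfInterest.from_predicate(
            lambda v, s=side: (frac(v, 0) <= 0.20)
            & (frac(v, 2) >= 0.70) & (frac(v, 2) <= 0.93)
            & side_mask(v, s)
        )
        rois[f"coronoid_{side}"] = RegionOfInterest.from_predicate(
            lambda v, s=side: (frac(v, 2) >= 0.90) & side_mask(v, s)
        )
        rois[f"gonion_ramus_{side}"] = RegionOfInterest.from_predicate(
            lambda v, s=side: (frac(v, 0) <= 0.16)
            & (frac(v, 2) >= 0.10) & (frac(v, 2) <= 0.45)
            & side_mask(v, s)
        )
        rois[f"gonion_corpus_{side}"] = RegionOfInterest.from_predicate(
            lambda v, s=side: (frac(v, 2) <= 0.06)
            & (np.abs(v[:, 1]) >= 0.45 * half_y)
            & (np.abs(v[:, 1]) <= 0.92 * half_y)
            & (frac(v, 0) >= 0.08) & (frac(v, 0) <= 0.28)
            & side_mask(v, s)
        )
    rois["gt"] = RegionOfInterest.from_predicate(
        lambda v: (frac(v, 0) >= 0.78)
        & (np.abs(v[:, 1]) <= 0.075 * half_y)
        & (frac(v, 2) <= 0.55)
    )
    return rois


#: default outward hints for the gonion support planes: the posterior
#: ramus border leans back by roughly the gonial tilt, the inferior
#: corpus border faces straight down
GONION_RAMUS_OUTWARD = (-1.0, 0.0, -0.33)
GONION_CORPUS_OUTWARD = (0.0, 0.0, -1.0)


# ----- automatic detectors --------------------------------------------------


def _lateral_direction(side: str) -> np.ndarray:
    if side == "L":
        return np.array([0.0, 1.0, 0.0])
    if side == "R":
        return np.array([0.0, -1.0, 0.0])
    raise ValueError(f"side must be L or R, got {side!r}")


def detect_condyle_poles(
    mesh: TriangleMesh, condyle_roi: RegionOfInterest, side: str
) -> tuple[np.ndarray, np.ndarray]:
    """LP and MP: most lateral / most medial vertex of the condyle ROI."""
    lateral = _lateral_direction(side)
    idx = condyle_roi.resolve(mesh)
    if np.abs(mesh.vertices[idx, 1]).min() < 1.0:
        warnings.warn(
            "condyle ROI touches the midline; medial pole may be ambiguous",
            stacklevel=2,
        )
    _, lp = extremal_point(mesh, lateral, condyle_roi)
    _, mp = extremal_point(mesh, -lateral, condyle_roi)
    if (lp - mp) @ lateral <= 0:
        raise ValueError("degenerate condyle ROI: LP not lateral of MP")
    return lp, mp


def detect_coronoid_process(
    mesh: TriangleMesh, coronoid_roi: RegionOfInterest, side: str
) -> np.ndarray:
    """CP: vertex of largest discrete curvature within the coronoid ROI."""
    if "curvature" not in mesh._cache:
        mesh._cache["curvature"] = discrete_curvature(mesh)
    curv, _ = mesh._cache["curvature"]
    idx = coronoid_roi.resolve(mesh)
    vals = curv[idx]
    vals = np.where(np.isnan(vals), -np.inf, vals)
    best = int(np.argmax(vals))  # first index on ties -> lowest vertex id
    if vals[best] < 1e-5:
        raise ValueError("no protrusion in ROI (max curvature below tolerance)")
    return mesh.vertices[idx[best]].copy()


def detect_genial_tubercle(mesh: TriangleMesh, gt_roi: RegionOfInterest) -> np.ndarray:
    """GT: most posterior (−x extremal) vertex of the lingual midline ROI."""
    _, p = extremal_point(mesh, [-1.0, 0.0, 0.0], gt_roi)
    return p


def detect_gonion(
    mesh: TriangleMesh,
    ramus_border_roi: RegionOfInterest,
    corpus_border_roi: RegionOfInterest,
    side: str,
    ring_mm: float = 8.0,
    ramus_outward=GONION_RAMUS_OUTWARD,
    corpus_outward=GONION_CORPUS_OUTWARD,
    max_angle_deg: float = 15.0,
) -> np.ndarray:
    """GO via the three-plane construction.

    A supporting plane of the posterior ramus border and one of the
    inferior corpus border form an obtuse dihedral wedge; the plane
    bisecting that wedge cuts the rounded gonial edge, and the point of
    the cut closest to the two planes' intersection line is the gonion.
    Candidate cut points are restricted to within ``ring_mm`` of the two
    border ROIs so the bisector cannot latch onto distant anatomy (it is
    an infinite plane). The outward hints select the hull facet serving
    as each border's tangent plane.
    """
    # the posterior ramus border carries a flat strip -> extreme-band fit;
    # the inferior corpus border is curved and its outward direction is
    # straight down -> alignment strategy
    plane_a = support_plane(
        mesh, ramus_border_roi, outward=ramus_outward,
        max_angle_deg=max_angle_deg, strategy="fit",
    )
    plane_b = support_plane(
        mesh, corpus_border_roi, outward=corpus_outward,
        max_angle_deg=max_angle_deg, strategy="align",
    )
    bisector = bisecting_plane(plane_a, plane_b)
    line_pt, line_dir = plane_line(plane_a, plane_b)

    polylines = plane_surface_intersection(mesh, bisector)
    if not polylines:
        raise ValueError("no gonial edge intersection (bisector misses mesh)")

    # candidate points: continuous closest approach of every intersection
    # segment to the corner line (vertex-only candidates would quantize
    # the gonion to the mesh edge spacing)
    seg_a, seg_b = [], []
    for poly in polylines:
        p = poly.points
        if len(p) < 2:
            seg_a.append(p)
            seg_b.append(p)
            continue
        seg_a.append(p[:-1])
        seg_b.append(p[1:])
        if poly.closed:
            seg_a.append(p[-1:])
            seg_b.append(p[:1])
    a = np.concatenate(seg_a)
    b = np.concatenate(seg_b)
    u = b - a
    w = a - line_pt
    # project out the line direction, then minimize over the segment
    mu = u - np.outer(u @ line_dir, line_dir)
    mw = w - np.outer(w @ line_dir, line_dir)
    denom = np.einsum("ij,ij->i", mu, mu)
    s = np.where(denom > 0, -np.einsum("ij,ij->i", mw, mu) / np.where(denom == 0, 1, denom), 0.0)
    s = np.clip(s, 0.0, 1.0)
    candidates = a + s[:, None] * u

    from scipy.spatial import cKDTree

    roi_pts = np.concatenate(
        [
            mesh.vertices[ramus_border_roi.resolve(mesh)],
            mesh.vertices[corpus_border_roi.resolve(mesh)],
        ]
    )
    near = cKDTree(roi_pts).query(candidates, k=1)[0] <= ring_mm
    if not near.any():
        raise ValueError("no gonial edge intersection near the border ROIs")
    candidates = candidates[near]
    rel = candidates - line_pt
    d2 = np.einsum("ij,ij->i", rel, rel) - (rel @ line_dir) ** 2
    return candidates[int(np.argmin(d2))].copy()


def detect_all(
    mesh: TriangleMesh,
    rois: dict | None = None,
    subject: str = "",
    timepoint: int = 1,
) -> LandmarkSet:
    """Run all automatic detectors; returns the 9 auto landmarks."""
    rois = rois if rois is not None else default_rois(mesh)
    out = LandmarkSet(subject, timepoint)
    for side in ("L", "R"):
        lp, mp = detect_condyle_poles(mesh, rois[f"condyle_{side}"], side)
        out.add("LP", side, lp, "auto")
        out.add("MP", side, mp, "auto")
        out.add("CP", side, detect_coronoid_process(mesh, rois[f"coronoid_{side}"], side), "auto")
        out.add(
            "GO",
            side,
            detect_gonion(
                mesh, rois[f"gonion_ramus_{side}"], rois[f"gonion_corpus_{side}"], side
            ),
            "auto",
        )
    out.add("GT", "M", detect_genial_tubercle(mesh, rois["gt"]), "auto")
    return out


# ----- manual landmark ingestion --------------------------------------------


def load_manual_landmarks(
    csv_path,
    meshes,
    snap_mm: float = TOL.manual_snap,
) -> tuple[dict, pd.DataFrame]:
    """Read manually placed landmarks and snap them to their mesh surface.

    ``meshes`` maps (subject, timepoint) -> TriangleMesh (or is a single
    mesh, applied to every row). Points within ``snap_mm`` of the surface
    are snapped to their nearest surface point; rows with unknown codes,
    missing coordinates or larger offsets are rejected and reported.

    Returns ``(sets, report)`` where ``sets`` maps (subject, timepoint) to
    a partial LandmarkSet and ``report`` lists rejected rows with reasons.
    """
    df = pd.read_csv(csv_path, dtype={"subject": str})
    missing_cols = set(LANDMARK_CSV_COLUMNS[:-1]) - set(df.columns)
    if missing_cols:
        raise ValueError(f"landmark CSV missing columns: {sorted(missing_cols)}")

    dup = df.duplicated(subset=["subject", "timepoint", "code", "side"], keep=False)
    if dup.any():
        first = df.loc[dup, ["subject", "timepoint", "code", "side"]].iloc[0]
        raise ValueError(
            "duplicate landmark rows for "
            f"(subject={first['subject']}, timepoint={first['timepoint']}, "
            f"code={first['code']}, side={first['side']})"
        )

    def mesh_for(key):
        if isinstance(meshes, TriangleMesh):
            return meshes
        return meshes.get(key)

    sets: dict = {}
    rejected = []
    for _, row in df.iterrows():
        key = (row["subject"], int(row["timepoint"]))
        reason = None
        if row["code"] not in ALL_CODES:
            reason = f"unknown code {row['code']!r}"
        elif row["side"] not in SIDES:
            reason = f"unknown side {row['side']!r}"
        else:
            coords = np.array([row["x_mm"], row["y_mm"], row["z_mm"]], dtype=float)
            if not np.isfinite(coords).all():
                reason = "missing or non-finite coordinate"
        if reason is None:
            mesh = mesh_for(key)
            if mesh is None:
                reason = f"no mesh for (subject, timepoint) {key}"
            else:
                snapped, dist = nearest_point_on_surface(mesh, coords[None, :])
                if dist[0] > snap_mm:
                    reason = f"point {dist[0]:.2f} mm off surface (> {snap_mm} mm)"
                else:
                    if key not in sets:
                        sets[key] = LandmarkSet(key[0], key[1])
                    sets[key].add(row["code"], row["side"], snapped[0], "manual")
        if reason is not None:
            rejected.append({**row.to_dict(), "reason": reason})
    report = pd.DataFrame(rejected, columns=list(df.columns) + ["reason"])
    return sets, report


# ----- repeatability --------------------------------------------------------


def icc_repeatability(measurements: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``measurements`` is an (n subjects x k repeats) matrix with no missing
    cells. Computed from the classical mean-squares decomposition and
    clipped below at 0.
    """
    y = np.asarray(measurements, dtype=float)
    if y.ndim != 2:
        raise ValueError("measurements must be a 2-D subjects x repeats matrix")
    n, k = y.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 repeats")
    if not np.isfinite(y).all():
        raise ValueError("missing cells are not allowed (no imputation)")
    grand = y.mean()
    row_m = y.mean(axis=1)
    col_m = y.mean(axis=0)
    msr = k * np.sum((row_m - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_m - grand) ** 2) / (k - 1)
    resid = y - row_m[:, None] - col_m[None, :] + grand
    mse = np.sum(resid**2) / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0:
        return 0.0
    icc = (msr - mse) / denom
    return float(min(max(icc, 0.0), 1.0))
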