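"""Morphometric parameters: inter-marker distances, angles, bone volume.

The default segment catalog is the study inventory of 25 distance
definitions in four orientation groups — anteroposterior (AP, 9),
superoinferior (SI, 3), anteroinferior (AI, 6) and mediolateral (ML, 7,
the "Bi-" bilateral widths) — plus two inter-segmental angles
(LP-GO-AMF per side with vertex GO, and left GO-GT-right GO with vertex
GT). Distances are reported in cm, angles in degrees, volume in cm^3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .landmarks import LandmarkSet
from .mesh import TriangleMesh, mesh_volume

__all__ = [
    "AngleDef",
    "SegmentCatalog",
    "SegmentDef",
    "default_catalog",
    "inter_marker_distance",
    "inter_segment_angle",
    "measure_all",
]

#: side-resolution rules for a distance definition
SAME_SIDE = "same-side"
BILATERAL = "bilateral"
MIDLINE_TO_SIDE = "midline-to-side"


@dataclass(frozen=True)
class SegmentDef:
    name: str
    group: str  # AP | SI | AI | ML
    code_a: str
    code_b: str
    rule: str  # SAME_SIDE | BILATERAL | MIDLINE_TO_SIDE

    def endpoints(self, side: str | None) -> tuple[tuple[str, str], tuple[str, str]]:
        if self.rule == BILATERAL:
            return (self.code_a, "L"), (self.code_a, "R")
        if self.rule == MIDLINE_TO_SIDE:
            if side not in ("L", "R"):
                raise ValueError(f"{self.name}: side L or R required")
            return (self.code_a, "M"), (self.code_b, side)
        if side not in ("L", "R"):
            raise ValueError(f"{self.name}: side L or R required")
        return (self.code_a, side), (self.code_b, side)

    @property
    def is_unilateral(self) -> bool:
        return self.rule != BILATERAL


@dataclass(frozen=True)
class AngleDef:
    """Angle at ``vertex`` between rays toward ``ray_a`` and ``ray_b``.

    Entries are (code, side) with side "*" standing for the per-side
    placeholder resolved at measurement time.
    """

    name: str
    ray_a: tuple
    vertex: tuple
    ray_b: tuple

    @property
    def is_unilateral(self) -> bool:
        return any(s == "*" for _, s in (self.ray_a, self.vertex, self.ray_b))

    def resolved(self, side: str | None):
        def fix(key):
            code, s = key
            if s == "*":
                if side not in ("L", "R"):
                    raise ValueError(f"{self.name}: side L or R required")
                return (code, side)
            return key

        return fix(self.ray_a), fix(self.vertex), fix(self.ray_b)


@dataclass
class SegmentCatalog:
    distances: list = field(default_factory=list)
    angles: list = field(default_factory=list)
    #: AP subgroup membership for nested group means
    subgroups: dict = field(default_factory=dict)

    def distance(self, name: str) -> SegmentDef:
        for d in self.distances:
            if d.name == name:
                return d
        raise KeyError(f"no distance named {name!r} in catalog")

    @property
    def groups(self) -> dict:
        out: dict = {}
        for d in self.distances:
            out.setdefault(d.group, []).append(d.name)
        return out


def default_catalog() -> SegmentCatalog:
    ap = [
        ("AMF-GO", "AMF", "GO"), ("GO-PMF", "GO", "PMF"), ("NO-PMF", "NO", "PMF"),
        ("MMF-PMF", "MMF", "PMF"), ("AMF-MMF", "AMF", "MMF"), ("AMF-NO", "AMF", "NO"),
        ("CP-MP", "CP", "MP"), ("GO-NO", "GO", "NO"), ("CP-LP", "CP", "LP"),
    ]
    si = [("GO-CP", "GO", "CP"), ("GO-LP", "GO", "LP"), ("GO-MP", "GO", "MP")]
    ai = [
        ("GT-CP", "GT", "CP"), ("GT-LP", "GT", "LP"), ("AMF-CP", "AMF", "CP"),
        ("GT-MP", "GT", "MP"), ("AMF-LP", "AMF", "LP"), ("AMF-MP", "AMF", "MP"),
    ]
    ml = ["AMF", "PMF", "CP", "MP", "MMF", "LP", "GO"]

    distances = []
    for name, a, b in ap:
        distances.append(SegmentDef(name, "AP", a, b, SAME_SIDE))
    for name, a, b in si:
        distances.append(SegmentDef(name, "SI", a, b, SAME_SIDE))
    for name, a, b in ai:
        rule = MIDLINE_TO_SIDE if a == "GT" else SAME_SIDE
        distances.append(SegmentDef(name, "AI", a, b, rule))
    for code in ml:
        distances.append(SegmentDef(f"Bi-{code}", "ML", code, code, BILATERAL))

    angles = [
        AngleDef("LP-GO-AMF", ("LP", "*"), ("GO", "*"), ("AMF", "*")),
        AngleDef("Bi-GO-GT", ("GO", "L"), ("GT", "M"), ("GO", "R")),
    ]
    subgroups = {
        "Mandible": ["AMF-GO", "GO-PMF"],
        "Anterior (Body)": ["NO-PMF", "MMF-PMF", "AMF-MMF", "AMF-NO"],
        "Posterior (Ramus)": ["CP-MP", "GO-NO", "CP-LP"],
    }
    return SegmentCatalog(distances, angles, subgroups)


# ----- measurement operations -----------------------------------------------


def inter_marker_distance(
    lset: LandmarkSet, definition: SegmentDef, side: str | None = None
) -> float:
    """Euclidean distance between the definition's endpoints, in cm."""
    (ca, sa), (cb, sb) = definition.endpoints(side)
    try:
        pa, pb = lset.get(ca, sa), lset.get(cb, sb)
    except KeyError as exc:
        raise KeyError(f"{definition.name}: {exc.args[0]}") from None
    d_mm = float(np.linalg.norm(pa - pb))
    if d_mm < 1e-9:
        warnings.warn(
            f"{definition.name}: coincident endpoints (degenerate distance 0)",
            stacklevel=2,
        )
    return d_mm / 10.0


def inter_segment_angle(
    lset: LandmarkSet, definition: AngleDef, side: str | None = None
) -> float:
    """Angle at the definition's vertex between its two rays, in degrees."""
    (ca, sa), (cv, sv), (cb, sb) = definition.resolved(side)
    a, v, b = lset.get(ca, sa), lset.get(cv, sv), lset.get(cb, sb)
    u, w = a - v, b - v
    nu, nw = np.linalg.norm(u), np.linalg.norm(w)
    if nu < 1e-9 or nw < 1e-9:
        raise ValueError(f"{definition.name}: ray endpoint coincides with vertex")
    cosang = np.clip((u @ w) / (nu * nw), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def measure_all(
    lset: LandmarkSet,
    mesh: TriangleMesh | None = None,
    catalog: SegmentCatalog | None = None,
) -> pd.DataFrame:
    """All catalog distances, angles and (if a mesh is given) bone volume.

    Unilateral definitions are computed per side plus a side mean;
    bilateral widths and the midline angle appear once (side "B").
    Returns a long-format frame: subject, timepoint, parameter, group,
    side, value, units.
    """
    catalog = catalog or default_catalog()
    rows = []

    def emit(parameter, group, side, value, units):
        rows.append(
            {
                "subject": lset.subject, "timepoint": lset.timepoint,
                "parameter": parameter, "group": group, "side": side,
                "value": value, "units": units,
            }
        )

    for d in catalog.distances:
        try:
            if d.is_unilateral:
                vl = inter_marker_distance(lset, d, "L")
                vr = inter_marker_distance(lset, d, "R")
                emit(d.name, d.group, "L", vl, "cm")
                emit(d.name, d.group, "R", vr, "cm")
                emit(d.name, d.group, "mean", (vl + vr) / 2.0, "cm")
            else:
                emit(d.name, d.group, "B", inter_marker_distance(lset, d), "cm")
        except KeyError as exc:
            raise KeyError(f"parameter {d.name}: {exc.args[0]}") from None
    for a in catalog.angles:
        if a.is_unilateral:
            vl = inter_segment_angle(lset, a, "L")
            vr = inter_segment_angle(lset, a, "R")
            emit(a.name, "angle", "L", vl, "deg")
            emit(a.name, "angle", "R", vr, "deg")
            emit(a.name, "angle", "mean", (vl + vr) / 2.0, "deg")
        else:
            emit(a.name, "angle", "B", inter_segment_angle(lset, a), "deg")
    if mesh is not None:
        emit("volume", "volume", "B", mesh_volume(mesh), "cm3")
    return pd.DataFrame(rows)
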