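"""Automatic landmark detectors, manual-landmark ingestion, ICC."""

import numpy as np
import pandas as pd
import pytest

from mandigrow.landmarks import (
    LandmarkSet,
    default_rois,
    detect_all,
    detect_condyle_poles,
    detect_coronoid_process,
    detect_genial_tubercle,
    detect_gonion,
    icc_repeatability,
    load_manual_landmarks,
)
from mandigrow.mesh import RegionOfInterest, TriangleMesh, write_mesh
from mandigrow.synthetic import icosphere

from .conftest import make_fillet_wedge


def mirrored(mesh: TriangleMesh) -> TriangleMesh:
    v = mesh.vertices * np.array([1.0, -1.0, 1.0])
    return TriangleMesh(v, mesh.faces[:, ::-1].copy(), validate=False)


# ----- condyle poles --------------------------------------------------------


def test_condyle_poles_ellipsoid():
    cond = icosphere(1.0, 4).scaled([3.0, 7.0, 4.0])
    cond = TriangleMesh(cond.vertices + np.array([0.0, 25.0, 0.0]), cond.faces, validate=False)
    roi = RegionOfInterest.from_predicate(lambda v: np.full(len(v), True))
    lp, mp = detect_condyle_poles(cond, roi, "L")
    assert lp[1] == pytest.approx(32.0, abs=0.05)
    assert mp[1] == pytest.approx(18.0, abs=0.05)


def test_condyle_poles_swap_on_mirror(template):
    rois = default_rois(template)
    lp_l, mp_l = detect_condyle_poles(template, rois["condyle_L"], "L")
    m = mirrored(template)
    rois_m = default_rois(m)
    lp_r, mp_r = detect_condyle_poles(m, rois_m["condyle_R"], "R")
    flip = np.array([1.0, -1.0, 1.0])
    assert np.allclose(lp_r, lp_l * flip, atol=1e-6)
    assert np.allclose(mp_r, mp_l * flip, atol=1e-6)


def test_condyle_midline_roi_warns():
    cond = icosphere(1.0, 3).scaled([3.0, 7.0, 4.0])
    roi = RegionOfInterest.from_predicate(lambda v: np.full(len(v), True))
    with pytest.warns(UserWarning, match="midline"):
        detect_condyle_poles(cond, roi, "L")


# ----- coronoid process -----------------------------------------------------


def _spike_plate(offset_x=0.0, start_index=0):
    """Fan spike on a small plate; returns (verts, faces) with local indexing."""
    k, radius, height = 10, 3.0, 6.0
    ang = np.linspace(0, 2 * np.pi, k, endpoint=False)
    ring = np.column_stack([radius * np.cos(ang) + offset_x, radius * np.sin(ang), np.zeros(k)])
    v = np.vstack([[offset_x, 0.0, height], ring])
    f = [[0, 1 + i, 1 + (i + 1) % k] for i in range(k)]
    return v, np.array(f) + start_index


def test_coronoid_cone_tip():
    v, f = _spike_plate()
    mesh = TriangleMesh(v, f)
    roi = RegionOfInterest.from_predicate(lambda p: np.full(len(p), True))
    cp = detect_coronoid_process(mesh, roi, "L")
    assert np.allclose(cp, [0, 0, 6.0], atol=1e-12)


def test_coronoid_equal_spikes_tie_break():
    v1, f1 = _spike_plate(0.0, 0)
    v2, f2 = _spike_plate(20.0, len(v1))
    mesh = TriangleMesh(np.vstack([v1, v2]), np.vstack([f1, f2]))
    roi = RegionOfInterest.from_predicate(lambda p: np.full(len(p), True))
    cp = detect_coronoid_process(mesh, roi, "L")
    # identical spikes: the lower-index apex (first spike) wins
    assert np.allclose(cp, [0, 0, 6.0], atol=1e-12)


def test_coronoid_flat_roi_fails():
    sph = icosphere(radius=1000.0, subdivisions=3)  # K = 1e-6, below threshold
    roi = RegionOfInterest.from_predicate(lambda p: p[:, 2] > 950.0)
    with pytest.raises(ValueError, match="no protrusion"):
        detect_coronoid_process(sph, roi, "L")


# ----- genial tubercle ------------------------------------------------------


def test_gt_bump_posterior_extreme():
    # hemisphere bump on a plate facing -x
    sph = icosphere(2.0, 3)
    v = sph.vertices + np.array([10.0, 0.0, 0.0])
    mesh = TriangleMesh(v, sph.faces, validate=False)
    roi = RegionOfInterest.from_predicate(lambda p: np.full(len(p), True))
    gt = detect_genial_tubercle(mesh, roi)
    assert gt[0] == pytest.approx(8.0, abs=0.01)


def test_gt_midline_self_mirror(template):
    gt = detect_genial_tubercle(template, default_rois(template)["gt"])
    m = mirrored(template)
    gt_m = detect_genial_tubercle(m, default_rois(m)["gt"])
    assert np.allclose(gt, gt_m * np.array([1.0, -1.0, 1.0]), atol=1e-6)
    assert abs(gt[1]) < 1e-9


# ----- gonion ---------------------------------------------------------------


def test_gonion_fillet_closed_form():
    r = 3.0
    wedge = make_fillet_wedge(r=r)
    ramus = RegionOfInterest.from_predicate(lambda v: (v[:, 0] < 1e-9) & (v[:, 2] > r + 0.5))
    corpus = RegionOfInterest.from_predicate(lambda v: (v[:, 2] < 1e-9) & (v[:, 0] > r + 0.5))
    go = detect_gonion(
        wedge, ramus, corpus, "L",
        ramus_outward=(-1, 0, 0), corpus_outward=(0, 0, -1),
    )
    expect = r * (1 - 1 / np.sqrt(2))
    assert abs(go[0] - expect) <= 1e-3 * r
    assert abs(go[2] - expect) <= 1e-3 * r
    # brute force over the full intersection curve
    from mandigrow.mesh import Plane, bisecting_plane, plane_surface_intersection, support_plane

    a = support_plane(wedge, ramus, (-1, 0, 0), strategy="contact")
    b = support_plane(wedge, corpus, (0, 0, -1))
    c = bisecting_plane(a, b)
    pts = np.concatenate([p.points for p in plane_surface_intersection(wedge, c)])
    d_all = np.sqrt(pts[:, 0] ** 2 + pts[:, 2] ** 2)  # corner line = y axis
    d_go = np.sqrt(go[0] ** 2 + go[2] ** 2)
    assert d_go <= d_all.min() + 1e-9


def test_gonion_mirror_symmetry(template):
    rois = default_rois(template)
    go_l = detect_gonion(template, rois["gonion_ramus_L"], rois["gonion_corpus_L"], "L")
    m = mirrored(template)
    rois_m = default_rois(m)
    go_r = detect_gonion(m, rois_m["gonion_ramus_R"], rois_m["gonion_corpus_R"], "R")
    assert np.allclose(go_r, go_l * np.array([1.0, -1.0, 1.0]), atol=1e-6)


def test_gonion_scaling_equivariance(template):
    s = 2.5
    rois = default_rois(template)
    go = detect_gonion(template, rois["gonion_ramus_L"], rois["gonion_corpus_L"], "L")
    big = template.scaled(s)
    big._cache["anchors"] = template._cache["anchors"]
    rois_b = default_rois(big)
    go_b = detect_gonion(
        big, rois_b["gonion_ramus_L"], rois_b["gonion_corpus_L"], "L", ring_mm=8.0 * s
    )
    assert np.allclose(go_b, go * s, atol=1e-6 * s)


def test_gonion_parallel_planes_fail(unit_cube):
    top = RegionOfInterest.from_predicate(lambda v: v[:, 2] > 10 - 1e-9)
    bottom = RegionOfInterest.from_predicate(lambda v: v[:, 2] < 1e-9)
    with pytest.raises(ValueError, match="parallel"):
        detect_gonion(unit_cube, top, bottom, "L",
                      ramus_outward=(0, 0, 1), corpus_outward=(0, 0, -1))


# ----- full detection + manual ingestion ------------------------------------


def test_detect_all_nine_auto_landmarks(template):
    lset = detect_all(template)
    assert len(lset.entries) == 9
    assert not lset.is_complete  # manual codes still missing


def test_manual_merge_reaches_17(template, tmp_path):
    lset = detect_all(template, subject="S1", timepoint=1)
    truth = template._cache.get("truth")
    from mandigrow.synthetic import _truth_landmarks

    truth = _truth_landmarks(template)
    rows = []
    for code in ("AMF", "MMF", "PMF", "NO"):
        for side in ("L", "R"):
            p = truth.get(code, side)
            rows.append(
                {"subject": "S1", "timepoint": 1, "code": code, "side": side,
                 "x_mm": p[0], "y_mm": p[1], "z_mm": p[2], "source": "manual"}
            )
    csv = tmp_path / "manual.csv"
    pd.DataFrame(rows).to_csv(csv, index=False)
    sets, report = load_manual_landmarks(csv, template)
    assert len(report) == 0
    merged = lset.merge(sets[("S1", 1)])
    assert merged.is_complete
    assert len(merged.entries) == 17


def test_manual_off_surface_rejected(template, tmp_path):
    lo, hi = template.bounds
    far = hi + 5.0  # 5 mm outside the bounding box
    df = pd.DataFrame(
        [{"subject": "S1", "timepoint": 1, "code": "AMF", "side": "L",
          "x_mm": far[0], "y_mm": far[1], "z_mm": far[2], "source": "manual"}]
    )
    csv = tmp_path / "bad.csv"
    df.to_csv(csv, index=False)
    sets, report = load_manual_landmarks(csv, template)
    assert len(sets) == 0
    assert len(report) == 1
    assert "off surface" in report.reason.iloc[0]


def test_manual_duplicate_rows_fail(template, tmp_path):
    row = {"subject": "S1", "timepoint": 1, "code": "AMF", "side": "L",
           "x_mm": 0.0, "y_mm": 0.0, "z_mm": 0.0, "source": "manual"}
    csv = tmp_path / "dup.csv"
    pd.DataFrame([row, row]).to_csv(csv, index=False)
    with pytest.raises(ValueError, match="duplicate.*AMF"):
        load_manual_landmarks(csv, template)


def test_manual_unknown_code_reported(template, tmp_path):
    df = pd.DataFrame(
        [{"subject": "S1", "timepoint": 1, "code": "XX", "side": "L",
          "x_mm": 0.0, "y_mm": 0.0, "z_mm": 0.0, "source": "manual"}]
    )
    csv = tmp_path / "unk.csv"
    df.to_csv(csv, index=False)
    sets, report = load_manual_landmarks(csv, template)
    assert "unknown code" in report.reason.iloc[0]


def test_detectors_deterministic(template):
    a = detect_all(template)
    b = detect_all(template)
    for key in a.entries:
        assert np.array_equal(a.entries[key].point, b.entries[key].point)


def test_noise_free_recovery_small_study(small_study):
    """Auto-detected landmarks track transported ground truth within 0.5 mm."""
    for subj in small_study.subjects:
        for t in small_study.timepoints:
            mesh = small_study.mesh(subj, t)
            det = detect_all(mesh, subject=subj, timepoint=t)
            truth = small_study.landmarks_truth(subj, t)
            for key, lm in det.entries.items():
                err = np.linalg.norm(lm.point - truth.get(*key))
                assert err <= 0.5, f"{key} at {subj} T{t}: {err:.2f} mm"


# ----- ICC ------------------------------------------------------------------


def test_icc_identical_repeats_is_one():
    y = np.tile(np.array([[1.0], [2.0], [3.0], [4.0]]), (1, 3))
    assert icc_repeatability(y) == pytest.approx(1.0, abs=1e-12)


def test_icc_pure_noise_near_zero():
    rng = np.random.default_rng(11)
    y = 5.0 + rng.normal(0, 1.0, size=(200, 4))  # no between-subject signal
    assert icc_repeatability(y) <= 0.05


def test_icc_fixture_matches_mean_squares_oracle():
    rng = np.random.default_rng(12)
    y = rng.normal(size=(5, 3)) + rng.normal(size=(5, 1)) * 2.0
    icc = icc_repeatability(y)
    # hand-computed two-way ANOVA mean squares
    n, k = y.shape
    grand = y.mean()
    msr = k * ((y.mean(1) - grand) ** 2).sum() / (n - 1)
    msc = n * ((y.mean(0) - grand) ** 2).sum() / (k - 1)
    sse = ((y - y.mean(1, keepdims=True) - y.mean(0, keepdims=True) + grand) ** 2).sum()
    mse = sse / ((n - 1) * (k - 1))
    expect = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    assert icc == pytest.approx(expect, abs=1e-12)
    # independent library route
    import pingouin as pg

    df = pd.DataFrame(
        {"subject": np.repeat(np.arange(n), k), "rater": np.tile(np.arange(k), n),
         "score": y.ravel()}
    )
    tbl = pg.intraclass_corr(df, targets="subject", raters="rater", ratings="score")
    # two-way random, absolute agreement, single rater
    icc2 = float(tbl.loc[tbl.Type.str.contains("A,1|ICC2$"), "ICC"].iloc[0])
    assert icc == pytest.approx(icc2, abs=1e-9)


def test_icc_rejects_missing_cells():
    y = np.array([[1.0, 2.0], [3.0, np.nan]])
    with pytest.raises(ValueError, match="missing"):
        icc_repeatability(y)
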