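"""Podosome detection, morphometrics, tracking, perturbation response."""

import numpy as np
import pytest

from mtflim.podosomes import (
    PodosomeRecord,
    Track,
    depletion_metrics,
    detect_clusters,
    detect_podosomes,
    link_tracks,
    normalize_by_brightest,
    perturbation_response,
    ring_tension_stats,
)


def _paint_cores(shape, centers, radius_um=0.3, px=0.1, bg=100.0, core=5.0):
    img = np.full(shape, bg)
    rr, cc = np.indices(shape)
    for ctr in centers:
        d = np.hypot(rr - ctr[0], cc - ctr[1]) * px
        img[d <= radius_um] = core
    return img


def test_uniform_image_yields_no_podosomes():
    img = np.full((50, 50), 100.0)
    assert detect_podosomes(img, 100.0) == []


def test_noiseless_detection_exact_recall_and_centroids():
    centers = [(15, 15), (15, 45), (45, 15), (45, 45), (30, 30)]
    img = _paint_cores((60, 60), centers)
    recs = detect_podosomes(img, 100.0, pixel_size=0.1)
    assert len(recs) == 5
    for rec in recs:
        err = min(
            np.hypot(rec.centroid[0] - c[0], rec.centroid[1] - c[1]) for c in centers
        )
        assert err <= 1.0
        assert rec.core_radius == pytest.approx(0.3, abs=0.05)
        assert not rec.ring_mask[rec.core_mask].any()  # ring disjoint from core


def test_watershed_splits_touching_cores():
    img = _paint_cores((60, 60), [(30, 26), (30, 34)])
    recs = detect_podosomes(img, 100.0, pixel_size=0.1)
    assert len(recs) == 2
    cols = sorted(r.centroid[1] for r in recs)
    assert cols[0] == pytest.approx(26, abs=1.5)
    assert cols[1] == pytest.approx(34, abs=1.5)


def test_background_must_be_positive():
    with pytest.raises(ValueError, match="background"):
        detect_podosomes(np.ones((10, 10)), 0.0)


def test_depletion_percent_arithmetic():
    img = _paint_cores((40, 40), [(20, 20)], core=30.0)
    rec = detect_podosomes(img, 100.0, pixel_size=0.1)[0]
    depletion, radius = depletion_metrics(rec, img, 100.0, pixel_size=0.1)
    assert depletion == pytest.approx(70.0, abs=1e-9)
    img_full = _paint_cores((40, 40), [(20, 20)], core=0.0)
    rec2 = detect_podosomes(img_full, 100.0, pixel_size=0.1)[0]
    assert depletion_metrics(rec2, img_full, 100.0)[0] == pytest.approx(100.0)
    # core at background level: zero depletion
    img_none = np.full((40, 40), 100.0)
    assert depletion_metrics(rec2, img_none, 100.0)[0] == pytest.approx(0.0)


def test_deeper_exclusion_increases_measured_depletion():
    """Monotonicity across a fixture ladder of core intensities."""
    depths = []
    for core_val in (60.0, 40.0, 20.0, 5.0):
        img = _paint_cores((40, 40), [(20, 20)], core=core_val)
        rec = detect_podosomes(img, 100.0, pixel_size=0.1)[0]
        depths.append(rec.depletion_pct)
    assert all(np.diff(depths) > 0)


def test_ring_stats_means_and_cell_average():
    shape = (30, 30)
    F = np.full(shape, 0.10)
    rho = np.ones(shape)
    valid = np.ones(shape, bool)
    rings = [np.zeros(shape, bool), np.zeros(shape, bool)]
    rings[0][5:10, 5:10] = True
    rings[1][20:25, 20:25] = True
    F[rings[1]] = 0.12
    F[rings[0]] = 0.08
    recs = [
        PodosomeRecord(id=i, frame=0, centroid=(7 + 13 * i, 7 + 13 * i),
                       core_radius=0.3, depletion_pct=80.0,
                       core_mask=np.zeros(shape, bool), ring_mask=rings[i])
        for i in range(2)
    ]
    df, summary = ring_tension_stats(recs, F, rho, valid)
    assert df["ring_mean_F"].tolist() == pytest.approx([0.08, 0.12])
    assert summary["cell_mean_F"] == pytest.approx(0.10)


def test_ring_stats_flags_starved_podosomes():
    shape = (20, 20)
    ring = np.zeros(shape, bool)
    ring[0, 0] = True
    rec = PodosomeRecord(id=0, frame=0, centroid=(1, 1), core_radius=0.3,
                         depletion_pct=50.0, core_mask=np.zeros(shape, bool),
                         ring_mask=ring)
    with pytest.warns(UserWarning):
        df, summary = ring_tension_stats([rec], np.ones(shape) * 0.1,
                                         np.ones(shape), np.zeros(shape, bool))
    assert df["excluded"].all()
    assert summary["n_podosomes"] == 0


def test_cluster_detection_excludes_podosome_neighborhoods():
    shape = (80, 80)
    rho = np.ones(shape)
    rr, cc = np.indices(shape)
    cluster_centers = [(15, 15), (15, 60), (60, 15)]
    for ctr in cluster_centers:
        rho[np.hypot(rr - ctr[0], cc - ctr[1]) * 0.1 <= 0.5] = 2.0
    F = np.zeros(shape)
    pod = PodosomeRecord(id=0, frame=0, centroid=(60, 60), core_radius=0.3,
                         depletion_pct=80.0, core_mask=np.zeros(shape, bool),
                         ring_mask=np.zeros(shape, bool))
    rho[np.hypot(rr - 60, cc - 60) * 0.1 <= 0.5] = 2.0  # bright but near podosome
    clus = detect_clusters(rho, [pod], background=1.0, pixel_size=0.1,
                           F_map=F, rho_map=rho)
    assert len(clus) == 3
    for c in clus:
        assert c.mean_density == pytest.approx(2.0)
        assert c.mean_F == pytest.approx(0.0)
    assert detect_clusters(np.ones(shape), [], background=1.0) == []


def _rec(frame, centroid):
    shape = (50, 50)
    return PodosomeRecord(id=0, frame=frame, centroid=centroid, core_radius=0.3,
                          depletion_pct=80.0, core_mask=np.zeros(shape, bool),
                          ring_mask=np.zeros(shape, bool))


def test_track_stationary_podosome():
    frames = [[_rec(f, (20.0, 20.0))] for f in range(3)]
    tracks = link_tracks(frames, gating_radius=0.5, pixel_size=0.1)
    assert len(tracks) == 1
    assert len(tracks[0].records) == 3
    assert tracks[0].lineage == "de-novo"


def test_track_identities_preserved_within_gating():
    frames = [
        [_rec(0, (20.0, 20.0)), _rec(0, (20.0, 40.0))],
        [_rec(1, (21.0, 20.0)), _rec(1, (21.0, 40.0))],
    ]
    tracks = link_tracks(frames, gating_radius=0.5, pixel_size=0.1)
    assert len(tracks) == 2
    for tr in tracks:
        cols = [r.centroid[1] for r in tr.records]
        assert max(cols) - min(cols) < 1.0  # no identity swap


def test_missed_detection_terminates_track():
    frames = [[_rec(0, (20.0, 20.0))], [], [_rec(2, (20.0, 20.0))]]
    tracks = link_tracks(frames, gating_radius=0.5, pixel_size=0.1)
    assert len(tracks) == 2


def test_split_tagging():
    frames = [
        [_rec(0, (20.0, 20.0))],
        [_rec(1, (20.0, 20.0)), _rec(1, (20.0, 28.0))],
    ]
    tracks = link_tracks(frames, gating_radius=0.5, pixel_size=0.1,
                         split_radius=1.0)
    lineages = sorted(t.lineage for t in tracks)
    assert lineages == ["de-novo", "split"]


def _track_with_radii(tid, centroid, r_before, r_after):
    recs = []
    for f, r in ((0, r_before), (1, r_after)):
        rec = _rec(f, centroid)
        rec.core_radius = r
        recs.append(rec)
    return Track(id=tid, records=recs, birth_frame=0, death_frame=1)


def test_perturbation_response_percent_change_and_grouping():
    roi = np.zeros((50, 50), bool)
    roi[10:30, 10:30] = True
    tracks = [
        _track_with_radii(0, (20.0, 20.0), 0.40, 0.30),  # proximal, -25%
        _track_with_radii(1, (40.0, 40.0), 0.40, 0.40),  # distal, 0%
    ]
    df, summary = perturbation_response(tracks, roi, t_event=0.5,
                                        frame_times=[0.0, 1.0])
    prox = df[df["group"] == "proximal"]["pct_radius_change"].iloc[0]
    assert prox == pytest.approx(-25.0)
    assert summary["distal"] == pytest.approx(0.0)
    assert summary["proximal"] < summary["distal"]


def test_perturbation_response_mad_outlier_exclusion():
    roi = np.zeros((50, 50), bool)
    roi[:25] = True
    tracks = [
        _track_with_radii(i, (10.0, 10.0 + i), 0.40, 0.40 * (1 - 0.10 - 0.002 * i))
        for i in range(8)
    ]
    tracks.append(_track_with_radii(99, (10.0, 30.0), 0.40, 0.04))  # -90% outlier
    df, _ = perturbation_response(tracks, roi, t_event=0.5, frame_times=[0.0, 1.0])
    assert 99 not in df["track_id"].tolist()
    assert len(df) == 8


def test_track_absent_on_one_side_excluded():
    roi = np.ones((50, 50), bool)
    only_pre = Track(id=0, records=[_rec(0, (20.0, 20.0))], birth_frame=0,
                     death_frame=0)
    df, summary = perturbation_response([only_pre], roi, t_event=0.5,
                                        frame_times=[0.0, 1.0])
    assert len(df) == 0


def test_normalize_by_brightest_per_cell():
    vals = np.array([2.0, 4.0, 1.0, 5.0])
    cells = np.array([0, 0, 1, 1])
    out = normalize_by_brightest(vals, cells)
    assert out.tolist() == [0.5, 1.0, 0.2, 1.0]
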