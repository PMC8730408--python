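import numpy as np
import pandas as pd
import pytest

from mavessel.geometry import build_ma_channel
from mavessel.transport import (CellTrack, PassageRecord, REGION_BODY,
                                REGION_PARENT, detect_events,
                                entry_probability, perfusion_map,
                                residence_summary, tracks_from_dataframe)

GEOM = build_ma_channel(3.0, length=30.0)


def make_track(regions, xs=None, cell_id=0, cell_type=3, dt=1.0):
    n = len(regions)
    if xs is None:
        xs = np.zeros(n)
    xyz = np.column_stack([xs, np.full(n, 2.5), np.full(n, 5.0)])
    return CellTrack(cell_id=cell_id, cell_type=cell_type,
                     frames=np.arange(n), t_model=np.arange(n) * dt,
                     xyz=xyz, region=np.asarray(regions))


def drift_x(n, speed):
    return (np.arange(n) * speed) % GEOM.L


# -- event detection --------------------------------------------------------

def test_traversal_without_entry():
    n = 80
    track = make_track([REGION_PARENT] * n, xs=drift_x(n, 0.5))
    recs = detect_events(track, GEOM, frame_dt_s=0.01)
    assert len(recs) == 1
    assert not recs[0].entered


def test_residence_time_from_body_run():
    regions = [REGION_PARENT] * 10 + [REGION_BODY] * 50 + [REGION_PARENT] * 10
    track = make_track(regions)
    recs = detect_events(track, GEOM, frame_dt_s=0.005)
    entered = [r for r in recs if r.entered]
    assert len(entered) == 1
    assert entered[0].residence_s == pytest.approx(0.25)
    assert not entered[0].censored


def test_single_frame_blip_debounced():
    regions = [REGION_PARENT] * 10 + [REGION_BODY] + [REGION_PARENT] * 10
    track = make_track(regions)
    recs = detect_events(track, GEOM, frame_dt_s=0.01, debounce=3)
    assert not any(r.entered for r in recs)


def test_cell_seeded_inside_ma_excluded():
    regions = [REGION_BODY] * 30 + [REGION_PARENT] * 10
    track = make_track(regions)
    assert detect_events(track, GEOM, frame_dt_s=0.01) == []


def test_censored_when_still_inside_at_end():
    regions = [REGION_PARENT] * 10 + [REGION_BODY] * 20
    track = make_track(regions)
    recs = detect_events(track, GEOM, frame_dt_s=0.01)
    entered = [r for r in recs if r.entered]
    assert len(entered) == 1
    assert entered[0].censored
    assert entered[0].t_exit_s is None


def test_short_track_yields_nothing():
    track = make_track([REGION_PARENT])
    assert detect_events(track, GEOM, frame_dt_s=0.01) == []


def test_passage_count_from_multiple_circuits():
    n = 200
    speed = GEOM.L / 60.0  # ~3.3 circuits
    track = make_track([REGION_PARENT] * n, xs=drift_x(n, speed))
    recs = detect_events(track, GEOM, frame_dt_s=0.01)
    assert len(recs) == 3


# -- entry probability ------------------------------------------------------

def _records(entries, passages, cell_type=3):
    recs = []
    for k in range(passages):
        recs.append(PassageRecord(cell_id=k % 4, cell_type=cell_type,
                                  passage_index=k, entered=k < entries))
    return recs


@pytest.mark.parametrize("entries,passages,expected",
                         [(3, 12, 0.25), (0, 7, 0.0), (12, 12, 1.0)])
def test_entry_probability_ratio(entries, passages, expected):
    p, ci = entry_probability(_records(entries, passages), 3)
    assert p == pytest.approx(expected)
    assert ci[0] <= p <= ci[1]


def test_entry_probability_no_passages_rejected():
    with pytest.raises(ValueError):
        entry_probability([], 3)


def test_entry_probability_invariant_to_relabeling_and_order(rng):
    recs = _records(5, 20)
    p1, _ = entry_probability(recs, 3)
    shuffled = list(recs)
    rng.shuffle(shuffled)
    relabeled = [PassageRecord(cell_id=r.cell_id + 100,
                               cell_type=r.cell_type,
                               passage_index=r.passage_index,
                               entered=r.entered) for r in shuffled]
    p2, _ = entry_probability(relabeled, 3)
    assert p1 == p2


# -- residence summary ------------------------------------------------------

def _entered(cell_id, t_in, t_out, cell_type=3, censored=False):
    return PassageRecord(cell_id=cell_id, cell_type=cell_type,
                         passage_index=0, entered=True, t_enter_s=t_in,
                         t_exit_s=None if censored else t_out,
                         censored=censored)


def test_residence_mean():
    recs = [_entered(0, 0.0, 0.25), _entered(1, 0.0, 0.35),
            _entered(2, 0.0, 0.30)]
    m = residence_summary(recs, 3)
    assert m.residence_mean_s == pytest.approx(0.30)
    assert m.n_censored == 0


def test_censored_events_reported_separately():
    recs = [_entered(0, 0.0, 0.25), _entered(1, 0.0, None, censored=True)]
    m = residence_summary(recs, 3)
    assert m.residence_mean_s == pytest.approx(0.25)
    assert m.n_censored == 1


def test_all_censored_flagged():
    recs = [_entered(0, 0.0, None, censored=True)]
    m = residence_summary(recs, 3)
    assert m.censored_only
    assert m.residence_mean_s is None


def test_bootstrap_ci_covers_exponential_mean():
    """The bootstrap CI for the mean covers the true mean in >= 90% of
    replications of exponential samples."""
    rng = np.random.default_rng(7)
    true_mean = 0.3
    hits = 0
    n_rep = 100
    for rep in range(n_rep):
        times = rng.exponential(true_mean, size=25)
        recs = [_entered(k, 0.0, t) for k, t in enumerate(times)]
        m = residence_summary(recs, 3, n_boot=400, seed=rep)
        lo, hi = m.residence_ci
        hits += lo <= true_mean <= hi
    assert hits >= 90


# -- perfusion map ----------------------------------------------------------

def test_no_body_visits_zero_perfusion():
    n = 50
    tracks = [make_track([REGION_PARENT] * n, xs=drift_x(n, 0.4),
                         cell_type=2)]
    _, frac = perfusion_map(tracks, GEOM)
    assert frac == 0.0


def test_uniform_body_fill_approaches_full_perfusion(rng):
    c, rho = GEOM.body_center, GEOM.body_radius
    pts = c + rng.uniform(-1, 1, (30_000, 3)) * rho
    inside = GEOM.classify_points(pts) == 1
    pts = pts[inside]
    track = CellTrack(cell_id=0, cell_type=2,
                      frames=np.arange(len(pts) + 1),
                      t_model=np.arange(len(pts) + 1, dtype=float),
                      xyz=np.vstack([[GEOM.L / 2, 2.5, 5.0], pts]),
                      region=np.concatenate([[REGION_PARENT],
                                             np.ones(len(pts), dtype=int)]))
    _, frac = perfusion_map([track], GEOM)
    assert frac > 0.95


def test_voxel_larger_than_body_rejected():
    with pytest.raises(ValueError):
        perfusion_map([], GEOM, voxel_um=2 * GEOM.R1)


# -- track round trip -------------------------------------------------------

def test_tracks_from_dataframe_round_trip():
    df = pd.DataFrame({
        "frame": [0, 1, 2, 0, 1, 2],
        "t_model": [0.0, 1.0, 2.0, 0.0, 1.0, 2.0],
        "cell": [0, 0, 0, 1, 1, 1],
        "cell_type": [2, 2, 2, 3, 3, 3],
        "x": [1.0, 2.0, 3.0] * 2, "y": [2.5] * 6, "z": [5.0] * 6,
        "region": [0, 0, 0, 0, 1, 1],
    })
    tracks = tracks_from_dataframe(df)
    assert len(tracks) == 2
    assert tracks[1].cell_type == 3
    assert tracks[1].region.tolist() == [0, 1, 1]


def test_metric_stable_under_frame_refinement():
    """Halving the frame interval changes the residence time by less than
    one coarse frame interval."""
    coarse = [REGION_PARENT] * 10 + [REGION_BODY] * 40 + [REGION_PARENT] * 10
    fine = [r for r in coarse for _ in range(2)]
    rc = detect_events(make_track(coarse), GEOM, frame_dt_s=0.01)
    rf = detect_events(make_track(fine), GEOM, frame_dt_s=0.005)
    tc = [r.residence_s for r in rc if r.entered][0]
    tf = [r.residence_s for r in rf if r.entered][0]
    assert abs(tc - tf) < 0.01
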