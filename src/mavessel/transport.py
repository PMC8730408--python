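"""Transport statistics from cell tracks.

Two metrics quantify thrombosis-prone conditions inside a microaneurysm:

* **entry probability** -- the number of times cells of a type travelled
  into the MA body divided by their total number of passages through the
  MA-bearing channel segment (the periodic domain makes each recirculation
  a new passage);
* **residence time** -- the physical time between a cell's (debounced)
  entry into the MA body lumen and its exit.  Cells still inside when the
  run ends are censored and reported separately, never mixed into means.

Cells seeded inside the MA at t = 0 are excluded from both metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import MAChannelGeometry

#: region codes in track tables
REGION_PARENT, REGION_BODY = 0, 1


@dataclass
class CellTrack:
    """Per-frame center-of-mass trajectory of one cell."""

    cell_id: int
    cell_type: int
    frames: np.ndarray       # strictly increasing frame indices
    t_model: np.ndarray
    xyz: np.ndarray          # (n, 3)
    region: np.ndarray       # 0 parent, 1 ma_body

    def __post_init__(self) -> None:
        if len(self.frames) > 1 and not np.all(np.diff(self.frames) > 0):
            raise ValueError("track frames must be strictly increasing")


@dataclass
class PassageRecord:
    """One traversal of the channel by one cell."""

    cell_id: int
    cell_type: int
    passage_index: int
    entered: bool
    t_enter_s: float | None = None
    t_exit_s: float | None = None
    censored: bool = False

    @property
    def residence_s(self) -> float | None:
        if self.t_enter_s is None or self.t_exit_s is None:
            return None
        return self.t_exit_s - self.t_enter_s


@dataclass
class TransportMetrics:
    """Entry probability and residence-time summary for one cell type."""

    cell_type: int
    n_passages: int
    n_entries: int
    n_censored: int
    entry_probability: float
    entry_ci: tuple[float, float]
    residence_times_s: np.ndarray
    residence_mean_s: float | None
    residence_std_s: float | None
    residence_ci: tuple[float, float] | None
    censored_only: bool = False


def tracks_from_dataframe(df: pd.DataFrame) -> list[CellTrack]:
    """Split a driver track table into per-cell tracks."""
    out = []
    for cell, g in df.groupby("cell"):
        g = g.sort_values("frame")
        out.append(CellTrack(
            cell_id=int(cell), cell_type=int(g.cell_type.iloc[0]),
            frames=g.frame.to_numpy(), t_model=g.t_model.to_numpy(),
            xyz=g[["x", "y", "z"]].to_numpy(),
            region=g.region.to_numpy()))
    return out


def _debounced_body_runs(region: np.ndarray, m: int) -> list[tuple[int, int]]:
    """Maximal index runs classified ma_body lasting >= m frames."""
    runs = []
    start = None
    for k, r in enumerate(region):
        if r == REGION_BODY and start is None:
            start = k
        elif r != REGION_BODY and start is not None:
            if k - start >= m:
                runs.append((start, k))
            start = None
    if start is not None and len(region) - start >= m:
        runs.append((start, len(region)))
    return runs


def detect_events(track: CellTrack, geom: MAChannelGeometry,
                  frame_dt_s: float, debounce: int = 3
                  ) -> list[PassageRecord]:
    """Passage and MA-entry events for one cell track.

    A passage is one traversal of the neck-adjacent channel segment,
    counted as a crossing of the neck-center plane by the cell's unwrapped
    trajectory (one per periodic image; the odometer freezes during body
    dwell).  Entry requires the center of mass to
    classify as ``ma_body`` for at least ``debounce`` consecutive frames;
    the residence time spans the maximal body-classified run.  Cells whose
    first frame is already inside the MA (seeded there) yield no records.
    """
    n = len(track.frames)
    if n < 2:
        return []
    if track.region[0] == REGION_BODY:
        return []  # seeded inside the MA: excluded from the statistics
    x = track.xyz[:, 0]
    # unwrap the periodic x coordinate, freezing the odometer while the
    # cell dwells inside the body (its wobble there is not travel)
    dx = np.diff(x)
    dx -= geom.L * np.round(dx / geom.L)
    inside = track.region == REGION_BODY
    progress = np.where(inside, 0.0, np.concatenate([[0.0], dx]))
    odometer = np.cumsum(progress)
    # a passage is one traversal of the neck-adjacent channel segment:
    # count crossings of the neck-center plane (x = body center) by the
    # unwrapped trajectory, one per periodic image
    xc = geom.body_center[0]
    total = odometer[-1]
    if total >= 0:
        t0 = (xc - x[0]) % geom.L
        n_cross = int(np.floor((total - t0) / geom.L)) + 1 \
            if total >= t0 > 0 else (1 if t0 == 0 and total > 0 else 0)
        if t0 == 0 and total > 0:
            n_cross = int(np.floor(total / geom.L)) + 1
    else:
        t0 = (x[0] - xc) % geom.L
        n_cross = int(np.floor((-total - t0) / geom.L)) + 1 \
            if -total >= t0 > 0 else 0
    n_passages = max(n_cross, 0)

    runs = _debounced_body_runs(track.region, debounce)
    records: list[PassageRecord] = []
    idx = 0
    for start, stop in runs:
        censored = stop >= n and track.region[-1] == REGION_BODY
        body_frames = stop - start
        t_enter = float(track.frames[start]) * frame_dt_s
        rec = PassageRecord(
            cell_id=track.cell_id, cell_type=track.cell_type,
            passage_index=idx, entered=True,
            t_enter_s=t_enter,
            t_exit_s=None if censored
            else t_enter + body_frames * frame_dt_s,
            censored=censored)
        records.append(rec)
        idx += 1
    # passages that did not enter (every entry itself counts as reaching
    # the neck, so the total can never fall below the entry count)
    n_plain = max(n_passages - len(records), 0)
    # a cell that entered at least once counts its entry as one passage;
    # if it never completed a full traversal but entered, the entry still
    # stands on its own
    for _ in range(n_plain):
        records.append(PassageRecord(
            cell_id=track.cell_id, cell_type=track.cell_type,
            passage_index=idx, entered=False))
        idx += 1
    return records


def entry_probability(records: list[PassageRecord], cell_type: int,
                      n_boot: int = 2000, seed: int = 0
                      ) -> tuple[float, tuple[float, float]]:
    """Entries / passages for one cell type, with a nonparametric
    bootstrap confidence interval over cells."""
    recs = [r for r in records if r.cell_type == cell_type]
    n_pass = len(recs)
    if n_pass == 0:
        raise ValueError("no passages: entry probability undefined")
    n_ent = sum(r.entered for r in recs)
    p = n_ent / n_pass
    # bootstrap over cells
    cells = sorted({r.cell_id for r in recs})
    per_cell = {c: [r.entered for r in recs if r.cell_id == c]
                for c in cells}
    rng = np.random.default_rng(seed)
    stats = []
    for _ in range(n_boot):
        sample = rng.choice(cells, size=len(cells), replace=True)
        flat = [e for c in sample for e in per_cell[c]]
        if flat:
            stats.append(np.mean(flat))
    if stats:
        lo, hi = np.percentile(stats, [2.5, 97.5])
    else:
        lo = hi = p
    return p, (float(lo), float(hi))


def residence_summary(records: list[PassageRecord], cell_type: int,
                      n_boot: int = 2000, seed: int = 0) -> TransportMetrics:
    """Residence-time summary over completed (uncensored) entries."""
    recs = [r for r in records if r.cell_type == cell_type]
    entered = [r for r in recs if r.entered]
    complete = [r for r in entered if not r.censored]
    censored = [r for r in entered if r.censored]
    times = np.array([r.residence_s for r in complete])
    p, ci = entry_probability(records, cell_type, n_boot=n_boot, seed=seed) \
        if recs else (float("nan"), (float("nan"), float("nan")))
    if len(complete) == 0:
        if not entered:
            mean = std = None
            rci = None
            conly = False
        else:
            mean = std = None
            rci = None
            conly = True
        return TransportMetrics(
            cell_type=cell_type, n_passages=len(recs),
            n_entries=len(entered), n_censored=len(censored),
            entry_probability=p, entry_ci=ci,
            residence_times_s=times, residence_mean_s=mean,
            residence_std_s=std, residence_ci=rci, censored_only=conly)
    rng = np.random.default_rng(seed + 1)
    boots = [float(np.mean(rng.choice(times, size=len(times), replace=True)))
             for _ in range(n_boot)]
    rci = tuple(float(v) for v in np.percentile(boots, [2.5, 97.5]))
    return TransportMetrics(
        cell_type=cell_type, n_passages=len(recs), n_entries=len(entered),
        n_censored=len(censored), entry_probability=p, entry_ci=ci,
        residence_times_s=times,
        residence_mean_s=float(times.mean()),
        residence_std_s=float(times.std(ddof=1)) if len(times) > 1 else 0.0,
        residence_ci=rci)


def perfusion_map(tracks: list[CellTrack], geom: MAChannelGeometry,
                  voxel_um: float = 2.0) -> tuple[np.ndarray, float]:
    """Occupancy of the MA body by parent-seeded cell centers, on a voxel
    grid; the perfused fraction is occupied body voxels over all body
    voxels.  (An operational summary of how far inflowing blood reaches
    into the body lumen.)"""
    if voxel_um > geom.R1:
        raise ValueError("voxel size exceeds the body diameter")
    c = geom.body_center
    rho = geom.body_radius
    lo = c - rho
    dims = np.maximum(np.ceil(2 * rho / voxel_um).astype(int), 1)
    if np.isscalar(dims):
        dims = np.array([dims] * 3)
    grid = np.zeros((int(dims[0]), int(dims[1]), int(dims[2])),
                    dtype=np.int64)
    # which voxels lie inside the body lumen
    axes = [lo[ax] + voxel_um * (np.arange(grid.shape[ax]) + 0.5)
            for ax in range(3)]
    centers = np.stack(np.meshgrid(*axes, indexing="ij"), -1)
    flat = centers.reshape(-1, 3)
    body = (geom.classify_points(flat) == 1).reshape(grid.shape)
    for tr in tracks:
        if tr.region[0] == REGION_BODY:
            continue  # perfusion = reach of parent-seeded cells
        pts = tr.xyz[tr.region == REGION_BODY]
        if not len(pts):
            continue
        ijk = np.floor((pts - lo) / voxel_um).astype(int)
        ok = np.all((ijk >= 0) & (ijk < np.array(grid.shape)), axis=1)
        for i, j, k in ijk[ok]:
            grid[i, j, k] += 1
    n_body = int(body.sum())
    if n_body == 0:
        return grid, 0.0
    frac = float(((grid > 0) & body).sum() / n_body)
    return grid, frac


def analyze_run(tracks_df: pd.DataFrame, geom: MAChannelGeometry,
                frame_dt_s: float, debounce: int = 3,
                seed: int = 0) -> dict:
    """All transport metrics for one run's track table."""
    tracks = tracks_from_dataframe(tracks_df)
    records: list[PassageRecord] = []
    for tr in tracks:
        records.extend(detect_events(tr, geom, frame_dt_s,
                                     debounce=debounce))
    out: dict = {"records": records}
    for label, ctype in (("platelet", 3), ("rbc", 2)):
        recs = [r for r in records if r.cell_type == ctype]
        if recs:
            out[label] = residence_summary(records, ctype, seed=seed)
    _, frac = perfusion_map(tracks, geom)
    out["perfused_fraction"] = frac
    return out
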