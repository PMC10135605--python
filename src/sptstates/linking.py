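"""Frame-to-frame linking of localizations and step-trace extraction.

Linking is a per-frame globally optimal assignment (Hungarian algorithm on
squared displacement) between live tracks and new localizations, with no
link allowed beyond ``search_range_um``. Tracks unseen for up to ``memory``
frames stay live and may resume their id; steps that span such gaps are
excluded from step traces rather than rescaled, so every retained step has
the same lag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from sptstates.config import DEFAULT_FRAME_INTERVAL_S

logger = logging.getLogger(__name__)


@dataclass
class StepTrace:
    """Uniform-lag step lengths of one trajectory."""

    particle_id: int
    r: np.ndarray  # um, lag of one frame
    t: float  # s


def link(
    localizations: pd.DataFrame,
    search_range_um: float = 0.8,
    memory: int = 1,
) -> pd.DataFrame:
    """Connect per-frame localizations into trajectories.

    Parameters
    ----------
    localizations:
        DataFrame with columns ``frame``, ``x_um``, ``y_um`` (extra columns
        are carried through). Row order within a frame does not affect the
        result.
    search_range_um:
        Maximum displacement allowed for a single link, um.
    memory:
        Number of consecutive frames a particle may go undetected and still
        resume its id.

    Returns
    -------
    The input rows with a ``particle_id`` column, sorted by particle and
    frame.
    """
    required = {"frame", "x_um", "y_um"}
    if not required <= set(localizations.columns):
        raise ValueError(f"localizations must have columns {sorted(required)}")
    df = localizations.sort_values(["frame", "x_um", "y_um"], kind="mergesort")
    df = df.reset_index(drop=True)

    next_id = 0
    # live tracks: id -> (x, y, last_frame)
    live: dict[int, tuple[float, float, int]] = {}
    ids = np.full(len(df), -1, dtype=np.int64)

    for f, sub in df.groupby("frame", sort=True):
        f = int(f)
        live = {i: v for i, v in live.items() if f - v[2] <= memory + 1}
        pts = sub[["x_um", "y_um"]].to_numpy()
        idx = sub.index.to_numpy()
        track_ids = sorted(live)  # deterministic: lowest id first
        if track_ids and len(pts):
            prev = np.array([live[i][:2] for i in track_ids])
            d = np.linalg.norm(prev[:, None, :] - pts[None, :, :], axis=2)
            cost = np.where(d <= search_range_um, d**2, 1e12)
            rows, cols = linear_sum_assignment(cost)
            assigned = set()
            for ri, ci in zip(rows, cols):
                if d[ri, ci] <= search_range_um:
                    tid = track_ids[ri]
                    ids[idx[ci]] = tid
                    live[tid] = (pts[ci, 0], pts[ci, 1], f)
                    assigned.add(ci)
        else:
            assigned = set()
        for ci in range(len(pts)):
            if ci not in assigned:
                ids[idx[ci]] = next_id
                live[next_id] = (pts[ci, 0], pts[ci, 1], f)
                next_id += 1

    out = df.copy()
    out["particle_id"] = ids
    return out.sort_values(["particle_id", "frame"]).reset_index(drop=True)


def filter_tracks(trajectories: pd.DataFrame, min_steps: int = 10) -> pd.DataFrame:
    """Keep trajectories with at least ``min_steps`` steps (min_steps+1 rows)."""
    sizes = trajectories.groupby("particle_id")["frame"].size()
    keep = sizes[sizes >= min_steps + 1].index
    n_in, n_out = len(sizes), len(keep)
    logger.info("filter_tracks: kept %d of %d tracks (min_steps=%d)", n_out, n_in, min_steps)
    if n_out == 0:
        logger.warning("filter_tracks: no tracks survive min_steps=%d", min_steps)
    return trajectories[trajectories["particle_id"].isin(keep)].reset_index(drop=True)


def to_steps(
    trajectory: pd.DataFrame, frame_interval: float = DEFAULT_FRAME_INTERVAL_S
) -> StepTrace:
    """Euclidean step lengths at lag one frame for a single trajectory.

    Displacements across detection gaps (frame difference > 1) are dropped,
    not rescaled, so the step trace has a uniform lag.
    """
    traj = trajectory.sort_values("frame")
    pid = int(traj["particle_id"].iloc[0]) if "particle_id" in traj.columns else -1
    xy = traj[["x_um", "y_um"]].to_numpy()
    frames = traj["frame"].to_numpy()
    if len(xy) < 2:
        logger.warning("to_steps: single-point track %s yields empty trace", pid)
        return StepTrace(particle_id=pid, r=np.empty(0), t=frame_interval)
    d = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    contiguous = np.diff(frames) == 1
    return StepTrace(particle_id=pid, r=d[contiguous], t=frame_interval)


def all_step_traces(
    trajectories: pd.DataFrame, frame_interval: float = DEFAULT_FRAME_INTERVAL_S
) -> list[StepTrace]:
    """Step traces for every particle; empty traces are dropped."""
    traces = [
        to_steps(g, frame_interval) for _, g in trajectories.groupby("particle_id")
    ]
    return [tr for tr in traces if len(tr.r)]
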