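"""Pairwise distance-change mobility of heterochromatic foci.

The central statistic: for every pair of tracked foci, the 3D Euclidean
distance between them is measured at each common time point, and the
inter-frame change

    change[n] = distance[t_{n+1}] - distance[t_n]

is formed.  Because inter-point distances are invariant under rigid
motion, this cancels translation and rotation of the whole nucleus and
isolates the relative motion of the foci.  Mobility (µm/min) is the
magnitude of the change divided by the frame interval; a 0–95 min series
at 5-min intervals has 20 samples and hence 19 change values per pair.
Signed changes are kept on the series (for line plots of distance drift);
mobility uses the absolute value (speed-like, matching box-plot usage).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .foci import FocusTrack
from .synthdata import ImageStack4D

__all__ = [
    "PairDistanceSeries",
    "pairwise_distance_series",
    "mobility",
    "mobility_by_group",
    "time_projection",
    "series_to_frame",
]


@dataclass
class PairDistanceSeries:
    """Distances (µm) and inter-frame distance changes for one focus pair."""

    pair: tuple[int, int]
    t: np.ndarray  # minutes
    distance: np.ndarray  # µm, length k
    change: np.ndarray  # µm, length k-1

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.distance = np.asarray(self.distance, dtype=float)
        self.change = np.asarray(self.change, dtype=float)
        if self.change.size != self.distance.size - 1:
            raise ValueError("change must have one fewer entry than distance")
        if (self.distance < 0).any():
            raise ValueError("distances must be non-negative")


def pairwise_distance_series(
    tracks: Sequence[FocusTrack], frame_interval: float | None = None
) -> list[PairDistanceSeries]:
    """Distance and change series for every unordered track pair.

    Each pair is evaluated over the common contiguous frame range of its
    two tracks; pairs sharing fewer than 2 frames are omitted.  Track
    times are used when present, otherwise ``frame_interval`` (default 1)
    converts frame indices to minutes.
    """
    if len(tracks) < 2:
        raise ValueError("need at least 2 tracks for pairwise distances")
    out: list[PairDistanceSeries] = []
    for a, b in combinations(tracks, 2):
        lo = max(a.frames[0], b.frames[0])
        hi = min(a.frames[-1], b.frames[-1])
        if hi - lo + 1 < 2:
            continue
        ia = slice(lo - a.frames[0], hi - a.frames[0] + 1)
        ib = slice(lo - b.frames[0], hi - b.frames[0] + 1)
        d = np.linalg.norm(a.positions[ia] - b.positions[ib], axis=1)
        if a.times_min is not None:
            t = a.times_min[ia]
        else:
            dt = frame_interval if frame_interval is not None else 1.0
            t = np.arange(lo, hi + 1) * dt
        out.append(
            PairDistanceSeries((a.track_id, b.track_id), t, d, np.diff(d))
        )
    return out


def mobility(series: PairDistanceSeries, dt: float) -> np.ndarray:
    """|change in distance| / dt, one µm/min value per inter-frame step."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    return np.abs(series.change) / dt


def mobility_by_group(
    tracks_by_group: dict[str, Sequence[FocusTrack]], dt: float
) -> dict[str, np.ndarray]:
    """Pool all pair-interval mobility values per group (box-plot input)."""
    out = {}
    for label, tracks in tracks_by_group.items():
        vals = [
            mobility(s, dt) for s in pairwise_distance_series(tracks)
        ]
        out[label] = np.concatenate(vals) if vals else np.empty(0)
    return out


def time_projection(
    stack: ImageStack4D | np.ndarray, n_frames: int
) -> np.ndarray:
    """Maximum-intensity projection over time (then z) of the first frames.

    Static foci collapse to tight puncta; mobile foci smear into clouds,
    which is what makes the projection a quick visual mobility readout.
    """
    data = stack.data if isinstance(stack, ImageStack4D) else np.asarray(stack)
    if data.ndim != 4:
        raise ValueError("expected a 4D (t, z, y, x) stack")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if n_frames > data.shape[0]:
        raise ValueError(
            f"requested {n_frames} frames but stack has {data.shape[0]}"
        )
    return data[:n_frames].max(axis=(0, 1))


def series_to_frame(
    series: Sequence[PairDistanceSeries], dt: float
) -> pd.DataFrame:
    """Tidy long table: pair, t_min, distance_um, change_um, mobility_um_min.

    The change/mobility columns are NaN on each pair's first time point
    (no preceding interval).
    """
    rows = []
    for s in series:
        mob = mobility(s, dt)
        for i, (t, d) in enumerate(zip(s.t, s.distance)):
            rows.append(
                {
                    "pair": f"{s.pair[0]}-{s.pair[1]}",
                    "t_min": float(t),
                    "distance_um": float(d),
                    "change_um": float(s.change[i - 1]) if i > 0 else np.nan,
                    "mobility_um_min": float(mob[i - 1]) if i > 0 else np.nan,
                }
            )
    return pd.DataFrame(rows)
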