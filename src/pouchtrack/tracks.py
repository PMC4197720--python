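"""Per-cell migration metrics for time-lapse centroid tracks.

A :class:`Track` is the ordered 2D centroid trajectory of one pouch
epithelial cell, sampled at (nominally) regular intervals.  Three metrics
summarize how directed the migration of a cell is:

velocity
    total distance traveled along the path divided by elapsed time
    (μm/min).

persistence
    ratio of the straight-line (net) displacement from the first to the
    last point over the total path length.  1 means a perfectly straight
    path, values near 0 a path that wanders back onto itself.

deviation angles
    for every consecutive triple of positions, the signed angle between
    the displacement vector entering the middle point and the one leaving
    it, in degrees in (-180, 180].  Their distribution summarizes the
    directional coherence of a group of cells.

Tracks whose observation does not span the full analysis window are
excluded by :func:`filter_complete_tracks` before any metric is computed,
mirroring the practice of only analysing cells that can be followed
reliably for the whole recording.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import InputValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "Track",
    "TrackMetrics",
    "AngleHistogram",
    "filter_complete_tracks",
    "path_length",
    "velocity",
    "persistence",
    "deviation_angles",
    "compute_track_metrics",
    "bin_angles",
    "summarize_group_metrics",
]


@dataclass
class Track:
    """Ordered time-stamped 2D centroid positions of one cell.

    Parameters
    ----------
    track_id : str
        Unique identifier of the cell track.
    group : str
        Experimental group / genotype-class label.
    t_min : ndarray
        Strictly increasing sample times in minutes.
    x_um, y_um : ndarray
        Centroid coordinates in μm (mathematical convention: y up).
    meta : dict
        Opaque extra per-point annotations (parallel arrays) carried
        through filtering and round-tripped by the CSV reader/writer.
    """

    track_id: str
    group: str
    t_min: np.ndarray
    x_um: np.ndarray
    y_um: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t_min = np.asarray(self.t_min, dtype=float)
        self.x_um = np.asarray(self.x_um, dtype=float)
        self.y_um = np.asarray(self.y_um, dtype=float)
        n = self.t_min.size
        if self.t_min.ndim != 1 or self.x_um.shape != (n,) or self.y_um.shape != (n,):
            raise InputValidationError(
                f"track {self.track_id!r}: t/x/y must be 1-D arrays of equal length"
            )
        if n < 2:
            raise InputValidationError(
                f"track {self.track_id!r}: needs at least 2 points, got {n}"
            )
        if not (
            np.all(np.isfinite(self.t_min))
            and np.all(np.isfinite(self.x_um))
            and np.all(np.isfinite(self.y_um))
        ):
            raise InputValidationError(
                f"track {self.track_id!r}: non-finite time or coordinate value"
            )
        if not np.all(np.diff(self.t_min) > 0):
            raise InputValidationError(
                f"track {self.track_id!r}: timestamps must be strictly increasing"
            )

    @property
    def n_points(self) -> int:
        return self.t_min.size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Track):
            return NotImplemented
        return (
            self.track_id == other.track_id
            and self.group == other.group
            and np.array_equal(self.t_min, other.t_min)
            and np.array_equal(self.x_um, other.x_um)
            and np.array_equal(self.y_um, other.y_um)
        )


@dataclass
class TrackMetrics:
    """Migration metrics of one track."""

    track_id: str
    group: str
    velocity_um_per_min: float
    persistence: float          # NaN when the path length is zero
    deviation_angles_deg: np.ndarray
    n_valid_steps: int          # number of deviation angles computed
    n_skipped_triples: int = 0  # triples dropped for zero-length displacement

    @property
    def persistence_defined(self) -> bool:
        return not math.isnan(self.persistence)


@dataclass
class AngleHistogram:
    """Binned deviation-angle counts for one group over (-180, 180]."""

    bin_edges_deg: np.ndarray
    counts: np.ndarray
    group: str = ""

    def __post_init__(self) -> None:
        self.bin_edges_deg = np.asarray(self.bin_edges_deg, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.size != self.bin_edges_deg.size - 1:
            raise InputValidationError("histogram counts/edges size mismatch")
        if np.any(self.counts < 0):
            raise InputValidationError("histogram counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


# ---------------------------------------------------------------------------
# filtering


def filter_complete_tracks(
    tracks: Iterable[Track],
    window_start_min: float,
    window_end_min: float,
    *,
    nominal_dt_min: float | None = None,
    max_gap_factor: float = 1.5,
) -> list[Track]:
    """Keep only tracks observed throughout the analysis window, cropped to it.

    A track is retained when it has a sample at or before ``window_start_min``
    and one at or after ``window_end_min``, and no sampling gap inside the
    cropped window exceeds ``max_gap_factor`` times the nominal sampling
    interval.  ``nominal_dt_min`` defaults to the median sampling interval
    over all input tracks.
    """
    if window_end_min <= window_start_min:
        raise InputValidationError("window_end_min must exceed window_start_min")
    tracks = list(tracks)
    if not tracks:
        return []
    if nominal_dt_min is None:
        all_dts = np.concatenate([np.diff(tr.t_min) for tr in tracks])
        nominal_dt_min = float(np.median(all_dts))
    max_gap = max_gap_factor * nominal_dt_min

    kept: list[Track] = []
    for tr in tracks:
        if tr.t_min[0] > window_start_min or tr.t_min[-1] < window_end_min:
            continue
        sel = (tr.t_min >= window_start_min) & (tr.t_min <= window_end_min)
        if sel.sum() < 2:
            continue
        t = tr.t_min[sel]
        if np.any(np.diff(t) > max_gap):
            continue
        meta = {
            k: (np.asarray(v)[sel] if np.ndim(v) == 1 and len(v) == tr.n_points else v)
            for k, v in tr.meta.items()
        }
        kept.append(
            Track(tr.track_id, tr.group, t, tr.x_um[sel], tr.y_um[sel], meta)
        )
    logger.info(
        "filter_complete_tracks: kept %d of %d tracks for window [%g, %g] min",
        len(kept), len(tracks), window_start_min, window_end_min,
    )
    return kept


# ---------------------------------------------------------------------------
# per-track metrics


def path_length(track: Track) -> float:
    """Total distance traveled: the sum of Euclidean segment lengths (μm)."""
    return float(np.hypot(np.diff(track.x_um), np.diff(track.y_um)).sum())


def velocity(track: Track) -> float:
    """Total distance traveled divided by elapsed time (μm/min)."""
    elapsed = track.t_min[-1] - track.t_min[0]
    if elapsed <= 0:
        raise InputValidationError(
            f"track {track.track_id!r}: zero elapsed time"
        )
    return path_length(track) / elapsed


def persistence(track: Track) -> float:
    """Net displacement over path length, in [0, 1].

    Returns NaN for a stationary cell (zero path length); callers that
    aggregate over groups exclude and count such tracks.
    """
    total = path_length(track)
    if total == 0.0:
        logger.warning(
            "track %r: zero path length, persistence undefined", track.track_id
        )
        return math.nan
    net = math.hypot(
        track.x_um[-1] - track.x_um[0], track.y_um[-1] - track.y_um[0]
    )
    # guard against rounding pushing the ratio just above 1
    return min(net / total, 1.0)


def _deviation_angles(track: Track) -> tuple[np.ndarray, int]:
    """Signed turning angles plus the count of skipped degenerate triples."""
    dx = np.diff(track.x_um)
    dy = np.diff(track.y_um)
    seg_len = np.hypot(dx, dy)
    valid = (seg_len[:-1] > 0) & (seg_len[1:] > 0)
    n_skipped = int((~valid).sum())
    if valid.size == 0 or not valid.any():
        return np.empty(0), n_skipped
    v1x, v1y = dx[:-1][valid], dy[:-1][valid]
    v2x, v2y = dx[1:][valid], dy[1:][valid]
    cross = v1x * v2y - v1y * v2x
    dot = v1x * v2x + v1y * v2y
    ang = np.degrees(np.arctan2(cross, dot))
    # atan2 maps a perfect reversal to -180; normalize into (-180, 180]
    ang[ang == -180.0] = 180.0
    return ang, n_skipped


def deviation_angles(track: Track) -> np.ndarray:
    """Signed angle between consecutive displacement vectors, degrees.

    For each consecutive position triple the angle measures the turn from
    the displacement p_i→p_{i+1} to p_{i+1}→p_{i+2}; counter-clockwise
    turns are positive.  Triples containing a zero-length displacement are
    skipped (and counted by :func:`compute_track_metrics`).  Tracks with
    fewer than 3 points yield an empty array.
    """
    return _deviation_angles(track)[0]


def compute_track_metrics(track: Track) -> TrackMetrics:
    """Bundle velocity, persistence and deviation angles for one track."""
    angles, n_skipped = _deviation_angles(track)
    return TrackMetrics(
        track_id=track.track_id,
        group=track.group,
        velocity_um_per_min=velocity(track),
        persistence=persistence(track),
        deviation_angles_deg=angles,
        n_valid_steps=int(angles.size),
        n_skipped_triples=n_skipped,
    )


# ---------------------------------------------------------------------------
# histograms and group summaries


def bin_angles(
    angles: Sequence[float] | np.ndarray,
    n_bins: int = 8,
    group: str = "",
    absolute: bool = False,
) -> AngleHistogram:
    """Bin deviation angles into equal-width bins partitioning (-180, 180].

    Bins follow the half-open ``(lo, hi]`` convention, so a value lying on
    a bin edge is assigned to the bin it closes.  ``n_bins`` must divide
    360 so bins align with the cardinal directions.

    With ``absolute=True`` the magnitudes |angle| are binned over
    [0, 180] instead (0 falls in the first bin), discarding the left/right
    turn sign.
    """
    if n_bins < 2 or (not absolute and 360 % n_bins != 0):
        raise InputValidationError(
            f"n_bins must be >= 2 and divide 360, got {n_bins}"
        )
    a = np.asarray(angles, dtype=float)
    if a.size and (np.any(a <= -180.0) or np.any(a > 180.0)):
        bad = a[(a <= -180.0) | (a > 180.0)][0]
        raise InputValidationError(
            f"angle {bad} outside (-180, 180]; normalize upstream angles first"
        )
    if absolute:
        a = np.abs(a)
        width = 180.0 / n_bins
        edges = width * np.arange(n_bins + 1)
        shifted = a
    else:
        width = 360.0 / n_bins
        edges = -180.0 + width * np.arange(n_bins + 1)
        shifted = a + 180.0
    counts = np.zeros(n_bins, dtype=int)
    if a.size:
        idx = np.ceil(shifted / width).astype(int) - 1
        idx = np.clip(idx, 0, n_bins - 1)  # float fuzz at the extremes; |0| -> bin 0
        np.add.at(counts, idx, 1)
    return AngleHistogram(edges, counts, group=group)


def _mean_sem(values: np.ndarray) -> tuple[float, float]:
    mean = float(np.mean(values))
    if values.size < 2:
        return mean, math.nan
    sem = float(np.std(values, ddof=1) / math.sqrt(values.size))
    return mean, sem


def summarize_group_metrics(
    metrics: Iterable[TrackMetrics],
) -> dict[str, dict]:
    """Per-group mean ± s.e.m. of velocity and persistence.

    Tracks with undefined (NaN) persistence are excluded from the
    persistence summary and reported under ``n_persistence_excluded``.
    Groups with a single track get an undefined (NaN) s.e.m. and are
    flagged with ``sem_defined = False``.
    """
    by_group: dict[str, list[TrackMetrics]] = {}
    for m in metrics:
        by_group.setdefault(m.group, []).append(m)

    out: dict[str, dict] = {}
    for group in sorted(by_group):
        ms = by_group[group]
        vel = np.array([m.velocity_um_per_min for m in ms])
        per = np.array([m.persistence for m in ms])
        defined = ~np.isnan(per)
        n_excluded = int((~defined).sum())
        if n_excluded:
            logger.info(
                "group %r: excluded %d track(s) with undefined persistence",
                group, n_excluded,
            )
        vmean, vsem = _mean_sem(vel)
        if defined.any():
            pmean, psem = _mean_sem(per[defined])
        else:
            pmean, psem = math.nan, math.nan
        out[group] = {
            "n": len(ms),
            "velocity": {"mean": vmean, "sem": vsem, "n": len(ms)},
            "persistence": {
                "mean": pmean,
                "sem": psem,
                "n": int(defined.sum()),
            },
            "n_persistence_excluded": n_excluded,
            "sem_defined": len(ms) >= 2,
        }
    return out


def pooled_group_angles(
    metrics: Iterable[TrackMetrics],
    per_cell_mean: bool = False,
) -> dict[str, np.ndarray]:
    """Deviation angles per group, pooled over all steps of all tracks.

    With ``per_cell_mean=True`` each track contributes a single value —
    the circular mean of its deviation angles — so cells rather than
    steps are the unit (tracks without valid angles contribute nothing).
    """
    pools: dict[str, list[np.ndarray]] = {}
    for m in metrics:
        a = m.deviation_angles_deg
        if per_cell_mean:
            if a.size == 0:
                continue
            rad = np.radians(a)
            a = np.array(
                [math.degrees(math.atan2(np.sin(rad).mean(), np.cos(rad).mean()))]
            )
            if a[0] == -180.0:
                a[0] = 180.0
        pools.setdefault(m.group, []).append(a)
    return {
        g: (np.concatenate(arrs) if arrs else np.empty(0))
        for g, arrs in sorted(pools.items())
    }
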