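"""Novel-object-recognition (NOR) metrics from tracked position logs.

A mouse explores a 40x40 cm arena containing two objects; exploration of an
object is scored whenever the tracked nose point is within 2 cm of the
object's boundary but not on top of it (climbing is excluded).  The
preference index is the percentage of total exploration time devoted to the
novel object — 50% means no preference.  Animals enter the analysis only if
they explored both identical objects for at least 20 s each during training.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np
import shapely
from shapely.geometry import Polygon

from .errors import InputError

__all__ = [
    "ArenaObject",
    "NorTrack",
    "detect_exploration",
    "preference_index",
    "inclusion_filter",
    "activity_metrics",
]

ARENA_CM = 40.0


@dataclass
class ArenaObject:
    """One object in the arena: identity, role, and footprint polygon (cm)."""

    id: str
    role: str  # "familiar" | "novel"
    center: Tuple[float, float]
    footprint: List[Tuple[float, float]]

    def polygon(self) -> Polygon:
        poly = Polygon(self.footprint)
        if not poly.is_valid or poly.area <= 0:
            raise InputError(f"object {self.id!r} has a degenerate footprint")
        return poly


@dataclass
class NorTrack:
    """Per-frame nose and centroid coordinates plus the object layout."""

    nose_xy: np.ndarray  # (frames, 2), cm; NaN = tracking dropout
    centroid_xy: np.ndarray
    frame_rate_hz: float
    objects: List[ArenaObject]
    phase: str = "testing"  # "training" | "testing"

    def __post_init__(self) -> None:
        self.nose_xy = np.asarray(self.nose_xy, dtype=float)
        self.centroid_xy = np.asarray(self.centroid_xy, dtype=float)
        if self.nose_xy.ndim != 2 or self.nose_xy.shape[1] != 2:
            raise InputError("nose_xy must be (frames, 2)")
        if self.nose_xy.shape != self.centroid_xy.shape:
            raise InputError("nose and centroid tracks must align")
        if len(self.objects) != 2:
            raise InputError("exactly two objects per phase")
        finite = self.nose_xy[np.isfinite(self.nose_xy).all(axis=1)]
        if finite.size and (
            finite.min() < -1e-9 or finite.max() > ARENA_CM + 1e-9
        ):
            raise InputError(f"coordinates must lie within the {ARENA_CM:.0f} cm arena")

    @property
    def n_frames(self) -> int:
        return len(self.nose_xy)

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz


def _interpolate_gaps(xy: np.ndarray, max_missing_frac: float) -> np.ndarray:
    """Fill NaN dropouts by linear interpolation; error above the tolerance."""
    ok = np.isfinite(xy).all(axis=1)
    frac_missing = 1.0 - ok.mean()
    if frac_missing > max_missing_frac:
        raise InputError(
            f"{frac_missing:.0%} of frames lack coordinates "
            f"(tolerance {max_missing_frac:.0%})"
        )
    if frac_missing == 0:
        return xy
    out = xy.copy()
    idx = np.arange(len(xy))
    for c in range(2):
        out[~ok, c] = np.interp(idx[~ok], idx[ok], xy[ok, c])
    return out


def detect_exploration(
    track: NorTrack, radius_cm: float = 2.0, max_missing_frac: float = 0.10
) -> Dict[str, float]:
    """Cumulative exploration time (s) per object.

    A frame counts toward an object when the nose is strictly closer than
    ``radius_cm`` to the object's boundary *and* not inside its footprint
    (the climbing proxy).  Distance is measured to the boundary, not the
    center, so the rule is independent of object size.
    """
    if track.n_frames == 0:
        raise InputError("empty track")
    nose = _interpolate_gaps(track.nose_xy, max_missing_frac)
    pts = shapely.points(nose)
    times: Dict[str, float] = {}
    for obj in track.objects:
        poly = obj.polygon()
        near = shapely.distance(poly.exterior, pts) < radius_cm
        climbing = shapely.contains(poly, pts)
        times[obj.id] = int((near & ~climbing).sum()) / track.frame_rate_hz
    return times


def preference_index(t_novel: float, t_familiar: float) -> float:
    """Novel-object preference: ``100 * t_novel / (t_novel + t_familiar)``.

    50 means equal exploration of the two objects; the index is undefined
    (raises) when total exploration is zero.
    """
    if t_novel < 0 or t_familiar < 0:
        raise InputError("exploration times must be non-negative")
    total = t_novel + t_familiar
    if total <= 0:
        raise InputError("preference index undefined: zero total exploration")
    return 100.0 * t_novel / total


def inclusion_filter(
    t_object_a: float, t_object_b: float, min_s: float = 20.0
) -> bool:
    """Training-phase inclusion rule: both objects explored at least ``min_s``
    seconds (boundary inclusive)."""
    return t_object_a >= min_s and t_object_b >= min_s


def activity_metrics(track: NorTrack, max_missing_frac: float = 0.10) -> Dict[str, float]:
    """Distance traveled (cm) and mean velocity (cm/s) from the centroid."""
    if track.n_frames == 0:
        raise InputError("empty track")
    if track.n_frames == 1:
        return {"distance_cm": 0.0, "mean_velocity_cm_s": 0.0}
    xy = _interpolate_gaps(track.centroid_xy, max_missing_frac)
    steps = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    dist = float(steps.sum())
    return {
        "distance_cm": dist,
        "mean_velocity_cm_s": dist / track.duration_s,
    }
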