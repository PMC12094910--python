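"""Stimulus-locked trial extraction, locomotion classification, and metrics.

Continuous ROI-averaged hemodynamic traces are cut into peri-stimulus trials
(5 s pre / 20 s post onset for 2-s stimulations; 10 s pre / 60 s post for
16-s), each trial re-zeroed by its pre-stimulus mean.  Each trial's locomotion
trace is classified into one of four categories from a 2x2 grid of two
windows — running/not in the 4 s before onset, running/not between onset and
4 s after offset:

    1  no running in either window (rest trial)
    2  running before but not during the stimulation
    3  running starting at stimulus onset (none before)
    4  running before and during the stimulation

Per-trial metrics (trapezoidal AUC and maximum peak per chromophore, plus
locomotion AUC) are taken over the window from stimulus onset to 5 s past it
(2-s protocol) or 20 s past it (16-s protocol).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = [
    "LocomotionTrace",
    "Trial",
    "STIM_PROTOCOLS",
    "segment_trials",
    "classify_locomotion",
    "trial_metrics",
    "build_trial_table",
    "rank_by_locomotion",
    "filter_rest_and_onset_trials",
]

logger = logging.getLogger(__name__)

#: Per-protocol timing (seconds): pre-onset extent, post-onset extent,
#: stimulus duration, and metric-window length past onset.
STIM_PROTOCOLS = {
    "2s": {"pre_s": 5.0, "post_s": 20.0, "stim_s": 2.0, "metric_s": 5.0},
    "16s": {"pre_s": 10.0, "post_s": 60.0, "stim_s": 16.0, "metric_s": 20.0},
}


@dataclass
class LocomotionTrace:
    """Treadmill-sensor movement trace: zeros at rest, positive values moving."""

    values: np.ndarray
    times_s: np.ndarray
    trigger_times_s: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.trigger_times_s = np.asarray(self.trigger_times_s, dtype=float)
        if self.values.shape != self.times_s.shape:
            raise InputError("locomotion values and times must align")
        if np.any(self.values < 0):
            raise InputError("locomotion magnitudes must be non-negative")
        if self.times_s.size > 1 and not np.all(np.diff(self.times_s) > 0):
            raise InputError("locomotion times must be strictly increasing")

    def resample(self, new_times_s: np.ndarray) -> np.ndarray:
        """Linear interpolation onto another clock (e.g. the imaging clock)."""
        return np.interp(new_times_s, self.times_s, self.values)


@dataclass
class Trial:
    """One peri-stimulus trial: re-zeroed hemodynamic traces plus locomotion.

    ``times_s`` is trial-relative, starting at 0; stimulus onset sits at
    ``onset_s`` (5 s for the 2-s protocol, 10 s for 16-s) and ends at
    ``offset_s``.
    """

    times_s: np.ndarray
    hbt: np.ndarray
    hbo: np.ndarray
    hbr: np.ndarray
    loco: np.ndarray
    onset_s: float
    offset_s: float
    stim_type: str
    animal_id: str = ""
    group: str = ""
    session_id: str = ""
    trial_id: int = 0

    @property
    def frame_rate_hz(self) -> float:
        return 1.0 / float(self.times_s[1] - self.times_s[0])


def segment_trials(
    hemo: Dict[str, np.ndarray],
    times_s: np.ndarray,
    loco: LocomotionTrace,
    stim_type: str,
    labels: Optional[dict] = None,
) -> List[Trial]:
    """Cut continuous ROI traces into peri-stimulus trials.

    ``hemo`` maps 'hbt'/'hbo'/'hbr' to traces on the clock ``times_s``.
    Triggers come from ``loco.trigger_times_s``.  Trials whose full window
    would fall outside the recording are dropped with a logged warning.  Each
    trial's hemodynamic traces are re-zeroed by subtracting the mean of the
    pre-onset window.
    """
    if stim_type not in STIM_PROTOCOLS:
        raise InputError(f"unknown stimulation protocol {stim_type!r}")
    proto = STIM_PROTOCOLS[stim_type]
    triggers = loco.trigger_times_s
    if triggers.size == 0:
        raise InputError("no stimulus triggers supplied")
    times_s = np.asarray(times_s, dtype=float)
    fr = 1.0 / float(times_s[1] - times_s[0])
    n = len(times_s)
    loco_on_clock = loco.resample(times_s)
    labels = labels or {}

    trials: List[Trial] = []
    n_dropped = 0
    for i, t0 in enumerate(np.asarray(triggers, dtype=float), start=1):
        lo = int(round((t0 - proto["pre_s"]) * fr))
        hi = int(round((t0 + proto["post_s"]) * fr))
        if lo < 0 or hi > n:
            n_dropped += 1
            logger.warning(
                "trial %d at %.2f s dropped: window [%d, %d) outside recording",
                i, t0, lo, hi,
            )
            continue
        pre = slice(0, int(round(proto["pre_s"] * fr)))
        seg = {}
        for name in ("hbt", "hbo", "hbr"):
            tr = np.asarray(hemo[name], dtype=float)[lo:hi]
            seg[name] = tr - tr[pre].mean()
        trials.append(
            Trial(
                times_s=times_s[lo:hi] - times_s[lo],
                hbt=seg["hbt"],
                hbo=seg["hbo"],
                hbr=seg["hbr"],
                loco=loco_on_clock[lo:hi],
                onset_s=proto["pre_s"],
                offset_s=proto["pre_s"] + proto["stim_s"],
                stim_type=stim_type,
                trial_id=i,
                **labels,
            )
        )
    if not trials:
        raise InputError("zero usable triggers: every trial window fell outside")
    if n_dropped:
        logger.warning("%d of %d trials dropped", n_dropped, len(triggers))
    return trials


def _debounce(moving: np.ndarray, min_run: int) -> np.ndarray:
    """Suppress runs of moving samples shorter than ``min_run`` (sensor jitter)."""
    if min_run <= 1:
        return moving
    out = moving.copy()
    padded = np.concatenate([[False], moving, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    for start, stop in zip(edges[::2], edges[1::2]):
        if stop - start < min_run:
            out[start:stop] = False
    return out


def classify_locomotion(
    trial: Trial, move_threshold: float = 0.0, debounce_s: float = 0.125
) -> int:
    """Assign the trial's four-way locomotion category.

    ``running(W)`` is true when any debounced sample in window W exceeds
    ``move_threshold``; the pre window is [onset-4 s, onset) and the stim
    window is [onset, offset+4 s).  The four (pre, stim) combinations map to
    categories 1-4, which are exhaustive and mutually exclusive.
    """
    t = trial.times_s
    pre_lo, pre_hi = trial.onset_s - 4.0, trial.onset_s
    stim_lo, stim_hi = trial.onset_s, trial.offset_s + 4.0
    if t[0] > pre_lo + 1e-9 or t[-1] < stim_hi - (t[1] - t[0]) - 1e-9:
        raise InputError(
            "trial too short to contain the [onset-4 s, offset+4 s) "
            "classification windows"
        )
    moving = _debounce(
        trial.loco > move_threshold,
        int(round(debounce_s * trial.frame_rate_hz)),
    )
    pre = moving[(t >= pre_lo) & (t < pre_hi)].any()
    stim = moving[(t >= stim_lo) & (t < stim_hi)].any()
    if not pre and not stim:
        return 1
    if pre and not stim:
        return 2
    if not pre and stim:
        return 3
    return 4


def trial_metrics(trial: Trial) -> Dict[str, float]:
    """Trapezoidal AUC and maximum peak over the post-onset metric window.

    The window runs from stimulus onset to ``metric_s`` past it (5 s for the
    2-s protocol, 20 s for 16-s); endpoints inclusive.  AUC units are uM*s for
    hemodynamics and a.u.*s for locomotion.
    """
    proto = STIM_PROTOCOLS[trial.stim_type]
    lo, hi = trial.onset_s, trial.onset_s + proto["metric_s"]
    t = trial.times_s
    sel = (t >= lo - 1e-9) & (t <= hi + 1e-9)
    if not sel.any() or t[-1] < hi - 1e-9:
        raise InputError("metric window extends outside the trial")
    tw = t[sel]
    out: Dict[str, float] = {}
    for name in ("hbt", "hbo", "hbr"):
        y = getattr(trial, name)[sel]
        out[f"{name}_auc"] = float(np.trapezoid(y, tw))
        out[f"{name}_peak"] = float(y.max())
    out["loco_auc"] = float(np.trapezoid(trial.loco[sel], tw))
    return out


def build_trial_table(
    trials: Sequence[Trial],
    move_threshold: float = 0.0,
    debounce_s: float = 0.125,
) -> pd.DataFrame:
    """One row per trial: labels, locomotion category, and metrics."""
    rows = []
    for tr in trials:
        row = {
            "animal_id": tr.animal_id,
            "group": tr.group,
            "session_id": tr.session_id,
            "trial_id": tr.trial_id,
            "stim_type": tr.stim_type,
            "loco_category": classify_locomotion(tr, move_threshold, debounce_s),
        }
        row.update(trial_metrics(tr))
        rows.append(row)
    return pd.DataFrame(rows)


def rank_by_locomotion(
    table: pd.DataFrame,
    frac: float = 0.2,
    stratify: Optional[Sequence[str]] = ("animal_id", "session_id"),
) -> pd.DataFrame:
    """Rank trials by locomotion AUC (ascending) and flag extreme subsets.

    Adds ``loco_rank`` (dense ascending ranks within each stratification
    unit), and boolean ``bottom20``/``top20`` columns marking the
    ``floor(frac * n)`` least- and most-locomoting trials per unit, ties
    broken by trial id (earlier trial first).  With fewer than 5 trials in a
    unit both subsets are empty and a warning is issued.
    """
    if "loco_auc" not in table.columns or table["loco_auc"].isna().any():
        raise InputError("loco_auc must be present for every trial")
    out = table.copy()
    out["loco_rank"] = 0
    out["bottom20"] = False
    out["top20"] = False

    if stratify:
        grouper = out.groupby(list(stratify), sort=False).indices.values()
    else:
        grouper = [np.arange(len(out))]

    for idx in grouper:
        idx = np.asarray(idx)
        sub = out.iloc[idx]
        out.iloc[idx, out.columns.get_loc("loco_rank")] = (
            sub["loco_auc"].rank(method="dense").astype(int).to_numpy()
        )
        n_sel = int(np.floor(frac * len(idx)))
        if len(idx) < 5:
            warnings.warn(
                f"fewer than 5 trials in stratum; extreme subsets left empty",
                stacklevel=2,
            )
            continue
        order = np.lexsort((sub["trial_id"].to_numpy(), sub["loco_auc"].to_numpy()))
        out.iloc[idx[order[:n_sel]], out.columns.get_loc("bottom20")] = True
        out.iloc[idx[order[::-1][:n_sel]], out.columns.get_loc("top20")] = True
    return out


def filter_rest_and_onset_trials(
    table: pd.DataFrame,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Split the table into the rest (category 1) and onset-locomotion
    (category 3) analysis sets; the other categories are excluded from the
    main analysis because of the strong locomotion confound."""
    rest = table[table["loco_category"] == 1]
    onset = table[table["loco_category"] == 3]
    if rest.empty and onset.empty:
        warnings.warn("no category-1 or category-3 trials available", stacklevel=2)
    for name, sub in (("rest", rest), ("onset-locomotion", onset)):
        if not sub.empty:
            counts = sub.groupby("group", sort=False).size().to_dict()
            logger.info("%s set: %d trials (%s)", name, len(sub), counts)
    return rest, onset
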