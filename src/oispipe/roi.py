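"""Region-of-interest detection on stimulus-evoked response maps.

The whisker-barrel ROI is the largest 8-connected region of pixels whose
z-scored evoked-HbT value exceeds a threshold (default 1.5 SD, the SD being
taken over the entire spatial map).  Within that region, artery/vein/parenchyma
sub-ROIs are *suggested* automatically — a PCA of pixel time series identifies
the vessel-like components — but are designed to be overridden by manually
drawn masks, which take precedence exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .errors import InputError
from .spectroscopy import HemoMaps

__all__ = ["RoiSet", "detect_whisker_roi", "suggest_vessel_rois"]

_EIGHT_CONN = np.ones((3, 3), dtype=bool)


@dataclass
class RoiSet:
    """Named boolean pixel masks sharing one image grid.

    ``provenance`` records, per mask, whether it was detected automatically or
    supplied as a manual override, and the threshold used.
    """

    masks: Dict[str, np.ndarray]
    provenance: Dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) > 1:
            raise InputError(f"ROI masks must share one grid; got shapes {shapes}")
        for name, m in self.masks.items():
            self.masks[name] = np.asarray(m, dtype=bool)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]


def detect_whisker_roi(zmap: np.ndarray, k: float = 1.5) -> np.ndarray:
    """Whisker-barrel ROI from a z-scored evoked-response map.

    Pixels with ``z > k`` are "active"; the ROI returned is the largest
    8-connected component of the active set, ties broken in favour of the
    component containing the global-maximum pixel.

    Raises :class:`InputError` if no pixel is active (absent or weak response).
    """
    zmap = np.asarray(zmap, dtype=float)
    if not np.all(np.isfinite(zmap)):
        raise InputError("z-map contains non-finite values")
    active = zmap > k
    if not active.any():
        raise InputError(f"no active region: no pixel exceeds {k} SD")
    labels, n = ndimage.label(active, structure=_EIGHT_CONN)
    sizes = ndimage.sum_labels(active, labels, index=np.arange(1, n + 1))
    best = sizes.max()
    winners = np.flatnonzero(sizes == best) + 1
    if len(winners) > 1:
        peak_label = labels[np.unravel_index(np.argmax(zmap), zmap.shape)]
        label = peak_label if peak_label in winners else winners[0]
    else:
        label = winners[0]
    return labels == label


def _boxcar_regressor(
    n_frames: int, frame_rate_hz: float, triggers: Sequence[float], stim_s: float
) -> np.ndarray:
    reg = np.zeros(n_frames)
    for t0 in triggers:
        lo = int(round(t0 * frame_rate_hz))
        hi = int(round((t0 + stim_s) * frame_rate_hz))
        reg[max(lo, 0) : min(hi, n_frames)] = 1.0
    return reg


def suggest_vessel_rois(
    hemo: HemoMaps,
    whisker_mask: np.ndarray,
    triggers: Sequence[float],
    stim_duration_s: float = 2.0,
    decile: float = 0.9,
    overrides: Optional[Dict[str, np.ndarray]] = None,
) -> RoiSet:
    """Suggest artery/vein/parenchyma candidate masks within the whisker ROI.

    The pixel HbT time series inside the whisker mask are decomposed by PCA.
    The component whose time course correlates most strongly with a boxcar
    stimulus regressor carries the stimulus-locked arterial signal: the artery
    candidate is the top ``decile`` of pixels by |loading| on it, restricted to
    pixels with positive evoked HbT.  The vein candidate is the top decile of
    the remaining pixels by HbR washout magnitude (most negative evoked HbR).
    Parenchyma is every whisker-ROI pixel in neither candidate.  The three
    masks are disjoint by construction.

    ``overrides`` maps mask names to manual masks which replace the automatic
    suggestion exactly (recorded in the provenance).
    """
    whisker_mask = np.asarray(whisker_mask, dtype=bool)
    if whisker_mask.sum() < 10:
        raise InputError(
            f"whisker mask has {int(whisker_mask.sum())} pixels; need >= 10"
        )
    overrides = overrides or {}

    X = hemo.dhbt[:, whisker_mask]  # (frames, pixels)
    Xc = X - X.mean(axis=0)
    # PCA via SVD of the centered time-by-pixel matrix
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    n_comp = min(5, len(s))
    reg = _boxcar_regressor(hemo.n_frames, hemo.frame_rate_hz, triggers, stim_duration_s)
    regc = reg - reg.mean()
    denom = np.linalg.norm(regc)
    corr = np.zeros(n_comp)
    if denom > 0:
        for i in range(n_comp):
            if s[i] < 0.01 * s[0]:  # skip numerical-noise components
                continue
            pc = U[:, i] * s[i]
            npc = np.linalg.norm(pc - pc.mean())
            if npc > 0:
                corr[i] = abs(np.dot(pc - pc.mean(), regc)) / (npc * denom)
    best = int(np.argmax(corr))

    loading = np.abs(Vt[best])
    evoked_hbt = X.mean(axis=0)
    evoked_hbr = hemo.dhbr[:, whisker_mask].min(axis=0)  # washout depth (<= 0)

    n_pix = whisker_mask.sum()
    n_top = max(1, int(np.ceil((1 - decile) * n_pix)))

    # artery: strongest stimulus-locked loading among positively responding pixels
    score_a = np.where(evoked_hbt > 0, loading, -np.inf)
    artery_local = np.zeros(n_pix, dtype=bool)
    artery_local[np.argsort(score_a)[::-1][:n_top]] = True

    # vein: deepest HbR washout among pixels not already claimed
    score_v = np.where(artery_local, np.inf, evoked_hbr)
    vein_local = np.zeros(n_pix, dtype=bool)
    vein_local[np.argsort(score_v)[:n_top]] = True
    vein_local &= ~artery_local

    paren_local = ~(artery_local | vein_local)

    def to_grid(local: np.ndarray) -> np.ndarray:
        m = np.zeros(whisker_mask.shape, dtype=bool)
        m[whisker_mask] = local
        return m

    masks = {
        "artery": to_grid(artery_local),
        "vein": to_grid(vein_local),
        "parenchyma": to_grid(paren_local),
    }
    provenance = {name: {"source": "auto", "decile": decile} for name in masks}
    for name, m in overrides.items():
        masks[name] = np.asarray(m, dtype=bool)
        provenance[name] = {"source": "manual-override"}
    masks["whisker"] = whisker_mask
    provenance["whisker"] = {"source": "input"}
    return RoiSet(masks=masks, provenance=provenance)
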