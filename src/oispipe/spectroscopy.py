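"""Spectral unmixing of multispectral reflectance into hemoglobin changes.

Widefield imaging records cortical reflectance at several wavelengths; because
oxy- and deoxyhemoglobin absorb differently across those wavelengths, the
attenuation changes can be unmixed into micromolar concentration changes
dHbO and dHbR (dHbT = dHbO + dHbR) by least squares under the modified
Beer-Lambert law with a per-wavelength pathlength correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from .config import SpectroConfig
from .errors import ConfigError, InputError, NumericalError

__all__ = [
    "ReflectanceStack",
    "HemoMaps",
    "compute_baseline_concentrations",
    "absorbance_change",
    "unmix",
    "spatial_response_map",
]


@dataclass
class ReflectanceStack:
    """Multispectral reflectance time series plus acquisition metadata.

    ``data`` is indexed ``(wavelength, frame, row, col)`` and must be strictly
    positive (attenuation is a log-ratio).  Trigger times mark stimulus onsets
    on the recording clock.
    """

    data: np.ndarray
    wavelengths_nm: np.ndarray
    frame_rate_hz: float = 32.0
    pixel_size_um: float = 75.0
    trigger_times_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    stim_duration_s: float = 2.0
    animal: str = ""
    group: str = ""
    session: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.trigger_times_s = np.asarray(self.trigger_times_s, dtype=float)
        if self.data.ndim != 4:
            raise InputError(
                f"stack must be 4-D (wavelength, frame, row, col); got {self.data.ndim}-D"
            )
        if self.data.shape[0] != len(self.wavelengths_nm):
            raise InputError(
                f"stack has {self.data.shape[0]} channels but "
                f"{len(self.wavelengths_nm)} wavelengths declared"
            )
        if self.frame_rate_hz <= 0:
            raise InputError("frame rate must be positive")
        bad = ~(self.data > 0)
        if bad.any():
            w, t = np.argwhere(bad)[0][:2]
            raise InputError(
                "reflectance intensities must be strictly positive; first "
                f"offending sample at wavelength index {w}, frame {t}"
            )
        dur = self.duration_s
        if self.trigger_times_s.size and (
            self.trigger_times_s.min() < 0 or self.trigger_times_s.max() > dur
        ):
            raise InputError(
                f"trigger times must lie within the recording [0, {dur:.2f}] s"
            )

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate_hz


@dataclass
class HemoMaps:
    """Per-pixel micromolar hemoglobin concentration changes.

    Arrays are indexed ``(frame, row, col)`` on the source stack's grid and
    clock.  ``dhbt == dhbo + dhbr`` holds elementwise by construction.
    """

    dhbo: np.ndarray
    dhbr: np.ndarray
    dhbt: np.ndarray
    frame_rate_hz: float
    baseline_window: Tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        self.dhbo = np.asarray(self.dhbo, dtype=float)
        self.dhbr = np.asarray(self.dhbr, dtype=float)
        self.dhbt = np.asarray(self.dhbt, dtype=float)
        if not (self.dhbo.shape == self.dhbr.shape == self.dhbt.shape):
            raise InputError("dhbo/dhbr/dhbt must share one shape")
        if not np.allclose(self.dhbt, self.dhbo + self.dhbr, atol=1e-9):
            raise InputError("dhbt must equal dhbo + dhbr (tolerance 1e-9)")

    @property
    def n_frames(self) -> int:
        return self.dhbt.shape[0]

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate_hz

    def roi_mean(self, mask: np.ndarray) -> dict:
        """ROI-averaged traces {'hbo', 'hbr', 'hbt'} in uM."""
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise InputError("ROI mask is empty")
        return {
            "hbo": self.dhbo[:, mask].mean(axis=1),
            "hbr": self.dhbr[:, mask].mean(axis=1),
            "hbt": self.dhbt[:, mask].mean(axis=1),
        }


def compute_baseline_concentrations(
    total_hb_uM: float, saturation: float
) -> Tuple[float, float]:
    """Split resting total hemoglobin into oxy/deoxy by baseline saturation.

    Returns ``(hbo0, hbr0)`` in uM with ``hbo0 = total * S`` and
    ``hbr0 = total * (1 - S)``.
    """
    if total_hb_uM <= 0:
        raise InputError("total hemoglobin must be positive")
    if not 0 <= saturation <= 1:
        raise InputError(f"saturation must lie in [0, 1]; got {saturation}")
    hbo0 = total_hb_uM * saturation
    return hbo0, total_hb_uM - hbo0


def absorbance_change(
    stack: ReflectanceStack, baseline_window: Tuple[int, int]
) -> np.ndarray:
    """Attenuation change ``dA = -ln(R / R0)`` relative to a baseline window.

    ``R0`` is the per-pixel mean intensity over ``baseline_window`` (half-open
    frame interval).  Returns an array indexed like the stack.
    """
    lo, hi = baseline_window
    if not (0 <= lo < hi <= stack.n_frames):
        raise ConfigError(
            f"baseline window [{lo}, {hi}) must be non-empty and inside "
            f"[0, {stack.n_frames})"
        )
    r0 = stack.data[:, lo:hi].mean(axis=1, keepdims=True)
    return -np.log(stack.data / r0)


def unmix(
    dA: np.ndarray,
    cfg: SpectroConfig,
    roi_class: str = "tissue",
    frame_rate_hz: float = 32.0,
    baseline_window: Tuple[int, int] = (0, 0),
) -> HemoMaps:
    """Least-squares unmixing of attenuation changes into (dHbO, dHbR).

    Solves, independently per pixel and frame, the overdetermined system

        dA(l) = [eps_HbO(l) * dHbO + eps_HbR(l) * dHbR] * L(l)

    with the pathlength column ``L`` selected by ``roi_class`` (the class sets
    the assumed baseline saturation the pathlength table was built for).

    Raises :class:`NumericalError` if the design matrix condition number
    exceeds ``cfg.condition_bound``.
    """
    dA = np.asarray(dA, dtype=float)
    if dA.ndim != 4:
        raise InputError("dA must be 4-D (wavelength, frame, row, col)")
    if dA.shape[0] != cfg.n_wavelengths:
        raise ConfigError(
            f"dA has {dA.shape[0]} channels but config declares "
            f"{cfg.n_wavelengths} wavelengths"
        )
    M = cfg.design_matrix(roi_class)
    cond = np.linalg.cond(M)
    if cond > cfg.condition_bound:
        raise NumericalError(
            f"unmixing design is ill-conditioned (cond={cond:.3g} > "
            f"{cfg.condition_bound:.3g})"
        )
    n_l = dA.shape[0]
    flat = dA.reshape(n_l, -1)  # one least-squares solve for all pixels/frames
    coef, *_ = np.linalg.lstsq(M, flat, rcond=None)
    shape = dA.shape[1:]
    dhbo = coef[0].reshape(shape)
    dhbr = coef[1].reshape(shape)
    return HemoMaps(
        dhbo=dhbo,
        dhbr=dhbr,
        dhbt=dhbo + dhbr,
        frame_rate_hz=frame_rate_hz,
        baseline_window=baseline_window,
    )


def spatial_response_map(
    hemo: HemoMaps,
    triggers: Sequence[float],
    stim_window_s: Tuple[float, float] = (0.0, 5.0),
    baseline_window_s: Tuple[float, float] = (-5.0, 0.0),
) -> np.ndarray:
    """Trial-averaged stimulus-evoked dHbT difference map, spatially z-scored.

    For each usable trigger the mean dHbT over the evoked window minus the mean
    over the pre-stimulus baseline window is computed per pixel; the trial
    average of that difference is then standardized by its own spatial mean and
    standard deviation.  If the map is spatially constant (SD below 1e-12) an
    all-zero map is returned rather than dividing by ~0.

    Window bounds are in seconds relative to each trigger, half-open.
    """
    fr = hemo.frame_rate_hz
    n = hemo.n_frames
    diffs = []
    for t0 in np.asarray(triggers, dtype=float):
        b_lo = int(round((t0 + baseline_window_s[0]) * fr))
        b_hi = int(round((t0 + baseline_window_s[1]) * fr))
        s_lo = int(round((t0 + stim_window_s[0]) * fr))
        s_hi = int(round((t0 + stim_window_s[1]) * fr))
        if b_lo < 0 or s_hi > n or b_hi <= b_lo or s_hi <= s_lo:
            continue
        diffs.append(
            hemo.dhbt[s_lo:s_hi].mean(axis=0) - hemo.dhbt[b_lo:b_hi].mean(axis=0)
        )
    if not diffs:
        raise InputError("no trigger has both windows inside the recording")
    mean_map = np.mean(diffs, axis=0)
    sd = mean_map.std()
    if sd < 1e-12:
        return np.zeros_like(mean_map)
    return (mean_map - mean_map.mean()) / sd
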