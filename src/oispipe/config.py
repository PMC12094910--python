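"""Spectroscopy configuration: extinction coefficients, photon pathlengths, baselines.

The spectral model is the modified Beer–Lambert law

    dA(lambda) = [eps_HbO(lambda) * dHbO + eps_HbR(lambda) * dHbR] * L(lambda)

where ``dA`` is the attenuation change relative to baseline, ``eps`` are molar
extinction coefficients of oxy- and deoxyhemoglobin, and ``L`` is the effective
(scattering-lengthened) photon pathlength through tissue at each wavelength.
``L`` depends on the assumed baseline oxygen saturation of the compartment being
imaged, so the table is keyed by tissue class ("tissue" for parenchyma/whisker
region at 80% saturation, "artery" at 90%).

The shipped extinction values are band-center values taken from standard
compiled hemoglobin absorption spectra; the imaging filters' bandwidths are
recorded for reference but no band-averaging is applied.  The pathlength table
is a documented default: the values scale the recovered concentrations but,
because the synthetic forward model and the unmixing share the same table,
round-trip correctness is independent of their absolute accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .errors import ConfigError

#: Band centers of the four illumination wavelengths (nm).
DEFAULT_WAVELENGTHS_NM = (494.0, 560.0, 575.0, 595.0)

#: Half-bandwidths of the interference filters (nm), recorded but unused.
DEFAULT_BANDWIDTHS_NM = (20.0, 5.0, 14.0, 5.0)

#: Molar extinction coefficients (1/(uM*cm)) at the band centers,
#: columns = (HbO, HbR), from compiled hemoglobin spectra.
DEFAULT_EPSILON = (
    (0.0212, 0.0192),
    (0.0326, 0.0535),
    (0.0556, 0.0374),
    (0.0041, 0.0141),
)

#: Effective photon pathlength (cm) per wavelength, per baseline-saturation
#: class.  Documented defaults; override via YAML for quantitative work.
DEFAULT_PATHLENGTH_CM = {
    "tissue": (0.40, 0.20, 0.18, 0.30),
    "artery": (0.38, 0.19, 0.17, 0.28),
}

DEFAULT_BASELINE_SATURATION = {"tissue": 0.80, "artery": 0.90}


@dataclass
class SpectroConfig:
    """Parameters of the spectral unmixing stage.

    Attributes
    ----------
    wavelengths_nm
        Strictly increasing band centers, one per imaging channel.
    epsilon
        ``(n_wavelengths, 2)`` extinction matrix, columns (HbO, HbR),
        units 1/(uM*cm).
    pathlength_cm
        Map from tissue class to per-wavelength effective pathlength (cm).
    baseline_total_hb_uM
        Assumed resting total hemoglobin concentration (uM).
    baseline_saturation
        Map from tissue class to assumed resting oxygen saturation.
    bandwidths_nm
        Filter half-bandwidths (nm); informational only.
    condition_bound
        Maximum acceptable condition number of the unmixing design matrix.
    """

    wavelengths_nm: np.ndarray = field(
        default_factory=lambda: np.asarray(DEFAULT_WAVELENGTHS_NM, dtype=float)
    )
    epsilon: np.ndarray = field(
        default_factory=lambda: np.asarray(DEFAULT_EPSILON, dtype=float)
    )
    pathlength_cm: dict = field(
        default_factory=lambda: {
            k: np.asarray(v, dtype=float) for k, v in DEFAULT_PATHLENGTH_CM.items()
        }
    )
    baseline_total_hb_uM: float = 100.0
    baseline_saturation: dict = field(
        default_factory=lambda: dict(DEFAULT_BASELINE_SATURATION)
    )
    bandwidths_nm: np.ndarray = field(
        default_factory=lambda: np.asarray(DEFAULT_BANDWIDTHS_NM, dtype=float)
    )
    condition_bound: float = 1e8

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.epsilon = np.asarray(self.epsilon, dtype=float)
        self.bandwidths_nm = np.asarray(self.bandwidths_nm, dtype=float)
        self.pathlength_cm = {
            k: np.asarray(v, dtype=float) for k, v in self.pathlength_cm.items()
        }
        self.validate()

    @property
    def n_wavelengths(self) -> int:
        return len(self.wavelengths_nm)

    def validate(self) -> None:
        w = self.wavelengths_nm
        if w.ndim != 1 or len(w) < 3:
            raise ConfigError(
                "at least 3 wavelengths are required for overdetermined "
                f"two-chromophore unmixing (got {len(w)})"
            )
        if not np.all(np.diff(w) > 0):
            raise ConfigError("wavelengths must be strictly increasing")
        if self.epsilon.shape != (len(w), 2):
            raise ConfigError(
                f"epsilon must have shape ({len(w)}, 2), got {self.epsilon.shape}"
            )
        if not np.all(self.epsilon > 0):
            raise ConfigError("extinction coefficients must be strictly positive")
        for cls, L in self.pathlength_cm.items():
            if L.shape != (len(w),):
                raise ConfigError(
                    f"pathlength table for class {cls!r} must have one entry "
                    f"per wavelength (expected {len(w)}, got {L.shape})"
                )
            if not np.all(L > 0):
                raise ConfigError(f"pathlengths for class {cls!r} must be positive")
        if self.baseline_total_hb_uM <= 0:
            raise ConfigError("baseline total hemoglobin must be positive")
        for cls, s in self.baseline_saturation.items():
            if not 0 < s <= 1:
                raise ConfigError(
                    f"baseline saturation for class {cls!r} must lie in (0, 1]"
                )

    def design_matrix(self, roi_class: str) -> np.ndarray:
        """Unmixing design ``M[l, i] = eps_i(l) * L(l)`` for a tissue class."""
        if roi_class not in self.pathlength_cm:
            raise ConfigError(
                f"unknown tissue class {roi_class!r}; "
                f"known: {sorted(self.pathlength_cm)}"
            )
        return self.epsilon * self.pathlength_cm[roi_class][:, None]

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "wavelengths_nm": self.wavelengths_nm.tolist(),
            "epsilon": self.epsilon.tolist(),
            "pathlength_cm": {k: v.tolist() for k, v in self.pathlength_cm.items()},
            "baseline_total_hb_uM": float(self.baseline_total_hb_uM),
            "baseline_saturation": {
                k: float(v) for k, v in self.baseline_saturation.items()
            },
            "bandwidths_nm": self.bandwidths_nm.tolist(),
            "condition_bound": float(self.condition_bound),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SpectroConfig":
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SpectroConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if not isinstance(d, dict):
            raise ConfigError(f"malformed spectroscopy config: {path}")
        return cls.from_dict(d)
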