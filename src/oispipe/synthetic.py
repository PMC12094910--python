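"""Forward-model synthetic data with known ground truth.

Every input the pipeline consumes can be generated here: multispectral
reflectance stacks rendered from planted hemodynamic fields through the exact
inverse of the unmixing model, bout-structured locomotion traces, trial-level
cohorts with planted group effects, toy histology sections with exact stain
fractions, and NOR exploration tracks with a known object preference.

The stimulus-evoked response uses a gamma-variate kernel whose parameters are
chosen so that the HbT response to a 2-s stimulation peaks 3.3-4.6 s after
onset, the physiological range for whisker-stimulation functional hyperemia
in awake mice.

The cohort generator's behavioural model: when locomotion is concurrent with
the stimulation (categories 3/4), the locomotion-coupled vascular response
dominates and is identical across disease groups, so any planted group
deficit is expressed only in rest-state (category 1/2) trials.  This mirrors
the phenomenon the trial-classification stage exists to expose — group
differences visible at rest and masked by locomotion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .behavior import ArenaObject, NorTrack
from .config import SpectroConfig
from .errors import ConfigError, InputError
from .spectroscopy import ReflectanceStack
from .trials import STIM_PROTOCOLS, LocomotionTrace

__all__ = [
    "gamma_kernel",
    "stimulus_response",
    "GroupSpec",
    "CohortSpec",
    "simulate_hemodynamics",
    "render_reflectance",
    "simulate_locomotion",
    "schedule_locomotion",
    "simulate_session_traces",
    "simulate_cohort_traces",
    "simulate_cohort",
    "render_histology",
    "simulate_nor_track",
]

#: Default gamma-variate kernel: peak time and shape.  With a 2-s boxcar
#: stimulus the convolved response peaks ~3.8 s after onset.
KERNEL_PEAK_S = 2.8
KERNEL_SHAPE = 3.0


def gamma_kernel(
    t: np.ndarray, peak_time_s: float = KERNEL_PEAK_S, shape: float = KERNEL_SHAPE
) -> np.ndarray:
    """Gamma-variate impulse response, unit peak at ``peak_time_s``."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    x = t[pos] / peak_time_s
    out[pos] = x**shape * np.exp(shape * (1.0 - x))
    return out


def stimulus_response(
    times_s: np.ndarray,
    onset_s: float,
    stim_duration_s: float,
    amplitude: float = 1.0,
    peak_time_s: float = KERNEL_PEAK_S,
    shape: float = KERNEL_SHAPE,
) -> np.ndarray:
    """Boxcar stimulus convolved with the gamma kernel, scaled to ``amplitude`` peak."""
    times_s = np.asarray(times_s, dtype=float)
    dt = float(times_s[1] - times_s[0])
    kt = np.arange(0, peak_time_s * 8, dt)
    kern = gamma_kernel(kt, peak_time_s, shape)
    box = ((times_s >= onset_s) & (times_s < onset_s + stim_duration_s)).astype(float)
    resp = np.convolve(box, kern)[: len(times_s)] * dt
    peak = resp.max()
    if peak > 0:
        resp *= amplitude / peak
    return resp


# ----------------------------------------------------------------------
# locomotion


def simulate_locomotion(
    duration_s: float,
    sample_rate_hz: float = 32.0,
    bout_rate_hz: float = 0.03,
    bout_duration_mean_s: float = 2.0,
    bout_duration_sigma: float = 0.5,
    max_magnitude: int = 10,
    seed: int = 0,
    trigger_times_s: Optional[Sequence[float]] = None,
) -> LocomotionTrace:
    """Poisson-process locomotion bouts with lognormal durations.

    Magnitudes are positive integers (arbitrary sensor units) during bouts and
    exactly zero elsewhere, matching an optical treadmill sensor.
    """
    if bout_rate_hz < 0 or bout_duration_mean_s <= 0:
        raise InputError("bout rate must be >= 0 and durations positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * sample_rate_hz))
    times = np.arange(n) / sample_rate_hz
    values = np.zeros(n)
    if bout_rate_hz > 0:
        n_bouts = rng.poisson(bout_rate_hz * duration_s)
        onsets = rng.uniform(0, duration_s, size=n_bouts)
        durations = rng.lognormal(
            np.log(bout_duration_mean_s), bout_duration_sigma, size=n_bouts
        )
        for t0, d in zip(onsets, durations):
            lo = int(round(t0 * sample_rate_hz))
            hi = min(int(round((t0 + d) * sample_rate_hz)), n)
            if hi > lo:
                values[lo:hi] = rng.integers(1, max_magnitude + 1)
    return LocomotionTrace(
        values=values,
        times_s=times,
        trigger_times_s=np.asarray(
            trigger_times_s if trigger_times_s is not None else [], dtype=float
        ),
    )


def schedule_locomotion(
    duration_s: float,
    trigger_times_s: Sequence[float],
    categories: Sequence[int],
    stim_duration_s: float,
    sample_rate_hz: float = 32.0,
    magnitude: int = 5,
    bout_s: float = 2.0,
    seed: int = 0,
) -> LocomotionTrace:
    """Construct a locomotion trace realizing a requested category per trial.

    Category 2 places a bout strictly inside [onset-4, onset); category 3 a
    bout starting at onset; category 4 both; category 1 leaves the peri-trial
    windows clean.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * sample_rate_hz))
    times = np.arange(n) / sample_rate_hz
    values = np.zeros(n)

    def put(t0: float, dur: float) -> None:
        lo = max(int(round(t0 * sample_rate_hz)), 0)
        hi = min(int(round((t0 + dur) * sample_rate_hz)), n)
        if hi > lo:
            values[lo:hi] = rng.integers(1, magnitude + 1)

    for t0, cat in zip(trigger_times_s, categories):
        if cat not in (1, 2, 3, 4):
            raise InputError(f"locomotion category must be 1-4, got {cat}")
        pre_bout = min(bout_s, 3.0)
        if cat in (2, 4):
            put(t0 - 3.5, pre_bout)  # inside [onset-4, onset)
        if cat in (3, 4):
            put(t0, min(bout_s, stim_duration_s + 3.5))
    return LocomotionTrace(
        values=values,
        times_s=times,
        trigger_times_s=np.asarray(trigger_times_s, dtype=float),
    )


# ----------------------------------------------------------------------
# cohort specification


@dataclass
class GroupSpec:
    """One disease group's planted response parameters."""

    name: str
    n_animals: int = 2
    rest_peak_uM: float = 2.0  # stimulus-evoked HbT peak in rest trials
    hbo_to_hbt_ratio: float = 1.3  # dHbO = ratio * dHbT; dHbR = (1-ratio) * dHbT


@dataclass
class CohortSpec:
    """Study design for a simulated cohort.

    Defaults match the imaging design: four groups, 30 trials per 2-s
    session (15 for 16-s), 32-Hz sampling.  The locomotion-coupled response
    (``loco_peak_uM``) is shared across groups.
    """

    groups: List[GroupSpec] = field(
        default_factory=lambda: [
            GroupSpec("WT"),
            GroupSpec("AD"),
            GroupSpec("ATH", rest_peak_uM=1.5),  # -25% planted deficit
            GroupSpec("MIX"),
        ]
    )
    stim_type: str = "2s"
    sessions_per_animal: int = 1
    trials_per_session: Optional[int] = None  # default 30 (2s) / 15 (16s)
    sample_rate_hz: float = 32.0
    trial_interval_s: float = 26.0
    lead_in_s: float = 12.0
    amplitude_trial_sd_uM: float = 0.25
    amplitude_animal_sd_uM: float = 0.08
    trace_noise_uM: float = 0.05
    loco_peak_uM: float = 3.0
    loco_gain_uM_per_au: float = 0.05
    category_probs: Tuple[float, float, float, float] = (0.45, 0.05, 0.45, 0.05)

    def __post_init__(self) -> None:
        if self.stim_type not in STIM_PROTOCOLS:
            raise ConfigError(f"unknown stimulation protocol {self.stim_type!r}")
        if self.trials_per_session is None:
            self.trials_per_session = 30 if self.stim_type == "2s" else 15
        if abs(sum(self.category_probs) - 1.0) > 1e-9:
            raise ConfigError("category probabilities must sum to 1")
        proto = STIM_PROTOCOLS[self.stim_type]
        if self.trial_interval_s < proto["pre_s"] + proto["post_s"]:
            raise ConfigError("trial interval shorter than the trial window")

    def trigger_times(self) -> np.ndarray:
        n = self.trials_per_session
        return self.lead_in_s + STIM_PROTOCOLS[self.stim_type]["pre_s"] + (
            np.arange(n) * self.trial_interval_s
        )

    def session_duration_s(self) -> float:
        proto = STIM_PROTOCOLS[self.stim_type]
        return float(self.trigger_times()[-1] + proto["post_s"] + 5.0)


def simulate_session_traces(
    spec: CohortSpec,
    group: GroupSpec,
    animal_id: str,
    session_id: str,
    animal_offset_uM: float,
    seed: int,
) -> dict:
    """One animal-session of ROI-level traces with per-trial ground truth.

    Returns times, hbt/hbo/hbr traces, a LocomotionTrace carrying the
    triggers, and the planted per-trial amplitudes and categories.
    """
    rng = np.random.default_rng(seed)
    proto = STIM_PROTOCOLS[spec.stim_type]
    triggers = spec.trigger_times()
    duration = spec.session_duration_s()
    fr = spec.sample_rate_hz
    times = np.arange(int(round(duration * fr))) / fr

    categories = rng.choice(
        [1, 2, 3, 4], size=len(triggers), p=list(spec.category_probs)
    )
    loco = schedule_locomotion(
        duration,
        triggers,
        categories,
        proto["stim_s"],
        sample_rate_hz=fr,
        seed=int(rng.integers(2**31)),
    )

    hbt = np.zeros_like(times)
    amplitudes = np.empty(len(triggers))
    for i, (t0, cat) in enumerate(zip(triggers, categories)):
        if cat in (3, 4):
            base = spec.loco_peak_uM  # locomotion-dominated, group-independent
        else:
            base = group.rest_peak_uM + animal_offset_uM
        amp = base + rng.normal(0, spec.amplitude_trial_sd_uM)
        amplitudes[i] = amp
        hbt += stimulus_response(times, t0, proto["stim_s"], amp)

    # slow locomotion-coupled baseline component, shared across groups
    smooth = ndimage.gaussian_filter1d(loco.values, sigma=fr * 0.5)
    hbt += spec.loco_gain_uM_per_au * smooth
    hbt += rng.normal(0, spec.trace_noise_uM, size=len(times))

    r = group.hbo_to_hbt_ratio
    hbo = r * hbt
    hbr = (1.0 - r) * hbt
    return {
        "animal_id": animal_id,
        "group": group.name,
        "session_id": session_id,
        "times_s": times,
        "hemo": {"hbt": hbt, "hbo": hbo, "hbr": hbr},
        "loco": loco,
        "truth": {
            "categories": categories.tolist(),
            "amplitudes_uM": amplitudes.tolist(),
            "rest_peak_uM": group.rest_peak_uM,
            "animal_offset_uM": animal_offset_uM,
        },
    }


def simulate_cohort_traces(spec: CohortSpec, seed: int = 0) -> Tuple[List[dict], dict]:
    """ROI-trace-level cohort: every animal-session plus a ground-truth record."""
    rng = np.random.default_rng(seed)
    sessions: List[dict] = []
    truth = {"groups": {}, "seed": seed}
    for g in spec.groups:
        truth["groups"][g.name] = {
            "rest_peak_uM": g.rest_peak_uM,
            "n_animals": g.n_animals,
        }
        for a in range(g.n_animals):
            animal_id = f"{g.name}_{a + 1:02d}"
            offset = rng.normal(0, spec.amplitude_animal_sd_uM)
            for s in range(spec.sessions_per_animal):
                sessions.append(
                    simulate_session_traces(
                        spec,
                        g,
                        animal_id,
                        f"day{s + 1}",
                        offset,
                        seed=int(rng.integers(2**31)),
                    )
                )
    return sessions, truth


# ----------------------------------------------------------------------
# imaging-level simulation


def _spatial_layout(shape: Tuple[int, int]) -> Dict[str, np.ndarray]:
    """Planted scene: Gaussian whisker blob, artery and vein stripes."""
    h, w = shape
    rows, cols = np.mgrid[0:h, 0:w]
    cy, cx = h * 0.5, w * 0.5
    sigma = min(h, w) / 8.0
    blob = np.exp(-(((rows - cy) ** 2 + (cols - cx) ** 2) / (2 * sigma**2)))
    stripe_w = max(1, w // 24)
    artery = (np.abs(cols - (cx - 2 * stripe_w)) <= stripe_w) & (blob > 0.2)
    vein = (np.abs(cols - (cx + 2 * stripe_w)) <= stripe_w) & (blob > 0.2)
    return {"blob": blob, "artery": artery, "vein": vein}


def simulate_hemodynamics(
    shape: Tuple[int, int] = (64, 64),
    duration_s: float = 60.0,
    frame_rate_hz: float = 32.0,
    trigger_times_s: Sequence[float] = (10.0, 35.0),
    stim_duration_s: float = 2.0,
    peak_dhbt_uM: float = 2.0,
    hbo_to_hbt_ratio: float = 1.3,
    loco: Optional[LocomotionTrace] = None,
    loco_gain_uM_per_au: float = 0.0,
) -> dict:
    """Planted hemodynamic concentration fields on an image grid.

    The evoked HbT response is a gamma-variate time course spatially
    modulated by a central Gaussian blob; an "artery" stripe responds 1.5x
    stronger and an adjacent "vein" stripe carries a doubled, delayed HbR
    washout.  Returns dhbo/dhbr/dhbt fields plus the scene masks.
    """
    n = int(round(duration_s * frame_rate_hz))
    times = np.arange(n) / frame_rate_hz
    trace = np.zeros(n)
    for t0 in trigger_times_s:
        trace += stimulus_response(times, t0, stim_duration_s, peak_dhbt_uM)
    if loco is not None and loco_gain_uM_per_au > 0:
        trace = trace + loco_gain_uM_per_au * ndimage.gaussian_filter1d(
            loco.resample(times), sigma=frame_rate_hz * 0.5
        )

    scene = _spatial_layout(shape)
    weight = scene["blob"] * (1.0 + 0.5 * scene["artery"])
    dhbt = trace[:, None, None] * weight[None, :, :]

    r = hbo_to_hbt_ratio
    dhbo = r * dhbt
    dhbr = (1.0 - r) * dhbt
    # vein: doubled, delayed washout
    delay = int(round(0.5 * frame_rate_hz))
    delayed = np.roll(trace, delay)
    delayed[:delay] = 0.0
    extra = (r - 1.0) * delayed[:, None, None] * scene["vein"][None, :, :]
    dhbr = dhbr - extra
    dhbo = dhbo + extra  # keep dhbt = dhbo + dhbr exact

    return {
        "times_s": times,
        "dhbo": dhbo,
        "dhbr": dhbr,
        "dhbt": dhbo + dhbr,
        "scene": scene,
        "trigger_times_s": np.asarray(trigger_times_s, dtype=float),
        "stim_duration_s": stim_duration_s,
        "frame_rate_hz": frame_rate_hz,
    }


def render_reflectance(
    dhbo: np.ndarray,
    dhbr: np.ndarray,
    cfg: SpectroConfig,
    roi_class: str = "tissue",
    noise_sigma: float = 0.0,
    seed: int = 0,
    r0: float = 1000.0,
    frame_rate_hz: float = 32.0,
    trigger_times_s: Sequence[float] = (),
    stim_duration_s: float = 2.0,
    **stack_labels,
) -> ReflectanceStack:
    """Forward-render concentration fields to a multispectral stack.

    ``R(l,t,x,y) = R0 * exp(-[eps_HbO dHbO + eps_HbR dHbR] L) * (1 + eta)``
    with multiplicative Gaussian noise truncated at 4 sigma so intensities
    stay positive; ``noise_sigma = 0`` gives an exact round trip through the
    unmixing stage.
    """
    if noise_sigma < 0 or noise_sigma > 0.2:
        raise InputError("noise sigma must lie in [0, 0.2] to keep R positive")
    M = cfg.design_matrix(roi_class)  # (n_wavelengths, 2)
    od = (
        M[:, 0][:, None, None, None] * dhbo[None]
        + M[:, 1][:, None, None, None] * dhbr[None]
    )
    data = r0 * np.exp(-od)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        eta = np.clip(
            rng.normal(0, noise_sigma, size=data.shape), -4 * noise_sigma, 4 * noise_sigma
        )
        data = data * (1.0 + eta)
    return ReflectanceStack(
        data=data,
        wavelengths_nm=cfg.wavelengths_nm,
        frame_rate_hz=frame_rate_hz,
        trigger_times_s=np.asarray(trigger_times_s, dtype=float),
        stim_duration_s=stim_duration_s,
        **stack_labels,
    )


def simulate_cohort(
    spec: CohortSpec,
    outdir,
    cfg: Optional[SpectroConfig] = None,
    shape: Tuple[int, int] = (64, 64),
    seed: int = 0,
    noise_sigma: float = 0.0,
) -> dict:
    """Write a full on-disk imaging cohort consumable by the CLI.

    One stack directory per animal-session (TIFF per wavelength + JSON
    sidecar), a locomotion CSV per session, and a ``truth.json`` recording
    the planted per-group effect sizes.
    """
    from . import io as _io  # deferred: io imports this module's containers

    cfg = cfg or SpectroConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    proto = STIM_PROTOCOLS[spec.stim_type]
    sessions, truth = simulate_cohort_traces(spec, seed=int(rng.integers(2**31)))
    layout = []
    for sess in sessions:
        name = f"{sess['animal_id']}_{sess['session_id']}"
        stack_dir = outdir / name
        # spatially modulate the session ROI trace by the planted blob
        scene = _spatial_layout(shape)
        dhbt = sess["hemo"]["hbt"][:, None, None] * scene["blob"][None, :, :]
        ratio = next(
            g.hbo_to_hbt_ratio for g in spec.groups if g.name == sess["group"]
        )
        dhbo = ratio * dhbt
        dhbr = (1.0 - ratio) * dhbt
        stack = render_reflectance(
            dhbo,
            dhbr,
            cfg,
            noise_sigma=noise_sigma,
            seed=int(rng.integers(2**31)),
            frame_rate_hz=spec.sample_rate_hz,
            trigger_times_s=sess["loco"].trigger_times_s,
            stim_duration_s=proto["stim_s"],
            animal=sess["animal_id"],
            group=sess["group"],
            session=sess["session_id"],
        )
        _io.write_stack(stack_dir, stack)
        _io.write_locomotion(stack_dir / "locomotion.csv", sess["loco"])
        layout.append(
            {
                "dir": name,
                "animal_id": sess["animal_id"],
                "group": sess["group"],
                "session_id": sess["session_id"],
            }
        )
        truth.setdefault("sessions", {})[name] = sess["truth"]
    truth["layout"] = layout
    truth["stim_type"] = spec.stim_type
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
    return truth


# ----------------------------------------------------------------------
# histology and behavior


def _blobby_mask(
    shape: Tuple[int, int],
    region: np.ndarray,
    fraction: float,
    rng: np.random.Generator,
    smooth_px: float = 6.0,
) -> np.ndarray:
    """Blob-shaped mask covering exactly round(fraction * region area) pixels.

    A smoothed random field restricted to ``region`` is thresholded at the
    quantile that yields the requested pixel count, so the planted fraction
    is pixel-exact while the shapes stay plaque-like.
    """
    n_target = int(round(fraction * region.sum()))
    if n_target == 0:
        return np.zeros(shape, dtype=bool)
    fld = ndimage.gaussian_filter(rng.standard_normal(shape), smooth_px)
    vals = fld[region]
    if n_target >= len(vals):
        return region.copy()
    cut = np.partition(vals, -n_target)[-n_target]
    mask = region & (fld >= cut)
    # resolve quantile ties to hit the exact count
    excess = int(mask.sum()) - n_target
    if excess > 0:
        idx = np.argwhere(mask & (fld == cut))
        for r, c in idx[:excess]:
            mask[r, c] = False
    return mask


def render_histology(
    kind: str,
    stain_fraction: float,
    seed: int = 0,
    size: int = 512,
) -> dict:
    """Toy histology image with an exactly known stained-area fraction.

    ``kind='dab'``: an RGB section rendered through the inverse stain-
    deconvolution transform — hematoxylin-toned tissue with DAB-dense blobs
    covering ``stain_fraction`` of the tissue.  ``kind='oilredo'``: an 8-bit
    grayscale aortic arch (polygon returned) with dark lipid blobs covering
    ``stain_fraction`` of the arch area.
    """
    if not 0 <= stain_fraction <= 1:
        raise InputError("stain fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    shape = (size, size)
    if kind == "dab":
        from skimage.color import hed2rgb

        tissue = np.ones(shape, dtype=bool)
        stain = _blobby_mask(shape, tissue, stain_fraction, rng)
        hed = np.zeros(shape + (3,))
        hed[..., 0] = 0.35  # hematoxylin counterstain everywhere
        hed[..., 2] = np.where(stain, 0.6, 0.02)
        rgb = np.clip(hed2rgb(hed), 0, 1)
        return {"image": rgb, "stain_mask": stain, "tissue_mask": tissue,
                "fraction": stain_fraction}
    if kind == "oilredo":
        m = size
        poly = np.array(
            [
                (0.15 * m, 0.20 * m),
                (0.15 * m, 0.80 * m),
                (0.85 * m, 0.80 * m),
                (0.85 * m, 0.20 * m),
            ]
        )
        from skimage.draw import polygon2mask

        arch = polygon2mask(shape, poly)
        stain = _blobby_mask(shape, arch, stain_fraction, rng)
        img = np.full(shape, 230.0)
        img[arch] = 200.0  # unstained arch tissue, above threshold
        img[stain] = 60.0  # Oil-Red-O positive, below threshold
        return {
            "image": img.astype(np.uint8),
            "polygon": poly,
            "stain_mask": stain,
            "arch_mask": arch,
            "fraction": stain_fraction,
        }
    raise InputError(f"unknown histology kind {kind!r}")


def simulate_nor_track(
    preference: float,
    n_frames: int = 10_000,
    frame_rate_hz: float = 30.0,
    seed: int = 0,
    visit_mean_frames: int = 60,
    travel_frames: int = 15,
) -> NorTrack:
    """Biased exploration track: the nose dwells near the novel object with
    probability ``preference`` per visit, so the expected preference index
    approaches ``100 * preference`` as the track grows."""
    if not 0 <= preference <= 1:
        raise InputError("preference must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    half = 2.0
    objects = [
        ArenaObject(
            "familiar", "familiar", (10.0, 10.0),
            [(10 - half, 10 - half), (10 + half, 10 - half),
             (10 + half, 10 + half), (10 - half, 10 + half)],
        ),
        ArenaObject(
            "novel", "novel", (30.0, 30.0),
            [(30 - half, 30 - half), (30 + half, 30 - half),
             (30 + half, 30 + half), (30 - half, 30 + half)],
        ),
    ]
    nose = np.empty((n_frames, 2))
    i = 0
    while i < n_frames:
        # wander in the middle, away from both objects
        n_w = min(travel_frames, n_frames - i)
        nose[i : i + n_w] = 20.0 + rng.normal(0, 1.0, size=(n_w, 2))
        i += n_w
        if i >= n_frames:
            break
        obj = objects[1] if rng.random() < preference else objects[0]
        n_v = min(1 + rng.geometric(1.0 / visit_mean_frames), n_frames - i)
        ang = rng.uniform(0, 2 * np.pi, size=n_v)
        d = half + rng.uniform(0.3, 1.5, size=n_v)  # 0.3-1.5 cm off the boundary
        cx, cy = obj.center
        pts = np.column_stack([cx + d * np.cos(ang), cy + d * np.sin(ang)])
        nose[i : i + n_v] = np.clip(pts, 0.0, 40.0)
        i += n_v
    centroid = np.clip(nose + rng.normal(0, 0.2, size=nose.shape), 0.0, 40.0)
    return NorTrack(
        nose_xy=nose,
        centroid_xy=centroid,
        frame_rate_hz=frame_rate_hz,
        objects=objects,
        phase="testing",
    )
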