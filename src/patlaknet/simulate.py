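"""Synthetic whole-body dynamic FDG-PET cohorts with known kinetics.

The simulator emulates a hybrid whole-body dynamic protocol: a 20-frame
early single-bed acquisition over the blood pool (8x5 s, 4x10 s, 4x25 s,
4x45 s), 13 whole-body passes, and a late ~20-min static SUV acquisition
at ~60 min post-injection.  Tissue time-activity curves follow an
irreversible two-tissue compartment model (k4 = 0 by default), so every
voxel carries an exact ground-truth net influx rate

    Ki = K1 * k3 / (k2 + k3)        [mL s^-1 mL^-1]

The plasma input function is a Feng-type tri-exponential, a parametric
stand-in for an image-derived input function.  All times are in seconds
and activity concentrations in kBq/mL unless a series is tagged "SUV".
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.signal import fftconvolve

logger = logging.getLogger(__name__)

__all__ = [
    "PlasmaInputFunction",
    "KineticParams",
    "AcquisitionProtocol",
    "DynamicSeries",
    "LesionSpec",
    "PhantomSubject",
    "feng_input",
    "tissue_tac",
    "frame_average",
    "ki_true",
    "render_subject",
    "make_cohort",
    "build_atlas",
    "TISSUE_DEFAULTS",
    "BACKGROUND",
    "LUNG",
    "LIVER",
    "BRAIN",
    "BLOOD",
    "SOFT",
]


class InvalidParameterError(ValueError):
    """Raised for non-finite or out-of-range kinetic/input-function parameters."""


class DegenerateParameterError(ValueError):
    """Raised when a macro-parameter is requested for degenerate micro-parameters."""


# ---------------------------------------------------------------------------
# plasma input function
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlasmaInputFunction:
    """Feng-type tri-exponential plasma curve.

    Cp(t) = (a1*(t-t0) - a2 - a3) e^{-lam1 (t-t0)}
            + a2 e^{-lam2 (t-t0)} + a3 e^{-lam3 (t-t0)}     for t > t0,
    and 0 for t <= t0.  Decay rates must satisfy lam1 > lam2 > lam3 > 0.

    Defaults are the classic FDG blood-curve shape rescaled so that a
    ~280 MBq injection in a 75 kg subject yields clinically plausible
    concentrations (peak ~30 kBq/mL shortly after t0, late tail ~4 kBq/mL).
    """

    a1: float = 5.25        # kBq mL^-1 s^-1
    a2: float = 7.7         # kBq/mL, paired with lam2
    a3: float = 8.1         # kBq/mL, paired with lam3
    lam1: float = 0.0689    # s^-1
    lam2: float = 0.001985  # s^-1
    lam3: float = 0.000174  # s^-1
    t0: float = 10.0        # s, appearance delay

    def __post_init__(self) -> None:
        vals = [self.a1, self.a2, self.a3, self.lam1, self.lam2, self.lam3, self.t0]
        if not all(math.isfinite(v) for v in vals):
            raise InvalidParameterError("input-function parameters must be finite")
        if not (self.lam1 > self.lam2 > self.lam3 > 0):
            raise InvalidParameterError(
                f"decay rates must satisfy lam1 > lam2 > lam3 > 0, got "
                f"{self.lam1}, {self.lam2}, {self.lam3}"
            )

    def __call__(self, t):
        return feng_input(t, self)


def feng_input(t, pif: PlasmaInputFunction):
    """Evaluate the plasma input function at time(s) ``t`` (seconds).

    Negative values (possible only through pathological parameters) are
    clamped to zero with a logged warning.
    """
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise InvalidParameterError("time values must be finite")
    x = t - pif.t0
    with np.errstate(over="ignore", under="ignore"):
        cp = (
            (pif.a1 * x - pif.a2 - pif.a3) * np.exp(-pif.lam1 * x)
            + pif.a2 * np.exp(-pif.lam2 * x)
            + pif.a3 * np.exp(-pif.lam3 * x)
        )
    cp = np.where(x > 0, cp, 0.0)
    if np.any(cp < 0):
        logger.warning("input function clamped at 0 for %d sample(s)", int(np.sum(cp < 0)))
        cp = np.maximum(cp, 0.0)
    return cp if cp.ndim else float(cp)


# ---------------------------------------------------------------------------
# kinetics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KineticParams:
    """Two-tissue compartment micro-parameters (irreversible when k4 = 0)."""

    K1: float           # mL s^-1 mL^-1, plasma -> free
    k2: float           # s^-1, free -> plasma
    k3: float           # s^-1, free -> bound
    k4: float = 0.0     # s^-1, bound -> free (model-mismatch stress only)
    vb: float = 0.0     # blood volume fraction, [0, 1)

    def __post_init__(self) -> None:
        vals = [self.K1, self.k2, self.k3, self.k4, self.vb]
        if not all(math.isfinite(v) for v in vals):
            raise InvalidParameterError("kinetic parameters must be finite")
        if min(self.K1, self.k2, self.k3, self.k4) < 0:
            raise InvalidParameterError("rate constants must be >= 0")
        if not (0.0 <= self.vb <= 1.0):
            # vb = 1 is the pure blood-pool voxel (C = Cp exactly)
            raise InvalidParameterError(f"vb must be in [0, 1], got {self.vb}")


def ki_true(params: KineticParams) -> float:
    """Net influx rate Ki = K1*k3/(k2+k3) of the irreversible model."""
    denom = params.k2 + params.k3
    if denom == 0.0:
        raise DegenerateParameterError("k2 + k3 must be > 0 for Ki")
    return params.K1 * params.k3 / denom


def _tac_fine(params: KineticParams, pif: PlasmaInputFunction, t_end: float,
              dt: float = 0.25):
    """Tissue TAC on a fine uniform grid [0, t_end] by numerical convolution.

    Returns ``(grid, C)`` where C includes the vascular contribution:
    C = (1-vb)*C_tissue + vb*Cp.
    """
    n = int(np.ceil(t_end / dt)) + 1
    grid = np.arange(n) * dt
    cp = feng_input(grid, pif)
    beta = params.k2 + params.k3
    if params.k4 == 0.0:
        if beta == 0.0:
            c_tissue = params.K1 * _cumtrapz(cp, dt)
        else:
            ki = params.K1 * params.k3 / beta
            c_tissue = ki * _cumtrapz(cp, dt) \
                + (params.K1 * params.k2 / beta) * _exp_conv(cp, beta, grid, dt)
    else:
        # general two-tissue solution: sum of two exponential convolutions
        s = params.k2 + params.k3 + params.k4
        disc = math.sqrt(max(s * s - 4.0 * params.k2 * params.k4, 0.0))
        a1 = 0.5 * (s - disc)
        a2 = 0.5 * (s + disc)
        if a2 == a1:  # repeated root, vanishing measure; nudge
            a2 = a1 * (1 + 1e-12) + 1e-18
        w1 = params.K1 * (params.k3 + params.k4 - a1) / (a2 - a1)
        w2 = params.K1 * (a2 - params.k3 - params.k4) / (a2 - a1)
        c_tissue = w1 * _exp_conv(cp, a1, grid, dt) + w2 * _exp_conv(cp, a2, grid, dt)
    return grid, (1.0 - params.vb) * c_tissue + params.vb * cp


def _exp_conv(cp: np.ndarray, rate: float, grid: np.ndarray, dt: float) -> np.ndarray:
    """(e^{-rate t} conv cp) on the grid, trapezoid-corrected at the endpoints."""
    n = len(grid)
    conv = fftconvolve(cp, np.exp(-rate * grid))[:n] * dt
    # rectangle -> trapezoid: subtract half the endpoint contributions
    # (kernel(0) = 1 pairs with cp(t); cp(0) = 0 kills the other end)
    return conv - 0.5 * dt * (cp + cp[0] * np.exp(-rate * grid))


def _cumtrapz(y: np.ndarray, dt: float) -> np.ndarray:
    out = np.empty_like(y)
    out[0] = 0.0
    np.cumsum(0.5 * dt * (y[1:] + y[:-1]), out=out[1:])
    return out


def tissue_tac(params: KineticParams, pif: PlasmaInputFunction, times,
               dt: float = 0.25):
    """Tissue activity concentration on the sample grid ``times`` (s).

    ``times`` must be strictly increasing and start at 0.  The curve is
    computed by high-resolution numerical convolution and interpolated
    onto the requested grid.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 1:
        raise ValueError("times must be a 1-D sample grid")
    if times[0] != 0.0 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing, starting at 0")
    grid, c = _tac_fine(params, pif, float(times[-1]), dt=dt)
    return np.interp(times, grid, c)


def frame_average(params: KineticParams, pif: PlasmaInputFunction, windows,
                  dt: float = 0.25) -> np.ndarray:
    """Mean of the tissue TAC over each ``(start, duration)`` window."""
    windows = list(windows)
    t_end = max(s + d for s, d in windows)
    grid, c = _tac_fine(params, pif, t_end, dt=dt)
    cum = _cumtrapz(c, dt)
    out = np.empty(len(windows))
    for i, (s, d) in enumerate(windows):
        if d <= 0:
            raise ValueError("frame durations must be > 0")
        out[i] = (np.interp(s + d, grid, cum) - np.interp(s, grid, cum)) / d
    return out


# ---------------------------------------------------------------------------
# acquisition protocol
# ---------------------------------------------------------------------------

def _paper_early_frames():
    frames, t = [], 0.0
    for dur, n in ((5.0, 8), (10.0, 4), (25.0, 4), (45.0, 4)):
        for _ in range(n):
            frames.append((t, dur))
            t += dur
    return frames


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Frame timing of the hybrid whole-body dynamic protocol.

    Defaults: 20 early cardiac frames covering 0-360 s, thirteen 180-s
    whole-body passes back-to-back from 600 s p.i., and a 20-min SUV
    acquisition starting at 3600 s.
    """

    early_frames: tuple = field(default_factory=lambda: tuple(_paper_early_frames()))
    pass_windows: tuple = field(
        default_factory=lambda: tuple((600.0 + 180.0 * k, 180.0) for k in range(13))
    )
    suv_window: tuple = (3600.0, 1200.0)

    def __post_init__(self) -> None:
        for name, frames in (("early_frames", self.early_frames),
                             ("pass_windows", self.pass_windows)):
            prev_end = -np.inf
            for start, dur in frames:
                if dur <= 0:
                    raise ValueError(f"{name}: durations must be > 0")
                if start < prev_end - 1e-9:
                    raise ValueError(f"{name}: frames must be non-overlapping and ordered")
                prev_end = start + dur
        if self.pass_windows and self.suv_window[0] < self.pass_windows[-1][0] + self.pass_windows[-1][1]:
            raise ValueError("suv_window must start after the last pass")

    @property
    def n_passes(self) -> int:
        return len(self.pass_windows)

    @property
    def t_end(self) -> float:
        return self.suv_window[0] + self.suv_window[1]


# ---------------------------------------------------------------------------
# image series container
# ---------------------------------------------------------------------------

@dataclass
class DynamicSeries:
    """A stack of image frames with timing metadata.

    ``frames`` has shape (T, S, H, W): T time frames over S transaxial
    slices.  ``timing`` is a list of (start s, duration s).
    """

    frames: np.ndarray
    timing: list
    voxel_size_mm: float = 4.0
    slice_thickness_mm: float = 40.0
    units: str = "kBq/mL"
    weight_kg: float | None = None
    injected_mbq: float | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 4:
            raise ValueError("frames must have shape (T, S, H, W)")
        if self.frames.shape[0] != len(self.timing):
            raise ValueError(
                f"frame count {self.frames.shape[0]} does not match "
                f"{len(self.timing)} timing entries"
            )
        if any(d <= 0 for _, d in self.timing):
            raise ValueError("durations must be > 0")

    @property
    def mid_times(self) -> np.ndarray:
        return np.array([s + 0.5 * d for s, d in self.timing])

    def to_suv(self) -> "DynamicSeries":
        """Convert kBq/mL concentrations to SUV (g/mL) using subject metadata."""
        if self.units == "SUV":
            return self
        if self.weight_kg is None or self.injected_mbq is None:
            raise ValueError("weight and injected activity required for SUV conversion")
        factor = self.weight_kg / self.injected_mbq  # (kBq/mL) * kg / MBq is unitless SUV
        return replace(self, frames=self.frames * factor, units="SUV")


# ---------------------------------------------------------------------------
# phantom subjects
# ---------------------------------------------------------------------------

BACKGROUND, LUNG, LIVER, BRAIN, BLOOD, SOFT = 0, 1, 2, 3, 4, 5

TISSUE_DEFAULTS: dict[int, KineticParams] = {
    # FDG-like micro-parameters in s^-1 (typical minute-scale literature
    # values / 60); k3 set so organ Ki values (~1e-4 to 5e-4 mL/s/mL) fall
    # well inside the evaluated intensity range of clinical Ki maps, clear
    # of the 5e-5 exclusion threshold; blood has Ki = 0.
    LUNG: KineticParams(K1=6.7e-4, k2=4.2e-3, k3=1.0e-3, vb=0.15),
    LIVER: KineticParams(K1=1.4e-2, k2=1.6e-2, k3=1.7e-4, vb=0.20),
    BRAIN: KineticParams(K1=1.7e-3, k2=2.2e-3, k3=1.05e-3, vb=0.05),
    BLOOD: KineticParams(K1=0.0, k2=1e-3, k3=0.0, vb=1.0),
    SOFT: KineticParams(K1=1.3e-3, k2=6.7e-3, k3=6.6e-4, vb=0.05),
}

# lesion recipes: multiplicative factors on the host tissue's rates plus an
# explicit vb; categories refer to intended visibility on (SUV, Ki) images.
_LESION_RECIPES = {
    "visible_on_both": dict(host=SOFT, K1=2.5, k2=1.0, k3=4.0, k4=0.0, vb=0.10),
    "invisible_suv_visible_ki": dict(host=LIVER, K1=1.0, k2=1.0, k3=3.5, k4=0.0, vb=0.20),
    "visible_suv_invisible_ki": dict(host=LUNG, K1=5.0, k2=1.0, k3=2.0, k4=5e-4, vb=0.30),
    "invisible_on_both": dict(host=SOFT, K1=1.2, k2=1.0, k3=1.2, k4=0.0, vb=0.05),
}


@dataclass
class LesionSpec:
    label: int
    center: tuple          # (slice, row, col) voxel indices
    radius_mm: float
    category: str


@dataclass
class PhantomSubject:
    """Label atlas + per-tissue kinetics + lesions + ground-truth Ki map."""

    label_map: np.ndarray              # (S, H, W) integer atlas
    params_by_label: dict
    pif: PlasmaInputFunction
    weight_kg: float
    injected_mbq: float
    lesion_specs: list
    voxel_size_mm: float = 4.0
    slice_thickness_mm: float = 40.0

    def __post_init__(self) -> None:
        labels = np.unique(self.label_map)
        missing = [int(l) for l in labels if int(l) not in self.params_by_label]
        if missing:
            raise ValueError(f"labels {missing} missing from params_by_label")

    @property
    def ki_truth(self) -> np.ndarray:
        """Ground-truth Ki map, K1*k3/(k2+k3) per voxel."""
        out = np.zeros(self.label_map.shape, dtype=float)
        for label, p in self.params_by_label.items():
            if p.k2 + p.k3 > 0:
                out[self.label_map == label] = ki_true(p)
        return out


def _ellipse(mask_out, sl, cy, cx, ry, rx, label):
    h, w = mask_out.shape[1:]
    yy, xx = np.ogrid[:h, :w]
    inside = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
    mask_out[sl][inside] = label


def build_atlas(matrix: int = 64, n_slices: int = 6, rng=None,
                geometry_jitter: float = 0.04) -> np.ndarray:
    """Multi-slice 2-D whole-body label atlas (head / thorax / abdomen / pelvis).

    Organ ellipses are mildly jittered per subject when ``rng`` is given,
    so cohort members differ spatially as well as kinetically.
    """
    if rng is None:
        rng = np.random.default_rng(0)

    def j(v):  # jitter a geometric quantity
        return v * (1.0 + geometry_jitter * rng.uniform(-1, 1))

    m = matrix
    atlas = np.zeros((n_slices, m, m), dtype=np.int16)
    c = m / 2.0
    # body sections in roughly clinical proportions
    n_head = max(1, round(n_slices / 6))
    n_pelvis = max(1, round(n_slices / 6)) if n_slices >= 5 else max(0, n_slices - 4)
    n_thorax = max(1, round(n_slices / 3)) if n_slices >= 3 else 1
    n_abdomen = max(1, n_slices - n_head - n_thorax - n_pelvis)
    roles = (["head"] * n_head + ["thorax"] * n_thorax
             + ["abdomen"] * n_abdomen + ["pelvis"] * n_pelvis)[:n_slices]
    for sl, role in enumerate(roles):
        if role == "head":  # soft-tissue scalp + brain
            _ellipse(atlas, sl, j(c), j(c), j(0.38 * m), j(0.33 * m), SOFT)
            _ellipse(atlas, sl, j(c), j(c), j(0.28 * m), j(0.24 * m), BRAIN)
        elif role == "thorax":  # body + lungs + cardiac blood pool
            _ellipse(atlas, sl, j(c), j(c), j(0.36 * m), j(0.44 * m), SOFT)
            _ellipse(atlas, sl, j(c), j(0.30 * m), j(0.24 * m), j(0.13 * m), LUNG)
            _ellipse(atlas, sl, j(c), j(0.70 * m), j(0.24 * m), j(0.13 * m), LUNG)
            _ellipse(atlas, sl, j(0.55 * m), j(0.52 * m), j(0.11 * m), j(0.11 * m), BLOOD)
        elif role == "abdomen":  # body + liver + small aortic blood pool
            _ellipse(atlas, sl, j(c), j(c), j(0.38 * m), j(0.42 * m), SOFT)
            _ellipse(atlas, sl, j(0.45 * m), j(0.34 * m), j(0.20 * m), j(0.18 * m), LIVER)
            _ellipse(atlas, sl, j(0.50 * m), j(0.60 * m), j(0.05 * m), j(0.05 * m), BLOOD)
        else:  # pelvis: soft tissue only
            _ellipse(atlas, sl, j(c), j(c), j(0.34 * m), j(0.40 * m), SOFT)
    return atlas


def _jitter_params(p: KineticParams, rng, variability: float) -> KineticParams:
    if variability == 0.0 or p.vb == 1.0:  # blood pool stays pure blood
        return p
    def f():
        return float(np.exp(rng.normal(0.0, variability)))
    vb = min(max(p.vb * (1.0 + 0.5 * variability * rng.uniform(-1, 1)), 0.0), 0.95)
    return KineticParams(K1=p.K1 * f(), k2=p.k2 * f(), k3=p.k3 * f(),
                         k4=p.k4, vb=vb)


def make_cohort(n_subjects: int, variability: float = 0.1,
                n_lesions_per_subject: int = 3, seed: int | None = None,
                matrix: int = 64, n_slices: int = 6,
                voxel_size_mm: float = 4.0, slice_thickness_mm: float = 40.0,
                lesion_radius_mm: float = 8.0) -> list:
    """Generate a cohort of phantom subjects with jittered kinetics and lesions.

    Lesion contrasts cycle through recipes populating all three visibility
    categories (visible on both / on either / on neither of SUV and Ki).
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if lesion_radius_mm < voxel_size_mm:
        raise ValueError(
            f"lesion radius {lesion_radius_mm} mm below voxel size {voxel_size_mm} mm"
        )
    ss = np.random.SeedSequence(seed)
    categories = list(_LESION_RECIPES)
    subjects = []
    for child in ss.spawn(n_subjects):
        rng = np.random.default_rng(child)
        atlas = build_atlas(matrix, n_slices, rng=rng,
                            geometry_jitter=0.04 if variability > 0 else 0.0)
        params = {BACKGROUND: KineticParams(K1=0.0, k2=1e-3, k3=0.0, vb=0.0)}
        for label, p in TISSUE_DEFAULTS.items():
            params[label] = _jitter_params(p, rng, variability)
        weight = float(np.clip(rng.normal(75.0, 10.0 * (variability > 0)), 50.0, 100.0))
        dose_per_kg = float(np.clip(rng.normal(3.71, 1.05 * (variability > 0)), 1.5, 6.0))
        # blood concentration scales with injected dose per kg (the premise of
        # SUV normalization), modulated by a small physiological spread
        amp = (dose_per_kg / 3.71) * float(np.exp(rng.normal(0.0, 0.2 * variability)))
        base = PlasmaInputFunction()
        pif = replace(base, a1=base.a1 * amp, a2=base.a2 * amp, a3=base.a3 * amp)
        lesions = []
        r_vox = lesion_radius_mm / voxel_size_mm
        for li in range(n_lesions_per_subject):
            cat = categories[li % len(categories)]
            recipe = _LESION_RECIPES[cat]
            host = recipe["host"]
            hp = params[host]
            label = 10 + li
            lp = KineticParams(K1=hp.K1 * recipe["K1"], k2=hp.k2 * recipe["k2"],
                               k3=hp.k3 * recipe["k3"], k4=recipe["k4"],
                               vb=recipe["vb"])
            center = _place_lesion(atlas, host, r_vox, rng)
            if center is None:
                continue
            sl, cy, cx = center
            yy, xx = np.ogrid[:matrix, :matrix]
            disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r_vox ** 2
            atlas[sl][disk] = label
            params[label] = lp
            lesions.append(LesionSpec(label=label, center=(sl, cy, cx),
                                      radius_mm=lesion_radius_mm, category=cat))
        subjects.append(PhantomSubject(
            label_map=atlas, params_by_label=params, pif=pif,
            weight_kg=weight, injected_mbq=dose_per_kg * weight,
            lesion_specs=lesions, voxel_size_mm=voxel_size_mm,
            slice_thickness_mm=slice_thickness_mm,
        ))
    return subjects


def _place_lesion(atlas, host_label, r_vox, rng, margin: float = 1.5):
    """Pick a random in-organ center keeping the lesion inside the host."""
    cand = np.argwhere(atlas == host_label)
    if cand.size == 0:
        return None
    for _ in range(200):
        sl, cy, cx = cand[rng.integers(len(cand))]
        rr = int(np.ceil(r_vox * margin))
        y0, y1 = cy - rr, cy + rr + 1
        x0, x1 = cx - rr, cx + rr + 1
        if y0 < 0 or x0 < 0 or y1 > atlas.shape[1] or x1 > atlas.shape[2]:
            continue
        patch = atlas[sl, y0:y1, x0:x1]
        if np.all(patch == host_label):
            return int(sl), int(cy), int(cx)
    return None


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def render_subject(subject: PhantomSubject, protocol: AcquisitionProtocol,
                   noise_scale: float = 1.0, psf_fwhm: float = 2.0,
                   seed: int | None = None, dt: float = 0.25):
    """Render one subject into (early, passes, suv) dynamic series.

    Per voxel, the tissue TAC is frame-averaged over each window; a
    Gaussian PSF of ``psf_fwhm`` mm mirrors the post-reconstruction
    filter; Gaussian noise with variance proportional to signal/duration
    (a scaled-Poisson surrogate) is added frame-wise independently, so
    the long SUV window is correspondingly less noisy.  Deterministic
    given ``seed``.
    """
    if noise_scale < 0:
        raise ValueError("noise_scale must be >= 0")
    windows = list(protocol.early_frames) + list(protocol.pass_windows) + [protocol.suv_window]
    if not windows:
        raise ValueError("protocol defines no frames")
    rng = np.random.default_rng(seed)

    # one frame-averaged TAC per label (all voxels of a label share kinetics)
    tac_by_label = {
        int(label): frame_average(subject.params_by_label[int(label)], subject.pif,
                                  windows, dt=dt)
        for label in np.unique(subject.label_map)
    }

    n_frames = len(windows)
    vols = np.zeros((n_frames, *subject.label_map.shape), dtype=float)
    for label, tac in tac_by_label.items():
        m = subject.label_map == label
        vols[:, m] = tac[:, None]

    if psf_fwhm > 0:
        sigma = psf_fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0))) / subject.voxel_size_mm
        for f in range(n_frames):
            for s in range(vols.shape[1]):
                vols[f, s] = gaussian_filter(vols[f, s], sigma, mode="constant")

    if noise_scale > 0:
        durs = np.array([d for _, d in windows])[:, None, None, None]
        std = noise_scale * np.sqrt(np.maximum(vols, 0.0) / durs)
        vols = vols + rng.normal(size=vols.shape) * std

    n_early = len(protocol.early_frames)
    n_pass = len(protocol.pass_windows)
    meta = dict(voxel_size_mm=subject.voxel_size_mm,
                slice_thickness_mm=subject.slice_thickness_mm,
                weight_kg=subject.weight_kg, injected_mbq=subject.injected_mbq)
    early = DynamicSeries(vols[:n_early], list(protocol.early_frames), **meta)
    passes = DynamicSeries(vols[n_early:n_early + n_pass], list(protocol.pass_windows), **meta)
    suv = DynamicSeries(vols[n_early + n_pass:], [protocol.suv_window], **meta).to_suv()
    return early, passes, suv
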