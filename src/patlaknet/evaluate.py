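"""Evaluation statistics for predicted vs. reference Ki parametric maps.

Voxelwise error metrics (MAE, ME, MRAE%, RE%, MSE, RMSE, PSNR, global
SSIM), organ-VOI statistics (AME, AMRE%), lesion detectability indices
(TBR = tumor max / background mean - 1 and CNR = TBR / background SD),
joint-histogram regression, Spearman rank correlations, lesion
visibility categorization and line profiles.  Metrics are computed
patient-wise over an evaluation mask that excludes reference voxels
below 5e-5 (which subsumes negative values), applied after converting
maps back to original intensity units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
from scipy import stats

from .patlak import ParametricMap

__all__ = [
    "VOI",
    "LesionRecord",
    "EvalReport",
    "eval_mask",
    "voxel_metrics",
    "organ_metrics",
    "lesion_metrics",
    "joint_histogram",
    "spearman_by_organ",
    "categorize_lesions",
    "line_profile",
    "EVAL_THRESHOLD",
]

EVAL_THRESHOLD = 5e-5  # mL s^-1 mL^-1; voxels below are excluded from evaluation

VISIBLE_ON_BOTH = "visible_on_both"
INVISIBLE_ON_BOTH = "invisible_on_both"
VISIBLE_ON_EITHER = "visible_on_either"
INVISIBLE_SUV_VISIBLE_KI = "invisible_suv_visible_ki"
VISIBLE_SUV_INVISIBLE_KI = "visible_suv_invisible_ki"


@dataclass(frozen=True)
class VOI:
    """Spherical volume of interest (a circle on thin 2-D slice stacks)."""

    center_mm: tuple          # (z, y, x) in mm, origin at the volume corner
    diameter_mm: float = 10.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0:
            raise ValueError("diameter must be > 0")

    def rasterize(self, shape, voxel_size_mm: float,
                  slice_thickness_mm: float) -> np.ndarray:
        """Boolean mask on an (S, H, W) grid (voxel centers at (i+1/2)*spacing)."""
        s, h, w = shape
        zc, yc, xc = self.center_mm
        r = self.diameter_mm / 2.0
        zz = (np.arange(s) + 0.5) * slice_thickness_mm
        yy = (np.arange(h) + 0.5) * voxel_size_mm
        xx = (np.arange(w) + 0.5) * voxel_size_mm
        d2 = ((zz - zc) ** 2)[:, None, None] + ((yy - yc) ** 2)[None, :, None] \
            + ((xx - xc) ** 2)[None, None, :]
        mask = d2 <= r * r
        if not mask.any():
            raise ValueError(f"VOI {self.label!r} does not intersect the image grid")
        return mask


@dataclass
class LesionRecord:
    """A lesion with its background VOI and visibility category."""

    lesion_voi: np.ndarray       # boolean mask
    background_voi: np.ndarray   # boolean mask
    category: str = ""
    subsplit: str = ""
    label: str = ""

    def __post_init__(self) -> None:
        if self.category == VISIBLE_ON_EITHER and self.subsplit not in (
                INVISIBLE_SUV_VISIBLE_KI, VISIBLE_SUV_INVISIBLE_KI):
            raise ValueError("visible_on_either requires a consistent sub-split")


@dataclass
class EvalReport:
    """All per-volume, per-VOI and per-lesion statistics for one map pair."""

    mae: float = np.nan
    me: float = np.nan
    mrae_pct: float = np.nan
    re_pct: float = np.nan
    mse: float = np.nan
    rmse: float = np.nan
    psnr: float = np.nan
    ssim: float = np.nan
    n_voxels: int = 0
    organ: dict = field(default_factory=dict)      # label -> {ame, amre_pct}
    lesions: dict = field(default_factory=dict)    # label -> {tbr, cnr, ...}
    joint: dict = field(default_factory=dict)      # slope, intercept, correlation
    spearman: dict = field(default_factory=dict)   # organ -> (rho, p)

    def to_dict(self) -> dict:
        return {
            "MAE": self.mae, "ME": self.me, "MRAE_pct": self.mrae_pct,
            "RE_pct": self.re_pct, "MSE": self.mse, "RMSE": self.rmse,
            "PSNR": self.psnr, "SSIM": self.ssim, "n_voxels": self.n_voxels,
            "organ": self.organ, "lesions": self.lesions, "joint": self.joint,
            "spearman": self.spearman,
        }


def _as_array(m):
    return m.ki if isinstance(m, ParametricMap) else np.asarray(m, dtype=float)


def eval_mask(ref, threshold: float = EVAL_THRESHOLD) -> np.ndarray:
    """Evaluation mask: reference voxels >= ``threshold`` (in original units).

    The threshold subsumes negativity; with threshold 0, exactly the
    negative voxels are excluded.
    """
    ref = _as_array(ref)
    mask = ref >= threshold
    if not mask.any():
        raise ValueError("evaluation mask is empty: nothing to evaluate")
    return mask


def voxel_metrics(pred, ref, mask) -> EvalReport:
    """Patient-wise voxel metrics over the evaluation mask."""
    pred, ref = _as_array(pred), _as_array(ref)
    if pred.shape != ref.shape:
        raise ValueError("pred and ref shapes must match")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty evaluation mask")
    p, r = pred[mask], ref[mask]
    d = p - r
    rep = EvalReport(n_voxels=int(mask.sum()))
    rep.mae = float(np.mean(np.abs(d)))
    rep.me = float(np.mean(d))
    rep.mrae_pct = float(np.mean(np.abs(d / r)) * 100.0)
    rep.re_pct = float(np.mean(d / r) * 100.0)
    rep.mse = float(np.mean(d ** 2))
    rep.rmse = float(np.sqrt(rep.mse))
    intensity = float(max(p.max(), r.max()))
    if rep.mse == 0.0:
        rep.psnr = float("inf")
        rep.ssim = 1.0
    else:
        rep.psnr = float(10.0 * np.log10(intensity ** 2 / rep.mse))
        c1 = (0.01 * intensity) ** 2
        c2 = (0.02 * intensity) ** 2
        mu_r, mu_p = float(np.mean(r)), float(np.mean(p))
        var_r, var_p = float(np.var(r)), float(np.var(p))
        cov = float(np.mean((r - mu_r) * (p - mu_p)))
        rep.ssim = ((2 * mu_r * mu_p + c1) * (2 * cov + c2)) / (
            (mu_r ** 2 + mu_p ** 2 + c1) * (var_r + var_p + c2))
    return rep


def organ_metrics(pred, ref, vois: dict) -> dict:
    """Per-VOI AME = |mean(pred-ref)| and AMRE% = |sum pred - sum ref|/sum ref * 100.

    ``vois`` maps a label to a boolean mask.  A zero reference sum flags
    AMRE as undefined (NaN).
    """
    pred, ref = _as_array(pred), _as_array(ref)
    out = {}
    for label, m in vois.items():
        m = np.asarray(m, dtype=bool)
        if not m.any():
            raise ValueError(f"VOI {label!r} is empty after rasterization")
        d = pred[m] - ref[m]
        sum_ref = float(ref[m].sum())
        if sum_ref == 0.0:
            amre = float("nan")
        else:
            amre = abs(float(pred[m].sum()) - sum_ref) / sum_ref * 100.0
        out[label] = {"ame": abs(float(np.mean(d))), "amre_pct": amre,
                      "undefined_amre": sum_ref == 0.0}
    return out


def lesion_metrics(image, lesion: LesionRecord, reference=None) -> dict:
    """TBR and CNR of one lesion, optionally with relative errors vs. a reference."""
    image = _as_array(image)
    lm = np.asarray(lesion.lesion_voi, dtype=bool)
    bm = np.asarray(lesion.background_voi, dtype=bool)
    if not lm.any() or not bm.any():
        raise ValueError("lesion and background VOIs must be nonempty")
    bg_mean = float(np.mean(image[bm]))
    if bg_mean <= 0:
        raise ValueError("background mean must be > 0")
    tbr = float(np.max(image[lm])) / bg_mean - 1.0
    bg_sd = float(np.std(image[bm]))
    cnr = float("inf") if bg_sd == 0.0 else tbr / bg_sd
    out = {"tbr": tbr, "cnr": cnr}
    if reference is not None:
        ref_out = lesion_metrics(reference, lesion)
        out["tbr_ref"] = ref_out["tbr"]
        out["cnr_ref"] = ref_out["cnr"]
        out["tbr_rel_err_pct"] = (tbr - ref_out["tbr"]) / ref_out["tbr"] * 100.0 \
            if ref_out["tbr"] != 0 else float("nan")
        out["cnr_rel_err_pct"] = (cnr - ref_out["cnr"]) / ref_out["cnr"] * 100.0 \
            if np.isfinite(ref_out["cnr"]) and ref_out["cnr"] != 0 else float("nan")
    return out


def joint_histogram(pred, ref, mask, n_bins: int = 64):
    """Voxelwise OLS of pred on ref, Pearson correlation and a 2-D histogram."""
    pred, ref = _as_array(pred), _as_array(ref)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    p, r = pred[mask], ref[mask]
    out = {"hist": None, "slope": np.nan, "intercept": np.nan,
           "correlation": np.nan, "undefined": False}
    hist, xedges, yedges = np.histogram2d(r, p, bins=n_bins)
    out["hist"] = (hist, xedges, yedges)
    if np.ptp(r) == 0.0:
        out["undefined"] = True
        return out
    slope, intercept = np.polyfit(r, p, 1)
    out["slope"] = float(slope)
    out["intercept"] = float(intercept)
    if np.ptp(p) == 0.0:
        out["undefined"] = True
    else:
        out["correlation"] = float(np.corrcoef(r, p)[0, 1])
    return out


def _exact_spearman_p(rho_obs: float, n: int) -> float:
    """Two-sided exact permutation p-value for the Spearman coefficient."""
    ranks = np.arange(1, n + 1, dtype=float)
    perms = np.array(list(permutations(ranks)))
    a = (ranks - ranks.mean()) / ranks.std()
    b = (perms - ranks.mean()) / ranks.std()
    rhos = b @ a / n
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def spearman_by_organ(pred_means, ref_means) -> tuple:
    """Spearman rank correlation of per-subject VOI means, with p-value.

    Exact permutation p for n <= 9, t-approximation otherwise.  Inputs
    that are all ties raise (the rank correlation is undefined).
    """
    pred_means = np.asarray(pred_means, dtype=float)
    ref_means = np.asarray(ref_means, dtype=float)
    n = len(pred_means)
    if n < 3 or len(ref_means) != n:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(pred_means) == 0.0 or np.ptp(ref_means) == 0.0:
        raise ValueError("ties-only input: rank correlation undefined")
    rho = float(stats.spearmanr(pred_means, ref_means).statistic)
    if n <= 9:
        p = _exact_spearman_p(rho, n)
    else:
        p = float(stats.spearmanr(pred_means, ref_means).pvalue)
    return rho, p


def categorize_lesions(lesions, suv_image, ki_image,
                       tbr_threshold: float = 1.5) -> dict:
    """Assign visibility categories from TBR in the SUV and Ki images.

    A lesion is "visible" in an image iff its TBR there is >= the
    threshold (a proxy for human visual inspection).  Returns
    label -> (category, subsplit).
    """
    if suv_image is None or ki_image is None:
        raise ValueError("both SUV and Ki images are required")
    out = {}
    for lesion in lesions:
        vis_suv = lesion_metrics(suv_image, lesion)["tbr"] >= tbr_threshold
        vis_ki = lesion_metrics(ki_image, lesion)["tbr"] >= tbr_threshold
        if vis_suv and vis_ki:
            cat, sub = VISIBLE_ON_BOTH, ""
        elif not vis_suv and not vis_ki:
            cat, sub = INVISIBLE_ON_BOTH, ""
        elif vis_ki:
            cat, sub = VISIBLE_ON_EITHER, INVISIBLE_SUV_VISIBLE_KI
        else:
            cat, sub = VISIBLE_ON_EITHER, VISIBLE_SUV_INVISIBLE_KI
        out[lesion.label or id(lesion)] = (cat, sub)
    return out


def line_profile(image: np.ndarray, row: int | None = None,
                 endpoints=None):
    """1-D intensity profile along a row or between two (r, c) endpoints.

    Nearest-voxel sampling; returns ``(coords, values)`` ready for
    plotting, where coords are fractional (row, col) sample positions.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("line_profile expects a 2-D image")
    if row is not None:
        if not (0 <= row < image.shape[0]):
            raise ValueError("row outside the grid")
        cols = np.arange(image.shape[1])
        coords = np.stack([np.full_like(cols, row), cols], axis=1)
        return coords, image[row, :].copy()
    (r0, c0), (r1, c1) = endpoints
    for r, c in ((r0, c0), (r1, c1)):
        if not (0 <= r < image.shape[0] and 0 <= c < image.shape[1]):
            raise ValueError("endpoint outside the grid")
    length = int(np.hypot(r1 - r0, c1 - c0))
    if length == 0:
        raise ValueError("zero-length segment")
    t = np.linspace(0.0, 1.0, length + 1)
    rr = r0 + t * (r1 - r0)
    cc = c0 + t * (c1 - c0)
    values = image[np.round(rr).astype(int), np.round(cc).astype(int)]
    return np.stack([rr, cc], axis=1), values
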