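"""Voxelwise Patlak graphical analysis with an image-derived input function.

For irreversible tracer kinetics, once a relative equilibrium is reached
between the reversible and vascular compartments, the tissue curve obeys

    C(t)/Cp(t) = Ki * Int_0^t Cp(tau) dtau / Cp(t) + V

so that an ordinary least-squares fit of y = C/Cp against the normalized
integrated time x = Int Cp / Cp yields the net influx rate Ki (slope) and
the distribution volume V (intercept), voxel by voxel.  The reference
pipeline extracts Cp from a blood-pool VOI (early cardiac frames plus the
blood-pool samples of each whole-body pass) and fits all passes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .simulate import DynamicSeries

logger = logging.getLogger(__name__)

__all__ = [
    "SampledInputFunction",
    "ParametricMap",
    "PatlakTransform",
    "extract_if_image_derived",
    "patlak_transform",
    "patlak_fit_voxelwise",
    "reference_ki",
]


@dataclass
class SampledInputFunction:
    """Plasma input function sampled at frame mid-times."""

    times: np.ndarray       # s, strictly increasing
    cp: np.ndarray          # same units as the fitted series
    provenance: str = "image-derived VOI"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.cp = np.asarray(self.cp, dtype=float)
        if self.times.shape != self.cp.shape or self.times.ndim != 1:
            raise ValueError("times and cp must be matching 1-D arrays")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.cp < 0):
            raise ValueError("cp must be non-negative")

    def to_dict(self) -> dict:
        return {"times_s": self.times.tolist(), "cp": self.cp.tolist(),
                "provenance": self.provenance}

    @classmethod
    def from_dict(cls, d: dict) -> "SampledInputFunction":
        return cls(np.asarray(d["times_s"]), np.asarray(d["cp"]),
                   d.get("provenance", "image-derived VOI"))


@dataclass
class ParametricMap:
    """Voxelwise Ki (slope) and V (intercept) images with an evaluation mask."""

    ki: np.ndarray                       # mL s^-1 mL^-1
    v: np.ndarray | None                 # unitless distribution volume
    mask: np.ndarray                     # boolean, where the fit is defined
    r_squared: np.ndarray | None = None
    residual_norm: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.v is not None and self.v.shape != self.ki.shape:
            raise ValueError("ki and v shapes must match")
        if self.mask.shape != self.ki.shape:
            raise ValueError("mask shape must match ki")


def extract_if_image_derived(early: DynamicSeries, passes: DynamicSeries,
                             blood_voi: np.ndarray) -> SampledInputFunction:
    """Image-derived input function from a blood-pool VOI.

    ``blood_voi`` is a boolean mask on the (S, H, W) grid shared by both
    series.  Cp is the VOI mean per frame, concatenating the early
    cardiac frames with the blood-pool samples of each pass; times are
    frame mid-times, merged in monotone order.
    """
    blood_voi = np.asarray(blood_voi, dtype=bool)
    if blood_voi.shape != early.frames.shape[1:]:
        raise ValueError(
            f"VOI shape {blood_voi.shape} outside image grid {early.frames.shape[1:]}"
        )
    if not blood_voi.any():
        raise ValueError("empty blood VOI")
    times = np.concatenate([early.mid_times, passes.mid_times])
    cp = np.concatenate([
        early.frames[:, blood_voi].mean(axis=1),
        passes.frames[:, blood_voi].mean(axis=1),
    ])
    order = np.argsort(times, kind="stable")
    times, cp = times[order], cp[order]
    if np.any(cp < 0):
        logger.warning("clamped %d negative IF sample(s) to 0", int(np.sum(cp < 0)))
        cp = np.maximum(cp, 0.0)
    return SampledInputFunction(times, cp, provenance="image-derived VOI")


class PatlakTransform(NamedTuple):
    x: np.ndarray            # normalized integrated time at valid samples, s
    valid: np.ndarray        # boolean mask into the input samples
    n_dropped: int


def _cum_integral(times: np.ndarray, cp: np.ndarray) -> np.ndarray:
    """Trapezoidal cumulative integral of cp from t = 0 with Cp(0) = 0."""
    if times[0] > 0:
        times = np.concatenate([[0.0], times])
        cp = np.concatenate([[0.0], cp])
        cum = np.concatenate([[0.0], np.cumsum(0.5 * np.diff(times) * (cp[1:] + cp[:-1]))])
        return cum[1:]
    return np.concatenate([[0.0], np.cumsum(0.5 * np.diff(times) * (cp[1:] + cp[:-1]))])


def patlak_transform(ifc: SampledInputFunction) -> PatlakTransform:
    """Normalized integrated time x(t) = Int_0^t Cp / Cp(t).

    Samples with Cp <= 0 are dropped and counted; fewer than two valid
    samples is an error.
    """
    cum = _cum_integral(ifc.times, ifc.cp)
    valid = ifc.cp > 0
    n_dropped = int(np.sum(~valid))
    if valid.sum() < 2:
        raise ValueError("fewer than 2 valid input-function samples")
    if n_dropped:
        logger.info("patlak_transform dropped %d sample(s) with cp <= 0", n_dropped)
    x = cum[valid] / ifc.cp[valid]
    return PatlakTransform(x=x, valid=valid, n_dropped=n_dropped)


def _if_at(ifc: SampledInputFunction, t: np.ndarray):
    """(cp, cumulative integral) interpolated at times ``t``."""
    cum = _cum_integral(ifc.times, ifc.cp)
    cp = np.interp(t, ifc.times, ifc.cp)
    ci = np.interp(t, ifc.times, cum)
    return cp, ci


def patlak_fit_voxelwise(series: DynamicSeries, ifc: SampledInputFunction,
                         t_star: float, weights: np.ndarray | None = None
                         ) -> ParametricMap:
    """Voxelwise OLS Patlak fit over frames with mid-time >= ``t_star``.

    Negative slopes are kept; masking is deferred to evaluation.  An
    optional per-frame weight vector turns the fit into weighted least
    squares (off by default).
    """
    mids = series.mid_times
    if t_star > mids[-1]:
        raise ValueError(f"t_star = {t_star} s beyond last frame mid-time {mids[-1]} s")
    sel = mids >= t_star
    cp, ci = _if_at(ifc, mids[sel])
    usable = cp > 0
    if usable.sum() < 2:
        raise ValueError("fewer than 2 fitted frames with positive cp")
    if not usable.all():
        logger.info("dropping %d fitted frame(s) with cp <= 0", int(np.sum(~usable)))
    frames = series.frames[sel][usable]
    cp, ci = cp[usable], ci[usable]

    x = ci / cp                                        # (T,)
    y = frames / cp[:, None, None, None]               # (T, S, H, W)
    if weights is None:
        w = np.ones_like(x)
    else:
        w = np.asarray(weights, dtype=float)[sel][usable]
        if np.any(w < 0):
            raise ValueError("weights must be >= 0")
    wsum = w.sum()
    xbar = (w * x).sum() / wsum
    ybar = np.tensordot(w, y, axes=(0, 0)) / wsum      # (S, H, W)
    xc = x - xbar
    sxx = (w * xc * xc).sum()
    sxy = np.tensordot(w * xc, y, axes=(0, 0))         # y centering drops out
    ki = sxy / sxx
    v = ybar - ki * xbar

    resid = y - (ki[None] * x[:, None, None, None] + v[None])
    ss_res = np.tensordot(w, resid ** 2, axes=(0, 0))
    ss_tot = np.tensordot(w, (y - ybar[None]) ** 2, axes=(0, 0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, 1.0)
    mask = np.all(np.isfinite(y), axis=0)
    return ParametricMap(ki=ki, v=v, mask=mask, r_squared=r2,
                         residual_norm=np.sqrt(ss_res))


def reference_ki(early: DynamicSeries, passes: DynamicSeries,
                 blood_voi: np.ndarray, t_star: float | None = None):
    """Reference Ki/V maps: image-derived IF + Patlak fit over all passes.

    ``t_star`` defaults to the first pass start, so every acquired pass
    enters the fit; this output is the training target downstream.
    Returns ``(ParametricMap, SampledInputFunction)``.
    """
    ifc = extract_if_image_derived(early, passes, blood_voi)
    if t_star is None:
        t_star = passes.timing[0][0]
    pmap = patlak_fit_voxelwise(passes, ifc, t_star=t_star)
    return pmap, ifc
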