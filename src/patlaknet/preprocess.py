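"""Normalization, cropping, input configurations and cross-validation splits.

Eleven input configurations are trained in the study design this package
replicates: six "with SUV" (SUV alone, then SUV plus passes 13, 13-12,
13-11, 13-10, 13-9) and five "without SUV" (passes 13 down to 13-9).
Images are normalized to the range [0-2] by fixed per-image-type factors:
the across-subject mean of per-subject maxima, divided by 2.  Slices are
center-cropped to a common matrix (168x168 at clinical scale) and each
pair of transaxial input/target slices forms one training sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "InputConfig",
    "NormalizationTable",
    "enumerate_configs",
    "compute_norm_factor",
    "normalize",
    "denormalize",
    "crop_center",
    "make_folds",
    "assemble_dataset",
    "channel_keys",
    "KI_KEY",
    "SUV_KEY",
]

SUV_KEY = "suv"
KI_KEY = "ki"


def pass_key(index: int) -> str:
    return f"p{index}"


@dataclass(frozen=True)
class InputConfig:
    """One network input configuration.

    ``passes`` is a contiguous suffix of the pass sequence in descending
    order (13, 12, ..., p with p >= 9), possibly empty only when the SUV
    channel is present.
    """

    name: str
    with_suv: bool
    passes: tuple = ()

    def __post_init__(self) -> None:
        if self.passes:
            expected = tuple(range(13, 13 - len(self.passes), -1))
            if self.passes != expected or self.passes[-1] < 9:
                raise ValueError(
                    f"passes must be a contiguous suffix 13..p with p >= 9, got {self.passes}"
                )
        elif not self.with_suv:
            raise ValueError("a config without SUV must include at least one pass")

    @property
    def channel_count(self) -> int:
        return len(self.passes) + (1 if self.with_suv else 0)


def _config_name(with_suv: bool, passes: tuple) -> str:
    if not passes:
        return SUV_KEY
    span = f"p13-{passes[-1]}" if len(passes) > 1 else "p13"
    return f"{SUV_KEY}_{span}" if with_suv else span


def enumerate_configs() -> list:
    """The 11 input configurations, "with SUV" group first."""
    configs = []
    for with_suv in (True, False):
        start = 0 if with_suv else 1
        for n in range(start, 6):
            passes = tuple(range(13, 13 - n, -1))
            configs.append(InputConfig(_config_name(with_suv, passes), with_suv, passes))
    return configs


def channel_keys(config: InputConfig) -> list:
    """Ordered channel keys: (SUV?, pass13, pass12, ...)."""
    keys = [SUV_KEY] if config.with_suv else []
    keys += [pass_key(p) for p in config.passes]
    return keys


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def compute_norm_factor(images) -> float:
    """Across-subject mean of per-subject maxima, divided by 2."""
    maxima = [float(np.max(np.asarray(im))) for im in images]
    if not maxima:
        raise ValueError("at least one subject image required")
    if not all(np.isfinite(m) for m in maxima):
        raise ValueError("images must be finite")
    factor = float(np.mean(maxima)) / 2.0
    if factor <= 0:
        raise ValueError("all-zero images yield a zero normalization factor")
    return factor


class NormalizationTable(dict):
    """Fixed per-image-type normalization factors (type key -> factor)."""

    def __setitem__(self, key, value):
        if value <= 0:
            raise ValueError(f"factor for {key!r} must be > 0")
        super().__setitem__(key, float(value))

    @classmethod
    def from_subjects(cls, volumes_by_type: dict) -> "NormalizationTable":
        """``volumes_by_type`` maps type key -> list of per-subject volumes."""
        table = cls()
        for key, vols in volumes_by_type.items():
            table[key] = compute_norm_factor(vols)
        return table


def normalize(image: np.ndarray, factor: float) -> np.ndarray:
    if factor <= 0:
        raise ValueError("normalization factor must be > 0")
    return np.asarray(image) / factor


def denormalize(image: np.ndarray, factor: float) -> np.ndarray:
    if factor <= 0:
        raise ValueError("normalization factor must be > 0")
    return np.asarray(image) * factor


# ---------------------------------------------------------------------------
# geometry and splits
# ---------------------------------------------------------------------------

def crop_center(image: np.ndarray, target=(168, 168)) -> np.ndarray:
    """Centered in-plane crop of the trailing two axes (no padding)."""
    th, tw = target
    h, w = image.shape[-2:]
    if h < th or w < tw:
        raise ValueError(f"image in-plane size {(h, w)} smaller than target {(th, tw)}")
    y0 = (h - th) // 2
    x0 = (w - tw) // 2
    return image[..., y0:y0 + th, x0:x0 + tw]


def make_folds(n_subjects: int = 19, n_folds: int = 9,
               seed: int | None = None) -> list:
    """Cross-validation test folds as lists of subject indices.

    Subjects are shuffled once (seeded) and split into contiguous blocks
    of floor(n/k) subjects, the last fold absorbing the remainder -- for
    19 subjects in 9 folds the sizes are [2]*8 + [3].
    """
    if n_folds < 1 or n_folds > n_subjects:
        raise ValueError("need 1 <= n_folds <= n_subjects")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_subjects)
    base = n_subjects // n_folds
    folds = [sorted(order[i * base:(i + 1) * base].tolist()) for i in range(n_folds - 1)]
    folds.append(sorted(order[(n_folds - 1) * base:].tolist()))
    return folds


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

def assemble_dataset(subject_volumes: list, config: InputConfig,
                     norm: NormalizationTable, target=None):
    """Paired 2-D slice samples for one input configuration.

    ``subject_volumes`` is a list of dicts mapping channel keys (``suv``,
    ``p13`` ... ``p9``, already in SUV units) and ``ki`` (the reference
    Ki map) to (S, H, W) volumes.  Returns ``(X, y, index)`` where X is
    (N, C, h, w) float32, y is (N, 1, h, w) float32 and ``index`` lists
    (subject, slice) per sample.  Channel order is (SUV?, pass13,
    pass12, ...) for every sample.
    """
    keys = channel_keys(config)
    xs, ys, index = [], [], []
    for si, vols in enumerate(subject_volumes):
        for key in keys + [KI_KEY]:
            if key not in vols:
                raise KeyError(f"subject {si} is missing channel {key!r}")
        chans = [normalize(np.asarray(vols[k], dtype=np.float32), norm[k]) for k in keys]
        tgt = normalize(np.asarray(vols[KI_KEY], dtype=np.float32), norm[KI_KEY])
        if target is not None:
            chans = [crop_center(c, target) for c in chans]
            tgt = crop_center(tgt, target)
        n_slices = tgt.shape[0]
        for sl in range(n_slices):
            xs.append(np.stack([c[sl] for c in chans], axis=0))
            ys.append(tgt[sl][None])
            index.append((si, sl))
    X = np.stack(xs).astype(np.float32)
    y = np.stack(ys).astype(np.float32)
    return X, y, index
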