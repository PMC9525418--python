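"""End-to-end pipeline: simulate -> Patlak reference -> train -> predict -> evaluate.

One call renders a synthetic cohort, generates reference Ki maps by
Patlak analysis of all whole-body passes, trains one network per
requested input configuration on the training split, predicts Ki maps
for the held-out subjects and reports patient-wise voxel metrics plus
the joint-histogram regression of predicted on reference Ki.  Every
artifact is reproducible from (config, seed) alone.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
from scipy.ndimage import binary_erosion

from . import evaluate as ev
from .io import RunConfig, atomic_write_json
from .model import TrainConfig, predict_ki, save_model, train
from .patlak import reference_ki
from .preprocess import (KI_KEY, NormalizationTable, channel_keys,
                         enumerate_configs, make_folds, pass_key)
from .simulate import BLOOD, AcquisitionProtocol, make_cohort, render_subject

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "render_cohort", "blood_pool_voi", "subject_channels"]

CONFIGS_BY_NAME = {c.name: c for c in enumerate_configs()}


def blood_pool_voi(subject) -> np.ndarray:
    """Blood-pool VOI: the eroded cardiac blood label (limits partial volume)."""
    mask = subject.label_map == BLOOD
    eroded = np.zeros_like(mask)
    for s in range(mask.shape[0]):
        eroded[s] = binary_erosion(mask[s])
    return eroded if eroded.any() else mask


def iter_cohort(cfg: RunConfig, protocol: AcquisitionProtocol | None = None):
    """Simulate, render and Patlak-fit a cohort, one subject at a time.

    Yields per-subject records; streaming keeps only one subject's frame
    stacks in memory at once.
    """
    protocol = protocol or AcquisitionProtocol()
    subjects = make_cohort(
        cfg.n_subjects, variability=cfg.variability,
        n_lesions_per_subject=cfg.n_lesions_per_subject, seed=cfg.seed,
        matrix=cfg.matrix, n_slices=cfg.n_slices, voxel_size_mm=cfg.voxel_size_mm,
        slice_thickness_mm=cfg.slice_thickness_mm)
    seeds = np.random.SeedSequence(cfg.seed).spawn(len(subjects))
    for subject, sseed in zip(subjects, seeds):
        early, passes, suv = render_subject(
            subject, protocol, noise_scale=cfg.noise_scale,
            psf_fwhm=cfg.psf_fwhm_mm, seed=sseed)
        ref, ifc = reference_ki(early, passes, blood_pool_voi(subject),
                                t_star=cfg.t_star_s)
        yield dict(subject=subject, early=early, passes=passes,
                   suv=suv, ref=ref, ifc=ifc)


def render_cohort(cfg: RunConfig, protocol: AcquisitionProtocol | None = None):
    """All cohort records as a list (convenient for small cohorts)."""
    return list(iter_cohort(cfg, protocol))


def subject_channels(record) -> dict:
    """Per-type volumes in SUV units plus the reference Ki target."""
    out = {"suv": record["suv"].frames[0]}
    passes_suv = record["passes"].to_suv()
    for i in range(passes_suv.frames.shape[0]):
        out[pass_key(i + 1)] = passes_suv.frames[i]
    out[KI_KEY] = record["ref"].ki
    return out


def _norm_table(channel_maps, indices, keys) -> NormalizationTable:
    return NormalizationTable.from_subjects(
        {k: [channel_maps[i][k] for i in indices] for k in keys})


def run_pipeline(cfg: RunConfig, out_dir) -> dict:
    """Execute all stages; writes report.json and the config snapshot.

    Returns ``{"configs": {name: summary}, "curve": [(name, MRAE%)], ...}``.
    Any stage failure aborts with the stage name; partial outputs persist.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.save(out / "config.yaml")
    stage = "simulate+reference"
    try:
        # stream subjects; keep only float32 channel maps to bound memory
        channel_maps = []
        for record in iter_cohort(cfg):
            channels = {k: np.asarray(v, dtype=np.float32)
                        for k, v in subject_channels(record).items()}
            channel_maps.append(channels)
            del record

        stage = "split"
        folds = make_folds(cfg.n_subjects, cfg.n_folds, seed=cfg.seed)
        test_idx = folds[cfg.eval_fold]
        train_idx = [i for i in range(cfg.n_subjects) if i not in test_idx]

        results: dict = {"configs": {}, "curve": [], "test_subjects": test_idx,
                         "seed": cfg.seed}
        for ci, name in enumerate(cfg.config_names):
            stage = f"train[{name}]"
            config = CONFIGS_BY_NAME[name]
            keys = channel_keys(config) + [KI_KEY]
            norm_idx = list(range(cfg.n_subjects)) if getattr(cfg, "global_norm", False) \
                else train_idx
            norm = _norm_table(channel_maps, norm_idx, keys)
            from .preprocess import assemble_dataset
            X, y, _ = assemble_dataset([channel_maps[i] for i in train_idx],
                                       config, norm, target=cfg.crop_target)
            tcfg = TrainConfig(epochs=cfg.epochs, batch_size=cfg.batch_size,
                               widths=tuple(cfg.widths),
                               window_size=cfg.window_size,
                               holdout_fraction=cfg.holdout_fraction,
                               seed=(cfg.seed * 131 + ci) % (2 ** 31))
            model, history = train((X, y), tcfg)
            save_model(model, out / f"model_{name}.npz")

            stage = f"evaluate[{name}]"
            per_subject = []
            pooled_pred, pooled_ref = [], []
            for i in test_idx:
                pred = predict_ki(model, channel_maps[i], config, norm,
                                  target=cfg.crop_target)
                ref_ki = channel_maps[i][KI_KEY]
                if cfg.persist_images:
                    from .io import write_volume
                    write_volume(pred.ki, out / f"pred_{name}_subj{i:02d}.nii.gz",
                                 cfg.voxel_size_mm, cfg.slice_thickness_mm)
                    write_volume(ref_ki, out / f"ref_subj{i:02d}.nii.gz",
                                 cfg.voxel_size_mm, cfg.slice_thickness_mm)
                mask = ev.eval_mask(ref_ki, cfg.eval_threshold)
                rep = ev.voxel_metrics(pred.ki, ref_ki, mask)
                per_subject.append(rep.to_dict())
                pooled_pred.append(pred.ki[mask])
                pooled_ref.append(ref_ki[mask])
            joint = ev.joint_histogram(np.concatenate(pooled_pred),
                                       np.concatenate(pooled_ref),
                                       np.ones(sum(p.size for p in pooled_pred),
                                               dtype=bool))
            metric_names = ["MAE", "ME", "MRAE_pct", "RE_pct", "MSE", "RMSE",
                            "PSNR", "SSIM"]
            summary = {m: float(np.mean([s[m] for s in per_subject]))
                       for m in metric_names}
            summary.update({f"{m}_std": float(np.std([s[m] for s in per_subject]))
                            for m in metric_names})
            summary["n_voxels"] = int(np.sum([s["n_voxels"] for s in per_subject]))
            summary["joint_slope"] = joint["slope"]
            summary["joint_correlation"] = joint["correlation"]
            summary["loss_history"] = {k: history[k] for k in
                                       ("train_loss", "holdout_loss")}
            summary["per_subject"] = per_subject
            results["configs"][name] = summary
            results["curve"].append((name, summary["MRAE_pct"]))
            logger.info("config %s: held-out MRAE%% = %.3f", name,
                        summary["MRAE_pct"])

        stage = "report"
        atomic_write_json(_json_safe(results), out / "report.json")
        _write_summary_csv(results, out / "summary.csv")
        return results
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def _json_safe(obj):
    if isinstance(obj, dict):
        return {str(k): _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return f if np.isfinite(f) else repr(f)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _write_summary_csv(results: dict, path) -> None:
    import pandas as pd
    rows = []
    for name, summary in results["configs"].items():
        row = {"config": name}
        row.update({k: v for k, v in summary.items()
                    if isinstance(v, (int, float))})
        rows.append(row)
    df = pd.DataFrame(rows)
    from .io import _atomic
    _atomic(Path(path), lambda tmp: df.to_csv(tmp, index=False))
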