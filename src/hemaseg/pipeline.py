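"""End-to-end experiment pipeline: simulate → preprocess → split → train →
evaluate → compare → agreement.

Every constant consumed anywhere in the pipeline lives in one config dict
(YAML-serialisable); every artifact directory carries the config hash; all
randomness flows from the single global seed through named per-stage
substreams, so a rerun with the same config reproduces the metric CSVs
byte for byte.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as hio
from .experiments import (TrainConfig, evaluate_slices, friedman_test,
                          nemenyi_posthoc, stratified_split, train)
from .interobserver import size_binned_agreement, agreement_report, plot_size_binned
from .losses import LossSpec, parse_components
from .metrics import MaskPair, aggregate_folds, evaluate_pairs
from .model import build_model, load_checkpoint, save_checkpoint
from .preprocess import AugmentSpec, WindowSpec, preprocess_volume
from .synthdata import PhantomSpec, generate_phantom_dataset

__all__ = ["DEFAULT_CONFIG", "resolve_config", "run_pipeline", "STAGES"]

STAGES = ("simulate", "preprocess", "split", "train", "evaluate", "compare",
          "agreement")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "preset": "tiny",
    "adapter_m": 8,
    "policy": "adapters_plus_decoder",
    "prompt_mode": "full_image",
    "phantom": {
        "n_scans": 15, "slices_per_scan": [4, 6], "image_size": 64,
        "fraction_positive": 0.73, "lesions_per_positive_scan": [1, 2],
        "lesion_area_px": [60, 400], "lesion_hu": [50.0, 90.0],
        "brain_hu": 30.0, "skull_hu": 900.0, "noise_sd": 3.0,
        "annotator_perturb_px": 2.0, "miss_rate_small": 0.2,
        "small_lesion_px": 100,
    },
    "preprocess": {
        "window": [0.0, 140.0], "target": 64, "orient": True,
        "head_threshold_hu": 100.0,
    },
    "split": {"test_frac": 0.2, "n_folds": 3},
    "train": {
        "epochs": 6, "lr": 1e-3, "weight_decay": 0.1, "batch_size": 2,
        "augment": False, "fold": 0,
    },
    "variants": {
        "bce": "bce:1.0",
        "bce_bl": "bce:0.5,boundary:0.5",
        "dice": "dice:1.0",
    },
    "metrics": {"percentile": 95.0},
    "agreement": {
        "bins": [[0, 50], [50, 100], [100, 200], [200, 400], [400, "inf"]],
    },
    "compare": {"alpha": 0.05, "metric": "dice"},
}


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in (override or {}).items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def resolve_config(overrides: dict | None = None, seed: int | None = None) -> dict:
    config = _deep_merge(DEFAULT_CONFIG, overrides or {})
    if seed is not None:
        config["seed"] = int(seed)
    return config


def _model_seed(seed: int, variant: str) -> int:
    digest = hashlib.sha256(f"{seed}:{variant}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _loss_spec(config: dict, variant: str) -> LossSpec:
    return LossSpec(components=parse_components(config["variants"][variant]))


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(config: dict, out: Path) -> None:
    spec_kwargs = copy.deepcopy(config["phantom"])
    for key in ("slices_per_scan", "lesions_per_positive_scan",
                "lesion_area_px", "lesion_hu"):
        spec_kwargs[key] = tuple(spec_kwargs[key])
    spec = PhantomSpec(seed=int(hio.substream(config["seed"], "simulate")
                                .integers(2**31)), **spec_kwargs)
    dataset = generate_phantom_dataset(spec)
    data_dir = out / "data"
    uid_rng = hio.substream(config["seed"], "dicom-uids")
    for scan in dataset.scans:
        hio.write_ct_series(data_dir / "scans" / scan.scan_id, scan.raw,
                            scan.slope, scan.intercept, scan.scan_id, uid_rng)
        (data_dir / "masks_a").mkdir(parents=True, exist_ok=True)
        (data_dir / "masks_b").mkdir(parents=True, exist_ok=True)
        hio.write_mask(data_dir / "masks_a" / f"{scan.scan_id}.nii", scan.gt)
        hio.write_mask(data_dir / "masks_b" / f"{scan.scan_id}.nii", scan.annot_b)
    dataset.manifest.to_csv(data_dir / "manifest.csv", index=False)


def stage_preprocess(config: dict, out: Path) -> None:
    data_dir = out / "data"
    pre_dir = out / "preprocessed"
    pre_dir.mkdir(parents=True, exist_ok=True)
    pcfg = config["preprocess"]
    window = WindowSpec(*pcfg["window"])
    for scan_dir in sorted((data_dir / "scans").iterdir()):
        volume = hio.read_ct_series(scan_dir)
        gt = hio.read_mask(data_dir / "masks_a" / f"{volume.scan_id}.nii")
        ab = hio.read_mask(data_dir / "masks_b" / f"{volume.scan_id}.nii")
        slices, gt_out, angle = preprocess_volume(
            volume, window=window, target=pcfg["target"], orient=pcfg["orient"],
            head_threshold_hu=pcfg["head_threshold_hu"], masks=gt)
        _, ab_out, _ = preprocess_volume(
            volume, window=window, target=pcfg["target"], orient=pcfg["orient"],
            head_threshold_hu=pcfg["head_threshold_hu"], masks=ab)
        np.savez(pre_dir / f"{volume.scan_id}.npz", slices=slices, gt=gt_out,
                 annot_b=ab_out, angle=angle)


def stage_split(config: dict, out: Path) -> None:
    manifest = pd.read_csv(out / "data" / "manifest.csv")
    table = (manifest.groupby("scan_id")["scan_positive"].any()
             .reset_index().rename(columns={"scan_positive": "positive"}))
    seed = int(hio.substream(config["seed"], "split").integers(2**31))
    split = stratified_split(table, seed, test_frac=config["split"]["test_frac"],
                             n_folds=config["split"]["n_folds"])
    payload = {
        "seed": split.seed,
        "test_ids": split.test_ids,
        "folds": [{"train_ids": t, "val_ids": v} for t, v in split.folds],
        "strata": {k: bool(v) for k, v in split.strata.items()},
    }
    (out / "split.json").write_text(json.dumps(payload, indent=2, sort_keys=True))


def _load_slices(out: Path, scan_ids, mask_key: str = "gt") -> list:
    items = []
    for sid in scan_ids:
        with np.load(out / "preprocessed" / f"{sid}.npz") as npz:
            slices, masks = npz["slices"], npz[mask_key]
        for z in range(slices.shape[0]):
            items.append({"image": slices[z], "mask": masks[z],
                          "scan_id": sid, "slice_index": z})
    return items


def stage_train(config: dict, out: Path) -> None:
    split = json.loads((out / "split.json").read_text())
    fold = split["folds"][config["train"]["fold"]]
    train_items = _load_slices(out, fold["train_ids"])
    ckpt_dir = out / "checkpoints"
    ckpt_dir.mkdir(parents=True, exist_ok=True)
    tcfg_block = config["train"]
    for variant in sorted(config["variants"]):
        model = build_model(config["preset"], adapter_m=config["adapter_m"],
                            seed=_model_seed(config["seed"], variant))
        augment_spec = AugmentSpec() if tcfg_block["augment"] else None
        tcfg = TrainConfig(
            epochs=tcfg_block["epochs"], lr=tcfg_block["lr"],
            weight_decay=tcfg_block["weight_decay"],
            batch_size=tcfg_block["batch_size"],
            loss=_loss_spec(config, variant),
            seed=_model_seed(config["seed"], f"train:{variant}"),
            policy=config["policy"], prompt_mode=config["prompt_mode"],
            augment_spec=augment_spec)
        logger = hio.JsonlLogger(out / "logs" / f"{variant}.jsonl")
        logger.log({"event": "start", "variant": variant,
                    "loss": config["variants"][variant],
                    "seed": tcfg.seed, "policy": tcfg.policy})
        history = train(model, train_items, tcfg, logger=logger)
        logger.log({"event": "done", "final_loss": history["epoch_loss"][-1],
                    "trainable_params": history["trainable_params"]})
        save_checkpoint(model, ckpt_dir / f"{variant}.npz")


def stage_evaluate(config: dict, out: Path) -> None:
    split = json.loads((out / "split.json").read_text())
    test_ids = split["test_ids"]
    metrics_dir = out / "metrics"
    metrics_dir.mkdir(parents=True, exist_ok=True)
    percentile = config["metrics"]["percentile"]
    for variant in sorted(config["variants"]):
        model = build_model(config["preset"], adapter_m=config["adapter_m"],
                            seed=_model_seed(config["seed"], variant))
        load_checkpoint(model, out / "checkpoints" / f"{variant}.npz")
        slice_rows, scan_pairs, scan_ids = [], [], []
        for sid in test_ids:
            items = _load_slices(out, [sid])
            preds = evaluate_slices(model, items,
                                    prompt_mode=config["prompt_mode"])
            pairs = [MaskPair(P=p, GT=item["mask"])
                     for p, item in zip(preds, items)]
            ids = [f"{sid}:{item['slice_index']}" for item in items]
            slice_rows.append(evaluate_pairs(pairs, unit_ids=ids, level="slice"))
            scan_pairs.append(MaskPair(
                P=np.stack(preds, axis=0),
                GT=np.stack([item["mask"] for item in items], axis=0)))
            scan_ids.append(sid)
        slice_df = pd.concat(slice_rows, ignore_index=True)
        scan_df = evaluate_pairs(scan_pairs, unit_ids=scan_ids, level="scan")
        slice_df.to_csv(metrics_dir / f"{variant}_slices.csv", index=False)
        scan_df.to_csv(metrics_dir / f"{variant}_scans.csv", index=False)
        summary = aggregate_folds([slice_df], mode="slice")
        summary.to_csv(metrics_dir / f"{variant}_summary.csv", index=False)


def stage_compare(config: dict, out: Path) -> None:
    metric = config["compare"]["metric"]
    alpha = config["compare"]["alpha"]
    variants = sorted(config["variants"])
    columns = {}
    for variant in variants:
        df = pd.read_csv(out / "metrics" / f"{variant}_scans.csv")
        columns[variant] = df.set_index("unit_id")[metric]
    matrix = pd.DataFrame(columns).dropna()
    result = friedman_test(matrix.to_numpy())
    payload = {"metric": metric, "alpha": alpha, "models": variants,
               "n_blocks": int(len(matrix)),
               "statistic": result.statistic, "p_value": result.p_value,
               "mean_ranks": dict(zip(variants, map(float, result.ranks)))}
    if result.p_value < alpha:
        post = nemenyi_posthoc(matrix.to_numpy(), alpha=alpha,
                               model_names=variants)
        payload["critical_difference"] = post.critical_difference
        post.posthoc.to_csv(out / "compare_posthoc.csv")
    (out / "compare.json").write_text(json.dumps(payload, indent=2,
                                                 sort_keys=True))


def stage_agreement(config: dict, out: Path) -> None:
    manifest = pd.read_csv(out / "data" / "manifest.csv")
    pairs = []
    for sid in sorted(manifest["scan_id"].unique()):
        with np.load(out / "preprocessed" / f"{sid}.npz") as npz:
            gt, ab = npz["gt"], npz["annot_b"]
        for z in range(gt.shape[0]):
            pairs.append((gt[z], ab[z]))
    report = agreement_report(pairs)
    bins = [(float(lo), float(hi)) for lo, hi in
            ((b[0], b[1]) for b in config["agreement"]["bins"])]
    binned = size_binned_agreement(pairs, bins=bins)
    report.to_csv(out / "agreement_slices.csv", index=False)
    binned.to_csv(out / "agreement_binned.csv", index=False)
    plot_size_binned(binned, out / "agreement_bins.png")


_STAGE_FN = {
    "simulate": stage_simulate, "preprocess": stage_preprocess,
    "split": stage_split, "train": stage_train, "evaluate": stage_evaluate,
    "compare": stage_compare, "agreement": stage_agreement,
}


def run_pipeline(config: dict, output, stages=None) -> Path:
    """Execute the requested stages in order; artifacts land under ``output``.

    A failure halts with the stage name in the error context.  Stages read
    their inputs from the artifact directory, so resuming from a later stage
    against existing artifacts reproduces identical downstream outputs.
    """
    out = Path(output)
    out.mkdir(parents=True, exist_ok=True)
    chash = hio.config_hash(config)
    (out / "config_hash.txt").write_text(chash + "\n")
    hio.dump_yaml(config, out / "config_resolved.yaml")
    logger = hio.JsonlLogger(out / "run.jsonl")
    logger.log({"event": "run_start", "config_hash": chash,
                "seed": config["seed"],
                "versions": {"numpy": np.__version__, "pandas": pd.__version__}})
    for stage in (stages or STAGES):
        if stage not in _STAGE_FN:
            raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
        try:
            _STAGE_FN[stage](config, out)
        except Exception as exc:
            logger.log({"event": "stage_failed", "stage": stage, "error": str(exc)})
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        logger.log({"event": "stage_done", "stage": stage})
    return out
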