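"""End-to-end demo pipeline: simulate -> masks -> train -> inpaint -> evaluate.

Each stage writes into its own numbered directory under the run root and
drops a ``stage.json`` marker on success; re-running resumes after the
last completed stage, and any stage that does run forces every downstream
stage to run again.  The resolved config is written beside the outputs.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import yaml

from . import masks as mask_mod
from .config import stage_rng
from .diffusion import simple_loss
from .leaves import DiseaseStyle, LeafSpec, generate_dataset
from .metrics import (
    MetricReport,
    RandomProjectionExtractor,
    extract_features,
    fid,
    inception_score,
    kid,
    psnr,
    ssim_global,
)
from .nets import load_checkpoint, save_checkpoint, train_epsilon_model
from .repaint import JumpSchedule, inpaint
from .schedule import build_noise_schedule

log = logging.getLogger("leafdiffuse.pipeline")

__all__ = ["run_pipeline", "STAGE_DIRS"]

STAGE_DIRS = {
    "simulate": "1_simulate",
    "masks": "2_masks",
    "train": "3_train",
    "inpaint": "4_inpaint",
    "evaluate": "5_evaluate",
}


def _read_images(paths: list[Path]) -> np.ndarray:
    import imageio.v3 as iio

    return np.stack([np.asarray(iio.imread(p), dtype=np.float64) / 255.0 for p in paths])


def _marker(stage_dir: Path) -> Path:
    return stage_dir / "stage.json"


def _complete(stage_dir: Path, info: dict) -> None:
    _marker(stage_dir).write_text(json.dumps({"status": "complete", **info}, indent=2))


def run_pipeline(config: dict, out_dir: str | Path | None = None) -> Path:
    """Execute the five stages; returns the run directory.

    A stage failure halts the run with the stage name; partial state stays
    on disk and a subsequent call resumes from the failed stage.
    """
    run_dir = Path(out_dir if out_dir is not None else config["out_root"])
    run_dir.mkdir(parents=True, exist_ok=True)
    (run_dir / "config.yaml").write_text(yaml.safe_dump(config, sort_keys=True))
    seed = int(config["seed"])
    force = False
    t0 = time.time()
    for stage in STAGE_DIRS:
        stage_dir = run_dir / STAGE_DIRS[stage]
        if not force and _marker(stage_dir).exists():
            log.info("stage %s already complete; skipping", stage)
            continue
        force = True  # everything downstream must re-run
        stage_dir.mkdir(parents=True, exist_ok=True)
        log.info("running stage %s", stage)
        try:
            _STAGE_FNS[stage](config, run_dir, stage_dir, stage_rng(seed, stage))
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    log.info("pipeline finished in %.1f s", time.time() - t0)
    return run_dir


def _stage_simulate(config, run_dir, stage_dir, rng):
    synth = config["synth"]
    spec = LeafSpec(size=int(synth["size"]))
    classes = {
        "healthy": {"count": int(synth["healthy_count"]), "style": None},
        "diseased": {
            "count": int(synth["disease_count"]),
            "style": synth["disease_style"],
            "intensity": synth["intensity"],
            "edge_bias": synth["edge_bias"],
        },
    }
    manifest = generate_dataset(
        classes, stage_dir, rng, spec=spec, paired_domains=("healthy", "diseased")
    )
    _complete(stage_dir, {"classes": {k: v["count"] for k, v in manifest.classes.items()}})


def _stage_masks(config, run_dir, stage_dir, rng):
    sim_dir = run_dir / STAGE_DIRS["simulate"]
    size = int(config["synth"]["size"])
    dilate_radius = max(1, round(config["masks"]["dilate_frac"] * size))
    healthy = sorted((sim_dir / "images" / "healthy").glob("*.png"))
    n_ok = 0
    for path in healthy:
        image = _read_images([path])[0]
        inst = mask_mod.leaf_mask_otsu(image)
        inst = mask_mod.dilate_mask(inst, dilate_radius)
        known = mask_mod.invert_mask(inst)
        mask_mod.save_mask_png(
            known, stage_dir / f"known_{path.stem}.png", provenance="otsu+dilate+invert"
        )
        n_ok += 1
    catalogue = mask_mod.default_catalogue((size, size))
    for i in range(int(config["repaint"]["n_images"])):
        m = mask_mod.sample_split_mask((size, size), catalogue, rng)
        mask_mod.save_mask_png(m, stage_dir / f"split_{i:03d}.png", provenance="split-catalogue")
    _complete(stage_dir, {"n_leaf_masks": n_ok})


def _stage_train(config, run_dir, stage_dir, rng):
    sim_dir = run_dir / STAGE_DIRS["simulate"]
    images = _read_images(sorted((sim_dir / "images" / "diseased").glob("*.png")))
    schedule = build_noise_schedule(
        int(config["diffusion"]["steps"]),
        config["diffusion"]["schedule"],
        float(config["diffusion"]["beta_min"]),
        float(config["diffusion"]["beta_max"]),
    )
    model = train_epsilon_model(
        images,
        schedule,
        hidden=int(config["model"]["channels"]),
        steps=int(config["model"]["train_steps"]),
        batch_size=int(config["model"]["batch_size"]),
        lr=float(config["model"]["lr"]),
        rng=rng,
    )
    # record the final training objective on a held-out-style probe batch
    probe_rng = np.random.default_rng(rng.integers(2**31))
    ts = probe_rng.integers(1, schedule.T + 1, size=images.shape[0])
    noise = probe_rng.standard_normal(images.shape)
    from .diffusion import to_diffusion_range

    loss = simple_loss(model, to_diffusion_range(images), ts, noise, schedule)
    save_checkpoint(stage_dir / "model.npz", model, schedule, config["model"])
    _complete(stage_dir, {"n_params": model.n_params, "probe_loss": loss})


def _stage_inpaint(config, run_dir, stage_dir, rng):
    import imageio.v3 as iio

    sim_dir = run_dir / STAGE_DIRS["simulate"]
    msk_dir = run_dir / STAGE_DIRS["masks"]
    model, schedule, _ = load_checkpoint(run_dir / STAGE_DIRS["train"] / "model.npz")
    healthy = sorted((sim_dir / "images" / "healthy").glob("*.png"))
    jumps = JumpSchedule(
        jump_length=int(config["repaint"]["jump_length"]),
        n_resamples=int(config["repaint"]["resamples"]),
    )
    n = min(int(config["repaint"]["n_images"]), len(healthy))
    for i in range(n):
        image = _read_images([healthy[i]])[0]
        if config["masks"]["use_split_masks"]:
            m = mask_mod.load_mask_png(msk_dir / f"split_{i:03d}.png")
        else:
            m = mask_mod.load_mask_png(msk_dir / f"known_{healthy[i].stem}.png")
        out = inpaint(model, image, m, schedule, jumps, rng)
        iio.imwrite(stage_dir / f"inpaint_{i:03d}.png", (out * 255).round().astype(np.uint8))
        (stage_dir / f"inpaint_{i:03d}.source.json").write_text(
            json.dumps({"input": healthy[i].name, "mask": m.convention})
        )
    _complete(stage_dir, {"n_inpainted": n})


def _stage_evaluate(config, run_dir, stage_dir, rng):
    sim_dir = run_dir / STAGE_DIRS["simulate"]
    inp_dir = run_dir / STAGE_DIRS["inpaint"]
    real = _read_images(sorted((sim_dir / "images" / "diseased").glob("*.png")))
    fake_paths = sorted(inp_dir.glob("inpaint_*.png"))
    fake = _read_images(fake_paths)
    sources = [
        json.loads((p.parent / f"{p.stem}.source.json").read_text())["input"]
        for p in fake_paths
    ]
    inputs = _read_images([sim_dir / "images" / "healthy" / s for s in sources])
    extractor = RandomProjectionExtractor(d=16, pool=4)
    feats_real = extract_features(real, extractor)
    feats_fake = extract_features(fake, extractor)
    mcfg = config["metrics"]
    fid_val = fid(feats_real, feats_fake)
    kid_mean, kid_std = kid(
        feats_real,
        feats_fake,
        n_subsets=int(mcfg["n_subsets"]),
        subset_size=int(mcfg["subset_size"]),
        rng=rng,
    )
    # toy class posteriors: softmax over the first feature dimensions
    logits = feats_fake[:, :4]
    probs = np.exp(logits - logits.max(axis=1, keepdims=True))
    probs /= probs.sum(axis=1, keepdims=True)
    is_mean, is_std = inception_score(probs, n_splits=int(mcfg["is_splits"]))
    report = MetricReport(
        psnr=float(np.mean([psnr(a, b) for a, b in zip(inputs, fake)])),
        ssim=float(np.mean([ssim_global(a, b) for a, b in zip(inputs, fake)])),
        is_mean=is_mean,
        is_std=is_std,
        fid=fid_val,
        kid_mean=kid_mean,
        kid_std=kid_std,
    )
    (stage_dir / "report.json").write_text(json.dumps(report.as_dict(), indent=2, sort_keys=True))
    _complete(stage_dir, {"report": "report.json"})


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "masks": _stage_masks,
    "train": _stage_train,
    "inpaint": _stage_inpaint,
    "evaluate": _stage_evaluate,
}
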