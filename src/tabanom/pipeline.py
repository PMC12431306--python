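"""End-to-end orchestration: train -> reconstruct -> score -> evaluate.

The pipeline trains only on normal images (the unsupervised invariant: no
mask or label ever reaches a training loop), reconstructs test images by
partial re-noising with AR conditioning, embeds input and reconstruction
through a shared SF network, and scores per-pixel and per-image anomalies.
The lambda/omega fusion parameters are fitted on pseudo-defective
validation images generated by the synthetic module, never on the test set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import diffusion as dm
from . import metrics as M
from . import scoring as sc
from . import synth
from .ar import ARNetwork, SELAConfig
from .codec import CodecConfig, build_codec, fit_codec
from .config import RunConfig, desk_profile
from .sf import SFNetwork, fit_sf
from .unet import UNetDenoiser

__all__ = ["TrainedModels", "build_models", "train_pipeline", "detect_images",
           "fit_score_weights", "evaluate_dataset", "run_demo"]


@dataclass
class TrainedModels:
    codec: object
    denoiser: UNetDenoiser
    ar: ARNetwork | None
    sf: SFNetwork
    schedule: dm.NoiseSchedule
    weights: sc.ScoreWeights
    config: RunConfig

    def save(self, out_dir):
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.denoiser.save(out / "denoiser.npz")
        if self.ar is not None:
            self.ar.save(out / "ar.npz")
        self.sf.save(out / "sf.npz")
        if hasattr(self.codec, "save"):
            self.codec.save(out / "codec.npz")
        meta = {
            "schedule": {"T": self.schedule.T,
                         "beta_start": float(self.schedule.betas[0]),
                         "beta_end": float(self.schedule.betas[-1])},
            "weights": {"lam": self.weights.lam,
                        "omega": self.weights.omega.tolist(),
                        "gamma": list(self.weights.gamma)},
        }
        (out / "manifest.json").write_text(json.dumps(meta, indent=2))


def build_models(cfg: RunConfig, seed: int) -> TrainedModels:
    codec = build_codec(CodecConfig(latent_channels=cfg.codec.latent_channels,
                                    downscale=cfg.codec.downscale,
                                    mode=cfg.codec.mode), seed=seed)
    latent_c = cfg.codec.latent_channels
    skip_w = tuple(
        cfg.model.ar_widths[i] if cfg.model.use_ar and i in cfg.model.ar_skip_levels
        else 0
        for i in range(4))
    den = UNetDenoiser(latent_c, widths=cfg.model.widths, ar_widths=skip_w,
                       attn_levels=cfg.model.attn_levels,
                       patchify=cfg.model.patchify, seed=seed)
    ar = None
    if cfg.model.use_ar:
        ar = ARNetwork(3, latent_c, cfg.codec.downscale,
                       widths=cfg.model.ar_widths,
                       sela=SELAConfig(channels=cfg.model.ar_widths[3],
                                       r=cfg.model.sela_r,
                                       groups=cfg.model.sela_groups),
                       attn_levels=cfg.model.ar_attn_levels,
                       patchify=cfg.model.patchify, seed=seed + 1)
    sf = SFNetwork(widths=cfg.sf.widths, seed=seed + 2)
    schedule = dm.make_schedule(cfg.diffusion.T, cfg.diffusion.beta_start,
                                cfg.diffusion.beta_end)
    omega = cfg.score.omega
    if isinstance(omega, (tuple, list)):
        w = sc.ScoreWeights(lam=cfg.score.lam, omega=np.asarray(omega))
    else:
        w = sc.ScoreWeights(lam=cfg.score.lam)
    return TrainedModels(codec=codec, denoiser=den, ar=ar, sf=sf,
                         schedule=schedule, weights=w, config=cfg)


def _as_nchw(images) -> np.ndarray:
    arr = np.stack([getattr(s, "image", s) for s in images])
    return np.ascontiguousarray(arr.transpose(0, 3, 1, 2)).astype(np.float32)


def train_pipeline(train_samples, cfg: RunConfig, seed: int,
                   models: TrainedModels | None = None,
                   log=None) -> TrainedModels:
    """Train codec (if learned), diffusion (+AR) and SF on normal samples."""
    for s in train_samples:
        if getattr(s, "mask", None) is not None and np.asarray(s.mask).any():
            raise ValueError("training set must contain only normal images")
    models = models or build_models(cfg, seed)
    x = _as_nchw(train_samples)
    if cfg.codec.mode == "learned":
        fit_codec(x, models.codec, epochs=cfg.codec.epochs, lr=cfg.codec.lr,
                  seed=seed, callback=log)
    dm.fit_diffusion(x, models.denoiser, models.ar, models.codec,
                     models.schedule, epochs=cfg.diffusion.epochs,
                     batch_size=cfg.diffusion.batch_size,
                     lr=cfg.diffusion.lr, seed=seed,
                     augment=cfg.diffusion.augment,
                     ema_decay=cfg.diffusion.ema_decay, callback=log)
    fit_sf(x, models.sf, strategy=cfg.sf.strategy, epochs=cfg.sf.epochs,
           lr=cfg.sf.lr, seed=seed, callback=log)
    return models


def _reconstruct_all(models: TrainedModels, images_nchw: np.ndarray,
                     seed: int, batch: int = 25) -> np.ndarray:
    cfg = models.config
    clip = (0.0, 1.0) if cfg.codec.mode == "identity" else None
    k = max(1, cfg.diffusion.n_recon)
    runs = []
    for j in range(k):      # average reconstructions over independent noise draws
        rng = np.random.default_rng(seed + 1000 * j)
        outs = []
        for lo in range(0, len(images_nchw), batch):
            outs.append(dm.reconstruct_batch(
                images_nchw[lo:lo + batch], models.denoiser, models.ar,
                models.codec, models.schedule, cfg.t_start, rng,
                mode=cfg.diffusion.mode,
                sample_steps=cfg.diffusion.sample_steps, clip=clip))
        runs.append(np.concatenate(outs))
    return np.mean(runs, axis=0, dtype=np.float32)


def detect_images(models: TrainedModels, samples, seed: int = 0):
    """Reconstruct and score samples; returns (scores, fused maps, recons)."""
    cfg = models.config
    x = _as_nchw(samples)
    xhat = _reconstruct_all(models, x, seed)
    pyr = models.sf.extract_pyramid(x)
    pyr_hat = models.sf.extract_pyramid(xhat)
    shape = x.shape[2:]
    scores, fused = [], []
    for i in range(len(x)):
        am = sc.score_pair([lv[i] for lv in pyr], [lv[i] for lv in pyr_hat],
                           models.weights, shape, interp=cfg.score.interp,
                           sigma=cfg.score.sigma)
        scores.append(am.image_score)
        fused.append(am.fused)
    return np.asarray(scores), fused, xhat


def fit_score_weights(models: TrainedModels, spec: synth.TabletSpec,
                      seed: int) -> sc.ScoreWeights:
    """Fit lambda/omega on generated pseudo-defective validation pairs."""
    cfg = models.config
    rng = np.random.default_rng(seed + 7919)
    val, labels = [], []
    for i in range(cfg.score.n_val_normal):
        val.append(synth.render_normal(spec, cfg.image_size,
                                       seed=int(rng.integers(2 ** 31))))
        labels.append(0)
    kinds = list(synth.DEFECT_KINDS)
    for i in range(cfg.score.n_val_defective):
        base = synth.render_normal(spec, cfg.image_size,
                                   seed=int(rng.integers(2 ** 31)))
        kind = kinds[i % len(kinds)]
        val.append(synth.inject_defect(base, synth.DefectSpec(kind=kind),
                                       seed=int(rng.integers(2 ** 31))))
        labels.append(1)
    x = _as_nchw(val)
    xhat = _reconstruct_all(models, x, seed + 13)
    pyr = models.sf.extract_pyramid(x)
    pyr_hat = models.sf.extract_pyramid(xhat)
    pairs = [([lv[i] for lv in pyr], [lv[i] for lv in pyr_hat])
             for i in range(len(x))]
    fit_omega = models.config.score.omega == "learned"
    w = sc.fit_fusion_params(pairs, labels, shape=x.shape[2:],
                             grid_step=cfg.score.grid_step,
                             fit_omega=fit_omega,
                             fixed_lam=None if cfg.score.fit_lambda else cfg.score.lam,
                             sigma=cfg.score.sigma,
                             interp=cfg.score.interp, seed=seed)
    models.weights = w
    return w


def evaluate_dataset(scores, test_samples, fused_maps) -> M.MetricsReport:
    labels = [0 if s.label == "good" else 1 for s in test_samples]
    maps, masks = [], []
    for s, m in zip(test_samples, fused_maps):
        if s.mask is not None:
            maps.append(m)
            masks.append(s.mask)
    return M.evaluate_scores(scores, labels, maps or None, masks or None)


def _demo_data(cfg: RunConfig, seed: int, n_train: int, n_test_normal: int,
               n_test_defective: int):
    spec = synth.TabletSpec()
    rng = np.random.default_rng(seed)
    train = [synth.render_normal(spec, cfg.image_size,
                                 seed=int(rng.integers(2 ** 31)))
             for _ in range(n_train)]
    test = [synth.render_normal(spec, cfg.image_size,
                                seed=int(rng.integers(2 ** 31)))
            for _ in range(n_test_normal)]
    kinds = list(synth.DEFECT_KINDS)
    for i in range(n_test_defective):
        base = synth.render_normal(spec, cfg.image_size,
                                   seed=int(rng.integers(2 ** 31)))
        test.append(synth.inject_defect(
            base, synth.DefectSpec(kind=kinds[i % len(kinds)]),
            seed=int(rng.integers(2 ** 31))))
    return spec, train, test


def _demo_eval(models: TrainedModels, spec, test, seed: int, out_dir, log):
    fit_score_weights(models, spec, seed)
    scores, fused, xhat = detect_images(models, test, seed=seed + 1)
    report = evaluate_dataset(scores, test, fused)
    result = {
        "report": report,
        "scores": scores,
        "labels": np.asarray([0 if s.label == "good" else 1 for s in test]),
        "weights": models.weights,
        "models": models,
        "test": test,
        "fused": fused,
        "reconstructions": xhat,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        models.save(out / "checkpoints")
        with open(out / "metrics.json", "w") as fh:
            json.dump({"ap": report.ap, "f1": report.f1, "auroc": report.auroc,
                       "pro": report.pro, "aupro": report.aupro,
                       "threshold": report.threshold,
                       "n_images": report.n_images}, fh, indent=2)
    return result


def run_demo(seed: int = 0, cfg: RunConfig | None = None, use_ar: bool = True,
             n_train: int = 200, n_test_normal: int = 25,
             n_test_defective: int = 25, out_dir=None, log=None) -> dict:
    """Desk-scale end-to-end benchmark on synthetic tablets.

    Generates data, trains every stage, fits fusion weights on held-out
    pseudo-defective pairs, detects on the test set and reports metrics.
    """
    cfg = cfg or desk_profile()
    if not use_ar:
        from dataclasses import replace
        cfg = replace(cfg, model=replace(cfg.model, use_ar=False))
    spec, train, test = _demo_data(cfg, seed, n_train, n_test_normal,
                                   n_test_defective)
    models = train_pipeline(train, cfg, seed, log=log)
    return _demo_eval(models, spec, test, seed, out_dir, log)


def run_demo_pair(seed: int = 0, cfg: RunConfig | None = None,
                  n_train: int = 200, n_test_normal: int = 25,
                  n_test_defective: int = 25, log=None) -> tuple:
    """Run the desk benchmark with and without the AR network on identical
    data and seeds, sharing the SF feature extractor between the arms.

    Returns (result_with_ar, result_without_ar).
    """
    from dataclasses import replace

    cfg = cfg or desk_profile()
    cfg_ar = replace(cfg, model=replace(cfg.model, use_ar=True))
    cfg_no = replace(cfg, model=replace(cfg.model, use_ar=False))
    spec, train, test = _demo_data(cfg, seed, n_train, n_test_normal,
                                   n_test_defective)
    models_ar = train_pipeline(train, cfg_ar, seed, log=log)
    x = _as_nchw(train)
    models_no = build_models(cfg_no, seed)
    dm.fit_diffusion(x, models_no.denoiser, None, models_no.codec,
                     models_no.schedule, epochs=cfg.diffusion.epochs,
                     batch_size=cfg.diffusion.batch_size, lr=cfg.diffusion.lr,
                     seed=seed, augment=cfg.diffusion.augment,
                     ema_decay=cfg.diffusion.ema_decay, callback=log)
    models_no.sf = models_ar.sf    # shared extractor: same data, same seed
    res_ar = _demo_eval(models_ar, spec, test, seed, None, log)
    res_no = _demo_eval(models_no, spec, test, seed, None, log)
    return res_ar, res_no
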