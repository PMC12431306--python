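"""Anomaly measurement between input and reconstruction feature pyramids.

Per scale i, with feature maps F_i (input) and F^_i (reconstruction):

    dE_i(p) = sqrt( sum_c (F_i[c,p] - F^_i[c,p])^2 )          Euclidean
    dC_i(p) = 1 - <F_i[:,p], F^_i[:,p]> / (|F_i||F^_i| + eps)  cosine distance
    M_i     = lambda * dE_i + (1 - lambda) * dC_i

The per-scale maps are upsampled to the input resolution and fused with
nonnegative weights omega (sum 1) into the pixel score field S; the image
score is the maximum of a Gaussian-smoothed S.  lambda defaults to 0.85
(grid-search optimum); omega defaults to uniform and can be fitted.

Euclidean distance responds to magnitude (shape/size) differences, cosine
distance to direction (texture/colour-distribution) differences; the blend
covers both defect families.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.transform import resize

__all__ = [
    "ScoreWeights", "AnomalyMap", "euclidean_map", "cosine_map", "scale_map",
    "pyramid_maps", "fuse_maps", "image_score", "render_overlay",
    "score_pair", "fit_fusion_params",
]

DEFAULT_LAMBDA = 0.85


@dataclass
class ScoreWeights:
    lam: float = DEFAULT_LAMBDA
    omega: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    gamma: tuple = (4, 8, 16, 0)  # 0 = upsample the global level to full frame

    def __post_init__(self):
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lambda must lie in [0, 1]")
        self.omega = np.asarray(self.omega, dtype=np.float64)
        if np.any(self.omega < 0) or not np.isclose(self.omega.sum(), 1.0):
            raise ValueError("omega must be nonnegative and sum to 1")


@dataclass
class AnomalyMap:
    per_scale: list          # M_i fields at native scale resolutions
    fused: np.ndarray        # S, input resolution, nonnegative
    image_score: float


def euclidean_map(F: np.ndarray, F_hat: np.ndarray) -> np.ndarray:
    """Channelwise Euclidean distance field; (C,H,W) -> (H,W)."""
    F, F_hat = np.asarray(F, np.float64), np.asarray(F_hat, np.float64)
    if F.shape != F_hat.shape:
        raise ValueError(f"shape mismatch {F.shape} vs {F_hat.shape}")
    return np.sqrt(((F - F_hat) ** 2).sum(axis=0))


def cosine_map(F: np.ndarray, F_hat: np.ndarray, eps_denom: float = 1e-8) -> np.ndarray:
    """Cosine distance field 1 - cos(F, F_hat) per position; range [0, 2]."""
    F, F_hat = np.asarray(F, np.float64), np.asarray(F_hat, np.float64)
    if F.shape != F_hat.shape:
        raise ValueError(f"shape mismatch {F.shape} vs {F_hat.shape}")
    dot = (F * F_hat).sum(axis=0)
    norms = np.sqrt((F ** 2).sum(axis=0)) * np.sqrt((F_hat ** 2).sum(axis=0))
    return 1.0 - dot / (norms + eps_denom)


def scale_map(dE: np.ndarray, dC: np.ndarray, lam: float) -> np.ndarray:
    """M_i = lambda*dE + (1-lambda)*dC."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    dE, dC = np.asarray(dE), np.asarray(dC)
    if dE.shape != dC.shape:
        raise ValueError("dE and dC must share a shape")
    return lam * dE + (1.0 - lam) * dC


def pyramid_maps(pyr: "FeaturePyramid | list", pyr_hat, lam: float = DEFAULT_LAMBDA,
                 eps_denom: float = 1e-8) -> list:
    """Per-scale anomaly maps M_i between two pyramids of one image."""
    return [scale_map(euclidean_map(F, Fh), cosine_map(F, Fh, eps_denom), lam)
            for F, Fh in zip(pyr, pyr_hat)]


def _upsample(m: np.ndarray, target: tuple, interp: str) -> np.ndarray:
    if m.shape == tuple(target):
        return np.asarray(m, np.float64)
    if m.size == 1:  # global level -> constant field
        return np.full(target, float(m.reshape(-1)[0]))
    if interp == "nearest":
        order = 0
    elif interp == "bilinear":
        order = 1
    else:
        raise ValueError(f"unknown interpolation {interp!r}")
    return resize(np.asarray(m, np.float64), target, order=order,
                  anti_aliasing=False, preserve_range=True)


def fuse_maps(maps: list, weights: ScoreWeights, shape: tuple | None = None,
              interp: str = "bilinear") -> np.ndarray:
    """Upsample each M_i to the input resolution and omega-weight-sum."""
    if len(weights.omega) != len(maps):
        raise ValueError("omega length must match the number of scale maps")
    if shape is None:
        g0 = weights.gamma[0]
        shape = (maps[0].shape[0] * g0, maps[0].shape[1] * g0)
    out = np.zeros(shape, dtype=np.float64)
    for m, w, g in zip(maps, weights.omega, weights.gamma):
        target = shape if g == 0 else (m.shape[0] * g, m.shape[1] * g)
        up = _upsample(m, target, interp)
        if up.shape != tuple(shape):
            raise ValueError(
                f"scale map upsampled to {up.shape}, expected {tuple(shape)}")
        out += w * up
    return out


def image_score(S: np.ndarray, sigma: float = 2.0) -> float:
    """Image-level score: maximum of the Gaussian-smoothed fused field."""
    S = np.asarray(S, np.float64)
    if sigma > 0:
        S = gaussian_filter(S, sigma)
    return float(S.max(initial=0.0))


_JET_STOPS = np.array([  # compact blue->cyan->yellow->red map
    (0.0, 0.0, 0.5), (0.0, 0.0, 1.0), (0.0, 1.0, 1.0),
    (1.0, 1.0, 0.0), (1.0, 0.0, 0.0), (0.5, 0.0, 0.0)])


def _colormap(v: np.ndarray) -> np.ndarray:
    """Map values in [0,1] to RGB through piecewise-linear jet-like stops."""
    pos = np.linspace(0, 1, len(_JET_STOPS))
    return np.stack([np.interp(v, pos, _JET_STOPS[:, c]) for c in range(3)], axis=-1)


def render_overlay(S: np.ndarray, x: np.ndarray,
                   heat_weight: float = 0.6, image_weight: float = 0.4) -> np.ndarray:
    """Min-max normalise S, colour-map it, and blend 0.6*heat + 0.4*image."""
    S = np.asarray(S, np.float64)
    x = np.asarray(x, np.float64)
    if S.shape != x.shape[:2]:
        raise ValueError("score field and image spatial dims must match")
    lo, hi = S.min(), S.max()
    norm = (S - lo) / (hi - lo) if hi > lo else np.zeros_like(S)
    heat = _colormap(norm)
    return np.clip(heat_weight * heat + image_weight * x, 0.0, 1.0)


def score_pair(pyr, pyr_hat, weights: ScoreWeights, shape: tuple,
               interp: str = "bilinear", sigma: float = 2.0,
               eps_denom: float = 1e-8) -> AnomalyMap:
    """Full per-image scoring: per-scale maps, fused field, image score."""
    maps = pyramid_maps(pyr, pyr_hat, weights.lam, eps_denom)
    fused = fuse_maps(maps, weights, shape=shape, interp=interp)
    return AnomalyMap(per_scale=maps, fused=fused,
                      image_score=image_score(fused, sigma))


# --------------------------------------------------------------------- fitting

def _auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    from .metrics import auroc
    return auroc(scores, labels)


def _image_scores_per_scale(pair_pyramids: list, shape: tuple, lam: float,
                            gamma: tuple, sigma: float, interp: str) -> np.ndarray:
    """(n_images, n_scales) matrix of smoothed per-scale image maxima."""
    rows = []
    for pyr, pyr_hat in pair_pyramids:
        maps = pyramid_maps(pyr, pyr_hat, lam)
        row = []
        for m, g in zip(maps, gamma):
            target = shape if g == 0 else (m.shape[0] * g, m.shape[1] * g)
            row.append(image_score(_upsample(m, target, interp), sigma))
        rows.append(row)
    return np.asarray(rows)


def fit_fusion_params(pair_pyramids: list, labels, shape: tuple,
                      grid_step: float = 0.05, fit_omega: bool = True,
                      fixed_lam: float | None = None,
                      omega_steps: int = 300, omega_lr: float = 0.1,
                      sigma: float = 2.0, interp: str = "bilinear",
                      gamma: tuple = (4, 8, 16, 0), seed: int = 0) -> ScoreWeights:
    """Choose lambda by grid search on image-level AUROC and fit omega.

    ``pair_pyramids`` is a list of (pyramid, reconstruction pyramid) for a
    validation set whose binary ``labels`` mark defective images.  lambda is
    scanned over {0, grid_step, ..., 1} with uniform omega (or pinned to
    ``fixed_lam``); then omega = softmax(theta) is optimised by gradient
    ascent on a pairwise logistic surrogate of the AUROC of the
    omega-weighted per-scale image scores (AUROC itself is a rank
    statistic, hence not differentiable).
    """
    labels = np.asarray(labels).astype(int)
    if labels.min() == labels.max():
        raise ValueError("validation set must contain both classes")
    n_scales = len(pair_pyramids[0][0])
    grid = np.arange(0.0, 1.0 + 1e-9, grid_step)
    grid[-1] = min(grid[-1], 1.0)
    uniform = ScoreWeights(lam=0.0, omega=np.full(n_scales, 1.0 / n_scales),
                           gamma=gamma)
    if fixed_lam is not None:
        best_lam = float(fixed_lam)
    else:
        best_lam, best_auc = 0.0, -np.inf
        for lam in grid:
            scores = []
            for pyr, pyr_hat in pair_pyramids:
                w = ScoreWeights(lam=float(lam), omega=uniform.omega, gamma=gamma)
                scores.append(score_pair(pyr, pyr_hat, w, shape, interp,
                                         sigma).image_score)
            auc = _auroc(np.asarray(scores), labels)
            if auc > best_auc + 1e-12:
                best_auc, best_lam = auc, float(lam)

    omega = np.full(n_scales, 1.0 / n_scales)
    if fit_omega:
        per_scale = _image_scores_per_scale(pair_pyramids, shape, best_lam,
                                            gamma, sigma, interp)
        # optimise on standardised columns (scale-free conditioning) ...
        mu, sd = per_scale.mean(axis=0), per_scale.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        z = (per_scale - mu) / sd
        pos, neg = z[labels == 1], z[labels == 0]
        theta = np.zeros(n_scales)
        for _ in range(omega_steps):
            w = np.exp(theta - theta.max())
            w /= w.sum()
            margins = (pos @ w)[:, None] - (neg @ w)[None, :]
            sgm = 1.0 / (1.0 + np.exp(margins))          # derivative weight
            dmarg = (pos[:, None, :] - neg[None, :, :])  # (P, N, K)
            grad_w = (sgm[:, :, None] * dmarg).mean(axis=(0, 1))
            grad_theta = w * (grad_w - float(grad_w @ w))
            theta += omega_lr * grad_theta
        w = np.exp(theta - theta.max())
        w /= w.sum()
        # ... then translate to weights on the raw maps: w_k/sd_k induces the
        # same ranking as the standardised optimum (mean offsets shift every
        # image equally), so the fitted ranking transfers to Eq-style fusion.
        omega = (w / sd) / (w / sd).sum()
    return ScoreWeights(lam=best_lam, omega=omega, gamma=gamma)
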