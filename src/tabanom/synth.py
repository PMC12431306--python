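"""Procedural tablet images with pixel-accurate defect masks.

Emulates desk-scale pharmaceutical inspection data: a disk or capsule
tablet on a dark tray under a mild lighting gradient, with an embossed
score line and granular surface texture.  Defect injection covers the
taxonomy of structural damage (chip at the rim, crack, wear), surface
contamination (coloured blob), scratches (thin polylines) and holes
(dark ellipses), each altering pixels only inside its returned mask.

Datasets are written in the MVTec AD directory convention::

    out_dir/train/good/*.png
    out_dir/test/good/*.png
    out_dir/test/<kind>/*.png
    out_dir/ground_truth/<kind>/<stem>_mask.png

with training images strictly normal — no mask ever exists under train/.
Everything is deterministic given the seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import line_aa

__all__ = [
    "TabletSpec", "DefectSpec", "ImageSample",
    "render_normal", "inject_defect", "generate_dataset", "load_dataset",
    "DEFECT_KINDS",
]

DEFECT_KINDS = ("chip", "crack", "wear", "contamination", "scratch", "hole")

MASK_DELTA = 2.0 / 255.0  # changed-pixel threshold defining the mask


@dataclass(frozen=True)
class TabletSpec:
    shape: str = "disk"                      # disk | capsule
    radius_frac: float = 0.36                # tablet radius / image side
    base_color: tuple = (0.92, 0.90, 0.86)   # chalky white
    background_color: tuple = (0.18, 0.18, 0.20)
    emboss: bool = True                      # diametral score line
    lighting: float = 0.08                   # gradient strength
    texture: float = 0.02                    # granular noise amplitude
    jitter_frac: float = 0.04                # centre jitter / image side

    def __post_init__(self):
        if self.shape not in ("disk", "capsule"):
            raise ValueError(f"unknown tablet shape {self.shape!r}")
        for c in (*self.base_color, *self.background_color):
            if not 0.0 <= c <= 1.0:
                raise ValueError("colors must lie in [0, 1]")


@dataclass(frozen=True)
class DefectSpec:
    kind: str
    size_frac: tuple = (0.10, 0.28)   # defect extent / tablet radius
    intensity: tuple = (0.25, 0.6)    # contrast of the alteration
    count: tuple = (1, 1)

    def __post_init__(self):
        if self.kind not in DEFECT_KINDS:
            raise ValueError(f"unknown defect kind {self.kind!r}")


@dataclass
class ImageSample:
    image: np.ndarray                 # (H, W, 3) float32 in [0,1]
    mask: np.ndarray | None = None    # (H, W) bool, None or empty for normal
    label: str = "good"
    name: str = ""
    footprint: np.ndarray | None = field(default=None, repr=False)
    center: tuple | None = field(default=None, repr=False)
    radius: float | None = field(default=None, repr=False)


def _footprint_alpha(spec: TabletSpec, H: int, W: int, cy: float, cx: float,
                     r: float) -> np.ndarray:
    """Anti-aliased tablet silhouette from a signed distance field."""
    yy, xx = np.mgrid[0:H, 0:W].astype(np.float64)
    if spec.shape == "disk":
        d = np.hypot(yy - cy, xx - cx) - r
    else:  # capsule: half-height rectangle capped by half-disks
        half_len = 0.5 * r
        body_r = 0.5 * r
        dx = np.maximum(np.abs(xx - cx) - half_len, 0.0)
        d = np.hypot(yy - cy, dx) - body_r
    return np.clip(0.5 - d, 0.0, 1.0)


def render_normal(spec: TabletSpec, size: int = 64, seed: int = 0) -> ImageSample:
    """Deterministic normal tablet image with empty mask."""
    H = W = int(size)
    rng = np.random.default_rng(seed)
    r = spec.radius_frac * size
    extent = r   # capsule half-length + cap radius also totals r
    jit = spec.jitter_frac * size
    if extent + jit + 4 > size / 2:
        raise ValueError("tablet does not fit inside the frame with a 4 px margin")
    cy = H / 2 + rng.uniform(-jit, jit)
    cx = W / 2 + rng.uniform(-jit, jit)

    alpha = _footprint_alpha(spec, H, W, cy, cx, r)

    # background with a directional lighting gradient
    theta = rng.uniform(0, 2 * np.pi)
    yy, xx = np.mgrid[0:H, 0:W].astype(np.float64)
    ramp = ((yy - H / 2) * np.sin(theta) + (xx - W / 2) * np.cos(theta)) / size
    light = 1.0 + spec.lighting * ramp
    img = np.asarray(spec.background_color)[None, None, :] * light[:, :, None]

    # tablet body: base colour, granular texture, rim shading, emboss line
    body = np.ones((H, W, 3)) * np.asarray(spec.base_color)[None, None, :]
    tex = gaussian_filter(rng.standard_normal((H, W)), 1.0)
    tex /= max(np.abs(tex).max(), 1e-9)
    body *= (1.0 + spec.texture * tex)[:, :, None]
    if spec.shape == "disk":
        rr = np.hypot(yy - cy, xx - cx) / max(r, 1e-9)
    else:
        dx = np.maximum(np.abs(xx - cx) - 0.5 * r, 0.0)
        rr = np.hypot(yy - cy, dx) / max(0.5 * r, 1e-9)
    body *= (1.0 - 0.12 * np.clip(rr, 0, 1) ** 2)[:, :, None]   # convex shading
    if spec.emboss:
        band = np.abs(yy - cy) < max(size / 64.0, 1.0)
        depth = 0.12 * np.clip(1.0 - rr, 0, 1)
        body[band] *= (1.0 - depth[band])[:, None]
    body *= light[:, :, None]

    img = img * (1 - alpha[:, :, None]) + body * alpha[:, :, None]
    img = np.clip(img, 0, 1).astype(np.float32)
    return ImageSample(image=img, mask=np.zeros((H, W), bool), label="good",
                       footprint=alpha > 0.5, center=(cy, cx), radius=float(r))


def _rim_point(rng, sample: ImageSample):
    cy, cx = sample.center
    ang = rng.uniform(0, 2 * np.pi)
    # walk outward until leaving the footprint: works for both shapes
    fp = sample.footprint
    H, W = fp.shape
    step = 0.5
    y, x = cy, cx
    while True:
        y2, x2 = y + step * np.sin(ang), x + step * np.cos(ang)
        iy, ix = int(round(y2)), int(round(x2))
        if not (0 <= iy < H and 0 <= ix < W) or not fp[iy, ix]:
            return y, x, ang
        y, x = y2, x2


def _interior_point(rng, sample: ImageSample, margin: float = 3.0):
    fp = sample.footprint
    ys, xs = np.nonzero(fp)
    if len(ys) == 0:
        raise ValueError("tablet footprint is empty; cannot place a defect")
    for _ in range(200):
        i = rng.integers(len(ys))
        y, x = float(ys[i]), float(xs[i])
        iy, ix = int(y), int(x)
        lo_y, hi_y = max(iy - int(margin), 0), min(iy + int(margin) + 1, fp.shape[0])
        lo_x, hi_x = max(ix - int(margin), 0), min(ix + int(margin) + 1, fp.shape[1])
        if fp[lo_y:hi_y, lo_x:hi_x].all():
            return y, x
    return float(ys[0]), float(xs[0])


def _draw_polyline(canvas_shape, pts, width: float) -> np.ndarray:
    """Anti-aliased polyline coverage in [0,1]."""
    acc = np.zeros(canvas_shape)
    for (y0, x0), (y1, x1) in zip(pts[:-1], pts[1:]):
        rr, cc, val = line_aa(int(round(y0)), int(round(x0)),
                              int(round(y1)), int(round(x1)))
        ok = (rr >= 0) & (rr < canvas_shape[0]) & (cc >= 0) & (cc < canvas_shape[1])
        acc[rr[ok], cc[ok]] = np.maximum(acc[rr[ok], cc[ok]], val[ok])
    if width > 1.0:
        acc = np.clip(gaussian_filter(acc, (width - 1.0) / 2.0) * width, 0, 1)
    return acc


def inject_defect(sample: ImageSample, defect: DefectSpec, seed: int = 0) -> ImageSample:
    """Return a defective copy; pixels outside the mask are untouched."""
    if sample.label != "good" or (sample.mask is not None and sample.mask.any()):
        raise ValueError("inject_defect expects a normal input sample")
    rng = np.random.default_rng(seed)
    img = sample.image.astype(np.float64).copy()
    H, W, _ = img.shape
    r = sample.radius if sample.radius else 0.3 * H
    if r < 6:
        raise ValueError("tablet too small to place a defect")
    n = int(rng.integers(defect.count[0], defect.count[1] + 1))
    if n == 0:
        return ImageSample(image=sample.image.copy(),
                           mask=np.zeros((H, W), bool), label="good",
                           name=sample.name, footprint=sample.footprint,
                           center=sample.center, radius=sample.radius)
    yy, xx = np.mgrid[0:H, 0:W].astype(np.float64)
    bg = np.asarray(TabletSpec().background_color)

    for _ in range(n):
        size = rng.uniform(*defect.size_frac) * r
        strength = rng.uniform(*defect.intensity)
        if defect.kind == "chip":
            y, x, _ = _rim_point(rng, sample)
            bite = np.hypot(yy - y, xx - x) <= max(size, 2.0)
            region = bite & sample.footprint
            img[region] = bg * (1.0 + rng.uniform(-0.05, 0.05))
        elif defect.kind == "crack":
            y, x = _interior_point(rng, sample)
            ang = rng.uniform(0, 2 * np.pi)
            pts = [(y, x)]
            for _ in range(4):
                ang += rng.uniform(-0.7, 0.7)
                step = max(size, 3.0)
                y, x = y + step * np.sin(ang), x + step * np.cos(ang)
                pts.append((y, x))
            cov = _draw_polyline((H, W), pts, width=1.5) * sample.footprint
            img *= (1.0 - strength * cov)[:, :, None]
        elif defect.kind == "wear":
            cy, cx = sample.center
            rr_n = np.hypot(yy - cy, xx - cx) / r
            band = (rr_n > 0.75) & sample.footprint
            ang0 = rng.uniform(0, 2 * np.pi)
            arc = np.abs(((np.arctan2(yy - cy, xx - cx) - ang0 + np.pi)
                          % (2 * np.pi)) - np.pi) < rng.uniform(0.5, 1.2)
            noise = np.clip(gaussian_filter(rng.standard_normal((H, W)), 1.5), 0, None)
            cov = band & arc
            img *= (1.0 - 0.5 * strength * cov * noise / max(noise.max(), 1e-9))[:, :, None]
        elif defect.kind == "contamination":
            y, x = _interior_point(rng, sample)
            blob = np.exp(-(((yy - y) ** 2 + (xx - x) ** 2) / (2 * max(size, 2.0) ** 2)))
            blob = np.clip(blob * 1.5, 0, 1) * sample.footprint
            color = rng.uniform(0, 1, size=3)
            img = img * (1 - strength * blob[:, :, None]) \
                + strength * blob[:, :, None] * color[None, None, :]
        elif defect.kind == "scratch":
            y, x = _interior_point(rng, sample)
            ang = rng.uniform(0, 2 * np.pi)
            length = max(2.0 * size, 6.0)
            pts = [(y - 0.5 * length * np.sin(ang), x - 0.5 * length * np.cos(ang)),
                   (y, x),
                   (y + 0.5 * length * np.sin(ang + rng.uniform(-0.3, 0.3)),
                    x + 0.5 * length * np.cos(ang + rng.uniform(-0.3, 0.3)))]
            cov = _draw_polyline((H, W), pts, width=1.0) * sample.footprint
            sign = -1.0 if rng.uniform() < 0.7 else 1.0
            img = np.clip(img + sign * strength * cov[:, :, None], 0, 1)
        elif defect.kind == "hole":
            y, x = _interior_point(rng, sample)
            a, b = max(size, 2.0), max(size * rng.uniform(0.5, 1.0), 1.5)
            ang = rng.uniform(0, np.pi)
            u = (yy - y) * np.cos(ang) + (xx - x) * np.sin(ang)
            v = -(yy - y) * np.sin(ang) + (xx - x) * np.cos(ang)
            ell = np.clip(1.5 * (1.0 - np.hypot(u / a, v / b)), 0, 1) * sample.footprint
            img *= (1.0 - (0.4 + strength) * np.clip(ell, 0, 1))[:, :, None]

    img = np.clip(img, 0, 1).astype(np.float32)
    mask = np.abs(img.astype(np.float64) - sample.image.astype(np.float64)
                  ).max(axis=2) > MASK_DELTA
    img[~mask] = sample.image[~mask]   # sub-threshold residue stays untouched
    if not mask.any():
        raise ValueError(f"defect {defect.kind!r} produced no visible change")
    return ImageSample(image=img, mask=mask, label=defect.kind, name=sample.name,
                       footprint=sample.footprint, center=sample.center,
                       radius=sample.radius)


def _save_image(path: Path, img: np.ndarray):
    iio.imwrite(path, (np.clip(img, 0, 1) * 255).round().astype(np.uint8))


def generate_dataset(out_dir, n_train: int = 200, n_test_normal: int = 25,
                     n_test_defective: int = 25, defect_mix: dict | None = None,
                     spec: TabletSpec | None = None, size: int = 64,
                     seed: int = 0) -> dict:
    """Write an MVTec-AD-layout dataset; returns per-split file lists."""
    spec = spec or TabletSpec()
    if defect_mix is None:
        defect_mix = {k: 1.0 / len(DEFECT_KINDS) for k in DEFECT_KINDS}
    probs = np.asarray(list(defect_mix.values()), float)
    if not np.isclose(probs.sum(), 1.0):
        raise ValueError("defect mix proportions must sum to 1")
    kinds = list(defect_mix.keys())
    rng = np.random.default_rng(seed)
    out = Path(out_dir)
    (out / "train" / "good").mkdir(parents=True, exist_ok=True)
    (out / "test" / "good").mkdir(parents=True, exist_ok=True)
    written = {"train": [], "test_good": [], "test_defect": []}

    for i in range(n_train):
        s = render_normal(spec, size, seed=int(rng.integers(2 ** 31)))
        p = out / "train" / "good" / f"{i:04d}.png"
        _save_image(p, s.image)
        written["train"].append(p)
    for i in range(n_test_normal):
        s = render_normal(spec, size, seed=int(rng.integers(2 ** 31)))
        p = out / "test" / "good" / f"{i:04d}.png"
        _save_image(p, s.image)
        written["test_good"].append(p)

    counts = rng.multinomial(n_test_defective, probs)
    idx = 0
    for kind, cnt in zip(kinds, counts):
        if cnt == 0:
            continue
        (out / "test" / kind).mkdir(parents=True, exist_ok=True)
        (out / "ground_truth" / kind).mkdir(parents=True, exist_ok=True)
        for _ in range(cnt):
            base = render_normal(spec, size, seed=int(rng.integers(2 ** 31)))
            d = inject_defect(base, DefectSpec(kind=kind),
                              seed=int(rng.integers(2 ** 31)))
            stem = f"{idx:04d}"
            _save_image(out / "test" / kind / f"{stem}.png", d.image)
            iio.imwrite(out / "ground_truth" / kind / f"{stem}_mask.png",
                        (d.mask * 255).astype(np.uint8))
            written["test_defect"].append(out / "test" / kind / f"{stem}.png")
            idx += 1
    return written


def load_dataset(root) -> dict:
    """Read an MVTec-AD-layout directory into ImageSamples.

    Returns {"train": [...], "test": [...]}; test samples carry masks for
    defective classes (nonzero pixels = defect).
    """
    root = Path(root)
    out = {"train": [], "test": []}
    train_dir = root / "train" / "good"
    if not train_dir.is_dir():
        raise FileNotFoundError(f"no train/good under {root}")
    for p in sorted(train_dir.glob("*.png")):
        img = iio.imread(p).astype(np.float32) / 255.0
        out["train"].append(ImageSample(image=img, label="good", name=p.stem))
    for cls_dir in sorted((root / "test").iterdir()):
        if not cls_dir.is_dir():
            continue
        cls = cls_dir.name
        for p in sorted(cls_dir.glob("*.png")):
            img = iio.imread(p).astype(np.float32) / 255.0
            mask = None
            if cls != "good":
                mp = root / "ground_truth" / cls / f"{p.stem}_mask.png"
                if not mp.exists():
                    raise FileNotFoundError(f"missing ground-truth mask {mp}")
                mask = iio.imread(mp) > 0
            out["test"].append(ImageSample(image=img, mask=mask, label=cls,
                                           name=f"{cls}/{p.stem}"))
    return out
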