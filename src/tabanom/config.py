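"""Run configuration: nested sections, YAML round-trip, and profiles.

``full`` mirrors a production-scale setup (256 px images, T=1000, 500
epochs, latent codec); ``desk`` is the CPU-scale profile used by the demo
and the test-suite benchmarks (64 px, T=100, 30 epochs, pixel-space
identity codec, packed U-Net).  Every field can be overridden from YAML or
CLI flags.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace

import yaml

__all__ = ["RunConfig", "DiffusionCfg", "CodecCfg", "ModelCfg", "SFCfg",
           "ScoreCfg", "desk_profile", "full_profile", "load_config"]


@dataclass
class DiffusionCfg:
    T: int = 1000
    beta_start: float = 1e-4
    beta_end: float = 0.02
    t_start_frac: float = 0.5
    mode: str = "standard"
    sample_steps: int = 50
    n_recon: int = 1          # reconstructions averaged per image at test time
    epochs: int = 500
    batch_size: int = 16
    lr: float = 1e-2
    augment: bool = False
    ema_decay: float = 0.995


@dataclass
class CodecCfg:
    mode: str = "learned"
    latent_channels: int = 4
    downscale: int = 4
    epochs: int = 30
    lr: float = 2e-3


@dataclass
class ModelCfg:
    widths: tuple = (64, 128, 192, 256)
    ar_widths: tuple = (64, 128, 192, 256)
    ar_skip_levels: tuple = (0, 1, 2, 3)   # decoder levels receiving AR skips
    attn_levels: tuple = (3,)
    ar_attn_levels: tuple = (2, 3)
    patchify: int = 1
    sela_r: int = 4
    sela_groups: int = 4
    use_ar: bool = True


@dataclass
class SFCfg:
    widths: tuple = (16, 32, 64, 128)
    strategy: str = "autoencode"
    epochs: int = 10
    lr: float = 2e-3


@dataclass
class ScoreCfg:
    lam: float = 0.85
    fit_lambda: bool = False         # re-run the grid search per training run
    omega: str | tuple = "learned"   # "learned", "uniform", or explicit tuple
    interp: str = "bilinear"
    sigma: float = 2.0
    grid_step: float = 0.05
    n_val_normal: int = 16
    n_val_defective: int = 16


@dataclass
class RunConfig:
    image_size: int = 256
    seed: int = 0
    diffusion: DiffusionCfg = field(default_factory=DiffusionCfg)
    codec: CodecCfg = field(default_factory=CodecCfg)
    model: ModelCfg = field(default_factory=ModelCfg)
    sf: SFCfg = field(default_factory=SFCfg)
    score: ScoreCfg = field(default_factory=ScoreCfg)

    @property
    def t_start(self) -> int:
        return max(1, int(round(self.diffusion.t_start_frac * self.diffusion.T)))

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def full_profile(**overrides) -> RunConfig:
    return replace(RunConfig(), **overrides)


def desk_profile(**overrides) -> RunConfig:
    cfg = RunConfig(
        image_size=64,
        diffusion=DiffusionCfg(T=100, beta_start=1e-3, beta_end=0.2,
                               t_start_frac=0.25, sample_steps=10, n_recon=2,
                               epochs=30, batch_size=8, lr=3e-3),
        codec=CodecCfg(mode="identity", latent_channels=3, downscale=1),
        model=ModelCfg(widths=(16, 24, 32, 48), ar_widths=(16, 24, 32, 48),
                       ar_skip_levels=(2, 3), patchify=2),
        sf=SFCfg(widths=(8, 16, 32, 64), epochs=10),
        score=ScoreCfg(sigma=3.0, n_val_normal=12, n_val_defective=12),
    )
    return replace(cfg, **overrides)


def _merge(dc, data: dict):
    kwargs = {}
    for k, v in data.items():
        cur = getattr(dc, k)
        if hasattr(cur, "__dataclass_fields__"):
            kwargs[k] = _merge(cur, v)
        elif isinstance(cur, tuple) and isinstance(v, (list, tuple)):
            kwargs[k] = tuple(v)
        else:
            kwargs[k] = v
    return replace(dc, **kwargs)


def load_config(path, base: RunConfig | None = None) -> RunConfig:
    """Read YAML onto a base config (default: the full profile)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    profile = data.pop("profile", None)
    if base is None:
        base = desk_profile() if profile == "desk" else RunConfig()
    return _merge(base, data)
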