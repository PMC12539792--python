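"""Two-hypothesis imaging model for joint signal detection-estimation tasks.

The measurement model is

    H0:  g = b + n
    H1:  g = s(A_s) + b + n

with ``g`` a 2-D pixel array, ``b`` a (possibly random) background image,
``n`` i.i.d. zero-mean Gaussian pixel noise, and ``s(A_s) = A_s * s_ref`` a
Gaussian signal of random amplitude ``A_s`` imaged through an isotropic
Gaussian point response function (PRF).  Because the convolution of two
isotropic Gaussians is Gaussian, the post-PRF signal image has the closed
form evaluated by :func:`render_unit_signal`; no explicit convolution is
performed.

Pixel-coordinate convention: the coordinate of pixel ``m`` is its 0-based
integer grid position ``(row, col)``, so a signal center of ``(32, 32)``
sits exactly on the grid point ``(32, 32)`` of a 64x64 image.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .errors import ConfigurationError, DataError, DimensionError

__all__ = [
    "AmplitudePrior",
    "LumpyParams",
    "TaskConfig",
    "ImageBatch",
    "PRESETS",
    "get_preset",
    "render_unit_signal",
    "simulate_batch",
    "gaussian_loglik",
    "gaussian_utility",
]


@dataclass(frozen=True)
class AmplitudePrior:
    """Prior on the signal amplitude: ``gaussian(mean, sd)`` or ``uniform(lo, hi)``."""

    kind: str  # "gaussian" | "uniform"
    mean: float = 0.0
    sd: float = 1.0
    lo: float = 0.0
    hi: float = 1.0

    def validate(self) -> None:
        if self.kind == "gaussian":
            if self.sd < 0:
                raise ConfigurationError("gaussian amplitude prior needs sd >= 0")
        elif self.kind == "uniform":
            if not self.lo < self.hi:
                raise ConfigurationError("uniform amplitude prior needs lo < hi")
        else:
            raise ConfigurationError(f"unknown amplitude prior kind {self.kind!r}")

    @staticmethod
    def gaussian(mean: float, sd: float) -> "AmplitudePrior":
        return AmplitudePrior(kind="gaussian", mean=float(mean), sd=float(sd))

    @staticmethod
    def uniform(lo: float, hi: float) -> "AmplitudePrior":
        return AmplitudePrior(kind="uniform", lo=float(lo), hi=float(hi))

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.kind == "gaussian":
            return rng.normal(self.mean, self.sd, size=n)
        return rng.uniform(self.lo, self.hi, size=n)

    @property
    def center(self) -> float:
        """Prior mean (gaussian) or support midpoint (uniform)."""
        if self.kind == "gaussian":
            return self.mean
        return 0.5 * (self.lo + self.hi)

    def contains(self, theta: float) -> bool:
        if self.kind == "uniform":
            return self.lo <= theta <= self.hi
        return True

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class LumpyParams:
    """Parameters of the lumpy stochastic background (see :mod:`idealobs.generators`)."""

    n_lumps: int = 20
    lump_magnitude: float = 1.0
    lump_width: float = 4.0
    latent_dim: Optional[int] = None  # default 2 * n_lumps (one 2-D center per lump)

    def validate(self) -> None:
        if self.n_lumps < 0:
            raise ConfigurationError("n_lumps must be >= 0")
        if self.lump_width <= 0 or self.lump_magnitude <= 0:
            raise ConfigurationError("lump width and magnitude must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class TaskConfig:
    """All scalar parameters of one detection-estimation task.

    Attributes
    ----------
    image_side:
        Image side length in pixels (square images).
    signal_center:
        Signal center ``r_s = (row, col)`` in pixel coordinates.
    signal_width:
        Gaussian signal width ``w_s`` (pixels).
    prf_height, prf_width:
        Height ``h`` and width ``w_m`` of the Gaussian PRF.  ``prf_width = 0``
        means no blur, in which case the signal image is the raw Gaussian
        ``h * exp(-||r - r_s||^2 / (2 w_s^2))`` at unit amplitude.
    noise_sd:
        Standard deviation of the i.i.d. Gaussian pixel noise.
    amplitude_prior:
        Prior on the signal amplitude under H1.
    utility_width:
        Width ``sigma_u`` of the Gaussian estimation utility
        ``u(a, b) = exp(-(a - b)^2 / (2 sigma_u^2))``.
    background_mode:
        ``"bke_zero"`` (background known exactly and equal to zero) or
        ``"lumpy"`` (random lumpy background drawn per image).
    """

    image_side: int = 64
    signal_center: tuple[float, float] = (32.0, 32.0)
    signal_width: float = 1.0
    prf_height: float = 16.0
    prf_width: float = 3.87
    noise_sd: float = 40.0
    amplitude_prior: AmplitudePrior = field(
        default_factory=lambda: AmplitudePrior.gaussian(9.0, 4.0)
    )
    utility_width: float = 3.0
    background_mode: str = "bke_zero"
    lumpy: Optional[LumpyParams] = None

    def validate(self) -> None:
        if self.image_side <= 0:
            raise ConfigurationError("image_side must be a positive integer")
        if self.signal_width <= 0:
            raise ConfigurationError("signal_width must be positive")
        if self.prf_width < 0 or self.prf_height <= 0:
            raise ConfigurationError("prf_height must be positive, prf_width >= 0")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        if self.utility_width <= 0:
            raise ConfigurationError("utility_width must be positive")
        if self.background_mode not in ("bke_zero", "lumpy"):
            raise ConfigurationError(
                f"unknown background_mode {self.background_mode!r}"
            )
        self.amplitude_prior.validate()
        if self.background_mode == "lumpy":
            (self.lumpy or LumpyParams()).validate()

    @property
    def lumpy_params(self) -> LumpyParams:
        return self.lumpy if self.lumpy is not None else LumpyParams()

    def to_dict(self) -> dict:
        d = {
            "image_side": self.image_side,
            "signal_center": list(self.signal_center),
            "signal_width": self.signal_width,
            "prf_height": self.prf_height,
            "prf_width": self.prf_width,
            "noise_sd": self.noise_sd,
            "amplitude_prior": self.amplitude_prior.to_dict(),
            "utility_width": self.utility_width,
            "background_mode": self.background_mode,
        }
        if self.lumpy is not None:
            d["lumpy"] = self.lumpy.to_dict()
        return d

    @staticmethod
    def from_dict(d: dict) -> "TaskConfig":
        d = dict(d)
        prior = d.get("amplitude_prior")
        if isinstance(prior, dict):
            d["amplitude_prior"] = AmplitudePrior(**prior)
        lumpy = d.get("lumpy")
        if isinstance(lumpy, dict):
            d["lumpy"] = LumpyParams(**lumpy)
        center = d.get("signal_center")
        if center is not None:
            d["signal_center"] = tuple(float(c) for c in center)
        cfg = TaskConfig(**d)
        cfg.validate()
        return cfg

    @staticmethod
    def from_yaml(path: str | Path) -> "TaskConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if not isinstance(d, dict):
            raise ConfigurationError(f"{path}: expected a mapping")
        return TaskConfig.from_dict(d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _preset_sks_bke_gaussian() -> TaskConfig:
    # 64x64, Gaussian signal ws=1 at (32,32), PRF h=16 wm=3.87, noise sd 40,
    # amplitude N(9, 4^2), utility width 3, zero background.
    return TaskConfig()


def _preset_sks_bks_lumpy() -> TaskConfig:
    # Unblurred Gaussian signal (h=1, wm=0) of width 3 at the image center,
    # amplitude U(0.05, 0.15), noise sd 0.01, utility width 0.05, lumpy
    # random background normalized to [0, 1].
    return TaskConfig(
        image_side=64,
        signal_center=(32.0, 32.0),
        signal_width=3.0,
        prf_height=1.0,
        prf_width=0.0,
        noise_sd=0.01,
        amplitude_prior=AmplitudePrior.uniform(0.05, 0.15),
        utility_width=0.05,
        background_mode="lumpy",
        lumpy=LumpyParams(n_lumps=20, lump_magnitude=1.0, lump_width=4.0),
    )


PRESETS = {
    "sks_bke_gaussian": _preset_sks_bke_gaussian,
    "sks_bks_lumpy": _preset_sks_bks_lumpy,
}


def get_preset(name: str) -> TaskConfig:
    try:
        factory = PRESETS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
    cfg = factory()
    cfg.validate()
    return cfg


def pixel_grid(side: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/col coordinate grids with 0-based integer pixel centers."""
    rows, cols = np.mgrid[0:side, 0:side]
    return rows.astype(float), cols.astype(float)


def render_unit_signal(cfg: TaskConfig) -> np.ndarray:
    """Noiseless signal image at unit amplitude after PRF blur.

    Entry ``m`` equals ``h ws^2/(wm^2+ws^2) * exp(-||r_m - r_s||^2 / (2(wm^2+ws^2)))``
    (the closed-form convolution of the Gaussian signal with the Gaussian
    PRF); the amplitude-``a`` signal image is ``a`` times this, by linearity.
    """
    cfg.validate()
    rows, cols = pixel_grid(cfg.image_side)
    r0, c0 = cfg.signal_center
    d2 = (rows - r0) ** 2 + (cols - c0) ** 2
    w2 = cfg.prf_width**2 + cfg.signal_width**2
    amp = cfg.prf_height * cfg.signal_width**2 / w2
    return amp * np.exp(-d2 / (2.0 * w2))


@dataclass
class ImageBatch:
    """A stack of simulated measured images with ground truth.

    ``amplitudes`` holds the true signal amplitude per image and is NaN for
    signal-absent images (a sentinel rather than 0, so accidental use in a
    utility computation is loud).  ``background_latents`` records the latent
    vector of each random background draw (all-NaN rows for ``bke_zero``),
    which oracle-mode observers may use, e.g. to initialize chains.
    """

    images: np.ndarray  # (n, side, side)
    labels: np.ndarray  # (n,) in {0, 1}
    amplitudes: np.ndarray  # (n,), NaN under H0
    seed: int
    config: TaskConfig
    background_latents: Optional[np.ndarray] = None  # (n, k) or None

    def __post_init__(self) -> None:
        n = len(self.images)
        if not (len(self.labels) == len(self.amplitudes) == n):
            raise DimensionError("ImageBatch field lengths are inconsistent")
        if not np.all(np.isfinite(self.images)):
            raise DataError("ImageBatch images must be finite-valued")

    @property
    def n_present(self) -> int:
        return int(np.sum(self.labels == 1))

    @property
    def n_absent(self) -> int:
        return int(np.sum(self.labels == 0))

    def present(self) -> "ImageBatch":
        return self._subset(self.labels == 1)

    def absent(self) -> "ImageBatch":
        return self._subset(self.labels == 0)

    def _subset(self, mask: np.ndarray) -> "ImageBatch":
        lat = None if self.background_latents is None else self.background_latents[mask]
        return ImageBatch(
            images=self.images[mask],
            labels=self.labels[mask],
            amplitudes=self.amplitudes[mask],
            seed=self.seed,
            config=self.config,
            background_latents=lat,
        )

    def save(self, path: str | Path) -> None:
        """Persist as an NPZ container with a JSON-serialized config attribute."""
        arrays = {
            "images": self.images,
            "labels": self.labels,
            "amplitudes": self.amplitudes,
            "seed": np.asarray(self.seed),
            "config_json": np.asarray(json.dumps(self.config.to_dict())),
        }
        if self.background_latents is not None:
            arrays["background_latents"] = self.background_latents
        np.savez_compressed(path, **arrays)

    @staticmethod
    def load(path: str | Path) -> "ImageBatch":
        with np.load(path, allow_pickle=False) as npz:
            cfg = TaskConfig.from_dict(json.loads(str(npz["config_json"])))
            lat = npz["background_latents"] if "background_latents" in npz else None
            return ImageBatch(
                images=npz["images"],
                labels=npz["labels"],
                amplitudes=npz["amplitudes"],
                seed=int(npz["seed"]),
                config=cfg,
                background_latents=lat,
            )


def simulate_batch(
    cfg: TaskConfig, n_present: int, n_absent: int, seed: int
) -> ImageBatch:
    """Simulate ``n_present`` H1 and ``n_absent`` H0 images.

    One root seed is split deterministically into amplitude, background, and
    noise streams, so switching the background model on or off does not
    perturb the noise (or amplitude) draws.
    """
    cfg.validate()
    if n_present < 0 or n_absent < 0:
        raise ConfigurationError("image counts must be >= 0")
    n = n_present + n_absent
    side = cfg.image_side

    amp_ss, bg_ss, noise_ss = np.random.SeedSequence(seed).spawn(3)
    amp_rng = np.random.default_rng(amp_ss)
    noise_rng = np.random.default_rng(noise_ss)

    labels = np.concatenate(
        [np.ones(n_present, dtype=np.int64), np.zeros(n_absent, dtype=np.int64)]
    )
    amplitudes = np.full(n, np.nan)
    amplitudes[:n_present] = cfg.amplitude_prior.sample(amp_rng, n_present)

    images = noise_rng.normal(0.0, cfg.noise_sd, size=(n, side, side))

    latents = None
    if cfg.background_mode == "lumpy":
        from .generators import lumpy_background_generator

        lp = cfg.lumpy_params
        gen = lumpy_background_generator(
            side=side,
            n_lumps=lp.n_lumps,
            lump_magnitude=lp.lump_magnitude,
            lump_width=lp.lump_width,
            latent_dim=lp.latent_dim,
        )
        bg_rng = np.random.default_rng(bg_ss)
        latents = bg_rng.standard_normal((n, gen.latent_dim))
        for i in range(n):
            images[i] += gen.generate(latents[i])

    if n_present:
        s_ref = render_unit_signal(cfg)
        images[:n_present] += amplitudes[:n_present, None, None] * s_ref

    return ImageBatch(
        images=images,
        labels=labels,
        amplitudes=amplitudes,
        seed=int(seed),
        config=cfg,
        background_latents=latents,
    )


def gaussian_loglik(g: np.ndarray, mean_image: np.ndarray, noise_sd: float) -> float:
    """Log density of ``g`` under i.i.d. Gaussian pixel noise around ``mean_image``.

    The additive normalization constant is fixed to 0; it cancels in every
    likelihood ratio used by the samplers and observers.
    """
    g = np.asarray(g, dtype=float)
    m = np.asarray(mean_image, dtype=float)
    if g.shape != m.shape:
        raise DimensionError(f"shape mismatch: {g.shape} vs {m.shape}")
    if noise_sd <= 0:
        raise ConfigurationError("noise_sd must be positive")
    r = g - m
    return float(-np.dot(r.ravel(), r.ravel()) / (2.0 * noise_sd**2))


def gaussian_utility(a, b, utility_width: float):
    """Gaussian estimation utility ``u(a, b) = exp(-(a-b)^2 / (2 sigma_u^2))``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return np.exp(-((a - b) ** 2) / (2.0 * utility_width**2))
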