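"""Latent-variable generator contract and reference generators.

A :class:`LatentGenerator` maps a latent vector ``z ~ N(0, I_k)``
deterministically to a signal or background image, optionally with a
parameter readout ``theta(z)``.  This is the contract a trained deep
generative model would satisfy; the package ships two reference
implementations that need no training:

* :func:`exact_signal_generator` -- a one-dimensional latent signal model
  whose push-forward of the standard-normal prior is *exactly* the Gaussian
  amplitude prior of the SKS/BKE task;
* :func:`lumpy_background_generator` -- a lumpy stochastic background whose
  latent coordinates smoothly encode lump centers, standing in for a
  data-driven stochastic object model on the SKS/BKS task.

The radially averaged power spectrum (:func:`radial_power_spectrum`) is the
diagnostic used to validate any generator against direct simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.special import expit

from .errors import ConfigurationError, DimensionError
from .imaging import TaskConfig, render_unit_signal

__all__ = [
    "LatentGenerator",
    "exact_signal_generator",
    "lumpy_background_generator",
    "radial_power_spectrum",
    "compare_spectra",
]


@dataclass
class LatentGenerator:
    """A deterministic map from latent vectors to images.

    Attributes
    ----------
    latent_dim:
        Dimension ``k`` of the latent space; the latent prior is N(0, I_k).
    generate:
        ``z (k,) -> image (side, side)``; pure (equal ``z`` gives bit-equal
        output).
    param_readout:
        Optional ``z -> theta`` mapping for signal generators where the
        latent determines the signal parameter.
    kind:
        ``"signal"`` or ``"background"``.
    params:
        Opaque internal parameters (the analogue of trained weights).
    """

    latent_dim: int
    generate: Callable[[np.ndarray], np.ndarray]
    kind: str
    param_readout: Optional[Callable[[np.ndarray], float]] = None
    params: dict = field(default_factory=dict)


def exact_signal_generator(cfg: TaskConfig) -> LatentGenerator:
    """Latent signal model for the Gaussian-amplitude SKS/BKE task.

    With ``k = 1`` and ``theta(z) = mu_A + sigma_A z``, the push-forward of
    the standard-normal latent prior equals the task's amplitude prior
    exactly, so posterior sampling in latent space is exactly posterior
    sampling of the amplitude.
    """
    cfg.validate()
    if cfg.amplitude_prior.kind != "gaussian":
        raise ConfigurationError(
            "exact_signal_generator requires a gaussian amplitude prior"
        )
    mu = cfg.amplitude_prior.mean
    sd = cfg.amplitude_prior.sd
    s_ref = render_unit_signal(cfg)

    def readout(z: np.ndarray) -> float:
        return float(mu + sd * np.asarray(z, dtype=float).reshape(()))

    def generate(z: np.ndarray) -> np.ndarray:
        return readout(z) * s_ref

    return LatentGenerator(
        latent_dim=1,
        generate=generate,
        param_readout=readout,
        kind="signal",
        params={"mu_A": mu, "sigma_A": sd, "s_ref": s_ref},
    )


def _latent_to_centers(
    z: np.ndarray, n_lumps: int, latent_dim: int, side: int, mix: Optional[np.ndarray]
) -> np.ndarray:
    z = np.asarray(z, dtype=float).reshape(latent_dim)
    coords = z if mix is None else mix @ z
    # logistic squashing keeps centers inside the image and the map smooth in z
    return side * expit(coords).reshape(n_lumps, 2)


def lumpy_background_generator(
    side: int,
    n_lumps: int = 20,
    lump_magnitude: float = 1.0,
    lump_width: float = 4.0,
    latent_dim: Optional[int] = None,
) -> LatentGenerator:
    """Lumpy stochastic background driven by a Gaussian latent vector.

    The latent vector deterministically encodes the lump centers:
    ``centers = side * logistic(z)`` (pairs of latent coordinates per lump),
    or ``side * logistic(W z)`` through a fixed mixing matrix when
    ``latent_dim != 2 * n_lumps``.  ``generate(z)`` superposes ``n_lumps``
    Gaussian blobs of the given magnitude and width and min-max normalizes
    the result to [0, 1] (mirroring intensity-normalized image ensembles).
    Blobs are evaluated on a local window of 4 widths around each center;
    beyond that radius a blob's contribution (< 4e-4 of its magnitude) is
    defined to be zero.
    """
    if side <= 0 or lump_width <= 0 or lump_magnitude <= 0 or n_lumps < 0:
        raise ConfigurationError("lumpy generator parameters must be positive")
    k = 2 * n_lumps if latent_dim is None else int(latent_dim)
    if n_lumps > 0 and k <= 0:
        raise ConfigurationError("latent_dim must be positive")
    mix = None
    if n_lumps > 0 and k != 2 * n_lumps:
        # fixed (not trained) mixing matrix so the map stays deterministic
        mix_rng = np.random.default_rng(20240917)
        mix = mix_rng.standard_normal((2 * n_lumps, k)) / np.sqrt(k)
    radius = int(np.ceil(4.0 * lump_width))
    two_w2 = 2.0 * lump_width**2

    def generate(z: np.ndarray) -> np.ndarray:
        img = np.zeros((side, side))
        if n_lumps == 0:
            return img
        centers = _latent_to_centers(z, n_lumps, k, side, mix)
        for cy, cx in centers:
            y0 = max(0, int(np.floor(cy)) - radius)
            y1 = min(side, int(np.floor(cy)) + radius + 1)
            x0 = max(0, int(np.floor(cx)) - radius)
            x1 = min(side, int(np.floor(cx)) + radius + 1)
            if y0 >= y1 or x0 >= x1:
                continue
            dy2 = (np.arange(y0, y1) - cy) ** 2
            dx2 = (np.arange(x0, x1) - cx) ** 2
            img[y0:y1, x0:x1] += lump_magnitude * np.exp(
                -(dy2[:, None] + dx2[None, :]) / two_w2
            )
        lo, hi = img.min(), img.max()
        if hi > lo:
            img = (img - lo) / (hi - lo)
        else:
            img = np.zeros((side, side))
        return img

    return LatentGenerator(
        latent_dim=max(k, 1),
        generate=generate,
        kind="background",
        params={
            "side": side,
            "n_lumps": n_lumps,
            "lump_magnitude": lump_magnitude,
            "lump_width": lump_width,
        },
    )


def radial_power_spectrum(images: np.ndarray) -> np.ndarray:
    """Radially averaged, unit-max-normalized power spectrum of an image stack.

    Per image the mean is removed (no DC component), the 2-D DFT squared
    modulus is taken, and power is averaged within integer annuli indexed by
    the ceiling of the Euclidean distance from the Fourier center; the
    per-annulus averages are then averaged over images and normalized to
    unit maximum.  For an ``N x N`` image the maximum radial index is
    ``ceil(N/sqrt(2))`` (46 for N=64, 182 for N=256).  No window or padding
    is applied.
    """
    images = np.asarray(images, dtype=float)
    if images.ndim == 2:
        images = images[None]
    if images.ndim != 3 or images.shape[0] < 1:
        raise DimensionError("expected a non-empty stack of 2-D images")
    n_rows, n_cols = images.shape[1:]
    if n_rows != n_cols:
        raise DimensionError("radial power spectrum requires square images")
    n = n_rows
    freqs = np.fft.fftshift(np.fft.fftfreq(n)) * n
    kr, kc = np.meshgrid(freqs, freqs, indexing="ij")
    dist = np.sqrt(kr**2 + kc**2)
    idx = np.ceil(dist).astype(int)
    n_bins = idx.max() + 1
    counts = np.bincount(idx.ravel(), minlength=n_bins)

    centered = images - images.mean(axis=(1, 2), keepdims=True)
    power = np.abs(np.fft.fftshift(np.fft.fft2(centered), axes=(1, 2))) ** 2
    mean_power = power.mean(axis=0)
    curve = np.bincount(idx.ravel(), weights=mean_power.ravel(), minlength=n_bins)
    curve = curve / counts
    peak = curve.max()
    # rounding residue of the mean removal (constant images) is not content
    scale = np.max(np.abs(images)) if images.size else 0.0
    negligible = (16 * np.finfo(float).eps * scale * n * n) ** 2
    if peak > negligible:
        curve = curve / peak
    else:
        curve = np.zeros_like(curve)
    return curve


def compare_spectra(curve_a: np.ndarray, curve_b: np.ndarray) -> float:
    """Maximum absolute difference between two normalized spectral curves."""
    a = np.asarray(curve_a, dtype=float)
    b = np.asarray(curve_b, dtype=float)
    if a.shape != b.shape:
        raise DimensionError(f"curve length mismatch: {a.shape} vs {b.shape}")
    if a.size == 0:
        return 0.0
    return float(np.max(np.abs(a - b)))
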