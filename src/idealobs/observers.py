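"""Observers for joint detection-estimation tasks.

The ideal-observer test statistic factorizes as ``T(g) = Lambda(g) U(g)``:
the pure-detection likelihood ratio times the utility-weighted posterior
mean of the signal parameter.  This module composes observers from three
interchangeable ingredient sources:

* ``Lambda`` -- exact log marginal likelihood ratio (conjugate SKS/BKE
  task), or a trained detection network's posterior probability mapped
  through Bayes' rule;
* ``U`` -- the closed form (conjugate case) or a Metropolis-Hastings
  estimate through a latent generator;
* ``theta_hat`` -- the analytic posterior mean, a trained estimation
  network, or the sample-based grid maximizer.

The *sub-ideal* observer drops the ``U`` factor and uses ``Lambda`` alone
for detection, decoupling estimation from detection; it lower-bounds the
ideal observer's AEROC.  All pipeline statistics are kept in the log domain
(EROC analysis is invariant to the strictly monotone exp).
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .analytic import (
    AnalyticIOModel,
    analytic_estimate,
    analytic_statistic,
    analytic_utility_weighted_mean,
)
from .errors import DataError, DimensionError
from .imaging import ImageBatch, render_unit_signal
from .mcmc import (
    ChainSettings,
    estimate_utility_weighted_mean,
    run_sks_bke_chains,
    run_sks_bks_chains,
)

__all__ = [
    "ObserverResult",
    "batch_hash",
    "likelihood_ratio_from_posterior",
    "hybrid_statistic",
    "sub_ideal_observer",
    "analytic_observer",
    "hybrid_mcmc_observer_bke",
    "hybrid_mcmc_observer_bks",
]


@dataclass
class ObserverResult:
    """Per-image test statistics and parameter estimates for one observer."""

    statistics: np.ndarray
    estimates: np.ndarray
    observer_name: str = ""
    batch_hash: Optional[str] = None

    def __post_init__(self) -> None:
        self.statistics = np.asarray(self.statistics, dtype=float)
        self.estimates = np.asarray(self.estimates, dtype=float)
        if self.statistics.shape != self.estimates.shape:
            raise DimensionError("statistics and estimates must align per image")
        if not np.all(np.isfinite(self.statistics)):
            raise DataError("observer statistics must be finite")

    def subset(self, mask: np.ndarray) -> "ObserverResult":
        return ObserverResult(
            statistics=self.statistics[mask],
            estimates=self.estimates[mask],
            observer_name=self.observer_name,
            batch_hash=self.batch_hash,
        )


def batch_hash(batch: ImageBatch) -> str:
    """Stable identity of an evaluation batch (hash of its pixel data)."""
    h = hashlib.sha1(np.ascontiguousarray(batch.images).tobytes())
    return h.hexdigest()[:16]


def likelihood_ratio_from_posterior(p, prior_odds: float = 1.0):
    """Map a posterior probability Pr(H1|g) to the likelihood ratio.

    ``Lambda = [p / (1 - p)] / prior_odds`` with ``prior_odds =
    Pr(H1)/Pr(H0)`` (1 for balanced sets).  Probabilities at exactly 0 or 1
    are clamped to eps = 1e-12 with a warning.
    """
    if prior_odds <= 0:
        raise DataError("prior_odds must be positive")
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise DataError("posterior probabilities must lie in [0, 1]")
    if np.any((p == 0) | (p == 1)):
        warnings.warn(
            "posterior probabilities at {0,1} clamped to eps=1e-12",
            RuntimeWarning,
            stacklevel=2,
        )
        p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return (p / (1.0 - p)) / prior_odds


def hybrid_statistic(lr, u_hat):
    """Hybrid test statistic ``T = Lambda * U`` (log-domain arithmetic).

    ``u_hat`` must lie in (0, 1]; ``lr`` must be positive.  The product is
    formed as ``exp(log Lambda + log U)`` to avoid underflow.
    """
    lr = np.asarray(lr, dtype=float)
    u = np.asarray(u_hat, dtype=float)
    if lr.shape != u.shape:
        raise DimensionError("Lambda and U must align per image")
    if np.any(lr <= 0):
        raise DataError("likelihood ratios must be positive")
    if np.any((u <= 0) | (u > 1)):
        raise DataError("U estimates must lie in (0, 1]")
    return np.exp(np.log(lr) + np.log(u))


def sub_ideal_observer(
    batch: ImageBatch,
    lr_source: Callable[[ImageBatch], np.ndarray],
    estimator_source: Callable[[ImageBatch], np.ndarray],
    name: str = "sub_ideal",
) -> ObserverResult:
    """Observer using the detection likelihood ratio alone as its statistic.

    ``lr_source``/``estimator_source`` map a batch to per-image (log or
    linear) statistics and amplitude estimates.  By construction the
    statistics do not depend on the estimates, so the estimation step
    cannot affect detection performance.
    """
    stats = np.asarray(lr_source(batch), dtype=float)
    estimates = np.asarray(estimator_source(batch), dtype=float)
    return ObserverResult(
        statistics=stats,
        estimates=estimates,
        observer_name=name,
        batch_hash=batch_hash(batch),
    )


# ---------------------------------------------------------------------------
# Oracle-mode pipelines (no trained components anywhere)
# ---------------------------------------------------------------------------


def analytic_observer(
    batch: ImageBatch, model: Optional[AnalyticIOModel] = None
) -> ObserverResult:
    """Closed-form ideal observer for the conjugate SKS/BKE task.

    Statistic: exact ``log Lambda(g)`` (the constant conjugate ``U`` factor
    shifts the log statistic uniformly and cannot change any ranking);
    estimate: posterior-mean amplitude.
    """
    model = model or AnalyticIOModel.from_task(batch.config)
    log_lr = analytic_statistic(model, batch.images)
    log_u = np.log(analytic_utility_weighted_mean(model, batch.images))
    return ObserverResult(
        statistics=log_lr + log_u,
        estimates=analytic_estimate(model, batch.images),
        observer_name="analytic_io",
        batch_hash=batch_hash(batch),
    )


def hybrid_mcmc_observer_bke(
    batch: ImageBatch,
    settings: ChainSettings,
    model: Optional[AnalyticIOModel] = None,
) -> tuple[ObserverResult, dict]:
    """Hybrid ideal observer for SKS/BKE: exact ``Lambda`` times MCMC ``U``.

    ``U(g)`` is estimated by pCN latent-space sampling through the exact
    latent signal generator; ``Lambda`` is the exact log marginal
    likelihood ratio and the amplitude estimate the analytic posterior
    mean.  Returns the result plus chain diagnostics.
    """
    model = model or AnalyticIOModel.from_task(batch.config)
    theta_hat = analytic_estimate(model, batch.images)
    theta_samples, rates = run_sks_bke_chains(
        batch.images,
        model.s_ref,
        model.noise_sd,
        model.prior_mean,
        model.prior_sd,
        settings,
    )
    u_hat = estimate_utility_weighted_mean(
        theta_samples, theta_hat, model.utility_width
    )
    log_lr = analytic_statistic(model, batch.images)
    result = ObserverResult(
        statistics=log_lr + np.log(u_hat),
        estimates=theta_hat,
        observer_name="hybrid_mcmc",
        batch_hash=batch_hash(batch),
    )
    diagnostics = {
        "acceptance_rate_mean": float(np.mean(rates)),
        "acceptance_rate_min": float(np.min(rates)),
        "acceptance_rate_max": float(np.max(rates)),
        "n_samples": settings.n_samples,
        "burn_in": settings.burn_in,
        "pcn_beta": settings.pcn_beta,
        "u_hat_mean": float(np.mean(u_hat)),
    }
    return result, diagnostics


def hybrid_mcmc_observer_bks(
    batch: ImageBatch,
    log_lr: np.ndarray,
    settings: ChainSettings,
    estimate_grid: Optional[np.ndarray] = None,
    estimates: Optional[np.ndarray] = None,
) -> tuple[ObserverResult, dict]:
    """Hybrid observer for the lumpy-background SKS/BKS task.

    ``log_lr`` is the per-image log likelihood-ratio statistic from any
    source (typically a trained detection network).  ``U(g)`` is estimated
    by joint (theta, z) Metropolis-Hastings through the task's lumpy
    background generator, with the latent block initialized at the
    simulator's recorded background latents.  Amplitude estimates default
    to the sample-based grid maximizer over ``estimate_grid`` (the prior
    support by default); pass ``estimates`` to use an external estimator.
    """
    from .generators import lumpy_background_generator
    from .mcmc import sample_based_estimator

    cfg = batch.config
    if cfg.background_mode != "lumpy":
        raise DataError("hybrid_mcmc_observer_bks expects a lumpy-background task")
    lp = cfg.lumpy_params
    gen = lumpy_background_generator(
        side=cfg.image_side,
        n_lumps=lp.n_lumps,
        lump_magnitude=lp.lump_magnitude,
        lump_width=lp.lump_width,
        latent_dim=lp.latent_dim,
    )
    theta_samples, rates = run_sks_bks_chains(
        batch.images,
        render_unit_signal(cfg),
        gen,
        cfg.noise_sd,
        cfg.amplitude_prior,
        settings,
        init_latents=batch.background_latents,
    )
    if estimates is None:
        if estimate_grid is None:
            prior = cfg.amplitude_prior
            estimate_grid = np.linspace(prior.lo, prior.hi, 101)
        estimates = sample_based_estimator(
            theta_samples, cfg.utility_width, estimate_grid
        )
    u_hat = estimate_utility_weighted_mean(
        theta_samples, np.asarray(estimates, dtype=float), cfg.utility_width
    )
    result = ObserverResult(
        statistics=np.asarray(log_lr, dtype=float) + np.log(u_hat),
        estimates=np.asarray(estimates, dtype=float),
        observer_name="hybrid_mcmc",
        batch_hash=batch_hash(batch),
    )
    diagnostics = {
        "acceptance_rate_mean": float(np.mean(rates)),
        "acceptance_rate_min": float(np.min(rates)),
        "acceptance_rate_max": float(np.max(rates)),
        "u_hat_mean": float(np.mean(u_hat)),
        "u_hat_min": float(np.min(u_hat)),
    }
    return result, diagnostics
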