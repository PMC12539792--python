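"""Closed-form ideal observer for the Gaussian SKS/BKE task.

For a known background (taken as zero), signal image ``A * s_ref`` with
``A ~ N(mu_A, sigma_A^2)``, and i.i.d. Gaussian noise of standard deviation
``sigma_n``, the model is conjugate: the posterior of the amplitude given a
signal-present image ``g`` is Gaussian with

    variance  v      = sigma_n^2 sigma_A^2 / (sigma_n^2 + sigma_A^2 ||s_ref||^2)
    mean      A_hat  = (sigma_A^2 <s_ref, g> + sigma_n^2 mu_A)
                       / (sigma_n^2 + sigma_A^2 ||s_ref||^2)

``A_hat`` is the ideal-observer amplitude estimate.  Marginalizing the
amplitude analytically gives the exact log marginal likelihood ratio

    log Lambda(g) = 1/2 log(v / sigma_A^2) + A_hat^2 / (2 v)
                    - mu_A^2 / (2 sigma_A^2),

which this module uses as the canonical detection statistic (any strictly
monotone transform of it produces the same EROC curve).  Because ``v`` does
not depend on ``g``, the utility-weighted posterior mean with a Gaussian
utility of width ``sigma_u`` has the closed form
``U(g) = sigma_u / sqrt(sigma_u^2 + v)``, constant across images.

The quadrature functions re-derive all of these quantities by adaptive 1-D
integration over the amplitude and are kept free of the closed forms; they
serve as independent oracles for both this module and the MCMC samplers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad
from scipy.stats import norm

from .errors import DimensionError
from .imaging import TaskConfig, gaussian_utility, render_unit_signal

__all__ = [
    "AnalyticIOModel",
    "analytic_estimate",
    "analytic_statistic",
    "conjugate_posterior",
    "analytic_utility_weighted_mean",
    "quadrature_posterior_moments",
    "quadrature_log_marginal_ratio",
    "quadrature_utility_weighted_mean",
]


@dataclass(frozen=True)
class AnalyticIOModel:
    """Sufficient description of the conjugate SKS/BKE observer."""

    s_ref: np.ndarray
    noise_sd: float
    prior_mean: float
    prior_sd: float
    utility_width: float

    @property
    def s_norm_sq(self) -> float:
        return float(np.sum(self.s_ref**2))

    @property
    def posterior_variance(self) -> float:
        sn2 = self.noise_sd**2
        sa2 = self.prior_sd**2
        return sn2 * sa2 / (sn2 + sa2 * self.s_norm_sq)

    @staticmethod
    def from_task(cfg: TaskConfig) -> "AnalyticIOModel":
        if cfg.amplitude_prior.kind != "gaussian":
            raise ValueError("analytic IO requires a gaussian amplitude prior")
        return AnalyticIOModel(
            s_ref=render_unit_signal(cfg),
            noise_sd=cfg.noise_sd,
            prior_mean=cfg.amplitude_prior.mean,
            prior_sd=cfg.amplitude_prior.sd,
            utility_width=cfg.utility_width,
        )

    def signal_dot(self, g: np.ndarray) -> np.ndarray:
        """Matched-filter output ``<s_ref, g>`` for one image or a stack."""
        g = np.asarray(g, dtype=float)
        if g.shape[-2:] != self.s_ref.shape:
            raise DimensionError(
                f"image shape {g.shape[-2:]} does not match s_ref {self.s_ref.shape}"
            )
        return np.tensordot(g, self.s_ref, axes=([-2, -1], [0, 1]))


def analytic_estimate(model: AnalyticIOModel, g: np.ndarray) -> np.ndarray:
    """Posterior-mean amplitude estimate; affine in ``g``; vectorized over stacks."""
    t = model.signal_dot(g)
    sn2 = model.noise_sd**2
    sa2 = model.prior_sd**2
    return (sa2 * t + sn2 * model.prior_mean) / (sn2 + sa2 * model.s_norm_sq)


def analytic_statistic(model: AnalyticIOModel, g: np.ndarray) -> np.ndarray:
    """Exact log marginal likelihood ratio ``log Lambda(g)``."""
    a_hat = analytic_estimate(model, g)
    v = model.posterior_variance
    sa2 = model.prior_sd**2
    return (
        0.5 * np.log(v / sa2)
        + a_hat**2 / (2.0 * v)
        - model.prior_mean**2 / (2.0 * sa2)
    )


def conjugate_posterior(
    model: AnalyticIOModel, g: np.ndarray
) -> tuple[np.ndarray, float]:
    """Posterior (mean, variance) of the amplitude given ``g`` under H1."""
    return analytic_estimate(model, g), model.posterior_variance


def analytic_utility_weighted_mean(model: AnalyticIOModel, g: np.ndarray) -> np.ndarray:
    """Expected Gaussian utility of the ideal estimate under the posterior.

    ``U(g) = E[u(A_hat, A) | g, H1] = sigma_u / sqrt(sigma_u^2 + v)``; the
    conjugate posterior variance is image-independent, so the value is a
    constant broadcast to the batch shape of ``g``.
    """
    a_hat = analytic_estimate(model, g)
    su = model.utility_width
    value = su / np.sqrt(su**2 + model.posterior_variance)
    return np.broadcast_to(np.asarray(value), np.shape(a_hat)).copy()


# ---------------------------------------------------------------------------
# Quadrature oracles (independent of the closed forms above)
# ---------------------------------------------------------------------------


def _relative_loglik(model: AnalyticIOModel, g: np.ndarray):
    """Return h(A) = log p(g | A s_ref) - log p(g | 0) as a function of A."""
    t = float(model.signal_dot(np.asarray(g, dtype=float)))
    s2 = model.s_norm_sq
    sn2 = model.noise_sd**2

    def h(a: float) -> float:
        return (a * t - 0.5 * a**2 * s2) / sn2

    a_star = t / s2  # maximizer of h
    return h, h(a_star)


def _prior_bounds(model: AnalyticIOModel) -> tuple[float, float]:
    return (
        model.prior_mean - 8.0 * model.prior_sd,
        model.prior_mean + 8.0 * model.prior_sd,
    )


def quadrature_posterior_moments(
    model: AnalyticIOModel, g: np.ndarray
) -> tuple[float, float]:
    """Posterior mean and variance of the amplitude by adaptive 1-D quadrature."""
    h, h_max = _relative_loglik(model, g)
    lo, hi = _prior_bounds(model)
    prior = norm(model.prior_mean, model.prior_sd).pdf

    def w(a):
        return prior(a) * np.exp(h(a) - h_max)

    z0 = quad(w, lo, hi, limit=200)[0]
    m1 = quad(lambda a: a * w(a), lo, hi, limit=200)[0] / z0
    m2 = quad(lambda a: (a - m1) ** 2 * w(a), lo, hi, limit=200)[0] / z0
    return m1, m2


def quadrature_log_marginal_ratio(model: AnalyticIOModel, g: np.ndarray) -> float:
    """log Lambda(g) by quadrature: log ∫ p(A) p(g|A s_ref)/p(g|0) dA."""
    h, h_max = _relative_loglik(model, g)
    lo, hi = _prior_bounds(model)
    prior = norm(model.prior_mean, model.prior_sd).pdf
    integral = quad(lambda a: prior(a) * np.exp(h(a) - h_max), lo, hi, limit=200)[0]
    return float(np.log(integral) + h_max)


def quadrature_utility_weighted_mean(model: AnalyticIOModel, g: np.ndarray) -> float:
    """U(g) by quadrature, with the estimate itself taken from quadrature."""
    mean, _ = quadrature_posterior_moments(model, g)
    h, h_max = _relative_loglik(model, g)
    lo, hi = _prior_bounds(model)
    prior = norm(model.prior_mean, model.prior_sd).pdf

    def w(a):
        return prior(a) * np.exp(h(a) - h_max)

    z0 = quad(w, lo, hi, limit=200)[0]
    num = quad(
        lambda a: gaussian_utility(mean, a, model.utility_width) * w(a),
        lo,
        hi,
        limit=200,
    )[0]
    return float(num / z0)
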