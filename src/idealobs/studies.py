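"""End-to-end reproduction studies.

Two study drivers tie the package together:

* :func:`reproduce_sks_bke` -- the conjugate Gaussian SKS/BKE validation
  study: simulate an evaluation set, score it with the closed-form ideal
  observer and with the hybrid observer (exact log likelihood ratio times
  the pCN-MCMC estimate of the utility-weighted posterior mean), and
  summarize both by AEROC with bootstrap uncertainty.  Because the
  conjugate ``U(g)`` is image-independent, the two observers are
  statistically equivalent; the study quantifies how close the Monte Carlo
  pipeline gets.

* :func:`sks_bks_ordering_study` -- the lumpy-background SKS/BKS study
  where no analytic ideal observer exists: the likelihood ratio and the
  amplitude estimator are learned networks shared by both observers, and
  the hybrid observer additionally weights the statistic by the MCMC
  ``U(g)``.  The ideal-observer property under test is the ordering
  AEROC(hybrid) >= AEROC(sub-ideal).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .analytic import AnalyticIOModel
from .eroc import (
    ErocCurve,
    aeroc_uncertainty,
    compute_eroc,
    paired_aeroc_delta_uncertainty,
)
from .imaging import ImageBatch, TaskConfig, get_preset, simulate_batch
from .mcmc import ChainSettings
from .nets import NetHyperparams, train_detection, train_estimation
from .observers import (
    ObserverResult,
    analytic_observer,
    batch_hash,
    hybrid_mcmc_observer_bke,
    hybrid_mcmc_observer_bks,
    sub_ideal_observer,
)

__all__ = [
    "BKS_CHAIN_DEFAULTS",
    "BKS_NET_DEFAULTS",
    "split_results",
    "reproduce_sks_bke",
    "sks_bks_ordering_study",
]

# Joint-chain step sizes for the lumpy SKS/BKS task.  With noise sd 0.01 on
# a 64x64 image the posterior over (amplitude, background latent) is very
# concentrated, so both blocks need far smaller moves than the SKS/BKE
# defaults to keep Metropolis-Hastings acceptance in a healthy range.
BKS_CHAIN_DEFAULTS = ChainSettings(
    n_samples=1000, burn_in=300, pcn_beta=2e-4, theta_proposal_sd=0.002, seed=0
)

# Learned-observer configuration for the lumpy task: a shrinkage-regularized
# linear readout over 4x4-average-pooled pixels.
BKS_NET_DEFAULTS = NetHyperparams()


def split_results(
    batch: ImageBatch, result: ObserverResult
) -> tuple[ObserverResult, ObserverResult, np.ndarray]:
    """Split one batch-wide result into (present, absent, true amplitudes)."""
    present = batch.labels == 1
    return result.subset(present), result.subset(~present), batch.amplitudes[present]


def _curve_and_uncertainty(
    batch: ImageBatch,
    result: ObserverResult,
    n_boot: int,
    boot_seed: int,
) -> tuple[ErocCurve, float]:
    rp, ra, truths = split_results(batch, result)
    curve = compute_eroc(rp, ra, truths, batch.config.utility_width)
    _, half_width = aeroc_uncertainty(
        rp, ra, truths, batch.config.utility_width, n_boot=n_boot, seed=boot_seed
    )
    return curve, half_width


def reproduce_sks_bke(
    n_present: int = 400,
    n_absent: int = 400,
    seed: int = 1,
    chain_settings: Optional[ChainSettings] = None,
    n_boot: int = 2000,
    config: Optional[TaskConfig] = None,
) -> dict:
    """Run the SKS/BKE validation study end to end.

    Returns a dict with per-observer AEROCs and bootstrap half-widths, the
    paired AEROC difference with its own uncertainty, EROC curves, and the
    MCMC diagnostics.
    """
    cfg = config or get_preset("sks_bke_gaussian")
    settings = chain_settings or ChainSettings(seed=seed + 1)
    batch = simulate_batch(cfg, n_present, n_absent, seed=seed)
    model = AnalyticIOModel.from_task(cfg)

    res_analytic = analytic_observer(batch, model)
    res_hybrid, diagnostics = hybrid_mcmc_observer_bke(batch, settings, model)

    curve_a, hw_a = _curve_and_uncertainty(batch, res_analytic, n_boot, seed + 2)
    curve_h, hw_h = _curve_and_uncertainty(batch, res_hybrid, n_boot, seed + 3)
    ap, aa, truths = split_results(batch, res_analytic)
    hp, ha, _ = split_results(batch, res_hybrid)
    delta, hw_delta = paired_aeroc_delta_uncertainty(
        hp, ha, ap, aa, truths, cfg.utility_width, n_boot=n_boot, seed=seed + 4
    )
    return {
        "config": cfg.to_dict(),
        "seed": seed,
        "n_present": n_present,
        "n_absent": n_absent,
        "batch_hash": batch_hash(batch),
        "analytic": {"aeroc": curve_a.aeroc, "half_width_95": hw_a},
        "hybrid_mcmc": {"aeroc": curve_h.aeroc, "half_width_95": hw_h},
        "delta_aeroc": delta,
        "delta_half_width_95": hw_delta,
        "chain_diagnostics": diagnostics,
        "curves": {"analytic": curve_a, "hybrid_mcmc": curve_h},
        "batch": batch,
        "results": {"analytic": res_analytic, "hybrid_mcmc": res_hybrid},
    }


@dataclass
class BksStudySettings:
    """Problem sizes and components of the SKS/BKS ordering study."""

    n_train_per_class: int = 2000
    n_present: int = 100
    n_absent: int = 100
    n_boot: int = 1000
    chain: ChainSettings = field(default_factory=lambda: BKS_CHAIN_DEFAULTS)
    nets: NetHyperparams = field(default_factory=lambda: BKS_NET_DEFAULTS)


def sks_bks_ordering_study(
    seed: int = 1,
    settings: Optional[BksStudySettings] = None,
    config: Optional[TaskConfig] = None,
) -> dict:
    """Hybrid vs sub-ideal observer on the lumpy-background SKS/BKS task.

    The detection network supplies the (log-odds) likelihood-ratio
    statistic and the estimation network the amplitude estimates for BOTH
    observers, so the comparison isolates the effect of the
    utility-weighted posterior-mean factor ``U(g)`` that only the hybrid
    observer applies.
    """
    st = settings or BksStudySettings()
    cfg = config or get_preset("sks_bks_lumpy")

    train = simulate_batch(
        cfg, st.n_train_per_class, st.n_train_per_class, seed=seed + 100
    )
    hp = NetHyperparams(**{**st.nets.__dict__, "seed": seed + 200})
    det = train_detection(train, hp)
    est = train_estimation(train, cfg.utility_width, hp)

    batch = simulate_batch(cfg, st.n_present, st.n_absent, seed=seed)
    log_lr = det.predict_logit(batch.images)
    estimates = est.predict(batch.images)

    res_sub = sub_ideal_observer(
        batch, lambda b: log_lr, lambda b: estimates, name="sub_ideal"
    )
    chain = ChainSettings(**{**st.chain.__dict__, "seed": seed + 300})
    res_hybrid, diagnostics = hybrid_mcmc_observer_bks(
        batch, log_lr, chain, estimates=estimates
    )

    curve_h, hw_h = _curve_and_uncertainty(batch, res_hybrid, st.n_boot, seed + 2)
    curve_s, hw_s = _curve_and_uncertainty(batch, res_sub, st.n_boot, seed + 3)
    hp_res, ha_res, truths = split_results(batch, res_hybrid)
    sp_res, sa_res, _ = split_results(batch, res_sub)
    delta, hw_delta = paired_aeroc_delta_uncertainty(
        hp_res, ha_res, sp_res, sa_res, truths, cfg.utility_width,
        n_boot=st.n_boot, seed=seed + 4,
    )
    return {
        "config": cfg.to_dict(),
        "seed": seed,
        "n_present": st.n_present,
        "n_absent": st.n_absent,
        "batch_hash": batch_hash(batch),
        "hybrid_mcmc": {"aeroc": curve_h.aeroc, "half_width_95": hw_h},
        "sub_ideal": {"aeroc": curve_s.aeroc, "half_width_95": hw_s},
        "delta_aeroc": delta,
        "delta_half_width_95": hw_delta,
        "chain_diagnostics": diagnostics,
        "curves": {"hybrid_mcmc": curve_h, "sub_ideal": curve_s},
        "batch": batch,
        "results": {"hybrid_mcmc": res_hybrid, "sub_ideal": res_sub},
    }
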