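"""Estimation ROC (EROC) curve construction and AEROC estimation.

An EROC curve plots, as the decision threshold ``t`` sweeps, the expected
utility of the parameter estimates on true-positive cases,

    y(t) = (1/N1) sum_i u_i 1[T_i > t],      u_i = u(theta_hat_i, theta_i),

against the false positive fraction ``x(t) = (1/N0) #{j : T_j > t}``.  The
ordinate averages utility over *all* signal-present cases (utility times
detection indicator), so the curve is non-decreasing and its right endpoint
equals the mean utility.  With thresholds at midpoints between distinct
pooled statistic values (plus sentinels), the trapezoidal area under the
curve equals the two-sample pairwise form

    AEROC = (1/(N1 N0)) sum_i sum_j u_i (1[T_i > T_j] + 1/2 1[T_i = T_j])

exactly; ties receive half credit.  With utility identically one the AEROC
reduces to the Wilcoxon AUC, and both forms are invariant under strictly
increasing transforms of the statistic.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .errors import ComparisonError, DataError, DimensionError
from .imaging import gaussian_utility
from .observers import ObserverResult

__all__ = [
    "ErocCurve",
    "compute_eroc",
    "pairwise_aeroc",
    "aeroc_uncertainty",
    "compare_observers",
]


@dataclass
class ErocCurve:
    """One observer's EROC curve and its area."""

    thresholds: np.ndarray  # descending, with +/- inf sentinels
    fpf: np.ndarray  # non-decreasing in [0, 1]
    expected_utility_tp: np.ndarray  # in [0, 1]
    aeroc: float
    n_present: int
    n_absent: int
    observer_name: str = ""
    batch_hash: Optional[str] = None

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["threshold", "fpf", "expected_utility_tp"])
            for t, x, y in zip(self.thresholds, self.fpf, self.expected_utility_tp):
                writer.writerow([t, x, y])

    def summary(self) -> dict:
        return {
            "observer_name": self.observer_name,
            "aeroc": self.aeroc,
            "n_present": self.n_present,
            "n_absent": self.n_absent,
        }


def _case_utilities(
    result_present: ObserverResult, true_amplitudes: np.ndarray, utility_width: float
) -> np.ndarray:
    truths = np.asarray(true_amplitudes, dtype=float)
    if truths.shape != result_present.statistics.shape:
        raise DimensionError("true amplitudes must align with the H1 results")
    if not np.all(np.isfinite(truths)):
        raise DataError("true amplitudes must be finite for all H1 cases")
    return gaussian_utility(result_present.estimates, truths, utility_width)


def compute_eroc(
    result_present: ObserverResult,
    result_absent: ObserverResult,
    true_amplitudes: np.ndarray,
    utility_width: float,
) -> ErocCurve:
    """EROC curve by threshold sweep; area by trapezoid.

    ``result_present`` holds statistics/estimates on the signal-present
    images (with ``true_amplitudes`` their ground truth) and
    ``result_absent`` the statistics on signal-absent images.
    """
    tp = np.asarray(result_present.statistics, dtype=float)
    ta = np.asarray(result_absent.statistics, dtype=float)
    if tp.size == 0 or ta.size == 0:
        raise DataError("both classes must be non-empty")
    if result_present.batch_hash != result_absent.batch_hash:
        raise ComparisonError("present/absent results come from different batches")
    u = _case_utilities(result_present, true_amplitudes, utility_width)

    pooled = np.unique(np.concatenate([tp, ta]))  # ascending distinct values
    mids = 0.5 * (pooled[:-1] + pooled[1:])
    thresholds = np.concatenate([[np.inf], mids[::-1], [-np.inf]])
    fpf = np.array([np.mean(ta > t) for t in thresholds])
    utp = np.array([np.sum(u * (tp > t)) / tp.size for t in thresholds])
    aeroc = float(np.trapezoid(utp, fpf))
    return ErocCurve(
        thresholds=thresholds,
        fpf=fpf,
        expected_utility_tp=utp,
        aeroc=aeroc,
        n_present=tp.size,
        n_absent=ta.size,
        observer_name=result_present.observer_name,
        batch_hash=result_present.batch_hash,
    )


def pairwise_aeroc(
    stats_present: np.ndarray, stats_absent: np.ndarray, utilities: np.ndarray
) -> float:
    """Two-sample form of the AEROC with half credit for ties.

    Computed with sorted-search counting, equivalent to the explicit double
    sum over (present, absent) pairs.
    """
    tp = np.asarray(stats_present, dtype=float)
    ta = np.sort(np.asarray(stats_absent, dtype=float))
    u = np.asarray(utilities, dtype=float)
    below = np.searchsorted(ta, tp, side="left")
    ties = np.searchsorted(ta, tp, side="right") - below
    return float(np.sum(u * (below + 0.5 * ties)) / (tp.size * ta.size))


def aeroc_uncertainty(
    result_present: ObserverResult,
    result_absent: ObserverResult,
    true_amplitudes: np.ndarray,
    utility_width: float,
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """Point AEROC and 95% half-width by stratified case bootstrap.

    Cases are resampled with replacement within each class; the half-width
    is half the distance between the 2.5th and 97.5th percentiles of the
    bootstrap AEROC distribution.
    """
    if n_boot < 100:
        raise DataError("n_boot must be >= 100")
    tp = np.asarray(result_present.statistics, dtype=float)
    ta = np.asarray(result_absent.statistics, dtype=float)
    u = _case_utilities(result_present, true_amplitudes, utility_width)
    point = pairwise_aeroc(tp, ta, u)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        ip = rng.integers(0, tp.size, tp.size)
        ia = rng.integers(0, ta.size, ta.size)
        boots[b] = pairwise_aeroc(tp[ip], ta[ia], u[ip])
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return point, float(0.5 * (hi - lo))


def paired_aeroc_delta_uncertainty(
    result_a_present: ObserverResult,
    result_a_absent: ObserverResult,
    result_b_present: ObserverResult,
    result_b_absent: ObserverResult,
    true_amplitudes: np.ndarray,
    utility_width: float,
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """Paired bootstrap of an AEROC difference between two observers.

    Both observers are evaluated on the same cases, so the same resampled
    case indices are applied to both; returns the point difference
    (a - b) and the 95% half-width of its bootstrap distribution.
    """
    ap = np.asarray(result_a_present.statistics, dtype=float)
    aa = np.asarray(result_a_absent.statistics, dtype=float)
    bp = np.asarray(result_b_present.statistics, dtype=float)
    ba = np.asarray(result_b_absent.statistics, dtype=float)
    if ap.shape != bp.shape or aa.shape != ba.shape:
        raise ComparisonError("paired comparison needs results on the same cases")
    ua = _case_utilities(result_a_present, true_amplitudes, utility_width)
    ub = _case_utilities(result_b_present, true_amplitudes, utility_width)
    point = pairwise_aeroc(ap, aa, ua) - pairwise_aeroc(bp, ba, ub)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        ip = rng.integers(0, ap.size, ap.size)
        ia = rng.integers(0, aa.size, aa.size)
        boots[b] = pairwise_aeroc(ap[ip], aa[ia], ua[ip]) - pairwise_aeroc(
            bp[ip], ba[ia], ub[ip]
        )
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return float(point), float(0.5 * (hi - lo))


def paired_curve_difference(
    result_a_present: ObserverResult,
    result_a_absent: ObserverResult,
    result_b_present: ObserverResult,
    result_b_absent: ObserverResult,
    true_amplitudes: np.ndarray,
    utility_width: float,
    fpf_grid: np.ndarray,
    n_boot: int = 500,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise EROC difference (a - b) on a common fpf grid with bootstrap sd.

    Used to check "nowhere lower" dominance claims within Monte Carlo error:
    the observed difference should not fall below roughly minus twice the
    bootstrap standard deviation anywhere on the grid.
    """

    def curves_diff(ip, ia):
        d = np.empty(len(fpf_grid))
        ca = compute_eroc(
            result_a_present.subset(ip), result_a_absent.subset(ia),
            np.asarray(true_amplitudes)[ip], utility_width,
        )
        cb = compute_eroc(
            result_b_present.subset(ip), result_b_absent.subset(ia),
            np.asarray(true_amplitudes)[ip], utility_width,
        )
        ya = np.interp(fpf_grid, ca.fpf, ca.expected_utility_tp)
        yb = np.interp(fpf_grid, cb.fpf, cb.expected_utility_tp)
        d[:] = ya - yb
        return d

    n1 = result_a_present.statistics.size
    n0 = result_a_absent.statistics.size
    point = curves_diff(np.arange(n1), np.arange(n0))
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, len(fpf_grid)))
    for b in range(n_boot):
        boots[b] = curves_diff(
            rng.integers(0, n1, n1), rng.integers(0, n0, n0)
        )
    return point, boots.std(axis=0, ddof=1)


def compare_observers(
    curve_a: ErocCurve, curve_b: ErocCurve
) -> tuple[float, bool]:
    """AEROC difference (a - b) and pointwise dominance of curve_a.

    Dominance holds iff curve_a's expected utility is >= curve_b's at every
    point of the union of the two fpf grids (linear interpolation).  Curves
    must come from the same evaluation batch.
    """
    if (
        curve_a.batch_hash is not None
        and curve_b.batch_hash is not None
        and curve_a.batch_hash != curve_b.batch_hash
    ):
        raise ComparisonError("EROC curves computed on different evaluation batches")
    delta = curve_a.aeroc - curve_b.aeroc
    grid = np.union1d(curve_a.fpf, curve_b.fpf)
    ya = np.interp(grid, curve_a.fpf, curve_a.expected_utility_tp)
    yb = np.interp(grid, curve_b.fpf, curve_b.expected_utility_tp)
    dominance = bool(np.all(ya >= yb - 1e-12))
    return float(delta), dominance


def write_summary_json(
    path: str | Path, curve: ErocCurve, half_width_95: Optional[float] = None
) -> None:
    d = curve.summary()
    if half_width_95 is not None:
        d["half_width_95"] = half_width_95
    with open(path, "w") as fh:
        json.dump(d, fh, indent=2)
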