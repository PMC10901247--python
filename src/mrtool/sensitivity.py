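"""Sensitivity suite: Cochran's Q, MR-PRESSO global/outlier tests with
iterative removal, leave-one-out, Steiger direction test, F-statistics.

The heterogeneity verdict follows the rule "Q > k-1 OR p < 0.05" with strict
inequalities.  MR-PRESSO p-values are Monte-Carlo tail probabilities with the
+1 correction, reproducible bit-exactly from (seed, n_sim).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InsufficientInstrumentsError, ValidationError
from .estimators import ivw
from .harmonize import HarmonizedSet

PRESSO_MIN_SNPS = 4


@dataclass
class SensitivityReport:
    q: float | None = None
    q_df: int | None = None
    q_p: float | None = None
    heterogeneous: bool | None = None
    presso_global_p: float | None = None
    presso_outliers: list[tuple[str, float]] = field(default_factory=list)
    loo: pd.DataFrame | None = None
    loo_driven_by_single_snp: bool | None = None
    steiger_r2_exposure: float | None = None
    steiger_r2_outcome: float | None = None
    steiger_direction: bool | None = None
    steiger_p: float | None = None
    f_stats: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "q": self.q, "q_df": self.q_df, "q_p": self.q_p,
            "heterogeneous": self.heterogeneous,
            "presso_global_p": self.presso_global_p,
            "presso_outliers": [list(t) for t in self.presso_outliers],
            "loo_driven_by_single_snp": self.loo_driven_by_single_snp,
            "steiger_r2_exposure": self.steiger_r2_exposure,
            "steiger_r2_outcome": self.steiger_r2_outcome,
            "steiger_direction": self.steiger_direction,
            "steiger_p": self.steiger_p,
            "f_stats": self.f_stats,
        }
        if self.loo is not None:
            d["loo"] = self.loo.to_dict(orient="records")
        return d


def cochran_q(h: HarmonizedSet, beta_ivw: float) -> tuple[float, int, float, bool]:
    """Cochran's Q over per-SNP Wald ratios at the supplied causal estimate.

    Returns (q, df, p, heterogeneous) with heterogeneous = (Q > k-1) OR
    (p < 0.05), both strict.
    """
    k = len(h)
    if k < 2:
        raise InsufficientInstrumentsError("cochran_q needs k >= 2")
    ratios = h.by / h.bx
    w = (h.bx / h.se_y) ** 2  # = (se_y/bx)^-2
    q = float(np.sum(w * (ratios - beta_ivw) ** 2))
    df = k - 1
    p = float(sps.chi2.sf(q, df))
    heterogeneous = (q > df) or (p < 0.05)
    return q, df, p, heterogeneous


def _loo_betas(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """IVW beta excluding each SNP in turn (vectorized). Shapes broadcast over
    the last axis."""
    sxy = np.sum(w * bx * by, axis=-1, keepdims=True)
    sxx = np.sum(w * bx * bx, axis=-1, keepdims=True)
    return (sxy - w * bx * by) / (sxx - w * bx * bx)


def _presso_residuals(h: HarmonizedSet, rng: np.random.Generator, n_sim: int):
    """Observed and simulated weighted residuals for the global/outlier tests.

    Returns (res_obs[k], rss_obs, res_sim[n_sim, k], rss_sim[n_sim]).
    """
    bx, by, se_x, se_y = h.bx, h.by, h.se_x, h.se_y
    w = 1.0 / se_y**2
    beta_loo = _loo_betas(bx, by, w)
    res_obs = w * (by - beta_loo * bx) ** 2
    rss_obs = float(np.sum(res_obs))

    k = len(h)
    bx_sim = rng.normal(bx, se_x, size=(n_sim, k))
    by_sim = rng.normal(beta_loo * bx, se_y, size=(n_sim, k))
    beta_loo_sim = _loo_betas(bx_sim, by_sim, w)
    res_sim = w * (by_sim - beta_loo_sim * bx_sim) ** 2
    rss_sim = np.sum(res_sim, axis=1)
    return res_obs, rss_obs, res_sim, rss_sim


def presso_global(
    h: HarmonizedSet, n_sim: int = 1000, seed: int = 0,
) -> tuple[float, float]:
    """MR-PRESSO global test: observed leave-one-out residual sum of squares
    against its parametric null distribution.

    Returns (rss_obs, global_p) with global_p = (1 + #{rss* >= rss_obs})
    / (n_sim + 1).
    """
    if len(h) < PRESSO_MIN_SNPS:
        raise InsufficientInstrumentsError(
            f"presso_global needs k >= {PRESSO_MIN_SNPS}")
    rng = np.random.default_rng(seed)
    _, rss_obs, _, rss_sim = _presso_residuals(h, rng, n_sim)
    global_p = (1 + int(np.sum(rss_sim >= rss_obs))) / (n_sim + 1)
    return rss_obs, float(global_p)


def presso_outlier_loop(
    h: HarmonizedSet,
    n_sim: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[HarmonizedSet, list[tuple[str, float]], float]:
    """Iteratively remove outlier SNPs while the global test is significant.

    Per-SNP outlier p-values are Monte-Carlo tails of each SNP's weighted
    residual, Bonferroni-adjusted by the current k.  The SNP with the smallest
    outlier p is removed and the tests recomputed until the global p exceeds
    ``alpha``, no SNP remains significant, or fewer than 4 SNPs remain.

    Returns (cleaned set, removed [(snp_id, outlier_p), ...], final global p).
    """
    if len(h) < PRESSO_MIN_SNPS:
        raise InsufficientInstrumentsError(
            f"presso_outlier_loop needs k >= {PRESSO_MIN_SNPS}")
    rng = np.random.default_rng(seed)
    current = h
    removed: list[tuple[str, float]] = []
    while True:
        k = len(current)
        res_obs, rss_obs, res_sim, rss_sim = _presso_residuals(current, rng, n_sim)
        global_p = (1 + int(np.sum(rss_sim >= rss_obs))) / (n_sim + 1)
        if global_p > alpha:
            break
        p_out = (1 + np.sum(res_sim >= res_obs, axis=0)) / (n_sim + 1)
        p_adj = np.minimum(1.0, p_out * k)
        j = int(np.argmin(p_out))
        if p_adj[j] > alpha:
            break
        removed.append((current.snp_ids[j], float(p_adj[j])))
        current = current.drop_ids([current.snp_ids[j]], "presso-outlier")
        if len(current) < PRESSO_MIN_SNPS:
            break
    return current, removed, float(global_p)


def leave_one_out(h: HarmonizedSet, ivw_mode: str = "mre") -> tuple[pd.DataFrame, bool]:
    """IVW excluding each SNP in turn.

    Flags "driven by a single SNP" when the full-set IVW is significant at
    0.05 but some leave-one-out estimate is not.
    """
    k = len(h)
    if k < 3:
        raise InsufficientInstrumentsError("leave_one_out needs k >= 3")
    full = ivw(h, mode=ivw_mode)
    rows = []
    for j in range(k):
        keep = [i for i in range(k) if i != j]
        est = ivw(h.subset(keep), mode=ivw_mode)
        rows.append({
            "left_out": h.snp_ids[j],
            "beta": est.beta, "se": est.se, "pval": est.pval,
        })
    loo = pd.DataFrame(rows, columns=["left_out", "beta", "se", "pval"])
    driven = bool(full.pval < 0.05 and (loo["pval"] >= 0.05).any())
    return loo, driven


def _r2_from_t(b: np.ndarray, se: np.ndarray, n: float) -> float:
    t2 = (b / se) ** 2
    return float(np.sum(t2 / (t2 + n - 2.0)))


def steiger_direction(
    h: HarmonizedSet,
    n_x: float | None = None,
    n_y: float | None = None,
) -> tuple[float, float, bool, float]:
    """Directionality test comparing variance explained by the instruments in
    the exposure versus the outcome.

    Per-SNP r^2 uses the t-statistic form t^2/(t^2 + n - 2), summed over
    instruments.  The p-value comes from a Fisher-z two-sample comparison of
    r = sqrt(r^2) between the traits.

    Returns (r2_exposure, r2_outcome, direction_supported, p).
    """
    n_x = h.n_x if n_x is None else float(n_x)
    n_y = h.n_y if n_y is None else float(n_y)
    if n_x <= 3 or n_y <= 3:
        raise ValidationError("sample sizes must exceed 3")
    if len(h) < 1:
        raise InsufficientInstrumentsError("steiger needs k >= 1")
    r2_x = _r2_from_t(h.bx, h.se_x, n_x)
    r2_y = _r2_from_t(h.by, h.se_y, n_y)
    # summed r^2 can exceed 1 only pathologically; clamp for atanh
    r_x = np.sqrt(min(r2_x, 1.0 - 1e-12))
    r_y = np.sqrt(min(r2_y, 1.0 - 1e-12))
    z = (np.arctanh(r_x) - np.arctanh(r_y)) / np.sqrt(
        1.0 / (n_x - 3.0) + 1.0 / (n_y - 3.0))
    p = float(2.0 * sps.norm.sf(abs(z)))
    return r2_x, r2_y, bool(r2_x > r2_y), p


def sensitivity_report(
    h: HarmonizedSet,
    n_sim: int = 1000,
    seed: int = 0,
    ivw_mode: str = "mre",
    run_presso: bool = True,
) -> SensitivityReport:
    """Run every applicable sensitivity test for one harmonized pair."""
    rep = SensitivityReport()
    k = len(h)
    rep.f_stats = {
        s: float((h.bx[i] / h.se_x[i]) ** 2) for i, s in enumerate(h.snp_ids)
    }
    if k >= 2:
        est = ivw(h, mode=ivw_mode)
        rep.q, rep.q_df, rep.q_p, rep.heterogeneous = cochran_q(h, est.beta)
    if run_presso and k >= PRESSO_MIN_SNPS:
        _, rep.presso_global_p = presso_global(h, n_sim=n_sim, seed=seed)
    if k >= 3:
        rep.loo, rep.loo_driven_by_single_snp = leave_one_out(h, ivw_mode=ivw_mode)
    rep.steiger_r2_exposure, rep.steiger_r2_outcome, rep.steiger_direction, \
        rep.steiger_p = steiger_direction(h)
    return rep
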