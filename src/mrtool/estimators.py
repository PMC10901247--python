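"""Causal-effect estimators: Wald ratio, IVW, MR-Egger, weighted median.

Conventions
-----------
* IVW defaults to multiplicative random effects: the fixed-effects SE is
  inflated by sqrt(max(1, Q/(k-1))).
* MR-Egger re-orients SNPs so every exposure effect is non-negative (signs of
  bx and by flipped jointly); inference uses a t distribution with k-2 df and
  a residual dispersion floored at 1.
* The weighted median uses first-order inverse-variance weights bx^2/se_y^2
  and a seeded parametric bootstrap for its SE.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .errors import DegenerateInstrumentError, InsufficientInstrumentsError
from .harmonize import HarmonizedSet


@dataclass
class MREstimate:
    method: str  # wald | ivw | egger | weighted_median
    beta: float
    se: float
    pval: float
    n_snp: int
    extras: dict = field(default_factory=dict)


def wald_ratio(h: HarmonizedSet, second_order_se: bool = False) -> MREstimate:
    """Single-SNP causal estimate by/bx with first-order (delta) SE.

    ``second_order_se`` adds the exposure-uncertainty term
    sqrt(se_y^2/bx^2 + by^2 se_x^2 / bx^4).
    """
    if len(h) != 1:
        raise InsufficientInstrumentsError(f"wald_ratio needs k=1, got {len(h)}")
    bx, by = float(h.bx[0]), float(h.by[0])
    se_x, se_y = float(h.se_x[0]), float(h.se_y[0])
    if bx == 0.0:
        raise DegenerateInstrumentError("exposure effect is zero")
    beta = by / bx
    if second_order_se:
        se = np.sqrt(se_y**2 / bx**2 + by**2 * se_x**2 / bx**4)
    else:
        se = se_y / abs(bx)
    pval = 2.0 * sps.norm.sf(abs(beta / se))
    return MREstimate("wald", beta, float(se), float(pval), 1)


def _ivw_core(bx: np.ndarray, by: np.ndarray, se_y: np.ndarray):
    w = 1.0 / se_y**2
    sxx = np.sum(w * bx * bx)
    beta = np.sum(w * bx * by) / sxx
    se_fixed = np.sqrt(1.0 / sxx)
    q = np.sum(w * (by - beta * bx) ** 2)
    return beta, se_fixed, q


def ivw(h: HarmonizedSet, mode: str = "mre") -> MREstimate:
    """Inverse-variance weighted estimate (WLS of by on bx through the origin,
    weights 1/se_y^2).

    mode ``fixed`` uses the fixed-effects SE; ``mre`` (default) multiplies it
    by sqrt(max(1, Q/(k-1))).
    """
    k = len(h)
    if k < 2:
        raise InsufficientInstrumentsError("ivw needs k >= 2; use wald_ratio")
    beta, se_fixed, q = _ivw_core(h.bx, h.by, h.se_y)
    dispersion = max(1.0, q / (k - 1))
    se = se_fixed * np.sqrt(dispersion) if mode == "mre" else se_fixed
    pval = 2.0 * sps.norm.sf(abs(beta / se))
    return MREstimate(
        "ivw", float(beta), float(se), float(pval), k,
        extras={"mode": mode, "q": float(q), "dispersion": float(dispersion)},
    )


def egger(h: HarmonizedSet) -> MREstimate:
    """MR-Egger: weighted regression of by on bx with a free intercept.

    The intercept and its p-value form the directional-pleiotropy test.
    """
    k = len(h)
    if k < 3:
        raise InsufficientInstrumentsError("egger needs k >= 3")
    flip = np.where(h.bx < 0, -1.0, 1.0)
    bx = h.bx * flip
    by = h.by * flip
    w = 1.0 / h.se_y**2

    sw = np.sum(w)
    swx = np.sum(w * bx)
    swy = np.sum(w * by)
    swxx = np.sum(w * bx * bx)
    swxy = np.sum(w * bx * by)
    det = sw * swxx - swx**2
    slope = (sw * swxy - swx * swy) / det
    intercept = (swxx * swy - swx * swxy) / det

    resid = by - intercept - slope * bx
    q_egger = np.sum(w * resid**2)
    sigma2 = max(1.0, q_egger / (k - 2))
    var_slope = sigma2 * sw / det
    var_intercept = sigma2 * swxx / det

    se_slope = np.sqrt(var_slope)
    se_intercept = np.sqrt(var_intercept)
    df = k - 2
    p_slope = 2.0 * sps.t.sf(abs(slope / se_slope), df)
    p_intercept = 2.0 * sps.t.sf(abs(intercept / se_intercept), df)
    return MREstimate(
        "egger", float(slope), float(se_slope), float(p_slope), k,
        extras={
            "egger_intercept": float(intercept),
            "egger_intercept_se": float(se_intercept),
            "egger_intercept_p": float(p_intercept),
            "q_egger": float(q_egger),
            "dispersion": float(sigma2),
        },
    )


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    v = values[order]
    w = weights[order] / np.sum(weights)
    s = np.cumsum(w) - 0.5 * w
    return float(np.interp(0.5, s, v))


def weighted_median(
    h: HarmonizedSet,
    n_boot: int = 1000,
    seed: int = 0,
    use_se_x: bool = False,
) -> MREstimate:
    """Weighted median of per-SNP Wald ratios.

    Weights are the first-order inverse variance bx^2/se_y^2 (optionally the
    full delta variance including se_x).  The SE is the SD of the estimate
    over ``n_boot`` seeded parametric-bootstrap resamples.
    """
    k = len(h)
    if k < 3:
        raise InsufficientInstrumentsError("weighted_median needs k >= 3")

    def _wm(bx, by):
        ratios = by / bx
        if use_se_x:
            var = h.se_y**2 / bx**2 + by**2 * h.se_x**2 / bx**4
        else:
            var = h.se_y**2 / bx**2
        return _weighted_median(ratios, 1.0 / var)

    est = _wm(h.bx, h.by)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        bx_star = rng.normal(h.bx, h.se_x)
        by_star = rng.normal(h.by, h.se_y)
        boots[i] = _wm(bx_star, by_star)
    se = float(np.std(boots, ddof=1))
    pval = 2.0 * sps.norm.sf(abs(est / se)) if se > 0 else 1.0
    return MREstimate(
        "weighted_median", float(est), se, float(pval), k,
        extras={"n_boot": n_boot, "seed": seed},
    )


def run_all_methods(
    h: HarmonizedSet,
    n_boot: int = 1000,
    seed: int = 0,
    ivw_mode: str = "mre",
) -> list[MREstimate]:
    """Method dispatch by instrument count: k=1 Wald, k=2 IVW only,
    k>=3 IVW + Egger + weighted median."""
    k = len(h)
    if k == 0:
        raise InsufficientInstrumentsError("empty harmonized set")
    if k == 1:
        return [wald_ratio(h)]
    if k == 2:
        return [ivw(h, mode=ivw_mode)]
    return [
        ivw(h, mode=ivw_mode),
        egger(h),
        weighted_median(h, n_boot=n_boot, seed=seed),
    ]
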