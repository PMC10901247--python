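"""Orchestration of the bidirectional screen.

``run_pair`` chains selection -> harmonization -> MR-PRESSO cleaning ->
estimation -> sensitivity -> verdict for one exposure-outcome pair; screens
loop this over many exposures and outcome roles, isolating per-pair failures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .errors import (
    EmptyHarmonizationError,
    InsufficientInstrumentsError,
    MRToolError,
    ValidationError,
)
from .estimators import MREstimate, run_all_methods
from .harmonize import HarmonizedSet, harmonize
from .iv_selection import SelectionConfig, select_instruments
from .sensitivity import (
    PRESSO_MIN_SNPS,
    SensitivityReport,
    presso_outlier_loop,
    sensitivity_report,
)
from .summary_io import LdMatrix, SummaryStats


@dataclass
class StudyConfig:
    """Settings shared by every pair in a screen."""

    direction: str = "forward"          # forward | reverse | both
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    palindrome_policy: str = "drop"
    ivw_mode: str = "mre"
    n_boot: int = 1000
    n_sim: int = 1000
    presso_alpha: float = 0.05
    run_presso: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.direction not in ("forward", "reverse", "both"):
            raise ValidationError(f"bad direction {self.direction!r}")


@dataclass
class PairResult:
    exposure_id: str
    outcome_id: str
    n_snp_initial: int = 0
    n_snp_final: int = 0
    estimates: list[MREstimate] = field(default_factory=list)
    sensitivity: SensitivityReport | None = None
    harmonized: HarmonizedSet | None = None
    presso_removed: list[tuple[str, float]] = field(default_factory=list)
    verdict: str = "skipped(not-run)"

    def primary_estimate(self) -> MREstimate | None:
        """IVW when available, else the single-SNP Wald ratio."""
        for m in ("ivw", "wald"):
            for e in self.estimates:
                if e.method == m:
                    return e
        return None

    def to_dict(self) -> dict:
        return {
            "exposure_id": self.exposure_id,
            "outcome_id": self.outcome_id,
            "n_snp_initial": self.n_snp_initial,
            "n_snp_final": self.n_snp_final,
            "estimates": [
                {"method": e.method, "beta": e.beta, "se": e.se,
                 "pval": e.pval, "n_snp": e.n_snp, "extras": e.extras}
                for e in self.estimates
            ],
            "sensitivity": None if self.sensitivity is None
            else self.sensitivity.to_dict(),
            "presso_removed": [list(t) for t in self.presso_removed],
            "verdict": self.verdict,
        }


def derive_verdict(estimates: list[MREstimate],
                   sensitivity: SensitivityReport | None) -> str:
    """Pure verdict function over recorded estimates and sensitivity fields.

    causal-positive/-negative requires: primary (IVW or Wald) p < 0.05, no
    heterogeneity, Egger intercept p >= 0.05 when k >= 3, and the effect not
    driven by a single SNP.
    """
    primary = None
    for m in ("ivw", "wald"):
        for e in estimates:
            if e.method == m:
                primary = e
                break
        if primary:
            break
    if primary is None:
        return "skipped(no-estimate)"
    if primary.pval >= 0.05:
        return "null"
    if sensitivity is not None:
        if sensitivity.heterogeneous:
            return "null"
        if sensitivity.loo_driven_by_single_snp:
            return "null"
    for e in estimates:
        if e.method == "egger" and e.extras.get("egger_intercept_p", 1.0) < 0.05:
            return "null"
    return "causal-positive" if primary.beta > 0 else "causal-negative"


def run_pair(
    exposure: SummaryStats,
    outcome: SummaryStats,
    ld: LdMatrix,
    config: StudyConfig | None = None,
) -> PairResult:
    """Full single-pair analysis; degeneracies downgrade to a skipped verdict
    rather than raising."""
    config = config or StudyConfig()
    result = PairResult(exposure_id=exposure.trait_id, outcome_id=outcome.trait_id)

    instruments = select_instruments(exposure, ld, config.selection)
    result.n_snp_initial = len(instruments)
    if len(instruments) == 0:
        result.verdict = "skipped(no-instruments)"
        return result

    try:
        h = harmonize(exposure, outcome, instruments.snp_ids,
                      palindrome_policy=config.palindrome_policy)
    except EmptyHarmonizationError:
        result.verdict = "skipped(no-harmonized-snps)"
        return result

    if config.run_presso and len(h) >= PRESSO_MIN_SNPS:
        h, removed, _ = presso_outlier_loop(
            h, n_sim=config.n_sim, alpha=config.presso_alpha, seed=config.seed)
        result.presso_removed = removed

    result.harmonized = h
    result.n_snp_final = len(h)
    try:
        result.estimates = run_all_methods(
            h, n_boot=config.n_boot, seed=config.seed, ivw_mode=config.ivw_mode)
    except (InsufficientInstrumentsError, MRToolError) as exc:
        result.verdict = f"skipped({exc})"
        return result
    result.sensitivity = sensitivity_report(
        h, n_sim=config.n_sim, seed=config.seed, ivw_mode=config.ivw_mode,
        run_presso=config.run_presso)
    result.verdict = derive_verdict(result.estimates, result.sensitivity)
    return result


def summary_frame(results: list[PairResult]) -> pd.DataFrame:
    """One row per pair sorted by primary p; no multiple-testing correction is
    applied to the verdicts, but Bonferroni and BH columns are reported."""
    rows = []
    for r in results:
        primary = r.primary_estimate()
        rows.append({
            "exposure_id": r.exposure_id,
            "outcome_id": r.outcome_id,
            "n_snp": r.n_snp_final,
            "method": None if primary is None else primary.method,
            "beta": np.nan if primary is None else primary.beta,
            "se": np.nan if primary is None else primary.se,
            "pval": np.nan if primary is None else primary.pval,
            "verdict": r.verdict,
        })
    df = pd.DataFrame(rows)
    mask = df["pval"].notna()
    df["pval_bonferroni"] = np.nan
    df["pval_bh"] = np.nan
    if mask.any():
        pvals = df.loc[mask, "pval"].to_numpy()
        df.loc[mask, "pval_bonferroni"] = np.minimum(1.0, pvals * mask.sum())
        df.loc[mask, "pval_bh"] = multipletests(pvals, method="fdr_bh")[1]
    df = df.sort_values(["pval", "exposure_id", "outcome_id"],
                        na_position="last", kind="mergesort")
    return df.reset_index(drop=True)


def run_screen(
    taxa: list[SummaryStats],
    outcomes: list[SummaryStats],
    ld: LdMatrix,
    config: StudyConfig | None = None,
) -> tuple[list[PairResult], pd.DataFrame]:
    """One PairResult per exposure per outcome dataset; per-pair failures are
    isolated so the screen always completes."""
    if not taxa:
        raise ValidationError("empty exposure list")
    if not outcomes:
        raise ValidationError("no outcome datasets")
    config = config or StudyConfig()
    results = []
    for exp in taxa:
        for out in outcomes:
            try:
                results.append(run_pair(exp, out, ld, config))
            except MRToolError as exc:
                results.append(PairResult(
                    exposure_id=exp.trait_id, outcome_id=out.trait_id,
                    verdict=f"skipped({exc})"))
    return results, summary_frame(results)


def run_bidirectional(
    exposure_set: list[SummaryStats],
    outcome: SummaryStats,
    ld: LdMatrix,
    config: StudyConfig | None = None,
) -> tuple[list[PairResult], list[PairResult]]:
    """Forward screen (each exposure -> outcome) plus the reverse screen with
    roles swapped; reverse instruments come from the outcome trait itself at
    the same thresholds."""
    config = config or StudyConfig()
    forward, _ = run_screen(exposure_set, [outcome], ld, config)
    reverse = []
    for taxon in exposure_set:
        try:
            reverse.append(run_pair(outcome, taxon, ld, config))
        except MRToolError as exc:
            reverse.append(PairResult(
                exposure_id=outcome.trait_id, outcome_id=taxon.trait_id,
                verdict=f"skipped({exc})"))
    return forward, reverse
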