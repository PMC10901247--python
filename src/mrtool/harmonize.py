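"""Align exposure and outcome summary statistics to a common effect allele.

Resolves allele swaps (sign flip) and strand complements; palindromic A/T and
C/G SNPs are dropped by default, or aligned by allele frequency under the
``infer`` policy (ambiguous frequencies near 0.5 still dropped).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyHarmonizationError, ValidationError
from .summary_io import SummaryStats

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: eaf band within which a palindrome's strand cannot be inferred
AMBIGUITY_BAND = (0.42, 0.58)


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True iff the allele pair is {A,T} or {C,G}."""
    return _COMPLEMENT.get(effect_allele) == other_allele


@dataclass
class HarmonizedSet:
    """Aligned per-SNP exposure/outcome effects for one trait pair.

    Parallel arrays of equal length k; ``dropped`` maps excluded snp_ids to a
    reason (missing-in-outcome | palindromic | palindromic-ambiguous |
    incompatible-alleles).
    """

    snp_ids: list[str]
    bx: np.ndarray
    se_x: np.ndarray
    by: np.ndarray
    se_y: np.ndarray
    eaf_x: np.ndarray  # NaN where unavailable
    eaf_y: np.ndarray
    n_x: float
    n_y: float
    dropped: dict[str, str] = field(default_factory=dict)
    exposure_id: str = ""
    outcome_id: str = ""

    def __post_init__(self) -> None:
        k = len(self.snp_ids)
        for name in ("bx", "se_x", "by", "se_y", "eaf_x", "eaf_y"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (k,):
                raise ValidationError(f"{name} length {arr.shape} != {k} snps")
            setattr(self, name, arr)

    def __len__(self) -> int:
        return len(self.snp_ids)

    def subset(self, keep: list[int] | np.ndarray) -> "HarmonizedSet":
        keep = np.asarray(keep, dtype=int)
        return HarmonizedSet(
            snp_ids=[self.snp_ids[i] for i in keep],
            bx=self.bx[keep], se_x=self.se_x[keep],
            by=self.by[keep], se_y=self.se_y[keep],
            eaf_x=self.eaf_x[keep], eaf_y=self.eaf_y[keep],
            n_x=self.n_x, n_y=self.n_y,
            dropped=dict(self.dropped),
            exposure_id=self.exposure_id, outcome_id=self.outcome_id,
        )

    def drop_ids(self, ids: list[str], reason: str) -> "HarmonizedSet":
        idx = [i for i, s in enumerate(self.snp_ids) if s not in set(ids)]
        out = self.subset(idx)
        for s in ids:
            out.dropped[s] = reason
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "snp_id": self.snp_ids,
            "bx": self.bx, "se_x": self.se_x,
            "by": self.by, "se_y": self.se_y,
            "eaf_x": self.eaf_x, "eaf_y": self.eaf_y,
            "n_x": self.n_x, "n_y": self.n_y,
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame,
                   exposure_id: str = "", outcome_id: str = "") -> "HarmonizedSet":
        return cls(
            snp_ids=[str(s) for s in df["snp_id"]],
            bx=df["bx"].to_numpy(float), se_x=df["se_x"].to_numpy(float),
            by=df["by"].to_numpy(float), se_y=df["se_y"].to_numpy(float),
            eaf_x=df["eaf_x"].to_numpy(float), eaf_y=df["eaf_y"].to_numpy(float),
            n_x=float(df["n_x"].iloc[0]), n_y=float(df["n_y"].iloc[0]),
            exposure_id=exposure_id, outcome_id=outcome_id,
        )


def _nan(x: float | None) -> float:
    return float("nan") if x is None else float(x)


def harmonize(
    exposure: SummaryStats,
    outcome: SummaryStats,
    instruments: list[str],
    palindrome_policy: str = "drop",
) -> HarmonizedSet:
    """Align outcome effects to the exposure's effect allele per instrument.

    palindrome_policy: ``drop`` (default) removes every A/T and C/G SNP;
    ``infer`` aligns palindromes whose eaf on both sides falls outside the
    ambiguity band [0.42, 0.58], dropping the rest.
    """
    if not instruments:
        raise EmptyHarmonizationError("no instruments supplied")
    if palindrome_policy not in ("drop", "infer"):
        raise ValidationError(f"unknown palindrome policy {palindrome_policy!r}")

    ids, bx, se_x, by, se_y, eaf_x, eaf_y = [], [], [], [], [], [], []
    dropped: dict[str, str] = {}
    n_x_vals, n_y_vals = [], []

    for snp in instruments:
        ex = exposure.get(snp)
        if snp not in outcome:
            dropped[snp] = "missing-in-outcome"
            continue
        out = outcome.get(snp)

        if is_palindromic(ex.effect_allele, ex.other_allele):
            if palindrome_policy == "drop":
                dropped[snp] = "palindromic"
                continue
            # infer: use allele frequencies to orient
            fx, fy = ex.eaf, out.eaf
            lo, hi = AMBIGUITY_BAND
            if (fx is None or fy is None or lo <= fx <= hi or lo <= fy <= hi):
                dropped[snp] = "palindromic-ambiguous"
                continue
            # outcome alleles must be the same pair (possibly swapped/complemented,
            # indistinguishable for palindromes)
            if {out.effect_allele, out.other_allele} != {ex.effect_allele,
                                                         ex.other_allele}:
                dropped[snp] = "incompatible-alleles"
                continue
            same_side = (fx < 0.5) == (fy < 0.5)
            b_out, f_out = (out.beta, out.eaf) if same_side else (-out.beta,
                                                                  1.0 - out.eaf)
        else:
            ea, oa = out.effect_allele, out.other_allele
            if (ea, oa) == (ex.effect_allele, ex.other_allele):
                b_out, f_out = out.beta, out.eaf
            elif (ea, oa) == (ex.other_allele, ex.effect_allele):
                b_out = -out.beta
                f_out = None if out.eaf is None else 1.0 - out.eaf
            else:
                cea, coa = _COMPLEMENT[ea], _COMPLEMENT[oa]
                if (cea, coa) == (ex.effect_allele, ex.other_allele):
                    b_out, f_out = out.beta, out.eaf
                elif (cea, coa) == (ex.other_allele, ex.effect_allele):
                    b_out = -out.beta
                    f_out = None if out.eaf is None else 1.0 - out.eaf
                else:
                    dropped[snp] = "incompatible-alleles"
                    continue

        ids.append(snp)
        bx.append(ex.beta)
        se_x.append(ex.se)
        by.append(b_out)
        se_y.append(out.se)
        eaf_x.append(_nan(ex.eaf))
        eaf_y.append(_nan(f_out))
        n_x_vals.append(ex.n)
        n_y_vals.append(out.n)

    if not ids:
        raise EmptyHarmonizationError(
            f"no SNP survived harmonization (dropped: {dropped})")

    return HarmonizedSet(
        snp_ids=ids,
        bx=np.array(bx), se_x=np.array(se_x),
        by=np.array(by), se_y=np.array(se_y),
        eaf_x=np.array(eaf_x), eaf_y=np.array(eaf_y),
        n_x=float(np.mean(n_x_vals)), n_y=float(np.mean(n_y_vals)),
        dropped=dropped,
        exposure_id=exposure.trait_id, outcome_id=outcome.trait_id,
    )
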