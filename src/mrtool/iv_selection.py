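"""Instrument selection: significance filter, MAF filter, greedy LD clumping,
and weak-instrument (F-statistic) exclusion.

The stages run in a fixed order — significance, MAF, clumping, F — and every
candidate SNP receives exactly one disposition in the audit trail.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import ValidationError
from .summary_io import LdMatrix, SnpRecord, SummaryStats


@dataclass(frozen=True)
class SelectionConfig:
    """Thresholds for the four selection stages.

    Defaults: p < 5e-6 (the relaxed genome-wide threshold), MAF >= 0.01,
    clumping at r^2 < 0.001 within a 10,000 kb window, F >= 10.
    """

    p_threshold: float = 5e-6
    maf_min: float = 0.01
    clump_r2: float = 0.001
    clump_kb: float = 10_000.0
    f_min: float = 10.0

    def __post_init__(self) -> None:
        if not (0.0 < self.p_threshold < 1.0):
            raise ValidationError("p_threshold must be in (0,1)")
        if not (0.0 <= self.maf_min < 0.5):
            raise ValidationError("maf_min must be in [0, 0.5)")
        if not (0.0 <= self.clump_r2 <= 1.0):
            raise ValidationError("clump_r2 must be in [0,1]")
        if not (self.clump_kb > 0):
            raise ValidationError("clump_kb must be positive")
        if self.f_min < 0:
            raise ValidationError("f_min must be non-negative")


@dataclass
class InstrumentSet:
    """Retained instruments plus a per-candidate audit trail.

    ``audit`` maps every candidate snp_id to a ``(disposition, statistic)``
    pair, where disposition is one of ``kept``, ``dropped:pvalue``,
    ``dropped:maf``, ``dropped:clumped-by:<id>``, ``dropped:weakF``,
    ``dropped:missing-eaf``, ``dropped:missing-ld``.
    """

    snp_ids: list[str] = field(default_factory=list)
    audit: dict[str, tuple[str, float]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.snp_ids)

    def audit_frame(self) -> pd.DataFrame:
        rows = [
            {"snp_id": s, "disposition": d, "statistic": v}
            for s, (d, v) in self.audit.items()
        ]
        return pd.DataFrame(rows, columns=["snp_id", "disposition", "statistic"])


def filter_significance(stats: SummaryStats, p_threshold: float) -> list[str]:
    """Ids with pval < p_threshold, ascending p, ties broken by snp_id."""
    hits = [(r.pval, r.snp_id) for r in stats.records if r.pval < p_threshold]
    hits.sort()
    return [s for _, s in hits]


def filter_maf(
    stats: SummaryStats,
    ids: list[str],
    maf_min: float,
    on_missing: str = "drop",
) -> list[str]:
    """Keep ids whose minor-allele frequency min(eaf, 1-eaf) >= maf_min."""
    kept = []
    for s in ids:
        eaf = stats.get(s).eaf
        if eaf is None:
            if on_missing == "error":
                raise ValidationError(f"{s}: eaf missing, cannot apply MAF filter")
            continue
        if min(eaf, 1.0 - eaf) >= maf_min:
            kept.append(s)
    return kept


def ld_clump(
    stats: SummaryStats,
    ids: list[str],
    ld: LdMatrix,
    clump_r2: float = 0.001,
    clump_kb: float = 10_000.0,
    on_missing: str = "drop",
    audit: dict[str, tuple[str, float]] | None = None,
) -> list[str]:
    """Greedy clumping: repeatedly retain the smallest-p unclumped SNP and
    clump every remaining SNP on the same chromosome within ``clump_kb``
    kilobases whose r^2 with it is >= ``clump_r2``.
    """
    present = []
    for s in ids:
        if s not in ld:
            if on_missing == "error":
                raise ValidationError(f"{s}: absent from LD matrix")
            if audit is not None:
                audit[s] = ("dropped:missing-ld", float("nan"))
            continue
        present.append(s)

    # candidate order: ascending p, tie-break lexicographic by id
    order = sorted(present, key=lambda s: (stats.get(s).pval, s))
    window_bp = clump_kb * 1000.0
    retained: list[str] = []
    clumped_by: dict[str, str] = {}
    for idx in order:
        if idx in clumped_by:
            continue
        retained.append(idx)
        rec_i = stats.get(idx)
        for other in order:
            if other == idx or other in clumped_by or other in retained:
                continue
            rec_j = stats.get(other)
            if rec_j.chrom != rec_i.chrom:
                continue
            if abs(rec_j.pos - rec_i.pos) > window_bp:
                continue
            if ld.r2(idx, other) >= clump_r2:
                clumped_by[other] = idx
    if audit is not None:
        for s, by in clumped_by.items():
            audit[s] = (f"dropped:clumped-by:{by}", ld.r2(s, by))
    return retained


def f_statistic(record: SnpRecord) -> float:
    """Instrument strength as the squared z statistic (beta/se)^2."""
    return (record.beta / record.se) ** 2


def f_statistic_r2(record: SnpRecord) -> float:
    """Alternative F = R^2 (n-2) / (1 - R^2) with R^2 from the t form."""
    t2 = (record.beta / record.se) ** 2
    r2 = t2 / (t2 + record.n - 2.0)
    return r2 * (record.n - 2.0) / (1.0 - r2)


def select_instruments(
    stats: SummaryStats,
    ld: LdMatrix,
    config: SelectionConfig | None = None,
) -> InstrumentSet:
    """Run all four stages in order and record a complete audit."""
    config = config or SelectionConfig()
    audit: dict[str, tuple[str, float]] = {}

    sig = filter_significance(stats, config.p_threshold)
    sig_set = set(sig)
    for r in stats.records:
        if r.snp_id not in sig_set:
            audit[r.snp_id] = ("dropped:pvalue", r.pval)

    after_maf = []
    for s in sig:
        eaf = stats.get(s).eaf
        if eaf is None:
            audit[s] = ("dropped:missing-eaf", float("nan"))
            continue
        maf = min(eaf, 1.0 - eaf)
        if maf < config.maf_min:
            audit[s] = ("dropped:maf", maf)
            continue
        after_maf.append(s)

    after_clump = ld_clump(
        stats, after_maf, ld,
        clump_r2=config.clump_r2, clump_kb=config.clump_kb, audit=audit,
    )

    retained = []
    for s in after_clump:
        f = f_statistic(stats.get(s))
        if f < config.f_min:
            audit[s] = ("dropped:weakF", f)
            continue
        audit[s] = ("kept", f)
        retained.append(s)

    return InstrumentSet(snp_ids=retained, audit=audit)
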