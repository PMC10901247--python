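"""Read, validate and write GWAS summary statistics and LD matrices.

File formats are tab-separated text with a header row.  Summary-statistic
columns can be renamed through a ``column_map`` so that both IEU-style and
GWAS-SSF-style exports load without preprocessing.  Floats are written with
10 significant digits so a read -> write -> read round trip is value-exact.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import EmptyInputError, FormatError, IntegrityError, RangeError

VALID_BASES = frozenset("ACGT")

#: canonical column order for summary-statistic TSVs
CANONICAL_COLUMNS = [
    "snp_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n",
]


@dataclass(frozen=True)
class SnpRecord:
    """One per-SNP association record.

    ``beta`` is the per-allele effect of ``effect_allele`` on the trait
    (log-odds for binary traits, SD units for quantitative traits).
    ``eaf`` may be ``None`` when the source file does not report it.
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    pval: float
    n: float

    def validate(self, strict: bool = False) -> str | None:
        """Return a reason string if the record is invalid, else None."""
        if self.effect_allele not in VALID_BASES or self.other_allele not in VALID_BASES:
            return "allele not a single base"
        if self.effect_allele == self.other_allele:
            return "identical alleles"
        if not (self.se > 0) or not math.isfinite(self.se):
            return "se not positive"
        if not math.isfinite(self.beta):
            return "beta not finite"
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            return "eaf out of range"
        if not (0.0 < self.pval <= 1.0):
            return "pval out of range"
        if not (self.n > 0):
            return "n not positive"
        if self.pos < 1:
            return "pos not positive"
        if strict:
            p_recomputed = 2.0 * sps.norm.sf(abs(self.beta / self.se))
            if abs(p_recomputed - self.pval) > 1e-3:
                return "pval inconsistent with beta/se"
        return None


@dataclass
class SummaryStats:
    """Ordered per-SNP summary statistics for one trait."""

    trait_id: str
    trait_type: str  # "binary" | "quantitative"
    records: list[SnpRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.trait_type not in ("binary", "quantitative"):
            raise FormatError(f"unknown trait_type {self.trait_type!r}")
        ids = [r.snp_id for r in self.records]
        dupes = [s for s, c in Counter(ids).items() if c > 1]
        if dupes:
            raise IntegrityError(f"duplicate snp_id(s): {sorted(dupes)[:5]}")
        self._index = {s: i for i, s in enumerate(ids)}

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def get(self, snp_id: str) -> SnpRecord:
        return self.records[self._index[snp_id]]

    @property
    def snp_ids(self) -> list[str]:
        return [r.snp_id for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "snp_id": r.snp_id, "chrom": r.chrom, "pos": r.pos,
                "effect_allele": r.effect_allele, "other_allele": r.other_allele,
                "eaf": r.eaf, "beta": r.beta, "se": r.se, "pval": r.pval, "n": r.n,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=CANONICAL_COLUMNS)


@dataclass
class LdMatrix:
    """Square matrix of pairwise allelic correlations (r, not r^2)."""

    snp_ids: list[str]
    r: np.ndarray
    positions: dict[str, tuple[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        k = len(self.snp_ids)
        if self.r.shape != (k, k):
            raise FormatError(
                f"LD matrix shape {self.r.shape} does not match {k} snp ids")
        if len(set(self.snp_ids)) != k:
            raise IntegrityError("duplicate snp ids in LD matrix")
        if np.nanmax(np.abs(self.r)) > 1.0 + 1e-12:
            raise RangeError("|r| > 1 in LD matrix")
        if np.max(np.abs(self.r - self.r.T)) > 1e-8:
            raise IntegrityError("LD matrix asymmetric beyond 1e-8")
        if np.max(np.abs(np.diag(self.r) - 1.0)) > 1e-8:
            raise IntegrityError("LD matrix diagonal not unit")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def r2(self, a: str, b: str) -> float:
        return float(self.r[self._index[a], self._index[b]] ** 2)


def _fmt(x: float | None) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return "NA"
    return format(x, ".10g")


def read_summary_stats(
    path,
    column_map: Mapping[str, str] | None = None,
    trait_id: str = "trait",
    trait_type: str = "quantitative",
    strict: bool = False,
) -> tuple[SummaryStats, dict[str, int]]:
    """Load a TSV of summary statistics.

    ``column_map`` maps canonical names (see :data:`CANONICAL_COLUMNS`) to the
    names used in the file.  Rows failing validation are dropped and counted in
    the returned tally keyed by reason; a duplicate ``snp_id`` is an error.

    Returns ``(stats, dropped_tally)``.
    """
    column_map = dict(column_map or {})
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if df.empty:
        raise EmptyInputError(f"{path}: no data rows")
    rename = {v: k for k, v in column_map.items()}
    df = df.rename(columns=rename)
    required = [c for c in CANONICAL_COLUMNS if c != "eaf"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mapped column(s) {missing}")
    has_eaf = "eaf" in df.columns

    records: list[SnpRecord] = []
    tally: Counter[str] = Counter()
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        d = row._asdict()
        snp_id = str(d["snp_id"])
        if snp_id in seen:
            raise IntegrityError(f"{path}: duplicate snp_id {snp_id!r}")
        seen.add(snp_id)
        eaf = None
        if has_eaf:
            raw = d["eaf"]
            if raw is not None and not (isinstance(raw, float) and math.isnan(raw)) \
                    and str(raw) != "NA":
                eaf = float(raw)
        try:
            rec = SnpRecord(
                snp_id=snp_id,
                chrom=str(d["chrom"]),
                pos=int(d["pos"]),
                effect_allele=str(d["effect_allele"]).upper(),
                other_allele=str(d["other_allele"]).upper(),
                eaf=eaf,
                beta=float(d["beta"]),
                se=float(d["se"]),
                pval=float(d["pval"]),
                n=float(d["n"]),
            )
        except (TypeError, ValueError):
            tally["unparseable row"] += 1
            continue
        reason = rec.validate(strict=strict)
        if reason is not None:
            tally[reason] += 1
            continue
        records.append(rec)
    if not records:
        raise EmptyInputError(f"{path}: all {len(df)} rows failed validation")
    return SummaryStats(trait_id, trait_type, records), dict(tally)


def write_summary_stats(stats: SummaryStats, path) -> None:
    """Write canonical TSV; floats carry 10 significant digits."""
    with open(path, "w") as fh:
        fh.write("\t".join(CANONICAL_COLUMNS) + "\n")
        for r in stats.records:
            fh.write("\t".join([
                r.snp_id, r.chrom, str(r.pos), r.effect_allele, r.other_allele,
                _fmt(r.eaf), _fmt(r.beta), _fmt(r.se), _fmt(r.pval), _fmt(r.n),
            ]) + "\n")


def read_ld_matrix(path) -> LdMatrix:
    """Load a TSV LD matrix whose first row and first column are snp ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] != df.shape[1]:
        raise FormatError(f"{path}: LD matrix not square {df.shape}")
    ids = [str(s) for s in df.index]
    if ids != [str(s) for s in df.columns]:
        raise FormatError(f"{path}: row ids differ from column ids")
    r = df.to_numpy(dtype=float)
    if np.max(np.abs(r)) > 1.0 + 1e-12:
        raise RangeError(f"{path}: |r| > 1")
    return LdMatrix(snp_ids=ids, r=r)


def write_ld_matrix(ld: LdMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join([""] + ld.snp_ids) + "\n")
        for i, s in enumerate(ld.snp_ids):
            fh.write("\t".join([s] + [_fmt(v) for v in ld.r[i]]) + "\n")


def identity_ld(stats_or_ids: SummaryStats | Iterable[str]) -> LdMatrix:
    """Identity LD matrix (all SNPs independent) over the given ids."""
    if isinstance(stats_or_ids, SummaryStats):
        ids = stats_or_ids.snp_ids
    else:
        ids = list(stats_or_ids)
    return LdMatrix(snp_ids=ids, r=np.eye(len(ids)))
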