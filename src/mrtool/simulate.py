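"""Synthetic GWAS summary statistics with known causal structure.

Traits are simulated on the standardized scale so per-SNP standard errors
have the closed form 1/sqrt(2 n maf (1-maf)) and calibration targets have
analytic truth.  Sampling noise is independent between the two traits (the
two-sample assumption) but correlated within LD blocks of a trait.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats as sps

from .errors import ValidationError
from .summary_io import LdMatrix, SnpRecord, SummaryStats

_NONPALINDROMIC_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                         ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass(frozen=True)
class SimTruth:
    """Ground-truth parameters of one synthetic exposure-outcome pair."""

    beta_causal: float = 0.0
    n_instruments: int = 30
    n_null_snps: int = 100
    pleiotropy_frac: float = 0.0
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    inside_violation: float = 0.0   # corr(instrument strength, pleiotropy)
    n_x: float = 20_000
    n_y: float = 20_000
    ld_block_size: int = 1
    ld_rho: float = 0.0
    palindrome_frac: float = 0.0
    gamma_min: float = 0.04         # |true exposure effect| lower bound
    gamma_max: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pleiotropy_frac", "palindrome_frac"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must be in [0,1], got {v}")
        if self.n_x <= 3 or self.n_y <= 3:
            raise ValidationError("sample sizes must exceed 3")
        if self.n_instruments < 1:
            raise ValidationError("need at least one instrument")
        if self.n_null_snps < 0:
            raise ValidationError("n_null_snps must be non-negative")
        if not (-1.0 <= self.inside_violation <= 1.0):
            raise ValidationError("inside_violation must be in [-1,1]")
        if self.ld_block_size < 1:
            raise ValidationError("ld_block_size must be >= 1")
        if not (0.0 <= abs(self.ld_rho) < 1.0):
            raise ValidationError("|ld_rho| must be < 1")
        if not (0.0 < self.gamma_min <= self.gamma_max):
            raise ValidationError("need 0 < gamma_min <= gamma_max")


def analytic_se(n: float, maf: np.ndarray) -> np.ndarray:
    """Standard error of a standardized per-allele effect estimate."""
    return 1.0 / np.sqrt(2.0 * n * maf * (1.0 - maf))


def _build_ld(m: int, block: int, rho: float) -> np.ndarray:
    r = np.eye(m)
    if block > 1 and rho != 0.0:
        for start in range(0, m, block):
            stop = min(start + block, m)
            r[start:stop, start:stop] = rho
            np.fill_diagonal(r[start:stop, start:stop], 1.0)
    return r


def _correlated_noise(rng: np.random.Generator, r: np.ndarray,
                      block: int) -> np.ndarray:
    m = r.shape[0]
    z = rng.standard_normal(m)
    if block <= 1:
        return z
    out = np.empty(m)
    for start in range(0, m, block):
        stop = min(start + block, m)
        sub = r[start:stop, start:stop]
        chol = np.linalg.cholesky(sub)
        out[start:stop] = chol @ z[start:stop]
    return out


def _records(ids, chroms, poss, alleles, eafs, betas, ses, n) -> list[SnpRecord]:
    recs = []
    for i, s in enumerate(ids):
        b, se = float(betas[i]), float(ses[i])
        recs.append(SnpRecord(
            snp_id=s, chrom=chroms[i], pos=int(poss[i]),
            effect_allele=alleles[i][0], other_allele=alleles[i][1],
            eaf=float(eafs[i]), beta=b, se=se,
            pval=float(max(2.0 * sps.norm.sf(abs(b / se)), 1e-300)),
            n=float(n),
        ))
    return recs


def simulate_pair(
    truth: SimTruth,
    exposure_id: str = "sim-exposure",
    outcome_id: str = "sim-outcome",
    snp_prefix: str = "rs",
) -> tuple[SummaryStats, SummaryStats, LdMatrix, SimTruth]:
    """Simulate one exposure-outcome pair of summary-statistic files.

    The first ``n_instruments`` SNPs carry true exposure effects gamma drawn
    uniformly in +/-[gamma_min, gamma_max]; outcome effects are
    beta_causal * gamma plus a pleiotropy term alpha (zero for valid
    instruments).  ``inside_violation`` correlates alpha with |gamma|.
    Observed effects are the LD-convolved truth plus within-block-correlated
    noise scaled by the analytic SE.
    """
    rng = np.random.default_rng(truth.seed)
    m = truth.n_instruments + truth.n_null_snps
    ids = [f"{snp_prefix}{i + 1}" for i in range(m)]

    # genomic layout: one block per chromosome slot, blocks 1 Mb apart within
    # a chromosome so only same-block SNPs fall inside any sane clump window
    block = truth.ld_block_size
    n_blocks = (m + block - 1) // block
    chroms, poss = [], []
    for b in range(n_blocks):
        chrom = str(b % 22 + 1)
        base = 1_000_000 * (b // 22 + 1) * 50
        for j in range(block):
            idx = b * block + j
            if idx >= m:
                break
            chroms.append(chrom)
            poss.append(base + j * 1000)

    maf = rng.uniform(0.05, 0.5, size=m)
    n_pal = int(round(truth.palindrome_frac * m))
    pal_idx = set(rng.choice(m, size=n_pal, replace=False).tolist()) if n_pal else set()
    alleles = []
    for i in range(m):
        pool = _PALINDROMIC_PAIRS if i in pal_idx else _NONPALINDROMIC_PAIRS
        alleles.append(pool[rng.integers(len(pool))])

    # true per-SNP effects; instruments oriented exposure-increasing, the
    # usual convention for summary-level simulation (sign is a relabelling
    # of alleles, but it matters for directional pleiotropy)
    gamma = np.zeros(m)
    k = truth.n_instruments
    gamma[:k] = rng.uniform(truth.gamma_min, truth.gamma_max, size=k)

    alpha = np.zeros(m)
    n_pleio = int(round(truth.pleiotropy_frac * k))
    if n_pleio:
        pleio_idx = rng.choice(k, size=n_pleio, replace=False)
        eps = rng.normal(0.0, 1.0, size=n_pleio)
        if truth.inside_violation != 0.0:
            # mix standardized |gamma| into the pleiotropy draw
            g = np.abs(gamma[pleio_idx])
            gstd = (g - g.mean()) / (g.std() if g.std() > 0 else 1.0)
            rho_iv = truth.inside_violation
            eps = rho_iv * gstd + np.sqrt(1.0 - rho_iv**2) * eps
        alpha[pleio_idx] = truth.pleiotropy_mean + truth.pleiotropy_sd * eps

    big_gamma = truth.beta_causal * gamma + alpha

    r = _build_ld(m, block, truth.ld_rho)
    # marginal (LD-convolved) true effects seen by single-SNP regression
    gamma_marg = r @ gamma
    big_gamma_marg = r @ big_gamma

    se_x = analytic_se(truth.n_x, maf)
    se_y = analytic_se(truth.n_y, maf)
    bx_hat = gamma_marg + se_x * _correlated_noise(rng, r, block)
    by_hat = big_gamma_marg + se_y * _correlated_noise(rng, r, block)

    exposure = SummaryStats(exposure_id, "quantitative", _records(
        ids, chroms, poss, alleles, maf, bx_hat, se_x, truth.n_x))
    outcome = SummaryStats(outcome_id, "quantitative", _records(
        ids, chroms, poss, alleles, maf, by_hat, se_y, truth.n_y))
    positions = {ids[i]: (chroms[i], poss[i]) for i in range(m)}
    ld = LdMatrix(snp_ids=list(ids), r=r, positions=positions)
    return exposure, outcome, ld, truth


@dataclass
class BidirectionalWorld:
    """Two traits A and B where A causes B and B does not cause A."""

    trait_a: SummaryStats
    trait_b: SummaryStats
    ld: LdMatrix
    truth_forward: SimTruth
    truth_reverse: SimTruth
    instruments_a: list[str] = field(default_factory=list)
    instruments_b: list[str] = field(default_factory=list)


def simulate_bidirectional_world(
    truth_forward: SimTruth,
    truth_reverse_null: SimTruth | None = None,
) -> BidirectionalWorld:
    """Simulate a shared SNP panel where A -> B with ``beta_causal`` and the
    reverse effect is zero.

    Instruments for A and for B are disjoint SNP sets; trait B's instruments
    affect B directly and A not at all, so the Steiger r^2 asymmetry emerges
    from the generative model.
    """
    tf = truth_forward
    tr = truth_reverse_null or replace(tf, beta_causal=0.0,
                                       seed=tf.seed + 1_000_003)
    if tr.beta_causal != 0.0:
        raise ValidationError("reverse truth must have beta_causal = 0")
    rng = np.random.default_rng(tf.seed)

    ka, kb = tf.n_instruments, tr.n_instruments
    m = ka + kb + tf.n_null_snps
    ids = [f"rs{i + 1}" for i in range(m)]
    chroms = [str(i % 22 + 1) for i in range(m)]
    poss = [50_000_000 * (i // 22 + 1) for i in range(m)]
    maf = rng.uniform(0.05, 0.5, size=m)
    alleles = [_NONPALINDROMIC_PAIRS[rng.integers(len(_NONPALINDROMIC_PAIRS))]
               for _ in range(m)]

    gamma_a = np.zeros(m)   # direct effects on A
    gamma_b = np.zeros(m)   # direct effects on B
    gamma_a[:ka] = rng.uniform(tf.gamma_min, tf.gamma_max, size=ka)
    gamma_b[ka:ka + kb] = rng.uniform(tr.gamma_min, tr.gamma_max, size=kb)

    # A <- gamma_a; B <- gamma_b + beta_causal * (total effect on A)
    true_a = gamma_a
    true_b = gamma_b + tf.beta_causal * gamma_a

    se_a = analytic_se(tf.n_x, maf)
    se_b = analytic_se(tf.n_y, maf)
    a_hat = true_a + se_a * rng.standard_normal(m)
    b_hat = true_b + se_b * rng.standard_normal(m)

    trait_a = SummaryStats("sim-trait-A", "quantitative", _records(
        ids, chroms, poss, alleles, maf, a_hat, se_a, tf.n_x))
    trait_b = SummaryStats("sim-trait-B", "quantitative", _records(
        ids, chroms, poss, alleles, maf, b_hat, se_b, tf.n_y))
    ld = LdMatrix(snp_ids=list(ids), r=np.eye(m),
                  positions={ids[i]: (chroms[i], poss[i]) for i in range(m)})
    return BidirectionalWorld(
        trait_a=trait_a, trait_b=trait_b, ld=ld,
        truth_forward=tf, truth_reverse=tr,
        instruments_a=ids[:ka], instruments_b=ids[ka:ka + kb],
    )


PRESETS: dict[str, SimTruth] = {
    "clean": SimTruth(beta_causal=0.1, n_instruments=30, n_null_snps=100,
                      seed=0),
    "null": SimTruth(beta_causal=0.0, n_instruments=30, n_null_snps=100,
                     seed=0),
    "directional-pleiotropy": SimTruth(
        beta_causal=0.1, n_instruments=30, n_null_snps=100,
        pleiotropy_frac=0.3, pleiotropy_mean=0.02, pleiotropy_sd=0.005,
        seed=0),
    "outlier": SimTruth(beta_causal=0.1, n_instruments=20, n_null_snps=50,
                        seed=0),
    "bidirectional": SimTruth(beta_causal=0.1, n_instruments=30,
                              n_null_snps=60, seed=0),
}
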