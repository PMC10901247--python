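import numpy as np
import pytest

from mrtool.harmonize import HarmonizedSet
from mrtool.summary_io import SnpRecord, SummaryStats


def make_record(snp_id="rs1", chrom="1", pos=1000, ea="A", oa="G", eaf=0.3,
                beta=0.1, se=0.01, pval=None, n=10000.0) -> SnpRecord:
    from scipy import stats as sps
    if pval is None:
        pval = float(max(2.0 * sps.norm.sf(abs(beta / se)), 1e-300))
    return SnpRecord(snp_id=snp_id, chrom=chrom, pos=pos, effect_allele=ea,
                     other_allele=oa, eaf=eaf, beta=beta, se=se, pval=pval, n=n)


def make_stats(records, trait_id="trait", trait_type="quantitative") -> SummaryStats:
    return SummaryStats(trait_id, trait_type, list(records))


def make_harmonized(bx, by, se_x=None, se_y=None, n_x=10000.0, n_y=10000.0,
                    snp_ids=None) -> HarmonizedSet:
    bx = np.asarray(bx, dtype=float)
    by = np.asarray(by, dtype=float)
    k = len(bx)
    se_x = np.full(k, 0.01) if se_x is None else np.asarray(se_x, dtype=float)
    se_y = np.full(k, 0.01) if se_y is None else np.asarray(se_y, dtype=float)
    ids = snp_ids or [f"rs{i + 1}" for i in range(k)]
    return HarmonizedSet(
        snp_ids=list(ids), bx=bx, se_x=se_x, by=by, se_y=se_y,
        eaf_x=np.full(k, np.nan), eaf_y=np.full(k, np.nan),
        n_x=n_x, n_y=n_y)


def random_harmonized(rng: np.random.Generator, k: int = 8) -> HarmonizedSet:
    bx = rng.uniform(0.03, 0.15, k) * rng.choice([-1.0, 1.0], k)
    se_x = rng.uniform(0.005, 0.02, k)
    se_y = rng.uniform(0.005, 0.02, k)
    by = 0.2 * bx + rng.normal(0, se_y)
    return make_harmonized(bx, by, se_x, se_y)


@pytest.fixture
def rng():
    return np.random.default_rng(20240214)
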