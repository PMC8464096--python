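import numpy as np
import pytest
from hypothesis import settings

from mrpipe.harmonize import HarmonizedInstrument
from mrpipe.sumstats_io import GwasRecord

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def mk_record(
    snp_id="rs1", chrom="1", pos=1000, ea="A", oa="G", eaf=0.3,
    beta=0.1, se=0.02, pval=1e-9, n=100_000,
) -> GwasRecord:
    return GwasRecord(
        snp_id=snp_id, chrom=chrom, pos=pos, effect_allele=ea, other_allele=oa,
        eaf=eaf, beta=beta, se=se, pval=pval, n=n,
    )


def mk_h(bx, by, sy, sx=0.01, snp_id="rs1", eaf=0.3) -> HarmonizedInstrument:
    return HarmonizedInstrument(
        snp_id=snp_id, beta_x=bx, se_x=sx, beta_y=by, se_y=sy,
        eaf_x=eaf, eaf_y=eaf, status="aligned",
    )


def hs_from_arrays(bx, by, sy, sx=None):
    bx = np.asarray(bx, dtype=float)
    by = np.asarray(by, dtype=float)
    sy = np.asarray(sy, dtype=float)
    sx = np.full_like(bx, 0.01) if sx is None else np.asarray(sx, dtype=float)
    return [
        mk_h(bx[i], by[i], sy[i], sx=sx[i], snp_id=f"rs{i + 1}")
        for i in range(len(bx))
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
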