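import numpy as np
import pytest

from mrkit.gwas_io import HarmonizedSet, SummaryRecord


def make_record(snp_id="rs1", ea="A", oa="G", eaf=0.3, beta=0.1, se=0.01,
                pvalue=1e-9, info=0.95):
    return SummaryRecord(snp_id=snp_id, effect_allele=ea, other_allele=oa,
                         eaf=eaf, beta=beta, se=se, pvalue=pvalue, info=info)


def make_hset(gamma, se_gamma, beta, se_beta, ids=None):
    gamma = np.asarray(gamma, float)
    n = gamma.size
    ids = ids if ids is not None else [f"rs{i}" for i in range(n)]
    return HarmonizedSet(
        snp_ids=list(ids),
        gamma=gamma,
        se_gamma=np.broadcast_to(np.asarray(se_gamma, float), (n,)).copy(),
        beta=np.asarray(beta, float),
        se_beta=np.broadcast_to(np.asarray(se_beta, float), (n,)).copy(),
    )


@pytest.fixture
def three_snp_set():
    """Three instruments with alpha_i = {0.04, 0.05, 0.02} and all
    v_i = 0.0004 (gamma=1 so se_beta=0.02)."""
    return make_hset(
        gamma=[1.0, 1.0, 1.0],
        se_gamma=0.01,
        beta=[0.04, 0.05, 0.02],
        se_beta=0.02,
    )
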