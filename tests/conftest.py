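import numpy as np
import pytest

from protmr import MRInput, ScenarioConfig, SNPRecord, SummaryStatSet, simulate_region


def make_record(vid="rs1", chrom="1", pos=1000, a1="A", a2="G", eaf=0.3,
                beta=0.1, se=0.01, p=1e-9, n=10_000) -> SNPRecord:
    return SNPRecord(vid, chrom, pos, a1, a2, eaf, beta, se, p, n)


def make_set(records, trait_id="prot", trait_type="quantitative", **kw) -> SummaryStatSet:
    return SummaryStatSet(trait_id, trait_type, {r.variant_id: r for r in records}, **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_mr_input(rng):
    def _make(k=6, seed=None):
        g = np.random.default_rng(seed) if seed is not None else rng
        bx = g.uniform(0.05, 0.4, k)
        return MRInput(
            protein_id="prot",
            variant_ids=[f"rs{i}" for i in range(k)],
            bx=bx,
            sx=g.uniform(0.005, 0.02, k),
            by=0.2 * bx + g.normal(0, 0.01, k),
            sy=g.uniform(0.005, 0.02, k),
            n_exposure=30_000,
            n_outcome=500_000,
        )
    return _make


@pytest.fixture
def small_region():
    return simulate_region(ScenarioConfig(m_snps=40, seed=11))
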