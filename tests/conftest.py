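import pandas as pd
import pytest

from arcirc import (SimConfig, make_genome, simulate_bsj_counts,
                    simulate_site_evidence)


@pytest.fixture(scope="session")
def clean_cfg():
    """Deterministic zero-noise simulation settings shared across tests."""
    return SimConfig(seed=7, zero_noise=True, seq_error=0.0)


@pytest.fixture(scope="session")
def bundle(clean_cfg):
    return make_genome(clean_cfg)


@pytest.fixture(scope="session")
def counts_and_truth(bundle, clean_cfg):
    return simulate_bsj_counts(bundle, clean_cfg)


@pytest.fixture(scope="session")
def evidence_and_truth(bundle, clean_cfg):
    return simulate_site_evidence(bundle, clean_cfg)


@pytest.fixture()
def tiny_exons():
    """One plus-strand gene with 10 exons of 100 bp spaced by 200-bp introns."""
    rows = []
    for i in range(10):
        s = 1000 + i * 300
        rows.append({"chrom": "chrT", "start": s, "end": s + 99,
                     "name": f"exon{i + 1}", "strand": "+"})
    return pd.DataFrame(rows)
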