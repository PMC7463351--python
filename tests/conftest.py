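import numpy as np
import pandas as pd
import pytest

import elevexpr as ex


@pytest.fixture(scope="session")
def bundle():
    """Small synthetic study (2,000 background + 190 candidate genes)."""
    return ex.paper_like_fixture(seed=0)


@pytest.fixture(scope="session")
def fitted_model(bundle):
    cm = bundle.counts
    model = ex.NegativeBinomialDE()
    model.fit(
        cm.counts.T,
        zones=cm.zones(),
        blocks=cm.blocks(),
        gene_ids=cm.gene_ids,
    )
    return model


@pytest.fixture(scope="session")
def normalized(bundle):
    cm = bundle.counts
    sf = ex.estimate_size_factors(cm)
    return pd.DataFrame(
        ex.normalize(cm, sf), index=cm.gene_ids, columns=cm.sample_ids
    )


@pytest.fixture
def tiny_counts():
    """3 genes x 6 samples, 2 zones x 3 blocks, all-positive counts."""
    samples = [
        ex.SampleInfo("L1", "lowland", b) for b in (1, 2, 3)
    ] + [ex.SampleInfo("H1", "highland", b) for b in (1, 2, 3)]
    counts = np.array(
        [[10, 12, 9, 40, 44, 38], [5, 6, 7, 5, 6, 4], [100, 90, 110, 95, 105, 99]]
    )
    return ex.CountMatrix(
        gene_ids=["g1", "g2", "g3"],
        sample_ids=[f"s{i}" for i in range(6)],
        counts=counts,
        samples=samples,
    )
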