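import numpy as np
import pytest

import ppialign as pa

BENCHMARK_SEED = 7


@pytest.fixture(scope="session")
def benchmark_run():
    """One full pipeline run on the default synthetic benchmark."""
    cfg = pa.SimConfig(rng_seed=BENCHMARK_SEED)
    net1, net2, hom, truth = pa.simulate_paired_networks(cfg)
    result = pa.run_alignment(net1, net2, hom)
    return {
        "cfg": cfg,
        "net1": net1,
        "net2": net2,
        "hom": hom,
        "truth": truth,
        "result": result,
    }


@pytest.fixture()
def toy_conserved_pair():
    """Two composite nodes joined by one conserved edge (0.5 + 0.2)."""
    net1 = pa.WeightedNetwork.from_edges("y", [("u1", "v1", 0.5)])
    net2 = pa.WeightedNetwork.from_edges("f", [("u2", "v2", 0.2)])
    hom = pa.HomologyMap.from_records([("u1", "u2", 1.0), ("v1", "v2", 1.0)])
    return net1, net2, hom


@pytest.fixture()
def rng():
    return np.random.default_rng(20260922)
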