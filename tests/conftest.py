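import pytest

import saltmem as sm


@pytest.fixture(scope="session")
def strong_sim():
    """Strong-effect simulation (2000 genes, |log2 effect| = 3, NB
    dispersion 0.05, 3 replicates) with the full analysis run on it."""
    config = sm.SimConfig(n_genes=2000, seed=11)
    cm, graph, promoters, consensi, truth = sm.simulate_all(config)
    factors = sm.size_factors(cm)
    dispersions = sm.estimate_dispersion(cm, factors)
    c1 = sm.wald_contrast(cm, factors, dispersions, "T1_0h", "T1_3h")
    c2 = sm.wald_contrast(cm, factors, dispersions, "T1_3h", "T2_3h")
    catalog = sm.classify_memory(c1, c2)
    return {
        "config": config,
        "cm": cm,
        "graph": graph,
        "promoters": promoters,
        "consensi": consensi,
        "truth": truth,
        "factors": factors,
        "dispersions": dispersions,
        "contrast1": c1,
        "contrast2": c2,
        "catalog": catalog,
    }
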