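import numpy as np
import pytest

from coexnet import detect, network, synthetic


@pytest.fixture(scope="session")
def planted5():
    """Five planted modules (sizes 40-120) + 200 background genes at a
    signal/noise ratio of 3, with the full network chain precomputed."""
    config = synthetic.SyntheticConfig(
        n_samples=120,
        module_sizes=(40, 60, 80, 100, 120),
        n_background=200,
        factor_strength=1.0,
        noise_sd=1.0 / 3.0,
        loading_spread=0.5,  # heterogeneous loadings give modules real hub structure
        seed=7,
    )
    expr, truth = synthetic.generate_expression(config)
    log_expr = np.log2(expr)
    adj = network.signed_adjacency(network.correlation_matrix(log_expr), beta=6)
    tom = network.topological_overlap(adj)
    dend = detect.average_linkage_dendrogram(tom.dissimilarity(), list(tom.gene_ids))
    partition = detect.dynamic_tree_cut(dend, detect.CutParams(minModuleSize=30))
    return {
        "config": config,
        "expr": expr,
        "truth": truth,
        "log_expr": log_expr,
        "adj": adj,
        "tom": tom,
        "dend": dend,
        "partition": partition,
    }
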