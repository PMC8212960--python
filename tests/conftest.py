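import networkx as nx
import numpy as np
import pandas as pd
import pytest

from cernet.datatypes import ExpressionData, SimulationConfig


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Desk-scale study conditions shared across tests."""
    return SimulationConfig(rng_seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    from cernet.simulate import simulate_all

    return simulate_all(small_config)


def null_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A configuration with every planted effect switched off."""
    fields = dict(
        n_de_lnc=0,
        n_de_pcg=0,
        n_true_cerna=0,
        de_lfc=0.0,
        signature_coefs=(),
        seed_bias=0.0,
        rng_seed=seed,
    )
    fields.update(overrides)
    return SimulationConfig(**fields)


def toy_bipartite(n_lnc=4, n_pcg=6, p=0.7, seed=0) -> nx.Graph:
    """Small random lncRNA-PCG graph with type attributes, no isolates."""
    rng = np.random.default_rng(seed)
    G = nx.Graph()
    lncs = [f"L{i}" for i in range(n_lnc)]
    pcgs = [f"P{i}" for i in range(n_pcg)]
    for l in lncs:
        for q in pcgs:
            if rng.random() < p:
                G.add_edge(l, q)
    for l in lncs:
        if l not in G or G.degree(l) == 0:
            G.add_edge(l, pcgs[int(rng.integers(n_pcg))])
    for q in pcgs:
        if q not in G or G.degree(q) == 0:
            G.add_edge(lncs[int(rng.integers(n_lnc))], q)
    for n in G.nodes:
        G.nodes[n]["type"] = "lncRNA" if n.startswith("L") else "PCG"
    return G


def expression_from_log2(log2_tumor, log2_normal, gene_ids, gene_types):
    """Build ExpressionData from log2(x+1)-scale arrays (inverse transform)."""
    n = log2_tumor.shape[1]
    patients = [f"P{j:03d}" for j in range(n)]
    t_cols = [f"{p}-T" for p in patients]
    n_cols = [f"{p}-N" for p in patients]
    fpkm = np.maximum(
        np.exp2(np.concatenate([log2_tumor, log2_normal], axis=1)) - 1.0, 0.0
    )
    expr = pd.DataFrame(fpkm, index=gene_ids, columns=t_cols + n_cols)
    samples = pd.DataFrame(
        {"patient": patients * 2, "tissue": ["tumor"] * n + ["normal"] * n},
        index=t_cols + n_cols,
    )
    gene_type = pd.Series(gene_types, index=gene_ids)
    return ExpressionData(expr, gene_type, samples)
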