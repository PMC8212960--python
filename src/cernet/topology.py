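"""Topological characterization of the ceRNA network.

Centralities (degree, normalized betweenness, Wasserman-Faust closeness),
log-log power-law fit of the degree distribution, hypergeometric
over-representation analysis of lncRNA-neighborhood PCGs against
user-supplied GMT gene sets, and a quantified bidirectional-clustering
check of tumor/normal separability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score
from statsmodels.stats.multitest import multipletests

from cernet.datatypes import ExpressionData, log2p1

__all__ = [
    "node_centralities",
    "top_nodes",
    "hub_nodes",
    "PowerLawFit",
    "powerlaw_fit",
    "ora",
    "lncRNA_neighbor_genes",
    "bicluster_check",
]


def node_centralities(G: nx.Graph) -> pd.DataFrame:
    """Degree, betweenness and closeness per node with per-metric ranks.

    Betweenness is shortest-path betweenness normalized by the number of
    node pairs; closeness uses the Wasserman-Faust component correction
    so disconnected graphs still yield values in [0, 1].
    """
    if G.number_of_nodes() == 0:
        raise ValueError("empty network")
    deg = dict(G.degree())
    btw = nx.betweenness_centrality(G, normalized=True)
    clo = nx.closeness_centrality(G, wf_improved=True)
    table = pd.DataFrame(
        {
            "type": [G.nodes[n].get("type", "") for n in G.nodes],
            "degree": [deg[n] for n in G.nodes],
            "betweenness": [btw[n] for n in G.nodes],
            "closeness": [clo[n] for n in G.nodes],
        },
        index=list(G.nodes),
    )
    for metric in ("degree", "betweenness", "closeness"):
        table[f"rank_{metric}"] = (
            table[metric].rank(ascending=False, method="min").astype(int)
        )
    table.index.name = "node"
    return table.sort_values("degree", ascending=False)


def top_nodes(table: pd.DataFrame, metric: str, k: int = 20) -> list:
    """Top-k node ids by one centrality metric."""
    return list(table.sort_values(metric, ascending=False).index[:k])


def hub_nodes(table: pd.DataFrame, k: int = 20, min_metrics: int = 2,
              node_type: str | None = None) -> list:
    """Nodes appearing in the top-k of at least ``min_metrics`` centralities."""
    sub = table if node_type is None else table[table["type"] == node_type]
    counts: dict = {}
    for metric in ("degree", "betweenness", "closeness"):
        for n in top_nodes(sub, metric, k):
            counts[n] = counts.get(n, 0) + 1
    return sorted([n for n, c in counts.items() if c >= min_metrics])


@dataclass
class PowerLawFit:
    slope: float
    intercept: float
    r_squared: float


def powerlaw_fit(degrees) -> PowerLawFit:
    """OLS fit of log10 frequency vs log10 degree.

    Uses only degrees >= 1 with observed frequency >= 1; requires at
    least 3 distinct degrees.
    """
    degrees = np.asarray([d for d in degrees if d >= 1], dtype=float)
    ks, freq = np.unique(degrees, return_counts=True)
    if len(ks) < 3:
        raise ValueError("need at least 3 distinct degrees for the fit")
    x = np.log10(ks)
    y = np.log10(freq.astype(float))
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 1.0
    return PowerLawFit(float(slope), float(intercept), float(r2))


def ora(
    genes: set,
    universe: set,
    gene_sets: dict[str, set],
    p_adjust: str = "fdr_bh",
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``genes`` in each gene set.

    For each set the upper-tail p is P(X >= overlap) with
    X ~ Hypergeometric(|universe|, |set & universe|, |genes|); gene sets
    with no member in the universe are skipped.
    """
    genes = set(genes) & set(universe)
    if not set(genes) <= set(universe):
        raise ValueError("genes must be a subset of the universe")
    M = len(universe)
    n = len(genes)
    rows = []
    for name, members in gene_sets.items():
        K = len(members & universe)
        if K == 0:
            continue
        k = len(members & genes)
        p = float(stats.hypergeom.sf(k - 1, M, K, n))
        rows.append({"set": name, "set_size": K, "overlap": k, "p": p})
    out = pd.DataFrame(rows, columns=["set", "set_size", "overlap", "p"])
    if len(out):
        out["q"] = multipletests(out["p"], method=p_adjust)[1]
    else:
        out["q"] = pd.Series(dtype=float)
    return out.sort_values("p").reset_index(drop=True)


def lncRNA_neighbor_genes(
    G: nx.Graph, lncRNAs, min_shared: int = 2
) -> dict:
    """PCG neighborhoods of a lncRNA set.

    Returns a dict with: ``shared_pcgs`` — PCGs adjacent to at least
    ``min_shared`` of the given lncRNAs; ``pcg_partner_counts`` — per-PCG
    number of adjacent query lncRNAs; ``lnc_pcg_counts`` — per-lncRNA PCG
    neighbor count; ``jaccard`` — pairwise Jaccard similarity of the
    lncRNA neighbor sets.
    """
    lncRNAs = list(lncRNAs)
    missing = [l for l in lncRNAs if l not in G]
    if missing:
        raise ValueError(f"lncRNAs not in network: {missing}")
    neigh = {l: {v for v in G.neighbors(l)
                 if G.nodes[v].get("type") == "PCG"} for l in lncRNAs}
    counts: dict = {}
    for l in lncRNAs:
        for p in neigh[l]:
            counts[p] = counts.get(p, 0) + 1
    shared = sorted([p for p, c in counts.items() if c >= min_shared])
    jac = pd.DataFrame(1.0, index=lncRNAs, columns=lncRNAs)
    for i, a in enumerate(lncRNAs):
        for b in lncRNAs[i + 1:]:
            union = neigh[a] | neigh[b]
            j = len(neigh[a] & neigh[b]) / len(union) if union else 0.0
            jac.loc[a, b] = jac.loc[b, a] = j
    return {
        "shared_pcgs": shared,
        "pcg_partner_counts": pd.Series(counts, dtype=int).sort_values(
            ascending=False
        ),
        "lnc_pcg_counts": pd.Series(
            {l: len(neigh[l]) for l in lncRNAs}, dtype=int
        ).sort_values(ascending=False),
        "jaccard": jac,
    }


def bicluster_check(
    data: ExpressionData, genes, k: int = 2
) -> tuple[pd.Series, float, float]:
    """Quantify tumor/normal separation by hierarchical clustering.

    Samples (and genes, for the bidirectional view) are clustered by
    average linkage on 1 - Pearson distance of z-scored log2(x+1) rows;
    the sample tree is cut at ``k`` clusters and compared with the
    tumor/normal labels. Returns (labels, adjusted Rand index, accuracy).
    """
    genes = list(genes)
    if len(genes) < 2:
        raise ValueError("need at least 2 genes")
    cols = data.sample_ids()
    if len(cols) < 4:
        raise ValueError("need at least 4 samples")
    X = log2p1(data.expr.loc[genes, cols].values)
    sd = X.std(axis=1)
    if (sd == 0).any():
        dropped = [g for g, s in zip(genes, sd) if s == 0]
        warnings.warn(f"constant gene rows dropped: {dropped}", stacklevel=2)
        keep = sd > 0
        X = X[keep]
        genes = [g for g, s in zip(genes, sd) if s > 0]
        if len(genes) < 2:
            raise ValueError("fewer than 2 non-constant genes")
    Z = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, keepdims=True)

    # sample tree on 1 - Pearson between sample columns
    corr = np.corrcoef(Z.T)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    labels = hierarchy.fcluster(link, t=k, criterion="maxclust")
    # gene tree computed for the bidirectional view (order only)
    if len(genes) > 2:
        gcorr = np.corrcoef(Z)
        gdist = np.clip(1.0 - gcorr, 0.0, 2.0)
        np.fill_diagonal(gdist, 0.0)
        hierarchy.linkage(squareform(gdist, checks=False), method="average")

    tissue = data.samples.loc[cols, "tissue"].values
    truth = (tissue == "tumor").astype(int)
    ari = float(adjusted_rand_score(truth, labels))
    acc_direct = float(np.mean((labels == labels.max()) == truth))
    accuracy = max(acc_direct, 1.0 - acc_direct)
    return pd.Series(labels, index=cols, name="cluster"), ari, accuracy
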