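"""Construction of the dysregulated lncRNA-PCG ceRNA network.

Two candidate networks are intersected: (i) miRNA-mediated pairs whose
shared-miRNA count is hypergeometrically significant, and (ii) DE
lncRNA-PCG pairs positively co-expressed in tumor samples. The
intersection is the specific dysregulated ceRNA network on which risk
lncRNAs are prioritized.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from cernet.datatypes import ExpressionData, log2p1

logger = logging.getLogger(__name__)

__all__ = [
    "target_sets",
    "mirna_universe",
    "shared_mirna_test",
    "build_cerna_candidates",
    "coexpression_pairs",
    "intersect_networks",
    "to_edge_table",
    "network_from_edge_table",
]


def target_sets(table: pd.DataFrame) -> dict[str, set[str]]:
    """Per-target miRNA sets from a (mirna, target) edge list."""
    dedup = table.drop_duplicates(subset=["mirna", "target"])
    return {t: set(g["mirna"]) for t, g in dedup.groupby("target", sort=True)}


def mirna_universe(*tables: pd.DataFrame) -> set[str]:
    """Union of miRNAs appearing in any table."""
    out: set[str] = set()
    for tab in tables:
        out |= set(tab["mirna"])
    return out


def shared_mirna_test(
    lnc_set: set[str], pcg_set: set[str], m: int
) -> tuple[int, float]:
    """Shared-miRNA hypergeometric test for one lncRNA-PCG pair.

    With t = |pcg_set| miRNAs targeting the PCG, n = |lnc_set| targeting
    the lncRNA and r shared, returns (r, P(X >= r)) for
    X ~ Hypergeometric(m, t, n).
    """
    t, n = len(pcg_set), len(lnc_set)
    if max(t, n) > m:
        raise ValueError(f"target set larger than universe: t={t}, n={n}, m={m}")
    r = len(lnc_set & pcg_set)
    p = float(stats.hypergeom.sf(r - 1, m, t, n))
    return r, min(max(p, 0.0), 1.0)


def build_cerna_candidates(
    tab_pcg: pd.DataFrame,
    tab_lnc: pd.DataFrame,
    p_cut: float = 0.01,
    m: int | None = None,
) -> pd.DataFrame:
    """All lncRNA-PCG pairs sharing >= 1 miRNA with hypergeometric p < p_cut.

    The universe size m defaults to the union of miRNAs in both tables.
    Returns columns lncRNA, PCG, r, t, n, p_hyper, q_hyper.
    """
    if tab_pcg.empty or tab_lnc.empty:
        raise ValueError("interaction tables must be nonempty")
    sets_p = target_sets(tab_pcg)
    sets_l = target_sets(tab_lnc)
    universe = sorted(mirna_universe(tab_pcg, tab_lnc))
    if m is None:
        m = len(universe)
    pos = {mir: i for i, mir in enumerate(universe)}

    lncs = sorted(sets_l)
    pcgs = sorted(sets_p)
    L = np.zeros((len(lncs), len(universe)), dtype=np.int32)
    P = np.zeros((len(pcgs), len(universe)), dtype=np.int32)
    for i, g in enumerate(lncs):
        L[i, [pos[x] for x in sets_l[g]]] = 1
    for i, g in enumerate(pcgs):
        P[i, [pos[x] for x in sets_p[g]]] = 1

    shared = L @ P.T  # r for every pair
    t_sizes = P.sum(axis=1)
    n_sizes = L.sum(axis=1)
    li, pi = np.nonzero(shared)
    r = shared[li, pi]
    t = t_sizes[pi]
    n = n_sizes[li]
    p = stats.hypergeom.sf(r - 1, m, t, n)
    keep = p < p_cut
    out = pd.DataFrame(
        {
            "lncRNA": np.asarray(lncs, dtype=object)[li[keep]],
            "PCG": np.asarray(pcgs, dtype=object)[pi[keep]],
            "r": r[keep],
            "t": t[keep],
            "n": n[keep],
            "p_hyper": p[keep],
        }
    )
    if len(out):
        out["q_hyper"] = multipletests(out["p_hyper"], method="fdr_bh")[1]
    else:
        out["q_hyper"] = pd.Series(dtype=float)
    return out.sort_values(["lncRNA", "PCG"]).reset_index(drop=True)


def coexpression_pairs(
    data: ExpressionData,
    de_lnc: list[str],
    de_pcg: list[str],
    pcc_cut: float = 0.5,
    p_cut: float = 0.01,
    tissue: str | None = "tumor",
) -> pd.DataFrame:
    """Positively co-expressed DE lncRNA-PCG pairs.

    Pearson correlation of log2(x+1) over the selected samples
    (tumor-only by default, ``tissue=None`` for all samples); pairs with
    pcc > pcc_cut and two-sided p < p_cut are retained. The threshold is
    signed: strong negative correlation is excluded.
    """
    cols = data.sample_ids(tissue)
    if len(cols) < 4:
        raise ValueError("need at least 4 samples for correlation")
    N = len(cols)
    X = log2p1(data.expr.loc[de_lnc, cols].values)
    Y = log2p1(data.expr.loc[de_pcg, cols].values)

    sx = X.std(axis=1)
    sy = Y.std(axis=1)
    ok_x = sx > 0
    ok_y = sy > 0
    for g, ok in zip(list(de_lnc), ok_x):
        if not ok:
            logger.warning("zero-variance lncRNA skipped in co-expression: %s", g)
    for g, ok in zip(list(de_pcg), ok_y):
        if not ok:
            logger.warning("zero-variance PCG skipped in co-expression: %s", g)

    Xc = (X - X.mean(axis=1, keepdims=True)) / np.where(sx > 0, sx, 1.0)[:, None]
    Yc = (Y - Y.mean(axis=1, keepdims=True)) / np.where(sy > 0, sy, 1.0)[:, None]
    pcc = (Xc @ Yc.T) / N
    pcc = np.clip(pcc, -1.0, 1.0)
    pcc[~ok_x, :] = np.nan
    pcc[:, ~ok_y] = np.nan

    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = pcc * np.sqrt((N - 2) / (1.0 - pcc**2))
    pval = 2.0 * stats.t.sf(np.abs(tstat), N - 2)
    pval = np.where(np.abs(pcc) >= 1.0, 0.0, pval)

    keep = (pcc > pcc_cut) & (pval < p_cut)
    keep &= ~np.isnan(pcc)
    li, pi = np.nonzero(keep)
    out = pd.DataFrame(
        {
            "lncRNA": np.asarray(list(de_lnc), dtype=object)[li],
            "PCG": np.asarray(list(de_pcg), dtype=object)[pi],
            "pcc": pcc[li, pi],
            "p_pcc": pval[li, pi],
        }
    )
    if len(out):
        out["q_pcc"] = multipletests(out["p_pcc"], method="fdr_bh")[1]
    else:
        out["q_pcc"] = pd.Series(dtype=float)
    return out.sort_values(["lncRNA", "PCG"]).reset_index(drop=True)


def intersect_networks(
    cerna: pd.DataFrame, coexpr: pd.DataFrame, de_table: pd.DataFrame | None = None
) -> nx.Graph:
    """Bipartite ceRNA network: exact intersection of the two pair lists.

    Edge attributes merge the hypergeometric and correlation statistics;
    node attributes carry the type and, when ``de_table`` is given, the
    DE log2FC and p.
    """
    merged = cerna.merge(coexpr, on=["lncRNA", "PCG"], how="inner")
    G = nx.Graph()
    for row in merged.itertuples(index=False):
        attrs = {k: getattr(row, k) for k in merged.columns
                 if k not in ("lncRNA", "PCG")}
        G.add_edge(row.lncRNA, row.PCG, **attrs)
        G.nodes[row.lncRNA]["type"] = "lncRNA"
        G.nodes[row.PCG]["type"] = "PCG"
    if de_table is not None:
        for node in G.nodes:
            if node in de_table.index:
                G.nodes[node]["log2FC"] = float(de_table.loc[node, "log2FC"])
                G.nodes[node]["p"] = float(de_table.loc[node, "p"])
    return G


def to_edge_table(G: nx.Graph) -> pd.DataFrame:
    """Flatten the network to the TSV edge-list layout."""
    rows = []
    for u, v, attrs in G.edges(data=True):
        l, p = (u, v) if G.nodes[u].get("type") == "lncRNA" else (v, u)
        rows.append({"lncRNA": l, "PCG": p, **attrs})
    cols = ["lncRNA", "PCG", "r", "t", "n", "p_hyper", "pcc", "p_pcc"]
    out = pd.DataFrame(rows)
    ordered = [c for c in cols if c in out.columns] + [
        c for c in out.columns if c not in cols
    ]
    return out[ordered].sort_values(["lncRNA", "PCG"]).reset_index(drop=True)


def network_from_edge_table(edges: pd.DataFrame) -> nx.Graph:
    """Rebuild the bipartite graph from an edge table."""
    G = nx.Graph()
    for row in edges.itertuples(index=False):
        attrs = {
            k: getattr(row, k) for k in edges.columns if k not in ("lncRNA", "PCG")
        }
        G.add_edge(row.lncRNA, row.PCG, **attrs)
        G.nodes[row.lncRNA]["type"] = "lncRNA"
        G.nodes[row.PCG]["type"] = "PCG"
    return G
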