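"""End-to-end orchestration: simulate -> DE -> network -> RWR -> signature.

`run_full_analysis` chains every stage on one synthetic dataset and
returns the intermediate objects plus a flat dict of headline numbers;
it backs both the CLI and the reproduction script.
"""

from __future__ import annotations

import numpy as np

from cernet import cerna, diffexpr, prognosis, rwr, simulate, topology
from cernet.datatypes import SimulationConfig

__all__ = ["run_full_analysis"]


def run_full_analysis(
    config: SimulationConfig | None = None,
    n_perm: int = 2000,
    restart: float = 0.7,
    max_search_candidates: int = 10,
    horizons: tuple = (1, 3, 5, 10),
) -> dict:
    """Run the whole pipeline on synthetic data; returns a results dict.

    The per-lncRNA survival screen feeds at most
    ``max_search_candidates`` lncRNAs (smallest screen p first) into the
    exhaustive subset search to keep the 2^k - 1 enumeration desk-scale.
    """
    if config is None:
        config = SimulationConfig()
    data, tab_pcg, tab_lnc, seeds, survival, truth = simulate.simulate_all(config)

    filtered = diffexpr.filter_low_expression(data)
    de_table = diffexpr.paired_moderated_t(filtered)
    de_lnc, de_pcg = diffexpr.select_de(de_table)

    candidates = cerna.build_cerna_candidates(tab_pcg, tab_lnc)
    coexpr = cerna.coexpression_pairs(filtered, de_lnc, de_pcg)
    G = cerna.intersect_networks(candidates, coexpr, de_table)

    results: dict = {
        "config": config,
        "truth": truth,
        "data": data,
        "survival": survival,
        "de_table": de_table,
        "network": G,
        "n_de_lnc": len(de_lnc),
        "n_de_pcg": len(de_pcg),
        "n_network_lnc": sum(
            1 for n in G.nodes if G.nodes[n]["type"] == "lncRNA"
        ),
        "n_network_pcg": sum(1 for n in G.nodes if G.nodes[n]["type"] == "PCG"),
        "n_network_edges": G.number_of_edges(),
    }
    if G.number_of_edges() == 0:
        return results

    cent = topology.node_centralities(G)
    try:
        fit = topology.powerlaw_fit(cent["degree"].values)
        results["degree_powerlaw_slope"] = fit.slope
        results["degree_powerlaw_r2"] = fit.r_squared
    except ValueError:
        pass

    cfg = rwr.RWRConfig(restart=restart, n_perm=n_perm, rng_seed=config.rng_seed)
    mapped = [s for s in seeds if s in G]
    results["n_seeds_mapped"] = len(mapped)
    if not mapped:
        return results
    scores = rwr.permutation_significance(G, mapped, cfg)
    risk_lnc = list(scores.index[(scores["type"] == "lncRNA") & scores["risk"]])
    results["rwr_scores"] = scores
    results["risk_lncRNAs"] = risk_lnc
    results["n_risk_lnc"] = len(risk_lnc)
    try:
        _, wilcoxon_p = rwr.compare_score_distributions(scores)
        results["risk_score_wilcoxon_p"] = wilcoxon_p
    except ValueError:
        pass

    if risk_lnc:
        labels, ari, acc = topology.bicluster_check(data, risk_lnc)
        results["bicluster_ari"] = ari
        results["bicluster_accuracy"] = acc

    screen = prognosis.screen_survival_lncRNAs(risk_lnc, data, survival)
    results["screen"] = screen
    if screen.empty:
        results["n_survival_lnc"] = 0
        return results
    kept = screen[screen["kept"]].sort_values("p")
    results["n_survival_lnc"] = int(len(kept))
    search_set = list(kept["lncRNA"][:max_search_candidates])
    if not search_set:
        return results

    model, models = prognosis.exhaustive_signature_search(
        search_set, data, survival, horizons=horizons
    )
    results["all_models"] = models
    results["n_models_evaluated"] = int(models.attrs["n_evaluated"])
    if model is None:
        return results
    results["signature"] = model
    results["signature_size"] = len(model.lncRNAs)
    results["signature_logrank_p"] = model.logrank_p
    for h, auc in model.aucs.items():
        results[f"auc_{h}"] = auc

    high = (model.scores.values > model.cutoff).astype(float)
    cox_table = prognosis.independence_analysis(survival, high)
    results["cox_table"] = cox_table
    multi = cox_table[
        (cox_table["variable"] == "signature")
        & (cox_table["analysis"] == "multivariable")
    ]
    if len(multi):
        results["signature_hr_multivariable"] = float(multi["HR"].iloc[0])
    results["n_patients_survival"] = int(len(survival))
    if not np.isnan(model.median_survival.get("low", np.nan)):
        results["median_survival_low_risk"] = model.median_survival["low"]
    if not np.isnan(model.median_survival.get("high", np.nan)):
        results["median_survival_high_risk"] = model.median_survival["high"]
    return results
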