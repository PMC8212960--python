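"""Synthetic paired tumor/normal study generator with planted ground truth.

Emulates the five inputs of the pipeline — expression matrix with paired
tumor/normal samples, two miRNA-target edge lists, a disease seed-gene
list, and a survival table — so that every downstream stage can be tested
against known planted structure without any external download.

Generative model
----------------
FPKM-like values are 2**N(mu_g, sigma_g) - 1 truncated at zero, so the
pipeline's log2(x+1) transform recovers approximately Gaussian working
values. Gene means mu_g ~ N(base_log_mean, base_log_sd); gene variances
sigma_g^2 ~ s0^2 * d0 / chi^2_d0 (scaled inverse chi-square), the
hierarchical form under which empirical-Bayes variance shrinkage is
well-specified. Planted DE genes are shifted by +-de_lfc in tumor
samples and grouped into co-regulation modules sharing a tumor-only
latent factor, which induces positive co-expression among same-module
lncRNA-PCG pairs; the planted true ceRNA pairs are drawn from those
same-module combinations and additionally receive extra shared miRNAs
in the interaction tables. Module factors (rather than one factor per
pair) are what allow dense hub-structured networks: a gene's pairwise
correlation does not attenuate with its degree.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from cernet.datatypes import (
    LNCRNA,
    NORMAL,
    PCG,
    TUMOR,
    ExpressionData,
    GroundTruth,
    SimulationConfig,
    log2p1,
)

__all__ = [
    "simulate_expression",
    "simulate_interactions",
    "simulate_survival",
    "simulate_disease_genes",
    "simulate_all",
]


def _gene_ids(config: SimulationConfig) -> tuple[list[str], list[str]]:
    lnc = [f"LNC{i:05d}" for i in range(config.n_lncRNA)]
    pcg = [f"PCG{i:05d}" for i in range(config.n_PCG)]
    return lnc, pcg


def _plant_structure(config: SimulationConfig, rng: np.random.Generator,
                     lnc_ids: list[str], pcg_ids: list[str]) -> GroundTruth:
    """Choose DE genes, signs, the signature, and true ceRNA pairs."""
    de_lnc = sorted(rng.choice(config.n_lncRNA, config.n_de_lnc, replace=False))
    de_pcg = sorted(rng.choice(config.n_PCG, config.n_de_pcg, replace=False))
    de_lnc_ids = [lnc_ids[i] for i in de_lnc]
    de_pcg_ids = [pcg_ids[i] for i in de_pcg]

    signs = {}
    for g in de_lnc_ids + de_pcg_ids:
        signs[g] = int(rng.choice([-1, 1]))

    if config.signature_lncRNAs is not None:
        sig_ids = list(config.signature_lncRNAs)
        bad = set(sig_ids) - set(de_lnc_ids)
        if bad:
            raise ValueError(f"signature lncRNAs not planted as DE: {sorted(bad)}")
    else:
        sig_ids = de_lnc_ids[: len(config.signature_coefs)]
    signature = list(zip(sig_ids, config.signature_coefs))

    # DE genes are grouped into tumor-only co-regulation modules (block
    # assignment, the signature lncRNAs share module 0 so the disease
    # seeds can concentrate around them); every fifth PCG also bridges
    # into the next module so the planted network stays connected. True
    # ceRNA pairs are same-module lncRNA-PCG combos.
    M = config.n_modules
    lnc_order = sig_ids + [g for g in de_lnc_ids if g not in sig_ids]
    modules: dict[str, tuple[int, ...]] = {}
    for i, g in enumerate(lnc_order):
        modules[g] = (i * M // len(lnc_order),)
    for i, g in enumerate(de_pcg_ids):
        m = i * M // len(de_pcg_ids)
        modules[g] = (m, (m + 1) % M) if M > 1 and i % 5 == 0 else (m,)

    combos = [
        (l, p)
        for l in lnc_order
        for p in de_pcg_ids
        if set(modules[l]) & set(modules[p])
    ]
    n_pairs = min(config.n_true_cerna, len(combos))
    idx = rng.choice(len(combos), size=n_pairs, replace=False)
    pairs = {combos[i] for i in idx}

    return GroundTruth(
        de_lnc_ids=set(de_lnc_ids),
        de_pcg_ids=set(de_pcg_ids),
        de_signs=signs,
        modules=modules,
        true_cerna_pairs=pairs,
        true_signature=signature,
    )


def simulate_expression(
    config: SimulationConfig, truth: GroundTruth | None = None
) -> tuple[ExpressionData, GroundTruth]:
    """Generate the paired tumor/normal expression matrix.

    Returns the matrix plus the (possibly newly planted) ground truth.
    A pre-populated ``truth`` is reused so expression, interactions and
    seeds stay mutually consistent within one ``simulate_all`` run.
    """
    config.validate()
    if config.n_patients < 3:
        raise ValueError("need at least 3 patients for a paired design")
    rng = np.random.default_rng(config.rng_seed)
    lnc_ids, pcg_ids = _gene_ids(config)
    genes = lnc_ids + pcg_ids
    if truth is None:
        truth = _plant_structure(config, rng, lnc_ids, pcg_ids)

    n_genes = len(genes)
    n = config.n_patients
    mu = rng.normal(config.base_log_mean, config.base_log_sd, size=n_genes)
    # gene variances ~ scaled inverse chi-square(d0, s0^2)
    d0 = config.var_prior_df
    s0sq = config.within_log_sd**2
    sigma = np.sqrt(s0sq * d0 / rng.chisquare(d0, size=n_genes))

    noise_t = rng.normal(0.0, 1.0, size=(n_genes, n)) * sigma[:, None]
    noise_n = rng.normal(0.0, 1.0, size=(n_genes, n)) * sigma[:, None]
    log_t = mu[:, None] + noise_t
    log_n = mu[:, None] + noise_n

    gene_pos = {g: i for i, g in enumerate(genes)}
    for g in sorted(truth.de_lnc_ids | truth.de_pcg_ids):
        log_t[gene_pos[g]] += truth.de_signs[g] * config.de_lfc

    # tumor-only shared latent factor per co-regulation module
    factors = rng.normal(0.0, 1.0, size=(config.n_modules, n))
    for g in sorted(truth.modules):
        for m in truth.modules[g]:
            log_t[gene_pos[g]] += config.latent_weight * factors[m]

    patients = [f"P{j:04d}" for j in range(n)]
    t_samples = [f"{p}-T" for p in patients]
    n_samples = [f"{p}-N" for p in patients]
    values = np.concatenate([log_t, log_n], axis=1)
    fpkm = np.maximum(np.exp2(values) - 1.0, 0.0)
    expr = pd.DataFrame(fpkm, index=genes, columns=t_samples + n_samples)

    samples = pd.DataFrame(
        {
            "patient": patients + patients,
            "tissue": [TUMOR] * n + [NORMAL] * n,
        },
        index=t_samples + n_samples,
    )
    samples.index.name = "sample"
    gene_type = pd.Series(
        [LNCRNA] * len(lnc_ids) + [PCG] * len(pcg_ids), index=genes, name="type"
    )
    return ExpressionData(expr, gene_type, samples), truth


def simulate_interactions(
    config: SimulationConfig, truth: GroundTruth
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate miRNA-PCG and miRNA-lncRNA edge lists.

    Background target sets are Poisson-sized independent draws from the
    miRNA universe. Each co-regulation module owns a dedicated pool of
    ``overlap_boost`` miRNAs injected into every member's target set, so
    planted same-module ceRNA pairs share at least that many miRNAs
    while a gene's set size stays bounded regardless of how many pairs
    it participates in.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed + 1)
    lnc_ids, pcg_ids = _gene_ids(config)
    mirnas = np.array([f"MIR{i:04d}" for i in range(config.n_miRNA)])

    sets: dict[str, set[str]] = {}
    for g in lnc_ids + pcg_ids:
        k = min(int(rng.poisson(config.targets_per_gene)), config.n_miRNA)
        sets[g] = set(rng.choice(mirnas, size=k, replace=False)) if k else set()

    if config.overlap_boost:
        pools = {
            m: set(rng.choice(mirnas, size=config.overlap_boost, replace=False))
            for m in range(config.n_modules)
        }
        for g, mods in sorted(truth.modules.items()):
            for m in mods:
                sets[g].update(pools[m])

    def to_table(ids: list[str]) -> pd.DataFrame:
        rows = [(m, g) for g in ids for m in sorted(sets[g])]
        return pd.DataFrame(rows, columns=["mirna", "target"])

    return to_table(pcg_ids), to_table(lnc_ids)


def simulate_survival(
    data: ExpressionData, config: SimulationConfig, truth: GroundTruth
) -> pd.DataFrame:
    """Generate a survival table for the tumor samples.

    Event times are exponential with log-hazard equal to the planted
    signature's linear predictor on centered log2(x+1) expression;
    censoring is independent uniform calibrated to ``censor_rate``.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed + 2)
    tumor = data.tissue_matrix(TUMOR)
    missing = [g for g, _ in truth.true_signature if g not in data.genes]
    if missing:
        raise ValueError(f"signature lncRNAs absent from matrix: {missing}")

    lp = np.zeros(tumor.shape[1])
    for g, coef in truth.true_signature:
        e = log2p1(tumor.loc[g].values)
        lp += float(coef) * (e - e.mean())

    scale = config.baseline_hazard_scale * np.exp(-lp)
    T = rng.exponential(scale)
    if config.censor_rate == 0:
        time, event = T, np.ones_like(T, dtype=int)
    else:
        c_max = _uniform_censor_bound(T, config.censor_rate)
        C = rng.uniform(0.0, c_max, size=T.shape)
        time = np.minimum(T, C)
        event = (T <= C).astype(int)
    time = np.maximum(time, 1e-8)

    age = np.clip(np.round(rng.normal(58, 10, size=T.shape)), 25, 90).astype(int)
    stage = rng.choice(["I", "II", "III", "IV"], size=T.shape,
                       p=[0.18, 0.55, 0.22, 0.05])
    return pd.DataFrame(
        {
            "sample": tumor.columns,
            "time": time,
            "event": event,
            "age": age,
            "stage": stage,
        }
    )


def _uniform_censor_bound(T: np.ndarray, rate: float) -> float:
    """Upper bound of Uniform(0, c) censoring achieving P(C < T) ~ rate."""
    lo, hi = 1e-9, float(T.max()) * 1e6

    def frac(c: float) -> float:
        return float(np.mean(np.minimum(T / c, 1.0)))

    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if frac(mid) > rate:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_disease_genes(
    truth: GroundTruth, config: SimulationConfig, bias: float | None = None
) -> list[str]:
    """Draw the disease seed-gene list over PCGs.

    A ``bias`` fraction of seeds comes from PCG partners of planted ceRNA
    pairs — partners of signature-lncRNA pairs first, so the disease
    genes cluster around the survival-relevant lncRNAs — and the
    remainder is uniform over the other PCGs.
    """
    config.validate()
    if bias is None:
        bias = config.seed_bias
    if not 0 <= bias <= 1:
        raise ValueError("bias must lie in [0, 1]")
    if config.n_seed_genes > config.n_PCG:
        raise ValueError("n_seed_genes exceeds the number of PCGs")
    rng = np.random.default_rng(config.rng_seed + 3)
    _, pcg_ids = _gene_ids(config)
    sig_lncs = {g for g, _ in truth.true_signature}
    sig_partners = sorted(
        {p for l, p in truth.true_cerna_pairs if l in sig_lncs}
    )
    other_partners = sorted(
        {p for _, p in truth.true_cerna_pairs} - set(sig_partners)
    )

    n_bias = min(
        int(round(bias * config.n_seed_genes)),
        len(sig_partners) + len(other_partners),
    )
    seeds = set(sig_partners[: n_bias])
    if len(seeds) < n_bias:
        extra = rng.choice(
            other_partners, size=n_bias - len(seeds), replace=False
        )
        seeds.update(extra)
    rest = [g for g in pcg_ids if g not in seeds]
    n_rest = config.n_seed_genes - len(seeds)
    seeds.update(rng.choice(rest, size=n_rest, replace=False))
    truth.seed_gene_ids = set(seeds)
    return sorted(seeds)


def simulate_all(config: SimulationConfig):
    """Run every generator consistently; returns
    (expression, mirna_pcg, mirna_lnc, seeds, survival, truth)."""
    data, truth = simulate_expression(config)
    tab_pcg, tab_lnc = simulate_interactions(config, truth)
    seeds = simulate_disease_genes(truth, config)
    survival = simulate_survival(data, config, truth)
    return data, tab_pcg, tab_lnc, seeds, survival, truth
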