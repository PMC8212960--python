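# cernet

Risk-lncRNA prioritization and prognostic-signature discovery on
miRNA-mediated ceRNA networks.

Long non-coding RNAs (lncRNAs) can act as competing endogenous RNAs
(ceRNAs): by sponging shared miRNAs they indirectly regulate
protein-coding genes (PCGs). `cernet` implements, as a reusable and
tested pipeline, the network-medicine analysis that exploits this: build
a disease-specific dysregulated lncRNA–PCG ceRNA network from paired
tumor/normal expression profiles, prioritize candidate risk lncRNAs by
network propagation from known disease genes, and distill a compact
prognostic lncRNA signature by exhaustive subset search under a Cox
risk-score model. It is aimed at computational biologists who want each
stage — differential expression, network construction, random walk with
restart, survival modelling — available as a well-specified library
function rather than a one-off analysis script.

## The method

**Network construction.** Genes with mean FPKM < 1 in tumor or normal
tissue are removed; differentially expressed (DE) lncRNAs and PCGs are
called from per-patient paired differences of log2(FPKM+1) with an
empirical-Bayes moderated t-statistic (*p* < 0.05 and |log2FC| > 1). Two
candidate pair sets are intersected:

1. *miRNA-mediated pairs.* For a lncRNA targeted by *n* miRNAs and a PCG
   targeted by *t* miRNAs out of a universe of *m*, sharing *r* miRNAs,
   the upper-tail hypergeometric probability

   p = 1 − Σ_{i=0}^{r−1} C(t, i) C(m−t, n−i) / C(m, n)

   is kept at *p* < 0.01 (and r ≥ 1).
2. *Co-expressed pairs.* DE lncRNA–PCG pairs with Pearson correlation
   PCC > 0.5 and *p* < 0.01 on tumor samples.

**Risk lncRNAs.** On the intersected bipartite network, a random walk
with restart p_{t+1} = (1−r) W p_t + r p_0 (W column-normalized, p_0
uniform over disease seed PCGs, restart r = 0.7, convergence 1e-10)
scores every node's proximity to the disease genes. Significance is
empirical: pseudo-seed sets of the same size are resampled uniformly
without replacement from the PCG nodes (10,000 permutations) and each
lncRNA's p-value is the fraction of permutations whose score exceeds its
real score; lncRNAs with p < 0.05 are called risk lncRNAs.

**Prognostic signature.** Each risk lncRNA is screened by the maximally
selected log-rank statistic (maxstat) on its expression; survivors
(log-rank *p* < 0.05) enter an exhaustive search over all 2^k − 1
non-empty subsets. Every subset is fit jointly by Cox regression (Efron
ties), patients are split at the median of the risk score
Σ_i x_i e_i (x_i the Cox coefficient, e_i the log2(FPKM+1) expression),
and the subset minimizing the two-group log-rank p wins. The final model
is evaluated by Kaplan–Meier curves, IPCW time-dependent ROC AUC at 1,
3, 5 and 10 years, and univariate/multivariable Cox analysis against age
(>58 vs ≤58) and stage (III/IV vs I/II).

Because the cohort-scale inputs this analysis consumes (TCGA-style
expression matrices, curated miRNA-target databases, disease-gene
catalogs) are external downloads, the package ships a first-class synthetic-data generator
(`cernet.simulate`) that emulates all five inputs with planted ground
truth — DE genes, co-regulation modules, ceRNA pairs, disease seeds and
a survival signature — so every stage is testable end to end.

## Worked example

```python
from cernet.datatypes import SimulationConfig
from cernet.pipeline import run_full_analysis

results = run_full_analysis(SimulationConfig(rng_seed=1), n_perm=10_000)
sig = results["signature"]
print(f"network: {results['n_network_lnc']} lncRNAs, "
      f"{results['n_network_pcg']} PCGs, {results['n_network_edges']} edges")
print(f"risk lncRNAs (empirical p < 0.05): {results['n_risk_lnc']}")
print(f"risk vs non-risk score separation: Wilcoxon p = "
      f"{results['risk_score_wilcoxon_p']:.3g}")
print(f"survival screen kept {results['n_survival_lnc']} lncRNAs -> "
      f"{results['n_models_evaluated']} models searched")
print(f"best signature: {', '.join(sig.lncRNAs)}")
print(f"log-rank p = {sig.logrank_p:.3g}; median survival low vs high risk: "
      f"{sig.median_survival['low']:.2f} vs {sig.median_survival['high']:.2f} years")
print("AUC at 1/3/5/10 years: "
      + "/".join(f"{sig.aucs[h]:.2f}" for h in (1, 3, 5, 10)))
```

prints

```
network: 30 lncRNAs, 117 PCGs, 962 edges
risk lncRNAs (empirical p < 0.05): 8
risk vs non-risk score separation: Wilcoxon p = 3.61e-05
survival screen kept 8 lncRNAs -> 255 models searched
best signature: LNC00036, LNC00034, LNC00003, LNC00032, LNC00004
log-rank p = 3.14e-06; median survival low vs high risk: 15.11 vs 4.00 years
AUC at 1/3/5/10 years: 0.70/0.68/0.68/0.79
```

Read: of the 30 network lncRNAs, 8 sit significantly closer to the
disease seed genes than random seed sets would place them; those 8 also
separate tumor from normal samples by clustering, all pass the per-gene
survival screen, and the best of the 255 candidate signatures splits the
cohort into groups with clearly different survival (15.1 vs 4.0 years
median) and useful discrimination at every horizon.

The same stages are available as a CLI for file-based work:

```bash
cernet simulate --seed 5 --outdir data
cernet de --expr data/expression.tsv --samples data/samples.tsv --out de_table.tsv
cernet network --expr data/expression.tsv --samples data/samples.tsv \
    --mirna-pcg data/mirna_pcg.tsv --mirna-lnc data/mirna_lnc.tsv \
    --de-table de_table.tsv --out network.tsv
cernet rwr --network network.tsv --seeds data/seeds.txt --nperm 10000 --seed 5 --out scores.tsv
cernet signature --expr data/expression.tsv --samples data/samples.tsv \
    --surv data/survival.tsv --candidates risk.txt --outdir sig
```

## Layout

| module | contents |
| --- | --- |
| `cernet.simulate` | synthetic cohort generator with planted truth |
| `cernet.diffexpr` | low-expression filter, moderated paired t, DE selection |
| `cernet.cerna` | hypergeometric shared-miRNA test, co-expression, intersection |
| `cernet.rwr` | column normalization, RWR, permutation significance |
| `cernet.topology` | centralities, degree power-law fit, ORA, biclustering |
| `cernet.prognosis` | log-rank, maxstat, KM, Cox (Efron), subset search, tdROC |
| `cernet.pipeline` / `cernet.cli` | orchestration and command-line front end |

See `docs/methods.md` for modelling assumptions, parameter defaults and
numerical choices.
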