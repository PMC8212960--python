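# Methods

This note records the models, defaults and numerical choices behind
`cernet`, and what the synthetic study conditions do and do not show
about real cohort data.

## Differential expression

The paired design compares, per gene, the per-patient difference
d_p = log2(tumor_p + 1) − log2(normal_p + 1). The pseudocount keeps FPKM
zeros finite; all downstream working values (correlation, clustering,
risk scores) use the same log2(x+1) transform. log2FC is the mean of
d_p and the ordinary one-sample t is moderated by empirical-Bayes
variance shrinkage: the gene-wise sample variances s² (df = n−1) are
modelled as s² ~ s0²·F(df, d0), the prior (d0, s0²) is estimated by
matching the mean and variance of log s² to the log-F law
(digamma/trigamma moment equations, trigamma inverted by bisection-free
root finding), and the posterior variance is
s̃² = (d0·s0² + df·s²)/(d0 + df) with the moderated t referred to a t
distribution on df + d0 degrees of freedom. When the observed
log-variance spread is no wider than the sampling noise, d0 = ∞ and the
statistic degenerates to a z-score against the common variance. A gene
with zero variance across all pairs still gets a finite statistic
through the shrunk posterior variance; in the unmoderated code path
(`moderate=False`, the d0 → 0 limit) such a gene's t is defined as 0.
This reimplementation reproduces Bioconductor limma's intercept-only
eBayes fit to machine precision on shared input (cross-checked in the
test suite via Rscript when available).

DE selection defaults to the conjunctive rule p < 0.05 AND
|log2FC| > 1; the disjunctive OR rule is available by flag but calls
nearly everything on realistic data. The low-expression filter requires
mean FPKM ≥ 1 in *both* tissue groups by default (an EITHER mode is a
flag), and is applied before the paired test.

## ceRNA network

The shared-miRNA test for a lncRNA–PCG pair is the upper-tail
hypergeometric probability P(X ≥ r) with X ~ Hypergeom(m, t, n),
evaluated through scipy's log-space survival function, so universes of
thousands of miRNAs cannot overflow. The universe m defaults to the
union of miRNAs appearing in either interaction table (override
available). Candidate pairs require r ≥ 1 and p < 0.01; no
multiple-testing correction is applied to these per-pair thresholds
(BH-adjusted columns are emitted for information only).

Co-expression uses Pearson correlation of log2(x+1) over tumor samples
only by default — the network is meant to capture tumor-specific
dysregulation — with an all-samples mode available; which sample set a
given cohort warrants is a judgement call, and both modes are shipped.
The threshold PCC > 0.5 is signed: strongly anti-correlated pairs are
excluded, matching the ceRNA hypothesis of co-activation through shared
miRNA loss. Two-sided p-values come from t = PCC·√((N−2)/(1−PCC²)) on
N−2 df. Zero-variance genes are skipped with a log entry.

The final network is the exact edge intersection of the two candidate
sets; nodes are only the endpoints of surviving edges.

## Random walk with restart

Propagation iterates p_{t+1} = (1−r)·W·p_t + r·p_0 on the
column-normalized (unweighted) adjacency matrix until the L1 change
falls below 1e-10. The restart probability has no canonical published
value for this analysis class; the default r = 0.7, standard in
disease-gene prioritization, is a mandatory config field recorded in
output provenance. p_0 is normalized to 1/|seeds| per mapped seed; by
linearity this only rescales scores relative to an unnormalized
indicator vector, leaving ranks and empirical p-values unchanged while
making probability conservation (Σp = 1 on a seed-containing component)
a testable invariant. Isolated nodes are excluded from the walk;
lncRNAs unreachable from every seed keep score 0.

Significance is a permutation test on the fixed topology: each round
draws |seeds| pseudo-seed PCGs uniformly without replacement from the
network's PCG nodes, and a lncRNA's empirical p is the fraction of
rounds whose score strictly exceeds its real score. "Strictly exceeds"
is implemented with a guard of 10× the convergence tolerance so that an
iteration artifact can never break an analytic tie; without the guard,
re-drawing a seed set score-equivalent to the real one is decided by
floating-point noise. A degree-preserving bipartite edge-rewiring mode
is available as an alternative perturbation scheme, and a small-sample
(m+1)/(n+1) estimator can replace the plain m/n ratio by flag. Risk
lncRNAs are those with empirical p < 0.05; the risk vs non-risk score
distributions are compared by a two-sided Wilcoxon rank-sum test (exact
null when tie-free and both groups ≤ 25, tie-corrected normal
approximation otherwise).

Calibration caveat: empirical p-values are exchangeable-uniform only
where real and pseudo seeds are drawn from one population — within a
connected component. lncRNAs in components the seeds cannot reach have
score atoms at zero and degenerate p-values by construction, and
p-values of different lncRNAs within one run co-move strongly (all
scores respond to the same resampled seed sets). The test suite
therefore checks null uniformity with one lncRNA p-value per
independent simulated cohort, on the largest connected component.

## Topology

Betweenness is shortest-path betweenness normalized by (N−1)(N−2)/2;
closeness uses the Wasserman–Faust component correction (configurable
to harmonic closeness), so disconnected graphs yield finite values.
Hubs are nodes in the top-k (default 20) of at least two of the three
centralities. The degree power law is fit by OLS on
(log10 k, log10 freq(k)) over degrees with nonzero frequency — the
histogram-regression presentation of degree scaling, chosen over
maximum-likelihood tail fitting because its slope and R² are the
quantities practitioners quote for these networks; it requires ≥ 3
distinct degrees. Over-representation analysis reuses the
hypergeometric kernel on user-supplied GMT collections against an
explicit universe (no live annotation services, for determinism), with
BH adjustment. The bidirectional-clustering check quantifies Fig-style
heatmap separation as a number: average-linkage hierarchical clustering
on 1 − Pearson distance of z-scored log2(x+1) rows, sample tree cut at
k = 2, reported as adjusted Rand index and accuracy against the
tumor/normal labels.

## Survival modelling

*Log-rank.* At each distinct event time, observed group-1 events are
compared with the hypergeometric expectation d·n1/n and variance
d·(n1/n)(1−n1/n)(n−d)/(n−1); the summed (O−E)²/V statistic is referred
to χ²(1).

*maxstat.* The per-lncRNA screen scans every distinct expression value
within the (0.1, 0.9) quantile range as a cutoff, keeps cutoffs with at
least one event on both sides, and returns the cutoff maximizing the
log-rank statistic (ties → lower cutoff). The selection-honest
Lausen–Schumacher improved-Bonferroni p is emitted alongside the
uncorrected p; the screen's keep decision uses the uncorrected p < 0.05,
which is anti-conservative by construction — the corrected column is
there so users can see by how much.

*Cox.* The partial likelihood with Efron tie handling is maximized by
Newton–Raphson with step-halving, converging at gradient ∞-norm < 1e-8
(covariates are centered internally for conditioning). When no two
events are tied the Efron terms collapse to Breslow and the evaluation
is fully vectorized over suffix cumulative sums, which is what makes
the exhaustive subset search cheap. Monotone likelihoods (complete
separation) flatten the gradient as β diverges, so separation is
detected by a coefficient-magnitude guard (|β| > 15) and flagged on the
result rather than raised. Standard errors come from the inverse
observed information; CIs are Wald on the log-hazard scale.

*Exhaustive search.* All 2^k − 1 non-empty subsets of the screened
candidates (guarded to k ≤ 20) are evaluated: joint Cox fit → risk
score Σ x_i e_i → dichotomization → log-rank p. The default split is
the median risk score, matching the final evaluation; a per-subset
maxstat split is available by flag. Ties on the minimum p prefer the
smaller subset (parsimony), then lexicographic order. Subsets whose fit
fails (separation, non-convergence, degenerate split) are recorded as
failed and skipped. Subset evaluations are independent, so the contract
permits parallel execution with identical results.

*Time-dependent ROC.* Cumulative-case/dynamic-control AUC at each
horizon t: cases are patients with observed events by t, weighted by
the inverse Kaplan–Meier estimate of the censoring survival function
evaluated just before their event time (IPCW); controls are patients
still at risk beyond t, whose common weight cancels. With no censoring
this reduces exactly to the plain rank AUC. Horizons with no cases or
no controls return NaN rather than a number.

*Independence analysis.* Univariate and joint multivariable Cox fits of
the dichotomized signature against age (> 58 vs ≤ 58) and stage (III/IV
vs I/II), reported as HR with 95% CI and Wald p.

Follow-up times are treated as years throughout; a days → years
conversion is the caller's responsibility.

## Synthetic study conditions

The generator emulates a paired tumor/normal FPKM cohort at desk scale.
Defaults: 60 patients (120 samples), 150 lncRNAs, 600 PCGs, 300 miRNAs,
30/120 planted DE lncRNAs/PCGs with |log2FC| = 2 (sign random per
gene), background log2 expression N(4, 1), gene-wise within-group
variances s0²·d0/χ²_d0 with s0 = 0.5, d0 = 8 (the hierarchical form
under which eBayes shrinkage is well-specified), 300 planted ceRNA
pairs, censoring 30%, baseline survival scale 10 years. FPKM values are
2^N − 1 truncated at zero so the pipeline's log2(x+1) recovers Gaussian
working values.

Planted co-expression operates through co-regulation *modules*: DE
genes are block-assigned to 4 modules, each module has a tumor-only
latent factor z_m ~ N(0,1) added (weight 1.0) to its members' log2
values, and every fifth PCG bridges two modules so the planted network
is connected. A per-pair latent factor was rejected because a gene in d
pairs would correlate with each partner only at
w²/√((d·w²+σ²)(w²+σ²)), which falls below the PCC > 0.5 threshold for
d ≥ 3 — capping the achievable network at a near-forest, unlike the
dense hub-structured networks this analysis is designed for. For the
same reason the shared-miRNA boost is a per-module pool of
`overlap_boost` miRNAs injected into every member's target set: per-pair
injection inflates a hub's target-set size with every additional pair
and dilutes its own hypergeometric significance. The three signature
lncRNAs (planted log-hazards 0.8, −0.8, 0.6 per log2-expression unit)
share module 0, and the disease seed list is biased (fraction 0.8)
toward PCG partners of signature-lncRNA pairs first — disease genes
cluster around the survival-relevant lncRNAs, which is precisely the
structure RWR is meant to exploit. Survival times are exponential with
log-hazard equal to the centered signature linear predictor; censoring
is independent Uniform(0, c) with c calibrated by bisection to the
target censoring fraction. Age and stage are simulated independent of
expression, so the signature-independence Cox test is honest by
construction.

What passing tests on these conditions do *not* show: the generator has
no batch effects, no library-size or isoform artifacts, no
miRNA-family seed-match structure, no correlation between stage and
expression, and Gaussian log-expression with exchangeable patients —
real cohorts violate all of these. Recovery rates and calibration
results transfer to real data only insofar as those assumptions do.

## Problem sizes in tests and the reproduction script

The test suite and `scripts/acceptance.py` run the full pipeline at the
default desk scale above (networks of ~150 nodes, 10,000 permutations,
exhaustive search over at most 2^10 − 1 subsets after keeping the 10
best-screened lncRNAs; the 2^17 − 1 = 131,071-subset enumeration is
verified with the Cox step stubbed, since the counting property is
independent of the fit). Parameter-recovery checks use 400–500 patients
where the asymptotics require it. These sizes were chosen so any stage
reruns in seconds while every statistical property remains measurable.
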