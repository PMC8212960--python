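"""Shared data containers for the ceRNA-network pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LNCRNA = "lncRNA"
PCG = "PCG"

TUMOR = "tumor"
NORMAL = "normal"


@dataclass
class ExpressionData:
    """A genes x samples FPKM-like expression matrix with paired metadata.

    Attributes
    ----------
    expr : pd.DataFrame
        Nonnegative expression values, index = gene ids, columns = sample ids.
    gene_type : pd.Series
        Per-gene type, ``"lncRNA"`` or ``"PCG"``, indexed like ``expr``.
    samples : pd.DataFrame
        Sample metadata indexed by sample id with columns ``patient`` and
        ``tissue`` (``"tumor"`` | ``"normal"``).
    """

    expr: pd.DataFrame
    gene_type: pd.Series
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.expr.values < 0).any():
            raise ValueError("expression values must be nonnegative")
        if not self.expr.index.equals(self.gene_type.index):
            self.gene_type = self.gene_type.reindex(self.expr.index)
        missing = set(self.expr.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples missing metadata: {sorted(missing)[:5]}")

    @property
    def genes(self) -> pd.Index:
        return self.expr.index

    def sample_ids(self, tissue: str | None = None) -> list[str]:
        if tissue is None:
            return list(self.expr.columns)
        meta = self.samples.loc[self.expr.columns]
        return list(meta.index[meta["tissue"] == tissue])

    def tissue_matrix(self, tissue: str) -> pd.DataFrame:
        return self.expr[self.sample_ids(tissue)]

    def genes_of_type(self, gene_type: str) -> pd.Index:
        return self.genes[self.gene_type.loc[self.genes] == gene_type]

    def subset_genes(self, genes) -> "ExpressionData":
        genes = pd.Index(genes)
        return ExpressionData(
            self.expr.loc[genes], self.gene_type.loc[genes], self.samples
        )

    def paired_patients(self) -> list[str]:
        """Patients with exactly one tumor and one normal sample."""
        meta = self.samples.loc[self.expr.columns]
        counts = meta.groupby("patient")["tissue"].agg(
            lambda t: sorted(t) == [NORMAL, TUMOR]
        )
        return list(counts.index[counts])

    def paired_matrices(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """(tumor, normal) matrices with columns aligned patient-by-patient."""
        meta = self.samples.loc[self.expr.columns]
        patients = self.paired_patients()
        by = {(row["patient"], row["tissue"]): s for s, row in meta.iterrows()}
        t_cols = [by[(p, TUMOR)] for p in patients]
        n_cols = [by[(p, NORMAL)] for p in patients]
        return self.expr[t_cols], self.expr[n_cols]


def log2p1(x):
    """log2(x + 1) working transform used throughout the pipeline."""
    return np.log2(np.asarray(x, dtype=float) + 1.0)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study-condition generator.

    Counts default to a desk-scale rendering of a paired tumor/normal
    transcriptomics cohort; effect sizes are on the log2 scale.
    """

    n_patients: int = 60
    n_lncRNA: int = 150
    n_PCG: int = 600
    n_miRNA: int = 300
    n_de_lnc: int = 30
    n_de_pcg: int = 120
    de_lfc: float = 2.0
    base_log_mean: float = 4.0
    base_log_sd: float = 1.0
    within_log_sd: float = 0.5
    var_prior_df: float = 8.0
    n_true_cerna: int = 300
    n_modules: int = 4
    targets_per_gene: float = 10.0
    overlap_boost: int = 8
    latent_weight: float = 1.0
    n_seed_genes: int = 40
    seed_bias: float = 0.8
    signature_coefs: tuple = (0.8, -0.8, 0.6)
    signature_lncRNAs: tuple | None = None
    censor_rate: float = 0.3
    baseline_hazard_scale: float = 10.0
    rng_seed: int = 0

    def validate(self) -> None:
        counts = dict(
            n_patients=self.n_patients,
            n_lncRNA=self.n_lncRNA,
            n_PCG=self.n_PCG,
            n_miRNA=self.n_miRNA,
        )
        for name, v in counts.items():
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if self.n_de_lnc > self.n_lncRNA:
            raise ValueError("n_de_lnc exceeds n_lncRNA")
        if self.n_de_pcg > self.n_PCG:
            raise ValueError("n_de_pcg exceeds n_PCG")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must lie in [0, 1)")
        if self.overlap_boost > self.n_miRNA:
            raise ValueError("overlap_boost exceeds the miRNA universe")
        if self.n_modules <= 0:
            raise ValueError("n_modules must be positive")
        if len(self.signature_coefs) > self.n_de_lnc:
            raise ValueError("signature larger than the planted DE lncRNA set")


@dataclass
class GroundTruth:
    """Planted truth emitted by the generator, consumed only by tests."""

    de_lnc_ids: set = field(default_factory=set)
    de_pcg_ids: set = field(default_factory=set)
    de_signs: dict = field(default_factory=dict)
    modules: dict = field(default_factory=dict)
    true_cerna_pairs: set = field(default_factory=set)
    seed_gene_ids: set = field(default_factory=set)
    true_signature: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in sorted(self.de_lnc_ids):
            rows.append(("de_lnc", g, "", self.de_signs.get(g, "")))
        for g in sorted(self.de_pcg_ids):
            rows.append(("de_pcg", g, "", self.de_signs.get(g, "")))
        for l, p in sorted(self.true_cerna_pairs):
            rows.append(("cerna_pair", l, p, ""))
        for g in sorted(self.seed_gene_ids):
            rows.append(("seed", g, "", ""))
        for g, c in self.true_signature:
            rows.append(("signature", g, "", c))
        return pd.DataFrame(rows, columns=["kind", "id", "partner", "value"])
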