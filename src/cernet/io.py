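"""Plain-TSV readers/writers for every pipeline artifact.

Formats: expression.tsv (gene, type, then one column per sample),
samples.tsv (sample, patient, tissue), mirna_*.tsv (mirna, target),
seeds.txt (one symbol per line), survival.tsv (sample, time, event,
age, stage), GMT gene-set collections.
"""

from __future__ import annotations

import os

import pandas as pd

from cernet.datatypes import ExpressionData


def write_expression(data: ExpressionData, expr_path: str, samples_path: str) -> None:
    out = data.expr.copy()
    out.insert(0, "type", data.gene_type.loc[out.index])
    out.index.name = "gene"
    out.to_csv(expr_path, sep="\t")
    meta = data.samples.copy()
    meta.index.name = "sample"
    meta.to_csv(samples_path, sep="\t")


def read_expression(expr_path: str, samples_path: str) -> ExpressionData:
    tab = pd.read_csv(expr_path, sep="\t", index_col=0)
    gene_type = tab["type"]
    expr = tab.drop(columns=["type"]).astype(float)
    samples = pd.read_csv(samples_path, sep="\t", index_col=0)
    return ExpressionData(expr, gene_type, samples)


def write_interactions(table: pd.DataFrame, path: str) -> None:
    table[["mirna", "target"]].to_csv(path, sep="\t", index=False)


def read_interactions(path: str) -> pd.DataFrame:
    tab = pd.read_csv(path, sep="\t")
    if not {"mirna", "target"} <= set(tab.columns):
        tab = pd.read_csv(path, sep="\t", header=None, names=["mirna", "target"])
    return tab[["mirna", "target"]]


def write_gene_list(genes, path: str) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def read_gene_list(path: str) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_survival(table: pd.DataFrame, path: str) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_survival(path: str) -> pd.DataFrame:
    tab = pd.read_csv(path, sep="\t")
    tab["time"] = tab["time"].astype(float)
    tab["event"] = tab["event"].astype(int)
    return tab


def write_edge_table(edges: pd.DataFrame, path: str) -> None:
    edges.to_csv(path, sep="\t", index=False)


def read_edge_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_gmt(path: str) -> dict[str, set[str]]:
    """Parse a GMT gene-set collection: name <TAB> description <TAB> genes..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def write_gmt(sets: dict[str, set[str]], path: str, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *sorted(members)]) + "\n")


def write_dataset(outdir: str, data: ExpressionData, tab_pcg, tab_lnc,
                  seeds, survival, truth) -> None:
    """Emit the full synthetic dataset bundle into a directory."""
    os.makedirs(outdir, exist_ok=True)
    write_expression(data, os.path.join(outdir, "expression.tsv"),
                     os.path.join(outdir, "samples.tsv"))
    write_interactions(tab_pcg, os.path.join(outdir, "mirna_pcg.tsv"))
    write_interactions(tab_lnc, os.path.join(outdir, "mirna_lnc.tsv"))
    write_gene_list(sorted(seeds), os.path.join(outdir, "seeds.txt"))
    write_survival(survival, os.path.join(outdir, "survival.tsv"))
    truth.to_frame().to_csv(os.path.join(outdir, "truth.tsv"), sep="\t", index=False)
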