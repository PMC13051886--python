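"""Readers and writers for the pipeline's plain-text formats.

All tables are TSV.  Expression matrices are features x samples with the
sample annotations (sample, group, batch, donor) in a sidecar TSV.  Gene-set
collections use the standard GMT layout (name, description, members).
Single-cell counts travel as a MatrixMarket coordinate triplet with
barcodes.tsv / features.tsv sidecars.
"""

from __future__ import annotations

from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from mircell.diffexpr import DEResult, ExpressionMatrix
from mircell.enrich import FeatureSetCollection

__all__ = [
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "read_site_table",
    "write_site_table",
    "read_interaction_table",
    "write_interaction_table",
    "read_ct_table",
    "write_ct_table",
    "read_mtx",
    "write_mtx",
    "write_de_result",
    "write_enrichment",
    "write_site_rows",
    "write_network",
]

DE_COLUMNS = ["log2FC", "t", "p", "q", "adj_p", "mean_expr"]


def read_expression(values_path: str | Path, samples_path: str | Path) -> ExpressionMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    samples = pd.read_csv(samples_path, sep="\t", index_col=0)
    return ExpressionMatrix(values, samples)


def write_expression(
    m: ExpressionMatrix, values_path: str | Path, samples_path: str | Path
) -> None:
    m.values.to_csv(values_path, sep="\t")
    m.samples.to_csv(samples_path, sep="\t")


def read_gmt(path: str | Path) -> FeatureSetCollection:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            name, _desc, *members = parts
            sets[name] = [m for m in members if m]
    return FeatureSetCollection(sets=sets, source=str(path))


def write_gmt(sets: FeatureSetCollection, path: str | Path, description: str = "") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


def read_site_table(path: str | Path) -> pd.DataFrame:
    from mircell.siteact import validate_site_table

    return validate_site_table(pd.read_csv(path, sep="\t"))


def write_site_table(sites: pd.DataFrame, path: str | Path) -> None:
    sites.to_csv(path, sep="\t", index=False)


def read_interaction_table(path: str | Path) -> pd.DataFrame:
    from mircell.siteact import validate_interaction_table

    return validate_interaction_table(pd.read_csv(path, sep="\t"))


def write_interaction_table(inter: pd.DataFrame, path: str | Path) -> None:
    inter.to_csv(path, sep="\t", index=False)


def read_ct_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "group", "assay", "replicate", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    return df


def write_ct_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_mtx(prefix: str | Path) -> ad.AnnData:
    """Read matrix.mtx + barcodes.tsv + features.tsv written by :func:`write_mtx`."""
    prefix = Path(prefix)
    mat = spio.mmread(prefix / "matrix.mtx").tocsr()
    obs = pd.read_csv(prefix / "barcodes.tsv", sep="\t", index_col=0)
    var = pd.read_csv(prefix / "features.tsv", sep="\t", index_col=0)
    if "mito" in var.columns:
        var["mito"] = var["mito"].astype(bool)
    # matrix is stored genes x cells (features in rows)
    return ad.AnnData(X=np.asarray(mat.T.todense()), obs=obs, var=var)


def write_mtx(adata: ad.AnnData, prefix: str | Path) -> None:
    prefix = Path(prefix)
    prefix.mkdir(parents=True, exist_ok=True)
    X = adata.X
    if hasattr(X, "toarray"):
        X = X.toarray()
    spio.mmwrite(prefix / "matrix.mtx", sparse.coo_matrix(np.asarray(X).T))
    adata.obs.to_csv(prefix / "barcodes.tsv", sep="\t")
    adata.var.to_csv(prefix / "features.tsv", sep="\t")


def write_de_result(r: DEResult, path: str | Path) -> None:
    out = r.table[DE_COLUMNS].copy()
    out.index.name = "feature"
    out.to_csv(path, sep="\t")


def write_enrichment(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t")


def write_site_rows(rows: pd.DataFrame, path: str | Path, explode: bool = False) -> None:
    """Site-enrichment rows in a fixed column order; optionally one row per miRNA."""
    from mircell.siteact import explode_rows_per_mirna

    df = explode_rows_per_mirna(rows) if explode else rows.copy()
    if "mirnas" in df.columns:
        df["mirnas"] = df["mirnas"].map(",".join)
    order = [c for c in ("motif", "mirnas", "mirna", "estimated_activity",
                         "size", "overlap", "site_overlap", "log2_or",
                         "p", "adj_p", "direction") if c in df.columns]
    df[order].to_csv(path, sep="\t", index=False)


def write_network(g, edges_path: str | Path, graphml_path: str | Path | None = None) -> None:
    import networkx as nx

    rows = [
        {"mirna": u, "gene": v, **d}
        for u, v, d in g.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["mirna", "gene", "evidence", "source"]).to_csv(
        edges_path, sep="\t", index=False
    )
    if graphml_path is not None:
        h = g.copy()
        for _, d in h.nodes(data=True):
            if "pathways" in d:
                d["pathways"] = ";".join(d["pathways"])
        h.graph.pop("pathway_ora", None)
        nx.write_graphml(h, graphml_path)
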