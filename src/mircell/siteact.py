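"""Binding-site enrichment, miRNA activity inference, and target networks.

A miRNA leaves a footprint on the transcriptome through the 7-mer binding
motifs in its targets' 3'UTRs.  If a motif is overrepresented among
up-regulated genes, the owning miRNA's activity is inferred *Downregulated*
(its brake was released); overrepresentation among down-regulated genes
implies *Upregulated* activity.  Each motif x direction contingency table is
tested with the two-sided Fisher exact test (minimum-likelihood convention),
the sample odds ratio reported on the log2 scale with Haldane-Anscombe
correction for zero cells.  Inferred activities are then intersected with the
observed DE-miRNAs (keeping direction-concordant ones), and a bipartite
miRNA-target network is assembled from interaction evidence.
"""

from __future__ import annotations

import math
import warnings
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from mircell.diffexpr import DEResult, bh_adjust
from mircell.enrich import FeatureSetCollection, ora_hypergeometric

__all__ = [
    "validate_site_table",
    "validate_interaction_table",
    "filter_interactions_by_confidence",
    "site_enrichment",
    "intersect_influential",
    "build_network",
]

SITE_COLUMNS = ["motif", "mirna", "gene", "n_sites"]
INTERACTION_COLUMNS = ["mirna", "gene", "evidence", "source"]
DEFAULT_CONFIDENCE = frozenset({"very high", "high"})


def validate_site_table(sites: pd.DataFrame) -> pd.DataFrame:
    """Check the binding-site schema: 7-mer motifs, unique (motif,mirna,gene)."""
    missing = [c for c in SITE_COLUMNS if c not in sites.columns]
    if missing:
        raise ValueError(f"site table missing columns: {missing}")
    bad = sites["motif"].astype(str).map(
        lambda m: len(m) != 7 or set(m) - set("ACGU")
    )
    if bad.any():
        raise ValueError(
            f"motifs must be 7-mers over ACGU: {sites.loc[bad, 'motif'].head().tolist()}"
        )
    if (sites["n_sites"] < 1).any():
        raise ValueError("n_sites must be >= 1")
    if sites.duplicated(subset=["motif", "mirna", "gene"]).any():
        raise ValueError("(motif, mirna, gene) rows must be unique")
    return sites


def validate_interaction_table(inter: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in INTERACTION_COLUMNS if c not in inter.columns]
    if missing:
        raise ValueError(f"interaction table missing columns: {missing}")
    bad = set(inter["evidence"].unique()) - {"validated", "predicted"}
    if bad:
        raise ValueError(f"unknown evidence labels: {sorted(bad)}")
    if inter.duplicated(subset=["mirna", "gene", "source"]).any():
        raise ValueError("(mirna, gene, source) rows must be unique")
    return inter


def filter_interactions_by_confidence(
    inter: pd.DataFrame, keep: frozenset[str] | set[str] = DEFAULT_CONFIDENCE
) -> pd.DataFrame:
    """Keep validated edges plus predicted edges in the allowed confidence classes."""
    if "confidence" not in inter.columns:
        return inter
    mask = (inter["evidence"] == "validated") | inter["confidence"].isin(keep)
    return inter.loc[mask].reset_index(drop=True)


def _fisher_log2_or(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher p and log2 sample OR with +0.5 zero-cell correction."""
    p = float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
    if min(a, b, c, d) == 0:
        a2, b2, c2, d2 = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        a2, b2, c2, d2 = a, b, c, d
    return p, math.log2((a2 * d2) / (b2 * c2))


def site_enrichment(
    sites: pd.DataFrame,
    de_up: Sequence[str],
    de_down: Sequence[str],
    universe: Sequence[str],
    alpha: float = 0.05,
    return_all: bool = False,
) -> pd.DataFrame:
    """Fisher enrichment of every binding motif in up- and down-regulated genes.

    For each motif and each DE direction the 2x2 table is
    (a) DEGs of that direction bearing the motif, (b) other universe genes
    bearing it, (c) DEGs lacking it, (d) the rest.  Gene-level presence drives
    the table; ``site_overlap`` (total sites in the overlapping DEGs) is
    descriptive.  estimated_activity is *Downregulated* when the motif is
    enriched (OR > 1) among UP genes and *Upregulated* when enriched among
    DOWN genes.  BH adjustment runs across all motif x direction tests; rows
    with adjusted p < ``alpha`` are retained unless ``return_all``.
    """
    validate_site_table(sites)
    uni = list(dict.fromkeys(universe))
    if not uni:
        raise ValueError("empty gene universe")
    uni_set = set(uni)
    up_set, down_set = set(de_up), set(de_down)
    if up_set & down_set:
        raise ValueError(f"de_up and de_down overlap: {sorted(up_set & down_set)[:5]}")
    if not up_set <= uni_set or not down_set <= uni_set:
        raise ValueError("DE gene lists must be subsets of the universe")

    in_uni = sites[sites["gene"].isin(uni_set)]
    rows = []
    for motif, grp in in_uni.groupby("motif", sort=True):
        motif_genes = set(grp["gene"])
        mirnas = sorted(grp["mirna"].unique())
        size = len(motif_genes)
        for direction, de_set, activity in (
            ("up", up_set, "Downregulated"),
            ("down", down_set, "Upregulated"),
        ):
            if not de_set:
                continue
            a = len(motif_genes & de_set)
            b = size - a
            c = len(de_set) - a
            d = len(uni_set) - size - c
            p, log2_or = _fisher_log2_or(a, b, c, d)
            overlap_genes = motif_genes & de_set
            site_overlap = int(
                grp.loc[grp["gene"].isin(overlap_genes), "n_sites"].sum()
            )
            rows.append(
                {
                    "motif": motif,
                    "mirnas": mirnas,
                    "direction": direction,
                    "estimated_activity": activity,
                    "size": size,
                    "overlap": a,
                    "site_overlap": site_overlap,
                    "log2_or": log2_or,
                    "p": p,
                }
            )
    if not rows:
        return pd.DataFrame(
            columns=["motif", "mirnas", "direction", "estimated_activity",
                     "size", "overlap", "site_overlap", "log2_or", "p", "adj_p"]
        )
    out = pd.DataFrame(rows)
    out["adj_p"] = bh_adjust(out["p"].to_numpy())
    out = out.sort_values(["p", "motif"], kind="stable").reset_index(drop=True)
    if return_all:
        return out
    # significant enrichment means overrepresentation: OR > 1 as well
    keep = (out["adj_p"] < alpha) & (out["log2_or"] > 0)
    return out.loc[keep].reset_index(drop=True)


def intersect_influential(
    rows: pd.DataFrame, de_mirnas: Mapping[str, str]
) -> pd.DataFrame:
    """Keep motifs whose inferred activity matches an observed DE-miRNA.

    ``de_mirnas`` maps miRNA id to its DE direction ("Upregulated" /
    "Downregulated", or "up"/"down").  A row survives when at least one of its
    motif's miRNAs is DE in the same direction as the estimated activity; the
    miRNA list is pruned to the concordant members.
    """
    norm = {"up": "Upregulated", "down": "Downregulated"}
    de_dir = {m: norm.get(d, d) for m, d in de_mirnas.items()}
    bad = set(de_dir.values()) - {"Upregulated", "Downregulated"}
    if bad:
        raise ValueError(f"unknown DE directions: {sorted(bad)}")
    kept = []
    for _, row in rows.iterrows():
        concordant = [
            m for m in row["mirnas"] if de_dir.get(m) == row["estimated_activity"]
        ]
        if concordant:
            new = row.copy()
            new["mirnas"] = concordant
            kept.append(new)
    if not kept:
        return rows.iloc[0:0].copy()
    return pd.DataFrame(kept).reset_index(drop=True)


def build_network(
    influential: pd.DataFrame,
    interactions: pd.DataFrame,
    de_genes: DEResult,
    pathways: FeatureSetCollection | None = None,
    q_max: float = 0.1,
    min_abs_fc: float = 1.5,
    ora_alpha: float = 0.1,
    min_set_size: int = 1,
) -> nx.DiGraph:
    """Assemble the bipartite miRNA -> target network from interaction evidence.

    An edge is kept when its miRNA is influential (appears in the concordant
    intersection) and its gene is DE in the direction *opposite* the miRNA's
    inferred activity (a down-active miRNA releases its targets, so they go
    up).  Gene-side pathway membership is annotated by ORA with universe = all
    genes carrying at least one interaction.  The graph carries node
    attributes ``kind`` (mirna/gene), ``direction``, and per-gene ``pathways``.
    """
    validate_interaction_table(interactions)
    if interactions.empty:
        raise ValueError("interaction table is empty")
    from mircell.diffexpr import call_de

    mirna_activity: dict[str, str] = {}
    for _, row in influential.iterrows():
        for m in row["mirnas"]:
            mirna_activity[m] = row["estimated_activity"]

    calls = call_de(de_genes, q_max=q_max, min_abs_fc=min_abs_fc)
    gene_dir = {g: "up" for g in calls.up} | {g: "down" for g in calls.down}

    g = nx.DiGraph()
    for _, row in interactions.iterrows():
        mirna, gene = row["mirna"], row["gene"]
        activity = mirna_activity.get(mirna)
        if activity is None:
            continue
        wanted = "up" if activity == "Downregulated" else "down"
        if gene_dir.get(gene) != wanted:
            continue
        g.add_node(mirna, kind="mirna", direction=activity)
        g.add_node(gene, kind="gene", direction=gene_dir[gene])
        g.add_edge(mirna, gene, evidence=row["evidence"], source=row["source"])
    if g.number_of_edges() == 0:
        warnings.warn("regulatory network is empty")

    if pathways is not None and g.number_of_edges() > 0:
        universe = sorted(set(interactions["gene"]))
        net_genes = [n for n, d in g.nodes(data=True) if d["kind"] == "gene"]
        de_in_uni = [x for x in net_genes if x in set(universe)]
        ora = ora_hypergeometric(
            de_in_uni, universe, pathways, min_size=min_set_size
        )
        enriched = ora.index[ora["adj_p"] < ora_alpha].tolist()
        membership: dict[str, list[str]] = {x: [] for x in net_genes}
        for name in enriched:
            for gene in pathways.sets[name]:
                if gene in membership:
                    membership[gene].append(name)
        nx.set_node_attributes(g, membership, "pathways")
        g.graph["pathway_ora"] = ora
    return g


def extract_pathway_subnetwork(g: nx.DiGraph, pathway: str) -> nx.DiGraph:
    """Subgraph restricted to genes annotated with ``pathway`` (plus their miRNAs)."""
    genes = {
        n for n, d in g.nodes(data=True)
        if d.get("kind") == "gene" and pathway in d.get("pathways", [])
    }
    mirnas = {u for u, v in g.edges if v in genes}
    return g.subgraph(genes | mirnas).copy()


def explode_rows_per_mirna(rows: pd.DataFrame) -> pd.DataFrame:
    """One output row per (motif, miRNA) pair, mirroring a per-member table layout."""
    return rows.explode("mirnas").rename(columns={"mirnas": "mirna"}).reset_index(
        drop=True
    )
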