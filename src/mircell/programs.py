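"""Cell-program quantification: TF activity, AUC signature scoring, frequencies.

Transcription-factor activity is proxied per cell by the importance of each TF
in a regression-tree ensemble predicting the cell's gene-expression vector
from the gene x TF signed network-membership matrix.  Rare programs (Tc17,
CD8 Treg) are quantified per cell by the area under the signature-gene
recovery curve within the top-ranked fraction of the cell's expression
ranking; cells at or above a fixed threshold (CD8-Treg 0.17, Tc17 0.22) are
labeled positive, and per-donor positive fractions are compared between
groups with Welch's t-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from mircell import qpcr, scpipe
from mircell.enrich import FeatureSetCollection, ora_hypergeometric
from mircell.synthio import CD8_TREG_SIGNATURE, TC17_SIGNATURE  # noqa: F401

__all__ = [
    "CD8_TREG_SIGNATURE",
    "TC17_SIGNATURE",
    "TREG_AUC_THRESHOLD",
    "TC17_AUC_THRESHOLD",
    "tf_activity_mdt",
    "donor_mean_activity",
    "aucell_score",
    "classify_cells",
    "verify_signature_markers",
    "compare_frequencies",
]

TREG_AUC_THRESHOLD = 0.17
TC17_AUC_THRESHOLD = 0.22


@dataclass
class ActivityMatrix:
    """TF x cell importance scores (each cell's scores sum to 1)."""

    scores: pd.DataFrame  # TFs x cells
    degenerate_cells: list[str]
    params: dict


def tf_activity_mdt(
    adata: ad.AnnData,
    net: pd.DataFrame,
    n_trees: int = 100,
    max_depth: int = 3,
    seed: int = 0,
    min_targets: int = 5,
) -> ActivityMatrix:
    """TF activities from per-cell regression-tree ensembles.

    ``net`` has columns (tf, target, weight).  For each cell, an ensemble of
    regression trees predicts the cell's log expression across genes from the
    gene x TF signed-weight matrix (one predictor per TF, seeded bootstrap
    over genes); activity is each TF's total impurity-reduction importance,
    normalized to sum 1 per cell.  Cells with constant expression get uniform
    activities and are flagged degenerate.
    """
    for c in ("tf", "target", "weight"):
        if c not in net.columns:
            raise ValueError(f"network missing column {c!r}")
    if (net["weight"] == 0).any() or not np.isfinite(net["weight"]).all():
        raise ValueError("weights must be finite and nonzero")
    if net.duplicated(subset=["tf", "target"]).any():
        raise ValueError("(tf, target) pairs must be unique")
    gene_index = {g: i for i, g in enumerate(adata.var_names)}
    tfs = []
    cols = []
    for tf, sub in net.groupby("tf", sort=True):
        idx = [gene_index[t] for t in sub["target"] if t in gene_index]
        if len(idx) < min_targets:
            warnings.warn(f"TF {tf!r} has < {min_targets} targets in data; dropped")
            continue
        col = np.zeros(adata.n_vars)
        for t, w in zip(sub["target"], sub["weight"]):
            if t in gene_index:
                col[gene_index[t]] = w
        tfs.append(tf)
        cols.append(col)
    if len(tfs) < 2:
        raise ValueError("fewer than 2 TFs with sufficient targets")
    M = np.column_stack(cols)  # genes x TFs
    L = np.asarray(adata.layers["lognorm"])
    rng = np.random.default_rng(seed)
    scores = np.empty((len(tfs), adata.n_obs))
    degenerate = []
    for ci in range(adata.n_obs):
        y = L[ci]
        if np.ptp(y) == 0:
            scores[:, ci] = 1.0 / len(tfs)
            degenerate.append(adata.obs_names[ci])
            continue
        forest = RandomForestRegressor(
            n_estimators=n_trees,
            max_depth=max_depth,
            bootstrap=True,
            random_state=int(rng.integers(2**31 - 1)),
        )
        forest.fit(M, y)
        imp = forest.feature_importances_
        if imp.sum() <= 0:
            scores[:, ci] = 1.0 / len(tfs)
            degenerate.append(adata.obs_names[ci])
        else:
            scores[:, ci] = imp / imp.sum()
    return ActivityMatrix(
        scores=pd.DataFrame(scores, index=tfs, columns=adata.obs_names),
        degenerate_cells=degenerate,
        params={"n_trees": n_trees, "max_depth": max_depth, "seed": seed},
    )


def donor_mean_activity(
    activity: ActivityMatrix, meta: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-donor mean activity per TF, with Welch group tests.

    Returns (TF x donor means, per-TF test table).  P-values are deliberately
    not corrected for multiplicity (a ``multiple_testing`` note flags this);
    a Shapiro-Wilk screen per group is reported alongside.
    """
    donors = meta["donor"].astype(str)
    counts = donors.value_counts()
    empty = [d for d in counts.index if counts[d] == 0]
    if empty:
        warnings.warn(f"donors without cells excluded: {empty}")
    means = activity.scores.T.groupby(donors.values).mean().T
    group_of = meta.groupby(donors.values)["group"].first()
    if (group_of.value_counts() < 2).any():
        raise ValueError("need >= 2 donors per group")
    rows = []
    for tf in means.index:
        res = qpcr.group_test(means.loc[tf], group_of.loc[means.columns])
        rows.append({"tf": tf, **{k: v for k, v in res.items() if k != "shapiro_p"},
                     "shapiro_case_p": res["shapiro_p"]["case"],
                     "shapiro_control_p": res["shapiro_p"]["control"]})
    tests = pd.DataFrame(rows).set_index("tf")
    tests.attrs["multiple_testing"] = "uncorrected per-TF Welch tests"
    return means, tests


def aucell_score(
    adata: ad.AnnData,
    signature: Sequence[str],
    top_fraction: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-cell AUC of the signature-gene recovery curve.

    Genes are ranked per cell by descending raw count, ties broken by one
    seeded random permutation shared across cells (so zero-inflation does not
    bias the ranking deterministically).  The recovery curve counts signature
    genes among the top x ranks for x = 1..ceil(top_fraction * n_genes); the
    AUC is its area divided by the maximum achievable area (all signature
    genes at the very top).
    """
    if not 0 < top_fraction <= 0.5:
        raise ValueError("top_fraction must lie in (0, 0.5]")
    sig_idx = [adata.var_names.get_loc(g) for g in signature if g in adata.var_names]
    if not sig_idx:
        raise ValueError("no signature gene present in the dataset")
    X = scpipe._dense_counts(adata).astype(float)
    n_genes = adata.n_vars
    x_max = int(np.ceil(top_fraction * n_genes))
    rng = np.random.default_rng(seed)
    tiebreak = rng.permutation(n_genes) / (n_genes + 1.0)
    keyed = X + tiebreak[None, :]  # counts are integers; permutation breaks ties
    # rank positions: argsort descending per cell
    order = np.argsort(-keyed, axis=1, kind="stable")
    rank_of = np.empty_like(order)
    rows = np.arange(X.shape[0])[:, None]
    rank_of[rows, order] = np.arange(n_genes)[None, :]
    sig_ranks = rank_of[:, sig_idx]  # 0-based rank of each signature gene
    n_sig = len(sig_idx)
    # area under the step recovery curve over x = 1..x_max equals
    # sum over signature genes of max(0, x_max - rank) (gene at 0-based rank r
    # is counted in every window x > r)
    contrib = np.clip(x_max - sig_ranks, 0, None).sum(axis=1)
    xs = np.arange(1, x_max + 1)
    max_area = np.minimum(xs, n_sig).sum()
    auc = contrib / max_area
    return pd.DataFrame(
        {"auc": auc},
        index=adata.obs_names,
    )


def classify_cells(scores: pd.DataFrame, threshold: float) -> pd.Series:
    """Binary program label: AUC >= threshold (0 labels all, >1 labels none)."""
    return (scores["auc"] >= threshold).rename("positive")


def verify_signature_markers(
    adata: ad.AnnData,
    labels: pd.Series | np.ndarray,
    pathway_sets: FeatureSetCollection,
    top_n: int = 250,
    min_set_size: int = 1,
    adj_p_max: float = 0.1,
) -> pd.DataFrame:
    """ORA of the positive class's top marker genes against pathway sets.

    Markers are ranked by decreasing mean pairwise AUC (positive vs negative
    cells); the top ``top_n`` feed a hypergeometric ORA with universe = all
    scored genes; rows at BH-adjusted p < ``adj_p_max`` are returned.
    """
    lab = np.asarray(labels).astype(bool)
    n_pos = int(lab.sum())
    if n_pos < 5:
        raise ValueError("positive class has < 5 cells")
    if n_pos == lab.size:
        raise ValueError("negative class is empty")
    auc = scpipe.score_markers(adata, lab.astype(int))
    ranked = auc[1].sort_values(ascending=False)  # cluster "1" = positive class
    markers = ranked.index[:top_n].tolist()
    ora = ora_hypergeometric(
        markers, list(adata.var_names), pathway_sets, min_size=min_set_size
    )
    return ora[ora["adj_p"] < adj_p_max]


def compare_frequencies(
    labels: pd.Series | np.ndarray,
    meta: pd.DataFrame,
    min_cells: int = 10,
) -> tuple[pd.DataFrame, dict]:
    """Per-donor positive fractions and a Welch test between groups."""
    lab = pd.Series(np.asarray(labels).astype(bool), index=meta.index)
    rows = []
    for donor, sub in meta.groupby(meta["donor"].astype(str)):
        if len(sub) < min_cells:
            warnings.warn(f"donor {donor!r} excluded (< {min_cells} cells)")
            continue
        rows.append(
            {
                "donor": donor,
                "group": sub["group"].iloc[0],
                "n_cells": len(sub),
                "fraction": float(lab.loc[sub.index].mean()),
            }
        )
    fractions = pd.DataFrame(rows).set_index("donor")
    if (fractions["group"].value_counts() < 2).any():
        raise ValueError("need >= 2 donors per group")
    test = qpcr.group_test(fractions["fraction"], fractions["group"])
    return fractions, test
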