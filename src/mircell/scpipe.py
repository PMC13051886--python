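"""Single-cell stage: gating, QC, clustering, and pseudobulk NB-QL DE.

Cells arrive as an :class:`anndata.AnnData` of raw counts (cells x genes) with
``donor`` and ``group`` in ``.obs`` and a mitochondrial flag in ``.var``.  The
stage gates CD8 T cells (CD3G and one of CD8A/CD8B expressed), removes
low-quality cells by median-absolute-deviation filters, normalizes to the
median library size on the log2 scale, selects highly variable genes against
a loess mean-variance trend, optionally aligns batches with a simplified
mutual-nearest-neighbor correction in PCA space, clusters a Jaccard-weighted
shared-nearest-neighbor graph with Louvain, and tests pseudobulk (per-donor
summed) counts with a negative-binomial quasi-likelihood F-test after TMM
normalization.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import anndata as ad
import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors
from statsmodels.nonparametric.smoothers_lowess import lowess

from mircell.diffexpr import _fit_variance_prior, storey_qvalue

__all__ = [
    "Pseudobulk",
    "gate_cd8",
    "qc_filter",
    "normalize_log",
    "select_hvgs",
    "correct_batch",
    "snn_louvain",
    "label_transfer",
    "score_markers",
    "pseudobulk",
    "tmm_factors",
    "nb_ql_test",
]

GATING_GENES = ("CD3G", "CD8A", "CD8B")


def _dense_counts(adata: ad.AnnData) -> np.ndarray:
    X = adata.X
    if hasattr(X, "toarray"):
        X = X.toarray()
    return np.asarray(X)


def gate_cd8(adata: ad.AnnData) -> ad.AnnData:
    """Keep cells expressing CD3G together with at least one of CD8A/CD8B.

    "Expression" is any nonzero count; genes must be present in ``.var``.
    """
    missing = [g for g in GATING_GENES if g not in adata.var_names]
    if missing:
        raise ValueError(f"gating genes absent from dataset: {missing}")
    X = _dense_counts(adata)
    col = {g: adata.var_names.get_loc(g) for g in GATING_GENES}
    keep = (X[:, col["CD3G"]] > 0) & (
        (X[:, col["CD8A"]] > 0) | (X[:, col["CD8B"]] > 0)
    )
    out = adata[keep].copy()
    out.uns["gate_cd8"] = {"n_in": adata.n_obs, "n_kept": int(keep.sum())}
    return out


def qc_filter(adata: ad.AnnData, nmads: float = 3.0) -> ad.AnnData:
    """Remove low-quality cells by MAD rules on three QC metrics.

    A cell is flagged when log1p(total counts) or log1p(detected genes) falls
    more than ``nmads`` MADs below the median, or the mitochondrial percentage
    rises more than ``nmads`` MADs above it.
    """
    if "mito" not in adata.var.columns:
        raise ValueError("gene metadata must carry a 'mito' flag")
    X = _dense_counts(adata)
    total = X.sum(axis=1)
    detected = (X > 0).sum(axis=1)
    mito_pct = np.divide(
        X[:, adata.var["mito"].to_numpy(bool)].sum(axis=1),
        np.maximum(total, 1),
    ) * 100.0

    def _mad(metric: np.ndarray, med: float) -> float:
        mad = stats.median_abs_deviation(metric, scale="normal")
        # discrete metrics can give MAD = 0 in homogeneous data; floor the
        # spread at 5% of the median so no-variation never flags everything
        return max(mad, 0.05 * max(abs(med), 1.0))

    def _low(metric: np.ndarray) -> np.ndarray:
        med = np.median(metric)
        return metric < med - nmads * _mad(metric, med)

    def _high(metric: np.ndarray) -> np.ndarray:
        med = np.median(metric)
        return metric > med + nmads * _mad(metric, med)

    if math.isinf(nmads):
        flagged = np.zeros(adata.n_obs, dtype=bool)
        per_metric = {"low_total": 0, "low_detected": 0, "high_mito": 0}
    else:
        low_total = _low(np.log1p(total))
        low_det = _low(np.log1p(detected))
        high_mito = _high(mito_pct)
        flagged = low_total | low_det | high_mito
        per_metric = {
            "low_total": int(low_total.sum()),
            "low_detected": int(low_det.sum()),
            "high_mito": int(high_mito.sum()),
        }
    if (~flagged).sum() < 10:
        raise ValueError("fewer than 10 cells would remain after QC")
    out = adata[~flagged].copy()
    out.obs["total_counts"] = total[~flagged]
    out.obs["detected_genes"] = detected[~flagged]
    out.obs["mito_pct"] = mito_pct[~flagged]
    out.uns["qc_filter"] = {"n_in": adata.n_obs, "n_removed": int(flagged.sum()),
                            **per_metric}
    return out


def normalize_log(adata: ad.AnnData) -> ad.AnnData:
    """Library-size normalization to the median total, then log2(x + 1)."""
    X = _dense_counts(adata).astype(float)
    totals = X.sum(axis=1)
    if (totals <= 0).any():
        bad = adata.obs_names[totals <= 0].tolist()
        raise ValueError(f"cells with zero total counts (QC them out first): {bad[:5]}")
    target = float(np.median(totals))
    adata.layers["lognorm"] = np.log2(X * (target / totals)[:, None] + 1.0)
    return adata


def select_hvgs(adata: ad.AnnData, n: int = 5000) -> list[str]:
    """Top ``n`` genes by residual variance above a loess mean-variance trend.

    The trend is fit on per-gene (mean, variance) of the log layer; ties in
    the residuals are broken by gene id for determinism.
    """
    if "lognorm" not in adata.layers:
        raise ValueError("run normalize_log first")
    if n > adata.n_vars:
        raise ValueError(f"n={n} exceeds {adata.n_vars} genes")
    L = np.asarray(adata.layers["lognorm"])
    means = L.mean(axis=0)
    variances = L.var(axis=0, ddof=1)
    fitted = lowess(variances, means, frac=0.3, return_sorted=False)
    resid = variances - fitted
    order = sorted(
        range(adata.n_vars), key=lambda i: (-resid[i], adata.var_names[i])
    )
    return [adata.var_names[i] for i in order[:n]]


def correct_batch(
    adata: ad.AnnData,
    batch_key: str = "donor",
    hvgs: list[str] | None = None,
    n_pcs: int = 50,
    k: int = 20,
    seed: int = 0,
    sigma: float | None = None,
) -> np.ndarray:
    """Simplified mutual-nearest-neighbor batch alignment in PCA space.

    PCA is computed on the (HVG-restricted) log layer; batches are merged in
    decreasing-size order.  For each incoming batch, mutual k-nearest-neighbor
    cell pairs against the already-merged cells define per-pair difference
    vectors; every incoming cell is shifted by a Gaussian-kernel-smoothed
    average of those differences.  This captures the translation component of
    batch effects but none of the original algorithm's cosine normalization or
    per-gene corrections.
    """
    if "lognorm" not in adata.layers:
        raise ValueError("run normalize_log first")
    batches = adata.obs[batch_key].astype(str)
    L = np.asarray(adata.layers["lognorm"])
    if hvgs is not None:
        idx = [adata.var_names.get_loc(g) for g in hvgs]
        L = L[:, idx]
    n_pcs = min(n_pcs, min(L.shape) - 1)
    emb = PCA(n_components=n_pcs, random_state=seed).fit_transform(L)
    uniq = batches.value_counts().index.tolist()  # decreasing size
    if len(uniq) < 2:
        return emb
    for b in uniq:
        if (batches == b).sum() < k:
            raise ValueError(f"batch {b!r} has fewer than k={k} cells")
    merged_mask = (batches == uniq[0]).to_numpy()
    corrected = emb.copy()
    for b in uniq[1:]:
        inc_mask = (batches == b).to_numpy()
        ref = corrected[merged_mask]
        inc = corrected[inc_mask]
        nn_ref = NearestNeighbors(n_neighbors=min(k, len(ref))).fit(ref)
        nn_inc = NearestNeighbors(n_neighbors=min(k, len(inc))).fit(inc)
        _, ref_of_inc = nn_ref.kneighbors(inc)
        _, inc_of_ref = nn_inc.kneighbors(ref)
        pairs = []
        inc_nbrs = [set(row) for row in inc_of_ref]
        for i_inc, row in enumerate(ref_of_inc):
            for i_ref in row:
                if i_inc in inc_nbrs[i_ref]:
                    pairs.append((i_ref, i_inc))
        if pairs:
            pr = np.array([p[0] for p in pairs])
            pi = np.array([p[1] for p in pairs])
            diffs = ref[pr] - inc[pi]
            anchors = inc[pi]
            if sigma is None:
                d_nn, _ = nn_inc.kneighbors(inc)
                sigma_eff = float(np.mean(d_nn[:, -1])) or 1.0
            else:
                sigma_eff = sigma
            d2 = ((inc[:, None, :] - anchors[None, :, :]) ** 2).sum(axis=2)
            w = np.exp(-d2 / (2.0 * sigma_eff**2))
            w_sum = w.sum(axis=1, keepdims=True)
            # cells far from every anchor fall back to the mean difference
            far = w_sum[:, 0] <= 1e-12
            corr = np.where(
                far[:, None],
                diffs.mean(axis=0)[None, :],
                (w @ diffs) / np.maximum(w_sum, 1e-12),
            )
            corrected[inc_mask] = inc + corr
        merged_mask = merged_mask | inc_mask
    return corrected


def snn_louvain(
    embedding: np.ndarray,
    k: int = 5,
    seed: int = 0,
    resolution: float = 1.0,
) -> np.ndarray:
    """Louvain communities on a Jaccard-weighted shared-nearest-neighbor graph.

    Each cell's neighbor set is its k nearest by Euclidean distance in the
    embedding (self excluded); an edge joins two cells when either lists the
    other, weighted by the Jaccard index of their neighbor sets; zero-weight
    edges are dropped.  Labels 0..C-1 are ordered by descending cluster size.
    """
    emb = np.asarray(embedding, dtype=float)
    n = emb.shape[0]
    if k >= n:
        raise ValueError("k must be < number of cells")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(emb)
    _, idx = nn.kneighbors(emb)
    nbr = [set(row[1:]) for row in idx]
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in nbr[i]:
            if i < j:
                inter = len(nbr[i] & nbr[j])
                if inter:
                    union = len(nbr[i] | nbr[j])
                    g.add_edge(i, j, weight=inter / union)
            elif j < i and i not in nbr[j]:
                inter = len(nbr[i] & nbr[j])
                if inter:
                    union = len(nbr[i] | nbr[j])
                    g.add_edge(j, i, weight=inter / union)
    communities = nx.community.louvain_communities(
        g, weight="weight", resolution=resolution, seed=seed
    )
    communities = sorted(communities, key=lambda c: (-len(c), min(c)))
    labels = np.empty(n, dtype=int)
    for lab, cells in enumerate(communities):
        for c in cells:
            labels[c] = lab
    return labels


def label_transfer(
    adata: ad.AnnData,
    reference_profiles: pd.DataFrame,
    use_genes: list[str] | None = None,
    min_overlap: int = 50,
    score_floor: float = 0.0,
) -> pd.DataFrame:
    """Assign each cell the reference label with highest Spearman correlation.

    ``reference_profiles`` is genes x labels.  Correlation is computed over
    the intersection of ``use_genes`` (default: all genes) with the reference
    genes; ties in the argmax break by label order.  This is a deliberately
    simplified nearest-profile classifier without iterative fine-tuning.
    """
    if reference_profiles.shape[1] < 2:
        raise ValueError("need >= 2 reference labels")
    pool = adata.var_names if use_genes is None else pd.Index(use_genes)
    common = pool.intersection(reference_profiles.index)
    if len(common) < min_overlap:
        raise ValueError(
            f"gene overlap {len(common)} below required {min_overlap}"
        )
    L = np.asarray(adata.layers["lognorm"])
    sub = L[:, [adata.var_names.get_loc(g) for g in common]]
    ref = reference_profiles.loc[common]
    cell_ranks = stats.rankdata(sub, axis=1)
    ref_ranks = stats.rankdata(ref.to_numpy(), axis=0)
    cr = cell_ranks - cell_ranks.mean(axis=1, keepdims=True)
    rr = ref_ranks - ref_ranks.mean(axis=0, keepdims=True)
    denom = np.sqrt((cr**2).sum(axis=1))[:, None] * np.sqrt((rr**2).sum(axis=0))[None, :]
    with np.errstate(invalid="ignore"):
        corr = (cr @ rr) / np.where(denom > 0, denom, np.nan)
    corr = np.nan_to_num(corr, nan=-1.0)
    best = corr.argmax(axis=1)
    return pd.DataFrame(
        {
            "label": reference_profiles.columns[best],
            "score": corr[np.arange(corr.shape[0]), best],
            "low_confidence": corr.max(axis=1) < score_floor,
        },
        index=adata.obs_names,
    )


def score_markers(
    adata: ad.AnnData, labels: np.ndarray | pd.Series
) -> pd.DataFrame:
    """Mean pairwise AUC of each gene for each cluster vs every other cluster.

    The AUC is the Mann-Whitney U statistic divided by n1*n2 (ties count 0.5),
    i.e. the probability that a random cell of the cluster expresses the gene
    higher than a random cell of the comparison cluster; values are averaged
    over all comparisons.  Genes x clusters.
    """
    labels = np.asarray(labels)
    uniq = pd.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need >= 2 clusters")
    L = np.asarray(adata.layers["lognorm"])
    out = {}
    masks = {u: labels == u for u in uniq}
    for u in uniq:
        if masks[u].sum() == 0:
            raise ValueError(f"cluster {u!r} is empty")
    for u in uniq:
        aucs = []
        for v in uniq:
            if u == v:
                continue
            a, b = L[masks[u]], L[masks[v]]
            both = np.vstack([a, b])
            ranks = stats.rankdata(both, axis=0)
            n1, n2 = a.shape[0], b.shape[0]
            r1 = ranks[:n1].sum(axis=0)
            auc = (r1 - n1 * (n1 + 1) / 2.0) / (n1 * n2)
            aucs.append(auc)
        out[u] = np.mean(aucs, axis=0)
    return pd.DataFrame(out, index=adata.var_names)


# ---------------------------------------------------------------------------
# pseudobulk and NB quasi-likelihood DE


@dataclass
class Pseudobulk:
    """Per-donor summed counts with group labels and TMM factors."""

    counts: pd.DataFrame  # genes x donors
    groups: pd.Series  # donor -> case/control
    lib_sizes: pd.Series = field(init=False)
    factors: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        self.groups = self.groups.loc[self.counts.columns]
        self.lib_sizes = self.counts.sum(axis=0)


def pseudobulk(adata: ad.AnnData, min_cells: int = 10) -> Pseudobulk:
    """Sum raw counts per donor; donors with fewer than ``min_cells`` are dropped."""
    X = _dense_counts(adata)
    donors = adata.obs["donor"].astype(str)
    group_of = {}
    keep_cols = {}
    for donor, mask in donors.groupby(donors).groups.items():
        rows = donors.index.get_indexer(mask)
        grp = adata.obs.loc[mask, "group"].unique()
        if len(grp) > 1:
            raise ValueError(f"donor {donor!r} has mixed group labels: {list(grp)}")
        if len(rows) < min_cells:
            warnings.warn(f"donor {donor!r} dropped ({len(rows)} < {min_cells} cells)")
            continue
        keep_cols[donor] = X[rows].sum(axis=0)
        group_of[donor] = grp[0]
    if not keep_cols:
        raise ValueError("no donor passed the min_cells filter")
    counts = pd.DataFrame(keep_cols, index=adata.var_names)
    return Pseudobulk(counts=counts, groups=pd.Series(group_of))


def tmm_factors(
    pb: Pseudobulk, trim_m: float = 0.3, trim_a: float = 0.05
) -> pd.Series:
    """Trimmed-mean-of-M normalization factors, geometric mean 1.

    The reference column is the one whose 75th-percentile/library ratio is
    closest to the mean such ratio.  For each column, log2 ratios M (after
    depth normalization) are trimmed symmetrically by ``trim_m`` and average
    abundances A by ``trim_a``; the factor is 2 to the inverse-variance
    weighted mean of the surviving M values.
    """
    Y = pb.counts.to_numpy(dtype=float)
    if Y.shape[1] < 2:
        raise ValueError("need >= 2 columns")
    lib = Y.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("all-zero column in pseudobulk")
    f75 = np.quantile(Y, 0.75, axis=0) / lib
    ref = int(np.argmin(np.abs(f75 - f75.mean())))
    yr, nr = Y[:, ref], lib[ref]
    factors = np.ones(Y.shape[1])
    for j in range(Y.shape[1]):
        if j == ref:
            continue
        yj, nj = Y[:, j], lib[j]
        ok = (yj > 0) & (yr > 0)
        if ok.sum() == 0:
            continue
        pj, pr = yj[ok] / nj, yr[ok] / nr
        M = np.log2(pj / pr)
        A = 0.5 * np.log2(pj * pr)
        n_ok = ok.sum()
        lo_m, hi_m = np.floor(n_ok * trim_m), np.ceil(n_ok * (1 - trim_m))
        lo_a, hi_a = np.floor(n_ok * trim_a), np.ceil(n_ok * (1 - trim_a))
        rank_m = stats.rankdata(M)
        rank_a = stats.rankdata(A)
        keep = (rank_m >= lo_m + 1) & (rank_m <= hi_m) & \
               (rank_a >= lo_a + 1) & (rank_a <= hi_a)
        if keep.sum() == 0:
            continue
        w = (nj - yj[ok]) / (nj * yj[ok]) + (nr - yr[ok]) / (nr * yr[ok])
        inv_var = 1.0 / w[keep]
        factors[j] = 2.0 ** (np.sum(M[keep] * inv_var) / np.sum(inv_var))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=pb.counts.columns, name="tmm_factor")


def _nb_irls(
    Y: np.ndarray, X: np.ndarray, offset: np.ndarray, phi: np.ndarray,
    n_iter: int = 25, tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized NB GLM fit (log link) across genes.

    Y is genes x samples, X samples x p, offset samples (log scale), phi the
    per-gene dispersion.  Returns (beta genes x p, mu genes x samples).
    """
    G, n = Y.shape
    p = X.shape[1]
    init = np.log((Y + 0.5) / np.exp(offset)[None, :])
    beta, *_ = np.linalg.lstsq(X, init.T, rcond=None)
    beta = beta.T  # G x p
    phi_col = phi[:, None]
    for _ in range(n_iter):
        eta = beta @ X.T + offset[None, :]
        eta = np.clip(eta, -30.0, 30.0)
        mu = np.exp(eta)
        W = mu / (1.0 + phi_col * mu)
        z = (eta - offset[None, :]) + (Y - mu) / mu
        XtWX = np.einsum("gn,np,nq->gpq", W, X, X)
        XtWz = np.einsum("gn,np->gp", W * z, X)
        XtWX += 1e-10 * np.eye(p)[None, :, :]
        new = np.linalg.solve(XtWX, XtWz[..., None])[..., 0]
        delta = np.max(np.abs(new - beta))
        beta = new
        if delta < tol:
            break
    eta = np.clip(beta @ X.T + offset[None, :], -30.0, 30.0)
    return beta, np.exp(eta)


def _nb_deviance(Y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    phi_col = phi[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(Y > 0, Y * np.log(Y / mu), 0.0)
        term2 = (Y + 1.0 / phi_col) * np.log(
            (1.0 + phi_col * Y) / (1.0 + phi_col * mu)
        )
    return 2.0 * (term1 - term2).sum(axis=1)


def _nb_loglik(Y: np.ndarray, mu: np.ndarray, phi: float) -> np.ndarray:
    r = 1.0 / phi
    return (
        gammaln(Y + r) - gammaln(r) - gammaln(Y + 1.0)
        + r * np.log(r / (r + mu)) + Y * np.log(mu / (r + mu) + 1e-300)
    ).sum(axis=1)


def nb_ql_test(
    pb: Pseudobulk,
    min_cpm: float = 1.0,
    phi_grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Pseudobulk DE by negative-binomial GLM with a quasi-likelihood F-test.

    Genes below ``min_cpm`` counts-per-million in fewer than the smaller
    group's number of donors are filtered.  Per-gene NB dispersions are
    profiled on a grid and smoothed by a loess trend on abundance; the
    trended dispersion enters the GLM (offsets log(lib * TMM factor)).  The
    quasi-dispersion is the residual deviance over its df, shrunk by the same
    empirical-Bayes moment matching used for the moderated t; the QL F
    statistic is the one-df deviance drop over the shrunken quasi-dispersion,
    referred to an F distribution with augmented denominator df.  q is the
    Storey q-value.
    """
    groups = pb.groups
    sizes = groups.value_counts()
    if (sizes < 2).any():
        raise ValueError("each group needs >= 2 donors")
    if pb.factors is None:
        pb.factors = tmm_factors(pb)
    Y_all = pb.counts.to_numpy(dtype=float)
    lib = pb.lib_sizes.to_numpy(dtype=float)
    eff_lib = lib * pb.factors.loc[pb.counts.columns].to_numpy(float)
    cpm = Y_all / lib[None, :] * 1e6
    min_n = int(sizes.min())
    keep = (cpm >= min_cpm).sum(axis=1) >= min_n
    genes = pb.counts.index[keep]
    Y = Y_all[keep]
    if Y.shape[0] == 0:
        raise ValueError("no gene passed the expression filter")
    n = Y.shape[1]
    offset = np.log(eff_lib)
    is_case = (groups.loc[pb.counts.columns] == "case").to_numpy(float)
    X_full = np.column_stack([np.ones(n), is_case])
    X_null = np.ones((n, 1))
    df_resid = n - 2
    if df_resid < 1:
        raise ValueError("residual degrees of freedom < 1")

    if phi_grid is None:
        phi_grid = np.exp(np.linspace(np.log(1e-4), np.log(10.0), 19))
    loglik = np.empty((Y.shape[0], phi_grid.size))
    for gidx, phi in enumerate(phi_grid):
        phi_vec = np.full(Y.shape[0], phi)
        _, mu = _nb_irls(Y, X_full, offset, phi_vec)
        loglik[:, gidx] = _nb_loglik(Y, mu, phi)
    phi_hat = phi_grid[np.argmax(loglik, axis=1)]

    # loess trend of log dispersion on abundance; the trend enters the GLM
    abund = np.log2(Y.mean(axis=1) / np.exp(offset).mean() * 1e6 + 0.5)
    if np.ptp(abund) > 0:
        trend = lowess(np.log(phi_hat), abund, frac=0.5, return_sorted=False)
        phi_trend = np.exp(trend)
    else:
        phi_trend = np.full_like(phi_hat, np.exp(np.mean(np.log(phi_hat))))
    phi_trend = np.clip(phi_trend, 1e-6, None)

    beta_full, mu_full = _nb_irls(Y, X_full, offset, phi_trend)
    _, mu_null = _nb_irls(Y, X_null, offset, phi_trend)
    dev_full = _nb_deviance(Y, mu_full, phi_trend)
    dev_null = _nb_deviance(Y, mu_null, phi_trend)
    dev_drop = np.maximum(dev_null - dev_full, 0.0)

    s2 = np.maximum(dev_full / df_resid, 1e-10)
    d0, s0_sq = _fit_variance_prior(s2, float(df_resid))
    s2_shrunk = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
    df_total = min(d0 + df_resid, 1e6)
    F = dev_drop / s2_shrunk
    p = stats.f.sf(F, 1, df_total)
    q, _ = storey_qvalue(p)
    log2fc = beta_full[:, 1] / math.log(2.0)
    return pd.DataFrame(
        {
            "log2FC": log2fc,
            "phi": phi_hat,
            "phi_trend": phi_trend,
            "quasi_dispersion": s2,
            "F": F,
            "p": p,
            "q": q,
            "mean_cpm": Y.mean(axis=1) / np.exp(offset).mean() * 1e6,
        },
        index=genes,
    )
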