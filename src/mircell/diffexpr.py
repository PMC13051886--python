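"""Expression preprocessing and moderated differential expression.

Bulk expression arrives as normalized log2 intensity matrices (features in
rows, samples in columns).  The differential-expression core is the
empirical-Bayes moderated t-test: per-feature residual variances are shrunk
toward a common prior estimated by moment matching of log variances, and the
moderated statistic is referred to a t distribution with augmented degrees of
freedom.  Multiple testing is handled by Storey's q-value (pi0 estimated on a
lambda grid with a cubic smoother) and by Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionMatrix",
    "ModeratedTParams",
    "DEResult",
    "QValueModel",
    "filter_top_expressed",
    "quantile_normalize",
    "average_duplicate_features",
    "filter_low_intensity",
    "estimate_array_weights",
    "estimate_surrogate_variables",
    "moderated_t_test",
    "storey_qvalue",
    "bh_adjust",
    "classical_mds",
    "call_de",
]

_D0_CAP = 1e6  # prior df reported as finite; beyond this shrinkage is total


@dataclass
class ExpressionMatrix:
    """Log2 expression values (features x samples) with sample annotations.

    ``samples`` is indexed by sample id and must carry a ``group`` column with
    values ``case``/``control``; ``batch`` and ``donor`` columns are optional.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            raise ValueError("feature ids must be unique")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression values must be finite")
        missing = self.values.columns.difference(self.samples.index)
        if len(missing):
            raise ValueError(f"samples without annotation: {list(missing)}")
        self.samples = self.samples.loc[self.values.columns]

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def groups(self) -> pd.Series:
        return self.samples["group"]


@dataclass
class ModeratedTParams:
    """Empirical-Bayes variance-shrinkage parameters.

    d0 is the prior degrees of freedom (np.inf allowed as a flag, estimated
    values are capped and reported finite), s0_sq the prior variance, s_g_sq
    the per-feature residual variances with residual df d_g.
    """

    d0: float
    s0_sq: float
    s_g_sq: np.ndarray | None = None
    d_g: float | None = None

    def __post_init__(self) -> None:
        if self.d0 < 0:
            raise ValueError("d0 must be >= 0")
        if not self.s0_sq > 0 and self.d0 > 0:
            raise ValueError("s0_sq must be > 0")


@dataclass
class DEResult:
    """Per-feature differential-expression table plus fitted EB parameters.

    ``table`` is indexed by feature with columns log2FC, t, p, q, adj_p,
    mean_expr; q is the Storey q-value, adj_p the BH-adjusted p.
    """

    table: pd.DataFrame
    params: ModeratedTParams
    qvalue_model: "QValueModel | None" = None


@dataclass
class QValueModel:
    lambdas: np.ndarray
    pi0_lambda: np.ndarray
    pi0: float
    smoother: str = "cubic polynomial evaluated at max(lambda)"

    def __post_init__(self) -> None:
        if not (0 < self.pi0 <= 1):
            raise ValueError("pi0 must lie in (0, 1]")


# ---------------------------------------------------------------------------
# preprocessing


def filter_top_expressed(m: ExpressionMatrix, k: int) -> ExpressionMatrix:
    """Keep the ``k`` features with highest mean expression across samples.

    Ties are broken lexicographically on the feature id so the selection is
    deterministic.  Typical choices are k=400 (CD8 T cells, neutrophils) and
    k=500 (monocytes).
    """
    if not 1 <= k <= m.n_features:
        raise ValueError(f"k={k} out of range [1, {m.n_features}]")
    means = m.values.mean(axis=1)
    order = sorted(m.values.index, key=lambda f: (-means[f], f))
    keep = sorted(order[:k], key=list(m.values.index).index)
    return ExpressionMatrix(m.values.loc[keep], m.samples.copy())


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the common distribution of mean order statistics.

    Each column's sorted values are replaced by the row-wise mean of all
    sorted columns; tied values within a column receive the mean of the
    reference values their ranks span.
    """
    if m.n_samples < 2:
        raise ValueError("quantile normalization needs >= 2 samples")
    x = m.values.to_numpy(dtype=float)
    ref = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        col = x[:, j]
        order = np.argsort(col, kind="stable")
        ranks = np.empty_like(order)
        ranks[order] = np.arange(len(col))
        # average the reference over each tie run
        sorted_col = col[order]
        vals = ref.copy()
        start = 0
        for end in range(1, len(col) + 1):
            if end == len(col) or sorted_col[end] != sorted_col[start]:
                if end - start > 1:
                    vals[start:end] = ref[start:end].mean()
                start = end
        out[:, j] = vals[ranks]
    return ExpressionMatrix(
        pd.DataFrame(out, index=m.values.index, columns=m.values.columns),
        m.samples.copy(),
    )


def average_duplicate_features(
    m: ExpressionMatrix, mapping: Mapping[str, str]
) -> ExpressionMatrix:
    """Collapse probes to genes by arithmetic mean of each gene's probe rows."""
    if not mapping:
        raise ValueError("empty probe-to-gene mapping")
    missing = [f for f in m.values.index if f not in mapping]
    if missing:
        raise ValueError(f"mapping does not cover probes: {missing[:5]}")
    genes = pd.Series({f: mapping[f] for f in m.values.index}, name="gene")
    collapsed = m.values.groupby(genes).mean()
    return ExpressionMatrix(collapsed, m.samples.copy())


def filter_low_intensity(m: ExpressionMatrix, threshold: float) -> ExpressionMatrix:
    """Drop features whose median intensity across samples is below threshold.

    The boundary is inclusive: a median exactly at the threshold is kept.
    """
    if not np.isfinite(threshold) and threshold > 0:
        raise ValueError("threshold must be finite or -inf")
    keep = m.values.median(axis=1) >= threshold
    if not keep.any():
        raise ValueError("intensity filter removed all features")
    return ExpressionMatrix(m.values.loc[keep], m.samples.copy())


# ---------------------------------------------------------------------------
# design helpers


def _design_matrix(
    m: ExpressionMatrix, covariates: pd.DataFrame | None = None
) -> tuple[np.ndarray, list[str]]:
    """Intercept + case indicator (+ optional sample-level covariates)."""
    groups = m.groups()
    bad = set(groups.unique()) - {"case", "control"}
    if bad:
        raise ValueError(f"unknown group labels: {sorted(bad)}")
    cols = [np.ones(m.n_samples), (groups == "case").to_numpy(float)]
    names = ["intercept", "group_case"]
    if covariates is not None and covariates.shape[1] > 0:
        cov = covariates.loc[m.values.columns]
        for c in cov.columns:
            cols.append(cov[c].to_numpy(float))
            names.append(str(c))
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # name the offending columns for the error message
        r = np.linalg.qr(X, mode="r")
        dep = [names[i] for i in range(X.shape[1]) if abs(r[i, i]) < 1e-10]
        raise ValueError(f"singular design; collinear columns: {dep}")
    return X, names


def estimate_array_weights(
    m: ExpressionMatrix, covariates: pd.DataFrame | None = None
) -> pd.Series:
    """Per-array quality weights from an unweighted first-pass fit.

    weight_j is proportional to the inverse of array j's mean squared residual
    and normalized to mean 1.  This is a simplified heuristic, not the
    gene-by-gene REML of the original array-weights estimator.
    """
    X, _ = _design_matrix(m, covariates)
    Y = m.values.to_numpy(dtype=float)
    H = X @ linalg.pinv(X)
    R = Y - Y @ H.T
    msr = (R**2).mean(axis=0)
    w = 1.0 / np.maximum(msr, 1e-12)
    w = w / w.mean()
    return pd.Series(w, index=m.values.columns, name="weight")


def estimate_surrogate_variables(
    m: ExpressionMatrix,
    n_sv: int | str = "auto",
    seed: int | None = None,
    n_perm: int = 20,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Surrogate sample-level covariates from the residual matrix.

    The primary design (intercept + group) is regressed out; the right singular
    vectors of the residual matrix are candidate surrogates, orthogonal to the
    fitted group-mean structure by construction.  With ``n_sv="auto"`` the
    number kept is chosen parallel-analysis style: leading singular values must
    exceed the 95th percentile of singular values from ``n_perm`` row-permuted
    residual matrices.
    """
    if m.n_samples < 4:
        raise ValueError("need >= 4 samples to estimate surrogate variables")
    X, _ = _design_matrix(m, covariates)
    max_sv = m.n_samples - np.linalg.matrix_rank(X)
    if isinstance(n_sv, int) and n_sv >= max_sv + 1:
        raise ValueError(f"n_sv={n_sv} too large for {m.n_samples} samples")
    Y = m.values.to_numpy(dtype=float)
    H = X @ linalg.pinv(X)
    R = Y - Y @ H.T
    _, s, vt = np.linalg.svd(R, full_matrices=False)
    if n_sv == "auto":
        rng = np.random.default_rng(seed)
        null_s = np.empty((n_perm, len(s)))
        p_dim = np.linalg.matrix_rank(X)
        # permuting within rows destroys shared column structure; the second
        # residualization restores the observed matrix's rank deficiency, and
        # the rescaling compensates the variance that projection removes
        scale = math.sqrt(m.n_samples / (m.n_samples - p_dim))
        for b in range(n_perm):
            Rp = rng.permuted(R, axis=1)
            Rp = (Rp - Rp @ H.T) * scale
            null_s[b] = np.linalg.svd(Rp, compute_uv=False)
        thresh = np.percentile(null_s, 95, axis=0)
        k = 0
        while k < max_sv and s[k] > thresh[k]:
            k += 1
        n_sv = k
    n_sv = int(n_sv)
    sv = vt[:n_sv].T
    return pd.DataFrame(
        sv, index=m.values.columns, columns=[f"SV{i+1}" for i in range(n_sv)]
    )


# ---------------------------------------------------------------------------
# moderated t


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton on the log scale)."""
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(polygamma(2, y))
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return y


def _fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match (d0, s0^2) on log residual variances.

    Uses the scaled-F model for sample variances: log s2 has mean
    log s0^2 + digamma(df/2) - log(df/2) - digamma(d0/2) + log(d0/2) and excess
    variance trigamma(d0/2) beyond the trigamma(df/2) sampling term.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 1e-300
    z = np.log(np.where(ok, s2, 1e-300))
    e = z - digamma(df / 2.0) + math.log(df / 2.0)
    e_mean = e.mean()
    e_var = e.var(ddof=1) - float(polygamma(1, df / 2.0))
    if e_var > 0:
        d0 = 2.0 * _trigamma_inverse(e_var)
        if d0 > _D0_CAP:
            d0 = _D0_CAP
        s0_sq = math.exp(e_mean + float(digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    else:
        d0 = _D0_CAP
        s0_sq = math.exp(e_mean)
    return d0, s0_sq


def moderated_t_test(
    m: ExpressionMatrix,
    covariates: pd.DataFrame | None = None,
    weights: pd.Series | None = None,
    params: ModeratedTParams | None = None,
) -> DEResult:
    """Empirical-Bayes moderated t-test of case vs control.

    Per feature, log2 expression is regressed on intercept + group indicator
    (+ covariates), optionally with per-array observation weights.  Residual
    variances s_g^2 with df d_g are shrunk to

        s~_g^2 = (d0 s0^2 + d_g s_g^2) / (d0 + d_g)

    with the prior (d0, s0^2) estimated by moment matching of log variances
    unless ``params`` is supplied (d0=0 reproduces the classical t exactly;
    d0=inf pools all features to s0^2).  The moderated statistic is referred to
    a t distribution on d0 + d_g df.  log2FC is the case-vs-control
    coefficient; q is the Storey q-value, adj_p the BH adjustment.
    """
    X, _ = _design_matrix(m, covariates)
    n, p_dim = X.shape
    d_g = n - p_dim
    if d_g < 1:
        raise ValueError("residual degrees of freedom < 1")
    Y = m.values.to_numpy(dtype=float)
    if weights is not None:
        w = weights.loc[m.values.columns].to_numpy(float)
        if (w <= 0).any():
            raise ValueError("weights must be positive")
    else:
        w = np.ones(n)
    XtWX = X.T @ (X * w[:, None])
    XtWX_inv = linalg.inv(XtWX)
    A = XtWX_inv @ X.T * w[None, :]
    B = Y @ A.T  # features x p
    R = Y - B @ X.T
    s2 = (R**2 * w[None, :]).sum(axis=1) / d_g
    coef = B[:, 1]  # group_case column
    v_gg = XtWX_inv[1, 1]

    if params is None:
        d0, s0_sq = _fit_variance_prior(s2, float(d_g))
        params = ModeratedTParams(d0=d0, s0_sq=s0_sq, s_g_sq=s2, d_g=float(d_g))
    else:
        params = ModeratedTParams(
            d0=params.d0, s0_sq=params.s0_sq, s_g_sq=s2, d_g=float(d_g)
        )
    d0 = params.d0
    if math.isinf(d0):
        s2_tilde = np.full_like(s2, params.s0_sq)
        df_total = np.inf
    elif d0 == 0:
        s2_tilde = s2
        df_total = float(d_g)
    else:
        s2_tilde = (d0 * params.s0_sq + d_g * s2) / (d0 + d_g)
        df_total = d0 + d_g
    with np.errstate(divide="ignore", invalid="ignore"):
        t = coef / np.sqrt(s2_tilde * v_gg)
    t = np.where(np.isfinite(t), t, 0.0)
    if math.isinf(df_total):
        pvals = 2.0 * stats.norm.sf(np.abs(t))
    else:
        pvals = 2.0 * stats.t.sf(np.abs(t), df=min(df_total, _D0_CAP))
    q, qmodel = storey_qvalue(pvals)
    table = pd.DataFrame(
        {
            "log2FC": coef,
            "t": t,
            "p": pvals,
            "q": q,
            "adj_p": bh_adjust(pvals),
            "mean_expr": Y.mean(axis=1),
        },
        index=m.values.index,
    )
    return DEResult(table=table, params=params, qvalue_model=qmodel)


# ---------------------------------------------------------------------------
# multiple testing


def storey_qvalue(
    p: Sequence[float], pi0: float | None = None
) -> tuple[np.ndarray, QValueModel]:
    """Storey q-values with smoothed pi0 estimation.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) is computed on the grid
    0.05, 0.10, ..., 0.95; a cubic polynomial fit evaluated at the largest
    lambda gives the estimate, clipped to (0, 1].  Fixing ``pi0=1`` reproduces
    Benjamini-Hochberg exactly.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    lambdas = np.arange(0.05, 0.951, 0.05)
    m_tests = p.size
    pi0_lambda = np.array(
        [(p > lam).sum() / (m_tests * (1.0 - lam)) for lam in lambdas]
    )
    if pi0 is None:
        coeffs = np.polyfit(lambdas, pi0_lambda, deg=3)
        pi0_hat = float(np.polyval(coeffs, lambdas.max()))
        pi0_hat = min(pi0_hat, 1.0)
        if pi0_hat <= 0:
            positive = pi0_lambda[pi0_lambda > 0]
            pi0_hat = float(positive.min()) if positive.size else 1.0
            pi0_hat = min(pi0_hat, 1.0)
    else:
        if not 0 < pi0 <= 1:
            raise ValueError("pi0 must lie in (0, 1]")
        pi0_hat = float(pi0)
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, m_tests + 1)
    q_sorted = pi0_hat * p[order] * m_tests / ranks
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m_tests)
    q[order] = q_sorted
    model = QValueModel(lambdas=lambdas, pi0_lambda=pi0_lambda, pi0=pi0_hat)
    return q, model


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# MDS and DE calling


def classical_mds(
    m: ExpressionMatrix, dims: int = 2, top_features: int = 500
) -> pd.DataFrame:
    """Torgerson classical scaling of pairwise expression distances.

    The distance between two samples is the root-mean-square of their
    ``top_features`` largest absolute log-expression differences (recomputed
    per pair).  Axes are ordered by descending eigenvalue; each axis's sign is
    fixed so its largest-|loading| sample is positive.
    """
    if dims >= m.n_samples:
        raise ValueError("dims must be < n_samples")
    Y = m.values.to_numpy(dtype=float)
    n = m.n_samples
    k = min(top_features, Y.shape[0])
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            diff = np.abs(Y[:, i] - Y[:, j])
            top = np.partition(diff, len(diff) - k)[len(diff) - k :]
            D[i, j] = D[j, i] = math.sqrt(float((top**2).mean()))
    J = np.eye(n) - np.ones((n, n)) / n
    Bmat = -0.5 * J @ (D**2) @ J
    evals, evecs = np.linalg.eigh(Bmat)
    order = np.argsort(evals)[::-1][:dims]
    lam = np.clip(evals[order], 0.0, None)
    coords = evecs[:, order] * np.sqrt(lam)[None, :]
    for a in range(dims):
        imax = np.argmax(np.abs(coords[:, a]))
        if coords[imax, a] < 0:
            coords[:, a] = -coords[:, a]
    return pd.DataFrame(
        coords, index=m.values.columns, columns=[f"dim{i+1}" for i in range(dims)]
    )


@dataclass
class DECall:
    up: list = field(default_factory=list)
    down: list = field(default_factory=list)

    @property
    def features(self) -> list:
        return self.up + self.down


def call_de(r: DEResult, q_max: float = 0.1, min_abs_fc: float = 1.5) -> DECall:
    """Call DE features at q < q_max and |linear fold change| > min_abs_fc.

    Both thresholds are strict; min_abs_fc is on the linear scale (1.5 means
    |log2FC| > log2 1.5).
    """
    if q_max <= 0 or min_abs_fc < 1:
        raise ValueError("invalid thresholds")
    lfc_min = math.log2(min_abs_fc)
    t = r.table
    sig = (t["q"] < q_max) & (t["log2FC"].abs() > lfc_min)
    up = t.index[sig & (t["log2FC"] > 0)].tolist()
    down = t.index[sig & (t["log2FC"] < 0)].tolist()
    return DECall(up=up, down=down)
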