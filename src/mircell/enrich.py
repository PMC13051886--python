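"""Set-level statistics: ORA, directional z-scores, and preranked GSEA.

Overrepresentation analysis uses the hypergeometric upper tail against an
explicit universe.  The directional z-score (u - d) / sqrt(n) summarizes how
one-sided a category's differential-expression signal is, where u and d are
the up- and down-regulated members and n the category size.  Preranked GSEA
implements the classical weighted running-sum statistic with feature-label
permutation and sign-matched normalization.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from mircell.diffexpr import DEResult, bh_adjust

__all__ = [
    "FeatureSetCollection",
    "GSEAResult",
    "ora_hypergeometric",
    "enrichment_zscore",
    "gsea_preranked",
    "rank_by_signed_logp",
]


@dataclass
class FeatureSetCollection:
    """Named, non-empty sets of feature ids (miRNA categories or gene sets)."""

    sets: dict[str, list[str]]
    source: str | None = None

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"set {name!r} is empty")
        # preserve insertion order but drop duplicate members
        self.sets = {n: list(dict.fromkeys(m)) for n, m in self.sets.items()}

    def __len__(self) -> int:
        return len(self.sets)

    def items(self):
        return self.sets.items()


@dataclass
class GSEAResult:
    """Per-set enrichment scores with permutation significance."""

    table: pd.DataFrame  # index set name: ES, NES, p, adj_p, size
    leading_edge: dict[str, list[str]] = field(default_factory=dict)
    params: dict = field(default_factory=dict)


def ora_hypergeometric(
    de: Sequence[str],
    universe: Sequence[str],
    sets: FeatureSetCollection,
    min_size: int = 8,
    de_up: Sequence[str] | None = None,
    de_down: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Hypergeometric overrepresentation of a DE list in each feature set.

    Sets with fewer than ``min_size`` members in the universe are dropped.
    p = P(X >= overlap) for X ~ Hypergeom(N=|universe|, K=|set in universe|,
    n=|de|); BH adjustment across retained sets; rows sorted by p.  If up/down
    sub-lists are given, each row carries u, d and the directional z-score.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    uni = set(universe)
    offenders = [f for f in de if f not in uni]
    if offenders:
        raise ValueError(f"DE features outside the universe: {offenders[:10]}")
    de_set = set(de)
    up_set = set(de_up) if de_up is not None else set()
    down_set = set(de_down) if de_down is not None else set()
    rows = []
    for name, members in sets.items():
        in_uni = [f for f in members if f in uni]
        n = len(in_uni)
        if n < min_size:
            continue
        overlap = sum(1 for f in in_uni if f in de_set)
        p = float(stats.hypergeom.sf(overlap - 1, len(uni), n, len(de_set)))
        u = sum(1 for f in in_uni if f in up_set)
        d = sum(1 for f in in_uni if f in down_set)
        z = enrichment_zscore(u, d, n) if n > 0 else np.nan
        rows.append(
            {"set": name, "n": n, "overlap": overlap, "u": u, "d": d,
             "z": z, "p": min(p, 1.0)}
        )
    if not rows:
        return pd.DataFrame(
            columns=["set", "n", "overlap", "u", "d", "z", "p", "adj_p"]
        ).set_index("set")
    out = pd.DataFrame(rows).set_index("set")
    out["adj_p"] = bh_adjust(out["p"].to_numpy())
    return out.sort_values("p", kind="stable")


def enrichment_zscore(u: int, d: int, n: int) -> float:
    """Directional enrichment z-score (u - d) / sqrt(n).

    u and d are the up- and down-regulated DE members of the category and n
    its total size; the sign follows the dominant direction.
    """
    if n <= 0:
        raise ValueError("category size n must be > 0")
    if u < 0 or d < 0 or max(u, d) > n:
        raise ValueError("need 0 <= u, d <= n")
    return (u - d) / math.sqrt(n)


def _running_sum_es(
    stat_sorted: np.ndarray, hit_mask: np.ndarray, p_w: float
) -> tuple[float, int]:
    """ES of a ranked list: signed extremum of the weighted running sum.

    Returns (ES, index of the extremum in the ranked list).
    """
    n = stat_sorted.size
    n_hit = int(hit_mask.sum())
    if n_hit == 0 or n_hit == n:
        raise ValueError("set must hit a strict, non-empty subset of features")
    w = np.abs(stat_sorted) ** p_w
    nr = w[hit_mask].sum()
    if nr == 0:
        # all member stats are exactly zero: fall back to equal hit weights
        inc = np.where(hit_mask, 1.0 / n_hit, 0.0)
    else:
        inc = np.where(hit_mask, w / nr, 0.0)
    dec = np.where(hit_mask, 0.0, 1.0 / (n - n_hit))
    running = np.cumsum(inc - dec)
    i_max = int(np.argmax(running))
    i_min = int(np.argmin(running))
    # an exact |extremum| tie resolves to the positive excursion
    if running[i_max] >= -running[i_min]:
        return float(running[i_max]), i_max
    return float(running[i_min]), i_min


def gsea_preranked(
    stats_map: Mapping[str, float] | pd.Series,
    sets: FeatureSetCollection,
    p_w: float = 1.0,
    n_perm: int = 1000,
    seed: int | None = None,
) -> GSEAResult:
    """Preranked GSEA with feature-label permutation.

    Features are ranked by the statistic in descending order (ties broken by
    feature id).  The running sum adds |stat|^p_w / N_R at set members and
    subtracts 1/(N - |S|) elsewhere; ES is the signed extremum.  The null is
    built by permuting feature labels ``n_perm`` times; NES = ES divided by
    the mean |null ES| of matching sign, and p is the (add-one smoothed)
    fraction of same-sign null ES at least as extreme.  BH across sets.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    s = pd.Series(stats_map, dtype=float)
    if not s.index.is_unique:
        raise ValueError("feature ids in the ranking must be unique")
    order = sorted(s.index, key=lambda f: (-s[f], f))
    ranked_ids = np.array(order)
    stat_sorted = s.loc[order].to_numpy()
    n = stat_sorted.size
    id_pos = {f: i for i, f in enumerate(ranked_ids)}
    rng = np.random.default_rng(seed)

    rows, leading = [], {}
    for name, members in sets.items():
        pos = sorted(id_pos[f] for f in members if f in id_pos)
        if not pos:
            warnings.warn(f"set {name!r} has no member in the ranking; skipped")
            continue
        if len(pos) == n:
            raise ValueError(f"set {name!r} covers every ranked feature")
        hit = np.zeros(n, dtype=bool)
        hit[pos] = True
        es, i_ext = _running_sum_es(stat_sorted, hit, p_w)
        if es >= 0:
            lead = [f for f in ranked_ids[: i_ext + 1] if hit[id_pos[f]]]
        else:
            lead = [f for f in ranked_ids[i_ext:] if hit[id_pos[f]]]
        # permutation null: shuffle which ranks are hits
        k = len(pos)
        null_es = np.empty(n_perm)
        for b in range(n_perm):
            perm_hit = np.zeros(n, dtype=bool)
            perm_hit[rng.choice(n, size=k, replace=False)] = True
            null_es[b], _ = _running_sum_es(stat_sorted, perm_hit, p_w)
        same_sign = null_es[np.sign(null_es) == np.sign(es)] if es != 0 else null_es
        if same_sign.size:
            denom = float(np.abs(same_sign).mean())
            nes = es / denom if denom > 0 else 0.0
            p = (1.0 + float((np.abs(same_sign) >= abs(es)).sum())) / (
                1.0 + same_sign.size
            )
        else:
            nes, p = 0.0, 1.0 / (1.0 + n_perm)
        rows.append({"set": name, "ES": es, "NES": nes, "p": p, "size": k})
        leading[name] = lead
    if not rows:
        table = pd.DataFrame(columns=["ES", "NES", "p", "adj_p", "size"])
    else:
        table = pd.DataFrame(rows).set_index("set")
        table["adj_p"] = bh_adjust(table["p"].to_numpy())
        table = table[["ES", "NES", "p", "adj_p", "size"]]
    return GSEAResult(
        table=table,
        leading_edge=leading,
        params={"p_w": p_w, "n_perm": n_perm, "seed": seed},
    )


def rank_by_signed_logp(r: DEResult) -> pd.Series:
    """Ranking statistic -log10(p) * sign(log2FC); p clamped at 1e-300."""
    t = r.table
    p = np.clip(t["p"].to_numpy(dtype=float), 1e-300, 1.0)
    score = -np.log10(p) * np.sign(t["log2FC"].to_numpy(dtype=float))
    return pd.Series(score, index=t.index, name="signed_logp")
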