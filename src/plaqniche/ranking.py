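"""Gene ranking by signed probabilistic fold change (PFC) and derived tools.

PFC = (-log10 adjusted p) * log2 fold change combines significance and
effect direction into one signed score. On top of it sit percentile-rank
combination across comparisons, divergence ranking between contrasts,
preranked gene-set enrichment (weighted Kolmogorov-Smirnov running sum
with a gene-permutation null), and covariate-adjusted Spearman
correlation for clinical associations.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .diffexp import bh_adjust
from .synthgen import as_rng

__all__ = [
    "signed_pfc",
    "percentile_ranks",
    "percentile_combine",
    "divergence_rank",
    "preranked_enrichment",
    "adjusted_spearman",
]

ADJ_P_FLOOR = 1e-300


def signed_pfc(adj_p, lfc):
    """Signed probabilistic fold change: (-log10 adj p) * log2 FC.

    Adjusted p-values are floored at 1e-300 before logging (zeros warn);
    the log base only scales the values — rankings are base-invariant.
    """
    adj_p = np.asarray(adj_p, dtype=float)
    lfc = np.asarray(lfc, dtype=float)
    if np.any(adj_p == 0):
        warnings.warn("adjusted p of 0 floored at 1e-300")
    pf = np.clip(adj_p, ADJ_P_FLOOR, 1.0)
    out = -np.log10(pf) * lfc
    if out.ndim == 0:
        return float(out)
    return out


def percentile_ranks(scores: pd.Series) -> pd.Series:
    """Percentile of each score within the table: 100 * ascending rank / n.

    Ties share the average rank, so tied scores share percentiles.
    """
    r = scores.rank(method="average", ascending=True)
    return 100.0 * r / len(scores)


def _pfc_table(tab: pd.DataFrame) -> pd.Series:
    if "pfc" in tab.columns:
        return tab["pfc"].astype(float)
    return pd.Series(signed_pfc(tab["adj_p"], tab["lfc"]), index=tab.index, name="pfc")


def percentile_combine(a: pd.DataFrame, b: pd.DataFrame, top_n: int = 10) -> pd.DataFrame:
    """Average the two PFC percentile ranks over the shared genes.

    Each table is a DE result (indexed by gene, with adj_p/lfc or a
    precomputed 'pfc' column). Genes are restricted to the intersection,
    percentiles computed within each table, and the mean percentile is the
    combined response score; the ``top_n`` genes by combined score are
    returned in descending order.
    """
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        raise ValueError("tables share no genes")
    pa = percentile_ranks(_pfc_table(a.loc[shared]))
    pb = percentile_ranks(_pfc_table(b.loc[shared]))
    out = pd.DataFrame(
        {"percentile_a": pa, "percentile_b": pb, "combined": (pa + pb) / 2.0}
    )
    return out.sort_values("combined", ascending=False).head(top_n)


def divergence_rank(a: pd.DataFrame, b: pd.DataFrame, top_n: int = 10) -> pd.DataFrame:
    """Rank shared genes by PFC divergence between two contrasts.

    The divergence score is pfc_a - pfc_b; genes are ordered by |score|,
    with opposite-sign PFC pairs ranked above same-sign pairs of equal
    |score|.
    """
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        raise ValueError("tables share no genes")
    pa = _pfc_table(a.loc[shared])
    pb = _pfc_table(b.loc[shared])
    score = pa - pb
    opposite = np.sign(pa) * np.sign(pb) < 0
    out = pd.DataFrame(
        {"pfc_a": pa, "pfc_b": pb, "divergence": score, "opposite_sign": opposite}
    )
    # two-key sort: |divergence| desc, opposite-sign pairs first on ties
    out["_abs"] = out["divergence"].abs()
    out = out.sort_values(["_abs", "opposite_sign"], ascending=[False, False])
    return out.drop(columns="_abs").head(top_n)


def enrichment_score(ranks: pd.Series, gene_set, weight: float = 1.0):
    """Weighted KS running-sum enrichment score for one gene set.

    Genes are ordered by descending score; set members step the running
    sum up by |score|^weight (normalized over the set), non-members step
    it down by 1/(N - n_set). The ES is the extremum of largest magnitude.
    Returns (es, running_sum).
    """
    order = ranks.sort_values(ascending=False)
    in_set = order.index.isin(set(gene_set))
    n = len(order)
    n_set = int(in_set.sum())
    if n_set == 0 or n_set == n:
        raise ValueError("gene set must be a proper non-empty subset of the ranking")
    w = np.abs(order.to_numpy(dtype=float)) ** weight
    hit = np.where(in_set, w, 0.0)
    hit_sum = hit.sum()
    if hit_sum == 0:
        hit = in_set.astype(float)
        hit_sum = hit.sum()
    step = hit / hit_sum - (~in_set).astype(float) / (n - n_set)
    running = np.cumsum(step)
    i = int(np.argmax(np.abs(running)))
    return float(running[i]), running


def preranked_enrichment(
    ranks: pd.Series,
    sets: dict,
    n_perm: int = 10000,
    seed=0,
    weight: float = 1.0,
) -> pd.DataFrame:
    """Preranked gene-set enrichment with a gene-permutation null.

    For each named set (>= 3 member genes present in the ranking, proper
    subset), the weighted KS enrichment score is compared to ``n_perm``
    random same-size gene sets: NES = ES / mean |null ES| of matching
    sign, p = two-sided null tail count with +1 smoothing, BH across sets.
    Sets with fewer than 3 mapped genes are skipped with a warning.
    """
    rng = as_rng(seed)
    genes = np.asarray(ranks.index)
    records = []
    for name, members in sets.items():
        mapped = [g for g in members if g in ranks.index]
        if len(mapped) < 3:
            warnings.warn(f"set {name!r} has <3 genes in the ranking; skipped")
            continue
        if len(mapped) >= len(ranks):
            raise ValueError(f"set {name!r} covers every ranked gene; ES undefined")
        es, _ = enrichment_score(ranks, mapped, weight)
        null = np.empty(n_perm)
        for b in range(n_perm):
            rand = genes[rng.choice(len(genes), size=len(mapped), replace=False)]
            null[b], _ = enrichment_score(ranks, rand, weight)
        same_sign = null * np.sign(es) > 0
        denom = np.abs(null[same_sign]).mean() if same_sign.any() else np.abs(null).mean()
        nes = es / denom if denom > 0 else 0.0
        p = (1.0 + np.sum(np.abs(null) >= abs(es))) / (1.0 + n_perm)
        records.append(
            {"set_name": name, "n_genes": len(mapped), "es": es, "nes": nes, "p": p}
        )
    out = pd.DataFrame.from_records(records)
    if not out.empty:
        out["adj_p"] = bh_adjust(out["p"])
        out = out.set_index("set_name")
    return out


def adjusted_spearman(x, y, covariates=None):
    """Covariate-adjusted Spearman correlation.

    Ranks x, y and each covariate, residualizes the x- and y-ranks on the
    covariate ranks (with intercept) by least squares, and reports the
    Pearson correlation of the residuals with a t-distribution p-value on
    n - 2 - c degrees of freedom. Without covariates this reduces exactly
    to the plain Spearman rho.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    C = (
        np.empty((n, 0))
        if covariates is None
        else np.atleast_2d(np.asarray(covariates, dtype=float))
    )
    if C.shape[0] != n and C.shape[1] == n:
        C = C.T
    c = C.shape[1]
    if n < c + 3:
        raise ValueError("need n >= number of covariates + 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant x or y: correlation undefined")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    Z = np.column_stack([np.ones(n)] + [stats.rankdata(C[:, j]) for j in range(c)])
    bx, *_ = np.linalg.lstsq(Z, rx, rcond=None)
    by, *_ = np.linalg.lstsq(Z, ry, rcond=None)
    ex = rx - Z @ bx
    ey = ry - Z @ by
    rho = float(np.dot(ex, ey) / np.sqrt(np.dot(ex, ex) * np.dot(ey, ey)))
    df = n - 2 - c
    t = rho * np.sqrt(df / max(1e-300, 1.0 - rho**2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return rho, float(p)
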