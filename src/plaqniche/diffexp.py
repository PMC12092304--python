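"""Covariate-adjusted differential expression.

Four routes share one design-matrix contract:

* pseudobulk negative-binomial Wald tests on donor-summed counts (the
  donor is the replication unit; per-gene dispersions are ML-estimated and
  shrunk toward a log-mean trend);
* a two-part hurdle test on log-normalized unit-level expression
  (detection logistic + positive-expression linear, combined LR chi^2);
* a negative-binomial GLM on isotype-normalized protein counts;
* Wilcoxon one-vs-rest marker detection.

Balanced downsampling caps single-sample dominance (50%), group imbalance
(3-fold) and group size (3,000 units) before unit-level testing. Gene
filters drop genes below detection-fraction floors and genes whose symbol
starts with RPS, RPL, MT or HB (ribosomal / mitochondrial / hemoglobin).
Significance throughout: BH-adjusted p < 0.05 and |log2 FC| >= log2(1.5).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .synthgen import as_rng

__all__ = [
    "LFC_THRESHOLD",
    "DesignSpec",
    "DownsampleConstraints",
    "bh_adjust",
    "balance_downsample",
    "gene_filter",
    "normalize_log1p",
    "pseudobulk_nb_test",
    "hurdle_test",
    "protein_nb_test",
    "find_markers",
]

LFC_THRESHOLD = float(np.log2(1.5))
ADJ_P_THRESHOLD = 0.05
EXCLUDE_PREFIXES = ("RPS", "RPL", "MT", "HB")
LN2 = float(np.log(2.0))


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaN-tolerant)."""
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


# --------------------------------------------------------------------------
# design handling
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class DesignSpec:
    """Comparison design: a two-level group plus adjustment covariates.

    ``covariates`` is a list of (column, kind) pairs with kind in
    {'continuous', 'categorical'}; continuous covariates are standardized
    (mean 0, sd 1) within the analysis subset. ``random_effect`` names a
    grouping column (typically the sample id); it is fitted as a fixed
    categorical covariate — a conservative approximation for balanced
    designs, see the methods note.
    """

    group: str = "group"
    covariates: tuple = ()
    random_effect: str | None = None


def build_design(meta: pd.DataFrame, design: DesignSpec):
    """Design matrix (intercept first, group effect column named 'group').

    Returns (X, group_col_name, group_levels). Raises on collinearity,
    naming the aliased columns, and on single-level groups.
    """
    levels = sorted(pd.unique(meta[design.group].astype(str)))
    if len(levels) != 2:
        raise ValueError(f"group must have exactly two levels, got {levels}")
    cols = {"intercept": np.ones(len(meta))}
    cols["group"] = (meta[design.group].astype(str) == levels[1]).astype(float).to_numpy()
    covs = list(design.covariates)
    if design.random_effect is not None:
        covs.append((design.random_effect, "categorical"))
    for name, kind in covs:
        v = meta[name]
        if kind == "continuous":
            arr = v.astype(float).to_numpy()
            sd = arr.std(ddof=0)
            if sd == 0:
                warnings.warn(f"covariate {name!r} is constant; dropped")
                continue
            cols[name] = (arr - arr.mean()) / sd
        elif kind == "categorical":
            dummies = pd.get_dummies(v.astype(str), prefix=name, drop_first=True)
            for c in dummies.columns:
                cols[c] = dummies[c].astype(float).to_numpy()
        else:
            raise ValueError(f"unknown covariate kind: {kind}")
    X = pd.DataFrame(cols, index=meta.index)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        aliased = _aliased_columns(X.to_numpy(), list(X.columns))
        raise ValueError(f"design is collinear; aliased columns: {aliased}")
    return X, "group", levels


def _aliased_columns(X: np.ndarray, names: list[str]) -> list[str]:
    keep: list[int] = []
    aliased: list[str] = []
    for j in range(X.shape[1]):
        trial = keep + [j]
        if np.linalg.matrix_rank(X[:, trial]) == len(trial):
            keep.append(j)
        else:
            aliased.append(names[j])
    return aliased


# --------------------------------------------------------------------------
# balanced downsampling
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class DownsampleConstraints:
    """Caps applied per comparison before unit-level testing."""

    max_sample_share: float = 0.5
    max_group_fold: float = 3.0
    max_group_size: int = 3000


def balance_downsample(
    units: pd.DataFrame,
    constraints: DownsampleConstraints = DownsampleConstraints(),
    seed=0,
) -> pd.DataFrame:
    """Uniformly subsample units until all three balance constraints hold.

    ``units`` needs columns unit, sample, group (two non-empty groups).
    Passes, repeated to a fixed point: (i) within each multi-sample group,
    trim the largest sample to floor(max_share * group total) until no
    sample exceeds the share cap (single-sample groups are exempt — their
    share is necessarily 1); (ii) cap each group at max_group_size;
    (iii) cap the larger group at max_group_fold times the smaller. All
    subsampling is uniform without replacement and deterministic given the
    seed. Returns the retained rows.
    """
    rng = as_rng(seed)
    required = {"unit", "sample", "group"}
    if not required <= set(units.columns):
        raise ValueError(f"units needs columns {sorted(required)}")
    groups = list(pd.unique(units["group"]))
    if len(groups) != 2 or units.groupby("group").size().min() == 0:
        raise ValueError("comparison requires exactly two non-empty groups")
    df = units.reset_index(drop=True)

    def share_ok(sub: pd.DataFrame) -> bool:
        if sub["sample"].nunique() <= 1:
            return True
        return sub["sample"].value_counts().max() <= constraints.max_sample_share * len(sub)

    def subsample(idx: np.ndarray, k: int) -> np.ndarray:
        return rng.choice(idx, size=k, replace=False)

    keep = np.ones(len(df), dtype=bool)
    for _ in range(200):  # fixed point reached long before this
        changed = False
        # (i) per-sample share cap
        for g in groups:
            while True:
                gi = np.flatnonzero(keep & (df["group"] == g).to_numpy())
                sub = df.iloc[gi]
                if share_ok(sub):
                    break
                counts = sub["sample"].value_counts()
                worst = counts.idxmax()
                target = int(np.floor(constraints.max_sample_share * len(sub)))
                wi = gi[(sub["sample"] == worst).to_numpy()]
                drop = subsample(wi, len(wi) - target)
                keep[drop] = False
                changed = True
        # (ii) group-size cap
        sizes = {}
        for g in groups:
            gi = np.flatnonzero(keep & (df["group"] == g).to_numpy())
            if len(gi) > constraints.max_group_size:
                kept = subsample(gi, constraints.max_group_size)
                drop = np.setdiff1d(gi, kept)
                keep[drop] = False
                changed = True
                gi = kept
            sizes[g] = len(gi)
        # (iii) fold cap
        big, small = max(groups, key=sizes.get), min(groups, key=sizes.get)
        if sizes[small] and sizes[big] > constraints.max_group_fold * sizes[small]:
            gi = np.flatnonzero(keep & (df["group"] == big).to_numpy())
            kept = subsample(gi, int(constraints.max_group_fold * sizes[small]))
            keep[np.setdiff1d(gi, kept)] = False
            changed = True
        if not changed:
            break
    return df[keep]


# --------------------------------------------------------------------------
# gene filtering and normalization
# --------------------------------------------------------------------------


def gene_filter(
    counts: pd.DataFrame,
    groups: pd.Series,
    mode: str = "pseudobulk",
    prefix_exclude=EXCLUDE_PREFIXES,
) -> list[str]:
    """Genes eligible for testing under the route-specific detection rules.

    Detection fraction is the share of units with count > 0, computed per
    comparison group. 'pseudobulk' and 'hd' keep genes detected in >= 1% of
    either group; 'hurdle' requires >= 1% of both groups and >= 10% of
    either. Symbols starting with any of ``prefix_exclude`` (case
    sensitive) are removed regardless.
    """
    if mode not in ("pseudobulk", "hurdle", "hd"):
        raise ValueError(f"unknown mode: {mode}")
    groups = groups.reindex(counts.columns)
    levels = pd.unique(groups.dropna())
    if len(levels) != 2:
        raise ValueError("gene_filter expects exactly two groups")
    det = {}
    for g in levels:
        sub = counts.loc[:, (groups == g).to_numpy()]
        det[g] = (sub > 0).mean(axis=1)
    d1, d2 = det[levels[0]], det[levels[1]]
    if mode == "hurdle":
        keep = ((d1 >= 0.01) & (d2 >= 0.01)) & ((d1 >= 0.10) | (d2 >= 0.10))
    else:
        keep = (d1 >= 0.01) | (d2 >= 0.01)
    names = counts.index[keep.to_numpy()]
    names = [g for g in names if not str(g).startswith(tuple(prefix_exclude))]
    return list(names)


def normalize_log1p(counts: pd.DataFrame) -> pd.DataFrame:
    """log1p of counts scaled to the median library size (natural log)."""
    lib = counts.sum(axis=0).astype(float)
    lib[lib == 0] = 1.0
    target = float(np.median(lib))
    return np.log1p(counts / lib * target)


# --------------------------------------------------------------------------
# pseudobulk negative-binomial route
# --------------------------------------------------------------------------


THETA_CEILING = 1e7


def _nb_loglik(y: np.ndarray, mu: np.ndarray, theta: float) -> float:
    p = theta / (theta + mu)
    return float(stats.nbinom.logpmf(y, theta, p).sum())


def _estimate_theta(y: np.ndarray, mu: np.ndarray, X: np.ndarray | None = None) -> float:
    """Profile-ML size parameter theta (Var = mu + mu^2/theta), mu fixed.

    With a design matrix supplied the likelihood is Cox-Reid adjusted
    (penalty 0.5 log det X'WX), removing the downward bias of plain ML when
    the residual degrees of freedom are few.
    """
    mu = np.asarray(mu, dtype=float)
    if np.all(y == 0):
        return np.inf

    def nll(lt: float) -> float:
        theta = np.exp(lt)
        ll = _nb_loglik(y, mu, theta)
        if X is not None:
            w = mu / (1.0 + mu / theta)
            _, logdet = np.linalg.slogdet(X.T @ (X * w[:, None]))
            ll -= 0.5 * logdet
        return -ll

    res = optimize.minimize_scalar(
        nll,
        bounds=(np.log(1e-3), np.log(THETA_CEILING)),
        method="bounded",
        options={"xatol": 1e-3},
    )
    return float(np.exp(res.x))


def _fit_nb_wald(y, X, offset, theta, df_resid=None):
    """Wald test for the 'group' column of an NB GLM with fixed dispersion.

    The Wald statistic is referred to a t distribution with the residual
    degrees of freedom (normal when ``df_resid`` is None), acknowledging
    that the dispersion is estimated from few replicates.
    """
    alpha = min(1.0 / theta, 1e3) if np.isfinite(theta) else 1e-8
    fam = sm.families.NegativeBinomial(alpha=max(alpha, 1e-8))
    model = sm.GLM(y, X, family=fam, offset=offset)
    fit = model.fit(maxiter=100, tol=1e-8)
    j = list(X.columns).index("group")
    beta = fit.params.iloc[j]
    se = fit.bse.iloc[j]
    z = beta / se if se > 0 else 0.0
    if df_resid is not None and df_resid > 0:
        p = 2.0 * stats.t.sf(abs(z), df_resid)
    else:
        p = 2.0 * stats.norm.sf(abs(z))
    return beta / LN2, p


def pseudobulk_nb_test(
    counts: pd.DataFrame,
    donors: pd.Series,
    meta: pd.DataFrame,
    design: DesignSpec = DesignSpec(),
    genes: list | None = None,
    comparison: str = "",
) -> pd.DataFrame:
    """Donor-level negative-binomial Wald tests on pseudobulk sums.

    Raw counts are summed by donor; each gene gets an NB GLM with log link,
    offset log(donor library size) and the standardized design covariates.
    Dispersions are Cox-Reid-adjusted profile-ML per gene, then shrunk
    50/50 in log space toward a degree-1 trend of log-dispersion on
    log-mean; the Wald statistic is referred to a t distribution with
    moderated degrees of freedom (twice the donor-level residual df,
    counting the information the trend shrinkage pools across genes),
    since the dispersion is estimated from few replicates. Every filtered gene receives a p-value
    (no independent filtering); BH across tested genes; significant iff
    adj p < 0.05 and |log2 FC| >= log2(1.5). ``meta`` is indexed by donor
    and carries the design columns.
    """
    donors = donors.reindex(counts.columns)
    pb = counts.T.groupby(donors.to_numpy()).sum().T  # genes x donors
    dmeta = meta.loc[pb.columns]
    X, _, levels = build_design(dmeta, design)
    n1 = int((dmeta[design.group].astype(str) == levels[0]).sum())
    n2 = int((dmeta[design.group].astype(str) == levels[1]).sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 donors")
    if genes is None:
        genes = list(pb.index)
    offset = np.log(pb.sum(axis=0).astype(float).to_numpy())

    Y = pb.loc[genes].to_numpy(dtype=float)
    Xn = X.to_numpy(dtype=float)
    # stage 1: Poisson fits for mu, Cox-Reid profile-ML dispersion per gene
    thetas = np.empty(len(genes))
    for i, y in enumerate(Y):
        fit = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit()
        mu = np.clip(np.asarray(fit.fittedvalues, dtype=float), 1e-8, None)
        thetas[i] = _estimate_theta(y, mu, Xn)
    # stage 2: shrink log-dispersion toward a log-mean trend; estimates at
    # the near-Poisson ceiling carry no dispersion signal and are excluded
    # from the trend fit
    logmean = np.log(np.clip(Y.mean(axis=1), 1e-8, None))
    finite = np.isfinite(thetas)
    log_theta = np.where(finite, np.log(np.clip(thetas, 1e-8, None)), np.log(THETA_CEILING))
    usable = finite & (thetas < 0.9 * THETA_CEILING)
    if usable.sum() >= 10:
        coef = np.polyfit(logmean[usable], log_theta[usable], 1)
        trend = np.polyval(coef, logmean)
    else:
        trend = np.full(len(genes), np.median(log_theta))
    theta_shrunk = np.exp(0.5 * log_theta + 0.5 * trend)

    # moderated df: residual df plus an equal prior contribution, because
    # the 50/50 trend shrinkage roughly doubles the dispersion information
    df_resid = 2 * (len(pb.columns) - X.shape[1])
    lfc = np.full(len(genes), np.nan)
    pval = np.full(len(genes), np.nan)
    for i, y in enumerate(Y):
        try:
            lfc[i], pval[i] = _fit_nb_wald(y, X, offset, theta_shrunk[i], df_resid)
        except (np.linalg.LinAlgError, ValueError):
            continue
    return _finalize_table(genes, lfc, pval, comparison, n1, n2)


def _finalize_table(genes, lfc, pval, comparison, n1, n2, all_genes=None):
    adj = bh_adjust(pval)
    tab = pd.DataFrame(
        {
            "gene": list(genes),
            "lfc": lfc,
            "p": pval,
            "adj_p": adj,
            "significant": (adj < ADJ_P_THRESHOLD) & (np.abs(lfc) >= LFC_THRESHOLD),
            "tested": ~np.isnan(pval),
            "n_group1": n1,
            "n_group2": n2,
        }
    )
    tab["comparison"] = comparison
    if all_genes is not None:
        rest = [g for g in all_genes if g not in set(genes)]
        if rest:
            extra = pd.DataFrame({"gene": rest})
            extra["lfc"] = np.nan
            extra["p"] = np.nan
            extra["adj_p"] = np.nan
            extra["significant"] = False
            extra["tested"] = False
            extra["n_group1"] = n1
            extra["n_group2"] = n2
            extra["comparison"] = comparison
            tab = pd.concat([tab, extra], ignore_index=True)
    tab.loc[~tab["tested"], "significant"] = False
    return tab.set_index("gene")


# --------------------------------------------------------------------------
# hurdle route
# --------------------------------------------------------------------------


def _lrt_logistic(det: np.ndarray, X: pd.DataFrame):
    """LR chi^2 (df 1) for the group column of a detection logistic model.

    Degenerate detection patterns (all 0 or all 1, separation, failed
    convergence) contribute 0 with 0 df.
    """
    if det.all() or not det.any():
        return 0.0, 0
    X0 = X.drop(columns="group")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f1 = sm.GLM(det.astype(float), X, family=sm.families.Binomial()).fit(
                maxiter=100
            )
            f0 = sm.GLM(det.astype(float), X0, family=sm.families.Binomial()).fit(
                maxiter=100
            )
        lr = 2.0 * (f1.llf - f0.llf)
        if not np.isfinite(lr):
            return 0.0, 0
        return max(lr, 0.0), 1
    except (np.linalg.LinAlgError, ValueError):
        return 0.0, 0


def _lrt_linear(y: np.ndarray, X: np.ndarray, group_col: int):
    """Gaussian LR chi^2 (df 1) for the group column of a linear model."""
    n = len(y)
    if n <= X.shape[1] + 1:
        return 0.0, 0
    X0 = np.delete(X, group_col, axis=1)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        return 0.0, 0
    rss1 = _rss(y, X)
    rss0 = _rss(y, X0)
    if rss1 <= 0:
        return 0.0, 0
    return max(n * np.log(rss0 / rss1), 0.0), 1


def _rss(y, X):
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def hurdle_test(
    normalized_expr: pd.DataFrame,
    meta: pd.DataFrame,
    design: DesignSpec = DesignSpec(),
    genes: list | None = None,
    comparison: str = "",
) -> pd.DataFrame:
    """Two-part hurdle test on log-normalized unit-level expression.

    Per gene, a logistic model of detection (expr > 0) and a linear model
    of expression among detected units are each compared to their
    group-free null by likelihood ratio; the combined statistic is the sum
    of the two LR chi^2 with summed degrees of freedom. The log2 fold
    change is the difference of group means of the normalized expression
    divided by ln 2, independent of the model fit. BH across genes.
    """
    meta = meta.loc[normalized_expr.columns]
    X, _, levels = build_design(meta, design)
    Xn = X.to_numpy()
    gcol = list(X.columns).index("group")
    grp2 = (meta[design.group].astype(str) == levels[1]).to_numpy()
    n1, n2 = int((~grp2).sum()), int(grp2.sum())
    if genes is None:
        genes = list(normalized_expr.index)
    E = normalized_expr.loc[genes].to_numpy(dtype=float)
    lfc = (E[:, grp2].mean(axis=1) - E[:, ~grp2].mean(axis=1)) / LN2
    pval = np.full(len(genes), np.nan)
    for i, y in enumerate(E):
        det = y > 0
        chi_d, df_d = _lrt_logistic(det, X)
        if det.sum() >= 3:
            chi_c, df_c = _lrt_linear(y[det], Xn[det], gcol)
        else:
            chi_c, df_c = 0.0, 0
        df = df_d + df_c
        pval[i] = stats.chi2.sf(chi_d + chi_c, df) if df else 1.0
    return _finalize_table(genes, lfc, pval, comparison, n1, n2)


# --------------------------------------------------------------------------
# protein route
# --------------------------------------------------------------------------


def protein_nb_test(
    protein_counts: pd.DataFrame,
    meta: pd.DataFrame,
    design: DesignSpec = DesignSpec(),
    min_pct: float = 0.01,
    comparison: str = "",
) -> pd.DataFrame:
    """Negative-binomial GLM per protein on isotype-normalized counts.

    Proteins detected in fewer than ``min_pct`` of both groups are left
    untested. Non-integer input (normalized counts) is rounded with a
    warning. The design typically carries standardized CDR and region as
    latent covariates alongside the group effect. No library-size offset
    is used: isotype normalization already corrects capture depth, and a
    total-count offset would leak composition bias from responsive
    proteins into the rest of the panel.
    """
    meta = meta.loc[protein_counts.columns]
    vals = protein_counts.to_numpy(dtype=float)
    if not np.allclose(vals, np.round(vals)):
        warnings.warn("non-integer protein counts rounded for NB fitting")
    vals = np.round(vals)
    X, _, levels = build_design(meta, design)
    grp2 = (meta[design.group].astype(str) == levels[1]).to_numpy()
    n1, n2 = int((~grp2).sum()), int(grp2.sum())
    det1 = (vals[:, ~grp2] > 0).mean(axis=1)
    det2 = (vals[:, grp2] > 0).mean(axis=1)
    testable = (det1 >= min_pct) | (det2 >= min_pct)
    offset = np.zeros(vals.shape[1])
    lfc = np.full(len(protein_counts), np.nan)
    pval = np.full(len(protein_counts), np.nan)
    Xn = X.to_numpy(dtype=float)
    for i in np.flatnonzero(testable):
        y = vals[i]
        try:
            fit = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit()
            mu = np.clip(np.asarray(fit.fittedvalues, dtype=float), 1e-8, None)
            theta = _estimate_theta(y, mu, Xn)
            lfc[i], pval[i] = _fit_nb_wald(y, X, offset, theta)
        except (np.linalg.LinAlgError, ValueError):
            continue
    return _finalize_table(list(protein_counts.index), lfc, pval, comparison, n1, n2)


# --------------------------------------------------------------------------
# marker detection
# --------------------------------------------------------------------------


def find_markers(
    normalized_expr: pd.DataFrame,
    clusters: pd.Series,
    min_pct: float = 0.25,
    only_pos: bool = True,
    lfc_floor: float = 0.0,
    prefix_exclude=EXCLUDE_PREFIXES,
) -> dict:
    """Wilcoxon one-vs-rest marker tables, one per cluster.

    Genes must be detected in strictly more than ``min_pct`` of the cluster
    of interest (and pass the prefix exclusion and |lfc| >= lfc_floor); the
    rank-sum test compares in-cluster vs all other units, BH is applied
    within each cluster, and positive-LFC genes only are kept when
    ``only_pos``. Singleton clusters are skipped with a warning. The
    niche-cluster contrast profile uses min_pct 0.1, both signs and an LFC
    threshold of log2(1.5).
    """
    clusters = clusters.reindex(normalized_expr.columns)
    keep_genes = [
        g for g in normalized_expr.index if not str(g).startswith(tuple(prefix_exclude))
    ]
    E = normalized_expr.loc[keep_genes]
    out = {}
    for cl in pd.unique(clusters.dropna()):
        in_cl = (clusters == cl).to_numpy()
        if in_cl.sum() < 2 or (~in_cl).sum() < 2:
            warnings.warn(f"cluster {cl!r} too small; skipped")
            continue
        A = E.loc[:, in_cl].to_numpy(dtype=float)
        B = E.loc[:, ~in_cl].to_numpy(dtype=float)
        pct_in = (A > 0).mean(axis=1)
        pct_out = (B > 0).mean(axis=1)
        lfc = (A.mean(axis=1) - B.mean(axis=1)) / LN2
        testable = pct_in > min_pct
        if lfc_floor > 0:
            testable &= np.abs(lfc) >= lfc_floor
        pv = np.full(len(keep_genes), np.nan)
        if testable.any():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = stats.mannwhitneyu(
                    A[testable], B[testable], axis=1, alternative="two-sided"
                )
            pv[testable] = res.pvalue
        tab = _finalize_table(keep_genes, lfc, pv, f"cluster {cl} vs rest",
                              int(in_cl.sum()), int((~in_cl).sum()))
        tab["pct_in"] = pct_in
        tab["pct_out"] = pct_out
        if only_pos:
            tab = tab[(tab["lfc"] > 0) | ~tab["tested"]]
        out[cl] = tab.sort_values("adj_p")
    return out
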