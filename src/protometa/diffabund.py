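"""Blocked linear models with empirical-Bayes moderated statistics.

Each feature (protein, peptide or metabolite) is fit by ordinary least
squares on its observed samples against a shared design matrix — typically
condition-by-method cell means plus subject fixed effects as the blocking
surrogate for a paired cohort.  Per-feature residual variances s_g^2 with
d_g residual degrees of freedom are then shrunk toward a global prior
(d0, s0^2) estimated by method of moments on log s_g^2 under a scaled
inverse-chi-square prior, and contrasts are tested with the moderated
t-statistic

    t_g = c' beta_g / (s_tilde_g * sqrt(c' (X'X)^-1 c)),
    s_tilde_g^2 = (d0 s0^2 + d_g s_g^2) / (d0 + d_g),

referred to a Student-t distribution with d0 + d_g degrees of freedom
(standard normal when d0 is infinite).  p-values are controlled across
features by Benjamini-Hochberg step-up FDR.

The module also carries the concordance toolkit used to compare two
sample-preparation methods: coefficient of variation of technical
replicates, set overlaps of significant features, rank-sum comparison of
fold-change magnitudes, correlation of t-value vectors, a random-split
heterogeneity test, and hypergeometric over-representation of annotation
sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, special, stats
from scipy.optimize import brentq
from statsmodels.stats.multitest import multipletests

from .data import FeatureMatrix, SampleAnnotation


# ---------------------------------------------------------------------------
# designs and contrasts


@dataclass(frozen=True)
class ContrastSpec:
    """Named linear combination of design coefficients."""

    name: str
    weights: dict[str, float]


def cell_means_design(
    ann: SampleAnnotation,
    factors: tuple[str, ...] = ("condition", "method"),
    block: str | None = "subject_id",
    covariates: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Cell-means design with optional subject blocking columns.

    One indicator column per observed combination of ``factors`` (named by
    joining the levels with '_'), plus 0/1 dummies for all but the first
    level of the blocking variable and of each categorical covariate.  For a
    complete paired layout the subject fixed effects absorb between-subject
    variation, so within-subject contrasts match those of a correlated-
    errors fit.
    """
    t = ann.table
    cells = t[list(factors)].astype(str).agg("_".join, axis=1)
    design = pd.get_dummies(cells, dtype=float)
    for cov in covariates:
        dummies = pd.get_dummies(t[cov].astype(str), prefix=cov, dtype=float)
        design = pd.concat([design, dummies.iloc[:, 1:]], axis=1)
    if block is not None:
        dummies = pd.get_dummies(t[block].astype(str), prefix="block", dtype=float)
        design = pd.concat([design, dummies.iloc[:, 1:]], axis=1)
    design.index = list(t["sample_id"])
    return design


def _check_full_rank(design: pd.DataFrame) -> None:
    X = design.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify aliased columns by greedy QR elimination
        aliased = []
        kept: list[int] = []
        for j in range(X.shape[1]):
            cand = X[:, kept + [j]]
            if np.linalg.matrix_rank(cand) == len(kept) + 1:
                kept.append(j)
            else:
                aliased.append(design.columns[j])
        raise ValueError(f"design is rank-deficient; aliased coefficients: {aliased}")


# ---------------------------------------------------------------------------
# per-feature OLS


@dataclass
class FeatureFit:
    """Per-feature OLS results against a common design."""

    feature_ids: list
    coef_names: list
    beta: np.ndarray  # (n_features, k)
    sigma2: np.ndarray  # (n_features,) residual variance, NaN when d_g = 0
    df_residual: np.ndarray  # (n_features,)
    cov_unscaled: np.ndarray  # (n_features, k, k) = (X'X)^-1 on observed rows
    ok: np.ndarray  # (n_features,) bool: all coefficients estimable


def fit_feature_models(m: FeatureMatrix, design: pd.DataFrame) -> FeatureFit:
    """Observed-entries OLS per feature (row-deletion for missing values).

    Features whose observed rows do not support the full design (rank
    deficiency on the observed subset) are flagged ``ok=False`` with
    undefined estimates; features that fit exactly (d_g = 0) keep their
    coefficients but have no residual variance.
    """
    if not m.is_log:
        raise ValueError("fit_feature_models expects a log-scale matrix")
    if list(design.index) != m.sample_ids:
        design = design.loc[m.sample_ids]
    _check_full_rank(design)
    X = design.to_numpy(dtype=float)
    Y = m.values.to_numpy(dtype=float)
    n_feat, _ = Y.shape
    k = X.shape[1]

    beta = np.full((n_feat, k), np.nan)
    sigma2 = np.full(n_feat, np.nan)
    dfres = np.zeros(n_feat, dtype=int)
    cov = np.full((n_feat, k, k), np.nan)
    ok = np.zeros(n_feat, dtype=bool)

    obs = ~np.isnan(Y)
    # batch features sharing a missingness pattern: one matrix factorization each
    patterns, inverse = np.unique(obs, axis=0, return_inverse=True)
    for p_idx, pattern in enumerate(patterns):
        rows = np.where(inverse == p_idx)[0]
        Xo = X[pattern]
        n_obs = Xo.shape[0]
        if n_obs < k or np.linalg.matrix_rank(Xo) < k:
            continue
        xtx_inv = linalg.inv(Xo.T @ Xo)
        Yo = Y[np.ix_(rows, pattern)]
        b = Yo @ Xo @ xtx_inv.T
        resid = Yo - b @ Xo.T
        d = n_obs - k
        beta[rows] = b
        dfres[rows] = d
        cov[rows] = xtx_inv
        ok[rows] = True
        if d > 0:
            sigma2[rows] = (resid**2).sum(axis=1) / d
    return FeatureFit(
        feature_ids=m.feature_ids,
        coef_names=list(design.columns),
        beta=beta,
        sigma2=sigma2,
        df_residual=dfres,
        cov_unscaled=cov,
        ok=ok,
    )


# ---------------------------------------------------------------------------
# empirical-Bayes moderation


@dataclass(frozen=True)
class ModerationParams:
    d0: float  # prior degrees of freedom; 0 = classical limit, may be math.inf
    s0_sq: float  # prior variance

    def __post_init__(self) -> None:
        if not self.d0 >= 0:
            raise ValueError("d0 must be non-negative")
        if not self.s0_sq > 0:
            raise ValueError("s0_sq must be positive")


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0; trigamma is strictly decreasing."""
    f = lambda y: special.polygamma(1, y) - x
    lo, hi = 1e-8, 1e8
    return brentq(f, lo, hi, xtol=1e-10, rtol=1e-12)


def estimate_moderation(sigma2, df_residual) -> ModerationParams:
    """Method-of-moments fit of the scaled inverse-chi-square variance prior.

    Works on e_g = log s_g^2 - digamma(d_g/2) + log(d_g/2), whose mean is
    log s0^2 + digamma(d0/2) - log(d0/2) and whose excess variance over the
    sampling term trigamma(d_g/2) equals trigamma(d0/2).  d0 is recovered by
    inverting the trigamma function; when the observed dispersion does not
    exceed the sampling variance the prior is degenerate (d0 infinite) and
    s0^2 is the geometric-mean-based limit of the same formula.
    """
    s2 = np.asarray(sigma2, dtype=float)
    d = np.asarray(df_residual, dtype=float)
    use = np.isfinite(s2) & (s2 > 0) & (d > 0)
    if use.sum() < 10:
        raise ValueError(f"need >= 10 features with positive residual df, got {use.sum()}")
    s2, d = s2[use], d[use]
    e = np.log(s2) - special.digamma(d / 2.0) + np.log(d / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(np.mean(special.polygamma(1, d / 2.0)))
    if np.var(np.log(s2)) == 0.0:
        # all residual variances identical: point-mass prior at that value
        return ModerationParams(d0=math.inf, s0_sq=float(s2[0]))
    if evar <= 0:
        return ModerationParams(d0=math.inf, s0_sq=float(np.exp(emean)))
    d0 = 2.0 * _trigamma_inverse(evar)
    s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return ModerationParams(d0=d0, s0_sq=s0_sq)


# ---------------------------------------------------------------------------
# moderated t and multiplicity


@dataclass
class DiffResult:
    """Per-feature differential statistics for one contrast."""

    contrast: str
    table: pd.DataFrame  # index feature; logFC, t, p, adj_p, df_residual, df_total

    def significant(self, alpha: float = 0.05) -> set:
        adj = self.table["adj_p"]
        return set(self.table.index[adj.notna() & (adj < alpha)])

    @property
    def t_values(self) -> pd.Series:
        return self.table["t"]


def moderated_t(
    fit: FeatureFit, contrast: ContrastSpec, mod: ModerationParams
) -> DiffResult:
    """Moderated t-test of a contrast, with BH-adjusted two-sided p-values.

    d0 = 0 degenerates to the classical t-statistic; d0 = inf pins every
    variance at s0^2 and uses the normal reference.
    """
    unknown = [c for c in contrast.weights if c not in fit.coef_names]
    if unknown:
        raise ValueError(f"contrast names unknown coefficients: {unknown}")
    c = np.array([contrast.weights.get(name, 0.0) for name in fit.coef_names])
    logfc = fit.beta @ c
    var_unscaled = np.einsum("i,fij,j->f", c, fit.cov_unscaled, c)
    d = fit.df_residual.astype(float)
    s2 = fit.sigma2.copy()

    if math.isinf(mod.d0):
        s_tilde2 = np.full_like(logfc, mod.s0_sq)
        df_total = np.full_like(logfc, np.inf)
    else:
        s2_eff = np.where(np.isnan(s2) & (d == 0), 0.0, s2)
        denom = mod.d0 + d
        s_tilde2 = (mod.d0 * mod.s0_sq + d * s2_eff) / np.where(denom > 0, denom, np.nan)
        df_total = mod.d0 + d

    with np.errstate(invalid="ignore", divide="ignore"):
        t = logfc / np.sqrt(s_tilde2 * var_unscaled)
    t = np.where(fit.ok, t, np.nan)
    p = np.full_like(t, np.nan)
    finite_df = np.isfinite(df_total) & (df_total > 0)
    usable = np.isfinite(t)
    idx = usable & finite_df
    p[idx] = 2.0 * stats.t.sf(np.abs(t[idx]), df_total[idx])
    idx = usable & ~finite_df & np.isinf(df_total)
    p[idx] = 2.0 * stats.norm.sf(np.abs(t[idx]))
    table = pd.DataFrame(
        {
            "logFC": logfc,
            "t": t,
            "p": p,
            "adj_p": bh_adjust(p),
            "df_residual": d,
            "df_total": df_total,
        },
        index=fit.feature_ids,
    )
    return DiffResult(contrast=contrast.name, table=table)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values; NaN entries pass through
    and do not count toward the number of tests."""
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    valid = np.isfinite(p)
    if np.any((p[valid] < 0) | (p[valid] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if valid.sum():
        out[valid] = multipletests(p[valid], method="fdr_bh")[1]
    return out


def condition_contrast(
    m: FeatureMatrix,
    ann: SampleAnnotation,
    value_cond: str = "TT",
    ref_cond: str = "NAT",
    block: str | None = "subject_id",
) -> DiffResult:
    """One-stop paired contrast: fit, moderate, and test value - reference.

    Convenience wrapper for the common blocked two-condition comparison
    (e.g. tumour vs adjacent normal within one extraction method).
    """
    ann = ann.for_samples(m.sample_ids)
    design = cell_means_design(ann, factors=("condition",), block=block)
    fit = fit_feature_models(m, design)
    mod = estimate_moderation(fit.sigma2, fit.df_residual)
    contrast = ContrastSpec(
        name=f"{value_cond}_vs_{ref_cond}", weights={value_cond: 1.0, ref_cond: -1.0}
    )
    return moderated_t(fit, contrast, mod)


# ---------------------------------------------------------------------------
# concordance metrics


def cv_percent(x) -> float:
    """Coefficient of variation: population SD over mean, in percent."""
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise ValueError("cv_percent needs at least 2 observed values")
    mu = x.mean()
    if mu == 0:
        raise ValueError("cv_percent undefined for zero mean")
    return float(np.sqrt(np.mean((x - mu) ** 2)) * 100.0 / mu)


def wilcoxon_rank_sum(a, b) -> tuple[float, float]:
    """Two-sided Wilcoxon/Mann-Whitney test with continuity correction.

    Returns the Mann-Whitney W (rank-sum of ``a`` minus n_a(n_a+1)/2) and its
    two-sided p-value: exact by enumeration for small tie-free samples, and
    the normal approximation with tie-corrected variance and 0.5 continuity
    correction otherwise (the regime of the large cohort comparisons this
    test is used for).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="auto", use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


@dataclass
class OverlapSummary:
    """Disjoint-region decomposition of significant/detected feature sets."""

    membership: pd.DataFrame  # features x set-name boolean flags
    shared: int  # features present in every set
    unique: dict[str, int]  # features present only in that set
    percent_largest: float  # largest disjoint region / union size * 100


def overlap_sets(sets: dict[str, set]) -> OverlapSummary:
    """Summarise overlap structure of feature sets (one per method/contrast)."""
    names = list(sets)
    universe = sorted(set().union(*sets.values())) if names else []
    membership = pd.DataFrame(
        {n: [f in sets[n] for f in universe] for n in names}, index=universe, dtype=bool
    )
    if not universe:
        return OverlapSummary(membership, 0, {n: 0 for n in names}, 0.0)
    patterns = membership.apply(lambda row: tuple(row), axis=1)
    region_sizes = patterns.value_counts()
    shared = int(membership.all(axis=1).sum())
    unique = {
        n: int((membership[n] & ~membership.drop(columns=n).any(axis=1)).sum())
        for n in names
    }
    percent = float(region_sizes.iloc[0]) / len(universe) * 100.0
    return OverlapSummary(membership, shared, unique, percent)


def concordance_t(
    res1: DiffResult, res2: DiffResult, method: str = "spearman"
) -> tuple[float, float]:
    """Correlation of matched t-values between two differential results."""
    shared = res1.table.index.intersection(res2.table.index)
    t1 = res1.table.loc[shared, "t"]
    t2 = res2.table.loc[shared, "t"]
    keep = t1.notna() & t2.notna()
    if keep.sum() < 4:
        raise ValueError("need >= 4 shared features with defined t-values")
    if method == "spearman":
        r = stats.spearmanr(t1[keep], t2[keep])
    elif method == "pearson":
        r = stats.pearsonr(t1[keep], t2[keep])
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r.statistic), float(r.pvalue)


# ---------------------------------------------------------------------------
# random-split heterogeneity test


@dataclass
class SplitResult:
    result: DiffResult
    groups: dict  # sample_id -> "group1" | "group2"
    left_out: list


def random_split_test(
    m: FeatureMatrix, ann: SampleAnnotation, seed: int
) -> dict[str, SplitResult]:
    """Tissue-heterogeneity check: contrast two random halves of each method.

    Within each extraction-method subset, samples are split into two random
    groups balanced within tissue type (condition); the model adjusts for
    tissue type and tests group1 - group2.  Under homogeneous tissue the
    contrast is null, so significant features indicate heterogeneity rather
    than method effects.  Odd strata leave one sample out at random
    (recorded in ``left_out``).
    """
    rng = np.random.default_rng(seed)
    ann = ann.for_samples(m.sample_ids)
    out: dict[str, SplitResult] = {}
    for method in sorted(ann.table["method"].unique()):
        sub = ann.table[ann.table["method"] == method]
        if len(sub) < 4:
            raise ValueError(f"method subset {method!r} has fewer than 4 samples")
        groups: dict = {}
        left_out: list = []
        for _, stratum in sub.groupby("condition"):
            ids = list(stratum["sample_id"])
            rng.shuffle(ids)
            if len(ids) % 2:
                left_out.append(ids.pop())
            half = len(ids) // 2
            groups.update({s: "group1" for s in ids[:half]})
            groups.update({s: "group2" for s in ids[half:]})
        keep = [s for s in sub["sample_id"] if s in groups]
        sub_m = FeatureMatrix(
            values=m.values[keep], is_log=m.is_log, feature_kind=m.feature_kind
        )
        sub_ann = ann.for_samples(keep)
        tbl = sub_ann.table.copy()
        tbl["split_group"] = [groups[s] for s in tbl["sample_id"]]
        sub_ann = SampleAnnotation(tbl)
        design = cell_means_design(
            sub_ann, factors=("split_group",), block=None, covariates=("condition",)
        )
        fit = fit_feature_models(sub_m, design)
        mod = estimate_moderation(fit.sigma2, fit.df_residual)
        contrast = ContrastSpec(
            name=f"random_split_{method}", weights={"group1": 1.0, "group2": -1.0}
        )
        res = moderated_t(fit, contrast, mod)
        out[method] = SplitResult(result=res, groups=groups, left_out=left_out)
    return out


# ---------------------------------------------------------------------------
# over-representation


def ora_hypergeometric(
    signif: set, universe: set, sets: dict[str, set]
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation per annotation set.

    Memberships are intersected with the universe; the p-value is
    P[X >= overlap] for X hypergeometric(|universe|, |set|, |signif|), with
    BH adjustment across sets.
    """
    if not signif <= universe:
        raise ValueError("significant ids must be a subset of the universe")
    M, n = len(universe), len(signif)
    rows = []
    for name, members in sets.items():
        members_u = members & universe
        k = len(members_u & signif)
        p = float(stats.hypergeom.sf(k - 1, M, len(members_u), n))
        rows.append({"set": name, "set_size": len(members_u), "overlap": k, "p": min(p, 1.0)})
    table = pd.DataFrame(rows).set_index("set")
    table["adj_p"] = bh_adjust(table["p"].to_numpy())
    return table


# ---------------------------------------------------------------------------
# I/O for results


def write_diff_result(res: DiffResult, path) -> None:
    out = res.table.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t", na_rep="NA")


def read_diff_result(path, contrast: str = "") -> DiffResult:
    table = pd.read_csv(path, sep="\t", index_col="feature_id", na_values=["NA"])
    return DiffResult(contrast=contrast, table=table)
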