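"""Characterisation of lost vs surviving taxa, turnover, and driver models.

Lost taxa are profiled along several axes: the size of the co-occurrence
community they belong to (small community ~ habitat specialist), their
species contribution to beta diversity (SCBD; a taxon's share of the
total sum-of-squares of the Hellinger-transformed taxon-by-slice matrix),
cophenetic distances on a phylogeny, and their functional type
(forb/graminoid/shrub/tree) and family. Compositional change between
consecutive slices is summarised by the replacement (turnover) component
of presence/absence dissimilarity, and candidate drivers of the loss
series are screened with pairwise binomial GLMs using likelihood-ratio
tests.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from .timeslice import TaxonOccupancy


# --------------------------------------------------------------------------
# species contribution to beta diversity

def scbd(abundance: pd.DataFrame) -> pd.Series:
    """SCBD score per taxon from a taxon x slice abundance table.

    Each slice's column is converted to relative abundance and square-root
    transformed (Hellinger); each taxon's series is centred on its mean
    across slices; SCBD_j is taxon j's share of the total sum of squares.
    Scores are non-negative and sum to 1. An all-zero table raises; a
    degenerate table with zero total variance returns the uniform vector.
    """
    X = abundance.to_numpy(dtype=float).T  # slices x taxa
    if X.shape[0] < 2:
        raise ValueError("need at least 2 slices")
    if (X < 0).any():
        raise ValueError("abundances must be non-negative")
    row_sums = X.sum(axis=1, keepdims=True)
    if (row_sums == 0).all():
        raise ValueError("all-zero abundance table")
    with np.errstate(invalid="ignore", divide="ignore"):
        Y = np.sqrt(np.where(row_sums > 0, X / row_sums, 0.0))
    Y = Y - Y.mean(axis=0, keepdims=True)
    ss = (Y**2).sum(axis=0)
    total = ss.sum()
    if total == 0:
        vals = np.full(X.shape[1], 1.0 / X.shape[1])
    else:
        vals = ss / total
    return pd.Series(vals, index=abundance.index, name="scbd")


# --------------------------------------------------------------------------
# group comparisons

@dataclass(frozen=True)
class GroupComparison:
    statistic: float
    pvalue: float
    location_lost: float
    location_other: float
    test: str


def group_compare(
    values_lost,
    values_other,
    test: str = "wilcoxon",
    n_comparisons: int = 1,
) -> GroupComparison:
    """Two-sided rank-sum (Wilcoxon/Mann-Whitney) or Welch t comparison.

    With ``n_comparisons`` > 1 the p-value is Bonferroni-corrected (used
    for the pairwise functional-type and family contrasts). The rank-sum
    reports group medians, the t-test group means.
    """
    x = np.asarray(values_lost, dtype=float)
    y = np.asarray(values_other, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    if test == "wilcoxon":
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        loc_x, loc_y = float(np.median(x)), float(np.median(y))
    elif test == "t":
        if len(x) < 2 or len(y) < 2:
            raise ValueError("t-test needs at least 2 values per group")
        res = stats.ttest_ind(x, y, equal_var=False)
        loc_x, loc_y = float(np.mean(x)), float(np.mean(y))
    else:
        raise ValueError(f"unknown test {test!r}")
    p = min(1.0, float(res.pvalue) * n_comparisons)
    return GroupComparison(float(res.statistic), p, loc_x, loc_y, test)


# --------------------------------------------------------------------------
# cophenetic distances

def cophenetic_matrix(tree) -> pd.DataFrame:
    """Tip-to-tip path-length (cophenetic) distance matrix from a tree.

    ``tree`` is a Newick string or a dendropy Tree. Symmetric with zero
    diagonal.
    """
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(labels)
    M = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d = pdm.patristic_distance(taxa[i], taxa[j])
        M[i, j] = M[j, i] = d
    return pd.DataFrame(M, index=labels, columns=labels)


def cophenetic_compare(tree, lost, other) -> dict:
    """Mean within-lost vs lost-to-other cophenetic distance, with p-value.

    All taxa must be tips of the tree; missing tips raise with the list of
    missing names. The comparison is a two-sided rank-sum over the two
    sets of pairwise distances.
    """
    M = cophenetic_matrix(tree)
    lost = sorted(set(lost))
    other = sorted(set(other))
    missing = [t for t in lost + other if t not in M.index]
    if missing:
        raise ValueError(f"taxa missing from tree: {missing}")
    within = [M.loc[a, b] for a, b in itertools.combinations(lost, 2)]
    between = [M.loc[a, b] for a in lost for b in other]
    cmp = group_compare(within, between, test="wilcoxon")
    return {
        "mean_within_lost": float(np.mean(within)) if within else np.nan,
        "mean_lost_to_other": float(np.mean(between)) if between else np.nan,
        "pvalue": cmp.pvalue,
    }


# --------------------------------------------------------------------------
# functional-type and family loss proportions

def type_and_family_loss(
    occ: TaxonOccupancy,
    traits: pd.DataFrame,
    min_family_nondb: int = 5,
) -> dict:
    """Lost non-dbtaxa proportions per functional type and per family.

    ``traits`` is indexed like ``occ.taxa`` with ``functional_type`` and
    ``family`` columns. Per iteration, a taxon is lost when absent from
    the modern slice; the proportion is lost non-dbtaxa over the group's
    total taxa. Families with fewer than ``min_family_nondb`` non-dbtaxa
    are excluded. Returns per-group summaries (median and 5-95 bands) and
    Bonferroni-corrected pairwise t-tests between groups.
    """
    traits = traits.loc[occ.taxa]
    modern = occ.presence[:, :, occ.grid.modern]  # n_iter x n_taxa
    lost_nondb = ~modern & ~occ.db_flag[None, :]

    def per_group(column: str, keep: list[str]) -> tuple[pd.DataFrame, dict]:
        groups = {}
        for name in keep:
            mask = (traits[column] == name).to_numpy()
            if not mask.any():
                continue
            groups[name] = 100.0 * lost_nondb[:, mask].sum(axis=1) / mask.sum()
        summary = pd.DataFrame(
            {
                name: {
                    "median_pct": float(np.median(v)),
                    "p5": float(np.percentile(v, 5)),
                    "p95": float(np.percentile(v, 95)),
                }
                for name, v in groups.items()
            }
        ).T
        pairs = {}
        names = sorted(groups)
        n_cmp = max(1, len(names) * (len(names) - 1) // 2)
        for a, b in itertools.combinations(names, 2):
            if np.ptp(groups[a]) == 0 and np.ptp(groups[b]) == 0:
                # degenerate constant series: identical -> p 1, else separated
                p = 1.0 if groups[a][0] == groups[b][0] else 0.0
                pairs[(a, b)] = p
                continue
            pairs[(a, b)] = group_compare(
                groups[a], groups[b], test="t", n_comparisons=n_cmp
            ).pvalue
        return summary, pairs

    type_summary, type_tests = per_group(
        "functional_type", sorted(traits["functional_type"].unique())
    )
    nondb_counts = traits.loc[~occ.db_flag, "family"].value_counts()
    families = sorted(nondb_counts.index[nondb_counts >= min_family_nondb])
    family_summary, family_tests = per_group("family", families)
    return {
        "type_summary": type_summary,
        "type_tests": type_tests,
        "family_summary": family_summary,
        "family_tests": family_tests,
    }


# --------------------------------------------------------------------------
# turnover

def replacement_component(a: int, b: int, c: int, family: str = "baselga") -> float:
    """Replacement (turnover) part of presence/absence dissimilarity.

    ``a`` shared taxa, ``b``/``c`` taxa unique to either assemblage.
    Baselga-style (Simpson): min(b, c) / (a + min(b, c));
    Podani/Carvalho-style: 2 min(b, c) / (a + b + c).
    """
    m = min(b, c)
    if family == "baselga":
        denom = a + m
    elif family == "podani":
        denom = a + b + c
        m = 2 * m
    else:
        raise ValueError(f"unknown decomposition family {family!r}")
    if denom == 0:
        return np.nan
    return m / denom


def turnover(occ: TaxonOccupancy, family: str = "baselga") -> pd.DataFrame:
    """Replacement series per slice transition, with median and 5-95 bands.

    Computed on presence/absence per iteration; transitions where both
    slices are empty are undefined (NaN).
    """
    pres = occ.presence
    n_iter, _, n_slices = pres.shape
    vals = np.full((n_iter, n_slices - 1), np.nan)
    for t in range(n_slices - 1):
        p0 = pres[:, :, t]
        p1 = pres[:, :, t + 1]
        a = (p0 & p1).sum(axis=1)
        b = (p0 & ~p1).sum(axis=1)
        c = (~p0 & p1).sum(axis=1)
        for it in range(n_iter):
            vals[it, t] = replacement_component(a[it], b[it], c[it], family)
    rows = []
    for t in range(n_slices - 1):
        col = vals[:, t]
        ok = np.isfinite(col)
        rows.append(
            {
                "transition": t,
                "median": float(np.median(col[ok])) if ok.any() else np.nan,
                "p5": float(np.percentile(col[ok], 5)) if ok.any() else np.nan,
                "p95": float(np.percentile(col[ok], 95)) if ok.any() else np.nan,
            }
        )
    out = pd.DataFrame(rows).set_index("transition")
    out.attrs["per_iteration"] = vals
    return out


# --------------------------------------------------------------------------
# binomial driver model

@dataclass
class DriverFit:
    """Pairwise binomial-GLM screens of loss drivers.

    One row per covariate: coefficient, likelihood-ratio chi-square
    against the intercept-only model (df = 1) and its p-value;
    ``flagged`` marks fits rescued by an L2 penalty after separation.
    """

    table: pd.DataFrame


def _penalised_logit(y: np.ndarray, x: np.ndarray, alpha: float = 1.0):
    """Ridge-penalised logistic fit used when the ML fit separates."""
    import statsmodels.api as sm

    X = sm.add_constant(x)
    model = sm.Logit(y, X)
    res = model.fit_regularized(alpha=alpha, L1_wt=0.0, disp=0)
    eta = X @ res.params
    ll = float(np.sum(y * eta - np.log1p(np.exp(eta))))
    p0 = y.mean()
    ll0 = float(np.sum(y * np.log(p0) + (1 - y) * np.log1p(-p0))) if 0 < p0 < 1 else 0.0
    return float(res.params[1]), max(0.0, 2 * (ll - ll0))


def driver_glm(response: np.ndarray, covariates: pd.DataFrame) -> DriverFit:
    """Fit a binomial GLM per covariate and report likelihood-ratio tests.

    ``response`` is a binary array (n_iter x n_points or flat) marking
    slices/iterations where a positive net loss was observed; each
    covariate column must align with the last response axis and is tiled
    across iterations. Covariates carrying a temporal lag (e.g. turnover
    shifted one slice earlier) are expected to be pre-aligned by the
    caller (see :func:`lag_series`).
    """
    import statsmodels.api as sm

    resp = np.asarray(response, dtype=float)
    if resp.ndim == 1:
        resp = resp[None, :]
    n_iter, n_pts = resp.shape
    if n_pts != len(covariates):
        raise ValueError("covariates not aligned with response axis")
    y_full = resp.ravel()
    rows = []
    for name in covariates.columns:
        x_full = np.tile(covariates[name].to_numpy(dtype=float), n_iter)
        ok = np.isfinite(x_full) & np.isfinite(y_full)
        y, x = y_full[ok], x_full[ok]
        if np.ptp(x) == 0:
            rows.append(
                {"covariate": name, "coef": 0.0, "chi2": 0.0, "pvalue": 1.0, "flagged": False}
            )
            continue
        X = sm.add_constant(x)
        flagged = False
        try:
            from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

            with warnings.catch_warnings():
                warnings.simplefilter("error", PerfectSeparationWarning)
                fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
            coef = float(fit.params[1])
            chi2 = max(0.0, 2 * (fit.llf - fit.llnull))
            if not np.isfinite(chi2) or abs(coef) > 50:
                raise RuntimeError("separation suspected")
        except Exception:
            flagged = True
            coef, chi2 = _penalised_logit(y, x)
        rows.append(
            {
                "covariate": name,
                "coef": coef,
                "chi2": chi2,
                "pvalue": float(stats.chi2.sf(chi2, df=1)),
                "flagged": flagged,
            }
        )
    return DriverFit(pd.DataFrame(rows).set_index("covariate"))


def lag_series(values: np.ndarray, lag: int = 1) -> np.ndarray:
    """Shift a slice-indexed series so earlier values align with later ones.

    ``lag=1`` aligns each point with the value one slice earlier (the
    leading positions become NaN and are dropped by the GLM).
    """
    v = np.asarray(values, dtype=float)
    out = np.full_like(v, np.nan)
    if lag == 0:
        return v.copy()
    out[lag:] = v[:-lag]
    return out
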