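"""Association between per-call factors and replicate concordance status.

Every SNV position of every replicate pair is pooled into one table with a
binary concordance status (1 = same genotype called in both replicates,
0 = called in one only or with differing genotypes) and the factor values
at that position.  Four complementary views of factor importance:

* group comparison — factor means in the reproduced vs not-reproduced
  groups with a two-sided t-test;
* per-factor R² — one-way ANOVA share of concordance-rate variation
  explained by the factor's bins;
* mutual information between status and the binned factor (plug-in
  estimate, nats);
* univariate-logistic AIC per factor, and the order in which factors enter
  an L1-penalised multivariate logistic model as the penalty relaxes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .binning import BinScheme
from .io import FACTOR_NAMES, CallSet


def pool_status(pairs: Sequence[tuple[CallSet, CallSet]]) -> pd.DataFrame:
    """Pool all SNV calls of all pairs into a status table.

    One row per (pair, position) where the position is an SNV call in at
    least one replicate (N1 + N2 - Nc rows per pair).  Factor columns hold
    the mean of the two replicates' values at the position; when only one
    replicate called the variant, the other replicate's value comes from
    its consensus record, and if that is also absent the single available
    value is used.
    """
    rows = []
    for pair_id, (a, b) in enumerate(pairs):
        for key in sorted(set(a.variants) | set(b.variants)):
            va, vb = a.variants.get(key), b.variants.get(key)
            status = int(va is not None and vb is not None and va.genotype == vb.genotype)
            row = {
                "sample_id": a.sample_id, "pair_id": pair_id,
                "chrom": key[0], "pos": key[1], "status": status,
            }
            for f in FACTOR_NAMES:
                vals = [x for x in (a.factor_at(key, f), b.factor_at(key, f)) if x is not None]
                row[f] = float(np.mean(vals)) if vals else np.nan
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class GroupDifference:
    factor_name: str
    mean_concordant: float
    sd_concordant: float
    mean_discordant: float
    sd_discordant: float
    t_pvalue: float


def group_difference_test(table: pd.DataFrame, factor_name: str) -> GroupDifference:
    """Mean +/- sd of a factor in the reproduced (status=1) and
    not-reproduced (status=0) groups, with a Welch two-sided t-test."""
    x1 = table.loc[table["status"] == 1, factor_name].dropna()
    x0 = table.loc[table["status"] == 0, factor_name].dropna()
    if len(x1) < 2 or len(x0) < 2:
        raise ValueError("each status group needs at least 2 values")
    _, p = stats.ttest_ind(x1, x0, equal_var=False)
    return GroupDifference(factor_name,
                           float(x1.mean()), float(x1.std(ddof=1)),
                           float(x0.mean()), float(x0.std(ddof=1)),
                           float(p))


def factor_r2(stratified: pd.DataFrame) -> tuple[float, float]:
    """One-way ANOVA R² of per-pair concordance rates grouped by bin.

    ``stratified`` is the long table from
    :func:`varconcord.binning.stratified_rates_over_pairs` (columns ``bin``
    and ``rate``).  Returns (R², ANOVA p-value); R² = SS_between /
    SS_total is the share of concordance-rate variation the factor's bins
    explain on their own.
    """
    groups = [g["rate"].to_numpy() for _, g in stratified.groupby("bin") if len(g) >= 1]
    groups = [g for g in groups if len(g)]
    if len(groups) < 2:
        raise ValueError("need at least 2 non-empty bins")
    allv = np.concatenate(groups)
    grand = allv.mean()
    ss_total = float(((allv - grand) ** 2).sum())
    ss_between = float(sum(len(g) * (g.mean() - grand) ** 2 for g in groups))
    r2 = 1.0 if ss_total == 0 else ss_between / ss_total
    test_groups = [g for g in groups if len(g) >= 2]
    if len(test_groups) >= 2 and ss_total > 0:
        _, p = stats.f_oneway(*test_groups)
        p = float(p)
    else:
        p = float("nan")
    return r2, p


def mutual_information(table: pd.DataFrame, factor_name: str,
                       scheme: BinScheme, unit: str = "nats") -> float:
    """Plug-in mutual information I(status; binned factor).

    I = sum_{s,b} p(s,b) ln[ p(s,b) / (p(s) p(b)) ], with 0 ln 0 := 0.
    Rows whose factor value falls outside the scheme are dropped.
    """
    sub = table[["status", factor_name]].dropna()
    if sub.empty:
        raise ValueError("empty status table")
    bins = scheme.assign(sub[factor_name].to_numpy())
    keep = bins >= 0
    status = sub["status"].to_numpy()[keep]
    bins = bins[keep]
    if len(bins) == 0:
        raise ValueError(f"no {factor_name} values fall inside the bin scheme")
    joint = np.zeros((2, scheme.n_bins))
    np.add.at(joint, (status, bins), 1.0)
    return mi_from_joint(joint, unit=unit)


def mi_from_joint(joint: np.ndarray, unit: str = "nats") -> float:
    """Mutual information of a joint count (or probability) matrix."""
    joint = np.asarray(joint, dtype=float)
    p = joint / joint.sum()
    ps = p.sum(axis=1, keepdims=True)
    pb = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log(p / (ps @ pb))
    mi = float(np.nansum(terms))
    mi = max(mi, 0.0)  # clip tiny negative rounding residue
    if unit == "bits":
        return mi / np.log(2)
    if unit != "nats":
        raise ValueError("unit must be 'nats' or 'bits'")
    return mi


@dataclass(frozen=True)
class AicResult:
    factor_name: str
    aic: float
    separation_flagged: bool = False


def univariate_aic(table: pd.DataFrame, factor_name: str) -> AicResult:
    """AIC of the univariate logistic model status ~ factor.

    Fit by maximum likelihood (two parameters); AIC = 2k - 2 ln L.  Under
    perfect separation the MLE diverges; the fit is then taken from a
    ridge-stabilised refit and flagged.
    """
    import statsmodels.api as sm

    sub = table[["status", factor_name]].dropna()
    y = sub["status"].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both status classes must be present")
    X = sm.add_constant(sub[factor_name].to_numpy(dtype=float))
    model = sm.Logit(y, X)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=RuntimeWarning)
            res = model.fit(disp=False, maxiter=200)
        if not res.mle_retvals.get("converged", True):
            raise RuntimeError("not converged")
        # k = 2 (intercept + slope) by model definition, even when the
        # factor is degenerate and the fit is rank-deficient
        return AicResult(factor_name, 2 * 2 - 2 * float(res.llf))
    except Exception:
        res = model.fit_regularized(disp=False, alpha=1e-6, maxiter=500)
        llf = float(model.loglike(res.params))
        warnings.warn(f"possible separation fitting {factor_name!r}; "
                      "AIC from penalised refit")
        return AicResult(factor_name, 2 * 2 - 2 * llf, separation_flagged=True)


@dataclass(frozen=True)
class LassoEntry:
    factor_name: str
    rank: int                 # 1 = entered first; tied factors share a rank
    entry_lambda: Optional[float]  # None if never entered on the grid
    tied_with: tuple[str, ...] = ()


def lasso_entry_order(table: pd.DataFrame, factor_names: Sequence[str],
                      n_lambda: int = 100, lambda_min_ratio: float = 1e-3,
                      exclude: Sequence[str] = ()) -> list[LassoEntry]:
    """Order in which factors enter the L1-penalised logistic model.

    Predictors are standardised to unit variance; the penalty grid runs
    from lambda_max (where every coefficient is zero, lambda_max =
    max_j |x_j'(y - ybar)| / n) down to ``lambda_min_ratio * lambda_max``
    over ``n_lambda`` log-spaced points.  A factor's entry point — the
    largest lambda at which its coefficient is nonzero — is bracketed on
    the grid and refined by bisection; earlier entry means stronger
    association with concordance status.  Factors that are
    duplicates after standardisation (|correlation| = 1) enter at the same
    lambda mathematically and are reported as an explicit tie, as are
    factors first appearing at the same grid point.  ``exclude`` removes
    factors before fitting (used to re-rank without a dominant factor).
    """
    from sklearn.linear_model import LogisticRegression

    names = [f for f in factor_names if f not in set(exclude)]
    if len(names) < 2:
        raise ValueError("need at least 2 factors")
    sub = table[["status", *names]].dropna()
    y = sub["status"].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both status classes must be present")
    X = sub[names].to_numpy(dtype=float)
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)

    # exact-duplicate predictors tie by symmetry; fit on one representative
    rep_of: dict[str, str] = {}
    keep_idx: list[int] = []
    for j, name in enumerate(names):
        dup = None
        for i in keep_idx:
            if abs(float(np.corrcoef(X[:, i], X[:, j])[0, 1])) > 1 - 1e-12:
                dup = names[i]
                break
        if dup is None:
            keep_idx.append(j)
            rep_of[name] = name
        else:
            rep_of[name] = dup
    Xk = X[:, keep_idx]
    kept = [names[i] for i in keep_idx]

    n = len(y)
    lam_max = float(np.max(np.abs(Xk.T @ (y - y.mean()))) / n)
    lambdas = np.geomspace(lam_max, lambda_min_ratio * lam_max, n_lambda)

    def coefs_at(lam: float) -> np.ndarray:
        clf = LogisticRegression(solver="liblinear", l1_ratio=1.0,
                                 C=1.0 / (n * lam), tol=1e-8, max_iter=2000)
        clf.fit(Xk, y)
        return clf.coef_[0]

    def refine(j: int, lo: float, hi: float, iters: int = 20) -> float:
        # entry threshold of factor j: active at lo, inactive at hi
        for _ in range(iters):
            mid = np.sqrt(lo * hi)
            if abs(coefs_at(mid)[j]) > 1e-9:
                lo = mid
            else:
                hi = mid
        return float(np.sqrt(lo * hi))

    entry_lam: dict[str, Optional[float]] = {f: None for f in kept}
    prev = lam_max
    for lam in lambdas:
        coef = coefs_at(lam)
        for j, f in enumerate(kept):
            if entry_lam[f] is None and abs(coef[j]) > 1e-9:
                entry_lam[f] = refine(j, float(lam), prev) if lam < prev else float(lam)
        prev = float(lam)
        if all(v is not None for v in entry_lam.values()):
            break

    full_entry = {f: entry_lam[rep_of[f]] for f in names}
    # group ties: same entry lambda (or duplicate representative)
    order = sorted(names, key=lambda f: (-(full_entry[f] or -np.inf),
                                         full_entry[f] is None))
    entries: list[LassoEntry] = []
    rank = 0
    prev_lam = object()
    for f in order:
        lam = full_entry[f]
        if lam != prev_lam:
            rank = len(entries) + 1
            prev_lam = lam
        ties = tuple(g for g in names if g != f and full_entry[g] == lam and lam is not None)
        entries.append(LassoEntry(f, rank, lam, ties))
    return entries


@dataclass(frozen=True)
class AssociationSummary:
    """Per-factor association measures, one row per factor."""

    table: pd.DataFrame  # columns: factor, r2, anova_p, mi_nats, mi_bits, aic, lasso_rank

    def to_json(self) -> str:
        return self.table.to_json(orient="records")


def summarize_associations(status_table: pd.DataFrame,
                           schemes: dict[str, BinScheme],
                           stratified: Optional[dict[str, pd.DataFrame]] = None,
                           factor_names: Sequence[str] = FACTOR_NAMES) -> AssociationSummary:
    """Assemble MI, AIC, lasso rank (and R² when stratified rates are
    supplied) for each factor into one summary table."""
    entries = lasso_entry_order(status_table, list(factor_names))
    rank = {e.factor_name: e.rank for e in entries}
    rows = []
    for f in factor_names:
        mi = mutual_information(status_table, f, schemes[f])
        aic = univariate_aic(status_table, f)
        row = {
            "factor": f,
            "mi_nats": mi,
            "mi_bits": mi / np.log(2),
            "aic": aic.aic,
            "lasso_rank": rank.get(f),
        }
        if stratified is not None and f in stratified:
            r2, p = factor_r2(stratified[f])
            row["r2"] = r2
            row["anova_p"] = p
        rows.append(row)
    return AssociationSummary(pd.DataFrame(rows))
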