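"""Attribution of expression deregulation to gene dosage.

The central question: of the genes whose copy number is altered in a tumor,
how many are deregulated beyond the background rate seen in two-copy genes?
The pooled difference between the two deregulation rates estimates the
fraction of copy-number-altered genes deregulated directly by dosage.
Supporting analyses: the regression of deregulated-gene counts on genome
burden, a forward-stepwise decomposition of burden onto chromosome arms, the
exclusive-set comparison of high- versus low-burden tumors with recurrence
bounds, and per-gene correlation of expression with an arm's burden.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

from .expression import SamResult


# ---------------------------------------------------------------------------
# Cross-tabulation: CN status x expression status
# ---------------------------------------------------------------------------

@dataclass
class AttributionSummary:
    """Pooled dosage-attribution rates plus the per-tumor count table.

    Rates use the ratio-of-means convention: mean per-tumor deregulated
    count divided by mean per-tumor group size, times 100.
    """

    per_tumor: pd.DataFrame   # columns: sample, n_alt, ex_alt, n_cn2, ex_cn2,
                              # ex_total
    rate_altered: float       # % deregulated among CN-altered genes
    rate_cn2: float           # % deregulated among two-copy genes
    dosage_difference: float  # percentage points
    chi2_p: float
    share_altered_of_deregulated: float  # % of deregulated genes CN-altered


def attribution_from_counts(per_tumor: pd.DataFrame) -> AttributionSummary:
    """Pooled attribution rates from per-tumor (n_alt, ex_alt, n_cn2, ex_cn2)."""
    mean_n_alt = per_tumor["n_alt"].mean()
    mean_ex_alt = per_tumor["ex_alt"].mean()
    mean_n_cn2 = per_tumor["n_cn2"].mean()
    mean_ex_cn2 = per_tumor["ex_cn2"].mean()
    rate_alt = 100.0 * mean_ex_alt / mean_n_alt if mean_n_alt else 0.0
    rate_cn2 = 100.0 * mean_ex_cn2 / mean_n_cn2 if mean_n_cn2 else 0.0
    mean_ex_total = mean_ex_alt + mean_ex_cn2
    share = 100.0 * mean_ex_alt / mean_ex_total if mean_ex_total else 0.0
    table = np.array([
        [per_tumor["ex_alt"].sum(), per_tumor["n_alt"].sum() - per_tumor["ex_alt"].sum()],
        [per_tumor["ex_cn2"].sum(), per_tumor["n_cn2"].sum() - per_tumor["ex_cn2"].sum()],
    ])
    if table.sum(axis=1).min() > 0 and table.sum(axis=0).min() > 0:
        _, p, _, _ = sps.chi2_contingency(table, correction=False)
    else:
        p = 1.0
    out = per_tumor.copy()
    if "ex_total" not in out.columns:
        out["ex_total"] = out["ex_alt"] + out["ex_cn2"]
    return AttributionSummary(
        per_tumor=out, rate_altered=rate_alt, rate_cn2=rate_cn2,
        dosage_difference=rate_alt - rate_cn2, chi2_p=float(p),
        share_altered_of_deregulated=share)


def crosstab_attribution(dosage: pd.DataFrame,
                         calls: pd.DataFrame) -> AttributionSummary:
    """Cross-tabulate per-gene dosage status against expression status.

    ``dosage`` holds values {1, 2, 3} (CN1/CN2/CN3) and ``calls`` values
    {-1, 0, 1}; both are genes x tumors over identical universes.
    """
    if set(dosage.columns) != set(calls.columns):
        raise ValueError("tumor sets differ between dosage and call matrices")
    if not dosage.index.equals(calls.index):
        calls = calls.reindex(dosage.index)
        if calls.isna().any().any():
            raise ValueError("gene universes differ between matrices")
    rows = []
    for sample in dosage.columns:
        alt = dosage[sample] != 2
        dereg = calls[sample] != 0
        rows.append({
            "sample": sample,
            "n_alt": int(alt.sum()),
            "ex_alt": int((alt & dereg).sum()),
            "n_cn2": int((~alt).sum()),
            "ex_cn2": int((~alt & dereg).sum()),
            "ex_total": int(dereg.sum()),
        })
    return attribution_from_counts(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Regressions
# ---------------------------------------------------------------------------

@dataclass
class RegressionFit:
    slope: float
    intercept: float
    r: float
    p: float
    predictors: list[str] = field(default_factory=list)
    coefficients: dict[str, float] = field(default_factory=dict)
    adj_r2: float = float("nan")
    contribution_share: dict[str, float] = field(default_factory=dict)


def burden_expression_regression(burden_pct, deregulated_counts) -> RegressionFit:
    """OLS of per-tumor deregulated-gene counts on %CN-AG."""
    x = np.asarray(burden_pct, dtype=float)
    y = np.asarray(deregulated_counts, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 tumors")
    if np.std(x) == 0:
        raise ValueError("zero burden variance: correlation undefined")
    res = sps.linregress(x, y)
    return RegressionFit(slope=float(res.slope), intercept=float(res.intercept),
                         r=float(res.rvalue), p=float(res.pvalue))


def _adj_r2(model) -> float:
    return float(model.rsquared_adj)


def arm_mlr_decomposition(predictors: pd.DataFrame, response,
                          forward_p_enter: float = 0.05) -> RegressionFit:
    """Forward-stepwise multiple linear regression of a response on per-arm
    burdens.

    Predictors enter by smallest partial-F p-value while below
    ``forward_p_enter``. Reports the selected arms in entry order, the final
    adjusted r-squared, and each predictor's incremental r-squared as a share
    of the final model's r-squared (the first entry's share is the headline
    "fraction of the variation accounted for" statistic). Near-collinear
    candidates (condition number above 1e8 after entry) are skipped.
    """
    y = np.asarray(response, dtype=float)
    X = predictors.astype(float)
    selected: list[str] = []
    r2_steps: list[float] = []
    current_r2 = 0.0
    remaining = [c for c in X.columns if np.std(X[c]) > 0]
    n = len(y)
    while remaining:
        best = None
        for cand in remaining:
            cols = selected + [cand]
            design = sm.add_constant(X[cols])
            if np.linalg.cond(design.to_numpy()) > 1e8:
                continue
            fit = sm.OLS(y, design).fit()
            # partial F for the newly entered term == squared t-test
            p = float(fit.pvalues[cand])
            if best is None or p < best[1]:
                best = (cand, p, fit)
        if best is None or best[1] >= forward_p_enter:
            break
        cand, _, fit = best
        selected.append(cand)
        remaining.remove(cand)
        r2_steps.append(float(fit.rsquared))
        current_r2 = float(fit.rsquared)
        final_fit = fit
    if not selected:
        return RegressionFit(slope=float("nan"), intercept=float("nan"),
                             r=0.0, p=1.0, adj_r2=0.0)
    increments = np.diff([0.0] + r2_steps)
    shares = {arm: float(inc / current_r2) if current_r2 else 0.0
              for arm, inc in zip(selected, increments)}
    coeffs = {c: float(final_fit.params[c]) for c in selected}
    first = selected[0]
    return RegressionFit(
        slope=coeffs[first], intercept=float(final_fit.params["const"]),
        r=float(np.sqrt(current_r2)), p=float(final_fit.f_pvalue),
        predictors=selected, coefficients=coeffs,
        adj_r2=_adj_r2(final_fit), contribution_share=shares)


# ---------------------------------------------------------------------------
# Exclusive-set analysis
# ---------------------------------------------------------------------------

RECURRENCE_STRATA = ("ge6", "4to5", "1to3", "0")


@dataclass
class ExclusiveSetReport:
    n_high: int
    n_low: int
    n_common: int
    n_exclusive_high: int
    strata: dict[str, int]            # counts at >=6 / 4-5 / 1-3 / 0 tumors
    pct_shared: float                 # |common| / |D_low| x 100
    pct_exclusive_of_high: float      # |exclusive_high| / |D_high| x 100
    pct_dosage_bound: float           # altered in >= threshold / |exclusive| x 100
    recurrence_threshold: int
    exclusive_high_genes: list[str] = field(default_factory=list)
    degenerate: bool = False          # empty D_high: percentages undefined


def exclusive_set_from_counts(n_high: int, n_low: int, n_common: int,
                              strata: dict[str, int],
                              recurrence_threshold: int = 4) -> ExclusiveSetReport:
    """Exclusive-set percentages from pre-tabulated set sizes."""
    n_excl = n_high - n_common
    if sum(strata.values()) != n_excl:
        raise ValueError("recurrence strata must sum to the exclusive set size")
    degenerate = n_high == 0 or n_low == 0 or n_excl == 0
    pct_shared = 100.0 * n_common / n_low if n_low else 0.0
    pct_excl = 100.0 * n_excl / n_high if n_high else 0.0
    bound_count = strata["ge6"] + strata["4to5"] if recurrence_threshold == 4 \
        else sum(v for k, v in strata.items() if k in ("ge6", "4to5", "1to3"))
    pct_bound = 100.0 * bound_count / n_excl if n_excl else 0.0
    return ExclusiveSetReport(
        n_high=n_high, n_low=n_low, n_common=n_common, n_exclusive_high=n_excl,
        strata=dict(strata), pct_shared=pct_shared,
        pct_exclusive_of_high=pct_excl, pct_dosage_bound=pct_bound,
        recurrence_threshold=recurrence_threshold, degenerate=degenerate)


def exclusive_set_analysis(sam_high: SamResult, sam_low: SamResult,
                           dosage: pd.DataFrame, high_tumors: list[str],
                           recurrence_threshold: int = 4) -> ExclusiveSetReport:
    """Genes deregulated only in high-burden tumors, with recurrence bounds.

    ``pct_dosage_bound`` is the share of the exclusive-high set that is CN
    altered in at least ``recurrence_threshold`` of the high-group tumors —
    a conservative cap on how many of those genes dosage could explain.
    """
    d_high = set(sam_high.called_genes)
    d_low = set(sam_low.called_genes)
    common = d_high & d_low
    exclusive = sorted(d_high - d_low)
    sub = dosage.loc[dosage.index.intersection(exclusive), list(high_tumors)]
    n_altered = (sub != 2).sum(axis=1).reindex(exclusive, fill_value=0)
    strata = {
        "ge6": int((n_altered >= 6).sum()),
        "4to5": int(((n_altered >= 4) & (n_altered <= 5)).sum()),
        "1to3": int(((n_altered >= 1) & (n_altered <= 3)).sum()),
        "0": int((n_altered == 0).sum()),
    }
    n_excl = len(exclusive)
    bound_count = int((n_altered >= recurrence_threshold).sum())
    return ExclusiveSetReport(
        n_high=len(d_high), n_low=len(d_low), n_common=len(common),
        n_exclusive_high=n_excl, strata=strata,
        pct_shared=100.0 * len(common) / len(d_low) if d_low else 0.0,
        pct_exclusive_of_high=100.0 * n_excl / len(d_high) if d_high else 0.0,
        pct_dosage_bound=100.0 * bound_count / n_excl if n_excl else 0.0,
        recurrence_threshold=recurrence_threshold,
        exclusive_high_genes=exclusive,
        degenerate=not d_high or not d_low or not exclusive)


# ---------------------------------------------------------------------------
# Per-gene correlation with one arm's burden
# ---------------------------------------------------------------------------

def arm_burden_gene_correlation(arm_burden: pd.Series,
                                expr_linear: pd.DataFrame,
                                alpha: float = 0.05) -> pd.DataFrame:
    """Pearson correlation of each gene's intensity with an arm's %CN-AG.

    No multiple-testing correction is applied (raw p < alpha flags), matching
    the convention of per-gene screens against a single burden covariate.
    Constant-expression genes are excluded and flagged.
    """
    tumors = [t for t in expr_linear.columns if t in arm_burden.index]
    if len(tumors) < 3:
        raise ValueError("need at least 3 tumors with both measurements")
    x = arm_burden.loc[tumors].to_numpy(float)
    if np.std(x) == 0:
        raise ValueError("arm burden is constant across tumors")
    rows = []
    for gene, vals in expr_linear[tumors].iterrows():
        y = vals.to_numpy(float)
        if np.std(y) == 0:
            rows.append({"gene_id": gene, "r": np.nan, "p": np.nan,
                         "significant": False, "constant": True})
            continue
        r, p = sps.pearsonr(x, y)
        rows.append({"gene_id": gene, "r": float(r), "p": float(p),
                     "significant": bool(p < alpha), "constant": False})
    return pd.DataFrame(rows).set_index("gene_id")
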