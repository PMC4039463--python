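"""Survival analysis of burden and expression-profile groups.

Overall survival is cause-specific: only deaths from the primary tumor count
as events; deaths of other or unknown cause are censored at the death time,
and untreated patients are excluded entirely. FIGO stage is coded ordinally
IB1 < IB2 < IIA < IIB < IIIB < IVA < IVB.

Kaplan-Meier estimation, the k-group log-rank test and the Cox proportional
hazards model (Breslow tie handling) are provided by lifelines; the
ROC/Youden burden cutoff and the Spearman co-linearity checks are computed
directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test

FIGO_ORDER = ("IB1", "IB2", "IIA", "IIB", "IIIB", "IVA", "IVB")

STATUS_ALIVE = "alive"
STATUS_DEATH = "death"
STATUS_CENSORED_DEATH = "censored-death"


def figo_rank(stage: str) -> int:
    """Ordinal code of a FIGO stage (IB1 = 0 ... IVB = 6)."""
    try:
        return FIGO_ORDER.index(stage)
    except ValueError:
        raise ValueError(f"unknown FIGO stage {stage!r}") from None


@dataclass
class SurvivalCohort:
    """Treated patients with cause-specific event coding.

    ``data`` columns: sample, time (months), event (1 = death from the
    primary tumor), stage, figo_rank plus any passed-through label columns.
    """

    data: pd.DataFrame
    n_excluded_untreated: int

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def n_events(self) -> int:
        return int(self.data["event"].sum())

    @property
    def survival_rate(self) -> float:
        """End-of-follow-up surviving proportion (%): alive plus censored."""
        return 100.0 * (self.n - self.n_events) / self.n if self.n else float("nan")

    @property
    def mean_time_to_death(self) -> float:
        """Mean follow-up months among patients who died of the tumor."""
        events = self.data[self.data["event"] == 1]
        return float(events["time"].mean()) if len(events) else float("nan")


def _normalise_status(status: str) -> str:
    s = str(status).strip().lower()
    if s in ("alive", "censored"):
        return STATUS_ALIVE
    if s in ("death", "dead", "deceased"):
        return STATUS_DEATH
    if s in ("death*", "censored-death"):
        return STATUS_CENSORED_DEATH
    raise ValueError(f"unknown status {status!r}")


def build_cohort(clinical: pd.DataFrame,
                 keep_columns: list[str] | None = None) -> SurvivalCohort:
    """Build the analysis cohort from a clinical table.

    Expects columns ``sample``, ``stage``, ``followup_months``, ``status``
    (alive / death / censored-death, or the table-style Death* for a death of
    unknown cause) and either a boolean ``treated`` column or a ``treatment``
    text column where "UNTREATED" marks exclusion. Untreated patients are
    removed; censored-deaths are censored at the death time.
    """
    df = clinical.copy()
    missing = df["followup_months"].isna()
    if missing.any():
        raise ValueError(
            "missing follow-up time for: " +
            ", ".join(df.loc[missing, "sample"].astype(str)))
    if "treated" in df.columns:
        treated = df["treated"].astype(bool)
    elif "treatment" in df.columns:
        treated = df["treatment"].str.upper() != "UNTREATED"
    else:
        treated = pd.Series(True, index=df.index)
    n_excluded = int((~treated).sum())
    df = df[treated].copy()
    if len(df) == 0:
        warnings.warn("all patients untreated: empty survival cohort")
    status = df["status"].map(_normalise_status)
    out = pd.DataFrame({
        "sample": df["sample"].to_numpy(),
        "time": df["followup_months"].astype(float).to_numpy(),
        "event": (status == STATUS_DEATH).astype(int).to_numpy(),
        "stage": df["stage"].to_numpy(),
    })
    out["figo_rank"] = [figo_rank(s) for s in out["stage"]]
    for col in keep_columns or []:
        out[col] = df[col].to_numpy()
    return SurvivalCohort(data=out.reset_index(drop=True),
                          n_excluded_untreated=n_excluded)


@dataclass
class KMEstimate:
    group: str
    event_times: np.ndarray
    at_risk: np.ndarray
    survival: np.ndarray     # product-limit S(t) at the event times

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(cohort: SurvivalCohort,
                groups: pd.Series | None = None) -> dict[str, KMEstimate]:
    """Kaplan-Meier product-limit estimate per group (one 'all' group when
    no grouping is given)."""
    df = cohort.data
    if groups is None:
        labels = pd.Series("all", index=df["sample"])
    else:
        labels = groups
    out = {}
    for name, sub in df.groupby(labels.reindex(df["sample"]).to_numpy()):
        if len(sub) == 0:
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"])
        ev = kmf.event_table
        ev = ev[ev["observed"] > 0]
        times = ev.index.to_numpy(float)
        surv = kmf.survival_function_.loc[times, "KM_estimate"].to_numpy()
        out[str(name)] = KMEstimate(group=str(name), event_times=times,
                                    at_risk=ev["at_risk"].to_numpy(),
                                    survival=surv)
    return out


def logrank_test(cohort: SurvivalCohort, groups: pd.Series) -> tuple[float, int, float]:
    """k-group log-rank test; returns (chi-square, df, p)."""
    df = cohort.data
    g = groups.reindex(df["sample"]).to_numpy()
    if pd.isna(g).any():
        raise ValueError("every patient needs a group label")
    k = len(pd.unique(g))
    if k < 2:
        raise ValueError("need at least 2 groups")
    res = multivariate_logrank_test(df["time"], g, df["event"])
    return float(res.test_statistic), k - 1, float(res.p_value)


def roc_burden_cutoff(burdens, events) -> dict:
    """Burden cutoff maximising the Youden index J = sens + spec - 1.

    High burden predicts death; candidate cutoffs are the observed burden
    values (patients at or above the cutoff form the high group). Ties in J
    resolve toward the lower cutoff. Invariant to patient order.
    """
    b = np.asarray(burdens, dtype=float)
    e = np.asarray(events, dtype=int)
    n_pos = e.sum()
    n_neg = len(e) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both event classes required")
    best = None
    for cut in sorted(np.unique(b)):
        high = b >= cut
        sens = (e[high] == 1).sum() / n_pos
        spec = (e[~high] == 0).sum() / n_neg
        j = sens + spec - 1
        if best is None or j > best["youden_j"] + 1e-12:
            best = {"cutoff": float(cut), "sensitivity": float(sens),
                    "specificity": float(spec), "youden_j": float(j),
                    "n_high": int(high.sum()), "n_low": int((~high).sum()),
                    "mean_high": float(b[high].mean()),
                    "mean_low": float(b[~high].mean()) if (~high).any() else float("nan")}
    return best


def cox_adjusted(cohort: SurvivalCohort, covariates: pd.DataFrame) -> pd.DataFrame:
    """Cox proportional-hazards fit (Breslow ties) for the given covariates.

    ``covariates`` is indexed by sample. Returns per-covariate coefficient,
    SE, Wald p and a significance flag; monotone-likelihood (perfect
    separation) problems are flagged with a capped coefficient.
    """
    df = cohort.data.set_index("sample")
    X = covariates.reindex(df.index)
    if X.isna().any().any():
        raise ValueError("missing covariate values")
    for col in X.columns:
        if np.std(X[col].to_numpy(float)) == 0:
            raise ValueError(f"zero-variance covariate {col!r}")
    if cohort.n_events < 2:
        raise ValueError("need at least 2 events")
    frame = pd.concat([df[["time", "event"]], X.astype(float)], axis=1)
    cph = CoxPHFitter()
    flagged = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cph.fit(frame, duration_col="time", event_col="event",
                    fit_options={"precision": 1e-10})
        except ConvergenceError:
            flagged = True
            cph = CoxPHFitter(penalizer=0.1)
            cph.fit(frame, duration_col="time", event_col="event")
    summary = cph.summary
    out = pd.DataFrame({
        "coef": summary["coef"],
        "se": summary["se(coef)"],
        "p": summary["p"],
    })
    out["significant"] = out["p"] < 0.05
    out["flagged"] = flagged | (out["coef"].abs() > 20)
    out["coef"] = out["coef"].clip(-20, 20)
    return out


def spearman_colinearity(figo_ranks, measures: pd.DataFrame) -> pd.DataFrame:
    """Spearman rank correlation of each measure with FIGO stage.

    Uses mid-ranks for ties and the t-approximation p-value. Constant
    measures are flagged with an undefined correlation.
    """
    x = np.asarray(figo_ranks, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 patients")
    rows = []
    for col in measures.columns:
        y = measures[col].to_numpy(float)
        if np.std(y) == 0 or np.std(x) == 0:
            rows.append({"measure": col, "rho": np.nan, "p": np.nan,
                         "constant": True})
            continue
        rho, p = sps.spearmanr(x, y)
        rows.append({"measure": col, "rho": float(rho), "p": float(p),
                     "constant": False})
    return pd.DataFrame(rows).set_index("measure")
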