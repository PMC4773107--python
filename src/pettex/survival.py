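"""Survival dichotomization and Cox modelling of texture features.

The prognostic workflow mirrors a two-stage design: features are first
screened against 3-year disease-specific survival (DSS) with ROC curves,
dichotomized at the Youden-index cutoff, and the resulting binary
predictors enter univariate and covariate-adjusted Cox proportional
hazards models (covariates: age, adenocarcinoma histology, stage III,
radical surgery). Because three texture terms are tested, the Cox stage
applies a Bonferroni-corrected significance threshold of 0.05 / 3 = 0.017.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test
from scipy import stats

__all__ = [
    "BONFERRONI_ALPHA",
    "COVARIATES",
    "RocCutoffResult",
    "CoxResult",
    "three_year_labels",
    "roc_youden",
    "stratification_concordance",
    "cox_fit",
    "km_logrank",
    "survival_report",
]

#: Cox-stage significance threshold: 0.05 over the three texture terms
BONFERRONI_ALPHA = round(0.05 / 3, 3)

COVARIATES = ["age", "adeno", "stage3", "surgery"]


@dataclass(frozen=True)
class RocCutoffResult:
    metric: str
    auc: float
    auc_p: float
    cutoff: float
    sensitivity: float
    specificity: float
    direction: int  # +1: high values are high-risk, -1: low values are


@dataclass(frozen=True)
class CoxResult:
    term: str
    hr: float
    hr_ci_low: float
    hr_ci_high: float
    p: float
    model: str  # 'univariate' | 'adjusted'
    covariates: tuple[str, ...]


# ---------------------------------------------------------------------------
# 3-year outcome labels
# ---------------------------------------------------------------------------


def three_year_labels(cohort: pd.DataFrame, horizon: float = 36.0
                      ) -> tuple[pd.Series, int]:
    """Binary 3-year DSS outcome per patient.

    1 = disease-specific death at or before the horizon; 0 = followed at
    least to the horizon (alive, censored, or died later). Patients
    censored before the horizon cannot be classified and are excluded;
    the excluded count is returned alongside the labels.
    """
    t = cohort["time_months"].to_numpy(float)
    e = cohort["event"].to_numpy(int)
    died_early = (e == 1) & (t <= horizon)
    survived = t >= horizon
    usable = died_early | survived
    if not usable.any():
        raise ValueError("no patient can be classified at the 3-year horizon")
    labels = pd.Series(died_early[usable].astype(int),
                       index=cohort.index[usable], name="dss3y")
    return labels, int((~usable).sum())


# ---------------------------------------------------------------------------
# ROC / Youden
# ---------------------------------------------------------------------------


def _structural_components(pos: np.ndarray, neg: np.ndarray):
    """DeLong structural components: V10 per positive, V01 per negative."""
    neg_s = np.sort(neg)
    pos_s = np.sort(pos)
    lo = np.searchsorted(neg_s, pos, side="left")
    hi = np.searchsorted(neg_s, pos, side="right")
    v10 = (lo + 0.5 * (hi - lo)) / len(neg)
    lo = np.searchsorted(pos_s, neg, side="right")
    hi = np.searchsorted(pos_s, neg, side="left")
    v01 = ((len(pos) - lo) + 0.5 * (lo - hi)) / len(pos)
    return v10, v01


def roc_youden(values, labels, metric: str = "") -> RocCutoffResult:
    """Empirical ROC with the Youden-index cutoff.

    The AUC is the rank (Mann–Whitney) statistic; the test of AUC != 0.5
    uses the DeLong paired-rank variance with a normal reference. The
    cutoff search runs over midpoints between adjacent sorted unique
    values; orientation is auto-detected so the reported AUC is >= 0.5 and
    ``direction`` records which side is high-risk. Youden ties break
    toward higher specificity.
    """
    v = np.asarray(values, dtype=np.float64)
    y = np.asarray(labels, dtype=int)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("need both outcome classes present")
    if np.all(v == v[0]):
        raise ValueError("feature is constant; ROC undefined")
    pos, neg = v[y == 1], v[y == 0]
    v10, v01 = _structural_components(pos, neg)
    auc = float(v10.mean())
    var = (np.var(v10, ddof=1) / len(pos) if len(pos) > 1 else 0.0) + (
        np.var(v01, ddof=1) / len(neg) if len(neg) > 1 else 0.0
    )
    if var > 0:
        z = (auc - 0.5) / np.sqrt(var)
        auc_p = float(2 * stats.norm.sf(abs(z)))
    else:
        auc_p = 1.0 if auc == 0.5 else 0.0

    direction = 1 if auc >= 0.5 else -1
    if direction == -1:
        auc = 1.0 - auc

    uniq = np.unique(v)
    cands = (uniq[:-1] + uniq[1:]) / 2.0
    pos_s, neg_s = np.sort(pos), np.sort(neg)
    if direction == 1:  # high-risk group: v > c
        sens_all = 1.0 - np.searchsorted(pos_s, cands, side="right") / len(pos)
        spec_all = np.searchsorted(neg_s, cands, side="right") / len(neg)
    else:  # high-risk group: v < c
        sens_all = np.searchsorted(pos_s, cands, side="left") / len(pos)
        spec_all = 1.0 - np.searchsorted(neg_s, cands, side="left") / len(neg)
    # max Youden; ties toward higher specificity
    order = np.lexsort((spec_all, sens_all + spec_all - 1.0))
    k = order[-1]
    cutoff, sens, spec = float(cands[k]), float(sens_all[k]), float(spec_all[k])
    return RocCutoffResult(metric=metric, auc=auc, auc_p=auc_p, cutoff=cutoff,
                           sensitivity=sens, specificity=spec,
                           direction=direction)


def stratification_concordance(values_a, cutoff_a, values_b, cutoff_b,
                               direction: int = 1) -> float:
    """Fraction of lesions assigned the same risk stratum under the two
    variants' cutoffs."""
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if direction == 1:
        ha, hb = a > cutoff_a, b > cutoff_b
    else:
        ha, hb = a < cutoff_a, b < cutoff_b
    return float((ha == hb).mean())


# ---------------------------------------------------------------------------
# Cox / Kaplan-Meier
# ---------------------------------------------------------------------------


def cox_fit(cohort: pd.DataFrame, terms: list[str],
            duration_col: str = "time_months", event_col: str = "event",
            ties: str = "efron", model: str = "univariate") -> list[CoxResult]:
    """Efron-ties Cox proportional hazards fit; one result row per term.

    Wald CIs are formed on the log-hazard scale and exponentiated.
    Raises on rank-deficient designs and non-convergence, naming the
    offending terms.
    """
    if ties != "efron":
        raise ValueError("only Efron tie handling is implemented")
    if cohort[event_col].sum() < 1:
        raise ValueError("need at least one event to fit a Cox model")
    X = cohort[terms].to_numpy(float)
    if np.linalg.matrix_rank(X - X.mean(axis=0)) < len(terms):
        raise ValueError(f"rank-deficient design matrix for terms {terms}")
    cph = CoxPHFitter()
    try:
        cph.fit(cohort[[duration_col, event_col, *terms]],
                duration_col=duration_col, event_col=event_col,
                fit_options={"precision": 1e-14, "r_precision": 0.0,
                             "max_steps": 100})
    except ConvergenceError as err:
        raise ValueError(f"Cox fit failed to converge for terms {terms}: {err}")
    summ = cph.summary
    out = []
    for term in terms:
        row = summ.loc[term]
        out.append(CoxResult(
            term=term,
            hr=float(row["exp(coef)"]),
            hr_ci_low=float(row["exp(coef) lower 95%"]),
            hr_ci_high=float(row["exp(coef) upper 95%"]),
            p=float(row["p"]),
            model=model,
            covariates=tuple(t for t in terms if t != term),
        ))
    return out


def km_logrank(cohort: pd.DataFrame, groups,
               duration_col: str = "time_months", event_col: str = "event"):
    """Two-group Kaplan–Meier curves and the log-rank p-value.

    Returns ``(curves, p, flag)`` where ``curves`` maps group label to the
    fitted survival function and ``flag`` notes a group with zero events.
    """
    g = np.asarray(groups)
    labels = np.unique(g)
    if len(labels) != 2:
        raise ValueError("need exactly two nonempty groups")
    curves = {}
    flag = None
    for lab in labels:
        sel = g == lab
        km = KaplanMeierFitter(label=str(lab))
        km.fit(cohort.loc[sel, duration_col], cohort.loc[sel, event_col])
        curves[lab] = km
        if cohort.loc[sel, event_col].sum() == 0:
            flag = f"group {lab} has zero events"
    sel = g == labels[0]
    res = logrank_test(
        cohort.loc[sel, duration_col], cohort.loc[~sel, duration_col],
        cohort.loc[sel, event_col], cohort.loc[~sel, event_col],
    )
    return curves, float(res.p_value), flag


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------


def survival_report(cohort: pd.DataFrame, features_a: pd.DataFrame,
                    features_b: pd.DataFrame, terms: list[str],
                    alpha: float = BONFERRONI_ALPHA) -> dict[str, pd.DataFrame]:
    """ROC screening, dichotomized Cox models, and cross-variant concordance.

    ``cohort`` must be indexed like the feature tables (patient id). Each
    multivariable model contains exactly one dichotomized texture term plus
    the four clinical covariates — never two texture terms together,
    because of their collinearity.
    """
    cohort = cohort.set_index("patient_id") if "patient_id" in cohort.columns else cohort
    labels, n_excluded = three_year_labels(cohort)
    roc_rows, uni_rows, adj_rows, conc_rows = [], [], [], []
    cuts: dict[tuple[str, str], RocCutoffResult] = {}
    for variant, feats in (("hct", features_a), ("act", features_b)):
        for term in terms:
            vals = feats.loc[labels.index, term]
            roc = roc_youden(vals.to_numpy(), labels.to_numpy(),
                             metric=term)
            cuts[(variant, term)] = roc
            roc_rows.append({"variant": variant, "metric": term,
                             "auc": roc.auc, "auc_p": roc.auc_p,
                             "cutoff": roc.cutoff, "sensitivity": roc.sensitivity,
                             "specificity": roc.specificity,
                             "direction": roc.direction,
                             "n_excluded_3y": n_excluded})
            col = f"{term}_high"
            df = cohort.copy()
            allv = feats.loc[df.index, term].to_numpy()
            high = allv > roc.cutoff if roc.direction == 1 else allv < roc.cutoff
            df[col] = high.astype(int)
            for res in cox_fit(df, [col], model="univariate"):
                uni_rows.append({"variant": variant, "term": res.term,
                                 "hr": res.hr, "ci_low": res.hr_ci_low,
                                 "ci_high": res.hr_ci_high, "p": res.p,
                                 "significant": res.p < alpha})
            for res in cox_fit(df, [col, *COVARIATES], model="adjusted"):
                if res.term != col:
                    continue
                adj_rows.append({"variant": variant, "term": res.term,
                                 "hr": res.hr, "ci_low": res.hr_ci_low,
                                 "ci_high": res.hr_ci_high, "p": res.p,
                                 "significant": res.p < alpha,
                                 "covariates": ",".join(COVARIATES)})
    for term in terms:
        ra, rb = cuts[("hct", term)], cuts[("act", term)]
        conc_rows.append({
            "metric": term,
            "concordance": stratification_concordance(
                features_a[term].to_numpy(), ra.cutoff,
                features_b[term].to_numpy(), rb.cutoff,
                direction=ra.direction,
            ),
        })
    return {
        "roc": pd.DataFrame(roc_rows),
        "cox_univariate": pd.DataFrame(uni_rows),
        "cox_adjusted": pd.DataFrame(adj_rows),
        "concordance": pd.DataFrame(conc_rows),
        "alpha": alpha,
    }
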