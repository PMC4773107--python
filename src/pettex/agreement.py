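"""Paired agreement statistics between two attenuation-correction variants.

For each metric measured under both variants (A = HCT, B = ACT) on the
same lesions:

* **Wilcoxon signed-rank** two-sided p for a systematic paired shift;
* **ICC(2,1)** — two-way random effects, absolute agreement, single
  measures — with the F-distribution 95% CI; *precision* is half the CI
  width, in percent;
* **Bland–Altman** on percentage differences ``100 (B - A) / mean(A, B)``:
  mean, SD, lower/upper reproducibility limits (mean -/+ 1.96 SD) and
  *variation* = URL - LRL;
* **Spearman** absolute rank correlation between features.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .texture import FEATURE_NAMES

__all__ = [
    "METRIC_ORDER",
    "WilcoxonResult",
    "IccResult",
    "BlandAltmanResult",
    "precision_from_ci",
    "variation_from_limits",
    "wilcoxon_signed_rank",
    "icc_agreement",
    "bland_altman",
    "spearman_matrix",
    "agreement_report",
]

#: report row order: the three SUV metrics then the 12 texture features
METRIC_ORDER = ["suvmax", "suvmean", "tlg", *FEATURE_NAMES]


def precision_from_ci(ci_low: float, ci_high: float) -> float:
    """Half the width of an ICC 95% CI, in percent."""
    return 100.0 * (ci_high - ci_low) / 2.0


def variation_from_limits(lrl: float, url: float) -> float:
    """Range between the reproducibility limits."""
    return url - lrl


# ---------------------------------------------------------------------------
# Wilcoxon
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WilcoxonResult:
    p: float
    n_effective: int
    degenerate: bool  # all paired differences were zero


def wilcoxon_signed_rank(a, b) -> WilcoxonResult:
    """Two-sided signed-rank test on paired samples.

    Zero differences are dropped. Exact null distribution when the
    effective n <= 25 with untied absolute differences, otherwise the
    normal approximation with tie and continuity correction.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = b - a
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return WilcoxonResult(p=1.0, n_effective=0, degenerate=True)
    exact = n <= 25 and len(np.unique(np.abs(d))) == n
    res = stats.wilcoxon(d, correction=not exact,
                         method="exact" if exact else "approx")
    return WilcoxonResult(p=float(res.pvalue), n_effective=n, degenerate=False)


# ---------------------------------------------------------------------------
# ICC(2,1)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IccResult:
    icc: float
    ci_low: float
    ci_high: float
    precision_pct: float
    flag: str | None = None  # 'undefined' | 'perfect' | None


def icc_agreement(a, b, alpha: float = 0.05) -> IccResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measures.

    Computed from the two-way ANOVA mean squares of the n x 2 table; the CI
    follows the F-distribution method of McGraw & Wong. Degenerate inputs:
    zero between-subject variance makes the ICC undefined (NaN + flag);
    exactly identical members give ICC 1 with zero-width CI.
    """
    x = np.column_stack([np.asarray(a, float), np.asarray(b, float)])
    n, k = x.shape
    if n < 3:
        raise ValueError("need at least 3 paired observations for the ICC")

    grand = x.mean()
    row_m = x.mean(axis=1)
    col_m = x.mean(axis=0)
    msr = k * ((row_m - grand) ** 2).sum() / (n - 1)
    msc = n * ((col_m - grand) ** 2).sum() / (k - 1)
    sse = ((x - row_m[:, None] - col_m[None, :] + grand) ** 2).sum()
    mse = sse / ((n - 1) * (k - 1))

    if msr == 0:
        return IccResult(icc=float("nan"), ci_low=float("nan"),
                         ci_high=float("nan"), precision_pct=float("nan"),
                         flag="undefined")
    if mse == 0 and msc == 0:
        return IccResult(icc=1.0, ci_low=1.0, ci_high=1.0,
                         precision_pct=0.0, flag="perfect")

    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    if 1 - icc < 1e-12:  # numerically perfect agreement
        return IccResult(icc=1.0, ci_low=1.0, ci_high=1.0,
                         precision_pct=0.0, flag="perfect")

    # McGraw & Wong (1996) F-based interval via the Satterthwaite df
    a_ = k * icc / (n * (1 - icc))
    b_ = 1 + k * icc * (n - 1) / (n * (1 - icc))
    v = (a_ * msc + b_ * mse) ** 2 / (
        (a_ * msc) ** 2 / (k - 1) + (b_ * mse) ** 2 / ((n - 1) * (k - 1))
    )
    f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lo = n * (msr - f_l * mse) / (
        f_l * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    hi = n * (f_u * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_u * msr
    )
    return IccResult(icc=float(icc), ci_low=float(lo), ci_high=float(hi),
                     precision_pct=precision_from_ci(float(lo), float(hi)))


# ---------------------------------------------------------------------------
# Bland–Altman
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BlandAltmanResult:
    mean_pct: float
    sd_pct: float
    lrl_pct: float
    url_pct: float
    variation_pct: float


def bland_altman(a, b, ids=None) -> BlandAltmanResult:
    """Percentage-difference Bland–Altman statistics for B vs A."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1D and of equal length")
    if len(a) < 2:
        raise ValueError("need at least 2 pairs")
    mean_ab = (a + b) / 2.0
    if np.any(mean_ab == 0):
        i = int(np.flatnonzero(mean_ab == 0)[0])
        name = ids[i] if ids is not None else i
        raise ValueError(f"pair mean is zero for lesion {name}; percentage "
                         "difference undefined")
    d = 100.0 * (b - a) / mean_ab
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    lrl = mean - 1.96 * sd
    url = mean + 1.96 * sd
    return BlandAltmanResult(mean_pct=mean, sd_pct=sd, lrl_pct=lrl,
                             url_pct=url,
                             variation_pct=variation_from_limits(lrl, url))


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------


def spearman_matrix(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise |rho| and p-values between feature columns.

    Average ranks handle ties; a constant column yields NaN and is left
    flagged by the NaN itself. Requires >= 5 rows.
    """
    if len(table) < 5:
        raise ValueError("need at least 5 lesions for rank correlations")
    cols = list(table.columns)
    m = len(cols)
    rho = np.full((m, m), np.nan)
    pval = np.full((m, m), np.nan)
    for i in range(m):
        xi = table[cols[i]].to_numpy(float)
        const_i = np.all(xi == xi[0])
        for j in range(i, m):
            xj = table[cols[j]].to_numpy(float)
            if const_i or np.all(xj == xj[0]):
                continue
            if i == j:
                rho[i, j], pval[i, j] = 1.0, 0.0
                continue
            r, p = stats.spearmanr(xi, xj)
            rho[i, j] = rho[j, i] = abs(float(r))
            pval[i, j] = pval[j, i] = float(p)
    return (pd.DataFrame(rho, index=cols, columns=cols),
            pd.DataFrame(pval, index=cols, columns=cols))


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------


def agreement_report(table_a: pd.DataFrame, table_b: pd.DataFrame,
                     metrics: list[str] | None = None) -> pd.DataFrame:
    """One agreement row per metric for two per-lesion metric tables.

    Tables are indexed by lesion id with one column per metric; they are
    joined on the index and every metric gets Wilcoxon, ICC and
    Bland–Altman columns. Raises on the first unmatched lesion id.
    """
    missing = table_a.index.symmetric_difference(table_b.index)
    if len(missing):
        raise ValueError(f"unmatched lesion id: {missing[0]}")
    table_b = table_b.loc[table_a.index]
    metrics = metrics or [m for m in METRIC_ORDER if m in table_a.columns]
    rows = []
    for m in metrics:
        a = table_a[m].to_numpy(float)
        b = table_b[m].to_numpy(float)
        w = wilcoxon_signed_rank(a, b)
        icc = icc_agreement(a, b)
        ba = bland_altman(a, b, ids=list(table_a.index))
        rows.append({
            "metric": m,
            "wilcoxon_p": w.p,
            "wilcoxon_degenerate": w.degenerate,
            "icc": icc.icc,
            "icc_ci_low": icc.ci_low,
            "icc_ci_high": icc.ci_high,
            "icc_flag": icc.flag,
            "precision_pct": icc.precision_pct,
            "ba_mean_pct": ba.mean_pct,
            "ba_sd_pct": ba.sd_pct,
            "lrl_pct": ba.lrl_pct,
            "url_pct": ba.url_pct,
            "variation_pct": ba.variation_pct,
        })
    return pd.DataFrame(rows)
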