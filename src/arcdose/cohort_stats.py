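"""Paired-comparison and correlation machinery for plan cohorts.

A cohort table has one row per patient and one column per (metric, variant)
pair named ``"<metric>::<variant>"`` — e.g. ``"mld_cgy::3DCRT"`` and
``"mld_cgy::DCAT45"`` — plus per-patient geometry columns (target volumes,
distances, shape statistics).

Paired comparisons follow a normality gate: the Shapiro–Wilk test is applied
to the paired differences; normally distributed differences (p >= alpha) get
a two-tailed paired Student t-test with a t-based confidence interval, the
rest a Wilcoxon matched-pair signed-rank test with a Hodges–Lehmann
pseudo-median estimate and its order-statistic confidence interval.  Raw
p-values are reported without multiple-testing correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations_with_replacement

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "PairedTestResult",
    "paired_compare",
    "rank_correlation",
    "rank_by_variant",
    "cohort_report",
    "VARIANTS",
    "PLAN_METRIC_COLUMNS",
]

VARIANTS = ("3DCRT", "DCAT0", "DCAT30", "DCAT45", "DCAT90")

#: plan metrics carried per variant, with the direction that is clinically better
PLAN_METRIC_COLUMNS = {
    "cn": "higher",
    "hi": "lower",
    "dhd": "lower",
    "mu": "lower",
    "d1cc_cord_cgy": "lower",
    "mean_oesophagus_cgy": "lower",
    "v20_pct": "lower",
    "v5_pct": "lower",
    "mld_cgy": "lower",
}


@dataclass
class PairedTestResult:
    """Outcome of one paired comparison (estimate is A minus B)."""

    normality_p: float
    test: str                 # "paired t" | "wilcoxon" | "degenerate"
    estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    direction: str            # "favours A" | "favours B" | "none"
    n: int


def _hodges_lehmann_ci(d: np.ndarray, alpha: float) -> tuple[float, float, float]:
    """Pseudo-median of the differences and its signed-rank CI.

    The estimate is the median of the Walsh averages (d_i + d_j)/2, i <= j;
    the interval takes the k-th smallest and k-th largest Walsh average with
    k from the normal approximation to the signed-rank null distribution.
    """
    n = d.size
    walsh = np.sort([(a + b) / 2.0 for a, b in combinations_with_replacement(d, 2)])
    est = float(np.median(walsh))
    m = walsh.size
    z = stats.norm.ppf(1 - alpha / 2)
    k = int(np.floor(n * (n + 1) / 4.0 - z * np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)))
    k = max(k, 0)
    lo = float(walsh[min(k, m - 1)])
    hi = float(walsh[max(m - 1 - k, 0)])
    return est, lo, hi


def paired_compare(a, b, alpha: float = 0.05) -> PairedTestResult:
    """Compare paired samples with a Shapiro–Wilk normality gate.

    ``estimate`` is positive when A exceeds B; ``direction`` names the arm
    with the smaller values when p < alpha.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    n = a.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    d = a - b
    if np.allclose(d, 0.0):
        return PairedTestResult(1.0, "degenerate", 0.0, 0.0, 0.0, 1.0, "none", n)

    normality_p = float(stats.shapiro(d).pvalue)
    if normality_p >= alpha:
        est = float(d.mean())
        se = float(d.std(ddof=1) / np.sqrt(n))
        tcrit = stats.t.ppf(1 - alpha / 2, n - 1)
        lo, hi = est - tcrit * se, est + tcrit * se
        p = float(stats.ttest_rel(a, b).pvalue)
        test = "paired t"
    else:
        nz = d[d != 0]  # zero differences dropped, average ranks for ties
        p = float(stats.wilcoxon(nz, zero_method="wilcox").pvalue)
        est, lo, hi = _hodges_lehmann_ci(nz, alpha)
        test = "wilcoxon"

    if p < alpha:
        direction = "favours B" if est > 0 else "favours A"
    else:
        direction = "none"
    return PairedTestResult(normality_p, test, est, lo, hi, p, direction, n)


def rank_correlation(x, y) -> tuple[float, float]:
    """Spearman rank correlation with two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("samples must have equal length")
    if x.size < 5:
        raise ValueError("need at least 5 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("rank correlation undefined for constant input")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def rank_by_variant(table: pd.DataFrame, better: str = "lower") -> pd.Series:
    """Count, per variant (column), the patients for which it is best.

    A patient with a unique best variant contributes 1 to that variant; ties
    split the count equally among the tied variants (flagged in the log).
    Patients with any missing cell are excluded.
    """
    if better not in ("lower", "higher"):
        raise ValueError("better must be 'lower' or 'higher'")
    if table.shape[1] < 2:
        raise ValueError("need at least 2 variants")
    counts = pd.Series(0.0, index=table.columns)
    n_ties = 0
    for patient, row in table.iterrows():
        if row.isna().any():
            logger.info("patient %s excluded from ranking (missing cells)", patient)
            continue
        best = row.min() if better == "lower" else row.max()
        winners = row.index[row == best]
        if len(winners) > 1:
            n_ties += 1
        counts[winners] += 1.0 / len(winners)
    if n_ties:
        logger.info("%d patients had tied best variants (counts split)", n_ties)
    return counts


def _col(metric: str, variant: str) -> str:
    return f"{metric}::{variant}"


def cohort_report(cohort: pd.DataFrame, alpha: float = 0.05,
                  arc_variant: str = "DCAT45") -> dict[str, pd.DataFrame]:
    """Full cohort comparison report.

    Returns a dict of DataFrames:

    * ``"paired"`` — per-metric paired test of the arc variant against 3D CRT
      (estimate is arc minus static, so negative favours the arc technique
      for lower-is-better metrics);
    * ``"summary"`` — mean ± sd per metric and variant;
    * ``"correlations"`` — the Spearman set: paired lung-metric differences
      against V_PTV, V_lung and 1/d(CTV, cord), and arc-plan metrics against
      the sphericity surrogate, the isocentre displacement R and d(CTV, skin);
    * ``"constraints"`` — planning-restriction pass percentage per variant;
    * ``"ranks"`` — best-variant counts across the arc collimator variants.
    """
    if cohort.empty:
        raise ValueError("empty cohort")
    from .dvh import CONSTRAINTS  # late import to avoid a cycle

    paired_rows = []
    for metric in PLAN_METRIC_COLUMNS:
        ca, cb = _col(metric, arc_variant), _col(metric, "3DCRT")
        if ca not in cohort or cb not in cohort:
            logger.warning("metric %s absent from cohort; omitted", metric)
            continue
        sub = cohort[[ca, cb]].dropna()
        res = paired_compare(sub[ca].to_numpy(), sub[cb].to_numpy(), alpha=alpha)
        paired_rows.append({
            "metric": metric, "test": res.test, "estimate": res.estimate,
            "ci_low": res.ci_low, "ci_high": res.ci_high, "p_value": res.p_value,
            "normality_p": res.normality_p, "direction": res.direction, "n": res.n,
        })
    paired = pd.DataFrame(paired_rows).set_index("metric")

    summary_rows = {}
    for metric in PLAN_METRIC_COLUMNS:
        for variant in VARIANTS:
            c = _col(metric, variant)
            if c in cohort:
                summary_rows.setdefault(metric, {})[f"{variant}_mean"] = cohort[c].mean()
                summary_rows.setdefault(metric, {})[f"{variant}_sd"] = cohort[c].std(ddof=1)
    summary = pd.DataFrame.from_dict(summary_rows, orient="index")

    corr_rows = []

    def _corr(label, x, y):
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() >= 5 and not (np.all(x[ok] == x[ok][0]) or np.all(y[ok] == y[ok][0])):
            rho, p = rank_correlation(x[ok], y[ok])
            corr_rows.append({"pair": label, "rho": rho, "p_value": p, "n": int(ok.sum())})

    diff_metrics = ("mld_cgy", "v20_pct", "v5_pct")
    predictors = {
        "V_PTV": cohort.get("v_ptv_cm3"),
        "V_lung": cohort.get("v_lung_cm3"),
        "1/d_CTV-cord": 1.0 / cohort["d_ctv_cord_mm"] if "d_ctv_cord_mm" in cohort else None,
    }
    for metric in diff_metrics:
        ca, cb = _col(metric, arc_variant), _col(metric, "3DCRT")
        if ca not in cohort or cb not in cohort:
            continue
        diff = (cohort[ca] - cohort[cb]).to_numpy()
        for pname, pvals in predictors.items():
            if pvals is not None:
                _corr(f"d{metric} vs {pname}", np.asarray(pvals, float), diff)
    # paired-difference cross-correlations (V5 vs V20, MLD vs V20, MLD vs V5)
    diffs = {}
    for metric in diff_metrics:
        ca, cb = _col(metric, arc_variant), _col(metric, "3DCRT")
        if ca in cohort and cb in cohort:
            diffs[metric] = (cohort[ca] - cohort[cb]).to_numpy()
    for m1, m2 in (("v20_pct", "v5_pct"), ("mld_cgy", "v20_pct"), ("mld_cgy", "v5_pct")):
        if m1 in diffs and m2 in diffs:
            _corr(f"d{m1} vs d{m2}", diffs[m1], diffs[m2])

    shape_predictors = {
        "psi_tilde": cohort.get("psi_tilde"),
        "R": cohort.get("r_mm"),
        "d_CTV-skin": cohort.get("d_ctv_skin_mm"),
    }
    for metric in ("hi", "cn", "mean_oesophagus_cgy", "v20_pct", "v5_pct", "mld_cgy"):
        c = _col(metric, arc_variant)
        if c not in cohort:
            continue
        vals = cohort[c].to_numpy()
        for pname, pvals in shape_predictors.items():
            if pvals is not None:
                _corr(f"{metric} vs {pname}", np.asarray(pvals, float), vals)
    correlations = pd.DataFrame(corr_rows).set_index("pair") if corr_rows else pd.DataFrame()

    constraint_rows = {}
    limits = {name: (attr, limit) for name, (attr, limit) in CONSTRAINTS.items()
              if attr in ("v20_pct", "v5_pct", "mld_cgy", "d1cc_cord_cgy", "mean_oesophagus_cgy")}
    for variant in VARIANTS:
        for cname, (attr, limit) in limits.items():
            c = _col(attr, variant)
            if c in cohort:
                vals = cohort[c].dropna()
                constraint_rows.setdefault(cname, {})[variant] = float(
                    100.0 * (vals < limit).mean()
                )
    constraints = pd.DataFrame.from_dict(constraint_rows, orient="index")

    arc_only = [v for v in VARIANTS if v != "3DCRT"]
    rank_rows = {}
    for metric, better in PLAN_METRIC_COLUMNS.items():
        cols = [_col(metric, v) for v in arc_only if _col(metric, v) in cohort]
        if len(cols) >= 2:
            counts = rank_by_variant(cohort[cols], better=better)
            rank_rows[metric] = {c.split("::")[1]: v for c, v in counts.items()}
    ranks = pd.DataFrame.from_dict(rank_rows, orient="index")

    return {"paired": paired, "summary": summary, "correlations": correlations,
            "constraints": constraints, "ranks": ranks}
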