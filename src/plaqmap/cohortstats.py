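"""Group comparisons and correlations on per-vessel metric tables.

Lipid metrics in this population are skewed, so location is reported as
median with interquartile range and group differences are tested with the
two-sided Wilcoxon rank-sum (Mann-Whitney U) test: exact enumeration for
small tie-free samples, otherwise the normal approximation with tie and
continuity corrections.  Correlations are Spearman (rank) by default, or
Pearson with an optional base-10 log transform of x and a 95% confidence
band for the fitted line.

``paper_analysis`` bundles the study's nine analyses over a cohort table:
symptomatic-vs-asymptomatic comparisons of lipid content and distribution
indices, stenosis/volume and bilateral correlations, cohort index medians
and the bifurcation placement rate.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "median_iqr",
    "GroupComparison",
    "rank_sum_test",
    "CorrelationResult",
    "correlate",
    "linear_confidence_band",
    "cohort_table_from_pipeline",
    "paper_analysis",
    "report_text",
]

_EXACT_MAX_N = 12  # exact rank-sum enumeration up to this pooled size


def _exact_ranksum_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by full enumeration of group labelings.

    Valid with ties (midranks); the two-sided p is the null probability of a
    U at least as far from its mean ``n_a*n_b/2`` as observed.  Returns
    ``(u_observed, p)``.
    """
    from itertools import combinations

    n_a, n_b = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)  # midranks
    offset = n_a * (n_a + 1) / 2.0
    u_obs = ranks[:n_a].sum() - offset
    center = n_a * n_b / 2.0
    dev = abs(u_obs - center)
    count = 0
    total = 0
    for idx in combinations(range(n_a + n_b), n_a):
        u = ranks[list(idx)].sum() - offset
        if abs(u - center) >= dev - 1e-9:
            count += 1
        total += 1
    return float(u_obs), count / total


def median_iqr(values) -> tuple[float, float, float]:
    """Median and quartiles (linear-interpolation convention).

    Returns ``(median, q1, q3)``.  Raises on empty input.
    """
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if values.size == 0:
        raise ValueError("median_iqr of an empty sample is undefined")
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return float(med), float(q1), float(q3)


@dataclass
class GroupComparison:
    """Two-group rank-sum comparison with medians and IQRs."""

    n_a: int
    n_b: int
    median_a: float
    q1_a: float
    q3_a: float
    median_b: float
    q1_b: float
    q3_b: float
    u_statistic: float
    rank_sum_a: float
    p_value: float
    method: str  # "exact" | "asymptotic"


def rank_sum_test(group_a, group_b) -> GroupComparison:
    """Two-sided Wilcoxon rank-sum test between two samples.

    Uses exact enumeration of the U null distribution (midranks, so ties are
    handled) when the pooled sample has at most 12 observations, otherwise
    the normal approximation with tie correction and continuity correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    exact = a.size + b.size <= _EXACT_MAX_N
    if exact:
        u, p = _exact_ranksum_p(a, b)
    else:
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        u, p = float(res.statistic), float(res.pvalue)
    med_a, q1_a, q3_a = median_iqr(a)
    med_b, q1_b, q3_b = median_iqr(b)
    return GroupComparison(
        n_a=int(a.size),
        n_b=int(b.size),
        median_a=med_a,
        q1_a=q1_a,
        q3_a=q3_a,
        median_b=med_b,
        q1_b=q1_b,
        q3_b=q3_b,
        u_statistic=u,
        rank_sum_a=u + a.size * (a.size + 1) / 2.0,
        p_value=float(p),
        method="exact" if exact else "asymptotic",
    )


@dataclass
class CorrelationResult:
    """Correlation with the quantities needed to draw a 95% fit band."""

    method: str  # "spearman" | "pearson"
    r: float
    p_value: float
    n: int
    log10_x: bool = False
    slope: float = float("nan")
    intercept: float = float("nan")
    residual_sd: float = float("nan")
    x_mean: float = float("nan")
    x_ss: float = float("nan")  # sum of squared x deviations


def correlate(x, y, method: str = "spearman", log10_x: bool = False) -> CorrelationResult:
    """Correlate two paired samples.

    Spearman is Pearson on average ranks (the tie convention); Pearson
    optionally applies a base-10 log transform to ``x`` first (requires
    positive ``x``) and carries the simple-linear-fit quantities (on the
    transformed scale) for :func:`linear_confidence_band`.

    Raises on fewer than 3 pairs, zero variance in either variable, or
    non-positive ``x`` under the log option.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("correlation requires at least 3 complete pairs")
    if log10_x:
        if np.any(x <= 0):
            raise ValueError("log10 transform requires positive x values")
        x = np.log10(x)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: a variable has zero variance")
    if method == "spearman":
        res = stats.spearmanr(x, y)
        return CorrelationResult(
            method="spearman",
            r=float(res.statistic),
            p_value=float(res.pvalue),
            n=int(x.size),
            log10_x=log10_x,
        )
    if method == "pearson":
        res = stats.pearsonr(x, y)
        fit = stats.linregress(x, y)
        resid = y - (fit.intercept + fit.slope * x)
        dof = x.size - 2
        return CorrelationResult(
            method="pearson",
            r=float(res.statistic),
            p_value=float(res.pvalue),
            n=int(x.size),
            log10_x=log10_x,
            slope=float(fit.slope),
            intercept=float(fit.intercept),
            residual_sd=float(np.sqrt((resid**2).sum() / dof)),
            x_mean=float(x.mean()),
            x_ss=float(((x - x.mean()) ** 2).sum()),
        )
    raise ValueError(f"unknown correlation method: {method!r}")


def linear_confidence_band(result: CorrelationResult, x_grid) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fitted line and pointwise 95% confidence band at ``x_grid``.

    ``x_grid`` is on the (possibly log-transformed) fitting scale.
    Returns ``(y_hat, lower, upper)``.
    """
    if result.method != "pearson" or not np.isfinite(result.slope):
        raise ValueError("confidence band requires a Pearson fit result")
    x_grid = np.asarray(x_grid, dtype=float)
    y_hat = result.intercept + result.slope * x_grid
    dof = result.n - 2
    t_crit = stats.t.ppf(0.975, dof)
    se = result.residual_sd * np.sqrt(
        1.0 / result.n + (x_grid - result.x_mean) ** 2 / result.x_ss
    )
    return y_hat, y_hat - t_crit * se, y_hat + t_crit * se


# --------------------------------------------------------------------------
# study-level report
# --------------------------------------------------------------------------

REQUIRED_COLUMNS = (
    "patient",
    "side",
    "symptomatic_vessel",
    "stenosis_pct",
    "mean_lipid_pct",
    "mean_lipid_mm3",
    "mean_wall_mm3",
    "max_slice_lipid_pct",
    "max_slice_lld_pct",
    "max_slice_lai",
)


def cohort_table_from_pipeline(df: pd.DataFrame) -> pd.DataFrame:
    """Canonicalise a pipeline result table (``est_*`` columns) for analysis."""
    renamed = df.rename(
        columns={c: c.removeprefix("est_") for c in df.columns if c.startswith("est_")}
    )
    return renamed


def _comparison(table, column, groups) -> dict:
    sym = table.loc[groups, column]
    asym = table.loc[~groups, column]
    return asdict(rank_sum_test(sym, asym))


def _corr(x, y, method, log10_x=False) -> dict:
    out = asdict(correlate(x, y, method=method, log10_x=log10_x))
    return {k: out[k] for k in ("method", "r", "p_value", "n", "log10_x")}


def paper_analysis(
    cohort: pd.DataFrame,
    stenosis_cutoff: float = 50.0,
    group_by_patient: bool = False,
) -> dict:
    """Run the study's nine analyses on a per-vessel cohort table.

    Group comparisons (symptomatic vs asymptomatic vessels) of max-slice
    lipid % (stenosis >= cutoff subset), slice-averaged lipid %, LLD% and
    LAI; Spearman correlations of stenosis against wall and lipid volume and
    of left against right wall and lipid volume; Pearson correlation of wall
    volume against log10 lipid volume; cohort medians of LLD% and LAI; and,
    when available, the fraction of vessels whose maximal-lipid slice is the
    bifurcation slice.

    By default the symptomatic group is the culprit vessel only, with
    contralateral vessels of symptomatic patients analysed as asymptomatic;
    ``group_by_patient=True`` groups all vessels of symptomatic patients
    instead (the grouping used is recorded in the report metadata).
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table is missing required columns: {missing}")

    groups = (
        cohort["patient_symptomatic"].astype(bool)
        if group_by_patient
        else cohort["symptomatic_vessel"].astype(bool)
    )
    sten = cohort["stenosis_pct"] >= stenosis_cutoff

    left = cohort[cohort["side"] == "left"].sort_values("patient")
    right = cohort[cohort["side"] == "right"].sort_values("patient")
    paired = left.merge(right, on="patient", suffixes=("_l", "_r"))

    lai_med = median_iqr(cohort["max_slice_lai"])
    lld_med = median_iqr(cohort["max_slice_lld_pct"])

    report = {
        "meta": {
            "n_vessels": int(len(cohort)),
            "n_patients": int(cohort["patient"].nunique()),
            "grouping": "patient" if group_by_patient else "culprit_vessel",
            "stenosis_cutoff": float(stenosis_cutoff),
        },
        "group_comparisons": {
            "max_slice_lipid_pct_stenosis_subset": _comparison(
                cohort[sten], "max_slice_lipid_pct", groups[sten]
            ),
            "mean_lipid_pct": _comparison(cohort, "mean_lipid_pct", groups),
            "lld_pct": _comparison(cohort, "max_slice_lld_pct", groups),
            "lai": _comparison(cohort, "max_slice_lai", groups),
        },
        "correlations": {
            "stenosis_vs_wall_volume": _corr(
                cohort["stenosis_pct"], cohort["mean_wall_mm3"], "spearman"
            ),
            "stenosis_vs_lipid_volume": _corr(
                cohort["stenosis_pct"], cohort["mean_lipid_mm3"], "spearman"
            ),
            "log_lipid_vs_wall_volume": _corr(
                cohort["mean_lipid_mm3"],
                cohort["mean_wall_mm3"],
                "pearson",
                log10_x=True,
            ),
            "left_vs_right_wall_volume": _corr(
                paired["mean_wall_mm3_l"], paired["mean_wall_mm3_r"], "spearman"
            ),
            "left_vs_right_lipid_volume": _corr(
                paired["mean_lipid_mm3_l"], paired["mean_lipid_mm3_r"], "spearman"
            ),
        },
        "cohort_medians": {
            "lld_pct": {"median": lld_med[0], "q1": lld_med[1], "q3": lld_med[2]},
            "lai": {"median": lai_med[0], "q1": lai_med[1], "q3": lai_med[2]},
        },
    }
    if "bifurcation_is_max" in cohort.columns:
        report["bifurcation_max_fraction_pct"] = float(
            100.0 * cohort["bifurcation_is_max"].mean()
        )
    return report


def report_text(report: dict) -> str:
    """Human-readable rendering of a :func:`paper_analysis` report."""
    lines = [
        f"Cohort: {report['meta']['n_vessels']} vessels / "
        f"{report['meta']['n_patients']} patients "
        f"(grouping: {report['meta']['grouping']})",
        "",
        "Group comparisons (symptomatic vs asymptomatic, Wilcoxon rank-sum):",
    ]
    for name, c in report["group_comparisons"].items():
        lines.append(
            f"  {name}: {c['median_a']:.2f} (IQR {c['q1_a']:.2f}-{c['q3_a']:.2f}, "
            f"n={c['n_a']}) vs {c['median_b']:.2f} "
            f"(IQR {c['q1_b']:.2f}-{c['q3_b']:.2f}, n={c['n_b']}), "
            f"P = {c['p_value']:.4f} [{c['method']}]"
        )
    lines.append("")
    lines.append("Correlations:")
    for name, c in report["correlations"].items():
        tag = " (log10 x)" if c["log10_x"] else ""
        lines.append(
            f"  {name}: {c['method']} r = {c['r']:.3f}{tag}, "
            f"P = {c['p_value']:.4f}, n = {c['n']}"
        )
    m = report["cohort_medians"]
    lines.append("")
    lines.append(
        f"Cohort medians: LLD% {m['lld_pct']['median']:.1f} "
        f"(IQR {m['lld_pct']['q1']:.1f}-{m['lld_pct']['q3']:.1f}); "
        f"LAI {m['lai']['median']:.2f} "
        f"(IQR {m['lai']['q1']:.2f}-{m['lai']['q3']:.2f})"
    )
    if "bifurcation_max_fraction_pct" in report:
        lines.append(
            "Maximal lipid at the bifurcation slice: "
            f"{report['bifurcation_max_fraction_pct']:.1f}% of vessels"
        )
    return "\n".join(lines)
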