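"""Group statistics: demographics tests, covariate-adjusted GLM
comparisons, Bonferroni correction, and partial Pearson correlations.

Group comparisons of network parameters use an ordinary least squares
model ``metric ~ intercept + group + age + gender + education``; the
reported t is for the group coefficient, with the healthy-control group
coded 1 so that a positive t means HC > patient.  Nodal tests are
corrected with Bonferroni over the 90-node family, separately per
centrality type.  Correlations with clinical variables are Pearson
correlations of the residuals after regressing out the same covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm

__all__ = [
    "GroupComparisonResult",
    "CorrelationResult",
    "GroupAnalysisReport",
    "ttest_two_sample",
    "chi_square_2x2",
    "glm_group_test",
    "bonferroni",
    "partial_pearson",
    "run_group_analysis",
    "GLOBAL_PARAMETERS",
    "NODAL_PARAMETERS",
]

GLOBAL_PARAMETERS = ["gamma", "lambda", "sigma", "cp", "lp", "loce", "ge"]
NODAL_PARAMETERS = ["degree", "efficiency", "betweenness"]
COVARIATES = ["age", "gender", "education"]


@dataclass
class GroupComparisonResult:
    metric_name: str
    t_value: float
    p_raw: float
    df: int
    group1_mean: float
    group1_sd: float
    group2_mean: float
    group2_sd: float
    p_bonferroni: float = float("nan")


@dataclass
class CorrelationResult:
    parameter: str
    clinical_variable: str
    r: float
    p: float
    n_effective: int


def ttest_two_sample(x, y) -> tuple[float, float, int]:
    """Two-tailed pooled-variance t-test; returns (t, p, df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    df = x.size + y.size - 2
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
        # degenerate: no within-group variance
        if x.mean() == y.mean():
            return 0.0, 1.0, df
        return float("inf") * np.sign(x.mean() - y.mean()), 0.0, df
    t, p = sps.ttest_ind(x, y, equal_var=True)
    return float(t), float(p), df


def chi_square_2x2(counts) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, no continuity correction, df=1."""
    tab = np.asarray(counts, dtype=float)
    if tab.shape != (2, 2) or (tab < 0).any():
        raise ValueError("counts must be a non-negative 2x2 table")
    if tab.sum() == 0:
        raise ValueError("empty table")
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        raise ValueError("chi-square undefined: a row or column marginal is zero")
    chi2, p, _, _ = sps.chi2_contingency(tab, correction=False)
    return float(chi2), float(p)


def _design_matrix(cohort: pd.DataFrame) -> np.ndarray:
    """[1, is_hc, age, gender, education]; HC coded 1 so t>0 means HC>patient."""
    is_hc = (cohort["group"] == "HC").to_numpy(dtype=float)
    X = np.column_stack(
        [
            np.ones(len(cohort)),
            is_hc,
            cohort["age"].to_numpy(dtype=float),
            cohort["gender"].to_numpy(dtype=float),
            cohort["education"].to_numpy(dtype=float),
        ]
    )
    return X


def glm_group_test(metric, cohort: pd.DataFrame, metric_name: str = "") -> GroupComparisonResult:
    """Covariate-adjusted group comparison of one per-subject metric.

    Fits ``metric ~ 1 + group + age + gender + education`` by OLS and
    reports the two-sided t-test of the group coefficient (HC coded 1).
    Covariates that are constant across subjects carry no adjustment
    information and are dropped (with all covariates constant the test
    reduces exactly to the pooled t-test); a design that is still
    rank-deficient after that raises, naming the collinear columns.
    Raw per-group mean +/- sd are reported for the table layout.
    """
    y = np.asarray(metric, dtype=float)
    if np.isnan(y).any():
        raise ValueError("metric contains missing values")
    X = _design_matrix(cohort)
    cols = ["intercept", "group", *COVARIATES]
    keep = [j for j in range(X.shape[1]) if j < 2 or np.ptp(X[:, j]) > 0]
    X = X[:, keep]
    cols = [cols[j] for j in keep]
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        corr = np.corrcoef(X[:, 1:], rowvar=False)
        pairs = [
            (cols[1:][a], cols[1:][b])
            for a in range(corr.shape[0])
            for b in range(a + 1, corr.shape[0])
            if abs(corr[a, b]) > 1 - 1e-10
        ]
        raise ValueError(
            f"design matrix rank-deficient (rank {rank} < {X.shape[1]}); "
            f"collinear columns: {pairs or cols[1:]}"
        )
    fit = sm.OLS(y, X).fit()
    hc = y[(cohort["group"] == "HC").to_numpy()]
    pt = y[(cohort["group"] != "HC").to_numpy()]
    return GroupComparisonResult(
        metric_name=metric_name,
        t_value=float(fit.tvalues[1]),
        p_raw=float(fit.pvalues[1]),
        df=int(fit.df_resid),
        group1_mean=float(hc.mean()),
        group1_sd=float(hc.std(ddof=1)) if hc.size > 1 else float("nan"),
        group2_mean=float(pt.mean()),
        group2_sd=float(pt.std(ddof=1)) if pt.size > 1 else float("nan"),
    )


def bonferroni(p_values, n_tests: int | None = None) -> np.ndarray:
    """p_adj = min(1, p * n_tests); n_tests defaults to the family size."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if n_tests is None:
        n_tests = p.size
    if n_tests < p.size:
        raise ValueError("n_tests must be at least the number of p-values")
    return np.minimum(1.0, p * n_tests)


def partial_pearson(x, y, covariates=None, labels=("x", "y")) -> CorrelationResult:
    """Pearson correlation of x and y after regressing out covariates.

    Both variables are residualized on [intercept + covariates] by least
    squares; p is two-sided from t = r * sqrt(df / (1 - r^2)) with
    df = n - 2 - n_covariates.  Zero-variance residuals yield NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have the same length")
    n = x.size
    if covariates is None:
        Z = np.ones((n, 1))
        ncov = 0
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        if C.shape[0] != n:
            raise ValueError("covariate rows must match x/y length")
        Z = np.column_stack([np.ones(n), C])
        ncov = C.shape[1]
        if np.linalg.matrix_rank(Z) < Z.shape[1]:
            raise ValueError("covariate design matrix is rank-deficient")
    rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
    ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    df = n - 2 - ncov
    # residuals that are numerically zero (x or y lies in the covariate
    # span) leave the correlation undefined
    tol_x = 1e-10 * max(x.std(), 1.0)
    tol_y = 1e-10 * max(y.std(), 1.0)
    if rx.std() <= tol_x or ry.std() <= tol_y or df < 1:
        return CorrelationResult(labels[0], labels[1], float("nan"), float("nan"), n)
    r = float(np.corrcoef(rx, ry)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = float(2 * sps.t.sf(abs(t), df))
    return CorrelationResult(labels[0], labels[1], r, p, n)


# ---------------------------------------------------------------------------
# report assembly


@dataclass
class GroupAnalysisReport:
    demographics: pd.DataFrame
    global_comparison: pd.DataFrame
    nodal_comparison: pd.DataFrame
    correlations: pd.DataFrame
    flagged_global: list = field(default_factory=list)


def _fmt_ms(mean: float, sd: float) -> str:
    return f"{mean:.3f} ± {sd:.3f}"


def _demographics_table(cohort: pd.DataFrame) -> pd.DataFrame:
    hc = cohort[cohort["group"] == "HC"]
    pt = cohort[cohort["group"] != "HC"]
    rows = []
    rows.append({"variable": "n", "HC": str(len(hc)), "SSNHL": str(len(pt)),
                 "statistic": np.nan, "p": np.nan, "test": ""})
    for var in ["age", "education", "pta"]:
        t, p, _ = ttest_two_sample(hc[var], pt[var])
        rows.append(
            {
                "variable": var,
                "HC": _fmt_ms(hc[var].mean(), hc[var].std(ddof=1)),
                "SSNHL": _fmt_ms(pt[var].mean(), pt[var].std(ddof=1)),
                "statistic": t,
                "p": p,
                "test": "t",
            }
        )
    tab = [
        [int((hc["gender"] == 1).sum()), int((hc["gender"] == 0).sum())],
        [int((pt["gender"] == 1).sum()), int((pt["gender"] == 0).sum())],
    ]
    chi2, p = chi_square_2x2(tab)
    rows.append(
        {
            "variable": "gender (male/female)",
            "HC": f"{tab[0][0]}/{tab[0][1]}",
            "SSNHL": f"{tab[1][0]}/{tab[1][1]}",
            "statistic": chi2,
            "p": p,
            "test": "chi2",
        }
    )
    for var in ["thi", "duration"]:
        if var in pt.columns and pt[var].notna().any():
            rows.append(
                {
                    "variable": var,
                    "HC": "N/A",
                    "SSNHL": _fmt_ms(pt[var].mean(), pt[var].std(ddof=1)),
                    "statistic": np.nan,
                    "p": np.nan,
                    "test": "",
                }
            )
    return pd.DataFrame(rows)


def run_group_analysis(
    global_metrics: pd.DataFrame,
    nodal_tables: dict[str, pd.DataFrame],
    cohort: pd.DataFrame,
    alpha: float = 0.05,
    node_labels: list[str] | None = None,
) -> GroupAnalysisReport:
    """Full between-group statistical report.

    Parameters
    ----------
    global_metrics
        Per-subject global parameters, indexed by subject_id, columns at
        least ``GLOBAL_PARAMETERS``.
    nodal_tables
        subject_id -> nodal metric table (columns include
        ``NODAL_PARAMETERS``).
    cohort
        Subject metadata with group/age/gender/education and clinical
        variables (pta, thi, duration).
    alpha
        Significance level used to flag parameters for the clinical
        correlation analysis.

    Global parameters are tested with the covariate-adjusted GLM and
    reported with raw p-values; nodal parameters additionally receive
    Bonferroni correction over the node family, per centrality type.
    Parameters flagged at ``alpha`` are correlated (partial Pearson,
    same covariates) with PTA, THI and duration within the patient
    group.
    """
    cohort = cohort.set_index("subject_id") if "subject_id" in cohort.columns else cohort
    subjects = list(global_metrics.index)
    cohort = cohort.loc[subjects]

    # --- global parameters ------------------------------------------------
    grows = []
    flagged: list[str] = []
    # normalized parameters are absent (all-NaN) when no null ensemble
    # was computed; skip those columns rather than failing
    params = [
        p
        for p in GLOBAL_PARAMETERS
        if p in global_metrics.columns and global_metrics[p].notna().any()
    ]
    for par in params:
        res = glm_group_test(global_metrics[par].to_numpy(), cohort, par)
        grows.append(
            {
                "parameter": par,
                "HC": _fmt_ms(res.group1_mean, res.group1_sd),
                "SSNHL": _fmt_ms(res.group2_mean, res.group2_sd),
                "t": res.t_value,
                "p": res.p_raw,
            }
        )
        if res.p_raw < alpha:
            flagged.append(par)
    global_tab = pd.DataFrame(grows)

    # --- nodal parameters -------------------------------------------------
    first = nodal_tables[subjects[0]]
    n_nodes = len(first)
    labels = (
        node_labels
        if node_labels is not None
        else (list(first["label"]) if "label" in first.columns else list(range(n_nodes)))
    )
    nrows = []
    flagged_nodal: list[tuple[str, int]] = []
    for par in NODAL_PARAMETERS:
        mat = np.column_stack(
            [nodal_tables[s][par].to_numpy(dtype=float) for s in subjects]
        )  # nodes x subjects
        stats_per_node = [
            glm_group_test(mat[i], cohort, f"{par}:{labels[i]}") for i in range(n_nodes)
        ]
        p_adj = bonferroni([r.p_raw for r in stats_per_node], n_tests=n_nodes)
        for i, res in enumerate(stats_per_node):
            nrows.append(
                {
                    "metric": par,
                    "node": i,
                    "label": labels[i],
                    "HC_mean": res.group1_mean,
                    "SSNHL_mean": res.group2_mean,
                    "t": res.t_value,
                    "p": res.p_raw,
                    "p_bonferroni": p_adj[i],
                }
            )
            if p_adj[i] < alpha:
                flagged_nodal.append((par, i))
    nodal_tab = pd.DataFrame(nrows)

    # --- clinical correlations (patients only) ----------------------------
    pt = cohort[cohort["group"] != "HC"]
    pt_ids = list(pt.index)
    cov = pt[COVARIATES].to_numpy(dtype=float)
    crows = []

    def _corr(values: np.ndarray, par_name: str) -> None:
        for clin in ["pta", "thi", "duration"]:
            if clin not in pt.columns:
                continue
            yv = pt[clin].to_numpy(dtype=float)
            ok = ~np.isnan(yv)
            if ok.sum() < cov.shape[1] + 3:
                continue
            res = partial_pearson(values[ok], yv[ok], cov[ok], labels=(par_name, clin))
            crows.append(
                {
                    "parameter": par_name,
                    "clinical_variable": clin,
                    "r": res.r,
                    "p": res.p,
                    "n": res.n_effective,
                }
            )

    for par in flagged:
        _corr(global_metrics.loc[pt_ids, par].to_numpy(dtype=float), par)
    for par, node in flagged_nodal:
        vals = np.array(
            [nodal_tables[s][par].to_numpy(dtype=float)[node] for s in pt_ids]
        )
        _corr(vals, f"{par}:{labels[node]}")
    corr_tab = pd.DataFrame(
        crows, columns=["parameter", "clinical_variable", "r", "p", "n"]
    )

    return GroupAnalysisReport(
        demographics=_demographics_table(cohort.reset_index()),
        global_comparison=global_tab,
        nodal_comparison=nodal_tab,
        correlations=corr_tab,
        flagged_global=flagged,
    )
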