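"""Group-level statistics over the study x method metric table.

The testing scheme mirrors standard practice for clustered repeated-measures
source-imaging comparisons: Friedman tests across methods (studies as
blocks), pairwise Wilcoxon signed-rank tests with Bonferroni correction, and
a generalized estimating equations (GEE) model with the study as cluster
variable for the threshold-dependent metrics (evaluated at 30/60/90%
thresholds with method, threshold and their interaction as factors).

Friedman, Wilcoxon and GEE are delegated to scipy / statsmodels; this module
owns the model specification, degrees-of-freedom bookkeeping and the summary
tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "StatResult",
    "friedman_across_methods",
    "pairwise_wilcoxon_bonferroni",
    "gee_threshold_model",
    "summarize_results",
    "GEE_THRESHOLDS",
]

GEE_THRESHOLDS = (30, 60, 90)


@dataclass
class StatResult:
    """A single hypothesis-test result."""

    test_name: str
    statistic: float
    degrees_of_freedom: int | None
    p_value: float
    correction: str = "none"  # none | Bonferroni
    comparison_labels: tuple = ()

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError("p-value must lie in [0, 1]")
        if self.degrees_of_freedom is not None and self.degrees_of_freedom < 1:
            raise ValueError("degrees of freedom must be >= 1")


def _pivot(table: pd.DataFrame, metric: str, methods=None) -> pd.DataFrame:
    """Studies x methods matrix of one metric (threshold-independent rows)."""
    df = table.drop_duplicates(subset=["study_id", "method"])
    wide = df.pivot(index="study_id", columns="method", values=metric)
    if methods is not None:
        wide = wide[list(methods)]
    if wide.isna().any().any():
        missing = wide[wide.isna().any(axis=1)].index.tolist()
        raise ValueError(f"incomplete block design; studies with missing methods: {missing}")
    return wide


def friedman_across_methods(table: pd.DataFrame, metric: str, methods=None) -> StatResult:
    """Friedman chi-square across methods with studies as blocks (df = k-1)."""
    wide = _pivot(table, metric, methods)
    cols = [wide[c].to_numpy() for c in wide.columns]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # nan for all-tied ranks
        stat, p = sps.friedmanchisquare(*cols)
    if np.isnan(stat):  # identical columns: zero statistic by convention
        stat, p = 0.0, 1.0
    return StatResult(
        "Friedman", float(stat), len(cols) - 1, float(p),
        comparison_labels=tuple(wide.columns),
    )


def pairwise_wilcoxon_bonferroni(
    table: pd.DataFrame, metric: str, methods=None
) -> list[StatResult]:
    """Wilcoxon signed-rank test for every method pair, Bonferroni corrected.

    Zeros handled by the Pratt method.  The corrected p is the raw p times
    the number of comparisons (C(k,2); 10 for five methods), capped at 1.
    All-zero difference vectors are degenerate and reported with p = 1.
    """
    wide = _pivot(table, metric, methods)
    pairs = list(combinations(wide.columns, 2))
    n_comp = len(pairs)
    out = []
    for a, b in pairs:
        x, y = wide[a].to_numpy(), wide[b].to_numpy()
        if np.all(x == y):
            stat, p = 0.0, 1.0
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                stat, p = sps.wilcoxon(x, y, zero_method="pratt")
        out.append(
            StatResult(
                "Wilcoxon signed-rank",
                float(stat),
                None,
                float(min(p * n_comp, 1.0)),
                correction="Bonferroni",
                comparison_labels=(a, b),
            )
        )
    return out


def gee_threshold_model(
    table: pd.DataFrame,
    metric: str = "sd_mm",
    thresholds=GEE_THRESHOLDS,
) -> dict[str, StatResult]:
    """GEE with study clusters: metric ~ method * threshold (categorical).

    Exchangeable working correlation, Gaussian family, robust sandwich
    covariance.  Returns Wald chi-square results for the method, threshold
    and interaction terms; with 5 methods and 3 thresholds the degrees of
    freedom are 4, 2 and 8 respectively.  If every cluster is a singleton
    the model falls back to an independence working correlation with a
    warning.
    """
    df = table[table["threshold_pct"].isin(thresholds)].copy()
    if df.empty:
        raise ValueError(f"no rows at thresholds {thresholds}")
    df["method"] = df["method"].astype(str)
    df["threshold_pct"] = df["threshold_pct"].astype(int)
    df = df.rename(columns={metric: "y"})

    y = df["y"].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        # constant response: no variation to test (common for map_dmin when
        # every thresholded map touches the focus); degenerate results
        warnings.warn(f"{metric} is constant at thresholds {thresholds}; tests degenerate")
        k = df["method"].nunique()
        t = df["threshold_pct"].nunique()
        dfs = {"method": k - 1, "threshold": t - 1, "interaction": (k - 1) * (t - 1)}
        return {
            term: StatResult(f"GEE Wald ({term})", 0.0, dof, 1.0)
            for term, dof in dfs.items()
        }

    cluster_sizes = df.groupby("study_id").size()
    if (cluster_sizes <= 1).all():
        warnings.warn("all clusters are singletons; using independence working correlation")
        cov_struct = sm.cov_struct.Independence()
    else:
        cov_struct = sm.cov_struct.Exchangeable()

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.gee(
            "y ~ C(method) * C(threshold_pct)",
            groups="study_id",
            data=df,
            family=sm.families.Gaussian(),
            cov_struct=cov_struct,
        )
        res = model.fit()

    out: dict[str, StatResult] = {}
    names = list(res.model.exog_names)
    terms = {
        "method": [n for n in names if n.startswith("C(method)") and ":" not in n],
        "threshold": [n for n in names if n.startswith("C(threshold_pct)") and ":" not in n],
        "interaction": [n for n in names if ":" in n],
    }
    # The sandwich covariance has rank limited by the number of clusters; with
    # few clusters it is not usable for joint Wald tests, so fall back to the
    # model-based (naive) covariance in that regime.
    n_clusters = df["study_id"].nunique()
    V = np.asarray(res.cov_robust if n_clusters > len(names) else res.cov_naive)
    beta = np.asarray(res.params)
    for term, cols in terms.items():
        L = np.zeros((len(cols), len(names)))
        for i, c in enumerate(cols):
            L[i, names.index(c)] = 1.0
        lb = L @ beta
        lvl = L @ V @ L.T
        chi2 = float(lb @ np.linalg.solve(lvl, lb))
        dof = len(cols)
        out[term] = StatResult(
            f"GEE Wald ({term})",
            chi2,
            dof,
            float(sps.chi2.sf(chi2, dof)),
            comparison_labels=tuple(cols),
        )
    return out


def summarize_results(table: pd.DataFrame, seizure_free_only: bool = False) -> dict:
    """Per-method medians and quartiles of dmin at study and patient level.

    Patient level takes the median across each patient's studies first, then
    summarizes across patients.  ``seizure_free_only`` filters on a boolean
    ``seizure_free`` column when present.
    """
    df = table.drop_duplicates(subset=["patient_id", "study_id", "method"]).copy()
    if seizure_free_only:
        if "seizure_free" not in df.columns:
            raise ValueError("table has no seizure_free column")
        df = df[df["seizure_free"]]

    def q(s):
        return pd.Series(
            {
                "median": s.median(),
                "q1": s.quantile(0.25),
                "q3": s.quantile(0.75),
                "n": len(s),
            }
        )

    study_level = df.groupby("method")["dmin_mm"].apply(q).unstack()
    per_patient = df.groupby(["method", "patient_id"])["dmin_mm"].median().reset_index()
    patient_level = per_patient.groupby("method")["dmin_mm"].apply(q).unstack()
    return {"study_level": study_level, "patient_level": patient_level}
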