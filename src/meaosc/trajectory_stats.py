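"""Weighted binomial GEE for oscillation-emergence trajectories.

The response is the fraction of wells oscillating per plate and week;
plates are clusters with an exchangeable working correlation; the number
of wells per plate enters as an observation-level weight.  The linear
predictor is

    logit(p_ij) = b0 + b1*t_ij + b2*C80 + b3*C50 + b4*t_ij*C80 + b5*t_ij*C50

with t the centered week and C80/C50 indicators for the 80:20 and 50:50
glutamatergic:GABAergic compositions (pure glutamatergic cultures as
reference).  Estimation is delegated to statsmodels' GEE (binomial logit,
exchangeable, robust sandwich covariance); Wald χ² statistics and odds
ratios with 95% CIs are derived from the robust standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

DESIGN_COLUMNS = ["intercept", "week_c", "C80", "C50", "week_c:C80", "week_c:C50"]

_CONDITION_ALIASES = {
    "iGluta-alone": "reference",
    "iGluta": "reference",
    "80:20": "C80",
    "50:50": "C50",
}


@dataclass
class GEEDesign:
    y: np.ndarray  # per-row oscillating fraction
    X: np.ndarray  # n x 6, columns DESIGN_COLUMNS
    weights: np.ndarray  # wells per plate-week row
    clusters: np.ndarray  # plate ids
    columns: list[str] = field(default_factory=lambda: list(DESIGN_COLUMNS))


@dataclass
class GEEFit:
    beta: np.ndarray
    robust_se: np.ndarray
    alpha_hat: float
    wald_chi2: np.ndarray
    p_values: np.ndarray
    odds_ratios: np.ndarray
    or_ci_low: np.ndarray
    or_ci_high: np.ndarray
    n_clusters: int
    converged: bool
    n_iterations: int
    columns: list[str] = field(default_factory=lambda: list(DESIGN_COLUMNS))

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coefficient": self.columns,
                "beta": self.beta,
                "robust_se": self.robust_se,
                "wald_chi2": self.wald_chi2,
                "p": self.p_values,
                "odds_ratio": self.odds_ratios,
                "or_ci_low": self.or_ci_low,
                "or_ci_high": self.or_ci_high,
            }
        )


def build_design(
    table: pd.DataFrame,
    reference_condition: str = "iGluta-alone",
    center_weeks: bool = True,
) -> GEEDesign:
    """Build the 6-column design from an occurrence table.

    Weeks are centered at the mean of the observed week values (each
    distinct plate-week row counted once per row, matching how the table
    is laid out).  Unknown condition labels raise.
    """
    required = {"plate_id", "condition", "week", "n_wells", "n_oscillating"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"occurrence table missing columns {sorted(missing)}")
    conds = table["condition"].astype(str)
    unknown = sorted(set(conds) - set(_CONDITION_ALIASES))
    if unknown:
        raise ValueError(f"unknown condition labels {unknown}")
    ref_role = _CONDITION_ALIASES.get(reference_condition)
    if ref_role != "reference":
        raise ValueError(f"unsupported reference condition {reference_condition!r}")

    week = table["week"].to_numpy(dtype=float)
    t = week - week.mean() if center_weeks else week
    c80 = (conds.map(_CONDITION_ALIASES) == "C80").to_numpy(dtype=float)
    c50 = (conds.map(_CONDITION_ALIASES) == "C50").to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(t), t, c80, c50, t * c80, t * c50])
    n = table["n_wells"].to_numpy(dtype=float)
    k = table["n_oscillating"].to_numpy(dtype=float)
    if np.any(n < 1) or np.any(k < 0) or np.any(k > n):
        raise ValueError("need 1 <= n_wells and 0 <= n_oscillating <= n_wells")
    return GEEDesign(
        y=k / n,
        X=X,
        weights=n,
        clusters=table["plate_id"].to_numpy(),
    )


def fit_gee(
    table_or_design: pd.DataFrame | GEEDesign,
    maxiter: int = 100,
) -> GEEFit:
    """Fit the weighted binomial-logit GEE with exchangeable correlation.

    Robust (sandwich) standard errors are used for all inference; the
    binomial scale is fixed at 1.  Non-convergence is flagged on the
    returned fit rather than raised.
    """
    design = (
        table_or_design
        if isinstance(table_or_design, GEEDesign)
        else build_design(table_or_design)
    )
    if np.unique(design.clusters).size < 2:
        raise ValueError("GEE needs at least 2 clusters")
    if np.linalg.matrix_rank(design.X) < design.X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    model = sm.GEE(
        design.y,
        design.X,
        groups=design.clusters,
        family=sm.families.Binomial(),
        cov_struct=sm.cov_struct.Exchangeable(),
        weights=design.weights,
    )
    result = model.fit(maxiter=maxiter, scale=1.0)
    beta = np.asarray(result.params)
    se = np.asarray(result.bse)  # robust by default for GEE
    chi2 = (beta / se) ** 2
    p = stats.chi2.sf(chi2, df=1)
    ci_low = np.exp(beta - 1.96 * se)
    ci_high = np.exp(beta + 1.96 * se)
    n_iter = len(getattr(result, "fit_history", {}).get("params", []))
    converged = bool(getattr(result, "converged", n_iter < maxiter))
    return GEEFit(
        beta=beta,
        robust_se=se,
        alpha_hat=float(result.cov_struct.dep_params),
        wald_chi2=chi2,
        p_values=p,
        odds_ratios=np.exp(beta),
        or_ci_low=ci_low,
        or_ci_high=ci_high,
        n_clusters=int(np.unique(design.clusters).size),
        converged=converged,
        n_iterations=n_iter,
        columns=list(design.columns),
    )


def wald_test(fit: GEEFit, coefficient: str | int) -> tuple[float, float]:
    """Wald χ²(1) test for one coefficient from the robust SE."""
    idx = (
        coefficient
        if isinstance(coefficient, int)
        else fit.columns.index(coefficient)
    )
    se = fit.robust_se[idx]
    if se == 0:
        raise ValueError("robust SE is zero; Wald test undefined")
    chi2 = float((fit.beta[idx] / se) ** 2)
    return chi2, float(stats.chi2.sf(chi2, df=1))
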