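"""Period x condition linear mixed-effects models with post-hoc contrasts.

Each connectivity/power summary table (one row per unit x period x
condition, where a unit is a channel or a channel pair) is fitted with

    value ~ 1 + taskPeriod * condition + (1 | patient) + (1 | patient:unit)

i.e. treatment-coded fixed effects with the baseline period and the
'same' condition as references, a random intercept per patient and a
random intercept per unit nested in patient.  Fitting delegates to
statsmodels' MixedLM; this stage contributes the design construction,
the Bonferroni families (power: alpha 0.05/6, PLV: 0.05/3, net GC: 0.05)
and the contrast machinery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy import stats
import statsmodels.formula.api as smf

__all__ = [
    "FAMILY_ALPHA",
    "ModelFitResult",
    "fit_period_condition_lmm",
    "posthoc_contrasts",
]

#: Family-wise alpha per outcome: six power models (3 regions x 2 bands),
#: three PLV models (one per selected frequency range), net GC at 0.05.
FAMILY_ALPHA = {"power": 0.05 / 6, "plv": 0.05 / 3, "netgc": 0.05}

VALUE_COLUMNS = {"power": "mean_power", "plv": "mean_plv", "netgc": "mean_net_gc"}

REQUIRED = ("patient", "unit", "period", "condition")


@dataclass
class ModelFitResult:
    """Fitted period x condition mixed model and its fixed-effect table.

    ``df_method`` records the denominator-degrees-of-freedom convention
    (residual-df fallback); switching the method changes p-values but not
    estimates.
    """

    outcome: str
    formula: str
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    significant: pd.Series
    df_resid: float
    df_method: str
    alpha_family: float
    random_effects: dict
    converged: bool
    dropped_nested_term: bool
    result: object = field(repr=False)
    design_info: object = field(repr=False)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": self.params,
                "se": self.bse,
                "t": self.tvalues,
                "p": self.pvalues,
                "significant": self.significant,
            }
        )


def _prepare(table: pd.DataFrame, value_col: str) -> pd.DataFrame:
    missing = [c for c in (*REQUIRED, value_col) if c not in table.columns]
    if missing:
        raise ValueError(f"model table missing columns: {missing}")
    df = table.copy()
    df["period"] = df["period"].astype(str)
    df["condition"] = df["condition"].astype(str)
    if df["patient"].nunique() < 2:
        raise ValueError("need >= 2 patients for a patient random intercept")
    cells = df.groupby(["period", "condition"]).size()
    if (cells == 0).any():
        raise ValueError("all period x condition cells must be populated")
    return df


def fit_period_condition_lmm(table: pd.DataFrame, outcome: str,
                             alpha_family: float | None = None,
                             value_col: str | None = None,
                             baseline_period: str = "baseline") -> ModelFitResult:
    """Fit value ~ taskPeriod * condition with patient/unit random intercepts.

    ``outcome`` in {"power", "plv", "netgc"} picks the value column and
    the Bonferroni family alpha (overridable).  A singular nested
    variance component triggers a flagged refit without the unit term.
    p-values use t statistics with residual degrees of freedom.
    """
    if outcome not in VALUE_COLUMNS:
        raise ValueError(f"unknown outcome {outcome!r}")
    value_col = value_col or VALUE_COLUMNS[outcome]
    alpha = FAMILY_ALPHA[outcome] if alpha_family is None else alpha_family
    df = _prepare(table, value_col)

    fixed = (
        f"{value_col} ~ C(period, Treatment({baseline_period!r})) "
        "* C(condition, Treatment('same'))"
    )
    vc = {"unit": "0 + C(unit)"}
    dropped = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(fixed, df, groups="patient", re_formula="1",
                            vc_formula=vc)
        try:
            res = model.fit(reml=True, method=["lbfgs", "powell"], maxiter=2000)
        except (np.linalg.LinAlgError, ValueError):
            res = None
        if res is None or not res.converged:
            dropped = True
            model = smf.mixedlm(fixed, df, groups="patient", re_formula="1")
            res = model.fit(reml=True, method=["lbfgs", "powell"], maxiter=2000)

    exog = model.exog
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        # name the aliased column for the caller
        _, r = np.linalg.qr(exog)
        aliased = model.exog_names[int(np.argmin(np.abs(np.diag(r))))]
        raise ValueError(f"rank-deficient fixed-effect design: column {aliased!r}")

    k_fe = len(model.exog_names)
    fe = res.fe_params
    bse = res.bse_fe
    tvals = fe / bse
    df_resid = len(df) - k_fe
    pvals = 2 * stats.t.sf(np.abs(tvals), df_resid)
    pvals = pd.Series(pvals, index=fe.index)
    n_periods = df["period"].nunique()
    assert k_fe == 2 * n_periods, "unexpected fixed-effect count"

    random_effects = {
        "patient_var": float(np.asarray(res.cov_re).ravel()[0]),
        "unit_var": (float(np.asarray(res.vcomp).ravel()[0])
                     if not dropped and len(res.vcomp) else None),
        "residual_var": float(res.scale),
    }
    return ModelFitResult(
        outcome=outcome, formula=fixed, params=fe, bse=bse, tvalues=tvals,
        pvalues=pvals, significant=pvals < alpha, df_resid=df_resid,
        df_method="residual", alpha_family=alpha,
        random_effects=random_effects, converged=bool(res.converged),
        dropped_nested_term=dropped, result=res,
        design_info=model.data.design_info,
    )


def _cell_rows(fit: ModelFitResult, cells: pd.DataFrame) -> np.ndarray:
    """Fixed-effect design rows for given (period, condition) cells."""
    (mat,) = patsy.build_design_matrices([fit.design_info], cells)
    return np.asarray(mat)


def posthoc_contrasts(fit: ModelFitResult,
                      contrasts: list | None = None,
                      periods: list | None = None) -> pd.DataFrame:
    """Pairwise period contrasts and within-period condition contrasts.

    Period contrasts average over the two conditions (marginal means);
    condition contrasts are same - different within each period.  All use
    the fixed-effect covariance; p-values are reported raw and
    Bonferroni-adjusted within the contrast family.  Custom ``contrasts``
    may be given as ``(label, cells_plus, cells_minus)`` where each cells
    element is a list of (period, condition) tuples averaged with equal
    weight.
    """
    data = fit.result.model.data.frame
    periods = periods or list(pd.unique(data["period"]))
    conds = ["same", "different"]

    spec = []
    if contrasts is None:
        for a in range(len(periods)):
            for b in range(a + 1, len(periods)):
                spec.append(
                    (
                        f"{periods[a]} - {periods[b]}",
                        [(periods[a], c) for c in conds],
                        [(periods[b], c) for c in conds],
                    )
                )
        for p in periods:
            spec.append((f"same - different @ {p}", [(p, "same")],
                         [(p, "different")]))
    else:
        spec = contrasts

    k_fe = len(fit.params)
    cov = np.asarray(fit.result.cov_params())[:k_fe, :k_fe]
    beta = fit.params.to_numpy()

    rows = []
    for label, plus, minus in spec:
        lp = _cell_rows(fit, pd.DataFrame(plus, columns=["period", "condition"]))
        lm = _cell_rows(fit, pd.DataFrame(minus, columns=["period", "condition"]))
        L = lp.mean(axis=0) - lm.mean(axis=0)
        est = float(L @ beta)
        var = float(L @ cov @ L)
        if var < 0:
            raise ValueError(f"contrast {label!r} not estimable")
        se = np.sqrt(var)
        if se == 0:
            t, p = 0.0, 1.0
        else:
            t = est / se
            p = float(2 * stats.t.sf(abs(t), fit.df_resid))
        rows.append({"contrast": label, "estimate": est, "se": se, "t": t,
                     "p": p})
    out = pd.DataFrame(rows)
    out["p_bonferroni"] = np.minimum(out["p"] * len(out), 1.0)
    return out
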