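"""Inference over per-bead and per-condensate tables.

Bead pull-down measurements are hierarchical: beads are nested in wells,
wells in experiment replicates, and both grouping levels contribute
variance that must not be pooled away.  The primary tool is therefore a
linear mixed model — fixed condition effects, random intercepts for
replicate and for well nested in replicate — fit by REML
(:mod:`statsmodels` ``MixedLM``).  The balanced special case is the nested
ANOVA reported in figure captions; both are served by the same engine.

Simpler designs use the unpaired two-tailed Student t test
(pooled-variance) and two-way ANOVA (Type II sums of squares).

Fixed-effect p-values use the Wald statistic referred to a t distribution
with containment degrees of freedom (wells are the experimental units for
a between-well condition contrast):
``df = n_wells - n_conditions - (n_replicates - 1)``.  This keeps the
type-I error of the well-level contrast near nominal in small designs,
where the normal approximation is anticonservative.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

logger = logging.getLogger(__name__)

__all__ = [
    "TestResult",
    "MixedModelResult",
    "t_test_unpaired",
    "fit_bead_mixed_model",
    "two_way_anova",
]


@dataclass
class TestResult:
    """Two-sample test outcome."""

    statistic: float
    df: float
    p_value: float
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int
    degenerate: bool = False


@dataclass
class MixedModelResult:
    """Mixed-model fit summary.

    ``fixed_effects`` columns: term, estimate, se, statistic, df, p_value.
    ``variance_components``: replicate and well intercept variances plus
    the residual variance (all >= 0 by construction of REML).
    """

    fixed_effects: pd.DataFrame
    variance_components: dict[str, float]
    group_sizes: dict[str, int]
    converged: bool
    singular: bool
    method: str = "REML, Wald t with containment df"


def t_test_unpaired(a, b) -> TestResult:
    """Unpaired two-tailed Student t test with pooled variance.

    Degenerate zero-variance inputs are resolved rather than propagating
    NaN: equal means give ``t = 0, p = 1``; unequal means give an
    effectively infinite statistic and ``p -> 0``, flagged degenerate.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError(
            f"each group needs n >= 2, got n_a={a.size}, n_b={b.size}"
        )
    na, nb = a.size, b.size
    df = na + nb - 2
    pooled_var = (
        (na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)
    ) / df
    diff = a.mean() - b.mean()
    if pooled_var == 0:
        if diff == 0:
            return TestResult(0.0, df, 1.0, a.mean(), b.mean(), na, nb)
        logger.warning(
            "zero pooled variance with unequal means; p-value degenerate"
        )
        t = np.inf if diff > 0 else -np.inf
        return TestResult(
            float(t), df, 0.0, a.mean(), b.mean(), na, nb, degenerate=True
        )
    t = diff / np.sqrt(pooled_var * (1.0 / na + 1.0 / nb))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return TestResult(float(t), df, max(p, np.nextafter(0, 1)),
                      float(a.mean()), float(b.mean()), na, nb)


def _containment_df(n_wells: int, n_conditions: int, n_replicates: int) -> int:
    """Between-well error df for a condition contrast: wells minus
    condition means minus replicate block effects, floored at 1."""
    return max(n_wells - n_conditions - (n_replicates - 1), 1)


def fit_bead_mixed_model(
    table: pd.DataFrame,
    response: str = "mean_score",
    condition: str = "condition",
    replicate: str = "replicate_id",
    well: str = "well_id",
) -> MixedModelResult:
    """Linear mixed model for per-bead scores.

    ``response ~ condition`` with random intercepts for experiment
    replicate and for well nested in replicate, estimated by REML.  Well
    labels are disambiguated internally as ``replicate:well`` so reused
    well names across replicates stay nested.  Wald statistics on the
    condition contrasts are referred to a t distribution with containment
    degrees of freedom.  Singular fits (a variance component at the 0
    boundary) are flagged, not hidden.
    """
    required = {response, condition, replicate, well}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"table is missing columns: {sorted(missing)}")
    data = table[[response, condition, replicate, well]].copy()
    data.columns = ["y", "cond", "rep", "well"]
    data["cond"] = data["cond"].astype(str)
    data["rep"] = data["rep"].astype(str)
    data["well_in_rep"] = data["rep"] + ":" + data["well"].astype(str)

    conditions = sorted(data["cond"].unique())
    if len(conditions) < 2:
        raise ValueError(
            f"need >= 2 conditions, got {conditions}"
        )
    counts = data.groupby("cond").size()
    thin = counts[counts < 2]
    if len(thin):
        raise ValueError(
            f"condition(s) with a single bead: {list(thin.index)}"
        )

    n_wells = data["well_in_rep"].nunique()
    n_reps = data["rep"].nunique()
    df_t = _containment_df(n_wells, len(conditions), n_reps)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # boundary/convergence chatter
        model = sm.MixedLM.from_formula(
            "y ~ C(cond)",
            groups="rep",
            re_formula="1",
            vc_formula={"well": "0 + C(well_in_rep)"},
            data=data,
        )
        fit = model.fit(reml=True, method=["lbfgs", "cg"])

    fe = fit.fe_params
    se = fit.bse_fe
    rows = []
    for term in fe.index:
        est = float(fe[term])
        s = float(se[term])
        stat = est / s if s > 0 else np.nan
        p = float(2.0 * sps.t.sf(abs(stat), df_t)) if np.isfinite(stat) else np.nan
        rows.append(
            {
                "term": term,
                "estimate": est,
                "se": s,
                "statistic": stat,
                "df": df_t,
                "p_value": min(max(p, np.nextafter(0, 1)), 1.0)
                if np.isfinite(stat) else np.nan,
            }
        )
    fixed = pd.DataFrame(rows)

    rep_var = float(np.asarray(fit.cov_re).ravel()[0]) if fit.cov_re.size else 0.0
    well_var = float(fit.vcomp[0]) if len(fit.vcomp) else 0.0
    resid_var = float(fit.scale)
    singular = bool(
        rep_var <= 1e-10 * resid_var or well_var <= 1e-10 * resid_var
    )
    if singular:
        logger.info(
            "singular fit: variance component at boundary "
            "(replicate %.3g, well %.3g, residual %.3g)",
            rep_var, well_var, resid_var,
        )
    return MixedModelResult(
        fixed_effects=fixed,
        variance_components={
            "replicate": rep_var,
            "well": well_var,
            "residual": resid_var,
        },
        group_sizes={
            "n_beads": len(data),
            "n_wells": n_wells,
            "n_replicates": n_reps,
            "n_conditions": len(conditions),
        },
        converged=bool(fit.converged),
        singular=singular,
    )


def two_way_anova(
    table: pd.DataFrame,
    response: str,
    factor_a: str,
    factor_b: str,
    interaction: bool = True,
) -> pd.DataFrame:
    """Two-way ANOVA with Type II sums of squares.

    Handles balanced and unbalanced layouts.  Requesting the interaction
    with empty cells is an error.  Returns the standard ANOVA table
    (sum_sq, df, F, PR(>F)) indexed by term.
    """
    for col in (response, factor_a, factor_b):
        if col not in table.columns:
            raise ValueError(f"column {col!r} not in table")
    if interaction:
        cells = table.groupby([factor_a, factor_b], observed=True).size()
        la = table[factor_a].nunique()
        lb = table[factor_b].nunique()
        if len(cells) < la * lb:
            raise ValueError(
                "empty cells in the two-factor layout; refit with "
                "interaction=False or complete the design"
            )
        if (cells < 2).any():
            raise ValueError(
                "interaction term needs n >= 2 per cell; thin cells: "
                f"{cells[cells < 2].index.tolist()}"
            )
    rhs = f"C(Q('{factor_a}')) * C(Q('{factor_b}'))" if interaction else (
        f"C(Q('{factor_a}')) + C(Q('{factor_b}'))"
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = smf.ols(f"Q('{response}') ~ {rhs}", data=table).fit()
        anova = sm.stats.anova_lm(fit, typ=2)
    # constant response: sums of squares are pure rounding noise; the
    # convention here is F = 0, p = 1 (no evidence of any effect)
    if np.allclose(table[response].var(ddof=0), 0.0):
        effect_rows = anova.index != "Residual"
        anova.loc[effect_rows, "F"] = 0.0
        anova.loc[effect_rows, "PR(>F)"] = 1.0
    return anova
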