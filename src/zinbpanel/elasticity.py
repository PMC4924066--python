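"""Post-estimation elasticities of the expected hourly crash frequency.

For the mixture mean E[n_it] = (1 - q_it) * lambda_it:

* a continuous covariate x appearing only in the count state has elasticity
  beta * xbar at the sample mean (percent change in E[n] per 1% change in x);
* an indicator appearing only in the count state has pseudo-elasticity
  1 - exp(-beta): the relative change in E[n] attributable to the indicator
  being 1, measured against the indicator-on mean;
* a covariate in the zero state (or both states) has no closed form at the
  mean — its elasticity is averaged over observations, since it depends on
  the distribution of q_it.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from .data import PanelDataset
from .fit import FitResult
from .model import ConfigError, expected_count, linear_predictors


def elasticity_nb_continuous(beta: float, xbar: float) -> float:
    """Mean-evaluated elasticity beta * xbar of a count-state-only continuous
    covariate."""
    return float(beta) * float(xbar)


def pseudo_elasticity_indicator(beta: float) -> float:
    """Pseudo-elasticity 1 - exp(-beta) = (e^beta - 1)/e^beta of a
    count-state-only indicator."""
    return 1.0 - math.exp(-float(beta))


@dataclasses.dataclass
class ElasticityRecord:
    variable: str
    states: str  # count, zero, both
    kind: str  # continuous, indicator
    method: str  # mean_closed_form, observation_averaged
    value: float
    xbar: float | None = None


@dataclasses.dataclass
class ElasticityReport:
    records: list

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(r) for r in self.records])


def _coef(fit: FitResult, design: list, variable: str, state: str) -> float:
    if variable not in design:
        return 0.0
    j = design.index(variable) + 1  # +1 for intercept
    prefix = "nb" if state == "count" else "zero"
    return float(fit.estimates[fit.param_names.index(f"{prefix}:{j}")])


def elasticity_observation_averaged(
    data: PanelDataset, fit: FitResult, variable: str, kind: str = "continuous"
) -> float:
    """Observation-averaged elasticity of E[n_it] for a covariate in either
    or both states.

    Continuous: mean over rows of x_it * (beta_nb - beta_z * q_it), the exact
    derivative d ln E / d ln x with absent-state coefficients 0.  Indicator:
    mean over rows of the relative change in E[n_it] when the indicator
    toggles 0 -> 1 holding everything else fixed, measured against the
    indicator-on level (reducing to 1 - exp(-beta) for count-state-only
    indicators).
    """
    if variable not in data.frame.columns:
        raise ConfigError(f"unknown variable {variable!r}")
    in_count = variable in fit.count_design
    in_zero = variable in fit.zero_design
    if not (in_count or in_zero):
        raise ConfigError(f"{variable!r} is in neither design")
    b_nb = _coef(fit, fit.count_design, variable, "count")
    b_z = _coef(fit, fit.zero_design, variable, "zero")
    work = data.with_designs(fit.count_design, fit.zero_design)
    if kind == "continuous":
        lp = linear_predictors(work, fit.params)
        x = data.frame[variable].to_numpy(dtype=float)
        return float(np.mean(x * (b_nb - b_z * lp.q_it)))
    if kind != "indicator":
        raise ConfigError("kind must be 'continuous' or 'indicator'")
    df1 = data.frame.copy()
    df0 = data.frame.copy()
    df1[variable] = 1.0
    df0[variable] = 0.0
    lp1 = linear_predictors(
        PanelDataset(df1, fit.count_design, fit.zero_design), fit.params
    )
    lp0 = linear_predictors(
        PanelDataset(df0, fit.count_design, fit.zero_design), fit.params
    )
    e1 = expected_count(lp1.lambda_it, lp1.q_it)
    e0 = expected_count(lp0.lambda_it, lp0.q_it)
    ok = e1 > 0  # rows where the indicator-on state is certain-zero carry no ratio
    if not ok.any():
        raise ConfigError(f"indicator-on expected count is 0 on every row for {variable!r}")
    return float(np.mean((e1[ok] - e0[ok]) / e1[ok]))


def elasticity_report(
    data: PanelDataset,
    fit: FitResult,
    variable_kinds: dict,
    categories: dict | None = None,
) -> ElasticityReport:
    """Elasticities for every design variable of a fitted model.

    ``variable_kinds`` maps variable name to ``continuous`` or ``indicator``.
    Count-state-only variables use the mean-evaluated closed form; variables
    touching the zero state are observation-averaged (and labelled so).
    """
    records = []
    seen = []
    for v in list(fit.count_design) + [
        v for v in fit.zero_design if v not in fit.count_design
    ]:
        if v in seen:
            continue
        seen.append(v)
        kind = variable_kinds.get(v, "continuous")
        in_count = v in fit.count_design
        in_zero = v in fit.zero_design
        states = "both" if (in_count and in_zero) else ("count" if in_count else "zero")
        if states == "count":
            b = _coef(fit, fit.count_design, v, "count")
            if kind == "continuous":
                xbar = float(np.mean(data.frame[v].to_numpy(dtype=float)))
                value = elasticity_nb_continuous(b, xbar)
                records.append(
                    ElasticityRecord(v, states, kind, "mean_closed_form", value, xbar)
                )
            else:
                value = pseudo_elasticity_indicator(b)
                records.append(
                    ElasticityRecord(v, states, kind, "mean_closed_form", value)
                )
        else:
            value = elasticity_observation_averaged(data, fit, v, kind)
            records.append(
                ElasticityRecord(v, states, kind, "observation_averaged", value)
            )
    return ElasticityReport(records)


def render_elasticity_text(report: ElasticityReport, categories: dict | None = None) -> str:
    """Formatted text table grouped by characteristic category."""
    df = report.to_frame()
    categories = categories or {}
    df["category"] = [categories.get(v, "other") for v in df["variable"]]
    lines = ["Elasticity estimates for crash frequency (crash/hour)", "=" * 60]
    for cat, grp in df.groupby("category", sort=True):
        lines.append(f"-- {cat} characteristics --")
        for _, row in grp.iterrows():
            tag = "*" if row["method"] == "observation_averaged" else " "
            lines.append(f"  {row['variable']:<42s} {row['value']:>8.3f}{tag}")
    lines.append("(* observation-averaged: variable enters the zero state)")
    return "\n".join(lines)
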