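"""File I/O and report assembly: panel CSVs, model-spec configs, and
Table-shaped text/JSON output for fits, Vuong tests and elasticities.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .data import PanelDataset, PanelSchemaError
from .elasticity import ElasticityReport
from .fit import FitResult
from .selection import VuongResult

logger = logging.getLogger("zinbpanel")


@dataclasses.dataclass
class ModelSpec:
    """User-supplied model specification (the package does no variable search:
    p-values are reported and the covariate lists are the user's)."""

    count_state: list
    zero_state: list
    model: str = "zinb_re"
    re_mode: str = "sigma"
    quad_order: int = 15

    @classmethod
    def from_yaml(cls, path) -> "ModelSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(
            count_state=list(raw.get("count_state", [])),
            zero_state=list(raw.get("zero_state", [])),
            model=raw.get("model", "zinb_re"),
            re_mode=raw.get("re_mode", "sigma"),
            quad_order=int(raw.get("quad_order", 15)),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def read_panel_csv(path, spec: Optional[ModelSpec] = None) -> PanelDataset:
    """Read a long-format panel CSV (``site_id,time_id,count,<covariate...>``).

    Rows with missing values in the required fields (keys, count, and any
    design covariate) are dropped and the drop count logged, mirroring the
    deletion of segment-hours without real-time traffic or environmental
    readings.  Non-integer counts are a schema error naming the rows.
    """
    df = pd.read_csv(path)
    for col in ("site_id", "time_id", "count"):
        if col not in df.columns:
            raise PanelSchemaError(f"missing required column {col!r}")
    needed = ["site_id", "time_id", "count"]
    if spec is not None:
        for v in list(spec.count_state) + list(spec.zero_state):
            if v not in df.columns:
                raise PanelSchemaError(f"missing required column {v!r}")
            if v not in needed:
                needed.append(v)
    n0 = len(df)
    df = df.dropna(subset=needed)
    dropped = n0 - len(df)
    if dropped:
        logger.info("dropped %d rows with missing required fields", dropped)
    counts = df["count"].to_numpy()
    bad = np.flatnonzero(counts != np.floor(counts))
    if bad.size:
        raise PanelSchemaError(f"non-integer counts at rows {bad[:10].tolist()}")
    panel = PanelDataset(
        df.reset_index(drop=True),
        spec.count_state if spec else (),
        spec.zero_state if spec else (),
    )
    panel.dropped_rows = dropped
    return panel


def write_panel_csv(data: PanelDataset, path) -> None:
    data.frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def fit_to_dict(fit: FitResult) -> dict:
    """Machine-readable fit record (JSON-serializable)."""
    arr = lambda a: None if a is None else [None if not np.isfinite(v) else float(v) for v in a]
    return {
        "model": fit.model_label,
        "re_mode": fit.re_mode,
        "quad_order": fit.quad_order,
        "count_design": list(fit.count_design),
        "zero_design": list(fit.zero_design),
        "param_names": list(fit.param_names),
        "estimates": arr(fit.estimates),
        "se": arr(fit.se),
        "tstats": arr(fit.tstats),
        "pvalues": arr(fit.pvalues),
        "loglik": fit.loglik,
        "neg2ll": fit.neg2ll,
        "aic": fit.aic,
        "bic": fit.bic,
        "k_free": fit.k_free,
        "n_obs": fit.n_obs,
        "n_sites": fit.n_sites,
        "converged": fit.converged,
        "n_iter": fit.n_iter,
        "boundary": list(fit.boundary),
        "se_flag": fit.se_flag,
    }


def render_fit_text(fit: FitResult) -> str:
    """Coefficient table shaped like the usual two-state presentation:
    zero-state block, count-state block, then dispersion/effects and fit
    statistics."""
    tab = fit.coef_table()
    lines = [
        f"{fit.model_label} estimation results "
        f"(N = {fit.n_obs}, sites = {fit.n_sites})",
        "=" * 72,
        f"{'Variable':<42s}{'Estimate':>12s}{'t-Statistic':>14s}",
    ]
    for state in ("zero-state", "count-state", "dispersion/effects"):
        grp = tab[tab["state"] == state]
        if grp.empty:
            continue
        lines.append(f"-- {state} --")
        for _, row in grp.iterrows():
            t = f"{row['t']:.2f}" if np.isfinite(row["t"]) else "n/a"
            lines.append(f"{row['variable']:<42s}{row['estimate']:>12.3f}{t:>14s}")
    lines += [
        "-" * 72,
        f"-2 Log Likelihood{fit.neg2ll:>20,.0f}",
        f"AIC (smaller is better){fit.aic:>14,.0f}",
        f"BIC (smaller is better){fit.bic:>14,.0f}",
    ]
    if fit.boundary:
        lines.append(f"boundary parameters: {', '.join(fit.boundary)}")
    if not fit.converged:
        lines.append(f"WARNING: optimizer did not converge ({fit.message})")
    return "\n".join(lines)


def render_summary_text(summary: pd.DataFrame) -> str:
    lines = [
        "Summary statistics "
        f"(N = {summary.attrs['n_obs']}, sites = {summary.attrs['n_sites']}, "
        f"t_i in [{summary.attrs['t_min']}, {summary.attrs['t_max']}], "
        f"zeros = {100 * summary.attrs['zero_fraction']:.1f}%)",
        "=" * 72,
        f"{'Variable':<24s}{'Mean':>12s}{'Std. Dev':>12s}{'Minimum':>12s}{'Maximum':>12s}",
    ]
    for v, row in summary.iterrows():
        lines.append(
            f"{v:<24s}{row['mean']:>12.3f}{row['std']:>12.3f}"
            f"{row['min']:>12.3f}{row['max']:>12.3f}"
        )
    return "\n".join(lines)


def vuong_to_dict(res: VuongResult) -> dict:
    return {
        "V": res.V,
        "m_bar": res.m_bar,
        "s_m": res.s_m,
        "n": int(len(res.m)),
        "threshold": res.threshold,
        "decision": res.decision,
        "comparison": res.comparison,
    }


@dataclasses.dataclass
class RunReport:
    """Bundle of one full analysis run; every number traces to a result
    object and the whole report is reproducible from (input, config, seed)."""

    input_digest: dict
    spec: ModelSpec
    summary_text: str
    fit: FitResult
    vuong: Optional[VuongResult]
    elasticity: Optional[ElasticityReport]
    seed: int

    def render_text(self) -> str:
        parts = [
            "RUN REPORT",
            "=" * 72,
            f"input: {self.input_digest}",
            f"model: {self.spec.model} (re_mode={self.spec.re_mode}, "
            f"quad_order={self.spec.quad_order}), seed={self.seed}",
            "",
            "[1] Panel summary",
            self.summary_text,
            "",
            "[2] Estimation",
            render_fit_text(self.fit),
        ]
        if self.vuong is not None:
            parts += [
                "",
                "[3] Vuong test for zero inflation",
                f"V = {self.vuong.V:.2f} ({self.vuong.comparison}); "
                f"decision: {self.vuong.decision} at |V| > {self.vuong.threshold}",
            ]
        if self.elasticity is not None:
            from .elasticity import render_elasticity_text

            parts += ["", "[4] Elasticities", render_elasticity_text(self.elasticity)]
        return "\n".join(parts)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.txt").write_text(self.render_text())
        payload = {
            "input": self.input_digest,
            "spec": dataclasses.asdict(self.spec),
            "seed": self.seed,
            "fit": fit_to_dict(self.fit),
            "vuong": vuong_to_dict(self.vuong) if self.vuong else None,
            "elasticity": (
                self.elasticity.to_frame().to_dict(orient="records")
                if self.elasticity
                else None
            ),
        }
        (out / "report.json").write_text(json.dumps(payload, indent=2))
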