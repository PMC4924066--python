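"""Unbalanced panel container for segment-by-hour crash counts.

A panel holds one row per (site, hour) with a non-negative integer count and
named covariate columns (continuous, or 0/1 indicators).  Sites are road
segments; hours need not be contiguous and the number of observations t_i may
differ across sites (sensor outages make the panel unbalanced).
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("zinbpanel")

REQUIRED_COLUMNS = ("site_id", "time_id", "count")


class PanelSchemaError(ValueError):
    """The table does not satisfy the panel schema."""


@dataclasses.dataclass
class PanelDataset:
    """An unbalanced panel of counts and covariates.

    Parameters
    ----------
    frame
        Long-format table with columns ``site_id``, ``time_id``, ``count``
        plus covariates.  Rows are re-sorted by (site, time) on construction
        so that each site occupies a contiguous block.
    count_design, zero_design
        Ordered covariate names entering the count-state (negative binomial)
        and zero-state (logit) linear predictors.  An intercept is implicit
        in both designs.
    """

    frame: pd.DataFrame
    count_design: Sequence[str] = ()
    zero_design: Sequence[str] = ()

    def __post_init__(self) -> None:
        df = self.frame
        for col in REQUIRED_COLUMNS:
            if col not in df.columns:
                raise PanelSchemaError(f"missing required column {col!r}")
        counts = df["count"].to_numpy()
        if not np.issubdtype(np.asarray(counts).dtype, np.number):
            raise PanelSchemaError("count column must be numeric")
        if np.any(counts < 0) or np.any(counts != np.floor(counts)):
            bad = np.flatnonzero((counts < 0) | (counts != np.floor(counts)))
            raise PanelSchemaError(
                f"counts must be non-negative integers (rows {bad[:5].tolist()}...)"
            )
        if df.duplicated(["site_id", "time_id"]).any():
            raise PanelSchemaError("duplicate (site_id, time_id) pairs")
        for name in list(self.count_design) + list(self.zero_design):
            if name not in df.columns:
                raise PanelSchemaError(f"design names unknown covariate {name!r}")
        df = df.sort_values(["site_id", "time_id"], kind="mergesort")
        df = df.reset_index(drop=True)
        object.__setattr__(self, "frame", df)
        codes, uniques = pd.factorize(df["site_id"], sort=True)
        self._site_codes = codes
        self._site_labels = uniques
        # contiguous block starts per site, for segment reductions
        self._site_starts = np.flatnonzero(np.r_[True, np.diff(codes) != 0])
        self.count_design = list(self.count_design)
        self.zero_design = list(self.zero_design)

    # -- dimensions ----------------------------------------------------
    @property
    def n_obs(self) -> int:
        """N = sum_i t_i, the total number of (site, hour) rows."""
        return len(self.frame)

    @property
    def n_sites(self) -> int:
        return len(self._site_labels)

    @property
    def site_sizes(self) -> np.ndarray:
        """t_i per site, in site-label order."""
        return np.diff(np.r_[self._site_starts, self.n_obs])

    @property
    def site_starts(self) -> np.ndarray:
        return self._site_starts

    @property
    def site_codes(self) -> np.ndarray:
        return self._site_codes

    @property
    def site_labels(self):
        return self._site_labels

    @property
    def counts(self) -> np.ndarray:
        return self.frame["count"].to_numpy(dtype=np.int64)

    # -- design matrices -----------------------------------------------
    def design_matrix(self, names: Sequence[str]) -> np.ndarray:
        """Design matrix [1, X] with the implicit leading intercept.

        Cached per design tuple (likelihood evaluation calls this in a hot
        loop); the returned array must not be mutated.
        """
        key = tuple(names)
        cache = getattr(self, "_design_cache", None)
        if cache is None:
            cache = {}
            object.__setattr__(self, "_design_cache", cache)
        if key not in cache:
            cols = [np.ones(self.n_obs)]
            cols += [self.frame[n].to_numpy(dtype=float) for n in names]
            cache[key] = np.column_stack(cols)
        return cache[key]

    def count_matrix(self) -> np.ndarray:
        return self.design_matrix(self.count_design)

    def zero_matrix(self) -> np.ndarray:
        return self.design_matrix(self.zero_design)

    def site_slice(self, site_id) -> "PanelDataset":
        """Sub-panel for one site (keeps the designs)."""
        sub = self.frame[self.frame["site_id"] == site_id]
        if sub.empty:
            raise KeyError(site_id)
        return PanelDataset(sub.copy(), self.count_design, self.zero_design)

    def with_designs(self, count_design, zero_design) -> "PanelDataset":
        return PanelDataset(self.frame, count_design, zero_design)


def summarize_panel(data: PanelDataset) -> pd.DataFrame:
    """Per-variable summary (mean, sd, min, max) plus panel dimensions.

    Mirrors the usual presentation of segment-hour study data: one row per
    variable starting with the crash count, then every covariate column, with
    the panel dimensions (N, number of sites, spread of t_i) attached as
    DataFrame attrs.
    """
    if data.n_obs == 0:
        raise PanelSchemaError("empty panel")
    df = data.frame
    variables = ["count"] + [
        c for c in df.columns if c not in ("site_id", "time_id", "count")
    ]
    rows = []
    for v in variables:
        x = df[v].to_numpy(dtype=float)
        rows.append(
            {
                "variable": v,
                "mean": float(np.mean(x)),
                "std": float(np.std(x, ddof=1)) if len(x) > 1 else 0.0,
                "min": float(np.min(x)),
                "max": float(np.max(x)),
            }
        )
    out = pd.DataFrame(rows).set_index("variable")
    t = data.site_sizes
    out.attrs["n_obs"] = int(data.n_obs)
    out.attrs["n_sites"] = int(data.n_sites)
    out.attrs["t_min"] = int(t.min())
    out.attrs["t_max"] = int(t.max())
    out.attrs["zero_fraction"] = float(np.mean(data.counts == 0))
    return out
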