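"""Linear model of opsin diversity against habitat depth.

Light attenuates rapidly with depth in a freshwater column, so species
living deeper are expected to retain fewer distinct opsin transcripts.
The model is an ordinary least-squares regression of the number of
distinct opsin transcripts per species on mean habitat depth in metres,
reported with adjusted R-squared and the two-sided slope p-value.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm


@dataclasses.dataclass
class DepthRecord:
    """One species: mean habitat depth (m) and distinct opsin-transcript count."""

    species: str
    depth_m: float
    n_opsins: int
    lineage: str | None = None

    def __post_init__(self):
        if not np.isfinite(self.depth_m) or self.depth_m < 0:
            raise ValueError(f"depth must be finite and >= 0, got {self.depth_m}")
        if self.n_opsins < 0 or int(self.n_opsins) != self.n_opsins:
            raise ValueError(f"n_opsins must be a non-negative integer, got {self.n_opsins}")


@dataclasses.dataclass
class FitResult:
    """OLS fit of opsin count on depth."""

    slope: float       # opsins per metre
    intercept: float   # opsins at the surface
    r2: float
    adj_r2: float
    p_slope: float     # two-sided, t distribution with n - 2 df
    n: int

    def report(self) -> str:
        return (
            f"n = {self.n}; slope = {self.slope:.4g} opsins/m; "
            f"intercept = {self.intercept:.3g}; adjusted R^2 = {self.adj_r2:.2f}; "
            f"p = {self.p_slope:.3g}"
        )


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame(
            [
                {
                    "species": r.species,
                    "depth_m": r.depth_m,
                    "n_opsins": r.n_opsins,
                    "lineage": r.lineage,
                }
                for r in records
            ]
        )
    return df


def fit_depth_model(
    records: Sequence[DepthRecord] | pd.DataFrame,
    exclude_zero: bool = False,
) -> FitResult:
    """OLS of distinct opsin-transcript count on mean habitat depth.

    Requires at least three species with non-identical depths.
    ``exclude_zero`` drops species with no detected opsins before
    fitting, for sensitivity analysis.
    """
    df = _as_frame(records)
    if exclude_zero:
        df = df[df["n_opsins"] > 0]
    if len(df) < 3:
        raise ValueError("need at least 3 records to fit")
    if df["depth_m"].nunique() < 2:
        raise ValueError("degenerate design: all depths identical")
    x = sm.add_constant(df["depth_m"].to_numpy(dtype=float))
    model = sm.OLS(df["n_opsins"].to_numpy(dtype=float), x).fit()
    return FitResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r2=float(model.rsquared),
        adj_r2=float(model.rsquared_adj),
        p_slope=float(model.pvalues[1]),
        n=int(model.nobs),
    )


def summarize_depth_bands(
    records: Sequence[DepthRecord] | pd.DataFrame,
    depth_cutoff: float = 200.0,
    multi_threshold: int = 2,
) -> pd.DataFrame:
    """2x2 contingency of shallow/deep against single/multi-opsin species.

    Rows: depth <= cutoff (shallow) vs > cutoff (deep); columns: fewer
    than ``multi_threshold`` distinct opsins vs at least that many.
    """
    if depth_cutoff <= 0:
        raise ValueError("depth_cutoff must be positive")
    df = _as_frame(records)
    table = pd.DataFrame(
        0,
        index=pd.Index(["shallow", "deep"], name="band"),
        columns=pd.Index(["single", "multi"], name="opsins"),
    )
    for _, row in df.iterrows():
        band = "shallow" if row["depth_m"] <= depth_cutoff else "deep"
        kind = "multi" if row["n_opsins"] >= multi_threshold else "single"
        table.loc[band, kind] += 1
    return table


def read_depth_table(path) -> pd.DataFrame:
    """Read a species depth table (TSV/CSV with species, depth_m, n_opsins[, lineage])."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    required = {"species", "depth_m", "n_opsins"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"depth table missing columns: {sorted(missing)}")
    return df
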