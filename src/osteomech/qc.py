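"""Outlier regimen and descriptive cohort statistics.

QC follows a two-stage interquartile-range (IQR) regimen: stage 1 removes
specimens whose fit RMSE is an IQR outlier; stage 2 computes IQR fences for
every mechanical parameter on the stage-1 survivors and removes a specimen
if any parameter falls outside its fences.  Fences are frozen after they
are computed (no iterative re-fencing), which makes the pipeline
deterministic and idempotent on its own output.

Descriptive statistics: coefficients of variation, Pearson correlations of
per-donor parameter medians against donor BMD (with the weak / moderate /
strong tiering by |r|), specimen-level Spearman rank correlations, grouped
mean ± SD summary tables, and normalized TMD histograms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "OutlierReport",
    "CorrelationTier",
    "iqr_filter",
    "qc_pipeline",
    "cv",
    "tier_of",
    "donor_median_correlation",
    "spearman_matrix",
    "group_summary",
    "tmd_histogram",
    "mixed_model_table",
    "DEFAULT_PARAM_COLUMNS",
]

DEFAULT_PARAM_COLUMNS = (
    "E_pr", "E_mx", "sigma_y", "sigma_u", "p", "eta", "k_D",
    "E_inf", "E_0", "tan_delta", "D_max", "D_end",
)


@dataclass
class OutlierReport:
    n_input: int
    n_removed_rmse: int
    n_removed_params: dict
    surviving_ids: list
    iqr_multiplier: float

    @property
    def n_removed_stage2(self) -> int:
        return self.n_input - self.n_removed_rmse - len(self.surviving_ids)


@dataclass(frozen=True)
class CorrelationTier:
    coefficient: float
    tier: str  # weak | moderate | strong


def tier_of(r: float) -> str:
    """Correlation strength tier by |r|: <=0.29 weak, 0.30-0.49 moderate, >=0.5 strong."""
    a = abs(r)
    if a >= 0.5:
        return "strong"
    if a >= 0.295:  # printed convention: 0.30-0.49 is moderate
        return "moderate"
    return "weak"


def iqr_filter(values, multiplier: float = 1.5):
    """Index sets ``(kept, removed)`` of the IQR outlier rule.

    Quartiles by linear interpolation; values outside the closed interval
    ``[Q1 - m*IQR, Q3 + m*IQR]`` are removed.  Fewer than 4 finite values:
    no-op with a warning.
    """
    values = np.asarray(values, dtype=float)
    idx = np.arange(values.size)
    finite = np.isfinite(values)
    if finite.sum() < 4:
        warnings.warn("fewer than 4 values; IQR filter is a no-op", stacklevel=2)
        return idx, np.array([], dtype=int)
    q1, q3 = np.percentile(values[finite], [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - multiplier * iqr, q3 + multiplier * iqr
    inside = finite & (values >= lo) & (values <= hi)
    return idx[inside], idx[~inside]


def qc_pipeline(
    fit_table: pd.DataFrame,
    param_columns=None,
    multiplier: float = 1.5,
    id_column: str = "specimen_id",
):
    """Two-stage IQR outlier removal on a cohort fit table.

    Stage 1 filters on ``rmse``; stage 2 computes per-parameter fences on the
    stage-1 survivors and drops a row if any parameter is outside.  Rows
    flagged ``converged == False`` are removed up front (they carry no
    physical parameters).  Returns ``(OutlierReport, filtered_table)``.
    """
    if "rmse" not in fit_table.columns:
        raise KeyError("fit table must contain an 'rmse' column")
    if param_columns is None:
        param_columns = [c for c in DEFAULT_PARAM_COLUMNS if c in fit_table.columns]
    missing = [c for c in param_columns if c not in fit_table.columns]
    if missing:
        raise KeyError(f"fit table lacks parameter columns: {missing}")

    table = fit_table.copy()
    if "converged" in table.columns:
        table = table[table["converged"].fillna(False).astype(bool)]
    n_input = len(table)

    kept, _ = iqr_filter(table["rmse"].to_numpy(), multiplier)
    stage1 = table.iloc[kept]
    n_removed_rmse = n_input - len(stage1)

    # stage-2 fences frozen on stage-1 survivors
    removed_per_param = {}
    drop = np.zeros(len(stage1), dtype=bool)
    for col in param_columns:
        vals = stage1[col].to_numpy(dtype=float)
        finite = np.isfinite(vals)
        if finite.sum() < 4:
            removed_per_param[col] = 0
            continue
        q1, q3 = np.percentile(vals[finite], [25, 75])
        iqr = q3 - q1
        out = finite & ((vals < q1 - multiplier * iqr) | (vals > q3 + multiplier * iqr))
        removed_per_param[col] = int(out.sum())
        drop |= out

    filtered = stage1.loc[~drop]
    ids = (filtered[id_column].tolist() if id_column in filtered.columns
           else filtered.index.tolist())
    report = OutlierReport(
        n_input=n_input,
        n_removed_rmse=n_removed_rmse,
        n_removed_params=removed_per_param,
        surviving_ids=ids,
        iqr_multiplier=multiplier,
    )
    return report, filtered


def cv(values) -> float:
    """Coefficient of variation: sample SD divided by mean."""
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    mean = values.mean()
    if mean == 0.0:
        raise ZeroDivisionError("CV undefined for zero mean")
    if values.size < 2:
        return 0.0
    return float(values.std(ddof=1) / mean)


def donor_median_correlation(
    fit_table: pd.DataFrame,
    donor_bmd: pd.DataFrame | pd.Series,
    param_columns=None,
    donor_column: str = "donor_id",
):
    """Pearson r of per-donor parameter medians against donor BMD, tiered.

    ``donor_bmd`` maps donor id -> BMD (Series, or DataFrame with
    ``donor_id``/``bmd`` columns).  Requires >= 3 donors.  Returns a dict
    ``parameter -> CorrelationTier``.
    """
    if isinstance(donor_bmd, pd.DataFrame):
        donor_bmd = donor_bmd.set_index(donor_column)["bmd"]
    if param_columns is None:
        param_columns = [c for c in DEFAULT_PARAM_COLUMNS if c in fit_table.columns]
    medians = fit_table.groupby(donor_column)[list(param_columns)].median()
    medians = medians.join(donor_bmd.rename("bmd"), how="inner")
    if len(medians) < 3:
        raise ValueError("donor-median correlation needs at least 3 donors")
    out = {}
    for col in param_columns:
        sub = medians[[col, "bmd"]].dropna()
        if len(sub) < 3 or sub[col].nunique() < 2:
            out[col] = CorrelationTier(float("nan"), "undefined")
            continue
        r, _ = stats.pearsonr(sub[col], sub["bmd"])
        out[col] = CorrelationTier(float(r), tier_of(r))
    return out


def spearman_matrix(specimen_table: pd.DataFrame, columns=None) -> pd.DataFrame:
    """Pairwise Spearman rho over specimen-level columns (average ranks on ties).

    Constant columns give NaN entries.  Requires >= 4 specimens.
    """
    if columns is None:
        columns = [c for c in specimen_table.columns
                   if pd.api.types.is_numeric_dtype(specimen_table[c])]
    data = specimen_table[list(columns)]
    if len(data) < 4:
        raise ValueError("Spearman matrix needs at least 4 specimens")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant columns produce NaN by design
        rho = data.corr(method="spearman")
    for c in columns:
        if data[c].nunique(dropna=True) < 2:
            rho.loc[c, :] = np.nan
            rho.loc[:, c] = np.nan
    return rho


def group_summary(table: pd.DataFrame, grouping, value_columns=None) -> pd.DataFrame:
    """Per-group mean, SD and n in a long-format summary table."""
    if value_columns is None:
        value_columns = [c for c in DEFAULT_PARAM_COLUMNS if c in table.columns]
    rows = []
    for keys, sub in table.groupby(grouping, dropna=False):
        if not isinstance(keys, tuple):
            keys = (keys,)
        base = dict(zip([grouping] if isinstance(grouping, str) else grouping, keys))
        for col in value_columns:
            vals = sub[col].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            rows.append({
                **base, "parameter": col, "n": int(vals.size),
                "mean": float(vals.mean()) if vals.size else float("nan"),
                "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                "flagged_empty": vals.size == 0,
            })
    return pd.DataFrame(rows)


def tmd_histogram(values, bin_width: float = 25.0) -> pd.DataFrame:
    """Normalized (unit-area) TMD histogram as (bin_left, bin_right, density)."""
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    lo = np.floor(values.min() / bin_width) * bin_width
    hi = np.ceil(values.max() / bin_width) * bin_width
    edges = np.arange(lo, hi + bin_width, bin_width)
    if edges.size < 2:
        edges = np.array([lo, lo + bin_width])
    density, edges = np.histogram(values, bins=edges, density=True)
    return pd.DataFrame({
        "bin_left": edges[:-1], "bin_right": edges[1:], "density": density,
    })


def mixed_model_table(
    fit_table: pd.DataFrame,
    param_columns=None,
    fixed_effects=("group", "age", "sex"),
    donor_column: str = "donor_id",
) -> pd.DataFrame:
    """Tidy long-format export for mixed-effects testing in external software.

    One row per specimen and parameter, with the donor id (random effect),
    the fixed-effect columns and a heteroscedasticity grouping label
    (tissue x sex).  Hypothesis testing itself is deliberately out of scope.
    """
    if param_columns is None:
        param_columns = [c for c in DEFAULT_PARAM_COLUMNS if c in fit_table.columns]
    keep = [donor_column, *[c for c in ("specimen_id", "tissue", *fixed_effects)
                            if c in fit_table.columns]]
    long = fit_table.melt(
        id_vars=keep, value_vars=list(param_columns),
        var_name="parameter", value_name="value",
    )
    if {"tissue", "sex"}.issubset(long.columns):
        long["variance_group"] = long["tissue"].astype(str) + ":" + long["sex"].astype(str)
    return long
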