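"""Quantitative evaluation metrics: CV, dilution linearity, cohort power.

Conventions: intensities live on the log2 scale; the coefficient of
variation is always computed on the natural scale (values exponentiated
base 2 first), so CV% is comparable with raw-intensity benchmarks.
Correlations with the dilution series use log2-transformed tissue
proportions, excluding samples where the proportion is zero.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import IntensityMatrix
from .missingness import MissingnessLabels
from .ruv import ReplicateDesign

__all__ = [
    "percent_cv",
    "cv_table",
    "median_cv",
    "dilution_correlation",
    "cohort_power",
    "mnar_mcar_intensity_test",
]


def percent_cv(values) -> float:
    """CV% of log2 intensities on the natural scale.

    Exponentiates (base 2), then 100 * sample sd (ddof=1) / mean.
    Undefined (NaN) with fewer than two observed values.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 2:
        return float("nan")
    nat = np.exp2(v)
    return float(100.0 * nat.std(ddof=1) / nat.mean())


def cv_table(
    x: IntensityMatrix,
    meta: pd.DataFrame,
    peptide_set=None,
    group_by: str = "sample",
) -> pd.DataFrame:
    """Per-peptide CV% within each group, plus the group medians.

    ``group_by`` is one of ``sample`` (all runs of a sample type across
    instruments — the experiment-wide convention), ``sample_instrument``,
    or ``experiment`` (every run in one group). Returns a tidy frame with
    columns ``group``, ``peptide_id``, ``cv_pct``.
    """
    values = x.values if peptide_set is None else x.values[list(peptide_set)]
    meta_idx = meta.set_index("run_id").reindex(values.index)
    if group_by == "sample":
        keys = meta_idx["sample_type"]
    elif group_by == "sample_instrument":
        keys = meta_idx["sample_type"] + "/" + meta_idx["instrument"]
    elif group_by == "experiment":
        keys = pd.Series("all", index=values.index)
    else:
        raise ValueError(f"unknown group_by {group_by!r}")
    rows = []
    for group, sub in values.groupby(keys.to_numpy()):
        nat = np.exp2(sub.to_numpy(dtype=float))
        counts = (~np.isnan(nat)).sum(axis=0)
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(nat, axis=0)
            sd = np.nanstd(nat, axis=0, ddof=1)
            cv = np.where(counts >= 2, 100.0 * sd / mean, np.nan)
        rows.append(pd.DataFrame({"group": group, "peptide_id": sub.columns, "cv_pct": cv}))
    return pd.concat(rows, ignore_index=True)


def median_cv(x: IntensityMatrix, meta: pd.DataFrame, peptide_set=None,
              group_by: str = "sample") -> float:
    """Median CV% over all (group, peptide) combinations."""
    table = cv_table(x, meta, peptide_set=peptide_set, group_by=group_by)
    return float(table["cv_pct"].median())


def dilution_correlation(
    x: IntensityMatrix,
    meta: pd.DataFrame,
    proportions: dict[str, float],
    peptide_set=None,
    proportion_scale: str = "log2",
    min_points: int = 3,
) -> pd.Series:
    """Per-peptide Pearson correlation with the tissue dilution series.

    ``proportions`` maps sample_type -> tissue proportion. Runs from
    zero-proportion samples are excluded when the proportion is taken on
    the log2 scale (the default); with ``proportion_scale='linear'`` they
    are included at 0. Peptides with fewer than ``min_points`` observed
    runs or zero variance come back NaN.
    """
    sample_of = meta.set_index("run_id")["sample_type"].reindex(x.run_ids)
    prop = sample_of.map(proportions).astype(float)
    if proportion_scale == "log2":
        keep = prop > 0
        xvar = np.log2(prop[keep])
    elif proportion_scale == "linear":
        keep = prop.notna()
        xvar = prop[keep]
    else:
        raise ValueError(f"unknown proportion_scale {proportion_scale!r}")
    values = x.values if peptide_set is None else x.values[list(peptide_set)]
    values = values.loc[keep[keep].index]
    xv = xvar.to_numpy(dtype=float)
    out = {}
    for p in values.columns:
        y = values[p].to_numpy(dtype=float)
        ok = ~np.isnan(y)
        if ok.sum() < min_points or np.std(y[ok]) == 0 or np.std(xv[ok]) == 0:
            out[p] = np.nan
            continue
        out[p] = float(np.corrcoef(xv[ok], y[ok])[0, 1])
    return pd.Series(out, name="dilution_r")


def _triplicate_means(
    x: IntensityMatrix, design: ReplicateDesign, sample_type: str, meta: pd.DataFrame
) -> pd.DataFrame:
    """Per replicate group of one sample type, the per-peptide mean of the
    observed values (the analysis unit for cohort comparisons)."""
    sample_of = meta.set_index("run_id")["sample_type"]
    rows = []
    names = []
    for gname, runs in sorted(design.groups().items()):
        runs = [r for r in runs if r in x.run_ids]
        if not runs or sample_of[runs[0]] != sample_type:
            continue
        rows.append(x.values.loc[runs].mean(axis=0, skipna=True))
        names.append(gname)
    return pd.DataFrame(rows, index=names)


def cohort_power(
    x: IntensityMatrix,
    meta: pd.DataFrame,
    design: ReplicateDesign,
    sample_a: str,
    sample_b: str,
    cohort_sizes,
    peptide_set=None,
    iterations: int = 10,
    alpha: float = 0.05,
    equal_var: bool = True,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulated cohort comparisons between two sample types.

    The analysis unit is the technical-replicate-group mean. For each
    cohort size n and iteration, n units per group are drawn without
    replacement, each peptide is tested with a two-sided unpaired t-test,
    and the fraction of the peptide set reaching p < alpha is recorded.
    Returns one row per cohort size with the mean percentage significant
    and its 95% confidence interval over iterations.
    """
    rng = np.random.default_rng(seed)
    units_a = _triplicate_means(x, design, sample_a, meta)
    units_b = _triplicate_means(x, design, sample_b, meta)
    if peptide_set is not None:
        units_a = units_a[list(peptide_set)]
        units_b = units_b[list(peptide_set)]
    rows = []
    for n in cohort_sizes:
        if n > len(units_a) or n > len(units_b):
            logging.getLogger(__name__).warning(
                "cohort size %d exceeds available units (%d, %d); skipped",
                n, len(units_a), len(units_b),
            )
            continue
        pcts = []
        for _ in range(iterations):
            sel_a = units_a.iloc[rng.choice(len(units_a), size=n, replace=False)]
            sel_b = units_b.iloc[rng.choice(len(units_b), size=n, replace=False)]
            res = stats.ttest_ind(
                sel_a.to_numpy(), sel_b.to_numpy(), axis=0,
                equal_var=equal_var, nan_policy="omit",
            )
            pvals = np.asarray(res.pvalue, dtype=float)
            tested = ~np.isnan(pvals)
            pcts.append(100.0 * (pvals[tested] < alpha).sum() / tested.sum())
        pcts = np.asarray(pcts)
        mean = float(pcts.mean())
        if iterations > 1:
            half = stats.t.ppf(0.975, iterations - 1) * pcts.std(ddof=1) / np.sqrt(iterations)
        else:
            half = 0.0
        rows.append(
            {"cohort_size": n, "pct_significant": mean,
             "ci_low": mean - half, "ci_high": mean + half, "iterations": iterations}
        )
    return pd.DataFrame(rows)


def mnar_mcar_intensity_test(
    labels: MissingnessLabels,
    x: IntensityMatrix,
    meta: pd.DataFrame,
    statistic: str = "median",
    equal_var: bool = True,
) -> dict:
    """Compare non-missing intensities of MNAR- vs MCAR-labelled peptides.

    For each labelled (peptide, sample_type) the per-peptide summary
    (median by default) of its observed intensities within that sample
    type is collected; the two label classes are compared with a
    two-sided unpaired t-test. Detection-limit censoring predicts MNAR
    peptides sit lower.
    """
    sample_of = meta.set_index("run_id")["sample_type"].reindex(x.run_ids)
    summarize = {"median": np.nanmedian, "mean": np.nanmean}[statistic]
    groups: dict[str, list[float]] = {"MNAR": [], "MCAR": []}
    for label in groups:
        sub = labels.labels[labels.labels["label"] == label]
        for sample, peps in sub.groupby("sample_type")["peptide_id"]:
            runs = x.run_ids[sample_of.to_numpy() == sample]
            block = x.values.loc[runs, list(peps)].to_numpy(dtype=float)
            with np.errstate(invalid="ignore"), warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                vals = summarize(block, axis=0)
            groups[label].extend(vals[~np.isnan(vals)].tolist())
    if min(len(groups["MNAR"]), len(groups["MCAR"])) < 2:
        raise ValueError("both MNAR and MCAR classes need >= 2 labelled peptides")
    t, p = stats.ttest_ind(groups["MNAR"], groups["MCAR"], equal_var=equal_var)
    return {
        "t": float(t),
        "p_value": float(p),
        "mnar_mean": float(np.mean(groups["MNAR"])),
        "mcar_mean": float(np.mean(groups["MCAR"])),
        "n_mnar": len(groups["MNAR"]),
        "n_mcar": len(groups["MCAR"]),
    }
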