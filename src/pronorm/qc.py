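"""Post-quantification run QC and peptide-set selections.

These are the filters applied between upstream quantification (OpenSWATH /
PyProphet style exports) and normalization: exclusion of low-quality runs,
removal of inconsistently observed peptides, and the observation-frequency
peptide selections used throughout evaluation. All selections are pure
functions of the observation mask and the metadata; thresholds are strict
inequalities ("more than" / "less than").
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .matrix import IntensityMatrix

__all__ = [
    "filter_runs_qc",
    "filter_inconsistent_peptides",
    "select_frequent_peptides",
    "select_tissue_specific_peptides",
    "observation_fraction",
]

logger = logging.getLogger(__name__)

#: Run pairs sharing fewer common peptides than this contribute no
#: correlation term (correlation on a tiny overlap is noise).
MIN_COMMON_PEPTIDES = 50


def observation_fraction(x: IntensityMatrix, meta: pd.DataFrame) -> pd.DataFrame:
    """Per (sample_type, peptide) fraction of runs with an observed value.

    Denominators count the runs of each sample type actually present in
    ``x`` (i.e. post-QC runs).
    """
    mask = x.mask()
    sample_of = meta.set_index("run_id")["sample_type"]
    return mask.groupby(sample_of.reindex(mask.index)).mean()


def _mean_replicate_correlation(values: np.ndarray, min_common: int) -> np.ndarray:
    """Mean pairwise Pearson correlation of each row with the other rows.

    Pairwise-complete on the observed entries; pairs overlapping in fewer
    than ``min_common`` peptides are skipped. Rows with no usable pair
    get NaN.
    """
    m = values.shape[0]
    sums = np.full((m, m), np.nan)
    for i in range(m):
        for j in range(i + 1, m):
            both = ~np.isnan(values[i]) & ~np.isnan(values[j])
            if both.sum() < min_common:
                continue
            a, b = values[i, both], values[j, both]
            if a.std() == 0 or b.std() == 0:
                continue
            r = np.corrcoef(a, b)[0, 1]
            sums[i, j] = sums[j, i] = r
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(sums, axis=1)


def filter_runs_qc(
    x: IntensityMatrix,
    meta: pd.DataFrame,
    peptide_meta: pd.DataFrame,
    min_proteins: int = 1200,
    min_mean_corr: float = 0.9,
    min_common_peptides: int = MIN_COMMON_PEPTIDES,
) -> tuple[IntensityMatrix, pd.DataFrame]:
    """Remove runs failing either baseline quality criterion.

    A run is excluded if (i) peptides are observed from fewer than
    ``min_proteins`` distinct proteins (proteins counted with >= 1
    supporting peptide), or (ii) its mean Pearson correlation with the
    other runs of the same sample type, on pairwise-complete log2
    intensities, is below ``min_mean_corr``. Sample types with a single
    run skip criterion (ii) with a warning.

    Returns the filtered matrix and metadata annotated with ``qc_pass``
    and ``qc_reason`` for every run (including the excluded ones).
    """
    meta = meta.copy()
    meta["qc_pass"] = True
    meta["qc_reason"] = ""
    meta_idx = meta.set_index("run_id")

    protein_of = peptide_meta.set_index("peptide_id")["protein_id"]
    mask = x.mask()
    proteins = protein_of.reindex(mask.columns)
    # distinct proteins with >=1 observed peptide, per run
    counts = mask.T.groupby(proteins).any().sum(axis=0)
    fail_proteins = counts < min_proteins

    fail_corr = pd.Series(False, index=x.run_ids)
    sample_of = meta_idx["sample_type"].reindex(x.run_ids)
    for sample, runs in x.run_ids.to_series().groupby(sample_of):
        runs = list(runs)
        if len(runs) < 2:
            logger.warning("sample_type %s has a single run; correlation QC skipped", sample)
            continue
        mean_r = _mean_replicate_correlation(
            x.values.loc[runs].to_numpy(dtype=float), min_common_peptides
        )
        bad = np.nan_to_num(mean_r, nan=1.0) < min_mean_corr
        fail_corr.loc[np.asarray(runs)[bad]] = True

    for run in x.run_ids:
        reasons = []
        if fail_proteins.get(run, False):
            reasons.append("min_proteins")
        if fail_corr.get(run, False):
            reasons.append("min_mean_corr")
        if reasons:
            meta.loc[meta["run_id"] == run, ["qc_pass", "qc_reason"]] = [False, "+".join(reasons)]

    keep = meta.set_index("run_id")["qc_pass"].reindex(x.run_ids)
    filtered = IntensityMatrix(x.values.loc[keep.to_numpy(dtype=bool)], scale=x.scale)
    return filtered, meta


def filter_inconsistent_peptides(
    x: IntensityMatrix,
    meta: pd.DataFrame,
    min_fraction: float = 0.10,
    sample_set: list[str] | None = None,
) -> IntensityMatrix:
    """Drop peptides not observed in > ``min_fraction`` of replicates of
    at least one sample type in ``sample_set``."""
    if not sample_set:
        raise ValueError("sample_set must be non-empty")
    frac = observation_fraction(x, meta)
    frac = frac.reindex(sample_set)
    keep = (frac > min_fraction).any(axis=0)
    return IntensityMatrix(x.values.loc[:, keep[keep].index], scale=x.scale)


def select_frequent_peptides(
    x: IntensityMatrix,
    meta: pd.DataFrame,
    threshold: float = 0.80,
    sample_set: list[str] | None = None,
    peptide_meta: pd.DataFrame | None = None,
    origin_filter: str | None = None,
) -> pd.Index:
    """Peptides observed in > ``threshold`` of runs of *every* sample type
    in ``sample_set`` (optionally restricted to one origin class)."""
    if not sample_set:
        raise ValueError("sample_set must be non-empty")
    frac = observation_fraction(x, meta).reindex(sample_set)
    keep = (frac > threshold).all(axis=0)
    selected = keep[keep].index
    if origin_filter is not None:
        if peptide_meta is None:
            raise ValueError("origin filtering requires peptide metadata")
        origin = peptide_meta.set_index("peptide_id")["origin"]
        selected = selected[origin.reindex(selected).eq(origin_filter)]
    return selected


def select_tissue_specific_peptides(
    x: IntensityMatrix,
    meta: pd.DataFrame,
    peptide_meta: pd.DataFrame,
    positive_sample: str,
    negative_sample: str,
    present_threshold: float = 0.80,
    absent_threshold: float = 0.05,
    origin_filter: str = "human",
) -> pd.Index:
    """Peptides specific to one tissue: frequently observed in the sample
    containing it and (nearly) absent from the sample lacking it."""
    if positive_sample == negative_sample:
        raise ValueError("positive and negative samples must differ")
    frac = observation_fraction(x, meta)
    pos = frac.loc[positive_sample]
    neg = frac.loc[negative_sample] if negative_sample in frac.index else pd.Series(0.0, index=pos.index)
    keep = (pos > present_threshold) & (neg < absent_threshold)
    selected = keep[keep].index
    origin = peptide_meta.set_index("peptide_id")["origin"]
    return selected[origin.reindex(selected).eq(origin_filter)]
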