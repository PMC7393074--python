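"""Removal of unwanted variation with technical replicates and negative controls.

The model for m runs of n peptides on the log2 scale is

    Y = M X beta + W alpha + eps

where M (m x m1) assigns runs to technical-replicate groups, W alpha is the
unwanted variation of dimension k to be estimated and subtracted, and the
biological signal X beta (here, the tissue dilution series) is constant
within replicate groups and is preserved. Negative-control peptides --
features assumed untouched by the biology, here yeast peptides rescaled to
equal per-sample means -- anchor the estimate of W.

Two estimators are provided in scikit-learn style:

``RUV3``
    the complete-data estimator: residualize against M, take the top-k
    left singular directions of the residual, project, regress the control
    sub-matrix to obtain W, and subtract W alpha.
``RUVIIIC``
    the complete-cases variant for matrices with missing values: for each
    target peptide, RUV-III is run on the sub-matrix of runs where the
    peptide and a common set of control peptides are all observed, and
    only that peptide's normalized column is written back. Missing entries
    stay missing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import IntensityMatrix

from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "ReplicateDesign",
    "build_replicate_design",
    "ControlSet",
    "scale_negative_controls",
    "RUV3",
    "RUVIIIC",
    "MedianNormalizer",
    "ruv3",
    "ruv3c",
    "median_normalize",
    "peptide_eligibility",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# replicate design
# ---------------------------------------------------------------------------

@dataclass
class ReplicateDesign:
    """Partition of runs into technical-replicate groups.

    ``group_of`` maps run_id -> group label; runs absent from the mapping
    are unassigned and take no part in normalization. Every group's runs
    share one sample type, and under the cross-instrument constraint all
    runs of a group come from distinct instruments.
    """

    group_of: dict[str, str]
    cross_instrument: bool = True
    seed: int | None = None

    @property
    def m1(self) -> int:
        return len(set(self.group_of.values()))

    @property
    def assigned_runs(self) -> list:
        return list(self.group_of)

    def groups(self) -> dict[str, list]:
        out: dict[str, list] = {}
        for run, grp in self.group_of.items():
            out.setdefault(grp, []).append(run)
        return out

    def membership_matrix(self, run_ids) -> np.ndarray:
        """Binary indicator M for the given (assigned) runs; columns are the
        replicate groups represented among them, one 1 per row."""
        run_ids = list(run_ids)
        labels = [self.group_of[r] for r in run_ids]
        cols = sorted(set(labels))
        col_idx = {g: j for j, g in enumerate(cols)}
        M = np.zeros((len(run_ids), len(cols)))
        for i, g in enumerate(labels):
            M[i, col_idx[g]] = 1.0
        return M


def build_replicate_design(
    meta: pd.DataFrame,
    group_size: int = 3,
    cross_instrument: bool = True,
    seed: int | None = None,
) -> ReplicateDesign:
    """Randomly partition each sample type's runs into replicate groups.

    Groups of ``group_size`` runs are drawn within sample type; with
    ``cross_instrument`` each group's runs come from distinct instruments
    (the maintenance states then differ within groups, which is what lets
    the estimator see instrument and drift effects as within-replicate
    variation). Leftover runs stay unassigned. Deterministic given seed.
    """
    if group_size < 2:
        raise ValueError("group_size must be >= 2")
    rng = np.random.default_rng(seed)
    group_of: dict[str, str] = {}
    for sample, sub in meta.groupby("sample_type", sort=True):
        runs = sub["run_id"].tolist()
        instruments = sub.set_index("run_id")["instrument"]
        if cross_instrument and instruments.nunique() < group_size:
            raise ValueError(
                f"sample_type {sample!r} has runs on {instruments.nunique()} instruments; "
                f"cannot form cross-instrument groups of {group_size}"
            )
        order = rng.permutation(len(runs))
        pool = [runs[i] for i in order]
        g = 0
        if not cross_instrument:
            while len(pool) >= group_size:
                members, pool = pool[:group_size], pool[group_size:]
                for r in members:
                    group_of[r] = f"{sample}/g{g}"
                g += 1
        else:
            by_instr: dict[str, list] = {}
            for r in pool:
                by_instr.setdefault(instruments[r], []).append(r)
            while True:
                # take one run from each of the group_size best-stocked
                # instruments; keeps the partition feasible as long as possible
                avail = sorted(
                    (i for i in by_instr if by_instr[i]),
                    key=lambda i: (-len(by_instr[i]), str(i)),
                )
                if len(avail) < group_size:
                    break
                members = [by_instr[i].pop() for i in avail[:group_size]]
                for r in members:
                    group_of[r] = f"{sample}/g{g}"
                g += 1
    return ReplicateDesign(group_of=group_of, cross_instrument=cross_instrument, seed=seed)


# ---------------------------------------------------------------------------
# negative controls
# ---------------------------------------------------------------------------

@dataclass
class ControlSet:
    """Negative-control peptides with their rescaled intensities.

    ``scaled`` is the full matrix with only the control columns shifted so
    that each control's mean log2 intensity is identical across sample
    types (the unweighted grand mean of the per-sample-type means).
    """

    peptide_ids: list
    scaled: IntensityMatrix

    def control_frame(self) -> pd.DataFrame:
        return self.scaled.values[self.peptide_ids]


def scale_negative_controls(
    x: IntensityMatrix, controls, meta: pd.DataFrame
) -> ControlSet:
    """Equalize each control peptide's per-sample-type mean log2 intensity.

    Controls (here, peptides from yeast proteins) genuinely differ between
    sample types because the yeast proportion differs; shifting each
    control by (grand mean - sample mean) removes that compositional
    signal so that what remains is unwanted variation. Missing entries and
    non-control peptides are untouched.
    """
    controls = [c for c in controls if c in x.peptide_ids]
    if not controls:
        raise ValueError("empty control set")
    sample_of = meta.set_index("run_id")["sample_type"].reindex(x.run_ids)
    values = x.values.copy()
    sub = values[controls]
    sample_means = sub.groupby(sample_of.to_numpy()).mean()  # sample_type x control
    grand = sample_means.mean(axis=0)  # unweighted over sample types
    shift = (grand - sample_means).reindex(sample_of.to_numpy())
    shift.index = x.run_ids
    values[controls] = sub + shift
    return ControlSet(peptide_ids=list(controls), scaled=IntensityMatrix(values, scale=x.scale))


# ---------------------------------------------------------------------------
# RUV-III on complete data
# ---------------------------------------------------------------------------

def _ruv3_core(
    Y: np.ndarray, M: np.ndarray, control_idx: np.ndarray, k: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """The complete-data estimator. Returns (normalized, W, alpha).

    Steps: (1) Y0 = Y - M (M'M)^-1 M' Y; (2) U = top-k left singular
    directions of Y0; (3) alpha = U' Y; (4) alpha_c = control columns of
    alpha; (5) W = Yc~ alpha_c' (alpha_c alpha_c')^-1 where Yc~ is the
    control sub-matrix centered by its column means; (6) Y - W alpha.

    Centering in step (5) makes every column of W -- and hence the
    removed component W alpha -- mean-zero over the rows, so each
    peptide's mean intensity is preserved. Without it, the controls'
    absolute intensity levels leak into the factor regression through
    any run-constant unwanted factor and the normalized matrix loses its
    location.
    """
    m, n = Y.shape
    m1 = M.shape[1]
    if not 1 <= k <= m - m1:
        raise ValueError(f"k={k} must satisfy 1 <= k <= rows - groups = {m - m1}")
    if control_idx.size == 0:
        raise ValueError("at least one control column is required")
    # residualize against the replicate membership (subtract group means)
    group_means = M @ np.linalg.solve(M.T @ M, M.T @ Y)
    Y0 = Y - group_means
    scale = np.abs(Y).max()
    if np.abs(Y0).max() <= 1e-12 * max(scale, 1.0):
        raise ValueError("no within-replicate variation: residual matrix is zero")
    U, _, _ = np.linalg.svd(Y0, full_matrices=False)
    U = U[:, :k]
    alpha = U.T @ Y
    alpha_c = alpha[:, control_idx]
    gram = alpha_c @ alpha_c.T
    cond = np.linalg.cond(gram)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            "alpha_c alpha_c' is numerically singular; use fewer factors or more controls"
        )
    Yc = Y[:, control_idx]
    Yc = Yc - Yc.mean(axis=0, keepdims=True)
    W = Yc @ alpha_c.T @ np.linalg.inv(gram)
    return Y - W @ alpha, W, alpha


class RUV3(TransformerMixin, BaseEstimator):
    """Complete-data RUV-III estimator.

    Parameters
    ----------
    design : ReplicateDesign
        Replicate grouping; every row of the fitted matrix must be assigned.
    controls : sequence of peptide ids
        Negative-control columns (assumed already scaled).
    k : int
        Dimension of the unwanted-variation factor space, 1 <= k <=
        rows - groups.

    Attributes
    ----------
    W_ : ndarray of shape (m, k)
        Estimated unwanted-variation factors.
    alpha_ : ndarray of shape (k, n)
        Loadings of the factors on the peptides.
    normalized_ : IntensityMatrix
        Y - W alpha for the fitted matrix.

    Notes
    -----
    The estimator is not inductive: W is a per-run quantity, so
    ``transform`` applies only to the matrix seen by ``fit``. The product
    W alpha is invariant to rotations of the singular directions, so ties
    among singular values are harmless.
    """

    def __init__(self, design: ReplicateDesign = None, controls=None, k: int = 1):
        self.design = design
        self.controls = controls
        self.k = k

    def fit(self, X, y=None):
        x = X if isinstance(X, IntensityMatrix) else IntensityMatrix.from_frame(pd.DataFrame(X))
        values = x.values
        if values.isna().any().any():
            raise ValueError("RUV3 requires a complete matrix; use RUVIIIC for missing data")
        unassigned = [r for r in values.index if r not in self.design.group_of]
        if unassigned:
            raise ValueError(f"rows not assigned to replicate groups: {unassigned[:5]}")
        control_idx = np.flatnonzero(values.columns.isin(self.controls))
        M = self.design.membership_matrix(values.index)
        normalized, W, alpha = _ruv3_core(values.to_numpy(dtype=float), M, control_idx, self.k)
        self.W_ = W
        self.alpha_ = alpha
        self.n_features_in_ = values.shape[1]
        self._fit_index = values.index
        self.normalized_ = IntensityMatrix(
            pd.DataFrame(normalized, index=values.index, columns=values.columns)
        )
        return self

    def transform(self, X):
        frame = X.values if isinstance(X, IntensityMatrix) else pd.DataFrame(X)
        if not frame.index.equals(self._fit_index):
            raise ValueError("RUV3 can only transform the matrix it was fitted on")
        return self.normalized_.values


def ruv3(Y: IntensityMatrix, design: ReplicateDesign, controls, k: int) -> RUV3:
    """Functional wrapper: fit :class:`RUV3` and return the fitted estimator."""
    if isinstance(controls, ControlSet):
        controls = controls.peptide_ids
    return RUV3(design=design, controls=list(controls), k=k).fit(Y)


# ---------------------------------------------------------------------------
# eligibility and RUV-III-C
# ---------------------------------------------------------------------------

def peptide_eligibility(
    x: IntensityMatrix, design: ReplicateDesign, k: int
) -> pd.DataFrame:
    """Which peptides can be normalized with k factors.

    For peptide p, with R_p the assigned runs where p is observed and G_p
    the distinct replicate groups among them, p is eligible iff
    ``|R_p| - G_p >= k`` (the residual degrees of freedom must cover the
    factor dimension). Returns a frame with ``n_rows``, ``n_groups`` and
    ``eligible`` per peptide.
    """
    assigned = [r for r in x.run_ids if r in design.group_of]
    mask = x.mask().loc[assigned]
    groups = pd.Series([design.group_of[r] for r in assigned], index=assigned)
    n_rows = mask.sum(axis=0)
    n_groups = mask.groupby(groups).any().sum(axis=0)
    return pd.DataFrame(
        {
            "n_rows": n_rows.astype(int),
            "n_groups": n_groups.astype(int),
            "eligible": (n_rows - n_groups) >= k,
        }
    )


class RUVIIIC(TransformerMixin, BaseEstimator):
    """Per-peptide complete-case RUV-III for matrices with missing values.

    For each target peptide p, the estimator collects the assigned,
    control-bearing runs where p is observed, restricts to the control
    peptides observed in *all* of those runs, runs RUV-III on the
    complete sub-matrix of those runs, and writes back the normalized
    column for p only. The factor subspace of each sub-problem is
    estimated from *every* column that is fully observed on the selected
    runs (not just the target and the controls); the control regression
    then uses the shared controls. On a matrix with no missing values
    every sub-problem therefore coincides with complete-data RUV-III on
    the whole matrix, and the two estimators agree exactly.

    Originally missing entries of p stay missing; ineligible peptides
    (too few residual degrees of freedom, or no shared control) come back
    entirely missing and are listed in ``report_``.

    Runs in which no control peptide is observed (sample types without
    control material) receive missing output for every peptide.

    Parameters
    ----------
    design : ReplicateDesign
    controls : ControlSet
        Scaled negative controls (see :func:`scale_negative_controls`).
    k : int
        Factor dimension; the study-scale default in this field is 20,
        small benchmark matrices need far less.
    targets : sequence of peptide ids, optional
        Defaults to all non-control peptides.
    min_controls : int, optional
        Minimum number of shared control peptides a sub-problem needs;
        defaults to ``k + 1``. With k or fewer controls the control
        regression has no residual degrees of freedom and the
        normalized values are numerically wild, so such peptides are
        reported ineligible instead.

    Attributes
    ----------
    normalized_ : IntensityMatrix
    report_ : DataFrame with columns peptide_id, n_rows, n_groups,
        n_controls, eligible, reason.
    """

    def __init__(self, design: ReplicateDesign = None, controls: ControlSet = None,
                 k: int = 1, targets=None, min_controls: int | None = None):
        self.design = design
        self.controls = controls
        self.k = k
        self.targets = targets
        self.min_controls = min_controls

    def fit(self, X, y=None):
        x = X if isinstance(X, IntensityMatrix) else IntensityMatrix.from_frame(pd.DataFrame(X))
        if self.k < 1:
            raise ValueError("k must be >= 1")
        scaled = self.controls.scaled.values.reindex(index=x.run_ids)
        control_ids = [c for c in self.controls.peptide_ids if c in x.peptide_ids]
        targets = list(self.targets) if self.targets is not None else \
            [p for p in x.peptide_ids if p not in set(control_ids)]

        # work on the matrix with control columns replaced by scaled values
        values = x.values.copy()
        values[control_ids] = scaled[control_ids]
        arr = values.to_numpy(dtype=float)
        col_of = {p: j for j, p in enumerate(values.columns)}
        obs = ~np.isnan(arr)

        assigned = np.array([r in self.design.group_of for r in values.index])
        ctl_cols = np.array([col_of[c] for c in control_ids], dtype=int)
        control_bearing = obs[:, ctl_cols].any(axis=1) if len(ctl_cols) else np.zeros(len(arr), bool)
        group_labels = np.array(
            [self.design.group_of.get(r, "") for r in values.index], dtype=object
        )

        out = np.full_like(arr, np.nan)
        records = []
        for p in targets:
            j = col_of[p]
            rows = np.flatnonzero(obs[:, j] & assigned & control_bearing)
            rec = {"peptide_id": p, "n_rows": len(rows), "n_groups": 0,
                   "n_controls": 0, "eligible": False, "reason": ""}
            if len(rows) == 0:
                rec["reason"] = "no_rows"
                records.append(rec)
                continue
            n_groups = len(set(group_labels[rows]))
            rec["n_groups"] = n_groups
            shared = ctl_cols[obs[np.ix_(rows, ctl_cols)].all(axis=0)]
            rec["n_controls"] = len(shared)
            if len(shared) == 0:
                rec["reason"] = "no_shared_controls"
                records.append(rec)
                continue
            min_controls = self.k + 1 if self.min_controls is None else self.min_controls
            if len(shared) < min_controls:
                rec["reason"] = "too_few_controls"
                records.append(rec)
                continue
            if len(rows) - n_groups < self.k:
                rec["reason"] = "insufficient_rows"
                records.append(rec)
                continue
            complete_cols = np.flatnonzero(obs[rows].all(axis=0))
            # target first, then every other fully observed column
            cols = np.concatenate(([j], complete_cols[complete_cols != j]))
            sub = arr[np.ix_(rows, cols)]
            ctl_pos = np.flatnonzero(np.isin(cols, shared))
            M = _membership(group_labels[rows])
            try:
                normalized, _, _ = _ruv3_core(sub, M, ctl_pos, self.k)
            except (ValueError, np.linalg.LinAlgError) as exc:
                rec["reason"] = f"degenerate: {exc}"
                records.append(rec)
                continue
            out[rows, j] = normalized[:, 0]
            rec["eligible"] = True
            records.append(rec)

        self.report_ = pd.DataFrame.from_records(
            records, columns=["peptide_id", "n_rows", "n_groups", "n_controls", "eligible", "reason"]
        )
        self.normalized_ = IntensityMatrix(
            pd.DataFrame(out, index=values.index, columns=values.columns)[targets]
        )
        self._fit_index = values.index
        return self

    def transform(self, X):
        frame = X.values if isinstance(X, IntensityMatrix) else pd.DataFrame(X)
        if not frame.index.equals(self._fit_index):
            raise ValueError("RUVIIIC can only transform the matrix it was fitted on")
        return self.normalized_.values


def _membership(labels: np.ndarray) -> np.ndarray:
    cols = sorted(set(labels))
    idx = {g: j for j, g in enumerate(cols)}
    M = np.zeros((len(labels), len(cols)))
    for i, g in enumerate(labels):
        M[i, idx[g]] = 1.0
    return M


def ruv3c(
    x: IntensityMatrix,
    design: ReplicateDesign,
    controls: ControlSet,
    k: int,
    target_peptides=None,
) -> tuple[IntensityMatrix, pd.DataFrame]:
    """Functional wrapper around :class:`RUVIIIC`.

    Returns the normalized matrix (target peptides as columns) and the
    eligibility report.
    """
    est = RUVIIIC(design=design, controls=controls, k=k, targets=target_peptides).fit(x)
    return est.normalized_, est.report_


# ---------------------------------------------------------------------------
# median normalization baseline
# ---------------------------------------------------------------------------

class MedianNormalizer(TransformerMixin, BaseEstimator):
    """Subtract each run's median observed log2 intensity from that run."""

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        frame = X.values if isinstance(X, IntensityMatrix) else pd.DataFrame(X)
        medians = frame.median(axis=1, skipna=True)
        empty = medians.isna()
        if empty.any():
            logger.warning("%d run(s) with no observations left unchanged", int(empty.sum()))
            medians = medians.fillna(0.0)
        return frame.sub(medians, axis=0)


def median_normalize(x: IntensityMatrix) -> IntensityMatrix:
    """Per-run median centering; missing entries are ignored and preserved."""
    return IntensityMatrix(MedianNormalizer().fit_transform(x), scale=x.scale)
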