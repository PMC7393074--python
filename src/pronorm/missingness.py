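"""Missing-value taxonomy, technical replacement, and TP/FP accounting.

Missing values in a peptide matrix arise three ways: the peptide is truly
absent from the sample (true missing), its intensity sits near the limit of
detection (missing not at random, MNAR), or detection failed despite
adequate abundance (missing completely at random, MCAR). With many
technical replicates the three can be told apart from missingness patterns
alone, and MCAR/MNAR holes can be filled by *technical replacement*: a
draw from a normal distribution centred on the peptide's mean normalized
intensity within its replicate group.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import IntensityMatrix
from .ruv import BaseEstimator, ReplicateDesign, TransformerMixin

__all__ = [
    "MissingnessLabels",
    "classify_missingness",
    "ReplacementResult",
    "TechnicalReplacer",
    "technical_replacement",
    "likely_tp_fp_peptides",
    "replacement_accounting",
    "majority_rule",
]

logger = logging.getLogger(__name__)


def majority_rule(group_size: int) -> int:
    """Smallest observation count that is 'more than half' of a group."""
    return group_size // 2 + 1


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

@dataclass
class MissingnessLabels:
    """Per (sample_type, peptide) missingness label.

    ``labels`` is a long DataFrame with columns ``sample_type``,
    ``peptide_id``, ``label`` where label is one of ``true_missing``,
    ``MNAR``, ``MCAR``, ``intermediate``; each peptide gets exactly one
    label per sample type.
    """

    labels: pd.DataFrame
    group_size: int
    thresholds: dict

    def peptides(self, label: str, sample_type: str | None = None) -> pd.Index:
        sub = self.labels
        if sample_type is not None:
            sub = sub[sub["sample_type"] == sample_type]
        return pd.Index(sub.loc[sub["label"] == label, "peptide_id"].unique())


def classify_missingness(
    x: IntensityMatrix,
    meta: pd.DataFrame,
    group_size: int = 6,
    true_missing_threshold: float = 0.90,
    mnar_min: float = 5,
    mcar_max: float = 1,
    seed: int | None = None,
) -> MissingnessLabels:
    """Label each peptide's missingness mechanism within each sample type.

    Peptides missing in at least ``true_missing_threshold`` of a sample
    type's replicates are called true missing. The rest are judged on
    random groups of ``group_size`` replicates: a mean missing count per
    group of at least ``mnar_min`` labels the peptide MNAR (consistently
    at the edge of detection), at most ``mcar_max`` labels it MCAR, and
    anything between is intermediate. Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    sample_of = meta.set_index("run_id")["sample_type"].reindex(x.run_ids)
    missing = x.values.isna()
    records = []
    for sample, runs in x.run_ids.to_series().groupby(sample_of):
        runs = list(runs)
        if group_size > len(runs):
            raise ValueError(
                f"group_size {group_size} exceeds the {len(runs)} replicates of {sample!r}"
            )
        sub = missing.loc[runs]
        frac = sub.mean(axis=0)
        order = rng.permutation(len(runs))
        n_groups = len(runs) // group_size
        grouped = np.array(runs)[order[: n_groups * group_size]].reshape(n_groups, group_size)
        per_group = np.stack([sub.loc[g].sum(axis=0).to_numpy() for g in grouped])
        mean_missing = per_group.mean(axis=0)
        for p, f, mm in zip(sub.columns, frac.to_numpy(), mean_missing):
            if f >= true_missing_threshold:
                label = "true_missing"
            elif mm >= mnar_min:
                label = "MNAR"
            elif mm <= mcar_max:
                label = "MCAR"
            else:
                label = "intermediate"
            records.append({"sample_type": sample, "peptide_id": p, "label": label})
    return MissingnessLabels(
        labels=pd.DataFrame.from_records(records),
        group_size=group_size,
        thresholds={
            "true_missing_threshold": true_missing_threshold,
            "mnar_min": mnar_min,
            "mcar_max": mcar_max,
            "seed": seed,
        },
    )


# ---------------------------------------------------------------------------
# technical replacement
# ---------------------------------------------------------------------------

@dataclass
class ReplacementResult:
    """Filled matrix plus an audit trail of which cells were synthesized."""

    filled: IntensityMatrix
    replaced_mask: pd.DataFrame
    rule: tuple[int, int]  # (group size, min observations required)
    seed: int | None

    def write(self, matrix_path, mask_path) -> None:
        self.filled.write_wide(matrix_path)
        mask = self.replaced_mask.astype(int).rename_axis("run_id")
        with open(mask_path, "w") as fh:
            fh.write(f"# technical replacement rule: {self.rule[0]} MS (>= {self.rule[1]})\n")
            mask.to_csv(fh)


class TechnicalReplacer(TransformerMixin, BaseEstimator):
    """Replace missing values from technical replicates.

    Within each replicate group g the per-peptide log-CV (standard
    deviation divided by mean, both on log2-scale values) is computed over
    peptides observed at least twice, and averaged into meanLogCV(g). A
    peptide missing in some runs of g but observed in at least
    ``min_observed`` of them has each missing slot replaced by an
    independent draw from

        Normal(mu, sd_fraction * meanLogCV(g) * mu),

    mu being its mean observed log2 intensity in g. All arithmetic stays
    on the log2 scale; draws are not truncated.

    Parameters
    ----------
    design : ReplicateDesign
        Groups of 2-6 replicates. The conventional rules are >= 1 of 2,
        >= 2 of 3-6, or a majority of 4-6 (:func:`majority_rule`).
    min_observed : int
        Observation count required before replacement occurs.
    sd_fraction : float
        Scale of the replacement spread relative to meanLogCV * mu.
    random_state : int, optional

    Attributes
    ----------
    replaced_mask_ : DataFrame, True where a value was synthesized.
    """

    def __init__(self, design: ReplicateDesign = None, min_observed: int = 2,
                 sd_fraction: float = 0.25, random_state: int | None = None):
        self.design = design
        self.min_observed = min_observed
        self.sd_fraction = sd_fraction
        self.random_state = random_state

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        x = X if isinstance(X, IntensityMatrix) else IntensityMatrix.from_frame(pd.DataFrame(X))
        if self.min_observed < 1:
            raise ValueError("min_observed must be >= 1")
        rng = np.random.default_rng(self.random_state)
        values = x.values.copy()
        mask = pd.DataFrame(False, index=values.index, columns=values.columns)
        run_set = set(values.index)
        for gname, runs in sorted(self.design.groups().items()):
            runs = [r for r in runs if r in run_set]
            if len(runs) < 2:
                continue
            sub = values.loc[runs]
            arr = sub.to_numpy(dtype=float)
            obs = ~np.isnan(arr)
            counts = obs.sum(axis=0)
            multi = counts >= 2
            if not multi.any():
                logger.warning("group %s has no multiply-observed peptide; skipped", gname)
                continue
            with np.errstate(invalid="ignore"), warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                means = np.nanmean(arr, axis=0)
                sds = np.nanstd(arr, axis=0, ddof=1)
            log_cv = sds[multi] / means[multi]
            mean_log_cv = float(np.nanmean(log_cv))
            fill = (counts >= self.min_observed) & (counts < len(runs))
            for j in np.flatnonzero(fill):
                mu = means[j]
                # |.| keeps the scale parameter valid when mu is negative
                sd = abs(self.sd_fraction * mean_log_cv * mu)
                rows = np.flatnonzero(~obs[:, j])
                draws = rng.normal(mu, sd, size=len(rows))
                for r, d in zip(rows, draws):
                    values.loc[runs[r], sub.columns[j]] = d
                    mask.loc[runs[r], sub.columns[j]] = True
        self.replaced_mask_ = mask
        return values

    def result(self, X) -> ReplacementResult:
        filled = self.transform(X)
        sizes = {len(v) for v in self.design.groups().values()}
        return ReplacementResult(
            filled=IntensityMatrix(filled),
            replaced_mask=self.replaced_mask_,
            rule=(max(sizes) if sizes else 0, self.min_observed),
            seed=self.random_state,
        )


def technical_replacement(
    x: IntensityMatrix,
    design: ReplicateDesign,
    min_observed: int = 2,
    sd_fraction: float = 0.25,
    seed: int | None = None,
) -> ReplacementResult:
    """Functional wrapper around :class:`TechnicalReplacer`."""
    return TechnicalReplacer(
        design=design, min_observed=min_observed, sd_fraction=sd_fraction, random_state=seed
    ).result(x)


# ---------------------------------------------------------------------------
# true/false positive accounting
# ---------------------------------------------------------------------------

def likely_tp_fp_peptides(
    x: IntensityMatrix,
    meta: pd.DataFrame,
    tp_threshold: float = 0.90,
    fp_threshold: float = 0.10,
) -> dict[str, tuple[pd.Index, pd.Index]]:
    """Likely true/false positive peptides per sample type.

    Computed on the pre-replacement matrix over the whole experiment:
    peptides observed in more than ``tp_threshold`` of a sample type's
    replicates are likely genuinely present (true positives); those seen
    in less than ``fp_threshold`` are likely spurious (false positives).
    """
    sample_of = meta.set_index("run_id")["sample_type"].reindex(x.run_ids)
    frac = x.mask().groupby(sample_of.to_numpy()).mean()
    out = {}
    for sample in frac.index:
        row = frac.loc[sample]
        out[sample] = (row.index[row > tp_threshold], row.index[row < fp_threshold])
    return out


def replacement_accounting(
    before: IntensityMatrix,
    result: ReplacementResult,
    sets: dict[str, tuple[pd.Index, pd.Index]],
    meta: pd.DataFrame,
    consistent_fraction: float = 0.10,
) -> dict:
    """Quantify the effect of technical replacement.

    Per sample type: the percentage of possible slots observed after
    replacement among likely-TP peptides (TP%) and likely-FP peptides
    (FP%). The overall proportion of missing values replaced is counted
    over peptides observed in more than ``consistent_fraction`` of a
    sample's replicates, summing numerators and denominators across
    samples before dividing.
    """
    sample_of = meta.set_index("run_id")["sample_type"].reindex(before.run_ids)
    after_mask = result.filled.mask()
    before_mask = before.mask()
    frac = before_mask.groupby(sample_of.to_numpy()).mean()

    rows = []
    replaced_num = 0
    replaced_den = 0
    for sample, (tp, fp) in sets.items():
        runs = before.run_ids[sample_of.to_numpy() == sample]
        n_runs = len(runs)
        rec = {"sample_type": sample, "n_runs": n_runs}
        for name, peps in (("tp", tp), ("fp", fp)):
            possible = n_runs * len(peps)
            observed = int(after_mask.loc[runs, peps].to_numpy().sum()) if possible else 0
            rec[f"{name}_pct"] = 100.0 * observed / possible if possible else np.nan
        consistent = frac.loc[sample]
        consistent = consistent.index[consistent > consistent_fraction]
        missing_before = (~before_mask.loc[runs, consistent]).to_numpy().sum()
        replaced = result.replaced_mask.loc[runs, consistent].to_numpy().sum()
        rec["missing_slots"] = int(missing_before)
        rec["replaced_slots"] = int(replaced)
        replaced_num += int(replaced)
        replaced_den += int(missing_before)
        rows.append(rec)

    per_sample = pd.DataFrame(rows).set_index("sample_type")
    return {
        "per_sample": per_sample,
        "tp_pct_mean": float(per_sample["tp_pct"].mean()),
        "fp_pct_mean": float(per_sample["fp_pct"].mean()),
        "replaced_pct": 100.0 * replaced_num / replaced_den if replaced_den else np.nan,
    }
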