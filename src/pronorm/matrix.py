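"""Core containers and IO for peptide quantification matrices.

The central object is the :class:`IntensityMatrix`: a run x peptide grid of
log2-transformed peptide intensities with an explicit missing marker (NaN).
Undetected peptides are *absent values*, never zeros -- a zero intensity is
meaningless on the log scale and would silently corrupt every downstream
statistic, so readers map literal 0 / empty / "NA" cells to missing.

Run and peptide annotations travel as plain :class:`pandas.DataFrame` tables
(``RunMetadata``, ``PeptideMetadata`` layouts below); validation helpers
enforce their invariants without forcing a custom container on users.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "IntensityMatrix",
    "read_quant_table",
    "read_wide_matrix",
    "summarize_precursors",
    "validate_run_metadata",
    "validate_peptide_metadata",
    "infer_origin",
    "ParseError",
]

#: Column layout of a run-metadata table.
RUN_METADATA_COLUMNS = ["run_id", "instrument", "day", "sample_type"]

#: Column layout of a peptide-metadata table.
PEPTIDE_METADATA_COLUMNS = ["peptide_id", "protein_id", "origin", "unique_mapping"]


class ParseError(ValueError):
    """Raised when an input table violates the expected dialect."""


@dataclass
class IntensityMatrix:
    """Run x peptide grid of peptide intensities.

    Parameters
    ----------
    values
        DataFrame indexed by run id with one column per peptide id.
        ``NaN`` marks a missing (undetected) entry.
    scale
        ``"log2"`` (the working scale of every operation in this package)
        or ``"natural"``.
    """

    values: pd.DataFrame
    scale: str = "log2"

    def __post_init__(self) -> None:
        if self.scale not in ("log2", "natural"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate run_ids")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate peptide_ids")
        vals = self.values.to_numpy(dtype=float)
        observed = vals[~np.isnan(vals)]
        if observed.size and not np.all(np.isfinite(observed)):
            raise ValueError("non-finite intensity encountered")
        if self.scale == "natural" and observed.size and np.any(observed <= 0):
            raise ValueError("natural-scale intensities must be > 0")

    # -- basic geometry -------------------------------------------------
    @property
    def run_ids(self) -> pd.Index:
        return self.values.index

    @property
    def peptide_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def mask(self) -> pd.DataFrame:
        """Boolean observation mask (True where a value is present)."""
        return self.values.notna()

    def to_log2(self) -> "IntensityMatrix":
        if self.scale == "log2":
            return self
        return IntensityMatrix(np.log2(self.values), scale="log2")

    def copy(self) -> "IntensityMatrix":
        return IntensityMatrix(self.values.copy(), scale=self.scale)

    # -- IO --------------------------------------------------------------
    def write_wide(self, path: str | Path) -> None:
        """Write a wide CSV (or Parquet if the suffix is ``.parquet``).

        First column is ``run_id``; empty cells are missing. Reading the
        file back with :func:`read_wide_matrix` (``scale="log2"``)
        round-trips values bit-exactly via the ``repr`` float format.
        """
        path = Path(path)
        if path.suffix == ".parquet":
            self.values.rename_axis("run_id").reset_index().to_parquet(path, index=False)
        else:
            out = self.values.rename_axis("run_id")
            # %.17g round-trips IEEE doubles exactly
            out.to_csv(path, float_format="%.17g")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, scale: str = "log2") -> "IntensityMatrix":
        return cls(frame.astype(float), scale=scale)


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix in (".tsv", ".tab", ".txt") else ","
    return pd.read_csv(path, sep=sep, float_precision="round_trip")


def infer_origin(protein_id: str) -> str:
    """Classify a protein identifier into ``human``/``yeast``/``iRT``/``other``.

    Follows UniProt mnemonic conventions (``..._YEAST``, ``..._HUMAN``);
    spiked retention-time calibration peptides carry an ``iRT`` token.
    """
    pid = str(protein_id)
    upper = pid.upper()
    if "IRT" in upper:
        return "iRT"
    if "YEAST" in upper:
        return "yeast"
    if "HUMAN" in upper:
        return "human"
    return "other"


def validate_run_metadata(meta: pd.DataFrame, matrix: IntensityMatrix | None = None) -> pd.DataFrame:
    """Validate (and lightly normalize) a run-metadata table.

    Ensures one record per run, non-negative day indices and, when a
    matrix is supplied, coverage of every run in it.
    """
    missing_cols = [c for c in RUN_METADATA_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise ParseError(f"run metadata missing columns {missing_cols}")
    if meta["run_id"].duplicated().any():
        dup = meta.loc[meta["run_id"].duplicated(), "run_id"].iloc[0]
        raise ParseError(f"duplicate run metadata record for {dup!r}")
    if (meta["day"] < 0).any():
        raise ParseError("acquisition day must be >= 0")
    if matrix is not None:
        unknown = matrix.run_ids.difference(meta["run_id"])
        if len(unknown):
            raise ParseError(f"runs without metadata: {list(unknown[:5])}")
    out = meta.copy()
    if "qc_pass" not in out.columns:
        out["qc_pass"] = True
        out["qc_reason"] = ""
    return out


def validate_peptide_metadata(pmeta: pd.DataFrame) -> pd.DataFrame:
    missing_cols = [c for c in PEPTIDE_METADATA_COLUMNS if c not in pmeta.columns]
    if missing_cols:
        raise ParseError(f"peptide metadata missing columns {missing_cols}")
    if pmeta["peptide_id"].duplicated().any():
        raise ParseError("duplicate peptide metadata records")
    return pmeta


def _to_missing(series: pd.Series, zero_as_missing: bool) -> pd.Series:
    vals = pd.to_numeric(series, errors="coerce")
    bad = vals.isna() & series.notna() & (series.astype(str).str.strip() != "") \
        & (~series.astype(str).str.upper().isin(["NA", "NAN"]))
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ParseError(f"malformed intensity at data line {row + 1}: {series.iloc[row]!r}")
    if zero_as_missing:
        vals = vals.mask(vals == 0)
    return vals


def read_quant_table(
    path: str | Path,
    layout: str = "long",
    zero_as_missing: bool = True,
    origin_of=infer_origin,
) -> tuple[IntensityMatrix, pd.DataFrame]:
    """Read a peptide quantification table into a log2 matrix.

    Parameters
    ----------
    path
        TSV/CSV file. ``long`` layout needs columns
        ``run_id peptide_id protein_id intensity`` (an optional ``charge``
        column triggers precursor summing); ``wide`` layout is parsed by
        :func:`read_wide_matrix` (no peptide metadata available there).
    layout
        ``"long"`` or ``"wide"``.
    zero_as_missing
        Map literal 0 intensities to missing (upstream pipelines export
        undetected peptides as zeros).

    Returns
    -------
    (IntensityMatrix, PeptideMetadata)
        Natural-scale intensities are log2-transformed; missing entries
        are preserved as NaN, never zero-filled.
    """
    if layout == "wide":
        x = read_wide_matrix(path, scale="natural", zero_as_missing=zero_as_missing)
        pmeta = pd.DataFrame(
            {
                "peptide_id": x.peptide_ids,
                "protein_id": pd.NA,
                "origin": "other",
                "unique_mapping": True,
            }
        )
        return x, pmeta
    if layout != "long":
        raise ValueError(f"unknown layout {layout!r}")

    df = _read_table(path)
    required = ["run_id", "peptide_id", "protein_id", "intensity"]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise ParseError(f"long table missing columns {missing_cols}")
    df = df.copy()
    df["intensity"] = _to_missing(df["intensity"], zero_as_missing)
    if (df["intensity"].dropna() <= 0).any():
        raise ParseError("intensities must be positive on the natural scale")

    if "charge" in df.columns:
        x = summarize_precursors(df)
    else:
        dup = df.duplicated(subset=["run_id", "peptide_id"])
        if dup.any():
            pair = df.loc[dup, ["run_id", "peptide_id"]].iloc[0]
            raise ParseError(
                f"duplicate (run, peptide) pair {tuple(pair)}: ambiguous without a charge column"
            )
        wide = df.pivot(index="run_id", columns="peptide_id", values="intensity")
        x = IntensityMatrix(np.log2(wide), scale="log2")

    mapping = df[["peptide_id", "protein_id"]].drop_duplicates()
    n_proteins = mapping.groupby("peptide_id")["protein_id"].nunique()
    pmeta = (
        mapping.drop_duplicates("peptide_id")
        .assign(
            origin=lambda t: t["protein_id"].map(origin_of),
            unique_mapping=lambda t: t["peptide_id"].map(n_proteins).eq(1),
        )
        .reset_index(drop=True)
    )
    return x, validate_peptide_metadata(pmeta)


def read_wide_matrix(
    path: str | Path, scale: str = "log2", zero_as_missing: bool = False
) -> IntensityMatrix:
    """Read a wide run x peptide CSV (first column ``run_id``)."""
    df = _read_table(path).set_index("run_id")
    df = df.astype(float)
    if zero_as_missing:
        df = df.mask(df == 0)
    x = IntensityMatrix(df, scale=scale)
    return x.to_log2() if scale == "natural" else x


def summarize_precursors(precursors: pd.DataFrame) -> IntensityMatrix:
    """Sum precursor intensities across charge states into peptide intensities.

    Summation happens on the natural scale; the result is log2-transformed.
    A peptide is missing in a run iff no precursor of it was quantified in
    that run. Total natural-scale intensity per run is conserved.
    """
    required = ["run_id", "peptide_id", "intensity"]
    missing_cols = [c for c in required if c not in precursors.columns]
    if missing_cols:
        raise ParseError(f"precursor table missing columns {missing_cols}")
    obs = precursors.dropna(subset=["intensity"])
    if (obs["intensity"] < 0).any():
        raise ParseError("negative precursor intensity")
    summed = obs.groupby(["run_id", "peptide_id"])["intensity"].sum()
    wide = summed.unstack("peptide_id")
    # runs/peptides that only ever had missing precursors keep their slots
    all_runs = precursors["run_id"].unique()
    all_peps = precursors["peptide_id"].unique()
    wide = wide.reindex(index=all_runs, columns=all_peps)
    return IntensityMatrix(np.log2(wide), scale="log2")
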