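"""The ProNorM pipeline: QC -> control scaling -> RUV-III-C -> technical
replacement -> evaluation, driven by a single keyed config.

All randomness flows from named seeds in the config; rerunning a persisted
config on identical inputs reproduces byte-identical numeric outputs. Each
run writes a manifest recording versions, seeds, the config hash and the
matrix dimensions after every stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .matrix import IntensityMatrix, read_quant_table, read_wide_matrix, validate_run_metadata
from .metrics import cv_table, dilution_correlation
from .missingness import (
    likely_tp_fp_peptides,
    replacement_accounting,
    technical_replacement,
)
from .qc import filter_inconsistent_peptides, filter_runs_qc
from .ruv import build_replicate_design, ruv3c, scale_negative_controls

__all__ = ["PipelineConfig", "pronorm_run", "sweep_k"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Keyed configuration of a ProNorM run (YAML on disk)."""

    matrix: str = ""
    layout: str = "long"
    metadata: str = ""
    controls_file: str = ""
    output_dir: str = "pronorm_out"
    k: int = 20
    group_size: int = 3
    cross_instrument: bool = True
    seed: int = 0
    min_proteins: int = 1200
    min_mean_corr: float = 0.9
    inconsistent_min_fraction: float = 0.10
    inconsistent_sample_set: list[str] = field(default_factory=list)
    target: list[str] = field(default_factory=list)  # default: all non-controls
    replacement_enabled: bool = True
    replacement_min_observed: int = 2
    sd_fraction: float = 0.25
    proportions: dict[str, float] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        canonical = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def _load_controls(path: str | Path) -> list[str]:
    lines = Path(path).read_text().splitlines()
    return [ln.strip() for ln in lines if ln.strip() and not ln.startswith("#")]


def pronorm_run(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the manifest dict.

    Stage failures abort with the stage name and cause, and partial
    outputs are removed.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "pronorm_version": __version__,
        "config_hash": config.config_hash(),
        "config": asdict(config),
        "seeds": {"design": config.seed, "replacement": config.seed + 1},
        "stages": [],
    }
    stage_name = "init"

    def stage(name, fn, *args, **kwargs):
        nonlocal stage_name
        stage_name = name
        t0 = time.perf_counter()
        result = fn(*args, **kwargs)
        logger.info("stage %-28s %6.2fs", name, time.perf_counter() - t0)
        return result

    try:
        x, pmeta = stage("read", read_quant_table, config.matrix, layout=config.layout)
        meta = validate_run_metadata(pd.read_csv(config.metadata, sep="\t"), x)
        controls = _load_controls(config.controls_file)
        _record(manifest, "read", x)

        x, meta = stage(
            "filter_runs_qc", filter_runs_qc, x, meta, pmeta,
            min_proteins=config.min_proteins, min_mean_corr=config.min_mean_corr,
        )
        _record(manifest, "filter_runs_qc", x)

        sample_set = config.inconsistent_sample_set or sorted(meta.loc[meta["qc_pass"], "sample_type"].unique())
        x = stage(
            "filter_inconsistent_peptides", filter_inconsistent_peptides,
            x, meta, min_fraction=config.inconsistent_min_fraction, sample_set=sample_set,
        )
        _record(manifest, "filter_inconsistent_peptides", x)

        design = stage(
            "build_replicate_design", build_replicate_design, meta[meta["qc_pass"]],
            group_size=config.group_size, cross_instrument=config.cross_instrument,
            seed=config.seed,
        )
        _record(manifest, "build_replicate_design", x, extra={"m1": design.m1})

        control_set = stage("scale_negative_controls", scale_negative_controls, x, controls, meta)
        _record(manifest, "scale_negative_controls", x)

        targets = config.target or None
        normalized, report = stage("ruv3c", ruv3c, x, design, control_set, config.k, targets)
        _record(manifest, "ruv3c", normalized, extra={"eligible": int(report["eligible"].sum())})
        normalized.write_wide(out / "normalized.csv")
        report.to_csv(out / "eligibility.tsv", sep="\t", index=False)

        final = normalized
        if config.replacement_enabled:
            result = stage(
                "technical_replacement", technical_replacement, normalized, design,
                min_observed=config.replacement_min_observed,
                sd_fraction=config.sd_fraction, seed=config.seed + 1,
            )
            result.write(out / "filled.csv", out / "replaced_mask.csv")
            sets = likely_tp_fp_peptides(normalized, meta)
            accounting = replacement_accounting(normalized, result, sets, meta)
            accounting["per_sample"].to_csv(out / "replacement_report.tsv", sep="\t")
            manifest["replacement"] = {
                k: v for k, v in accounting.items() if k != "per_sample"
            }
            _record(manifest, "technical_replacement", result.filled)
            final = result.filled

        reports = stage("evaluation", _evaluate, final, meta, config)
        for name, table in reports.items():
            table.to_csv(out / f"{name}.tsv", sep="\t", index=False)
        _record(manifest, "evaluation", final)

        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return manifest
    except Exception as exc:
        shutil.rmtree(out, ignore_errors=True)
        raise RuntimeError(f"pipeline failed at stage {stage_name!r}: {exc}") from exc


def _record(manifest: dict, name: str, x: IntensityMatrix, extra: dict | None = None) -> None:
    entry = {"stage": name, "n_runs": int(x.shape[0]), "n_peptides": int(x.shape[1])}
    if extra:
        entry.update(extra)
    manifest["stages"].append(entry)


def _evaluate(x: IntensityMatrix, meta: pd.DataFrame, config: PipelineConfig) -> dict[str, pd.DataFrame]:
    reports = {"cv_by_sample": cv_table(x, meta, group_by="sample")}
    if config.proportions:
        r = dilution_correlation(x, meta, config.proportions)
        reports["dilution_correlation"] = r.rename_axis("peptide_id").reset_index()
    return reports


def sweep_k(x, design, control_set, meta, proportions, ks, peptide_set=None) -> pd.DataFrame:
    """Median dilution correlation for each candidate factor dimension k.

    A reporting utility, not an automatic selector: pick k where the
    correlation with the known dilution series is high and stable.
    """
    rows = []
    for k in ks:
        normalized, report = ruv3c(x, design, control_set, k, peptide_set)
        r = dilution_correlation(normalized, meta, proportions, peptide_set=peptide_set)
        rows.append(
            {
                "k": int(k),
                "median_dilution_r": float(r.median()),
                "n_eligible": int(report["eligible"].sum()),
            }
        )
    return pd.DataFrame(rows)
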