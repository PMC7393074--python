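# pronorm

Normalization and missing-value replacement for longitudinal,
multi-instrument DIA-MS peptide quantification data.

Large proteomic studies acquire data over months on several mass
spectrometers. Instrument sensitivity decays with time since the last
clean, differs between machines, and recovers after maintenance; the
resulting unwanted variation inflates replicate CVs to the point where
real biological differences are obscured, and pushes low-abundance
peptides below the limit of detection, leaving the intensity matrix
riddled with missing values. `pronorm` addresses both problems:

* **RUV-III-C normalization** — removal of unwanted variation from a
  run × peptide log2-intensity matrix *with missing values*, using
  technical replicates and negative-control peptides. The model is
  `Y = MXβ + Wα + ε`: `M` assigns runs to replicate groups, `Wα` is the
  unwanted variation of dimension `k` to be estimated and subtracted,
  and the biology `Xβ` (constant within replicate groups) is preserved.
  The complete-data estimator residualizes `Y` against `M`, extracts the
  top-`k` left singular directions of the residual, and regresses the
  (centered) control sub-matrix on their loadings to obtain `W`. The
  complete-cases variant runs this per peptide on the runs where the
  peptide and a shared set of controls are all observed, so missing
  values never enter the estimation and are returned untouched.
* **Technical replacement** — missing values of a peptide observed in
  enough runs of its technical-replicate group are replaced by draws
  from `Normal(μ, 0.25 · meanLogCV · μ)` centred on the group mean, with
  an audit mask recording every synthesized cell.
* **Missingness taxonomy** — classification of (peptide, sample) holes
  into true missing / MNAR / MCAR from replicate patterns alone.
* **A synthetic cohort generator** — multi-instrument, multi-month
  designs with dilution-series ground truth, instrument offsets,
  sensitivity drift, low-rank contamination and LOD/random dropout, so
  the whole stack is testable without external data.
* **Evaluation metrics** — natural-scale CV%, dilution-series Pearson
  correlation, and cohort-power simulation on replicate-group means.

Estimators follow scikit-learn conventions (`fit`/`transform`,
`get_params`, fitted attributes with trailing underscores): `RUV3`,
`RUVIIIC`, `MedianNormalizer`, `TechnicalReplacer`. Module-level
functions (`ruv3c`, `technical_replacement`, ...) are thin wrappers.

## Worked example

Simulate a two-instrument, four-block benchmark cohort (160 runs × 500
peptides, 150 yeast negative controls) with known ground truth, and run
the full stack:

```python
from pronorm.benchmark import run_benchmark

result = run_benchmark(seed=1)
for name, value in result["metrics"].items():
    print(f"{name:32s} {value:8.3f}")
```

prints

```
raw_median_dilution_r               0.552
normalized_median_dilution_r        0.989
raw_median_cv_pct                  96.441
normalized_median_cv_pct           14.267
recovery_rms_adjusted               0.397
noise_sd                            0.150
n_eligible                        300.000
replaced_pct                       29.745
tp_pct_before                      95.757
tp_pct_after                       97.802
fp_pct_before                       0.349
fp_pct_after                        0.349
```

Reading these: before normalization, drift and instrument offsets crush
the per-peptide correlation with the known ovarian-tissue dilution
series to a median of 0.55 and inflate the natural-scale CV of peptides
that should be constant to 96 %. After RUV-III-C (k = 3) the
correlation is 0.99 and the CV is 14 %; the residual against the
generating signal is 0.40 log2 units, within 3× the simulated noise sd
(0.15). Technical replacement under the ≥2-of-3 rule then fills 30 % of
the remaining missing values, raising the observation rate of
likely-present peptides from 95.8 % to 97.8 % while leaving the rate of
likely-spurious peptides unchanged.

A command-line interface mirrors the library:

```bash
pronorm simulate --n-instruments 2 --n-blocks 4 --seed 1 --out sim/
pronorm normalize --matrix sim/matrix.csv --metadata sim/metadata.tsv \
    --controls-file controls.txt --k 20 --out norm/
pronorm run config.yaml        # the full pipeline from a YAML config
```

`pronorm run` executes QC → control scaling → RUV-III-C → technical
replacement → evaluation and writes a manifest (seeds, config hash,
per-stage dimensions) alongside the outputs; identical config and inputs
reproduce byte-identical results.

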