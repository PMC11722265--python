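# File formats

All tabular outputs are CSV with header rows; traces, libraries and models
use HDF5. Every pipeline stage writes a `<stage>.provenance.json` sidecar
with the resolved config hash, seed and package version.

## Voltage traces

HDF5 (`.h5`): datasets `time` (ms) and `vm` (mV); attrs `protocol` (JSON of
the stimulus fields: amplitude pA, onset/offset/duration ms, dt ms,
temperature °C, noise_mean/noise_sd pA, q10, t_ref °C), `failed`, optional
`seed`. CSV alternative: columns `time_ms`, `vm_mV`.

## Parameters

CSV, one row per cell, columns in canonical order:
`C` (µF/cm²), `Rinput` (MΩ), `tau` (ms), `gNat`, `gNa`, `gKd`, `gM`,
`gKv31`, `gL` (mS/cm²), `Eleak` (mV), `tau_max` (ms), `VT` (mV), `rss` (–).
Fitted-parameter tables prefix columns with `map_`.

## Features

CSV, one row per cell/simulation, the 23 columns of
`features.FEATURE_NAMES` (snake_case: `ap_threshold` … `vm_skewness`;
voltages mV, widths/latency/ISIs ms, counts and ratios dimensionless) plus
a boolean `well_defined`. Undefined entries are empty (NaN). Transformed /
z-space companions use the same columns.

## Simulation libraries

HDF5: datasets `theta` (n×13), `x_raw`, `x_transformed` (n×23, NaN for
undefined), `defined` (n), `std_mean`/`std_sd` (23, the feature
standardizer), `prior_lower`/`prior_upper` (13); attrs `seed`, `protocol`
(JSON).

## Expression

CSV of raw counts, one row per cell, one column per gene (unique names).
MTX + gene/cell lists are accepted by the preprocessing step when loaded
into a DataFrame first.

## Gene-linkage outputs

`cv_curve.csv`: `lam`, `cv_r2_mean`, `cv_r2_sd`, `n_genes_mean`.
`r2_per_parameter.csv`: `parameter`, `r2`.
`latent.csv`: `latent_1`, `latent_2` (+ optional `family`).
Family-mean parameter matrices: rows = group labels, columns = parameters,
values z-scored by the fitted cohort's mean/SD.

## Pipeline config

YAML with the fields of `pipeline.PipelineConfig` (unknown keys are
rejected). `protocol:` holds stimulus-field overrides; `prior_lower` /
`prior_upper` override the prior box.
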