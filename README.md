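# tepstab

Stability analysis of TMS-evoked EEG potentials (TEPs): how many pulses does a
block need before the averaged response stops changing?

Given pulse-locked EEG epochs, the pipeline

1. **preprocesses** them (pulse-artifact AR interpolation over −2..12 ms,
   downsampling to 1 kHz, baseline correction over −500..−10 ms, 1 Hz
   highpass with pre-stimulus-safe piecewise filtering, robust bad-channel
   detection, 58–62 Hz bandstop, amplitude-based bad-trial rejection, 200 Hz
   lowpass, common average reference);
2. reduces each average to two **outcome waveforms** — the 5-channel local
   TEP over the stimulated motor cortex and the all-channel global mean
   field amplitude (GMFA) — sliced into early (15–80 ms) and late
   (80–350 ms) windows;
3. computes **stability curves**: Lin's concordance correlation coefficient
   (CCC) between candidate averages (first 10, 15, 20, … pulses, or random
   nested subsets) and the gold-standard all-pulse average, and derives the
   **minimum number of pulses (MNP)** — the smallest count from which the
   CCC stays above 0.8 for every larger count;
4. models MNP against experimental/clinical covariates (hemisphere, day,
   block order, stimulation intensity, medication use, age) with **GEE**
   (identity-link Gaussian, exchangeable working correlation clustered by
   subject, bias-reduced sandwich errors).

Because clinical TMS–EEG recordings are rarely shareable, a first-class
**synthetic-data module** generates 64-channel pediatric-style blocks and
whole cohorts with known ground truth (dominant lateralised N100-like
template, 1/f background, line noise, pulse/muscle/movement artifacts,
covariate-dependent SNR), so every stage is testable offline.

## CLI

```bash
# simulate a cohort of synthetic blocks
tepstab simulate --config examples/cohort.yaml --seed 7 --out runs/cohort

# stability curves + MNP for every block (2 measures x 2 windows)
tepstab stability --in runs/cohort --config examples/cohort.yaml --out runs/stab

# GEE models of MNP against covariates, and summary tables
tepstab stats runs/stab/mnp.csv --out runs/stats
tepstab report runs/stab/mnp.csv --out runs/summary.csv
```

Config files (YAML or JSON) have optional `synthetic`, `cohort`,
`preprocess` and `analysis` sections whose keys mirror the config
dataclasses (`SyntheticConfig`, `CohortConfig`, `PreprocConfig`,
`AnalysisConfig`). A single `--seed` makes the whole run reproducible; every
output CSV/JSON is stamped with the package version and a config hash.

## Library use

```python
from tepstab import (AnalysisConfig, PreprocConfig, SyntheticConfig,
                     BlockMetadata, generate_block, block_stability, mnp)

meta = BlockMetadata("S01", age_years=10, hemisphere="left", day=1,
                     block_order=1, rmt_pct_mso=85, asm_use=False, n_pulses=100)
block = generate_block(SyntheticConfig(seed=1), meta)
curves = block_stability(block, AnalysisConfig(), PreprocConfig(mode="subset_only"))
print({k: mnp(c).mnp for k, c in curves.items()})
```

`PreprocConfig.mode` selects how candidate subsets are handled:
`per_subset` re-runs the full preprocessing chain on each subset (mimicking
an experiment that collected fewer pulses), `subset_only` averages subsets
of the fully preprocessed block (fast; final grid point is exactly
concordant by construction).

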