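# mobint

Tools for two quantitative questions that come up when studying how a
transcription factor engages chromatin:

1. **Where does a tracked molecule live on the compact–open chromatin
   axis?** From single-molecule tracking (SMT) trajectories, `mobint`
   computes per-track time-averaged MSD features — the anomalous exponent
   α, the radius of confinement R_c and the mean frame-to-frame jump —
   classifies each track as Confined (α ≤ 0.7), Brownian (0.7 < α < 1) or
   Directed (α ≥ 1), detects and segments mixed-behaviour ("butterfly")
   tracks, applies the standard quality filters (5-frame minimum duration;
   Confined tracks with mean jump > 100 nm removed), and gates the
   resulting two-parameter (R_c, mean jump) distribution against a histone
   H2B reference to report low- and high-mobility-chromatin (LoMC/HiMC)
   fractions as mean ± s.d. over 20,000-track down-sampled triplicates.
2. **Which proteins does a bait preferentially contact?** From a TurboID
   proximity-labeling protein-group table (MaxQuant style, four groups ×
   four replicates), `mobint` runs the Perseus-style caller: QC and
   valid-value filters, log2 transform, left-censored imputation from
   Normal(mean − 1.8·sd, (0.3·sd)²) per sample column, per-protein
   t-tests of each bait group against both controls with
   Benjamini–Hochberg correction, interactor calls (>2-fold and adjusted
   p < 0.05 against **both** controls), and differential scoring of the
   WT/mutant log2 ratio against a mean ± 3 s.d. cohort cutoff.

A synthetic-data module generates trajectories (confined / Brownian /
directed / butterfly mixtures with localization noise) and proteomics
matrices (planted interactors, intensity-dependent missingness) with known
ground truth, so the whole pipeline is testable without any external data.
Intended users: microscopists and proteomics analysts who have track
tables or protein-group tables in hand and want a reproducible, seeded
implementation of these two analyses.

## Worked example

```python
import numpy as np
from mobint import (ExperimentSpec, simulate_experiment, simulate_h2b_reference,
                    run_classification, ClassifyConfig, calibrate_gates,
                    summarize_mobility)

# 2,000 synthetic tracks: 40% confined, 30% Brownian, 20% directed,
# 10% butterfly, geometric track lengths, 30 nm localization error
tracks, truth = simulate_experiment(ExperimentSpec(n_tracks=2000, seed=7))
result = run_classification(tracks, ClassifyConfig(downsample_n=500, seed=7))
print("stage log:", result.stage_log)
print(result.features["motion_class"].value_counts().to_dict())

# gate against an H2B-like reference and summarize the triplicate
h2b, _ = simulate_h2b_reference(1500, 7)
h2b_result = run_classification(h2b, ClassifyConfig(downsample_n=500, seed=7))
gates = calibrate_gates(h2b_result.features)
print(summarize_mobility(result.replicates, gates).stats.round(4))
```

prints

```
stage log: {'input_tracks': 2000, 'after_duration_filter': 1610, 'butterfly_parents': 180, 'dropped_fit_failures': 0, 'classified_rows': 1746, 'after_confined_jump_filter': 1632, 'replicate_size': 500}
{'Confined': 784, 'Directed': 561, 'Brownian': 287}
        mean     sd  n_replicates
LoMC  0.2427  0.005           3.0
HiMC  0.0427  0.007           3.0
```

Reading it: 390 of 2,000 tracks fail the 5-frame duration filter; 180
tracks contain an outlier jump and are segmented, their segments
re-entering classification (hence 1,746 classified rows); 114 Confined
rows exceed the 100 nm jump ceiling and are removed; each of the three
seeded down-sampled replicates keeps 500 rows. Against the H2B-calibrated
gates, about 24% of this factor's tracks sit in low-mobility (compact)
chromatin and 4% in high-mobility (open) chromatin, with the s.d. taken
across the triplicate.

The same flows are available from the shell:

```sh
mobint simulate-tracks --n-tracks 2000 --seed 7 --out tracks.csv
mobint classify tracks.csv --out-dir out/ --downsample-n 500
mobint simulate-proteomics --n-proteins 1000 --seed 7 --out pg.txt
mobint interactome pg.txt --design design.json --out-dir out/
```

A commented config template is in `examples/config.yaml`; every run writes
a `manifest.json` (config snapshot, seeds, stage-by-stage row counts)
sufficient to reproduce it bit-identically.

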