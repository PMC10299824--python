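# Methods

This note records the models, estimators, default parameters and design
choices behind the two pipelines, and what the synthetic data do and do not
establish about behaviour on real data.

## 1. Single-molecule tracking: two-parameter motion classification

### Input model

A track is the frame-indexed 2D path of one fluorescently labelled molecule
(coordinates in µm), produced upstream by a localization/linking tool and
exported as a delimited table. The default frame interval is 10 ms (100 Hz
stroboscopic imaging). Frames within a track may be non-contiguous (the
linker can bridge short gaps); *duration* counts localizations, not frame
span, because the duration filter is meant to act on the amount of
evidence, and a frame-span variant can be had by filtering on the frame
range externally. Pixel-unit tables are converted on read with a
`coord_scale` factor, because every downstream threshold (100 nm jump
ceiling) is physical.

### TA-MSD and the anomalous exponent

The time-averaged MSD at lag τ (frames) is the mean squared displacement
over **all overlapping pairs** τ frames apart — the standard,
lowest-variance estimator. The anomalous exponent α is the unweighted
least-squares slope of log MSD versus log τ over lags 1–4 (configurable).
The short default window is deliberate: experimental SMT tracks are mostly
tens of frames long, and short lags are the only regime where the pair
counts (duration − τ) keep the estimator usable across the whole track
population. Lags with MSD ≤ 0 are excluded; fewer than two usable lags
flags the fit as failed and the track is dropped downstream.

Two consequences of this estimator are worth keeping in mind:

* **Localization error flattens α.** Noise adds a constant 4σ² to every
  MSD value, so an observed free-diffusion track has
  MSD(τ) = 4DΔtτ + 4σ² and fits α < 1. With the package defaults
  (D = 0.3 µm²/s, σ = 30 nm) the Brownian class centres near α ≈ 0.86,
  comfortably inside the (0.7, 1) band. For a *noise-free* Brownian track
  the fitted α is symmetric about 1.0 (measured mean 0.997, s.d. 0.03 for
  1000-frame tracks), so the α ≥ 1 → Directed boundary necessarily sends
  about half of ideal noise-free Brownian tracks to the Directed class.
  This is a property of the published banding, not of the estimator;
  class-recovery statements below therefore always include realistic
  localization error.
* **The classification bands are hard thresholds**: α ≤ 0.7 Confined,
  0.7 < α < 1 Brownian, α ≥ 1 Directed, boundaries exactly as stated.

### Confinement radius

The radius of confinement Rc is estimated by nonlinear least squares on the
saturating confined-diffusion model

    MSD(τ) = Rc² · (1 − exp(−4 D τ Δt / Rc²)),

with Rc and D free, initialized from the late-lag plateau and the initial
slope. On exact model curves the fit recovers Rc to ≤ 1e-6 relative error;
if it fails to converge the fallback is √(mean MSD over the last quartile
of lags), i.e. the plateau estimate, with a diagnostic flag. An all-zero
curve gives Rc = 0. Note that localization noise inflates the apparent
plateau by 4σ², so apparent radii carry a small positive bias on noisy
data; gates calibrated on equally noisy reference data (below) absorb this.

### Mean jump

The average displacement is the mean Euclidean distance between
localizations in **consecutive** frames only; gapped pairs are excluded
("frame-to-frame" is taken literally). A track with no consecutive pair is
flagged and dropped.

### Butterfly detection and segmentation

Tracks mixing confined and free behaviour are detected by an outlier jump.
The published rule states the threshold as "the average jump among the
track + a jump threshold of 1.5" without units; this package's default
reads it as a relative factor — a step is an outlier when it exceeds
2.5 × the track's mean jump — because that reading is unit-free and robust
to magnification differences. Two alternatives are config-selectable:
`additive_sd` (mean + 1.5 s.d. of jumps) and `absolute` (a fixed length in
µm). None is asserted as the original.

Detected tracks are split at each outlier step; the outlier displacement
belongs to neither segment. Segments re-enter feature extraction and
α classification on their own, carry their parent's id, and segments
shorter than the minimum duration are discarded. Butterfly parents are
excluded from the final two-parameter table — segmentation exists
precisely so the mixed track does not contribute a meaningless averaged
point.

For isotropic Gaussian steps the jump magnitudes are Rayleigh, and
P(jump > 2.5 × mean) ≈ 0.74% per step regardless of scale. The relative
rule therefore fires spuriously on long homogeneous tracks (≈ 98% of
500-frame tracks contain at least one such tail jump). This is benign by
construction: a spurious split of a homogeneous track yields segments of
the same class, which re-enter the table individually. It does mean that
per-track class recovery must be stated per detector: the α classifier is
evaluated on homogeneous tracks, the butterfly detector on switching
tracks (a genuinely switching track is detected with probability ≈ 1 at
these lengths, by the switch jump or any tail jump, and its confined and
directed segments then classify separately).

### Filters, ordering, down-sampling

Stage order: duration filter (≥ 5 frames) → feature extraction → butterfly
detection/segmentation → segment features → α classification →
confined-jump filter (Confined rows, including confined butterfly
segments, with mean jump > 100 nm are removed) → down-sampling. The
published description does not fully fix the order; this order follows the
narrative order of the analysis it implements and is logged stage by stage
(row counts in the run manifest). All filters are idempotent.

Down-sampling draws `reps` (default 3) uniform subsets of
min(20,000, pool) rows without replacement, replicate *i* from an
independent generator seeded `seed + i`, so one master seed reproduces the
triplicate exactly.

### LoMC/HiMC gating

The two-parameter plane is (Rc, mean jump). Gates are axis-aligned
rectangles calibrated on a histone H2B reference table: LoMC is the region
at or below the 75th percentile of **both** H2B marginals, HiMC at or
above the 95th percentile of both. The published figures show gate regions
but never print numeric boundaries, so the percentile construction (and
its 75/95 defaults) is this package's choice: it is deterministic,
parameter-light, anchored to the H2B distribution, and produces disjoint
gates whenever lo < hi. Membership is boundary-inclusive; rows with
missing features are `neither`; in the degenerate all-identical
calibration case LoMC wins the overlap. Gating operates in linear µm space
(the published thresholds are linear); a log-space option would only
change the percentile geometry, not the defaults, and is not needed for
rectangles on marginal percentiles.

Per-replicate gate fractions are summarized as mean ± s.d. (n−1
denominator; a single replicate reports s.d. 0). `compare_conditions`
emits the tidy long table (condition × replicate × gate × fraction) that a
two-way ANOVA with multiple comparisons consumes, plus pairwise mean
differences; the ANOVA itself is deliberately left to standard statistical
software.

## 2. Synthetic trajectory generator

Motion classes (all 2D, Δt = 10 ms, positions then perturbed by iid
Gaussian localization error, default σ = 30 nm per coordinate):

* **brownian** — Gaussian steps, per-axis variance 2DΔt; default
  D = 0.3 µm²/s (chosen so the noise floor places fitted α mid-band,
  ≈ 0.86).
* **confined** — the same walk hard-reflected at a circle of radius Rc
  about the start point; defaults D = 0.05 µm²/s, Rc = 50 nm, giving
  4DΔt/Rc² ≈ 0.8 so the disk is explored within a few frames and α sits
  well below 0.7. Reflection (rather than a harmonic well) matches the
  single-parameter "radius of confinement" semantics; the invariant
  "no point farther than Rc + noise from the start" is exact.
* **directed** — drift v·Δt along a per-track random heading plus
  diffusion; defaults v = 5 µm/s, D = 0.02 µm²/s so the drift term
  dominates the short-lag MSD and α sits well above 1. The drift speed is
  at the high end of intracellular directed transport; it is chosen to
  make the Directed class genuinely separable within a 4-frame fitting
  window, which is what "well-separated mixture" means operationally.
* **butterfly** — confined until a switch frame (default mid-track), then
  directed, continuous at the switch.

Track lengths are geometric (photobleaching-like survival, default mean 20
frames) truncated below at 1; the 5-frame filter is applied downstream so
it can be tested. The H2B reference generator uses 85% confined tracks
(D = 0.03 µm²/s, Rc = 40 nm) plus a 15% mobile fraction.

What the generator does **not** emulate: blinking/gap statistics tied to
photophysics, stage drift, anisotropic or 3D motion, state switching other
than the single confined→directed change, and the detection-dependent
track-length/mobility coupling of real SPT (fast molecules leave the focal
plane sooner). Passing tests therefore demonstrate correctness of the
estimators and rules under the stated generative models, not performance
on any particular microscope's data.

## 3. Proteomics: differential-interactome caller

Pipeline order (fixed): QC filter (contaminant / reverse / only-by-site
rows out) → valid-values filter (keep proteins with 4/4 observed values in
at least one group; the design must have exactly four replicates per
group) → log2 → left-shifted imputation → per-protein t-tests →
interactor calls → differential scoring. Stage row counts are logged.

* **Imputation** is per sample column (the Perseus convention; the
  alternative whole-matrix variant is not offered because the workflow
  being reproduced is the MaxQuant/Perseus one): each missing cell draws
  from Normal(mean − 1.8·sd, (0.3·sd)²) with mean/sd from that column's
  observed values. Observed cells are bit-identical before and after; a
  fixed seed reproduces the matrix. One imputation pass feeds every
  downstream comparison.
* **Tests** are two-sided two-sample Student t-tests (equal variance;
  Welch selectable) of each bait group against each control, with
  Benjamini-Hochberg adjustment across all proteins within one
  comparison. Zero-variance rows get p = 1 when the means agree, else the
  smallest positive float, and are flagged.
* **Calls**: significant ⇔ linear fold change > 2 against **both**
  controls and adjusted p < 0.05 in **both** tests, strict inequalities
  (literal reading of ">" and "cutoff").
* **Differential scoring**: the WT/R35A log2 ratio per protein is compared
  against the cohort mean ± 3 s.d.; the cohort defaults to all quantified
  proteins (the volcano-plot population), with a significant-only option.
  Values strictly outside the band are labelled WT- or R35A-preferential.
  A zero-spread cohort labels nothing.

### Synthetic proteomics

Baselines are log-normal (log2 ~ Normal(25, 2²)), replicate noise 0.3 on
the log2 scale, four groups × four replicates. Missingness is logistic
left-censoring, P(missing | x) = expit((22 − x)/1) on log2 intensity —
the MNAR behaviour the imputation presumes. Flag rows are assigned at
configurable rates.

Planted interactors (effects added on the log2 scale per group) default to
a pinned baseline of log2 = 28 when `planted_baseline_log2` is set, i.e.
abundant, well-detected proteins. This choice matters for recovery
statements: a planted protein whose control-group abundance falls below
the censoring region loses replicates, and imputation re-creates them near
the detection floor — inflating that group's variance far beyond the
nominal replicate s.d. and (correctly, conservatively) suppressing the
call. A stated condition like "8-fold enrichment with within-group s.d.
0.3" is only realized in data when the protein's cells are actually
observed, which the pinned baseline guarantees (per-cell censoring
probability ≈ 2.5 × 10⁻³ at log2 = 28).

## 4. Numerical choices and degenerate inputs

* Percentiles: NumPy's default (linear interpolation).
* Confined-model fit: `scipy.optimize.curve_fit`, positivity bounds,
  plateau/slope initialization, 10,000 function evaluations; failures fall
  back to the plateau estimate with a flag.
* Track tables are written with full float repr, so read∘write is exact.
* Empty inputs (no tracks, header-only files, zero proteins) propagate as
  empty outputs without error; all-flagged or all-censored matrices raise
  only where a statistic becomes undefined (imputation with < 2 observed
  values per column, cohort of < 2 proteins).
* Down-sampling with a pool smaller than the budget returns the whole pool
  per replicate.
* Problem sizes in the test suite and acceptance script (hundreds of
  tracks of 200–1000 frames, 1,000–10,000 proteins) are chosen as the
  smallest sizes at which the Monte-Carlo tolerances of the checks are
  comfortably resolved.

## 5. Known limitations

* α and Rc are per-track point estimates; no per-frame (HMM) state
  segmentation, no jump-distance mixture fitting, no D inference.
* The butterfly rule's published wording is ambiguous; three readings are
  implemented, none asserted as the original (see §1).
* Gate boundaries are a percentile construction, not the original
  (unpublished) figure regions; absolute gate fractions are therefore not
  comparable to the published figures, only contrasts between conditions
  processed with the same gates.
* The caller assumes between-run normalization happened upstream
  (MaxQuant LFQ); no peptide-level modelling, no match-between-runs
  handling.
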