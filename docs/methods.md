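# Methods

This note documents the models, conventions and numerical choices made
in `strokerecovnet`, in the order the pipeline runs.

## Cohorts and the proportional recovery rule

A cohort is a table of patients with baseline (T0) and follow-up (T1)
Fugl-Meyer upper-extremity scores (FMAUE, 0–66) and days since stroke at
both visits.  The PRR baseline predicts the FMAUE gain as
`β (66 − FMAUE_T0) + C` with β = 0.7, C = 0.4.  Recoverers (REC) are
patients with absolute PRR error strictly below 20 points; the strict
inequality matters — a patient with error exactly 19.0 exists in the
subacute table and must count as REC for the published non-recoverer
counts to reproduce.  Error summaries exclude patients at the FMAUE
ceiling at baseline (both cohorts) and, for the subacute cohort, also at
follow-up; ceiling patients are retained for model training throughout.
Medians use midpoint interpolation for even counts; IQR is Q3 − Q1 with
linear-interpolation quantiles.

## Montage, hemisphere swap, epoching

Fifty lateral 10-10 channels form six regions of interest: frontal,
central, occipital per hemisphere (7/11/7 channels each).  Midline and
other channels are read but ignored.  Homologous pairs are derived from
label digit parity (odd = left); the T7/T8/P7/P8 naming variant is
normalized to T3/T4/T5/T6.  For left-hemisphere lesions the homologous
channel signals are exchanged so the right-side labels always carry the
*affected* hemisphere (AH); right-lesion recordings pass unchanged.

Analysis uses the temporally central 180 s of the (assumed artifact-free)
recording, cut into 10-s epochs with overlap 0, 25, 50 or 75%; the epoch
count is `floor((180 − 10)/step) + 1` with `step = 10(1 − overlap)`.
Artifact removal (robust referencing, ICA component rejection) is out of
scope: inputs are taken as cleaned signals.

## Spectral features (141)

Per-epoch PSDs use Welch's method on 2-s Hamming segments without
overlap (5 segments, 0.5 Hz resolution).  Bands: delta 1–4, theta 4–8,
alpha 8–13, beta 13–30, gamma 30–48 Hz.

Numerical conventions:

- *Band integrals* (relative power, DAR, DTABR) are trapezoid integrals
  of the scope-mean PSD over the closed band interval, normalized by the
  1–48 Hz integral.  Adjacent bands share their edge bin, so the five
  band fractions tile [1, 48] and sum to exactly 1.
- *Discrete bin membership* (pdBSI, dirpdBSI) is lower-closed/upper-open
  with 48 Hz closing gamma, so no bin is counted twice in a band sum.
- *IAF* (spectral centroid of alpha) uses the closed interval [8, 13]:
  both edge bins belong to the band, making the centroid of a flat
  spectrum the band midpoint (10.5 Hz).

The symmetry indices sum PSD over the left (L) and right (R) ROI channel
sets per bin: pdBSI is the mean of |L−R|/(L+R), dirpdBSI drops the
absolute value.  Bins with zero total power are dropped (K adjusted);
all-zero bands raise an error rather than producing NaN.  After the
hemisphere swap L is the unaffected side, so dirpdBSI > 0 means
unaffected-hemisphere power excess and stroke-typical affected-side
delta excess shows as negative central dirpdBSI.  Degenerate DAR/DTABR
denominators raise a flagged-epoch error rather than emitting inf, so
the feature table stays finite.

Scopes: relative power uses 5 bands × (average + 9 ROIs + AH/UH) = 60;
DAR average + 9 ROIs + AH/UH = 12; DTABR average + the six *lateral*
ROIs + AH/UH = 9 (the lateralized-ROI reading is what makes the
inventory total 141); pdBSI and dirpdBSI each 6 bands (broadband +
five canonical) × {F, C, O, average} = 24; IAF 12.

## Connectivity features (80)

Each of the six lateral ROIs contributes one signal: the mean of its
member channels (the simplest linear reduction; pooled pairwise
coherency was considered and rejected as it has no per-ROI time series).
Cross-spectra use the same Welch parameters as the PSDs.  Connectivity
is the imaginary part of coherency — insensitive to zero-lag
(volume-conduction-like) coupling — rectified *before* band averaging:
`w_ij = mean over band bins of |Im Coh_ij|`.  Signed averaging can
cancel physiologically distinct lead/lag contributions and graphs need
non-negative weights.

Graphs are sparsified with a proportional threshold: the largest
percentile p (1% steps, linear-interpolation percentile over the 15
off-diagonal weights, ties kept at ≥ threshold) whose graph is
connected.  Since lowering p only adds edges, connectivity is monotone
in p and the scan is implemented as a binary search; the result is
identical to exhaustive enumeration (tested).  A weight pattern with
exact zeros that no threshold can connect falls back to keeping every
positive edge, with a flag.

Metrics follow Brain Connectivity Toolbox conventions: shortest-path
distance 1/w, characteristic path length = mean pairwise distance,
Onnela geometric-mean weighted clustering normalized by the network
maximum weight, local efficiency = mean inverse distance within the
neighbour-induced subgraph.  The small-world ω = L_r/L_w − C_w/C_l uses
10 seeded degree-preserving, connectivity-preserving rewirings for L_r
(weights travel with edges) and a deterministic ring-lattice
rearrangement of the weight multiset for C_l (edge slots ordered by
ring distance receive weights in descending order).  When that lattice
is triangle-free (possible on sparse 6-node graphs) the clustering
ratio is capped at 1 (0 if the graph itself has no triangles) to keep ω
finite.  On 6-node graphs ω is a rough descriptor only: the
lattice/random sign separation familiar from large networks does not
hold at this size, and the package treats ω as one feature among 80,
not as a calibrated small-world test.  The rich-club feature reads the
75th percentile on the node-strength distribution: rich nodes have
strength strictly above it, and each node contributes its count of
edges to rich nodes divided by its own strength.

Nodal metrics are reported for the two motor ROIs: CR (affected central)
and CL (unaffected central).

## Feature selection

Rankings are computed on the epoch rows of the training subjects of the
current fold only.  ReliefF for the continuous target is RReliefF
(Robnik-Šikonja & Kononenko accumulators) with k = 10 neighbours,
Manhattan distance on min-max-scaled features, a full deterministic pass
over instances and uniform neighbour weights.  mRMR uses relevance =
|Pearson r(feature, target)| and redundancy = mean |Pearson r| with the
already-selected set (difference criterion); the first pick is the
relevance argmax and ties break by feature name.  Zero-variance features
rank last with a warning.  The model search considers all 15 non-empty
subsets of the top four ranked features, indexed *positionally* so one
grid point maps consistently onto each fold's own ranking.

## The regression network

Inputs are the selected EEG features plus the fixed clinical triple
(FMAUE_T0, days since stroke, days to follow-up), standardized by
training-set mean/sd.  Architecture grid: hidden layers (8), (16), (32),
(16, 8), (32, 16), (32, 16, 8) with ReLU; MSE loss; Adam at learning
rate 0.01 for exactly 20 passes; batch sizes 64, 128 or full-batch.
Hidden weights are He-initialized from the config seed; the linear
output layer is zero-initialized with its bias set to the training
target mean, so optimization starts at the bias-only solution and spends
the short budget learning deviations.  Targets stay on the raw FMAUE
scale.  Note an inherent property of this fixed budget: full-batch
training performs only 20 Adam updates (step size ≤ ~lr each), which
cannot fit large-scale structure; mini-batch configs converge far
better, and the desk-scale default grid therefore uses batch 64.

A subject's prediction is the exact median of its epoch predictions,
clipped to [0, 66] after aggregation.

## Nested LOSO evaluation

For each outer test subject: an inner leave-one-subject-out loop over
the remaining subjects scores every grid point (overlap × selector ×
feature subset × layers × batch size) by the RMSE of subject-level
(window-median, clipped) predictions on the inner left-out subjects;
subject-level rather than pooled-epoch RMSE because aggregation precedes
scoring in the pipeline's definition of a prediction.  Ceiling subjects
are excluded from outer testing and inner validation but always train.
The RMSE-minimizing grid point (ties broken by canonical grid order:
less overlap, selector name, smaller subset, smaller network, smaller
batch) is re-ranked and retrained on all non-test subjects and produces
the test prediction.  Per-training seeds derive from the run seed and
the fold/grid coordinates, so a fixed run seed reproduces every choice
bit-identically.  Rankings are cached per (overlap, selector,
training-subject-set); the leakage contract — no test epoch ever touches
ranking, standardization or weights of its own fold — is asserted by a
dedicated audit test.

Model-vs-PRR comparison uses the median absolute error with IQR, and a
paired sign-flip permutation test on the per-subject error differences
(median statistic, 10 000 draws, two-sided with +1 smoothing).  Two
caveats discovered during development: constant paired differences are
degenerate for this statistic (the flipped median always has the same
magnitude, p = 1), and at n = 13 the smallest attainable p is 2⁷/2¹³ ≈
0.016; the test is therefore reported alongside the raw error medians,
never alone.  Group contrasts (REC vs NO-REC) use window-level
two-sided Mann–Whitney U tests on the no-overlap feature table with
Bonferroni correction by the number of tested features, plus Cohen's d
from pooled SD.

## Consistency scores

Domain consistency compares two models' per-domain selection frequencies
(domains: spectral, brain symmetry, node connectivity, network; a
domain counts as selected in a fold if ≥ 1 of its features is in the
final model): `1 − Σ w_d |fA_d − fB_d| / Σ w_d`, with weights w_d the
mean domain frequency across the compared datasets.  The Σw divisor is
the simplest normalization meeting the stated [0, 1] bound; other
normalizations exist and cannot be adjudicated without the original
data.  Cluster consistency clusters features by complete linkage on
1 − |Spearman ρ| cut at 0.7 (features merge while |ρ| ≥ 0.3; constant
features become singletons) and takes the Jaccard similarity of the
cluster sets touched by each model's selections.  The reference
clustering is computed on the first-named dataset's feature matrix.

## Synthetic cohorts

The generator emulates exactly the statistical structure the pipeline
assumes, with defaults chosen once for realism:

- per-ROI-pair band oscillators (3 sinusoids at uniform-random in-band
  frequencies) shared between homologous ROIs, amplitudes
  delta/theta/alpha/beta/gamma = 4/3/6/2/1 µV (alpha-dominant resting
  EEG);
- a per-subject latent z ~ N(0,1) scaling the affected hemisphere's
  delta amplitude by exp(0.5 z) — the slow-wave excess over the lesioned
  side that central directional pdBSI detects;
- per-channel 1/f noise (exponent 1.0, sd 1 µV);
- one lagged coupling by default: CR → CL alpha, 6-sample lag, gain 0.8,
  guaranteeing non-zero imaginary coherency for that pair;
- outcomes: ΔFMAUE = PRR(T0) + noise (sd 3 points), minus
  10 points × z under the planted-effect model; T1 clipped to [0, 66];
  baseline scores uniform on [5, 45] so ceiling effects stay rare.

What the generator does *not* emulate: volume conduction and realistic
lead fields, artifacts, non-stationarity, realistic cross-frequency
structure, channel-specific noise topographies.  Passing tests therefore
demonstrate that the pipeline recovers planted effects of the assumed
form and leaks no information — not that these effect sizes are
attainable on clinical recordings.

Problem sizes used by the test-bed experiments: 20 subjects × 180 s for
parameter recovery (5 seeds per outcome model, reduced grid: no overlap,
mRMR, 15 subsets, (8,) hidden, batch 64), which the package treats as
its standard desk-scale configuration; the full 2160-point grid remains
available through `make_grid()`.

A calibration caveat for the null (`prr_only`) condition: per-seed
paired permutation tests are non-significant, but pooling subjects
across seeds (n = 100 pairs) has enough power to detect the model's
real, tiny (~0.5 FMAUE points) variance cost from carrying noise EEG
features relative to the oracle rule.  "Indistinguishable from the PRR"
therefore holds at single-study power, not asymptotically — exactly the
behaviour expected of any data-driven model evaluated against the
generating rule.

## Known limitations

- The published headline model errors on the clinical cohorts cannot be
  reproduced here: the EEG recordings are not publicly deposited.  The
  reproducible benchmarks are the PRR numbers computable from the
  published cohort tables, which the acceptance script recomputes.
- ω on 6-node graphs is descriptive, not inferential (see above).
- RReliefF's neighbour count and the mRMR estimators are fixed,
  reasonable choices; the original work does not specify them.
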