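# Methods

`swayclust` re-implements, as a tested pipeline, an analysis of quiet-standing
postural sway in post-stroke patients: multivariate motion-capture recordings
are standardised, cut into fixed-length data slots, clustered under dynamic
time warping (DTW), the clustering configuration is chosen by three validity
indices, and the clusters are characterised by per-slot sway parameters with
nonparametric post-hoc tests. Because no patient recordings are deposited,
every stage is exercised end-to-end on a synthetic cohort generator that
emulates the study conditions.

## Data model

A recording is a 30-s, 60-Hz trajectory of 11 signal sources — the whole-body
centre of mass (COM) plus ten markers (shoulder, hip, knee, ankle, toe;
left/right) — each with X (medial-lateral), Y (anterior-posterior) and
Z (vertical) displacement: 33 kinematic variables, in millimetres. Subject
metadata carries stroke subtype (cerebral hemorrhage CH / infarction CI),
age, days after onset and hemiplegic side. Files are plain CSV with a YAML
metadata sidecar; an optional TRC reader maps third-party marker names onto
the same contract. The reader rejects missing samples by default and can
linearly interpolate gaps up to a configurable length (default limit 5
samples when enabled); longer gaps are an error.

## Preprocessing

Per recording, in order:

1. **Offset.** The time-averaged midpoint of the two ankle markers is
   subtracted (one constant 3-vector per recording). Subtracting a constant
   rather than the per-sample midpoint preserves ankle sway itself, which the
   downstream feature analysis uses; per-sample subtraction would zero it out.
2. **Height scaling.** Every coordinate is divided by l1+l2+l3, the mean
   shoulder-hip, hip-knee and knee-ankle marker distances (means over time
   and both sides). Output is dimensionless, making the pipeline invariant to
   a global geometric rescaling of the subject (asserted to 1e-12 in tests).
   Segment lengths are computed before the offset; pairwise distances are
   offset-invariant, so the order is immaterial.
3. **Filtering.** A zero-phase (forward-backward) 2nd-order Butterworth
   low-pass at 12 Hz, applied per column via `scipy.signal.sosfiltfilt` with
   its default odd-extension padding. The double pass squares the magnitude
   response and cancels phase lag (cross-correlation peak at lag 0).
4. **Slotting.** The recording is cut into consecutive non-overlapping
   t-second windows (left-aligned, trailing remainder discarded): a 30-s
   recording yields 6 slots at t=5 (300 samples each), 5 at t=6, 3 at t=10.
   Filtering happens before slotting so slot edges carry no extra transient.

## DTW distance

Slots are compared with classic DTW: symmetric step pattern (steps (1,0),
(0,1), (1,1), all weight 1), no warping window by default (an optional
Sakoe-Chiba band is available for speed), no path-length normalisation (all
compared slots have equal length, so normalisation would only rescale).
Two multivariate modes:

- **independent** (default): univariate DTW per kinematic variable, the 33
  distances summed — each variable of one slot is compared with the
  corresponding variable of the other;
- **dependent**: one dynamic program over time with the Euclidean norm
  across all variables as local cost.

The wording of the source procedure is ambiguous between the two readings,
so both are implemented and the whole pipeline runs under either; the
independent reading is the default. On one variable they coincide (tested).
DTW is symmetric and non-negative but not a metric; no triangle inequality
is assumed anywhere. The dynamic program is verified exactly against
brute-force enumeration of all monotone warp paths for short sequences.
Inner loops are numba-compiled; accumulation is double precision; warp-path
traceback prefers the diagonal on ties (affects paths only, never distances).

**DBA averaging.** DTW barycenter averaging aligns every member to the
current average and replaces each average sample by the mean of the samples
aligned to it. Alignment for averaging uses squared local cost, for which
the mean update is the exact minimiser, so the summed squared alignment
cost is non-increasing (asserted) and iteration stops on relative decrease
< 1e-6 or `max_iter`. Initialisation is the medoid member (deterministic),
and the average keeps the init's length. Under independent mode each
variable is averaged along its own univariate alignment; dependent mode
warps all variables along one path — this keeps averaging consistent with
the distance geometry of each mode.

## Clustering

- **DTW-PAM**: k-medoids on the precomputed distance matrix. Random initial
  medoids, then steepest-descent swaps (apply the single most cost-reducing
  medoid/non-medoid exchange until none helps). Verified swap-optimal post
  hoc and against exhaustive medoid-set enumeration on small instances.
- **DTW-DBA**: k-means-style loop with DBA centroid sequences; slots are
  assigned to the nearest centroid by DTW, centroids re-averaged, to an
  assignment fixed point or `max_iter`. A cluster emptied during iteration
  is re-seeded with the slot farthest from its nearest centroid.

Both repeat over random restarts (default 10, matching the protocol's ten
repetitions) keeping the lowest total cost — the sum of each slot's distance
to its own centroid; selection is by cost, not by validity index, and runs
are deterministic given a seed. Labels are 0-based internally; every
rendered table is 1-based.

## Validity indices and grid search

Davies-Bouldin (lower better), Calinski-Harabasz (higher) and Dunn (higher)
are computed **in DTW-distance space**, consistent with the clustering
geometry: "centroids" are the solution's medoids (PAM) or DBA averages, and
squared DTW distances stand in for squared Euclidean distances in the C-H
sums. This is the main under-specification of the source procedure and the
package's declared convention. The C-H global centre is the overall medoid
(PAM) or the DBA average of all slots (DBA). Dunn follows the standard
definition (minimum between-cluster slot distance over maximum cluster
diameter), which matches the "higher is better" selection rule. Degenerate
cases: coincident centroids are an error for DB; zero within-cluster
scatter (C-H) or zero diameter (Dunn) return +inf with a warning.

The grid search covers t in {3, 5, 6, 10} s × K in {3, 4, 5} × method,
computing one distance matrix per t and re-scoring the best-of-restarts
solution per cell. How three indices were combined into one choice is not
stated in the source procedure, so the rule is pluggable: the default lets
each index nominate its best cell (majority vote, C-H breaking ties) and
the full table is always written so a human can decide.

## Sway parameters

Per slot and per variable: **amplitude** = max − min; **SD** = sample
standard deviation (n−1 denominator, a sample statistic over a finite
slot); **sway frequency** = the frequency of the largest magnitude bin of
the FFT spectrum after mean removal, DC excluded (resolution rate/length =
0.2 Hz for 5-s slots). "First most prominent peak" is read as the global
maximum — deterministic and parameter-free; a prominence-based first-peak
variant is available behind a flag. No taper window is applied before the
FFT: the signal is already conditioned by the 12-Hz low-pass and the mean
removal, and a window would bias the amplitude comparison between bins. A
constant series has no frequency and yields NaN, dropped downstream.

## Post-hoc statistics

For each (variable, parameter) family the per-cluster groups are gated:
Tukey-Kramer only if **every** group passes Shapiro-Wilk normality and
Bartlett's homogeneity test at alpha_gate (default 0.05); any failure —
including a constant group, on which Shapiro-Wilk is undefined — takes the
rank-based branch. "Pairwise Wilcoxon" on independent cluster groups is the
rank-sum (Mann-Whitney) form; the C(K,2) p-values of one family are
Benjamini-Hochberg adjusted jointly (no correction across the 33 variables,
matching the per-row reporting of the reproduced procedure), and pairs with
adjusted p < 0.05 are reported. Identical constant groups get p = 1 by
convention. Slots from one recording are treated as independent — a
faithful reproduction of the procedure, not a statistical endorsement; a
mixed-effects treatment of within-subject correlation is out of scope.

The transition table lists, per (subject, session) sorted by onset day,
every slot's cluster label and the majority label (ties break to the lower
cluster index and are flagged). Cluster characteristics report median onset
days, median age and the CH/CI mix per cluster.

## Synthetic cohort generator

Each recording is a static standing pose (built from the subject's segment
lengths, default 500/430/420 mm scaled by a per-subject stature factor in
[0.9, 1.1]) plus sway: per marker channel a sinusoid at the recording's
planted cluster frequency with an **independent random phase per channel**,
scaled by (marker baseline × cluster amplitude multiplier × axis factor),
plus Gaussian noise low-passed at 5 Hz and rescaled to 0.5 mm SD. The COM
is a fixed-weight trunk-heavy average of the ten markers, so height scaling
and COM features are exercised. Defaults (frozen as the study conditions):

- roster: 10 subjects (5 CH, 5 CI) with repeated sessions, 31 recordings of
  30 s at 60 Hz; ages, onset-day schedules and hemiplegic sides follow the
  cohort schema the pipeline targets;
- planted regimes: K=4, frequencies 0.6/0.8/1.2/1.4 Hz — inside the
  0.5–1.5 Hz band reported for post-stroke quiet standing and multiples of
  the 0.2 Hz bin of a 5-s slot, so spectral recovery is exact;
- amplitude multipliers 1/5/9/13 with marker baselines shoulder 14, hip 10,
  knee 3.5, ankle 1.5, toe 1 mm (trunk sways more than the leg);
- optional hemiplegia asymmetry ratio (default 1: no asymmetry is planted).

Two generator design points deserve note. First, within-regime DTW scatter
grows linearly with amplitude (phases differ between recordings and the
unabsorbed alignment residual scales with A), so the multipliers are spaced
by a constant *additive* gap: every adjacent pair of regimes is then
separated by a margin that dominates the scatter of the largest regime,
which is what "well-separated planted clusters" has to mean in this
geometry. Second, phases are independent per channel rather than coherent
per recording: coherent phases would place each regime on a one-dimensional
phase arc whose length scales with amplitude — a degenerate benchmark in
which splitting the largest arc always pays — whereas independent phases
spread within-regime variation over all 30 marker channels, giving
concentrated, roughly isotropic clusters. The cost is realism: genuine body
sway is strongly coherent across segments, and the COM of the synthetic
cohort (an average of incoherent channels) sways less than perfect
coherence would give. Passing recovery tests on this generator therefore
shows the pipeline separates amplitude/frequency regimes under DTW; it does
not show sensitivity to the subtler coordination differences of real
patients, and no claim about patient data follows from it.

`planted_onset_drift` assigns the true regime as a step function of onset
day for CH subjects (≤180 d → cluster 4, ≤420 → 3, ≤900 → 2, else 1,
emulating gradual recovery) and one onset-independent regime per CI
subject, so the transition-table machinery has a known answer.

## Problem sizes and numerical choices

The analysis drivers run the full 31 × 30 s cohort (186 slots at t=5). The
test suite and the acceptance script run recovery at 31 × 15 s (93 slots,
3 per recording) — the package's own choice of a desk-scale problem that
keeps the O(n²) DTW distance matrices (300×300 dynamic programs × 33
variables per pair) tractable while preserving the cohort structure; the
full-scale slotting arithmetic (186 slots) is still checked directly.
Restart counts: PAM always uses the protocol's 10; the DBA grid in the
analysis driver uses 3 restarts with capped iterations as a documented
runtime compromise. Ties throughout break toward the lowest index
(assignment ties, medoid ties, majority-label ties), making every stage
deterministic under a fixed seed. Floating-point comparisons in swap
acceptance use a 1e-12 slack so cost cycling cannot occur.

## Known limitations

- The sway model is a single sinusoid plus filtered noise; real sway is
  broadband, non-stationary and cross-correlated between segments.
- Validity indices in DTW space are a convention, not the only reading of
  the source procedure; mean-based (Euclidean) C-H on raw slots is not
  implemented.
- Slot non-independence within a recording is inherited by the post-hoc
  tests, as in the reproduced procedure.
- DTW-DBA is substantially more expensive than DTW-PAM and is run at
  reduced restarts in the grid driver.
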