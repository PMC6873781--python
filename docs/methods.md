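# Methods

This note documents the models, algorithms and numerical choices behind
`msdyn`, and what its synthetic validation does and does not demonstrate.

## The microstate model

Resting-state EEG topography is modelled as a sequence of quasi-stable scalp
maps: at each sample the (average-referenced) scalp potential vector
`x_t ∈ R^C` is approximated by `x_t ≈ a_t · m_{l_t}`, where `m_k` is one of K
unit-norm template maps, `l_t` a per-sample class label, and `a_t` a signed
amplitude.  Polarity is deliberately uninformative: `m` and `−m` denote the
same microstate, so every comparison between a data sample and a template
uses the absolute (or squared) spatial correlation.  Spatial correlation is
the Pearson correlation across channels; in average-reference space (every
map zero-mean) it reduces to the cosine between the vectors.

Global field power, `GFP(t) = population std over channels of x_t`, measures
instantaneous field strength; for average-referenced data it equals the RMS
across channels.  Clustering uses only samples at strict local GFP maxima,
where topographic signal-to-noise is highest.  Plateaus in the GFP trace
count as a single peak at their first sample (a deterministic tie-break).

## Preprocessing

* Band-pass: zero-phase (forward–backward) Butterworth of order 4 per
  direction, default band 1–40 Hz.  Zero-phase filtering matters here because
  phase shifts would distort the topography/time alignment the segmentation
  relies on.
* Downsampling: polyphase anti-aliased resampling; the default analysis rate
  is 125 Hz, so a 20–100 ms microstate segment spans ~3–12 samples.
* Bad-channel repair: spherical-spline interpolation (order m=4, Legendre
  expansion truncated at degree 7, ridge regularisation 1e-5, zero-sum
  constraint on the spline coefficients).  Good channels are left
  bit-identical.  Validated against a closed-form degree-1 spherical-harmonic
  field (reconstruction error < 5%).
* Average reference is applied last; channel-reduction lists and the analysis
  window (start/stop seconds) are configuration, not code.

## Modified k-means and GEV

The clustering objective is the global explained variance

    GEV = Σ_t GFP_t² · r²(x_t, m_{l_t}) / Σ_t GFP_t²
        = Σ_t (x_t · m_{l_t})² / Σ_t ‖x_t‖²   (average-reference space),

the GFP²-weighted share of topographic variance the templates explain.  The
two-step iteration assigns each map to the template with the largest squared
spatial correlation, then re-estimates each template as the dominant
eigenvector of its members' cross-product matrix `Σ x xᵀ` — the
polarity-proof analogue of the cluster mean (a sign-aligned average would
depend on alignment order).  Because the input maps are zero-mean, the
constant vector is in the null space of the cross-product matrix and the
eigenvector template stays zero-mean automatically.  Empty clusters are
re-seeded from the worst-fit map.  Iteration stops at an assignment fixed
point or when GEV changes by < 1e-8; the best of `n_restarts` seeded random
initialisations (default 100 for production fits, 20 inside the pipeline) is
kept.  Template sign is canonicalised (largest-magnitude channel positive)
purely for reproducibility of output files.

At k=2 and ≤ 8 maps the restarted algorithm attains the optimum found by
exhaustive search over all bipartitions (tested, tolerance 1e-6).

## Choosing the number of classes

No single cluster-validity index is reliable for topographic data, so the
package combines a configurable bank of seven standard criteria, each
adapted to the polarity-invariant geometry (distances are residuals to the
template *line*, `d²(x, m) = ‖x‖² − (x·m)²`, or the chordal correlation
distance `√(1−r²)` where a normalised scale is needed):

| criterion            | vote rule          |
|----------------------|--------------------|
| GEV curve            | maximum curvature (elbow) |
| dispersion W         | maximum curvature (elbow) |
| cross-validation criterion (residual variance × ((C−1)/(C−1−K))²) | minimum |
| Krzanowski–Lai       | maximum |
| Calinski–Harabasz    | maximum |
| Davies–Bouldin       | minimum |
| silhouette (template-based) | maximum |

Each criterion votes for one K; the chosen K is the lower median of the
votes, so ties resolve toward the smaller, more parsimonious model.  On
synthetic cohorts with 4 or 5 planted orthogonal templates at amplitude SNR
10 the vote is unanimous for the planted K.  Real microstate maps are
mutually correlated rather than orthogonal; the generator's
correlated-template stress mode is the honest way to probe that regime, and
unanimity should not be expected there.

## Back-fitting and temporal smoothing

Every continuous sample (not only GFP peaks) is assigned to the global
template with the highest `|r|`; ties break toward the lower class index,
and zero-variance (flat) samples inherit the previous label.  The label
sequence is then regularised by the classic segmentation-smoothing scheme:
sample `t` is relabelled to the class minimising

    GFP_t²(1 − r_{t,k}²) / (2e(C−1)) − λ · N_{b,k}(t),

where `N_{b,k}(t)` counts samples within ±b of `t` currently labelled `k`
and `e` is the current mean residual noise variance.  Defaults are b = 3
samples and λ (the Besag factor) = 10.  Relabelling proceeds in alternating
odd/even half-passes: a fully synchronous sweep can enter two-cycle
oscillations at large λ, whereas half-passes converge in a handful of
iterations and make the run count non-increasing in λ on realistic inputs.
λ = 0 leaves the labelling untouched.

## Temporal parameters

From the maximal constant-label runs of a segmentation:

* occurrence_k = runs of class k per second of analysed data (1/s);
* coverage_k = 100 × samples labelled k / total samples (%);
* duration_k = mean run length of class k in ms.

With boundary-inclusive counting the identity
`occurrence_k × duration_k/1000 = coverage_k/100` holds exactly.  The
default `mixed` mode counts the truncated first/last runs for occurrence and
coverage but excludes them from duration, where they bias dwell estimates
downward; both pure modes are available.  "Duration" is the *mean* dwell —
the convention that makes the identity above hold.  Per-class GEV uses the
winning correlation of the final labels; the total is the sum over classes.

## Statistics

Group comparisons use the Mann-Whitney U test with midrank ties and the
normal approximation (tie-corrected variance, 0.5 continuity correction),
reported as U, Z and two-sided p — the form in which such studies print
their results.  The five class-wise tests of one temporal parameter form one
Benjamini–Hochberg FDR family (m = 5); this family definition exactly
reproduces the published corrected row recomputed in the acceptance tests
from its printed uncorrected row.  BH is the step-up rule
`q_(i) = min_{j≥i} p_(j)·m/j`, capped at 1.  Spearman correlations (Pearson
on midranks, t-approximation p) relate significant microstate parameters to
clinical scores; Levene's test (ANOVA on absolute deviations from group
means) screens variance homogeneity; demographics use the pooled-variance
two-sample t-test (Welch by flag).  Alpha-band power is the Hann-windowed
Welch PSD (2 s windows, 50% overlap) integrated over 8–14 Hz and averaged
across channels, so a pure in-band sinusoid of amplitude a yields ≈ a²/2.

## Synthetic cohorts: what they emulate, and what they do not

The generator plants k_true mutually orthogonal, zero-mean, unit-norm
template maps (a seeded random rotation) and a per-subject first-order
Markov label chain with geometric dwell times (default mean dwell 80 ms at
125 Hz).  On a switch, the destination class is drawn proportionally to
entry weights; patients have the class-0 weight multiplied by
1 + group_effect (default 1.35).  The chain is simulated by a thinning
identity — an i.i.d. categorical sequence with consecutive duplicates
collapsed is exactly the jump chain — which vectorises the whole simulation.
Detailed balance gives the stationary segment frequencies in closed form,
`π_j ∝ w_j(S − w_j)`: a ×1.35 entry boost therefore raises class-0
occurrence and coverage by ≈ 18.4%, an effect the default 17 + 17 design
detects with essentially full power.

The signal is `x_t = m_{l_t} · a_t + noise`, where `a_t` is a 10 Hz sinusoid
(amplitude 15 µV) with fresh random phase and sign at every segment boundary
— so polarity carries no class information and the GFP has the rectified-
oscillation peak structure the clustering step expects — plus spatially
white Gaussian noise scaled to an entry-wise RMS SNR (default 5).  Clinical
scores are truncated normals with group means/SDs shaped like a euthymic
bipolar-vs-control sample (low MADRS/YMRS in both groups, STAI elevated in
patients); they are scaffolding for interface tests, not calibration
targets.

Defaults use 32 channels rather than a high-density montage: the clustering
mathematics is channel-count agnostic, and 204-channel realism runs are one
spec field away.  The generator does **not** model volume-conducted
correlated noise, artifacts (blinks, ECG, muscle), 1/f background spectra,
inter-subject topographic variability, or correlated templates (available as
a stress mode).  Passing recovery tests therefore demonstrates the
correctness of the algorithms under the model's own assumptions — not
field performance on real recordings, where map correlations and artifact
structure make both K selection and back-fitting noisier.

## Problem sizes and reproducibility

The acceptance script runs the full replica at the default study conditions
(34 subjects × 120 s × 32 channels, subject- and global-level K chosen
automatically over 2–8) and estimates detection/false-detection rates over
100 effect and 200 null replicate cohorts at the temporal-statistics level;
the whole run takes a few minutes on one CPU.  Unit and property tests use
smaller cohorts (2–6 subjects per group, 15–30 s) chosen so the suite stays
fast while still exercising every stage.  All randomness flows through
explicit integer seeds (NumPy `default_rng`/`spawn`); a pipeline re-run with
the same configuration produces byte-identical output tables.

## Known limitations

* The seven-criterion bank is this package's documented choice; the
  literature's meta-criterion is not publicly specified, so agreement is
  validated by planted-K recovery rather than by replication of a reference
  implementation.
* Independent-component-based artifact removal is out of scope (a manual,
  visual step); the analysis window is configuration.
* Printed-table reproduction is limited by the precision of published
  inputs: step-up FDR amplifies half-ULP input rounding by up to m/rank,
  which the acceptance tolerance accounts for.
* EDF files are read (via mne) but not written; matrix + YAML sidecar and
  HDF5 are the native interchange formats.
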