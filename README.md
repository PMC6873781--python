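# msdyn — resting-state EEG microstate dynamics

`msdyn` is a Python package for EEG microstate analysis of resting-state
recordings and for two-group comparisons of microstate temporal dynamics.
It is aimed at researchers who want a tested, scriptable replica of the
classic microstate workflow — the kind of analysis used to compare
patient and control cohorts on how long, how often, and how much of the
time each large-scale brain network configuration is expressed.

EEG microstates are short (tens of milliseconds) periods during which the
scalp potential topography stays quasi-stable before switching to another
configuration.  The pipeline:

1. **Preprocess** — band-pass filter (1–40 Hz), downsample (125 Hz),
   spherical-spline repair of bad channels, average reference.
2. **Cluster** — at the local maxima of the global field power
   (GFP(t) = spatial SD across electrodes), run a polarity-invariant
   modified k-means: maps are assigned by squared spatial correlation
   (`m` and `−m` are the same state) and templates re-estimated as the
   dominant eigenvector of the assigned maps.  The number of classes K is
   chosen by a median vote over seven cluster-validity criteria, and
   clustering proceeds subject → group → global.
3. **Back-fit** — label every continuous sample with the global template of
   highest |spatial correlation|, then smooth the labels (window half-size
   b = 3, Besag factor λ = 10) so low-GFP noise does not fragment segments.
4. **Quantify** — per class: occurrence (segments/s), coverage (% of
   analysed time), mean duration (ms), and the GFP²-weighted global
   explained variance

   GEV = Σ_t GFP²(t) · r²(x_t, m_label(t)) / Σ_t GFP²(t).

5. **Compare** — Mann-Whitney U (tie- and continuity-corrected Z) per class
   and parameter, Benjamini–Hochberg FDR within each five-class family,
   Spearman correlations with clinical scores, Levene variance checks, and
   Hanning/Welch alpha-band (8–14 Hz) power.

A synthetic two-group cohort generator with planted templates, Markov label
dynamics and a configurable patient effect makes the entire pipeline
testable end to end without any data download; see `docs/methods.md` for
the model, its assumptions, and its limits.

## Worked example

Simulate a small cohort (8 patients + 8 controls, 60 s at 125 Hz, 32
channels, five planted maps, +35 % entry-rate boost of one class in
patients), derive subject and global models, back-fit, and compare groups:

```python
import numpy as np, pandas as pd
from msdyn import (SyntheticSpec, simulate_cohort, compute_gfp, detect_gfp_peaks,
                   modified_kmeans, multilevel_clustering, backfit_labels,
                   smooth_labels, temporal_parameters, compare_groups)

cohort = simulate_cohort(SyntheticSpec(n_per_group=8, duration=60.0, seed=0))

rng = np.random.default_rng(17)
models = []
for rec in cohort.recordings:
    peaks = detect_gfp_peaks(compute_gfp(rec))
    maps = rec.data[:, peaks.peak_indices].T
    models.append(modified_kmeans(maps, 5, n_restarts=20, seed=rng.integers(2**31)))

global_model = multilevel_clustering(models, 5, seed=1, level="global")
recovery = np.abs(global_model.maps @ cohort.ground_truth.templates.T)
print(f"recovery |r|: {recovery.max(axis=0).round(3)}")

rows = []
for rec, (_, meta) in zip(cohort.recordings, cohort.clinical.iterrows()):
    seg = smooth_labels(backfit_labels(rec, global_model))
    ts = temporal_parameters(seg)
    rows += [dict(subject=meta.subject, group=meta.group, **{"class": c},
                  occurrence=ts.occurrence[c], coverage=ts.coverage[c],
                  duration=ts.duration[c]) for c in range(5)]
report = compare_groups(pd.DataFrame(rows))
occ = report[report.parameter == "occurrence"]
print(occ[["class", "mean_patient", "mean_control", "Z", "p", "p_fdr"]]
      .round(3).to_string(index=False))
```

Output:

```
recovery |r|: [1. 1. 1. 1. 1.]
 class  mean_patient  mean_control      Z     p  p_fdr
     0         1.756         1.769 -0.421 0.674  0.674
     1         1.679         1.702 -0.632 0.528  0.660
     2         1.629         1.683 -0.907 0.364  0.607
     3         1.581         1.731 -1.842 0.065  0.164
     4         2.017         1.712  2.629 0.009  0.043
```

All five planted template maps are recovered exactly (|spatial correlation|
= 1.0 at this SNR).  Fitted class 4 is the one carrying the planted patient
effect: patients produce 2.02 segments/s of it versus 1.71 in controls
(Mann-Whitney Z = 2.63), and the difference survives FDR correction within
the five-test occurrence family (p_FDR = 0.043); the other classes do not
differ.

The same analysis is available from the shell: `msd simulate`,
`msd preprocess`, `msd cluster`, `msd fit`, and `msd run --config study.yaml`
for the whole pipeline from one YAML file (with a provenance JSON and
byte-identical re-runs under fixed seeds).

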