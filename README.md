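# ktops — spike sorting with derivative-based features and phase-space overlap decomposition

`ktops` is a single-channel extracellular spike sorter for neurophysiologists
who need both the single-unit spikes **and** the overlapping waveforms of a
multi-unit recording assigned to their source neurons.  It implements a
two-stage pipeline:

1. **SPDF feature extraction.**  The recording is band-pass filtered and the
   spike *first derivative* (FD) drives detection with an adaptive threshold

   `Thr = ± q · median(|V̇(t)|) / 0.6745,  q ∈ [3, 5]`

   Each aligned event is summarized by six fiducial points P₁…P₆ (the FD
   zero-crossings and extrema around the spike) and a 24-dimensional feature
   vector: 11 *shape* features (durations, amplitudes, slopes and slope
   ratios between fiducials, e.g. F₁ = t_P₅ − t_P₁, F₂ = a_FD(P₄) −
   a_FD(P₂)), 8 *phase* features (FD/SD amplitudes at the fiducials, the
   coordinates of the trajectory in the FD-vs-SD phase plane) and 5
   *distribution* features (interquartile ranges, kurtosis and skewness of
   the FD/SD amplitude samples).

2. **K-TOPS clustering.**  K-means is swept over four assignment distances
   (sqEuclidean, Cityblock, Cosine, Correlation) and K = 2…min(10, ⌊√s⌋);
   every partition is scored by Silhouette (S), Davies–Bouldin (DB) and Dunn
   (D) under seven pairwise metrics, and the scores are fused into a
   cohesion–dispersion index

   `CD = w_s·p_S + w_DB·p_DB + w_D·p_D`

   with min–max normalized probabilities (1 at the optimum of each index).
   The CD-maximizing cell fixes the clustering; cluster means define the
   single-unit templates.  Waveforms that cannot be a single spike (several
   commensurate *fundamental minima* — troughs with V̇ = 0, V̈ > 0 — grouped
   detections, or anomalous amplitude) are decomposed by **template
   optimization in phase space**: artificial overlaps are synthesized as
   sums of templates over a grid of sub-2-ms shifts, and the Pearson-best
   artificial waveform assigns each constituent to its cluster.

Sorting quality is scored by the clustering-error index and the Error Index

`CE = sqrt((Σᵢ(dᵢ−δᵢ)² + Σₖ rₖ²) / (Σdᵢ + Σrₖ)),   EI = CE·sqrt(w_S + m_S)`

where dᵢ/rₖ are the diagonal/off-diagonal counts of the observed
classification matrix, δᵢ the true per-unit counts, and w_S, m_S the
well-/mis-classified totals.

The package also ships a ground-truth simulator that reproduces the standard
validation protocol: three spike templates (two triphasic with comparable
trough amplitudes, one biphasic) fired ~15 spikes/s each for 180 s at
44 kHz over band-limited noise — 2700 instances per template plus 45
two-template and 36 three-template overlaps with peak delays below 2 ms, at
3.55 dB SNR.

## Worked example

```bash
ktops simulate --seed 1 --out data/
ktops sort data/recording.f32 --seed 101 --out sorted/
ktops evaluate sorted/ data/truth.csv --out score.json
```

prints (seed 1):

```
wrote 4 files to data/ (8181 ground-truth events)
8375 events, 3 single-unit clusters -> sorted/
EI=5.196 CE=0.0575 well=8176 mis=4 unclassified=1
```

The simulator injected 8181 ground-truth events (8100 single-unit spikes
plus 81 overlaps).  The sorter kept 8375 detections after satellite pruning, selected
K = 3 clusters via the CD-index, and after overlap decomposition 8176 of
the 8181 true events were credited to the correct unit — 4 were assigned to
a wrong cluster and 1 was missed, giving a clustering error CE = 0.0575
and an Error Index of 5.2 events.  `sorted/` contains the event table,
feature matrix, cluster labels, per-cluster templates, the CD selection
report and the overlap-decomposition report.

The same run from Python:

```python
from ktops import PipelineConfig, Recording, sort_recording, evaluate_sort
from ktops.simulate import simulate

cfg = PipelineConfig()
cfg.sim.seed, cfg.seed = 1, 101
ds = simulate(cfg.sim)
result = sort_recording(Recording(ds.trace, ds.fs), cfg)
score, matrix = evaluate_sort(result, ds.truth, cfg)
print(score.ei, score.well, score.n_events)
```

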