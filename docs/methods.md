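# Methods

## Signal model and preprocessing

The input is a single-channel extracellular voltage trace V(t) sampled at
25–44 kHz.  All analysis happens on the band-pass-filtered trace and its
discrete derivatives: a zero-phase FIR band-pass (Hamming-windowed sinc,
≈ 4·fs/f_low taps, applied forward–backward) isolates the spike band —
450–2050 Hz for typical 25 kHz cortical recordings, 450–2600 Hz for the
44 kHz synthetic benchmark — and removes field-potential fluctuations.  The
first derivative (FD) and second derivative (SD) are central differences in
per-sample units (one-sided at the trace ends); every downstream feature is
internally consistent under this convention, so no conversion to mV/ms is
applied.

Detection operates on the FD.  The threshold is `Thr = q·median(|FD|)/0.6745`
(the median absolute value over 0.6745 estimates the noise standard
deviation robustly, because spikes occupy a small fraction of samples);
`q = 4` by default, the middle of the conventional 3–5 range.  Negative
threshold excursions are detected (configurable), excursions closer than
the 0.5 ms dead time are merged keeping the deeper one, and each detection
is re-centered on the deepest FD sample within ±0.7 ms.  The re-centering
radius is deliberately wider than the dead time: a wide triphasic spike
produces a secondary FD excursion while its after-potential decays
(~0.5–0.7 ms after the main descent) which must collapse onto the main
minimum rather than spawn a duplicate event.  Events are windowed 0.6 ms
before to 1.6 ms after the FD minimum, covering the 0.4–2.2 ms range of
physiological spike durations.

Two further guards clean the detection list.  An *artifact test* rejects
events whose FD peak-to-valley amplitude deviates from the population mean
by |z| > 3.29 (two-sided P < 0.001 under normality); in the pipeline these
are not discarded but routed to the overlap/outlier pool, since in the
synthetic benchmark the only amplitude-anomalous waveforms are
superpositions.  A *support test* removes detections that do not descend
into a voltage trough commensurate with the deepest trough nearby (at
least 30 % of its depth, within ±0.45 ms): when the noise floor is low the
adaptive threshold drops and intra-spike FD structure (after-potential
decay, filter side-lobes) crosses it, producing satellite detections that
are not events.

## Feature extraction

Six fiducial points anchor the features: P2 is the aligned FD minimum, P1
and P3 the nearest FD sign changes before/after it, P4 the FD maximum after
P3, P5 the next sign change, P6 the trailing FD minimum.  Zero crossings
are located with linear interpolation (the stored index is the sample at or
before the crossing; the stored time is interpolated).  Biphasic spikes may
lack a trailing valley; the fall-backs (window edge / remaining-window
extremum) are used and the event flagged.

The 24 features per event:

* F1–F11 (shape): duration t_P5 − t_P1; peak-to-valley a_P4 − a_P2 and
  valley-to-valley a_P6 − a_P2 amplitudes; Pearson correlation with a
  reference waveform (the epoch-mean FD by default); log10 slope magnitudes
  of the positive deflection and the valley-to-valley line (the raw slopes
  can be negative, so the logarithm is taken of the magnitude); the
  negative deflection slope; the RMS of the pre-P1 samples; the negative
  and positive slope ratios; the P2/P4 amplitude ratio.  Ratios with a zero
  denominator yield 0 and a flag.
* F12–F19 (phase): FD amplitudes at P1, P3, P4, P5, P6 and SD amplitudes
  at P1, P3, P5 — coordinates of the trajectory in the (FD, SD) plane.
* F20–F24 (distribution): interquartile ranges of the FD and SD samples
  over the whole window, raw (non-excess) kurtosis of the FD, and
  population skewness of FD and SD.

Durations are in ms, amplitudes in per-sample units, ratios and moments
dimensionless; every feature column is z-scored before clustering (the
mixed units would otherwise let large-unit features dominate the distance
computations).  A multicollinearity check reports pairwise correlations and
flags pairs outside [−0.25, 0.25] with P < 0.05; the weighted
dimensionality criterion `(ΣW/N_f)·(N_e/(N_e+N_f)) < C` supports dropping
low-weight features for multi-electrode settings (never below 3 features).

A per-feature weight function W(f) ∈ [0, 1] expresses how much each
feature contributes to the separation.  The default estimator is the Fisher
score (between-/within-cluster variance ratio, normalized to 1 at the
maximum) computed from a provisional clustering; see below for how the
pipeline uses it.

## Clustering and model selection

K-means (k-means++ initialization, 10 replicates, ≤ 100 iterations, empty
clusters re-seeded from the farthest point) is run for each of four
assignment distances — sqEuclidean (mean update), Cityblock (median
update), Cosine and Correlation (normalized-mean updates) — and each K from
2 to min(k_max, ⌊√s⌋); k_max defaults to 10.  Every partition is scored by
Silhouette, Davies–Bouldin and Dunn under seven pairwise metrics
(sqEuclidean, Euclidean, Cityblock, Cosine, Correlation, Hamming, Jaccard).
Hamming and Jaccard are set-type measures (coordinates "differ" iff their
values are not exactly equal; Jaccard normalizes over coordinates where at
least one vector is nonzero): on continuous features nearly every
coordinate differs, so their pairwise distances — and hence their validity
indices — are essentially constant, and they participate neutrally in the
selection.  This is the faithful behaviour of set-type measures on
real-valued vectors; mapping them onto the sign pattern of the features
instead was tried and rejected, because the induced binary geometry is
effectively two-clustered and systematically biased the selection toward
K = 2.  For tractability the
indices are evaluated on a random subsample of 1500 events (the K-means fit
itself always uses every event); with three well-separated clusters of
thousands of events the subsampled indices are stable to far better than
the margins that separate candidate cells.

The CD-index fuses the three indices per cell:
`CD = w_s·p_S + w_DB·p_DB + w_D·p_D` with equal weights by default, where
each p is the min–max normalized index (1 at the Silhouette/Dunn maximum
and at the Davies–Bouldin minimum).  The normalization domain is
*per-metric* by default: raw index values are only commensurate among cells
that share a validation metric — Dunn values under different metrics can
differ by an order of magnitude, and a global min–max would hand the
selection to whichever metric happens to produce extreme values rather
than to the best partition ("global" and
"per-combo" domains remain available).  The winning clustering is the
partition whose CD averaged over the validation metrics is largest — a
genuinely good partition scores well under most metrics, whereas a single
cell can top the table through one metric's quirks (single-cell argmax
remains available as ``selection="cell"``); the reported (distance,
metric, K) cell is the best cell of that partition.  Ties break toward
smaller K, then lexicographically.

After selection, the pipeline applies the weight function: Fisher scores
are computed from the selected labels, the standardized features are
multiplied by W(f), all four assignment distances are re-fit at the
selected K on the weighted features, and the CD-preferred re-fit becomes
the final partition.  K itself is *not* re-selected on weighted features —
the weights derive from the selected clustering, and re-running the model
selection on a space stretched toward that clustering's separations is
circular (empirically it collapses structure into fewer clusters).  The
weighting step matters: uninformative feature columns otherwise dilute the
between-cluster separation and cost roughly two percentage points of
assignment accuracy on the benchmark.  Estimating the weights *before*
selection from a provisional fixed-K clustering was also tried and
rejected: it stabilizes the choice of K only for some template ensembles
and degrades assignment accuracy.

Cluster-mean FD/SD waveforms define the single-unit templates.  Clusters
that are too small (below max(2, 2 % of events)) or whose template never
crosses the detection threshold are flagged as outlier clusters and their
events join the overlap pool.  Finally, members that correlate poorly with
their own template or have anomalous amplitude (robust within-cluster
z-score beyond 3.29) are also rerouted to the pool and the templates are
rebuilt from the cleaned clusters — these members are either overlaps that
slipped through or events K-means placed across a boundary, and both are
better handled by template matching than left in place.

## Overlap decomposition (TOPS)

A waveform reaches the overlap pool by one of four routes: grouped
detections closer than 2.2 ms; two or more commensurate supra-threshold
*fundamental minima* (time-domain troughs with FD = 0 crossing upward and
SD > 0, descending through the FD threshold, deeper than 30 % of the
window's deepest trough); the amplitude-anomaly (artifact) test; or
within-cluster atypicality.  Each candidate is analyzed in a wide ±3.2 ms
window.

Artificial overlaps are synthesized as point-by-point sums of the
single-unit templates over a shift grid of every 2 samples across ±2 ms
(plus a 0.25 ms margin, because the 2 ms delay bound applies to the
voltage troughs while template windows are FD-minimum-aligned), pairs and
triples with pairwise delays within the bound.  Every waveform is embedded
in a canonical window anchored at each constituent trough in turn — noise
can make any constituent's trough the deepest, and the real window is
anchored at its deepest FD minimum — and z-scored so that matching a real
window against the whole bank is a single matrix product of Pearson
correlations.

Assignment logic per candidate:

* **One fundamental minimum.**  The waveform is an ordinary single spike
  (best single-template match, assigned if r ≥ 0.5) unless a pair explains
  it far better (pair correlation exceeding the best single template's by
  ≥ 0.10 — merged troughs hide the second minimum at delays below
  ~0.3 ms), or its amplitude exceeds 1.3× the best-matching template's
  (quasi-simultaneous firing: one spike is credited to every single-unit
  cluster, the classical rule for superpositions with a single merged
  trough).
* **Several minima.**  Single, best pair and best triple compete; a richer
  composition must beat the simpler one by a margin (0.05 for pair over
  single, 0.01 for triple over pair; triples are searched only when no
  pair reaches r = 0.95).  Constituents contributing less than 10 % of the
  template energy stay unassigned; a best match below r = 0.5 leaves the
  event unclassified (or falls back to the quasi-simultaneous rule when
  the amplitude is anomalous).

Each assigned constituent is timestamped at its trough position inside the
matched artificial waveform.  Trajectory comparisons in the (FD, SD) phase
plane are available through the normal-deviation distance |n(θ)|: both
trajectories are normalized per axis by their joint extent, the template
centroid is the phase origin, and for each angular bin the minimal
point-to-trajectory distance is averaged, symmetrized over both directions
(a large template loop is otherwise close to any point cloud).  Segment
extraction around each minimum expands until the normalized trajectory
quasi-closes (endpoint gap below 5 % of the trajectory diameter) or the
midpoint to the adjacent minimum is reached.

On noise-free superpositions of the benchmark templates at grid shifts the
decomposition recovers the exact composition with r ≈ 1 (the only misses
are triples whose three troughs merge within ~0.6 ms, which are genuinely
ambiguous and fall under the quasi-simultaneous rule).

## Scoring

Against ground truth, detected assignments are matched to true constituents
by nearest time within 0.5 ms and clusters are matched to units by optimal
one-to-one assignment (Hungarian algorithm) on the single-unit contingency
table.  A single-unit event is well-classified if its matched cluster maps
to its unit; an overlap only if *every* constituent is credited to its true
cluster (partial recovery counts as misclassified, none as unclassified).
Each event contributes one count; an overlap's truth class is its first
constituent, so w_S + m_S + u_S = N_S holds exactly.  CE follows the counts
form above; EI = CE·√(w_S + m_S).  Without ground truth the correlation
form of CE is available: mean own-template correlations are compared to an
expected value Δ (default 0.95) and cross-template correlations to zero;
events then count as well-classified when r(event, own template) ≥ Δ and
misclassified when some other template correlates better.

## Synthetic benchmark generator

The generator emulates the standard three-unit validation protocol: 180 s
at 44 kHz, 2700 instances per template (≈ 15 spikes/s per unit), 45
two-template and 36 three-template overlaps with pairwise trough delays
uniform below 2 ms, all placements uniform at random with ≥ 2.5 ms
separation between events (plus the maximal overlap delay for overlap
slots) and a 10 ms edge margin.  Templates are parametric sums of Gaussian
lobes chosen to be morphologically distinct while satisfying the protocol's
constraints — T1 a fast narrow triphasic (trough 1.0 mV), T2 a wide slow
triphasic with a large after-potential (0.92 mV, comparable to T1), T3 a
positive-leading biphasic (0.85 mV); durations 0.4–2.2 ms; pairwise
correlation < 0.95 enforced at build time.  The amplitudes put every
template's FD clearly above the q = 4 threshold at the benchmark noise
level, matching the protocol's premise that no spikes go undetected.

Noise is Gaussian, band-limited to the analysis band (450–2600 Hz), unit
variance before scaling.  **SNR definition:** the ratio, in dB, of the mean
power of the injected spike component over the whole trace to the noise
variance; the noise is scaled so this equals 3.55 dB.  This trace-level
(duty-cycle-weighted) definition reproduces the noise regime of the
classical simulated datasets this protocol descends from (noise standard
deviation near 10 % of the spike amplitude); defining SNR over the spike
support alone would, at 3.55 dB, bury the spikes at ~3.5 standard
deviations of noise and contradict the protocol's premise of complete
detectability.  The definition is printed into every dataset's config
snapshot.  The generator is a pure function of (config, seed): identical
inputs give bit-identical datasets.

What the generator does *not* emulate: electrode drift, bursting-induced
amplitude adaptation, spatially correlated or biologically colored noise
(distant-spike background), and firing-rate structure (placements are
uniform, not Poisson or refractory-modulated beyond the separation
constraint).  Passing the benchmark therefore demonstrates the machinery on
stationary, well-separated units with Gaussian background — not robustness
to drift or to realistically colored noise.

## Problem sizes and numerical choices

The test suite exercises the full five-dataset benchmark (5 × 180 s,
≈ 8400 detections each) plus short 12 s configurations for the faster
end-to-end checks; one full dataset sorts in about a minute on one CPU.
Degenerate inputs are handled explicitly: all-identical feature rows and
fewer than 4 events raise errors; constant validity indices across a
normalization domain give p = 0.5 with a warning; singleton clusters
contribute silhouette 0; zero-variance windows zero their moment features
with a flag; zero-denominator feature ratios yield 0 with a flag.  All
randomness flows from explicit integer seeds through
`numpy.random.default_rng`.

## Known limitations

* Single channel only; no tetrode/array handling and no drift tracking.
* The overlap machinery assumes at most three units contribute to one
  waveform, mirroring the benchmark protocol.
* The 450–2600 Hz band is a configuration input; the kernel-based
  automatic band-selection idea is not implemented.
* Overlaps whose constituents all merge within ~0.3 ms are resolved by the
  quasi-simultaneous rule, which credits every cluster — correct for the
  benchmark's composition statistics but deliberately liberal (it can
  credit a unit that did not fire).
* At very low SNR (spike FD peaks within ~2 noise standard deviations of
  the threshold) detection completeness degrades before clustering does;
  the adaptive threshold cannot recover spikes that never cross it.
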