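"""End-to-end sorting pipeline: preprocess -> features -> clustering -> TOPS.

The pipeline stages are pure functions of (recording, config, seed); a
rerun with the same inputs reproduces the identical output.  Detected
events are first partitioned into single-spike candidates and overlap
candidates (detections closer than the grouping gap, events with several
supra-threshold fundamental minima, and amplitude-anomalous events caught
by the artifact test); K-means with CD-index selection sorts the singles
and defines the cluster templates, and TOPS decomposes the overlap pool
against those templates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .clustering import (CDCell, ClusteringResult, ClusterTemplate,
                         build_templates_and_flag_outliers, kmeans_fit,
                         kmeans_sweep, score_sweep)
from .config import PipelineConfig
from .features import (FeatureMatrix, extract_features, fisher_weights,
                       standardize)
from .preprocess import (DerivedRecording, MAD_SCALE, Recording, SpikeEvent,
                         ThresholdConfig, bandpass_filter, detect_and_align,
                         estimate_threshold, reject_artifacts)
from .tops import (OverlapAssignment, OverlapCandidate, assign_overlaps,
                   make_candidate)
from .validation import (Assignment, ClassificationMatrix, SortingScore,
                         match_clusters_to_truth, score_report)
from .simulate import GroundTruthEvent

log = logging.getLogger("ktops")


@dataclass
class SortResult:
    events: list[SpikeEvent]
    single_ids: list[int]
    feature_event_ids: list[int]
    labels: np.ndarray                    # cluster label per single event
    features: FeatureMatrix
    templates: list[ClusterTemplate]
    cells: list[CDCell]
    best_cell: CDCell
    clustering: ClusteringResult
    candidates: list[OverlapCandidate]
    overlap_assignments: list[OverlapAssignment]
    assignments: list[Assignment]
    thr_fd: float
    thr_v: float
    der: DerivedRecording = field(repr=False, default=None)


def _supra_minima_positions(der: DerivedRecording, thr_v: float
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Sample indices and depths of supra-threshold waveform minima over
    the whole trace (FD upward zero crossing, SD > 0, trough below
    -thr_v)."""
    fd, sd, v = der.fd, der.sd, der.filtered
    neg = fd < 0
    cross = neg[:-1] & ~neg[1:] & (sd[:-1] > 0)
    idx = np.flatnonzero(cross)
    deeper = np.where(v[idx + 1] < v[idx], idx + 1, idx)
    keep = v[deeper] < -thr_v
    return deeper[keep], v[deeper[keep]]


def _atypical_members(singles: list[SpikeEvent], labels: np.ndarray,
                      templates, z_max: float) -> np.ndarray:
    """Robust within-cluster outlier flags on own-template correlation and
    FD peak-to-valley amplitude."""
    flags = np.zeros(len(singles), dtype=bool)
    fds = np.array([ev.window_fd for ev in singles])
    p2v = fds.max(axis=1) - fds.min(axis=1)
    fz = (fds - fds.mean(axis=1, keepdims=True))
    fz /= np.where(fz.std(axis=1, keepdims=True) == 0, 1.0,
                   fz.std(axis=1, keepdims=True))
    for t in templates:
        if t.is_outlier:
            continue
        mask = labels == t.cluster_id
        if mask.sum() < 10:
            continue
        tz = t.template_fd - t.template_fd.mean()
        sd = tz.std()
        if sd == 0:
            continue
        tz /= sd
        r = fz[mask] @ tz / tz.size
        idx = np.flatnonzero(mask)
        for vals, two_sided in ((r, False), (p2v[mask], True)):
            med = np.median(vals)
            mad = np.median(np.abs(vals - med)) * 1.4826
            if mad == 0:
                continue
            z = (vals - med) / mad
            # correlation: only a poor fit is suspect; amplitude: both ways
            bad = np.abs(z) > z_max if two_sided else z < -z_max
            flags[idx[bad]] = True
    return flags


def sort_recording(rec: Recording, cfg: PipelineConfig) -> SortResult:
    """Run the full sorting pipeline on one recording."""
    cfg.validate()
    pp = cfg.preprocess
    der = bandpass_filter(rec, pp.band)
    tc = ThresholdConfig(q=pp.q, sign=pp.sign, dead_time_ms=pp.dead_time_ms)
    thr_fd = estimate_threshold(der.fd, tc)
    thr_v = pp.q * float(np.median(np.abs(der.filtered))) / MAD_SCALE
    events = detect_and_align(der, tc, pre_ms=pp.pre_ms, post_ms=pp.post_ms,
                              thr=thr_fd)
    log.info("detected %d events (thr_fd=%.4g)", len(events), thr_fd)
    if not events:
        empty = FeatureMatrix(values=np.zeros((0, 24)), weights=np.ones(24))
        return SortResult(events=[], single_ids=[], feature_event_ids=[],
                          labels=np.zeros(0, int),
                          features=empty, templates=[], cells=[],
                          best_cell=None, clustering=None, candidates=[],
                          overlap_assignments=[], assignments=[],
                          thr_fd=thr_fd, thr_v=thr_v, der=der)

    fs = rec.fs
    gap = int(round(cfg.tops.group_gap_ms * 1e-3 * fs))

    # 0. satellite pruning: every genuine spike (or overlap constituent)
    # descends into a voltage trough commensurate with the deepest trough
    # nearby; FD excursions without such support are residual intra-spike
    # structure (after-potential decay, filter side-lobes) or bare noise
    minima_pos, minima_depth = _supra_minima_positions(der, thr_v)
    pk = np.array([ev.peak_index for ev in events])
    half = int(round((cfg.tops.group_gap_ms - 0.1) * 1e-3 * fs))
    support = int(round(0.45e-3 * fs))
    keep = np.ones(len(events), dtype=bool)
    for i in range(len(events)):
        lo = np.searchsorted(minima_pos, pk[i] - half)
        hi = np.searchsorted(minima_pos, pk[i] + half)
        local_pos = minima_pos[lo:hi]
        local_depth = minima_depth[lo:hi]
        if local_pos.size == 0:
            keep[i] = False
            continue
        commensurate = local_depth <= cfg.tops.min_rel_depth * \
            local_depth.min()
        keep[i] = bool(np.any(
            np.abs(local_pos[commensurate] - pk[i]) <= support))
    n_sat = int((~keep).sum())
    if n_sat:
        log.info("pruned %d unsupported detections", n_sat)
    events = [ev for ev, k in zip(events, keep) if k]
    peaks = np.array([ev.peak_index for ev in events])

    # 1. group detections closer than the grouping gap -> overlap candidates
    groups: list[list[int]] = [[0]]
    for i in range(1, len(events)):
        if peaks[i] - peaks[groups[-1][-1]] < gap:
            groups[-1].append(i)
        else:
            groups.append([i])
    candidates: list[OverlapCandidate] = []
    single_ids: list[int] = []
    for g in groups:
        if len(g) > 1:
            candidates.append(make_candidate(
                der, [int(peaks[i]) for i in g], cfg.tops, "group",
                event_ids=g))
        else:
            single_ids.append(g[0])

    # 2. singles with several supra-threshold minima nearby -> candidates;
    # a second minimum counts only if commensurate with the deepest one
    kept: list[int] = []
    for i in single_ids:
        lo = np.searchsorted(minima_pos, peaks[i] - half)
        hi = np.searchsorted(minima_pos, peaks[i] + half)
        local = minima_depth[lo:hi]
        n_local = 0 if local.size == 0 else int(
            (local <= cfg.tops.min_rel_depth * local.min()).sum())
        if n_local >= 2:
            candidates.append(make_candidate(der, [int(peaks[i])], cfg.tops,
                                             "minima", event_ids=[i]))
        else:
            kept.append(i)
    single_ids = kept

    # 3. amplitude-anomalous events (artifact test) -> candidates
    kept_events, rejected = reject_artifacts(
        [events[i] for i in single_ids], z_max=pp.artifact_z)
    rejected_set = {id(ev) for ev in rejected}
    new_single_ids = []
    for i in single_ids:
        if id(events[i]) in rejected_set:
            candidates.append(make_candidate(der, [int(peaks[i])], cfg.tops,
                                             "amplitude", event_ids=[i]))
        else:
            new_single_ids.append(i)
    single_ids = new_single_ids
    log.info("%d single candidates, %d overlap candidates",
             len(single_ids), len(candidates))

    # 4. features + clustering sweep on the single candidates.  With Fisher
    # weighting the weight function W(f) is estimated from a provisional
    # fixed-K clustering and the whole sweep runs on the weighted features:
    # uninformative feature columns otherwise dilute the cluster separation
    # enough to destabilize the CD-based choice of K
    singles = [events[i] for i in single_ids]
    fm0 = standardize(extract_features(singles, fs))
    fm = fm0
    results = kmeans_sweep(fm, cfg.cluster, seed=cfg.seed)
    cells, best_cell, best = score_sweep(fm, results, cfg.cluster,
                                         seed=cfg.seed)
    log.info("selected K=%d (%s vs %s), CD=%.3f", best.k, best_cell.distance,
             best_cell.metric, best_cell.cd)
    if cfg.cluster.weighting == "fisher" and np.unique(best.labels).size > 1:
        # refine the assignment: re-estimate W(f) from the selected labels
        # on the unweighted features, re-fit every assignment distance at
        # the selected K and keep the fit the CD-index prefers; K stays
        # fixed by the sweep's choice
        w2 = fisher_weights(fm0, best.labels)
        fm = FeatureMatrix(values=fm0.values * w2, weights=w2,
                           standardized=True)
        refits = [kmeans_fit(fm.values, best.k, dist, seed=cfg.seed + 1,
                             replicates=cfg.cluster.replicates,
                             max_iter=cfg.cluster.max_iter)
                  for dist in cfg.cluster.kmeans_distances]
        _, refit_cell, best = score_sweep(fm, refits, cfg.cluster,
                                          seed=cfg.seed + 1)
        log.info("weighted refit: %s (CD %.3f)", best.distance,
                 refit_cell.cd)

    # 5. templates; outlier-cluster events join the overlap pool
    templates = build_templates_and_flag_outliers(
        singles, best, thr_fd, outlier_frac=cfg.cluster.outlier_frac)
    outlier_clusters = {t.cluster_id for t in templates if t.is_outlier}

    # 5b. within-cluster atypicality reroute: events that correlate poorly
    # with their own cluster template or have anomalous amplitude are sent
    # to the overlap pool for re-examination by TOPS
    atypical = _atypical_members(singles, best.labels, templates,
                                 cfg.cluster.reroute_z)
    final_single_ids: list[int] = []
    final_labels: list[int] = []
    for pos, i in enumerate(single_ids):
        lab = int(best.labels[pos])
        if lab in outlier_clusters:
            candidates.append(make_candidate(der, [int(peaks[i])], cfg.tops,
                                             "outlier", event_ids=[i]))
        elif atypical[pos]:
            candidates.append(make_candidate(der, [int(peaks[i])], cfg.tops,
                                             "atypical", event_ids=[i]))
        else:
            final_single_ids.append(i)
            final_labels.append(lab)
    log.info("rerouted %d atypical events to the overlap pool",
             int(atypical.sum()))
    # rebuild templates from the cleaned clusters
    if atypical.any():
        keep_mask = ~atypical
        kept_singles = [ev for ev, m in zip(singles, keep_mask) if m]
        if kept_singles:
            sub = ClusteringResult(
                labels=best.labels[keep_mask], k=best.k,
                distance=best.distance, centroids=best.centroids,
                inertia=best.inertia, replicate_seed=best.replicate_seed)
            templates = build_templates_and_flag_outliers(
                kept_singles, sub, thr_fd,
                outlier_frac=cfg.cluster.outlier_frac)

    # 6. TOPS decomposition of the overlap pool
    candidates.sort(key=lambda c: c.peak_index)
    overlap_assignments = assign_overlaps(candidates, templates, der,
                                          thr_fd, thr_v, cfg.tops)

    assignments = [Assignment(time_s=peaks[i] / fs, cluster=lab,
                              source="single")
                   for i, lab in zip(final_single_ids, final_labels)]
    for oa in overlap_assignments:
        src = "quasi" if oa.quasi_simultaneous else "overlap"
        for cid, t in oa.assignments:
            assignments.append(Assignment(time_s=t, cluster=cid, source=src))
    assignments.sort(key=lambda a: a.time_s)
    return SortResult(events=events, single_ids=final_single_ids,
                      feature_event_ids=list(single_ids),
                      labels=np.array(final_labels, dtype=int), features=fm,
                      templates=templates, cells=cells, best_cell=best_cell,
                      clustering=best, candidates=candidates,
                      overlap_assignments=overlap_assignments,
                      assignments=assignments, thr_fd=thr_fd, thr_v=thr_v,
                      der=der)


def evaluate_sort(result: SortResult, truth: list[GroundTruthEvent],
                  cfg: PipelineConfig) -> tuple[SortingScore,
                                                ClassificationMatrix]:
    """Score a sorting result against ground truth."""
    cm = match_clusters_to_truth(result.assignments, truth,
                                 tol_s=cfg.evaluate.time_tol_ms * 1e-3)
    return score_report(cm), cm


def kmeans_only_assignments(result: SortResult) -> list[Assignment]:
    """Assignments from the K-means step alone (no TOPS decomposition):
    overlap-pool events are credited to the single best-matching cluster by
    template correlation, mirroring what a plain K-means sort would output.
    """
    out = [Assignment(time_s=a.time_s, cluster=a.cluster, source="single")
           for a in result.assignments if a.source == "single"]
    singles = [t for t in result.templates if not t.is_outlier]
    for oa in result.overlap_assignments:
        cand = oa.candidate
        best, best_r = None, -2.0
        w = cand.window_fd
        for t in singles:
            tt = np.zeros_like(w)
            anchor = int(np.argmin(t.template_fd))
            lo = cand.window_fd.size // 2 - anchor
            hi = lo + t.template_fd.size
            src = t.template_fd[max(0, -lo):t.template_fd.size -
                                max(0, hi - w.size)]
            tt[max(0, lo):max(0, lo) + src.size] = src
            r = float(np.corrcoef(w, tt)[0, 1]) if tt.std() > 0 else -1.0
            if r > best_r:
                best, best_r = t.cluster_id, r
        if best is not None:
            out.append(Assignment(time_s=cand.peak_index / result.der.fs,
                                  cluster=best, source="single"))
    out.sort(key=lambda a: a.time_s)
    return out
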