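"""Template Optimization in Phase Space (TOPS): overlap decomposition.

A detected waveform produced by near-simultaneous firing of several units
cannot be assigned by K-means: its feature vector resembles none of the
single-unit clusters.  TOPS resolves such waveforms by (1) counting their
*fundamental minima* -- time-domain troughs where the first derivative
crosses zero upward and the second derivative is positive -- (2) building
*artificial* overlapping waveforms as sums of the single-unit templates over
a grid of relative time shifts below 2 ms, and (3) assigning the real
waveform the composition of the artificial waveform that matches it best in
the sense of the Pearson correlation coefficient.  A waveform with a single
supra-threshold minimum but anomalously large amplitude is treated as a
quasi-simultaneous superposition and assigned one spike per single-unit
cluster.  Trajectory comparisons in the (FD, SD) phase plane provide the
tie-break distance between a waveform segment and a template limit cycle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .config import TopsConfig
from .clustering import ClusterTemplate
from .preprocess import DerivedRecording


@dataclass
class FundamentalMinimum:
    index: int                 # sample position within the analyzed window
    depth: float               # filtered-voltage value at the minimum
    supra_threshold: bool


@dataclass
class ArtificialOverlap:
    composition: list[tuple[int, int]]   # (template cluster_id, shift samples)
    waveform_fd: np.ndarray
    waveform_sd: np.ndarray
    troughs: list[int]                   # FD-minimum sample per constituent


@dataclass
class OverlapCandidate:
    """A real waveform suspected to contain more than one spike."""

    peak_index: int            # absolute sample of the dominant FD minimum
    start: int                 # absolute sample of window start
    window_v: np.ndarray
    window_fd: np.ndarray
    window_sd: np.ndarray
    reason: str                # group | minima | amplitude
    event_ids: list[int] = field(default_factory=list)


@dataclass
class OverlapAssignment:
    candidate: OverlapCandidate
    n_minima: int
    match_r: float
    composition: list[tuple[int, int]]
    assignments: list[tuple[int, float]]    # (cluster_id, time_s)
    unclassified: bool = False
    quasi_simultaneous: bool = False


def find_fundamental_minima(v: np.ndarray, fd: np.ndarray, sd: np.ndarray,
                            thr_fd: float, thr_v: float | None = None,
                            rel_depth: float = 0.0
                            ) -> list[FundamentalMinimum]:
    """Time-domain minima of the waveform: FD sign change - to + with SD > 0.

    A minimum is supra-threshold when the FD descent leading into it crosses
    ``-thr_fd`` and (if given) the trough itself lies below ``-thr_v``,
    which excludes the shallow rebound minima that trail a spike's
    after-potential.  ``rel_depth`` additionally requires the trough to
    reach that fraction of the window's deepest trough -- a genuine
    constituent spike is commensurate with the dominant one, while filter
    side-lobes are not.
    """
    out: list[FundamentalMinimum] = []
    n = fd.size
    neg = fd < 0
    floor = rel_depth * float(v.min()) if rel_depth > 0 else 0.0
    for i in range(n - 1):
        if neg[i] and not neg[i + 1] and sd[i] > 0:
            j = i if v[i] <= v[i + 1] else i + 1
            # FD excursion on the descent into this trough
            k = i
            descent_min = fd[i]
            while k > 0 and fd[k - 1] < 0:
                k -= 1
                descent_min = min(descent_min, fd[k])
            supra = descent_min < -thr_fd
            if thr_v is not None:
                supra = supra and v[j] < -thr_v
            if rel_depth > 0:
                supra = supra and v[j] <= floor
            out.append(FundamentalMinimum(index=int(j), depth=float(v[j]),
                                          supra_threshold=bool(supra)))
    return out


@dataclass
class Segment:
    """A sub-window of an overlapping waveform around one minimum."""

    lo: int
    hi: int                    # inclusive bounds within the window
    minimum: int
    quasi_closed: bool = False


def extract_segments(fd: np.ndarray, sd: np.ndarray,
                     minima: list[FundamentalMinimum],
                     closure_eps: float = 0.05) -> list[Segment]:
    """Expand around each minimum until the phase trajectory quasi-closes.

    The trajectory is normalized per axis; expansion stops when the running
    endpoints come within ``closure_eps`` of the trajectory diameter of each
    other, or at the midpoint to an adjacent minimum / the window edge.
    """
    if not minima:
        raise ValueError("need at least one minimum")
    n = fd.size
    fscale = np.abs(fd).max() or 1.0
    sscale = np.abs(sd).max() or 1.0
    xf, xs = fd / fscale, sd / sscale
    idxs = [m.index for m in minima]
    segments = []
    for pos, m in enumerate(idxs):
        lo_bound = 0 if pos == 0 else (idxs[pos - 1] + m) // 2
        hi_bound = n - 1 if pos == len(idxs) - 1 else (m + idxs[pos + 1]) // 2
        lo = hi = m
        closed = False
        while lo > lo_bound or hi < hi_bound:
            if lo > lo_bound:
                lo -= 1
            if hi < hi_bound:
                hi += 1
            span = max(np.ptp(xf[lo:hi + 1]), np.ptp(xs[lo:hi + 1]), 1e-12)
            gap = np.hypot(xf[lo] - xf[hi], xs[lo] - xs[hi])
            if (hi - lo) > 4 and gap < closure_eps * span:
                closed = True
                break
        segments.append(Segment(lo=lo, hi=hi, minimum=m,
                                quasi_closed=not closed))
    return segments


# -- artificial overlaps ---------------------------------------------------

def _superpose(templates: dict[int, ClusterTemplate],
               composition: list[tuple[int, int]]
               ) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Point-by-point sum of shifted templates on a common buffer."""
    shifts = [s for _, s in composition]
    base = -min(shifts)
    length = max(s + base + templates[tid].template_fd.size
                 for tid, s in composition)
    fd = np.zeros(length)
    sd = np.zeros(length)
    troughs = []
    for tid, s in composition:
        t = templates[tid]
        o = s + base
        fd[o:o + t.template_fd.size] += t.template_fd
        sd[o:o + t.template_sd.size] += t.template_sd
        troughs.append(o + int(np.argmin(t.template_fd)))
    return fd, sd, troughs


def generate_artificial_overlaps(templates: list[ClusterTemplate],
                                 shifts: np.ndarray,
                                 order: int = 2) -> list[ArtificialOverlap]:
    """All template pairs (order 2) or triples (order 3) over a shift grid.

    Shifts are relative to the first constituent; pairwise peak delays are
    constrained to the grid extent (below the 2 ms bound by construction).
    """
    ts = {t.cluster_id: t for t in templates}
    ids = sorted(ts)
    if len(ids) < 2:
        warnings.warn("need at least 2 templates for artificial overlaps")
        return []
    out: list[ArtificialOverlap] = []
    max_d = int(np.max(np.abs(shifts))) + 1
    if order == 2:
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                for s in shifts:
                    comp = [(a, 0), (b, int(s))]
                    fd, sd, tr = _superpose(ts, comp)
                    out.append(ArtificialOverlap(comp, fd, sd, tr))
    elif order == 3:
        for a, b, c in _triples(ids):
            for s2 in shifts:
                for s3 in shifts:
                    if abs(int(s2) - int(s3)) >= max_d:
                        continue
                    comp = [(a, 0), (b, int(s2)), (c, int(s3))]
                    fd, sd, tr = _superpose(ts, comp)
                    out.append(ArtificialOverlap(comp, fd, sd, tr))
    else:
        raise ValueError("order must be 2 or 3")
    return out


def _triples(ids):
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            for k in range(j + 1, len(ids)):
                yield ids[i], ids[j], ids[k]


class OverlapBank:
    """Artificial overlaps embedded in a canonical window for fast matching.

    Each waveform is placed so that its global FD minimum sits at the anchor
    sample; rows are z-scored so the Pearson correlation with a z-scored
    real window is a single dot product.
    """

    def __init__(self, overlaps: list[ArtificialOverlap], pre: int,
                 post: int, jitter: int = 0):
        self.pre = pre
        self.post = post
        self.length = pre + post + 1
        self.overlaps = overlaps
        # one row per candidate anchor: the real window is aligned on its
        # deepest FD minimum, but noise can make any constituent's trough
        # the deepest, so every constituent trough is offered as an anchor;
        # `jitter` additionally offers anchors displaced by a few samples to
        # absorb alignment error of the real window
        row_list: list[np.ndarray] = []
        self.row_overlap: list[int] = []
        self.trough_offsets: list[list[int]] = []
        for i, ov in enumerate(overlaps):
            anchors = {int(np.argmin(ov.waveform_fd))}
            anchors.update(int(t) for t in ov.troughs)
            if jitter:
                anchors.update(a + d for a in list(anchors)
                               for d in range(-jitter, jitter + 1))
            for anchor in sorted(anchors):
                lo = anchor - pre
                hi = anchor + post + 1
                src_lo = max(0, lo)
                src_hi = min(ov.waveform_fd.size, hi)
                row = np.zeros(self.length)
                row[src_lo - lo:src_hi - lo] = ov.waveform_fd[src_lo:src_hi]
                row_list.append(row)
                self.row_overlap.append(i)
                self.trough_offsets.append([t - anchor for t in ov.troughs])
        rows = np.asarray(row_list)
        mu = rows.mean(axis=1, keepdims=True)
        sd = rows.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        self.z = (rows - mu) / sd

    def correlate(self, window_fd: np.ndarray) -> np.ndarray:
        w = np.asarray(window_fd, dtype=float)
        if w.size != self.length:
            raise ValueError("window length does not match bank")
        mu, sd = w.mean(), w.std()
        if sd == 0:
            return np.zeros(self.z.shape[0])
        wz = (w - mu) / sd
        return self.z @ wz / self.length


# -- phase-space distance --------------------------------------------------

def phase_distance(seg_fd: np.ndarray, seg_sd: np.ndarray,
                   tmpl_fd: np.ndarray, tmpl_sd: np.ndarray,
                   n_theta_bins: int = 360) -> float:
    """Mean normal deviation |n(theta)| between a signal trajectory and a
    template limit trajectory in the (FD, SD) phase plane.

    Both trajectories are normalized per axis by their joint extent (so the
    comparison is scale-aware but not biased toward small templates); the
    template centroid is the phase origin P0.  For each angular bin covered
    by the signal, the minimal distance from its points to the template
    trajectory is averaged.  Degenerate (zero-extent) trajectories return
    ``inf``.
    """
    if min(seg_fd.size, tmpl_fd.size) < 8:
        raise ValueError("trajectories need at least 8 points")
    fscale = max(np.abs(tmpl_fd).max(), np.abs(seg_fd).max())
    sscale = max(np.abs(tmpl_sd).max(), np.abs(seg_sd).max())
    if fscale == 0 or sscale == 0:
        return float("inf")
    t = np.column_stack([tmpl_fd / fscale, tmpl_sd / sscale])
    s = np.column_stack([seg_fd / fscale, seg_sd / sscale])
    p0 = t.mean(axis=0)
    d2 = ((s[:, None, :] - t[None, :, :]) ** 2).sum(axis=2)

    def binned_mean(points, dmin):
        theta = np.arctan2(points[:, 1] - p0[1], points[:, 0] - p0[0])
        bins = np.clip(((theta + np.pi) / (2 * np.pi)
                        * n_theta_bins).astype(int), 0, n_theta_bins - 1)
        total, covered = 0.0, 0
        for b in np.unique(bins):
            total += dmin[bins == b].mean()
            covered += 1
        return total / covered if covered else float("inf")

    # symmetrized: a large template loop is close to any point cloud, so
    # the deviation is averaged over both directions
    fwd = binned_mean(s, np.sqrt(d2.min(axis=1)))
    bwd = binned_mean(t, np.sqrt(d2.min(axis=0)))
    return 0.5 * (fwd + bwd)


# -- assignment ------------------------------------------------------------

def make_candidate(der: DerivedRecording, peak_indices: list[int],
                   cfg: TopsConfig, reason: str,
                   event_ids: list[int] | None = None) -> OverlapCandidate:
    """Build the wide analysis window around a (group of) detection(s)."""
    fs = der.fs
    pre = int(round(cfg.wide_pre_ms * 1e-3 * fs))
    post = int(round(cfg.wide_post_ms * 1e-3 * fs))
    center = min(peak_indices,
                 key=lambda p: der.fd[p])  # deepest FD minimum of the group
    lo = max(0, center - pre)
    hi = min(der.fd.size, center + post + 1)
    pad_l = pre - (center - lo)
    pad_r = post + 1 - (hi - center)
    window = lambda x: np.pad(x[lo:hi], (pad_l, pad_r))
    return OverlapCandidate(peak_index=int(center), start=lo - pad_l,
                            window_v=window(der.filtered),
                            window_fd=window(der.fd),
                            window_sd=window(der.sd), reason=reason,
                            event_ids=list(event_ids or []))


def _contributions(templates: dict[int, ClusterTemplate],
                   composition: list[tuple[int, int]]) -> np.ndarray:
    e = np.array([np.sum(templates[tid].template_fd ** 2)
                  for tid, _ in composition])
    return e / e.sum()


def assign_overlaps(candidates: list[OverlapCandidate],
                    templates: list[ClusterTemplate],
                    der: DerivedRecording, thr: float, thr_v: float,
                    cfg: TopsConfig) -> list[OverlapAssignment]:
    """Assign each candidate waveform's constituents to single-unit clusters.

    One supra-threshold minimum with anomalous amplitude means
    quasi-simultaneous firing: one spike is credited to every single-unit
    cluster.  With two or more minima, the best Pearson-matching artificial
    overlap determines the composition (triples are only searched when no
    pair reaches ``pair_good_r``); constituents contributing less than
    ``contribution_min`` of the energy stay unassigned, and a best match
    below ``r_min`` leaves the event unclassified.
    """
    fs = der.fs
    singles = [t for t in templates if not t.is_outlier]
    ts = {t.cluster_id: t for t in singles}
    pre = int(round(cfg.wide_pre_ms * 1e-3 * fs))
    post = int(round(cfg.wide_post_ms * 1e-3 * fs))
    # the delay bound applies to the spikes' troughs; FD-aligned template
    # windows can be offset from each other by a few extra samples, so the
    # grid carries a 0.25 ms margin beyond the configured bound
    max_shift = int(round((cfg.max_shift_ms + 0.25) * 1e-3 * fs))
    shifts = np.arange(-max_shift, max_shift + 1, cfg.shift_step)
    pair_bank = OverlapBank(
        generate_artificial_overlaps(singles, shifts, order=2), pre, post)
    triple_bank = None
    single_bank = OverlapBank(
        [ArtificialOverlap([(t.cluster_id, 0)], t.template_fd,
                           t.template_sd,
                           [int(np.argmin(t.template_fd))])
         for t in singles], pre, post, jitter=6)
    max_p2v = max(np.ptp(t.template_fd) for t in singles) if singles else 0.0

    def emit(cand, n_supra, bank, idx, r):
        ov = bank.overlaps[bank.row_overlap[idx]]
        contrib = _contributions(ts, ov.composition)
        assignments, kept_comp = [], []
        for (cid, shift), c, toff in zip(ov.composition, contrib,
                                         bank.trough_offsets[idx]):
            if c < cfg.contribution_min:
                continue
            kept_comp.append((cid, shift))
            assignments.append((cid, (cand.peak_index + toff) / fs))
        return OverlapAssignment(candidate=cand, n_minima=n_supra,
                                 match_r=r, composition=kept_comp,
                                 assignments=assignments)

    out: list[OverlapAssignment] = []
    for cand in candidates:
        minima = find_fundamental_minima(cand.window_v, cand.window_fd,
                                         cand.window_sd, thr, thr_v,
                                         rel_depth=cfg.min_rel_depth)
        n_supra = sum(m.supra_threshold for m in minima)
        t_center = cand.peak_index / fs
        p2v = np.ptp(cand.window_fd)

        r1 = single_bank.correlate(cand.window_fd)
        i1 = int(np.argmax(r1))
        best_tmpl = ts[single_bank.overlaps[
            single_bank.row_overlap[i1]].composition[0][0]]

        if n_supra <= 1:
            # one fundamental minimum: an ordinary single spike, unless a
            # pair explains the waveform far better (merged troughs hide the
            # second minimum) or the amplitude is anomalously large for the
            # best-matching template (quasi-simultaneous firing of all units)
            r_pair = pair_bank.correlate(cand.window_fd)
            i2 = int(np.argmax(r_pair))
            if float(r_pair[i2]) > float(r1[i1]) + cfg.single_pair_gain:
                out.append(emit(cand, n_supra, pair_bank, i2,
                                float(r_pair[i2])))
            elif p2v > cfg.quasi_amp_ratio * np.ptp(best_tmpl.template_fd):
                out.append(OverlapAssignment(
                    candidate=cand, n_minima=n_supra, match_r=float(r1[i1]),
                    composition=[(t.cluster_id, 0) for t in singles],
                    assignments=[(t.cluster_id, t_center) for t in singles],
                    quasi_simultaneous=True))
            elif float(r1[i1]) >= cfg.r_min:
                out.append(emit(cand, n_supra, single_bank, i1,
                                float(r1[i1])))
            else:
                out.append(OverlapAssignment(
                    candidate=cand, n_minima=n_supra, match_r=float(r1[i1]),
                    composition=[], assignments=[], unclassified=True))
            continue

        # several minima: competition between a single template, the best
        # pair and (when no pair is convincing) the best triple; a richer
        # composition must beat the simpler one by `order_margin`
        r_pair = pair_bank.correlate(cand.window_fd)
        i2 = int(np.argmax(r_pair))
        best_bank, best_i, best_r = single_bank, i1, float(r1[i1])
        if float(r_pair[i2]) > best_r + cfg.order_margin:
            best_bank, best_i, best_r = pair_bank, i2, float(r_pair[i2])
        if len(singles) >= 3 and best_r < cfg.pair_good_r:
            if triple_bank is None:
                triple_bank = OverlapBank(
                    generate_artificial_overlaps(singles, shifts, order=3),
                    pre, post)
            r_tri = triple_bank.correlate(cand.window_fd)
            i3 = int(np.argmax(r_tri))
            if float(r_tri[i3]) > best_r + cfg.triple_margin:
                best_bank, best_i, best_r = triple_bank, i3, float(r_tri[i3])

        if best_r >= cfg.r_min:
            out.append(emit(cand, n_supra, best_bank, best_i, best_r))
        elif p2v > cfg.quasi_amp_ratio * np.ptp(best_tmpl.template_fd):
            out.append(OverlapAssignment(
                candidate=cand, n_minima=n_supra, match_r=best_r,
                composition=[(t.cluster_id, 0) for t in singles],
                assignments=[(t.cluster_id, t_center) for t in singles],
                quasi_simultaneous=True))
        else:
            out.append(OverlapAssignment(
                candidate=cand, n_minima=n_supra, match_r=best_r,
                composition=[], assignments=[], unclassified=True))
    return out
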