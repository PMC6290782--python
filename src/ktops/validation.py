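"""Classification matrices, CE-index and Error Index.

Scoring against ground truth builds an observed classification matrix whose
diagonal d_i counts events assigned to the cluster matched with their true
unit and whose off-diagonal r_k counts events assigned to a wrong cluster;
delta_i is the number of events truly belonging to unit i, so missed events
appear as a deficit d_i - delta_i.  The clustering-error index is

    CE = sqrt((sum_i (d_i - delta_i)^2 + sum_k r_k^2) / (sum d_i + sum r_k))

and the Error Index scales it into an event count:

    EI = CE * sqrt(w_S + m_S) = CE * sqrt(N_S - u_S)

with w_S = sum d_i well-classified, m_S = sum r_k misclassified and
u_S = N_S - (w_S + m_S) unclassified events.  An overlapping waveform
counts as well-classified only when every constituent spike is credited to
its true cluster.  Without ground truth, CE is computed from template/event
correlations instead (own-cluster mean correlations against an expected
value Delta, cross-cluster mean correlations against zero).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .simulate import GroundTruthEvent


class ValidationError(ValueError):
    pass


@dataclass
class ClassificationMatrix:
    observed: np.ndarray        # K x K counts, rows clusters, cols true units
    truth_counts: np.ndarray    # delta_i per true unit
    class_ids: list[str]
    cluster_ids: list[int]
    n_events: int               # N_S
    overlap_counts: dict[str, int] = field(default_factory=dict)

    @property
    def d(self) -> np.ndarray:
        k = min(self.observed.shape)
        return np.diag(self.observed)[:k]

    @property
    def r(self) -> np.ndarray:
        mask = ~np.eye(*self.observed.shape, dtype=bool)
        return self.observed[mask]


@dataclass
class SortingScore:
    well: int
    mis: int
    unclassified: int
    ce: float
    ei: float
    n_events: int
    overlap_well: int = 0
    overlap_mis: int = 0
    overlap_unclassified: int = 0
    single_well: int = 0
    n_singles: int = 0
    n_overlaps: int = 0


def ce_from_counts(cm: ClassificationMatrix) -> float:
    """CE from an observed classification matrix and the true counts."""
    d = cm.d.astype(float)
    delta = cm.truth_counts.astype(float)[:d.size]
    r = cm.r.astype(float)
    denom = d.sum() + r.sum()
    if denom == 0:
        raise ValidationError("CE undefined: no classified events")
    return float(np.sqrt(((d - delta) ** 2).sum() + (r ** 2).sum()) / np.sqrt(denom))


def error_index(ce: float, well: int, mis: int) -> float:
    """EI = CE * sqrt(w_S + m_S)."""
    return float(ce * np.sqrt(well + mis))


def ce_from_correlations(r_own: np.ndarray, r_mixed: np.ndarray,
                         delta: float = 0.95) -> float:
    """CE from mean template/event correlations (no ground truth needed).

    ``r_own``: mean correlation between each cluster's template and its own
    events; ``r_mixed``: mean correlations between templates and the events
    of other clusters (all ordered pairs i != j).
    """
    r_own = np.asarray(r_own, dtype=float)
    r_mixed = np.asarray(r_mixed, dtype=float)
    denom = r_own.sum() + r_mixed.sum()
    if denom <= 0:
        raise ValidationError("CE undefined: non-positive correlation mass")
    num = ((r_own - delta) ** 2).sum() + (r_mixed ** 2).sum()
    return float(np.sqrt(num / denom))


def cluster_correlations(events_fd: np.ndarray, labels: np.ndarray,
                         templates: dict[int, np.ndarray]
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Mean own-cluster and cross-cluster template/event correlations."""
    ids = sorted(templates)
    r_own, r_mixed = [], []
    for i in ids:
        ti = templates[i]
        own = events_fd[labels == i]
        if own.shape[0] == 0:
            warnings.warn(f"cluster {i} empty; excluded from CE")
            continue
        r_own.append(np.mean([_corr(ev, ti) for ev in own]))
        for j in ids:
            if j == i:
                continue
            other = events_fd[labels == j]
            if other.shape[0]:
                r_mixed.append(np.mean([_corr(ev, ti) for ev in other]))
    return np.asarray(r_own), np.asarray(r_mixed)


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


# -- ground-truth matching -------------------------------------------------

@dataclass
class Assignment:
    """One spike credited to a cluster at a given time."""

    time_s: float
    cluster: int
    source: str = "single"      # single | overlap | quasi


def match_clusters_to_truth(assignments: list[Assignment],
                            truth: list[GroundTruthEvent],
                            tol_s: float = 0.5e-3) -> ClassificationMatrix:
    """Score sorted output against the ground-truth event table.

    Detected assignments are matched to truth constituents by nearest time
    within ``tol_s``; the cluster <-> unit correspondence is the optimal
    one-to-one assignment maximizing matched counts on single-unit events.
    An overlap is well-classified only if every constituent is credited to
    its true cluster; a partial recovery counts as misclassified, no
    recovery as unclassified.  Extra clusters beyond the number of true
    units contribute unclassified events only.
    """
    class_ids = sorted({tid for ev in truth for tid, _ in ev.composition})
    cls_pos = {c: i for i, c in enumerate(class_ids)}
    times = np.array([a.time_s for a in assignments])
    order = np.argsort(times)
    times = times[order]
    assign_sorted = [assignments[i] for i in order]
    clusters = sorted({a.cluster for a in assignments})

    def near(t: float) -> list[int]:
        lo = np.searchsorted(times, t - tol_s)
        hi = np.searchsorted(times, t + tol_s)
        return list(range(lo, hi))

    # contingency on single-unit truth for the cluster <-> unit mapping
    cont = np.zeros((len(clusters), len(class_ids)))
    cl_pos = {c: i for i, c in enumerate(clusters)}
    for ev in truth:
        if ev.kind != "single":
            continue
        tid, tpeak = ev.composition[0]
        cands = near(tpeak)
        if not cands:
            continue
        best = min(cands, key=lambda i: abs(times[i] - tpeak))
        cont[cl_pos[assign_sorted[best].cluster], cls_pos[tid]] += 1
    row, col = linear_sum_assignment(-cont)
    cluster_of_class = {class_ids[c]: clusters[r] for r, c in zip(row, col)}

    k = len(class_ids)
    observed = np.zeros((k, k), dtype=int)
    delta = np.zeros(k, dtype=int)
    n_events = len(truth)
    overlap_counts = {"well": 0, "mis": 0, "unclassified": 0}
    single_well = 0
    # inverse map: cluster -> class position (extra clusters -> None)
    class_of_cluster = {v: cls_pos[c] for c, v in cluster_of_class.items()}

    for ev in truth:
        primary = cls_pos[ev.composition[0][0]]
        delta[primary] += 1
        ok = True
        seen_any = False
        wrong_cluster = None
        for tid, tpeak in ev.composition:
            want = cluster_of_class.get(tid)
            cands = near(tpeak)
            got = [assign_sorted[i].cluster for i in cands]
            if got:
                seen_any = True
            if want is None or want not in got:
                ok = False
                for g in got:
                    if g != want:
                        wrong_cluster = g
        if ok:
            observed[primary, primary] += 1
            if ev.kind == "single":
                single_well += 1
            else:
                overlap_counts["well"] += 1
        elif seen_any:
            wc = class_of_cluster.get(wrong_cluster)
            if wc is None or wc == primary:
                wc = (primary + 1) % k   # extra-cluster row folded over
            observed[wc, primary] += 1
            if ev.kind != "single":
                overlap_counts["mis"] += 1
        else:
            if ev.kind != "single":
                overlap_counts["unclassified"] += 1
    return ClassificationMatrix(observed=observed, truth_counts=delta,
                                class_ids=class_ids,
                                cluster_ids=[cluster_of_class.get(c, -1)
                                             for c in class_ids],
                                n_events=n_events,
                                overlap_counts=overlap_counts | {
                                    "single_well": single_well})


def score_report(cm: ClassificationMatrix) -> SortingScore:
    """Well/mis/unclassified accounting plus CE and EI from a matrix."""
    well = int(cm.d.sum())
    mis = int(cm.r.sum())
    unclassified = cm.n_events - well - mis
    if unclassified < 0:
        raise ValidationError("negative unclassified count: double counting")
    ce = ce_from_counts(cm)
    ei = error_index(ce, well, mis)
    oc = cm.overlap_counts
    n_overlaps = oc.get("well", 0) + oc.get("mis", 0) + oc.get(
        "unclassified", 0)
    return SortingScore(
        well=well, mis=mis, unclassified=unclassified, ce=ce, ei=ei,
        n_events=cm.n_events,
        overlap_well=oc.get("well", 0), overlap_mis=oc.get("mis", 0),
        overlap_unclassified=oc.get("unclassified", 0),
        single_well=oc.get("single_well", 0),
        n_singles=cm.n_events - n_overlaps, n_overlaps=n_overlaps)
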