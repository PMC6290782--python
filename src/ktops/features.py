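"""Fiducial points and the 24-dimensional spike feature vector.

Each detected event is summarized by six fiducial points of its first
derivative (FD) -- three zero crossings (P1, P3, P5) interleaved with the
FD valley (P2), the FD peak (P4) and the trailing FD valley (P6) -- and by
24 features split into three families:

* shape (F1-F11): durations, amplitudes, slopes and slope ratios measured
  between fiducial points of the FD in the time domain;
* phase (F12-F19): FD amplitudes at P1, P3, P4, P5, P6 and SD amplitudes at
  P1, P3, P5, i.e. coordinates of the trajectory in the (FD, SD) phase
  plane;
* distribution (F20-F24): interquartile range, kurtosis and skewness of the
  FD/SD sample-amplitude distributions over the whole event window.

Durations are in milliseconds, amplitudes in per-sample derivative units;
ratio and moment features are dimensionless.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats

from .preprocess import SpikeEvent

N_FEATURES = 24
FEATURE_NAMES = tuple(f"F{i}" for i in range(1, N_FEATURES + 1))


class FiducialError(ValueError):
    """Raised when a required fiducial point cannot be located."""


@dataclass
class FiducialPoints:
    """Sample indices, times (ms) and amplitudes of P1..P6.

    ``p1 < p2 < p3 < p4 < p5 < p6``; the stored index of a zero crossing is
    the sample at or before the (linearly interpolated) crossing, while the
    stored time is the interpolated crossing time.
    """

    idx: np.ndarray          # 6 integer sample indices within the window
    t_ms: np.ndarray         # 6 interpolated times, ms relative to window start
    a_fd: np.ndarray         # FD amplitude at each point
    a_sd: np.ndarray         # SD amplitude at each point
    flags: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.idx) >= 0) or not np.all(
                np.diff(self.t_ms) > 0):
            raise FiducialError(f"fiducials out of order: {self.idx}")


def _zero_cross_before(x: np.ndarray, start: int) -> int | None:
    """Rightmost i < start with a sign change between i and i+1."""
    s = np.signbit(x)
    for i in range(start - 1, -1, -1):
        if x[i] == 0 or s[i] != s[i + 1]:
            return i
    return None


def _zero_cross_after(x: np.ndarray, start: int) -> int | None:
    """Leftmost i >= start with a sign change between i and i+1."""
    s = np.signbit(x)
    for i in range(start, x.size - 1):
        if x[i + 1] == 0 or s[i] != s[i + 1]:
            return i
    return None


def _interp_time(x: np.ndarray, i: int, fs: float) -> float:
    """Linear-interpolated zero-crossing time (ms) between samples i, i+1."""
    if i + 1 >= x.size:
        return i / fs * 1e3
    x0, x1 = x[i], x[i + 1]
    frac = 0.0 if x1 == x0 else float(x0 / (x0 - x1))
    return (i + np.clip(frac, 0.0, 1.0)) / fs * 1e3


def locate_fiducials(ev: SpikeEvent, fs: float,
                     fallback: bool = True) -> FiducialPoints:
    """Locate P1..P6 around the aligned FD minimum (taken as P2).

    P1/P3 are the nearest FD sign changes before/after P2, P4 the FD maximum
    between P3 and the window end, P5 the next sign change after P4 and P6
    the FD minimum after P5.  For biphasic spikes without a trailing valley
    the fall-backs (window edges / remaining-window extrema) are used and the
    event is flagged; with ``fallback=False`` a missing point raises
    :class:`FiducialError` instead.
    """
    fd, sd = ev.window_fd, ev.window_sd
    n = fd.size
    flags: set = set()
    p2 = int(ev.pre_samples)
    if fd[p2] != fd.min():
        p2 = int(np.argmin(fd))
        flags.add("realigned")

    p1 = _zero_cross_before(fd, p2)
    if p1 is None:
        if not fallback:
            raise FiducialError("no FD sign change before P2")
        p1, flags = 0, flags | {"p1_fallback"}
    p3 = _zero_cross_after(fd, p2)
    if p3 is None:
        if not fallback:
            raise FiducialError("no FD sign change after P2")
        p3, flags = min(p2 + 1, n - 2), flags | {"p3_fallback"}
    p4 = p3 + 1 + int(np.argmax(fd[p3 + 1:])) if p3 + 1 < n else p3
    p5 = _zero_cross_after(fd, max(p4, p3 + 1))
    if p5 is None:
        if not fallback:
            raise FiducialError("no FD sign change after P4")
        p5, flags = min(p4 + 1, n - 2), flags | {"p5_fallback"}
    if p5 + 1 < n:
        p6 = p5 + 1 + int(np.argmin(fd[p5 + 1:]))
    else:
        p6 = n - 1
        flags.add("p6_fallback")

    idx = np.array([p1, p2, p3, p4, p5, p6], dtype=int)
    if np.any(np.diff(idx) < 0):  # fallback points can collide at the edge
        idx = np.maximum.accumulate(idx)
        idx = np.minimum(idx, n - 1)
        p1, p2, p3, p4, p5, p6 = (int(v) for v in idx)
        flags.add("degenerate_order")
    t_ms = np.empty(6)
    # times: interpolated for the zero crossings P1/P3/P5, exact for extrema
    t_ms[0] = _interp_time(fd, p1, fs)
    t_ms[1] = p2 / fs * 1e3
    t_ms[2] = _interp_time(fd, p3, fs)
    t_ms[3] = p4 / fs * 1e3
    t_ms[4] = _interp_time(fd, p5, fs)
    t_ms[5] = p6 / fs * 1e3
    if not np.all(np.diff(t_ms) > 0):  # degenerate fallback collisions
        t_ms = np.maximum.accumulate(t_ms + np.arange(6) * 1e-9)
        flags.add("degenerate_times")
    return FiducialPoints(idx=idx, t_ms=t_ms, a_fd=fd[idx], a_sd=sd[idx],
                          flags=flags)


def _safe_ratio(num: float, den: float, flags: set, name: str) -> float:
    if den == 0:
        flags.add(f"{name}_zero_den")
        return 0.0
    return num / den


def compute_shape_features(ev: SpikeEvent, fp: FiducialPoints,
                           reference: np.ndarray) -> np.ndarray:
    """F1-F11 from the fiducial algebra.

    The logarithmic slope features F5/F7 use log10 of the slope magnitude
    (the raw slope can be negative), and F8 is the true RMS of the pre-P1 FD
    samples.  F4 is the Pearson correlation with ``reference``.
    """
    t = fp.t_ms
    a = fp.a_fd
    fl = fp.flags
    f = np.zeros(11)
    f[0] = t[4] - t[0]                                   # F1 duration
    f[1] = a[3] - a[1]                                   # F2 peak-to-valley
    f[2] = a[5] - a[1]                                   # F3 valley-to-valley
    sigma_ref = reference.std()
    sigma_ev = ev.window_fd.std()
    if sigma_ref == 0 or sigma_ev == 0:
        fl.add("f4_degenerate")
        f[3] = 0.0
    else:
        f[3] = float(np.corrcoef(ev.window_fd, reference)[0, 1])
    pos_slope = _safe_ratio(a[3] - a[1], t[3] - t[1], fl, "f5")
    f[4] = np.log10(abs(pos_slope)) if pos_slope != 0 else 0.0
    f[5] = _safe_ratio(a[5] - a[3], t[5] - t[3], fl, "f6")
    vv_slope = _safe_ratio(a[5] - a[1], t[5] - t[1], fl, "f7")
    f[6] = np.log10(abs(vv_slope)) if vv_slope != 0 else 0.0
    pre = ev.window_fd[:fp.idx[0] + 1]                   # samples up to P1
    f[7] = float(np.sqrt(np.mean(pre ** 2))) if pre.size else 0.0
    down = _safe_ratio(a[1] - a[0], t[1] - t[0], fl, "f9")
    up = _safe_ratio(a[2] - a[1], t[2] - t[1], fl, "f9")
    f[8] = _safe_ratio(down, up, fl, "f9")
    rise = _safe_ratio(a[3] - a[2], t[3] - t[2], fl, "f10")
    fall = _safe_ratio(a[4] - a[3], t[4] - t[3], fl, "f10")
    f[9] = _safe_ratio(rise, fall, fl, "f10")
    f[10] = _safe_ratio(a[1], a[3], fl, "f11")
    return f


def compute_phase_features(fp: FiducialPoints) -> np.ndarray:
    """F12-F19: FD amplitudes at P1,P3,P4,P5,P6 and SD at P1,P3,P5."""
    a, s = fp.a_fd, fp.a_sd
    return np.array([a[0], a[2], a[3], a[4], a[5], s[0], s[2], s[4]])


def compute_distribution_features(ev: SpikeEvent) -> np.ndarray:
    """F20-F24: IQR of FD/SD, raw kurtosis of FD, skewness of FD and SD.

    Population (biased) moment formulas over all window samples; kurtosis is
    the raw fourth standardized moment (3 for a normal distribution).
    Zero-variance windows yield 0 for the moment features.
    """
    fd, sd = ev.window_fd, ev.window_sd
    if fd.size < 8:
        raise ValueError("window too short for distribution features")
    f = np.zeros(5)
    f[0] = np.percentile(fd, 75) - np.percentile(fd, 25)
    f[1] = np.percentile(sd, 75) - np.percentile(sd, 25)
    if fd.std() == 0 or sd.std() == 0:
        ev.flags.add("zero_variance_window")
        return f
    f[2] = sstats.kurtosis(fd, fisher=False, bias=True)
    f[3] = sstats.skew(fd, bias=True)
    f[4] = sstats.skew(sd, bias=True)
    return f


def feature_vector(ev: SpikeEvent, fs: float,
                   reference: np.ndarray) -> np.ndarray:
    """The full 24-dimensional feature vector of one event."""
    fp = locate_fiducials(ev, fs)
    return np.concatenate([
        compute_shape_features(ev, fp, reference),
        compute_phase_features(fp),
        compute_distribution_features(ev),
    ])


@dataclass
class FeatureMatrix:
    """N_events x 24 feature matrix plus per-feature weights."""

    values: np.ndarray
    weights: np.ndarray
    standardized: bool = False
    names: tuple[str, ...] = FEATURE_NAMES

    @property
    def n_events(self) -> int:
        return self.values.shape[0]


def extract_features(events: list[SpikeEvent], fs: float,
                     reference: np.ndarray | None = None) -> FeatureMatrix:
    """Feature matrix for a set of events.

    The F4 reference waveform defaults to the mean FD waveform of the events
    themselves (per-epoch reference); pass a template to pin it instead.
    """
    if not events:
        return FeatureMatrix(values=np.zeros((0, N_FEATURES)),
                             weights=np.ones(N_FEATURES))
    if reference is None:
        reference = np.mean([ev.window_fd for ev in events], axis=0)
    rows = np.array([feature_vector(ev, fs, reference) for ev in events])
    return FeatureMatrix(values=rows, weights=np.ones(N_FEATURES))


def standardize(fm: FeatureMatrix, eps: float = 1e-12) -> FeatureMatrix:
    """Z-score each feature column; near-constant columns are zeroed."""
    x = fm.values
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    z = np.where(sd > eps, (x - mu) / np.where(sd > eps, sd, 1.0), 0.0)
    return FeatureMatrix(values=z, weights=fm.weights.copy(),
                         standardized=True, names=fm.names)


@dataclass
class CollinearityReport:
    mean_abs_r: float
    mean_p: float
    r_matrix: np.ndarray
    columns: np.ndarray                 # indices of testable (non-constant)
    flagged_pairs: list[tuple[int, int, float, float]]


def multicollinearity_test(fm: FeatureMatrix, r_band: float = 0.25,
                           p_thresh: float = 0.05) -> CollinearityReport:
    """Pairwise Pearson correlations across feature columns.

    Pairs whose correlation leaves the [-r_band, r_band] confidence band
    with P < ``p_thresh`` are flagged as collinear.  Constant columns are
    excluded with a warning.
    """
    x = fm.values
    if x.shape[0] < 10:
        raise ValueError("need at least 10 events for the collinearity test")
    sd = x.std(axis=0)
    cols = np.flatnonzero(sd > 1e-12)
    if cols.size < x.shape[1]:
        warnings.warn("constant feature columns excluded from the "
                      "collinearity test")
    r = np.corrcoef(x[:, cols], rowvar=False)
    n = x.shape[0]
    iu = np.triu_indices_from(r, k=1)
    rv = np.clip(r[iu], -0.999999, 0.999999)
    tstat = rv * np.sqrt((n - 2) / (1 - rv ** 2))
    pv = 2 * sstats.t.sf(np.abs(tstat), df=n - 2)
    flagged = [(int(cols[i]), int(cols[j]), float(rr), float(pp))
               for i, j, rr, pp in zip(iu[0], iu[1], rv, pv)
               if abs(rr) > r_band and pp < p_thresh]
    return CollinearityReport(mean_abs_r=float(np.mean(np.abs(rv))),
                              mean_p=float(np.mean(pv)), r_matrix=r,
                              columns=cols, flagged_pairs=flagged)


def optimize_dimensionality(fm: FeatureMatrix, n_electrodes: int,
                            c: float, min_features: int = 3) -> np.ndarray:
    """Greedy feature selection under the weighted dimensionality criterion.

    The criterion (sum(W)/N_f) * (N_e / (N_e + N_f)) < C is evaluated after
    iteratively dropping the lowest-weight feature; surviving indices are
    returned in their original order.  If the criterion cannot be met even
    at ``min_features`` features the highest-weight ``min_features`` are
    returned with a warning.
    """
    if not (0 < c <= 1):
        raise ValueError("C must lie in (0, 1]")
    order = np.argsort(fm.weights, kind="stable")  # ascending weight
    selected = list(range(fm.weights.size))
    drop_iter = iter(order)
    while len(selected) > min_features:
        nf = len(selected)
        lhs = (fm.weights[selected].sum() / nf) * (
            n_electrodes / (n_electrodes + nf))
        if lhs < c:
            return np.array(sorted(selected))
        selected.remove(int(next(drop_iter)))
    nf = len(selected)
    lhs = (fm.weights[selected].sum() / nf) * (
        n_electrodes / (n_electrodes + nf))
    if lhs >= c:
        warnings.warn("dimensionality criterion unsatisfiable; returning "
                      f"the {min_features} highest-weight features")
    return np.array(sorted(selected))


def fisher_weights(fm: FeatureMatrix, labels: np.ndarray) -> np.ndarray:
    """Per-feature Fisher score (between/within variance ratio) from a
    provisional clustering, normalized to [0, 1]."""
    x = fm.values
    overall = x.mean(axis=0)
    between = np.zeros(x.shape[1])
    within = np.zeros(x.shape[1])
    for lab in np.unique(labels):
        grp = x[labels == lab]
        between += grp.shape[0] * (grp.mean(axis=0) - overall) ** 2
        within += grp.shape[0] * grp.var(axis=0)
    score = between / np.where(within > 0, within, np.inf)
    top = score.max()
    return score / top if top > 0 else np.ones_like(score)
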