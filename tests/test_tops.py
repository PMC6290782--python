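"""Fundamental minima, artificial overlaps, phase distance and assignment."""

import numpy as np
import pytest

from conftest import cluster_templates
from ktops.config import TopsConfig
from ktops.preprocess import DerivedRecording, differentiate
from ktops.simulate import make_templates
from ktops.tops import (ArtificialOverlap, OverlapBank, assign_overlaps,
                        extract_segments, find_fundamental_minima,
                        generate_artificial_overlaps, make_candidate,
                        phase_distance)

FS = 44000.0


def _derived(v):
    fd, sd = differentiate(v)
    return DerivedRecording(v, fd, sd, FS, (450, 2600))


def _superposed_trace(specs, ids, trough_shifts, n=None, pad=60):
    """Trace with templates placed so their troughs sit at the given
    sample shifts (relative to the trace midpoint)."""
    n = n or int(0.2 * FS)
    v = np.zeros(n)
    t0 = n // 2
    for cid, s in zip(ids, trough_shifts):
        w = specs[cid].waveform
        st = t0 + s - int(np.argmin(w)) + pad
        v[st:st + w.size] += w
    return v


class TestFundamentalMinima:
    def test_clean_template_has_one_supra_minimum(self):
        specs = make_templates(FS)
        for spec in specs:
            v = _superposed_trace(specs, [specs.index(spec)], [0])
            der = _derived(v)
            mins = find_fundamental_minima(der.filtered, der.fd, der.sd,
                                           thr_fd=0.02, thr_v=0.2)
            assert sum(m.supra_threshold for m in mins) == 1

    def test_two_shifted_templates_two_minima(self):
        specs = make_templates(FS)
        v = _superposed_trace(specs, [0, 2], [0, 44])   # 1 ms apart
        der = _derived(v)
        mins = find_fundamental_minima(der.filtered, der.fd, der.sd,
                                       thr_fd=0.02, thr_v=0.2)
        assert sum(m.supra_threshold for m in mins) == 2

    def test_positive_half_sine_no_minima(self):
        t = np.linspace(0, np.pi, 200)
        v = np.sin(t)
        fd, sd = differentiate(v)
        mins = find_fundamental_minima(v, fd, sd, thr_fd=0.0)
        assert mins == []

    def test_minimum_criterion_fd_zero_sd_positive(self):
        v = np.cos(np.linspace(0, 4 * np.pi, 400))  # minima where sd > 0
        fd, sd = differentiate(v)
        mins = find_fundamental_minima(v, fd, sd, thr_fd=0.0)
        for m in mins:
            assert sd[m.index] > 0 or sd[max(0, m.index - 1)] > 0
            assert v[m.index] == pytest.approx(-1.0, abs=1e-3)


class TestSegments:
    def test_isolated_template_single_segment(self):
        specs = make_templates(FS)
        v = _superposed_trace(specs, [0], [0])
        der = _derived(v)
        peak = int(np.argmin(der.fd))
        lo, hi = peak - 80, peak + 80
        mins = find_fundamental_minima(der.filtered[lo:hi], der.fd[lo:hi],
                                       der.sd[lo:hi], thr_fd=0.02, thr_v=0.2)
        supra = [m for m in mins if m.supra_threshold]
        segs = extract_segments(der.fd[lo:hi], der.sd[lo:hi], supra)
        assert len(segs) == 1
        assert segs[0].lo <= supra[0].index <= segs[0].hi

    def test_two_minima_disjoint_at_midpoint(self):
        specs = make_templates(FS)
        v = _superposed_trace(specs, [0, 2], [0, 60])
        der = _derived(v)
        peak = int(np.argmin(der.fd))
        lo, hi = peak - 100, peak + 160
        mins = [m for m in find_fundamental_minima(
            der.filtered[lo:hi], der.fd[lo:hi], der.sd[lo:hi],
            thr_fd=0.02, thr_v=0.2) if m.supra_threshold]
        segs = extract_segments(der.fd[lo:hi], der.sd[lo:hi], mins)
        assert len(segs) == 2
        assert segs[0].hi <= segs[1].lo + 1

    def test_clean_segment_matches_own_trajectory(self):
        tmpl = cluster_templates(FS)[0]
        d = phase_distance(tmpl.template_fd, tmpl.template_sd,
                           tmpl.template_fd, tmpl.template_sd)
        assert d == pytest.approx(0.0, abs=1e-12)


class TestArtificialOverlaps:
    def test_pair_combinatorics(self):
        tmpls = cluster_templates(FS)
        shifts = np.array([-4, -2, 0, 2, 4])
        out = generate_artificial_overlaps(tmpls, shifts, order=2)
        assert len(out) == 3 * 5        # 3 unordered pairs x 5 shifts

    def test_zero_shift_identical_templates_doubles(self):
        t = cluster_templates(FS)[0]
        from ktops.clustering import ClusterTemplate
        twin = ClusterTemplate(cluster_id=99, template_fd=t.template_fd,
                               template_sd=t.template_sd, n_members=5,
                               is_outlier=False)
        out = generate_artificial_overlaps([t, twin], np.array([0]), order=2)
        assert len(out) == 1
        assert np.allclose(out[0].waveform_fd, 2 * t.template_fd)

    def test_single_template_warns_empty(self):
        t = cluster_templates(FS)[0]
        with pytest.warns(UserWarning):
            out = generate_artificial_overlaps([t], np.array([0]), order=2)
        assert out == []

    def test_grid_closure_contains_true_composition(self):
        tmpls = cluster_templates(FS)
        shifts = np.arange(-88, 89, 2)
        out = generate_artificial_overlaps(tmpls, shifts, order=2)
        comps = {tuple(o.composition) for o in out}
        assert ((0, 0), (2, 34)) in comps
        assert ((1, 0), (2, -62)) in comps


class TestPhaseDistance:
    def test_identity_and_nonnegativity(self):
        t = cluster_templates(FS)[1]
        assert phase_distance(t.template_fd, t.template_sd,
                              t.template_fd, t.template_sd) == 0.0

    def test_monotone_in_amplitude_scale(self):
        t = cluster_templates(FS)[2]
        prev = 0.0
        for c in (1.0, 1.2, 1.5, 2.0):
            d = phase_distance(c * t.template_fd, c * t.template_sd,
                               t.template_fd, t.template_sd)
            assert d >= prev - 1e-12
            prev = d
        assert prev > 0

    def test_identifies_own_template_under_noise(self):
        # argmin over templates for a noisy copy is the source template
        tmpls = cluster_templates(FS)
        rng = np.random.default_rng(12)
        hits = 0
        trials = 40
        for _ in range(trials):
            src = rng.integers(3)
            t = tmpls[src]
            noise = 0.1 * np.abs(t.template_fd).max()
            seg_fd = t.template_fd + noise * rng.standard_normal(
                t.template_fd.size)
            seg_sd = t.template_sd + noise * rng.standard_normal(
                t.template_sd.size)
            d = [phase_distance(seg_fd, seg_sd, u.template_fd, u.template_sd)
                 for u in tmpls]
            hits += int(np.argmin(d) == src)
        assert hits / trials >= 0.95

    def test_degenerate_trajectory_infinite(self):
        t = cluster_templates(FS)[0]
        d = phase_distance(np.zeros(16), np.zeros(16),
                           np.zeros(16), np.zeros(16))
        assert np.isinf(d)


class TestAssignment:
    def _setup(self):
        specs = make_templates(FS)
        tmpls = cluster_templates(FS)
        return specs, tmpls, TopsConfig()

    def test_exact_pair_recovered_with_high_r(self):
        specs, tmpls, cfg = self._setup()
        v = _superposed_trace(specs, [0, 1], [0, 40])
        der = _derived(v)
        cand = make_candidate(der, [int(np.argmin(der.fd))], cfg, "group")
        res = assign_overlaps([cand], tmpls, der, thr=0.02, thr_v=0.1,
                              cfg=cfg)[0]
        assert sorted(c for c, _ in res.composition) == [0, 1]
        assert res.match_r > 0.98

    def test_noise_free_closure_over_random_compositions(self):
        specs, tmpls, cfg = self._setup()
        rng = np.random.default_rng(3)
        ok = 0
        trials = 24
        for trial in range(trials):
            order = 2 if trial % 2 == 0 else 3
            ids = sorted(rng.choice(3, size=order, replace=False))
            while True:
                sh = [0] + [int(s) for s in
                            rng.integers(-44, 45, size=order - 1) * 2]
                if max(sh) - min(sh) <= 88:
                    break
            v = _superposed_trace(specs, ids, sh)
            der = _derived(v)
            cand = make_candidate(der, [int(np.argmin(der.fd))], cfg,
                                  "group")
            res = assign_overlaps([cand], tmpls, der, thr=0.02, thr_v=0.1,
                                  cfg=cfg)[0]
            got = sorted(c for c, _ in res.composition)
            want = [int(i) for i in ids]
            if got == want or (res.quasi_simultaneous
                               and set(want) <= set(got)):
                ok += 1
        assert ok / trials >= 0.9

    def test_quasi_simultaneous_assigned_to_all_clusters(self):
        specs, tmpls, cfg = self._setup()
        # sum of all three templates at identical trough positions: one
        # minimum, anomalously large amplitude
        v = _superposed_trace(specs, [0, 1, 2], [0, 0, 0])
        der = _derived(v)
        cand = make_candidate(der, [int(np.argmin(der.fd))], cfg,
                              "amplitude")
        res = assign_overlaps([cand], tmpls, der, thr=0.02, thr_v=0.1,
                              cfg=cfg)[0]
        got = sorted(c for c, _ in res.assignments)
        assert set(got) == {0, 1, 2}

    def test_clean_single_assigned_to_own_cluster(self):
        specs, tmpls, cfg = self._setup()
        for src in range(3):
            v = _superposed_trace(specs, [src], [0])
            der = _derived(v)
            cand = make_candidate(der, [int(np.argmin(der.fd))], cfg,
                                  "atypical")
            res = assign_overlaps([cand], tmpls, der, thr=0.02, thr_v=0.1,
                                  cfg=cfg)[0]
            assert [c for c, _ in res.assignments] == [src]
            assert res.match_r > 0.99
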