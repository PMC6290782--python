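"""Shared fixtures: analytic events, templates and a small synthetic set."""

from __future__ import annotations

import numpy as np
import pytest

from ktops.clustering import ClusterTemplate
from ktops.config import SimConfig
from ktops.preprocess import SpikeEvent, differentiate
from ktops.simulate import make_templates, simulate


FS = 40000.0
T_MS = 1.0  # period of the canonical sine event


@pytest.fixture()
def sine_event() -> SpikeEvent:
    """Canonical event whose FD is -sin(2*pi*t/T) on [0, 1.5T].

    Analytic fiducials: P1=0, P2=T/4, P3=T/2, P4=3T/4, P5=T, P6=5T/4.
    """
    n_period = int(round(T_MS * 1e-3 * FS))
    t = np.arange(int(1.5 * n_period) + 1)
    fd = -np.sin(2 * np.pi * t / n_period)
    sd = np.gradient(fd)
    pre = n_period // 4
    return SpikeEvent(peak_index=pre, window_fd=fd, window_sd=sd,
                      pre_samples=pre, post_samples=fd.size - pre - 1,
                      thr_at_detection=0.5)


@pytest.fixture(scope="session")
def templates44():
    return make_templates(44000.0)


def template_event(tmpl, fs: float, pre_ms: float = 0.6,
                   post_ms: float = 1.6) -> SpikeEvent:
    """Noise-free SpikeEvent built from a simulator template."""
    pre = int(round(pre_ms * 1e-3 * fs))
    post = int(round(post_ms * 1e-3 * fs))
    buf = np.zeros(tmpl.waveform.size + 2 * (pre + post))
    buf[pre + post:pre + post + tmpl.waveform.size] = tmpl.waveform
    fd, sd = differentiate(buf)
    peak = int(np.argmin(fd))
    return SpikeEvent(peak_index=peak,
                      window_fd=fd[peak - pre:peak + post + 1],
                      window_sd=sd[peak - pre:peak + post + 1],
                      pre_samples=pre, post_samples=post,
                      thr_at_detection=0.0)


def cluster_templates(fs: float = 44000.0) -> list[ClusterTemplate]:
    """Noise-free single-unit cluster templates from the generator shapes."""
    out = []
    for i, tmpl in enumerate(make_templates(fs)):
        ev = template_event(tmpl, fs)
        out.append(ClusterTemplate(cluster_id=i, template_fd=ev.window_fd,
                                   template_sd=ev.window_sd, n_members=10,
                                   is_outlier=False))
    return out


@pytest.fixture(scope="session")
def small_dataset():
    """A short (12 s) synthetic recording with ground truth."""
    cfg = SimConfig(duration_s=12.0, instances_per_template=50,
                    n_overlaps_pair=4, n_overlaps_triple=2, seed=7)
    return simulate(cfg)
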