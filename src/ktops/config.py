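"""Configuration objects for the sorting pipeline.

Every stage of the pipeline is parameterized through a small frozen-ish
dataclass; :class:`PipelineConfig` aggregates them and round-trips to YAML.
Unknown keys are rejected on load so that a typo in a config file fails
loudly instead of silently falling back to a default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml


class ConfigError(ValueError):
    """Raised when a configuration value or key is invalid."""


@dataclass
class SimConfig:
    """Synthetic-recording generator settings.

    Defaults reproduce the validation protocol used throughout the test
    suite: a 180 s single-channel trace at 44 kHz containing 2700 instances
    of each of three templates (three units firing at ~15 spikes/s each)
    plus 45 two-template and 36 three-template overlapping waveforms with
    pairwise peak delays below 2 ms, at an overall SNR of 3.55 dB.
    """

    fs: float = 44000.0
    duration_s: float = 180.0
    instances_per_template: int = 2700
    n_overlaps_pair: int = 45
    n_overlaps_triple: int = 36
    max_overlap_delay_ms: float = 2.0
    snr_db: float = 3.55
    noise_band: tuple[float, float] = (450.0, 2600.0)
    min_separation_ms: float = 2.5
    edge_margin_s: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        if self.fs <= 0:
            raise ConfigError("fs must be positive")
        if self.duration_s <= 0:
            raise ConfigError("duration_s must be positive")
        if min(self.instances_per_template, self.n_overlaps_pair,
               self.n_overlaps_triple) < 0:
            raise ConfigError("event counts must be non-negative")
        if self.max_overlap_delay_ms <= 0:
            raise ConfigError("max_overlap_delay_ms must be positive")
        lo, hi = self.noise_band
        if not (0 < lo < hi < self.fs / 2):
            raise ConfigError("noise_band must satisfy 0 < low < high < fs/2")


@dataclass
class PreprocessConfig:
    """Filtering, derivative-threshold detection and alignment settings.

    ``band`` is the analysis band in Hz (450-2600 Hz for the synthetic
    benchmark; 450-2050 Hz is the typical choice for 25 kHz cortical
    recordings).  ``q`` multiplies the MAD-based noise estimate of the first
    derivative; conventional values lie between 3 and 5.
    """

    band: tuple[float, float] = (450.0, 2600.0)
    q: float = 4.0
    sign: str = "negative"  # negative | positive | both
    dead_time_ms: float = 0.5
    pre_ms: float = 0.6
    post_ms: float = 1.6
    artifact_z: float = 3.29

    def validate(self) -> None:
        if not (3.0 <= self.q <= 5.0):
            raise ConfigError("q must lie in [3, 5]")
        if self.sign not in ("negative", "positive", "both"):
            raise ConfigError("sign must be negative|positive|both")
        if self.dead_time_ms <= 0:
            raise ConfigError("dead_time_ms must be positive")
        if self.pre_ms <= 0 or self.post_ms <= 0:
            raise ConfigError("window extents must be positive")


@dataclass
class ClusterConfig:
    """K-means sweep and validity-index settings."""

    kmeans_distances: tuple[str, ...] = (
        "sqeuclidean", "cityblock", "cosine", "correlation")
    validation_metrics: tuple[str, ...] = (
        "sqeuclidean", "euclidean", "cityblock", "cosine", "correlation",
        "hamming", "jaccard")
    k_min: int = 2
    k_max: int = 10
    replicates: int = 10
    max_iter: int = 100
    cd_weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    # validity indices are evaluated on a random subsample of events for
    # tractability; the K-means fit itself always uses every event
    validation_subsample: int = 1500
    outlier_frac: float = 0.02
    # min-max normalization domain for the CD probabilities: raw index
    # values are only commensurate among cells sharing a validation metric,
    # so "per-metric" is the default; "global" (all cells) and "per-combo"
    # are available
    normalization: str = "per-metric"
    # how the winning clustering is chosen from the scored cells: by the
    # partition whose CD averaged over validation metrics is largest
    # ("partition-mean", robust) or by the single best cell ("cell")
    selection: str = "partition-mean"
    # feature weight function W(f): "fisher" re-weights each feature by its
    # between/within-cluster variance ratio from a provisional clustering
    # (K = provisional_k) before the sweep, then refines the weights from
    # the selected clustering; "none" keeps all weights at 1
    weighting: str = "fisher"
    provisional_k: int = 3
    # robust-z threshold for routing within-cluster atypical events (low
    # own-template correlation or anomalous amplitude) to the overlap pool
    reroute_z: float = 3.29

    def validate(self) -> None:
        if self.k_min < 2:
            raise ConfigError("k_min must be >= 2")
        if self.k_max < self.k_min:
            raise ConfigError("k_max must be >= k_min")
        if abs(sum(self.cd_weights) - 1.0) > 1e-9:
            raise ConfigError("cd_weights must sum to 1")
        if self.normalization not in ("global", "per-metric", "per-combo"):
            raise ConfigError(
                "normalization must be global|per-metric|per-combo")
        if self.weighting not in ("fisher", "none"):
            raise ConfigError("weighting must be fisher|none")
        if self.selection not in ("partition-mean", "cell"):
            raise ConfigError("selection must be partition-mean|cell")


@dataclass
class TopsConfig:
    """Phase-space overlap-decomposition settings."""

    max_shift_ms: float = 2.0
    shift_step: int = 2              # samples, grid spacing of trial shifts
    closure_eps: float = 0.05        # fraction of trajectory diameter
    n_theta_bins: int = 360
    contribution_min: float = 0.10   # min energy share of an assigned part
    r_min: float = 0.5               # reject matches below this Pearson r
    pair_good_r: float = 0.95        # skip triples if a pair matches this well
    order_margin: float = 0.05       # extra r a richer composition must add
    triple_margin: float = 0.01      # extra r a triple must add over a pair
    # a single-minimum waveform is decomposed as a pair only on strong
    # evidence: the pair correlation must exceed the best single template's
    # by this gain (merged troughs make the minima count unreliable)
    single_pair_gain: float = 0.10
    wide_pre_ms: float = 3.2
    wide_post_ms: float = 3.2
    group_gap_ms: float = 2.2        # detections closer than this are grouped
    quasi_amp_ratio: float = 1.3     # amplitude ratio flagging merged overlaps
    # a supra-threshold minimum must reach this fraction of the deepest
    # trough in its window (rejects band-pass filter side-lobes)
    min_rel_depth: float = 0.3

    def validate(self) -> None:
        if self.max_shift_ms <= 0 or self.shift_step < 1:
            raise ConfigError("invalid TOPS shift grid")
        if not (0 < self.contribution_min < 1):
            raise ConfigError("contribution_min must be in (0, 1)")


@dataclass
class EvalConfig:
    """Ground-truth scoring settings."""

    time_tol_ms: float = 0.5
    delta: float = 0.95   # expected own-template correlation (correlation form)

    def validate(self) -> None:
        if self.time_tol_ms <= 0:
            raise ConfigError("time_tol_ms must be positive")
        if not (0 < self.delta <= 1):
            raise ConfigError("delta must be in (0, 1]")


@dataclass
class PipelineConfig:
    """Aggregate configuration for a full sorting run."""

    sim: SimConfig = field(default_factory=SimConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    tops: TopsConfig = field(default_factory=TopsConfig)
    evaluate: EvalConfig = field(default_factory=EvalConfig)
    seed: int = 0

    def validate(self) -> None:
        for sub in (self.sim, self.preprocess, self.cluster, self.tops,
                    self.evaluate):
            sub.validate()

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_tuples_to_lists(self.to_dict()), fh,
                           sort_keys=False)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        cfg = cls()
        _apply(cfg, data, path="")
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


def _tuples_to_lists(obj):
    if isinstance(obj, dict):
        return {k: _tuples_to_lists(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_tuples_to_lists(v) for v in obj]
    return obj


def _apply(obj, data: dict[str, Any], path: str) -> None:
    fields = {f.name: f for f in dataclasses.fields(obj)}
    for key, value in data.items():
        where = f"{path}{key}"
        if key not in fields:
            raise ConfigError(f"unknown configuration key: {where}")
        current = getattr(obj, key)
        if dataclasses.is_dataclass(current):
            if not isinstance(value, dict):
                raise ConfigError(f"{where} must be a mapping")
            _apply(current, value, path=where + ".")
        else:
            if isinstance(current, tuple) and isinstance(value, list):
                value = tuple(tuple(v) if isinstance(v, list) else v
                              for v in value)
            setattr(obj, key, value)
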