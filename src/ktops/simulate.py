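"""Ground-truth synthetic extracellular recording generator.

The generator emulates a single-channel extracellular recording containing
three known units firing independently on top of band-limited Gaussian
background noise.  Templates are parametric sums of Gaussian lobes: two
triphasic shapes (T1, T2) with comparable peak amplitudes but different
widths, and one biphasic shape (T3).  Single-unit instances are placed
uniformly at random with a minimum peak separation so that no two
single-unit spikes overlap; a configured number of two- and three-template
superpositions (pairwise peak delays below 2 ms) is then injected at
positions clear of the single-unit events.  Noise is scaled so that the
trace-level SNR -- 10*log10 of the mean power of the injected spike
component over the noise variance -- equals the configured value.

Every placement decision flows from one :class:`numpy.random.Generator`,
so a (config, seed) pair regenerates the identical dataset byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import signal as sps

from .config import SimConfig
from .preprocess import design_bandpass


class SimulationError(RuntimeError):
    pass


#: Default lobe parameterization: (amplitude rel. trough, center ms, sigma ms).
#: Times are relative to the time-domain trough.  T1/T2 are triphasic with
#: comparable peak amplitudes and distinct widths; T3 is biphasic.
DEFAULT_TEMPLATE_LOBES: dict[str, tuple[float, list[tuple[float, float, float]]]] = {
    "T1": (1.00, [(+0.50, -0.18, 0.055), (-1.00, 0.00, 0.07),
                  (+0.35, +0.20, 0.10)]),
    "T2": (0.92, [(+0.15, -0.32, 0.11), (-1.00, 0.00, 0.13),
                  (+0.75, +0.45, 0.22)]),
    "T3": (0.85, [(+0.85, -0.28, 0.13), (-1.00, 0.00, 0.10)]),
}


@dataclass
class TemplateSpec:
    template_id: str
    phases: str                  # "triphasic" | "biphasic"
    peak_amp: float              # mV, magnitude of the trough
    width_ms: float              # support where |v| > 1% of peak
    waveform: np.ndarray         # sampled voltage trace (mV)
    trough_offset: int = 0       # sample index of the trough within waveform


@dataclass
class GroundTruthEvent:
    time_s: float                                  # reference (first) peak
    kind: str                                      # single | overlap2 | overlap3
    composition: list[tuple[str, float]]           # (template_id, peak time s)


@dataclass
class SimulatedDataset:
    trace: np.ndarray
    fs: float
    truth: list[GroundTruthEvent]
    templates: list[TemplateSpec]
    config: SimConfig
    noise_sigma: float = 0.0
    clean: np.ndarray | None = field(default=None, repr=False)


def make_templates(fs: float, specs=None) -> list[TemplateSpec]:
    """Build the parametric spike templates sampled at ``fs``.

    Each template is a sum of Gaussian lobes normalized so that its trough
    magnitude equals ``peak_amp``.  Durations must fall inside the
    physiological 0.4-2.2 ms range.
    """
    if specs is None:
        specs = DEFAULT_TEMPLATE_LOBES
    out: list[TemplateSpec] = []
    for tid, (peak, lobes) in specs.items():
        t_min = min(c - 4 * s for _, c, s in lobes)
        t_max = max(c + 4 * s for _, c, s in lobes)
        t = np.arange(np.floor(t_min * 1e-3 * fs),
                      np.ceil(t_max * 1e-3 * fs) + 1) / fs * 1e3  # ms
        v = np.zeros_like(t)
        for a, c, s in lobes:
            v += a * np.exp(-0.5 * ((t - c) / s) ** 2)
        v *= peak / np.abs(v.min())
        support = np.flatnonzero(np.abs(v) > 0.01 * peak)
        width_ms = (support[-1] - support[0]) / fs * 1e3
        if not (0.4 <= width_ms <= 2.2):
            raise SimulationError(
                f"template {tid}: duration {width_ms:.2f} ms outside 0.4-2.2 ms")
        n_lobes = sum(1 for a, _, _ in lobes)
        out.append(TemplateSpec(
            template_id=tid,
            phases="triphasic" if n_lobes >= 3 else "biphasic",
            peak_amp=peak, width_ms=width_ms, waveform=v,
            trough_offset=int(np.argmin(v))))
    # distinguishability guard
    for i in range(len(out)):
        for j in range(i + 1, len(out)):
            r = _padded_corr(out[i].waveform, out[j].waveform)
            if r >= 0.95:
                raise SimulationError(
                    f"templates {out[i].template_id}/{out[j].template_id} "
                    f"too similar (r={r:.3f})")
    return out


def _padded_corr(a: np.ndarray, b: np.ndarray) -> float:
    n = max(a.size, b.size)
    aa = np.zeros(n)
    bb = np.zeros(n)
    aa[:a.size] = a
    bb[:b.size] = b
    return float(np.corrcoef(aa, bb)[0, 1])


def make_noise(fs: float, duration_s: float, band: tuple[float, float],
               rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to ``band``."""
    n = int(round(duration_s * fs))
    white = rng.standard_normal(n)
    taps = design_bandpass(fs, band)
    x = sps.filtfilt(taps, [1.0], white)
    return x / x.std()


def _place_times(rng: np.random.Generator, n_needed: int, fs: float,
                 duration_s: float, min_sep_s: float, margin_s: float
                 ) -> np.ndarray:
    """Draw ``n_needed`` event times with pairwise separation >= min_sep_s."""
    lo, hi = margin_s, duration_s - margin_s
    for _ in range(50):
        cand = np.sort(rng.uniform(lo, hi, size=int(n_needed * 2.5) + 32))
        keep = [cand[0]]
        for t in cand[1:]:
            if t - keep[-1] >= min_sep_s:
                keep.append(t)
        if len(keep) >= n_needed:
            sel = rng.choice(len(keep), size=n_needed, replace=False)
            return np.asarray(keep)[np.sort(sel)]
    raise SimulationError("could not place events at the required separation")


def inject_events(noise: np.ndarray, templates: list[TemplateSpec],
                  cfg: SimConfig, rng: np.random.Generator
                  ) -> SimulatedDataset:
    """Place single-unit spikes and overlap superpositions into the noise.

    Returns the noisy trace together with the ground truth.  The clean spike
    component is kept on the dataset for diagnostics and SNR verification.
    """
    fs = cfg.fs
    n = noise.size
    by_id = {t.template_id: t for t in templates}
    ids = [t.template_id for t in templates]

    n_single = cfg.instances_per_template * len(templates)
    n_over = cfg.n_overlaps_pair + cfg.n_overlaps_triple
    times = _place_times(rng, n_single + n_over, fs, cfg.duration_s,
                         cfg.min_separation_ms * 1e-3 +
                         cfg.max_overlap_delay_ms * 1e-3,
                         cfg.edge_margin_s)
    # random split of slots into single / overlap roles
    roles = np.zeros(times.size, dtype=int)
    roles[rng.choice(times.size, size=n_over, replace=False)] = 1

    single_ids = np.repeat(np.arange(len(templates)),
                           cfg.instances_per_template)
    rng.shuffle(single_ids)

    pair_combos = [(a, b) for i, a in enumerate(ids) for b in ids[i + 1:]]
    comp_plan: list[tuple[str, ...]] = []
    for k in range(cfg.n_overlaps_pair):
        comp_plan.append(pair_combos[k % len(pair_combos)])
    comp_plan += [tuple(ids)] * cfg.n_overlaps_triple
    rng.shuffle(comp_plan)

    clean = np.zeros(n)
    truth: list[GroundTruthEvent] = []
    i_single = 0
    i_over = 0
    max_delay = cfg.max_overlap_delay_ms * 1e-3
    for t0, role in zip(times, roles):
        if role == 0:
            tmpl = templates[single_ids[i_single]]
            i_single += 1
            peak = _add_template(clean, tmpl, t0, fs)
            truth.append(GroundTruthEvent(
                time_s=peak, kind="single",
                composition=[(tmpl.template_id, peak)]))
        else:
            comp = comp_plan[i_over]
            i_over += 1
            delays = np.concatenate(([0.0],
                                     rng.uniform(0.0, max_delay,
                                                 size=len(comp) - 1)))
            entries = []
            for tid, d in zip(comp, delays):
                peak = _add_template(clean, by_id[tid], t0 + d, fs)
                entries.append((tid, peak))
            truth.append(GroundTruthEvent(
                time_s=entries[0][1],
                kind=f"overlap{len(comp)}",
                composition=entries))
    truth.sort(key=lambda e: e.time_s)

    # SNR calibration: mean power of the spike component over the whole
    # trace, relative to noise variance
    p_signal = float(np.mean(clean ** 2))
    sigma = np.sqrt(p_signal / 10 ** (cfg.snr_db / 10))
    trace = clean + sigma * noise
    return SimulatedDataset(trace=trace, fs=fs, truth=truth,
                            templates=templates, config=cfg,
                            noise_sigma=sigma, clean=clean)


def _add_template(clean: np.ndarray, tmpl: TemplateSpec, t_trough: float,
                  fs: float) -> float:
    """Add a template so its trough lands at ``t_trough``; returns the
    realized trough time in seconds (after rounding to the sample grid)."""
    trough_idx = int(round(t_trough * fs))
    start = trough_idx - tmpl.trough_offset
    stop = start + tmpl.waveform.size
    if start < 0 or stop > clean.size:
        raise SimulationError("template placement outside the trace")
    clean[start:stop] += tmpl.waveform
    return trough_idx / fs


def simulate(cfg: SimConfig | None = None,
             seed: int | None = None) -> SimulatedDataset:
    """Generate a complete synthetic dataset from a config and seed."""
    cfg = cfg or SimConfig()
    cfg.validate()
    if seed is not None:
        cfg.seed = int(seed)
    rng = np.random.default_rng(cfg.seed)
    templates = make_templates(cfg.fs)
    noise = make_noise(cfg.fs, cfg.duration_s, cfg.noise_band, rng)
    return inject_events(noise, templates, cfg, rng)


def measured_snr_db(ds: SimulatedDataset) -> float:
    """Post-hoc SNR of an emitted dataset (requires the clean component)."""
    if ds.clean is None:
        raise SimulationError("clean spike component not retained")
    return float(10 * np.log10(np.mean(ds.clean ** 2) / ds.noise_sigma ** 2))


# -- persistence -----------------------------------------------------------

def truth_to_frame(truth: list[GroundTruthEvent]) -> pd.DataFrame:
    rows = []
    for ev in truth:
        comp = ";".join(f"{tid}:{t:.6f}" for tid, t in ev.composition)
        rows.append({"time_s": ev.time_s, "kind": ev.kind,
                     "composition": comp})
    return pd.DataFrame(rows, columns=["time_s", "kind", "composition"])


def truth_from_frame(df: pd.DataFrame) -> list[GroundTruthEvent]:
    out = []
    for _, row in df.iterrows():
        comp = []
        for part in str(row["composition"]).split(";"):
            tid, t = part.split(":")
            comp.append((tid, float(t)))
        out.append(GroundTruthEvent(time_s=float(row["time_s"]),
                                    kind=str(row["kind"]), composition=comp))
    return out


def emit_dataset(ds: SimulatedDataset, out_dir) -> dict[str, Path]:
    """Write recording (.f32 + .json sidecar), ground-truth CSV and the
    config snapshot (YAML, including the seed) to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rec_path = out / "recording.f32"
    ds.trace.astype("<f4").tofile(rec_path)
    sidecar = {"fs_hz": float(ds.fs), "units": "mV",
               "n_samples": int(ds.trace.size)}
    json_path = out / "recording.json"
    json_path.write_text(json.dumps(sidecar, indent=2))
    truth_path = out / "truth.csv"
    truth_to_frame(ds.truth).to_csv(truth_path, index=False)
    cfg_path = out / "config.yaml"
    snapshot = {"sim": _plain(ds.config.__dict__),
                "snr_definition": ("10*log10(mean power of injected spike "
                                   "component over noise variance)")}
    cfg_path.write_text(yaml.safe_dump(snapshot, sort_keys=False))
    return {"recording": rec_path, "sidecar": json_path,
            "truth": truth_path, "config": cfg_path}


def _plain(d: dict) -> dict:
    return {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}
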