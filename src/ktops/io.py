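"""Readers and writers for the pipeline's file formats.

Recordings travel as raw little-endian float32 samples plus a JSON sidecar
(``{"fs_hz": ..., "units": "mV", "n_samples": ...}``), or as a single-column
CSV with the sampling rate supplied separately; a single-channel WAV reader
is included for convenience.  All emitted tables use 0-based sample indices
and seconds.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .pipeline import SortResult
from .preprocess import Recording
from .validation import SortingScore


def read_recording(path, fs: float | None = None,
                   label: str = "") -> Recording:
    """Read a recording from .f32+sidecar, .csv or .wav."""
    path = Path(path)
    if path.suffix == ".f32":
        sidecar = path.with_suffix(".json")
        meta = json.loads(sidecar.read_text())
        samples = np.fromfile(path, dtype="<f4").astype(float)
        if meta.get("n_samples") not in (None, samples.size):
            raise ValueError(f"{path}: n_samples mismatch with sidecar")
        return Recording(samples=samples, fs=float(meta["fs_hz"]),
                         label=label or path.stem)
    if path.suffix == ".csv":
        if fs is None:
            raise ValueError("sampling rate required for CSV input")
        samples = pd.read_csv(path, header=None).iloc[:, 0].to_numpy(float)
        return Recording(samples=samples, fs=fs, label=label or path.stem)
    if path.suffix == ".wav":
        from scipy.io import wavfile
        rate, data = wavfile.read(path)
        if data.ndim != 1:
            raise ValueError("only single-channel WAV is supported")
        return Recording(samples=data.astype(float), fs=float(rate),
                         label=label or path.stem)
    raise ValueError(f"unsupported recording format: {path.suffix}")


def write_recording(rec: Recording, path) -> None:
    path = Path(path)
    rec.samples.astype("<f4").tofile(path)
    path.with_suffix(".json").write_text(json.dumps(
        {"fs_hz": rec.fs, "units": "mV", "n_samples": int(rec.samples.size)},
        indent=2))


def write_events_csv(result: SortResult, fs: float, path) -> None:
    rows = [{"event_id": i, "peak_index": ev.peak_index,
             "time_s": ev.peak_index / fs, "thr": ev.thr_at_detection}
            for i, ev in enumerate(result.events)]
    pd.DataFrame(rows, columns=["event_id", "peak_index", "time_s",
                                "thr"]).to_csv(path, index=False)


def write_features_csv(result: SortResult, path) -> None:
    df = pd.DataFrame(result.features.values,
                      columns=list(result.features.names))
    df.insert(0, "event_id", result.feature_event_ids)
    df.to_csv(path, index=False)
    Path(path).with_suffix(".weights.json").write_text(json.dumps(
        {n: float(w) for n, w in zip(result.features.names,
                                     result.features.weights)}, indent=2))


def write_sort_outputs(result: SortResult, fs: float, out_dir) -> None:
    """Cluster labels, templates, selection report and overlap report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outlier = {t.cluster_id: t.is_outlier for t in result.templates}
    pd.DataFrame({
        "event_id": result.single_ids,
        "cluster": result.labels,
        "is_outlier": [bool(outlier.get(int(l), False))
                       for l in result.labels],
    }).to_csv(out / "clusters.csv", index=False)
    for t in result.templates:
        pd.DataFrame({"sample_idx": np.arange(t.template_fd.size),
                      "fd": t.template_fd, "sd": t.template_sd}).to_csv(
            out / f"template_{t.cluster_id}.csv", index=False)
    if result.best_cell is not None:
        (out / "selection.json").write_text(json.dumps({
            "distance": result.best_cell.distance,
            "metric": result.best_cell.metric,
            "K": result.best_cell.k,
            "S": result.best_cell.scores.silhouette,
            "DB": result.best_cell.scores.davies_bouldin,
            "D": result.best_cell.scores.dunn,
            "CD": result.best_cell.cd,
        }, indent=2))
    rows = []
    for oa in result.overlap_assignments:
        comp = ";".join(f"{cid}:{shift / fs * 1e3:.3f}"
                        for cid, shift in oa.composition)
        rows.append({
            "event_id": oa.candidate.peak_index,
            "n_minima": oa.n_minima,
            "match_r": oa.match_r,
            "composition": comp,
            "assigned_clusters": ";".join(str(c) for c, _ in oa.assignments),
        })
    pd.DataFrame(rows, columns=["event_id", "n_minima", "match_r",
                                "composition", "assigned_clusters"]).to_csv(
        out / "overlaps.csv", index=False)
    pd.DataFrame({
        "time_s": [a.time_s for a in result.assignments],
        "cluster": [a.cluster for a in result.assignments],
        "source": [a.source for a in result.assignments],
    }).to_csv(out / "assignments.csv", index=False)


def write_score_json(score: SortingScore, path, extra: dict | None = None,
                     ) -> None:
    payload = {
        "n_events": score.n_events,
        "well": score.well, "mis": score.mis,
        "unclassified": score.unclassified,
        "overlap_well": score.overlap_well,
        "single_well": score.single_well,
        "CE": score.ce, "EI": score.ei,
    }
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2))
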