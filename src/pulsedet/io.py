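"""Readers and writers: traces, ground truth, detections, configs.

Conventions: times are 0-based milliseconds from the trace origin with
half-open [start, end) segments; raw sample arrays never embed metadata -
the sampling rate and generation parameters live in a JSON sidecar next to
the array file; ground truth and detections are TSV with a `trace_id`
column so multi-trace datasets can share files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import Detection, ModelConfig
from .simulate import (BaselineModel, NoiseModel, PoreConfig, Segment,
                       SimulationConfig, Trace)
from .train import TrainConfig
from .matching import MatchCostWeights

logger = logging.getLogger(__name__)

MS_DECIMALS = 6


def _sidecar_path(array_path: Path) -> Path:
    return array_path.with_suffix(".json")


def _truth_path(array_path: Path) -> Path:
    return array_path.with_suffix(".gt.tsv")


def write_trace(trace: Trace, path, trace_id: str | None = None) -> Path:
    """Write samples (.npy), metadata sidecar (.json) and ground truth (.gt.tsv)."""
    path = Path(path)
    if path.suffix != ".npy":
        path = path.with_suffix(".npy")
    path.parent.mkdir(parents=True, exist_ok=True)
    np.save(path, trace.samples_pa)
    meta: dict = {"sampling_rate_hz": trace.sampling_rate_hz}
    if dataclasses.is_dataclass(trace.metadata):
        meta["config"] = dataclasses.asdict(trace.metadata)
    elif isinstance(trace.metadata, dict):
        meta["config"] = trace.metadata
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    tid = trace_id or path.stem
    write_segments({tid: trace.ground_truth}, _truth_path(path))
    return path


def read_trace(path, sampling_rate_hz: float | None = None,
               ground_truth_path=None) -> Trace:
    """Read a trace from .npy (+ JSON sidecar) or .csv (time_s, current_pA)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    metadata = None
    if path.suffix == ".csv":
        frame = pd.read_csv(path)
        if not {"time_s", "current_pA"} <= set(frame.columns):
            raise ValueError("CSV needs columns time_s, current_pA")
        t = frame["time_s"].to_numpy(dtype=float)
        samples = frame["current_pA"].to_numpy(dtype=float)
        dt = np.diff(t)
        if dt.size == 0 or dt.min() <= 0 or np.ptp(dt) > 1e-6 * np.median(dt) + 1e-12:
            raise ValueError("CSV time steps must be regular and increasing")
        rate = 1.0 / float(np.median(dt))
    else:
        samples = np.load(path)
        sidecar = _sidecar_path(path)
        rate = sampling_rate_hz
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            rate = rate or meta.get("sampling_rate_hz")
            metadata = meta.get("config")
        if rate is None:
            raise ValueError(f"no sampling rate for {path}: provide a sidecar or flag")
    n_nan = int(np.isnan(samples).sum())
    if n_nan:
        raise ValueError(f"{path} contains {n_nan} NaN samples")
    truth: list[Segment] = []
    truth_path = Path(ground_truth_path) if ground_truth_path else _truth_path(path)
    if truth_path.exists():
        by_trace = read_segments(truth_path)
        if len(by_trace) == 1:
            truth = next(iter(by_trace.values()))
        else:
            truth = by_trace.get(path.stem, [])
    return Trace(samples, float(rate), ground_truth=truth, metadata=metadata)


# ---------------------------------------------------------------------------
# TSV: ground truth and detections
# ---------------------------------------------------------------------------

def write_segments(segments_by_trace: dict[str, list[Segment]], path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as f:
        f.write("trace_id\tstart_ms\tend_ms\n")
        for tid, segments in segments_by_trace.items():
            for seg in sorted(segments, key=lambda s: s.start_ms):
                f.write(f"{tid}\t{seg.start_ms:.{MS_DECIMALS}f}"
                        f"\t{seg.end_ms:.{MS_DECIMALS}f}\n")


def read_segments(path) -> dict[str, list[Segment]]:
    """Parse a ground-truth TSV; malformed rows fail with their line number."""
    out: dict[str, list[Segment]] = {}
    with open(path) as f:
        header = f.readline().rstrip("\n").split("\t")
        try:
            i_tid = header.index("trace_id")
            i_start = header.index("start_ms")
            i_end = header.index("end_ms")
        except ValueError as exc:
            raise ValueError(f"{path}: missing column ({exc})") from None
        for lineno, line in enumerate(f, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            try:
                tid = fields[i_tid]
                start, end = float(fields[i_start]), float(fields[i_end])
            except (IndexError, ValueError):
                raise ValueError(f"{path}:{lineno}: malformed row") from None
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start_ms >= end_ms")
            out.setdefault(tid, []).append(Segment(start, end))
    for segments in out.values():
        segments.sort(key=lambda s: s.start_ms)
    return out


def write_detections(detections_by_trace: dict[str, list[Detection]] | list[Detection],
                     path, trace_id: str = "trace") -> None:
    """TSV: trace_id, start_ms, end_ms, score; sorted by start, scores
    clipped to [0, 1] with a warning."""
    if isinstance(detections_by_trace, list):
        detections_by_trace = {trace_id: detections_by_trace}
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as f:
        f.write("trace_id\tstart_ms\tend_ms\tscore\n")
        for tid, dets in detections_by_trace.items():
            for det in sorted(dets, key=lambda d: d.segment.start_ms):
                score = det.score
                if not 0.0 <= score <= 1.0:
                    logger.warning("clipping out-of-range score %.3f", score)
                    score = min(1.0, max(0.0, score))
                f.write(f"{tid}\t{det.segment.start_ms:.{MS_DECIMALS}f}"
                        f"\t{det.segment.end_ms:.{MS_DECIMALS}f}\t{score:.6f}\n")


def read_detections(path) -> dict[str, list[Detection]]:
    frame = pd.read_csv(path, sep="\t")
    needed = {"trace_id", "start_ms", "end_ms", "score"}
    if not needed <= set(frame.columns):
        raise ValueError(f"{path}: detections TSV needs columns {sorted(needed)}")
    out: dict[str, list[Detection]] = {}
    for row in frame.itertuples(index=False):
        out.setdefault(str(row.trace_id), []).append(
            Detection(Segment(float(row.start_ms), float(row.end_ms)),
                      float(row.score)))
    return out


# ---------------------------------------------------------------------------
# YAML configuration
# ---------------------------------------------------------------------------

_CONFIG_KINDS = {
    "simulation": SimulationConfig,
    "model": ModelConfig,
    "train": TrainConfig,
}


def save_config(config, path) -> None:
    kind = {SimulationConfig: "simulation", ModelConfig: "model",
            TrainConfig: "train"}[type(config)]
    payload = {"kind": kind, **dataclasses.asdict(config)}
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def load_config(path):
    payload = yaml.safe_load(Path(path).read_text())
    kind = payload.pop("kind")
    cls = _CONFIG_KINDS[kind]
    if cls is SimulationConfig:
        if payload.get("pore"):
            payload["pore"] = PoreConfig(**payload["pore"])
        if payload.get("noise"):
            payload["noise"] = NoiseModel(**payload["noise"])
        if payload.get("baseline"):
            payload["baseline"] = BaselineModel(**payload["baseline"])
    elif cls is ModelConfig:
        payload["backbone_blocks"] = tuple(payload["backbone_blocks"])
        payload["backbone_stage_strides"] = tuple(payload["backbone_stage_strides"])
    elif cls is TrainConfig:
        if payload.get("loss_weights"):
            payload["loss_weights"] = MatchCostWeights(**payload["loss_weights"])
    return cls(**payload)
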