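"""Temporal windowing of traces and normalised training targets.

Traces are cut into consecutive, non-overlapping windows (default 0.5 s,
i.e. 5000 samples at 10 kHz).  Each ground-truth pulse is attached to every
window it overlaps, truncated at the window boundary, and expressed in
window-normalised (center, width) coordinates in [0, 1].  Only windows with
at least one pulse are used to train the detector; the separate pulse
counter is trained on all windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import h5py
import numpy as np

from .simulate import Segment, Trace

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_SECONDS = 0.5
SCALE_FLOOR = 1e-6
MAD_TO_SIGMA = 1.4826  # consistent scale factor for Gaussian noise


class InvalidWindowError(ValueError):
    """Requested window does not fit the trace."""


@dataclass
class Window:
    """One fixed-length chunk of a trace with normalised pulse targets.

    `targets` is an (n_pulses, 2) array of (center, width), each pulse
    satisfying c - w/2 >= 0 and c + w/2 <= 1.  `offset`/`scale` record the
    standardisation applied to `samples` so it can be inverted.
    """

    samples: np.ndarray
    origin_ms: float
    sampling_rate_hz: float
    targets: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))
    offset: float = 0.0
    scale: float = 1.0
    degenerate_scale: bool = False

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        self.targets = np.asarray(self.targets, dtype=np.float64).reshape(-1, 2)
        if self.targets.size:
            c, w = self.targets[:, 0], self.targets[:, 1]
            if (w <= 0).any() or (c - w / 2 < -1e-9).any() or (c + w / 2 > 1 + 1e-9).any():
                raise ValueError("normalised targets must lie inside the window")

    @property
    def is_empty(self) -> bool:
        return self.targets.shape[0] == 0

    @property
    def duration_ms(self) -> float:
        return self.samples.size / self.sampling_rate_hz * 1000.0

    def targets_ms(self) -> list[Segment]:
        """Targets mapped back to absolute [start, end) in ms."""
        dur = self.duration_ms
        out = []
        for c, w in self.targets:
            out.append(Segment(self.origin_ms + (c - w / 2) * dur,
                               self.origin_ms + (c + w / 2) * dur))
        return out


def split_windows(trace: Trace, window_seconds: float = DEFAULT_WINDOW_SECONDS) -> list[Window]:
    """Cut a trace into consecutive half-open windows with normalised targets.

    Pulses straddling a boundary appear truncated in every window they
    overlap.  A trailing remainder shorter than one window is dropped.
    """
    win_len = int(round(window_seconds * trace.sampling_rate_hz))
    if win_len <= 0 or win_len > trace.n_samples:
        raise InvalidWindowError(
            f"window of {window_seconds} s does not fit a trace of "
            f"{trace.n_samples} samples")
    n_windows = trace.n_samples // win_len
    if trace.n_samples % win_len:
        logger.info("dropping %d trailing samples not filling a window",
                    trace.n_samples % win_len)
    win_ms = win_len / trace.sampling_rate_hz * 1000.0
    windows = []
    for i in range(n_windows):
        t0 = i * win_ms
        t1 = t0 + win_ms
        targets = []
        for seg in trace.ground_truth:
            if seg.end_ms <= t0 or seg.start_ms >= t1:
                continue
            start = max(seg.start_ms, t0)
            end = min(seg.end_ms, t1)
            if end <= start:
                continue
            c = ((start + end) / 2 - t0) / win_ms
            w = (end - start) / win_ms
            targets.append((c, w))
        windows.append(Window(samples=trace.samples_pa[i * win_len:(i + 1) * win_len],
                              origin_ms=t0,
                              sampling_rate_hz=trace.sampling_rate_hz,
                              targets=np.array(targets).reshape(-1, 2)))
    return windows


def filter_nonempty(windows: list[Window]) -> list[Window]:
    """Keep only windows holding at least one pulse, preserving order."""
    return [w for w in windows if not w.is_empty]


def standardize(window: Window) -> Window:
    """Shift/scale samples to zero median and unit robust (MAD) scale.

    The transform is recorded cumulatively in `offset`/`scale` so the raw
    samples can be recovered; a constant window gets a floored scale and the
    `degenerate_scale` flag.
    """
    median = float(np.median(window.samples))
    mad = float(np.median(np.abs(window.samples - median)))
    scale = MAD_TO_SIGMA * mad
    degenerate = scale < SCALE_FLOOR
    if degenerate:
        logger.warning("near-constant window at %.1f ms: scale floored", window.origin_ms)
        scale = SCALE_FLOOR if np.ptp(window.samples) > 0 else 1.0
    samples = (window.samples - median) / scale
    return replace(window,
                   samples=samples,
                   offset=window.offset + median * window.scale,
                   scale=window.scale * scale,
                   degenerate_scale=window.degenerate_scale or degenerate)


def destandardize(window: Window) -> np.ndarray:
    """Invert :func:`standardize`, recovering the original samples."""
    return window.samples * window.scale + window.offset


# ---------------------------------------------------------------------------
# container I/O
# ---------------------------------------------------------------------------

def save_windows(path, splits: dict[str, list[Window]]) -> None:
    """Write named splits (train/val/test) to one HDF5 container."""
    with h5py.File(path, "w") as f:
        for name, windows in splits.items():
            grp = f.create_group(name)
            if not windows:
                continue
            grp.create_dataset("samples", data=np.stack([w.samples for w in windows]))
            grp.create_dataset("origin_ms", data=np.array([w.origin_ms for w in windows]))
            grp.create_dataset("sampling_rate_hz",
                               data=np.array([w.sampling_rate_hz for w in windows]))
            counts = np.array([w.targets.shape[0] for w in windows])
            grp.create_dataset("target_counts", data=counts)
            flat = (np.concatenate([w.targets for w in windows])
                    if counts.sum() else np.zeros((0, 2)))
            grp.create_dataset("targets", data=flat)


def load_windows(path) -> dict[str, list[Window]]:
    splits: dict[str, list[Window]] = {}
    with h5py.File(path, "r") as f:
        for name, grp in f.items():
            windows: list[Window] = []
            if "samples" in grp:
                samples = grp["samples"][...]
                origins = grp["origin_ms"][...]
                rates = grp["sampling_rate_hz"][...]
                counts = grp["target_counts"][...]
                flat = grp["targets"][...]
                offsets = np.concatenate([[0], np.cumsum(counts)])
                for i in range(samples.shape[0]):
                    windows.append(Window(samples=samples[i],
                                          origin_ms=float(origins[i]),
                                          sampling_rate_hz=float(rates[i]),
                                          targets=flat[offsets[i]:offsets[i + 1]]))
            splits[name] = windows
    return splits
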