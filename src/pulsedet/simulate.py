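"""Synthetic nanopore translocation traces with controlled signal/noise structure.

A solid-state nanopore under bias passes a steady open-pore ionic current;
each analyte translocation transiently blocks part of the pore volume and
produces a downward rectangular current pulse.  A generated trace is the sum
of three parts: the pulse train (low-pass filtered to emulate the analog
bandwidth of the amplifier), stationary background noise with a configurable
power spectrum (white + flicker + dielectric components), and baseline
variations (slow drift plus sporadic jumps).

Amplitudes follow the volume-exclusion resistive-pulse relation: a sphere of
diameter d in a pore of diameter D and effective length L_eff removes a
conducting volume ~ d^3, giving a conductance drop

    dG = G_pore * d^3 / (D^2 * L_eff),      L_eff = thickness + 0.8 * D,

with the open-pore conductance from the standard series combination of
channel and access resistance, G_pore = sigma * [4 L_eff / (pi D^2) + 1/D]^-1.

SNR here is the nanopore-community convention: pulse amplitude divided by the
peak-to-peak background noise, with peak-to-peak operationalised as 6x the
noise rms (the +-3 sigma span of Gaussian noise).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
from scipy import signal

# Bulk conductivity of KCl electrolyte, S/m per mol/L (1.28 S/m at 100 mM).
KCL_CONDUCTIVITY_PER_M = 12.8


class InvalidGeometryError(ValueError):
    """Analyte does not fit through the pore."""


class InfeasibleDensityError(RuntimeError):
    """Event rate too high for non-overlapping placement."""


class DegenerateNoiseModelError(ValueError):
    """Noise model with no positive spectral component."""


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PoreConfig:
    """Pore geometry and electrical operating point."""

    diameter_nm: float = 20.0
    thickness_nm: float = 20.0
    voltage_mv: float = 300.0
    electrolyte_mm: float = 100.0
    surface_charge_c_m2: float = -0.02

    def __post_init__(self):
        for name in ("diameter_nm", "thickness_nm", "voltage_mv", "electrolyte_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class NoiseModel:
    """Mixture weights for the background-noise power spectrum.

    The spectral shape is S(f) = white + pink * (f_ref / f) + dielectric *
    (f / f_ref); `rms_pa` sets the overall root-mean-square amplitude.
    Flicker (1/f) noise dominates at low frequency, dielectric loss rises
    proportionally to f; a reference frequency of 1 kHz makes the weights
    comparable.
    """

    white: float = 1.0
    pink: float = 0.0
    dielectric: float = 0.0
    rms_pa: float = 1.0
    reference_hz: float = 1000.0

    def __post_init__(self):
        if min(self.white, self.pink, self.dielectric) < 0:
            raise ValueError("noise component weights must be >= 0")

    def spectral_shape(self, freqs_hz: np.ndarray) -> np.ndarray:
        shape = np.zeros_like(freqs_hz)
        positive = freqs_hz > 0
        f = freqs_hz[positive]
        shape[positive] = (self.white
                           + self.pink * self.reference_hz / f
                           + self.dielectric * f / self.reference_hz)
        return shape


@dataclass(frozen=True)
class BaselineModel:
    """Slow drift plus sporadic jumps of the open-pore level.

    Zero amplitudes/rates disable the corresponding component.
    """

    drift_rms_pa: float = 0.0
    drift_corner_hz: float = 1.0
    jump_rate_hz: float = 0.0
    jump_rms_pa: float = 0.0

    def __post_init__(self):
        if min(self.drift_rms_pa, self.drift_corner_hz,
               self.jump_rate_hz, self.jump_rms_pa) < 0:
            raise ValueError("baseline rates and amplitudes must be >= 0")


@dataclass(frozen=True)
class Segment:
    """One pulse's [start, end) span in ms from the trace origin."""

    start_ms: float
    end_ms: float

    def __post_init__(self):
        if not self.start_ms < self.end_ms:
            raise ValueError("segment requires start < end")
        if self.start_ms < 0:
            raise ValueError("segment start must be >= 0")

    @property
    def duration_ms(self) -> float:
        return self.end_ms - self.start_ms

    @property
    def midpoint_ms(self) -> float:
        return 0.5 * (self.start_ms + self.end_ms)


@dataclass(frozen=True)
class SimulationConfig:
    pore: PoreConfig = field(default_factory=PoreConfig)
    analyte_diameter_nm: float = 10.0
    analyte_concentration_nm: float = 0.1
    event_duration_ms: float = 5.0
    snr: float = 4.0
    sampling_rate_hz: float = 10_000.0
    trace_length_s: float = 20.0
    noise: NoiseModel | None = field(default_factory=NoiseModel)
    baseline: BaselineModel | None = None  # None -> amplitude-scaled default
    capture_rate_per_nm_s: float = 10.0  # events/s at 1 nM and 300 mV
    analog_bandwidth_hz: float = 2000.0
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.analyte_diameter_nm < self.pore.diameter_nm:
            raise InvalidGeometryError("analyte diameter must be in (0, pore diameter)")
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if self.analyte_concentration_nm < 0:
            raise ValueError("concentration must be >= 0")
        n = self.trace_length_s * self.sampling_rate_hz
        if abs(n - round(n)) > 1e-6:
            raise ValueError("trace_length x sampling_rate must be an integer sample count")

    @property
    def n_samples(self) -> int:
        return int(round(self.trace_length_s * self.sampling_rate_hz))


@dataclass
class Trace:
    """A sampled current record with optional ground-truth pulse segments."""

    samples_pa: np.ndarray
    sampling_rate_hz: float
    ground_truth: list[Segment] = field(default_factory=list)
    metadata: dict | SimulationConfig | None = None

    def __post_init__(self):
        self.samples_pa = np.asarray(self.samples_pa, dtype=np.float64)
        dur = self.duration_ms
        prev_end = 0.0
        for seg in self.ground_truth:
            if seg.start_ms < prev_end - 1e-9 or seg.end_ms > dur + 1e-6:
                raise ValueError("ground-truth segments must be sorted, "
                                 "non-overlapping and inside the trace")
            prev_end = seg.end_ms

    @property
    def n_samples(self) -> int:
        return self.samples_pa.size

    @property
    def duration_ms(self) -> float:
        return self.n_samples / self.sampling_rate_hz * 1000.0


# ---------------------------------------------------------------------------
# physics
# ---------------------------------------------------------------------------

def open_pore_conductance(pore: PoreConfig) -> float:
    """Open-pore conductance in siemens (channel + access resistance)."""
    d_m = pore.diameter_nm * 1e-9
    l_eff = (pore.thickness_nm + 0.8 * pore.diameter_nm) * 1e-9
    sigma = KCL_CONDUCTIVITY_PER_M * pore.electrolyte_mm / 1000.0
    return sigma / (4.0 * l_eff / (np.pi * d_m ** 2) + 1.0 / d_m)


def open_pore_current_pa(pore: PoreConfig) -> float:
    return open_pore_conductance(pore) * pore.voltage_mv * 1e-3 * 1e12


def blockade_amplitude(analyte_diameter_nm: float, pore: PoreConfig) -> float:
    """Current blockage depth (pA) for a spherical analyte, ~ d^3."""
    if not 0 < analyte_diameter_nm < pore.diameter_nm:
        raise InvalidGeometryError(
            f"analyte diameter {analyte_diameter_nm} nm must be in "
            f"(0, {pore.diameter_nm}) nm")
    d_m = analyte_diameter_nm * 1e-9
    pore_d_m = pore.diameter_nm * 1e-9
    l_eff = (pore.thickness_nm + 0.8 * pore.diameter_nm) * 1e-9
    delta_g = open_pore_conductance(pore) * d_m ** 3 / (pore_d_m ** 2 * l_eff)
    return delta_g * pore.voltage_mv * 1e-3 * 1e12


def calibrate_snr(spike_amplitude_pa: float, target_snr: float) -> float:
    """Noise rms (pA) so that peak-to-peak noise (6 rms) = amplitude / SNR."""
    if spike_amplitude_pa <= 0 or target_snr <= 0:
        raise ValueError("amplitude and target SNR must be positive")
    return spike_amplitude_pa / target_snr / 6.0


# ---------------------------------------------------------------------------
# stochastic components
# ---------------------------------------------------------------------------

def sample_events(config: SimulationConfig, rng_seed: int | np.random.SeedSequence) -> list[Segment]:
    """Draw non-overlapping pulse segments from a Poisson capture process.

    The capture rate is k * c, linear in analyte concentration and scaled by
    bias voltage relative to the 300 mV reference.  Draws that would overlap
    an already-placed event are rejected and redrawn.
    """
    rng = np.random.default_rng(rng_seed)
    rate_hz = (config.capture_rate_per_nm_s * config.analyte_concentration_nm
               * config.pore.voltage_mv / 300.0)
    if rate_hz == 0:
        return []
    duration_ms = config.event_duration_ms
    trace_ms = config.trace_length_s * 1000.0
    if duration_ms >= trace_ms:
        raise InfeasibleDensityError("event duration exceeds trace length")
    n_events = rng.poisson(rate_hz * config.trace_length_s)
    placed: list[float] = []  # sorted start times
    max_retries = 1000
    for _ in range(n_events):
        for _attempt in range(max_retries):
            start = rng.uniform(0.0, trace_ms - duration_ms)
            lo = np.searchsorted(placed, start)
            ok = ((lo == 0 or placed[lo - 1] + duration_ms <= start)
                  and (lo == len(placed) or start + duration_ms <= placed[lo]))
            if ok:
                placed.insert(lo, start)
                break
        else:
            raise InfeasibleDensityError(
                f"could not place {n_events} non-overlapping events of "
                f"{duration_ms} ms in {trace_ms} ms")
    return [Segment(s, s + duration_ms) for s in placed]


def synth_noise(n_samples: int, model: NoiseModel, sampling_rate_hz: float,
                rng_seed: int | np.random.SeedSequence) -> np.ndarray:
    """Zero-mean noise whose periodogram follows the configured mixture.

    White Gaussian noise is shaped in the frequency domain by the square
    root of the model's spectral shape, then normalised to exactly zero
    mean and the requested rms.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    if model.white == model.pink == model.dielectric == 0:
        raise DegenerateNoiseModelError("all noise component weights are zero")
    rng = np.random.default_rng(rng_seed)
    white = rng.standard_normal(n_samples)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sampling_rate_hz)
    shape = np.sqrt(model.spectral_shape(freqs))
    spectrum = np.fft.rfft(white) * shape
    noise = np.fft.irfft(spectrum, n=n_samples)
    noise -= noise.mean()
    std = noise.std()
    if std > 0:
        noise *= model.rms_pa / std
    return noise


def _synth_baseline(n_samples: int, model: BaselineModel, sampling_rate_hz: float,
                    rng_seed: int | np.random.SeedSequence) -> np.ndarray:
    rng = np.random.default_rng(rng_seed)
    baseline = np.zeros(n_samples)
    if model.drift_rms_pa > 0:
        white = rng.standard_normal(n_samples)
        nyq = sampling_rate_hz / 2.0
        corner = min(model.drift_corner_hz, 0.99 * nyq)
        sos = signal.butter(2, corner / nyq, output="sos")
        drift = signal.sosfilt(sos, white)
        drift -= drift.mean()
        std = drift.std()
        if std > 0:
            drift *= model.drift_rms_pa / std
        baseline += drift
    if model.jump_rate_hz > 0 and model.jump_rms_pa > 0:
        duration_s = n_samples / sampling_rate_hz
        n_jumps = rng.poisson(model.jump_rate_hz * duration_s)
        for _ in range(n_jumps):
            at = rng.integers(0, n_samples)
            baseline[at:] += rng.normal(0.0, model.jump_rms_pa)
    return baseline


def default_baseline(spike_amplitude_pa: float) -> BaselineModel:
    """Amplitude-scaled default: drift rms at half the pulse depth below
    1 Hz, jumps at 0.05 /s with rms equal to the pulse depth."""
    return BaselineModel(drift_rms_pa=0.5 * spike_amplitude_pa,
                         drift_corner_hz=1.0,
                         jump_rate_hz=0.05,
                         jump_rms_pa=spike_amplitude_pa)


# ---------------------------------------------------------------------------
# trace and dataset generation
# ---------------------------------------------------------------------------

def _pulse_train(n_samples: int, segments: Sequence[Segment], amplitude_pa: float,
                 sampling_rate_hz: float, analog_bandwidth_hz: float) -> np.ndarray:
    train = np.zeros(n_samples)
    for seg in segments:
        i0 = int(round(seg.start_ms * 1e-3 * sampling_rate_hz))
        i1 = int(round(seg.end_ms * 1e-3 * sampling_rate_hz))
        train[i0:max(i1, i0 + 1)] = amplitude_pa
    nyq = sampling_rate_hz / 2.0
    if 0 < analog_bandwidth_hz < nyq:
        # 4-pole low-pass emulating the amplifier's analog bandwidth.
        sos = signal.butter(4, analog_bandwidth_hz / nyq, output="sos")
        train = signal.sosfilt(sos, train)
    return train


def generate_trace(config: SimulationConfig) -> Trace:
    """Baseline + noise - filtered pulse train, deterministic given the seed."""
    root = np.random.SeedSequence(config.seed)
    events_ss, noise_ss, baseline_ss = root.spawn(3)
    amplitude = blockade_amplitude(config.analyte_diameter_nm, config.pore)
    segments = sample_events(config, events_ss)
    n = config.n_samples

    samples = np.full(n, open_pore_current_pa(config.pore))
    baseline_model = config.baseline
    if baseline_model is None:
        baseline_model = default_baseline(amplitude)
    samples += _synth_baseline(n, baseline_model, config.sampling_rate_hz, baseline_ss)
    if config.noise is not None:
        rms = calibrate_snr(amplitude, config.snr)
        noise_model = replace(config.noise, rms_pa=rms)
        samples += synth_noise(n, noise_model, config.sampling_rate_hz, noise_ss)
    samples -= _pulse_train(n, segments, amplitude, config.sampling_rate_hz,
                            config.analog_bandwidth_hz)
    return Trace(samples, config.sampling_rate_hz, ground_truth=segments,
                 metadata=config)


def measure_snr(trace: Trace, edge_margin_frac: float = 0.25) -> float:
    """Empirical SNR: pulse depth over 6x rms of the pulse-free stretch.

    Uses the ground truth to separate pulse interiors (central portion,
    excluding `edge_margin_frac` of the duration on each side where the
    band-limiting filter rounds the edges) from noise-only samples.
    Assumes baseline variations are disabled or negligible.
    """
    if not trace.ground_truth:
        raise ValueError("measure_snr needs ground-truth segments")
    fs = trace.sampling_rate_hz
    x = trace.samples_pa
    in_pulse = np.zeros(x.size, dtype=bool)
    interior = np.zeros(x.size, dtype=bool)
    for seg in trace.ground_truth:
        i0 = int(round(seg.start_ms * 1e-3 * fs))
        i1 = int(round(seg.end_ms * 1e-3 * fs))
        pad = max(1, int(0.5 * (i1 - i0)))
        in_pulse[max(0, i0 - pad):min(x.size, i1 + pad)] = True
        m = max(1, int(edge_margin_frac * (i1 - i0)))
        interior[i0 + m:i1 - m] = True
    if not interior.any() or in_pulse.all():
        raise ValueError("trace has no usable pulse interior or noise stretch")
    level = np.median(x[~in_pulse])
    depth = level - x[interior].mean()
    rms = x[~in_pulse].std()
    return depth / (6.0 * rms)


DEFAULT_DIAMETERS_NM = tuple(float(d) for d in range(3, 18))
DEFAULT_CONCENTRATIONS_NM = tuple(np.logspace(np.log10(0.01), np.log10(1.0), 20))
DEFAULT_DURATIONS_MS = (0.5, 1.0, 1.5, 3.0, 5.0)


@dataclass(frozen=True)
class ParameterGrid:
    """Cartesian grid of analyte diameter x concentration x pulse duration."""

    diameters_nm: tuple[float, ...] = DEFAULT_DIAMETERS_NM
    concentrations_nm: tuple[float, ...] = DEFAULT_CONCENTRATIONS_NM
    durations_ms: tuple[float, ...] = DEFAULT_DURATIONS_MS

    def __len__(self) -> int:
        return (len(self.diameters_nm) * len(self.concentrations_nm)
                * len(self.durations_ms))

    def combinations(self) -> Iterator[tuple[float, float, float]]:
        return itertools.product(self.diameters_nm, self.concentrations_nm,
                                 self.durations_ms)


def iter_dataset(grid: ParameterGrid | None = None, trace_length_s: float = 20.0,
                 base_seed: int = 0, snr: float = 4.0,
                 template: SimulationConfig | None = None) -> Iterator[Trace]:
    """Stream one trace per grid combination in reproducible order."""
    grid = grid or ParameterGrid()
    template = template or SimulationConfig()
    root = np.random.SeedSequence(base_seed)
    children = root.spawn(len(grid))
    for ss, (diameter, conc, duration) in zip(children, grid.combinations()):
        config = replace(template,
                         analyte_diameter_nm=diameter,
                         analyte_concentration_nm=conc,
                         event_duration_ms=duration,
                         snr=snr,
                         trace_length_s=trace_length_s,
                         seed=int(ss.generate_state(1)[0] % (2 ** 31)))
        yield generate_trace(config)


def generate_dataset(grid: ParameterGrid | None = None, trace_length_s: float = 20.0,
                     base_seed: int = 0, snr: float = 4.0,
                     template: SimulationConfig | None = None) -> list[Trace]:
    """Materialised version of :func:`iter_dataset` (default grid: 1500 traces)."""
    return list(iter_dataset(grid, trace_length_s, base_seed, snr, template))
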