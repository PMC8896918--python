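"""Synthetic EEG segments with a controllable seizure signature.

Generates class-separable single-channel segments so the full pipeline
(decomposition, features, cross-validated classification) is testable
without downloading any public EEG benchmark:

* background ("H"): a band-limited rhythm — a sinusoid whose frequency
  is drawn from ``background_band`` (default 8–13 Hz, the posterior
  alpha range) with random phase — plus 1/f-shaped (pink) noise scaled
  to ``noise_sd`` RMS;
* seizure ("S"): the same background plus a high-amplitude periodic
  spike-wave train: biphasic transients (sharp positive spike followed
  by a slower negative wave) repeating at a frequency drawn from
  ``seizure_freq_band`` (default 2.5–5 Hz, inside the D5 band at the
  Bonn sampling rate), with amplitude ``seizure_amp`` well above the
  background;
* optional interictal ("I"): background plus sparse isolated spikes at
  ``spike_rate`` events/s with intermediate amplitude, for 3-class
  problems.

Randomness is keyed by (seed, class, segment index), so any individual
segment is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Tuple

import numpy as np

from .data_io import LabeledDataset, Signal, write_bonn_segment

__all__ = [
    "SynthSpec",
    "generate_background",
    "generate_seizure",
    "generate_interictal",
    "generate_dataset",
    "export_bonn_layout",
]

_CLASS_STREAM = {"H": 0, "S": 1, "I": 2}


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of the synthetic EEG generator.

    Amplitudes and noise SD are in µV; bands in Hz.  Defaults mirror the
    Bonn segment geometry (4096 samples at 173.61 Hz, 100 segments per
    class) with an alpha-band background and a 2.5–5 Hz spike-wave
    discharge whose amplitude is six times the background's.
    """

    n_segments_per_class: int = 100
    segment_length: int = 4096
    fs: float = 173.61
    background_band: Tuple[float, float] = (8.0, 13.0)
    background_amp: float = 50.0
    seizure_freq_band: Tuple[float, float] = (2.5, 5.0)
    seizure_amp: float = 300.0
    spike_rate: float = 1.0
    noise_sd: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_segments_per_class < 1:
            raise ValueError("n_segments_per_class must be >= 1")
        if self.segment_length < 64:
            raise ValueError(
                f"segment_length must be >= 64, got {self.segment_length}"
            )
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        for name in ("background_band", "seizure_freq_band"):
            lo, hi = getattr(self, name)
            if not (0 < lo < hi < self.fs / 2):
                raise ValueError(
                    f"{name}=({lo}, {hi}) must satisfy 0 < lo < hi < fs/2"
                )
        for name in ("background_amp", "seizure_amp", "spike_rate", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _rng(spec: SynthSpec, class_label: str, index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([spec.seed, _CLASS_STREAM[class_label], index])
    )


def _pink_noise(rng: np.random.Generator, n: int, sd: float) -> np.ndarray:
    """1/f-amplitude-shaped Gaussian noise with the requested RMS."""
    if sd == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    nonzero = freqs > 0
    scale[nonzero] = 1.0 / np.sqrt(freqs[nonzero])
    scale[0] = 0.0  # no DC drift
    shaped = np.fft.irfft(spectrum * scale, n)
    rms = np.sqrt(np.mean(np.square(shaped)))
    if rms == 0:
        return np.zeros(n)
    return shaped * (sd / rms)


def _background_samples(spec: SynthSpec, rng: np.random.Generator) -> np.ndarray:
    n = spec.segment_length
    t = np.arange(n) / spec.fs
    lo, hi = spec.background_band
    freq = rng.uniform(lo, hi)
    phase = rng.uniform(0, 2 * np.pi)
    rhythm = spec.background_amp * np.sin(2 * np.pi * freq * t + phase)
    return rhythm + _pink_noise(rng, n, spec.noise_sd)


def _spike_wave(spec: SynthSpec, rng: np.random.Generator, amp: float) -> np.ndarray:
    """Periodic biphasic spike-wave train at a frequency from seizure_freq_band."""
    n = spec.segment_length
    t = np.arange(n) / spec.fs
    lo, hi = spec.seizure_freq_band
    freq = rng.uniform(lo, hi)
    onset = rng.uniform(0, 1.0 / freq)
    # biphasic morphology: sharp positive spike + slower negative wave
    spike_width = 0.025  # s
    wave_width = 0.12  # s
    wave_delay = 0.09  # s after the spike peak
    phase_t = np.mod(t - onset, 1.0 / freq)  # time since last discharge
    train = amp * np.exp(-0.5 * ((phase_t - 2 * spike_width) / spike_width) ** 2)
    train -= 0.6 * amp * np.exp(
        -0.5 * ((phase_t - 2 * spike_width - wave_delay) / wave_width) ** 2
    )
    return train


def generate_background(spec: SynthSpec, index: int) -> Signal:
    """One background-class segment; deterministic given (seed, index)."""
    rng = _rng(spec, "H", index)
    return Signal(
        samples=_background_samples(spec, rng),
        fs=spec.fs,
        source_id=f"synthH{index:04d}",
        set_label="H",
    )


def generate_seizure(spec: SynthSpec, index: int) -> Signal:
    """One seizure-class segment: background plus the spike-wave train."""
    rng = _rng(spec, "S", index)
    samples = _background_samples(spec, rng) + _spike_wave(
        spec, rng, spec.seizure_amp
    )
    return Signal(
        samples=samples,
        fs=spec.fs,
        source_id=f"synthS{index:04d}",
        set_label="S",
    )


def generate_interictal(spec: SynthSpec, index: int) -> Signal:
    """One interictal-class segment: background plus sparse isolated spikes.

    Spike count is Poisson with mean ``spike_rate x duration``; spike
    amplitude is halfway between background and seizure amplitude.
    """
    rng = _rng(spec, "I", index)
    n = spec.segment_length
    samples = _background_samples(spec, rng)
    duration = n / spec.fs
    amp = 0.5 * (spec.background_amp + spec.seizure_amp)
    n_spikes = rng.poisson(spec.spike_rate * duration)
    t = np.arange(n) / spec.fs
    spike_width = 0.025
    for _ in range(n_spikes):
        center = rng.uniform(0, duration)
        samples += amp * np.exp(-0.5 * ((t - center) / spike_width) ** 2)
    return Signal(
        samples=samples,
        fs=spec.fs,
        source_id=f"synthI{index:04d}",
        set_label="I",
    )


def generate_dataset(spec: SynthSpec, three_class: bool = False) -> LabeledDataset:
    """n_segments_per_class segments per class, labels H/S (and I if 3-class)."""
    signals = []
    for i in range(spec.n_segments_per_class):
        signals.append(generate_background(spec, i))
    if three_class:
        for i in range(spec.n_segments_per_class):
            signals.append(generate_interictal(spec, i))
    for i in range(spec.n_segments_per_class):
        signals.append(generate_seizure(spec, i))
    return LabeledDataset(signals)


def export_bonn_layout(dataset: LabeledDataset, directory) -> Path:
    """Write a dataset to Bonn-layout ASCII directories, one per set label.

    Samples are rounded to the nearest integer to match the published
    distribution's integer ADC output format.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for sig in dataset:
        subdir = directory / str(sig.set_label)
        subdir.mkdir(exist_ok=True)
        rounded = Signal(
            samples=np.round(sig.samples),
            fs=sig.fs,
            source_id=sig.source_id,
            set_label=sig.set_label,
        )
        write_bonn_segment(rounded, subdir / f"{sig.source_id}.txt")
    return directory
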