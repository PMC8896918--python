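"""Reading EEG segments and writing results tables.

Bonn-layout segments are plain ASCII files with one integer (or real)
amplitude sample per line, 4096 samples per segment at 173.61 Hz in the
published distribution.  Clinical-style multichannel recordings arrive as
EDF or wide CSV (one column per channel, typically 21 channels at 256 Hz);
both are exposed as one :class:`Signal` per channel.  The files carry no
usable sampling-frequency header in the Bonn case, so ``fs`` is always
supplied by the caller.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "Signal",
    "LabeledDataset",
    "read_bonn_segment",
    "load_set_directory",
    "read_multichannel_csv",
    "read_edf",
    "write_bonn_segment",
    "write_results_table",
    "RESULTS_COLUMNS",
]

#: Column order of the results CSV (mirrors the published tables' layout).
RESULTS_COLUMNS = (
    "case",
    "subband",
    "feature",
    "classifier",
    "accuracy",
    "sensitivity",
    "specificity",
    "ppv",
    "npv",
    "mcc",
)


@dataclass(frozen=True)
class Signal:
    """A single-channel EEG segment.

    Parameters
    ----------
    samples : ndarray
        Amplitudes in file order (µV by convention, dimensionless here).
    fs : float
        Sampling frequency in Hz.
    source_id : str
        Provenance identifier (file name, synthetic tag, ...).
    set_label : str, optional
        Bonn set label (A–E) or a synthetic class name.
    """

    samples: np.ndarray
    fs: float
    source_id: str = ""
    set_label: Optional[str] = None

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1 or samples.size < 2:
            raise ValueError(
                f"Signal needs a 1-D array of length >= 2, got shape {samples.shape}"
            )
        if not np.all(np.isfinite(samples)):
            raise ValueError("Signal samples must all be finite")
        if not (self.fs > 0):
            raise ValueError(f"sampling frequency must be positive, got {self.fs}")

    def __len__(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        """Segment duration in seconds."""
        return len(self) / self.fs


@dataclass
class LabeledDataset:
    """A collection of labelled Signals sharing one sampling frequency."""

    signals: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.signals:
            return
        for sig in self.signals:
            if sig.set_label is None:
                raise ValueError(
                    f"every signal needs a set_label; {sig.source_id!r} has none"
                )
        fss = {sig.fs for sig in self.signals}
        if len(fss) > 1:
            raise ValueError(f"signals mix sampling frequencies: {sorted(fss)}")

    def __len__(self) -> int:
        return len(self.signals)

    def __iter__(self):
        return iter(self.signals)

    @property
    def fs(self) -> float:
        if not self.signals:
            raise ValueError("empty dataset has no sampling frequency")
        return self.signals[0].fs

    @property
    def set_labels(self) -> list:
        """Distinct set labels, in first-appearance order."""
        seen: dict = {}
        for sig in self.signals:
            seen.setdefault(sig.set_label, None)
        return list(seen)

    def subset(self, labels: Sequence[str]) -> "LabeledDataset":
        wanted = set(labels)
        return LabeledDataset([s for s in self.signals if s.set_label in wanted])


def read_bonn_segment(path, fs: float, set_label: Optional[str] = None) -> Signal:
    """Read one Bonn-layout ASCII segment (one sample per line).

    Trailing whitespace and a final blank line are tolerated; any other
    non-numeric content raises a :class:`ValueError` naming the offending
    line number.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"no such segment file: {path}")
    samples = []
    with open(path, "r", encoding="ascii") as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text:
                continue
            try:
                samples.append(float(text))
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno} is not a numeric sample: {text!r}"
                ) from None
    if not samples:
        raise ValueError(f"{path}: file contains no samples")
    return Signal(
        samples=np.asarray(samples, dtype=float),
        fs=fs,
        source_id=path.name,
        set_label=set_label,
    )


def write_bonn_segment(signal: Signal, path) -> Path:
    """Write a Signal's samples in Bonn layout (one value per line).

    Integral amplitudes are written without a decimal point so the Bonn
    distribution format round-trips exactly.
    """
    path = Path(path)
    with open(path, "w", encoding="ascii") as fh:
        for x in signal.samples:
            if float(x).is_integer():
                fh.write(f"{int(x)}\n")
            else:
                fh.write(f"{float(x)!r}\n")
    return path


def load_set_directory(directory, set_label: str, fs: float) -> LabeledDataset:
    """Load every segment file in ``directory`` as one Bonn set.

    Files are read in lexicographic order so the dataset is deterministic
    across runs and platforms.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"no such directory: {directory}")
    files = sorted(p for p in directory.iterdir() if p.is_file())
    if not files:
        raise ValueError(f"{directory}: directory contains no segment files")
    signals = []
    for p in files:
        try:
            signals.append(read_bonn_segment(p, fs=fs, set_label=set_label))
        except (ValueError, OSError) as exc:
            raise ValueError(f"failed reading {p}: {exc}") from exc
    return LabeledDataset(signals)


def read_multichannel_csv(path, fs: float, set_label: Optional[str] = None) -> list:
    """Read a wide clinical-style CSV (one column per channel) into Signals.

    The first row is taken as channel names.  Returns one Signal per
    channel; montage and referencing are out of scope.
    """
    import pandas as pd

    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"no such CSV file: {path}")
    frame = pd.read_csv(path)
    if frame.empty:
        raise ValueError(f"{path}: CSV contains no samples")
    return [
        Signal(
            samples=frame[col].to_numpy(dtype=float),
            fs=fs,
            source_id=f"{path.name}:{col}",
            set_label=set_label,
        )
        for col in frame.columns
    ]


def read_edf(path, set_label: Optional[str] = None) -> list:
    """Read an EDF recording into one Signal per channel (thin mne adapter)."""
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"no such EDF file: {path}")
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    data = raw.get_data()
    return [
        Signal(
            samples=np.asarray(data[i], dtype=float),
            fs=fs,
            source_id=f"{path.name}:{name}",
            set_label=set_label,
        )
        for i, name in enumerate(raw.ch_names)
    ]


def write_results_table(results, path) -> Path:
    """Write evaluation results as CSV.

    Header is ``case,subband,feature,classifier,accuracy,sensitivity,
    specificity,ppv,npv,mcc``; percentages are printed to 2 decimals and
    MCC to 3.  Undefined ratios (0/0) are printed as ``NA``.
    """
    results = list(results)
    if not results:
        raise ValueError("cannot write an empty results table")
    path = Path(path)

    def _pct(v: float) -> str:
        return "NA" if v is None or math.isnan(v) else f"{v:.2f}"

    def _mcc(v: float) -> str:
        return "NA" if v is None or math.isnan(v) else f"{v:.3f}"

    lines = [",".join(RESULTS_COLUMNS)]
    for res in results:
        m = res.metrics
        lines.append(
            ",".join(
                [
                    res.case_name,
                    res.subband,
                    res.feature,
                    res.classifier,
                    _pct(m.accuracy),
                    _pct(m.sensitivity),
                    _pct(m.specificity),
                    _pct(m.ppv),
                    _pct(m.npv),
                    _mcc(m.mcc),
                ]
            )
        )
    tmp = path.with_suffix(path.suffix + ".tmp")
    with open(tmp, "w", encoding="ascii", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")
    os.replace(tmp, path)
    return path
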