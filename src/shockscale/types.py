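"""Shared domain containers: ECG fragments and raw signal records."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ECGFragment:
    """A fixed-length single-lead voltage trace.

    Parameters
    ----------
    samples
        Voltage samples in millivolt.
    fs
        Sampling rate in Hz.
    label
        Rhythm class (``"C1"``..``"C4"``) or ``None`` for unlabeled input.
    id
        Opaque unique identifier.
    synthetic
        True for SMOTE-interpolated fragments, False for real/generated ones.
    """

    samples: np.ndarray
    fs: float
    label: str | None = None
    id: str = ""
    synthetic: bool = False

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def duration(self) -> float:
        """Fragment length in seconds."""
        return len(self.samples) / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(len(self.samples)) / self.fs


@dataclass
class SignalRecord:
    """A raw (possibly long) single-channel signal with optional annotations.

    ``annotations`` is a list of ``(sample_index, symbol)`` pairs with strictly
    increasing in-range indices.
    """

    samples: np.ndarray
    fs: float
    annotations: list[tuple[int, str]] = field(default_factory=list)
    name: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        idx = [i for i, _ in self.annotations]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("annotation indices must be strictly increasing")
        if idx and (idx[0] < 0 or idx[-1] >= len(self.samples)):
            raise ValueError("annotation index out of range")
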