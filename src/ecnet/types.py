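"""Core containers shared across the pipeline stages.

Every stage of the pipeline consumes and produces :class:`ROITimeSeries`
matrices (T timepoints x k regions, with a sampling interval ``tr`` in
seconds).  The containers here are deliberately thin: plain numpy arrays
with the few invariants each stage relies on checked at construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ROITimeSeries:
    """A T x k matrix of region time series sampled every ``tr`` seconds."""

    data: np.ndarray
    tr: float
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("ROITimeSeries.data must be 2-D (T x k)")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if not self.labels:
            self.labels = [f"R{i:02d}" for i in range(self.data.shape[1])]
        if len(self.labels) != self.data.shape[1]:
            raise ValueError("one label per region required")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]


@dataclass
class HRFCurve:
    """A sampled hemodynamic response, peak-normalized to 1.

    ``samples[0]`` is response onset; ``peak_time`` is seconds from onset
    to the (positive) peak.
    """

    samples: np.ndarray
    dt: float
    peak_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("HRF samples must be a non-empty vector")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        peak = np.max(np.abs(self.samples))
        if peak > 0:
            self.samples = self.samples / np.max(self.samples)
        if self.peak_time == 0.0:
            self.peak_time = float(np.argmax(self.samples) * self.dt)

    @property
    def duration(self) -> float:
        return self.samples.size * self.dt


def standardize_columns(data: np.ndarray) -> np.ndarray:
    """Zero-mean / unit-sd each column; reject zero-variance columns."""
    data = np.asarray(data, dtype=float)
    sd = data.std(axis=0, ddof=0)
    bad = np.flatnonzero(sd <= 0)
    if bad.size:
        raise ValueError(f"zero-variance columns cannot be standardized: {bad.tolist()}")
    return (data - data.mean(axis=0)) / sd
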