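"""Sampled current traces from voltage-clamp recordings."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import InputError


@dataclass
class SweepTrace:
    """A single voltage-clamp sweep.

    Parameters
    ----------
    samples
        Membrane current in pA at uniform sampling.
    sampling_rate
        Samples per second (Hz).
    stimulus_times
        Stimulus onset times in seconds, sorted ascending.
    polarity
        ``'inward'`` for negative-going synaptic currents (EPSCs/IPSCs at
        negative holding potentials), ``'outward'`` for positive-going ones
        (e.g. NMDAR-EPSCs at +40 mV).
    """

    samples: np.ndarray
    sampling_rate: float
    stimulus_times: tuple[float, ...] = field(default_factory=tuple)
    polarity: str = "inward"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise InputError("sampling_rate must be > 0")
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise InputError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise InputError("samples must be finite")
        if self.polarity not in ("inward", "outward"):
            raise InputError(f"polarity must be 'inward' or 'outward', got {self.polarity!r}")
        self.stimulus_times = tuple(float(t) for t in self.stimulus_times)
        if any(b < a for a, b in zip(self.stimulus_times, self.stimulus_times[1:])):
            raise InputError("stimulus_times must be sorted ascending")
        if any(t < 0 or t >= self.duration for t in self.stimulus_times):
            raise InputError("stimulus_times must lie within [0, duration)")

    @property
    def duration(self) -> float:
        """Trace duration in seconds."""
        return self.samples.size / self.sampling_rate

    @property
    def sign(self) -> float:
        """-1 for inward currents, +1 for outward."""
        return -1.0 if self.polarity == "inward" else 1.0

    def time(self) -> np.ndarray:
        """Sample times in seconds."""
        return np.arange(self.samples.size) / self.sampling_rate

    def index_at(self, t: float) -> int:
        """Index of the first sample at or after time ``t``."""
        return int(np.ceil(t * self.sampling_rate - 1e-9))

    # ------------------------------------------------------------------ I/O
    def to_files(self, data_path, header_path=None) -> None:
        """Write (time, current) as delimited text plus a JSON metadata sidecar."""
        data_path = Path(data_path)
        np.savetxt(data_path, np.column_stack([self.time(), self.samples]),
                   header="time_s\tcurrent_pA", delimiter="\t")
        header = {
            "sampling_rate": self.sampling_rate,
            "stimulus_times": list(self.stimulus_times),
            "polarity": self.polarity,
        }
        header_path = Path(header_path) if header_path else data_path.with_suffix(".json")
        header_path.write_text(json.dumps(header, indent=1))

    @classmethod
    def from_files(cls, data_path, header_path=None) -> "SweepTrace":
        data_path = Path(data_path)
        header_path = Path(header_path) if header_path else data_path.with_suffix(".json")
        meta = json.loads(header_path.read_text())
        arr = np.loadtxt(data_path, delimiter="\t")
        return cls(samples=arr[:, 1], sampling_rate=meta["sampling_rate"],
                   stimulus_times=tuple(meta.get("stimulus_times", ())),
                   polarity=meta.get("polarity", "inward"))
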