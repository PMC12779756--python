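"""Shared data containers: stimulation protocols, recordings, spike trains.

Units follow one convention throughout the package: seconds, Hz, microvolts,
millimetres, mV/mm for electric fields, and radians in [0, 2π) for phases.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class StimProtocol:
    """Sinusoidal stimulation protocol.

    The commanded waveform is ``amplitude-scaled sin(2πf(t − onset) + phase_at_onset)``
    inside [onset, offset) and zero elsewhere.

    Parameters
    ----------
    frequency : float
        Stimulation frequency in Hz (> 0).
    amplitude : float
        Stimulation current amplitude in µA (metadata; the commanded voltage
        trace is generated with a separate scale).
    onset, offset : float
        Stimulation window in seconds, ``offset > onset``.
    sampling_rate : float
        Rate at which the commanded waveform is realized, ≥ 4 × frequency.
    phase_at_onset : float
        Sine argument at ``t = onset``, radians.
    """

    frequency: float
    amplitude: float
    onset: float
    offset: float
    sampling_rate: float
    phase_at_onset: float = 0.0

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ValueError("frequency must be > 0")
        if self.offset <= self.onset:
            raise ValueError("offset must exceed onset")
        if self.sampling_rate < 4 * self.frequency:
            raise ValueError("sampling_rate must be at least 4x the stimulation frequency")

    @property
    def duration(self) -> float:
        return self.offset - self.onset

    def n_cycles(self) -> int:
        """Whole stimulation cycles between onset and offset."""
        return int(np.floor(self.frequency * self.duration + 1e-9))

    def phase(self, t: np.ndarray) -> np.ndarray:
        """Instantaneous phase of the stimulus at times ``t`` (s), radians in [0, 2π).

        The phase is the angle of the cosine-form analytic signal of the
        commanded sine: ``sin(x) = cos(x − π/2)``, so the analytic-signal
        angle is ``x − π/2``.  The same convention is used by the
        Hilbert-based phase extraction in :mod:`sacskit.spikemetrics`, so
        generator and analyzer agree.
        """
        t = np.asarray(t, dtype=float)
        x = TWO_PI * self.frequency * (t - self.onset) + self.phase_at_onset
        return np.mod(x - np.pi / 2.0, TWO_PI)


@dataclass
class Recording:
    """Multi-channel voltage time series.

    Attributes
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Voltages in µV.
    rate : float
        Sampling rate in Hz.
    geometry : list of (row, col) or None
        Per-channel integer grid position on a regular planar array.
    pitch : float
        Inter-electrode spacing in mm.
    band_label : str
        One of ``{"MUA", "LFP", "wideband"}``.
    """

    samples: np.ndarray
    rate: float
    geometry: list[tuple[int, int]] | None = None
    pitch: float = 0.5
    band_label: str = "wideband"

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples))
        if self.geometry is not None:
            self.geometry = [tuple(g) for g in self.geometry]
            if len(self.geometry) != self.n_channels:
                raise ValueError("geometry length must match channel count")
            if len(set(self.geometry)) != len(self.geometry):
                raise ValueError("geometry indices must be unique")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.rate

    def copy(self, samples: np.ndarray | None = None, rate: float | None = None) -> "Recording":
        return Recording(
            samples=self.samples.copy() if samples is None else samples,
            rate=self.rate if rate is None else rate,
            geometry=None if self.geometry is None else list(self.geometry),
            pitch=self.pitch,
            band_label=self.band_label,
        )

    # -- raw float32 binary + JSON sidecar I/O -------------------------------

    def save(self, prefix: str | Path) -> tuple[Path, Path]:
        """Write little-endian float32 binary (``.f32``) plus JSON sidecar."""
        prefix = Path(prefix)
        bin_path = prefix.with_suffix(".f32")
        meta_path = prefix.with_suffix(".json")
        self.samples.astype("<f4").tofile(bin_path)
        meta = {
            "rate_hz": self.rate,
            "n_channels": self.n_channels,
            "n_samples": self.n_samples,
            "dtype": "<f4",
            "order": "channels_x_time_C",
            "units": "uV",
            "geometry_row_col": self.geometry,
            "pitch_mm": self.pitch,
            "band_label": self.band_label,
        }
        meta_path.write_text(json.dumps(meta, indent=1))
        return bin_path, meta_path

    @classmethod
    def load(cls, prefix: str | Path) -> "Recording":
        prefix = Path(prefix)
        meta = json.loads(prefix.with_suffix(".json").read_text())
        data = np.fromfile(prefix.with_suffix(".f32"), dtype="<f4")
        samples = data.reshape(meta["n_channels"], meta["n_samples"]).astype(float)
        geom = meta.get("geometry_row_col")
        return cls(
            samples=samples,
            rate=meta["rate_hz"],
            geometry=None if geom is None else [tuple(g) for g in geom],
            pitch=meta.get("pitch_mm", 0.5),
            band_label=meta.get("band_label", "wideband"),
        )


@dataclass
class SpikeTrain:
    """Sorted spike times (s) of one neuron, strictly increasing."""

    neuron_id: str
    channel_id: int
    times: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("spike times must be strictly increasing")

    @property
    def n_spikes(self) -> int:
        return self.times.size

    def slice(self, start: float, stop: float) -> np.ndarray:
        """Spike times in [start, stop)."""
        return self.times[(self.times >= start) & (self.times < stop)]


def spiketrains_to_csv(trains: list[SpikeTrain], path: str | Path) -> Path:
    rows = [
        {"neuron_id": tr.neuron_id, "channel_id": tr.channel_id, "time_s": t}
        for tr in trains
        for t in tr.times
    ]
    df = pd.DataFrame(rows, columns=["neuron_id", "channel_id", "time_s"])
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def spiketrains_from_csv(path: str | Path) -> list[SpikeTrain]:
    df = pd.read_csv(path)
    trains = []
    for (nid, cid), grp in df.groupby(["neuron_id", "channel_id"], sort=True):
        trains.append(
            SpikeTrain(neuron_id=str(nid), channel_id=int(cid), times=np.sort(grp["time_s"].to_numpy()))
        )
    return trains
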