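"""Spike raster container and plain-text I/O.

A raster is the ordered list of (neuron id, spike time) events produced by a
simulation (or a synthetic generator), together with enough metadata to make
the run reproducible.  On disk it is a two-column tab-separated file plus a
JSON sidecar (``<raster>.meta.json``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass
class SpikeRaster:
    ids: np.ndarray  # neuron index per event
    times: np.ndarray  # spike time (ms) per event, globally sorted
    n_neurons: int
    duration: float  # ms
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.ids.shape != self.times.shape:
            raise ValueError("ids and times must have equal length")

    @property
    def n_events(self) -> int:
        return self.times.size

    def validate(self, min_isi: float = 0.0) -> None:
        """Check raster invariants; raises on violation."""
        if self.n_events == 0:
            return
        if self.times.min() < 0 or self.times.max() > self.duration:
            raise ValueError("spike times outside [0, duration]")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("events not sorted by time")
        if self.ids.min() < 0 or self.ids.max() >= self.n_neurons:
            raise ValueError("neuron id out of range")
        if min_isi > 0:
            for nid, train in self.by_neuron().items():
                if train.size > 1 and np.diff(train).min() < min_isi:
                    raise ValueError(f"neuron {nid} has ISI below {min_isi} ms")

    def by_neuron(self) -> dict[int, np.ndarray]:
        """Spike-time arrays keyed by neuron id (only spiking neurons)."""
        order = np.argsort(self.ids, kind="stable")
        ids_sorted = self.ids[order]
        times_sorted = self.times[order]
        out: dict[int, np.ndarray] = {}
        if ids_sorted.size == 0:
            return out
        bounds = np.flatnonzero(np.diff(ids_sorted)) + 1
        starts = np.concatenate([[0], bounds])
        ends = np.concatenate([bounds, [ids_sorted.size]])
        for s, e in zip(starts, ends):
            out[int(ids_sorted[s])] = np.sort(times_sorted[s:e])
        return out

    def spike_counts(self, neuron_ids: np.ndarray | None = None) -> np.ndarray:
        counts = np.bincount(self.ids, minlength=self.n_neurons)
        return counts if neuron_ids is None else counts[neuron_ids]

    def rates_hz(self, neuron_ids: np.ndarray | None = None,
                 t_start: float = 0.0) -> np.ndarray:
        """Mean firing rate (Hz) per neuron over [t_start, duration]."""
        mask = self.times >= t_start
        counts = np.bincount(self.ids[mask], minlength=self.n_neurons)
        span_s = (self.duration - t_start) / 1000.0
        rates = counts / span_s
        return rates if neuron_ids is None else rates[neuron_ids]

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savetxt(
            path,
            np.column_stack([self.ids, self.times]),
            fmt=("%d", "%.6f"),
            delimiter="\t",
            header="neuron_id\ttime_ms",
            comments="",
        )
        meta = {
            "n_neurons": self.n_neurons,
            "duration_ms": self.duration,
            "n_events": self.n_events,
            **_jsonable(self.metadata),
        }
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(meta, indent=2)
        )

    @classmethod
    def load(cls, path: str | Path) -> "SpikeRaster":
        path = Path(path)
        data = np.loadtxt(path, delimiter="\t", skiprows=1, ndmin=2)
        meta_path = path.with_suffix(path.suffix + ".meta.json")
        meta = json.loads(meta_path.read_text())
        n_neurons = int(meta.pop("n_neurons"))
        duration = float(meta.pop("duration_ms"))
        meta.pop("n_events", None)
        if data.size == 0:
            ids, times = np.empty(0, dtype=np.int64), np.empty(0)
        else:
            ids, times = data[:, 0].astype(np.int64), data[:, 1]
        return cls(ids=ids, times=times, n_neurons=n_neurons,
                   duration=duration, metadata=meta)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
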