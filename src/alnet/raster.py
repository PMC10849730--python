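"""Spike raster container shared by the simulator and the analysis layer."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class SpikeRaster:
    """Per-trial spike times with trial metadata.

    ``neuron_ids`` and ``times`` (ms) are parallel arrays; neurons are
    indexed PNs first.
    """

    neuron_ids: np.ndarray
    times: np.ndarray
    n_neurons: int
    n_pn: int
    duration: float
    odor: str = ""
    condition: str = ""
    seed: int = 0

    def spike_times_of(self, neuron: int) -> np.ndarray:
        return self.times[self.neuron_ids == neuron]

    def binned_counts(self, window: tuple, bin_ms: float,
                      population: str = "PN") -> np.ndarray:
        """(neurons x time-bins) spike-count matrix over ``window`` (ms).

        Bins tile the window exactly; the window length must be an integer
        multiple of ``bin_ms``.
        """
        a, b = window
        span = b - a
        n_bins = int(round(span / bin_ms))
        if abs(n_bins * bin_ms - span) > 1e-9 or n_bins < 1:
            raise ValueError("bins must tile the window exactly")
        if population == "PN":
            lo, hi = 0, self.n_pn
        elif population == "LN":
            lo, hi = self.n_pn, self.n_neurons
        else:
            lo, hi = 0, self.n_neurons
        sel = (self.neuron_ids >= lo) & (self.neuron_ids < hi) & \
              (self.times >= a) & (self.times < b)
        counts, _, _ = np.histogram2d(
            self.neuron_ids[sel], self.times[sel],
            bins=[np.arange(lo, hi + 1) - 0.5,
                  np.linspace(a, b, n_bins + 1)])
        return counts

    def rate_hz(self, window: tuple, population: str = "PN") -> np.ndarray:
        """Mean firing rate per neuron over ``window``."""
        a, b = window
        counts = self.binned_counts((a, b), b - a, population)
        return counts[:, 0] / ((b - a) / 1000.0)

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame({"neuron_id": self.neuron_ids,
                             "spike_time_ms": self.times})

    @classmethod
    def from_table(cls, df: pd.DataFrame, n_neurons: int, n_pn: int,
                   duration: float, **meta) -> "SpikeRaster":
        return cls(df["neuron_id"].to_numpy(dtype=np.int64),
                   df["spike_time_ms"].to_numpy(dtype=float),
                   n_neurons, n_pn, duration, **meta)
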