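"""Binned binary population activity.

The basic data object is a raster: a T x N matrix of zeros and ones whose
rows are time bins and whose columns are neurons.  An entry is 1 if the
neuron fired at least one spike in that bin (default bin width 20 ms).
Rows may optionally carry integer labels identifying stimulus repeats,
which are used only for train/test splitting, never during inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class SpikeRaster:
    """Binary population activity, one row per time bin.

    Parameters
    ----------
    activity : (T, N) array of 0/1
        Spike/silence indicator per time bin and neuron.
    bin_width : float
        Width of a time bin in seconds (> 0).
    repeat_labels : (T,) int array, optional
        Stimulus-repeat label of each time bin.
    """

    activity: np.ndarray
    bin_width: float = 0.02
    repeat_labels: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        a = np.asarray(self.activity)
        if a.ndim != 2 or a.shape[1] < 1:
            raise ValueError(f"activity must be a T x N matrix, got shape {a.shape}")
        if not np.isin(a, (0, 1)).all():
            bad = np.argwhere(~np.isin(a, (0, 1)))[0]
            raise ValueError(
                f"activity must be binary; offending entry at row {bad[0]}, "
                f"column {bad[1]}: {a[bad[0], bad[1]]!r}"
            )
        self.activity = a.astype(np.int8, copy=False)
        if self.bin_width <= 0:
            raise ValueError(f"bin_width must be positive, got {self.bin_width}")
        if self.repeat_labels is not None:
            labels = np.asarray(self.repeat_labels, dtype=np.int64)
            if labels.shape != (a.shape[0],):
                raise ValueError(
                    f"repeat_labels must have length T={a.shape[0]}, "
                    f"got shape {labels.shape}"
                )
            self.repeat_labels = labels

    @property
    def n_bins(self) -> int:
        return self.activity.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.activity.shape[1]

    def population_counts(self) -> np.ndarray:
        """Summed activity K(s) = sum_i s_i for every time bin."""
        return self.activity.sum(axis=1)

    def firing_rates(self) -> np.ndarray:
        """Per-neuron spike probability per bin."""
        return self.activity.mean(axis=0)

    def subset(self, neuron_indices) -> "SpikeRaster":
        """Raster restricted to a subset of neurons (columns)."""
        idx = np.asarray(neuron_indices, dtype=np.intp)
        return SpikeRaster(
            self.activity[:, idx], self.bin_width,
            None if self.repeat_labels is None else self.repeat_labels.copy(),
        )


def bin_spike_times(
    spike_times: list[np.ndarray],
    bin_width: float = 0.02,
    t_start: float = 0.0,
    t_end: float | None = None,
) -> SpikeRaster:
    """Bin per-neuron spike-time lists into a binary raster.

    Bin ``b`` covers the half-open interval
    ``[t_start + b*bin_width, t_start + (b+1)*bin_width)``; an entry is 1
    iff at least one spike of the neuron falls inside the bin.  Spikes
    outside ``[t_start, t_end)`` are dropped (the count is recorded on the
    module logger).
    """
    import logging

    if bin_width <= 0:
        raise ValueError(f"bin_width must be positive, got {bin_width}")
    if t_end is None:
        t_end = max((float(np.max(t)) for t in spike_times if len(t)), default=t_start) + bin_width
    if t_end <= t_start:
        raise ValueError(f"t_end ({t_end}) must exceed t_start ({t_start})")
    n_bins = int(np.ceil((t_end - t_start) / bin_width))
    activity = np.zeros((n_bins, len(spike_times)), dtype=np.int8)
    n_dropped = 0
    for i, times in enumerate(spike_times):
        t = np.asarray(times, dtype=float)
        in_range = (t >= t_start) & (t < t_end)
        n_dropped += int((~in_range).sum())
        bins = ((t[in_range] - t_start) / bin_width).astype(np.intp)
        bins = np.minimum(bins, n_bins - 1)  # guard exact-boundary float round-up
        activity[bins, i] = 1
    if n_dropped:
        logging.getLogger(__name__).info(
            "bin_spike_times: dropped %d spikes outside [%g, %g)",
            n_dropped, t_start, t_end,
        )
    return SpikeRaster(activity, bin_width=bin_width)
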