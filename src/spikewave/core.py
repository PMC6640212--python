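"""Accumulative spike-wave tensors and first-spike-time grids.

A stimulus seen by ``F`` feature maps of ``H x W`` neurons over ``T_max``
discrete time-steps is stored as a 4-D binary tensor ``S`` of shape
``(T_max, F, H, W)`` in *accumulative* format: if a neuron first spikes at
step ``i`` then ``S[t, f, r, c]`` is 0 for ``t < i`` and 1 for every
``t >= i``.  A neuron that never spikes contributes an all-zero column.
The redundancy is deliberate — it lets one tensor operation (a convolution,
a max-pool, a threshold) process every time-step simultaneously, and the
result of convolving an accumulative wave is automatically the accumulated
membrane potential up to each step.

The non-redundant dual is the first-spike-time grid: one integer per neuron
in ``{0, ..., T_max - 1}`` or the :data:`NO_SPIKE` sentinel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Sentinel spike time for a neuron that never fires.  Stored as -1 in the
#: integer grid (outside the valid bin range ``[0, t_max - 1]``); treated as
#: +infinity wherever spike times are compared.
NO_SPIKE: int = -1


@dataclass(frozen=True)
class SpikeTimeGrid:
    """First-spike times of an ``(F, H, W)`` grid of neurons.

    Parameters
    ----------
    times
        Integer array of shape ``(F, H, W)``.  Each entry is a bin index in
        ``[0, t_max - 1]`` or :data:`NO_SPIKE`.
    t_max
        Number of discrete time-steps (bins).
    """

    times: np.ndarray
    t_max: int

    def __post_init__(self) -> None:
        times = np.asarray(self.times)
        if times.ndim != 3:
            raise ValueError(f"times must be 3-D (F, H, W), got shape {times.shape}")
        if self.t_max < 1:
            raise ValueError(f"t_max must be positive, got {self.t_max}")
        if not np.issubdtype(times.dtype, np.integer):
            if not np.all(np.equal(np.mod(times, 1), 0)):
                raise ValueError("spike times must be integers")
            times = times.astype(np.int64)
        finite = times != NO_SPIKE
        if np.any((times[finite] < 0) | (times[finite] >= self.t_max)):
            raise ValueError(
                f"finite spike times must lie in [0, {self.t_max - 1}]"
            )
        object.__setattr__(self, "times", times.astype(np.int64))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.times.shape  # type: ignore[return-value]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpikeTimeGrid):
            return NotImplemented
        return self.t_max == other.t_max and np.array_equal(self.times, other.times)


def spike_times_to_wave(grid: SpikeTimeGrid) -> np.ndarray:
    """Expand a first-spike-time grid into an accumulative spike-wave tensor.

    ``wave[t, f, r, c]`` is 0 while ``t`` is before the neuron's spike bin
    and 1 from the spike bin to the final step; :data:`NO_SPIKE` neurons
    stay 0 throughout.

    Returns
    -------
    numpy.ndarray
        ``uint8`` tensor of shape ``(t_max, F, H, W)``.
    """
    t = np.arange(grid.t_max).reshape(-1, 1, 1, 1)
    times = grid.times[np.newaxis]
    wave = (times != NO_SPIKE) & (t >= times)
    return wave.astype(np.uint8)


def wave_to_spike_times(wave: np.ndarray) -> SpikeTimeGrid:
    """Collapse a valid accumulative wave into first-spike times.

    The first spike of each neuron is the smallest ``t`` with a 1 entry;
    all-zero columns map to :data:`NO_SPIKE`.  Inverse of
    :func:`spike_times_to_wave` on valid waves.

    Raises
    ------
    ValueError
        If the tensor is not binary and time-monotone.
    """
    wave = np.asarray(wave)
    if not validate_wave(wave):
        raise ValueError("input is not a valid accumulative spike-wave tensor")
    fired = wave[-1] != 0
    # argmax over the time axis returns the first 1 (accumulative format).
    first = np.argmax(wave != 0, axis=0)
    times = np.where(fired, first, NO_SPIKE).astype(np.int64)
    return SpikeTimeGrid(times=times, t_max=wave.shape[0])


def validate_wave(wave: np.ndarray) -> bool:
    """Check the two spike-wave invariants: binary values, monotone time axis.

    Pure predicate — returns ``False`` rather than raising for any 4-D
    tensor that violates the accumulative format.
    """
    wave = np.asarray(wave)
    if wave.ndim != 4 or wave.shape[0] < 1:
        return False
    if not np.isin(wave, (0, 1)).all():
        return False
    if wave.shape[0] > 1 and np.any(np.diff(wave.astype(np.int8), axis=0) < 0):
        return False
    return True
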