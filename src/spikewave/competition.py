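"""Winner-take-all selection and lateral / pointwise / feature inhibition.

Competition is what makes single-spike networks learn distinct features:
only the most salient neurons (earliest spike, then highest potential)
undergo plasticity, and each winner suppresses its spatial neighbourhood in
every feature map plus, optionally, its entire own feature map.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np


@dataclass(frozen=True)
class Winner:
    """A winning neuron: location triplet plus its firing step and potential."""

    feature: int
    row: int
    col: int
    spike_step: int
    potential: float

    @property
    def position(self) -> tuple[int, int, int]:
        return self.feature, self.row, self.col


def _firing_steps(tp: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-neuron first step with nonzero thresholded potential, and a mask
    of neurons that fire at all."""
    nonzero = tp != 0
    fired = nonzero.any(axis=0)
    first = np.argmax(nonzero, axis=0)
    return first, fired


def get_k_winners(
    tp: np.ndarray,
    k: int,
    inhibition_radius: int = 0,
    suppress_feature_map: bool = True,
) -> list[Winner]:
    """Select up to ``k`` winners from a thresholded potentials tensor.

    Winners are chosen iteratively: earliest firing step first, ties broken
    by the largest final potential, remaining ties by the lowest
    ``(feature, row, col)`` triplet.  After each pick the winner's spatial
    neighbourhood (Chebyshev distance ``<= inhibition_radius``, all feature
    maps; a radius of 0 suppresses nothing spatially) and — with
    ``suppress_feature_map`` — its whole feature map are removed from the
    candidate pool, so successive winners have distinct features and
    non-overlapping neighbourhoods.  Returns fewer than ``k`` winners when
    the candidates run out.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if inhibition_radius < 0:
        raise ValueError(f"inhibition_radius must be >= 0, got {inhibition_radius}")
    tp = np.asarray(tp)
    if tp.ndim != 4:
        raise ValueError(f"expected 4-D thresholded potentials, got {tp.shape}")
    first, fired = _firing_steps(tp)
    final_pot = tp[-1]
    _, n_rows, n_cols = fired.shape

    allowed = fired.copy()
    winners: list[Winner] = []
    for _ in range(k):
        if not allowed.any():
            break
        steps = np.where(allowed, first, np.iinfo(np.int64).max)
        best_step = steps.min()
        at_step = allowed & (steps == best_step)
        pots = np.where(at_step, final_pot, -np.inf)
        # argmax on the flattened row-major array returns the first maximum,
        # i.e. the lexicographically smallest (feature, row, col).
        flat = int(np.argmax(pots))
        f, r, c = np.unravel_index(flat, pots.shape)
        winners.append(
            Winner(int(f), int(r), int(c), int(best_step), float(final_pot[f, r, c]))
        )
        if suppress_feature_map:
            allowed[f] = False
        if inhibition_radius > 0:
            r0, r1 = max(0, r - inhibition_radius), r + inhibition_radius + 1
            c0, c1 = max(0, c - inhibition_radius), c + inhibition_radius + 1
            allowed[:, r0:r1, c0:c1] = False
        else:
            allowed[f, r, c] = False
    return winners


def lateral_inhibition_mask(
    shape: tuple[int, int, int], winners: Iterable[Winner], radius: int
) -> np.ndarray:
    """Binary mask that silences each winner's surround in all feature maps.

    Zeros fill the square of half-side ``radius`` around every winner's
    ``(row, col)`` across every feature; the winners' own cells stay 1.
    A radius of 0 denotes an empty surround, so the mask is all ones.
    """
    if radius < 0:
        raise ValueError(f"radius must be >= 0, got {radius}")
    mask = np.ones(shape, dtype=np.uint8)
    winners = list(winners)
    if radius > 0:
        for w in winners:
            r0, r1 = max(0, w.row - radius), w.row + radius + 1
            c0, c1 = max(0, w.col - radius), w.col + radius + 1
            mask[:, r0:r1, c0:c1] = 0
        for w in winners:
            mask[w.feature, w.row, w.col] = 1
    return mask


def pointwise_inhibition(tp: np.ndarray) -> np.ndarray:
    """Keep, at each location, only the most salient feature's spike column.

    Salience mirrors winner selection: the earliest-firing feature wins,
    ties go to the larger final potential, then to the lower feature index.
    Locations where no feature fires stay silent.  Returns a spike-wave.
    """
    tp = np.asarray(tp)
    if tp.ndim != 4:
        raise ValueError(f"expected 4-D thresholded potentials, got {tp.shape}")
    first, fired = _firing_steps(tp)
    final_pot = tp[-1]

    steps = np.where(fired, first, np.iinfo(np.int64).max)
    best_step = steps.min(axis=0, keepdims=True)  # (1, H, W)
    at_step = fired & (steps == best_step)
    pots = np.where(at_step, final_pot, -np.inf)
    best_feature = np.argmax(pots, axis=0)  # first max -> lowest feature index

    columns = (tp != 0).astype(np.uint8)  # (T, F, H, W)
    winner_col = np.take_along_axis(
        columns, best_feature[np.newaxis, np.newaxis], axis=1
    )  # (T, 1, H, W)
    out = np.zeros_like(columns)
    any_fired = fired.any(axis=0)[np.newaxis, np.newaxis]
    np.put_along_axis(
        out, best_feature[np.newaxis, np.newaxis], winner_col * any_fired, axis=1
    )
    return out


def feature_inhibition(wave: np.ndarray, features: Sequence[int]) -> np.ndarray:
    """Silence the listed feature maps at every time-step (dropout-style)."""
    wave = np.asarray(wave)
    n_features = wave.shape[1]
    features = list(features)
    for f in features:
        if not 0 <= f < n_features:
            raise IndexError(f"feature index {f} out of range [0, {n_features})")
    out = wave.copy()
    if features:
        out[:, features] = 0
    return out
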