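"""Spiking convolution, pooling, padding and firing operators.

All operators act on 4-D ``(time, feature, row, col)`` tensors.  Because
spike-waves are accumulative, a single valid cross-correlation applied to
every time-slice yields, at slice ``t``, the total membrane potential
contributed by all spikes up to step ``t`` — no explicit integration loop
over time is needed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


@dataclass
class ConvLayer:
    """A spiking convolutional layer: a bank of ``F_out`` synaptic kernels.

    ``weights`` has shape ``(F_out, F_in, K_h, K_w)``.  Weights are plain
    synaptic efficacies (no bias, no gradient); plasticity rules mutate
    them in place.
    """

    weights: np.ndarray
    init_mean: float = 0.8
    init_std: float = 0.05

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.weights.ndim != 4:
            raise ValueError(
                f"weights must be 4-D (F_out, F_in, K_h, K_w), got {self.weights.shape}"
            )
        if not np.isfinite(self.weights).all():
            raise ValueError("weights must be finite")

    @classmethod
    def init(
        cls,
        in_features: int,
        out_features: int,
        kernel_size: int | tuple[int, int],
        mean: float = 0.8,
        std: float = 0.05,
        rng: np.random.Generator | None = None,
    ) -> "ConvLayer":
        """Create a layer with normally distributed random weights."""
        if isinstance(kernel_size, int):
            kernel_size = (kernel_size, kernel_size)
        rng = np.random.default_rng() if rng is None else rng
        w = rng.normal(mean, std, size=(out_features, in_features, *kernel_size))
        return cls(weights=w, init_mean=mean, init_std=std)

    @property
    def out_features(self) -> int:
        return self.weights.shape[0]

    @property
    def in_features(self) -> int:
        return self.weights.shape[1]

    @property
    def kernel_size(self) -> tuple[int, int]:
        return self.weights.shape[2], self.weights.shape[3]


@dataclass
class PoolSpec:
    """Max-pooling geometry: window, stride (defaults to window), padding.

    The output spatial size is ``floor((H_in + 2*D_h) / R_h)`` by
    ``floor((W_in + 2*D_w) / R_w)``; windows that would run past the padded
    border are truncated so this size is always realizable.
    """

    window: tuple[int, int]
    stride: tuple[int, int] | None = None
    padding: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if isinstance(self.window, int):
            self.window = (self.window, self.window)
        if isinstance(self.stride, int):
            self.stride = (self.stride, self.stride)
        if isinstance(self.padding, int):
            self.padding = (self.padding, self.padding)
        if self.stride is None:
            self.stride = self.window
        if min(self.window) < 1 or min(self.stride) < 1 or min(self.padding) < 0:
            raise ValueError(f"invalid pooling spec {self}")

    def out_size(self, in_size: tuple[int, int]) -> tuple[int, int]:
        h = (in_size[0] + 2 * self.padding[0]) // self.stride[0]
        w = (in_size[1] + 2 * self.padding[1]) // self.stride[1]
        return h, w


def conv_forward(wave: np.ndarray, layer: ConvLayer) -> np.ndarray:
    """Valid-mode spiking convolution (stride 1) of a wave with a layer.

    Every time-slice of the input is cross-correlated with the weight
    kernels and summed over input features.  On an accumulative spike-wave
    the output slice at step ``t`` equals the accumulated potential from all
    input spikes at steps ``<= t``.

    Returns a potentials tensor of shape
    ``(T_max, F_out, H_in - K_h + 1, W_in - K_w + 1)``.
    """
    wave = np.asarray(wave)
    if wave.ndim != 4:
        raise ValueError(f"input must be 4-D (T, F, H, W), got {wave.shape}")
    t_max, f_in, h_in, w_in = wave.shape
    f_out, f_in_l, k_h, k_w = layer.weights.shape
    if f_in != f_in_l:
        raise ValueError(f"input has {f_in} features, layer expects {f_in_l}")
    if h_in < k_h or w_in < k_w:
        raise ValueError(
            f"kernel {k_h}x{k_w} larger than input {h_in}x{w_in} (valid mode)"
        )
    # (T, F_in, H', W', K_h, K_w) windows; contract with (F_out, F_in, K_h, K_w).
    windows = sliding_window_view(wave, (k_h, k_w), axis=(2, 3))
    return np.einsum(
        "tfhwij,ofij->tohw", windows.astype(np.float64), layer.weights, optimize=True
    )


def pad_wave(wave: np.ndarray, padding: int | tuple[int, int]) -> np.ndarray:
    """Zero-pad the two spatial axes of a wave; padding neurons never spike."""
    if isinstance(padding, int):
        padding = (padding, padding)
    if min(padding) < 0:
        raise ValueError(f"padding must be non-negative, got {padding}")
    wave = np.asarray(wave)
    return np.pad(wave, ((0, 0), (0, 0), (padding[0],) * 2, (padding[1],) * 2))


def pool(x: np.ndarray, spec: PoolSpec) -> np.ndarray:
    """Max-pool a spike-wave or potentials tensor per time-step and feature.

    On an accumulative spike-wave the window max is exactly the earliest
    spike within the window; on potentials it is the strongest neuron.
    Windows are anchored at multiples of the stride on the padded input and
    truncated at the border.
    """
    x = np.asarray(x)
    if x.ndim != 4:
        raise ValueError(f"input must be 4-D (T, F, H, W), got {x.shape}")
    (p_h, p_w), (r_h, r_w), (d_h, d_w) = spec.window, spec.stride, spec.padding
    padded = np.pad(x, ((0, 0), (0, 0), (d_h, d_h), (d_w, d_w)))
    h_pad, w_pad = padded.shape[2:]
    h_out, w_out = spec.out_size(x.shape[2:])
    if h_out < 1 or w_out < 1:
        raise ValueError(
            f"pooling stride {spec.stride} exceeds padded input {h_pad}x{w_pad}"
        )
    out = np.empty((x.shape[0], x.shape[1], h_out, w_out), dtype=x.dtype)
    for i in range(h_out):
        r0 = i * r_h
        r1 = min(r0 + p_h, h_pad)
        for j in range(w_out):
            c0 = j * r_w
            c1 = min(c0 + p_w, w_pad)
            out[:, :, i, j] = padded[:, :, r0:r1, c0:c1].max(axis=(2, 3))
    return out


def fire(
    p: np.ndarray, threshold: float, return_thresholded: bool = False
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Convert potentials into spikes: spike wherever potential > threshold.

    On accumulative potentials produced from a spike-wave with non-negative
    weights, the result is itself a valid accumulative wave: a neuron
    "fires" from its first threshold crossing onward, i.e. at most one
    spike.  With ``return_thresholded`` the thresholded potentials
    (:func:`threshold_op`) are returned as well, as needed by winner
    selection and plasticity.
    """
    p = np.asarray(p)
    wave = (p > threshold).astype(np.uint8)
    if return_thresholded:
        return wave, threshold_op(p, threshold)
    return wave


def fire_infinite(
    p: np.ndarray, return_thresholded: bool = False
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Infinite-threshold firing: only the final time-step can spike.

    Used for a decision layer read out by maximum potential: the wave is
    zero everywhere except the last step, where every neuron with a nonzero
    accumulated potential emits its (single) spike.  The optional second
    output is the potentials tensor with all pre-final slices zeroed.
    """
    p = np.asarray(p)
    if p.shape[0] < 1:
        raise ValueError("potentials tensor needs at least one time-step")
    wave = np.zeros(p.shape, dtype=np.uint8)
    wave[-1] = (p[-1] != 0).astype(np.uint8)
    if return_thresholded:
        tp = np.zeros_like(p, dtype=np.float64)
        tp[-1] = p[-1]
        return wave, tp
    return wave


def threshold_op(p: np.ndarray, threshold: float) -> np.ndarray:
    """Zero out every potential strictly below the threshold ("thresholded
    potentials"); entries at or above the threshold pass through unchanged."""
    p = np.asarray(p, dtype=np.float64)
    return np.where(p < threshold, 0.0, p)
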