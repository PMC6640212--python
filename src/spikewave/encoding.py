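"""Image-to-spike encoding: filter banks, normalization, rank-order latency.

The visual front-end follows the classic retina-inspired recipe: an input
image is passed through a bank of contrast detectors (difference-of-
Gaussians or Gabor kernels), responses are locally normalized and
optionally sparsified by intensity lateral inhibition, and the resulting
saliency map is converted to spike latencies by rank order — the stronger
the response, the earlier the (single) spike.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .core import NO_SPIKE, SpikeTimeGrid, spike_times_to_wave


def _grid(window_size: int) -> tuple[np.ndarray, np.ndarray]:
    if window_size < 1 or window_size % 2 == 0:
        raise ValueError(f"window_size must be odd and positive, got {window_size}")
    half = window_size // 2
    y, x = np.mgrid[-half : half + 1, -half : half + 1]
    return x.astype(np.float64), y.astype(np.float64)


def make_dog_kernel(
    window_size: int, sigma_center: float, sigma_surround: float
) -> np.ndarray:
    """Difference-of-Gaussians contrast kernel on an odd square window.

    The kernel is the difference of two unit-mass isotropic Gaussians
    (center minus surround), mean-subtracted so that uniform regions give a
    zero response.  ``sigma_center < sigma_surround`` yields an on-center
    detector; swapping the widths negates the kernel (off-center).
    """
    if sigma_center <= 0 or sigma_surround <= 0:
        raise ValueError("Gaussian widths must be positive")
    if sigma_center == sigma_surround:
        raise ValueError("sigma_center and sigma_surround must differ")
    x, y = _grid(window_size)
    r2 = x**2 + y**2

    def gauss(sigma: float) -> np.ndarray:
        return np.exp(-r2 / (2 * sigma**2)) / (2 * np.pi * sigma**2)

    kernel = gauss(sigma_center) - gauss(sigma_surround)
    return kernel - kernel.mean()


def make_gabor_kernel(
    window_size: int,
    wavelength: float,
    orientation: float,
    width: float,
    aspect: float = 1.0,
) -> np.ndarray:
    """Even-symmetric (cosine-phase) Gabor kernel, mean-subtracted.

    ``orientation`` is in radians; ``width`` is the Gaussian envelope sigma
    and ``aspect`` its ellipticity.  Even symmetry makes orientations theta
    and theta + pi equivalent.
    """
    if wavelength <= 0 or width <= 0 or aspect <= 0:
        raise ValueError("wavelength, width and aspect must be positive")
    x, y = _grid(window_size)
    x_r = x * np.cos(orientation) + y * np.sin(orientation)
    y_r = -x * np.sin(orientation) + y * np.cos(orientation)
    kernel = np.exp(-(x_r**2 + (aspect * y_r) ** 2) / (2 * width**2)) * np.cos(
        2 * np.pi * x_r / wavelength
    )
    return kernel - kernel.mean()


@dataclass
class FilterBank:
    """An ordered bank of same-size kernels with shared padding and clip.

    Applying the bank to an ``H x W`` image yields one feature map per
    kernel; with ``padding = window // 2`` the spatial size is preserved.
    Responses below ``clip_threshold`` are set to zero, discarding weak
    (and, with the default 0, all inhibitory) responses.
    """

    kernels: list[np.ndarray] = field(default_factory=list)
    padding: int = 0
    clip_threshold: float = 0.0

    def __post_init__(self) -> None:
        self.kernels = [np.asarray(k, dtype=np.float64) for k in self.kernels]
        if not self.kernels:
            raise ValueError("filter bank needs at least one kernel")
        shape = self.kernels[0].shape
        for k in self.kernels:
            if k.ndim != 2 or k.shape != shape:
                raise ValueError(
                    f"all kernels must share one 2-D window size, got {k.shape} vs {shape}"
                )
        if self.padding < 0:
            raise ValueError("padding must be non-negative")

    @property
    def window_size(self) -> int:
        return self.kernels[0].shape[0]


def apply_filter_bank(image: np.ndarray, bank: FilterBank) -> np.ndarray:
    """Cross-correlate each kernel with the zero-padded image and clip.

    Returns a ``(F_bank, H_out, W_out)`` intensity map with
    ``H_out = H + 2 * padding - window + 1`` (spatial size preserved when
    ``padding = window // 2``).
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError(f"image must be 2-D, got shape {image.shape}")
    k_h, k_w = bank.kernels[0].shape
    padded = np.pad(image, bank.padding)
    if padded.shape[0] < k_h or padded.shape[1] < k_w:
        raise ValueError(
            f"padded image {padded.shape} smaller than kernel window {k_h}x{k_w}"
        )
    from numpy.lib.stride_tricks import sliding_window_view

    windows = sliding_window_view(padded, (k_h, k_w))
    out = np.einsum("hwij,fij->fhw", windows, np.stack(bank.kernels), optimize=True)
    out[out < bank.clip_threshold] = 0.0
    return out


def local_normalization(
    intensity_map: np.ndarray, region_size: int, eps: float = 1e-12
) -> np.ndarray:
    """Divide each value by the mean of its square neighbourhood.

    The neighbourhood mean uses edge replication at the borders, so a
    constant map normalizes to 1 everywhere, and scaling the input by a
    positive constant leaves the output (asymptotically in ``eps``)
    unchanged.  ``eps`` is a small floor on the regional mean that guards
    dark regions against division by zero.
    """
    if region_size < 1 or region_size % 2 == 0:
        raise ValueError(f"region_size must be odd and positive, got {region_size}")
    intensity_map = np.asarray(intensity_map, dtype=np.float64)
    means = ndimage.uniform_filter(
        intensity_map, size=(1,) * (intensity_map.ndim - 2) + (region_size, region_size),
        mode="nearest",
    )
    return intensity_map / (means + eps)


def generate_inhibition_kernel(factors: Sequence[float]) -> np.ndarray:
    """Build a square suppression kernel from per-ring inhibition factors.

    ``factors[d - 1]`` is the multiplicative suppression applied at
    Chebyshev distance ``d`` from a salient point; the kernel has side
    ``2 * len(factors) + 1`` and value 1 at its center.
    """
    factors = list(factors)
    if not factors:
        raise ValueError("need at least one inhibition factor")
    if any(not 0.0 <= f <= 1.0 for f in factors):
        raise ValueError(f"inhibition factors must lie in [0, 1], got {factors}")
    n = len(factors)
    y, x = np.mgrid[-n : n + 1, -n : n + 1]
    dist = np.maximum(np.abs(x), np.abs(y))
    kernel = np.ones((2 * n + 1, 2 * n + 1))
    for d in range(1, n + 1):
        kernel[dist == d] = factors[d - 1]
    return kernel


def intensity_lateral_inhibition(
    intensity_map: np.ndarray, inhibition_kernel: np.ndarray
) -> np.ndarray:
    """Let salient points suppress their neighbours' intensities.

    Pixels are visited in descending order of their *input* intensity
    (row-major on ties), independently per feature map.  A pixel that has
    already been suppressed below its input value loses its right to
    suppress others.  Suppression multiplies each neighbour by the kernel
    factor at the corresponding offset, so no intensity ever increases.
    """
    inhibition_kernel = np.asarray(inhibition_kernel, dtype=np.float64)
    if (
        inhibition_kernel.ndim != 2
        or inhibition_kernel.shape[0] != inhibition_kernel.shape[1]
        or inhibition_kernel.shape[0] % 2 == 0
    ):
        raise ValueError("inhibition kernel must be an odd square matrix")
    if inhibition_kernel.min() < 0 or inhibition_kernel.max() > 1:
        raise ValueError("inhibition factors must lie in [0, 1]")
    intensity_map = np.asarray(intensity_map, dtype=np.float64)
    squeeze = intensity_map.ndim == 2
    maps = intensity_map[np.newaxis] if squeeze else intensity_map.copy()
    if maps.ndim != 3:
        raise ValueError("intensity map must be 2-D or 3-D (feature, row, col)")

    radius = inhibition_kernel.shape[0] // 2
    h, w = maps.shape[1:]
    out = maps.copy()
    for f in range(maps.shape[0]):
        original = maps[f]
        current = out[f]
        order = np.argsort(-original, axis=None, kind="stable")
        for flat in order:
            r, c = divmod(int(flat), w)
            val = original[r, c]
            if val <= 0:
                break  # remaining pixels are not salient
            if current[r, c] < val:
                continue  # already suppressed; loses its salience
            r0, c0 = max(0, r - radius), max(0, c - radius)
            r1, c1 = min(h, r + radius + 1), min(w, c + radius + 1)
            patch = inhibition_kernel[
                r0 - r + radius : r1 - r + radius, c0 - c + radius : c1 - c + radius
            ].copy()
            patch[r - r0, c - c0] = 1.0  # never self-suppress
            current[r0:r1, c0:c1] *= patch
    return out[0] if squeeze else out


def intensity_to_latency(intensity_map: np.ndarray, t_max: int) -> np.ndarray:
    """Rank-order latency coding: strong responses spike early.

    The nonzero intensities are sorted in descending order (row-major scan
    on ties) and partitioned into ``t_max`` near-equal bins; the first
    ``count mod t_max`` bins take one extra element.  Elements of bin ``k``
    spike at step ``k``; zero intensities never spike.  Returns a valid
    accumulative spike-wave of shape ``(t_max, F, H, W)``.
    """
    if t_max < 1:
        raise ValueError(f"t_max must be >= 1, got {t_max}")
    intensity_map = np.asarray(intensity_map, dtype=np.float64)
    if intensity_map.ndim == 2:
        intensity_map = intensity_map[np.newaxis]
    if intensity_map.ndim != 3:
        raise ValueError("intensity map must be 2-D or 3-D (feature, row, col)")

    flat = intensity_map.reshape(-1)
    nonzero = np.flatnonzero(flat)
    order = nonzero[np.argsort(-flat[nonzero], kind="stable")]
    n = order.size

    times = np.full(flat.shape, NO_SPIKE, dtype=np.int64)
    if n:
        base, extra = divmod(n, t_max)
        sizes = np.full(t_max, base)
        sizes[:extra] += 1
        bins = np.repeat(np.arange(t_max), sizes)
        times[order] = bins
    grid = SpikeTimeGrid(times=times.reshape(intensity_map.shape), t_max=t_max)
    return spike_times_to_wave(grid)
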