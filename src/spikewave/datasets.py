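"""Synthetic class-structured image generation and the default encoder.

The generator produces small grayscale images of oriented bars — one
orientation per class, with positional jitter and additive noise — sized so
the three-stage tutorial geometry (padded 5x5 / 3x3 / 5x5 kernels) elicits
spikes at every stage.  It stands in for a real digit dataset at desk
scale: the class structure is carried entirely by edge orientation, which
is exactly what the DoG front-end plus STDP feature learning can pick up.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encoding import (
    FilterBank,
    apply_filter_bank,
    intensity_to_latency,
    local_normalization,
    make_dog_kernel,
)

#: On/off-center DoG pairs at three scales (center sigma, surround sigma).
DEFAULT_DOG_SIGMAS: tuple[tuple[float, float], ...] = (
    (1.0, 2.0),
    (2.0, 1.0),
    (0.7, 1.4),
    (1.4, 0.7),
    (1.5, 3.0),
    (3.0, 1.5),
)


@dataclass
class LabeledImages:
    """A bundle of grayscale images with integer class labels."""

    images: np.ndarray  # (N, H, W), float in [0, 1]
    labels: np.ndarray  # (N,)

    def __len__(self) -> int:
        return len(self.images)

    def __getitem__(self, index: int) -> tuple[np.ndarray, int]:
        return self.images[index], int(self.labels[index])


def _bar_image(
    size: int, angle: float, offset: tuple[float, float], thickness: float, length: float
) -> np.ndarray:
    """Render one soft-edged oriented bar through the (offset) image center."""
    half = (size - 1) / 2.0
    y, x = np.mgrid[0:size, 0:size].astype(np.float64)
    x = x - half - offset[1]
    y = y - half - offset[0]
    along = x * np.cos(angle) + y * np.sin(angle)
    across = -x * np.sin(angle) + y * np.cos(angle)
    profile = np.exp(-(across**2) / (2 * thickness**2))
    profile[np.abs(along) > length / 2] = 0.0
    return profile


def generate_synthetic_dataset(
    n_classes: int = 2,
    samples_per_class: int = 100,
    image_size: int = 24,
    noise_level: float = 0.05,
    seed: int | np.random.Generator = 0,
    jitter: int = 2,
) -> LabeledImages:
    """Generate a deterministic-per-seed oriented-bar image set.

    Class ``k`` is a bar at angle ``k * pi / n_classes`` (class 0
    horizontal, the rest evenly spaced) crossed with a short orthogonal
    stub to break symmetry, plus integer positional jitter of up to
    ``jitter`` pixels and additive Gaussian noise of standard deviation
    ``noise_level``.  Images are float arrays in [0, 1]; samples are
    interleaved over classes.
    """
    if n_classes < 2:
        raise ValueError(f"need at least 2 classes, got {n_classes}")
    if image_size < 12:
        raise ValueError(f"image_size too small for the tutorial geometry: {image_size}")
    if samples_per_class < 1:
        raise ValueError("samples_per_class must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    n = n_classes * samples_per_class
    images = np.empty((n, image_size, image_size))
    labels = np.empty(n, dtype=np.int64)
    length = 0.75 * image_size
    for i in range(n):
        label = i % n_classes
        angle = label * np.pi / n_classes
        off = rng.integers(-jitter, jitter + 1, size=2).astype(np.float64) if jitter else np.zeros(2)
        img = _bar_image(image_size, angle, (off[0], off[1]), thickness=1.2, length=length)
        if noise_level > 0:
            img = img + rng.normal(0.0, noise_level, img.shape)
        images[i] = np.clip(img, 0.0, 1.0)
        labels[i] = label
    return LabeledImages(images=images, labels=labels)


def default_encoder(
    window_size: int = 7,
    sigmas: tuple[tuple[float, float], ...] = DEFAULT_DOG_SIGMAS,
    clip_threshold: float = 0.01,
    normalization_region: int = 9,
    t_max: int = 15,
):
    """Build the standard image-to-spike transform.

    Six DoG channels (on/off at three scales) with same-size padding, weak
    responses clipped, local mean normalization, then rank-order
    intensity-to-latency conversion over ``t_max`` time-steps.  Returns a
    callable mapping a 2-D image to a ``(t_max, 6, H, W)`` spike-wave.
    """
    bank = FilterBank(
        kernels=[make_dog_kernel(window_size, sc, ss) for sc, ss in sigmas],
        padding=window_size // 2,
        clip_threshold=clip_threshold,
    )

    def encode(image: np.ndarray) -> np.ndarray:
        responses = apply_filter_bank(image, bank)
        responses = local_normalization(responses, normalization_region)
        return intensity_to_latency(responses, t_max)

    return encode


def encode_dataset(dataset: LabeledImages, encoder=None) -> tuple[list[np.ndarray], list[int]]:
    """Encode every image of a labeled set into spike-waves."""
    encoder = default_encoder() if encoder is None else encoder
    waves = [encoder(img) for img in dataset.images]
    labels = [int(l) for l in dataset.labels]
    return waves, labels
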