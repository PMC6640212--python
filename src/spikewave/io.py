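"""Serialization and dataset plumbing.

Tensors interchange through a two-line plain-text format: the first line
holds the comma-separated shape, the second the comma-separated values in
row-major order.  Floats are written with shortest round-tripping decimal
representation, so read-after-write is bit-exact.  Also provides a caching
dataset wrapper (memory or disk), a reader for the standard IDX raster
format, and text-based network checkpoints.
"""

from __future__ import annotations

import struct
import warnings
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .layers import ConvLayer


class TensorFormatError(ValueError):
    """Raised when a text tensor file is malformed."""


def tensor_to_text(tensor: np.ndarray, destination: str | Path) -> None:
    """Write a tensor to the two-line text interchange format."""
    tensor = np.asarray(tensor)
    if tensor.ndim == 0:
        tensor = tensor.reshape(1)
    shape_line = ",".join(str(int(s)) for s in tensor.shape)
    flat = tensor.reshape(-1)
    if np.issubdtype(tensor.dtype, np.integer) or tensor.dtype == bool:
        values = (str(int(v)) for v in flat)
    else:
        values = (repr(float(v)) for v in flat)
    with open(destination, "w") as fh:
        fh.write(shape_line + "\n")
        fh.write(",".join(values) + "\n")


def text_to_tensor(source: str | Path) -> np.ndarray:
    """Read a tensor written by :func:`tensor_to_text`.

    Integer-valued files load as ``int64``, anything else as ``float64``.

    Raises
    ------
    TensorFormatError
        With a line diagnosis when the shape line is invalid or the value
        count does not match the shape product.
    """
    with open(source) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 2:
        raise TensorFormatError(
            f"{source}: expected 2 lines (shape, values), found {len(lines)}"
        )
    try:
        shape = tuple(int(tok) for tok in lines[0].split(","))
    except ValueError as exc:
        raise TensorFormatError(f"{source}: line 1 is not a comma-separated shape: {exc}")
    if any(s < 0 for s in shape):
        raise TensorFormatError(f"{source}: line 1 contains a negative dimension")
    tokens = lines[1].split(",") if lines[1] else []
    expected = int(np.prod(shape)) if shape else 0
    if len(tokens) != expected:
        raise TensorFormatError(
            f"{source}: line 2 has {len(tokens)} values, shape {shape} needs {expected}"
        )
    try:
        if all("." not in t and "e" not in t and "E" not in t and t not in ("inf", "-inf", "nan") for t in tokens):
            flat = np.array([int(t) for t in tokens], dtype=np.int64)
        else:
            flat = np.array([float(t) for t in tokens], dtype=np.float64)
    except ValueError as exc:
        raise TensorFormatError(f"{source}: line 2 contains a malformed value: {exc}")
    return flat.reshape(shape)


class CachedDataset:
    """Cache a transformed dataset in memory or on disk.

    Wraps a base sequence of ``(sample, label)`` pairs and a deterministic
    ``transform``; the transform runs once per index, after which accesses
    return the cached tensor bit-identically.  With ``cache_dir`` set the
    cache lives on disk (text tensors, surviving process restarts), else in
    memory.  A corrupted disk entry is recomputed transparently with a
    warning.
    """

    def __init__(
        self,
        base: Sequence[tuple[np.ndarray, int]],
        transform: Callable[[np.ndarray], np.ndarray] | None = None,
        cache_dir: str | Path | None = None,
    ) -> None:
        self.base = base
        self.transform = transform if transform is not None else lambda x: x
        self.cache_dir = Path(cache_dir) if cache_dir is not None else None
        if self.cache_dir is not None:
            self.cache_dir.mkdir(parents=True, exist_ok=True)
        self._memory: dict[int, np.ndarray] = {}
        self.hits = 0
        self.misses = 0

    def __len__(self) -> int:
        return len(self.base)

    def _entry_path(self, index: int) -> Path:
        assert self.cache_dir is not None
        return self.cache_dir / f"sample_{index:06d}.txt"

    def __getitem__(self, index: int) -> tuple[np.ndarray, int]:
        sample, label = self.base[index]
        if self.cache_dir is None:
            if index in self._memory:
                self.hits += 1
                return self._memory[index], label
            self.misses += 1
            value = self.transform(sample)
            self._memory[index] = value
            return value, label
        path = self._entry_path(index)
        if path.exists():
            try:
                value = text_to_tensor(path)
                self.hits += 1
                return value, label
            except TensorFormatError as exc:
                warnings.warn(
                    f"corrupted cache entry {path} ({exc}); recomputing", stacklevel=2
                )
        self.misses += 1
        value = self.transform(sample)
        tensor_to_text(value, path)
        return value, label

    def __iter__(self):
        for i in range(len(self)):
            yield self[i]


_IDX_DTYPES = {
    0x08: np.uint8,
    0x09: np.int8,
    0x0B: np.dtype(">i2"),
    0x0C: np.dtype(">i4"),
    0x0D: np.dtype(">f4"),
    0x0E: np.dtype(">f8"),
}


def read_idx(source: str | Path) -> np.ndarray:
    """Read an IDX raster file (the format of the standard MNIST dumps).

    No download is performed; this is an adapter for user-supplied files.
    """
    with open(source, "rb") as fh:
        magic = fh.read(4)
        if len(magic) != 4 or magic[0] != 0 or magic[1] != 0:
            raise ValueError(f"{source}: not an IDX file (bad magic {magic!r})")
        dtype_code, ndim = magic[2], magic[3]
        if dtype_code not in _IDX_DTYPES:
            raise ValueError(f"{source}: unknown IDX dtype code 0x{dtype_code:02x}")
        dims = struct.unpack(f">{ndim}I", fh.read(4 * ndim))
        data = np.frombuffer(fh.read(), dtype=_IDX_DTYPES[dtype_code])
    if data.size != int(np.prod(dims)):
        raise ValueError(f"{source}: payload size does not match header dims {dims}")
    return data.reshape(dims)


CHECKPOINT_VERSION = 1


def save_network_weights(net, directory: str | Path) -> None:
    """Dump every stage's weight tensor as text files plus a version tag."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    (directory / "VERSION").write_text(f"{CHECKPOINT_VERSION}\n")
    for i, stage in enumerate(net.stages):
        tensor_to_text(stage.layer.weights, directory / f"stage_{i}.txt")


def load_network_weights(net, directory: str | Path) -> None:
    """Restore stage weights saved by :func:`save_network_weights`."""
    directory = Path(directory)
    version = int((directory / "VERSION").read_text().strip())
    if version != CHECKPOINT_VERSION:
        raise ValueError(f"unsupported checkpoint version {version}")
    for i, stage in enumerate(net.stages):
        weights = text_to_tensor(directory / f"stage_{i}.txt").astype(np.float64)
        if weights.shape != stage.layer.weights.shape:
            raise ValueError(
                f"stage {i} checkpoint shape {weights.shape} does not match "
                f"layer shape {stage.layer.weights.shape}"
            )
        stage.layer.weights = weights
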