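"""Reference experiments: pattern selectivity and the end-to-end benchmark.

Both experiments are deterministic given a seed and sized to run in well
under a minute each on one CPU core; they are used by the test suite and
the reproduction script alike.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .competition import get_k_winners
from .core import NO_SPIKE, SpikeTimeGrid, spike_times_to_wave
from .datasets import default_encoder, encode_dataset, generate_synthetic_dataset
from .layers import ConvLayer, conv_forward, fire
from .network import EvalCounters, evaluate, train_rl, train_unsupervised, tutorial_network
from .plasticity import StdpRule, stdp_step


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    a = a.reshape(-1).astype(np.float64)
    b = b.reshape(-1).astype(np.float64)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


@dataclass
class SelectivityResult:
    """Outcome of the recurring-pattern STDP experiment."""

    best_cosine: float
    per_feature_cosine: np.ndarray
    n_presentations: int


def run_pattern_selectivity(
    seed: int,
    grid_size: int = 8,
    pattern_size: int = 20,
    n_features: int = 4,
    t_max: int = 10,
    n_presentations: int = 400,
    pattern_prob: float = 0.5,
    pattern_span: int = 4,
    noise_spikes: int = 12,
    threshold: float = 13.0,
    rule: StdpRule | None = None,
) -> SelectivityResult:
    """Expose one STDP conv layer to a recurring spike pattern among noise.

    A fixed set of ``pattern_size`` afferents (out of ``grid_size**2``)
    fires with fixed early latencies (within the first ``pattern_span``
    steps) on a random half of the presentations; on every presentation
    ``noise_spikes`` random afferents fire at random times.  The kernel
    covers the whole input grid, so the layer is a bank of ``n_features``
    single neurons competing by winner-take-all.  STDP should concentrate
    the winning neuron's weights on the pattern afferents: the result
    reports the cosine similarity between each feature's weight vector and
    the pattern's binary indicator.

    The operating point matters: the firing threshold sits just below the
    pattern's total drive, so the winner's first spike falls at the end of
    the pattern (every pattern afferent is then potentiated), while
    noise-only presentations stay sub-threshold and trigger no plasticity.
    """
    rng = np.random.default_rng(seed)
    n_afferents = grid_size * grid_size
    if not 0 < pattern_size < n_afferents:
        raise ValueError("pattern_size must be in (0, n_afferents)")
    rule = rule or StdpRule(0.1, -0.075, 0.0, 1.0, use_stabilizer=True)

    pattern_idx = rng.choice(n_afferents, size=pattern_size, replace=False)
    # recurring pattern: fixed afferents, fixed early latencies
    pattern_times = rng.integers(0, pattern_span, size=pattern_size)
    indicator = np.zeros(n_afferents)
    indicator[pattern_idx] = 1.0

    layer = ConvLayer.init(1, n_features, grid_size, mean=0.8, std=0.05, rng=rng)

    for _ in range(n_presentations):
        times = np.full(n_afferents, NO_SPIKE, dtype=np.int64)
        noisy = rng.choice(n_afferents, size=noise_spikes, replace=False)
        times[noisy] = rng.integers(0, t_max, size=noise_spikes)
        if rng.random() < pattern_prob:
            times[pattern_idx] = pattern_times
        wave = spike_times_to_wave(
            SpikeTimeGrid(times.reshape(1, grid_size, grid_size), t_max)
        )
        p = conv_forward(wave, layer)
        spikes, tp = fire(p, threshold, return_thresholded=True)
        winners = get_k_winners(tp, k=1, inhibition_radius=0)
        if winners:
            stdp_step(rule, wave, tp, spikes, winners, layer)

    cosines = np.array(
        [_cosine(layer.weights[f], indicator) for f in range(n_features)]
    )
    return SelectivityResult(
        best_cosine=float(cosines.max()),
        per_feature_cosine=cosines,
        n_presentations=n_presentations,
    )


@dataclass
class BenchmarkResult:
    """Outcome of the three-stage network on the synthetic oriented-bar task."""

    train_history: list[EvalCounters]
    best_train_accuracy: float
    final_train_accuracy: float
    test_counters: EvalCounters
    n_train: int
    n_test: int


def run_tutorial_benchmark(
    seed: int,
    n_classes: int = 2,
    samples_per_class: int = 100,
    test_samples_per_class: int = 30,
    stdp_epochs: tuple[int, int] = (2, 2),
    rstdp_epochs: int = 20,
    noise_level: float = 0.05,
) -> BenchmarkResult:
    """Train the preset network layer-wise on the synthetic bar dataset.

    S1 and S2 are trained by unsupervised STDP for ``stdp_epochs`` epochs
    each, then the decision layer by R-STDP for up to ``rstdp_epochs``
    epochs, after which a held-out set is evaluated.  All randomness
    (dataset, weight init) derives from ``seed``.
    """
    rng = np.random.default_rng(seed)
    train_set = generate_synthetic_dataset(
        n_classes=n_classes,
        samples_per_class=samples_per_class,
        noise_level=noise_level,
        seed=rng,
    )
    test_set = generate_synthetic_dataset(
        n_classes=n_classes,
        samples_per_class=test_samples_per_class,
        noise_level=noise_level,
        seed=rng,
    )
    encoder = default_encoder()
    train_waves, train_labels = encode_dataset(train_set, encoder)
    test_waves, test_labels = encode_dataset(test_set, encoder)

    net = tutorial_network(n_classes=n_classes, seed=rng)
    train_unsupervised(net, train_waves, layer_idx=1, epochs=stdp_epochs[0])
    train_unsupervised(net, train_waves, layer_idx=2, epochs=stdp_epochs[1])
    history = train_rl(net, train_waves, train_labels, epochs=rstdp_epochs)
    test_counters = evaluate(net, test_waves, test_labels)
    accs = [c.accuracy for c in history]
    return BenchmarkResult(
        train_history=history,
        best_train_accuracy=float(max(accs)),
        final_train_accuracy=float(accs[-1]),
        test_counters=test_counters,
        n_train=len(train_waves),
        n_test=len(test_waves),
    )
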