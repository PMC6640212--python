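"""The three-stage convolutional SNN and its training / evaluation loops.

The network follows the S1 -> C1 -> S2 -> C2 -> S3 -> C3 layout: three
spiking convolutional stages, each followed by max-pooling, with the last
pooling realized as a global read-out.  S1 and S2 are trained layer-wise by
unsupervised STDP; S3 is trained by reward-modulated STDP and read out by
the maximum membrane potential, mapped through a decision map from feature
index to class label.  Each convolutional stage consumes the zero-padded
output of the previous stage so no information is lost at the borders.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .competition import Winner, get_k_winners
from .layers import ConvLayer, PoolSpec, conv_forward, fire, fire_infinite, pad_wave, pool
from .plasticity import RStdpPair, StdpRule, punish, reward, stdp_step

#: Returned when a stimulus elicits no spike in the decision layer.
SILENT: int = -1


@dataclass
class ConvStage:
    """One trainable stage: conv layer, firing threshold, WTA parameters.

    ``threshold = None`` selects the infinite-threshold read-out (spikes
    only at the last time-step, used for decision layers).
    """

    layer: ConvLayer
    threshold: float | None
    padding: int = 0
    k_winners: int = 1
    inhibition_radius: int = 0
    rule: StdpRule | RStdpPair | None = None


@dataclass
class ForwardContext:
    """Synaptic data saved during a training forward pass.

    Holds, for the stage under training, everything plasticity needs: the
    stage's (padded) input wave, its output thresholded potentials and
    spike-wave, and the selected winners.  Cleared per stimulus.
    """

    layer_idx: int
    input_wave: np.ndarray | None = None
    output_tp: np.ndarray | None = None
    output_wave: np.ndarray | None = None
    winners: list[Winner] = field(default_factory=list)
    decision: int | None = None

    def as_dict(self) -> dict:
        return {
            "input_wave": self.input_wave,
            "output_tp": self.output_tp,
            "output_wave": self.output_wave,
            "winners": self.winners,
        }


@dataclass
class EvalCounters:
    """Correct / wrong / silent tallies over a set of presentations."""

    correct: int = 0
    wrong: int = 0
    silent: int = 0

    @property
    def total(self) -> int:
        return self.correct + self.wrong + self.silent

    @property
    def accuracy(self) -> float:
        return self.correct / self.total if self.total else 0.0


@dataclass
class Network:
    """A feed-forward spiking network of conv stages with interleaved pooling.

    ``pool_specs[i]`` is applied after stage ``i``; the final stage's
    pooling is replaced by the global max-potential read-out, so its spec
    may be ``None``.  ``decision_map[f]`` is the class label assigned to
    final-layer feature ``f``.
    """

    stages: list[ConvStage]
    pool_specs: list[PoolSpec | None]
    decision_map: list[int]

    def __post_init__(self) -> None:
        if len(self.pool_specs) != len(self.stages):
            raise ValueError("need one pooling spec slot per stage")
        last = self.stages[-1].layer.out_features
        if len(self.decision_map) != last:
            raise ValueError(
                f"decision_map has {len(self.decision_map)} entries for "
                f"{last} final features"
            )

    @property
    def n_trainable(self) -> int:
        return len(self.stages)


def _stage_forward(wave: np.ndarray, stage: ConvStage) -> tuple[np.ndarray, ...]:
    """Pad, convolve and fire one stage; returns (input, spikes, thresholded)."""
    x = pad_wave(wave, stage.padding)
    p = conv_forward(x, stage.layer)
    if stage.threshold is None:
        spikes, tp = fire_infinite(p, return_thresholded=True)
    else:
        spikes, tp = fire(p, stage.threshold, return_thresholded=True)
    return x, spikes, tp


def forward_test(net: Network, wave: np.ndarray) -> int:
    """Run a stimulus through the network and return its class decision.

    The decision is the label of the final-layer feature holding the
    maximum potential (global max-pool read-out); :data:`SILENT` when no
    final-layer neuron receives any potential.
    """
    x = wave
    for i, stage in enumerate(net.stages[:-1]):
        _, spikes, _ = _stage_forward(x, stage)
        x = pool(spikes, net.pool_specs[i])
    _, _, tp = _stage_forward(x, net.stages[-1])
    winners = get_k_winners(tp, k=1, inhibition_radius=0)
    if not winners:
        return SILENT
    return net.decision_map[winners[0].feature]


def forward_train(net: Network, wave: np.ndarray, max_layer: int) -> ForwardContext:
    """Forward pass interrupted after stage ``max_layer`` (1-based).

    Runs the same stage sequence as :func:`forward_test` but stops after
    the stage under training and saves the data its plasticity rule needs.
    For the final stage the winner also determines the network's decision.
    """
    if not 1 <= max_layer <= net.n_trainable:
        raise ValueError(
            f"max_layer must be in [1, {net.n_trainable}], got {max_layer}"
        )
    ctx = ForwardContext(layer_idx=max_layer)
    x = wave
    for i, stage in enumerate(net.stages):
        stage_input, spikes, tp = _stage_forward(x, stage)
        if i + 1 == max_layer:
            ctx.input_wave = stage_input
            ctx.output_tp = tp
            ctx.output_wave = spikes
            ctx.winners = get_k_winners(
                tp, k=stage.k_winners, inhibition_radius=stage.inhibition_radius
            )
            if i == len(net.stages) - 1:
                ctx.decision = (
                    net.decision_map[ctx.winners[0].feature] if ctx.winners else SILENT
                )
            return ctx
        x = pool(spikes, net.pool_specs[i])
    raise AssertionError("unreachable")  # pragma: no cover


def train_unsupervised(
    net: Network,
    waves: Sequence[np.ndarray],
    layer_idx: int,
    epochs: int = 1,
) -> Network:
    """Layer-wise unsupervised STDP training of stage ``layer_idx`` (1-based).

    For every stimulus, a forward pass up to the stage under training is
    followed by one STDP update on that stage's winners.  Other stages'
    weights are untouched.  Assumes earlier stages are already trained
    (layer-wise protocol; not enforced).
    """
    stage = net.stages[layer_idx - 1]
    if not isinstance(stage.rule, StdpRule):
        raise TypeError(f"stage {layer_idx} has no plain STDP rule")
    for _ in range(epochs):
        for wave in waves:
            ctx = forward_train(net, wave, layer_idx)
            if ctx.winners:
                stdp_step(
                    stage.rule,
                    ctx.input_wave,
                    ctx.output_tp,
                    ctx.output_wave,
                    ctx.winners,
                    stage.layer,
                )
    return net


def train_rl(
    net: Network,
    waves: Sequence[np.ndarray],
    labels: Sequence[int],
    epochs: int = 1,
) -> list[EvalCounters]:
    """Reward-modulated STDP training of the final stage.

    Per stimulus: full forward pass, decision compared to the label, reward
    on a match, punishment on a mismatch, no plasticity when silent.
    Returns the per-epoch counters (``correct + wrong + silent`` equals the
    number of presentations in every epoch); the network is updated in
    place.
    """
    stage = net.stages[-1]
    if not isinstance(stage.rule, RStdpPair):
        raise TypeError("final stage has no R-STDP rule pair")
    n_classes = max(net.decision_map) + 1
    history: list[EvalCounters] = []
    for _ in range(epochs):
        counters = EvalCounters()
        for wave, label in zip(waves, labels, strict=True):
            if not 0 <= label < n_classes:
                raise ValueError(f"label {label} outside decision map range")
            ctx = forward_train(net, wave, net.n_trainable)
            if ctx.decision == SILENT:
                counters.silent += 1
            elif ctx.decision == label:
                counters.correct += 1
                reward(stage.rule, ctx.as_dict(), stage.layer)
            else:
                counters.wrong += 1
                punish(stage.rule, ctx.as_dict(), stage.layer)
        history.append(counters)
    return history


def evaluate(
    net: Network, waves: Sequence[np.ndarray], labels: Sequence[int]
) -> EvalCounters:
    """Count correct / wrong / silent decisions without any plasticity."""
    counters = EvalCounters()
    for wave, label in zip(waves, labels, strict=True):
        decision = forward_test(net, wave)
        if decision == SILENT:
            counters.silent += 1
        elif decision == label:
            counters.correct += 1
        else:
            counters.wrong += 1
    return counters


def tutorial_network(
    n_classes: int = 2,
    in_features: int = 6,
    features: tuple[int, int, int] = (16, 32, 20),
    thresholds: tuple[float, float] = (40.0, 60.0),
    seed: int | np.random.Generator = 0,
) -> Network:
    """Build the three-stage preset network for ``n_classes`` classes.

    Geometry (for a 24 x 24 input): S1 5x5 kernels (pad 2) -> C1 2x2 pool
    -> S2 3x3 (pad 1) -> C2 3x3 pool -> S3 5x5 (pad 2, infinite threshold)
    -> global max-potential read-out.  The final feature count must be a
    multiple of ``n_classes``; features are assigned to classes in
    contiguous blocks.  Weights are drawn from a normal distribution
    (mean 0.8, std 0.05); the R-STDP pair keeps S3 weights in [0.2, 0.8]
    with the stabilizer off.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    f1, f2, f3 = features
    if f3 % n_classes:
        raise ValueError(f"final feature count {f3} not divisible by {n_classes}")
    s1 = ConvStage(
        layer=ConvLayer.init(in_features, f1, 5, rng=rng),
        threshold=thresholds[0],
        padding=2,
        k_winners=5,
        inhibition_radius=2,
        rule=StdpRule(0.004, -0.003),
    )
    s2 = ConvStage(
        layer=ConvLayer.init(f1, f2, 3, rng=rng),
        threshold=thresholds[1],
        padding=1,
        k_winners=8,
        inhibition_radius=1,
        rule=StdpRule(0.004, -0.003),
    )
    s3 = ConvStage(
        layer=ConvLayer.init(f2, f3, 5, rng=rng),
        threshold=None,
        padding=2,
        k_winners=1,
        inhibition_radius=0,
        rule=RStdpPair(
            stdp=StdpRule(0.02, -0.015, 0.2, 0.8, use_stabilizer=False),
            anti_stdp=StdpRule(-0.02, 0.0025, 0.2, 0.8, use_stabilizer=False),
        ),
    )
    decision_map = [c for c in range(n_classes) for _ in range(f3 // n_classes)]
    return Network(
        stages=[s1, s2, s3],
        pool_specs=[PoolSpec((2, 2)), PoolSpec((3, 3)), None],
        decision_map=decision_map,
    )
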