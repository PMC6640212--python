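"""STDP and reward-modulated STDP for winner-take-all spiking layers.

With at most one spike per neuron, spike-timing-dependent plasticity
reduces to a binary timing comparison per synapse.  For a winning
post-synaptic neuron *i* with first-spike step ``T_i`` and a pre-synaptic
neuron *j* with first-spike step ``T_j`` (no spike counts as +infinity):

    dW_ij = A+ * (W_ij - LB) * (UB - W_ij)   if T_j <= T_i   (potentiate)
    dW_ij = A- * (W_ij - LB) * (UB - W_ij)   if T_j >  T_i   (depress)

The multiplicative ``(W - LB)(UB - W)`` stabilizer slows learning near the
bounds and makes LB and UB fixed points.  With the stabilizer off, the bare
learning rate is applied and the result is clamped into ``[LB, UB]``.

Reward-modulated STDP pairs an STDP rule with an anti-STDP rule whose
learning-rate signs are negated: a correct decision triggers the STDP rule
(reward), a wrong one the anti-STDP rule (punishment).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .competition import Winner
from .core import NO_SPIKE, wave_to_spike_times
from .layers import ConvLayer


@dataclass
class StdpRule:
    """Learning rates, weight bounds and stabilizer flag for one STDP rule.

    ``a_plus`` applies when the pre-synaptic spike does not come after the
    post-synaptic one (``T_j <= T_i``), ``a_minus`` otherwise.  For plain
    STDP ``a_plus > 0 > a_minus``; an anti-STDP rule negates the signs.
    """

    a_plus: float
    a_minus: float
    lower_bound: float = 0.0
    upper_bound: float = 1.0
    use_stabilizer: bool = True

    def __post_init__(self) -> None:
        if not self.lower_bound < self.upper_bound:
            raise ValueError(
                f"lower_bound must be < upper_bound, got "
                f"[{self.lower_bound}, {self.upper_bound}]"
            )


@dataclass
class RStdpPair:
    """STDP / anti-STDP rule pair implementing reward-modulated STDP."""

    stdp: StdpRule
    anti_stdp: StdpRule

    def __post_init__(self) -> None:
        for a, b in (
            (self.stdp.a_plus, self.anti_stdp.a_plus),
            (self.stdp.a_minus, self.anti_stdp.a_minus),
        ):
            if a * b > 0:
                raise ValueError(
                    "anti-STDP learning rates must have signs opposite to the "
                    f"STDP rates (got {a} vs {b})"
                )


def stdp_step(
    rule: StdpRule,
    input_wave: np.ndarray,
    output_tp: np.ndarray,
    output_wave: np.ndarray,
    winners: Sequence[Winner],
    layer: ConvLayer,
) -> ConvLayer:
    """Apply one STDP update to the receptive fields of the winners.

    Each winner at ``(f, r, c)`` owns the kernel slice ``weights[f]`` and is
    connected to the input window ``rows [r, r + K_h), cols [c, c + K_w)``
    across all input features (valid-convolution geometry; ``input_wave``
    must be the layer's actual, already padded, input).  Non-winner weights
    are untouched.  The layer is updated in place and returned.
    """
    input_wave = np.asarray(input_wave)
    output_tp = np.asarray(output_tp)
    k_h, k_w = layer.kernel_size
    t_out, f_out = output_tp.shape[0], output_tp.shape[1]
    h_out, w_out = output_tp.shape[2], output_tp.shape[3]

    pre_times = wave_to_spike_times(input_wave).times  # (F_in, H, W)
    for win in winners:
        if not (0 <= win.feature < f_out and 0 <= win.row < h_out and 0 <= win.col < w_out):
            raise ValueError(f"winner {win.position} outside output tensor bounds")
        if not 0 <= win.spike_step < t_out:
            raise ValueError(f"winner spike step {win.spike_step} out of range")
        t_j = pre_times[:, win.row : win.row + k_h, win.col : win.col + k_w]
        potentiate = (t_j != NO_SPIKE) & (t_j <= win.spike_step)
        rate = np.where(potentiate, rule.a_plus, rule.a_minus)
        w = layer.weights[win.feature]
        if rule.use_stabilizer:
            w += rate * (w - rule.lower_bound) * (rule.upper_bound - w)
        else:
            w += rate
            np.clip(w, rule.lower_bound, rule.upper_bound, out=w)
    return layer


def reward(
    pair: RStdpPair,
    context: dict,
    layer: ConvLayer,
) -> ConvLayer:
    """Reinforce the saved forward pass: apply the STDP half of the pair."""
    return _apply_pair(pair.stdp, context, layer)


def punish(
    pair: RStdpPair,
    context: dict,
    layer: ConvLayer,
) -> ConvLayer:
    """Penalize the saved forward pass: apply the anti-STDP half of the pair."""
    return _apply_pair(pair.anti_stdp, context, layer)


def _apply_pair(rule: StdpRule, context: dict, layer: ConvLayer) -> ConvLayer:
    required = ("input_wave", "output_tp", "output_wave", "winners")
    missing = [k for k in required if context.get(k) is None]
    if missing:
        raise ValueError(f"plasticity context is missing {missing}")
    if not context["winners"]:  # silent stimulus: nothing to update
        return layer
    return stdp_step(
        rule,
        context["input_wave"],
        context["output_tp"],
        context["output_wave"],
        context["winners"],
        layer,
    )
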