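# spikewave

Simulation of convolutional spiking neural networks in which every neuron
emits **at most one spike per stimulus** and information is carried by
**time-to-first-spike (rank-order) coding**. Learning is by spike-timing-
dependent plasticity (STDP) on winner-take-all neurons, or by its
reward-modulated variant (R-STDP) for task-driven training of a decision
layer.

This class of networks matters because a single spike per neuron is cheap:
it maps naturally onto event-based neuromorphic hardware, and rank-order
latency coding mirrors the speed of rapid visual processing in cortex. The
package is aimed at computational-neuroscience and neuromorphic-computing
work where one wants to train and dissect such networks at desk scale, with
every operator testable against a brute-force definition.

## The computational model

A stimulus over `F` feature maps of `H x W` neurons and `T_max` discrete
time-steps is a 4-D binary **spike-wave tensor** `S` in *accumulative*
format: if neuron `(f, r, c)` first spikes at step `T_{f,r,c}` then

```
S[t, f, r, c] = 0  if t < T_{f,r,c},   1 otherwise
```

(a silent neuron contributes an all-zero column). The redundancy is the
point: one valid cross-correlation of `S` with a kernel stack `W` processes
*all* time-steps at once, and because `S` is accumulative the result
`P[t] = (S[t] * W)` is automatically the accumulated membrane potential up
to step `t`. Thresholding `P` yields the next layer's accumulative
spike-wave; max-pooling an accumulative wave extracts the earliest spike in
each window. A non-leaky integrate-and-fire neuron with one spike per
stimulus therefore costs one einsum and one comparison.

Plasticity reduces to a timing comparison per synapse. For a winning
post-synaptic neuron `i` (first spike `T_i`) and pre-synaptic neuron `j`
(first spike `T_j`, no spike = infinity):

```
dW_ij = A+ . (W_ij - LB)(UB - W_ij)   if T_j <= T_i
dW_ij = A- . (W_ij - LB)(UB - W_ij)   if T_j >  T_i
```

The multiplicative stabilizer `(W - LB)(UB - W)` makes the bounds fixed
points; with the stabilizer off the bare rate is applied and the weight is
clamped into `[LB, UB]`. R-STDP pairs this rule with a sign-negated
anti-STDP rule: a correct decision triggers the STDP half (reward), a wrong
one the anti-STDP half (punishment).

Winners are selected first by earliest spike time, then by maximum
potential; each winner suppresses its spatial neighbourhood in all feature
maps and its own feature map, enforcing sparse and diverse features.

## Worked example

The repository ships a synthetic two-class dataset generator (oriented bars
with jitter and noise, standing in for a digit dataset at desk scale) and a
three-stage preset network `S1 -> C1 -> S2 -> C2 -> S3 -> C3` encoded
through six difference-of-Gaussians channels. The whole workflow runs from
the shell:

```
$ spikewave --config cfg.yaml --seed 5 generate data
wrote 20 images (2 classes) to data
$ spikewave --config cfg.yaml --seed 5 train data --layer 1 --epochs 1
trained stage 1 for 1 epoch(s); checkpoint -> checkpoint
$ spikewave --config cfg.yaml --seed 5 train data --layer 2 --epochs 1
trained stage 2 for 1 epoch(s); checkpoint -> checkpoint
$ spikewave --config cfg.yaml --seed 5 train-rl data
epoch 1: correct=6 wrong=14 silent=0 accuracy=0.300
epoch 2: correct=20 wrong=0 silent=0 accuracy=1.000
epoch 3: correct=20 wrong=0 silent=0 accuracy=1.000
$ spikewave --config cfg.yaml --seed 5 evaluate data
correct=20 wrong=0 silent=0 accuracy=1.000
```

`correct`/`wrong`/`silent` count decisions per epoch (`silent` = the
stimulus elicited no spike in the decision layer, so no decision was made);
the R-STDP layer goes from chance (0.30) to perfect training accuracy in
one epoch on this 20-sample toy set.

The classic STDP selectivity experiment — one convolutional layer exposed
to a recurring spike pattern embedded in noise — is available from Python:

```python
>>> from spikewave.experiments import run_pattern_selectivity
>>> run_pattern_selectivity(seed=0).best_cosine
0.8591098253580261
```

i.e. after 400 presentations the winning feature's weight vector has cosine
similarity 0.86 with the binary indicator of the hidden pattern's
afferents: the layer found the pattern without supervision.

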