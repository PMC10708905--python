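# phenonet

Phenology-based probabilistic models and nestedness analysis for temporal
bipartite interaction networks.

Many bipartite interaction networks — plant–pollinator visitation webs,
buyer–seller market networks — are *nested*: the partners of
low-degree actors form subsets of the partners of high-degree actors,
giving the incidence matrix its characteristic staircase pattern.
`phenonet` implements a simple temporal mechanism for this structure:
actors can only interact on days they are both present, and the more
often a pair is copresent, the more likely a link is to appear in the
time-aggregated network. The package is for ecologists and network
scientists who have daily-resolved interaction data (or want to simulate
it) and ask how much of an aggregated network's structure is explained
by the timing of actor availability alone.

## The model

From a block of daily interaction records the package builds a binary
R×C incidence matrix (a link means at least one interaction during the
block) and the copresence matrix N, where n_ij counts the days row actor
i and column actor j were both active; an actor with no interaction on a
given day is assumed absent that day. With p the probability of an
interaction given one copresence and q = 1 − p, the **phenology model**
assigns each pair an independent link probability

&nbsp;&nbsp;&nbsp;&nbsp;p_ij = 1 − q^{n_ij}.

The single parameter q is set so the expected number of links equals the
empirical L: writing x_k for the number of pairs with k copresences
(k = 0..f, with f the number of sampled days) and Z = RC − L, q is the
unique root in [0, 1] of

&nbsp;&nbsp;&nbsp;&nbsp;Σ_k x_k q^k − Z = 0.

Three comparison models share the link-count constraint: the
Erdős–Rényi model (p_ij = L/RC), the degree-distribution model
(p_ij = k_i/2C + k_j/2R), and the presence model (same form as the
phenology model with n_ij replaced by the rounded-up mean presence of
the pair).

Nestedness is the spectral radius of the bipartite adjacency matrix —
equivalently the largest singular value of the incidence matrix —
normalized by its maximum √(2L − R − C + 1), and rescaled between an
Erdős–Rényi ensemble baseline (Δρ̃ = 0) and the empirical value
(Δρ̃ = 1). Model accuracy is scored per realization with the phi
coefficient and F-score, and a backbone test asks whether the links the
model explains (true positives) are more nested than the links it
misses (false negatives), both absolutely (ρ_TP/ρ_FN > 1) and in excess
over matched ER baselines.

## Worked example

The package ships a 6-day, 3×3-actor event list
(`phenonet.examples.toy_block`) whose copresence histogram is
{0: 1, 1: 2, 2: 4, 3: 2} with L = 6 links:

```python
import phenonet as pn
from phenonet.examples import toy_block

block = toy_block()
net = pn.build_network(block)          # R=3, C=3, L=6
N = pn.copresence_matrix(block, net)   # f = 6 days
probs = pn.phenology_probabilities(N, net)
print(round(probs.fit.q, 4), round(probs.fit.p, 4))
```

prints `0.4656 0.5344`: solving 1 + 2q + 4q² + 2q³ − 3 = 0 gives
q = 0.47 and p = 0.53 at two decimals. The resulting link probabilities

```
[[0.783 0.    0.534]
 [0.899 0.534 0.783]
 [0.899 0.783 0.783]]
```

sum to exactly 6 (the empirical link count); the pair that never
overlaps has probability 0, and the two pairs copresent on 3 days reach
1 − q³ ≈ 0.90. Downstream,

```python
res = pn.measure_nestedness(net, n_graphs=10_000, seed=1)
ass = pn.ensemble_assess(probs, net, n_realizations=1000, seed=1)
```

reports ρ_raw = 2.247, ρ = 0.849 against an ER baseline of
0.847 ± 0.045 (Δρ = 0.0025: a 3×3 toy is too small to be meaningfully
nested), and ensemble accuracy phi = 0.49 ± 0.27, F1 = 0.82 ± 0.11.

The same workflow is available from the shell:

```sh
phenonet simulate --out events.tsv --n-rows 30 --n-cols 30 --seed 1
phenonet run-all --input events.tsv --window month --out results/
```

`run-all` writes a JSON bundle with, per window and model, the fit, the
nestedness rescaling (Δρ̃ with mean and sd over realizations), the
confusion-matrix statistics, and the backbone test. Identical
configuration and seed give byte-identical bundles.

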