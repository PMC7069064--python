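# lollinet

Random-walk **hitting-time** characterization of weighted networks, built to
detect **isolated linear chains of nodes** — the "stick" of a lollipop graph
— in functional connectivity data.

## The problem

Functional brain networks (and weighted networks generally) are routinely
summarized by averages: mean path length, efficiency, small-worldness. But a
hierarchical processing stream — a chain of sequentially connected regions,
like a sensory pathway — shows up not in the average but in the *tail* of
the connectivity distribution: a chain attached to a densely connected core
(a lollipop graph) produces asymptotically maximal random-walk hitting
times. `lollinet` turns that theoretical result into a measurement pipeline:

1. **Connectivity.** Estimate partial correlations ρ_ij between regional
   time series (inverse covariance with Ledoit–Wolf shrinkage), giving a
   weighted network A = [|ρ_ij|] with degrees d_i = Σ_j |ρ_ij|.
2. **Self-loop normalization.** Add a self edge ρ′_ii = d_max − d_i to every
   node, so D′ = d_max·I while relative connectivity is preserved: a weakly
   connected node mostly sits on its self loop instead of being forced to
   move. The walk's transition matrix is P′ = D′⁻¹A′.
3. **Spectral hitting times.** With the normalized Laplacian
   ℒ = D′^(−1/2)(D′ − A′)D′^(−1/2) = I − P′ and its eigenpairs (λ_k, μ_k),
   the expected first-visit step counts are

       h_ij = Σ_{k>1} (d′/λ_k) · (μ_kj²/d′_j − μ_ki μ_kj /√(d′_i d′_j)),

   an asymmetric matrix H (reaching an isolated chain takes far longer than
   leaving it). Independent linear-solve and Monte-Carlo oracles cross-check
   the spectral route.
4. **Tail statistics.** Raw Kelley skewness P90 + P10 − 2·P50 of the
   hitting-time distribution compares the tails directly; a per-node **chain
   index** ζ_i = ρ_{i,i₁} + ρ_{i,i₂} − Σ_{j≥3} ρ_{i,i_j} (two strongest
   connections minus the rest) scores how chain-like each node's local
   topology is.
5. **Group harnesses.** Per-node to-hitting contrasts with Bonferroni
   correction, and OLS / paired-contrast models of skewness on condition,
   group, gender, and age.

The package also ships every synthetic study used to calibrate the method:
graph-family comparisons, progressive chain isolation, a G(n,m) modularity
regression, a stochastic-block-model control, and the lollipop clique/path
sweep.

## Worked example

```python
import numpy as np
import lollinet as ln

# five nodes: a strongly tied (0.9) to c,d,e; b weakly tied (0.1) to the same
w = np.zeros((5, 5))
for j in (2, 3, 4):
    w[0, j] = w[j, 0] = 0.9
    w[1, j] = w[j, 1] = 0.1
graph = ln.WeightedGraph(w, list("abcde"))

model = ln.normalize(graph)          # self-loop normalization
H = ln.hitting_spectral(model)       # spectral hitting times
print(model.p_prime[1, 1])           # 0.8889  <- b's self-loop probability
print(H.h[0, 1], H.h[1, 0])          # 37.0 13.0
```

Without normalization both a and b would have identical transition
probabilities; with it, the weakly connected b is reached in 37 expected
steps but escapes in 13 — the asymmetry that flags weak, chain-like
attachment. At study scale:

```python
res = ln.run_family_comparison(n=100, reps=10, seed=0)
print(res.table.groupby("family")[["max_hitting", "kelley"]].mean())
```

```
            max_hitting    kelley
complete          99.00      0.00
lollipop      183580.00  85527.00
random           179.60      5.64
smallworld       717.51     19.50
```

The 100-node lollipop (67-clique, 33-path) reaches a maximum hitting time of
183,580 steps — orders of magnitude beyond every other family — and its raw
Kelley skewness dwarfs the rest, while the complete graph sits at exactly
n − 1 = 99 with zero skewness. The `examples/` directory has one short
script per capability (normalization, families, chain isolation,
partial-correlation recovery, group contrasts), each printing the numbers it
computes and what they mean.

## Command line

A thin CLI wraps the library for file-based use:

```sh
lollinet simulate --family lollipop --n 100 --n-path 33 --out g.tsv
lollinet hitting --in g.tsv --method spectral --out H.tsv
lollinet skewness --in H.tsv
lollinet experiment isolation --seed 0 --out results/
```

Matrices are plain tab-separated text with label headers; panels are TSV;
reports are JSON.

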