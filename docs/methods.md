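# Methods

## Model

Let G1(V1, E1) and G2(V2, E2) be weighted undirected graphs with unique
string node labels and nonnegative edge weights, and let S be a set of node
labels present in both. G1 acts as the *proposer* and G2 as the *tester*.

The significance of S as a shared highly connected module is bounded in two
multiplicative steps, both derived from encoding lengths:

1. **Tester-side p-value.** Encoding S in G2 with the diffusion walker gives
   an alternate code length I_A(G2); the null code spends log2 |V2| bits per
   module node, I_0(G2) = |S|·log2 |V2|. If the alternate code is shorter by
   d bits, the probability under the null of data this compressible is at
   most 2^(−d) (the algorithmic-significance argument), so
   p(S, G2) ≤ 2^−(I_0(G2) − I_A(G2)).
2. **Correction for choosing S out of the proposer.** S was selected from the
   power set of G1, so a multiplicity correction is required. The encoding
   lengths in G1 define weights w_A = P(A) ≥ 2^(−I_A(A)) for a weighted
   Bonferroni correction, giving
   p_corrected ≤ p(S, G2) / P(S) ≤ 2^(I_A(G1)) · p(S, G2).

Combined:  log2 p ≤ I_A(G1) + I_A(G2) − I_0(G2). The bound is reported
verbatim even when it exceeds 1 (it is a bound, not an estimate; values above
1 read "not significant"). Only the tester's node count enters I_0, so the
bound is intentionally asymmetric under swapping the roles of two
different-sized graphs.

## The walker

The encoder is a deterministic greedy diffusion walk:

- State: the set of visited nodes and the subset of module nodes found so
  far (the *frontier*). The start node — chosen as the module node whose walk
  minimizes I_A, ties to the smallest label — is named for log2 |V| bits and
  seeds both sets.
- One step: a unit of probability mass is split equally over frontier nodes;
  each share spreads over that node's unvisited neighbors proportionally to
  edge weight. A frontier node with no (positively weighted) unvisited
  neighbor passes its share through its visited neighbors, one level deep,
  onto their unvisited neighbors; mass with no target at that depth is lost.
  The unvisited node of maximal mass is visited (ties to the smallest
  label) and contributes a 1-bit if it is in S, else a 0-bit.
- Halt: when all of S is found, when the maximal mass falls below 1/|V|²
  (the stop threshold), or after |V| visits. Unfound module nodes are
  hardcoded, appearing only through the (|S| − found) term of I_A.

Decoding replays the identical walk — the bits themselves tell the decoder
which visited nodes join the frontier — so (start, bitstring) identifies the
found subset exactly; this is asserted by round-trip tests.

log2 |V| is used as a real number throughout, and the distribution's
normalizer k (which would tighten P(A) = 2^(−I_A)/k) is never computed; all
probabilities use the conservative 2^(−I_A) bound.

## Closed forms

In the ideal case — every module node captured with no stray visits in both
graphs — I_A = log2 |V| + |S| − 1 on each side, and the pair bound collapses
algebraically to

    p_ideal ≤ 4 · (4/|V|)^(|S|−2)     (|V| > 4, |S| ≥ 2),

whose inversion gives the detectability floor
|S| ≥ 2 + (2 − log2 p_wanted)/(log2 |V| − 2), returned as the ceiling (the
"at least" reading). The floor assumes the null formula's smallness condition
|S| < 2|V|/log2 |V|; `null_encoding_length` enforces it as an error, while
`ideal_bound` only warns beyond it (the closed form remains the algebraic
best case, and the inversion must be evaluable there to stay consistent with
the floor on small graphs).

## Synthetic generator

The generator emulates metabolite co-perturbation networks at benchmark
scale and is the substrate of all stochastic tests. Per graph: a uniformly
random labeled tree (random Prüfer sequence) plus uniformly sampled extra
edges until |E| = round(n·d̄/2), guaranteeing connectivity with predictable
run time; weights i.i.d. Uniform(0.5, 1.5) — positive, bounded, mean 1, so
the module contrast (ratio of mean planted-edge weight to mean background
weight) reads directly as the planted weight. Planting adds the missing
path (|S|−1 edges along the label-sorted module order) or clique
(C(|S|,2) edges) and sets every pattern edge to contrast × mean(background),
realizing the requested ratio exactly; pruning then removes uniformly random
non-bridge, non-planted edges until the original density is restored.
Realized contrast is re-measured after pruning, since removing background
edges shifts the background mean slightly.

What the generator does *not* emulate: degree heterogeneity (real metabolite
networks are far from Erdős–Rényi-like), weight correlations along pathways,
negative raw weights (handled separately by the absolute-value preprocessing
step), and modules that are only partially present in one graph. Passing
sweep tests therefore demonstrate the method's behavior under controlled
contrast/density conditions, not performance on any particular real network.
The tree-first construction is known to bias the distribution over connected
graphs slightly; this is accepted for determinism and speed.

## Parameters and defaults

| parameter | meaning | default / range used |
|---|---|---|
| `avg_degree` | average unweighted node degree (edges = round(n·d̄/2)) | 5–25 |
| `module_fraction` | share of nodes in S | 0.5–1% at n ≥ 1000; 5% at n = 100 so the module has 5 nodes |
| `contrast` | mean planted weight / mean background weight | 1.0–2.0 |
| `pattern` | planted shape: `path` (worst case — maximal dispersion) or `clique` (best case) | both |
| stop threshold | walker halts below mass 1/n² (n = node count) | fixed |
| significance threshold | flag on each scan record | 0.05 (raw log2 bound always retained) |

Replicate seeds follow a stable ladder — base seed + CRC32 of the cell's
parameters + replicate index, reduced mod 2³¹ — so editing a grid never
silently reseeds surviving cells, and record sets are independent of
execution order. The desk-scale sweep uses n = 100, |S| = 5, 20 replicates
per cell over contrast {1.0, 1.5, 2.0} × degree {5, 15, 25} × both patterns.
Cells whose module size is below the closed-form floor for p = 0.05 are
skipped outright and marked as such.

## Numerical choices and degenerate inputs

- All tie-breaks (equal diffusion mass, equal-I_A starts) resolve by
  ascending label order; neighbor iteration is label-sorted so floating-point
  accumulation order is reproducible.
- Zero-weight edges stay in the topology but carry no diffusion mass; a
  frontier node whose unvisited neighbors all have weight zero triggers the
  pass-through rule.
- Empty graphs, empty modules, self-loops, and conflicting duplicate edges
  are rejected at construction or parse time with located error messages.
- Graphs of ≤ 4 nodes have no detectability closed form (log2 |V| − 2 ≤ 0);
  both closed-form functions raise there.

## Known limitations

- **The power-set weights are not a true sub-distribution.** The code family
  behind I_A is not self-delimiting (a short bitstring can be the prefix of
  a longer one from the same start, and the hardcoded-node count is not
  itself encoded), so Σ_A 2^(−I_A(A)) exceeds 1 — on random graphs of 5–10
  nodes the exhaustive sum lies around 2–3, and the |V| singleton modules
  alone always contribute exactly 1. The weighted-Bonferroni bound is
  therefore anti-conservative by at most that factor; for the ~20-bit
  compression margins of typical significant calls this costs under two bits
  of the budget, but callers comparing bounds near a threshold should keep
  it in mind.
- **The walker is greedy and not monotone in edge weight.** Adding a heavy
  edge inside S usually shortens the encoding but can occasionally lengthen
  it (or lose a module node) by permuting the visitation order into a less
  favorable sequence. Only the local property is guaranteed: a dominating
  edge from the start captures its partner on the first step.
- The walker here is one self-consistent instance of the diffusion-encoding
  family (descending-mass visitation, the I_A bookkeeping above, exact
  replay decodability); other instances — different stop thresholds,
  deeper pass-through, search-based walkers — would yield different, equally
  valid bounds.
- Scoring a module whose induced subgraph is disconnected in the tester
  forces walker misses or hardcoding, and the bound degrades sharply; this
  is by design (such a module is not a shared connected community) but means
  near-misses are indistinguishable from absent signal.
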