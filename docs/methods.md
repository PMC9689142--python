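# Methods

## Problem setting

Link prediction on an undirected simple graph: the observed edge set
`E` (|E| = M over N nodes) is split uniformly at random into a training
set `E_T` with `|E_T| = round(η·M)` and a probe set `E_P = E − E_T`.
A scorer is fitted on the training graph `G̃ = (V, E_T)` only and must
assign every unordered node pair a real score; accuracy is judged by
how it ranks the probe links against the nonexistent pairs
`E_U − E` (the universal pair set minus *all* observed edges — probe
links are excluded from the negative pool, since they are true links).
No connectivity repair is applied after splitting: probe endpoints that
become isolated simply receive zero scores from every
common-neighbour-based index, which is informative in itself.

## The walk model

**State space.** Each node contributes two basis states: coin `|0⟩`
(a self-loop direction) and coin `|1⟩` (its neighbourhood treated as a
single direction). The state is a *real* vector of length 2N laid out
as two N-blocks `[ψ0; ψ1]`; at t = 0 every entry equals α.

**Coin.** `G[j,k] = −A[j,k] + 2|Γ(j,k)|` where Γ is the common-neighbour
set, so in matrix form `G = −A + 2A²` (the diagonal of A² is the degree,
matching the set-intersection convention Γ(j,j) = N(j)). The form echoes
the Grover diffusion operator but carries raw common-neighbour counts:
no normalising denominator is applied, and consequently the evolution is
not unitary. This is a feature, not an omission — dropping the
probability-conservation constraint lets amplitudes act as accumulating
similarity mass.

**Shift.** Block-diagonal `S = [[I, 0], [0, D⁻¹A]]`. The identity block
is the self-loop: it damps traceback (amplitude oscillating back and
forth across a single edge). The lower block is the simple random-walk
transition matrix; rows of dangling (degree-0) nodes are identically
zero, so their coin-1 amplitude exits the system rather than raising an
error.

**Evolution.** `U = S · blockdiag(G, G) = [[G, 0], [0, (D⁻¹A)G]]`.
The block form means the two coin sectors evolve independently:
`ψ0(t) = Gᵗ ψ0(0)` and `ψ1(t) = ((D⁻¹A)G)ᵗ ψ1(0)`. The test suite
checks this block form against a literal outer-product/Kronecker
construction of the operators entrywise to 1e−12.

**Observation.** After t steps the ordered score of a pair reads the
amplitude at node j weighted by shared-neighbour support:
`P(j,k) = (|Γ(j,k)|/|E_T|)(ψ0(t)[j] + ψ1(t)[j])`. The ordered score is
asymmetric (it reads node j only); the stored pair score symmetrises by
the mean of both orderings (configurable: mean / sum / none — mean and
sum differ by a global factor 2 and induce identical rankings).

### Parameters

| parameter | default | meaning |
|---|---|---|
| `steps` | 2 | walk length; 2 mixes common-neighbour information one hop beyond Γ while keeping traceback damped |
| `amplitude_convention` | `1/√N` | initial amplitude; `1/N` available, a pure global rescaling of all scores (rank-invariant, property-tested) |
| `symmetrization` | mean | how the two ordered scores combine |
| `training_edge_count` | edges of fitted graph | |E_T| in the score prefactor |

Because AUC and precision are rank statistics, the amplitude convention
and mean-vs-sum choices are provably irrelevant to every reported
number; they are exposed only so the scoring function itself is fully
specified.

## Baseline indices

Local indices are computed in closed matrix form (`CN = A²` off the
diagonal, etc.); ratio indices define 0/0 = 0. AA weights each common
neighbour by 1/ln d_z; a degree-1 node can never be a common neighbour
of a distinct pair, but the weight is guarded (contributes 0, with a
warning) anyway. LP uses damping α = 0.001; Katz uses
α = min(0.01, 0.85/λ_max) and refuses α·λ_max ≥ 1. ACT is scored as the
*reciprocal* of the commute distance `l⁺jj + l⁺kk − 2l⁺jk` so that, like
every other index, larger means more similar; Cos+ is the cosine under
the Laplacian pseudoinverse. Cross-component pairs score 0 for both —
the pseudoinverse couples components numerically but they carry no
random-walk similarity. NC uses node weight
`w_j = Σ_{z∈N(j)} d_z / (d_max · 2M)` and the 2- and 3-step simple
random-walk transition probabilities; the weight normalisation admits
other readings that differ only by per-node constants, and this one is
fixed here as the package's convention.

## Evaluation

**Sampled AUC.** n independent with-replacement draws of one probe link
and one nonexistent pair; strict wins count 1, ties 0.5
(`AUC = (n₁ + 0.5 n₂)/n`). Ties are detected with an absolute tolerance
of 1e−12 on scores. The default n = 672,400 is the worst-case Bernoulli
prescription `n = z²/(4ε²)` with ε = 10⁻³ and z = 1.645: it bounds the
Monte-Carlo error by 10⁻³ at 90% confidence for any score matrix, and
the run-to-run standard deviation by `√(0.25/n) ≈ 6·10⁻⁴ < 10⁻³`.
An exhaustive evaluator over all probe × nonexistent comparisons
(guarded at 10⁷) serves as the sampler's oracle in tests. The
`std_error` field is the plug-in Monte-Carlo standard error computed
from the win/tie tallies.

**Precision@L.** Candidates are all pairs outside `E_T` (probe links
included — ranking training edges would trivially pollute the top of
the list); precision is the fraction of probe links among the top L,
with L = ⌊|E_T|/3⌋ by default and ties broken by ascending index pair
for bit-reproducibility.

**Benchmark.** For each repetition: split, fit every algorithm on the
training graph, evaluate AUC and precision; report per-algorithm mean
and standard deviation. Per-algorithm sampler seeds are derived from a
repetition-level seed plus a hash of the algorithm name, so results are
independent of the order algorithms are listed.

## Synthetic data

The generators stand in for real benchmark networks (which are external
downloads) with three standard models: Erdős–Rényi, planted-partition
and Watts–Strogatz small-world, all seed-deterministic. The
planted-partition default (N = 120, 4 blocks, p_in = 0.4, p_out = 0.02)
produces strong community structure: a removed within-block edge
retains many common neighbours, which is precisely the signal every
scorer here exploits, and the whole 15-algorithm benchmark runs in
seconds at that size. What passing tests on these graphs shows is that
the pipeline recovers planted common-neighbour structure well above
chance; what it does not show is performance on real networks with
heavy-tailed degrees, degree–degree correlations, or meso-scale
structure beyond assortative blocks. The packaged Zachary karate-club
graph (34 nodes, 78 edges, via networkx) is the one canonical real
fixture; its summary statistics (mean degree 4.588, max degree 17,
diameter 5, transitivity 0.256, assortativity −0.475) are pinned in the
tests.

## Numerical choices and degenerate inputs

* All operators and states are dense real arrays; at the intended
  scales (N up to a few thousand) the 2N-dimensional operators are
  desk-sized, and a sparse path would be an optimisation, not a
  contract.
* Duplicate edges and self-loops in input files are normalised away
  with a logged warning; the model assumes a simple graph.
* Diameter of a disconnected graph is reported for its largest
  component; degree-regular graphs get assortativity 0 with a warning
  (the Pearson correlation is 0/0 there).
* `|E_T| = floor(η·M + 0.5)` — plain half-up rounding, immune to
  banker's-rounding surprises.
* Score ties in ranking are broken by ascending node-index pair, which
  follows first-appearance order of labels in the input file.

## Known limitations

* The walk scorer assigns exactly zero to any pair without common
  neighbours, so it cannot rank distance-≥3 probe links above chance;
  this is inherent to the observation functional, not a bug.
* Scores are unnormalised and grow with degree and graph density;
  compare them only within one fitted graph.
* The exhaustive AUC evaluator is quadratic in pool sizes and guarded
  at 10⁷ comparisons; beyond that, use the sampler.
* No weighted, directed or temporal graphs.
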