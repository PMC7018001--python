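# Methods

## Model

A graph `G` with `n` nodes has adjacency `A` (symmetric, non-negative
weights, zero diagonal), degrees `g_i = Σ_j A_ij` and total weight
`2m = Σ_i g_i`.  The modularity matrix is

    B = A − g gᵀ / 2m,

a dense symmetric matrix whose rows and columns sum to zero.  For a
partition into communities labelled `c_i`, modularity is

    Q = (1/2m) Σ_ij B_ij δ(c_i, c_j),

with the double sum running over *all* pairs including `i = j`.  The
diagonal terms only add a partition-independent constant
(`Σ_i B_ii / 2m`), so including them changes no argmax; we include them
because that is the convention under which the classic benchmark values
are quoted (karate club record 0.41979, etc.).

For at most two communities, labels can be written as spins
`s_i ∈ {−1, +1}` and `Q = sᵀBs / 4m`.  Because `B·1 = 0`, the substitution
`s = 2x − 1` gives the exact identity `sᵀBs = 4 xᵀBx`: the spin (Ising)
and binary (QUBO) quadratic forms are interchangeable.  The package
carries both forms and tests the identity directly.

## k-concurrent one-hot encoding

To find all (at most `k`) communities in one optimization, node `i`
becomes a logical super-node of `k` binary variables `x_{i,j}`, one-hot
constrained (`Σ_j x_{i,j} = 1`).  Stacking the per-community indicator
vectors into `X`, the constrained objective `Σ_j x_jᵀ B x_j` is relaxed
with per-node quadratic penalties `γ_i (Σ_j x_{i,j} − 1)²` and expanded to
a single quadratic form; dropping constants, the sampler minimizes

    E(X) = −β Σ_j x_jᵀ B x_j + Σ_i γ_i (Σ_j x_{i,j} − 1)² − Σ_i γ_i,

equivalently: coupling `−2β B_{ii'}` inside each community block, linear
`−β B_ii − γ_i`, coupling `+2γ_i` inside each super-node.  For every
feasible one-hot `X`,

    E(X) = −β · 2m · Q − Σ_i γ_i

with `Q` evaluated on the `B` used to build the problem — an identity the
tests assert to 1e-9 on random assignments, and the contract that lets
energies be read as modularities.

Variables are column-stacked (`x_{i,j}` at index `i + j·n`), making the
block structure of the coefficient matrix literal.  Couplings are stored
sparsely, so a thresholded `B` (below) directly shrinks the problem.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `k` | `min(n, 16)` | community slots per super-node; `k = n` imposes no prior, the cap only bounds problem size (`N = k·n` variables) |
| `beta` | 1 | weight of the modularity term (dimensionless; only `γ/β` matters) |
| `penalty` (`γ`) | `1 + β·max_i Σ_j |B_ij|` | one-hot penalty magnitude; the default provably makes every violation cost more than any modularity gain, so the relaxed optimum is feasible |
| `num_reads` | 1000 | independent anneals; the result is best-of-reads |
| `sweeps` | 1000 | Metropolis sweeps per read |
| `threshold` (`t`) | 0 | zero out `|B_ij| ≤ t` (strict survival `>`, diagonal kept) before building the QUBO |

**Choosing the penalty.**  The safe default is conservative; annealing
quality improves markedly with the smallest `γ` that still yields feasible
reads, because the `2γ` intra-super-node couplings are the barrier a node
must cross (two flips) to change community once the anneal cools.
Feasibility is sharp in `γ`: on the binarized Les Misérables network,
`γ = 5` yields no feasible reads while `γ = 7` yields ~95%.  Hand-tuned
values for the bundled benchmarks: `γ = 5` (karate club, `k ≤ 4`), `γ = 3`
(karate club at larger `k`, where only a small feasible fraction is needed
for best-of-reads), `γ = 7` (Les Misérables, binarized).  Since feasible
samples are *selected*, not averaged, a low feasible fraction is harmless
as long as some reads are feasible; `best_partition` raises an explicit
error if none are.

## Annealer

Each read is an independent single-spin-flip Metropolis anneal from a
uniform random bitstring, with sequential variable order (fixed, for
reproducibility under seeding) and a geometric inverse-temperature ramp.
Local fields are cached and updated on accepted flips, and the inner loop
is JIT-compiled, so a read costs `O(sweeps · N)` attempts plus `O(degree)`
per accepted flip.  No spin-reversal transforms are applied.  Per-read
seeds are spawned from the user seed, so identical
`(problem, num_reads, schedule, seed)` gives identical output.

The automatic temperature range is

    β_hot  = ln 2   / max_u (|h_u| + Σ_v |J_uv|)
    β_cold = ln 100 / min( median |J| over nonzero couplings,
                           min |h| over nonzero linear terms )

The hot end accepts the worst possible flip with probability ½.  The cold
end deliberately freezes the *typical* coupling rather than the smallest
one: modularity coefficients span orders of magnitude (down to
`g_i g_j / 2m` for two leaves), and cooling far below the scale where any
move still occurs wastes sweeps in a frozen state — with a
smallest-coupling rule the karate-club record is reliably missed, with the
median rule it is reliably found.  The linear-term guard handles
penalty-dominated problems (e.g. a fully thresholded `B`), whose weakest
relevant scale is a linear bias, not a coupling.

An exhaustive solver (`≤ 22` variables, chunked enumeration) provides the
exact ground-state set and serves as the oracle in solver tests.  The
pipeline accepts any object mapping a QUBO to a sample set, so quantum or
hybrid backends can be plugged in; outputs are validated (bitstring
length, energy consistency) before decoding.

## Thresholding

`threshold_matrix(B, t)` zeroes off-diagonal entries with `|B_ij| ≤ t` and
reports the retained-pair count `E' = #{i < j : |B_ij| > t}`.  The
annealer runs on the sparsified matrix; modularity is *always* evaluated
on the original `B`.  On the karate club, `E'` falls 561 → 334 (t = 0.06)
→ 169 (t = 0.15) while the recovered community structure — and hence Q —
is unchanged well past 40% sparsification, which is what makes the
approach attractive for hardware with scarce couplers.

## Decoding and selection

Feasible bitstrings decode to partitions; infeasible ones are reported
per super-node and discarded by default (silently repairing would mask an
under-sized penalty).  An explicit repair mode instead assigns each
violating super-node greedily to its best community.  Among feasible
samples the partition maximizing Q on the original `B` wins; ties break
toward fewer non-empty communities, then the lexicographically smallest
canonical labeling, so results are deterministic.  `N_com` counts
non-empty communities — empty slots are legal, which is why the community
count can plateau at 4 while `k` grows.

## Synthetic data and what the tests show

The planted-partition generator draws each within-block pair with
probability `p_in` and each cross-block pair with `p_out < p_in`
(Bernoulli, seeded).  The recovery tests use four blocks of eight nodes
with `p_in = 0.9`, `p_out = 0.05` — strong, balanced, assortative
structure whose modularity optimum coincides with the planted labels with
high probability.  Real networks are harder in ways this generator does
not emulate: degree heterogeneity, overlapping or nested communities,
size imbalance, and structure near the detectability limit.  Passing the
recovery test therefore validates the encode–anneal–decode loop, not
state-of-the-art detection power.

A brute-force oracle enumerates every set partition (restricted-growth
strings, capped at `n = 10`, Bell(10) = 115 975) and anchors the toy-graph
tests: the pipeline must reproduce the exact maximum-modularity partition
on the triangle, the 4-path, two disjoint triangles, and the 6-node
barbell.

## Numerical choices

- Zero row/column sums of `B`, the spin/binary identity, sampler energy
  consistency, and the feasible-energy identity are asserted at 1e-9
  absolute (dense sums of ~10³ doubles).
- Thresholding keeps entries with `|B_ij| > t` strictly; at `t = 0` all
  `C(n,2)` pairs survive on graphs whose `B` has no exact off-diagonal
  zeros.
- Exhaustive ground-state ties are collected within 1e-9.
- Duplicate edges sum their weights (coappearance-count semantics);
  self-loops are dropped with a warning since the adjacency diagonal is
  zero by definition.
- Degenerate inputs: an edgeless graph is rejected (`2m = 0`); a fully
  thresholded `B` leaves a penalty-only QUBO whose feasible states all tie,
  and any one-hot state is returned with Q scored on the original matrix.

## Problem sizes used in the shipped experiments

The acceptance runs use `k = 4` (karate-club record and thresholding,
136 variables), `k = 1..8` for the convergence sweep (up to 272
variables), and `k = 8` on the 77-node Les Misérables graph (616
variables), with 1000–2000 reads of 1000 sweeps — a few minutes end to
end on one CPU.  The annealer itself handles whole problems into the
few-thousand-variable range without decomposition.

## Known limitations

- **Single-flip quality ceiling.**  Moving a node between communities
  requires two flips through a penalty-priced intermediate state, so once
  the anneal cools the landscape is glassy.  On the karate club the
  record partition is still reached reliably, but on larger benchmarks
  best-of-reads plateaus below the best published partitions — binarized
  Les Misérables saturates near Q ≈ 0.53 (best known ≈ 0.56) even with
  5000 reads — matching the published behaviour of classical annealing on
  this same QUBO encoding, where quantum-annealer runs of the identical
  formulation score higher.  Closing that gap needs cluster moves or a
  hybrid subproblem solver, both out of scope.
- Dense `B` construction is `O(n²)` memory; graphs beyond ~10⁴ nodes need
  a sparse formulation.
- The penalty magnitudes for best quality remain per-graph tunable; only
  the conservative feasibility bound is automatic.
- Directed graphs, multigraphs, overlapping communities, and resolution
  parameters are not modelled.
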