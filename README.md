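# qubomod

Multi-community detection by modularity maximization, formulated as a
quadratic unconstrained binary optimization (QUBO) problem with a
*k-concurrent* one-hot encoding and solved by a seeded classical
simulated-annealing sampler.

Community detection — splitting a network into groups of densely
interconnected nodes — shows up across systems biology and the social
sciences: orbital-connectivity graphs of proteins, metabolic networks,
friendship and collaboration networks.  The standard quality score is
Newman's modularity

```
Q = (1/2m) Σ_ij  B_ij δ(c_i, c_j),      B = A − g gᵀ / 2m,
```

where `A` is the (weighted) adjacency matrix, `g` the degree vector,
`2m = Σ_i g_i`, and `c_i` the community of node `i`.  Instead of recursive
bisection, all (at most `k`) communities are found in a single
optimization: each node becomes a *logical super-node* of `k` binary
variables `x_{i,j}` ("node `i` is in community `j`"), the one-hot
constraint `Σ_j x_{i,j} = 1` is enforced by a quadratic penalty of
magnitude `γ_i`, and maximizing

```
Xᵀ (β·blockdiag(B,…,B) + B_Γ) X − 2 Γᵀ X
```

over binary `X` maximizes `Q`.  The resulting QUBO is minimized here by a
classical annealer (independent single-spin-flip Metropolis anneals,
best-of-`num_reads`); any other backend — e.g. a quantum annealer adapter —
can be plugged in through a one-function sampler contract.  The modularity
matrix can additionally be *thresholded* (`|B_ij| ≤ t` zeroed) before
building the QUBO, shrinking the problem while quality is always evaluated
against the original `B`.

## Worked example

The Zachary karate-club network (34 nodes, 78 edges) ships as a fixture:

```python
from qubomod import load_benchmark, detect_communities

res = detect_communities(load_benchmark("zachary"), k=4, penalty=5.0,
                         num_reads=1000, seed=42)
print(round(res.modularity, 5), res.num_communities)
# 0.41979 4
```

`0.41979` is the record modularity for this graph (first reached by the
Louvain method), obtained here with four communities found in a single
anneal of the 136-variable QUBO.  The same run from the command line:

```sh
$ qubomod detect zachary.edgelist --k 4 --penalty 5 --num-reads 1000 --seed 42
{
  "graph": {"n": 34, "num_edges": 78, "total_weight_2m": 156.0},
  "k": 4,
  "penalty": [5.0],
  "retained_pairs": 561,
  "modularity": 0.41978961209730353,
  "num_communities": 4,
  "feasible_fraction": 0.946,
  "labels": {"0": 0, "1": 0, "2": 0, "3": 0, ...}
}
```

`feasible_fraction` is the share of anneal reads satisfying every one-hot
constraint; infeasible reads are discarded (or greedily repaired with
`--repair-infeasible`).  Other commands: `qubomod sweep-k` (quality vs.
slots per super-node), `qubomod threshold-scan` (quality vs. modularity-
matrix sparsification), `qubomod benchmark` (the bundled benchmark table):

```sh
$ qubomod benchmark --names zachary --k 4 --penalty 5 --seed 42
name    N   E   N_com  Mod
zachary 34  78  4      0.41979
```

## Layout

- `qubomod.graph` — graph model, edge-list/GML readers, bundled benchmarks
- `qubomod.modularity` — modularity matrix, partition quality, spin forms,
  thresholding
- `qubomod.qubo` — the k-concurrent one-hot QUBO builder
- `qubomod.anneal` — simulated annealer, exhaustive solver, sampler
  contract
- `qubomod.decode` — bitstring decoding, best-partition selection,
  experiment drivers
- `qubomod.synth` — planted-partition generator, toy graphs, brute-force
  oracle
- `qubomod.cli` — the `qubomod` command

See `docs/methods.md` for the model, parameter guidance, and limitations.
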