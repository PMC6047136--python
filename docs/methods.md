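# Methods

This note documents the models implemented in `netlinkpred`, the parameters
that matter, the numerical choices, what the synthetic benchmark does and does
not emulate, and the known limitations.

## Data model

The central object is a binary bipartite adjacency matrix `A` (`n_t` targets
in rows, `n_d` drugs in columns) with unique string labels on both axes.
Degrees are row/column sums: `k(t_l)` for targets, `k(d_i)` for drugs, and
`m = Σ A` is the interaction count. Side information enters as square
symmetric similarity matrices with unit diagonal and entries in [0, 1]
(drug–drug chemical similarity, target–target sequence similarity), aligned
to the network by label, not by position. Mild asymmetry from file rounding
(≤ 1e-6) is repaired by symmetrizing `(S + Sᵀ)/2`; anything larger is
rejected as a data error. One-mode projections connect two drugs iff they
share at least one target (and dually for targets); they are deliberately
unweighted — the prediction indices, not the projection, are where evidence
strength belongs.

## Bipartite recommenders

All four scorers fill in an `n_t × n_d` real score matrix; masking known
edges is the ranker's job, so scores at known positions are kept.

**NBI (mass diffusion).** Each drug column of `A` is an initial unit of
resource per known target. Phase 1 spreads it to drugs, each target dividing
its resource equally among its drugs; phase 2 spreads it back, each drug
dividing equally among its targets:

    F = A D_d⁻¹ Aᵀ D_t⁻¹ A,   D_t = diag(k(t_l)), D_d = diag(k(d_i)).

The diffusion conserves each drug column's total resource (its degree) —
this is asserted in the tests and is the quickest smoke test of the
implementation. Degree-zero drugs score an all-zero column with a warning.
When similarity matrices are supplied the topology score is blended as
`F' = Ŝ_t F Ŝ_dᵀ` with row-normalized similarities: each pair borrows
evidence from similar drugs and similar targets. This is the simplest
blending consistent with "similarity-augmented NBI"; identity similarities
reproduce the topology-only score exactly, which pins the convention down in
a test.

**HeatS.** The same two phases with receiver-degree averaging instead of
sender-degree splitting: `F = D_t⁻¹ A D_d⁻¹ Aᵀ A`. HeatS needs no
similarity matrices.

**Heterogeneous RWR.** A `(n_d + n_t)`-state Markov chain with block
transition matrix

    [ (1−λ)·rownorm(S_d)    λ·rownorm(Aᵀ) ]
    [ λ·rownorm(A)          (1−λ)·rownorm(S_t) ]

where rows of nodes without bipartite links keep full weight on their
similarity block (the walker has nowhere to cross), and all-zero similarity
rows fall back to uniform with a warning. For each drug `j` the walk restarts
at `e_j` with probability `c`; the fixed point `p = (1−c) Mᵀ p + c e_j` is
found by power iteration (L1 tolerance 1e-9, cap 10⁴ iterations;
non-convergence raises with the final residual). Column `j` of the score
matrix is the target block of `p`. Defaults `c = 0.7`, `λ = 0.5` follow the
heterogeneous-RWR literature's common choices; both are exposed.

**netcombo.** NBI and RWR scores live on incomparable scales (resource units
vs probability mass), so each matrix is min–max scaled to [0, 1] over the
unknown pairs and the two are averaged entrywise. Scaling over unknown pairs
(rather than all entries) keeps the operative part of the ranking — the
candidate pairs — spread over the full unit interval; entries outside the
range (possible only at known pairs) are clipped.

## Unipartite indices

The nine neighborhood indices follow their standard set definitions on the
binarized adjacency; ratio indices define 0/0 = 0 so isolated nodes score
zero instead of NaN, and Adamic–Adar skips degree-1 common neighbors
(`ln 1 = 0`). The local path index is `A² + εA³` with `ε = 0.01` by default —
the conventional value; at `ε = 0` it reduces to common neighbors
off-diagonal. Katz requires `β < 1/ρ(A)` and is computed by a direct solve of
`(I − βA)S = βA·…` via the matrix inverse; violations report the computed
spectral radius. Geodesic similarity is `1/d(x, y)` (0 when unreachable) —
among the candidate transforms of shortest-path distance, the inverse is used
and the others are out of scope. Hitting times solve the per-destination
linear system `H[x,y] = 1 + Σ_{z∈Γ(x)} H[z,y]/k_x`, `H[y,y] = 0`, exactly on
each connected component (cross-component pairs are +inf); the matrix is
asymmetric and is reported raw — lower means closer, and the CLI ranking
sorts it ascending.

## LP-BRIM communities

Barber modularity `Q_B = (1/m) Σ_{l,i} (A_{li} − k_l d_i / m) δ(g_l, g_i)`
is the objective of both phases. Label propagation starts every node with a
unique label and sweeps all nodes in a seeded random order (reshuffled per
sweep), each node adopting the most frequent label among its bipartite
neighbors with uniform-random tie-breaks under the run seed. A sweep with no
label changes *and* no coin-flipped ties is a genuine fixed point and stops
the phase; plateaus where only ties were re-flipped keep sweeping (bounded by
10·(n_t+n_d) sweeps) so 50/50 split states can resolve, and a strict
modularity drop returns the best partition seen. BRIM refinement then
alternates: holding targets fixed, each drug moves to the module maximizing
its `Q_B` contribution (computed as a single matrix product against the
modularity matrix `B = A − k dᵀ/m`; ties keep the current module, else lowest
id), then the converse, until the improvement is below 1e-12. `lpbrim` runs
the pipeline from 5 restarts by default and keeps the best `Q_B`; empty
modules are compacted to a contiguous id range.

## Yen's K shortest loopless paths

Dijkstra is implemented with heap entries carrying the partial path, so among
equal-length paths the lexicographically smallest node sequence pops first —
full determinism without a separate tie-break pass. Yen's construction then
deviates at every spur node of each accepted path, masking the root path's
nodes and the outgoing edges used by previously accepted paths with the same
root; candidates are deduplicated and kept in a heap ordered by
(length, node sequence). Unweighted graphs use unit edge costs through the
same code path.

## Evaluation protocol

`remove_links` hides `⌊fraction·m⌋` interactions (error when that is zero or
everything): uniformly, or with probability proportional to `k(t_l)·k(d_i)`
in `degree` mode, which preferentially hides links between frequently
interacting nodes. `benchmark` repeats removal/rescore/rank `reps` times and
averages. The ranked list is all non-training pairs, sorted by score with a
deterministic label tie-break; hidden links are the actives. With actives at
ranks `r_1 < … < r_n` among `N` candidates:

- `AUC = 1 − (Σ r_i − n(n+1)/2)/(n(N−n))` — the Mann–Whitney statistic;
- `AUAC = 1 − Σ r_i /(nN)` — the left-Riemann area under the accumulation
  curve;
- `AUCTOP` — the truncated-ROC area over the top `⌈χN⌉` rows, with actives
  below the cutoff contributing zero concordance (a pure-active window
  degenerates to the fraction of actives recovered);
- `EF = (n_top/⌈χN⌉)/(n/N)`;
- `BEDROC` — the Truchon–Bailey exponentially weighted form with `α = 20`.

Defaults `α = 20` and `χ = 0.1` are the common early-recognition choices; the
10% window is fixed by the protocol's AUCTOP(10%) convention, `α` and the EF
window are otherwise free parameters. Uniform removal is the benchmark
default.

`permutation_test` scores the intact network, then rewires the adjacency with
degree-preserving checkerboard swaps (2×2 submatrix flips; burn-in 10·m
successful swaps, m swaps between the `n_perm` samples; an attempt cap turns
a swap-free matrix such as a complete bipartite network into an explicit
error). Per pair, `z = (observed − mean)/sd` over the permuted scores and
`p` is the upper-tail standard-normal probability; constant pairs (`sd = 0`)
get the sentinel `p = 0.5`. Benjamini–Hochberg `q` values are attached before
any `p ≤ p_keep` filtering. A label-shuffling null (`null="shuffle"`) is
available as the literal "permute the matrices" alternative; the
degree-preserving null is the default because it is the defensible null for
networks with heterogeneous degrees.

**Calibration caveat (a measured limitation).** The normal approximation
behind these p-values is poor for diffusion scores: under the
degree-preserving null the per-pair score distribution is a discrete mixture
over the pair's own edge indicator — platykurtic (excess kurtosis ≈ −1.2) on
dense networks and strongly right-skewed on sparse ones — so the p-value
distribution on a structureless network deviates from uniform (KS distance
≈ 0.05–0.3 depending on scorer and null) no matter how many permutations are
drawn. The acceptance suite asserts the uniformity check anyway and the
corresponding test documents the failure; treat the p-values as a ranking
heuristic, not calibrated tail probabilities. Empirical-rank p-values would
be calibrated by exchangeability and are the natural fix if calibration is
ever needed.

## Synthetic benchmark

`gen_bipartite` plants `n_modules` blocks (drugs and targets split
near-evenly) and draws edges with `p_in` within blocks, `p_out` across;
empty rows/columns are repaired with one forced within-block edge so every
node satisfies the recommenders' degree assumptions. `gen_similarity` blends
the Jaccard similarity of interaction profiles (weight `sim_signal`) with
symmetric uniform noise — mirroring how chemical/sequence similarity
correlates with shared interaction partners, which is exactly the signal NBI
blending and heterogeneous RWR exploit. The default conditions (50 drugs ×
40 targets, 4 modules, `p_in = 0.5`, `p_out = 0.02`, `sim_signal = 0.8`)
give a network of ~280 interactions, dense enough to benchmark in seconds
yet sparse enough that ranking hidden links is non-trivial; real drug–target
classes are larger and sparser, so absolute metric values here say that the
machinery works, not what it would score on any particular curated dataset.
The generator does not emulate realistic chemistry or sequences, hub-heavy
scale-free degree distributions, or annotation noise (false-positive
interactions); conclusions about those require real data. Structureless
controls use `n_modules = 1` at the default within-block density.

## Problem sizes and reproducibility

Everything is seeded: generators and algorithms take explicit seeds, the CLI
derives per-component sub-seeds from one global `--seed` by hashing
`seed:component` (SHA-256 mod 2³¹), and every artifact embeds its parameters
in `#` metadata lines. Benchmarks in the test suite and the acceptance
script use 10 removal repetitions on the 50×40 conditions and 20 seeds for
module recovery — sizes chosen so the whole suite replays in well under a
minute while keeping the Monte-Carlo error of the asserted means an order of
magnitude below the asserted margins.

## Known limitations

- Dense `numpy` linear algebra throughout: fine into the low thousands of
  nodes, not engineered for genome-scale interactomes.
- The NBI similarity blending is one defensible convention; published
  variants differ and no attempt is made to match any specific one.
- Permutation p-values are not calibrated (see above); only the adjacency is
  permuted, similarity matrices are held fixed.
- No cross-validation variants (LOOCV, per-drug folds) — only repeated random
  link removal; no directed or temporal graphs.
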