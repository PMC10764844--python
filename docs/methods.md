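# Methods

This note records the model, the numerical choices, and the design calls
made where the design was genuinely open. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Model and assumptions

The package operates on undirected, unweighted graphs, possibly with
self-edges; directed graphs, multi-edges and continuous edge weights are
out of scope. The unit of mesoscale structure is the patch `A_x` induced by
a k-path `x = (x_1, …, x_k)`: a symmetric binary k×k matrix with
`A_x(i, j) = A(x_i, x_j)`. On-chain entries `(i, i±1)` are 1 by path
validity; the diagonal records self-edges. Patches are flattened
column-wise (Fortran order), so position `(i, j)` maps to vector index
`(j−1)·k + i` in 1-based terms.

**Diagonal convention.** Patch diagonals are carried in the data structures
but excluded from coding, reconstruction and the L1 patch error. Rationale:
all displayed motif structure concerns node pairs, and including a
diagonal of structural zeros in the least-squares fit would bias codes for
dictionaries with nonzero diagonal mass. This was an open call; it is
configurable only by editing `graph_core.coding_positions`.

## Exact k-path sampling

The target distribution — uniform over all k-paths — is realized exactly
rather than by MCMC. With `w_0(v) = 1` and
`w_j(v) = Σ_{u ~ v} w_{j−1}(u)`, drawing `x_1 ∝ w_{k−1}(x_1)` and each
successor among neighbors `∝ w_{k−i−1}` produces an exactly uniform k-walk;
rejecting walks with repeated nodes leaves the uniform distribution on
k-paths. Preprocessing is `O(k·|E|)` and is cached in a `PathSampler` so
minibatch learning and reconstruction amortize it. Walk counts are stored
as float64: they can exceed 2^63 on dense graphs at large k, only their
ratios matter for sampling, and on the small graphs where exactness is
asserted they are exactly representable. Self-edges participate in walks
(a walk may step v→v) but never survive the distinctness filter.

The rejection cap defaults to 10^6 attempts; on failure the error reports
the empirical acceptance rate, which estimates the k-path/k-walk ratio.

## Online dictionary learning

At each iteration t, N sampled patches form `X_t` (k²×N), are coded against
the current dictionary, and the sufficient statistics are updated with the
balanced 1/t schedule

    P_t = (1 − 1/t) P_{t−1} + (1/t) H Hᵀ / N,
    Q_t = (1 − 1/t) Q_{t−1} + (1/t) X Hᵀ / N,

after which each dictionary column takes its exact block minimizer of the
surrogate `tr(WᵀW P) − 2 tr(WᵀQ)` projected onto `[0, 1]`:
`W_j ← Proj(W_j − (W P_j − Q_j)/P_jj)`. Any weighting schedule with the
same fixed points would do; 1/t is the classic online-matrix-factorization
choice with known convergence behavior. Fixed points, not trajectories, are
the contract: the tests assert invariants of the limit (motif recovery,
surrogate monotonicity, bitwise reproducibility), not step-by-step values.

Choices that were open and how they were fixed:

* **Coding.** `min ‖x − Wh‖² + λ‖h‖₁, h ≥ 0`, solved by cyclic coordinate
  descent to a 10⁻⁸ coordinate-update tolerance and cross-checked against
  `scipy.optimize.nnls` in the tests. λ defaults to 0.
* **Clamping to [0, 1]** (not mere nonnegativity) enforces the definition
  of a latent motif as a weighted graph with weights in [0, 1].
* **Initialization** is i.i.d. uniform [0, 1] from the run seed — standard
  for NMF. The same seed reproduces `W_T` bitwise.
* **Dead atoms.** A column whose motif is never used in a round (`P_jj = 0`)
  is skipped with a warning; a column that collapses to exactly zero is
  reseeded from a random patch of the current minibatch, keeping the
  no-all-zero-column invariant.
* **Symmetry** is not enforced during learning (the data are symmetric, so
  symmetric motifs emerge); motifs are symmetrized only for display and
  for the community-size diagnostic.
* **Defaults** T = 100 minibatches of N = 1000 patches. The method only
  requires the minibatch to be much smaller than the patch population;
  these sizes make the 1/t averaging effectively converge on the fixtures
  used here while staying independent of network size.

## Reconstruction and the error bound

Reconstruction samples T k-paths (default `100·|E|/(k−1)`, i.e. ~100
on-chain visits per edge), codes each patch, clips the coded entries to
[0, 1], and averages per unordered node pair over all covering positions,
both orientations counted. Pairs never covered are absent (weight 0);
diagonal positions never contribute. Distinct patches are cached by byte
pattern, which on sparse or highly regular graphs collapses most coding
solves. Clipping before averaging was an open call: entries of a
nonnegative combination can exceed 1, weights are meant to be confidences
in [0, 1], and clipping can only shrink the per-entry approximation error.

**Masked (denoising) mode.** With `mask_on_chain` set, coding uses the
dictionary with on-chain entries zeroed and omits the 2(k−1) on-chain
vector positions from the objective, and on-chain positions of each patch
are discarded from the accumulator. An edge's weight then depends only on
its off-chain appearances. Without this, every observed edge is certified
by its own trivially-1 on-chain entries: reconstruction weights of planted
false edges are driven toward 1 and anomaly detection inverts (AUC below
chance on the planted-noise fixture). The masked mode is therefore the
denoising protocol; the unmasked mode is the reconstruction protocol.

**Which distance the bound controls.** The reconstruction error bound

    JD(G, G_recons;W) ≤ E_x[ ‖A_x − Â_x;W‖₁ ] / (2(k−1))

holds for the *coverage-weighted* Jaccard distance, in which each node pair
is weighted by the number of patch incidences covering it: the numerator
is then at most the total incidence error (Jensen), and every sampled path
contributes 2(k−1) on-chain incidences to the denominator — so the bound
holds deterministically for any dictionary, any graph, and any finite
sample. The unweighted pairwise Jaccard distance obeys no such bound on
sparse graphs, where a large number of barely-covered non-edges each carry
full weight in the distance but almost no mass in the patch error; the
package provides both (`metrics.weighted_jaccard_distance` for accuracy
reporting, since it reduces exactly to the binary Jaccard index on
thresholded graphs, and `ndr.coverage_weighted_jaccard_distance` for the
bound check). The `check_reconstruction_bound` helper estimates the right-hand side by
Monte Carlo on an independent patch sample and allows two standard errors
of slack for that estimate only.

The L1 norm runs over all off-diagonal entries (both triangles), matching
the coding convention; for a chain-only dictionary on an Erdős–Rényi graph
this makes the expected per-patch error `(k−1)(k−2)p`, which the tests
check against the analytic value.

## Generators and corruption models

* **ER(n, p)**: independent Bernoulli(p) over distinct pairs, implemented
  by chunked sampling of the linearized upper triangle.
* **WS(n, k, p)**: ring of n nodes each adjacent to its k nearest
  neighbors; each edge independently rewired with probability p by
  detaching one of its two ends (chosen with equal probability) and
  reattaching uniformly, redrawing on self-loop or duplicate collisions.
  The collision rule was unstated in the sources of this construction;
  redrawing conserves the edge count `nk/2` exactly, which downstream
  counts rely on.
* **BA(n, n0)**: growth from n0 isolated nodes; each arrival attaches n0
  distinct degree-proportional edges. The first arrival attaches uniformly
  (degree-proportional is undefined at all-zero degree), forced to all n0
  seeds. Final edge count `n0(n − n0)` exactly.
* **SBM(C_1…C_k0, B)**: independent Bernoulli with block probabilities;
  one block specializes exactly to ER.
* **−ER**: a uniform spanning tree is drawn with Wilson's loop-erased
  random-walk algorithm (exact uniformity, verified against the
  Kirchhoff count on a small fixture); `⌊|E_0|/2⌋` off-tree edges are
  removed, the floor resolving odd counts deterministically. The observed
  graph is connected by construction.
* **+ER**: "uniform" adds exactly `⌊|E|/2⌋` uniformly random nonedges;
  "block" picks `⌈0.05|V|⌉` nodes and adds each absent pair among them
  with probability 0.3. Both variants circulate under the same name in the
  literature this follows, so records carry the variant in their manifest.
* **+WS**: a WS(n0, k, p) graph planted on n0 uniformly chosen nodes; the
  planted set has exactly `n0⌊k/2⌋` edges, collisions with existing edges
  are logged and excluded from the positive-label set.

All generators are seed-deterministic through a single
`numpy.random.Generator` chain.

## Denoising evaluation

Candidates: for additive noise, all edges of the observed graph; for
subtractive noise, the removed edges plus an equal number of
never-existing nonedges sampled without replacement with probability
proportional to the product of endpoint degrees in the observed graph
(uniform nonedge sampling would concentrate on low-degree pairs and make
the task trivially easy for degree-based baselines). Labels are oriented
so 1 always means "true edge" and scores are confidences that an edge is
true; AUC is invariant under jointly flipping labels and scores, so this
orientation is a pure convention. Adamic–Adar terms with degree-1 common
neighbors are skipped (`ln 1 = 0` would diverge). The spectral baseline is
a rank-d (default 32) symmetric adjacency eigendecomposition scored by the
corresponding low-rank matrix entry. Threshold selection maximizes
accuracy on a 50% training split and reports held-out accuracy, precision,
recall and F-score.

## What the synthetic fixtures do and do not show

The test fixtures are generated programmatically: ER/WS/BA/SBM graphs at a
few hundred nodes, a pure path (a single patch type), a path-plus-triangle-
chain union (exactly two patch types at k = 3), and planted-noise SBMs.
They exercise exact distributional properties (sampler uniformity against
enumeration, generator edge-count identities, spanning-tree uniformity),
identifiability at the correct rank, the error bound, and the ordering of
denoising methods on structured noise. They do not emulate the degree
heterogeneity, clustering, or community-size distributions of real social
and protein-interaction networks, so passing tests demonstrate
correctness of the algorithms and their guarantees, not the accuracy
levels those algorithms reach on real data. Real networks can be supplied
as edge lists through the same API and CLI.

Problem sizes in the heavier tests (a 300-node SBM for denoising, ~20
bound trials at k ∈ {3, 6, 11}, 10⁵-draw uniformity checks) are the
package's chosen desk scale: large enough for the asserted separations to
be stable across seeds, small enough that the whole suite runs in minutes.

## Known limitations

* Rejection sampling makes large k on graphs with few long paths
  expensive; the sampler reports its acceptance rate and refuses past a
  configurable cap rather than degrading silently.
* The NNLS coding cache keys on exact patch bytes; on highly
  heterogeneous graphs at large k most patches are unique and
  reconstruction cost is dominated by per-patch solves.
* Learned dictionaries are local minimizers of a nonconvex objective;
  different seeds can give different motif sets of equal coding quality,
  so motif identity should not be over-interpreted (only the subspace
  they span is constrained by the data).
* The limiting (infinite-T) reconstruction is checked empirically through
  weight convergence, not computed in closed form.
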