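# netdict

Latent-motif dictionary learning for networks: learn a small set of k-node
weighted subgraph patterns ("latent motifs") that approximate the mesoscale
structure of a graph, reconstruct the graph from them, and use the
reconstruction weights to detect anomalous or missing edges.

## Who this is for

Network scientists and systems biologists who want a compact, interpretable
description of the *mesoscale* of a network — the connection patterns of
k-node subgraphs, between the microscale of single edges and global summary
statistics — and who want to use that description for concrete tasks:
comparing networks, denoising protein–protein interaction data, and ranking
candidate edges.

## The method

A **k-path** is a sequence of k distinct nodes with consecutive nodes
adjacent; the **mesoscale patch** `A_x` of a k-path `x` is the k×k adjacency
matrix of the subgraph induced by its nodes, ordered by the path. Entries
`(i, i+1)` are *on-chain* (always 1 for a valid path); all other
off-diagonal entries are *off-chain* and carry the structural signal.

1. **Sampling.** k-paths are drawn exactly uniformly at random by dynamic
   programming: counting the j-step walk extensions `w_j(v)` of every node
   lets one draw a uniform k-walk sequentially, and rejecting walks with
   repeated nodes yields uniform k-paths.
2. **Network dictionary learning (NDL).** Patches are column-wise
   vectorized into `k²`-vectors and streamed in minibatches through online
   nonnegative matrix factorization, `X ≈ W H` with `W ∈ [0,1]^{k²×r}`.
   Reshaping the columns of `W` gives r latent motifs `L_1, …, L_r` —
   k-node weighted graphs with edge weights in [0, 1].
3. **Network denoising and reconstruction (NDR).** Each sampled patch is
   approximated by its best nonnegative linear combination of motifs
   (nonnegative least squares). The reconstructed weight `A_recons(x, y)`
   of a node pair is the mean of the approximated entries over every
   sampled patch and position covering that pair; thresholding at θ gives a
   binary reconstruction. Weights are confidences that a pair is a true
   edge, so small-weight edges of an observed network are suspicious.
4. **Error bound.** The coverage-weighted Jaccard distance between a graph
   and its reconstruction satisfies

   `JD(G, G_recons;W) ≤ E_x[ ‖A_x − Â_x;W‖₁ ] / (2(k−1))`,

   where `x` is a uniform k-path and `Â_x;W` the best nonnegative
   approximation of the patch — a dictionary that codes patches well is
   guaranteed to reconstruct the network well.

Generators (Erdős–Rényi, Watts–Strogatz, Barabási–Albert, stochastic block
model), three corruption models (−ER edge deletion preserving a uniform
spanning tree, +ER and +WS false-edge injection), classical link-prediction
baselines (Jaccard coefficient, preferential attachment, Adamic–Adar,
spectral embedding) and ROC/AUC evaluation are included for end-to-end
denoising experiments.

## Worked example

```python
import numpy as np
import netdict as nd

# a two-block stochastic block model: dense blocks, sparse between
B = np.full((2, 2), 0.02); np.fill_diagonal(B, 0.25)
g = nd.sbm_graph([60, 60], B, seed=0)

dic = nd.learn_dictionary(g, k=6, r=9, T=50, N=300, seed=0)
err = nd.mean_patch_l1_error(g, dic, n_samples=500, seed=1)
rep = nd.check_reconstruction_bound(g, dic, T=20000, n_samples=500, seed=1)

wg = nd.reconstruct(g, dic, T=20000, seed=2)
binary = nd.threshold_graph(wg, 0.4)
acc = nd.accuracy_report(g, binary, 0.4)
```

Output:

```
graph: 120 nodes, 971 edges
mean patch L1 error: 4.295 +/- 0.085
coverage-weighted JD: 0.251  bound: 0.430  holds: True
Jaccard accuracy at theta=0.4: 0.997 (971/974 edges)
```

The nine learned motifs mis-state each 6-node patch by about 4.3 entries on
average (a patch has 30 off-diagonal entries), which caps the weighted
reconstruction distance at 0.43; the measured distance 0.25 respects the
bound, and after thresholding the weighted reconstruction at θ = 0.4 the
binary reconstruction recovers the graph almost exactly (Jaccard index
0.997: all 971 edges recovered, 3 spurious).

The same pipeline is available from the shell:

```sh
netdict generate --model sbm --sizes 60,60 --p-in 0.25 --p-out 0.02 --seed 0 --out sbm.txt
netdict learn sbm.txt --k 6 --r 9 -T 50 -N 300 --out dict.json
netdict reconstruct sbm.txt --dictionary dict.json --theta 0.4 --out-dir recon/
netdict denoise sbm.txt --noise +WS --n0 20 --ws-k 6 --k 6 --r 9 --out results.tsv
```

Every command logs its seed and writes a JSON manifest of all resolved
parameters next to its outputs.

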