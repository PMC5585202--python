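# Methods

## The network model

A musculoskeletal system is coded as a simple, undirected, unweighted
graph: one node per bone or muscle, one link per physical contact
(bone–bone articulation, muscle–bone attachment, or direct
muscle–muscle contact). Matrices are binary by construction — a
contact is present or absent — so the graph statistics below are
purely topological; they deliberately ignore size, shape and the
strength of attachments. Ligaments, vessels and nerves are out of
scope. Adjacency CSVs must be square, symmetric, 0/1, with a zero
diagonal (a part is never in contact with itself); every violation is
rejected with an error naming the offending cell, because silent
coercion of a miscoded matrix would corrupt every downstream
statistic.

## Whole-network parameters

`N`, `K`, density `D = 2K/(N(N−1))`, mean local clustering `C`,
characteristic path length `L` and degree heterogeneity
`H = sd(k)/mean(k)`. Numerical conventions, each chosen where the
definitions in the literature are ambiguous and each switchable:

* Nodes of degree 0 or 1 have no neighbour pair; their local
  clustering enters the average as 0 by default
  (`include_low_degree=True`). Excluding them is the other published
  convention and is exposed as a flag. Include-as-zero is the default
  because it keeps `C` defined on every network.
* `H` uses the population (divide-by-N) standard deviation by default;
  a sample-sd variant and a variance-to-mean variant (the index of
  dispersion, which also appears as a heterogeneity definition) are
  provided. The defaults cannot be discriminated against published
  3-decimal tables without the original matrices, so all three are
  first-class options rather than one being silently canonical.
* `L` averages over unordered pairs and is defined only on connected
  networks; a disconnected input raises instead of averaging
  infinities. Distances are integer link counts.
* Report tables round half-away-from-zero to 3 decimals (so 0.0505
  prints as 0.051); plain banker's rounding would print 0.050.

## Module detection

Walktrap (Pons–Latapy) with `t = 3` walk steps by default. The walk is
lazy: a self-loop is added to every node before the transition matrix
is built, matching the reference implementation — without it the
3-step profiles oscillate on bipartite-ish structures and the merge
sequence degrades measurably. Communities are agglomerated by the
minimal Ward-style increase in within-community squared walk distance,

    Δσ(C1,C2) = (1/N) · |C1||C2|/(|C1|+|C2|) · r²(C1,C2),
    r²(C1,C2) = Σ_k (P^t_{C1,k} − P^t_{C2,k})² / d_k ,

with community profiles recomputed exactly after every merge (not via
the incremental update), ties broken toward the lowest community
indices, and all N−1 merges recorded. Dendrogram heights are the
cumulative Ward cost, which is non-decreasing by construction. The
reported partition is the cut level (of all N) maximizing
Newman–Girvan Q, ties toward fewer modules. Given the network, node
order and `t`, the output is deterministic.

Walktrap is a greedy heuristic: on small graphs its best cut reaches
the exhaustively enumerated global maximum of Q most of the time but
not always (the acceptance script measures the agreement rate on
100 random ≤8-node graphs; exact-profile recomputation makes our cuts
match or slightly exceed the incremental reference implementation on
most graphs). On networks with real modular structure — the planted
benchmark below — recovery of the true partition is essentially
perfect.

The jackknife error of Q treats every link as an independent
observation: each of the K leave-one-link networks is rescored with
the partition held fixed, and `SE = sqrt((K−1)/K · Σ(Q_i − Q̄)²)`.
Re-detecting the partition per deletion is offered as a flag
(`redetect`), but the fixed-partition form is the default: a changing
partition would make the K leave-one-out values observations of
different quantities. Deleting a bridge may disconnect a leave-one-out
network; Q needs only link counts and degrees, so this is harmless.

Each module with ≥2 nodes is validated by a one-sided Wilcoxon
rank-sum test comparing, over the module's nodes, links to inside vs
links to outside the module (H_A: internal > external). Per-node
counts are heavily tied, so for combined sample size ≤ 20 the null is
obtained by full enumeration of group assignments (exact and
tie-correct); larger modules use the tie-corrected normal
approximation. Singleton modules are reported as not-testable rather
than p = 1: an undefined test is not evidence in either direction.

## Phylogenetic signal and ancestral states

Per-taxon network parameters are treated as continuous tip traits on a
rooted tree with branch lengths in time units (the tree need not be
ultrametric). Under Brownian motion tips are multivariate normal with
covariance `C_ij` = shared root-to-MRCA path length; the ML fit is the
GLS closed form (`μ̂ = (1ᵀC⁻¹x)/(1ᵀC⁻¹1)`, `σ̂² = rᵀC⁻¹r/n`).

* **Pagel's λ** scales off-diagonal covariances; the profile
  likelihood is maximized over [0, 1] by bounded scalar optimization
  (tolerance 1e-8), with endpoint snapping because the bounded
  optimizer never evaluates the exact boundary. A flag allows λ above
  1 up to the largest value keeping the transformed covariance valid.
  The p-value is a likelihood-ratio test against λ = 0 on χ²₁ without
  the 50:50 boundary mixture, matching the convention of the widely
  used comparative-methods implementations so p-values are comparable
  across tools; the mixture version is a flag.
* **Blomberg's K** follows the original ratio-of-MSE construction with
  expectation ≈ 1 under BM. Significance comes from tip-label
  permutations of the GLS mean-square error (signal = small MSE), with
  the observed arrangement counted among the permutations, so
  p ≥ 1/(n_perm+1). The permutation seed is a required argument — an
  unseeded permutation test is not reproducible.
* **Ancestral states** are the GLS/BLUP conditional expectations under
  the fitted BM model; the prediction variance includes the
  uncertainty of the estimated root state, and the 95% CI is
  ±1.96·sd. Phenogram exports place every node at (time from root,
  state) and connect each non-root node to its parent; a companion
  file records the tip-value quartiles for the marginal box plot.

Taxon names are matched between trees and trait tables
case-insensitively with underscores treated as spaces; an unambiguous
genus-only match is accepted with a warning.

Both estimators were checked against an independent reference
implementation (R `phytools::phylosig`) on fixed synthetic fixtures:
K agrees to 8 decimals and the λ profile likelihood to ~1e-3 of a
log-unit (optimizer tolerance); the frozen values live in the test
suite.

## The synthetic generator

The limb generator emulates the gross architecture of a forelimb
network: regions ordered proximal→distal, each with a serial chain of
bones (adjacent regions sharing one articulation), the terminal region
branching into five digit rays of three bones; muscles contact nodes
of their own region with probability `p_in` and other regions with
`p_out`, and every muscle's bone attachments are redrawn until it has
an origin and an insertion (≥2 bones). Defaults
(5 regions × 4 bones, 14 muscles/region, digit rays on, `p_in = 0.3`,
`p_out = 0.02`) give connected networks of ≈100 nodes — the size of a
real forelimb network — with the planted regions as ground-truth
modules. The module-recovery benchmark uses the plain-chain variant
(no digit rays, 16 muscles/region: five equal 20-node regions), a
standard planted-partition design.

What the generator does **not** emulate: real attachment-degree
distributions (real muscles are far sparser than bones are; generated
densities run higher than dissection-derived ones), anatomical
identity of nodes, and any biomechanical constraint. Passing the
recovery benchmarks therefore shows the detection pipeline is correct
on networks with known modular truth — not that any particular real
limb is modular.

Yule trees are simulated from two lineages with exponential waiting
times (rate = birth_rate × lineage count) and extended past the last
split so terminal branches are strictly positive; they are ultrametric
by construction. Brownian traits are evolved recursively along
branches (λ = 1) or drawn from the λ-transformed multivariate normal
(λ < 1). Everything is deterministic given its seed.

## Problem sizes

The test suite and the acceptance script use: 50 random graphs
(N ≤ 60) for the clustering/path-length oracles; 100 random ≤8-node
graphs for the exhaustive-enumeration comparison; 50 seeds of the
100-node planted benchmark; 100 replicates each for λ recovery under
BM and under iid noise on 64-tip trees; 200 replicates for the K
expectation; and 1000 null runs × 1000 permutations for the type-I
error of the K test. These sizes give stable Monte-Carlo estimates
(binomial SE ≤ ~0.7 percentage points on the type-I rate) while the
whole acceptance run stays under a minute.

## Known limitations

* Walktrap optimizes Q greedily along one dendrogram; it is not an
  exact modularity maximizer, and no claim of global optimality is
  made (see the measured small-graph agreement rate).
* The Wilcoxon module test treats a module's per-node counts as
  exchangeable observations; links shared between two nodes of the
  same module appear in two counts, so the test is a screening
  diagnostic, not an exact error-controlled procedure.
* λ and K are single-trait tests; no multivariate signal, and no OU or
  early-burst alternatives.
* The bundled published parameter table carries values rounded to 3
  decimals; only identities that survive that rounding (the density
  identity, group means of printed values) are asserted against it.
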