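# Methods

This note documents the models implemented in `coevotree`, their
assumptions, the tunable parameters and their defaults, what the synthetic
generator does and does not emulate, and the numerical choices made where
the design was genuinely open.

## Pair statistics

For a column pair (i, j) only sequences with amino acids at *both*
positions are counted; treating gaps as a 21st letter induces strong
spurious couplings between nearby columns because gaps come in blocks. The
single-column marginal counts entering the likelihood ratio are recomputed
on the same gap-filtered subset, so that

    log R_ij = log P(n_ab) − log P(n_a) − log P(n_b)

is a coherent ratio of Dirichlet-multinomial marginal likelihoods. The
single-column prior pseudocount is `lambda_single` (default 0.5, over 20
cells); consistency of the dependence-tree model forces the joint prior's
pseudocount to `lambda_single / 20` over 400 cells, which the code enforces.
All entropies and mutual informations are in nats; the CLI can convert MI
reports to bits.

**Stirling relation.** `log R / N → MI` as N grows, but the difference at
fixed N contains a systematic offset of roughly `(20·lambda_single)·ln N +
O(1)` nats coming from the `Γ(N + 20λ)` normalisation — ~50–80 nats at
N = 10⁴ under the default λ. The relation is therefore accurate in relative
terms only when `N·MI` dwarfs this offset (MI ≳ 1.5 nat at N = 10⁴); the
test suite asserts a 0.5 % relative agreement on strongly coupled pairs
(MI = ln m for m-letter deterministic couplings, m ≥ 5) and asserts only
the convergence trend for low-MI pairs, where a tight fixed-N bound is
analytically out of reach.

**Z-values.** Scores are standardised per alignment (subtract the mean,
divide by the population SD over all defined off-diagonal pairs), since raw
`log R` scales with alignment depth and phylogeny and cannot be compared
across domains. A degenerate constant matrix maps to all-zero Z with a
warning. Note that an L-column domain has L(L−1)/2 pairs, so the largest
attainable Z is bounded by ≈ √(n_pairs); Z > 4 analyses are meaningful only
for domains with ≳ 20 columns.

**Phylogenetic correction.** The average-product correction subtracts
`rowmean_i · rowmean_j / overallmean` from each pair. MI is non-negative
with zero meaning independence, whereas `log R` is negative for independent
pairs and posteriors are invariant under a global shift of all `log R`
values; the matrix is therefore shifted so its minimum is exactly zero
before the product term is computed. Row means are taken over the L−1
defined partners and the overall mean over all defined off-diagonal pairs
(the convention of the additive/product correction literature); the
additive variant (ASC) is provided for completeness but not used in the
default pipeline.

## The spanning-tree mixture

A dependence tree assigns each non-root column a parent; the alignment
likelihood factorises over edges, and summing the posterior weight of all
`L^(L−2)` labelled trees reduces, by the weighted matrix-tree theorem, to a
single cofactor determinant of the Laplacian of the edge-weight matrix
`β_ij`. With a uniform tree prior, `β = R` (optionally APC-corrected);
informative priors multiply in per-edge weights, and the blend

    log β_ij = α · log R_ij + log w_ij ,   α ∈ [0, 1]

discounts the data term, modelling the fact that phylogenetically related
sequences carry far fewer than N independent observations (α = 1: data
only; α = 0: prior only; default α = 0.1, configurable).

**Rescaling.** Raw β span hundreds of orders of magnitude. Before the
determinant, log-weights are affinely mapped so β spans
`[lambda_min, 1]` (`lambda_min` default 1e−12, near machine precision).
The map is strictly order-preserving but is an *approximation*: posteriors
from rescaled weights are not identical to those of the raw weights. It is
applied after prior blending, to the final β.

**Posteriors.** The probability that edge (i, j) belongs to the tree is the
weighted fraction of spanning trees containing it. Two routes are
implemented and cross-checked against exhaustive Prüfer enumeration:

* *effective resistance* (default): in a random spanning tree drawn
  proportionally to its weight product, `P(ij) = β_ij · R_eff(i, j)`; one
  inverse of the reduced Laplacian gives all pairs in O(L³) total;
* *contraction*: merge i and j (weights to any other node l become
  `β_il + β_jl`), take the contracted graph's tree-sum determinant, multiply
  by `β_ij`, divide by the full tree sum — one determinant per pair, fully
  in the log domain; slower, but independent of the matrix inverse and kept
  as an internal cross-check.

Because every tree has exactly L−1 edges, all posteriors are exactly
invariant under global rescaling of β; the implementation always factors
out the maximal log-weight before exponentiating. Invariants:
`Σ_{i<j} P(ij|D) = L−1` (equal-weight case: every posterior is 2/L), and
the determinant is independent of which Laplacian row/column is deleted
(index 0 is used; a test covers the independence). Determinants use
`slogdet`; a non-positive sign signals an effectively disconnected graph
and yields −∞ with a warning. The maximum-likelihood (Chow–Liu) tree is
computed by Kruskal on log β with deterministic tie-breaking (descending
weight, then lexicographic edge index).

## Contact maps

Residue positions are represented by the Cβ atom, or Cα for glycine; a
missing Cβ in a non-glycine residue falls back to Cα (logged) rather than
dropping the residue. Within a multi-model NMR entry the per-pair distance
is the minimum over models; across chains and structures the final distance
is the median (even count: mean of the two central values). Contact means
distance *strictly below* the threshold (default 8 Å, the CASP convention).
Primary-sequence separation is measured in match-state units via the
alignment column origins. Pairs never covered by a structure have
*undefined* contact status and are excluded from every tally, numerator and
denominator alike; `coverage_fraction` lets callers discard domains with
poor structural coverage. Residue-to-column mappings are supplied as
explicit two-column tables — the package does not re-derive alignment↔PDB
mappings.

## Chains of co-evolving contacts

For a distal pair (a, b) with standardised dependency `Z_ab`, a chain of
contacts is scored by the total shortfall `S = Σ_e max(0, Z_ab − Z_e)`
(contacts stronger than the pair contribute nothing), and the pair's final
score is `s = S/n_steps`. `s = 0` means a chain of contacts exists that all
co-evolve at least as strongly as the pair — the indirect dependency is
fully explained. The minimal-S chain is found by Dijkstra with the
non-negative costs `max(0, Z_ab − Z_e)`; the direct edge (a, b) is
excluded; ties break first on fewest contacts, then on the
lexicographically smallest node sequence (the choice is arbitrary but
deterministic, and only affects reporting, not S). Only contact edges on
the path are scored; the pair itself contributes only `Z_ab`.

Significance: the Z-values of all contacts in the domain are randomly
permuted (multiset preserved, pair Z_ab values fixed) and best chains are
recomputed; the pooled null s-distribution and the real/null enrichment
curve are reported in full rather than at fixed percentile cut-offs. The
default of 100 permutations and the Z > 4 selection threshold are
configurable, and the RNG seed is a required input.

Chain statistics report the reverse-cumulative distribution of spatial
distances with an exponential scale estimated as the mean excess over the
contact threshold (distal pairs are at least a threshold apart by
definition), and mean ± SD chain length binned by distance. The
"Å per step" figure is the inverse slope of the least-squares fit of chain
length on distance; the fitting convention is a package choice.

## Informative prior

The probability that a pair is in contact factorises as `f(d, h) = F(d)`
for separations `d ≤ d_switch` (short range, entropy-independent) and
`g(h)·F(d)` beyond, where h is the pair's column-entropy sum. `F` is the
empirical contact fraction per separation up to a cutoff `D` (default 14),
extended by a power-law tail `c·d^(−γ)` (γ default 1, matching the observed
≈ 1/d decay) with c fixed by continuity at D. `g` is fitted per entropy bin
(width 0.25 nat by default) by maximising the Bernoulli likelihood
`Π g·F(d_e) · Π (1 − g·F(d_e))` with bounded scalar search; an empty
interior bin is interpolated from its neighbours. The factorisation is
identifiable only up to a constant — F is estimated first from the
observed fractions, so g absorbs the mean contact enrichment of its bins;
the recovery tests plant a g with unit mean to pin the scale.

Edge prior probabilities are `p_ij ∝ f(d_ij, h_i + h_j)` normalised so that
`Σ_{i<j} p_ij = L − 1`, the expected edge count of a spanning tree in the
random-graph prior; any p reaching 1 is capped at 1 − 1e−9 with the mass
re-normalised over the free pairs. The tree-prior weight of an edge is the
odds `w = p/(1−p)` (the empty-graph probability cancels as a constant).
Known limitation: a separation/entropy prior slightly penalises genuinely
co-evolving *very distal* pairs; no correction is attempted.

## Synthetic data

The generator samples alignments i.i.d. from a planted dependence tree (or
forest): a root distribution per component (symmetric Dirichlet(1) draw)
and per-edge 20×20 conditionals `coupling·onehot(perm) + (1−coupling)·base`
with a per-edge random alphabet permutation, so strongly coupled columns
co-vary instead of being trivially conserved. Gaps are not simulated by
default (gap handling is tested on hand-built fixtures); no phylogenetic
correlation between sequences is simulated — the APC is exercised on matrix
fixtures, not on simulated phylogenies. A green tree-recovery test
therefore establishes correctness of the inference machinery on
tree-factorising i.i.d. data, not robustness to real phylogenetic
structure, alignment errors, or non-tree epistasis.

Scenario generation plants a toy contact graph with per-edge couplings and
coordinates; data are generated along a spanning forest of it (edges taken
in listed order, cycle-closers skipped), and ground truth labels direct
edges and indirect pairs. The stated five-residue scenario uses couplings
0.9 (A–B, B–C) and 0.5 (D–E) with A–C at 12 Å — strong chain, weaker
direct pair — fixed once as the package's standard world for the
disentangling demonstration.

## Numerical conventions

* Percentiles use linear interpolation; rankings are stable sorts with
  pair-index tie-breaks, so all curves are bit-for-bit reproducible.
* Z uses the population (not sample) standard deviation.
* Preprocessing iterates the column and sequence gap filters to a fixed
  point, making it idempotent; duplicates keep their first occurrence.
* All randomness flows through `numpy.random.default_rng` seeds; every CLI
  entry point that samples takes an explicit `--seed`.
* Plotting is deliberately omitted; all curve outputs are TSV.
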