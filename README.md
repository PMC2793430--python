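# coevotree

Disentangling **direct** from **indirect** residue co-evolution in protein
multiple sequence alignments, with a spanning-tree Bayesian network.

## The problem

Columns of a protein-domain alignment that co-evolve tend to be close in the
three-dimensional structure, which makes covariation statistics a route to
contact prediction. The catch is that strong statistical dependencies are
also observed between residues that are far apart in the structure: contacts
that co-evolve form *chains* that percolate through the structure, and a
chain A–B–C with two strongly coupled contacts induces a strong — but
indirect — dependency between the distal pair (A, C). Any contact predictor
built on raw pair statistics inherits these spurious signals.

`coevotree` provides both sides of this analysis:

* **chain analysis** — given Z-scored pair dependencies and a contact map,
  find for every distal co-evolving pair the chain of contacts that best
  explains it (minimal total score
  `S = Σ_e (Z_ab − Z_e)·Θ(Z_ab − Z_e)`, Dijkstra search), with a
  permutation null and summary statistics;
* **model-based disentangling** — a Bayesian network in which the columns
  are coupled along an unknown dependence tree. Pair dependencies are
  measured by `log R_ij`, the log-ratio of the Dirichlet-multinomial
  marginal likelihood of the joint column counts to the product of the
  single-column marginals (a finite-size–corrected mutual information:
  `log R ≈ N·MI` for large N). Summing over all `L^(L−2)` spanning trees via
  the weighted matrix-tree theorem (a single Laplacian cofactor
  determinant) yields for every pair the posterior probability
  `P(ij | D) = Σ_{T∋ij} P(T, D) / Σ_T P(T, D)` that the pair is *directly*
  coupled. Indirectly induced dependencies are absorbed by the chains that
  cause them and receive low posteriors.

Supporting machinery: alignment preprocessing (Stockholm match states,
gap/duplicate filters), Cβ/Cα contact maps from PDB structures, the
average-product correction (APC) adapted to `log R` via a min-shift, an
informative edge prior `f(d, h) = g(h)·F(d)` built from primary-sequence
separation and column-entropy sums with an `α`-blending of data and prior,
sensitivity/rank-based PPV evaluation, and a planted-tree synthetic-data
generator that makes every claim testable without downloads.

## Worked example

```python
import numpy as np
from coevotree import (score_matrix, build_beta, rescale_beta, edge_posteriors)
from coevotree.synthetic_data import fig_scenario, generate_contact_scenario

# five residues: contacts A-B, B-C strongly coupled (0.9), D-E weaker (0.5);
# (A, C) is distal -- its dependency is induced by the A-B-C chain
aln, contacts, truth = generate_contact_scenario(fig_scenario(), N=2000, seed=1)

mi = score_matrix(aln, kind="mi").values
lr = score_matrix(aln, kind="logR")
post = edge_posteriors(rescale_beta(build_beta(lr))).post

print(f"MI(A,C)={mi[0,2]:.3f}  MI(D,E)={mi[3,4]:.3f}")
print(f"posterior(A,C)={post[0,2]:.3f}  posterior(A,B)={post[0,1]:.3f}  "
      f"posterior(D,E)={post[3,4]:.3f}")
```

prints

```
MI(A,C)=1.698  MI(D,E)=0.898
posterior(A,C)=0.012  posterior(A,B)=0.990  posterior(D,E)=1.000
```

Raw mutual information ranks the indirect pair (A, C) *above* the genuine
contact (D, E); the spanning-tree posterior reverses this — the direct
contacts get posterior ≈ 1 while the induced dependency collapses to ≈ 0.01,
because every high-probability tree explains (A, C) through B.

Posterior matrices always satisfy `Σ_{i<j} P(ij|D) = L − 1` (a tree has
exactly L−1 edges), a useful integrity check on any run.

## Command line

```bash
coevotree prep      --in aln.sto --out aln.clean.fa
coevotree scores    --aln aln.clean.fa --stat z --out z.tsv
coevotree contacts  --pdb x.pdb --map map.tsv --chain A --length 120 --out cm.tsv
coevotree posterior --aln aln.clean.fa --apc --out post.tsv
coevotree chains    --z z.tsv --contacts cm.tsv --zmin 4 --nperm 100 --seed 7 --out chains.tsv
coevotree eval      --pred post.tsv --contacts cm.tsv --minsep 12 --out ppv.tsv
coevotree simulate  --length 30 --n 500 --seed 42 --out sim.fa
coevotree run       --aln aln.sto --out results/   # full pipeline + manifest
```

All tabular outputs are TSV with header comments naming units and
conventions; `run` writes a manifest (config hash, seed, stage timings) that
suffices to reproduce every output.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's headline behaviours from scratch on synthetic
data: planted-tree edge recovery from the posterior (L=30, N=500), the
five-residue indirect-dependency scenario, a percolating co-evolving chain
whose distal pairs are explained by the chain analysis, and an end-to-end
pipeline run with the posterior-sum invariant checked. Progress is reported
on stderr and the results JSON is written to `--out`.
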