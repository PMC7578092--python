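# navrin

Structure-based classification of ion-channel point variants through
residue interaction networks (RINs), graph kernels and machine learning,
with sequence-side support from alignment entropy and direct coupling
analysis.

## The problem

Gain-of-function point mutations in the voltage-gated sodium channel
NaV1.7 (*SCN9A*) cause chronic painful syndromes — inherited
erythromelalgia (IEM), paroxysmal extreme pain disorder (PEPD), small
fiber neuropathy (SFN) and painful diabetic neuropathy (PDN) — while many
other substitutions are functionally neutral. Electrophysiology assays
that settle pathogenicity are expensive, so a computational triage that
separates pathogenic (PAT) from neutral (NEUTRAL) candidates from
structure alone is valuable.

The approach implemented here compares variant structures by topology
rather than by coordinates:

1. **RIN construction.** Each structure becomes an undirected graph whose
   nodes are residues (labelled by sequence position) and whose edges are
   typed non-covalent contacts, detected in two steps: a closest-heavy-atom
   distance prefilter, then per-type rules with strict thresholds
   (hydrogen bond 3.5 Å, van der Waals slack 0.5 Å over the radii sum,
   ionic bridge 4.0 Å, π–π stacking 6.5 Å, π-cation 5.0 Å, disulfide
   2.5 Å). Residues without any non-covalent edge are dropped, so node
   presence itself carries signal.
2. **Graph kernels.** Ensembles of RINs are compared pairwise with the
   Vertex Histogram kernel, k(G₁,G₂) = Σ_l n₁(l)·n₂(l) over node labels l,
   and the Weisfeiler–Lehman subtree kernel, which sums histogram dot
   products over h = 5 rounds of neighbourhood relabelling (WL at h = 0
   reduces to VH).
3. **Learning.** Unsupervised: Dominant Set clustering — clusters are local
   maximizers of xᜠAx on the simplex found by replicator dynamics
   x_i ← x_i(Ax)_i/(xᵀAx), peeled off in sequence — and average-linkage
   dendrograms on the kernel-induced distance
   d_ij = √(k_ii + k_jj − 2 k_ij). Supervised: a precomputed-kernel SVM
   under stratified 10-fold cross-validation.
4. **Sequence side.** Per-column Shannon entropy S_i = −Σ_a f_i(a) ln f_i(a)
   over gap-filtered alignments, and pseudolikelihood direct coupling
   analysis (Potts model fields/couplings, Frobenius scores with average
   product correction) compared against structure contact maps.

Because homology models of the full channel are not reproducible at desk
scale, the package ships seeded synthetic generators that emulate the
study conditions: an 85-variant ensemble (31 PAT / 54 NEUTRAL) with a
planted contact-rewiring signature, and Gibbs-sampled Potts alignments
with known interaction edges.

## Worked example

```python
import numpy as np
from navrin.synthetic_fixtures import FixtureSpec, make_variant_ensemble
from navrin.rin import build_rin
from navrin.graph_kernels import similarity_matrix
from navrin.classification import LabeledEnsemble, cross_validate

structures, catalogue = make_variant_ensemble(FixtureSpec(seed=1))
rins = {vid: build_rin(s) for vid, s in structures.items()}
ids = sorted(rins)
K = similarity_matrix([rins[i].as_labeled_graph() for i in ids],
                      kernel="wl", h=5, ids=ids)
labels = np.array([1 if r.cls == "PAT" else 0 for r in catalogue])
report = cross_validate(LabeledEnsemble(kernel=K, labels=labels),
                        k=10, C=1.0, seed=1)
print(f"10-fold CV accuracy: {report.mean_accuracy:.2f}%")
```

prints

```
10-fold CV accuracy: 98.89%
```

meaning the WL-kernel SVM recovers the planted pathogenic/neutral split
almost perfectly. Rebuilding the ensemble with `rewiring_rate=0.0` (no
planted signal) drops the same readout to 63.47%, the majority-class
baseline 54/85 — the behaviour expected of a kernel with no discriminative
structure.

A command-line interface wraps the same steps:

```sh
navrin run --seed 1 --out-dir runs/demo   # full pipeline + manifest
navrin catalogue                          # packaged variant counts
navrin rin structure.pdb --out rin.tsv
```

## Layout

- `src/navrin/structure_io.py` — PDB reading, mutation strings, φ/ψ
  dihedrals, Ramachandran classes
- `src/navrin/rin.py` — typed contact detection and RIN graphs
- `src/navrin/graph_kernels.py` — VH and WL subtree kernels, kernel →
  distance conversion
- `src/navrin/clustering.py` — Dominant Set peeling, average linkage,
  Newick export
- `src/navrin/classification.py` — precomputed-kernel SVM cross-validation
- `src/navrin/variant_analysis.py` — variant catalogue, node-frequency
  contrast, channel domain map
- `src/navrin/msa_stats.py` — alignment I/O, gap-filter cascade, entropy
- `src/navrin/dca.py` — pseudolikelihood Potts fit, APC scores, contact maps
- `src/navrin/synthetic_fixtures.py` — seeded structure/alignment generators
- `src/navrin/cli_pipeline.py` — YAML-configured end-to-end runs

See `docs/methods.md` for the modelling choices and their rationale.
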