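# Methods

This note documents the models and procedures implemented in `navrin`, the
parameters that matter, the design decisions taken where the method left
room, and what the synthetic fixtures do and do not establish.

## Residue interaction networks

A structure is mapped to a graph in two steps. First, a distance prefilter
proposes residue pairs whose closest heavy atoms lie within 7.0 Å (7.5 Å
when both residues carry an aromatic ring, so that ring-centroid geometry
up to the 6.5 Å stacking threshold is not cut off by the atom-level
screen). Pairs closer than two positions along a chain are excluded:
covalent neighbours are not non-covalent contacts. Second, each candidate
pair is tested against per-type rules, emitting at most one edge per
interaction type per pair (the closest qualifying atom pair):

| type | rule | threshold (Å) |
|---|---|---|
| hydrogen bond | closest N/O⋯N/O heavy-atom pair | 3.5 |
| van der Waals | closest heavy-atom pair vs radii sum | sum + 0.5 |
| ionic bridge | Arg NH1/NH2/NE, Lys NZ, His ND1/NE2 vs Asp OD1/OD2, Glu OE1/OE2 | 4.0 |
| π–π stacking | aromatic ring centroid pair (Phe/Tyr/Trp/His) | 6.5 |
| π-cation | ring centroid vs cationic atom | 5.0 |
| disulfide | Cys SG pair | 2.5 |

The hydrogen-bond, van der Waals, ionic, stacking and cation thresholds
are the strict per-type values the pipeline is built around; the disulfide
threshold and the atom-group definitions are this package's documented
choices (the vdW radii table is C 1.70, N 1.55, O 1.52, S 1.80, P 1.80 Å).
The hydrogen-bond rule is geometric only — no donor/acceptor chemistry or
angle term — which over-calls H-bonds slightly relative to energy-based
detectors; for topology comparison this is acceptable and deterministic.

Residues left with no edge are dropped from the graph. This makes node
presence informative: the node-frequency analysis counts, per position,
the fraction of a variant group's networks in which that residue has at
least one non-covalent contact.

## Graph kernels

Node labels are residue sequence positions; edge types are ignored by the
kernels (typed analysis is done by filtering networks upstream). The
Vertex Histogram kernel is the dot product of label count vectors. The
Weisfeiler–Lehman subtree kernel performs h rounds of relabelling — each
node's new label is the pair (old label, sorted multiset of neighbour
labels) — and sums histogram dot products over rounds 0..h. Defaults:
h = 5, no normalization (cosine normalization is available as a flag).
Label compression uses one dictionary shared across the whole ensemble,
assigned in sorted multiset order, so histograms are identical across
runs and node orderings. Kernel matrices are checked symmetric and
positive semidefinite (minimum eigenvalue ≥ −1e−8 × trace); distances are
the feature-space Euclidean form d_ij = √(k_ii + k_jj − 2k_ij).

## Dominant Set clustering

Clusters are extracted from a non-negative symmetric similarity matrix
(diagonal zeroed) as local maximizers of xᵀAx on the simplex, found by
replicator dynamics from the barycenter, then peeled off and the process
repeated until fewer than two elements remain. Numerical choices:
convergence tolerance 1e−8 on the L1 step change, at most 10 000
iterations, support threshold 1e−4 on the converged weights. The start
point adds a deterministic index-graded perturbation of relative size
1e−3 to the barycenter: on matrices with an exact block symmetry the
barycenter is a saddle the dynamics would never leave; on matrices with
real structure the perturbation is negligible. Peeling is order-dependent;
the binary readout used for classification comparisons is "first
extracted set vs everything else", with the unassigned remainder pooled
into the second group by default (a flag keeps it separate).

## Average linkage

Implemented in-package so that ties on the minimum inter-cluster distance
are broken deterministically (lexicographically smallest member ids)
rather than by container order. Cluster–cluster distance is the mean over
cross pairs; merge heights are verified against scipy's implementation on
random (tie-free) matrices in the test suite. Dendrograms export to
Newick with branch lengths equal to merge-height differences.

## Kernel SVM cross-validation

Classification uses a maximum-margin SVM on the precomputed Gram matrix
(C = 1 by default) under stratified k-fold cross-validation (k = 10) with
a mandatory seed; accuracy is the unweighted mean of per-fold accuracies,
in percent. Stratification is used because at n = 85 unstratified folds
can lose a class entirely. A single-class training fold predicts that
class. On a kernel with no discriminative structure the expected accuracy
is the majority-class fraction, 54/85 ≈ 63.5% for the 31/54 catalogue
split — this degenerate baseline is reproduced exactly by running the CV
machinery on 85 identical graphs.

## Variant catalogue and node-frequency contrast

The packaged catalogue (`data/variant_catalogue_synthetic.tsv`) carries 85
variants in the study layout: ids 0–30 pathogenic (18 IEM, 6 SFN, 6 PEPD,
1 PDN), ids 31–84 neutral (4 nABN, 17 dbSNP, 33 inter-species pseudo
mutations; the 21 human neutral variants are flagged). Anchor entries
named in the study text (I136V; A863P at id 11; T1596I at id 30; M1532I
pathogenic vs M1532V neutral) are placed as published; the remaining
entries are synthetic placeholder substitutions, since the full published
list exists only as a figure. All count-level statistics are faithful.

Channel domain coordinates (wild-type numbering, 1-based inclusive):
DI 112–410, DII 715–978, DIII 1169–1477, DIV 1488–1784; anything else is
a linker. The frequency-contrast routine reports maximal runs of
consecutive positions where the PAT/NEUTRAL frequency difference meets a
threshold (default 0.2 — the published analysis identified bands
visually, so the threshold is exposed).

## Alignment statistics

The gap-filter cascade mirrors the preprocessing used before coupling
analysis: drop sequences with more than 50% gaps, keep columns with less
than 30% gaps, then drop sequences with more than 70% gaps over the
retained columns. Column indices are carried through, so downstream
entropy sites are addressed in original (wild-type) numbering; the
low-gap region is always computed from the data, never hard-coded.
Entropy is Shannon's formula in nats with frequencies normalized over the
non-gap symbols of each column; all-gap columns are flagged undefined.
Mutated sites are labelled low/high against the mean entropy over the
mutated sites themselves; a tie at the mean counts as low.

## Direct coupling analysis

The Potts model (fields h_i(a), couplings J_ij(a,b)) is fit by minimizing
the weighted negative log-pseudolikelihood — the sum over sites of the
conditional log-likelihood of each column given the rest — with L2
penalties, by L-BFGS from zero initialization (deterministic). The fit is
symmetric: one coupling matrix per unordered pair enters both sites'
conditionals. Defaults: q = 21 states (20 amino acids + gap) for letter
alignments, λ_h = 0.01, λ_J = 0.01·(q−1), sequence reweighting at 80%
identity. Pair scores are Frobenius norms of J_ij in the zero-sum gauge,
excluding the gap state by default (gaps are alignment artifacts), with
the average product correction F_ij − F_i F_j / F̄ applied. Contact maps
use closest-heavy-atom distance (default cutoff 8 Å, minimum separation
5); the headline readout is the positive predictive value of the top-n
APC-ranked pairs. The analytic gradient is verified against finite
differences in the tests.

## Synthetic fixtures

`make_helix_pdb` builds poly-alanine backbones from ideal internal
coordinates (NeRF chain extension) at constant φ/ψ, with carbonyl O and a
single side-chain proxy atom (CB) per residue; recomputed torsions match
the inputs within 2°, which is the self-consistency check used in tests.

`make_variant_ensemble` emulates the 85-variant study: every structure
shares a 40-residue helical core, and a trailing 8-residue sensor segment
is either compacted into mutual side-chain contact (pathogenic variants,
with probability `rewiring_rate`, default 1) or dispersed beyond contact
range. All structures receive 0.05 Å Gaussian coordinate jitter. The
planted signal therefore changes which residues appear as network nodes —
exactly the quantity the Vertex Histogram kernel and the node-frequency
analysis measure. At rewiring rate 0 the groups are indistinguishable and
classification falls to the majority baseline. What passing tests show:
the pipeline recovers planted topological group structure at realistic
ensemble size. What they do not show: performance on homology models of
real channel variants, where signal arises from modelling physics rather
than geometric planting.

`sample_potts_msa` Gibbs-samples independent chains (default 300 full
sweeps of burn-in per chain) from a planted Potts model — default L = 12,
q = 4, 8 edges with permuted ferromagnetic-style couplings of strength
1.2 — and returns the true edges for recovery scoring. Problem sizes
throughout (85 structures of ~48 residues, 2000 sequences of length 12)
were chosen as the smallest at which the statistical behaviour of
interest is stable and cleanly measurable.

## Known limitations

- The hydrogen-bond and van der Waals rules are geometric approximations;
  atom-group definitions and the radii table are documented choices, not
  a reimplementation of any specific contact-detection server.
- Ramachandran regions are coarse rectangles (right-handed α, β,
  left-handed α basins) sufficient for mechanism tests; a user-supplied
  region table is accepted for anything quantitative.
- The packaged variant catalogue is count-faithful but entry-synthetic
  outside the anchored variants.
- Dominant-set peeling is greedy and order-dependent; only the documented
  binary readout is used for comparisons.
- The pseudolikelihood fit is dense in L² q² parameters and intended for
  desk-scale alignments (L ≤ ~50), not full-length channels.
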