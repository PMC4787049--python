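# Methods

This note documents the models, numerical choices and limitations behind
each stage of gemprokit, and what the synthetic fixtures do and do not
emulate.

## GPR rules and enzyme complexes

A gene-protein-reaction (GPR) rule is a boolean expression over gene locus
ids: AND joins subunits that must co-occur in one enzyme complex, OR joins
isozymes. The grammar accepts case-insensitive `and`/`or`, parentheses and
gene ids matching `[A-Za-z0-9_.-]+`; negation never occurs in curated GEMs
and is not supported. Expansion to disjunctive normal form yields the
candidate complexes of a reaction; a gene's multiplicity within a
conjunction becomes its subunit copy number (so `g and g` encodes a
homodimer), and curated stoichiometry tables can override copy numbers by
matching on the subunit gene set. Complex identity for global censuses is
the multiset of (gene, copies): a gene is "multi-complex" when it appears in
two or more distinct complexes across the whole model, with complexes
deduplicated by that key. Gene fractions are taken over all model genes;
isozyme-reaction fractions over reactions with a non-empty GPR.

## Structure QC

Alignment of the structure-observed sequence to the wild type uses global
dynamic programming (Biopython PairwiseAligner) with match +1, mismatch 0,
gap open −2, gap extend −0.5, and free terminal gaps. The terminal-gap
choice reflects what the metrics mean: an unresolved tail is not an
alignment error, it only reduces completeness. Identity counts exact
matches over wild-type length; completeness counts resolved (aligned)
wild-type positions regardless of match, so identity ≤ completeness always.

The resolution score is `max(0, 1 − (resolution − 1 Å)/4 Å)` — 1.0 at 1 Å,
0 from 5 Å up — and a fixed 0.7 for NMR ensembles, which report no
resolution. The combined score weights (0.5 identity / 0.3 completeness /
0.2 resolution) are a package choice exposed in `QcConfig`; so are the
group-II bounds: mutation runs of at most 2 consecutive positions, ≤ 5
mutated positions total, interior gaps of ≤ 3 residues each and ≤ 5 total,
resolution ≤ 3 Å. Terminal gaps never affect the group (the classes are
about the protein interior) but do lower completeness. For homology models
the score is the mean of the model's TM-score and a secondary-structure
composition agreement term `s_comp = 1 − ½ Σ_c |f_model(c) − f_ref(c)|`
over the 8 classes; when no reference composition is supplied, s_comp
defaults to 1 (no penalty). For multi-chain entries, the chain with the
highest identity to the gene's sequence represents the gene.

Ranking is a strict total order — combined score, experimental before
model, identity, resolution, id — so results are permutation-invariant.

## Sequence refinement

Mutated residues of group-II structures are rebuilt in three stages.
Stripping retains exactly {N, CA, C, O}. Grafting places CB at 1.52 Å from
CA with an exact 110.5° N-CA-CB angle (in-plane bisector construction with
an out-of-plane tilt chosen for L-chirality), then builds the remaining
heavy atoms by NeRF internal-coordinate placement from an idealized
template table; chi angles start extended (180°, branches at −60°), which
is deterministic and leaves any strain to the minimizer. Ring geometries
are idealized and approximately planar — adequate for clash relief, not for
crystallographic refinement.

The minimizer is deliberately not a molecular-mechanics force field: its
single term is a repulsive harmonic clash potential `E = Σ k (r₀ − r)²`
over heavy-atom pairs with `r < r₀ = 0.8 (r_i + r_j)` (vdW radii C 1.70,
N 1.55, O 1.52, S 1.80, default 1.70 Å), excluding intra-residue pairs and
backbone 1-2/1-3 pairs across the peptide bond. Steepest descent with a
backtracking line search moves only the grafted atoms, so the energy is
non-increasing by construction and the backbone RMSD before/after is
exactly zero. Defaults: k = 1, initial step 0.01 Å, gradient tolerance
1e-4, 5000 iterations. Neighboring side chains are held fixed; a graft the
minimizer cannot fully relax is reported honestly in the clash count.

## Structural properties

SASA uses the probe-sphere definition (probe 1.4 Å) with a deterministic
golden-spiral lattice of 960 points per atom sphere — a seed-free numerical
stand-in for the classic slice-based algorithm. A lattice point is exposed
iff outside every neighbor's expanded sphere. Isolated-atom areas are exact
to well below 1%; 960 vs 3840 points agree within 1% on peptides. Points
below 60 are refused as too coarse. Exposed lattice points double as the
surface sample for residue depth: the mean over a residue's heavy atoms of
the distance to the nearest exposed point. This accessible-surface depth is
systematically ~(r_vdw + probe) larger than a molecular-surface depth;
monotone comparisons, not absolute values, are the supported use.

Secondary structure follows Kabsch–Sander: amide H reconstructed 1 Å from N
along the preceding C=O direction; hydrogen bond iff
`E = 27.888 (1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) < −0.5 kcal/mol`. Helix
classes (G/H/I for n = 3/4/5) require two consecutive n-turns and label the
residues interior to both — for an ideal 12-residue α-helix that is
residues 3–10, a deliberately conservative core assignment (full DSSP
implementations extend helices one residue further at each end). Bridges
use the parallel/antiparallel hydrogen-bond patterns; ladders of adjacent
bridges are E, isolated bridges B; hydrogen-bonded turns mark interior
residues T; a CA-trace kink above 70° marks a bend S. Priority
H > E > B > G > I > T > S.

Other definitions: disulfide = SG–SG pairs ≤ 5 Å, greedily paired nearest
first so each sulfur bonds once; contacts = heavy-atom pairs ≤ 4.5 Å
between residues ≥ 3 apart in sequence (both cutoffs config-overridable);
surface residue iff SASA strictly > 3 Å². Residue classes: nonpolar
{A,V,L,I,M,F,W,P,G}, polar {S,T,N,Q,Y,C}, positive {K,R,H}, negative {D,E}.
The 29-feature vector fixes a canonical column order; it includes the raw
residue count and the mean per-residue SASA alongside the percentage
features so that totals can be reconstructed from a row.

## Comparative clustering

Columns are z-scaled (sample sd, ddof = 1); constant columns are dropped
with a warning and missing cells imputed with the column mean beforehand.
PCA runs on the same scaled matrix (equivalently, correlation PCA), with
each component's sign fixed so its largest-magnitude loading is positive.
K-means uses k-means++ with 50 restarts and up to 300 Lloyd iterations; the
best-inertia restart wins. The elbow rule is explicit: with
`explained(k) = 1 − WCSS(k)/WCSS(1)`, choose the smallest k with
explained ≥ 0.75 whose next step gains < 0.05; if no k qualifies the data
is treated as unstructured (k = 1). Both thresholds are parameters.

## Complex stoichiometry LP

With P the proteins × enzymes copy-number matrix and p measured peptide
abundances, the fit minimizes total free peptide subject to
`P e + f = p, e ≥ 0, f ≥ 0` (HiGHS). Equality, not inequality: measured
abundance is fully partitioned into complexed plus free. The objective is
unweighted; molecular-weight weighting would be a one-line change but no
weighting scheme is canonical. The problem is always feasible (e = 0,
f = p) and the optimal Σf is unique even when e is degenerate; degenerate
alternatives are reported through FVA ranges — per-enzyme min/max with Σf
held at its optimum up to a relative 1e-6 plus absolute 1e-9 slack, since
exact equality on an LP optimum is numerically brittle.

## Ligand classification

Ligand graphs carry element, formal charge and a chirality flag per atom
and an order class per bond (1/2/3/aromatic). The canonical key is
Weisfeiler–Lehman-style refinement from (element, charge, degree, valence,
chirality) invariants; it is a fast heuristic, not an isomorphism
certificate — isomorphic graphs always collide, and rare highly symmetric
non-isomorphic pairs may too (none occur in the shipped library, verified
against a brute-force permutation oracle). The fingerprint hashes every
simple path of 0–7 bonds (1024 bits, blake2b); paths are canonicalized by
direction so the bitset is atom-order invariant. Tanimoto is |A∩B|/|A∪B|
with two empty sets defined as identical. The exclusion list (water,
glycerol, cryoprotectants, detergents, buffers, halide/alkali ions) is a
versioned reconstruction of common crystallization additives; metal
cofactors are retained by default (`keep_metals=False` drops them).
Superclass taxonomies (lipids, sugars, ...) are accepted as a user-supplied
code→class table rather than guessed.

## Temperature-constrained growth

Protein stability is modeled as a binary step: a gene is functional iff
T ≤ T_M, boundary inclusive. Genes without T_M data default to functional —
melting data covers a small minority of genes in real reconstructions, and
disabling unknowns would zero every prediction; `strict=True` flips the
default. A reaction is disabled (both bounds zero) when its GPR evaluates
false over the functional genes, so isozymes rescue reactions; GPR-less
reactions (exchanges, biomass) never disable. Since the disabled set grows
with T, constraint sets are nested and the growth curve is monotone
non-increasing; the implementation asserts this. A continuous
capacity-scaling hook (fraction-folded × bound) would slot into
`apply_tm_constraints`, but the step model is the documented default. FBA
is a plain LP (maximize objective flux under S v = 0 and bounds, HiGHS)
with infeasibility and unboundedness distinguished.

## Synthetic fixtures

The generators produce every input the pipeline needs, deterministically
(same parameters + seed → identical bytes) and with planted truth records
computed independently of the code paths they test:

* **Peptide builders** place ideal backbones (N-CA 1.458, CA-C 1.525,
  C-N 1.329 Å, standard angles, trans omega) by NeRF from uniform (φ, ψ).
  The α-helix fixture uses (−57°, −47°); the hairpin pairs a (−135°, 135°)
  strand with its 180°-flipped copy, register found by a deterministic
  local grid search maximizing reciprocal inter-strand hydrogen bonds.
  Mutant/gap fixtures use an open conformation (−170°, 70°) in which the
  idealized extended rotamers are mutually clash-free (found by dihedral
  scan), so refinement outcomes are attributable to the grafts; the random
  sequence generator additionally avoids the one bigram (CD1-bearing before
  CG2-bearing residue) whose ideal rotamers collide even there.
* **Toy metabolic models** are viable linear pathways (uptake bound 10 sets
  the growth optimum) whose conversion reactions draw GPR patterns with
  analytically known complex lists; truth statistics are counted from the
  pattern definitions, never by parsing.
* **Abundance sets** are p = P·e_true + |ε|, ε ~ N(0, sd), seeded; melting
  temperatures are uniform on [40, 70] °C, the range where such toy
  pathways lose reactions gradually.
* **Cluster blobs** are unit-variance Gaussians whose centers sit at the
  requested separation along random directions, spreading signal over all
  29 feature dimensions.

What the fixtures do **not** emulate: real side-chain rotamer diversity,
crystallographic disorder and B-factors, non-ideal backbone geometry,
realistic GPR size distributions, heavy-tailed abundance data, or
correlated property features. Passing tests therefore demonstrate
correctness of the algorithms under controlled geometry and known truth,
not benchmark accuracy on PDB-scale data; published-model statistics
(e.g. isozyme fractions of a specific organism's reconstruction) require
the corresponding published inputs, which are optional benchmark inputs,
never build requirements.

## Problem sizes

Defaults used by the test suite and the acceptance script: 12–140 residue
peptides; 8–20 reaction toy models (100 seeds where distributional claims
are made); 20 × 10 stoichiometric matrices over 50 seeds; 200 × 29 feature
matrices; 960-point SASA lattices. These sizes keep full runs in seconds
while leaving every algorithmic path exercised; all scale linearly or
quadratically if larger studies are needed.
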