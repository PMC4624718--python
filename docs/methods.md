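# Methods

## Model

The central assumption is evolutionary: the amino-acid distribution
observed at a position across *structurally similar* binding interfaces
reflects, other selection pressures being equal, the energetic preferences
of that position for binding. Using structural rather than sequence
neighbors avoids phylogenetic correlation between closely related
sequences and admits convergently evolved interfaces. The profile score
F(p,A) = Σ_a g(p,a)·M(A,a) is a log-odds-like quantity: Henikoff-weighted
observed frequencies g are smoothed through a substitution matrix M to
compensate for the finite template library (a position seen only with
leucine should still consider isoleucine plausible). The predicted ΔΔG of
a substitution is the drop in profile score F(p,WT) − F(p,Mut), summed
over sites for multi-site mutations. This additivity is an explicit
modeling assumption; it holds for one-sided mutations (the regime this
package supports — every record's substitutions must lie on one chain) but
is known to break when both sides of an interface are mutated
simultaneously.

Interface similarity is measured with three nested metrics. All share the
TM-score kernel 1/(1+d²/d0²) over aligned Cα pairs and are normalized by
the **query** interface length L_Q, so a fragmentary template match scores
low even if the matched fragment is accurate. Normalization by the query
(not the shorter or the average interface) is a deliberate choice: the
profile serves the query, and template coverage of the query is what
matters. d0 follows the standard length-dependent form
max(0.5, 1.24·(L−15)^⅓ − 1.8); the physicochemical variant hard-codes
d0 = 4 Å and a 0.25 penalty for chemical-class mismatches, with residues
grouped into six non-overlapping classes (K,R / E,D / N,Q,S,T / F,W /
C,A,I,L,M,P,V,G / H,Y).

The contact-overlap weight of an aligned pair is f_i = (c_i/a_i + c_i/b_i)/2,
where b_i and a_i count the cross-chain contacts of the query and template
residues and c_i counts query contacts whose partner maps onto a template
contact. The common-contact ratio f_c is computed as the number of query
interface contact pairs preserved under the correspondence divided by the
total number of query interface contacts — the definition is loose in the
literature; this reading makes f_c = 1 exactly on self-comparison and is
exposed for inspection on the alignment object.

## Alignment search

The correspondence between two interfaces is found heuristically: gapless
threading seeds in both chain pairings (A↔A′/B↔B′ and A↔B′/B↔A′), then
iterated {Kabsch superposition on the current pairs → order-preserving
dynamic programming on S(i,j) = 1/(1+d_ij²/d0²) with zero gap penalty}
until the pair set repeats, at most 20 rounds. The pairing/seed whose
final alignment maximizes the requested metric wins; ties break toward
smaller RMSD. This is not a sequence-order-independent aligner and makes
no claim of reproducing any particular program's scores — only the
published score formulas, which the tests verify against independent
brute-force summation.

## Interface definition and residue classes

A residue is interfacial when any heavy atom lies within 4.0 Å of the
partner chain (heavy-atom convention). Residue–residue contacts for the
overlap terms use a slightly looser 4.5 Å among interface residues, so
that every interface residue retains at least one contact in tightly
packed interfaces; both cutoffs are module constants. SASA is
Shrake–Rupley with 960 deterministic golden-spiral points, probe 1.4 Å
and Bondi-style element radii; relative accessibility divides by
theoretical Gly-X-Gly maxima, clamping values above 1 for classification
only. Classes partition all residues deterministically (ties at 25% count
as buried): rASA > 25% and rASA_c < 25% → core; exposed in both → rim with
a cross-chain contact, surface without; rASA ≤ 25% → support with a
contact, interior without. One published phrasing of the surface class
(exposed in the complex but buried in the monomer) is impossible under
burial monotonicity and is treated as a typo; the implemented partition
keeps "exposed in both, no contact".

## Profiles and features

Henikoff position-based weights are computed over the interface columns
only (the alignment exists nowhere else); exactly redundant aligned
interface sequences are removed before weighting. The adaptive profile
takes all hits at or above the strict cutoff (Iscore 0.25 by default) plus
up to n = 80 hits down to the loose cutoff (0.19), counting n globally
rather than per position. Sites covered by no template fall back to the
raw substitution-matrix difference M(WT,WT) − M(WT,Mut) and carry
n_seq = 0 so the forest can down-weight them; the other quality features
get finite sentinels (−1 for the mean site RMSD, 0 preserved contacts,
1 bit of divergence). Jensen–Shannon divergence uses base 2 and the equal
0.5/0.5 mixture against the BLOSUM62 background frequencies; the
across-site z-score is defined as 0 when the across-site spread is zero.
For multi-site mutations the quality features average over sites, except
n_seq, which takes the minimum (the weakest site limits confidence).

## Dataset rules

Replicate measurements of one (complex, mutation set) group are merged by
a single-pass, deliberately asymmetric rule: replicates strictly above
mean + 1·population-sd are discarded, the rest averaged. With exactly two
replicates the larger one equals mean + 1·sd and is therefore never
discarded — a direct consequence of the printed rule, preserved as such.
Curation is idempotent. The 60/15/25 train/test/validation split is
seeded and deterministic.

The template library keeps dimers (higher-order assemblies are split into
all chain pairs) whose chains both contribute at least 10 interface
residues, pruning later entries that share ≥ 70% sequence identity AND a
complex TM-score ≥ 0.8 with an earlier one. The complex-vs-complex
TM-score is an approximation: chains are paired by best sequence identity,
aligned chainwise by global sequence alignment, superposed once jointly,
and scored with the TM-score formula normalized by the shorter complex.
A full multi-chain structural aligner would iterate superposition and
allow sequence-independent pairings; for redundancy screening at ≥ 70%
identity the sequence-guided approximation is adequate, because nearly
identical sequences make the sequence alignment and the structural
alignment coincide.

## Random forest

500 trees by default; variables-per-split tuned over {2, 4, 6, 8, p/3} on
a testing split (an explicit test table, or an internal 20% carve-out),
then refit on all data with the winner; all seeds recorded. Importances
are reported both as permutation increase in residual error and as
impurity-based node purity. Repeated 10-fold cross-validation (3 repeats)
reports Pearson c on pooled out-of-fold predictions per repeat, averaged
across repeats — pooling is a choice; per-fold averaging is noisier at
these sample sizes. "Standard error of prediction" is the root-mean-square
residual. Leave-one-protein-out holds out every mutant of one complex at
a time and reports per-protein RMSE, flagging proteins with more than 10
mutants, whose estimates are stable enough to read individually.

## What the synthetic generator emulates — and what it does not

Toy dimers are two facing extended chains with full backbone plus a Cβ
pseudo-atom on every residue (including glycine), posed so that facing
residue pairs sit ~3.2 Å apart and sequence neighbors fall outside the
4 Å cutoff. Chain A's Cα trace zigzags while chain B's runs straight:
congruent traces would give the dimer an artificial two-fold symmetry
under which swapped chain pairings align exactly as well as the true one
(and collinear traces make superposition degenerate), which no real
interface exhibits.

Template families are copies of a base dimer with per-residue coordinate
noise graded from 0 up to σ (default 1 Å, spanning interface similarity
from 1.0 down past the loose cutoff), a random global rigid motion, and
interface sequences redrawn from a known per-position distribution
π(p,a) ∝ exp(M(a*,a)/τ) around a per-position preferred residue
(τ = 2): positions tolerate chemically similar residues, which is the
signal an interface profile is built to capture, and log π is then an
exact affine image of the substitution-matrix row — the natural ground
truth for recovery checks. Recovery is assessed as the mean Spearman
correlation between F(p,·) and log π(p,·) over positions aligned by at
least 15 sequences: per-position rank correlations at ~45 sampled
sequences necessarily fluctuate (multinomial sampling alone leaves
ρ ≈ 0.95), and the aggregate is the meaningful recovery statistic.

Mutation tables carry a linear ground truth in the sequence features
(pharmacophore deltas and volume change), optional per-protein offsets
with an accompanying protein-level covariate, replicate groups, and
injected high outliers placed in groups of three (two concordant + one
high), because two-replicate outliers are undroppable under the curation
rule. Protein-clustered tables give the random forest a protein-identity
signal that k-fold CV can exploit and leave-one-protein-out cannot,
reproducing the direction of the cross-protein generalization gap.

None of this is a physical protein model: there are no side chains beyond
Cβ, no packing, no electrostatics, and template "evolution" is i.i.d.
sampling rather than descent. Passing tests demonstrate that the formulas,
selection rules and learning machinery behave as specified — not that the
predictor reaches any particular accuracy on real complexes, which
additionally depends on the template library's coverage and on external
potential terms this package accepts but never computes.

## Problem sizes and numerical choices

Test and acceptance runs use 50-template families on ~28-residue
interfaces, mutation tables of 400–500 rows over 10–12 complexes, and
forests of 150–300 trees — sizes chosen so the full pipeline, including
repeated cross-validation, completes in minutes on one core while leaving
all statistical conclusions stable across seeds. Kabsch superposition
warns (rather than fails) on rank-deficient coordinate sets and proceeds
with the canonical SVD solution. Score ties during template collection
break lexicographically by template id; redundancy pruning in the library
is order-dependent by design (first kept wins).

## Known limitations

- Only dimeric complexes and one-sided mutations are supported.
- The alignment is sequential (order-preserving within chains); interfaces
  similar only under residue reordering will be under-scored.
- External potentials (all-atom, docking, statistical) are accepted as
  numeric feature columns; none are computed here, so headline accuracies
  on real data from composite models are out of reach of this package
  alone.
- The complex TM-score used for library redundancy is sequence-guided and
  single-superposition; it is not a general structural aligner.
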