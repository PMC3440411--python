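# Methods

This note records the models, conventions and numerical choices behind
`rbdscope`, in the spirit of the methods documentation of packages like
statsmodels or msprime: what is computed, under which assumptions, and
which decisions were genuinely open.

## Conservation rule and consensus motifs

A column of an alignment with *n* rows (the denominator always counts all
rows) is called conserved when the fraction of rows carrying a residue
with positive BLOSUM62 score against the column's most common residue is
at least 0.85. The most common residue is taken over standard amino acids
only; ties break alphabetically, which makes the call deterministic and
order-independent. Consensus listing uses a second, inclusive threshold:
any residue carried by at least 10% of the rows is listed, ordered by
descending frequency then alphabetically.

Conventions the thresholds alone do not fix:

- **Gaps and `X` count in the denominator and never as conserved.** This
  is the conservative direction — a column heavy with gaps can only lose
  conservation, never gain it. Columns without any standard residue get no
  modal residue and are never conserved.
- **The modal residue can itself fall below the 10% listing threshold**
  (possible in very diverse columns). It is then excluded from the listed
  residues, following the literal listing rule; the tabular output flags
  this with a `modal_listed` column.
- **Floating-point threshold comparisons** use a 1e-12 absolute guard so
  that exact boundary fractions (e.g. 2/20 against 0.10) compare as
  intended.

The windowed profile is the mean of the 0/1 conserved indicator over a
five-column window assigned to the centre column. Edge windows are
truncated rather than dropped, so the profile is defined at every column;
the first and last two values average over 3–4 columns.

`consensus_agreement` measures, over the conserved columns of a motif, the
fraction at which at least *k* of a set of other aligned sequences carry a
residue scoring positive against the column's modal residue. It is the
natural way to ask how much of a consensus survives in a small, distant
outgroup; it is undefined (an error) for motifs without conserved columns.

## Redundancy reduction

Fragments are records covering less than 50% of the alignment width with
non-gap residues (inclusive boundary; configurable). Non-redundancy uses
greedy incremental clustering at 80% identity: records sorted by
descending non-gap length (ties by id) either join the first
representative at or above the threshold or become representatives. The
identity denominator is the number of mutually non-gap columns; a pair
with no such column has identity 0. Greedy clustering guarantees that
every removed record is within the threshold of its representative; it
does not guarantee that representatives are pairwise below threshold when
similarity chains run through removed members, and the tests assert
exactly the guaranteed property. Raising the threshold can only increase
the number of representatives (asserted as a property test).

## Architecture and linker statistics

Coordinates are 1-based inclusive throughout. The linker after domain *i*
spans end(*i*)+1 .. start(*i*+1)−1 and is named after the preceding domain
(L3 lies between RBD3 and RBD4), so a protein lacking a domain simply has
a longer linker named after the last domain present — no special casing.
Every segmentation satisfies, and asserts, the tiling identity
N-terminus + Σ domains + Σ linkers + C-terminus = protein length.

Medians use the lower median for even counts, keeping every reported
median an observed integer length. The length-order check is strict
(ties violate) along the canonical order L1 > L3 > L4 > L2 > L5.

One boundary choice matters for the worked example: for the human
six-domain protein, the fourth domain uses its database-annotated start
position (587), not the structure-extended start three residues earlier,
because the annotated start is what yields the published linker-3 length
of 106 residues.

## Profile search

The search layer plays the analytical role of profile HMMs at desk scale.
A PSSM column scores residue *r* as
`log2((count + pc·bg_r) / (n_c + pc)) − log2(bg_r)` with pseudocount
pc = 1.0 and uniform background 0.05 by default (a composition estimated
from input can be supplied). Columns with no standard residue are neutral
(all zeros). Scores are bits; they are **not** comparable to HMMER bit
scores, so cutoffs must always be re-calibrated, never copied from an
HMM-based analysis.

Scanning is affine-gap local dynamic programming (Gotoh) of the profile
against an ungapped sequence, with gap open 11 and extend 1 in score
units. Ties between equally scoring local alignments resolve to the
smallest start, then smallest end — determinism over elegance. Residue
`X` scores 0 at every column.

Cutoff calibration evaluates the descending grid 90, 85, …, 0 and returns
the lowest grid value admitting zero decoys; because admission is monotone
in the cutoff, that value maximises admitted positives subject to zero
false hits. If every grid value admits a decoy the calibration fails
loudly, carrying the per-grid report. Decoys are a required input; the
generator provides i.i.d. background-composition decoys for synthetic
studies.

Jack-knife stability rebuilds the profile without each member in turn and
requires the left-out member to *strictly* outscore every decoy; a decoy
identical to a member therefore marks it unstable. Iterative search
accepts database sequences at or above the cutoff, appends them to the
alignment via their best local alignment path (profile columns deleted in
the path become gaps; inserted sequence residues are dropped — the seed
alignment is never re-expanded), rebuilds and repeats to convergence or a
round limit, with a warning on non-convergence. A cutoff calibrated on
the seed profile with a thin margin over the decoy score range can admit
borderline sequences after the profile has grown; choosing a calibration
grid floor that keeps the cutoff clear of the decoy range avoids this.

## Domain clustering

Distances between aligned domains are p-distances, 1 − identity over
mutually non-gap columns; a pair with no overlap gets distance 1.0 with a
warning. The tree is textbook Saitou–Nei neighbor joining with a
deterministic tie-break (lexicographically smallest label pair) and
negative branch-length estimates clamped to zero (logged); additive
matrices are reproduced exactly, which the tests assert on random additive
matrices and cross-check against an independent implementation. The
position-specificity of the clustering is quantified as nearest-neighbour
purity: the fraction of leaves whose closest leaf by matrix distance
shares their domain-position class (singleton classes are excluded with a
warning). Purity is this package's numeric stand-in for the qualitative
observation "each domain position forms its own cluster"; 1.0 means
perfect position-specific grouping, and random class labels give purity
near the class-frequency baseline.

## Synthetic families

The generator's defaults are the study conditions, fixed once:

- six domain classes with widths 78, 76, 79, 76, 82, 81 and planted
  conserved-column counts 27, 25, 35, 33, 32, 42 (i.e. 33–52% of columns);
- conserved columns emit their consensus residue with match probability
  0.95 and otherwise a uniformly chosen BLOSUM62-positive neighbour of the
  consensus, so the conservation rule's similar-residue pathway is
  exercised, not just exact matches (residues without a positive partner,
  such as cysteine, fall back to the consensus itself);
- background columns, linkers and termini draw i.i.d. from a uniform
  residue background;
- linker lengths are integer-uniform within ±10% of the medians 218 (L1),
  32 (L2), 101 (L3), 46 (L4), 19 (L5); the N-terminus is 2–4 residues and
  the C-terminal extension 30–60 residues;
- decoys are i.i.d. background sequences.

Output is byte-identical for identical (spec, seed); all randomness flows
through one `numpy` generator consumed in a fixed order.

What the generator does **not** emulate: phylogenetic correlation between
sequences (rows are i.i.d. given the consensus), indels inside domains,
compositional bias, and domain-length variation within a class. Passing
recovery tests therefore show the estimators are correct under the stated
generative model, not that real families are this clean; on real data,
correlated sequences make the effective n smaller and redundancy
filtering correspondingly more important.

## Problem sizes and runtime choices

The test suite and the acceptance script run on desk-scale instances
chosen to exercise every code path with comfortable statistical margins:
oracle-equivalence checks use 100 random small instances per operation;
parameter recovery uses a six-domain family of 100 sequences per domain
with 40% of 80 columns planted conserved; linker statistics use a
117-protein family; the pipeline demo uses 60 sequences. The whole suite
runs in well under a minute and the acceptance script in a few seconds on
one CPU.

## Known limitations

- The PSSM search has no insert/delete state model and no E-value
  statistics; it is a calibrated-score search, adequate for strongly
  conserved domains at desk scale.
- Greedy clustering is order-dependent by design (the order is fixed and
  documented); it is not a globally optimal clustering.
- The pipeline consumes precomputed per-domain alignments (or generates
  gap-free synthetic ones); it does not build multiple alignments.
- Newick output roots the unrooted NJ tree at an arbitrary internal node;
  only leaf path lengths and bipartitions are meaningful.
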