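# Methods

## Model

A macrocycle scaffold is an ordered sequence of structural motifs — small
backbone fragments with two labelled attachment points R1/R2 — joined head to
tail and closed into a ring.  Ring closure is either a direct single bond or
an inserted ester bridge written as a lactone, with the carbonyl carbon bonded
to the last unit's R2 and the bridging oxygen to the first unit's R1.  The
ester orientation is a fixed convention: it keeps canonical structures stable
across runs, at the price that a sequence and its reversal are distinct
molecules unless the sequence is palindromic (without the ester, ring
reversal is a genuine graph symmetry).

"Ring size" throughout means the number of motif units, not ring atoms; the
default common motifs contribute one backbone atom each, so twelve units plus
the ester close a 14-membered lactone.  The alkene motif is modelled with its
unsaturation exocyclic (ethylidene, C=CH–CH3) so that it, too, occupies a
single backbone position; an endocyclic C=C spanning two ring positions is a
chemically defensible alternative that would enlarge rings containing it.
Attachment points are directional: asymmetric motifs are always inserted in
registry orientation, which makes enumeration deterministic.

Emitted scaffolds carry no stereocenters; standardization's stereochemistry
assignment acts on whatever stereo is present (none by default).  This is
consistent with profiling via MACCS keys, which are 2D and chirality-blind.

## Motif transcription and calibration

The nine common motifs are transcriptions of the backbone units recurring in
eighteen well-known bioactive macrolide scaffolds.  Where the available
descriptions under-determine a structure (the three single-oxygen motifs
SM004/SM005/SM009, the aldehyde-bearing SM008, and the alkene SM013), the
shipped structure was selected by calibrating candidate fragments against the
published descriptor profile of the V1M reference library, which pins them
down tightly:

* the TPSA extremes force the single-oxygen trio to a ketone (17.07 Å²), a
  hydroxyl (20.23 Å²) and an ether-type oxygen (9.23 Å²): the profile minimum
  52.6 Å² is exactly lactone 26.30 + carbonyl 17.07 + ether 9.23, and the
  maximum 130.4 Å² is exactly the sum over all six oxygen units plus the
  lactone;
* at most one of the trio may donate a hydrogen bond, otherwise the HBD
  maximum of 3 (two α-hydroxy methyl units + one hydroxyl) is violated; the
  ether is realized as a methoxy branch rather than a backbone ring oxygen,
  which matches the minimum molecular weight and heavy-atom count exactly;
* a rotatable-bond maximum of 4 requires the aldehyde motif to be an
  acetaldehyde side chain –CH2–CHO (two rotatable bonds) — also the form this
  unit takes in 16-membered macrolides — rather than a directly attached
  formyl group;
* with these choices the profile minima (MW 378.5 g/mol, 27 heavy atoms,
  4 heteroatoms, HBD 0) are reproduced exactly over the composition space.

The seven rare motifs ship as clearly labelled synthetic stand-ins covering
the functional-group families of the rare category; the reference
configuration uses none of them, and users are expected to edit the table.

## Enumeration semantics

Compositions (unordered multisets of motifs, the "templates") are generated
per ring size from per-category combinations and their cartesian products,
deduplicated by sorted key in a per-ring-size template store (a hash set; the
contract is duplicate suppression, the data structure is an implementation
detail).  Every allowed repeat of a motif is a distinguishable unit, so each
template owns a block of `(Π_i P(n_i, k_i)) · L!/Π_i k_i!` instance-level
arrangements; blocks concatenate in template-generation order into one global
stream whose total length is the falling factorial n!/(n−L)! for a
single-ring-size, single-category run.  The skip parameter strides this
stream: position 0 is the first arrangement, each emission advances the
cursor by `max(skip, 1)`, and the skip counter carries across template
boundaries.  Coverage is reported as `library_size · skip / total`.  With
skip 0 the walk visits every position, and after canonical-SMILES
deduplication reproduces exactly the set an independent brute-force
(enumerate all sequences, canonicalize, deduplicate) yields — a property the
test suite checks on small registries.

Arrangements are materialized lazily by exact unranking (factorial number
system over multiset permutations), so a skip of 10^7 costs no more than a
skip of 1.  The unit pool is shuffled with a seeded RNG before combination
generation to keep repeated motifs from clustering; the seed is recorded in
`library_info.txt`, making runs bit-for-bit reproducible.

Structure-level deduplication happens at emission: a candidate whose
canonical SMILES was already emitted is skipped without counting toward the
library size.  Rotational or reflective ring-symmetry duplicates are thereby
subsumed by canonicalization; no special symmetry handling is applied.

Standardization applies, in order: hydrogen removal, sanitization, metal
disconnection, normalization, reionization, stereochemistry assignment
(RDKit's `rdMolStandardize` components).  The step is idempotent.

## Descriptor conventions

MW is the average-isotope molecular weight; SlogP the Wildman–Crippen
fragment estimate; TPSA the Ertl topological polar surface area.  HBA is the
Lipinski-style N+O count — including both ester oxygens — and HBD the
NH+OH count.  With these conventions HBA coincides with the heteroatom count
on oxygen-only libraries (their Pearson correlation is exactly 1), and the
reference HBA range 4–8 matches the heteroatom range.  Library summaries use
the sample standard deviation (ddof 1).  Histogram bins default to 15 g/mol
for MW and natural unit widths elsewhere, and are configurable; bins are
presentation, not method.  Constant columns yield missing correlation
entries, never zeros.

## Sampling semantics of scaled-down runs

Desk-scale statistics use a library of 10,000 scaffolds with skip chosen as
`total // 10_000`, i.e. a uniformly spread sample of the *whole* stream, in
which every pool unit appears with probability L/n (12/16 for the reference
configuration).  The published reference profile was instead produced by a
dense walk of the first ~11.5 % of the stream under an unrecorded shuffle, a
sample whose composition coverage depends on that shuffle's prefix.  The two
sampling designs agree closely on arrangement-insensitive quantities (SlogP
mean, MW/heavy-atom correlation) and within a few percent on composition
means (MW, TPSA, HBA), but they differ systematically on range extremes: a
uniformly spread sample reaches the true composition-space extremes, which a
prefix-limited walk need not.  The package reports the full-space values; the
acceptance suite documents where these exceed the published sample-limited
maxima (MW max, heavy-atom max).  Emulating the historical shuffle to
reproduce the prefix bias would require information that was never recorded,
so it is deliberately not attempted.

## Numerical choices and degenerate inputs

All space counting is exact big-integer arithmetic; floating point enters
only in the final coverage fraction.  Ties in best-probe similarity report
the first probe in input order, so per-probe assignment counts are
reproducible.  Tanimoto of two empty fingerprints is 0 by convention.  An
empty library summary, a zero-total coverage, a ring size beyond the unit
pool, and caps naming unknown motifs are all rejected with specific errors;
a library size beyond the reachable space terminates with the exhausted
count and a warning.  Requesting more units than the caps afford in the toy
fixture generator raises the caps and warns rather than failing.

## Probe simplification

For similarity profiling, full macrolides are reduced to comparable cores by
three rules applied to exocyclic substituents until a fixed point: O-linked
saturated 5/6-membered oxygen heterocycles (sugar-like rings) are excised
with the glycosidic oxygen capped as hydroxyl; O-acyl ester chains are
truncated to hydroxyl; substituted exocyclic amines are trimmed to primary
amines.  The macrocyclic ring itself is never modified.  Sugar detection by
ring pattern rather than a sugar dictionary is deliberately simple: it covers
desosamine/cladinose-type substituents but will also fire on any saturated
O-heterocycle attached through oxygen, and it leaves C-glycosides and
carbomethoxy branches untouched.

## What the fixtures do and do not show

The toy-fixture generator emits small registries of simple carbon/oxygen
fragments with feasible rules, sized so exhaustive oracles stay tractable.
Passing tests on these fixtures demonstrate correctness of the combinatorial
machinery (counting, deduplication, skip arithmetic, assembly) — they say
nothing about the chemical realism of any particular motif table, which is
the calibration suite's job.  Known limitations: synthetic feasibility,
stability and toxicity of emitted scaffolds are out of scope (unstable motifs
arrangements such as hydroxymethyl esters are enumerated, not filtered);
sugars are not attached to library scaffolds; descriptor-window filtering
during enumeration is not implemented (profile post hoc instead).

## Problem sizes

The shipped analysis scale: 261 admissible compositions for the reference
configuration (exact extremes), and 10,000-scaffold uniformly spread samples
for distribution statistics, which reproduce million-scale means to well
within the sampling noise of interest.
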