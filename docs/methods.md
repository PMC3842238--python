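# Methods

## Model and assumptions

The inference treats the ranked taxonomic classification of the host
organisms as a proxy for their species tree: phylum > class > order >
family > genus > species, with exactly one node per rank on every
root-to-tip path. This is the central assumption — the reconstruction is
only as good as the classification's fidelity to evolution, and it has no
notion of time, branch lengths or sequence divergence. The observable is
a single non-negative integer per species: the number of family
homologues detected in its proteome. Homologue detection itself
(similarity search against sequence databases) is upstream of this
package; counts are consumed as input.

Species whose classification is unresolved ("unclassified"/"uncultured")
are excluded before the tree is built: they cannot be placed and would
distort the majority denominators. Multiple strains of one species are
collapsed to one tip because the survey is at species level while
sequence databases enumerate strains; the default aggregation is the
maximum count across strains (a strain missing a gene most often reflects
assembly/annotation gaps rather than loss), with `sum` available for
pangenomic readings. Missing intermediate ranks are bridged with
placeholder nodes (`<child>_incertae_<rank>`) so the level-by-level walk
always sees one rank per step; intermediate ranks outside the canonical
six are not represented.

## The strict-majority parsimony rule

A parent is credited with the family only if strictly more than half of
its *surveyed* children carry it (`2·supporting > surveyed` in exact
integer arithmetic). Surveyed means the child's subtree contains at least
one completely sequenced genome; children with no sequenced genome are
excluded from numerator and denominator alike, since absence of evidence
in an unsequenced clade is not evidence of absence. One child out of one
is a strict majority; one out of two is not.

The credited ancestral count is the integer L1 median of the carrying
children's counts, ties broken toward the smaller integer (implemented as
the lower median of the sorted counts; the test suite checks equivalence
against brute-force minimisation of Σ|x−c|). The L1 median minimises the
summed copy-number change implied on the child branches, which is the
natural counting realisation of maximum parsimony. Ties go to the smaller
integer so that duplication, not loss, absorbs the ambiguity — the
conservative choice for a family whose expansion is the phenomenon of
interest.

Derived reports:

* **Origin** — among credited nodes with no credited ancestor ("maximal
  credited clades"), the one of highest rank. Ties are broken by the
  number of homologue-bearing surveyed species in the clade, then by
  name; the tie-break is this package's choice (the motivating dataset
  has a unique winner).
* **HGT candidates** — all other maximal credited clades. A bearing
  species is itself credited, so a lone presence deep inside an
  uncredited clade surfaces as a species-rank candidate. Origin plus
  candidates partition the homologue-bearing species: each bearer lies in
  exactly one reported clade (property-tested).
* **Gains/losses** — for every credited parent and surveyed child with a
  defined count: child > parent is a gain, 0 < child < parent a loss, and
  child = 0 a *complete loss*, kept in a separate field both because the
  biology differs (family extinction vs paralogue reduction) and to keep
  the loss invariant 0 < child < parent clean.
* **Family absent** — no credited node at all is a distinct result (CLI
  exit code 3), not an error.

The synthetic root holding the phyla together is outside the
genus-to-phylum walk and is never credited; the highest reportable origin
is a phylum.

## Conservation scan

Alignment columns are projected onto the ungapped coordinate system of a
designated reference sequence (for family A5, the preprothermopsin
precursor: numbering includes the signal and activation peptides, with
the mature peptidase domain spanning roughly residues 32–330). Counting
is per explicit residue: gaps and ambiguity codes never match, whatever
residue set the caller supplies. Candidate sites are positions where a
residue class reaches `min_fraction` of the sequences; the default
classes (D; D∪N; E; E∪Q; S∪T) encode the standard interchange arguments —
Asn→Asp by deamidation, Thr↔Ser as alternative nucleophiles. The default
threshold 0.6 is the lowest round value at which all five candidate
aspartate positions of the motivating family are reportable (the weakest,
129, reaches 71/75 only as the D∪N class); it is user-settable and 100%
conservation is deliberately not required, since peptidase families
routinely contain non-peptidase homologues with substituted active
sites. `extract_motif` slices on alignment columns between the mapped
endpoints, so insertion columns relative to the reference are preserved
as written (with gaps visible) rather than silently removed.

## Simulator

`simulate_family` emulates a gene family on a random ranked taxonomy:

* **Tree shape** — a fixed number of phyla (default 3), then a uniform
  children-per-node draw for each rank from a per-rank range (default
  2–3, species 2–4). The minimum of 2 is deliberate: a single-child
  lineage above the seeded origin would make presence percolate upward
  and render the true origin rank unidentifiable by any method, so the
  default study conditions keep the recovery question well posed.
* **Events** — one founding copy at the origin taxon (default rank:
  class). Walking down one rank at a time, every copy is lost with
  probability `p_loss` or (if surviving) duplicated with probability
  `p_dup`, independently per copy per step — a Galton–Watson branching
  process, so the expected species count after d steps is (1−p_loss)ᵈ·
  (1+p_dup·(1−p_loss))ᵈ per founding copy, reducing to (1+p_dup)ᵈ
  without loss. With probability `p_hgt` per rank step, one copy is
  transferred from a uniformly chosen bearing taxon to a uniformly
  chosen non-bearing taxon at that rank — clade-to-clade, mirroring the
  ancestral-lineage transfers the method is meant to flag, and the
  recipient's subtree inherits the copy thereafter.
* **Determinism** — one seeded generator drives tree shape, then the
  per-step duplication/loss draws (parents and children in name order),
  then the step's transfer draw. Identical parameters and seed give
  byte-identical tables and logs; replaying the event log from the
  origin reproduces the final species counts exactly (tested over
  hundreds of seeds).

`evaluate_recovery` scores inference output against the log: exact-taxon
origin recovery; transfer sensitivity/precision where a reported
candidate is a true positive if it names a logged destination clade or
any taxon inside it (empty candidate lists score precision 1); and
gain/loss F1 on the event-bearing taxon sets. With `p_loss` > 0 the
transfer precision is measured but not thresholded: losses can fragment
the origin clade below majority and make vertical presences look
transferred — a real limitation of the rank-based method, not of the
simulator.

What the simulator does *not* emulate: real taxonomies' wildly uneven
clade sizes and survey coverage, unsequenced lineages, correlated
phenotypes driving transfer propensity, or sequence-level evolution.
Passing recovery tests therefore demonstrate the algorithm's correctness
under its own model, not robustness to classification error in real data.

`simulate_alignment` builds ungapped alignments whose per-column residue
counts are specified exactly (`round(fraction·n)` sequences carry the
residue; fillers are drawn outside the specified set so counts cannot
drift). `synthetic_a5_alignment` instantiates it with the published
conservation profile of the thermopsin family's candidate catalytic
positions (n = 75; D at 129/144/228/257/302 in 28/48/61/70/61 sequences,
N129 in 43, T150 in 51, S150 in 22) and writes the documented motifs
(QDV, DNVWN, YDKITI, DAELV, DTG) into the reference row. It is a
synthetic stand-in: column content away from the profiled positions is
random, so only the profiled counts and motifs carry meaning.

## Packaged survey table and known inconsistencies

`data/thermopsin_lineages.tsv` transcribes the family A5 survey: 21
homologue-bearing species (17 classified, 4 unclassified and therefore
excluded from inference) plus representative sequenced genomes without
the family, with growth phenotypes (tri-state: blank cells mean
*unknown*, never *false*). Some per-species counts are inconsistent
between different statements of the source survey (e.g. *Sulfolobus
islandicus* is given both seven homologues and one) or not stated at all
(*Ferroplasma acidarmanus*, set here to 3); such rows carry a
`disputed` flag and nothing asserts their exact values. The table's
purpose is the qualitative pattern — origin in the Thermoplasmata,
transfers into the Sulfolobales, Thermofilaceae, *Caldivirga*,
*Thermoproteus* and *Pyrobaculum* sp. 1860 — which is robust to the
disputed integers. Specific ancestral copy numbers printed for the
original survey are likewise treated as illustrative: the published
inputs under-determine them, and this implementation's L1-median rule
reproduces some (Sulfolobus 5, Metallosphaera 2) but not all.

## Numerical and validation choices

Problem sizes used by the test suite and the acceptance script — 500
random trees of ≤ 50 tips for the median/majority oracles, 200 seeded
runs for replay identity and clean-regime recovery, 1000 runs for the
branching-process mean (asserted within 3 standard errors of 1.2⁴) —
were chosen to make sampling error negligible relative to the asserted
effects while keeping a full run in the seconds-to-minutes range.
Degenerate inputs are handled explicitly: empty record lists and
all-unclassified tables are rejected; a transfer drawn when no eligible
source/destination pair exists is skipped with a logged warning; trees
without attached species counts are rejected before the walk.
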