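# paleofam

Gene-family history on a ranked taxonomy: where did a protein family
originate, where was it transferred horizontally, and where were genes
gained or lost?

`paleofam` was built around peptidase family A5 (the thermopsin family),
the only peptidase family restricted to the Archaea. Its members are found
almost exclusively in hyperthermophilic acidophiles that are *not* each
other's closest relatives — a patchy distribution that suggests lateral
gene transfer. The package maps per-species homologue counts onto the
ranked taxonomic classification of the host organisms (phylum > class >
order > family > genus > species) and reconstructs the family's history
under a parsimony rule, without requiring sequence alignments or branch
lengths. It is aimed at protein-family curators who have a table of
per-genome homologue counts and want a first-pass evolutionary
interpretation.

## The method

Let a parent taxon *T* have surveyed children *c₁ … cₖ* (a child is
surveyed if its subtree contains at least one completely sequenced
genome). Walking bottom-up, rank by rank:

* *T* is credited with the family **iff strictly more than half** of its
  surveyed children carry it (for species, carrying means an observed
  count *n* > 0).
* When credited, *T*'s ancestral copy number is the integer **L1 median**
  of the carrying children's counts — `argmin_x Σᵢ |x − nᵢ|`, ties toward
  the smaller integer — the value minimising the total gain+loss magnitude
  implied on the child branches.

From the resulting assignment map:

* **origin** — the highest-ranked credited taxon with no credited
  ancestor;
* **HGT candidates** — every other maximal credited taxon: presences that
  cannot be joined to the origin clade by vertical descent;
* **gains / losses** — credited parent–child pairs with differing counts
  (a species dropping to 0 under a credited parent is a *complete loss*,
  reported separately from paralogue reduction).

A companion module scans multiple sequence alignments, numbered against a
reference precursor, for well-conserved positions within residue classes
(Asp; Asp/Asn; Glu; Glu/Gln; Thr/Ser) to nominate candidate catalytic
residues, and a simulator generates gene families on random ranked
taxonomies (per-copy duplication/loss, clade-to-clade transfer) with a
full ground-truth event log for validation.

## Worked example

The packaged survey table covers every archaeon reported to carry a
thermopsin homologue plus representative sequenced genomes without one
(38 rows, 21 homologue-bearing species):

```
$ paleofam infer --lineages src/paleofam/data/thermopsin_lineages.tsv --json report.json
origin: Thermoplasmata (class)
hgt candidate: Sulfolobales
hgt candidate: Thermofilaceae
hgt candidate: Caldivirga
hgt candidate: Pyrobaculum sp. 1860
hgt candidate: Thermoproteus
```

The family is inferred to have originated in the class **Thermoplasmata**
(phylum Euryarchaeota), where all four sequenced genomes carry it — a
surprise, since thermopsin itself was characterised from *Sulfolobus
acidocaldarius* (order Sulfolobales, phylum Crenarchaeota). Presence in
the Sulfolobales is flagged as an ancient horizontal transfer, with
further unexpected presences in the family Thermofilaceae, the genera
*Caldivirga* and *Thermoproteus*, and the species *Pyrobaculum* sp. 1860.
The JSON report additionally lists the inferred gains (e.g. *Acidianus*,
6 copies against 5 for the Sulfolobaceae ancestor) and losses (e.g.
*Metallosphaera*, 2 against 5).

Conservation scan of the (synthetic, profile-faithful) 75-sequence A5
peptidase-domain alignment:

```
$ paleofam simulate --seed 0 --out-dir sim --alignment
$ paleofam conserve --alignment sim/aln.fasta --reference THERMOPSIN \
      --positions 129,144,228,257,302 --classes D,DN,ST --min-fraction 0.6
75 sequences; 12 candidate (position, class) hits
```

Asp257 is conserved in 70 of 75 sequences, Asp228 and Asp302 in 61,
Asp144 in 48; position 129 holds Asp in 28 sequences and Asn in 43
(71/75 as a class, consistent with Asn→Asp deamidation), and position 150
holds Thr in 51 and Ser in 22 — the pattern expected if thermopsin is an
aspartic peptidase with at least two conserved catalytic aspartates.

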