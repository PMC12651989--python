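# Methods

## Gene grammar

A gene model is an ordered exon list with roles
`signal, (domain_even, domain_odd) × n, [tail]` and the introns between
them.  The conventions are:

* Coordinates are 1-based inclusive everywhere; conversion to half-open
  happens only inside format readers/writers.  Exon order is
  transcriptional; reverse-orientation (`re+co`) genes are stored 5'→3'
  of the mRNA and written back to GFF3 in genomic coordinates with
  strand `-`.
* **End phase.**  `end_phase` of an exon is the cumulative coding
  length modulo 3 at its 3' boundary.  Signal and internal odd exons
  end at phase 0 (codon boundary, "blunt" junctions); all even exons of
  a gene share one phase `even_end_phase ∈ {1, 2}` ("angled",
  codon-overlapping junctions).  The final exon of a gene is exempt
  from the phase check because it may contain the stop codon and a
  3'UTR.  The shared even phase is exactly what makes *any* even→odd
  skip junction frame-consistent, not just adjacent ones.
* **Odd introns carry in-frame stops.**  For architecture-only models
  this is asserted as a grammar fact; when sequence is available the
  flag is computed by scanning the intron in the frame carried over
  from the upstream exons.
* Validation never throws; it returns a list of violations naming the
  unit and rule.  `grammar_ok` means the list is empty.

## Packaged fixtures

The ten *H. manillensis* genes are shipped as one coordinate TSV per
genome assembly (guan/zheng/liu) plus in-code architectures for the
five decorsin genes (exon counts 13/9/14/3/14; motifs KGD@E3;
KGD@E3+RGD@E9; RGD@E3+RGD@E7; RGD@E3; RGD@E3).  Exon-level coordinates
and sequences of the real genes are not published, so the fixtures are
architecture-only: exons have `length_nt = 0` and no sequence, and
every sequence-requiring operation (assembly, GFF3 writing) refuses
them with a clear error instead of fabricating sequence.  The
liu-assembly `Hman_DV5` model is kept verbatim as an 11-exon fixture
(the assembly lacks exons 2–4); it is the canonical validation-failure
case and is excluded from enumeration-based reports for that source,
with a note in the report.

The hirudin-cluster genes (`Hman_HV1–4`, `Hman_TH`) are coordinate-only
entries used by the cluster-geometry module.

## Isoform enumeration

Products are depth-first walks over the DAG of frame-preserving
junctions (strictly increasing exon index, alternating parity), output
in lexicographic chain order so reports are byte-stable.  Termination:

* `tail_splice` — an odd exon splices to the tail exon; counted as an
  exon-skipping event, so it requires that mechanism;
* `intron_retention` — terminal only: the intron after an odd exon is
  retained and its in-frame stop ends translation.  Internal (stop-free)
  retention is not modeled; there is no evidence for stop-free odd
  introns in this family;
* `final_exon` — tail-less genes end at their last (odd) exon, with the
  stop assumed in/after that exon.

When exon skipping is not among the mechanisms, walks are restricted to
adjacent junctions.  Product identity is (chain, termination, retained
intron); sequence-identical products from different chains are distinct
by default because diversity is counted over exon combinations
(`dedupe="by_protein_sequence"` opts into collapsing).  The zero-repeat
chain (signal exon straight to tail, or signal-intron retention) is
excluded from factor counts unless requested.

**Checks.**  An independent subset enumerator (tests) confirms the
skip-only census equals `C(n+k, 2k)` per class with total
`Fibonacci(2n+1) − 1` for n ≤ 8, and that adding retention doubles each
class via the bijection chain↔chain+tail.

### Divergence from the published census

For the 6-repeat `Hman_DV3` gene the exhaustive counts are
21/70/84/45/11/1 (total 232).  The published counts agree for k = 1, 2,
5, 6 but print 61 trimeric, 32 tetrameric, 196 total, and a motif
census of 27 (two motifs) / 99 (≥ 1) / 126; exhaustive enumeration
gives 39 two-motif and 154 ≥ 1-motif products.  No additional
constraint consistent with the stated junction rule reproduces those
figures, and the underlying enumeration list is not available, so the
constraint (or enumeration error) cannot be recovered.  The report
layer therefore prints both sides with per-row agreement flags; only
the k = 1, 2, 5, 6 classes are treated as reproduction targets, the
rest are covered by the closed-form/brute-force oracle.

### Monomeric variant naming

Variants are grouped per gene by (motif exon, even partner), ordered by
that pair; an ordinal is appended when a gene has more than one group,
and `a`/`b` suffixes distinguish retention vs tail-splice termination
when both exist (`Hman_DV1s`, `Hman_DV2s-1…5`, `Hman_DV3s-1a…4b`,
`Hman_DV5sa/sb`).  Monomeric genes are skipped with a warning.

## Domain annotation

The scanner collects cysteine positions and grows six-cysteine windows
greedily from the N-terminus, taking the nearest admissible next
cysteine under a spacing envelope (defaults: gaps 2–12, 1–12, 1–12,
1–15, 3–20 residues between consecutive cysteines, accepting repeats of
roughly 39–51 residues consistent with published monomer lengths of
45–63 aa including termini).  Earliest-start/shortest-hit is a stated
convention for ambiguous cysteine clusters, not a claim about true
domain boundaries; the envelope is fully configurable because real
spacing is not published for these genes.  RGD/KGD motifs are only
annotated strictly between C5 and C6; if both tripeptides occur there,
the leftmost wins with a warning.

## Protein properties

* Molecular weight: sum of average residue masses plus one water
  (monoisotopic by flag), reported in kDa; computed via Biopython.
* Extinction coefficient: `ε = 5500·nW + 1490·nY + 125·nC`
  (L·mol⁻¹·cm⁻¹).  The per-cysteine term is implemented verbatim even
  though common conventions count cystine pairs — fidelity to the
  published formula wins.  Concentration is `A280 / ε` at 1 cm path.
* pI: bisection on pH ∈ [0, 14] of the Henderson–Hasselbalch net charge
  over the termini and D/E/C/Y/H/K/R side chains, tolerance 0.005 pH
  (≤ 60 iterations; the charge is strictly decreasing in pH).  pKa sets
  are selectable by name (`emboss` default, `lehninger`); since the
  tool behind the published MW/pI tables is unstated, those tables are
  treated as shape references, not numeric targets — also the published
  protein sequences themselves are unavailable.
* Rounding (2 decimals) is applied only at report boundaries.

## Cluster geometry

Span = `max(end) − min(start) + 1`.  The three published inter-cluster
gap figures are mutually inconsistent under any single rule derivable
from the published coordinates (zheng matches the nearest-envelope-edge
coordinate difference; guan matches the `Hman_DV1`-start to
`Hman_TH`-end difference; liu matches neither — it equals the
start-to-start difference of those genes, which is not an edge
distance).  The module therefore exposes two explicit conventions
(`nearest_edges`, `named_gene_pair`), each in a raw coordinate
"difference" mode and a strictly-between "intervening" mode, and the
report flags mismatches rather than silently choosing.  Gaps are
findings, not targets; spans are exact targets.

## Synthetic data generator

The generator emulates the study conditions: one signal exon, `n`
two-exon domain repeats, optional tail, even-exon end phase 1 (default;
2 exercised in tests since the codon split position is not specified),
introns of 60–180 nt with `GT…AG` ends, odd introns opening
`GTATAA…` so the in-frame stop sits within the first 30 nt by
construction (no rejection sampling).

Key design choice: all repeats of one gene share a single seeded
template — identical cysteine layout (gaps sampled within the scanner's
default envelope), identical split point between the even and odd exon
(between C2 and C3), and an invariant Ala/GCT codon spanning the
even→odd junction.  Consequently every skip junction yields a hybrid
domain that is again scaffold-conformant and stop-free, which is what
lets the round-trip guarantee hold for *all* products: enumerate →
assemble/translate → domain-annotate recovers each product's
`k_repeats` and `motif_count` exactly.  Filler residues exclude C and G,
so no spurious cysteine scaffolds or R/K-G-D motifs can arise; motifs
are placed between C5 and C6 of the requested repeats, inside the odd
exon.  Tail-less genes carry their stop and a short 3'UTR inside the
final odd exon.

What the generator does **not** emulate: real leech codon usage,
SignalP-validatable cleavage sites, sequence divergence between repeats
of real genes, non-canonical splice sites, or intron retention with
read-through.  Passing round-trip tests therefore demonstrates the
correctness of the enumeration/translation/annotation machinery on
grammar-conformant genes, not the scanner's sensitivity on diverged
natural sequences.

## Problem sizes and determinism

All enumerations here are desk-scale (the largest routine case, the
6-repeat gene under both mechanisms, has 464 products; the oracle suite
goes to n = 8, 1597 chains).  The test suite uses 20 seeded synthetic
genes (1–3 repeats, both phases, with and without tails) for the
end-to-end property.  Every random choice flows from an explicit seed;
reports contain no timestamps and are byte-identical across runs.

## Known limitations

* Real exon boundaries/sequences of the Hman genes are unpublished, so
  fixture-level reproduction stops at architecture and coordinates, and
  published MW/pI tables cannot be verified numerically.
* The published trimeric/tetrameric/total/motif-census figures remain
  unexplained (see above); the package reports the discrepancy.
* `E1` is allowed to splice to any even exon, as the parity rule
  states; whether signal-peptide constraints restrict `E1` to `E2` in
  some genes is unstated and not modeled.
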