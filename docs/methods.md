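# Methods

## Screening model

A candidate protein is accepted into the analysis when all of the
following hold, with every rule evaluated on every record so each can be
audited independently:

1. **Four-TM topology.** A Kyte–Doolittle hydropathy profile (sliding
   window of 19 residues, truncated — not mirrored — at the termini so the
   profile keeps one value per residue) is thresholded at 1.6. Maximal
   above-threshold runs become TM candidates; runs separated by fewer than
   3 sub-threshold positions are merged (short dips inside one helix),
   runs longer than 35 residues are split at their weakest interior point
   when both halves stay ≥ 15 residues (the fused-helix artifact of
   hydropathy methods), and runs shorter than 15 residues are discarded.
   Exactly four surviving intervals are labeled TM1–TM4; the inter-helix
   regions become EL1, CL, EL2 and the termini NTERM_IN/CTERM_IN under a
   fixed N-inside orientation, which is asserted for this family rather
   than inferred — a positive-inside charge heuristic is deliberately out
   of scope. Any other interval count, or helices so close that a loop
   would be empty, is a `NOT_FOUR_TM` rejection.
2. **Not a fragment.** Records shorter than 200 aa are rejected
   (`FRAGMENT`). Full-length members of this family run ~350–600 aa, so
   the floor is conservative; it is configurable.
3. **Not a duplicate.** Within each species, records with byte-identical
   sequences form a group and all but the lexicographically smallest id
   are rejected (`DUPLICATE`). Near-duplicates (splice isoforms) are
   retained on purpose; collapsing them would need alignment-based
   similarity and an arbitrary cutoff.

Family membership itself is an input contract: the caller asserts the
FASTA contains candidate family members (in practice the output of a
homology search).

Window, threshold, minimum length and merge gap follow standard
hydropathy-plot practice for TM helices and are all exposed in the
configuration. Coordinates are 1-based inclusive everywhere inside the
package; conversion happens only at I/O boundaries.

## Sequon calling

Sequons are all Asn-X-Ser/Thr triplets with X ≠ Pro, reported even when
overlapping. A sequon is assigned to the loop containing its **asparagine**
(the residue that carries the glycan); the triplet may straddle a segment
boundary. A sequon *passes* — is counted as a potential extracellular
N-glycosylation site — when its Asn lies in EL1 or EL2 **and** its
occupancy score strictly exceeds 0.5.

The score is a deterministic rule sum standing in for neural-network
occupancy predictors, built from the best-supported sequence determinants
of oligosaccharyltransferase efficiency: base potential 0.55; +0.15 when
the sequon is N-X-T (more efficiently occupied than N-X-S); −0.25 when a
proline immediately follows the sequon (suppresses transfer); −0.10 when
the Asn sits within 3 residues of a TM boundary (sterically
membrane-proximal); clamped to [0, 1]. The table is configurable. The
score is intentionally transparent rather than trained: it reproduces the
*logic* of a >0.5 occupancy cut, not any particular predictor's numeric
output, and the score of a site is invariant under translating the whole
protein (all rules are relative to the sequon and the topology).

## Conservation across orthologs

Alignments are inputs (aligned FASTA or Clustal), never computed here.
Each sequence's residues are mapped to alignment columns; columns with a
gap fraction above 0.5, and surviving blocks shorter than 5 columns, are
trimmed — a deliberately parameter-light, gap-only surrogate for
divergence-aware column filters, sufficient because the conservation
logic, not the trimming, is the object under test. "The same site" in two
species means *the same alignment column of the Asn* (strict default; a
±1-column tolerance mode exists). Conservation counts **species**, not
proteins: a species with several isoforms counts once if any isoform
carries the column sequon (switchable to per-protein). A group is
*conserved* when some column carries a passing extracellular sequon in
every member species.

## Trees

Trees are a visualization scaffold for presence/absence, so the package
builds them by neighbor joining on p-distances (mismatches over mutually
ungapped columns, pairwise deletion) rather than by likelihood methods:
NJ is exact on additive distances, fast at desk scale, and — with
Q-criterion ties broken by the lexicographically smallest clade keys and
negative branch lengths clamped to zero with the deficit moved to the
sister branch — byte-for-byte reproducible. The leaf annotation export is
a flat TSV (red = has a passing extracellular sequon, black = not, plus
per-loop bars and taxon group) for external viewers. Robinson–Foulds
distance (symmetric difference of non-trivial bipartitions) is included
as the oracle used to compare topologies in the tests.

## Synthetic data: what it emulates and what it cannot show

The generator replaces bulk database retrieval. A protein is assembled
segment by segment — NTERM(30–60) · TM(21–25) · EL1(40–70) · TM · CL
(60–110) · TM · EL2(40–70) · TM · CTERM(60–150) — giving full lengths of
roughly 310–560 aa. Two alphabet choices make the ground truth exhaustive
rather than probabilistic:

* **TM alphabet {I, V}** (mean Kyte–Doolittle 4.35) against **loop
  alphabet {G, W, Y, Q, K}** (mean −2.0). With window 19 and threshold
  1.6 the profile's crossing point then sits ~1 residue outside the true
  boundary with sub-residue jitter, so called TM boundaries land within
  ±3 residues of truth with margin to spare. Milder loop alphabets
  (means below about −1.9) would push the deterministic offset past 3.
* The loop alphabet contains **no N, S, T** — so the only sequons present
  are the planted ones and scanner tests are exact set equalities — and
  **no P**, so a planted sequon can never be suppressed by the
  proline-at-+3 penalty.

Each protein receives one planted sequon with per-taxon probability
`p_el_ngs`, at a uniform loop position at least 4 residues from the
flanking TM boundaries (clear of the membrane-proximal penalty), plus two
interior cysteines per extracellular loop (the docking-disulfide motif of
the family). Decoys drop or add one TM unit (3- or 5-TM architectures),
fragments truncate to 100–199 aa (always below both the length floor and
the first four TM units), and duplicates re-emit an existing record in the
same species under an id that sorts after its source. Default taxa emulate
the study conditions the screen is meant for: a chordate-like group
planted at probability 1.0 (every protein sequon-bearing), a
ctenophore-like group at 0.67, and a protostome-like group at 0.6 with
larger isoform counts.

Clade alignments for conservation tests derive descendants from one
ancestor by per-site substitution within each segment's own alphabet
(topology survives mutation), with the sequon's three sites held fixed or
the Asn overwritten to Gln for knockout members; no indels, so the true
alignment is the trivial ungapped one.

What passing these tests does **not** show: real sequences have
overlapping hydropathy distributions between loops and helices, signal
peptides, re-entrant loops and borderline TM calls; real sequons occur in
contexts the rule score only caricatures; real alignments have indels and
alignment error. The synthetic results validate the *logic and
bookkeeping* of the pipeline, not the accuracy of hydropathy topology
prediction or occupancy scoring on biological data. A `realistic` mode
draws loops from the full 20-letter alphabet (truth recomputed by the
motif scan) for stress testing the scanner, not for benchmarking.

## Numerical and design choices

* Threshold comparisons: TM calling uses ≥ threshold; the sequon pass rule
  is strict (> 0.5), so a score of exactly 0.5 fails.
* The interval-count monotonicity property (raising the TM threshold never
  increases the number or total length of called intervals) holds on the
  plateau-shaped profiles of this family's architecture and is asserted
  there; on arbitrary profiles a raised threshold can split one merged run
  into two, so the property is scoped to the generator's regime.
* Floats in every results TSV are formatted to 6 significant digits so
  re-runs diff byte-for-byte.
* Empty inputs are errors, not empty results (misconfiguration should fail
  loudly); ambiguity codes (B, Z, X, U) are rejected at ingest because the
  sequon rule is undefined for an ambiguous residue at the Asn or Ser/Thr
  position.
* Aggregation denominators: fractions are over accepted proteins only
  (screen-then-summarize); the species count per group is the number of
  distinct species the taxonomy lists for it, so a species whose records
  were all rejected still counts toward mean isoforms per species. A group
  with no accepted proteins reports a missing fraction and is vacuously
  "universal" (logged as a warning).
* Problem sizes in the test suite and acceptance script (500-protein
  screens, 200-protein topology recovery, 8-member clades, 100 NJ
  replicates of 5–12 taxa, ~2,000-protein determinism runs) were chosen as
  the smallest sizes at which the binomial checks have power; all complete
  in seconds.

## Known limitations

* The hydropathy heuristic will not reproduce record-by-record topology
  calls of HMM-based predictors on real data; borderline 3-vs-4-TM cases
  go to `NOT_FOUR_TM`.
* The occupancy score is not calibrated against experimental glycosylation
  data; only its threshold logic is meaningful.
* Duplicate detection is exact-identity within species; the same protein
  deposited under different databases with one residue changed is not
  caught.
* Strict column identity undercounts conservation when alignment error
  shifts a sequon by a column; the tolerance mode exists for exactly that
  but is off by default.
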