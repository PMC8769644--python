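# innexscan

Screening of innexin-family gap-junction proteins for N-glycosylation
consensus sites in their extracellular loops.

## The problem

Gap-junction channels form when a hemichannel in one cell docks onto a
hemichannel of its neighbor. Innexins — the primordial gap-junction
proteins of most animals, whose chordate homologs are the pannexins —
share a fixed membrane architecture: four transmembrane helices (TM1–TM4),
two extracellular loops (EL1, EL2), one cytoplasmic loop, and intracellular
N- and C-termini. N-linked glycosylation of the extracellular loops blocks
hemichannel docking, so whether an innexin carries an N-glycosylation
consensus site (a *sequon*, Asn-X-Ser/Thr with X ≠ Pro) in EL1 or EL2 is a
functional question: a glycosylated loop cannot form an intercellular
channel. Because each hemichannel is an oligomer of eight innexins (six for
the unrelated connexins), N co-expressed isoforms admit up to N⁸ (innexins)
or N⁶ (connexins) heteromeric hemichannels — isoform counts per species
matter too.

`innexscan` is for comparative sequence analysts who want to run this
screen reproducibly on protein collections: it infers the four-TM topology
from a Kyte–Doolittle hydropathy profile, rejects fragments, duplicates
and wrong-topology decoys, scans accepted sequences for sequons, restricts
them to the extracellular loops with a rule-based occupancy score
(strictly > 0.5 to pass), maps them into alignment columns to ask whether
a site is conserved across every species of a group, annotates
neighbor-joining trees with red/black presence marks, and aggregates
per-taxon fractions. A synthetic-data generator with exhaustive planted
ground truth stands in for database downloads, so every stage is testable
offline.

## Worked example

```bash
innexscan simulate --seed 7 --out demo/sim
innexscan screen --fasta demo/sim/dataset.fasta \
                 --taxonomy demo/sim/taxonomy.tsv --out demo/screen
innexscan aggregate --verdicts demo/screen/verdicts.tsv \
                    --taxonomy demo/sim/taxonomy.tsv --out demo/agg
cat demo/agg/summary.tsv
```

```text
taxon_group	n_species	n_proteins	n_with_el_ngs	fraction_with_el_ngs	mean_isoforms_per_species
chordates	8	26	26	1	3.25
ctenophores	6	18	11	0.611111	3
protostomes	8	42	27	0.642857	5.25
```

Each row is one simulated taxonomic group: number of sampled species,
accepted proteins, proteins with at least one passing extracellular sequon,
the fraction that is (the chordate-like group is planted at probability 1,
so its fraction is exactly 1.0), and the mean isoform count per species.
The `screen` step also writes `verdicts.tsv` (per-protein accept/reject
with reason codes `NOT_FOUR_TM`, `FRAGMENT`, `DUPLICATE` and the inferred
topology) and `sequons.tsv` (every site with its loop, score and pass
flag). `innexscan conserve` reports, per group and alignment column, how
many species carry a passing sequon at that column, and `innexscan
tree-annotate` exports the red/black leaf classes for tree viewers.

The same operations are available as a library:

```python
import innexscan as ix

records = ix.read_fasta("proteins.fasta")          # id|species|group headers
verdicts = ix.screen_dataset(records)
model = verdicts[0].topology                       # TopologyModel, 1-based spans
summary = ix.summarize_by_taxon(verdicts, ix.TaxonomyTable.from_records(records))
ix.hemichannel_diversity(2, 8)                     # -> 256
```

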