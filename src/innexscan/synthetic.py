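"""Synthetic innexin-like datasets with exhaustive planted ground truth.

Real screens start from bulk database downloads; here every pipeline stage
is exercised offline on generated four-TM proteins whose truth is known by
construction.  Two alphabet choices make the truth exhaustive rather than
probabilistic:

* TM helices are drawn from a strongly hydrophobic alphabet (I, V) and
  loops/termini from a mildly hydrophilic one (G, W, Y, Q, K), so the
  windowed hydropathy profile crosses the calling threshold within a
  residue or two of the true segment boundary;
* the loop alphabet contains no N, S or T, so the only N-X-S/T sequons in a
  generated protein are the planted ones, and no P, so a planted sequon is
  never suppressed by the proline-at-+3 rule.

Decoys (3- or 5-TM architectures), fragments (truncated below the length
floor) and duplicates (re-emitted under a new id in the same species) are
planted at configurable rates.  A ``realistic`` mode draws loops from the
full 20-letter alphabet for stress testing; its truth lists every sequon
falling in an extracellular loop, recomputed by the motif scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .io_formats import (
    Alignment,
    ProteinRecord,
    TaxonomyTable,
    write_fasta,
    write_results_table,
    write_taxonomy,
)
from .sequon import find_sequons
from .topology import KYTE_DOOLITTLE, SEGMENT_ORDER

TM_ALPHABET = "IV"
LOOP_ALPHABET = "GWYQK"
FULL_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

CLASS_LABELS = ("INNEXIN", "DECOY_3TM", "DECOY_5TM", "FRAGMENT", "DUPLICATE")

DEFAULT_SEGMENT_RANGES: dict[str, tuple[int, int]] = {
    "NTERM_IN": (30, 60),
    "TM": (21, 25),
    "EL1": (40, 70),
    "CL": (60, 110),
    "EL2": (40, 70),
    "CTERM_IN": (60, 150),
}


@dataclass(frozen=True)
class TaxonSpec:
    """One higher-level taxonomic group of the simulated study."""

    name: str
    n_species: int
    isoforms_min: int
    isoforms_max: int
    p_el_ngs: float       # probability a protein gets one planted EL sequon
    el1_weight: float = 0.5  # P(planted loop is EL1) vs EL2


#: Default study conditions: a chordate-like group where every protein
#: carries an extracellular sequon, a ctenophore-like group at the ~2/3
#: level, and a generic protostome-like group with many isoforms per species.
DEFAULT_TAXA: tuple[TaxonSpec, ...] = (
    TaxonSpec("chordates", n_species=8, isoforms_min=1, isoforms_max=6, p_el_ngs=1.0),
    TaxonSpec("ctenophores", n_species=6, isoforms_min=2, isoforms_max=8, p_el_ngs=0.67),
    TaxonSpec("protostomes", n_species=8, isoforms_min=2, isoforms_max=10, p_el_ngs=0.6),
)


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    taxa: tuple[TaxonSpec, ...] = DEFAULT_TAXA
    segment_ranges: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_SEGMENT_RANGES)
    )
    tm_threshold: float = 1.6
    tm_hydropathy_margin: float = 0.5
    decoy_fraction: float = 0.10
    fragment_fraction: float = 0.05
    duplicate_fraction: float = 0.05
    substitution_rate: float = 0.05
    el_cysteines: int = 2
    realistic: bool = False

    def validate(self) -> None:
        for name, p in (
            ("decoy_fraction", self.decoy_fraction),
            ("fragment_fraction", self.fragment_fraction),
            ("duplicate_fraction", self.duplicate_fraction),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        for t in self.taxa:
            if not 0.0 <= t.p_el_ngs <= 1.0:
                raise ValueError(f"taxon {t.name}: p_el_ngs must be in [0, 1]")
            if not 0.0 <= t.el1_weight <= 1.0:
                raise ValueError(f"taxon {t.name}: el1_weight must be in [0, 1]")
            if t.n_species < 1 or t.isoforms_min < 1 or t.isoforms_max < t.isoforms_min:
                raise ValueError(f"taxon {t.name}: bad species/isoform counts")
        if self.tm_hydropathy_margin <= 0:
            raise ValueError("tm_hydropathy_margin must be positive")
        for label, (lo, hi) in self.segment_ranges.items():
            if lo < 1 or hi < lo:
                raise ValueError(f"bad length range for {label}: ({lo}, {hi})")
        for el in ("EL1", "EL2"):
            if self.segment_ranges[el][0] < 11:
                raise ValueError(f"{el} too short to host an interior sequon")
        tm_mean = float(np.mean([KYTE_DOOLITTLE[a] for a in TM_ALPHABET]))
        loop_mean = float(np.mean([KYTE_DOOLITTLE[a] for a in LOOP_ALPHABET]))
        if tm_mean < self.tm_threshold + self.tm_hydropathy_margin:
            raise ValueError("TM alphabet not hydrophobic enough for the margin")
        if loop_mean > self.tm_threshold - self.tm_hydropathy_margin:
            raise ValueError("loop alphabet not hydrophilic enough for the margin")
        if not 0.0 <= self.substitution_rate < 1.0:
            raise ValueError("substitution_rate must be in [0, 1)")


@dataclass(frozen=True)
class TruthEntry:
    """Generator-side truth for one emitted record."""

    id: str
    species: str
    taxon_group: str
    class_label: str
    segments: dict[str, tuple[int, int]]  # empty for decoys/fragments/duplicates
    sequons: tuple[tuple[int, str], ...]  # (1-based Asn position, loop label)
    source_id: str = ""  # original record for DUPLICATE entries


@dataclass(frozen=True)
class SimDataset:
    records: tuple[ProteinRecord, ...]
    taxonomy: TaxonomyTable
    truth: tuple[TruthEntry, ...]


def _rand_string(rng: np.random.Generator, alphabet: str, length: int) -> list[str]:
    return [alphabet[i] for i in rng.integers(0, len(alphabet), size=length)]


def _segment_length(rng: np.random.Generator, ranges: dict[str, tuple[int, int]],
                    label: str) -> int:
    key = "TM" if label.startswith("TM") else label
    lo, hi = ranges[key]
    return int(rng.integers(lo, hi + 1))


def _build_architecture(rng: np.random.Generator, config: SimConfig,
                        labels: Sequence[str]) -> tuple[list[str], dict[str, tuple[int, int]]]:
    loop_alpha = FULL_ALPHABET if config.realistic else LOOP_ALPHABET
    chars: list[str] = []
    spans: dict[str, tuple[int, int]] = {}
    pos = 1
    for label in labels:
        length = _segment_length(rng, config.segment_ranges, label)
        alpha = TM_ALPHABET if label.startswith("TM") else loop_alpha
        chars.extend(_rand_string(rng, alpha, length))
        spans[label] = (pos, pos + length - 1)
        pos += length
    return chars, spans


def _plant_sequon(rng: np.random.Generator, chars: list[str],
                  span: tuple[int, int]) -> int:
    """Write one N-X-S/T at an interior loop position >=4 residues from the
    flanking TM boundaries; returns the 1-based Asn position."""
    s, e = span
    n_pos = int(rng.integers(s + 3, e - 3 + 1))
    x = LOOP_ALPHABET[int(rng.integers(0, len(LOOP_ALPHABET)))]
    third = "T" if rng.random() < 0.5 else "S"
    chars[n_pos - 1 : n_pos + 2] = ["N", x, third]
    return n_pos


def _plant_cysteines(rng: np.random.Generator, chars: list[str],
                     span: tuple[int, int], count: int,
                     protected: set[int]) -> None:
    # interior positions only: keeps the cysteines clear of the called loop
    # boundaries, which can differ from truth by a couple of residues
    s, e = span
    candidates = [p for p in range(s + 4, e - 3) if p not in protected]
    if count > len(candidates):
        raise ValueError("extracellular loop too short for requested cysteines")
    for p in rng.choice(len(candidates), size=count, replace=False):
        chars[candidates[int(p)] - 1] = "C"


def _realistic_truth_sequons(chars: list[str],
                             spans: dict[str, tuple[int, int]]) -> tuple[tuple[int, str], ...]:
    out = []
    seq = "".join(chars)
    for n_pos, _trip in find_sequons(seq):
        for el in ("EL1", "EL2"):
            s, e = spans[el]
            if s <= n_pos <= e:
                out.append((n_pos, el))
    return tuple(out)


def simulate_protein(config: SimConfig, rng: np.random.Generator,
                     protein_id: str, species: str, taxon_group: str,
                     p_el_ngs: float, el1_weight: float = 0.5
                     ) -> tuple[ProteinRecord, TruthEntry]:
    """One four-TM innexin-like protein with (maybe) one planted EL sequon."""
    chars, spans = _build_architecture(rng, config, SEGMENT_ORDER)
    sequons: tuple[tuple[int, str], ...] = ()
    protected: set[int] = set()
    if rng.random() < p_el_ngs:
        loop = "EL1" if rng.random() < el1_weight else "EL2"
        n_pos = _plant_sequon(rng, chars, spans[loop])
        sequons = ((n_pos, loop),)
        protected = {n_pos, n_pos + 1, n_pos + 2}
    for el in ("EL1", "EL2"):
        _plant_cysteines(rng, chars, spans[el], config.el_cysteines, protected)
    if config.realistic:
        sequons = _realistic_truth_sequons(chars, spans)
    record = ProteinRecord(id=protein_id, species=species, taxon_group=taxon_group,
                           sequence="".join(chars), source="synthetic")
    truth = TruthEntry(id=protein_id, species=species, taxon_group=taxon_group,
                       class_label="INNEXIN", segments=spans, sequons=sequons)
    return record, truth


_DECOY_3TM = ("NTERM_IN", "TM1", "EL1", "TM2", "CL", "TM3", "CTERM_IN")
_DECOY_5TM = ("NTERM_IN", "TM1", "EL1", "TM2", "CL", "TM3", "EL2", "TM4",
              "CL", "TM5", "CTERM_IN")


def _simulate_decoy(config: SimConfig, rng: np.random.Generator, protein_id: str,
                    species: str, taxon_group: str) -> tuple[ProteinRecord, TruthEntry]:
    three = rng.random() < 0.5
    labels = _DECOY_3TM if three else _DECOY_5TM
    # 5-TM decoy reuses the CL range for its extra loop; spans keyed by position
    chars: list[str] = []
    pos = 1
    loop_alpha = FULL_ALPHABET if config.realistic else LOOP_ALPHABET
    for label in labels:
        length = _segment_length(rng, config.segment_ranges, label if not label.startswith("TM") else "TM1")
        alpha = TM_ALPHABET if label.startswith("TM") else loop_alpha
        chars.extend(_rand_string(rng, alpha, length))
        pos += length
    record = ProteinRecord(id=protein_id, species=species, taxon_group=taxon_group,
                           sequence="".join(chars), source="synthetic")
    truth = TruthEntry(id=protein_id, species=species, taxon_group=taxon_group,
                       class_label="DECOY_3TM" if three else "DECOY_5TM",
                       segments={}, sequons=())
    return record, truth


def _simulate_fragment(config: SimConfig, rng: np.random.Generator, protein_id: str,
                       species: str, taxon_group: str) -> tuple[ProteinRecord, TruthEntry]:
    rec, _truth = simulate_protein(config, rng, protein_id, species, taxon_group,
                                   p_el_ngs=0.0)
    cut = int(rng.integers(100, 200))
    rec = ProteinRecord(id=rec.id, species=rec.species, taxon_group=rec.taxon_group,
                        sequence=rec.sequence[:cut], source="synthetic")
    truth = TruthEntry(id=protein_id, species=species, taxon_group=taxon_group,
                       class_label="FRAGMENT", segments={}, sequons=())
    return rec, truth


def simulate_dataset(config: SimConfig) -> SimDataset:
    """Full multi-taxon dataset with planted decoys, fragments and duplicates."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    records: list[ProteinRecord] = []
    truths: list[TruthEntry] = []
    innexin_indices: list[int] = []
    for taxon in config.taxa:
        for si in range(taxon.n_species):
            species = f"{taxon.name}_sp{si:02d}"
            n_iso = int(rng.integers(taxon.isoforms_min, taxon.isoforms_max + 1))
            for k in range(n_iso):
                pid = f"{taxon.name}_sp{si:02d}_i{k:02d}"
                u = rng.random()
                if u < config.decoy_fraction:
                    rec, truth = _simulate_decoy(config, rng, pid, species, taxon.name)
                elif u < config.decoy_fraction + config.fragment_fraction:
                    rec, truth = _simulate_fragment(config, rng, pid, species, taxon.name)
                else:
                    rec, truth = simulate_protein(config, rng, pid, species,
                                                  taxon.name, taxon.p_el_ngs,
                                                  taxon.el1_weight)
                    innexin_indices.append(len(records))
                records.append(rec)
                truths.append(truth)
    if not records:
        raise ValueError("configuration yields zero proteins")
    # duplicates re-emit an innexin under a new id in the same species;
    # the suffix sorts after the source id, so the source is the one kept
    for idx in innexin_indices:
        if rng.random() < config.duplicate_fraction:
            src = records[idx]
            dup_id = src.id + "_dup"
            records.append(
                ProteinRecord(id=dup_id, species=src.species,
                              taxon_group=src.taxon_group,
                              sequence=src.sequence, source="synthetic")
            )
            truths.append(
                TruthEntry(id=dup_id, species=src.species,
                           taxon_group=src.taxon_group, class_label="DUPLICATE",
                           segments={}, sequons=(), source_id=src.id)
            )
    taxonomy = TaxonomyTable.from_records(records)
    return SimDataset(records=tuple(records), taxonomy=taxonomy, truth=tuple(truths))


def simulate_clade_alignment(config: SimConfig, n_members: int,
                             preserve_sequon: Sequence[bool] | None = None,
                             rng: np.random.Generator | None = None,
                             group_name: str = "clade"
                             ) -> tuple[Alignment, list[ProteinRecord], list[TruthEntry]]:
    """Ortholog family: one ancestor, per-site substituted descendants.

    The ancestor always carries one EL sequon.  Descendants substitute each
    non-sequon site with probability ``substitution_rate`` within the
    segment's own alphabet (topology is preserved under mutation); the
    sequon's three sites are held fixed where ``preserve_sequon`` is true
    and the Asn is overwritten to Gln where false.  No indels, so the true
    alignment is the trivial ungapped one.
    """
    config.validate()
    if n_members < 2:
        raise ValueError("need at least two clade members")
    if not 0.0 <= config.substitution_rate < 1.0:
        raise ValueError("substitution rate must be in [0, 1)")
    if preserve_sequon is None:
        preserve_sequon = [True] * n_members
    if len(preserve_sequon) != n_members:
        raise ValueError("preserve_sequon length must equal n_members")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    _anc_rec, anc_truth = simulate_protein(
        config, rng, f"{group_name}_anc", f"{group_name}_anc", group_name,
        p_el_ngs=1.0,
    )
    anc = list(_anc_rec.sequence)
    (n_pos, loop_label) = anc_truth.sequons[0]
    sequon_sites = {n_pos, n_pos + 1, n_pos + 2}

    def alphabet_at(pos: int) -> str:
        for label, (s, e) in anc_truth.segments.items():
            if s <= pos <= e:
                return TM_ALPHABET if label.startswith("TM") else LOOP_ALPHABET
        raise AssertionError("position outside architecture")

    ids, rows, records, truths = [], [], [], []
    for m in range(n_members):
        chars = list(anc)
        for pos in range(1, len(chars) + 1):
            if pos in sequon_sites:
                continue
            if rng.random() < config.substitution_rate:
                alpha = alphabet_at(pos)
                choices = alpha.replace(chars[pos - 1], "") or alpha
                chars[pos - 1] = choices[int(rng.integers(0, len(choices)))]
        kept = bool(preserve_sequon[m])
        if not kept:
            chars[n_pos - 1] = "Q"
        mid = f"{group_name}_m{m:02d}"
        rec = ProteinRecord(id=mid, species=f"{group_name}_sp{m:02d}",
                            taxon_group=group_name, sequence="".join(chars),
                            source="synthetic")
        ids.append(mid)
        rows.append(rec.sequence)
        records.append(rec)
        truths.append(
            TruthEntry(id=mid, species=rec.species, taxon_group=group_name,
                       class_label="INNEXIN", segments=anc_truth.segments,
                       sequons=((n_pos, loop_label),) if kept else ())
        )
    return Alignment(ids=tuple(ids), rows=tuple(rows)), records, truths


def truth_to_frame(truths: Sequence[TruthEntry]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "id": t.id,
                "species": t.species,
                "taxon_group": t.taxon_group,
                "class_label": t.class_label,
                "sequons": ";".join(f"{p}:{lab}" for p, lab in t.sequons),
                "segments": ";".join(
                    f"{lab}:{s}-{e}" for lab, (s, e) in t.segments.items()
                ),
                "source_id": t.source_id,
            }
            for t in truths
        ],
        columns=["id", "species", "taxon_group", "class_label", "sequons",
                 "segments", "source_id"],
    )


def write_dataset(dataset: SimDataset, outdir: str | Path) -> dict[str, Path]:
    """Write dataset.fasta, taxonomy.tsv and truth.tsv into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "dataset.fasta",
        "taxonomy": outdir / "taxonomy.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_fasta(dataset.records, paths["fasta"])
    write_taxonomy(dataset.taxonomy, paths["taxonomy"])
    write_results_table(truth_to_frame(dataset.truth), paths["truth"])
    return paths
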