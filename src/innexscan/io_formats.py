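"""Readers and writers for the text formats the screen touches.

FASTA carries protein sequences; headers are either ``id|species|taxon_group``
(one file carries its own taxonomy) or a plain id, in which case metadata is
joined from a taxonomy TSV.  Alignments come in as aligned FASTA or Clustal.
All results leave as TSV with a header row.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import AlignIO, SeqIO

VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: characters that would break Newick leaf labels or the header grammar
_FORBIDDEN_ID_CHARS = frozenset("()[]{}:;,| \t")

#: fixed significant digits for every float written to results tables,
#: so re-runs diff byte-for-byte
FLOAT_FORMAT = "%.6g"


class FormatError(ValueError):
    """Malformed input file (FASTA, alignment or TSV)."""


@dataclass(frozen=True)
class ProteinRecord:
    """One candidate protein entering the screen."""

    id: str
    species: str
    taxon_group: str
    sequence: str
    source: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("empty record id")
        bad = set(self.id) & _FORBIDDEN_ID_CHARS
        if bad:
            raise FormatError(
                f"record id {self.id!r} contains forbidden character(s) {sorted(bad)!r}"
            )
        if not self.sequence:
            raise FormatError(f"record {self.id!r} has an empty sequence")
        for pos, aa in enumerate(self.sequence, start=1):
            if aa not in VALID_RESIDUES:
                raise FormatError(
                    f"record {self.id!r}: illegal residue {aa!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TaxonomyTable:
    """Maps record ids to (species, taxon_group)."""

    species: Mapping[str, str]
    taxon_group: Mapping[str, str]

    @property
    def ids(self) -> list[str]:
        return list(self.species)

    @property
    def groups(self) -> list[str]:
        return sorted(set(self.taxon_group.values()))

    def __contains__(self, record_id: str) -> bool:
        return record_id in self.species

    @classmethod
    def from_records(cls, records: Iterable[ProteinRecord]) -> "TaxonomyTable":
        species: dict[str, str] = {}
        group: dict[str, str] = {}
        for rec in records:
            if rec.id in species:
                raise FormatError(f"duplicate id {rec.id!r} in taxonomy")
            species[rec.id] = rec.species
            group[rec.id] = rec.taxon_group
        return cls(species=species, taxon_group=group)

    @classmethod
    def from_rows(cls, rows: Iterable[tuple[str, str, str]]) -> "TaxonomyTable":
        species: dict[str, str] = {}
        group: dict[str, str] = {}
        for rid, sp, grp in rows:
            if rid in species:
                raise FormatError(f"duplicate id {rid!r} in taxonomy")
            species[rid] = sp
            group[rid] = grp
        return cls(species=species, taxon_group=group)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": list(self.species),
                "species": list(self.species.values()),
                "taxon_group": [self.taxon_group[i] for i in self.species],
            }
        )


@dataclass(frozen=True)
class Alignment:
    """A gapped multiple sequence alignment; rows share one length."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.ids:
            raise FormatError("alignment has no rows")
        if len(self.ids) != len(set(self.ids)):
            raise FormatError("alignment has duplicate row ids")
        width = len(self.rows[0])
        for rid, row in zip(self.ids, self.rows):
            if len(row) != width:
                raise FormatError(
                    f"ragged alignment: row {rid!r} has length {len(row)}, expected {width}"
                )

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def row(self, record_id: str) -> str:
        try:
            return self.rows[self.ids.index(record_id)]
        except ValueError:
            raise KeyError(f"id {record_id!r} not in alignment") from None

    def ungapped(self, record_id: str) -> str:
        return self.row(record_id).replace("-", "")


def _normalize_sequence(record_id: str, raw: str) -> str:
    seq = raw.strip().upper()
    if seq.endswith("*"):
        seq = seq[:-1]
    return seq


def read_fasta(path: str | Path, taxonomy: TaxonomyTable | None = None) -> list[ProteinRecord]:
    """Read protein records from FASTA.

    Headers of the form ``id|species|taxon_group`` carry taxonomy inline;
    plain headers require ``taxonomy`` for the metadata join.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        header = entry.description.split()[0] if entry.description else entry.id
        parts = header.split("|")
        if len(parts) == 3:
            rid, species, group = parts
        elif len(parts) == 1:
            rid = parts[0]
            if taxonomy is None or rid not in taxonomy:
                raise FormatError(
                    f"record {rid!r}: plain header but no taxonomy entry to join"
                )
            species = taxonomy.species[rid]
            group = taxonomy.taxon_group[rid]
        else:
            raise FormatError(f"unparseable FASTA header {header!r}")
        if rid in seen:
            raise FormatError(f"duplicate id {rid!r} in {path.name}")
        seen.add(rid)
        seq = _normalize_sequence(rid, str(entry.seq))
        records.append(
            ProteinRecord(id=rid, species=species, taxon_group=group,
                          sequence=seq, source=path.name)
        )
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path,
                inline_taxonomy: bool = True, width: int = 60) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for rec in records:
            header = (
                f"{rec.id}|{rec.species}|{rec.taxon_group}" if inline_taxonomy else rec.id
            )
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_taxonomy(path: str | Path) -> TaxonomyTable:
    """Read a TSV with columns id, species, taxon_group."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"id", "species", "taxon_group"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"taxonomy file missing column(s) {sorted(missing)}")
    return TaxonomyTable.from_rows(
        (str(r.id), str(r.species), str(r.taxon_group)) for r in df.itertuples()
    )


def write_taxonomy(taxonomy: TaxonomyTable, path: str | Path) -> None:
    taxonomy.to_frame().to_csv(path, sep="\t", index=False)


def read_alignment(path: str | Path, dialect: str = "aligned-fasta") -> Alignment:
    """Read an alignment; ``dialect`` is ``aligned-fasta`` or ``clustal``.

    Gap characters '.' are normalized to '-'.
    """
    path = Path(path)
    if dialect == "aligned-fasta":
        ids: list[str] = []
        rows: list[str] = []
        for entry in SeqIO.parse(str(path), "fasta"):
            ids.append(entry.id.split("|")[0])
            rows.append(str(entry.seq).upper().replace(".", "-"))
        if not ids:
            raise FormatError(f"no alignment rows in {path}")
        width = len(rows[0])
        for rid, row in zip(ids, rows):
            if len(row) != width:
                raise FormatError(
                    f"ragged alignment row {rid!r} in {path.name}: "
                    f"length {len(row)} != {width}"
                )
        return Alignment(ids=tuple(ids), rows=tuple(rows))
    if dialect == "clustal":
        try:
            aln = AlignIO.read(str(path), "clustal")
        except ValueError as exc:
            raise FormatError(f"cannot parse {path.name} as Clustal: {exc}") from exc
        return Alignment(
            ids=tuple(r.id for r in aln),
            rows=tuple(str(r.seq).upper().replace(".", "-") for r in aln),
        )
    raise ValueError(f"unknown alignment dialect {dialect!r}")


def write_alignment(alignment: Alignment, path: str | Path,
                    dialect: str = "aligned-fasta") -> None:
    path = Path(path)
    if dialect == "aligned-fasta":
        with path.open("w", encoding="utf-8") as fh:
            for rid, row in zip(alignment.ids, alignment.rows):
                fh.write(f">{rid}\n{row}\n")
        return
    if dialect == "clustal":
        from Bio.Align import MultipleSeqAlignment
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord

        msa = MultipleSeqAlignment(
            SeqRecord(Seq(row), id=rid, description="")
            for rid, row in zip(alignment.ids, alignment.rows)
        )
        AlignIO.write(msa, str(path), "clustal")
        return
    raise ValueError(f"unknown alignment dialect {dialect!r}")


def write_results_table(rows: Sequence[Mapping] | pd.DataFrame, path: str | Path,
                        columns: Sequence[str] | None = None) -> None:
    """Write tabular results as TSV with a header row.

    Column order is ``columns`` if given, else the order of the first row
    (or the DataFrame's own order). Floats use 6 significant digits.
    """
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        df = pd.DataFrame(list(rows))
    if columns is not None:
        df = df.reindex(columns=list(columns))
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_results_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
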