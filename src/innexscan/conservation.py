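"""Sequon conservation across aligned orthologs.

Residue positions are lifted into alignment columns, unreliable columns are
trimmed by a gap-fraction rule, and a group of sequences (typically one
taxonomic group's orthologs) is asked whether any alignment column carries
a passing extracellular sequon in *all* of its members.  "Same site" is
defined strictly as the same alignment column of the asparagine; an
optional +/-1-column tolerance exists but is off by default.

Conservation counts species, not proteins: a species with several isoforms
counts once if any isoform carries the column sequon (configurable).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import Alignment
from .sequon import Sequon


@dataclass(frozen=True)
class ConservationReport:
    """Per-group column counts of passing extracellular sequons."""

    group: str
    n_members: int
    column_counts: dict[int, int]  # alignment column -> members with a passing EL sequon

    @property
    def conserved_columns(self) -> list[int]:
        if self.n_members == 0:
            return []
        return sorted(c for c, n in self.column_counts.items() if n == self.n_members)

    @property
    def group_conserved(self) -> bool:
        return bool(self.conserved_columns)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "group": self.group,
                "column": col,
                "n_with": n,
                "n_members": self.n_members,
                "conserved_all": n == self.n_members and self.n_members > 0,
            }
            for col, n in sorted(self.column_counts.items())
        ]
        return pd.DataFrame(
            rows, columns=["group", "column", "n_with", "n_members", "conserved_all"]
        )


def residue_to_column(gapped_row: str) -> np.ndarray:
    """1-based alignment column of each residue (k-th non-gap character)."""
    cols = np.flatnonzero(np.frombuffer(gapped_row.encode(), dtype=np.uint8) != ord("-")) + 1
    if cols.size == 0:
        raise ValueError("all-gap alignment row has no residues to map")
    return cols


def column_map(alignment: Alignment) -> dict[str, np.ndarray]:
    return {rid: residue_to_column(row) for rid, row in zip(alignment.ids, alignment.rows)}


def trim_columns(alignment: Alignment, max_gap_fraction: float = 0.5,
                 min_block: int = 5) -> tuple[Alignment, list[int]]:
    """Drop gappy columns and short surviving blocks.

    Columns whose gap fraction exceeds ``max_gap_fraction`` are removed;
    runs of surviving columns shorter than ``min_block`` are removed too.
    Returns the trimmed alignment and the kept 1-based column indices, so
    sequon columns can be re-expressed post-trim.
    """
    mat = np.array([list(row) for row in alignment.rows])
    gap_frac = (mat == "-").mean(axis=0)
    keep = gap_frac <= max_gap_fraction
    # drop surviving runs shorter than min_block
    kept_idx = np.flatnonzero(keep)
    blocks: list[list[int]] = []
    for i in kept_idx:
        if blocks and i == blocks[-1][-1] + 1:
            blocks[-1].append(int(i))
        else:
            blocks.append([int(i)])
    final = [i for b in blocks if len(b) >= min_block for i in b]
    if not final:
        raise ValueError("trimming removed every alignment column")
    trimmed = Alignment(
        ids=alignment.ids,
        rows=tuple("".join(row[i] for i in final) for row in alignment.rows),
    )
    return trimmed, [i + 1 for i in final]


def sequon_column_conservation(
    alignment: Alignment,
    sequons_by_id: Mapping[str, Sequence[Sequon]],
    groups: Mapping[str, str],
    species: Mapping[str, str] | None = None,
    col_map: Mapping[str, np.ndarray] | None = None,
    per_species: bool = True,
    tolerance: int = 0,
) -> list[ConservationReport]:
    """Count, per group and alignment column, members with a passing EL sequon there.

    ``groups`` maps member id -> group label; ``species`` maps id -> species
    (required for the default per-species counting).  A member missing from
    the alignment raises ``KeyError``.
    """
    for member in groups:
        if member not in alignment.ids:
            raise KeyError(f"member {member!r} missing from alignment")
    if col_map is None:
        col_map = column_map(alignment)
    if per_species and species is None:
        species = {m: m for m in groups}  # one protein == one species

    # member unit: species name under per_species, else protein id
    def unit(member: str) -> str:
        return species[member] if per_species else member

    group_units: dict[str, set[str]] = {}
    for member, grp in groups.items():
        group_units.setdefault(grp, set()).add(unit(member))

    # columns carrying a passing EL sequon, per member unit
    unit_columns: dict[str, set[int]] = {}
    for member, grp in groups.items():
        cmap = col_map[member]
        for s in sequons_by_id.get(member, ()):
            if not s.passes:
                continue
            if s.n_position < 1 or s.n_position > len(cmap):
                raise ValueError(
                    f"sequon position {s.n_position} outside ungapped row of {member!r}"
                )
            col = int(cmap[s.n_position - 1])
            for c in range(col - tolerance, col + tolerance + 1):
                unit_columns.setdefault(unit(member), set()).add(c)

    reports: list[ConservationReport] = []
    for grp in sorted(group_units):
        units = group_units[grp]
        counts: dict[int, int] = {}
        for u in units:
            for c in unit_columns.get(u, ()):
                counts[c] = counts.get(c, 0) + 1
        reports.append(
            ConservationReport(group=grp, n_members=len(units), column_counts=counts)
        )
    return reports


def restrict_reports(reports: Sequence[ConservationReport],
                     kept_columns: Sequence[int]) -> list[ConservationReport]:
    """Drop counts at trimmed-away columns (column indices stay original)."""
    kept = set(kept_columns)
    return [
        ConservationReport(
            group=r.group, n_members=r.n_members,
            column_counts={c: n for c, n in r.column_counts.items() if c in kept},
        )
        for r in reports
    ]


def reports_to_frame(reports: Sequence[ConservationReport]) -> pd.DataFrame:
    """Concatenated per-column rows plus one summary row per group."""
    frames = [r.to_frame() for r in reports]
    summary = pd.DataFrame(
        [
            {
                "group": r.group,
                "column": -1,
                "n_with": len(r.conserved_columns),
                "n_members": r.n_members,
                "conserved_all": r.group_conserved,
            }
            for r in reports
        ],
        columns=["group", "column", "n_with", "n_members", "conserved_all"],
    )
    return pd.concat(frames + [summary], ignore_index=True)
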