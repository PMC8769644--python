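"""Per-protein inclusion screen.

A candidate enters the analysis only if it (a) presents the family's
four-TM topology, (b) is not a fragment, and (c) is not a duplicate entry.
Family membership itself (criterion satisfied upstream by homology search)
is an input contract: the FASTA is assumed to contain candidate family
members.  All three checks run on every record so each rule can be audited
independently; an accepted record then gets its extracellular sequons
localized and scored.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .io_formats import ProteinRecord, TaxonomyTable
from .sequon import DEFAULT_RULES, Sequon, SequonRules, scan_protein
from .topology import TopologyError, TopologyModel, infer_topology

logger = logging.getLogger(__name__)

REASON_CODES = ("NOT_FOUR_TM", "FRAGMENT", "DUPLICATE")


@dataclass(frozen=True)
class ScreenConfig:
    """All tunables of the per-record screen."""

    window: int = 19
    tm_threshold: float = 1.6
    tm_min_len: int = 15
    tm_merge_gap: int = 3
    tm_max_len: int = 35
    min_length: int = 200  # records shorter than this are fragments
    sequon_rules: SequonRules = DEFAULT_RULES


@dataclass(frozen=True)
class ScreenVerdict:
    protein_id: str
    species: str
    taxon_group: str
    status: str  # ACCEPTED or REJECTED
    reason_codes: tuple[str, ...]
    topology: TopologyModel | None
    sequons: tuple[Sequon, ...]
    has_el_ngs: bool

    def __post_init__(self) -> None:
        if (self.status == "REJECTED") != bool(self.reason_codes):
            raise ValueError("status REJECTED iff reason codes present")
        if self.status == "REJECTED" and self.sequons:
            raise ValueError("rejected verdicts carry no sequons")
        if self.has_el_ngs != any(s.passes for s in self.sequons):
            raise ValueError("has_el_ngs inconsistent with sequon pass flags")


def detect_duplicates(records: Sequence[ProteinRecord]) -> set[str]:
    """Ids of within-species exact sequence duplicates.

    In each species, records sharing an identical sequence form a group and
    all but the lexicographically smallest id are flagged.
    """
    groups: dict[tuple[str, str], list[str]] = defaultdict(list)
    for rec in records:
        groups[(rec.species, rec.sequence)].append(rec.id)
    flagged: set[str] = set()
    for ids in groups.values():
        if len(ids) > 1:
            flagged.update(sorted(ids)[1:])
    return flagged


def screen_record(record: ProteinRecord, config: ScreenConfig = ScreenConfig(),
                  duplicate_flags: frozenset[str] | set[str] = frozenset()) -> ScreenVerdict:
    """Apply all inclusion rules to one record; reasons accumulate."""
    reasons: list[str] = []
    topology: TopologyModel | None = None
    if record.id in duplicate_flags:
        reasons.append("DUPLICATE")
    if len(record) < config.min_length:
        reasons.append("FRAGMENT")
    if len(record) < config.window:
        reasons.append("NOT_FOUR_TM")
    else:
        try:
            topology = infer_topology(
                record.sequence, window=config.window,
                threshold=config.tm_threshold, min_len=config.tm_min_len,
                merge_gap=config.tm_merge_gap, max_len=config.tm_max_len,
            )
        except TopologyError:
            reasons.append("NOT_FOUR_TM")
    ordered = tuple(r for r in REASON_CODES if r in reasons)
    if ordered:
        return ScreenVerdict(
            protein_id=record.id, species=record.species,
            taxon_group=record.taxon_group, status="REJECTED",
            reason_codes=ordered, topology=topology, sequons=(),
            has_el_ngs=False,
        )
    assert topology is not None
    sequons = tuple(scan_protein(record.id, record.sequence, topology,
                                 config.sequon_rules))
    return ScreenVerdict(
        protein_id=record.id, species=record.species,
        taxon_group=record.taxon_group, status="ACCEPTED", reason_codes=(),
        topology=topology, sequons=sequons,
        has_el_ngs=any(s.passes for s in sequons),
    )


def screen_dataset(records: Sequence[ProteinRecord],
                   taxonomy: TaxonomyTable | None = None,
                   config: ScreenConfig = ScreenConfig()) -> list[ScreenVerdict]:
    """Screen every record, in input order, deterministically."""
    if not records:
        raise ValueError("empty record list: nothing to screen")
    if taxonomy is not None:
        for rec in records:
            if rec.id not in taxonomy:
                raise KeyError(f"record {rec.id!r} missing from taxonomy")
    duplicates = detect_duplicates(records)
    verdicts = [screen_record(rec, config, duplicates) for rec in records]
    n_acc = sum(v.status == "ACCEPTED" for v in verdicts)
    by_reason = {
        code: sum(code in v.reason_codes for v in verdicts) for code in REASON_CODES
    }
    n_ngs = sum(v.has_el_ngs for v in verdicts)
    logger.info(
        "screened %d records: %d accepted, rejected by reason %s, %d with EL NGS",
        len(records), n_acc, by_reason, n_ngs,
    )
    return verdicts


def verdicts_to_frame(verdicts: Iterable[ScreenVerdict]) -> pd.DataFrame:
    """Flat verdict table as written to the results TSV."""
    rows = []
    for v in verdicts:
        rows.append(
            {
                "protein_id": v.protein_id,
                "species": v.species,
                "taxon_group": v.taxon_group,
                "status": v.status,
                "reason_codes": ",".join(v.reason_codes),
                "n_sequons_total": len(v.sequons),
                "n_sequons_el": sum(s.loop_label in ("EL1", "EL2") for s in v.sequons),
                "has_el_ngs": v.has_el_ngs,
                "topology": v.topology.to_string() if v.topology else "",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "protein_id", "species", "taxon_group", "status", "reason_codes",
            "n_sequons_total", "n_sequons_el", "has_el_ngs", "topology",
        ],
    )


def verdicts_from_frames(verdict_df: pd.DataFrame,
                         sequon_df: pd.DataFrame | None = None
                         ) -> dict[str, ScreenVerdict]:
    """Rebuild verdict objects from the flat TSV tables (topology omitted)."""
    sequons_by_id: dict[str, list[Sequon]] = defaultdict(list)
    if sequon_df is not None:
        for row in sequon_df.itertuples():
            sequons_by_id[str(row.protein_id)].append(
                Sequon(protein_id=str(row.protein_id),
                       n_position=int(row.n_position), triplet=str(row.triplet),
                       loop_label=str(row.loop_label),
                       occupancy_score=float(row.score), passes=bool(row.passes))
            )
    out: dict[str, ScreenVerdict] = {}
    for row in verdict_df.itertuples():
        pid = str(row.protein_id)
        reasons = tuple(
            c for c in str(row.reason_codes).split(",") if c
        ) if isinstance(row.reason_codes, str) else ()
        sequons = tuple(sequons_by_id.get(pid, ()))
        out[pid] = ScreenVerdict(
            protein_id=pid, species=str(row.species),
            taxon_group=str(row.taxon_group), status=str(row.status),
            reason_codes=reasons, topology=None, sequons=sequons,
            has_el_ngs=any(s.passes for s in sequons),
        )
    return out


def sequons_to_frame(verdicts: Iterable[ScreenVerdict]) -> pd.DataFrame:
    """Flat sequon table (accepted records only, one row per site)."""
    rows = []
    for v in verdicts:
        for s in v.sequons:
            rows.append(
                {
                    "protein_id": s.protein_id,
                    "n_position": s.n_position,
                    "triplet": s.triplet,
                    "loop_label": s.loop_label,
                    "score": s.occupancy_score,
                    "passes": s.passes,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["protein_id", "n_position", "triplet", "loop_label", "score", "passes"],
    )
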