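"""Taxon-level summaries of the screen.

For each higher-level taxonomic group: how many species and accepted
proteins it contributed, what fraction of those proteins carries at least
one passing extracellular sequon, and the mean number of isoforms per
species.  Also the combinatorial upper bound on heteromeric hemichannel
diversity: a hemichannel is an oligomer of eight innexins (or six
connexins), so N co-expressed isoforms admit up to N^8 (or N^6) ordered
subunit arrangements.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .io_formats import TaxonomyTable
from .screening import ScreenVerdict, verdicts_to_frame

logger = logging.getLogger(__name__)

INNEXIN_SUBUNITS = 8
CONNEXIN_SUBUNITS = 6


@dataclass(frozen=True)
class CladeSummary:
    taxon_group: str
    n_species: int
    n_proteins: int            # accepted only
    n_with_el_ngs: int
    fraction_with_el_ngs: float  # NaN when no accepted proteins
    mean_isoforms_per_species: float  # NaN when no species sampled

    def __post_init__(self) -> None:
        if self.n_with_el_ngs > self.n_proteins:
            raise ValueError("n_with_el_ngs exceeds n_proteins")


def _as_frame(verdicts: Sequence[ScreenVerdict] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(verdicts, pd.DataFrame):
        return verdicts
    return verdicts_to_frame(verdicts)


def summarize_by_taxon(verdicts: Sequence[ScreenVerdict] | pd.DataFrame,
                       taxonomy: TaxonomyTable) -> list[CladeSummary]:
    """One summary row per taxon group present in the taxonomy, sorted by name.

    Only ACCEPTED verdicts enter the counts; the species denominator is the
    number of distinct species the taxonomy lists for the group (the sampled
    species), so a species whose every record was rejected still counts.
    """
    df = _as_frame(verdicts)
    accepted = df[df["status"] == "ACCEPTED"]
    tax = taxonomy.to_frame()
    out: list[CladeSummary] = []
    for group, tax_grp in tax.groupby("taxon_group", sort=True):
        n_species = tax_grp["species"].nunique()
        acc = accepted[accepted["taxon_group"] == group]
        n_proteins = len(acc)
        n_with = int(acc["has_el_ngs"].sum())
        fraction = n_with / n_proteins if n_proteins else math.nan
        mean_iso = n_proteins / n_species if n_species else math.nan
        out.append(
            CladeSummary(
                taxon_group=str(group), n_species=int(n_species),
                n_proteins=n_proteins, n_with_el_ngs=n_with,
                fraction_with_el_ngs=fraction,
                mean_isoforms_per_species=mean_iso,
            )
        )
    return out


def summaries_to_frame(summaries: Iterable[CladeSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "taxon_group": s.taxon_group,
                "n_species": s.n_species,
                "n_proteins": s.n_proteins,
                "n_with_el_ngs": s.n_with_el_ngs,
                "fraction_with_el_ngs": s.fraction_with_el_ngs,
                "mean_isoforms_per_species": s.mean_isoforms_per_species,
            }
            for s in summaries
        ],
        columns=[
            "taxon_group", "n_species", "n_proteins", "n_with_el_ngs",
            "fraction_with_el_ngs", "mean_isoforms_per_species",
        ],
    )


def species_ngs_universality(verdicts: Sequence[ScreenVerdict] | pd.DataFrame,
                             taxonomy: TaxonomyTable) -> dict[str, bool]:
    """Per taxon group: does every accepted protein of every species carry a
    passing extracellular sequon?  Empty groups are vacuously true."""
    df = _as_frame(verdicts)
    accepted = df[df["status"] == "ACCEPTED"]
    out: dict[str, bool] = {}
    for group in taxonomy.groups:
        acc = accepted[accepted["taxon_group"] == group]
        if acc.empty:
            logger.warning("taxon group %r has no accepted proteins; "
                           "universality is vacuously true", group)
            out[group] = True
        else:
            out[group] = bool(acc["has_el_ngs"].all())
    return out


def hemichannel_diversity(n_isoforms: int, subunits: int = INNEXIN_SUBUNITS) -> int:
    """Upper bound on distinct heteromeric hemichannels from N isoforms.

    Counts ordered subunit arrangements, N**subunits, in exact integer
    arithmetic: 8 subunits per innexin hemichannel, 6 per connexin one.
    """
    if n_isoforms < 1:
        raise ValueError(f"n_isoforms must be >= 1, got {n_isoforms}")
    if subunits < 1:
        raise ValueError(f"subunits must be >= 1, got {subunits}")
    return n_isoforms ** subunits
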