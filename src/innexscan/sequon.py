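"""N-glycosylation sequon detection and extracellular-loop restriction.

A sequon is the consensus motif Asn-X-Ser/Thr with X any residue except
proline; the glycan attaches at the asparagine.  Only sequons whose Asn
falls inside one of the two extracellular loops (EL1, EL2) can be occupied
on a plasma-membrane protein, so the screen keeps exactly those, and only
when a rule-based occupancy score exceeds 0.5 (strict inequality).

The score is a transparent surrogate for neural-network occupancy
predictors: it starts from a base potential and applies the main sequence
determinants of occupancy reported in the glycobiology literature -- an
N-X-T sequon is more efficiently occupied than N-X-S, a proline immediately
after the sequon suppresses transfer, and membrane-proximal sequons are
sterically disfavoured.  The rule table is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

from .topology import EXTRACELLULAR_LOOPS, TopologyModel


@dataclass(frozen=True)
class SequonRules:
    """Configurable rule table for the surrogate occupancy score."""

    base: float = 0.55
    threonine_bonus: float = 0.15        # sequon is N-X-T rather than N-X-S
    proline_after_penalty: float = 0.25  # proline at position N+3
    membrane_penalty: float = 0.10       # Asn within `membrane_margin` of a TM boundary
    membrane_margin: int = 3
    threshold: float = 0.5               # strict: score must exceed this


DEFAULT_RULES = SequonRules()


@dataclass(frozen=True)
class Sequon:
    """One N-X-S/T site with its loop assignment and occupancy call."""

    protein_id: str
    n_position: int  # 1-based index of the Asn
    triplet: str
    loop_label: str  # EL1, EL2 or NONE
    occupancy_score: float
    passes: bool

    def __post_init__(self) -> None:
        if len(self.triplet) != 3 or self.triplet[0] != "N":
            raise ValueError(f"invalid sequon triplet {self.triplet!r}")
        if self.triplet[1] == "P" or self.triplet[2] not in "ST":
            raise ValueError(f"invalid sequon triplet {self.triplet!r}")


def find_sequons(sequence: str) -> list[tuple[int, str]]:
    """All N-X-S/T motifs (X != P) as (1-based Asn position, triplet).

    Overlapping motifs are all reported; positions are strictly increasing.
    """
    hits: list[tuple[int, str]] = []
    for i in range(len(sequence) - 2):
        if (
            sequence[i] == "N"
            and sequence[i + 1] != "P"
            and sequence[i + 2] in "ST"
        ):
            hits.append((i + 1, sequence[i : i + 3]))
    return hits


def localize_sequons(sequons: Sequence[tuple[int, str]],
                     topology: TopologyModel) -> list[str]:
    """Loop label for each sequon: EL1/EL2 if the Asn lies in that loop, else NONE.

    The Asn residue alone decides membership; the triplet may straddle a
    segment boundary.
    """
    labels: list[str] = []
    for n_pos, _triplet in sequons:
        seg = topology.segment_of(n_pos)  # raises if outside the span
        labels.append(seg.label if seg.label in EXTRACELLULAR_LOOPS else "NONE")
    return labels


def occupancy_score(sequence: str, n_position: int, topology: TopologyModel,
                    rules: SequonRules = DEFAULT_RULES) -> float:
    """Rule-based occupancy potential in [0, 1] for the sequon at ``n_position``."""
    i = n_position - 1
    if (
        i < 0
        or i + 2 >= len(sequence)
        or sequence[i] != "N"
        or sequence[i + 1] == "P"
        or sequence[i + 2] not in "ST"
    ):
        raise ValueError(f"no valid sequon at position {n_position}")
    score = rules.base
    if sequence[i + 2] == "T":
        score += rules.threonine_bonus
    if i + 3 < len(sequence) and sequence[i + 3] == "P":
        score -= rules.proline_after_penalty
    if any(abs(n_position - b) <= rules.membrane_margin
           for b in topology.tm_boundaries()):
        score -= rules.membrane_penalty
    return min(1.0, max(0.0, score))


def scan_protein(protein_id: str, sequence: str, topology: TopologyModel,
                 rules: SequonRules = DEFAULT_RULES) -> list[Sequon]:
    """Find, localize and score every sequon of one protein."""
    pairs = find_sequons(sequence)
    labels = localize_sequons(pairs, topology)
    out: list[Sequon] = []
    for (n_pos, triplet), label in zip(pairs, labels):
        score = occupancy_score(sequence, n_pos, topology, rules)
        passes = label in EXTRACELLULAR_LOOPS and score > rules.threshold
        out.append(
            Sequon(protein_id=protein_id, n_position=n_pos, triplet=triplet,
                   loop_label=label, occupancy_score=score, passes=passes)
        )
    return out


def count_loop_cysteines(sequence: str, topology: TopologyModel) -> tuple[int, int]:
    """Cysteine counts in (EL1, EL2); the loop cysteines form the docking disulfides."""
    counts = []
    for label in EXTRACELLULAR_LOOPS:
        span = topology.span(label)
        if span is None:
            counts.append(0)
        else:
            s, e = span
            counts.append(sequence[s - 1 : e].count("C"))
    return (counts[0], counts[1])
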