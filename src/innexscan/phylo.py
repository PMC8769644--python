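"""Desk-scale distance trees and presence/absence leaf annotation.

The tree is a visualization scaffold: leaves are screened proteins, and the
annotation export marks each leaf red (carries a passing extracellular
sequon) or black (does not), with per-loop bars, for external tree viewers.
Trees are built by neighbor joining on p-distances with deterministic
tie-breaking, so outputs are reproducible byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .io_formats import Alignment
from .screening import ScreenVerdict


@dataclass(frozen=True)
class DistanceMatrix:
    ids: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.matrix.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.matrix), 0.0):
            raise ValueError("distance matrix diagonal not zero")
        if (self.matrix < 0).any():
            raise ValueError("negative distances")

    def get(self, a: str, b: str) -> float:
        return float(self.matrix[self.ids.index(a), self.ids.index(b)])


def p_distance(alignment: Alignment) -> DistanceMatrix:
    """Pairwise fraction of mismatches over mutually non-gap columns."""
    if alignment.n_rows < 2:
        raise ValueError("p-distance needs at least two rows")
    mat = np.array([list(row) for row in alignment.rows])
    gaps = mat == "-"
    n = alignment.n_rows
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ~(gaps[i] | gaps[j])
            n_sites = int(both.sum())
            if n_sites == 0:
                raise ValueError(
                    f"rows {alignment.ids[i]!r} and {alignment.ids[j]!r} share "
                    "no comparable columns"
                )
            mism = int((mat[i, both] != mat[j, both]).sum())
            out[i, j] = out[j, i] = mism / n_sites
    return DistanceMatrix(ids=alignment.ids, matrix=out)


def _fmt(x: float) -> str:
    return f"{x:.6g}"


def nj_tree(dm: DistanceMatrix) -> str:
    """Neighbor-joining tree as a Newick string with branch lengths.

    Q-criterion ties are broken by the lexicographically smallest pair of
    clade keys (the smallest leaf id under each node), so the output is
    deterministic.  Negative branch lengths are clamped to zero with the
    deficit moved to the sister branch.
    """
    n0 = len(dm.ids)
    if n0 < 3:
        raise ValueError("neighbor joining needs at least three taxa")
    # active nodes: key (smallest leaf id in clade) -> newick substring
    newick: dict[str, str] = {rid: rid for rid in dm.ids}
    d: dict[frozenset[str], float] = {}
    for i in range(n0):
        for j in range(i + 1, n0):
            d[frozenset((dm.ids[i], dm.ids[j]))] = float(dm.matrix[i, j])
    active = sorted(dm.ids)

    def dist(a: str, b: str) -> float:
        return d[frozenset((a, b))]

    while len(active) > 3:
        n = len(active)
        r = {a: sum(dist(a, b) for b in active if b != a) for a in active}
        best: tuple[str, str] | None = None
        best_q = np.inf
        for ii in range(n):
            for jj in range(ii + 1, n):
                a, b = active[ii], active[jj]
                q = (n - 2) * dist(a, b) - r[a] - r[b]
                if q < best_q:
                    best_q, best = q, (a, b)
        assert best is not None
        a, b = best
        dab = dist(a, b)
        la = dab / 2 + (r[a] - r[b]) / (2 * (n - 2))
        lb = dab - la
        if la < 0:
            la, lb = 0.0, dab
        elif lb < 0:
            la, lb = dab, 0.0
        key = min(a, b)
        merged = f"({newick[a]}:{_fmt(la)},{newick[b]}:{_fmt(lb)})"
        for u in active:
            if u in (a, b):
                continue
            d[frozenset((u, key))] = (dist(u, a) + dist(u, b) - dab) / 2
        active = sorted(set(active) - {a, b} | {key})
        newick[key] = merged

    a, b, c = active  # already sorted
    dab, dac, dbc = dist(a, b), dist(a, c), dist(b, c)
    la = max(0.0, (dab + dac - dbc) / 2)
    lb = max(0.0, (dab + dbc - dac) / 2)
    lc = max(0.0, (dac + dbc - dab) / 2)
    return (
        f"({newick[a]}:{_fmt(la)},{newick[b]}:{_fmt(lb)},{newick[c]}:{_fmt(lc)});"
    )


def _bipartitions(newick: str) -> tuple[frozenset[str], set[frozenset[str]]]:
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)
    leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    ref = min(leaves)
    n = len(leaves)
    parts: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        clade = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if 1 < len(clade) < n - 1:
            side = clade if ref not in clade else leaves - clade
            parts.add(side)
    return leaves, parts


def robinson_foulds(newick1: str, newick2: str) -> int:
    """Symmetric-difference count of non-trivial bipartitions."""
    leaves1, parts1 = _bipartitions(newick1)
    leaves2, parts2 = _bipartitions(newick2)
    if leaves1 != leaves2:
        raise ValueError("trees have different leaf sets")
    return len(parts1 ^ parts2)


def annotate_tree(newick: str, verdicts: Iterable[ScreenVerdict] | Mapping[str, ScreenVerdict]
                  ) -> pd.DataFrame:
    """One annotation row per leaf: red/black class, EL1/EL2 bars, taxon group."""
    if not isinstance(verdicts, Mapping):
        verdicts = {v.protein_id: v for v in verdicts}
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)
    rows = []
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label
        if label not in verdicts:
            raise KeyError(f"leaf {label!r} has no screening verdict")
        v = verdicts[label]
        rows.append(
            {
                "leaf": label,
                "color_class": "red" if v.has_el_ngs else "black",
                "el1_bar": any(s.passes and s.loop_label == "EL1" for s in v.sequons),
                "el2_bar": any(s.passes and s.loop_label == "EL2" for s in v.sequons),
                "taxon_group": v.taxon_group,
            }
        )
    return pd.DataFrame(
        rows, columns=["leaf", "color_class", "el1_bar", "el2_bar", "taxon_group"]
    )


def random_binary_tree(n_taxa: int, rng: np.random.Generator,
                       min_branch: float = 0.05, max_branch: float = 0.5
                       ) -> tuple[str, DistanceMatrix]:
    """A random binary tree with positive branch lengths and its additive
    leaf-to-leaf distance matrix (a noise-free oracle for tree estimators)."""
    if n_taxa < 3:
        raise ValueError("need at least three taxa")
    ids = [f"t{i:02d}" for i in range(n_taxa)]
    # each active subtree: (newick substring, {leaf: distance to subtree root})
    subtrees: list[tuple[str, dict[str, float]]] = [(rid, {rid: 0.0}) for rid in ids]
    dist: dict[frozenset[str], float] = {}
    while len(subtrees) > 1:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        (nw_i, di) = subtrees[i]
        (nw_j, dj) = subtrees[j]
        bi, bj = rng.uniform(min_branch, max_branch, size=2)
        for x, dx in di.items():
            for y, dy in dj.items():
                dist[frozenset((x, y))] = dx + bi + dy + bj
        merged_nw = f"({nw_i}:{_fmt(bi)},{nw_j}:{_fmt(bj)})"
        merged_d = {x: dx + bi for x, dx in di.items()}
        merged_d.update({y: dy + bj for y, dy in dj.items()})
        subtrees = [s for k, s in enumerate(subtrees) if k not in (i, j)]
        subtrees.append((merged_nw, merged_d))
    newick = subtrees[0][0] + ";"
    mat = np.zeros((n_taxa, n_taxa))
    for i in range(n_taxa):
        for j in range(i + 1, n_taxa):
            mat[i, j] = mat[j, i] = dist[frozenset((ids[i], ids[j]))]
    return newick, DistanceMatrix(ids=tuple(ids), matrix=mat)
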