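"""Distance trees and trans-species polymorphism (TSP) screening.

MHC allelic lineages are frequently older than the species carrying them:
balancing selection preserves them across speciation events, so an allele
may sit closer to another species' allele than to any conspecific one.
This module builds neighbor-joining trees from the grouping module's
distance matrices and screens for the TSP pattern with a nearest-neighbor
criterion on the same matrix: an allele is flagged when its nearest
foreign-species allele is strictly closer than its nearest conspecific
allele.  This is a distance proxy for the clade-reading argument usually
made on a phylogeny; borderline alleles can differ between the two.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from skbio import DistanceMatrix as SkbioDM
from skbio.tree import TreeNode, nj

from .grouping import DistanceMatrix

logger = logging.getLogger("mhcrep")

__all__ = ["TspCall", "nj_tree", "tsp_screen", "write_newick"]


@dataclass
class TspCall:
    allele: str
    species: str
    nearest_foreign: str | None
    foreign_distance: float
    nearest_conspecific: str | None
    conspecific_distance: float
    tsp: bool | None  # None when undecidable (no conspecific comparator)


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree from a complete distance matrix (n >= 3).

    Taxa are ordered by label before joining so distance ties resolve
    deterministically; negative branch-length estimates are clamped to zero
    (logged).  Returns an unrooted scikit-bio tree.
    """
    if np.isnan(dm.matrix).any():
        raise ValueError("distance matrix contains missing values")
    if len(dm.names) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    order = sorted(range(len(dm.names)), key=lambda i: dm.names[i])
    names = [dm.names[i] for i in order]
    mat = dm.matrix[np.ix_(order, order)]
    tree = nj(SkbioDM(mat, ids=names))
    clamped = 0
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
            clamped += 1
    if clamped:
        logger.info("clamped %d negative branch lengths to 0", clamped)
    return tree


def write_newick(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


def tsp_screen(
    dm: DistanceMatrix,
    species_map: Mapping[str, str],
    groups: Mapping[str, str] | None = None,
) -> tuple[list[TspCall], dict]:
    """Nearest-neighbor screen for trans-species polymorphism.

    ``species_map`` assigns every allele in ``dm`` to a species.  For each
    allele the nearest foreign-species and nearest conspecific distances
    are compared; ``tsp=True`` when the foreign one is strictly smaller
    (a distance of exactly zero to a foreign allele also flags).  Alleles
    whose species has no other allele get ``tsp=None``.  The summary counts
    flagged alleles, optionally broken down by allele group.
    """
    missing = [n for n in dm.names if n not in species_map]
    if missing:
        raise ValueError(f"alleles without species tag: {missing[:5]}")
    if len(set(species_map[n] for n in dm.names)) < 2:
        raise ValueError("TSP screening needs alleles from at least 2 species")

    calls: list[TspCall] = []
    for i, name in enumerate(dm.names):
        sp = species_map[name]
        foreign = [(dm.matrix[i, j], dm.names[j]) for j, m in enumerate(dm.names)
                   if j != i and species_map[m] != sp]
        conspec = [(dm.matrix[i, j], dm.names[j]) for j, m in enumerate(dm.names)
                   if j != i and species_map[m] == sp]
        fd, fn = min(foreign, key=lambda t: (t[0], t[1])) if foreign else (float("nan"), None)
        cd, cn = min(conspec, key=lambda t: (t[0], t[1])) if conspec else (float("nan"), None)
        tsp: bool | None
        if cn is None:
            tsp = None
        else:
            tsp = bool(fd < cd)
        calls.append(TspCall(name, sp, fn, fd, cn, cd, tsp))

    flagged = [c.allele for c in calls if c.tsp]
    summary: dict = {"n_flagged": len(flagged), "flagged": flagged}
    if groups is not None:
        by_group: dict[str, list[str]] = {}
        for call in calls:
            if call.tsp:
                by_group.setdefault(groups.get(call.allele, "ungrouped"), []).append(
                    call.allele
                )
        summary["by_group"] = by_group
    return calls, summary


def write_tsp_table(calls: Sequence[TspCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "allele\tspecies\tnearest_foreign\tforeign_distance\t"
            "nearest_conspecific\tconspecific_distance\ttsp\n"
        )
        for c in calls:
            tsp = "NA" if c.tsp is None else str(int(c.tsp))
            fh.write(
                f"{c.allele}\t{c.species}\t{c.nearest_foreign}\t{c.foreign_distance:.6f}\t"
                f"{c.nearest_conspecific}\t{c.conspecific_distance:.6f}\t{tsp}\n"
            )
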