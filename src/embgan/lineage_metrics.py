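"""Lineage trees and comparison statistics.

A lineage tree maps Sulston-style cell names ("AB", "ABa", "ABpl", ...) to
birth and division times; the cell-cycle duration of a divided cell is the
interval between its birth and its division. Three statistics compare trees:

* **branch distance** - the L2 norm between identically ordered vectors of
  cell-cycle durations over the cells present (with completed cycles) in
  both trees; optionally restricted to a named sublineage.
* **global clock ratio** - the fold-difference in overall developmental rate
  between two embryos, read off the first principal component of the paired
  duration scatter (a nonparametric slope estimate: robust to which embryo
  is called "x" and which "y").
* **variability comparison** - intra-group pairwise branch distances for two
  groups of embryos, summarized by medians and a two-sided rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import ranksums

from .trackgraph import TrackGraph

__all__ = [
    "Cell",
    "LineageTree",
    "BranchDistanceResult",
    "cycle_vector",
    "branch_distance",
    "global_clock_ratio",
    "compare_variability",
    "pairwise_branch_distances",
    "lineage_tree_from_track_graph",
]


@dataclass
class Cell:
    name: str
    birth: float
    end: float  # division time if the cell divides, else last observed time
    parent: str | None = None
    daughters: tuple[str, ...] = ()

    @property
    def divided(self) -> bool:
        return len(self.daughters) == 2

    @property
    def duration(self) -> float:
        return self.end - self.birth


class LineageTree:
    """Named binary tree of cells with birth/division times (minutes)."""

    def __init__(self):
        self.cells: dict[str, Cell] = {}

    def add_cell(
        self,
        name: str,
        birth: float,
        end: float,
        parent: str | None = None,
    ) -> Cell:
        if name in self.cells:
            raise ValueError(f"duplicate cell name {name!r}")
        if end < birth:
            raise ValueError(f"cell {name!r} ends ({end}) before its birth ({birth})")
        cell = Cell(name, float(birth), float(end), parent)
        if parent is not None:
            pc = self.cells[parent]
            if len(pc.daughters) >= 2:
                raise ValueError(f"cell {parent!r} already has two daughters")
            pc.daughters = pc.daughters + (name,)
        self.cells[name] = cell
        return cell

    def __contains__(self, name: str) -> bool:
        return name in self.cells

    def __len__(self) -> int:
        return len(self.cells)

    @property
    def root(self) -> Cell:
        roots = [c for c in self.cells.values() if c.parent is None]
        if len(roots) != 1:
            raise ValueError(f"tree has {len(roots)} roots")
        return roots[0]

    def leaves(self) -> list[str]:
        return sorted(n for n, c in self.cells.items() if not c.daughters)

    def completed_cells(self) -> list[str]:
        """Names of cells with a completed cycle (i.e. observed to divide)."""
        return sorted(n for n, c in self.cells.items() if c.divided)

    def cycle_duration(self, name: str) -> float:
        cell = self.cells[name]
        if not cell.divided:
            raise ValueError(f"cell {name!r} has no completed cycle")
        return cell.duration

    def end_time(self) -> float:
        return max(c.end for c in self.cells.values())

    def validate(self) -> None:
        for c in self.cells.values():
            for d in c.daughters:
                if abs(self.cells[d].birth - c.end) > 1e-9:
                    raise ValueError(
                        f"daughter {d!r} born at {self.cells[d].birth}, but parent "
                        f"{c.name!r} divides at {c.end}"
                    )


@dataclass
class BranchDistanceResult:
    value: float
    n_matched_cells: int
    cell_names: list[str] = field(default_factory=list)


def cycle_vector(tree: LineageTree, cell_names: list[str]) -> np.ndarray:
    """Cell-cycle durations in the given order; errors on missing cells."""
    missing = [n for n in cell_names if n not in tree or not tree.cells[n].divided]
    if missing:
        raise KeyError(f"cells without completed cycles in tree: {missing}")
    return np.array([tree.cycle_duration(n) for n in cell_names], dtype=np.float64)


def _shared_cells(
    tree_a: LineageTree, tree_b: LineageTree, restrict_to_lineage: str | None
) -> list[str]:
    shared = set(tree_a.completed_cells()) & set(tree_b.completed_cells())
    if restrict_to_lineage is not None:
        shared = {n for n in shared if n.startswith(restrict_to_lineage)}
    # lexicographic order on Sulston names: any fixed shared order gives the
    # same L2, this one is reproducible
    return sorted(shared)


def branch_distance(
    tree_a: LineageTree,
    tree_b: LineageTree,
    restrict_to_lineage: str | None = None,
) -> BranchDistanceResult:
    """L2 distance between matched cell-cycle duration vectors.

    Only cells with completed cycles in *both* trees enter the comparison;
    an empty intersection is an error, not a zero distance.
    """
    names = _shared_cells(tree_a, tree_b, restrict_to_lineage)
    if not names:
        raise ValueError(
            "no cells with completed cycles are shared between the two trees"
            + (f" within lineage {restrict_to_lineage!r}" if restrict_to_lineage else "")
        )
    va = cycle_vector(tree_a, names)
    vb = cycle_vector(tree_b, names)
    return BranchDistanceResult(
        value=float(np.linalg.norm(va - vb)),
        n_matched_cells=len(names),
        cell_names=names,
    )


def global_clock_ratio(tree_a: LineageTree, tree_b: LineageTree) -> float:
    """Fold-difference in developmental rate of B relative to A.

    Matched cell-cycle durations are paired as 2D points (a_i, b_i); the
    first principal component of the centered (unstandardized) scatter gives
    a nonparametric slope whose B-loading over A-loading is the returned
    ratio, sign-normalized positive. Satisfies ratio(A,B) * ratio(B,A) = 1.
    """
    names = _shared_cells(tree_a, tree_b, None)
    if len(names) < 2:
        raise ValueError("need at least 2 matched cells with completed cycles")
    a = cycle_vector(tree_a, names)
    b = cycle_vector(tree_b, names)
    pts = np.stack([a - a.mean(), b - b.mean()], axis=1)
    cov = pts.T @ pts
    if not np.any(cov):
        raise ValueError("degenerate scatter: matched durations have zero variance")
    evals, evecs = np.linalg.eigh(cov)
    pc1 = evecs[:, np.argmax(evals)]
    if pc1[0] == 0.0:
        raise ValueError("degenerate scatter: no variance along the first tree")
    return float(abs(pc1[1] / pc1[0]))


def pairwise_branch_distances(
    trees: list[LineageTree], restrict_to_lineage: str | None = None
) -> np.ndarray:
    """All unordered within-group pairwise branch distances."""
    out = []
    for i in range(len(trees)):
        for j in range(i + 1, len(trees)):
            out.append(branch_distance(trees[i], trees[j], restrict_to_lineage).value)
    return np.array(out, dtype=np.float64)


def compare_variability(
    group_a: list[LineageTree],
    group_b: list[LineageTree],
    lineages: list[str] | None = None,
) -> pd.DataFrame:
    """Compare intra-group lineage variability between two groups of embryos.

    For each requested lineage (and for the whole tree when ``lineages`` is
    None or contains None), all intra-group pairwise branch distances are
    pooled per group; the table reports their medians and the two-sided
    rank-sum p-value comparing the two pooled distributions.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 trees for pairwise distances")
    rows = []
    for lineage in lineages if lineages is not None else [None]:
        da = pairwise_branch_distances(group_a, lineage)
        db = pairwise_branch_distances(group_b, lineage)
        stat, p = ranksums(da, db)
        rows.append(
            {
                "lineage": lineage if lineage is not None else "all",
                "median_a": float(np.median(da)),
                "median_b": float(np.median(db)),
                "n_pairs_a": da.size,
                "n_pairs_b": db.size,
                "ranksum_stat": float(stat),
                "p_value": float(p),
            }
        )
    return pd.DataFrame(rows)


def lineage_tree_from_track_graph(
    graph: TrackGraph, frame_interval_minutes: float = 1.0
) -> LineageTree:
    """Build a lineage tree from a named track graph.

    Tracks are followed from their roots; a detection with two successors is
    a division. Cell names are taken from the detections; unnamed tracks get
    positional names derived from their root key.
    """
    tree = LineageTree()
    roots = [
        d.key
        for t in graph.timepoints()
        for d in graph.frames[t]
        if graph.predecessor(d.key) is None
    ]

    def walk(key, parent_name):
        birth_t = key[0]
        cur = key
        while True:
            succ = graph.successors(cur)
            if len(succ) == 1:
                cur = succ[0]
                continue
            det = graph.get(key)
            name = det.name or f"track_t{key[0]}_i{key[1]}"
            tree.add_cell(
                name,
                birth=birth_t * frame_interval_minutes,
                end=(cur[0] + 1) * frame_interval_minutes if succ else cur[0] * frame_interval_minutes,
                parent=parent_name,
            )
            if not succ:
                return
            for s in succ:
                walk(s, name)
            return

    for root in sorted(roots):
        walk(root, None)
    return tree
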