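"""Repeat-unit grouping: alignment, JC distances, threshold clustering.

Units are aligned (sequence-only progressive alignment), pairwise JC
distances are computed with pairwise deletion, and units are clustered into
numbered groups by single linkage at a distance threshold (default 0.1).
Two bootstrap-support override rules refine the base rule, mirroring how the
published grouping handled its exceptions:

* merge: an otherwise-ungrouped unit joins a group when the unit plus a
  subset of that group forms a clade with support >= the override cutoff,
  even though every distance to the group is at or above the threshold;
* split: a sub-threshold link inside a component is cut when the two sides
  correspond to distinct well-supported clades.

All overrides are logged in the returned assignment.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .align import AlignParams, Alignment, progressive_align
from .distances import DistanceMatrix, jc_distance, jc_matrix
from .records import RepeatUnit
from .trees import bootstrap_support, nj_tree

__all__ = [
    "UNGROUPED",
    "GroupAssignment",
    "OverrideEvent",
    "align_units",
    "cluster_groups",
    "group_units",
    "nj_tree",
    "bootstrap_support",
    "jc_distance",
]

UNGROUPED = "ungrouped"


@dataclass(frozen=True)
class OverrideEvent:
    kind: str  # "merge" or "split"
    units: tuple[str, ...]
    group: int
    support: float


@dataclass
class GroupAssignment:
    """Unit -> group id (1..G, contiguous) or None for ungrouped."""

    assignment: dict[str, int | None]
    threshold: float
    overrides: list[OverrideEvent] = field(default_factory=list)

    @property
    def n_groups(self) -> int:
        return len({g for g in self.assignment.values() if g is not None})

    @property
    def n_ungrouped(self) -> int:
        return sum(1 for g in self.assignment.values() if g is None)

    def members(self, group: int) -> list[str]:
        return [u for u, g in self.assignment.items() if g == group]

    def label(self, unit: str) -> str:
        g = self.assignment[unit]
        return UNGROUPED if g is None else str(g)


def align_units(
    units: list[RepeatUnit],
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -4.0,
    gap_extend: float = -1.0,
) -> Alignment:
    """Progressive alignment of repeat units (>= 2 required)."""
    if len(units) < 2:
        raise ValueError("need at least two units to align")
    params = AlignParams(match=match, mismatch=mismatch, gap_open=gap_open, gap_extend=gap_extend)
    return progressive_align([u.name for u in units], [u.sequence for u in units], params)


def _supported_sides(
    tree_with_support, support_override: float
) -> list[frozenset[str]]:
    """Well-supported clade sides, smallest first (deterministic order)."""
    if tree_with_support is None:
        return []
    if isinstance(tree_with_support, dict):
        items = list(tree_with_support.items())
    else:  # a dendropy tree whose internal node labels carry support
        from .trees import _clade_sides

        items = [
            (side, float(node.label))
            for side, node in _clade_sides(tree_with_support).items()
            if node.label is not None
        ]
    sides = [
        (frozenset(side), float(sup))
        for side, sup in items
        if sup is not None and float(sup) >= support_override
    ]
    sides.sort(key=lambda x: (len(x[0]), sorted(x[0])))
    return [s for s, _ in sides]


def _support_of(tree_with_support, side: frozenset[str]) -> float:
    if isinstance(tree_with_support, dict):
        return float(tree_with_support[side])
    from .trees import _clade_sides

    return float(_clade_sides(tree_with_support)[side].label)


def cluster_groups(
    dmatrix: DistanceMatrix,
    threshold: float = 0.1,
    tree_with_support=None,
    support_override: float = 70.0,
    merge_distance_factor: float = 1.5,
) -> GroupAssignment:
    """Single-linkage threshold clustering with support-based overrides.

    Base rule: connected components of the graph linking pairs with
    d < threshold.  ``tree_with_support`` may be a dendropy tree whose
    internal node labels are percent supports, or a mapping from normalised
    bipartition frozensets to supports; when given, the split override runs
    first, then the merge override.  The merge override only reaches units
    whose nearest group member lies within ``merge_distance_factor`` times
    the threshold: it exists for near-threshold borderline cases, not for
    deeply divergent units, which stay ungrouped no matter how well they
    cluster.  Components of size one end up ungrouped.  Group ids are
    numbered contiguously from 1 in order of each group's first unit in the
    matrix label order.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    labels = list(dmatrix.labels)
    n = len(labels)
    adj = csr_matrix((dmatrix.values < threshold).astype(np.int8))
    _, comp_ids = connected_components(adj, directed=False)
    components: list[set[str]] = [
        {labels[i] for i in range(n) if comp_ids[i] == c}
        for c in range(comp_ids.max() + 1)
    ]

    overrides: list[OverrideEvent] = []
    supported = _supported_sides(tree_with_support, support_override)

    # split override: cut a component along a pair of disjoint supported clades
    changed = True
    while changed and supported:
        changed = False
        for comp in list(components):
            if len(comp) < 2:
                continue
            for s1 in supported:
                a = s1 & comp
                if not a or a == comp:
                    continue
                b = comp - a
                for s2 in supported:
                    if s2 is s1 or (s2 & s1):
                        continue
                    if b <= s2:
                        components.remove(comp)
                        components.append(a)
                        components.append(b)
                        overrides.append(
                            OverrideEvent(
                                kind="split",
                                units=tuple(sorted(a)),
                                group=-1,
                                support=min(
                                    _support_of(tree_with_support, s1),
                                    _support_of(tree_with_support, s2),
                                ),
                            )
                        )
                        changed = True
                        break
                if changed:
                    break
            if changed:
                break

    # merge override: attach a lone near-threshold unit to a group it forms
    # a clade with
    idx = {lab: i for i, lab in enumerate(labels)}
    for comp in [c for c in components if len(c) == 1]:
        (unit,) = comp
        for side in supported:
            if unit not in side or len(side) < 2:
                continue
            rest = side - {unit}
            targets = [c for c in components if len(c) >= 2 and rest <= c]
            if targets:
                target = targets[0]
                d_min = min(dmatrix.values[idx[unit], idx[v]] for v in target)
                if d_min >= merge_distance_factor * threshold:
                    continue
                components.remove(comp)
                target.add(unit)
                overrides.append(
                    OverrideEvent(
                        kind="merge",
                        units=(unit,),
                        group=-1,
                        support=_support_of(tree_with_support, side),
                    )
                )
                break

    # number groups by first appearance in label order
    order = {lab: i for i, lab in enumerate(labels)}
    grouped = sorted(
        (c for c in components if len(c) >= 2),
        key=lambda c: min(order[u] for u in c),
    )
    assignment: dict[str, int | None] = {lab: None for lab in labels}
    for gid, comp in enumerate(grouped, start=1):
        for u in comp:
            assignment[u] = gid
    # rewrite override group ids now that numbering exists
    fixed = []
    for ev in overrides:
        gid = assignment.get(ev.units[0])
        fixed.append(OverrideEvent(ev.kind, ev.units, gid if gid else -1, ev.support))
    return GroupAssignment(assignment=assignment, threshold=threshold, overrides=fixed)


@dataclass
class GroupingResult:
    alignment: Alignment
    dmatrix: DistanceMatrix
    tree: "object"
    supports: dict[frozenset[str], float]
    assignment: GroupAssignment


def group_units(
    units: list[RepeatUnit],
    threshold: float = 0.1,
    support_override: float = 70.0,
    bootstrap: int = 1000,
    seed: int = 0,
    align_params: AlignParams = AlignParams(),
) -> GroupingResult:
    """Full grouping stage: align -> distances -> NJ + bootstrap -> cluster."""
    alignment = align_units(
        units,
        match=align_params.match,
        mismatch=align_params.mismatch,
        gap_open=align_params.gap_open,
        gap_extend=align_params.gap_extend,
    )
    dmatrix = jc_matrix(alignment.labels, alignment.rows)
    supports: dict[frozenset[str], float] = {}
    tree = None
    if len(units) >= 3:
        tree, supports = bootstrap_support(alignment, n_replicates=bootstrap, seed=seed)
    assignment = cluster_groups(
        dmatrix,
        threshold=threshold,
        tree_with_support=supports if supports else None,
        support_override=support_override,
    )
    return GroupingResult(
        alignment=alignment,
        dmatrix=dmatrix,
        tree=tree,
        supports=supports,
        assignment=assignment,
    )
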