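"""Sequence-only progressive multiple alignment.

Pairwise global alignments (Needleman-Wunsch with affine gaps, via
Bio.Align.PairwiseAligner) provide both the guide distances and the merge
step: profiles are merged by aligning their column-majority consensus
strings and propagating the resulting gaps into every member row.  The guide
tree is a neighbor-joining tree on pairwise identity distances.  The whole
procedure is deterministic for fixed inputs and parameters.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align

from .records import GAP

__all__ = ["Alignment", "AlignParams", "pairwise_align", "progressive_align"]


@dataclass(frozen=True)
class AlignParams:
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -4.0
    gap_extend: float = -1.0


@dataclass
class Alignment:
    """Labelled gapped rows of equal length (gap character '-')."""

    labels: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.rows):
            raise ValueError("labels and rows differ in length")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("rows must all have the same length")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate labels in alignment")

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def __len__(self) -> int:
        return len(self.rows)

    def row(self, label: str) -> str:
        return self.rows[self.labels.index(label)]

    def degapped(self, label: str) -> str:
        return self.row(label).replace(GAP, "")

    def codes(self) -> np.ndarray:
        """(n, L) uint8 matrix of the rows' ASCII codes."""
        return np.frombuffer("".join(self.rows).encode("ascii"), dtype=np.uint8).reshape(
            len(self.rows), -1
        )

    def subset(self, labels: list[str]) -> "Alignment":
        return Alignment(labels=list(labels), rows=[self.row(l) for l in labels])


def _aligner(params: AlignParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    return aligner


def pairwise_align(a: str, b: str, params: AlignParams = AlignParams()) -> tuple[str, str]:
    """Global alignment of two ungapped sequences; first optimal alignment."""
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    aln = _aligner(params).align(a, b)[0]
    return str(aln[0]), str(aln[1])


def _identity(row_a: str, row_b: str) -> float:
    same = sum(1 for x, y in zip(row_a, row_b) if x == y and x != GAP)
    return same / len(row_a) if row_a else 0.0


def _consensus(rows: list[str]) -> str:
    """Column-majority consensus; gap-majority columns yield a placeholder
    base (so the pairwise aligner sees a concrete letter), ties broken in
    fixed A<C<G<T order."""
    out = []
    for col in zip(*rows):
        counts: dict[str, int] = {}
        for ch in col:
            if ch != GAP:
                counts[ch] = counts.get(ch, 0) + 1
        if not counts:
            out.append("N")
        else:
            best = max(sorted(counts), key=lambda c: counts[c])
            out.append(best)
    return "".join(out)


def _inject_gaps(rows: list[str], gapped_consensus: str) -> list[str]:
    """Expand profile rows to match the gap pattern of its aligned consensus."""
    out_rows = []
    for row in rows:
        out = []
        i = 0
        for ch in gapped_consensus:
            if ch == GAP:
                out.append(GAP)
            else:
                out.append(row[i])
                i += 1
        out_rows.append("".join(out))
    return out_rows


def _merge(profile_a: Alignment, profile_b: Alignment, params: AlignParams) -> Alignment:
    cons_a = _consensus(profile_a.rows)
    cons_b = _consensus(profile_b.rows)
    ga, gb = pairwise_align(cons_a, cons_b, params)
    rows_a = _inject_gaps(profile_a.rows, ga)
    rows_b = _inject_gaps(profile_b.rows, gb)
    return Alignment(labels=profile_a.labels + profile_b.labels, rows=rows_a + rows_b)


def progressive_align(
    labels: list[str], sequences: list[str], params: AlignParams = AlignParams()
) -> Alignment:
    """Progressive alignment over an NJ guide tree of pairwise identities."""
    from .trees import nj_tree  # deferred: trees imports distances only
    from .distances import DistanceMatrix

    if len(labels) != len(sequences):
        raise ValueError("labels and sequences differ in length")
    n = len(labels)
    if n == 0:
        raise ValueError("nothing to align")
    if n == 1:
        return Alignment(labels=list(labels), rows=[sequences[0]])
    if n == 2:
        ra, rb = pairwise_align(sequences[0], sequences[1], params)
        return Alignment(labels=list(labels), rows=[ra, rb])

    dist = np.zeros((n, n))
    for i in range(n - 1):
        for j in range(i + 1, n):
            ra, rb = pairwise_align(sequences[i], sequences[j], params)
            dist[i, j] = dist[j, i] = 1.0 - _identity(ra, rb)
    guide = nj_tree(DistanceMatrix(labels=list(labels), values=dist, model="p", deletion="none"))

    by_label = dict(zip(labels, sequences))
    profiles: dict[int, Alignment] = {}

    def build(node) -> Alignment:
        if node.taxon is not None:
            lab = node.taxon.label
            return Alignment(labels=[lab], rows=[by_label[lab]])
        children = [build(c) for c in node.child_nodes()]
        prof = children[0]
        for other in children[1:]:
            prof = _merge(prof, other, params)
        return prof

    merged = build(guide.seed_node)
    # restore the caller's label order
    return merged.subset(list(labels))
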