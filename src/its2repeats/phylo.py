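"""Repeat-masked spacer phylogenetics.

The repeat array is excised from each spacer, the remainders are aligned with
the same progressive engine used for units, columns containing any gap are
(optionally) removed, and an NJ tree with bootstrap support is built from JC
distances.  Trees are unrooted unless outgroup taxa are supplied.  The same
machinery accepts any aligned marker, so externally aligned sequences (e.g.
concatenated mitochondrial genes) can be fed through ``species_tree`` and the
resulting trees compared with ``compare_trees``.
"""
from __future__ import annotations

from dataclasses import dataclass

import dendropy

from .align import AlignParams, Alignment, progressive_align
from .distances import jc_matrix
from .records import GAP, MaskedSpacer, RepeatArray, SpacerRecord
from .trees import bootstrap_support, compare_trees, nj_tree, root_on_outgroup

__all__ = [
    "mask_repeats",
    "align_and_filter",
    "species_tree",
    "compare_trees",
    "MaskedSpacer",
    "SpeciesTreeResult",
]


def mask_repeats(record: SpacerRecord, array: RepeatArray | None) -> MaskedSpacer:
    """Excise the array span; flanking segments are joined.

    Lossless: the original sequence is ``masked[:start] + excised + masked[start:]``.
    ``array=None`` (or an empty span) leaves the sequence unchanged.
    """
    if array is None:
        return MaskedSpacer(
            id=record.id, sequence=record.sequence, source_id=record.id, excised=(0, 0)
        )
    start, end = array.start, array.end
    if not (0 <= start <= end <= len(record.sequence)):
        raise ValueError(
            f"array span {start}-{end} out of bounds for record {record.id!r} "
            f"of length {len(record.sequence)}"
        )
    return MaskedSpacer(
        id=record.id,
        sequence=record.sequence[:start] + record.sequence[end:],
        source_id=record.id,
        excised=(start, end),
    )


def align_and_filter(
    masked_records: list[MaskedSpacer],
    exclude_gap_columns: bool = True,
    params: AlignParams = AlignParams(),
) -> tuple[Alignment, int]:
    """Progressive alignment; optionally drop every column containing a gap.

    Returns the (possibly filtered) alignment and the number of columns
    removed.  Raises if fewer than two records are given or if filtering
    removes every column.
    """
    if len(masked_records) < 2:
        raise ValueError("need at least two records to align")
    aln = progressive_align(
        [m.id for m in masked_records], [m.sequence for m in masked_records], params
    )
    if not exclude_gap_columns:
        return aln, 0
    cols = list(zip(*aln.rows))
    keep = [i for i, col in enumerate(cols) if GAP not in col]
    removed = aln.length - len(keep)
    if not keep:
        raise ValueError("gap-column exclusion removed every column")
    rows = ["".join(r[i] for i in keep) for r in aln.rows]
    return Alignment(labels=list(aln.labels), rows=rows), removed


@dataclass
class SpeciesTreeResult:
    tree: dendropy.Tree
    supports: dict[frozenset[str], float]

    def newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=False).strip()


def species_tree(
    alignment: Alignment,
    bootstrap_n: int = 1000,
    seed: int = 0,
    outgroup: list[str] | None = None,
) -> SpeciesTreeResult:
    """JC distances -> NJ -> bootstrap; rooted on the outgroup when given."""
    if len(alignment) < 3:
        raise ValueError("need at least three sequences for a tree")
    tree, supports = bootstrap_support(alignment, n_replicates=bootstrap_n, seed=seed)
    if outgroup:
        tree = root_on_outgroup(tree, outgroup)
    return SpeciesTreeResult(tree=tree, supports=supports)
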