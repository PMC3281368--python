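"""Jukes-Cantor distances with pairwise deletion of gaps.

For each sequence pair, only alignment columns where both rows carry a
concrete base (A/C/G/T) are compared; gaps and ambiguity codes are excluded
(conservative pairwise deletion).  With p the fraction of differing valid
sites, d = -(3/4) ln(1 - 4p/3).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .records import ACGT
from .simulate import JCSaturationError

__all__ = ["DistanceMatrix", "jc_distance", "jc_matrix", "JCSaturationError"]

_ACGT_CODES = np.frombuffer(ACGT.encode("ascii"), dtype=np.uint8)


@dataclass
class DistanceMatrix:
    """Symmetric labelled distance matrix with its provenance tags."""

    labels: list[str]
    values: np.ndarray
    model: str = "JC"
    deletion: str = "pairwise"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("diagonal must be zero")
        if (self.values < -1e-12).any():
            raise ValueError("distances must be non-negative")
        if not np.isfinite(self.values).all():
            raise ValueError("distances must be finite")

    def __len__(self) -> int:
        return len(self.labels)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def reordered(self, labels: list[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(
            labels=list(labels),
            values=self.values[np.ix_(idx, idx)],
            model=self.model,
            deletion=self.deletion,
        )


def _valid_mask(row: str) -> np.ndarray:
    raw = np.frombuffer(row.encode("ascii"), dtype=np.uint8)
    return np.isin(raw, _ACGT_CODES)


def jc_distance(row_a: str, row_b: str, pairwise_deletion: bool = True) -> float:
    """JC distance between two equal-length gapped rows.

    Raises ValueError when no comparable sites remain and
    :class:`JCSaturationError` when p >= 3/4 (the estimator is undefined).
    ``pairwise_deletion=False`` refuses rows containing gaps/ambiguities
    instead of deleting the affected sites.
    """
    if len(row_a) != len(row_b):
        raise ValueError("rows must have equal length")
    a = np.frombuffer(row_a.upper().encode("ascii"), dtype=np.uint8)
    b = np.frombuffer(row_b.upper().encode("ascii"), dtype=np.uint8)
    valid = np.isin(a, _ACGT_CODES) & np.isin(b, _ACGT_CODES)
    if not pairwise_deletion and not valid.all():
        raise ValueError("rows contain gaps/ambiguities and pairwise deletion is off")
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError("no comparable sites (all columns gapped or ambiguous)")
    p = float(((a != b) & valid).sum()) / n_valid
    if p >= 0.75:
        raise JCSaturationError(f"observed difference p={p:.3f} >= 0.75 saturates JC")
    return float(-0.75 * np.log(1.0 - 4.0 * p / 3.0))


def jc_matrix(
    labels: list[str],
    rows: list[str],
    saturation: str = "raise",
) -> DistanceMatrix:
    """All-pairs JC distances of an alignment (vectorised).

    ``saturation="cap"`` clips p just below 3/4 instead of raising; used by
    bootstrap resampling where occasional saturated replicates are expected
    and must not abort the replicate set.
    """
    if len(labels) != len(rows):
        raise ValueError("labels and rows differ in length")
    if len({len(r) for r in rows}) > 1:
        raise ValueError("rows must have equal length")
    mat = np.frombuffer("".join(r.upper() for r in rows).encode("ascii"), dtype=np.uint8)
    mat = mat.reshape(len(rows), -1)
    return jc_matrix_from_codes(labels, mat, saturation=saturation)


def jc_matrix_from_codes(
    labels: list[str], mat: np.ndarray, saturation: str = "raise"
) -> DistanceMatrix:
    valid = np.isin(mat, _ACGT_CODES)
    pair_valid = valid[:, None, :] & valid[None, :, :]
    n_valid = pair_valid.sum(axis=2)
    diff = (mat[:, None, :] != mat[None, :, :]) & pair_valid
    zero = n_valid == 0
    if zero.any() and saturation != "cap":
        i, j = np.argwhere(zero)[0]
        raise ValueError(f"no comparable sites between {labels[i]!r} and {labels[j]!r}")
    p = diff.sum(axis=2) / np.where(zero, 1, n_valid)
    if saturation == "cap":
        # a replicate carrying no information about a pair is treated as
        # maximally distant rather than aborting the replicate set
        p = np.where(zero, 0.7499, np.minimum(p, 0.7499))
    elif (p >= 0.75).any():
        i, j = np.argwhere(p >= 0.75)[0]
        raise JCSaturationError(
            f"pair {labels[i]!r}/{labels[j]!r} saturates JC (p={p[i, j]:.3f})"
        )
    d = -0.75 * np.log(1.0 - 4.0 * p / 3.0)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return DistanceMatrix(labels=list(labels), values=d)
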