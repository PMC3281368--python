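"""Tandem-repeat detection and unit delimitation in a single spacer.

Detection follows dot-plot logic: the sequence is compared against itself,
matches appear as runs along diagonals (one diagonal per offset), and only
runs longer than a floor (default 30 nt, mirroring what is distinguishable on
a dot plot) are kept.  The tandem array and its unit period are inferred from
the offsets of the surviving matches; individual units are then delimited
using the conserved terminal motifs, falling back to periodic cuts where a
motif is absent.
"""
from __future__ import annotations

import statistics
from dataclasses import dataclass

import numpy as np

from .records import (
    ACGT,
    RepeatArray,
    RepeatUnit,
    SpacerRecord,
    complement,
    find_iupac,
)

__all__ = [
    "DiagonalMatch",
    "ArrayCandidate",
    "Stem",
    "InvertedReport",
    "self_dotplot",
    "infer_array",
    "delimit_units",
    "extract_units",
    "find_repeat_array",
    "inverted_content",
]


@dataclass(frozen=True)
class DiagonalMatch:
    """A self-match: sequence[start:start+length] ~ sequence[start+offset:...]."""

    offset: int
    start: int
    length: int
    identity: float


@dataclass(frozen=True)
class ArrayCandidate:
    start: int
    end: int
    period: int

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


def _codes(sequence: str) -> tuple[np.ndarray, np.ndarray]:
    raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    is_acgt = np.isin(raw, np.frombuffer(ACGT.encode("ascii"), dtype=np.uint8))
    return raw, is_acgt


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """(start, length) of maximal runs of True."""
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]
    return [(int(s), int(e - s)) for s, e in zip(starts, ends)]


def self_dotplot(
    sequence: str,
    word_size: int = 11,
    min_match_length: int = 30,
    min_identity: float = 0.7,
) -> list[DiagonalMatch]:
    """Self-comparison matches above a length floor.

    Word seeds (default 11-mers) select which diagonals to examine; each
    seeded diagonal is scanned exhaustively, exact runs are merged greedily
    across single mismatches while the merged identity stays >= min_identity,
    and every maximal surviving run of length >= min_match_length is reported
    once.  The trivial offset-0 diagonal is excluded.  With min_identity=1.0
    the output is exactly the maximal exact self-matches.
    """
    if not sequence:
        raise ValueError("empty sequence")
    if word_size < 4:
        raise ValueError("word_size must be >= 4")
    if min_match_length < word_size:
        raise ValueError("min_match_length must be >= word_size")
    seq = sequence.upper()
    n = len(seq)
    raw, is_acgt = _codes(seq)

    words: dict[str, list[int]] = {}
    for i in range(n - word_size + 1):
        w = seq[i : i + word_size]
        words.setdefault(w, []).append(i)
    diagonals: set[int] = set()
    for positions in words.values():
        if len(positions) < 2:
            continue
        for a in range(len(positions) - 1):
            for b in range(a + 1, len(positions)):
                diagonals.add(positions[b] - positions[a])

    matches: list[DiagonalMatch] = []
    for d in sorted(diagonals):
        if d <= 0 or d >= n:
            continue
        eq = (raw[: n - d] == raw[d:]) & is_acgt[: n - d] & is_acgt[d:]
        runs = _runs(eq)
        if not runs:
            continue
        # greedy merge across single mismatches, identity-checked
        merged: list[tuple[int, int, int]] = []  # start, span, mismatches
        cur_s, cur_len = runs[0]
        cur_mm = 0
        for s, ln in runs[1:]:
            gap = s - (cur_s + cur_len + cur_mm)
            span = s + ln - cur_s
            ident = (cur_len + ln) / span
            if gap == 1 and ident >= min_identity:
                cur_mm += 1
                cur_len += ln
            else:
                merged.append((cur_s, cur_len + cur_mm, cur_mm))
                cur_s, cur_len, cur_mm = s, ln, 0
        merged.append((cur_s, cur_len + cur_mm, cur_mm))
        for s, span, mm in merged:
            if span >= min_match_length:
                ident = (span - mm) / span
                if ident >= min_identity:
                    matches.append(DiagonalMatch(offset=d, start=s, length=span, identity=ident))
    matches.sort(key=lambda m: (m.offset, m.start))
    return matches


def _cluster_values(values: list[int], tol: int) -> list[tuple[int, int]]:
    """Cluster sorted integers within ``tol``; return (center, count) pairs."""
    if not values:
        return []
    values = sorted(values)
    clusters: list[list[int]] = [[values[0]]]
    for v in values[1:]:
        if v - clusters[-1][-1] <= tol:
            clusters[-1].append(v)
        else:
            clusters.append([v])
    return [(int(round(statistics.fmean(c))), len(c)) for c in clusters]


def _near_multiple(value: int, period: int, tol: int) -> bool:
    # alternating arrays with unequal unit lengths put offsets at
    # k*(a+b)/2 +/- |a-b|/2, so the allowance scales mildly with the period
    tol = max(tol, min(12, round(0.1 * period)))
    r = value % period
    return min(r, period - r) <= tol


def infer_array(
    matches: list[DiagonalMatch],
    sequence: str,
    tol: int = 3,
    min_coverage: float = 0.6,
    min_period: int = 30,
) -> ArrayCandidate | None:
    """Infer the tandem-array span and unit period from dot-plot matches.

    The period is the smallest offset-cluster centre or modal pairwise offset
    difference under which at least ``min_coverage`` of the total matched
    length lies on offsets that are near-multiples of it.  The span covers the
    densest contiguous block of period-consistent matches.  Offset-inconsistent
    or dispersed (non-adjacent) duplications yield ``None`` rather than an
    error.
    """
    if not matches:
        return None
    offsets = [m.offset for m in matches]
    centers = [c for c, _ in _cluster_values(offsets, tol)]
    diffs = []
    uniq = sorted(set(offsets))
    for i in range(len(uniq) - 1):
        for j in range(i + 1, len(uniq)):
            diffs.append(uniq[j] - uniq[i])
    diff_centers = [c for c, _ in _cluster_values(diffs, tol)]
    total_len = sum(m.length for m in matches)
    candidates = sorted({c for c in centers + diff_centers if c >= min_period})

    period = None
    consistent: list[DiagonalMatch] = []
    for c in candidates:
        sel = [m for m in matches if _near_multiple(m.offset, c, tol)]
        if sum(m.length for m in sel) >= min_coverage * total_len:
            period, consistent = c, sel
            break
    if period is None:
        return None

    # merge the coverage intervals of consistent matches into blocks
    intervals = sorted(
        (m.start, m.start + m.offset + m.length, m.length) for m in consistent
    )
    allowed_gap = max(2 * tol, period // 2)
    blocks: list[list[int]] = []  # start, end, matched length
    for s, e, ln in intervals:
        if blocks and s <= blocks[-1][1] + allowed_gap:
            blocks[-1][1] = max(blocks[-1][1], e)
            blocks[-1][2] += ln
        else:
            blocks.append([s, e, ln])
    best = max(blocks, key=lambda b: b[2])
    start, end = best[0], min(best[1], len(sequence))
    if end - start < 1.6 * period:
        return None
    return ArrayCandidate(start=start, end=end, period=period)


def _aln_identity(a: str, b: str) -> float:
    """Identity of the global alignment of two sequences, per alignment column."""
    from .align import pairwise_align

    if not a or not b:
        return 0.0
    ra, rb = pairwise_align(a, b)
    same = sum(1 for x, y in zip(ra, rb) if x == y and x != "-")
    return same / len(ra) if ra else 0.0


def _motif3_ends(sequence: str, motif3: str, start: int = 0, end: int | None = None) -> list[int]:
    """End positions (exclusive) of 3' motif occurrences."""
    return [p + len(motif3) for p in find_iupac(sequence, motif3, start, end)]


def _junction_starts(
    sequence: str,
    motif5: str,
    motif3: str,
    max_gap: int = 4,
    min_separation: int = 40,
) -> list[int]:
    """Positions where a unit plausibly starts inside an array: a 5' motif
    occurrence immediately preceded (within ``max_gap``) by a 3' motif end.

    Candidates closer than ``min_separation`` (well below any real unit
    length) are deduplicated, preferring the tightest motif3/motif5 adjacency;
    this suppresses phantom junctions from overlapping motif occurrences.
    """
    m5 = find_iupac(sequence, motif5)
    m3e = set(_motif3_ends(sequence, motif3))
    candidates = []
    for p in m5:
        gaps = [g for g in range(0, max_gap + 1) if (p - g) in m3e]
        if gaps:
            candidates.append((min(gaps), p))
    accepted: list[int] = []
    for _, p in sorted(candidates):
        if all(abs(p - q) >= min_separation for q in accepted):
            accepted.append(p)
    return sorted(accepted)


def delimit_units(
    sequence: str,
    array_span: tuple[int, int],
    period: int | float,
    motif5: str = "GGGTG",
    motif3: str = "CAYCC",
) -> RepeatArray:
    """Cut the array span into units anchored on terminal-motif occurrences.

    Boundaries are placed at 5' motif occurrences nearest to the periodic
    grid (the grid re-anchors on each accepted boundary, so unit-length
    variation does not accumulate).  If the motif occurrences within the span
    are regularly spaced at a sub-multiple of the given period, the period is
    refined accordingly.  Units lacking a motif hit within the snap window
    fall back to a pure periodic cut and are flagged ``"periodic"``.  Short
    terminal units are retained.
    """
    start, end = array_span
    period = int(round(period))
    if end - start < period:
        raise ValueError("array span shorter than one period")
    m5 = find_iupac(sequence, motif5, max(0, start - 10), end)
    junctions = set(_junction_starts(sequence, motif5, motif3))
    m3e = _motif3_ends(sequence, motif3, start, min(len(sequence), end + 10))

    # refine the period from motif spacing (handles alternating-group arrays
    # whose dominant self-similarity sits at a multiple of the unit length)
    anchors = sorted(p for p in m5 if p in junctions and start <= p < end)
    spacing_source = anchors if len(anchors) >= 2 else sorted(
        p for p in m5 if start <= p < end
    )
    if len(spacing_source) >= 2:
        spacings = [
            b - a for a, b in zip(spacing_source, spacing_source[1:]) if b - a >= 40
        ]
        if spacings:
            s_est = int(round(statistics.median(spacings)))
            k = max(1, int(round(period / s_est)))
            if k >= 2 and abs(period - k * s_est) <= 5 * k:
                period = s_est

    window = max(10, period // 3)

    def snap(target: int) -> tuple[int, str]:
        lo, hi = target - window, target + window
        cands = [p for p in m5 if lo <= p <= hi]
        if cands:
            junc = [p for p in cands if p in junctions]
            pool = junc if junc else cands
            return min(pool, key=lambda p: (abs(p - target), p)), "motif"
        return target, "periodic"

    # junction-anchored starts are authoritative; periodic walking only fills
    # stretches where no junction is seen (degraded or absent motifs)
    min_unit = len(motif5) + len(motif3)
    min_sep = max(min_unit, 40)
    first = snap(start)
    anchored = [first] + [
        (j, "motif") for j in anchors if j > first[0] + min_sep
    ]
    starts: list[tuple[int, str]] = []
    for nxt in anchored:
        if starts:
            while nxt[0] - starts[-1][0] > round(1.5 * period):
                pos, flag = snap(starts[-1][0] + period)
                if pos <= starts[-1][0] or pos >= nxt[0] - min_unit:
                    break
                starts.append((pos, flag))
        starts.append(nxt)
    while True:
        target = starts[-1][0] + period
        if target >= end - window:
            break
        pos, flag = snap(target)
        if pos <= starts[-1][0]:
            pos, flag = target, "periodic"
        starts.append((pos, flag))

    # refine the array end onto the nearest 3' motif end
    end_cands = [e for e in m3e if end - window <= e <= end + window]
    array_end = min(end_cands, key=lambda e: abs(e - end)) if end_cands else end
    while starts and array_end - starts[-1][0] < min_unit:
        starts.pop()
    if not starts:
        raise ValueError("no units could be delimited in the array span")

    # a fragment shorter than half a period betrays a chance motif junction
    # inside a real unit; merge it into whichever neighbour restores ~1 period
    # (genuinely truncated terminal units sit well above this floor)
    bounds = [[s, flag] for s, flag in starts]
    while len(bounds) > 1:
        sizes = [
            (bounds[i + 1][0] if i + 1 < len(bounds) else array_end) - bounds[i][0]
            for i in range(len(bounds))
        ]
        short = min(range(len(sizes)), key=lambda i: sizes[i])
        if sizes[short] >= 0.5 * period:
            break
        prev_merge = sizes[short - 1] + sizes[short] if short > 0 else None
        next_merge = (
            sizes[short] + sizes[short + 1] if short + 1 < len(bounds) else None
        )
        if next_merge is not None and (
            prev_merge is None or abs(next_merge - period) <= abs(prev_merge - period)
        ):
            bounds.pop(short + 1)
        else:
            bounds.pop(short)

    array_start = bounds[0][0]
    units = []
    for i, (s, flag) in enumerate(bounds):
        e = bounds[i + 1][0] if i + 1 < len(bounds) else array_end
        units.append(
            RepeatUnit(
                parent_id="",
                index=i + 1,
                start=s,
                end=e,
                name=f"unit-{i + 1}",
                sequence=sequence[s:e],
                boundary=flag,
            )
        )
    return RepeatArray(
        parent_id="", start=array_start, end=array_end, period=float(period), units=units
    )


def extract_units(record: SpacerRecord, array: RepeatArray) -> list[RepeatUnit]:
    """Name and extract the units of a delimited array, 5.8S -> 28S order."""
    out = []
    for i, u in enumerate(array.units, start=1):
        out.append(
            RepeatUnit(
                parent_id=record.id,
                index=i,
                start=u.start,
                end=u.end,
                name=f"{record.species_code}-{i}",
                sequence=record.sequence[u.start : u.end],
                boundary=u.boundary,
            )
        )
    return out


def find_repeat_array(
    record: SpacerRecord,
    word_size: int = 11,
    min_match_length: int = 30,
    min_identity: float = 0.7,
    motif5: str = "GGGTG",
    motif3: str = "CAYCC",
) -> RepeatArray | None:
    """Detect, infer, and delimit the repeat array of one record.

    Dot-plot self-comparison drives span/period inference; terminal-motif
    junctions (3' motif immediately followed by a 5' motif) refine the span
    and rescue arrays whose units have decayed beyond mutual self-similarity,
    which the published analysis could only place by cross-species comparison.
    Returns ``None`` when neither signal supports an array.
    """
    seq = record.sequence
    matches = self_dotplot(seq, word_size, min_match_length, min_identity)
    cand = infer_array(matches, seq)

    junctions = _junction_starts(seq, motif5, motif3)
    if cand is not None:
        lo = cand.start - int(1.5 * cand.period)
        hi = cand.end + int(1.5 * cand.period)
        junctions = [j for j in junctions if lo <= j <= hi]
    if len(junctions) >= 3:
        spacings = [b - a for a, b in zip(junctions, junctions[1:])]
        med = statistics.median(spacings)
        junctions = [
            j
            for i, j in enumerate(junctions)
            if (i > 0 and junctions[i] - junctions[i - 1] <= 2.5 * med)
            or (i + 1 < len(junctions) and junctions[i + 1] - junctions[i] <= 2.5 * med)
        ]

    if not junctions:
        if cand is None:
            return None
        span, period = cand.span, cand.period
    else:
        if len(junctions) >= 2:
            spacing = statistics.median(
                [b - a for a, b in zip(junctions, junctions[1:])]
            )
        elif cand is not None:
            spacing = cand.period
        else:
            spacing = 100  # generic unit length when only one junction is seen
        spacing = int(round(spacing))
        j0, jl = junctions[0], junctions[-1]
        # interior units (between junctions) serve as references when several
        # candidate terminal boundaries exist: the true terminal unit resembles
        # its neighbours far more than background-containing alternatives do
        refs = [seq[a:b] for a, b in zip(junctions, junctions[1:])][:3]

        def best_candidate(cands: list[int], target: int, unit_of) -> int:
            if len(cands) == 1 or not refs:
                return min(cands, key=lambda p: abs(p - target))
            scored = []
            for p in cands:
                u = unit_of(p)
                ident = max(_aln_identity(u, r) for r in refs) if u else 0.0
                scored.append((round(ident, 3), -abs(p - target), -p, p))
            return max(scored)[3]

        # the array starts one unit before the first junction, if a 5' motif is there
        lo = max(0, int(j0 - 1.6 * spacing))
        hi = int(j0 - 0.4 * spacing)
        head = find_iupac(seq, motif5, lo, hi + 1)
        a_start = (
            best_candidate(head, j0 - spacing, lambda p: seq[p:j0]) if head else j0
        )
        lo = int(jl + 0.4 * spacing)
        hi = min(len(seq), int(jl + 1.6 * spacing))
        tail = _motif3_ends(seq, motif3, lo, hi)
        a_end = (
            best_candidate(tail, jl + spacing, lambda e: seq[jl:e])
            if tail
            else min(len(seq), jl + spacing)
        )
        span = (a_start, a_end)
        period = spacing
        if cand is not None and not (cand.end <= span[0] or span[1] <= cand.start):
            span = (min(span[0], cand.start), max(span[1], cand.end))

    if span[1] - span[0] < period:
        return None
    array = delimit_units(seq, span, period, motif5, motif3)
    array.parent_id = record.id
    array.units = extract_units(record, array)
    return array


# ---------------------------------------------------------------------------
# inverted (hairpin-capable) content


@dataclass(frozen=True)
class Stem:
    """Two arms that are reverse complements of each other."""

    start1: int
    end1: int
    start2: int
    end2: int

    @property
    def length(self) -> int:
        return self.end1 - self.start1


@dataclass
class InvertedReport:
    stems: list[Stem]
    score: float  # fraction of positions covered by stem arms


def inverted_content(unit_sequence: str, min_stem: int = 4) -> InvertedReport:
    """Maximal reverse-complement self-matches (candidate hairpin stems).

    Scans every anti-diagonal (constant i+j) for maximal runs of positions
    where base i pairs with the complement of base j; arms must not overlap.
    """
    if min_stem < 4:
        raise ValueError("min_stem must be >= 4")
    seq = unit_sequence.upper()
    n = len(seq)
    comp = complement(seq)
    stems: list[Stem] = []
    for total in range(1, 2 * n - 2):
        i_lo = max(0, total - n + 1)
        i_hi = (total - 1) // 2  # inclusive; ensures i < j
        run = 0
        run_start = None
        for i in range(i_lo, i_hi + 2):
            ok = i <= i_hi and seq[i] == comp[total - i]
            if ok:
                if run == 0:
                    run_start = i
                run += 1
            elif run:
                if run >= min_stem:
                    j_hi = total - run_start  # inclusive
                    stems.append(
                        Stem(
                            start1=run_start,
                            end1=run_start + run,
                            start2=j_hi - run + 1,
                            end2=j_hi + 1,
                        )
                    )
                run = 0
    covered = np.zeros(n, dtype=bool)
    for s in stems:
        covered[s.start1 : s.end1] = True
        covered[s.start2 : s.end2] = True
    score = float(covered.mean()) if n else 0.0
    stems.sort(key=lambda s: (s.start1, s.start2))
    return InvertedReport(stems=stems, score=score)
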