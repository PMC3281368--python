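"""Synthetic spacer generator with planted tandem-repeat arrays.

The generator emulates a long rDNA internal transcribed spacer carrying one
tandem array of ~100-nt repeat units.  Units are drawn from a small number of
"group" consensus sequences (within-group divergence small, between-group
divergence large), may follow an alternating group pattern along the array,
carry conserved terminal motifs (GGGTG at the 5.8S end, CA(C/T)CC at the 28S
end), and sit between conserved flanks standing in for the 5.8S and 28S rRNA
genes.  A sidecar truth annotation records every planted coordinate and group
so downstream stages can be validated by parameter recovery without ever
reading the truth themselves.

The forward substitution process is Jukes-Cantor (uniform rates), matching the
distance model used for estimation, so planted divergences are recovered in
expectation by the JC estimator.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .records import ACGT, SpacerRecord, IUPAC_EXPANSIONS

__all__ = [
    "SimulationConfig",
    "TruthAnnotation",
    "JCSaturationError",
    "make_group_consensi",
    "make_singleton_consensi",
    "mutate_jc",
    "generate_dataset",
    "barbirostris_like_config",
]


class JCSaturationError(ValueError):
    """A requested or observed divergence is too close to the JC ceiling."""


# ---------------------------------------------------------------------------
# configuration


@dataclass
class SimulationConfig:
    """Parameters of one synthetic dataset.

    ``unit_patterns`` gives, per species, the group index of each unit along
    the array (5.8S -> 28S).  Positive integers 1..n_groups name shared
    groups; negative integers name private, highly divergent "singleton"
    consensi (each distinct negative value is its own consensus and is
    expected to end up ungrouped).  The string shortcuts ``"block"`` and
    ``"alternating"`` derive such lists automatically.
    """

    seed: int = 0
    species_codes: Sequence[str] = ("A1", "A2", "A3", "A4", "ca")
    units_per_species: Sequence[int] = (10, 8, 3, 8, 8)
    unit_length_range: tuple[int, int] = (95, 112)
    #: per species code: {unit ordinal (0-based) -> truncated length in nt}
    short_units: dict[str, dict[int, int]] = field(default_factory=dict)
    n_groups: int = 9
    within_group_divergence: float = 0.03
    between_group_divergence: float = 0.2
    unit_pattern: str | Sequence[Sequence[int]] = "block"
    motif5: str = "GGGTG"
    motif3: str = "CAYCC"
    flank_lengths: tuple[int, int] = (60, 60)
    background_lengths: tuple[int, int] = (150, 250)
    background_divergence: float = 0.05
    #: per species code: multiplier on the species' background branch length
    species_scale: dict[str, float] = field(default_factory=dict)
    indel_rate: float = 0.0
    isolines_per_species: int = 1
    within_species_divergence: float = 0.005

    def __post_init__(self) -> None:
        if len(self.species_codes) != len(self.units_per_species):
            raise ValueError("species_codes and units_per_species differ in length")
        if any(n < 1 for n in self.units_per_species):
            raise ValueError("units_per_species entries must be >= 1")
        if self.n_groups < 1:
            raise ValueError("n_groups must be >= 1")
        lo, hi = self.unit_length_range
        min_len = len(self.motif5) + len(self.motif3) + 10
        if lo < min_len:
            raise ValueError(
                f"unit_length_range minimum {lo} is too short to host both "
                f"terminal motifs (need >= {min_len})"
            )
        if lo > hi:
            raise ValueError("unit_length_range must be (min, max) with min <= max")
        if not self.within_group_divergence < self.between_group_divergence:
            raise ValueError(
                "within_group_divergence must be < between_group_divergence"
            )
        if self.isolines_per_species < 1:
            raise ValueError("isolines_per_species must be >= 1")
        self.resolved_patterns()  # validates custom unit patterns eagerly

    def resolved_patterns(self) -> list[list[int]]:
        """Per-species unit group indices, expanding the string shortcuts."""
        if isinstance(self.unit_pattern, str):
            patterns: list[list[int]] = []
            g = self.n_groups
            for i, n_units in enumerate(self.units_per_species):
                if self.unit_pattern == "block":
                    patterns.append([(i % g) + 1] * n_units)
                elif self.unit_pattern == "alternating":
                    a = (2 * i) % g + 1
                    b = (2 * i + 1) % g + 1
                    patterns.append([a if j % 2 == 0 else b for j in range(n_units)])
                else:
                    raise ValueError(f"unknown unit_pattern {self.unit_pattern!r}")
            return patterns
        patterns = [list(p) for p in self.unit_pattern]
        if [len(p) for p in patterns] != list(self.units_per_species):
            raise ValueError("custom unit_pattern lengths disagree with units_per_species")
        for p in patterns:
            for gi in p:
                if gi == 0 or gi > self.n_groups:
                    raise ValueError(f"group index {gi} out of range (1..{self.n_groups})")
        return patterns

    def singleton_ids(self) -> list[int]:
        ids = sorted(
            {gi for p in self.resolved_patterns() for gi in p if gi < 0}, reverse=True
        )
        return ids


def barbirostris_like_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The default study conditions: five species, 37 units, nine groups.

    Emulates the published architecture: ten units in the A1-like species
    (three groups cycling, last unit private), eight in A2/A4/campestris-like
    (two groups alternating), three mutually divergent units in A3 of which
    the first and last are truncated to 74 and 81 nt.
    """
    params = dict(
        seed=seed,
        species_codes=("A1", "A2", "A3", "A4", "ca"),
        units_per_species=(10, 8, 3, 8, 8),
        n_groups=9,
        unit_pattern=[
            [1, 2, 6, 1, 2, 6, 1, 2, 6, -1],
            [5, 7, 5, 7, 5, 7, -2, -3],
            [-4, -5, -6],
            [3, 8, 3, 8, 3, 8, 3, 8],
            [4, 9, 4, 9, 4, 9, 4, -7],
        ],
        short_units={"A3": {0: 74, 2: 81}},
        within_group_divergence=0.03,
        between_group_divergence=0.2,
        background_divergence=0.05,
        species_scale={"A3": 3.0},
    )
    params.update(overrides)
    return SimulationConfig(**params)


# ---------------------------------------------------------------------------
# truth sidecar


@dataclass
class UnitTruth:
    name: str
    start: int
    end: int
    group: int  # >0 shared group, <0 singleton consensus id

    @property
    def is_singleton(self) -> bool:
        return self.group < 0


@dataclass
class RecordTruth:
    record_id: str
    species_code: str
    array_start: int
    array_end: int
    units: list[UnitTruth]

    def __post_init__(self) -> None:
        prev = self.array_start
        for u in self.units:
            if not (self.array_start <= u.start and u.end <= self.array_end):
                raise ValueError(f"unit {u.name} outside the array span")
            if u.start != prev:
                raise ValueError(f"unit {u.name} not contiguous with previous unit")
            prev = u.end
        if self.units and prev != self.array_end:
            raise ValueError("units do not tile the array span")


@dataclass
class TruthAnnotation:
    seed: int
    records: dict[str, RecordTruth]

    def unit_count(self, record_id: str) -> int:
        return len(self.records[record_id].units)


# ---------------------------------------------------------------------------
# elementary operations


def _p_from_d(d: float) -> float:
    """Expected fraction of differing sites after JC divergence ``d``."""
    return 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))


def _star_branch(pairwise_target: float, length: int, n_protected: int) -> float:
    """Per-branch distance so two star branches compose to the pairwise target.

    Uses the JC semigroup identity p(2b) = 2p(b) - (4/3)p(b)^2 on the
    unprotected sites, then converts back to a whole-sequence distance, so
    the expected estimated distance between two derived sequences equals
    ``pairwise_target`` exactly rather than to first order.
    """
    if pairwise_target == 0:
        return 0.0
    f = (length - n_protected) / length
    p_u = _p_from_d(pairwise_target) / f
    if p_u >= 0.75:
        raise JCSaturationError(
            f"pairwise target {pairwise_target} saturates JC on the "
            f"substitutable fraction {f:.3f}"
        )
    q = 0.75 * (1.0 - math.sqrt(1.0 - 4.0 * p_u / 3.0))
    p_branch = q * f
    return -0.75 * math.log(1.0 - 4.0 * p_branch / 3.0)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.asarray(list(ACGT))[rng.integers(0, 4, size=length)])


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def mutate_jc(
    sequence: str,
    target_distance: float,
    seed,
    protect: Sequence[int] = (),
) -> str:
    """Evolve ``sequence`` so its expected estimated JC distance is the target.

    The number of substituted sites is the expected count under the model
    (stochastically rounded, so the expectation is exact), placed uniformly
    among the unprotected A/C/G/T sites; the per-site hit probability is
    scaled up by the protected fraction so that the distance estimated over
    the *whole* sequence converges to ``target_distance``.  Conditioning on
    the expected count keeps the planted divergence close to its target
    (recovery tests then measure the pipeline, not generator noise) while
    leaving every moment used by the JC estimator unchanged.  Protected
    positions (e.g. conserved terminal motifs) never change.

    Raises :class:`JCSaturationError` when the required per-site difference
    probability comes within 0.075 of the 3/4 ceiling (log argument < 0.1),
    where the JC estimator is effectively undefined.
    """
    if target_distance < 0:
        raise ValueError("target_distance must be >= 0")
    if target_distance == 0:
        return sequence
    rng = _as_rng(seed)
    codes = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8).copy()
    lut = {ord(b): i for i, b in enumerate(ACGT)}
    base_idx = np.full(codes.shape, -1, dtype=np.int64)
    for b, i in lut.items():
        base_idx[codes == b] = i
    substitutable = base_idx >= 0
    if len(protect):
        mask = np.zeros(len(sequence), dtype=bool)
        mask[np.asarray(list(protect), dtype=np.int64)] = True
        substitutable &= ~mask
    n_sub = int(substitutable.sum())
    length = len(sequence)
    f = n_sub / length if length else 0.0
    p_total = _p_from_d(target_distance)
    q = p_total / f if f > 0 else math.inf
    if 1.0 - 4.0 * q / 3.0 < 0.1:
        raise JCSaturationError(
            f"target distance {target_distance} saturates the JC model given a "
            f"substitutable fraction of {f:.3f}"
        )
    mean_count = q * n_sub
    count = int(mean_count) + int(rng.random() < (mean_count - int(mean_count)))
    count = min(count, n_sub)
    sites = rng.choice(np.flatnonzero(substitutable), size=count, replace=False)
    shifts = rng.integers(1, 4, size=count)
    out = codes.copy()
    acgt_codes = np.frombuffer(ACGT.encode("ascii"), dtype=np.uint8)
    out[sites] = acgt_codes[(base_idx[sites] + shifts) % 4]
    return out.tobytes().decode("ascii")


def _expand_motif(motif: str, rng: np.random.Generator) -> str:
    """One concrete expansion of an IUPAC motif (ambiguities resolved at random)."""
    out = []
    for ch in motif:
        choices = IUPAC_EXPANSIONS[ch]
        out.append(choices[rng.integers(0, len(choices))] if len(choices) > 1 else choices)
    return "".join(out)


def _motif_positions(config: SimulationConfig, unit_len: int) -> list[int]:
    m5, m3 = len(config.motif5), len(config.motif3)
    return list(range(m5)) + list(range(unit_len - m3, unit_len))


def _ancestral_unit(config: SimulationConfig, rng: np.random.Generator) -> str:
    lo, hi = config.unit_length_range
    length = hi
    middle = _random_seq(rng, length - len(config.motif5) - len(config.motif3))
    return config.motif5 + middle + _expand_motif(config.motif3, rng)


def _resize_unit(config: SimulationConfig, unit: str, new_len: int) -> str:
    """Shrink a unit to ``new_len`` by removing a centred interior block."""
    if new_len == len(unit):
        return unit
    if new_len > len(unit):
        raise ValueError("can only shrink units")
    m5, m3 = len(config.motif5), len(config.motif3)
    interior = unit[m5 : len(unit) - m3]
    remove = len(unit) - new_len
    if remove > len(interior):
        raise ValueError("unit too short to host both motifs after resizing")
    cut = (len(interior) - remove) // 2
    interior = interior[:cut] + interior[cut + remove :]
    return unit[:m5] + interior + unit[len(unit) - m3 :]


def _derive_consensi(
    config: SimulationConfig,
    rng: np.random.Generator,
    ancestor: str,
    n: int,
    pairwise: float,
) -> list[str]:
    lo, hi = config.unit_length_range
    protect = _motif_positions(config, len(ancestor))
    branch = _star_branch(pairwise, len(ancestor), len(protect))
    out = []
    for _ in range(n):
        cons = mutate_jc(ancestor, branch, rng, protect=protect)
        length = int(rng.integers(lo, hi + 1))
        out.append(_resize_unit(config, cons, length))
    return out


def make_group_consensi(config: SimulationConfig, seed=None) -> list[str]:
    """Consensus unit per group, pairwise diverged by ~between_group_divergence.

    Each consensus sits at half the between-group divergence from a common
    ancestral unit (star topology), so pairs are separated by the full
    between-group divergence in expectation.  Every consensus begins with the
    5' motif and ends with one concrete expansion of the 3' motif.
    """
    rng = _as_rng(config.seed if seed is None else seed)
    ancestor = _ancestral_unit(config, rng)
    return _derive_consensi(
        config, rng, ancestor, config.n_groups, config.between_group_divergence
    )


def make_singleton_consensi(
    config: SimulationConfig, n: int, seed=None, ancestor: str | None = None
) -> list[str]:
    """Private unit consensi diverged beyond the grouping threshold from everything."""
    rng = _as_rng(config.seed if seed is None else seed)
    if ancestor is None:
        ancestor = _ancestral_unit(config, rng)
    return _derive_consensi(config, rng, ancestor, n, 2.0 * config.between_group_divergence)


# ---------------------------------------------------------------------------
# dataset assembly


def _apply_indels(
    config: SimulationConfig, unit: str, rng: np.random.Generator
) -> str:
    """Plant small indels in the unit interior (motifs are never touched)."""
    if config.indel_rate <= 0:
        return unit
    m5, m3 = len(config.motif5), len(config.motif3)
    interior = list(unit[m5 : len(unit) - m3])
    i = 0
    out: list[str] = []
    while i < len(interior):
        if rng.random() < config.indel_rate:
            size = int(rng.integers(1, 4))
            if rng.random() < 0.5:
                out.append(_random_seq(rng, size))
                out.append(interior[i])
                i += 1
            else:
                i += size
        else:
            out.append(interior[i])
            i += 1
    return unit[:m5] + "".join(out) + unit[len(unit) - m3 :]


def generate_dataset(
    config: SimulationConfig,
) -> tuple[list[SpacerRecord], TruthAnnotation]:
    """Simulate spacer records plus the ground-truth annotation.

    Layout of every record: conserved 5' flank (5.8S stub), species-specific
    background spacer, the tandem array, more background, conserved 3' flank
    (28S stub).  Identical config+seed gives byte-identical output.
    """
    master = np.random.SeedSequence(config.seed)
    keys = ("consensi", "background", "species", "isolines")
    streams = {k: np.random.default_rng(s) for k, s in zip(keys, master.spawn(len(keys)))}

    rng = streams["consensi"]
    ancestor = _ancestral_unit(config, rng)
    group_consensi = _derive_consensi(
        config, rng, ancestor, config.n_groups, config.between_group_divergence
    )
    singleton_ids = config.singleton_ids()
    singleton_consensi = dict(
        zip(
            singleton_ids,
            _derive_consensi(
                config, rng, ancestor, len(singleton_ids), 2.0 * config.between_group_divergence
            ),
        )
    )

    rng = streams["background"]
    flank5 = _random_seq(rng, config.flank_lengths[0])
    flank3 = _random_seq(rng, config.flank_lengths[1])
    pre0 = _random_seq(rng, config.background_lengths[0])
    post0 = _random_seq(rng, config.background_lengths[1])

    patterns = config.resolved_patterns()
    records: list[SpacerRecord] = []
    truths: dict[str, RecordTruth] = {}
    rng = streams["species"]
    iso_rng = streams["isolines"]

    for code, n_units, pattern in zip(config.species_codes, config.units_per_species, patterns):
        scale = config.species_scale.get(code, 1.0)
        branch = config.background_divergence * scale / 2.0
        pre = mutate_jc(pre0, branch, rng) if branch > 0 else pre0
        post = mutate_jc(post0, branch, rng) if branch > 0 else post0

        unit_seqs: list[str] = []
        unit_groups: list[int] = []
        for j, gi in enumerate(pattern):
            cons = group_consensi[gi - 1] if gi > 0 else singleton_consensi[gi]
            protect = _motif_positions(config, len(cons))
            copy = mutate_jc(
                cons,
                _star_branch(config.within_group_divergence, len(cons), len(protect)),
                rng,
                protect=protect,
            )
            target_len = config.short_units.get(code, {}).get(j)
            if target_len is not None:
                copy = _resize_unit(config, copy, target_len)
            copy = _apply_indels(config, copy, rng)
            unit_seqs.append(copy)
            unit_groups.append(gi)

        array_seq = "".join(unit_seqs)
        base = flank5 + pre
        spacer = base + array_seq + post + flank3
        array_start = len(base)
        array_end = array_start + len(array_seq)

        # motif coordinates, protected during isoline-level mutation
        motif_sites: list[int] = []
        pos = array_start
        bounds: list[tuple[int, int]] = []
        for useq in unit_seqs:
            bounds.append((pos, pos + len(useq)))
            for k in _motif_positions(config, len(useq)):
                motif_sites.append(pos + k)
            pos += len(useq)

        n_iso = config.isolines_per_species
        for iso in range(1, n_iso + 1):
            rec_id = code if n_iso == 1 else f"{code}_iso{iso}"
            seq = spacer
            if n_iso > 1 and config.within_species_divergence > 0:
                seq = mutate_jc(
                    spacer,
                    config.within_species_divergence / 2.0,
                    iso_rng,
                    protect=motif_sites,
                )
            units = [
                UnitTruth(name=f"{code}-{j + 1}", start=s, end=e, group=g)
                for j, ((s, e), g) in enumerate(zip(bounds, unit_groups))
            ]
            records.append(
                SpacerRecord(
                    id=rec_id,
                    sequence=seq,
                    species_code=code,
                    flank5=(0, len(flank5)),
                    flank3=(len(seq) - len(flank3), len(seq)),
                )
            )
            truths[rec_id] = RecordTruth(
                record_id=rec_id,
                species_code=code,
                array_start=array_start,
                array_end=array_end,
                units=units,
            )

    return records, TruthAnnotation(seed=config.seed, records=truths)
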