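"""End-to-end pipeline: simulate -> detect -> group -> tree, with a run report.

All randomness flows from one top-level seed through named per-stage
substreams, so a fixed configuration reproduces every output byte for byte.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from pathlib import Path

from . import io as pio
from .align import AlignParams
from .detect import find_repeat_array
from .grouping import group_units
from .phylo import align_and_filter, mask_repeats, species_tree
from .records import RepeatArray, SpacerRecord
from .simulate import SimulationConfig, generate_dataset

log = logging.getLogger("its2repeats")

__all__ = ["RunConfig", "run_all", "stage_seed"]


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed (kept below 2**31)."""
    return (seed * 1000003 + zlib.crc32(stage.encode())) % (2**31)


@dataclasses.dataclass
class RunConfig:
    """Top-level pipeline configuration (fully serialisable)."""

    seed: int = 0
    out_dir: str = "its2repeats_out"
    input_fasta: str | None = None  # when None, the simulator provides input
    simulation: SimulationConfig | None = None
    # detection
    detect: bool = True
    word_size: int = 11
    min_match_length: int = 30
    min_identity: float = 0.7
    motif5: str = "GGGTG"
    motif3: str = "CAYCC"
    # grouping
    threshold: float = 0.1
    support_override: float = 70.0
    bootstrap_units: int = 1000
    # species tree
    exclude_gap_columns: bool = True
    bootstrap_tree: int = 1000
    outgroup: list[str] | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def run_all(config: RunConfig) -> dict:
    """Run every stage in order, persist all intermediates, return the report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": config.to_dict(), "stages": []}

    # --- input stage -------------------------------------------------------
    if config.input_fasta:
        records = pio.read_fasta(config.input_fasta)
        report["stages"].append("read")
    else:
        sim = config.simulation or SimulationConfig(seed=stage_seed(config.seed, "simulate"))
        records, truth = generate_dataset(sim)
        pio.write_fasta(records, out / "spacers.fasta")
        pio.write_truth(truth, out / "truth.tsv")
        pio.write_config(sim, out / "simulation.yaml")
        report["stages"].append("simulate")
    report["records"] = [r.id for r in records]

    # --- detection ---------------------------------------------------------
    arrays: dict[str, RepeatArray] = {}
    units = []
    if config.detect:
        all_matches = {}
        for rec in records:
            try:
                array = find_repeat_array(
                    rec,
                    word_size=config.word_size,
                    min_match_length=config.min_match_length,
                    min_identity=config.min_identity,
                    motif5=config.motif5,
                    motif3=config.motif3,
                )
            except ValueError as exc:
                raise RuntimeError(f"detect stage failed on record {rec.id!r}: {exc}") from exc
            if array is not None:
                arrays[rec.id] = array
                units.extend(array.units)
        pio.write_gff3(list(arrays.values()), out / "repeats.gff3")
        pio.write_units_fasta(units, out / "units.fasta")
        report["stages"].append("detect")
    report["unit_counts"] = {rec.id: len(arrays[rec.id].units) if rec.id in arrays else 0
                             for rec in records}

    # --- grouping ----------------------------------------------------------
    if len(units) >= 2:
        grouping = group_units(
            units,
            threshold=config.threshold,
            support_override=config.support_override,
            bootstrap=config.bootstrap_units,
            seed=stage_seed(config.seed, "group"),
        )
        pio.write_alignment_fasta(grouping.alignment, out / "units.aln.fasta")
        pio.write_phylip(grouping.dmatrix, out / "units.dist.phylip")
        pio.write_groups_tsv(grouping.assignment, out / "groups.tsv")
        if grouping.tree is not None:
            (out / "units.nj.nwk").write_text(
                grouping.tree.as_string(schema="newick").strip() + "\n"
            )
            report["unit_tree"] = str(out / "units.nj.nwk")
        report["group_count"] = grouping.assignment.n_groups
        report["ungrouped_count"] = grouping.assignment.n_ungrouped
        report["overrides"] = [
            dataclasses.asdict(e) for e in grouping.assignment.overrides
        ]
        report["stages"].append("group")
    else:
        log.info("grouping skipped: fewer than two repeat units detected")
        report["group_count"] = 0
        report["ungrouped_count"] = 0
        report["grouping_skipped"] = "fewer than two repeat units detected"

    # --- repeat-masked species tree ---------------------------------------
    masked = [mask_repeats(rec, arrays.get(rec.id)) for rec in records]
    pio.write_fasta(masked, out / "masked.fasta")
    if len(masked) >= 3:
        alignment, removed = align_and_filter(
            masked, exclude_gap_columns=config.exclude_gap_columns
        )
        pio.write_alignment_fasta(alignment, out / "masked.aln.fasta")
        result = species_tree(
            alignment,
            bootstrap_n=config.bootstrap_tree,
            seed=stage_seed(config.seed, "tree"),
            outgroup=config.outgroup,
        )
        (out / "species.nj.nwk").write_text(result.newick() + "\n")
        report["species_tree"] = str(out / "species.nj.nwk")
        report["gap_columns_removed"] = removed
        report["stages"].append("tree")

    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
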