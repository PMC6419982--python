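"""End-to-end pipeline: demultiplex → OTU picking → taxonomy → profiles.

The run report keeps per-stage read accounting — how many pairs were
assigned, rejected by reason, lost to short payloads, kept in accepted
OTUs, rescued, or flagged chimeric — because validation of an amplicon
pipeline hinges on being able to reconcile every input read.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import demux as dx
from . import otu as ot
from . import profiles as pf
from . import taxonomy as tx

logger = logging.getLogger("pairtax")


@dataclass
class PipelineConfig:
    """Tunable constants for one run; defaults are the method's standard
    operating point."""

    read_len: int = 70
    abundance_threshold: float = 0.001
    identity_levels: tuple[float, ...] = tx.DEFAULT_LEVELS
    min_spec: float = 50.0
    chimera_fold: float = 2.0
    max_primer_mismatch: int = 1
    rank: str = "genus"
    use_rescued: bool = True
    # paths
    fwd_fastq: str = ""
    rev_fastq: str = ""
    mapping: str = ""
    ref_fasta: str = ""
    ref_lineage: str = ""
    out_dir: str = "pairtax_out"

    def __post_init__(self) -> None:
        levels = tuple(self.identity_levels)
        if list(levels) != sorted(set(levels), reverse=True) or not all(
            0 < t <= 1 for t in levels
        ):
            raise ValueError("identity_levels must be strictly descending in (0,1]")
        if not 0 < self.abundance_threshold < 1:
            raise ValueError("abundance_threshold must be in (0,1)")
        if self.chimera_fold < 1:
            raise ValueError("chimera_fold must be >= 1")
        self.identity_levels = levels

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Plain ``key = value`` config file; '#' starts a comment.
        ``identity_levels`` is comma-separated."""
        values: dict = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, val = (s.strip() for s in line.split("=", 1))
            values[key] = val
        parsed: dict = {}
        hints = {f.name: f.type for f in dataclasses.fields(cls)}
        for key, val in values.items():
            if key not in hints:
                raise ValueError(f"unknown config key {key!r}")
            if key == "identity_levels":
                parsed[key] = tuple(float(v) for v in val.split(","))
            elif key in ("read_len", "max_primer_mismatch"):
                parsed[key] = int(val)
            elif key in ("abundance_threshold", "min_spec", "chimera_fold"):
                parsed[key] = float(val)
            elif key == "use_rescued":
                parsed[key] = val.lower() in ("1", "true", "yes")
            else:
                parsed[key] = val
        parsed.update(overrides)
        return cls(**parsed)

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        d["identity_levels"] = list(self.identity_levels)
        return d


@dataclass
class RunReport:
    config: dict
    stages: dict[str, dict] = field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({"config": self.config, "stages": self.stages}, indent=2))


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute all stages on files named in ``config``; writes every
    intermediate artifact under ``config.out_dir`` and returns the report.

    Any stage failure raises with the stage name; partial outputs are kept
    next to a ``FAILED`` marker file.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=config.echo())
    stage = "setup"
    try:
        sample_map = dx.parse_mapping(config.mapping)

        stage = "demux"
        result = dx.demultiplex(
            dx.read_pairs(config.fwd_fastq, config.rev_fastq), sample_map
        )
        result.report().to_csv(out_dir / "demux_report.tsv", sep="\t", index=False)
        n_input = result.n_assigned + result.n_rejected
        report.stages["demux"] = {
            "input_pairs": n_input,
            "assigned": result.n_assigned,
            "rejected_mismatch": sum(r == dx.REJECT_MISMATCH for _, r in result.rejected),
            "rejected_cross_sample": sum(r == dx.REJECT_CROSS for _, r in result.rejected),
        }
        logger.info("demux: %d/%d pairs assigned", result.n_assigned, n_input)

        stage = "reference"
        refs = tx.load_references(config.ref_fasta, config.ref_lineage or None)
        entry0 = sample_map.entries[0]
        db, n_ref_rejected = tx.trim_database(
            refs,
            entry0.fwd_primer,
            entry0.rev_primer,
            config.read_len,
            config.max_primer_mismatch,
        )
        report.stages["reference"] = {"loaded": len(refs), "trimmed": len(db),
                                      "rejected": n_ref_rejected}

        stage = "otu"
        entries = {e.sample_id: e for e in sample_map}
        tables: list[ot.SampleOTUTable] = []
        otu_stats = {}
        for sample_id, pairs_ in result.assigned.items():
            trimmed, n_short = dx.trim_sample(pairs_, entries[sample_id], config.read_len)
            derep = ot.dereplicate(trimmed)
            table, discarded = ot.pick_otus(
                derep, len(trimmed), config.abundance_threshold, sample_id
            )
            table, unassigned = ot.rescue_discarded(table, discarded)
            table = ot.flag_chimeras(table, config.chimera_fold)
            table.write(out_dir / f"{sample_id}_otus.tsv")
            tables.append(table)
            otu_stats[sample_id] = {
                "trimmed": len(trimmed),
                "too_short": n_short,
                "accepted_otus": len(table),
                "accepted_reads": sum(r.count for r in table),
                "rescued_reads": sum(r.rescued for r in table),
                "unassigned_reads": sum(unassigned.values()),
                "chimera_otus": sum(r.chimera for r in table),
            }
        report.stages["otu"] = otu_stats

        stage = "classify"
        all_assignments: dict[str, list[tx.Assignment]] = {}
        for table in tables:
            assignments = tx.classify_table(
                table, db, config.identity_levels, config.min_spec
            )
            tx.assignments_frame(assignments).to_csv(
                out_dir / f"{table.sample_id}_assignments.tsv", sep="\t", index=False
            )
            all_assignments[table.sample_id] = assignments
        report.stages["classify"] = {
            t.sample_id: len(all_assignments[t.sample_id]) for t in tables
        }

        stage = "profile"
        profiles = [
            pf.make_profile(
                t, all_assignments[t.sample_id], config.rank, config.use_rescued
            )
            for t in tables
            if any(not r.chimera for r in t.records)
        ]
        pf.write_profiles(profiles, out_dir)
        report.stages["profile"] = {p.sample_id: len(p.abundances) for p in profiles}

        report.write(out_dir / "run_report.json")
        return report
    except Exception as exc:
        (out_dir / "FAILED").write_text(f"stage {stage}: {exc}\n")
        report.write(out_dir / "run_report.json")
        raise RuntimeError(f"pipeline failed at stage {stage}: {exc}") from exc
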