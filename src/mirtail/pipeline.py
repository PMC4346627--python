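"""End-to-end orchestration: simulate -> trim -> align -> filter ->
count -> tail classification -> between-condition comparison.

A run is described by a :class:`RunConfig` (YAML-loadable); every stage
writes its intermediate table and the run emits a JSON manifest with
parameters, input checksums and per-stage record counts, sufficient to
re-run bit-identically.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from . import align_filter, diff_tailing, mirna_quant, preprocess, refio, simdata, tailing
from .core import Genome
from .simdata import DEFAULT_ADAPTER, SimConfig


@dataclass
class RunConfig:
    outdir: str = "mirtail_run"
    # input mode: simulate, or align provided FASTQ, or ingest provided SAM
    simulate: Optional[dict] = None  # SimConfig fields
    genome: Optional[str] = None
    annotation: Optional[str] = None
    fastq: dict[str, str] = field(default_factory=dict)  # condition -> path
    sam: dict[str, str] = field(default_factory=dict)  # condition -> path
    adapter: str = DEFAULT_ADAPTER
    min_length: int = 18
    max_mismatches: int = 3
    window: int = 3
    weighting: str = "fractional"
    min_tags: int = diff_tailing.DEFAULT_MIN_TAGS
    fold_threshold: float = 2.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def sim_config(self) -> SimConfig:
        cfg = dict(self.simulate or {})
        cfg.setdefault("seed", self.seed)
        cfg.setdefault("adapter", self.adapter)
        if "conditions" in cfg:
            cfg["conditions"] = tuple(cfg["conditions"])
        if "mature_length_range" in cfg:
            cfg["mature_length_range"] = tuple(cfg["mature_length_range"])
        if "offset_probs" in cfg:
            cfg["offset_probs"] = {int(k): v for k, v in cfg["offset_probs"].items()}
        return SimConfig(**cfg)


def validate_config(config: RunConfig) -> list[str]:
    """Collect configuration problems; an empty list means valid."""
    problems: list[str] = []
    if set(config.adapter) - set("ACGT"):
        problems.append("adapter contains non-ACGT characters")
    if config.min_length < 1:
        problems.append("min_length must be >= 1")
    if config.window < 0:
        problems.append("window must be >= 0")
    if config.max_mismatches < 0:
        problems.append("max_mismatches must be >= 0")
    if config.min_tags < 0:
        problems.append("min_tags must be >= 0")
    if config.weighting not in ("fractional", "unique"):
        problems.append("weighting must be 'fractional' or 'unique'")
    if config.simulate is None:
        for label, path in [("genome", config.genome), ("annotation", config.annotation)]:
            if path is None:
                problems.append(f"{label} path required when not simulating")
            elif not Path(path).exists():
                problems.append(f"{label} path does not exist: {path}")
        sources = config.fastq or config.sam
        if not sources:
            problems.append("either fastq or sam inputs required when not simulating")
        for cond, path in {**config.fastq, **config.sam}.items():
            if not Path(path).exists():
                problems.append(f"input for condition {cond!r} does not exist: {path}")
    else:
        try:
            config.sim_config().validate()
        except Exception as exc:  # configuration errors surfaced as problems
            problems.append(str(exc))
    return problems


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: RunConfig) -> dict:
    """Execute every stage and return the run manifest."""
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid configuration: " + "; ".join(problems))

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "mirtail_version": __version__,
        "parameters": dataclasses.asdict(config),
        "stages": {},
        "inputs": {},
    }

    # --- inputs -----------------------------------------------------------
    if config.simulate is not None:
        sim_cfg = config.sim_config()
        genome, mirnas, reads_by_cond, truth = simdata.write_simulation(sim_cfg, outdir / "sim")
        conditions = list(sim_cfg.conditions)
        manifest["stages"]["simulate"] = {
            cond: len(reads_by_cond[cond]) for cond in conditions
        }
        for name in ("genome.fa", "mirnas.gff3", "truth.tsv"):
            manifest["inputs"][name] = _sha256(outdir / "sim" / name)
    else:
        genome = refio.read_genome(config.genome)
        mirnas = refio.read_gff3(config.annotation, genome)
        conditions = list(config.fastq or config.sam)
        reads_by_cond = {
            cond: refio.read_fastq(path) for cond, path in config.fastq.items()
        }
        for label, path in [("genome", config.genome), ("annotation", config.annotation)]:
            manifest["inputs"][label] = _sha256(Path(path))

    index = mirna_quant.MirnaIndex(mirnas)
    names = sorted({m.name for m in mirnas})

    profiles_by_cond: dict[str, list] = {}
    count_tables: dict[str, pd.DataFrame] = {}
    for cond in conditions:
        stage: dict = {}
        # --- trim + N ----------------------------------------------------
        if cond in reads_by_cond:
            kept, trim_stats = preprocess.trim_reads(
                reads_by_cond[cond], adapter=config.adapter, min_length=config.min_length
            )
            stage["trim"] = trim_stats
            N = preprocess.library_size(kept)
            refio.write_fastq(kept, outdir / f"trimmed_{cond}.fastq")
            alignments = align_filter.toy_align(kept, genome, config.max_mismatches)
        else:  # pre-aligned SAM input: N from record count
            alignments, sam_stats = align_filter.read_sam(config.sam[cond])
            stage["sam_ingest"] = sam_stats
            N = len({a.read_id for a in alignments})
        stage["alignments"] = len(alignments)

        # --- min-mismatch retention --------------------------------------
        retained = align_filter.min_mismatch_filter(alignments)
        stage["retained_alignments"] = len(retained)
        refio.write_sam(retained, genome, outdir / f"filtered_{cond}.sam")

        # --- assignment + counts -----------------------------------------
        assignments = mirna_quant.assign_reads(
            retained, index, window=config.window, weighting=config.weighting
        )
        stage["assigned_reads"] = int(assignments["read_id"].nunique()) if len(assignments) else 0
        assignments.to_csv(outdir / f"assignments_{cond}.tsv", sep="\t", index=False)
        table = mirna_quant.build_count_table(assignments, N, cond, all_mirnas=names)
        table.to_csv(outdir / f"counts_{cond}.tsv", sep="\t", index=False)
        count_tables[cond] = table

        # --- tailing ------------------------------------------------------
        profiles = tailing.profiles_from_assignments(assignments, mirnas, genome, cond)
        profiles_by_cond[cond] = profiles
        tailing.profiles_to_frame(profiles).to_csv(
            outdir / f"tailing_{cond}.tsv", sep="\t", index=False
        )
        manifest["stages"][cond] = stage

    # --- between-condition comparison ------------------------------------
    if len(conditions) >= 2:
        wt, mut = conditions[0], conditions[1]
        composition = tailing.plus_one_composition(
            pd.concat(
                [tailing.profiles_to_frame(profiles_by_cond[c]) for c in (wt, mut)],
                ignore_index=True,
            )
        )
        composition.to_csv(outdir / "plus_one_composition.tsv", sep="\t", index=False)
        changes = diff_tailing.change_table(profiles_by_cond[wt], profiles_by_cond[mut])
        ranked = diff_tailing.rank_and_quartile(changes, min_tags=config.min_tags)
        expression = mirna_quant.expression_compare(count_tables[wt], count_tables[mut])
        expression.to_csv(outdir / "expression_ratio.tsv", sep="\t", index=False)
        annotated = diff_tailing.intersect_with_expression(
            ranked, expression, fold_threshold=config.fold_threshold
        )
        annotated.to_csv(outdir / "uridylation_change.tsv", sep="\t", index=False)
        manifest["stages"]["diff"] = {
            "n_analysed": int(ranked["analysed"].sum()),
            "top_quartile": int(ranked["in_top_quartile_decrease"].sum()),
        }

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
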