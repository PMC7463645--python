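"""End-to-end orchestration: consensus -> error rates -> diversity -> distances -> exports.

A run is a pure function of its inputs, configuration, and seed.  The input
is either a replicate table on disk (a completed lab study) or a simulation
configuration; every stage writes the documented delimited-text formats, so
stages compose via files and any stage can be re-run from the previous
stage's output.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import genotype_io, popgen
from .consensus import (
    ConsensusCall,
    RoundState,
    Thresholds,
    build_matrix,
    call_consensus,
    evaluate_sample,
)
from .errors import ErrorRateSummary, summarize_errors
from .simulate import SimulationConfig, StudyData, simulate_study
from .types import GenotypeMatrix, ReplicateTable

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "consensus_stage"]

logger = logging.getLogger("histstr")


@dataclass
class RunConfig:
    """Configuration of a pipeline run.

    Exactly one of ``replicates_path`` (a replicate table on disk) or
    ``simulation`` (a :class:`~histstr.simulate.SimulationConfig`) must be
    set.  ``historical_pops`` / ``modern_pops`` define the allele-turnover
    comparison; when omitted, populations whose name ends in ``_H`` form the
    historical group and the rest the modern group.
    """

    outdir: Path
    replicates_path: Optional[Path] = None
    simulation: Optional[SimulationConfig] = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    rarefaction_g: Optional[int] = None
    bootstrap_reps: int = 1000
    seed: int = 0
    historical_pops: Optional[Tuple[str, ...]] = None
    modern_pops: Optional[Tuple[str, ...]] = None

    def __post_init__(self) -> None:
        if (self.replicates_path is None) == (self.simulation is None):
            raise ValueError(
                "exactly one of replicates_path or simulation must be configured"
            )
        self.outdir = Path(self.outdir)

    @classmethod
    def from_yaml(cls, path, outdir, seed: Optional[int] = None) -> "RunConfig":
        """Load a run configuration from a YAML file.

        Recognised top-level keys: ``simulation`` (nested generator config),
        ``replicates`` (path to a replicate table), ``thresholds``,
        ``rarefaction_g``, ``bootstrap_reps``, ``seed``, ``historical_pops``,
        ``modern_pops``.
        """
        with open(path) as fh:
            spec = yaml.safe_load(fh) or {}
        sim = None
        if "simulation" in spec:
            sim_spec = dict(spec["simulation"])
            if seed is not None:
                sim_spec["seed"] = seed
            sim = SimulationConfig.from_dict(sim_spec)
        th = Thresholds(**spec.get("thresholds", {}))
        return cls(
            outdir=Path(outdir),
            replicates_path=Path(spec["replicates"]) if "replicates" in spec else None,
            simulation=sim,
            thresholds=th,
            rarefaction_g=spec.get("rarefaction_g"),
            bootstrap_reps=int(spec.get("bootstrap_reps", 1000)),
            seed=int(seed if seed is not None else spec.get("seed", 0)),
            historical_pops=tuple(spec["historical_pops"]) if "historical_pops" in spec else None,
            modern_pops=tuple(spec["modern_pops"]) if "modern_pops" in spec else None,
        )


@dataclass
class PipelineResult:
    matrix: GenotypeMatrix
    error_summary: Optional[ErrorRateSummary]
    diversity: pd.DataFrame
    fst: Optional[popgen.DistanceMatrix]
    jost_d: Optional[popgen.DistanceMatrix]
    turnover: Optional[popgen.AlleleTurnover]
    paths: Dict[str, Path]


def consensus_stage(
    table: ReplicateTable, thresholds: Thresholds
) -> Tuple[Dict[str, List[ConsensusCall]], Dict[str, "object"], GenotypeMatrix]:
    """Consensus-call a finished replicate table and apply the acceptance rules.

    The table is assumed to hold each sample's final replicate set (the lab
    work is done), so the evaluation is terminal: verdicts are *accept* or
    *discard*.
    """
    final_state = RoundState(extraction_round=thresholds.max_rounds, extended=True)
    calls_by_sample: Dict[str, List[ConsensusCall]] = {}
    decisions: Dict[str, object] = {}
    accepted: List[ConsensusCall] = []
    for sample in table.samples:
        calls = [
            call_consensus(table.replicates(sample, locus))
            for locus in table.loci
            if table.replicates(sample, locus)
        ]
        calls_by_sample[sample] = calls
        decision = evaluate_sample(calls, final_state, thresholds)
        decisions[sample] = decision
        if decision.verdict == "accept":
            accepted.extend(calls)
        else:
            logger.info(
                "sample %s discarded (failing loci: %s)",
                sample,
                ", ".join(decision.failing_loci) or "none",
            )
    matrix = build_matrix(accepted, table.populations, loci=table.loci)
    return calls_by_sample, decisions, matrix


def _split_groups(
    matrix: GenotypeMatrix, config: RunConfig
) -> Tuple[Tuple[str, ...], Tuple[str, ...]]:
    if config.historical_pops is not None and config.modern_pops is not None:
        return tuple(config.historical_pops), tuple(config.modern_pops)
    hist = tuple(p for p in matrix.population_ids if p.endswith("_H"))
    modern = tuple(p for p in matrix.population_ids if not p.endswith("_H"))
    return hist, modern


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full analysis and write the report bundle to ``config.outdir``.

    Outputs: consensus table, error summary, diversity summary, FST and
    Jost's D matrices (CSV + PHYLIP), allele-turnover report, GenAlEx and
    STRUCTURE exports, and a run log with the seed, thresholds and
    per-sample decisions.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}

    log_path = outdir / "run_log.txt"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        logger.info("seed=%d thresholds=%s", config.seed, config.thresholds)

        stage = "input"
        try:
            if config.simulation is not None:
                study = simulate_study(config.simulation, config.thresholds)
                table = study.replicate_table
                genotype_io.write_replicate_table(table, outdir / "replicates.csv")
                paths["replicates"] = outdir / "replicates.csv"
                calls_by_sample = study.calls
                decisions = study.decisions
                matrix = study.matrix
                for sample, decision in decisions.items():
                    if decision.verdict != "accept":
                        logger.info(
                            "sample %s discarded (failing loci: %s)",
                            sample,
                            ", ".join(decision.failing_loci) or "none",
                        )
            else:
                table = genotype_io.read_replicate_table(config.replicates_path)
                stage = "consensus"
                calls_by_sample, decisions, matrix = consensus_stage(
                    table, config.thresholds
                )

            stage = "consensus"
            all_calls = [c for calls in calls_by_sample.values() for c in calls]
            genotype_io.write_consensus_table(
                all_calls, table.populations, outdir / "consensus.csv", decisions
            )
            paths["consensus"] = outdir / "consensus.csv"
            n_accept = sum(1 for d in decisions.values() if d.verdict == "accept")
            logger.info(
                "consensus: %d samples evaluated, %d accepted", len(decisions), n_accept
            )

            stage = "errors"
            error_summary: Optional[ErrorRateSummary] = None
            replicated_samples = set(table.samples)
            if replicated_samples and any(
                len(table.replicates(s, l)) > 1 for s in table.samples for l in table.loci
            ):
                error_summary = summarize_errors(table, matrix)
                error_summary.per_locus.to_csv(outdir / "error_summary.csv", index=False)
                pd.Series(error_summary.pooled).to_csv(
                    outdir / "error_summary_pooled.csv", header=False
                )
                paths["error_summary"] = outdir / "error_summary.csv"

            stage = "diversity"
            diversity = popgen.diversity_summary(
                matrix,
                rarefaction_g=config.rarefaction_g,
                n_boot=config.bootstrap_reps,
                seed=config.seed,
            )
            diversity.to_csv(outdir / "diversity.csv", index=False)
            paths["diversity"] = outdir / "diversity.csv"

            stage = "distances"
            fst_dm = d_dm = None
            if len(matrix.population_ids) >= 2:
                fst_dm = popgen.distance_matrix(matrix, "fst")
                d_dm = popgen.distance_matrix(matrix, "jost_d")
                fst_dm.to_frame().to_csv(outdir / "fst.csv")
                d_dm.to_frame().to_csv(outdir / "jost_d.csv")
                genotype_io.write_phylip_distance(fst_dm, outdir / "fst.phy")
                genotype_io.write_phylip_distance(d_dm, outdir / "jost_d.phy")
                paths["fst"] = outdir / "fst.csv"
                paths["jost_d"] = outdir / "jost_d.csv"

            stage = "turnover"
            turnover = None
            hist, modern = _split_groups(matrix, config)
            if hist and modern:
                turnover = popgen.allele_turnover(matrix, hist, modern)
                rows = [
                    {"locus": l, "allele": a, "status": "lost"}
                    for l, a in sorted(turnover.lost)
                ] + [
                    {"locus": l, "allele": a, "status": "novel"}
                    for l, a in sorted(turnover.novel)
                ]
                pd.DataFrame(rows, columns=["locus", "allele", "status"]).to_csv(
                    outdir / "turnover.csv", index=False
                )
                paths["turnover"] = outdir / "turnover.csv"
                logger.info(
                    "turnover: %d alleles lost, %d novel", len(turnover.lost), len(turnover.novel)
                )

            stage = "exports"
            genotype_io.write_genalex(matrix, outdir / "genotypes_genalex.csv")
            genotype_io.write_structure(matrix, outdir / "genotypes.str")
            paths["genalex"] = outdir / "genotypes_genalex.csv"
            paths["structure"] = outdir / "genotypes.str"
        except Exception as exc:
            logger.exception("pipeline aborted at stage %r", stage)
            raise RuntimeError(f"pipeline aborted at stage {stage!r}: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()

    return PipelineResult(
        matrix=matrix,
        error_summary=error_summary,
        diversity=diversity,
        fst=fst_dm,
        jost_d=d_dm,
        turnover=turnover,
        paths=paths,
    )
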