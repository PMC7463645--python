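"""Multiple-tube consensus genotyping: quality indices and the genotyping workflow.

The multiple-tube approach repeats independent PCR amplifications of the
same DNA extract and calls, per sample and locus, the strictly most frequent
full genotype among the positive replicates.  The quality index (QI) is the
fraction of positive replicates that match that consensus; replicates that
deviate (through allelic drop-out or false alleles) lower it, while
amplification failures are excluded from the denominator and accounted
separately as the failure rate.

The workflow layer is a pure state machine: given the calls for one sample
and the current round state it answers *accept*, *extend_replicates* (run
three more PCRs from the same extract), *re_extract* (new DNA extraction,
fresh replicates) or *discard*.  It never triggers lab work itself — during
simulation a driver in :mod:`histstr.simulate` plays the lab's role.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .types import AllelePair, GenotypeMatrix, ReplicateRecord

__all__ = [
    "ConsensusCall",
    "Thresholds",
    "RoundState",
    "SampleDecision",
    "call_consensus",
    "quality_index",
    "evaluate_sample",
    "build_matrix",
]


@dataclass(frozen=True)
class ConsensusCall:
    """Consensus genotype of one sample at one locus.

    ``genotype is None`` means undetermined: either no positive replicate, or
    a tie for the most frequent genotype (no strict plurality).  ``qi`` is
    ``n_match / n_positive`` and is ``None`` when there is no positive
    replicate.
    """

    sample_id: str
    locus_id: str
    genotype: Optional[AllelePair]
    n_replicates: int
    n_positive: int
    n_match: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_match <= self.n_positive <= self.n_replicates):
            raise ValueError(
                f"inconsistent counts: match={self.n_match} "
                f"positive={self.n_positive} replicates={self.n_replicates}"
            )

    @property
    def qi(self) -> Optional[float]:
        if self.n_positive == 0:
            return None
        return self.n_match / self.n_positive

    @property
    def determined(self) -> bool:
        return self.genotype is not None

    @property
    def amplified(self) -> bool:
        """At least one positive PCR at this locus."""
        return self.n_positive > 0


@dataclass(frozen=True)
class Thresholds:
    """Reliability thresholds of the genotyping workflow.

    Defaults follow the protocol for degraded museum DNA: QI >= 0.75 at every
    locus, at least 6 of the panel's loci amplified, at least 4 positive PCRs
    per locus, 5 initial replicates, 3 extension replicates, and at most 2
    extraction rounds (the protocol loops "re-extract or discard" without a
    stated bound; bounding it makes the workflow terminate).
    """

    qi_min: float = 0.75
    min_loci_amplified: int = 6
    min_positive_per_locus: int = 4
    initial_replicates: int = 5
    extension_replicates: int = 3
    max_rounds: int = 2

    def __post_init__(self) -> None:
        if not (0 < self.qi_min <= 1):
            raise ValueError("qi_min must lie in (0, 1]")
        for name in (
            "min_loci_amplified",
            "min_positive_per_locus",
            "initial_replicates",
            "extension_replicates",
            "max_rounds",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


@dataclass
class RoundState:
    """Where one sample stands in the workflow.

    ``extraction_round`` counts DNA extractions (1-based); ``extended`` is
    True once the three extension replicates of the current extraction have
    been run.
    """

    extraction_round: int = 1
    extended: bool = False


@dataclass(frozen=True)
class SampleDecision:
    sample_id: str
    verdict: str  # accept | extend_replicates | re_extract | discard
    failing_loci: Tuple[str, ...] = ()

    _VERDICTS = ("accept", "extend_replicates", "re_extract", "discard")

    def __post_init__(self) -> None:
        if self.verdict not in self._VERDICTS:
            raise ValueError(f"unknown verdict {self.verdict!r}")


def call_consensus(replicates: Sequence[ReplicateRecord]) -> ConsensusCall:
    """Call the consensus genotype over the replicates of one sample x locus.

    The consensus is the strictly most frequent full (unordered) genotype
    among positive replicates; a replicate matching only one allele is a
    non-match.  A tie yields an undetermined call (the workflow treats it as
    QI-failing, triggering extension).  If every replicate failed the call is
    undetermined with no positives.
    """
    if not replicates:
        raise ValueError("at least one replicate record is required")
    samples = {r.sample_id for r in replicates}
    loci = {r.locus_id for r in replicates}
    if len(samples) > 1 or len(loci) > 1:
        raise ValueError(f"replicates span multiple samples/loci: {samples} x {loci}")
    sample_id, locus_id = replicates[0].sample_id, replicates[0].locus_id

    positives = [r.genotype for r in replicates if r.genotype is not None]
    n_rep, n_pos = len(replicates), len(positives)
    if n_pos == 0:
        return ConsensusCall(sample_id, locus_id, None, n_rep, 0, 0)
    counts: Dict[AllelePair, int] = {}
    for g in positives:
        counts[g] = counts.get(g, 0) + 1
    top = max(counts.values())
    winners = [g for g, c in counts.items() if c == top]
    genotype = winners[0] if len(winners) == 1 else None
    return ConsensusCall(sample_id, locus_id, genotype, n_rep, n_pos, top)


def quality_index(call: ConsensusCall) -> float:
    """QI of a call: matching positives / all positives.

    Raises
    ------
    ValueError
        If the call has no positive replicate (QI undefined).
    """
    if call.n_positive == 0:
        raise ValueError(f"QI undefined for {call.sample_id}/{call.locus_id}: no positive PCR")
    return call.n_match / call.n_positive


def evaluate_sample(
    calls: Sequence[ConsensusCall],
    round_state: RoundState,
    thresholds: Thresholds = Thresholds(),
) -> SampleDecision:
    """Decide the workflow verdict for one sample from its per-locus calls.

    Order of the rules:

    1. fewer than ``min_loci_amplified`` loci with a positive PCR, or any
       locus with fewer than ``min_positive_per_locus`` positives ->
       *re_extract* (or *discard* once extraction rounds are exhausted);
    2. any locus with QI below ``qi_min`` or an undetermined consensus ->
       *extend_replicates* if the extension has not been used this round,
       else *re_extract* while rounds remain, else *discard*;
    3. otherwise *accept*.
    """
    if not calls:
        raise ValueError("no calls supplied")
    sample_ids = {c.sample_id for c in calls}
    if len(sample_ids) > 1:
        raise ValueError(f"calls span multiple samples: {sample_ids}")
    loci = [c.locus_id for c in calls]
    if len(loci) != len(set(loci)):
        raise ValueError("duplicate loci in calls")
    sample_id = calls[0].sample_id
    rounds_remain = round_state.extraction_round < thresholds.max_rounds

    amplified = sum(1 for c in calls if c.amplified)
    depth_failing = tuple(
        c.locus_id for c in calls if c.n_positive < thresholds.min_positive_per_locus
    )
    if amplified < thresholds.min_loci_amplified or depth_failing:
        failing = depth_failing or tuple(c.locus_id for c in calls if not c.amplified)
        verdict = "re_extract" if rounds_remain else "discard"
        return SampleDecision(sample_id, verdict, failing)

    qi_failing = tuple(
        c.locus_id
        for c in calls
        if not c.determined or quality_index(c) < thresholds.qi_min
    )
    if qi_failing:
        if not round_state.extended:
            return SampleDecision(sample_id, "extend_replicates", qi_failing)
        if rounds_remain:
            return SampleDecision(sample_id, "re_extract", qi_failing)
        return SampleDecision(sample_id, "discard", qi_failing)
    return SampleDecision(sample_id, "accept", ())


def build_matrix(
    calls: Iterable[ConsensusCall],
    populations: Mapping[str, str],
    loci: Optional[Sequence[str]] = None,
) -> GenotypeMatrix:
    """Assemble accepted consensus calls into a :class:`GenotypeMatrix`.

    Undetermined calls become missing cells.  The caller is responsible for
    passing only calls of accepted samples.
    """
    calls = list(calls)
    if loci is None:
        loci = []
        for c in calls:
            if c.locus_id not in loci:
                loci.append(c.locus_id)
    entries: Dict[Tuple[str, str], Optional[AllelePair]] = {}
    for c in calls:
        entries[(c.sample_id, c.locus_id)] = c.genotype
    pops = {c.sample_id: populations[c.sample_id] for c in calls}
    return GenotypeMatrix(entries, pops, loci)
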