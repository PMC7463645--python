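"""Genotyping-error estimation from replicated PCRs against consensus genotypes.

Implements the replicate-classification protocol standard for multiple-tube
STR data: a positive replicate is scored against the consensus genotype of
its sample x locus; allelic drop-out (ADO) is the loss of one allele of a
heterozygous consensus, a false allele (FA) is any allele absent from the
consensus, and a replicate can show both at once.  Rates are reported per
locus and pooled:

* failure rate  = failed replicates / all replicates,
* ADO rate      = ADO replicates / positive replicates of heterozygous-
  consensus samples,
* FA rate       = FA replicates / positive replicates,
* overall error = replicates whose genotype differs from the consensus /
  positive replicates (a jointly ADO+FA replicate counts once).

Pooled rates are event-count ratios over pooled denominators (not unweighted
column means), with binomial standard errors; the mean allele count across
loci is an unweighted mean with the sample (n-1) standard deviation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .consensus import ConsensusCall
from .types import AllelePair, GenotypeMatrix, ReplicateRecord, ReplicateTable

__all__ = [
    "UndefinedStatisticError",
    "ReplicateClass",
    "ErrorRateSummary",
    "RegressionResult",
    "DropoutBias",
    "classify_replicate",
    "failure_rate",
    "ado_rate",
    "fa_rate",
    "overall_error_rate",
    "summarize_errors",
    "correct_genotyping_probability",
    "locus_correct_probability",
    "length_failure_regression",
    "length_ado_regression",
    "long_vs_short_dropout",
    "pooled_rate",
    "mean_sd",
]


class UndefinedStatisticError(ValueError):
    """An estimator's denominator is empty or its inputs are degenerate."""


@dataclass(frozen=True)
class ReplicateClass:
    """Classification of one replicate against its consensus genotype.

    ``kinds`` is a subset of {match, ado, fa, failure}; failure excludes all
    others, ADO is only defined against a heterozygous consensus, and a
    replicate may be simultaneously ADO and FA.
    """

    kinds: frozenset
    dropped_allele: Optional[int] = None
    false_alleles: Tuple[int, ...] = ()

    @property
    def is_failure(self) -> bool:
        return "failure" in self.kinds

    @property
    def is_match(self) -> bool:
        return "match" in self.kinds

    @property
    def is_ado(self) -> bool:
        return "ado" in self.kinds

    @property
    def is_fa(self) -> bool:
        return "fa" in self.kinds

    @property
    def altered(self) -> bool:
        """Positive replicate whose genotype differs from the consensus."""
        return bool(self.kinds & {"ado", "fa"})


def classify_replicate(replicate: ReplicateRecord, consensus: AllelePair) -> ReplicateClass:
    """Score one replicate against the consensus genotype of its cell.

    A failed amplification is ``{failure}``.  A positive replicate is ADO if
    the consensus is heterozygous and exactly one consensus allele is present
    (as a homozygote or paired with a spurious allele); it is FA if it
    carries any allele absent from the consensus; it is a match iff its
    genotype equals the consensus.
    """
    if replicate.genotype is None:
        return ReplicateClass(frozenset({"failure"}))
    g = replicate.genotype
    if g == consensus:
        return ReplicateClass(frozenset({"match"}))
    kinds = set()
    false_alleles = tuple(sorted({x for x in g.alleles if x not in consensus}))
    if false_alleles:
        kinds.add("fa")
    dropped = None
    if consensus.heterozygous:
        present = [x for x in consensus.alleles if x in g]
        if len(present) == 1:
            kinds.add("ado")
            dropped = consensus.b if present[0] == consensus.a else consensus.a
    return ReplicateClass(frozenset(kinds), dropped, false_alleles)


def _locus_counts(
    table: ReplicateTable, matrix: GenotypeMatrix, locus: str
) -> Dict[str, int]:
    """Event and denominator counts at one locus.

    Only samples with a determined consensus genotype contribute to the
    positive-PCR denominators; the failure denominator spans all replicates.
    """
    n_rep = n_fail = n_pos = n_het_pos = n_ado = n_fa = n_alt = 0
    for sample in table.samples:
        reps = table.replicates(sample, locus)
        n_rep += len(reps)
        n_fail += sum(1 for r in reps if r.failed)
        consensus = matrix.genotype(sample, locus)
        if consensus is None:
            continue
        for rec in reps:
            if rec.failed:
                continue
            n_pos += 1
            cls = classify_replicate(rec, consensus)
            if consensus.heterozygous:
                n_het_pos += 1
                if cls.is_ado:
                    n_ado += 1
            if cls.is_fa:
                n_fa += 1
            if cls.altered:
                n_alt += 1
    return {
        "n_replicates": n_rep,
        "n_failures": n_fail,
        "n_positive": n_pos,
        "n_het_positive": n_het_pos,
        "n_ado": n_ado,
        "n_fa": n_fa,
        "n_altered": n_alt,
    }


def failure_rate(table: ReplicateTable, locus: str) -> float:
    """Amplification failure at a locus, in percent of all replicates."""
    reps = [r for r in table.records if r.locus_id == locus]
    if not reps:
        raise UndefinedStatisticError(f"no replicates at locus {locus!r}")
    return 100.0 * sum(1 for r in reps if r.failed) / len(reps)


def ado_rate(table: ReplicateTable, matrix: GenotypeMatrix, locus: str) -> float:
    """ADO rate at a locus, in percent of positive PCRs of heterozygous-consensus samples."""
    c = _locus_counts(table, matrix, locus)
    if c["n_het_positive"] == 0:
        raise UndefinedStatisticError(
            f"ADO rate not applicable at {locus!r}: no heterozygous consensus"
        )
    return 100.0 * c["n_ado"] / c["n_het_positive"]


def fa_rate(table: ReplicateTable, matrix: GenotypeMatrix, locus: str) -> float:
    """False-allele rate at a locus, in percent of positive PCRs."""
    c = _locus_counts(table, matrix, locus)
    if c["n_positive"] == 0:
        raise UndefinedStatisticError(f"FA rate undefined at {locus!r}: no positive PCR")
    return 100.0 * c["n_fa"] / c["n_positive"]


def overall_error_rate(table: ReplicateTable, matrix: GenotypeMatrix, locus: str) -> float:
    """Percent of positive PCRs whose genotype differs from the consensus."""
    c = _locus_counts(table, matrix, locus)
    if c["n_positive"] == 0:
        raise UndefinedStatisticError(f"error rate undefined at {locus!r}: no positive PCR")
    return 100.0 * c["n_altered"] / c["n_positive"]


def pooled_rate(events: int, trials: int) -> Tuple[float, float]:
    """Pooled percentage and its binomial standard error (both in percent)."""
    if trials <= 0:
        raise UndefinedStatisticError("pooled rate undefined: empty denominator")
    p = events / trials
    return 100.0 * p, 100.0 * math.sqrt(p * (1.0 - p) / trials)


def mean_sd(values: Sequence[float]) -> Tuple[float, float]:
    """Unweighted mean and sample (n-1) standard deviation of per-locus values."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise UndefinedStatisticError("need at least two values for a sample SD")
    return float(arr.mean()), float(arr.std(ddof=1))


@dataclass
class ErrorRateSummary:
    """Per-locus and pooled genotyping-error rates (all rates in percent).

    ``per_locus`` has one row per locus with the observed allele range,
    allele count, event counts and the four rates; ``pooled`` holds the
    pooled-count rates with binomial standard errors plus the mean +/- SD of
    per-locus allele counts.
    """

    per_locus: pd.DataFrame
    pooled: Dict[str, float]


def summarize_errors(table: ReplicateTable, matrix: GenotypeMatrix) -> ErrorRateSummary:
    """Build the per-locus / pooled error-rate summary for a replicate study."""
    rows: List[Dict[str, object]] = []
    totals = {k: 0 for k in (
        "n_replicates", "n_failures", "n_positive", "n_het_positive",
        "n_ado", "n_fa", "n_altered",
    )}
    for locus in table.loci:
        c = _locus_counts(table, matrix, locus)
        for k in totals:
            totals[k] += c[k]
        alleles = sorted(matrix.observed_alleles(locus))
        row: Dict[str, object] = {
            "locus": locus,
            "range_min": alleles[0] if alleles else pd.NA,
            "range_max": alleles[-1] if alleles else pd.NA,
            "n_alleles": len(alleles),
            **c,
        }
        row["failure_pct"] = (
            100.0 * c["n_failures"] / c["n_replicates"] if c["n_replicates"] else np.nan
        )
        row["ado_pct"] = (
            100.0 * c["n_ado"] / c["n_het_positive"] if c["n_het_positive"] else np.nan
        )
        row["fa_pct"] = 100.0 * c["n_fa"] / c["n_positive"] if c["n_positive"] else np.nan
        row["error_pct"] = (
            100.0 * c["n_altered"] / c["n_positive"] if c["n_positive"] else np.nan
        )
        rows.append(row)
    per_locus = pd.DataFrame(rows)

    pooled: Dict[str, float] = {}
    for name, ev, denom in (
        ("failure", "n_failures", "n_replicates"),
        ("ado", "n_ado", "n_het_positive"),
        ("fa", "n_fa", "n_positive"),
        ("error", "n_altered", "n_positive"),
    ):
        if totals[denom] > 0:
            rate, se = pooled_rate(totals[ev], totals[denom])
        else:
            rate, se = np.nan, np.nan
        pooled[f"{name}_pct"] = rate
        pooled[f"{name}_se"] = se
    counts = per_locus["n_alleles"].to_numpy(dtype=float)
    if counts.size >= 2:
        pooled["mean_alleles"], pooled["sd_alleles"] = mean_sd(counts)
    else:
        pooled["mean_alleles"] = float(counts.mean()) if counts.size else np.nan
        pooled["sd_alleles"] = np.nan
    return ErrorRateSummary(per_locus=per_locus, pooled=pooled)


def correct_genotyping_probability(call: ConsensusCall, ado: float) -> float:
    """Probability that a consensus call is a false homozygote.

    For a homozygous consensus supported by ``k`` matching positive
    replicates, the probability that a true heterozygote produced ``k``
    independent same-allele drop-outs is ``ado**k``.  A heterozygous
    consensus cannot be produced by drop-out, so the probability is 0.
    """
    if not (0.0 <= ado < 1.0):
        raise ValueError("ado must lie in [0, 1)")
    if call.genotype is None:
        raise UndefinedStatisticError("call is undetermined")
    if call.genotype.heterozygous:
        return 0.0
    if call.n_match == 0:
        raise UndefinedStatisticError("homozygous call with no supporting replicate")
    return ado ** call.n_match


def locus_correct_probability(calls: Iterable[ConsensusCall], ado: float) -> float:
    """Locus-level probability of an undetected false homozygote.

    The maximum of :func:`correct_genotyping_probability` over the locus's
    determined calls — the weakest sample bounds the locus.
    """
    probs = [
        correct_genotyping_probability(c, ado) for c in calls if c.genotype is not None
    ]
    if not probs:
        raise UndefinedStatisticError("no determined calls at locus")
    return max(probs)


@dataclass(frozen=True)
class RegressionResult:
    """Ordinary least squares of a per-locus rate on fragment length."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def _rate_length_regression(
    summary: ErrorRateSummary,
    response: str,
    locus_lengths: Optional[Mapping[str, float]] = None,
) -> RegressionResult:
    frame = summary.per_locus
    if locus_lengths is None:
        lengths = (frame["range_min"].astype(float) + frame["range_max"].astype(float)) / 2.0
    else:
        lengths = frame["locus"].map(locus_lengths).astype(float)
    y = frame[response].astype(float)
    keep = lengths.notna() & y.notna()
    x, y = lengths[keep].to_numpy(), y[keep].to_numpy()
    if x.size < 3:
        raise UndefinedStatisticError("need at least three loci for a regression")
    if np.ptp(x) == 0:
        raise UndefinedStatisticError("constant predictor: fragment lengths identical")
    if np.ptp(y) == 0:
        # flat response: slope is exactly 0 but r^2 and the slope test are undefined
        return RegressionResult(0.0, float(y[0]), float("nan"), float("nan"), int(x.size))
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        n=int(x.size),
    )


def length_failure_regression(
    summary: ErrorRateSummary, locus_lengths: Optional[Mapping[str, float]] = None
) -> RegressionResult:
    """OLS of per-locus amplification-failure rate on mean fragment length.

    The default length covariate is the midpoint of the observed allele
    range.  Returns slope, r-squared, and the two-sided t-test p-value of
    the slope.
    """
    return _rate_length_regression(summary, "failure_pct", locus_lengths)


def length_ado_regression(
    summary: ErrorRateSummary, locus_lengths: Optional[Mapping[str, float]] = None
) -> RegressionResult:
    """OLS of per-locus ADO rate on mean fragment length."""
    return _rate_length_regression(summary, "ado_pct", locus_lengths)


@dataclass(frozen=True)
class DropoutBias:
    """Long- vs short-allele drop-out counts and the exact binomial test."""

    n_long_dropped: int
    n_short_dropped: int
    p_value: float


def long_vs_short_dropout(
    table: ReplicateTable, matrix: GenotypeMatrix, locus: str
) -> DropoutBias:
    """Test whether the longer allele of a heterozygote drops out more often.

    Counts ADO events at the locus by whether the dropped allele was the
    longer or the shorter of the consensus pair, and applies a two-sided
    exact binomial test against equal odds.
    """
    n_long = n_short = 0
    for sample in table.samples:
        consensus = matrix.genotype(sample, locus)
        if consensus is None or consensus.homozygous:
            continue
        for rec in table.replicates(sample, locus):
            if rec.failed:
                continue
            cls = classify_replicate(rec, consensus)
            if cls.is_ado and cls.dropped_allele is not None:
                if cls.dropped_allele == consensus.longer:
                    n_long += 1
                else:
                    n_short += 1
    total = n_long + n_short
    if total == 0:
        raise UndefinedStatisticError(f"no ADO event at locus {locus!r}")
    p = stats.binomtest(n_long, total, 0.5, alternative="two-sided").pvalue
    return DropoutBias(n_long, n_short, float(p))
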