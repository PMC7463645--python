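"""Replicate classification and failure/ADO/FA/overall error-rate estimation."""

import math

import numpy as np
import pytest

from histstr.consensus import ConsensusCall, build_matrix, call_consensus
from histstr.errors import (
    DropoutBias,
    UndefinedStatisticError,
    ado_rate,
    classify_replicate,
    correct_genotyping_probability,
    fa_rate,
    failure_rate,
    length_ado_regression,
    length_failure_regression,
    locus_correct_probability,
    long_vs_short_dropout,
    mean_sd,
    overall_error_rate,
    pooled_rate,
    summarize_errors,
)
from histstr.simulate import (
    ErrorParams,
    default_study_config,
    simulate_replicates,
    simulate_truth,
)
from histstr.types import AllelePair, GenotypeMatrix, ReplicateRecord, ReplicateTable

from conftest import records_for


HET = AllelePair(121, 125)
HOM = AllelePair(121, 121)


def rec(genotype, k=1):
    pair = None if genotype is None else AllelePair(*genotype)
    return ReplicateRecord("s", "P", "L", k, pair)


class TestClassifyReplicate:
    def test_false_homozygote_is_ado(self):
        cls = classify_replicate(rec((121, 121)), HET)
        assert cls.kinds == {"ado"}
        assert cls.dropped_allele == 125

    def test_spurious_allele_against_homozygote_is_fa(self):
        cls = classify_replicate(rec((121, 125)), HOM)
        assert cls.kinds == {"fa"}
        assert cls.false_alleles == (125,)

    def test_lost_allele_replaced_by_spurious_is_joint_ado_fa(self):
        cls = classify_replicate(rec((121, 129)), HET)
        assert cls.kinds == {"ado", "fa"}
        assert cls.dropped_allele == 125
        assert cls.false_alleles == (129,)

    def test_failure_excludes_all_other_kinds(self):
        cls = classify_replicate(rec(None), HET)
        assert cls.kinds == {"failure"}
        assert not cls.altered

    def test_exact_match(self):
        assert classify_replicate(rec((125, 121)), HET).kinds == {"match"}

    def test_no_consensus_allele_present_is_fa_not_ado(self):
        """Losing *both* alleles is not scored as drop-out of one."""
        cls = classify_replicate(rec((129, 131)), HET)
        assert cls.kinds == {"fa"}
        assert cls.dropped_allele is None


def build_study(cells):
    """(sample, consensus, replicate genotypes) triples -> (table, matrix)."""
    records, entries, pops = [], {}, {}
    for sample, consensus, genotypes in cells:
        pops[sample] = "P"
        entries[(sample, "L")] = None if consensus is None else AllelePair(*consensus)
        for k, g in enumerate(genotypes):
            pair = None if g is None else AllelePair(*g)
            records.append(ReplicateRecord(sample, "P", "L", k + 1, pair))
    table = ReplicateTable(records)
    matrix = GenotypeMatrix(entries, pops, ["L"])
    return table, matrix


class TestRates:
    def test_failure_rate_counts_failed_over_all_replicates(self):
        cells = [(f"s{i}", (121, 125), [(121, 125)] * 5) for i in range(49)]
        table, _ = build_study(cells)
        assert failure_rate(table, "L") == 0.0
        cells[0] = ("s0", (121, 125), [None, None] + [(121, 125)] * 3)
        table, _ = build_study(cells)
        assert failure_rate(table, "L") == pytest.approx(100 * 2 / 245)

    def test_ado_rate_over_heterozygous_positive_pcrs(self):
        """2 drop-outs over 8 het samples x 5 positives = 5.0%."""
        cells = [(f"h{i}", (121, 125), [(121, 125)] * 5) for i in range(8)]
        cells[0] = ("h0", (121, 125), [(121, 121)] + [(121, 125)] * 4)
        cells[1] = ("h1", (121, 125), [(125, 125)] + [(121, 125)] * 4)
        table, matrix = build_study(cells)
        assert ado_rate(table, matrix, "L") == pytest.approx(5.0)

    def test_ado_rate_excludes_homozygous_consensus_samples(self):
        cells = [
            ("het", (121, 125), [(121, 121)] + [(121, 125)] * 4),
            ("hom", (121, 121), [(121, 121)] * 5),  # not in the ADO denominator
        ]
        table, matrix = build_study(cells)
        assert ado_rate(table, matrix, "L") == pytest.approx(100 / 5)

    def test_all_homozygous_locus_is_not_applicable(self):
        table, matrix = build_study([("s", (121, 121), [(121, 121)] * 5)])
        with pytest.raises(UndefinedStatisticError, match="not applicable"):
            ado_rate(table, matrix, "L")

    def test_fa_rate_scale(self):
        """1 spurious-allele replicate among 270 positives = 0.37%."""
        cells = [(f"s{i}", (121, 125), [(121, 125)] * 5) for i in range(54)]
        cells[0] = ("s0", (121, 125), [(121, 129)] + [(121, 125)] * 4)
        table, matrix = build_study(cells)
        assert fa_rate(table, matrix, "L") == pytest.approx(100 / 270, abs=5e-3)

    def test_fa_rate_everything_spurious(self):
        table, matrix = build_study([("s", (121, 121), [(121, 123)] * 5)])
        assert fa_rate(table, matrix, "L") == 100.0

    def test_overall_error_counts_each_altered_replicate_once(self):
        """2 pure ADO + 1 pure FA + 1 joint among 100 positives -> 4.0%."""
        cells = [(f"s{i}", (121, 125), [(121, 125)] * 5) for i in range(20)]
        cells[0] = ("s0", (121, 125), [(121, 121), (125, 125)] + [(121, 125)] * 3)
        cells[1] = ("s1", (121, 125), [(129, 131)] + [(121, 125)] * 4)  # FA only
        cells[2] = ("s2", (121, 125), [(121, 129)] + [(121, 125)] * 4)  # ADO + FA
        table, matrix = build_study(cells)
        assert overall_error_rate(table, matrix, "L") == pytest.approx(4.0)
        assert ado_rate(table, matrix, "L") == pytest.approx(3.0)
        assert fa_rate(table, matrix, "L") == pytest.approx(2.0)

    def test_failure_parameter_recovery(self):
        """Simulated failure probability is recovered within 3 binomial SE."""
        p = 0.0588
        cfg = default_study_config(
            seed=31, include_modern=False,
            error=ErrorParams(failure=p, ado=0.0, fa=0.0),
        )
        table = simulate_replicates(simulate_truth(cfg))
        n_total = len(table)
        observed = sum(failure_rate(table, l) / 100 * 245 for l in table.loci) / n_total
        se = math.sqrt(p * (1 - p) / n_total)
        assert abs(observed - p) <= 3 * se


@pytest.fixture(scope="module")
def study():
    cfg = default_study_config(seed=17, include_modern=False)
    truth = simulate_truth(cfg)
    table = simulate_replicates(truth)
    calls = [
        call_consensus(table.replicates(s, l))
        for s in table.samples
        for l in table.loci
    ]
    matrix = build_matrix(calls, table.populations, loci=table.loci)
    return table, matrix


class TestSummarize:
    def test_pooled_rates_are_count_ratios_not_column_means(self, study):
        table, matrix = study
        summary = summarize_errors(table, matrix)
        tot = summary.per_locus.sum(numeric_only=True)
        assert summary.pooled["failure_pct"] == pytest.approx(
            100 * tot["n_failures"] / tot["n_replicates"]
        )
        assert summary.pooled["ado_pct"] == pytest.approx(
            100 * tot["n_ado"] / tot["n_het_positive"]
        )

    def test_component_events_are_subsets_of_altered(self, study):
        table, matrix = study
        per_locus = summarize_errors(table, matrix).per_locus
        assert (per_locus["n_ado"] <= per_locus["n_altered"]).all()
        assert (per_locus["n_fa"] <= per_locus["n_altered"]).all()
        assert (
            per_locus["n_altered"] <= per_locus["n_ado"] + per_locus["n_fa"]
        ).all()

    def test_rates_invariant_to_record_order(self, study):
        table, matrix = study
        reversed_table = ReplicateTable(
            list(reversed(table.records)), loci=table.loci, populations=table.populations
        )
        a = summarize_errors(table, matrix).per_locus.set_index("locus")
        b = summarize_errors(reversed_table, matrix).per_locus.set_index("locus")
        for col in ("failure_pct", "ado_pct", "fa_pct", "error_pct"):
            assert (a[col].fillna(-1) == b[col].reindex(a.index).fillna(-1)).all()

    def test_error_free_study_has_all_zero_rates(self):
        cfg = default_study_config(
            seed=3, include_modern=False, error=ErrorParams(failure=0, ado=0, fa=0)
        )
        truth = simulate_truth(cfg)
        table = simulate_replicates(truth)
        calls = [
            call_consensus(table.replicates(s, l))
            for s in table.samples
            for l in table.loci
        ]
        matrix = build_matrix(calls, table.populations, loci=table.loci)
        summary = summarize_errors(table, matrix)
        assert summary.pooled["failure_pct"] == 0
        assert summary.pooled["ado_pct"] == 0
        assert summary.pooled["fa_pct"] == 0
        assert summary.pooled["error_pct"] == 0

    def test_ado_estimator_recovers_effective_classified_rate(self):
        """The protocol's ADO estimator measures P(a consensus allele is lost),
        which is ado + (1-ado)*fa under slippage-substitution false alleles."""
        gen = ErrorParams()
        effective = gen.ado + (1 - gen.ado) * gen.fa
        hits = 0
        for run in range(20):
            cfg = default_study_config(seed=600 + run, include_modern=False)
            table = simulate_replicates(simulate_truth(cfg))
            calls = [
                call_consensus(table.replicates(s, l))
                for s in table.samples
                for l in table.loci
            ]
            matrix = build_matrix(calls, table.populations, loci=table.loci)
            tot = summarize_errors(table, matrix).per_locus.sum(numeric_only=True)
            est = tot["n_ado"] / tot["n_het_positive"]
            se = math.sqrt(effective * (1 - effective) / tot["n_het_positive"])
            hits += abs(est - effective) <= 3 * se
        assert hits >= 18


class TestPooledHelpers:
    def test_pooled_rate_and_binomial_se(self):
        rate, se = pooled_rate(7, 300)
        assert rate == pytest.approx(100 * 7 / 300)
        p = 7 / 300
        assert se == pytest.approx(100 * math.sqrt(p * (1 - p) / 300))

    def test_mean_sd_uses_sample_variance(self):
        mean, sd = mean_sd([4.0, 6.0])
        assert mean == 5.0
        assert sd == pytest.approx(math.sqrt(2.0))


class TestCorrectGenotypingProbability:
    def test_homozygote_probability_is_ado_power_k(self):
        call = ConsensusCall("s", "L", AllelePair(121, 121), 5, 3, 3)
        assert correct_genotyping_probability(call, 0.1) == pytest.approx(1e-3)

    def test_heterozygote_cannot_be_faked_by_dropout(self):
        call = ConsensusCall("s", "L", AllelePair(121, 125), 5, 5, 5)
        assert correct_genotyping_probability(call, 0.3) == 0.0

    def test_locus_probability_below_threshold_with_deep_support(self):
        """Homozygotes supported by >=4 replicates at ADO 4.07% give p < 0.001."""
        calls = [
            ConsensusCall(f"s{i}", "L", AllelePair(121, 121), 5, 4 + (i % 2), 4 + (i % 2))
            for i in range(10)
        ]
        assert locus_correct_probability(calls, 0.0407) < 1e-3


class TestLengthRegressions:
    def make_summary(self, failure, ado, lengths):
        import pandas as pd

        from histstr.errors import ErrorRateSummary

        frame = pd.DataFrame(
            {
                "locus": [f"L{i}" for i in range(len(failure))],
                "range_min": [l - 5 for l in lengths],
                "range_max": [l + 5 for l in lengths],
                "n_alleles": 5,
                "failure_pct": failure,
                "ado_pct": ado,
            }
        )
        return ErrorRateSummary(frame, {})

    def test_perfectly_linear_fixture_has_r_squared_one(self):
        lengths = [100, 140, 180, 220, 260]
        failure = [1.0 + 0.02 * l for l in lengths]
        fit = length_failure_regression(self.make_summary(failure, failure, lengths))
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.slope == pytest.approx(0.02)

    def test_permuted_response_loses_the_signal(self):
        rng = np.random.default_rng(0)
        lengths = list(range(100, 280, 20))
        failure = [1.0 + 0.02 * l for l in lengths]
        high_r2 = 0
        for _ in range(100):
            shuffled = list(rng.permutation(failure))
            fit = length_failure_regression(self.make_summary(shuffled, shuffled, lengths))
            high_r2 += fit.r_squared > 0.2
        assert high_r2 < 30  # signal is gone for the bulk of permutations

    def test_zero_variance_ado_has_undefined_slope_test(self):
        fit = length_ado_regression(self.make_summary([1, 2, 3], [2.0, 2.0, 2.0], [100, 150, 200]))
        assert fit.slope == 0.0
        assert math.isnan(fit.p_value)

    def test_constant_predictor_rejected(self):
        with pytest.raises(UndefinedStatisticError, match="constant"):
            length_failure_regression(self.make_summary([1, 2, 3], [1, 2, 3], [150, 150, 150]))

    def test_length_dependent_failure_is_recovered_from_simulation(self):
        cfg = default_study_config(
            seed=23, include_modern=False,
            error=ErrorParams(failure=0.03, failure_length_slope=0.03, ado=0.02, fa=0.005),
        )
        truth = simulate_truth(cfg)
        table = simulate_replicates(truth)
        calls = [
            call_consensus(table.replicates(s, l))
            for s in table.samples
            for l in table.loci
        ]
        matrix = build_matrix(calls, table.populations, loci=table.loci)
        fit = length_failure_regression(summarize_errors(table, matrix))
        assert fit.slope > 0
        assert fit.p_value < 0.05
        assert fit.n == 9

    def test_length_dependent_ado_gives_positive_slope(self):
        cfg = default_study_config(
            seed=29, include_modern=False,
            error=ErrorParams(failure=0.02, ado=0.05, ado_length_slope=0.03, fa=0.0),
        )
        truth = simulate_truth(cfg)
        table = simulate_replicates(truth)
        calls = [
            call_consensus(table.replicates(s, l))
            for s in table.samples
            for l in table.loci
        ]
        matrix = build_matrix(calls, table.populations, loci=table.loci)
        fit = length_ado_regression(summarize_errors(table, matrix))
        assert fit.slope > 0


class TestLongVsShortDropout:
    def build(self, events):
        """events: list of dropped 'long'/'short' for consensus (121, 125)."""
        cells = []
        for i, side in enumerate(events):
            shown = (121, 121) if side == "long" else (125, 125)
            cells.append((f"s{i}", (121, 125), [shown] + [(121, 125)] * 4))
        return build_study(cells)

    def test_balanced_dropout_is_not_significant(self):
        table, matrix = self.build(["long"] * 5 + ["short"] * 5)
        result = long_vs_short_dropout(table, matrix, "L")
        assert (result.n_long_dropped, result.n_short_dropped) == (5, 5)
        assert result.p_value == pytest.approx(1.0)

    def test_one_sided_dropout_exact_binomial(self):
        table, matrix = self.build(["long"] * 10)
        result = long_vs_short_dropout(table, matrix, "L")
        assert result.p_value == pytest.approx(2 * 0.5**10)

    def test_no_events_undefined(self):
        table, matrix = self.build([])
        cells = [("s", (121, 125), [(121, 125)] * 5)]
        table, matrix = build_study(cells)
        with pytest.raises(UndefinedStatisticError):
            long_vs_short_dropout(table, matrix, "L")

    def test_simulated_long_allele_bias_is_detected(self):
        cfg = default_study_config(
            seed=41, include_modern=False,
            error=ErrorParams(failure=0.0, ado=0.2, ado_long_bias=0.9, fa=0.0),
        )
        truth = simulate_truth(cfg)
        table = simulate_replicates(truth)
        calls = [
            call_consensus(table.replicates(s, l))
            for s in table.samples
            for l in table.loci
        ]
        matrix = build_matrix(calls, table.populations, loci=table.loci)
        n_long = n_short = 0
        for locus in table.loci:
            try:
                result = long_vs_short_dropout(table, matrix, locus)
            except UndefinedStatisticError:
                continue
            n_long += result.n_long_dropped
            n_short += result.n_short_dropped
        assert n_long > n_short
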