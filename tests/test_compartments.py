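"""Compartment-based lineage assignment: detection, classification, enrichment."""

import numpy as np
import pytest

from clonarch import (
    DetectionThresholds,
    LineageCallValue,
    SimulationConfig,
    aggregate_sample,
    build_default_architecture,
    classify_lineage,
    detect_in_compartment,
    enrichment_ratio,
    simulate_amplicons,
)
from clonarch.compartments import Detection
from clonarch.simulate import AmpliconMeasurement


def meas(compartment, alt, depth, mutation_id="m1"):
    return AmpliconMeasurement(
        sample="s1", mutation_id=mutation_id, compartment=compartment,
        alt_count=alt, depth=depth,
    )


class TestDetection:
    def test_clear_signal_is_present(self):
        assert detect_in_compartment(meas("PD1pos", 300, 1000)) is Detection.present

    def test_no_alt_reads_is_absent(self):
        assert detect_in_compartment(meas("PD1pos", 0, 1000)) is Detection.absent

    def test_shallow_depth_is_indeterminate(self):
        assert (
            detect_in_compartment(meas("PD1pos", 10, 50)) is Detection.indeterminate
        )

    def test_negative_thresholds_rejected(self):
        with pytest.raises(ValueError):
            DetectionThresholds(min_vaf=-0.01)

    def test_raising_min_vaf_only_loses_detections(self):
        m = meas("PD1pos", 30, 1000)  # VAF 0.03
        low = detect_in_compartment(m, DetectionThresholds(min_vaf=0.02))
        high = detect_in_compartment(m, DetectionThresholds(min_vaf=0.05))
        assert low is Detection.present and high is Detection.absent


class TestClassify:
    def test_pd1_only_is_t_specific(self):
        call = classify_lineage([meas("PD1pos", 300, 1000), meas("CD20pos", 0, 1000)])
        assert call.call is LineageCallValue.T_specific

    def test_both_compartments_is_multilineal(self):
        call = classify_lineage(
            [meas("PD1pos", 300, 1000), meas("CD20pos", 150, 1000)]
        )
        assert call.call is LineageCallValue.multilineal

    def test_cd20_only_is_b_specific(self):
        call = classify_lineage([meas("PD1pos", 0, 1000), meas("CD20pos", 400, 1000)])
        assert call.call is LineageCallValue.B_specific

    def test_neither_is_undetected(self):
        call = classify_lineage([meas("PD1pos", 0, 1000), meas("CD20pos", 0, 1000)])
        assert call.call is LineageCallValue.undetected

    def test_shallow_compartment_makes_call_indeterminate(self):
        call = classify_lineage([meas("PD1pos", 300, 1000), meas("CD20pos", 5, 50)])
        assert call.call is LineageCallValue.indeterminate

    def test_swapping_compartments_flips_t_and_b(self):
        t = classify_lineage([meas("PD1pos", 300, 1000), meas("CD20pos", 0, 1000)])
        b = classify_lineage([meas("PD1pos", 0, 1000), meas("CD20pos", 300, 1000)])
        assert t.call is LineageCallValue.T_specific
        assert b.call is LineageCallValue.B_specific

    def test_whole_tumor_never_changes_the_call(self):
        with_whole = classify_lineage(
            [
                meas("PD1pos", 300, 1000),
                meas("CD20pos", 0, 1000),
                meas("whole_tumor", 150, 1000),
            ]
        )
        assert with_whole.call is LineageCallValue.T_specific
        assert with_whole.enrichment_ratio == pytest.approx(2.0)

    def test_duplicate_compartment_rejected(self):
        with pytest.raises(ValueError):
            classify_lineage([meas("PD1pos", 1, 1000), meas("PD1pos", 2, 1000)])

    def test_mixed_mutations_rejected(self):
        with pytest.raises(ValueError):
            classify_lineage(
                [meas("PD1pos", 1, 1000), meas("CD20pos", 2, 1000, mutation_id="m2")]
            )


class TestEnrichment:
    def test_ratio_definition(self):
        r = enrichment_ratio(meas("PD1pos", 400, 1000), meas("whole_tumor", 100, 1000))
        assert r == pytest.approx(4.0)

    def test_equal_vafs_not_enriched(self):
        r = enrichment_ratio(meas("PD1pos", 100, 1000), meas("whole_tumor", 100, 1000))
        assert r == pytest.approx(1.0)

    def test_zero_whole_tumor_vaf_is_undefined(self):
        assert (
            enrichment_ratio(meas("PD1pos", 100, 1000), meas("whole_tumor", 0, 1000))
            is None
        )

    def test_mismatched_mutations_rejected(self):
        with pytest.raises(ValueError):
            enrichment_ratio(
                meas("PD1pos", 1, 100), meas("whole_tumor", 1, 100, mutation_id="m2")
            )


class TestAggregate:
    def test_gene_multilineal_if_any_mutation_is(self):
        calls = [
            classify_lineage([meas("PD1pos", 300, 1000, "tet2_A"),
                              meas("CD20pos", 150, 1000, "tet2_A")]),
            classify_lineage([meas("PD1pos", 300, 1000, "tet2_B"),
                              meas("CD20pos", 0, 1000, "tet2_B")]),
        ]
        summary = aggregate_sample(calls, {"tet2_A": "TET2", "tet2_B": "TET2"})
        assert summary["TET2"].multilineal and summary["TET2"].t_specific

    def test_undetected_calls_raise_no_flags(self):
        calls = [classify_lineage([meas("PD1pos", 0, 1000), meas("CD20pos", 0, 1000)])]
        summary = aggregate_sample(calls, {"m1": "TET2"})
        s = summary["TET2"]
        assert not (s.multilineal or s.t_specific or s.b_specific)

    def test_single_t_specific_call(self):
        calls = [classify_lineage([meas("PD1pos", 300, 1000, "rhoa"),
                                   meas("CD20pos", 0, 1000, "rhoa")])]
        summary = aggregate_sample(calls, {"rhoa": "RHOA"})
        assert summary["RHOA"].t_specific and not summary["RHOA"].multilineal

    def test_unknown_mutation_rejected(self):
        calls = [classify_lineage([meas("PD1pos", 1, 1000), meas("CD20pos", 1, 1000)])]
        with pytest.raises(KeyError):
            aggregate_sample(calls, {})


class TestSimulationRecovery:
    def test_calls_match_truth_on_deep_amplicons(self):
        """At amplicon depth 1000 and error 1e-3, the detection pattern
        recovers the generating lineage for essentially every mutation,
        and ancestral mutations are never mistaken for lineage-specific."""
        config = SimulationConfig(amplicon_depth_mean=1000.0, error_rate=0.001)
        tree = build_default_architecture(config)
        truth = {m.id: m.truth_lineage.value for m in tree.mutations.values()}
        rng = np.random.default_rng(77)
        total = correct = 0
        for _ in range(60):
            amps = simulate_amplicons(tree, config, rng=rng)
            for mut_id in truth:
                call = classify_lineage(
                    [m for m in amps if m.mutation_id == mut_id]
                )
                total += 1
                correct += call.call.value == truth[mut_id]
                if truth[mut_id] == "multilineal":
                    assert call.call not in (
                        LineageCallValue.T_specific,
                        LineageCallValue.B_specific,
                    )
        assert correct / total >= 0.99
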