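"""Synthetic cohort generator: architecture, VAF accounting, count model."""

import numpy as np
import pytest

from clonarch import (
    SimulationConfig,
    TruthLineage,
    build_default_architecture,
    expected_vaf,
    screen_variants,
    simulate_igh_colonies,
    simulate_pileup,
)
from clonarch.simulate import COMPARTMENTS, CompartmentMix


class TestArchitecture:
    def test_truth_lineage_follows_carrying_clone(self, tree):
        assert tree.mutations["RHOA_G17V"].truth_lineage is TruthLineage.T_specific
        assert tree.mutations["TET2_a"].truth_lineage is TruthLineage.multilineal
        assert tree.mutations["NOTCH1_a"].truth_lineage is TruthLineage.B_specific

    def test_disabling_b_subclone_removes_b_specific_truth(self):
        config = SimulationConfig(include_b_subclone=False)
        tree = build_default_architecture(config)
        assert all(
            m.truth_lineage is not TruthLineage.B_specific
            for m in tree.mutations.values()
        )

    def test_zero_ancestral_fraction_zeroes_all_cd20_vafs(self):
        purities = {
            "whole_tumor": CompartmentMix(ancestral=0.6, t_subclone=0.35, b_subclone=0.1),
            "PD1pos": CompartmentMix(ancestral=0.8, t_subclone=0.75, b_subclone=0.0),
            "CD20pos": CompartmentMix(ancestral=0.0, t_subclone=0.0, b_subclone=0.0),
        }
        config = SimulationConfig(compartment_purities=purities)
        tree = build_default_architecture(config)
        for mut in tree.mutations.values():
            assert expected_vaf(tree, mut, "CD20pos") == 0.0

    def test_invalid_purities_rejected(self):
        with pytest.raises(ValueError):
            CompartmentMix(ancestral=0.3, t_subclone=0.4, b_subclone=0.0)
        with pytest.raises(ValueError):
            SimulationConfig(
                compartment_purities={
                    "whole_tumor": CompartmentMix(
                        ancestral=0.5, t_subclone=0.1, b_subclone=0.1
                    )
                }
            )

    def test_pd1_enriched_cd20_depleted_for_t_subclone(self, tree, config):
        rhoa = tree.mutations["RHOA_G17V"]
        assert expected_vaf(tree, rhoa, "PD1pos") > expected_vaf(
            tree, rhoa, "whole_tumor"
        )
        assert expected_vaf(tree, rhoa, "CD20pos") == 0.0


class TestExpectedVaf:
    def test_het_is_half_carrier_fraction(self, tree):
        # ancestral carrier fraction 0.8 in PD1+, heterozygous
        tet2 = tree.mutations["TET2_a"]
        assert expected_vaf(tree, tet2, "PD1pos") == pytest.approx(0.4)

    def test_never_exceeds_carrier_fraction(self, tree):
        for mut in tree.mutations.values():
            for comp in COMPARTMENTS:
                assert expected_vaf(tree, mut, comp) <= tree.carrier_fraction(
                    mut.id, comp
                )

    def test_unknown_compartment_errors(self, tree):
        with pytest.raises(KeyError):
            expected_vaf(tree, tree.mutations["TET2_a"], "CD4pos")


class TestPileupCountModel:
    def test_mean_alt_count_matches_binomial_expectation(self, tree):
        # expected VAF 0.25 at depth 10 000 with no error: the mean alt
        # count over 200 replicates sits within 3 standard errors of 2500
        config = SimulationConfig(depth_mean=10_000.0, error_rate=0.0)
        purities = dict(config.compartment_purities)
        rng = np.random.default_rng(7)
        tet2 = tree.mutations["DNMT3A_a"]  # ancestral het
        # build a tree whose ancestral PD1+ fraction is 0.5 -> VAF 0.25
        purities["PD1pos"] = CompartmentMix(
            ancestral=0.5, t_subclone=0.45, b_subclone=0.0
        )
        tree25 = build_default_architecture(
            SimulationConfig(compartment_purities=purities)
        )
        assert expected_vaf(tree25, tet2, "PD1pos") == pytest.approx(0.25)
        alts = []
        for _ in range(200):
            sites = simulate_pileup(tree25, config, rng=rng)
            site = next(
                s for s in sites
                if s.contig == "DNMT3A" and s.sample.endswith("PD1pos")
            )
            alts.append(site.alt_total)
        # var(alt) = n p(1-p) + p^2 var(n) for Poisson depth
        var = 10_000 * 0.25 * 0.75 + 0.0625 * 10_000
        se = np.sqrt(var / 200)
        assert abs(np.mean(alts) - 2500) < 3 * se

    def test_zero_vaf_zero_error_never_yields_alt_reads(self, tree):
        config = SimulationConfig(error_rate=0.0)
        sites = simulate_pileup(tree, config, rng=np.random.default_rng(3))
        controls = [s for s in sites if s.contig == "CTRL"]
        assert controls and all(s.alt_total == 0 for s in controls)

    def test_fixed_seed_reproduces_site_list(self, tree, config):
        a = simulate_pileup(tree, config, rng=np.random.default_rng(42))
        b = simulate_pileup(tree, config, rng=np.random.default_rng(42))
        assert a == b

    def test_counts_respect_strand_invariants(self, tree, config):
        for s in simulate_pileup(tree, config, rng=np.random.default_rng(9)):
            assert 0 <= s.alt_fwd <= s.depth_fwd
            assert 0 <= s.alt_rev <= s.depth_rev

    def test_error_only_sites_rarely_pass_screen(self, tree):
        # negative control: at error 1e-3 and depth 100, error-only sites
        # clear the cascade in well under 1% of cases
        config = SimulationConfig(
            depth_mean=100.0, error_rate=0.001, n_control_sites=200
        )
        rng = np.random.default_rng(11)
        passed = total = 0
        for _ in range(5):
            sites = [
                s for s in simulate_pileup(tree, config, rng=rng)
                if s.contig == "CTRL"
            ]
            total += len(sites)
            passed += sum(c.retained for c in screen_variants(sites))
        assert total == 3000
        assert passed / total < 0.01


class TestIghSimulation:
    def test_planted_clone_shares_rearrangement(self):
        colonies = simulate_igh_colonies(12, [2 / 12], 72.0, seed=1)
        assert len(colonies) == 12
        keys = {}
        for c in colonies:
            keys.setdefault(c.vdj_key, []).append(c.colony_id)
        expanded = [ids for ids in keys.values() if len(ids) >= 2]
        assert len(expanded) == 1 and len(expanded[0]) == 2

    def test_full_identity_means_germline_v(self, germline_refs):
        colonies = simulate_igh_colonies(
            6, [], 100.0, seed=2, germline_refs=germline_refs
        )
        for c in colonies:
            assert c.v_sequence == germline_refs[c.v_gene]

    def test_no_clones_means_all_junctions_distinct(self):
        colonies = simulate_igh_colonies(12, [], 85.0, seed=3)
        junctions = [c.junction_aa for c in colonies]
        assert len(set(junctions)) == len(junctions)

    def test_invalid_target_identity_rejected(self):
        with pytest.raises(ValueError):
            simulate_igh_colonies(12, [], 0.0, seed=4)
        with pytest.raises(ValueError):
            simulate_igh_colonies(12, [], 101.0, seed=4)
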