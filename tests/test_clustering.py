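"""Tests of MNM cluster detection, null models and phasing."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import ks_2samp

from denovotrio import clustering as cl
from denovotrio.core import add_concat_pos

from conftest import make_mutations


class TestNearestDistances:
    def test_forward_scan_any_distances(self):
        df = make_mutations([100, 150, 10050], "a")
        d = cl.nearest_distances(df)
        assert list(d["any"]) == [50, 9900]

    def test_same_individual_skips_interleaved(self):
        df = make_mutations([100, 200, 300, 400], ["a", "b", "a", "b"])
        d = cl.nearest_distances(df)
        assert list(d["same_individual"]) == [200, 200]
        assert list(d["different_individual"]) == [100, 100, 100]

    def test_single_mutation_gives_empty_lists(self):
        df = make_mutations([500], "a")
        d = cl.nearest_distances(df)
        assert all(v.size == 0 for v in d.values())

    def test_unsorted_input_rejected(self):
        df = make_mutations([100, 50], "a")
        df = df.iloc[::-1].reset_index(drop=True)
        with pytest.raises(ValueError):
            cl.nearest_distances(df)


class TestIndependenceNull:
    def test_two_point_median_matches_order_statistic(self):
        # |X-Y| for two uniforms on [0,G]: P(D<=d)=1-(1-d/G)^2,
        # median = G(1-1/sqrt(2))
        counts = pd.DataFrame({"total": [2]})
        ns = cl.simulate_independence_null(counts, axis_length=3_000_000,
                                           replicates=3000, seed=3)
        med = ns.rank_medians["same_individual"][0]
        expected = 3_000_000 * (1 - 1 / np.sqrt(2))
        assert abs(med - expected) < 0.05 * expected

    def test_rank_medians_monotone(self):
        counts = pd.DataFrame({"total": np.full(10, 40)})
        ns = cl.simulate_independence_null(counts, axis_length=5_000_000,
                                           replicates=40, seed=4)
        for v in ns.rank_medians.values():
            assert (np.diff(v) >= 0).all()

    def test_zero_weight_region_receives_no_mutations(self):
        counts = pd.DataFrame({"w": [30, 30]})
        positions = np.arange(0, 1000, dtype=np.int64)
        weights = np.where(positions < 500, 1.0, 0.0)
        rng_draws = cl.simulate_independence_null(
            counts, axis_length=1000, replicates=20, seed=5,
            class_positions={"w": positions}, class_weights={"w": weights})
        # medians can only involve distances among positions < 500
        assert rng_draws.rank_medians["any"].max() < 500

    def test_mnm_free_cohort_distances_match_own_null(self, small_cohort):
        """With the cluster process off, observed same-individual distances
        are indistinguishable from the independence simulation."""
        from denovotrio.synthetic_cohort import (CohortConfig,
                                                 generate_families,
                                                 generate_genome,
                                                 generate_mutations)
        cfg = CohortConfig(n_families=60, seed=17, mnm_fraction=0.0,
                           chrom_lengths={"chr1": 3_000_000,
                                          "chr2": 3_000_000})
        g = generate_genome(cfg)
        fams = generate_families(cfg)
        truth = generate_mutations(g, fams, cfg)
        snvs = truth[truth["kind"] == "SNV"].assign(
            individual_id=truth["family_id"])
        snvs = add_concat_pos(snvs, g)
        observed = cl.nearest_distances(snvs)["same_individual"]
        counts = snvs.groupby("individual_id").size().to_frame("total")
        ns = cl.simulate_independence_null(counts, axis_length=g.total_length,
                                           replicates=100, seed=18)
        null_median_curve = ns.rank_medians["same_individual"]
        stat = ks_2samp(observed, null_median_curve)
        assert stat.pvalue > 0.01


class TestPermutationNull:
    def test_single_individual_is_degenerate(self):
        df = make_mutations([100, 5000, 90_000, 200_000], "a")
        res = cl.permutation_expected_fraction(df, 20_000, permutations=50,
                                               seed=1)
        assert res["observed"] == res["expected"]

    def test_observed_fraction_monotone_in_threshold(self, small_cohort,
                                                     small_calls):
        calls, _ = small_calls
        snvs = calls[calls["kind"] == "SNV"]
        fracs = [cl.observed_fraction_within(snvs, t)
                 for t in (100, 1000, 5000, 20_000, 100_000)]
        assert all(b >= a for a, b in zip(fracs, fracs[1:]))

    def test_exchangeable_labels_calibrate(self):
        """When labels carry no information, observed ~ permuted null."""
        rng = np.random.default_rng(31)
        pos = np.sort(rng.integers(0, 50_000_000, size=2000))
        df = pd.DataFrame({"concat_pos": pos,
                           "individual_id": rng.integers(0, 40, size=2000)})
        res = cl.permutation_expected_fraction(df, 20_000, permutations=200,
                                               seed=32)
        p_high = (1 + (res["permuted"] >= res["observed"]).sum()) / 201
        p_low = (1 + (res["permuted"] <= res["observed"]).sum()) / 201
        assert min(p_high, p_low) > 0.005

    def test_invalid_threshold_rejected(self):
        df = make_mutations([1, 2], ["a", "b"])
        with pytest.raises(ValueError):
            cl.permutation_expected_fraction(df, 0)


class TestBuildClusters:
    def test_gap_rule(self):
        df = make_mutations([100, 600, 30_000], "a")
        clusters = cl.build_clusters(df)
        assert len(clusters) == 1
        assert list(clusters[0].members["pos"]) == [100, 600]

    def test_single_linkage_spans_beyond_threshold(self):
        df = make_mutations([0, 15_000, 30_000], "a")
        clusters = cl.build_clusters(df)
        assert len(clusters) == 1 and len(clusters[0].members) == 3
        assert clusters[0].span == 30_000

    def test_partition_property(self, small_calls):
        calls, _ = small_calls
        clusters = cl.build_clusters(calls, include_indels=True)
        seen = set()
        for c in clusters:
            for row in c.members.itertuples():
                key = (row.family_id, row.chrom, row.pos)
                assert key not in seen
                seen.add(key)
            assert c.members["individual_id"].nunique() == 1
            assert len(c.members) == c.n_snv + c.n_indel

    def test_recovers_generator_truth_clusters(self, small_cohort):
        truth = small_cohort.truth.assign(
            individual_id=small_cohort.truth["family_id"])
        truth = add_concat_pos(truth, small_cohort.genome)
        snvs = truth[truth["kind"] == "SNV"]
        clusters = cl.build_clusters(snvs)
        rand = cl.cluster_truth_rand_index(snvs, clusters)
        assert rand >= 0.99


class TestTandemEvents:
    def test_study_scale_arithmetic(self):
        rows, pos = [], 0
        for _ in range(54):
            rows += [(pos, "i0"), (pos + 1, "i0")]
            pos += 100_000
        for j in range(17812 - 108):
            rows.append((pos, f"i{j % 283}"))
            pos += 400_000
        df = make_mutations([r[0] for r in rows], [r[1] for r in rows])
        ts = cl.tandem_events(df)
        assert ts.n_events == 54
        assert ts.n_adjoining_mutations == 108
        assert round(100 * ts.rate, 2) == 0.30
        assert (round(100 * ts.ci_low, 2), round(100 * ts.ci_high, 2)) \
            == (0.23, 0.40)

    def test_distance_two_is_not_adjoining(self):
        df = make_mutations([500, 502], "a")
        assert cl.tandem_events(df).n_events == 0

    def test_adjacent_triple_is_one_event(self):
        df = make_mutations([10, 11, 12], "a")
        ts = cl.tandem_events(df)
        assert ts.n_events == 1
        assert ts.n_adjoining_mutations == 3


class TestSubsampling:
    def test_thinning_preserves_target_mean(self, small_calls):
        calls, _ = small_calls
        snvs = calls[calls["kind"] == "SNV"]
        observed_mean = len(snvs) / snvs["individual_id"].nunique()
        target = 44.1
        res = cl.subsample_cluster_fraction(snvs, target, replicates=300,
                                            seed=41)
        assert res["keep_probability"] == pytest.approx(target / observed_mean)

    def test_thinning_independent_set_scales_pair_fraction(self):
        # for independent positions the clustered fraction is ~ proportional
        # to the retention probability (pair survival ~ p^2, denominator ~ p)
        rng = np.random.default_rng(42)
        n, n_ind = 6000, 30
        df = pd.DataFrame({
            "concat_pos": np.sort(rng.integers(0, 30_000_000, size=n)),
            "individual_id": rng.integers(0, n_ind, size=n),
            "kind": "SNV"})
        full = cl.observed_fraction_within(df, 20_000)
        target = 0.5 * n / n_ind
        res = cl.subsample_cluster_fraction(df, target, replicates=400,
                                            seed=43)
        assert res["mean_fraction"] == pytest.approx(0.5 * full, rel=0.15)

    def test_noop_thinning_returns_unthinned_fraction(self, small_calls):
        calls, _ = small_calls
        snvs = calls[calls["kind"] == "SNV"]
        observed_mean = len(snvs) / snvs["individual_id"].nunique()
        res = cl.subsample_cluster_fraction(snvs, observed_mean,
                                            replicates=5, seed=44)
        assert res["mean_fraction"] == pytest.approx(
            cl.observed_fraction_within(snvs, 20_000))

    def test_target_above_observed_rejected(self, small_calls):
        calls, _ = small_calls
        snvs = calls[calls["kind"] == "SNV"]
        with pytest.raises(ValueError):
            cl.subsample_cluster_fraction(snvs, 1e6)


class TestPhasing:
    def make_reads(self, spec):
        # spec: list of (read_id, {pos: is_alt})
        rows = [(rid, pos, alt) for rid, alleles in spec
                for pos, alt in alleles.items()]
        return pd.DataFrame(rows, columns=["read_id", "pos", "is_alt"])

    def test_contradictory_pair_is_inconsistent(self):
        # 11 reads support one phasing, 4 the other (73% < 90%)
        spec = [(f"r{i}", {100: True, 150: True}) for i in range(11)]
        spec += [(f"s{i}", {100: True, 150: False}) for i in range(4)]
        out = cl.phase_by_reads(self.make_reads(spec))
        assert out.loc[0, "verdict"] == cl.PHASE_INCONSISTENT

    def test_unanimous_cis_is_same_chromosome(self):
        spec = [(f"r{i}", {100: True, 150: True}) for i in range(10)]
        out = cl.phase_by_reads(self.make_reads(spec))
        assert out.loc[0, "verdict"] == cl.PHASE_SAME

    def test_ninety_percent_boundary_is_inclusive(self):
        spec = [(f"r{i}", {100: True, 150: True}) for i in range(9)]
        spec += [("s0", {100: True, 150: False})]
        out = cl.phase_by_reads(self.make_reads(spec))
        assert out.loc[0, "verdict"] == cl.PHASE_SAME

    def test_no_informative_reads_is_no_call(self):
        spec = [("r0", {100: True}), ("r1", {150: True})]
        out = cl.phase_by_reads(self.make_reads(spec))
        assert out.loc[0, "verdict"] == cl.PHASE_NO_CALL

    def test_ref_ref_reads_support_cis(self):
        spec = [(f"r{i}", {100: False, 150: False}) for i in range(5)]
        spec += [(f"s{i}", {100: True, 150: True}) for i in range(5)]
        out = cl.phase_by_reads(self.make_reads(spec))
        assert out.loc[0, "verdict"] == cl.PHASE_SAME
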