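"""Tests of the synthetic trio-cohort generator."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

from denovotrio.core import GenomeModel, read_pedigree
from denovotrio.synthetic_cohort import (
    CohortConfig,
    generate_depth_profiles,
    generate_families,
    generate_genome,
    generate_mutations,
    generate_tracks,
    simulate_observations,
)


class TestGenome:
    def test_gc_content_matches_configuration(self):
        cfg = CohortConfig(chrom_lengths={"chr1": 1_000_000}, gc_content=0.5,
                           n_fraction=0.0, seed=1)
        g = generate_genome(cfg)
        seq = g.sequence["chr1"]
        gc = ((seq == ord("C")) | (seq == ord("G"))).mean()
        assert 0.49 <= gc <= 0.51

    def test_cpg_dinucleotides_are_depleted(self):
        cfg = CohortConfig(chrom_lengths={"chr1": 1_000_000}, n_fraction=0.0,
                           seed=2)
        g = generate_genome(cfg)
        seq = g.sequence["chr1"]
        gc = ((seq == ord("C")) | (seq == ord("G"))).mean()
        n_cpg = int(((seq[:-1] == ord("C")) & (seq[1:] == ord("G"))).sum())
        expected_iid = (gc / 2) ** 2 * (seq.size - 1)
        assert n_cpg < 0.5 * expected_iid

    def test_fixed_seed_is_deterministic(self):
        cfg = CohortConfig(chrom_lengths={"chr1": 50_000, "chr2": 30_000},
                           seed=3)
        a, b = generate_genome(cfg), generate_genome(cfg)
        for c in a.chrom_names:
            assert np.array_equal(a.sequence[c], b.sequence[c])

    def test_zero_length_genome_rejected(self):
        with pytest.raises(ValueError):
            generate_genome(CohortConfig(chrom_lengths={"chr1": 0}))
        with pytest.raises(ValueError):
            generate_genome(CohortConfig(chrom_lengths={"chr1": 500}))

    def test_context_classes_partition_non_n_positions(self):
        cfg = CohortConfig(chrom_lengths={"chr1": 200_000}, n_fraction=0.01,
                           n_block_length=1000, seed=4)
        g = generate_genome(cfg)
        codes = g.context_codes("chr1")
        seq = g.sequence["chr1"]
        assert ((codes >= 0) == (seq != ord("N"))).all()


class TestFamilies:
    def test_age_moments_and_correlation(self):
        cfg = CohortConfig(n_families=5000, seed=5)
        fams = generate_families(cfg)
        f = np.array([x.father_age for x in fams])
        m = np.array([x.mother_age for x in fams])
        assert abs(f.mean() - 31.6) < 0.3
        assert abs(m.mean() - 28.9) < 0.3
        r2 = np.corrcoef(f, m)[0, 1] ** 2
        assert abs(r2 - 0.65) < 0.05

    def test_single_family(self):
        fams = generate_families(CohortConfig(n_families=1, seed=6))
        assert len(fams) == 1
        assert fams[0].father_age >= 15

    def test_invalid_age_parameters_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(father_age_sd=-1.0)
        with pytest.raises(ValueError):
            CohortConfig(n_families=0)


@pytest.fixture(scope="module")
def cohort_2000():
    cfg = CohortConfig(n_families=2000, seed=11,
                       chrom_lengths={"chr1": 1_500_000,
                                      "chr2": 1_500_000})
    g = generate_genome(cfg)
    fams = generate_families(cfg)
    return cfg, g, fams, generate_mutations(g, fams, cfg)


class TestMutations:

    def test_age_slopes_recovered_by_regression(self, cohort_2000):
        from denovotrio import rates
        cfg, _, fams, truth = cohort_2000
        counts = rates.family_counts(truth, fams)
        model = rates.parental_age_regression(
            counts, np.array([f.father_age for f in fams]),
            np.array([f.mother_age for f in fams]))
        assert abs(model.paternal_slope - cfg.paternal_slope) < 2 * model.paternal_se
        assert abs(model.maternal_slope - cfg.maternal_slope) < 2 * model.maternal_se

    def test_mean_count_matches_configured_cohort_mean(self, cohort_2000):
        cfg, _, fams, truth = cohort_2000
        per_fam = (truth["kind"] == "SNV").groupby(truth["family_id"]).sum()
        # Poisson mean ~62.9 per family, n=2000 -> SE of the mean ~0.18
        assert abs(per_fam.mean() - cfg.mean_snv_count) < 1.0

    def test_spectrum_converges_to_configured_weights(self, cohort_2000):
        from denovotrio.spectra import classify_calls
        cfg, g, _, truth = cohort_2000
        typed = classify_calls(truth.assign(individual_id=truth["family_id"]), g)
        observed = typed.groupby(["context_class"]).size()
        total_w = sum(cfg.spectrum.values())
        for ctx in ("CpG", "strong", "weak"):
            w = (cfg.spectrum[(ctx, "transition")]
                 + cfg.spectrum[(ctx, "transversion")]) / total_w
            assert abs(observed[ctx] / len(typed) - w) < 0.02

    def test_deletion_insertion_ratio(self, cohort_2000):
        _, _, _, truth = cohort_2000
        n_del = (truth["kind"] == "deletion").sum()
        n_ins = (truth["kind"] == "insertion").sum()
        assert 2.1 < n_del / n_ins < 3.2
        ref_len = truth.loc[truth["kind"] == "deletion", "ref_allele"].str.len()
        alt_len = truth.loc[truth["kind"] == "insertion", "alt_allele"].str.len()
        assert (ref_len - 1).max() <= 35
        assert (alt_len - 1).max() <= 8

    def test_cluster_members_share_family(self, cohort_2000):
        _, _, _, truth = cohort_2000
        clustered = truth[truth["cluster_id"].notna()]
        fams_per_cluster = clustered.groupby("cluster_id")["family_id"].nunique()
        assert (fams_per_cluster == 1).all()
        sizes = clustered.groupby("cluster_id").size()
        assert sizes.min() >= 2 and sizes.max() <= 8

    def test_no_mnm_process_gives_independence_level_clustering(self):
        from denovotrio.clustering import permutation_expected_fraction
        from denovotrio.core import add_concat_pos
        cfg = CohortConfig(n_families=200, seed=12, mnm_fraction=0.0,
                           chrom_lengths={"chr1": 3_000_000,
                                          "chr2": 3_000_000})
        g = generate_genome(cfg)
        fams = generate_families(cfg)
        truth = generate_mutations(g, fams, cfg)
        snvs = truth[truth["kind"] == "SNV"].assign(
            individual_id=truth["family_id"])
        snvs = add_concat_pos(snvs, g)
        res = permutation_expected_fraction(snvs, 20_000, permutations=200,
                                            seed=1)
        # without the cluster process, observed == permuted null level
        spread = np.percentile(res["permuted"], 99.5) - res["expected"]
        assert abs(res["observed"] - res["expected"]) < max(2 * spread, 0.01)

    def test_mnm_excess_over_null_matches_configured_fraction(self, small_cohort):
        from denovotrio.clustering import permutation_expected_fraction
        from denovotrio.core import add_concat_pos
        truth = small_cohort.truth
        snvs = truth[truth["kind"] == "SNV"].assign(
            individual_id=truth["family_id"])
        snvs = add_concat_pos(snvs, small_cohort.genome)
        res = permutation_expected_fraction(snvs, 20_000, permutations=100,
                                            seed=2)
        excess = res["observed"] - res["expected"]
        # ~3% of SNVs carry a clustered partner beyond chance level
        assert 0.015 < excess < 0.06


class TestObservations:
    def test_true_het_gives_decisive_likelihood_ratio(self, small_cohort):
        obs = small_cohort.observations
        dn = obs[obs["is_denovo"] & (obs["child_dp"] >= 40)]
        assert len(dn) > 50
        lr = dn["child_gl_ar"] - dn["child_gl_rr"]
        assert (lr > 10).mean() > 0.95

    def test_zero_depth_site_has_no_reads_and_is_uncallable(self):
        from denovotrio.denovo_calling import site_callability
        cfg = CohortConfig(n_families=1, seed=13, depth_mean=1e-9,
                           chrom_lengths={"chr1": 100_000},
                           background_sites_per_family=5, n_fraction=0.0)
        g = generate_genome(cfg)
        fams = generate_families(cfg)
        truth = generate_mutations(g, fams, cfg)
        obs, _ = simulate_observations(truth, fams, g, cfg)
        assert (obs["child_dp"] == 0).all()
        assert (obs[["child_alt_fwd", "child_alt_rev"]].to_numpy() == 0).all()
        assert site_callability(0, 30, 30) == 0.0

    def test_background_sites_never_reach_alt_fraction(self, small_cohort):
        # binomial tail oracle: P(alt >= 30% | depth 20, eps 0.005) < 1e-6
        assert binom.sf(5, 20, 0.005) < 1e-6
        obs = small_cohort.observations
        bg = obs[~obs["is_denovo"] & (obs["pop_lr"] == 0)]
        alt_frac = (bg["child_alt_fwd"] + bg["child_alt_rev"]) / \
            bg["child_dp"].clip(lower=1)
        assert (alt_frac >= 0.3).sum() == 0

    def test_depth_profiles_deterministic(self, small_cohort):
        cfg = small_cohort.config
        rng = np.random.default_rng(99)
        p1 = generate_depth_profiles(small_cohort.genome,
                                     small_cohort.families, cfg, rng)
        rng = np.random.default_rng(99)
        p2 = generate_depth_profiles(small_cohort.genome,
                                     small_cohort.families, cfg, rng)
        fam = small_cohort.families[0].family_id
        assert np.array_equal(p1[fam]["chr1"], p2[fam]["chr1"])


class TestTracks:
    def test_crossover_bins_mean_length(self, small_cohort):
        cfg = CohortConfig(n_families=400, seed=14,
                           chrom_lengths={"chr1": 10_000_000,
                                          "chr2": 10_000_000})
        g = small_cohort.genome  # geometry irrelevant to lengths; reuse
        fams = generate_families(cfg)
        cfg2 = CohortConfig(n_families=400, seed=14,
                            chrom_lengths={"chr1": 3_000_000,
                                           "chr2": 3_000_000},
                            crossover_bin_mean_length=201_000.0)
        tracks = generate_tracks(small_cohort.genome, fams, cfg2,
                                 np.random.default_rng(14))
        lengths = tracks.crossovers["end"] - tracks.crossovers["start"]
        assert len(lengths) > 200
        assert abs(lengths.mean() - 201_000) < 0.1 * 201_000

    def test_five_tracks_and_slope_cap(self, small_cohort):
        tracks = small_cohort.tracks
        assert len(tracks.replication) == 5
        cap = small_cohort.config.track_slope_cap
        for track in tracks.replication:
            for values in track.values():
                assert np.abs(np.diff(values)).max() <= cap + 1e-9

    def test_bins_within_chromosome_bounds(self, small_cohort):
        xo = small_cohort.tracks.crossovers
        lengths = small_cohort.genome.chrom_lengths
        assert (xo["start"] >= 0).all()
        assert (xo["end"] <= xo["chrom"].map(lengths)).all()
        assert (xo["start"] < xo["end"]).all()


class TestCohortFiles:
    def test_vcf_round_trip_preserves_observations(self, small_cohort,
                                                   small_cohort_dir):
        from denovotrio.denovo_calling import read_family_vcf
        fam = small_cohort.families[0]
        obs = small_cohort.observations
        fam_obs = obs[obs["family_id"] == fam.family_id].reset_index(drop=True)
        back = read_family_vcf(small_cohort_dir / "vcf" / f"{fam.family_id}.vcf",
                               fam)
        assert len(back) == len(fam_obs)
        merged = fam_obs.merge(back, on=["chrom", "pos"],
                               suffixes=("", "_rt"))
        assert (merged["child_dp"] == merged["child_dp_rt"]).all()
        assert (merged["child_alt_fwd"] == merged["child_alt_fwd_rt"]).all()
        assert np.allclose(merged["child_gl_ar"], merged["child_gl_ar_rt"],
                           atol=1e-4)

    def test_pedigree_round_trip(self, small_cohort, small_cohort_dir):
        fams = read_pedigree(small_cohort_dir / "pedigree.tsv")
        assert fams == small_cohort.families

    def test_fasta_round_trip(self, small_cohort, small_cohort_dir):
        g = GenomeModel.from_fasta(small_cohort_dir / "genome.fa")
        assert g.chrom_names == small_cohort.genome.chrom_names
        for c in g.chrom_names:
            assert np.array_equal(g.sequence[c],
                                  small_cohort.genome.sequence[c])

    def test_bed_intervals_are_zero_based_half_open(self, small_cohort_dir,
                                                    small_cohort):
        xo = pd.read_csv(small_cohort_dir / "crossovers.bed", sep="\t",
                         header=None,
                         names=["chrom", "start", "end", "family_id", "parent"])
        assert (xo["start"] < xo["end"]).all()
        assert xo.equals(xo.astype({"start": np.int64, "end": np.int64}))
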