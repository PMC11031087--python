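import numpy as np
import pytest
from scipy import stats

from mirevo.de import differential_expression, select_degs
from mirevo.scan import MirnaRecord, UtrRecord, scan_utr
from mirevo.simulate import (
    SimConfig,
    SimTruth,
    build_ancestor,
    implant_target_sites,
    simulate_competition_assay,
    simulate_conservation_track,
    simulate_counts,
    simulate_mirna_family,
    simulate_population_alleles,
    simulate_transcriptome,
    stage_rng,
)

from conftest import random_rna


class TestSimConfig:
    def test_invalid_utr_range(self):
        with pytest.raises(ValueError):
            SimConfig(utr_len_range=(100, 50))

    def test_all_zero_bias_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(substitution_bias={"U>C": 0.0})

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(substitution_bias={"U>C": -1.0})

    def test_zero_species_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_species=0)


class TestMirnaFamily:
    def test_degenerate_bias_only_uc(self):
        cfg = SimConfig(rng_seed=1, substitution_bias={"U>C": 1.0},
                        n_clusters=1, mirnas_per_cluster=1)
        _, truth = simulate_mirna_family(cfg, n_substitutions=10)
        assert len(truth.substitutions) == 10
        assert all((ref, alt) == ("U", "C") for _, _, ref, alt in truth.substitutions)

    def test_zero_substitutions_identical(self):
        cfg = SimConfig(rng_seed=2, n_clusters=2, mirnas_per_cluster=3)
        _, truth = simulate_mirna_family(cfg, n_substitutions=0)
        assert all(locus == truth.ancestor_te for locus in truth.loci.values())
        assert truth.substitutions == []

    def test_biased_fraction_matches_multinomial_oracle(self):
        # 1000 descendants x 1 substitution each: the ancestor composition is
        # fixed for every draw, so the expected U>C + A>G fraction has the
        # closed form below; compare the recorded tally against it.
        cfg = SimConfig(
            rng_seed=3,
            substitution_bias={"U>C": 2.0, "A>G": 2.0, "other": 1.0},
            n_clusters=100,
            mirnas_per_cluster=10,
            seed_protection=1.0,  # uniform over positions for the oracle
        )
        _, truth = simulate_mirna_family(cfg, n_substitutions=1)
        anc = truth.ancestor_te
        weight_per_base = {"U": 2 + 1 + 1, "A": 2 + 1 + 1, "C": 3, "G": 3}
        total_w = sum(weight_per_base[b] for b in anc)
        favored_w = sum(2 for b in anc if b in "UA")
        p_exp = favored_w / total_w
        n = len(truth.substitutions)
        assert n == 1000
        observed = sum(
            1 for _, _, ref, alt in truth.substitutions if (ref, alt) in (("U", "C"), ("A", "G"))
        )
        se = np.sqrt(p_exp * (1 - p_exp) * n)
        assert abs(observed - p_exp * n) < 4 * se

    def test_seed_protection_lowers_seed_substitution_rate(self):
        cfg = SimConfig(rng_seed=4, n_clusters=50, mirnas_per_cluster=4, seed_protection=0.0)
        _, truth = simulate_mirna_family(cfg, n_substitutions=5)
        seed_lo = truth.mature_offset + 1
        seed_hi = seed_lo + cfg.seed_len
        assert all(not (seed_lo <= pos < seed_hi) for _, pos, _, _ in truth.substitutions)

    def test_empty_family_error(self):
        with pytest.raises(ValueError, match="empty family"):
            simulate_mirna_family(SimConfig(n_clusters=0))

    def test_shared_ancestor_across_species(self):
        cfg = SimConfig(rng_seed=5, n_clusters=1, mirnas_per_cluster=2)
        anc = build_ancestor(cfg)
        _, t1 = simulate_mirna_family(cfg, species="sp1", ancestor=anc)
        _, t2 = simulate_mirna_family(cfg, species="sp2", ancestor=anc)
        assert t1.ancestor_te == t2.ancestor_te == anc.seq

    def test_deterministic(self):
        cfg = SimConfig(rng_seed=11)
        a = simulate_mirna_family(cfg)
        b = simulate_mirna_family(cfg)
        assert [m.mature_seq for m in a[0]] == [m.mature_seq for m in b[0]]
        assert a[1].substitutions == b[1].substitutions


class TestTranscriptome:
    def test_full_orthology_is_bijection(self):
        cfg = SimConfig(rng_seed=6, n_species=2, n_genes=50, ortholog_fraction=1.0)
        txome = simulate_transcriptome(cfg)
        genes_1 = {u.gene for u in txome.utrs["sp1"]}
        genes_2 = {u.gene for u in txome.utrs["sp2"]}
        assert genes_1 == genes_2 and len(genes_1) == 50
        assert all(txome.orthologs.ortholog(g, "sp2") == g for g in genes_1)

    def test_zero_genes_ok(self):
        txome = simulate_transcriptome(SimConfig(n_genes=0))
        assert txome.utrs["sp1"] == []

    def test_shared_count_in_binomial_interval(self):
        cfg = SimConfig(rng_seed=7, n_genes=1000, ortholog_fraction=0.5)
        txome = simulate_transcriptome(cfg)
        n_shared = len(txome.orthologs.shared)
        lo, hi = stats.binom.ppf([0.005, 0.995], 1000, 0.5)
        assert lo <= n_shared <= hi

    def test_lengths_within_range(self):
        cfg = SimConfig(rng_seed=8, n_genes=40, utr_len_range=(90, 110))
        txome = simulate_transcriptome(cfg)
        assert all(90 <= len(u.seq) <= 110 for sp in txome.utrs for u in txome.utrs[sp])


class TestImplant:
    def _fixture(self, seed=0, n=6, length=150):
        rng = np.random.default_rng(seed)
        utrs = [UtrRecord(f"g{i}", f"t{i}", random_rna(rng, length)) for i in range(n)]
        mirnas = [MirnaRecord(f"m{i}", random_rna(rng, 22)) for i in range(2)]
        return utrs, mirnas, rng

    def test_scanner_recovers_all_implanted(self):
        utrs, mirnas, rng = self._fixture()
        mod, truth = implant_target_sites(utrs, mirnas, sites_per_target=2, rng=rng)
        by_tx = {u.transcript: u for u in mod}
        by_name = {m.name: m for m in mirnas}
        for site in truth.sites:
            found = scan_utr(by_tx[site.transcript], by_name[site.mirna])
            assert any(f.start == site.start and f.site_class == "8mer" for f in found)

    def test_zero_sites_empty_truth(self):
        utrs, mirnas, rng = self._fixture()
        mod, truth = implant_target_sites(utrs, mirnas, sites_per_target=0, rng=rng)
        assert truth.sites == []
        assert [u.seq for u in mod] == [u.seq for u in utrs]

    def test_wobble_rate_one_needs_wobble_scanning(self):
        utrs, mirnas, rng = self._fixture(seed=3)
        mod, truth = implant_target_sites(utrs, mirnas, sites_per_target=1, wobble_rate=1.0, rng=rng)
        by_tx = {u.transcript: u for u in mod}
        by_name = {m.name: m for m in mirnas}
        wobbled = [s for s in truth.sites if s.wobble_count > 0]
        assert wobbled, "fixture must contain wobbled sites"
        for site in wobbled:
            with_w = scan_utr(by_tx[site.transcript], by_name[site.mirna],
                              allow_wobble=True, max_wobble=6)
            without = scan_utr(by_tx[site.transcript], by_name[site.mirna])
            assert any(f.start == site.start for f in with_w)
            assert not any(f.start == site.start and f.site_class == "8mer" for f in without)

    def test_too_short_utr_skipped_with_warning(self):
        rng = np.random.default_rng(1)
        utrs = [UtrRecord("g", "t", "ACGUACG")]  # cannot hold an 8mer footprint
        mirnas = [MirnaRecord("m", random_rna(rng, 22))]
        with pytest.warns(UserWarning, match="skipped"):
            _, truth = implant_target_sites(utrs, mirnas, sites_per_target=1, rng=rng)
        assert truth.skipped == [("t", "too_short")]

    def test_sites_non_overlapping_with_gap(self):
        utrs, mirnas, rng = self._fixture(n=3, length=400)
        _, truth = implant_target_sites(utrs, mirnas, sites_per_target=6, rng=rng)
        for tx, sites in truth.sites_by_transcript().items():
            spans = sorted((s.start, s.end) for s in sites)
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert s2 - e1 >= 2


class TestCounts:
    def test_depth_zero_error(self):
        with pytest.raises(ValueError):
            SimConfig(depth=0)

    def test_unknown_true_gene_rejected(self):
        cfg = SimConfig(rng_seed=0)
        with pytest.raises(ValueError, match="absent"):
            simulate_counts({"WT": 3, "ko1": 3}, {"ko1": {"nope": 1.0}}, cfg, ["g1"])

    def test_library_size_near_depth(self):
        cfg = SimConfig(rng_seed=9, depth=1e5, dispersion=0.05)
        genes = [f"g{i}" for i in range(400)]
        cm = simulate_counts({"WT": 4, "ko1": 4}, {"ko1": {}}, cfg, genes)
        libs = cm.counts.sum(axis=0).to_numpy(dtype=float)
        # SE of one library: sqrt(sum(mu + disp*mu^2)); bound loosely via 3 SE
        mu = cm.counts[cm.columns_for("WT")].mean(axis=1).to_numpy()
        se = np.sqrt(np.sum(mu + cfg.dispersion * mu**2))
        assert np.all(np.abs(libs - cfg.depth) < 3 * se + 0.05 * cfg.depth)

    def test_null_type_one_error_controlled(self):
        # no true effects: BH at 0.05 should essentially never call DEGs
        cfg = SimConfig(rng_seed=10, depth=2e5, dispersion=0.05, n_replicates=3)
        genes = [f"g{i}" for i in range(500)]
        any_hits = 0
        for rep in range(20):
            cfg_r = SimConfig(rng_seed=100 + rep, depth=2e5, dispersion=0.05)
            cm = simulate_counts({"WT": 3, "ko1": 3}, {"ko1": {}}, cfg_r, genes)
            degs = select_degs(differential_expression(cm, "ko1"))
            any_hits += bool(degs)
        assert any_hits <= 4  # P(X > 4 | Binom(20, 0.05)) < 0.005

    def test_planted_effect_recovered(self):
        # strong planted effects at high depth: select_degs power >= 0.8
        # (dispersion 0.01 keeps the 3v3 Welch test powered; a free parameter)
        genes = [f"g{i}" for i in range(500)]
        targets = {g: -2.0 for g in genes[:50]}
        recalls = []
        for rep in range(5):
            cfg = SimConfig(rng_seed=200 + rep, depth=1e6, dispersion=0.01)
            cm = simulate_counts({"WT": 3, "ko1": 3}, {"ko1": targets}, cfg, genes)
            degs = select_degs(differential_expression(cm, "ko1"))
            recalls.append(len(degs & set(targets)) / len(targets))
        assert np.mean(recalls) >= 0.8


class TestConservationTrackSim:
    def _utrs(self, n=20, length=100, seed=0):
        rng = np.random.default_rng(seed)
        return [
            UtrRecord(f"g{i}", f"t{i}", random_rna(rng, length),
                      genomic_intervals=((f"t{i}", 0, length, "+"),))
            for i in range(n)
        ]

    def test_noise_free_delta_exact(self):
        from mirevo.scan import TargetSite

        utrs = self._utrs(n=5)
        sites = [TargetSite("m", u.transcript, 10, 18, "8mer") for u in utrs]
        track = simulate_conservation_track(utrs, sites, base_mean=0.0,
                                            site_elevation_delta=1.0, noise_sd=0.0)
        for u in utrs:
            vals = track.values(u.transcript, 0, len(u.seq))
            assert np.all(vals[10:18] == 1.0)
            assert np.all(np.delete(vals, np.s_[10:18]) == 0.0)

    def test_delta_estimate_within_se_bound(self):
        from mirevo.scan import TargetSite

        utrs = self._utrs(n=500, length=120, seed=1)
        sites = [TargetSite("m", u.transcript, 20, 28, "8mer") for u in utrs]
        track = simulate_conservation_track(
            utrs, sites, base_mean=0.0, site_elevation_delta=0.5, noise_sd=1.0,
            rng=np.random.default_rng(42),
        )
        diffs = []
        for u in utrs:
            vals = track.values(u.transcript, 0, 120)
            diffs.append(vals[20:28].mean() - np.delete(vals, np.s_[20:28]).mean())
        assert abs(np.mean(diffs) - 0.5) < 0.1


class TestAlleles:
    def test_constant_daf_gives_max_mnd(self):
        df = simulate_population_alleles({"c": (50, (1e6, 1e6))}, seed=0)
        assert np.allclose(df["daf"], 0.5, atol=0.01)
        assert np.allclose(df["mnd"], 2 * df["daf"] * (1 - df["daf"]))

    def test_zero_class_absent(self):
        df = simulate_population_alleles({"a": (10, (1, 1)), "b": (0, (1, 1))}, seed=0)
        assert set(df["feature_class"]) == {"a"}

    def test_kw_power_on_shifted_betas(self):
        from mirevo.conservation import popgen_class_compare

        hits = 0
        for rep in range(20):
            df = simulate_population_alleles(
                {"lo": (200, (1.0, 9.0)), "hi": (200, (5.0, 5.0))}, seed=rep
            )
            res = popgen_class_compare(df)
            hits += res.tests["mnd"]["kw_pvalue"] < 0.05
        assert hits >= 19


class TestCompetitionSim:
    def test_fraction_one_all_genotype_a(self):
        assay = simulate_competition_assay(50, 1.0, seed=0)
        assert (assay.count_a, assay.count_b) == (50, 0)

    def test_large_n_binomial_se(self):
        assay = simulate_competition_assay(100_000, 0.5, seed=1)
        assert abs(assay.count_a / assay.total - 0.5) < 0.01

    def test_zero_offspring_error(self):
        with pytest.raises(ValueError, match="empty assay"):
            simulate_competition_assay(0, 0.5)


class TestDeterminismAndTruth:
    def test_stage_rng_streams_independent(self):
        a = stage_rng(1, "alpha").random(3)
        b = stage_rng(1, "beta").random(3)
        a2 = stage_rng(1, "alpha").random(3)
        assert np.array_equal(a, a2)
        assert not np.array_equal(a, b)

    def test_sim_truth_roundtrip(self):
        from mirevo.scan import TargetSite

        truth = SimTruth(
            ancestor_te="ACGU",
            family_tree={"m1": "ancestor"},
            true_sites=[TargetSite("m1", "t1", 0, 8, "8mer")],
            true_targets={"sp1": {"m1": ["g1"]}},
            true_de_genes={"ko1": {"g1": -2.0}},
            true_fraction=0.7,
        )
        again = SimTruth.from_json(truth.to_json())
        assert again == truth
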