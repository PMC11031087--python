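import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mirevo.conservation import (
    ConservationTrack,
    FeatureInterval,
    dunn_posthoc,
    feature_class_summary,
    map_scores_to_utr,
    mnd,
    popgen_class_compare,
    site_vs_nonsite_contrast,
)
from mirevo.scan import TargetSite, UtrRecord
from mirevo.simulate import simulate_conservation_track

from conftest import random_rna


class TestConservationTrack:
    def test_missing_positions_nan(self):
        track = ConservationTrack()
        track.add_array("chr1", 10, np.arange(5.0))
        vals = track.values("chr1", 8, 17)
        assert np.isnan(vals[:2]).all() and np.isnan(vals[7:]).all()
        assert np.array_equal(vals[2:7], np.arange(5.0))

    def test_overlap_rejected(self):
        track = ConservationTrack()
        track.add_array("chr1", 0, np.zeros(10))
        with pytest.raises(ValueError, match="overlap"):
            track.add_array("chr1", 5, np.zeros(3))

    def test_phastcons_range_enforced(self):
        track = ConservationTrack(semantics="phastcons")
        with pytest.raises(ValueError):
            track.add_array("chr1", 0, np.array([0.5, 1.5]))


class TestMapScoresToUtr:
    def _track(self):
        track = ConservationTrack()
        track.add_array("chr1", 100, np.arange(100.0))
        return track

    def test_single_block_plus(self):
        utr = UtrRecord("g", "t", "A" * 20, genomic_intervals=(("chr1", 110, 130, "+"),))
        got = map_scores_to_utr(self._track(), utr)
        assert np.array_equal(got, np.arange(10.0, 30.0))

    def test_minus_strand_reversed(self):
        utr = UtrRecord("g", "t", "A" * 20, genomic_intervals=(("chr1", 110, 130, "-"),))
        got = map_scores_to_utr(self._track(), utr)
        assert np.array_equal(got, np.arange(29.0, 9.0, -1.0))

    def test_two_block_concatenation_oracle(self):
        utr = UtrRecord(
            "g", "t", "A" * 15,
            genomic_intervals=(("chr1", 110, 120, "+"), ("chr1", 150, 155, "+")),
        )
        got = map_scores_to_utr(self._track(), utr)
        manual = np.concatenate([np.arange(10.0, 20.0), np.arange(50.0, 55.0)])
        assert np.array_equal(got, manual)

    def test_outside_extent_warns_and_nans(self):
        utr = UtrRecord("g", "t", "A" * 10, genomic_intervals=(("chr1", 95, 105, "+"),))
        with pytest.warns(UserWarning, match="outside"):
            got = map_scores_to_utr(self._track(), utr)
        assert np.isnan(got[:5]).all() and not np.isnan(got[5:]).any()

    def test_no_intervals_rejected(self):
        with pytest.raises(ValueError):
            map_scores_to_utr(self._track(), UtrRecord("g", "t", "ACGU"))


def _delta_fixture(n_genes, delta, noise_sd, seed, length=100):
    rng = np.random.default_rng(seed)
    utrs = [
        UtrRecord(f"g{i}", f"t{i}", random_rna(rng, length),
                  genomic_intervals=((f"t{i}", 0, length, "+"),))
        for i in range(n_genes)
    ]
    sites = [TargetSite("m", u.transcript, 30, 38, "8mer") for u in utrs]
    track = simulate_conservation_track(
        utrs, sites, base_mean=0.0, site_elevation_delta=delta, noise_sd=noise_sd, rng=rng
    )
    scores = {u.gene: track.values(u.transcript, 0, length) for u in utrs}
    sites_by_gene = {u.gene: [s] for u, s in zip(utrs, sites)}
    return scores, sites_by_gene


class TestSiteContrast:
    def test_noise_free_delta_one(self):
        scores, sites = _delta_fixture(20, delta=1.0, noise_sd=0.0, seed=0)
        res = site_vs_nonsite_contrast(scores, sites)
        assert np.allclose(res.table["diff"], 1.0)
        assert res.pvalue < 1e-100 or res.pvalue == 0.0

    def test_delta_recovery_within_bound(self):
        scores, sites = _delta_fixture(500, delta=0.5, noise_sd=1.0, seed=1)
        res = site_vs_nonsite_contrast(scores, sites)
        assert abs(res.mean_difference - 0.5) < 0.1
        assert res.pvalue < 0.05

    def test_null_rejection_rate_near_alpha(self):
        hits = 0
        n_runs = 100
        for rep in range(n_runs):
            scores, sites = _delta_fixture(60, delta=0.0, noise_sd=1.0, seed=1000 + rep, length=60)
            res = site_vs_nonsite_contrast(scores, sites, compute_pooled=False)
            hits += res.pvalue < 0.05
        assert 0.005 <= hits / n_runs <= 0.11

    def test_partition_covers_utr_once(self):
        scores, sites = _delta_fixture(5, delta=0.3, noise_sd=0.5, seed=2)
        res = site_vs_nonsite_contrast(scores, sites)
        for gene, arr in scores.items():
            n_site = sum(s.end - s.start for s in sites[gene])
            row = res.table.set_index("gene").loc[gene]
            total = row["site_mean"] * n_site + row["nonsite_mean"] * (len(arr) - n_site)
            assert total == pytest.approx(arr.sum(), rel=1e-9)

    def test_gene_without_sites_excluded(self):
        scores, sites = _delta_fixture(5, delta=0.5, noise_sd=1.0, seed=3)
        sites["g0"] = []
        res = site_vs_nonsite_contrast(scores, sites)
        assert "g0" in res.excluded
        assert res.n_genes == 4

    def test_wilcoxon_alternative(self):
        scores, sites = _delta_fixture(30, delta=0.8, noise_sd=0.5, seed=4)
        res = site_vs_nonsite_contrast(scores, sites, use_wilcoxon=True)
        assert res.method == "wilcoxon"
        assert res.pvalue < 0.01


class TestFeatureClassSummary:
    def _uniform_track(self, value=1.0):
        track = ConservationTrack()
        track.add_array("chr1", 0, np.full(1000, value))
        return track

    def test_constant_scores_non_significant(self):
        track = self._uniform_track()
        feats = [
            FeatureInterval("chr1", i * 10, i * 10 + 10, "A" if i % 2 else "B")
            for i in range(10)
        ]
        res = feature_class_summary(track, feats)
        assert res.kw_pvalue == pytest.approx(1.0)
        assert res.class_means["A"] == res.class_means["B"]

    def test_kw_matches_rank_oracle(self, rng):
        track = ConservationTrack()
        values = np.concatenate([rng.normal(0, 1, 500), rng.normal(1, 1, 500)])
        track.add_array("chr1", 0, values)
        feats = [FeatureInterval("chr1", i * 10, i * 10 + 10, "lo") for i in range(50)] + [
            FeatureInterval("chr1", 500 + i * 10, 510 + i * 10, "hi") for i in range(50)
        ]
        res = feature_class_summary(track, feats)
        # independent recomputation from pooled ranks of the per-feature means
        means = res.per_feature.groupby("feature_class")["mean_score"].apply(list)
        groups = [np.array(means["hi"]), np.array(means["lo"])]
        pooled = np.concatenate(groups)
        ranks = stats.rankdata(pooled)
        n = len(pooled)
        r1, r2 = ranks[: len(groups[0])], ranks[len(groups[0]) :]
        h = 12 / (n * (n + 1)) * (
            len(r1) * r1.mean() ** 2 + len(r2) * r2.mean() ** 2
        ) - 3 * (n + 1)
        assert res.kw_stat == pytest.approx(h, rel=1e-9)

    def test_empty_features_rejected(self):
        with pytest.raises(ValueError):
            feature_class_summary(self._uniform_track(), [])

    def test_small_class_excluded(self):
        track = self._uniform_track()
        feats = [
            FeatureInterval("chr1", 0, 10, "A"),
            FeatureInterval("chr1", 20, 30, "A"),
            FeatureInterval("chr1", 40, 50, "lonely"),
        ]
        res = feature_class_summary(track, feats)
        assert res.excluded_classes == ["lonely"]
        assert res.status == "declined"  # only one testable class remains


class TestMnd:
    def test_max_at_half(self):
        assert mnd(0.5) == 0.5

    def test_boundaries(self):
        assert mnd(0.0) == 0.0
        assert mnd(1.0) == 0.0

    def test_arithmetic(self):
        assert mnd(0.1) == pytest.approx(0.18)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            mnd(1.2)
        with pytest.raises(ValueError):
            mnd(-0.1)

    @settings(max_examples=200, deadline=None)
    @given(st.floats(min_value=0, max_value=1))
    def test_symmetry_property(self, p):
        assert mnd(p) == pytest.approx(mnd(1 - p), abs=1e-12)

    def test_grid_range(self):
        grid = np.arange(0, 1.0000001, 1e-3)
        vals = mnd(grid)
        assert vals.min() >= 0.0 and vals.max() <= 0.5


class TestPopgenCompare:
    def _table(self, rng, specs):
        rows = []
        for cls, (n, a, b) in specs.items():
            for daf in rng.beta(a, b, n):
                rows.append({"feature_class": cls, "daf": float(daf)})
        return pd.DataFrame(rows)

    def test_single_class_declined(self, rng):
        res = popgen_class_compare(self._table(rng, {"only": (30, 1, 1)}))
        assert res.status == "declined"
        assert res.tests == {}

    def test_unknown_class_rejected(self, rng):
        with pytest.raises(ValueError, match="unknown"):
            popgen_class_compare(self._table(rng, {"a": (10, 1, 1)}), classes=["a", "zzz"])

    def test_mnd_column_row_invariant(self, rng):
        df = self._table(rng, {"a": (50, 1, 3), "b": (50, 3, 1)})
        res = popgen_class_compare(df)
        assert res.status == "ok"
        # recompute per-class mean mnd from daf directly
        for row in res.per_class.itertuples():
            sub = df[df["feature_class"] == row.feature_class]
            assert row.mean_mnd == pytest.approx(
                float(np.mean(2 * sub["daf"] * (1 - sub["daf"])))
            )

    def test_power_on_shifted_betas(self):
        hits = 0
        for rep in range(30):
            rng = np.random.default_rng(500 + rep)
            df = self._table(rng, {"lo": (500, 1, 9), "hi": (500, 5, 5)})
            res = popgen_class_compare(df)
            hits += res.tests["daf"]["kw_pvalue"] < 0.05
        assert hits >= 29

    def test_kw_invariant_under_monotone_transform(self, rng):
        df = self._table(rng, {"a": (80, 1, 3), "b": (80, 2, 2)})
        res1 = popgen_class_compare(df)
        df2 = df.copy()
        df2["daf"] = df2["daf"] ** 3  # strictly monotone on [0, 1]
        res2 = popgen_class_compare(df2)
        assert res1.tests["daf"]["kw_stat"] == pytest.approx(res2.tests["daf"]["kw_stat"])


class TestDunn:
    def test_pairwise_count(self, rng):
        groups = {k: rng.normal(i, 1, 20) for i, k in enumerate("abc")}
        table = dunn_posthoc(groups)
        assert len(table) == 3
        assert (table["p_adjusted"] >= table["pvalue"] - 1e-12).all()

    def test_detects_shifted_group(self, rng):
        groups = {"a": rng.normal(0, 1, 50), "b": rng.normal(0, 1, 50), "c": rng.normal(3, 1, 50)}
        table = dunn_posthoc(groups).set_index(["group_a", "group_b"])
        assert table.loc[("a", "c"), "p_adjusted"] < 0.001
        assert table.loc[("a", "b"), "p_adjusted"] > 0.05
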