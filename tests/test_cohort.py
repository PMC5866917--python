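"""Frequency matrices, bootstrap clustering, coverage and enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from mutdomino.cohort import (
    TumorFrequencyMatrix,
    bootstrap_cluster,
    build_frequency_matrix,
    compare_set_fractions,
    compare_set_fractions_batch,
    coverage_null,
    heatmap_transform,
    neighborhood_enrichment,
    patient_coverage,
)
from mutdomino.hotspots import ResidueMutationProfile, detect_hotspots

from conftest import missense


def _manifest(counts):
    rows = []
    for ttype, n in counts.items():
        for i in range(n):
            rows.append({"sample": f"{ttype}{i:04d}", "tumor_type": ttype})
    return pd.DataFrame(rows)


def _call(gene="G1", pos=100):
    counts = np.zeros(400, dtype=int)
    counts[pos - 1] = 6
    profile = ResidueMutationProfile(gene_id=gene, length=400, counts=counts)
    return [c for c in detect_hotspots(profile) if c.passed][0]


class TestFrequencyMatrix:
    def test_small_cohorts_excluded(self):
        manifest = _manifest({"BIG": 50, "SMALL": 49})
        muts = [missense("G1", 100, "BIG0000", tumor_type="BIG")]
        m = build_frequency_matrix([_call()], muts, manifest)
        assert list(m.fractions.columns) == ["BIG"]

    def test_fraction_arithmetic(self):
        manifest = _manifest({"T": 50})
        muts = [missense("G1", 100, "T0000", tumor_type="T"),
                missense("G1", 100, "T0001", tumor_type="T")]
        m = build_frequency_matrix([_call()], muts, manifest, min_patients=4)
        assert m.fractions.loc["G1_100", "T"] == pytest.approx(2 / 50)

    def test_absent_hotspot_is_zero(self):
        manifest = _manifest({"T": 50})
        m = build_frequency_matrix([_call()], [], manifest)
        assert (m.fractions == 0).all().all()

    def test_sample_missing_from_manifest_raises(self):
        manifest = _manifest({"T": 50})
        muts = [missense("G1", 100, "UNKNOWN", tumor_type="T")]
        with pytest.raises(ValueError, match="missing from the manifest"):
            build_frequency_matrix([_call()], muts, manifest)

    def test_carrier_counts_bounded_by_cohort(self):
        manifest = _manifest({"T": 50})
        muts = [missense("G1", 100, f"T{i:04d}", tumor_type="T") for i in range(50)]
        m = build_frequency_matrix([_call()], muts, manifest)
        assert (m.fractions <= 1).all().all()


class TestBootstrapClustering:
    def _matrix(self, seed=0, duplicate=True):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(rng.uniform(0, 0.5, size=(30, 5)),
                          columns=["A", "B", "C", "D", "E"])
        if duplicate:
            df["B"] = df["A"]
        return TumorFrequencyMatrix(df, pd.Series(100, index=df.columns))

    def test_duplicate_columns_get_full_support(self):
        support = bootstrap_cluster(self._matrix(), n_bootstrap=200, seed=1)
        assert support.support[frozenset({"A", "B"})] == 1.0

    def test_single_bootstrap_gives_binary_support(self):
        support = bootstrap_cluster(self._matrix(), n_bootstrap=1, seed=2)
        assert set(support.support.values()) <= {0.0, 1.0}

    def test_constant_column_dropped_with_warning(self):
        m = self._matrix(duplicate=False)
        m.fractions["E"] = 0.25
        with pytest.warns(UserWarning, match="constant"):
            support = bootstrap_cluster(m, n_bootstrap=10, seed=3)
        assert support.dropped_columns == ["E"] and "E" not in support.labels

    def test_block_structure_recovered(self):
        rng = np.random.default_rng(4)
        base1 = rng.uniform(0, 0.5, 40)
        base2 = rng.uniform(0, 0.5, 40)
        df = pd.DataFrame({
            "A1": base1 + rng.normal(0, 0.02, 40),
            "A2": base1 + rng.normal(0, 0.02, 40),
            "B1": base2 + rng.normal(0, 0.02, 40),
            "B2": base2 + rng.normal(0, 0.02, 40),
        }).clip(0, 1)
        m = TumorFrequencyMatrix(df, pd.Series(100, index=df.columns))
        support = bootstrap_cluster(m, n_bootstrap=200, seed=5)
        within = support.support.get(frozenset({"A1", "A2"}), 0.0)
        assert within > 0.9

    def test_newick_export_contains_all_leaves(self):
        support = bootstrap_cluster(self._matrix(), n_bootstrap=5, seed=6)
        newick = support.to_newick()
        assert newick.endswith(";")
        for label in support.labels:
            assert label in newick


class TestHeatmapTransform:
    def _matrix(self, values):
        df = pd.DataFrame(values)
        return TumorFrequencyMatrix(df, pd.Series(100, index=df.columns))

    def test_log2_of_percentage(self):
        m = self._matrix({"T": [0.78], "U": [0.01]})
        out = heatmap_transform(m)
        assert out.loc[0, "T"] == pytest.approx(np.log2(78), abs=1e-9)
        assert out.loc[0, "U"] == pytest.approx(0.0)

    def test_row_below_display_threshold_dropped(self):
        m = self._matrix({"T": [0.30, 0.50], "U": [0.10, 0.10]})
        out = heatmap_transform(m)
        assert list(out.index) == [1]

    def test_zeros_rendered_below_minimum(self):
        m = self._matrix({"T": [0.5], "U": [0.0], "V": [0.04]})
        out = heatmap_transform(m)
        floor = out.loc[0, "U"]
        assert floor == pytest.approx(np.log2(4) - 1)
        assert floor < out.loc[0, "V"] < out.loc[0, "T"]

    def test_monotone_on_positive_entries(self):
        m = self._matrix({"T": [0.4], "U": [0.5], "V": [0.6]})
        out = heatmap_transform(m)
        assert out.loc[0, "T"] < out.loc[0, "U"] < out.loc[0, "V"]


class TestPatientCoverage:
    def test_empty_set_and_union_rule(self):
        manifest = _manifest({"T": 4})
        muts = [missense("G1", 100, "T0000", tumor_type="T"),
                missense("G1", 101, "T0000", tumor_type="T"),
                missense("G2", 5, "T0000", tumor_type="T"),
                missense("G1", 100, "T0001", tumor_type="T")]
        assert patient_coverage([], muts, manifest) == 0.0
        # sample T0000 hits three targets but counts once
        assert patient_coverage(["G1", "G2"], muts, manifest) == pytest.approx(0.5)
        assert patient_coverage([("G1", 100)], muts, manifest) == pytest.approx(0.5)

    def test_empty_manifest_rejected(self):
        with pytest.raises(ValueError):
            patient_coverage(["G1"], [], pd.DataFrame(columns=["sample"]))


class TestCoverageNull:
    def _cohort(self):
        manifest = _manifest({"T": 40})
        muts = []
        rng = np.random.default_rng(0)
        for g in range(12):
            carriers = rng.choice(40, size=6, replace=False)
            for c in carriers:
                muts.append(missense(f"G{g}", 10, f"T{c:04d}", tumor_type="T"))
        return muts, manifest

    def test_observed_at_null_mean_gives_half(self):
        muts, manifest = self._cohort()
        null = coverage_null(muts, manifest, set_size=3, observed=0.0,
                             n_draws=200, seed=1)
        mid = coverage_null(muts, manifest, set_size=3,
                            observed=float(null.null_values.mean()),
                            n_draws=200, seed=1)
        assert 0.35 < mid.p < 0.65

    def test_extreme_observed_is_significant(self):
        muts, manifest = self._cohort()
        res = coverage_null(muts, manifest, set_size=3, observed=1.0,
                            n_draws=200, seed=2)
        assert res.p < 1 / 200

    def test_seed_reproducibility(self):
        muts, manifest = self._cohort()
        a = coverage_null(muts, manifest, set_size=3, observed=0.5, n_draws=50, seed=7)
        b = coverage_null(muts, manifest, set_size=3, observed=0.5, n_draws=50, seed=7)
        assert np.array_equal(a.null_values, b.null_values)

    def test_pool_too_small_rejected(self):
        muts, manifest = self._cohort()
        with pytest.raises(ValueError, match="pool"):
            coverage_null(muts, manifest, set_size=12, observed=0.5)


class TestNeighborhoodEnrichment:
    EDGES = [("q", "a"), ("q", "b"), ("a", "b"), ("b", "c"), ("c", "d"), ("d", "e")]

    def test_all_nodes_labeled_no_enrichment(self):
        labels = {"a", "b", "c", "d", "e"}
        res = neighborhood_enrichment(self.EDGES, ["q"], labels,
                                      n_resamples=100, seed=1)
        assert res.observed == 2  # both neighbors labeled
        assert res.p >= 0.5

    def test_empty_label_set(self):
        res = neighborhood_enrichment(self.EDGES, ["q"], [], n_resamples=50, seed=2)
        assert res.observed == 0 and res.p >= 0.5

    def test_null_matches_hypergeometric_enumeration(self):
        # single query of degree 2 drawing from 5 candidates, 2 of them labeled:
        # labeled-neighbor count is hypergeometric(N=5, K=2, n=2)
        labels = {"a", "c"}
        res = neighborhood_enrichment(self.EDGES, ["q"], labels,
                                      n_resamples=4000, seed=3)
        exact_mean = hypergeom.mean(5, 2, 2)
        exact_sd = hypergeom.std(5, 2, 2)
        assert res.null_values.mean() == pytest.approx(exact_mean, abs=0.05)
        assert res.null_values.std() == pytest.approx(exact_sd, abs=0.05)

    def test_absent_query_warns_and_skips(self):
        with pytest.warns(UserWarning, match="absent"):
            res = neighborhood_enrichment(self.EDGES, ["missing", "q"], {"a"},
                                          n_resamples=20, seed=4)
        assert res.observed <= 2


class TestCompareSetFractions:
    def test_identical_proportions_not_significant(self):
        _, p, _ = compare_set_fractions((50, 100), (50, 100))
        assert p > 0.9

    def test_large_difference_matches_hypergeometric_oracle(self):
        stat, p, method = compare_set_fractions((90, 100), (10, 100))
        assert p < 1e-6
        # hypergeometric upper tail agrees on the order of magnitude
        oracle = hypergeom.sf(89, 200, 100, 100)
        assert oracle < 1e-6

    def test_small_expected_counts_use_fisher(self):
        _, _, method = compare_set_fractions((2, 5), (0, 5))
        assert method == "fisher"

    def test_zero_margin_table(self):
        stat, p, method = compare_set_fractions((0, 5), (0, 5))
        assert p == 1.0 and method == "fisher"

    def test_batch_of_one_adjusted_equals_raw(self):
        df = compare_set_fractions_batch([((5, 10), (6, 10))])
        assert df.loc[0, "p_adjusted"] == pytest.approx(df.loc[0, "p"])
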