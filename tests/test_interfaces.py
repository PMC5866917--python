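"""Interface extraction, alignment transfer and the region cluster test."""

import numpy as np
import pandas as pd
import pytest
from Bio.Align import substitution_matrices

from mutdomino.hotspots import ResidueMutationProfile
from mutdomino.interfaces import (
    ClusterTestResult,
    InterfaceAnnotation,
    extract_interface_residues,
    interface_cluster_test,
    local_align,
    map_interface_to_protein,
    select_significant,
)
from mutdomino.simulate import simulate_region_profile

BLOSUM62 = substitution_matrices.load("BLOSUM62")


def gotoh_local_score(a, b, open_gap=10.0, extend_gap=0.5):
    """Brute-force affine-gap Smith-Waterman score (independent oracle).

    Convention: a gap of length L costs open + (L-1) * extend, matching the
    implementation's scoring.
    """
    n, m = len(a), len(b)
    NEG = -1e9
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)  # gap in a (consuming b)
    F = np.full((n + 1, m + 1), NEG)  # gap in b (consuming a)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - open_gap, E[i][j - 1] - extend_gap)
            F[i][j] = max(H[i - 1][j] - open_gap, F[i - 1][j] - extend_gap)
            s = BLOSUM62[a[i - 1], b[j - 1]]
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def _pisa_rows(structure="1ABC", chain="A", interface="i1", partner_class="protein",
               partner="P2", css=0.4, residues=((10, 30.0), (11, 40.0))):
    return [
        {"structure_id": structure, "chain": chain, "residue_index": r,
         "residue_aa": "A", "ASA": 100.0, "BSA": bsa, "interface_id": interface,
         "partner_class": partner_class, "partner_id": partner, "CSS": css,
         "target_gene": "TG"}
        for r, bsa in residues
    ]


class TestInterfaceExtraction:
    def test_buried_residue_kept(self):
        df = pd.DataFrame(_pisa_rows(residues=((10, 30.0),)))
        (ann,) = extract_interface_residues(df)
        assert ann.segments == [(10, 10)] and ann.residue_bsa[10] == 30.0

    def test_low_bsa_excluded(self):
        df = pd.DataFrame(_pisa_rows(residues=((10, 20.0), (11, 30.0))))
        (ann,) = extract_interface_residues(df)
        assert 10 not in ann.residue_bsa and ann.segments == [(11, 11)]

    def test_css_threshold_is_partner_class_specific(self):
        protein = pd.DataFrame(_pisa_rows(css=0.1, partner_class="protein"))
        assert extract_interface_residues(protein) == []
        ligand = pd.DataFrame(_pisa_rows(css=0.1, partner_class="ligand"))
        assert len(extract_interface_residues(ligand)) == 1

    def test_contiguous_residues_merge_into_segments(self):
        df = pd.DataFrame(_pisa_rows(
            residues=((10, 30.0), (11, 30.0), (12, 30.0), (20, 30.0))))
        (ann,) = extract_interface_residues(df)
        assert ann.segments == [(10, 12), (20, 20)]

    def test_negative_area_rejected(self):
        df = pd.DataFrame(_pisa_rows(residues=((10, -1.0),)))
        with pytest.raises(ValueError, match="negative"):
            extract_interface_residues(df)


class TestLocalAlign:
    def test_identical_sequences(self):
        res = local_align("HEAGAWGHEE", "HEAGAWGHEE")
        assert res.identity == 1.0
        assert res.offset_map == {i: i for i in range(1, 11)}

    def test_classic_pair_matches_dp_oracle(self):
        res = local_align("HEAGAWGHEE", "PAWHEAE")
        assert res.score == pytest.approx(gotoh_local_score("HEAGAWGHEE", "PAWHEAE"))

    def test_all_negative_scores_give_empty_alignment(self):
        res = local_align("WWWW", "PPPP")  # W-P = -4 under BLOSUM62
        assert res.score == 0.0 and res.offset_map == {}

    def test_random_pairs_match_dp_oracle(self):
        rng = np.random.default_rng(5)
        aa = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        for _ in range(25):
            a = "".join(rng.choice(aa, rng.integers(8, 16)))
            b = "".join(rng.choice(aa, rng.integers(8, 16)))
            assert local_align(a, b).score == pytest.approx(gotoh_local_score(a, b))

    def test_offsets_strictly_increasing(self):
        res = local_align("HEAGAWGHEE", "PAWHEAE")
        items = sorted(res.offset_map.items())
        qs = [q for q, _ in items]
        ts = [t for _, t in items]
        assert qs == sorted(qs) and ts == sorted(ts) and len(set(ts)) == len(ts)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            local_align("", "MEK")


def _annotation(segments):
    return InterfaceAnnotation(
        target_gene="TG", structure_id="1ABC", chain="A", interface_id="i1",
        partner_class="protein", partner_id="P2", css=0.4, segments=segments,
    )


class TestCoordinateTransfer:
    def test_exact_substring_maps_one_to_one(self):
        structure = "MKLVACDEFGHTRS"
        target = "GGGMKLVACDEFGHTRSGGG"
        ann = map_interface_to_protein(_annotation([(5, 11)]), structure, target)
        assert ann.mapped_residues == {r: r + 3 for r in range(5, 12)}
        assert ann.unmapped_segments == []

    def test_short_segment_padded_before_alignment(self):
        structure = "MKLVACDEFGHTRS"
        target = "MKLVACDEFGHTRS"
        ann = map_interface_to_protein(_annotation([(6, 7)]), structure, target)
        # only the original residues are transferred, not the padding
        assert set(ann.mapped_residues) == {6, 7}

    def test_seven_columns_five_identities_rejected(self):
        # identity 5/7 ~ 71% on an alignment of <= 10 columns needs >= 80%
        structure = "ACDEFGH"
        target = "ACEDFGH"  # two conservative mismatches keep the full alignment
        ann = map_interface_to_protein(_annotation([(1, 7)]), structure, target)
        assert ann.mapped_residues == {} and ann.unmapped_segments == [(1, 7)]

    def test_twelve_columns_eight_identities_accepted(self):
        # identity 8/12 ~ 67% is enough once the alignment exceeds 10 columns
        structure = "ACDEFGHIKLMN"
        target = "ACEEFAHVKMMN"
        aln = local_align(structure, target)
        assert aln.length == 12 and aln.identity == pytest.approx(8 / 12)
        ann = map_interface_to_protein(_annotation([(1, 12)]), structure, target)
        assert len(ann.mapped_residues) == 12

    def test_transfer_is_injective_on_target(self):
        structure = "WWWWWACDEFGHWWWWWACDEFGHWWWWW"
        target = "YYYYACDEFGHYYYY"
        ann = map_interface_to_protein(
            _annotation([(6, 12), (18, 24)]), structure, target)
        mapped_targets = list(ann.mapped_residues.values())
        assert len(mapped_targets) == len(set(mapped_targets))
        assert ann.unmapped_segments == [(18, 24)]

    def test_segment_outside_chain_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            map_interface_to_protein(_annotation([(1, 99)]), "ACDEFGH", "ACDEFGH")


class TestClusterTest:
    def test_strong_interface_clustering_detected(self):
        # all 15 mutated residues inside an interface of 20/200 residues
        counts = np.zeros(200, dtype=int)
        counts[:15] = 1
        mask = np.arange(200) < 20
        profile = ResidueMutationProfile(gene_id="G", length=200, counts=counts)
        res = interface_cluster_test(profile, mask, cohort_size=100)
        assert res.p < 1e-3 and res.beta_interface > 0
        # direction agrees with a Fisher 2x2 oracle on (interface x mutated)
        from scipy.stats import fisher_exact
        odds, fisher_p = fisher_exact([[15, 5], [0, 180]], alternative="greater")
        assert fisher_p < 1e-3

    def test_uniform_mutations_give_roughly_uniform_p(self):
        mask = np.arange(300) < 30
        ps = [
            interface_cluster_test(
                simulate_region_profile(300, 30, mask, 1.0, seed=i),
                mask, cohort_size=100).p
            for i in range(200)
        ]
        ps = np.asarray(ps)
        assert 0.35 < ps.mean() < 0.65
        assert (ps < 0.05).mean() <= 0.12

    def test_zero_mutations_untestable(self):
        profile = ResidueMutationProfile(gene_id="G", length=100,
                                         counts=np.zeros(100, dtype=int))
        res = interface_cluster_test(profile, np.arange(100) < 10, cohort_size=50)
        assert res.untestable and res.p == 1.0

    def test_mask_length_mismatch_rejected(self):
        profile = ResidueMutationProfile(gene_id="G", length=100,
                                         counts=np.zeros(100, dtype=int))
        with pytest.raises(ValueError):
            interface_cluster_test(profile, np.zeros(99, bool), cohort_size=50)

    def test_disorder_covariate_enters_model(self):
        counts = np.zeros(200, dtype=int)
        counts[100:110] = 2  # mutations in a disordered, non-interface stretch
        disorder = np.zeros(200, bool)
        disorder[100:150] = True
        mask = np.arange(200) < 20
        profile = ResidueMutationProfile(gene_id="G", length=200, counts=counts)
        res = interface_cluster_test(profile, mask, disorder, cohort_size=100)
        assert res.beta_disorder > 0 and res.p >= 0.5


class TestSelectSignificant:
    def _result(self, p):
        return ClusterTestResult(
            target_gene="G", n_residues_in=10, n_residues_out=90,
            mutated_in=0, mutated_out=0, intercept=0.0, beta_interface=0.0,
            beta_disorder=0.0, p=p)

    def test_single_significant_retained(self):
        assert len(select_significant([self._result(0.01)])) == 1

    def test_all_tiny_p_retained(self):
        results = [self._result(1e-6) for _ in range(10)]
        assert len(select_significant(results)) == 10

    def test_uniform_null_mostly_rejected(self):
        rng = np.random.default_rng(3)
        results = [self._result(p) for p in rng.uniform(0.01, 1.0, size=100)]
        assert len(select_significant(results)) <= 2
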