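import numpy as np
import pandas as pd
import pytest

from crossprot.crossplatform import (CATEGORY_CONCORDANT, CATEGORY_DISCORDANT,
                                     CATEGORY_UNCOMPARED, chi_square_upper_tail,
                                     classify_pair, contains_pav,
                                     differentiation_flags, eaf_by_group,
                                     eaf_chi_square, sentinel_overlap,
                                     trans_regions, _merge_intervals)
from crossprot.io import GenotypeData, VARIANT_COLUMNS
from crossprot.pqtl import CredibleSet
from tests.conftest import make_credible_set


def variant_table(rows):
    return pd.DataFrame(rows, columns=["variant_id"] + VARIANT_COLUMNS).set_index("variant_id")


class TestClassifyPair:
    def test_shared_sentinel_same_sign_concordant(self):
        sa = make_credible_set(["x", "y"], "x", 1e-12, betas={"x": 0.5, "y": 0.1})
        sb = make_credible_set(["x", "z"], "x", 1e-10, platform="B",
                               betas={"x": 0.3, "z": 0.1})
        assert classify_pair(sa, sb).category == CATEGORY_CONCORDANT

    def test_opposite_signs_discordant(self):
        # archetype: aptamer beta -1.34 vs antibody beta +0.92 at the shared sentinel
        sa = make_credible_set(["x"], "x", 1e-300, betas={"x": -1.34})
        sb = make_credible_set(["x"], "x", 1e-300, platform="B", betas={"x": 0.92})
        out = classify_pair(sa, sb)
        assert out.category == CATEGORY_DISCORDANT
        assert out.compared_sentinel == "x"

    def test_shared_member_but_no_shared_sentinel_uncompared(self):
        sa = make_credible_set(["x", "shared"], "x", 1e-12)
        sb = make_credible_set(["y", "shared"], "y", 1e-10, platform="B")
        assert classify_pair(sa, sb).category == CATEGORY_UNCOMPARED

    def test_single_platform_categories(self):
        sa = make_credible_set(["x"], "x", 1e-12)
        assert classify_pair(sa, None).category == "A_only"
        assert classify_pair(None, sa).category == "B_only"

    def test_both_absent_errors(self):
        with pytest.raises(ValueError):
            classify_pair(None, None)

    def test_platform_swap_symmetry(self):
        sa = make_credible_set(["x", "y"], "x", 1e-12, betas={"x": -0.5, "y": 0.2})
        sb = make_credible_set(["x", "y"], "y", 1e-8, platform="B",
                               betas={"x": 0.4, "y": -0.3})
        fwd = classify_pair(sa, sb).category
        rev = classify_pair(sb, sa).category
        assert fwd == rev  # concordant/discordant invariant under swap


class TestContainsPav:
    variants = variant_table([
        ("m1", "1", 100, "A", "G", "missense", "GENE1"),
        ("m2", "1", 200, "A", "G", "missense", "OTHER"),
        ("n1", "1", 300, "A", "G", "none", ""),
    ])

    def test_missense_on_target_gene(self):
        s = make_credible_set(["m1", "n1"], "n1", 1e-9)
        assert contains_pav(s, self.variants, "GENE1")

    def test_missense_on_other_gene(self):
        s = make_credible_set(["m2"], "m2", 1e-9)
        assert not contains_pav(s, self.variants, "GENE1")

    def test_no_coding_members(self):
        s = make_credible_set(["n1"], "n1", 1e-9)
        assert not contains_pav(s, self.variants, "GENE1")


class TestEaf:
    def make_genotypes(self, dosages, labels):
        n = len(labels)
        variants = variant_table([("v1", "1", 100, "A", "G", "none", "")])
        g = GenotypeData(pd.DataFrame({"v1": dosages},
                                      index=[f"s{i}" for i in range(n)]), variants)
        return g, np.array(labels)

    def test_simple_frequency(self):
        g, labels = self.make_genotypes([0.0, 1.0, 2.0], ["G1"] * 3)
        out = eaf_by_group(g, labels, ["G1"])
        assert out.loc["v1", "eaf_G1"] == 0.5

    def test_all_reference_group(self):
        g, labels = self.make_genotypes([0.0, 0.0, 0.0], ["G1"] * 3)
        assert eaf_by_group(g, labels, ["G1"]).loc["v1", "eaf_G1"] == 0.0

    def test_missing_dosages_never_imputed(self):
        g, labels = self.make_genotypes([0.0, np.nan, 2.0], ["G1"] * 3)
        out = eaf_by_group(g, labels, ["G1"])
        assert out.loc["v1", "tot_G1"] == 4.0
        assert out.loc["v1", "eaf_G1"] == 0.5

    def test_empty_group_errors(self):
        g, labels = self.make_genotypes([0.0, 1.0], ["G1", "G1"])
        with pytest.raises(ValueError, match="empty ancestry group"):
            eaf_by_group(g, labels, ["G1", "G2"])


class TestEafChiSquare:
    def test_equal_frequencies(self):
        x2, df, p = eaf_chi_square([(10, 100), (10, 100)])
        assert x2 == 0.0 and p == 1.0

    def test_hand_contingency(self):
        x2, df, p = eaf_chi_square([(10, 100), (30, 100)])
        assert np.isclose(x2, 12.5)
        assert df == 1
        assert np.isclose(p, 4.07e-4, rtol=0.01)

    def test_pooled_monomorphic_flagged(self):
        x2, df, p = eaf_chi_square([(0, 100), (0, 50)])
        assert x2 == 0.0 and p == 1.0

    def test_upper_tail_mapping_df3(self):
        # four ancestry groups -> df = 3
        assert np.isclose(chi_square_upper_tail(230.7, 3), 9.76e-50, rtol=0.01)


class TestDifferentiationFlags:
    def test_quantile_convention(self):
        thr, flags = differentiation_flags(np.arange(1, 101, dtype=float))
        assert np.isclose(thr, 75.25)
        assert flags[79]  # value 80
        assert not flags[74]  # value 75

    def test_all_equal_nothing_flagged(self):
        thr, flags = differentiation_flags(np.full(10, 3.0))
        assert not flags.any()  # strict >

    def test_duplicate_max_keeps_top_values_flagged(self):
        vals = np.arange(1, 101, dtype=float)
        thr1, flags1 = differentiation_flags(vals)
        thr2, flags2 = differentiation_flags(np.append(vals, 100.0))
        assert thr1 <= thr2 < 100.0
        assert flags2[99] and flags2[100]  # the max stays flagged
        # flags remain a threshold rule: exactly the values above thr2
        np.testing.assert_array_equal(flags2[:100], vals > thr2)


class TestTransRegions:
    def sentinels(self, rows):
        return pd.DataFrame(rows, columns=["platform", "probe_id", "chrom", "pos"])

    def test_overlapping_windows_merge(self):
        out = trans_regions(self.sentinels([
            ("A", "p1", "1", 5_000_000), ("A", "p2", "1", 5_800_000)]))
        assert len(out) == 1
        assert out.iloc[0]["start"] == 4_500_000 and out.iloc[0]["end"] == 6_300_000

    def test_platform_specific_category(self):
        rows = [("A", f"p{i}", "1", 5_000_000 + i * 1000) for i in range(6)]
        out = trans_regions(self.sentinels(rows))
        assert out.iloc[0]["category"] == "A_specific"
        assert out.iloc[0]["protein_count_A"] == 6

    def test_rule_gap_not_pleiotropic(self):
        rows = ([("A", f"a{i}", "1", 5_000_000) for i in range(5)]
                + [("B", f"b{i}", "1", 5_100_000) for i in range(2)])
        out = trans_regions(self.sentinels(rows))
        assert out.iloc[0]["category"] == "not_pleiotropic"

    def test_shared_pleiotropic(self):
        rows = ([("A", f"a{i}", "9", 136_000_000) for i in range(5)]
                + [("B", f"b{i}", "9", 136_200_000) for i in range(5)])
        out = trans_regions(self.sentinels(rows))
        assert out.iloc[0]["category"] == "shared_pleiotropic"

    def test_merge_idempotent_and_order_free(self, rng):
        for _ in range(20):
            iv = [(int(s), int(s + rng.integers(1, 50))) for s in rng.integers(0, 200, 10)]
            merged = _merge_intervals(iv)
            assert _merge_intervals(merged) == merged
            perm = [iv[i] for i in rng.permutation(len(iv))]
            assert _merge_intervals(perm) == merged


class TestSentinelOverlap:
    ext = pd.DataFrame({
        "source": ["eqtl", "eqtl", "eqtl"],
        "variant_id": ["x", "x", "y"],
        "gene": ["GENE1", "GENE1", "GENE1"],
        "context": ["tissue1", "tissue2", "tissue1"],
        "sign": ["+", "+", "-"],
    })

    def test_concordant_across_all_contexts(self):
        s = make_credible_set(["x"], "x", 1e-9, betas={"x": 0.5})
        out = sentinel_overlap([s], self.ext, {"probe1": "GENE1"})
        assert bool(out.iloc[0]["matched"]) and bool(out.iloc[0]["concordant"])

    def test_conflicting_signs_excluded(self):
        s = make_credible_set(["x", "y"], "x", 1e-9, betas={"x": 0.5, "y": 0.1})
        out = sentinel_overlap([s], self.ext, {"probe1": "GENE1"})
        assert bool(out.iloc[0]["excluded"])

    def test_no_match_unflagged(self):
        s = make_credible_set(["z"], "z", 1e-9)
        out = sentinel_overlap([s], self.ext, {"probe1": "GENE1"})
        assert not bool(out.iloc[0]["matched"])

    def test_gene_mismatch_not_matched(self):
        s = make_credible_set(["x"], "x", 1e-9, betas={"x": 0.5})
        out = sentinel_overlap([s], self.ext, {"probe1": "OTHERGENE"})
        assert not bool(out.iloc[0]["matched"])
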