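"""Diversity statistics against brute-force enumeration oracles."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_panel
from soypop.popgen import (
    allele_frequencies,
    classify_sharing,
    fst_windows,
    ld_r2_windows,
    nucleotide_diversity_windows,
    pairwise_r2,
    private_variants_per_accession,
    weir_cockerham_components,
)


class TestAlleleFrequencies:
    def test_two_diploids_arithmetic(self):
        panel = make_panel([[1.0], [2.0]], groups=["G", "G"] )
        ft = allele_frequencies(panel)
        assert ft.freq.iloc[0, 0] == 0.75
        assert ft.n_alleles.iloc[0, 0] == 4

    def test_all_missing_group_is_nan(self):
        panel = make_panel(
            [[np.nan], [np.nan], [1.0]], groups=["A", "A", "B"]
        )
        ft = allele_frequencies(panel)
        assert np.isnan(ft.freq.loc[:, "A"].iloc[0])
        assert ft.freq.loc[:, "B"].iloc[0] == 0.5

    def test_agrees_with_counting_oracle(self, rng):
        """Vectorized frequencies equal per-genotype brute-force counts."""
        for _ in range(20):
            d = rng.choice([0, 1, 2, np.nan], size=(12, 30), p=[0.4, 0.2, 0.3, 0.1])
            groups = rng.choice(["A", "B", "C"], size=12).tolist()
            panel = make_panel(d, groups=groups)
            ft = allele_frequencies(panel)
            for g in "ABC":
                rows = [i for i, x in enumerate(groups) if x == g]
                if not rows:
                    continue
                for j in range(30):
                    vals = [d[i, j] for i in rows if not np.isnan(d[i, j])]
                    expect = sum(vals) / (2 * len(vals)) if vals else np.nan
                    got = ft.freq[g].iloc[j]
                    assert (np.isnan(expect) and np.isnan(got)) or got == pytest.approx(expect)

    def test_empty_group_errors(self):
        panel = make_panel([[0.0], [1.0]], groups=["A", "A"])
        panel.groups["missing_sample"] = "B"  # B has no panel rows
        with pytest.raises(ValueError, match="zero samples"):
            allele_frequencies(panel)


class TestSharing:
    def test_private_and_shared_all(self):
        groups = ["Primitive"] * 2 + ["World"] * 2 + ["Japan"] * 2
        d = np.array(
            [
                [0, 0, 0, 0, 1, 0],  # private Japan
                [1, 0, 1, 0, 1, 0],  # shared all
                [0, 0, 0, 0, 0, 0],  # absent
                [1, 1, 0, 0, 0, 2],  # Primitive + Japan
            ]
        ).T
        panel = make_panel(d, groups=groups)
        st = classify_sharing(allele_frequencies(panel))
        cats = st.per_variant.tolist()
        assert cats == [
            "private-Japan",
            "shared-all",
            "absent",
            "shared-Japan+Primitive",
        ]
        assert st.private_per_group["Japan"] == 1

    def test_counts_match_enumeration_oracle(self, rng):
        d = rng.choice([0, 1, 2, np.nan], size=(15, 500), p=[0.6, 0.15, 0.15, 0.1])
        groups = (["A"] * 5 + ["B"] * 5 + ["C"] * 5)
        panel = make_panel(d, groups=groups)
        st = classify_sharing(allele_frequencies(panel))
        # brute force: set of groups with any alt carrier
        expect = []
        for j in range(500):
            obs = set()
            for i, g in enumerate(groups):
                if not np.isnan(d[i, j]) and d[i, j] > 0:
                    obs.add(g)
            if not obs:
                expect.append("absent")
            elif len(obs) == 1:
                expect.append(f"private-{obs.pop()}")
            elif len(obs) == 3:
                expect.append("shared-all")
            else:
                expect.append("shared-" + "+".join(sorted(obs)))
        assert st.per_variant.tolist() == expect
        # categories partition segregating variants
        seg = sum(1 for c in expect if c != "absent")
        assert st.category_counts.drop("absent", errors="ignore").sum() == seg


class TestPrivatePerAccession:
    def test_singleton_and_doubleton(self):
        d = np.array([[1, 1], [0, 1], [0, 0]], dtype=float)
        panel = make_panel(d)
        counts = private_variants_per_accession(panel)
        assert counts.tolist() == [1, 0, 0]  # doubleton counts for nobody

    def test_matches_brute_force(self, rng):
        d = rng.choice([0, 1, 2, np.nan], size=(10, 200), p=[0.7, 0.1, 0.1, 0.1])
        panel = make_panel(d)
        counts = private_variants_per_accession(panel)
        expect = np.zeros(10, dtype=int)
        for j in range(200):
            carriers = [i for i in range(10) if not np.isnan(d[i, j]) and d[i, j] > 0]
            if len(carriers) == 1:
                expect[carriers[0]] += 1
        assert counts.tolist() == expect.tolist()


class TestNucleotideDiversity:
    def test_no_segregating_sites_pi_zero(self):
        panel = make_panel(np.zeros((6, 4)), groups=["G"] * 6)
        out = nucleotide_diversity_windows(panel, w=1000)
        assert (out["pi_G"] == 0).all()

    def test_closed_form_single_site(self):
        """One site, p=0.5, 100 alleles, W=500kb: (100/99)*0.5/5e5."""
        d = np.array([1.0] * 50)[:, None]  # 50 hets -> p=0.5, n=100 alleles
        panel = make_panel(d, groups=["G"] * 50)
        out = nucleotide_diversity_windows(panel, w=500_000)
        assert out["pi_G"].iloc[0] == pytest.approx((100 / 99) * 0.5 / 500_000)

    def test_matches_pairwise_difference_oracle(self, rng):
        """Unbiased per-site pi equals the mean over all allele pairs of the
        per-site difference indicator, summed and divided by W."""
        d = rng.choice([0, 1, 2, np.nan], size=(20, 40), p=[0.4, 0.2, 0.3, 0.1])
        panel = make_panel(d, groups=["G"] * 20, spacing=10)
        w = 2000
        out = nucleotide_diversity_windows(panel, w=w)
        total = 0.0
        for j in range(40):
            alleles = []
            for i in range(20):
                if not np.isnan(d[i, j]):
                    alleles += [1] * int(d[i, j]) + [0] * (2 - int(d[i, j]))
            n = len(alleles)
            if n < 2:
                continue
            diffs = sum(
                1 for a in range(n) for b in range(a + 1, n)
                if alleles[a] != alleles[b]
            )
            total += diffs / (n * (n - 1) / 2)
        assert out["pi_G"].iloc[0] == pytest.approx(total / w)

    def test_allele_label_swap_invariance(self, rng):
        d = rng.choice([0, 1, 2.0], size=(10, 30))
        p1 = make_panel(d, groups=["G"] * 10)
        p2 = make_panel(2.0 - d, groups=["G"] * 10)
        o1 = nucleotide_diversity_windows(p1, w=5000)
        o2 = nucleotide_diversity_windows(p2, w=5000)
        pd.testing.assert_frame_equal(o1, o2)


class TestFst:
    def test_identical_frequencies_near_zero(self, rng):
        """Duplicated groups: theta is O(-1/n), inside +-0.01 at n=200."""
        block = rng.choice([0, 1, 2.0], size=(200, 200))
        d = np.vstack([block, block])  # two identical groups
        panel = make_panel(d, groups=["A"] * 200 + ["B"] * 200)
        out = fst_windows(panel, w=10**8)
        assert abs(out["fst_total"].iloc[0]) < 0.01

    def test_fixed_difference_theta_one(self):
        d = np.vstack([np.zeros((40, 10)), np.full((40, 10), 2.0)])
        panel = make_panel(d, groups=["A"] * 40 + ["B"] * 40)
        out = fst_windows(panel, w=10**8)
        assert out["fst_total"].iloc[0] == pytest.approx(1.0, abs=0.02)

    def test_sample_order_and_label_swap_invariance(self, rng):
        d = rng.choice([0, 1, 2.0], size=(30, 100))
        groups = ["A"] * 10 + ["B"] * 10 + ["C"] * 10
        panel = make_panel(d, groups=groups)
        base = fst_windows(panel, w=10**8)

        perm = rng.permutation(30)
        shuffled = make_panel(d[perm], groups=[groups[i] for i in perm])
        pd.testing.assert_frame_equal(base, fst_windows(shuffled, w=10**8))

        flipped = make_panel(2.0 - d, groups=groups)
        pd.testing.assert_frame_equal(base, fst_windows(flipped, w=10**8))

    def test_pairwise_restriction_consistency(self, rng):
        """Pairwise theta equals total theta computed on the two groups alone."""
        d = rng.choice([0, 1, 2.0, np.nan], size=(40, 150))
        groups = ["A"] * 15 + ["B"] * 15 + ["C"] * 10
        panel = make_panel(d, groups=groups)
        out = fst_windows(panel, w=10**8)
        sub = make_panel(d[:30], groups=groups[:30])
        out_ab = fst_windows(sub, w=10**8)
        assert out["fst_A_B"].iloc[0] == pytest.approx(out_ab["fst_total"].iloc[0])

    def test_unusable_window_is_nan(self):
        panel = make_panel(np.zeros((8, 5)), groups=["A"] * 4 + ["B"] * 4)
        out = fst_windows(panel, w=10**8)
        assert np.isnan(out["fst_total"].iloc[0])


class TestLdR2:
    def test_duplicated_columns_r2_one(self):
        col = np.array([0, 1, 2, 0, 1, 2, 2, 0], dtype=float)
        panel = make_panel(np.column_stack([col, col]), groups=["G"] * 8)
        out = ld_r2_windows(panel, w=10**6, seed=0)
        assert out["r2_G"].iloc[0] == pytest.approx(1.0)

    def test_unlinked_sites_low_mean_r2(self, rng):
        d = rng.binomial(2, 0.3, size=(200, 60)).astype(float)
        panel = make_panel(d, groups=["G"] * 200)
        out = ld_r2_windows(panel, w=10**6, seed=1)
        assert out["r2_G"].iloc[0] < 0.02

    def test_matches_direct_correlation(self, rng):
        """pairwise_r2 equals np.corrcoef squared on complete pairs."""
        for _ in range(50):
            x = rng.choice([0, 1, 2.0], size=50)
            y = rng.choice([0, 1, 2.0], size=50)
            if x.var() == 0 or y.var() == 0:
                continue
            assert pairwise_r2(x, y) == pytest.approx(np.corrcoef(x, y)[0, 1] ** 2)

    def test_recoding_invariance(self, rng):
        x = rng.choice([0, 1, 2.0], size=40)
        y = rng.choice([0, 1, 2.0], size=40)
        assert pairwise_r2(x, y) == pytest.approx(pairwise_r2(2 - x, y))


def test_window_variant_totals_partition_panel(small_structured_panel):
    panel, _ = small_structured_panel
    out = nucleotide_diversity_windows(panel, w=500_000,
                                       chrom_length=50_000_000)
    n_snps = int((panel.variants["vtype"] == "SNP").sum())
    assert out["n_variants"].sum() == n_snps
    # windows tile the chromosome without overlap
    assert (out["start"].iloc[1:].to_numpy() == out["end"].iloc[:-1].to_numpy()).all()


def test_wc_components_reject_single_group():
    with pytest.raises(ValueError, match="two groups"):
        weir_cockerham_components(np.array([[0.5]]), np.array([[10]]), np.array([[0.5]]))
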