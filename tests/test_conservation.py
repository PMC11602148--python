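"""Polymorphism/divergence counting, PSS/NSS ratios and phylostratigraphy."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eboxgrammar.conservation import (
    CLADE_ORDER,
    DEFAULT_CLADE_SCHEME,
    CladeScheme,
    assign_phylostratum,
    count_polymorphisms,
    count_substitutions,
    distance_binned_variation,
    mk_resample,
    pss_nss_ratios,
    species_conservation,
)


def sites_frame(rows):
    return pd.DataFrame(
        rows, columns=["site_id", "contig", "start", "hexamer", "ebox_class",
                       "summit_distance"]
    )


ONE_SITE = sites_frame([("s0", "chr1", 100, "CATATG", "CAT-CAT", 0)])


def variants(entries):
    return pd.DataFrame(entries, columns=["contig", "pos", "ref", "alt", "maf"])


class TestPolymorphisms:
    @pytest.mark.parametrize(
        "pos,maf,expected",
        [
            (102, 0.05, 1),   # MAF cutoff is inclusive
            (102, 0.04, 0),
            (106, 0.30, 0),   # half-open: start+6 excluded
            (105, 0.30, 1),
            (99, 0.30, 0),
        ],
    )
    def test_boundaries(self, pos, maf, expected):
        v = variants([("chr1", pos, "A", "T", maf)])
        assert count_polymorphisms(ONE_SITE, v).iloc[0] == expected

    def test_counts_accumulate(self):
        v = variants([("chr1", 100, "C", "T", 0.1),
                      ("chr1", 103, "A", "G", 0.2),
                      ("chr2", 103, "A", "G", 0.2)])
        assert count_polymorphisms(ONE_SITE, v).iloc[0] == 2


class TestSubstitutions:
    def test_counting_and_exclusions(self):
        sites = sites_frame([
            ("a", "c", 0, "CAGATG", "CAT-CAG", 0),
            ("b", "c", 10, "CAGATG", "CAT-CAG", 0),
            ("c", "c", 20, "CAGATG", "CAT-CAG", 0),
            ("d", "c", 30, "CAGATG", "CAT-CAG", 0),
        ])
        aln = {
            "a": ("CAGATG", "CAGGTG"),  # one substitution
            "b": ("CAGATG", "CAGATG"),  # conserved
            "c": ("CAGATG", "CAG-TG"),  # indel -> excluded
        }
        res = count_substitutions(sites, aln)
        assert res["sub_count"].tolist()[:2] == [1, 0]
        assert res["status"].tolist() == ["ok", "ok", "indel", "uncovered"]
        assert np.isnan(res["sub_count"].iloc[2])


class TestDistanceBins:
    def test_flat_zero_curve(self):
        res = distance_binned_variation([10, 60, 120], [0, 0, 0])
        got = res.dropna(subset=["mean"])
        assert np.allclose(got["mean"], 0.0)

    def test_single_bin_covers_everything(self):
        res = distance_binned_variation([10, 400], [1, 3], bin_width=500,
                                        max_distance=500)
        assert len(res) == 1 and res["mean"].iloc[0] == 2.0

    def test_rising_rate_monotone_means(self):
        rng = np.random.default_rng(0)
        d = rng.integers(0, 500, 20_000)
        counts = rng.poisson(0.02 + d / 500 * 0.5)
        res = distance_binned_variation(d, counts)
        assert (np.diff(res["mean"]) > -0.02).all()
        assert res["mean"].iloc[-1] > res["mean"].iloc[0]


def _ratio_frame(n_pss=100, n_nss=100, pss_count=0.0, nss_count=0.0,
                 cls="CAT-CAT"):
    rows = []
    for i in range(n_pss):
        rows.append((f"p{i}", "c", i, "CATATG", cls, 10))
    for i in range(n_nss):
        rows.append((f"n{i}", "c", i, "CATATG", cls, 300))
    df = sites_frame(rows)
    df["poly_count"] = [pss_count] * n_pss + [nss_count] * n_nss
    df["sub_count"] = df["poly_count"]
    return df


class TestPssNss:
    def test_identical_rates_give_unit_ratios(self):
        df = _ratio_frame(pss_count=1, nss_count=1)
        res = pss_nss_ratios(df).set_index("ebox_class").loc["CAT-CAT"]
        assert np.isclose(res["p_ratio"], 1.0)
        assert np.isclose(res["d_ratio"], 1.0)

    def test_rate_arithmetic(self):
        # PSS rate 0.02/motif vs NSS 0.08/motif -> ratio 0.25
        df = _ratio_frame(n_pss=100, n_nss=100)
        df.loc[df["summit_distance"] == 10, "poly_count"] = \
            [1] * 2 + [0] * 98
        df.loc[df["summit_distance"] == 300, "poly_count"] = \
            [1] * 8 + [0] * 92
        res = pss_nss_ratios(df).set_index("ebox_class").loc["CAT-CAT"]
        assert np.isclose(res["pPSS"], 0.02) and np.isclose(res["pNSS"], 0.08)
        assert np.isclose(res["p_ratio"], 0.25)

    def test_boundaries_inclusive(self):
        rows = [("a", "c", 0, "CATATG", "CAT-CAT", 50),
                ("b", "c", 1, "CATATG", "CAT-CAT", 200),
                ("c", "c", 2, "CATATG", "CAT-CAT", 400),
                ("d", "c", 3, "CATATG", "CAT-CAT", 401)]
        df = sites_frame(rows)
        df["poly_count"] = 1
        df["sub_count"] = 1
        res = pss_nss_ratios(df).set_index("ebox_class").loc["CAT-CAT"]
        assert res["n_pPSS"] == 1 and res["n_pNSS"] == 2

    def test_counts_conserved_across_partition(self):
        df = _ratio_frame(pss_count=2, nss_count=3)
        res = pss_nss_ratios(df).set_index("ebox_class").loc["CAT-CAT"]
        total = res["pPSS"] * res["n_pPSS"] + res["pNSS"] * res["n_pNSS"]
        assert np.isclose(total, df["poly_count"].sum())

    def test_empty_nss_gives_missing_ratio(self):
        df = _ratio_frame(n_nss=0, pss_count=1)
        res = pss_nss_ratios(df).set_index("ebox_class").loc["CAT-CAT"]
        assert np.isnan(res["p_ratio"])

    def test_invalid_windows_rejected(self):
        df = _ratio_frame()
        with pytest.raises(ValueError):
            pss_nss_ratios(df, nss_range=(400, 200))
        with pytest.raises(ValueError):
            pss_nss_ratios(df, pss_halfwidth=250, nss_range=(200, 400))


class TestMKResample:
    def test_same_seed_reproduces_points(self):
        df = _ratio_frame(pss_count=1, nss_count=2)
        df.loc[::3, "poly_count"] = 0
        a = mk_resample(df, n_subsets=20, subset_size=50, seed=9)
        b = mk_resample(df, n_subsets=20, subset_size=50, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_all_zero_counts_give_undefined_quadrants(self):
        df = _ratio_frame(pss_count=0, nss_count=0)
        res = mk_resample(df, n_subsets=5, subset_size=50, seed=0)
        assert (res["quadrant"] == "undefined").all()

    def test_subset_size_larger_than_class_rejected(self):
        df = _ratio_frame()
        with pytest.raises(ValueError):
            mk_resample(df, n_subsets=1, subset_size=10_000)


class TestSpeciesConservation:
    def test_statuses(self):
        out = species_conservation(
            "CAGATG",
            {"rat": "CAGATG", "cow": "CAGGTG", "frog": "CA-ATG"},
            species_list=["rat", "cow", "frog", "absent"],
        )
        assert out == {"rat": "conserved", "cow": "diverged",
                       "frog": "excluded", "absent": "excluded"}

    def test_reference_must_be_gap_free(self):
        with pytest.raises(ValueError):
            species_conservation("CAG-TG", {})


def _statuses(n_by_clade):
    statuses, clades = {}, {}
    for clade, (n_cons, n_div) in n_by_clade.items():
        for i in range(n_cons + n_div):
            name = f"{clade}_{i}"
            statuses[name] = "conserved" if i < n_cons else "diverged"
            clades[name] = clade
    return statuses, clades


class TestPhylostratum:
    def test_placental_only(self):
        st_, cl = _statuses({"placental": (25, 14), "marsupial": (0, 3),
                             "monotreme": (0, 1), "non_mammal": (0, 16)})
        assert assign_phylostratum(st_, cl) == "placental"

    def test_full_depth(self):
        st_, cl = _statuses({"placental": (25, 14), "marsupial": (2, 1),
                             "monotreme": (1, 0), "non_mammal": (10, 6)})
        assert assign_phylostratum(st_, cl) == "non_mammal"

    def test_cumulative_gate_blocks_deep_conservation(self):
        st_, cl = _statuses({"placental": (10, 29), "marsupial": (0, 3),
                             "monotreme": (0, 1), "non_mammal": (10, 6)})
        assert assign_phylostratum(st_, cl) == "none"

    def test_excluded_species_do_not_count_as_conserved(self):
        st_, cl = _statuses({"placental": (19, 20)})
        cl["extra"] = "placental"
        st_["extra"] = "excluded"
        assert assign_phylostratum(st_, cl) == "none"

    @settings(derandomize=True, max_examples=60)
    @given(st.integers(0, 39), st.integers(0, 3), st.integers(0, 1),
           st.integers(0, 16))
    def test_monotone_in_conserved_counts(self, p, m, mo, nm):
        """Adding a conserved species never decreases the assigned depth."""
        depth_order = ("none",) + CLADE_ORDER

        def depth(p, m, mo, nm):
            st_, cl = _statuses({"placental": (p, 39 - p),
                                 "marsupial": (m, 3 - m),
                                 "monotreme": (mo, 1 - mo),
                                 "non_mammal": (nm, 16 - nm)})
            return depth_order.index(assign_phylostratum(st_, cl))

        base = depth(p, m, mo, nm)
        if p < 39:
            assert depth(p + 1, m, mo, nm) >= base
        if nm < 16:
            assert depth(p, m, mo, nm + 1) >= base

    def test_scheme_validation(self):
        with pytest.raises(ValueError):
            CladeScheme({"placental": (40, 39)})
        assert DEFAULT_CLADE_SCHEME.thresholds["placental"] == (20, 39)
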