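import numpy as np
import pandas as pd
import pytest

import ty1kit as tk
from ty1kit.assays import PlateCount, rtpcr_table


def perm(strain="WT", bio=1, tech=1, colonies=200, vol=1.0, dil=1000.0, cul=1000.0):
    return PlateCount(strain, bio, tech, "permissive", colonies, vol, dil, cul)


def sel(strain="WT", bio=1, tech=1, colonies=200, vol=1000.0, dil=1.0, cul=1000.0):
    return PlateCount(strain, bio, tech, "selective", colonies, vol, dil, cul)


class TestCfu:
    def test_standard_dilution_plating(self):
        # 200 colonies from 1 uL of a 1:1000 dilution of a 1 mL culture
        assert tk.cfu_in_culture(perm(colonies=200)) == pytest.approx(2e8)

    def test_undiluted_plating(self):
        pc = perm(colonies=15, vol=100.0, dil=1.0)
        assert tk.cfu_in_culture(pc) == pytest.approx(150.0)

    def test_whole_culture_identity(self):
        pc = perm(colonies=37, vol=1000.0, dil=1.0)
        assert tk.cfu_in_culture(pc) == 37

    def test_zero_permissive_colonies_rejected(self):
        with pytest.raises(ValueError, match="density"):
            tk.cfu_in_culture(perm(colonies=0))


class TestMobilityFrequency:
    def test_ratio_of_cfus(self):
        # selective CFU 200, permissive CFU 2e8
        f = tk.mobility_frequency(sel(colonies=200), perm(colonies=200))
        assert f == pytest.approx(1e-6)

    def test_zero_selective_colonies_gives_zero(self):
        assert tk.mobility_frequency(sel(colonies=0), perm(colonies=200)) == 0.0

    def test_identical_geometry_gives_one(self):
        s = sel(colonies=55, vol=1000.0, dil=1.0)
        p = perm(colonies=55, vol=1000.0, dil=1.0)
        assert tk.mobility_frequency(s, p) == pytest.approx(1.0)

    def test_mismatched_cultures_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            tk.mobility_frequency(sel(bio=1), perm(bio=2))


class TestSummarizeStrain:
    def _counts(self, sel_colonies_by_bio):
        counts = []
        for bio, c in enumerate(sel_colonies_by_bio, start=1):
            counts.append(perm(bio=bio, colonies=200))  # 2e8 CFU each
            counts.append(sel(bio=bio, colonies=c))
        return counts

    def test_mean_and_sd_over_biological_replicates(self):
        # frequencies 1e-6, 2e-6, 3e-6
        r = tk.summarize_strain(self._counts([200, 400, 600]))
        assert r.mean == pytest.approx(2e-6)
        assert r.dispersion == pytest.approx(1e-6)
        assert r.dispersion_type == "sd"
        assert not r.censored

    def test_two_biological_replicates_report_range(self):
        r = tk.summarize_strain(self._counts([200, 600]))
        assert r.n_bio == 2
        assert r.dispersion_type == "range"
        assert r.dispersion == pytest.approx(2e-6)

    def test_all_zero_selective_counts_are_censored(self):
        # total permissive CFU 1e9 across cultures -> upper limit 1e-9
        counts = []
        for bio in (1, 2):
            counts.append(perm(bio=bio, colonies=500))  # 5e8 each
            counts.append(sel(bio=bio, colonies=0))
        r = tk.summarize_strain(counts)
        assert r.censored
        assert r.upper_limit == pytest.approx(1e-9)
        assert r.mean == 0.0

    def test_technical_replicates_averaged_within_bio(self):
        counts = []
        for bio, cols in ((1, [200, 400]), (2, [400, 800]), (3, [600, 1200])):
            for tech, c in enumerate(cols, start=1):
                counts.append(perm(bio=bio, tech=tech, colonies=200))
                counts.append(sel(bio=bio, tech=tech, colonies=c))
        r = tk.summarize_strain(counts)
        # bio means: 1.5e-6, 3e-6, 4.5e-6
        assert r.bio_means == pytest.approx((1.5e-6, 3e-6, 4.5e-6))
        assert r.mean == pytest.approx(3e-6)

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError, match="biological replicates"):
            tk.summarize_strain(self._counts([100]))

    def test_upper_limit_decreases_with_more_cfu(self):
        limits = []
        for colonies in (100, 200, 400):
            counts = []
            for bio in (1, 2, 3):
                counts.append(perm(bio=bio, colonies=colonies))
                counts.append(sel(bio=bio, colonies=0))
            limits.append(tk.summarize_strain(counts).upper_limit)
        assert limits[0] > limits[1] > limits[2]


class TestFoldChange:
    def _result(self, mean, censored=False, upper=None):
        return tk.MobilityResult("s", (mean,), (mean,), mean, 0.0, "sd",
                                 censored, upper, 3)

    def test_uncensored_ratio(self):
        fc = tk.fold_change(self._result(1e-5), self._result(1e-7))
        assert fc.value == pytest.approx(100.0)
        assert str(fc) == "100"

    def test_censored_denominator_gives_lower_bound(self):
        fc = tk.fold_change(self._result(1e-5),
                            self._result(0.0, censored=True, upper=1e-8))
        assert fc.lower_bound
        assert fc.value == pytest.approx(1000.0)
        assert str(fc) == "> 1000"

    def test_equal_means_give_one(self):
        assert tk.fold_change(self._result(2e-6), self._result(2e-6)).value == pytest.approx(1.0)

    def test_reciprocal_product_is_one(self):
        a, b = self._result(3.3e-6), self._result(7.5e-7)
        assert tk.fold_change(a, b).value * tk.fold_change(b, a).value == pytest.approx(1.0)

    def test_both_censored_undefined(self):
        fc = tk.fold_change(self._result(0.0, censored=True, upper=1e-8),
                            self._result(0.0, censored=True, upper=1e-9))
        assert fc.undefined


class TestDensitometry:
    def test_reference_sample_is_one(self):
        q = tk.BandQuant("WT", 5.0, 2.0, 5.0, 2.0)
        assert tk.relative_level(q) == pytest.approx(1.0)

    def test_doubled_target_same_loading(self):
        q = tk.BandQuant("mut", 10.0, 2.0, 5.0, 2.0)
        assert tk.relative_level(q) == pytest.approx(2.0)

    def test_nonpositive_signal_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            tk.BandQuant("bad", 10.0, 0.0, 5.0, 2.0)

    def test_table_normalization(self):
        df = pd.DataFrame({
            "sample": ["WT", "mut1", "mut2"],
            "target_signal": [5.0, 10.0, 2.5],
            "loading_signal": [2.0, 2.0, 2.0],
        })
        out = tk.quantify_bands(df, reference="WT")
        assert out["relative_level"].tolist() == pytest.approx([1.0, 2.0, 0.5])


class TestRtpcr:
    def test_five_cycle_offset_doubles_to_32(self):
        assert tk.cycle_offset_fold(5, 2) == 32

    def test_zero_offset_is_identity(self):
        assert tk.cycle_offset_fold(0, 2) == 1

    def test_six_cycle_offset(self):
        assert tk.cycle_offset_fold(6, 2) == 64

    def test_bad_efficiency_rejected(self):
        with pytest.raises(ValueError, match="efficiency"):
            tk.cycle_offset_fold(5, 1.0)

    def test_molar_correction_200_vs_3000(self):
        assert tk.molar_correction(200, 3000) == 15

    def test_molar_correction_identity_and_tenfold(self):
        assert tk.molar_correction(100, 100) == 1
        assert tk.molar_correction(100, 1000) == 10

    def test_combined_estimate(self):
        est = tk.combined_abundance(5, 2, 200, 3000)
        assert est.combined_fold == 480
        assert est.combined_fold >= 450
        assert est.percent_of_reference == pytest.approx(100 / 480)
        assert est.percent_of_reference < 1.0

    def test_combined_identity(self):
        est = tk.combined_abundance(0, 2, 200, 200)
        assert est.combined_fold == 1
        assert est.percent_of_reference == 100.0

    def test_combined_is_multiplicative_in_cycles(self):
        base = tk.combined_abundance(3, 2, 200, 3000)
        more = tk.combined_abundance(3 + 2, 2, 200, 3000)
        assert more.combined_fold == pytest.approx(
            base.combined_fold * tk.cycle_offset_fold(2, 2)
        )

    def test_table_interface(self):
        df = pd.DataFrame({
            "sample": ["pGTy1dPOL"],
            "delta_cycles": [5],
            "ref_len": [200],
            "target_len": [3000],
        })
        out = rtpcr_table(df)
        assert out["combined_fold"].iloc[0] == 480
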