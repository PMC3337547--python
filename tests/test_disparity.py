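import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from snpdisparity.disparity import (
    HWE_CHI2_THRESHOLD,
    compute_disparity,
    detect_shifts,
    disparity_rates,
    disparity_score,
    het_stats,
    hwe_test,
    select_loci,
    shift_directions,
)
from snpdisparity.io import ValidationError
from snpdisparity.preprocess import filter_informative

from conftest import make_paired


class TestHetStats:
    def test_symmetric_triple(self):
        s = het_stats([0.4, 0.5, 0.6], [1, 1, 1], "rs1")
        assert s.mu == pytest.approx(0.5)
        assert s.sigma == pytest.approx(0.1)
        assert s.n_het == 3

    def test_single_het_has_undefined_sigma(self):
        s = het_stats([0.5, 0.1], [1, 0], "rs1")
        assert s.n_het == 1 and np.isnan(s.sigma)

    def test_missing_excluded(self):
        s = het_stats([0.45, 0.55, np.nan], [1, 1, 1], "rs1")
        assert s.mu == pytest.approx(0.5)
        assert s.sigma == pytest.approx(0.0707, abs=1e-4)
        assert s.n_het == 2

    def test_no_heterozygote_raises(self):
        with pytest.raises(ValidationError):
            het_stats([0.1, 0.9], [0, 2], "rs1")


class TestDetectShifts:
    def test_shift_toward_AA(self):
        stats = het_stats([0.45, 0.5, 0.55, 0.5], [1] * 4, "rs1")
        # mu=0.5, sigma~0.0408; tumour BAF 0.35 < mu - 2 sigma
        n_aa, n_bb, labels = detect_shifts([0.35, 0.5, 0.5, 0.5], np.arange(4), stats)
        assert (n_aa, n_bb) == (1, 0)
        assert labels == {0: "AA"}

    def test_inside_band_not_shifted(self):
        stats = het_stats([0.4, 0.45, 0.5, 0.55, 0.6], [1] * 5, "rs1")
        n_aa, n_bb, _ = detect_shifts([0.45] * 5, np.arange(5), stats)
        assert (n_aa, n_bb) == (0, 0)

    def test_eleven_of_twelve_shifted(self):
        rng = np.random.default_rng(0)
        blood = rng.normal(0.5, 0.03, size=12)
        stats = het_stats(blood, [1] * 12, "rs325349")
        tumour = np.concatenate([np.full(11, 0.05), [blood[11]]])
        n_aa, n_bb, _ = detect_shifts(tumour, np.arange(12), stats)
        assert (n_aa, n_bb) == (11, 0)

    def test_missing_tumour_skipped(self):
        stats = het_stats([0.45, 0.5, 0.55], [1] * 3, "rs1")
        n_aa, n_bb, _ = detect_shifts([np.nan, 0.5, 0.5], np.arange(3), stats)
        assert (n_aa, n_bb) == (0, 0)


class TestScoreAndRates:
    @pytest.mark.parametrize(
        "counts,expected",
        [((11, 0), 100.0), ((3, 1), 66.667), ((5, 5), 0.0), ((0, 0), 0.0), ((1, 3), 66.667)],
    )
    def test_score_examples(self, counts, expected):
        assert disparity_score(*counts) == pytest.approx(expected, abs=1e-3)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            disparity_score(-1, 2)

    @given(st.integers(0, 50), st.integers(0, 50), st.integers(1, 10))
    @settings(deadline=None, max_examples=100)
    def test_score_invariant_under_scaling(self, a, b, k):
        assert disparity_score(a * k, b * k) == pytest.approx(disparity_score(a, b))

    def test_rates_rs325349(self):
        r_aa, r_bb, r_ab, delta = disparity_rates(11, 0, 12)
        assert (r_aa, r_bb) == (100.0, 0.0)
        assert r_ab == pytest.approx(91.7, abs=0.05)
        assert delta == -100.0

    def test_rates_no_shift_all_zero(self):
        assert disparity_rates(0, 0, 10) == (0.0, 0.0, 0.0, 0.0)

    def test_rates_asymmetric(self):
        r_aa, r_bb, r_ab, delta = disparity_rates(8, 1, 34)
        assert r_aa == pytest.approx(88.9, abs=0.05)
        assert r_bb == pytest.approx(11.1, abs=0.05)
        assert r_ab == pytest.approx(26.5, abs=0.05)
        assert delta == pytest.approx(-77.8, abs=0.05)

    def test_shifts_exceeding_het_count_rejected(self):
        with pytest.raises(ValidationError):
            disparity_rates(8, 5, 10)


class TestHweTest:
    def test_counts_from_worked_example(self):
        chi2, in_hwe = hwe_test(99, 12, 1)
        assert chi2 == pytest.approx(0.823, abs=1e-3)
        assert in_hwe

    def test_exact_proportions_zero(self):
        chi2, in_hwe = hwe_test(25, 50, 25)
        assert chi2 == 0.0 and in_hwe

    def test_flag_false_above_threshold(self):
        chi2, in_hwe = hwe_test(30, 10, 10)
        assert chi2 > HWE_CHI2_THRESHOLD and not in_hwe

    def test_monomorph_degenerate(self):
        assert hwe_test(20, 0, 0) == (0.0, True)

    def test_threshold_is_inclusive(self):
        # flag is chi2 <= 3.841: the boundary itself is in HWE
        assert hwe_test(25, 50, 25)[1]
        from scipy import stats
        assert HWE_CHI2_THRESHOLD == pytest.approx(stats.chi2.ppf(0.95, 1), abs=5e-4)


class TestSelectLoci:
    @staticmethod
    def records(scores, n_het=12, shifts=None):
        shifts = shifts or [(s and 4 or 0, 0) for s in scores]
        return pd.DataFrame(
            {
                "score": scores,
                "n_het": n_het,
                "n_shift_AA": [a for a, _ in shifts],
                "n_shift_BB": [b for _, b in shifts],
            },
            index=pd.Index([f"rs{i}" for i in range(len(scores))], name="locus_id"),
        )

    def test_boundary_inclusive(self):
        recs = self.records([75.0, 74.9, 100.0], shifts=[(3, 0), (3, 0), (11, 0)])
        selected, strict = select_loci(recs)
        assert list(selected.index) == ["rs0", "rs2"]

    def test_strict_subset_requires_half_shifted(self):
        recs = self.records([100.0, 100.0], shifts=[(11, 0), (2, 0)])
        selected, strict = select_loci(recs)
        assert list(selected.index) == ["rs0", "rs1"]
        assert list(strict.index) == ["rs0"]  # 11/12 >= 0.5, 2/12 < 0.5


class TestPipelineProperties:
    def test_driver_matches_scalar_operations(self, sim_cohort):
        """The vectorised per-locus table must agree with the scalar
        het_stats / detect_shifts / score / rates path locus by locus."""
        data, _, _ = sim_cohort
        retained, _, calls = filter_informative(data)
        sub = retained.subset_loci(retained.loci.index[:80])
        sub_calls = calls.loc[sub.loci.index]
        records = compute_disparity(sub, sub_calls)
        for locus in records.index:
            blood = sub.blood_baf.loc[locus].to_numpy()
            tumour = sub.tumour_baf.loc[locus].to_numpy()
            c = sub_calls.loc[locus].to_numpy()
            stats = het_stats(blood, c, locus)
            het_idx = np.flatnonzero((c == 1) & np.isfinite(blood))
            n_aa, n_bb, _ = detect_shifts(tumour, het_idx, stats)
            row = records.loc[locus]
            assert (row["n_shift_AA"], row["n_shift_BB"]) == (n_aa, n_bb)
            assert row["score"] == pytest.approx(disparity_score(n_aa, n_bb))
            expected = disparity_rates(n_aa, n_bb, stats.n_het)
            assert (row["r_AA"], row["r_BB"], row["r_AB"], row["delta"]) == pytest.approx(expected)
            chi2, flag = hwe_test(int(row["n_AA"]), int(row["n_AB"]), int(row["n_BB"]))
            assert row["hwe_chi2"] == pytest.approx(chi2)
            assert bool(row["in_hwe"]) == flag

    def test_allele_swap_symmetry(self, sim_cohort):
        """Relabelling A<->B (BAF x -> 1-x) swaps the shift counts, negates
        delta, and leaves score, r_AB and the HWE statistic unchanged."""
        data, _, _ = sim_cohort
        retained, _, calls = filter_informative(data)
        records = compute_disparity(retained, calls)

        flipped = make_swapped(data)
        retained_f, _, calls_f = filter_informative(flipped)
        records_f = compute_disparity(retained_f, calls_f)

        assert list(records.index) == list(records_f.index)
        np.testing.assert_array_equal(
            records["n_shift_AA"].to_numpy(), records_f["n_shift_BB"].to_numpy()
        )
        np.testing.assert_array_equal(
            records["n_shift_BB"].to_numpy(), records_f["n_shift_AA"].to_numpy()
        )
        np.testing.assert_allclose(records["delta"], -records_f["delta"], atol=1e-9)
        np.testing.assert_allclose(records["score"], records_f["score"], atol=1e-9)
        np.testing.assert_allclose(records["r_AB"], records_f["r_AB"], atol=1e-9)
        np.testing.assert_allclose(records["hwe_chi2"], records_f["hwe_chi2"], atol=1e-9)

    def test_null_shift_rate_near_two_sd_tail(self, sim_null_cohort):
        """With no planted shifts the per-cell shifted fraction sits near
        the nominal 2-SD Gaussian tail mass (~4.6%)."""
        data, _, _ = sim_null_cohort
        retained, _, calls = filter_informative(data)
        dirs = shift_directions(retained, calls)
        het_cells = (calls.to_numpy() == 1).sum()
        shifted = (dirs.to_numpy() != 0).sum()
        rate = shifted / het_cells
        assert rate == pytest.approx(0.046, abs=0.012)

    def test_planted_shift_recovery(self, sim_cohort):
        data, _, truth = sim_cohort
        retained, _, calls = filter_informative(data)
        records = compute_disparity(retained, calls)
        _, strict = select_loci(records)
        planted = [l for l in truth.disparity.index if l in records.index]
        sensitivity = np.mean([l in set(strict.index) for l in planted])
        assert sensitivity >= 0.95


def make_swapped(data):
    """Mirror all BAF matrices (x -> 1 - x), relabelling the design alleles."""
    from snpdisparity.io import PairedArrayData

    return PairedArrayData(
        loci=data.loci.rename(columns={"allele_a": "allele_b", "allele_b": "allele_a"})[
            ["chromosome", "position", "allele_a", "allele_b", "gene", "cytoband"]
        ],
        blood_baf=1.0 - data.blood_baf,
        tumour_baf=1.0 - data.tumour_baf,
        blood_lrr=data.blood_lrr,
        tumour_lrr=data.tumour_lrr,
    )
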