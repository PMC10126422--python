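"""EHH combinatorics, IHH integration, iHS standardisation and selection."""

import numpy as np
import pandas as pd
import pytest

from popscan.ihs_scan import (
    HaplotypeSet,
    ehh_curve,
    ihh,
    read_phased_vcf,
    scan_ihs,
    select_top_snps,
    standardize_ihs,
    unstandardized_ihs,
)


def _haps(matrix, pos=None, chrom=None):
    matrix = np.asarray(matrix, dtype=np.int8)
    L = matrix.shape[1]
    return HaplotypeSet(
        haplotypes=matrix,
        chrom=np.array(chrom or ["1"] * L, dtype=object),
        pos=np.asarray(pos if pos is not None else np.arange(1, L + 1) * 1000),
    )


class TestEhhCurve:
    def test_starts_at_one(self):
        haps = _haps([[1, 0], [1, 1], [1, 0]])
        curve = ehh_curve(haps, 0, 1, "right")
        assert curve[0, 1] == 1.0

    def test_combinatorial_counting(self):
        # 3 carriers of the core allele whose next-site alleles are {0, 0, 1}
        haps = _haps([[1, 0], [1, 0], [1, 1], [0, 0]])
        curve = ehh_curve(haps, 0, 1, "right")
        # groups {2, 1}: (C(2,2) + C(1,2)) / C(3,2) = 1/3
        assert curve[1, 1] == pytest.approx(1 / 3)

    def test_identical_carriers_stay_at_one(self):
        haps = _haps([[1, 0, 1, 0], [1, 0, 1, 0], [0, 1, 1, 1]])
        curve = ehh_curve(haps, 0, 1, "right")
        assert (curve[:, 1] == 1.0).all()

    def test_single_carrier_undefined(self):
        haps = _haps([[1, 0], [0, 1], [0, 0]])
        assert ehh_curve(haps, 0, 1, "right") is None

    def test_non_increasing_on_simulation(self, neutral_haplotypes):
        haps, _ = neutral_haplotypes
        rng = np.random.default_rng(5)
        freq = haps.derived_freq
        cores = rng.choice(
            np.flatnonzero((freq > 0.2) & (freq < 0.8)), 15, replace=False
        )
        for core in cores:
            for allele in (0, 1):
                for direction in ("left", "right"):
                    curve = ehh_curve(haps, int(core), allele, direction)
                    if curve is None:
                        continue
                    assert (np.diff(curve[:, 1]) <= 1e-12).all()

    def test_left_right_symmetry_on_mirrored_data(self):
        rng = np.random.default_rng(3)
        mat = rng.integers(0, 2, (20, 11)).astype(np.int8)
        haps = _haps(mat)
        mirrored = _haps(mat[:, ::-1])
        a = ehh_curve(haps, 5, 1, "right")
        b = ehh_curve(mirrored, 5, 1, "left")
        np.testing.assert_allclose(a[:, 1], b[:, 1])


class TestIhh:
    def test_rectangle_area(self):
        # EHH 1 over 10 kb then crashes to 0 at the next marker
        curve = np.array([[0, 1.0], [10_000, 1.0], [10_001, 0.0]])
        val, reliable = ihh(curve)
        assert reliable
        # 10 kb full rectangle + half-step to the 0.05 crossing
        crossing = 0.5 * (1.0 + 0.05) * (0.95 / 1.0) * 1
        assert val == pytest.approx(10_000 + crossing)

    def test_hand_integrated_piecewise_curve(self):
        curve = np.array([[0, 1.0], [100, 0.8], [300, 0.4], [600, 0.02]])
        val, reliable = ihh(curve, cutoff=0.05)
        # trapezoids to 300, then interpolate 0.4 -> 0.02 crossing at 0.05
        expected = 0.5 * (1 + 0.8) * 100 + 0.5 * (0.8 + 0.4) * 200
        frac = (0.4 - 0.05) / (0.4 - 0.02)
        expected += 0.5 * (0.4 + 0.05) * 300 * frac
        assert reliable and val == pytest.approx(expected)

    def test_unfinished_curve_flagged(self):
        curve = np.array([[0, 1.0], [1000, 0.6], [2000, 0.3]])
        _, reliable = ihh(curve, cutoff=0.05)
        assert not reliable

    def test_gap_rule_flags(self):
        curve = np.array([[0, 1.0], [250_000, 0.01]])
        _, reliable = ihh(curve, cutoff=0.05, max_gap=200_000)
        assert not reliable

    def test_empty_curve_rejected(self):
        with pytest.raises(ValueError):
            ihh(np.empty((0, 2)))


class TestUnstandardizedIhs:
    def test_symmetry_and_log_identity(self):
        assert unstandardized_ihs(3.0, 3.0) == 0.0
        assert unstandardized_ihs(np.e * 2.0, 2.0) == pytest.approx(1.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            unstandardized_ihs(0.0, 1.0)

    def test_allele_relabel_flips_sign(self):
        rng = np.random.default_rng(8)
        mat = rng.integers(0, 2, (30, 41)).astype(np.int8)
        haps = _haps(mat, pos=np.arange(1, 42) * 100)
        flipped = _haps(1 - mat, pos=np.arange(1, 42) * 100)
        from popscan.ihs_scan import _score_core

        a = _score_core(haps, 20, cutoff=0.05, max_gap=200_000)
        b = _score_core(flipped, 20, cutoff=0.05, max_gap=200_000)
        if a is not None and b is not None:
            assert a == pytest.approx(-b)


class TestStandardizeIhs:
    def _frame(self, unihs, freq):
        return pd.DataFrame(
            {
                "chrom": "1",
                "pos": np.arange(len(unihs)) * 1000 + 1,
                "derived_freq": freq,
                "unihs": unihs,
                "reliable": True,
            }
        )

    def test_two_values_single_bin(self):
        frame = self._frame([-1.0, 1.0], [0.5, 0.5])
        res = standardize_ihs(frame, n_bins=1)
        np.testing.assert_allclose(sorted(res.frame.ihs), [-1.0, 1.0])

    def test_per_bin_mean_zero_sd_one(self):
        rng = np.random.default_rng(4)
        n = 400
        frame = self._frame(rng.normal(0, 1, n), rng.uniform(0.06, 0.94, n))
        res = standardize_ihs(frame, n_bins=10)
        for b, grp in res.frame.groupby("freq_bin"):
            assert grp.ihs.mean() == pytest.approx(0.0, abs=1e-9)
            assert grp.ihs.std(ddof=0) == pytest.approx(1.0, abs=1e-9)

    def test_small_bins_merged(self):
        # only two occupied frequency pockets, one with a single SNP
        frame = self._frame([0.5, -0.5, 0.2], [0.1, 0.1, 0.9])
        res = standardize_ihs(frame, n_bins=20)
        assert res.frame.ihs.notna().all()

    def test_degenerate_single_bin_rejected(self):
        frame = self._frame([0.3, 0.3], [0.5, 0.5])
        with pytest.raises(ValueError):
            standardize_ihs(frame, n_bins=1)


class TestSelectTopSnps:
    def _result(self, scores):
        from popscan.ihs_scan import IhsResult

        frame = pd.DataFrame(
            {
                "chrom": "1",
                "pos": np.arange(len(scores)) * 1000 + 1,
                "derived_freq": 0.5,
                "unihs": scores,
                "ihs": scores,
                "freq_bin": 0,
                "reliable": True,
            }
        )
        return IhsResult(frame=frame)

    def test_one_percent_of_thousand(self):
        res = self._result(np.linspace(-3, 3, 1000))
        assert len(select_top_snps(res, 0.01)) == 10

    def test_ties_included(self):
        res = self._result(np.ones(50))
        assert len(select_top_snps(res, 0.01)) == 50

    def test_ranked_by_absolute_value(self):
        res = self._result(np.array([-5.0, 4.0, 0.1, -0.2, 1.0]))
        top = select_top_snps(res, 0.2)
        assert top.ihs.iloc[0] == -5.0


class TestReadPhasedVcf:
    def test_polarisation_by_aa_tag(self, tmp_path):
        vcf = tmp_path / "p.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=AA,Number=1,Type=String,Description="x">\n'
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="x">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\n"
            "1\t100\t.\tA\tG\t.\t.\tAA=A\tGT\t0|1\t1|1\n"
            "1\t200\t.\tA\tG\t.\t.\tAA=G\tGT\t0|1\t1|1\n"
        )
        haps = read_phased_vcf(vcf)
        # AA=REF keeps coding; AA=ALT flips it
        np.testing.assert_array_equal(haps.haplotypes[:, 0], [0, 1, 1, 1])
        np.testing.assert_array_equal(haps.haplotypes[:, 1], [1, 0, 0, 0])
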