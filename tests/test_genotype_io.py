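"""Genotype data model, VCF round-trip, HWE test and QC filter rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from popscan.genotype_io import (
    MISSING,
    GenotypeDataset,
    QCError,
    QCParams,
    allele_frequencies,
    apply_qc,
    hwe_chi2,
    read_vcf,
    write_vcf,
)

TOY_VCF = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3
1\t100\tr1\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1
1\t200\tr2\tA\tG,T\t.\tPASS\t.\tGT\t0/0\t0/1\t1/2
1\t300\tr3\tA\tG\t.\tPASS\t.\tGT\t./.\t0/1\t0/0
2\t100\tr4\tC\tT\t.\tPASS\t.\tGT\t1/1\t0/0\t0/1
"""


@pytest.fixture
def toy_vcf(tmp_path):
    path = tmp_path / "toy.vcf"
    path.write_text(TOY_VCF)
    popmap = tmp_path / "popmap.txt"
    popmap.write_text("s1 A\ns2 A\ns3 B\n")
    return path, popmap


class TestReadVcf:
    def test_multiallelic_records_dropped(self, toy_vcf):
        ds = read_vcf(*toy_vcf)
        assert ds.n_snps == 3 and ds.n_samples == 3
        assert "r2" not in ds.snp_ids

    def test_genotype_coding_and_missing(self, toy_vcf):
        ds = read_vcf(*toy_vcf)
        j = ds.snp_ids.index("r1")
        assert list(ds.genotypes[:, j]) == [0, 1, 2]
        j = ds.snp_ids.index("r3")
        assert ds.genotypes[0, j] == MISSING

    def test_unlabelled_sample_rejected(self, toy_vcf, tmp_path):
        path, _ = toy_vcf
        short = tmp_path / "short.txt"
        short.write_text("s1 A\ns2 A\n")
        with pytest.raises(ValueError, match="absent from popmap"):
            read_vcf(path, short)
        ds = read_vcf(path, short, allow_unlabelled=True)
        assert ds.n_samples == 2

    def test_phase_detected(self, tmp_path):
        path = tmp_path / "p.vcf"
        path.write_text(TOY_VCF.replace("0/1", "0|1").replace("0/0", "0|0")
                        .replace("1/1", "1|1").replace("1/2", "1|2"))
        popmap = tmp_path / "pm.txt"
        popmap.write_text("s1 A\ns2 A\ns3 B\n")
        assert read_vcf(path, popmap).phased


class TestWriteVcf:
    def test_round_trip_identity(self, tmp_path):
        from popscan.synthetic_data import simulate_two_pop_snp

        ds, _ = simulate_two_pop_snp(F=0.1, n1=5, n2=5, L=40, seed=1,
                                     n_chromosomes=3)
        ds.genotypes[0, 0] = MISSING
        path = tmp_path / "rt.vcf"
        write_vcf(ds, path)
        popmap = tmp_path / "pm.txt"
        popmap.write_text("".join(f"{s} {p}\n"
                                  for s, p in zip(ds.sample_ids, ds.populations)))
        back = read_vcf(path, popmap)
        assert back.sample_ids == ds.sample_ids
        np.testing.assert_array_equal(back.genotypes, ds.genotypes)
        np.testing.assert_array_equal(back.pos, ds.pos)
        assert list(back.chrom) == list(ds.chrom)
        assert back.phased == ds.phased

    def test_missing_emitted_as_dot(self, tmp_path, toy_dataset):
        path = tmp_path / "m.vcf"
        write_vcf(toy_dataset, path)
        assert "./." in path.read_text()

    def test_empty_snp_set_rejected(self):
        with pytest.raises(ValueError):
            GenotypeDataset(
                sample_ids=["a", "b"], populations=["A", "A"],
                chrom=np.array([], dtype=object), pos=np.array([], dtype=int),
                snp_ids=[], genotypes=np.empty((2, 0), dtype=np.int8),
            )


class TestHweChi2:
    @pytest.mark.parametrize(
        "counts, chi2_expected, p_bound",
        [
            ((25, 50, 25), 0.0, None),          # exact HW proportions
            ((34, 64, 32), 0.0298, None),       # expected 33.51/64.99/31.50
            ((10, 0, 10), 20.0, 1e-4),          # total heterozygote deficit
        ],
    )
    def test_hand_worked_values(self, counts, chi2_expected, p_bound):
        chi2, p = hwe_chi2(*counts)
        assert chi2 == pytest.approx(chi2_expected, abs=5e-4)
        if p_bound is not None:
            assert p < p_bound

    def test_monomorphic_is_uninformative(self):
        assert hwe_chi2(10, 0, 0) == (0.0, 1.0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_chi2(-1, 5, 5)

    @given(
        a=st.integers(0, 200), b=st.integers(0, 200), c=st.integers(1, 200)
    )
    @settings(deadline=None, max_examples=50)
    def test_symmetric_in_homozygote_swap(self, a, b, c):
        assert hwe_chi2(a, b, c) == pytest.approx(hwe_chi2(c, b, a))


class TestAlleleFrequencies:
    def test_basic_and_missing_exclusion(self, toy_dataset):
        freq = allele_frequencies(toy_dataset)
        # column at pos (1, 50000) holds [2, 0, 1, MISSING]
        j = toy_dataset.snp_ids.index("s2")
        assert freq[j] == pytest.approx(3 / 6)

    def test_subset_by_population(self, toy_dataset):
        fa = allele_frequencies(toy_dataset, subset="A")
        fb = allele_frequencies(toy_dataset, subset="B")
        assert fa.shape == fb.shape
        with pytest.raises(KeyError):
            allele_frequencies(toy_dataset, subset="C")

    def test_complement_of_ref_frequency(self, toy_dataset):
        freq = allele_frequencies(toy_dataset)
        called = toy_dataset.genotypes != MISSING
        ref = np.where(called, 2 - toy_dataset.genotypes, 0).sum(axis=0) / (
            2 * called.sum(axis=0)
        )
        np.testing.assert_allclose(freq, 1 - ref)

    def test_estimates_track_simulated_truth(self):
        from popscan.synthetic_data import simulate_two_pop_snp

        ds, truth = simulate_two_pop_snp(F=0.05, n1=50, n2=50, L=500, seed=4)
        est = allele_frequencies(ds, subset="pop1")
        true = np.array(truth.true_freqs["pop1"])
        # columns were sorted by position at load; re-align via snp ids
        order = np.argsort([int(s[3:]) for s in ds.snp_ids])
        r = np.corrcoef(est[order], true)[0, 1]
        assert r > 0.95


class TestApplyQc:
    def test_low_call_rate_sample_removed(self, toy_dataset):
        ds = toy_dataset
        geno = ds.genotypes.copy()
        geno[3, :4] = MISSING  # sample b2 call rate 2/6
        ds2 = GenotypeDataset(ds.sample_ids, ds.populations, ds.chrom.copy(),
                              ds.pos.copy(), list(ds.snp_ids), geno)
        out, report = apply_qc(ds2, QCParams(min_snp_call_rate=0.0, hwe_p_min=0.0))
        assert out.n_samples == 3
        assert report.removed_samples[0][0] == "b2"

    def test_hwe_failures_removed(self):
        rng = np.random.default_rng(0)
        geno = rng.binomial(2, 0.5, size=(60, 10)).astype(np.int8)
        geno[:, 3] = 1  # all-heterozygote columns fail HWE hard
        geno[:, 7] = 1
        ds = GenotypeDataset(
            sample_ids=[f"s{i}" for i in range(60)],
            populations=["A"] * 30 + ["B"] * 30,
            chrom=np.array(["1"] * 10, dtype=object),
            pos=np.arange(1, 11) * 1000,
            snp_ids=[f"m{i}" for i in range(10)],
            genotypes=geno,
        )
        out, report = apply_qc(ds, QCParams())
        assert report.removed_snps_by_rule["hwe"] == 2
        assert out.n_snps == 8

    def test_disabled_thresholds_change_nothing(self, toy_dataset):
        params = QCParams(min_individual_call_rate=0.0, min_snp_call_rate=0.0,
                          hwe_p_min=0.0, autosomes_only=False)
        out, report = apply_qc(toy_dataset, params)
        np.testing.assert_array_equal(out.genotypes, toy_dataset.genotypes)
        assert report.n_snps_out == toy_dataset.n_snps

    def test_idempotent(self, toy_dataset):
        params = QCParams(min_individual_call_rate=0.5, min_snp_call_rate=0.5,
                          hwe_p_min=1e-6)
        once, _ = apply_qc(toy_dataset, params)
        twice, report = apply_qc(once, params)
        np.testing.assert_array_equal(once.genotypes, twice.genotypes)
        assert report.n_snps_in == report.n_snps_out
        assert report.n_samples_in == report.n_samples_out

    def test_everything_removed_raises_with_report(self, toy_dataset):
        ds = toy_dataset
        geno = ds.genotypes.copy()
        geno[:, 0] = MISSING  # every sample now misses a call
        ds2 = GenotypeDataset(ds.sample_ids, ds.populations, ds.chrom.copy(),
                              ds.pos.copy(), list(ds.snp_ids), geno)
        with pytest.raises(QCError) as err:
            apply_qc(ds2, QCParams(min_individual_call_rate=1.0))
        assert err.value.report.n_samples_in == 4

    def test_non_autosome_dropped(self, toy_dataset):
        ds = toy_dataset
        chrom = ds.chrom.copy()
        chrom[-1] = "X"
        ds2 = GenotypeDataset(ds.sample_ids, ds.populations, chrom,
                              ds.pos.copy(), list(ds.snp_ids),
                              ds.genotypes.copy())
        out, report = apply_qc(
            ds2, QCParams(min_individual_call_rate=0, min_snp_call_rate=0,
                          hwe_p_min=0))
        assert report.removed_snps_by_rule["non_autosomal"] == 1
        assert "X" not in out.chrom
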