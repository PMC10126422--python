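"""Two-locus r^2, EM haplotype frequencies, decay binning, Sved Ne."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from popscan.genotype_io import GenotypeDataset
from popscan.ihs_scan import HaplotypeSet
from popscan.ld_decay import (
    DEFAULT_BINS_BP,
    LDDecayTable,
    em_haplotype_freq,
    enumerate_ld_pairs,
    ld_decay_profile,
    ne_from_ld,
    r2_from_haplotype_freqs,
)


class TestR2:
    def test_perfect_coupling(self):
        assert r2_from_haplotype_freqs(0.5, 0.5, 0.5) == pytest.approx(1.0)

    def test_linkage_equilibrium(self):
        assert r2_from_haplotype_freqs(0.3, 0.6, 0.18) == pytest.approx(0.0)

    def test_direct_counting_example(self):
        # haplotypes {AB, AB, Ab, aB}
        assert r2_from_haplotype_freqs(0.75, 0.75, 0.5) == pytest.approx(1 / 9)

    def test_monomorphic_rejected(self):
        with pytest.raises(ValueError):
            r2_from_haplotype_freqs(1.0, 0.5, 0.5)

    @given(
        pA=st.floats(0.05, 0.95), pB=st.floats(0.05, 0.95),
        t=st.floats(0, 1),
    )
    @settings(deadline=None, max_examples=100)
    def test_bounded_and_symmetric(self, pA, pB, t):
        lo, hi = max(0.0, pA + pB - 1), min(pA, pB)
        pAB = lo + t * (hi - lo)
        r2 = r2_from_haplotype_freqs(pA, pB, pAB)
        assert -1e-12 <= r2 <= 1 + 1e-9
        # symmetry in the two loci: swap roles of A and B
        pBA = pAB  # freq(B1,A1) is the same haplotype class
        assert r2 == pytest.approx(r2_from_haplotype_freqs(pB, pA, pBA))


class TestEmHaplotypeFreq:
    def test_no_double_heterozygotes_closed_form(self):
        a = np.array([0, 2, 2, 0, 1])
        b = np.array([0, 2, 2, 0, 0])
        pAB, converged = em_haplotype_freq(a, b)
        # certain AB haplotypes: 2+2 from the (2,2) samples
        assert converged and pAB == pytest.approx(4 / 10)

    def test_all_double_heterozygotes_keeps_equilibrium(self):
        a = np.ones(10, dtype=int)
        b = np.ones(10, dtype=int)
        pAB, _ = em_haplotype_freq(a, b)
        # symmetric likelihood: EM stays at the LE start 0.25
        assert pAB == pytest.approx(0.25, abs=1e-6)

    def test_recovers_phased_truth_on_simulation(self, neutral_haplotypes):
        haps, _ = neutral_haplotypes
        mat = haps.haplotypes
        n = mat.shape[0] // 2
        geno = mat[0::2] + mat[1::2]
        freq = haps.derived_freq
        poly = np.flatnonzero((freq > 0.1) & (freq < 0.9))
        rng = np.random.default_rng(0)
        err = []
        for _ in range(40):
            i, j = rng.choice(poly, 2, replace=False)
            true_pab = float((mat[:, i] * mat[:, j]).mean())
            est, _ = em_haplotype_freq(geno[:, i], geno[:, j])
            err.append(abs(est - true_pab))
        assert np.mean(err) < 0.02 and max(err) < 0.08


def brute_force_profile(haps, bins=DEFAULT_BINS_BP, max_distance=1_000_000):
    """Independent oracle: direct haplotype counting over all pairs."""
    per_bin = [[] for _ in bins]
    mat = haps.haplotypes.astype(float)
    for i in range(haps.n_snps):
        for j in range(i + 1, haps.n_snps):
            if haps.chrom[i] != haps.chrom[j]:
                continue
            d = int(haps.pos[j] - haps.pos[i])
            if d == 0 or d > max_distance:
                continue
            pA, pB = mat[:, i].mean(), mat[:, j].mean()
            if pA in (0, 1) or pB in (0, 1):
                continue
            pAB = (mat[:, i] * mat[:, j]).mean()
            num = (pAB - pA * pB) ** 2
            den = pA * (1 - pA) * pB * (1 - pB)
            for k, (lo, hi) in enumerate(bins):
                if lo < d <= hi:
                    per_bin[k].append(num / den)
                    break
    return per_bin


class TestLdDecayProfile:
    def test_three_snps_single_bin(self):
        haps = HaplotypeSet(
            haplotypes=np.array([[0, 1, 0], [1, 0, 1], [0, 0, 1], [1, 1, 0]]),
            chrom=np.array(["1"] * 3, dtype=object),
            pos=np.array([1000, 2000, 3000]),
        )
        table = ld_decay_profile(haps)
        assert table.n_pairs[0] == 3
        assert table.n_pairs[1:].sum() == 0

    def test_matches_brute_force_exactly(self, neutral_haplotypes):
        haps, _ = neutral_haplotypes
        # 50-SNP slice keeps the brute-force oracle fast
        sub = HaplotypeSet(
            haplotypes=haps.haplotypes[:, :50],
            chrom=haps.chrom[:50],
            pos=haps.pos[:50],
        )
        table = ld_decay_profile(sub)
        oracle = brute_force_profile(sub)
        for k in range(len(DEFAULT_BINS_BP)):
            assert table.n_pairs[k] == len(oracle[k])
            if oracle[k]:
                assert table.mean_r2[k] == pytest.approx(np.mean(oracle[k]))
                assert table.prop_gt_02[k] == pytest.approx(
                    np.mean(np.asarray(oracle[k]) > 0.2)
                )

    def test_decay_non_increasing_on_recombining_simulation(
        self, neutral_haplotypes
    ):
        haps, _ = neutral_haplotypes
        table = ld_decay_profile(haps)
        means = table.mean_r2[table.n_pairs > 0]
        assert len(means) >= 4
        assert all(a >= b - 1e-9 for a, b in zip(means, means[1:]))

    def test_global_profile_is_pair_weighted_chromosome_average(self):
        from popscan.synthetic_data import simulate_haplotypes

        parts = []
        for c in ("1", "2", "3"):
            h, _ = simulate_haplotypes(
                n_haps=40, L=60, chrom_length=2_000_000, Ne=200,
                generations=100, seed=int(c), chrom_name=c,
            )
            parts.append(h)
        combined = HaplotypeSet(
            haplotypes=np.hstack([p.haplotypes for p in parts]),
            chrom=np.concatenate([p.chrom for p in parts]),
            pos=np.concatenate([p.pos for p in parts]),
        )
        table_all = ld_decay_profile(combined)
        per_chrom = [ld_decay_profile(p) for p in parts]
        for k in range(len(DEFAULT_BINS_BP)):
            n = sum(t.n_pairs[k] for t in per_chrom)
            assert table_all.n_pairs[k] == n
            if n:
                weighted = sum(
                    t.n_pairs[k] * t.mean_r2[k]
                    for t in per_chrom if t.n_pairs[k]
                ) / n
                assert table_all.mean_r2[k] == pytest.approx(weighted)

    def test_pair_enumeration_respects_chromosomes_and_distance(self, toy_dataset):
        pairs = list(enumerate_ld_pairs(toy_dataset.chrom, toy_dataset.pos,
                                        1_000_000))
        # chromosome 1: 3 pairs; chromosome 2: (100,5000), (5000,900000) and
        # (100,900000) all within 1 Mb
        assert len(pairs) == 6
        assert all(toy_dataset.chrom[i] == toy_dataset.chrom[j]
                   for i, j, _ in pairs)


class TestNeFromLd:
    def test_formula_inversion(self):
        table = LDDecayTable(
            bins=((1_900_000, 2_100_000),),  # midpoint 2 Mb -> c = 0.002? no:
            mean_r2=np.array([0.2 + 1 / (2 * 25)]),
            sd_r2=np.array([0.1]),
            n_pairs=np.array([10]),
            prop_gt_02=np.array([0.5]),
            prop_gt_03=np.array([0.3]),
        )
        traj = ne_from_ld(table, n_samples=25)
        c = 2_000_000 / 1e6 / 100  # 2 Mb at 1 cM/Mb = 0.02 Morgans
        assert traj.ne[0] == pytest.approx((1 / 0.2 - 1) / (4 * c))
        assert traj.generations_ago[0] == pytest.approx(1 / (2 * c))

    def test_round_trip_recovery(self):
        n = 40
        true_ne = 500
        bins, r2 = [], []
        for mid_kb in (5, 17.5, 37.5, 75, 300, 750):
            c = mid_kb * 1000 / 1e6 / 100
            bins.append((int(mid_kb * 1000 - 1000), int(mid_kb * 1000 + 1000)))
            r2.append(1 / (1 + 4 * true_ne * c) + 1 / (2 * n))
        table = LDDecayTable(
            bins=tuple(bins), mean_r2=np.array(r2), sd_r2=np.zeros(6),
            n_pairs=np.full(6, 100), prop_gt_02=np.zeros(6),
            prop_gt_03=np.zeros(6),
        )
        traj = ne_from_ld(table, n_samples=n)
        np.testing.assert_allclose(traj.ne, true_ne, rtol=1e-6)

    def test_sub_sampling_floor_skipped_with_warning(self):
        table = LDDecayTable(
            bins=((0, 10_000),), mean_r2=np.array([0.01]),
            sd_r2=np.array([0.01]), n_pairs=np.array([5]),
            prop_gt_02=np.array([0.0]), prop_gt_03=np.array([0.0]),
        )
        with pytest.warns(UserWarning, match="skipped"):
            traj = ne_from_ld(table, n_samples=25)
        assert traj.ne.size == 0

    def test_single_sample_rejected(self):
        table = LDDecayTable(
            bins=((0, 10_000),), mean_r2=np.array([0.5]),
            sd_r2=np.array([0.1]), n_pairs=np.array([5]),
            prop_gt_02=np.array([1.0]), prop_gt_03=np.array([1.0]),
        )
        with pytest.raises(ValueError):
            ne_from_ld(table, n_samples=1)
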