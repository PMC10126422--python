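"""Two-locus r^2, distance-binned LD-decay profiles, and an LD-based
effective-population-size trajectory.

r^2 is defined on haplotype frequencies: with p_A, p_B the allele
frequencies at the two loci and p_AB the two-locus haplotype frequency,

    r^2 = (p_AB - p_A p_B)^2 / (p_A (1-p_A) p_B (1-p_B)).

For phased input this is computed by direct haplotype counting; for
unphased genotypes p_AB is estimated by maximum likelihood over the
double-heterozygote phase ambiguity (EM).  Ne is recovered from binned
mean r^2 via the Sved drift relation E[r^2] ~= 1/(1 + 4Nc) plus the
1/(2n) finite-sample term.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeDataset

# Table-1-style distance bins, base pairs, left-open/right-closed
DEFAULT_BINS_BP = (
    (0, 10_000),
    (10_000, 25_000),
    (25_000, 50_000),
    (50_000, 100_000),
    (100_000, 500_000),
    (500_000, 1_000_000),
)


def r2_from_haplotype_freqs(pA: float, pB: float, pAB: float) -> float:
    """Squared correlation of allele indicators from haplotype frequencies."""
    if not (0 < pA < 1 and 0 < pB < 1):
        raise ValueError("r^2 undefined at a monomorphic locus")
    lo, hi = max(0.0, pA + pB - 1.0), min(pA, pB)
    if not (lo - 1e-12 <= pAB <= hi + 1e-12):
        raise ValueError(f"pAB={pAB} incompatible with pA={pA}, pB={pB}")
    d = pAB - pA * pB
    return d * d / (pA * (1 - pA) * pB * (1 - pB))


def em_haplotype_freq(genotypes_a, genotypes_b, max_iter: int = 100, tol: float = 1e-8):
    """ML two-locus haplotype frequency p_AB from unphased genotype codes.

    Genotypes are 0/1/2 alt-dosage; "A"/"B" denote the alternate alleles.
    Only the double heterozygote is phase-ambiguous; EM iterates its split
    between AB/ab and Ab/aB configurations, initialised at linkage
    equilibrium.

    Returns
    -------
    (pAB, converged) : the estimate and a convergence flag.
    """
    a = np.asarray(genotypes_a)
    b = np.asarray(genotypes_b)
    ok = (a != MISSING) & (b != MISSING)
    a, b = a[ok].astype(float), b[ok].astype(float)
    n = a.size
    if n < 2:
        raise ValueError("need >= 2 double-genotyped samples")
    pA = a.sum() / (2 * n)
    pB = b.sum() / (2 * n)
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        raise ValueError("both loci must be polymorphic")

    n_dh = int(((a == 1) & (b == 1)).sum())  # double heterozygotes
    # haplotype counts that are phase-certain:
    # each sample contributes floor-counts of AB haplotypes except double hets
    certain_ab = (
        np.where((a == 2) & (b == 2), 2, 0)
        + np.where((a == 2) & (b == 1), 1, 0)
        + np.where((a == 1) & (b == 2), 1, 0)
    ).sum()
    n_hap = 2 * n

    pAB = pA * pB  # linkage-equilibrium start
    converged = True
    if n_dh == 0:
        return certain_ab / n_hap, True
    for _ in range(max_iter):
        # frequencies of the four haplotypes (A=alt at locus 1, B=alt at 2)
        f_AB = pAB
        f_Ab = pA - pAB
        f_aB = pB - pAB
        f_ab = 1 - pA - pB + pAB
        denom = f_AB * f_ab + f_Ab * f_aB
        if denom <= 0:
            frac = 0.5
        else:
            frac = f_AB * f_ab / denom  # E-step: P(double het is AB/ab)
        new_pAB = (certain_ab + n_dh * frac) / n_hap
        if abs(new_pAB - pAB) < tol:
            pAB = new_pAB
            break
        pAB = new_pAB
    else:
        converged = False
    return float(pAB), converged


@dataclass
class LDDecayTable:
    """Distance-binned LD-decay summary (mean/sd r^2, counts, exceedance)."""

    bins: tuple = DEFAULT_BINS_BP
    mean_r2: np.ndarray = None
    sd_r2: np.ndarray = None
    n_pairs: np.ndarray = None
    prop_gt_02: np.ndarray = None
    prop_gt_03: np.ndarray = None

    def to_frame(self) -> pd.DataFrame:
        labels = [f"{lo // 1000}-{hi // 1000} Kb" for lo, hi in self.bins]
        return pd.DataFrame(
            {
                "distance": labels,
                "mean_r2": self.mean_r2,
                "sd_r2": self.sd_r2,
                "n_pairs": self.n_pairs,
                "prop_r2_gt_0.2": self.prop_gt_02,
                "prop_r2_gt_0.3": self.prop_gt_03,
            }
        )


def enumerate_ld_pairs(chrom, pos, max_distance: int):
    """Yield (i, j, distance) for intra-chromosomal pairs with
    0 < distance <= max_distance.  Pairs at duplicate positions (distance 0)
    are excluded."""
    pos = np.asarray(pos)
    chrom = np.asarray(chrom, dtype=object)
    for c in dict.fromkeys(chrom):
        idx = np.flatnonzero(chrom == c)
        p = pos[idx]
        for ii in range(idx.size):
            # positions sorted within chromosome: walk right until too far
            for jj in range(ii + 1, idx.size):
                d = int(p[jj] - p[ii])
                if d > max_distance:
                    break
                if d == 0:
                    continue
                yield int(idx[ii]), int(idx[jj]), d


def _pair_r2_phased(haps, i, j):
    a = haps[:, i].astype(float)
    b = haps[:, j].astype(float)
    pA, pB = a.mean(), b.mean()
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        return None
    pAB = (a * b).mean()
    return r2_from_haplotype_freqs(pA, pB, pAB)


def _pair_r2_genotypes(geno, i, j):
    a, b = geno[:, i], geno[:, j]
    ok = (a != MISSING) & (b != MISSING)
    if ok.sum() < 2:
        return None
    af = a[ok].mean() / 2
    bf = b[ok].mean() / 2
    if af in (0.0, 1.0) or bf in (0.0, 1.0):
        return None
    pAB, _ = em_haplotype_freq(a, b)
    pA = a[ok].sum() / (2 * ok.sum())
    pB = b[ok].sum() / (2 * ok.sum())
    pAB = min(max(pAB, max(0.0, pA + pB - 1)), min(pA, pB))
    return r2_from_haplotype_freqs(pA, pB, pAB)


def ld_decay_profile(data, bins=DEFAULT_BINS_BP, max_distance: int = 1_000_000):
    """Distance-binned LD-decay table over all intra-chromosomal pairs.

    ``data`` is either a :class:`GenotypeDataset` (unphased path, EM
    haplotype frequencies) or a ``HaplotypeSet`` from the simulator
    (phased path, direct haplotype counting).  Bin edges are
    left-open/right-closed in bp.  Empty bins get n_pairs = 0 and NaN
    statistics.
    """
    phased = hasattr(data, "haplotypes")
    if phased:
        mat = data.haplotypes
        chrom, pos = data.chrom, data.pos
        pair_r2 = lambda i, j: _pair_r2_phased(mat, i, j)
    else:
        mat = data.genotypes
        chrom, pos = data.chrom, data.pos
        pair_r2 = lambda i, j: _pair_r2_genotypes(mat, i, j)

    per_bin = [[] for _ in bins]
    edges_lo = np.array([b[0] for b in bins])
    edges_hi = np.array([b[1] for b in bins])
    for i, j, d in enumerate_ld_pairs(chrom, pos, max_distance):
        k = np.flatnonzero((d > edges_lo) & (d <= edges_hi))
        if k.size == 0:
            continue
        r2 = pair_r2(i, j)
        if r2 is None:
            continue
        per_bin[int(k[0])].append(r2)

    nb = len(bins)
    table = LDDecayTable(
        bins=tuple(bins),
        mean_r2=np.full(nb, np.nan),
        sd_r2=np.full(nb, np.nan),
        n_pairs=np.zeros(nb, dtype=int),
        prop_gt_02=np.full(nb, np.nan),
        prop_gt_03=np.full(nb, np.nan),
    )
    for k, vals in enumerate(per_bin):
        table.n_pairs[k] = len(vals)
        if vals:
            v = np.asarray(vals)
            table.mean_r2[k] = v.mean()
            table.sd_r2[k] = v.std()
            table.prop_gt_02[k] = (v > 0.2).mean()
            table.prop_gt_03[k] = (v > 0.3).mean()
    return table


@dataclass
class NeTrajectory:
    """Ne(t) points derived from binned r^2 via the Sved relation."""

    generations_ago: np.ndarray
    ne: np.ndarray
    c_morgans: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"generations_ago": self.generations_ago, "Ne": self.ne, "c": self.c_morgans}
        )


def ne_from_ld(table: LDDecayTable, n_samples: int, cm_per_mb: float = 1.0) -> NeTrajectory:
    """LD-based effective population size per distance bin.

    Each bin's midpoint distance is converted to a recombination fraction
    c (Morgans) with a constant genetic map (default 1 cM/Mb); the
    sampling term 1/(2n) is subtracted from mean r^2 and Ne is recovered
    from the Sved relation r^2_adj = 1/(1 + 4 N c), evaluated at time
    t = 1/(2c) generations ago.  Bins whose adjusted r^2 is non-positive
    are skipped with a warning.
    """
    if n_samples <= 1:
        raise ValueError("need more than one sample")
    ts, nes, cs = [], [], []
    for (lo, hi), r2, n_pairs in zip(table.bins, table.mean_r2, table.n_pairs):
        if n_pairs == 0 or not np.isfinite(r2):
            continue
        mid_bp = (lo + hi) / 2
        c = mid_bp / 1e6 * cm_per_mb / 100  # bp -> Morgans
        r2_adj = r2 - 1 / (2 * n_samples)
        if r2_adj <= 0:
            warnings.warn(
                f"bin ({lo},{hi}]: mean r^2 {r2:.4f} <= 1/(2n), Ne undefined; skipped"
            )
            continue
        nes.append((1 / r2_adj - 1) / (4 * c))
        ts.append(1 / (2 * c))
        cs.append(c)
    return NeTrajectory(
        generations_ago=np.asarray(ts), ne=np.asarray(nes), c_morgans=np.asarray(cs)
    )
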