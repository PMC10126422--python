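"""ANOVA-based per-SNP FST between two populations and sliding-window
aggregation.

The estimator is the allele-level analysis of variance: with r
populations, m_i alleles sampled in population i, allele frequency p_i,
and weighted mean frequency pbar = sum(m_i p_i)/sum(m_i),

    MSP = sum_i m_i (p_i - pbar)^2 / (r - 1)          (between populations)
    MSG = sum_i m_i p_i (1 - p_i) / sum_i (m_i - 1)   (within populations)
    nc  = (sum m_i - sum m_i^2 / sum m_i) / (r - 1)

    FST = (MSP - MSG) / (MSP + (nc - 1) MSG)

Negative values are reported raw (no clamping) so window ratio-of-sums
aggregation stays unbiased.  Windows are 50 kb stepped by 25 kb by
default, anchored at position 1 of each chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeDataset


@dataclass
class FstComponents:
    """Per-SNP mean squares and corrected sample size for the FST ratio."""

    msp: np.ndarray
    msg: np.ndarray
    nc: np.ndarray
    defined: np.ndarray  # False where overall-monomorphic / insufficient data
    chrom: np.ndarray = None
    pos: np.ndarray = None

    @property
    def numerator(self) -> np.ndarray:
        return self.msp - self.msg

    @property
    def denominator(self) -> np.ndarray:
        return self.msp + (self.nc - 1) * self.msg


def wc_components(alt_counts, sizes) -> FstComponents:
    """ANOVA mean squares from per-population allele counts.

    Parameters
    ----------
    alt_counts : array (r, L)
        Alternate-allele counts per population per SNP.
    sizes : array (r, L)
        Total alleles sampled (2 x called genotypes) per population per SNP.

    Populations with m_i <= 1 at a SNP are excluded from that SNP's sums;
    SNPs monomorphic over all populations (or with < 2 usable populations)
    are flagged undefined.
    """
    alt = np.atleast_2d(np.asarray(alt_counts, dtype=float))
    m = np.atleast_2d(np.asarray(sizes, dtype=float))
    if alt.shape != m.shape:
        raise ValueError("alt_counts and sizes must have the same shape")
    usable = m > 1
    m = np.where(usable, m, 0.0)
    alt = np.where(usable, alt, 0.0)
    r_eff = usable.sum(axis=0).astype(float)

    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(m > 0, alt / m, 0.0)
        m_sum = m.sum(axis=0)
        pbar = np.where(m_sum > 0, (m * p).sum(axis=0) / m_sum, np.nan)
        msp = (m * (p - pbar) ** 2).sum(axis=0) / (r_eff - 1)
        msg = (m * p * (1 - p)).sum(axis=0) / (m - usable).sum(axis=0)
        nc = (m_sum - (m**2).sum(axis=0) / m_sum) / (r_eff - 1)

    monomorphic = np.isclose(pbar, 0.0) | np.isclose(pbar, 1.0)
    defined = (r_eff >= 2) & ~monomorphic
    return FstComponents(
        msp=np.where(defined, msp, np.nan),
        msg=np.where(defined, msg, np.nan),
        nc=np.where(defined, nc, np.nan),
        defined=defined,
    )


def snp_fst(components: FstComponents) -> np.ndarray:
    """Raw per-SNP FST ratio; NaN where undefined (incl. zero denominator)."""
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = components.denominator
        fst = np.where(
            components.defined & (denom != 0), components.numerator / denom, np.nan
        )
    return fst


def components_from_dataset(dataset: GenotypeDataset, pop_a: str, pop_b: str) -> FstComponents:
    """Per-SNP ANOVA components between two labelled populations."""
    counts, sizes = [], []
    for label in (pop_a, pop_b):
        geno = dataset.genotypes[dataset.population_index(label)]
        called = geno != MISSING
        sizes.append(2 * called.sum(axis=0))
        counts.append(np.where(called, geno, 0).sum(axis=0))
    comp = wc_components(np.array(counts), np.array(sizes))
    comp.chrom = dataset.chrom
    comp.pos = dataset.pos
    return comp


@dataclass
class FstWindowTrack:
    """Sliding-window FST (ratio-of-sums and mean-of-ratios columns)."""

    frame: pd.DataFrame  # chrom, start, end, n_snps, fst, mean_snp_fst

    def __len__(self):
        return len(self.frame)


def windowed_fst(
    components: FstComponents, window: int = 50_000, step: int = 25_000
) -> FstWindowTrack:
    """Aggregate per-SNP components over sliding windows.

    Windows tile each chromosome from position 1 (1-based inclusive
    [start, start+window-1]); window FST is the ratio of summed numerators
    to summed denominators over defined SNPs in the window; the unweighted
    mean of per-SNP FST is emitted alongside.  Windows without usable SNPs
    are dropped.
    """
    if components.pos is None or components.chrom is None:
        raise ValueError("components need chrom/pos for windowing")
    num = components.numerator
    den = components.denominator
    persnp = snp_fst(components)
    rows = []
    chrom = np.asarray(components.chrom, dtype=object)
    pos = np.asarray(components.pos)
    for c in dict.fromkeys(chrom):
        on_c = chrom == c
        p = pos[on_c]
        ok = components.defined[on_c]
        if not ok.any():
            continue
        n_c, d_c, f_c = num[on_c], den[on_c], persnp[on_c]
        last = int(p.max())
        n_windows = (last - 1) // step + 1  # last window whose start <= last SNP
        for w in range(n_windows):
            start = 1 + w * step
            end = start + window - 1
            inw = ok & (p >= start) & (p <= end)
            if not inw.any():
                continue
            dsum = d_c[inw].sum()
            rows.append(
                {
                    "chrom": c,
                    "start": start,
                    "end": end,
                    "n_snps": int(inw.sum()),
                    "fst": n_c[inw].sum() / dsum if dsum != 0 else np.nan,
                    "mean_snp_fst": np.nanmean(f_c[inw]),
                }
            )
    return FstWindowTrack(frame=pd.DataFrame(rows))


def select_top_windows(track: FstWindowTrack, fraction: float = 0.05) -> pd.DataFrame:
    """Top windows by FST: ceil(fraction * N), boundary ties all included."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    frame = track.frame.dropna(subset=["fst"])
    if len(frame) < 1:
        raise ValueError("no defined windows")
    n_top = ceil(fraction * len(frame))
    ordered = frame.sort_values("fst", ascending=False, kind="mergesort")
    threshold = ordered["fst"].iloc[n_top - 1]
    return ordered[ordered["fst"] >= threshold].reset_index(drop=True)
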