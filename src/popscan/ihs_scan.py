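"""Extended haplotype homozygosity (EHH), integrated EHH (IHH), and the
integrated haplotype score (iHS).

For a core SNP and one of its alleles, EHH at distance x is the
probability that two randomly drawn carrier haplotypes are identical over
the interval from the core out to x:

    EHH = sum_h C(n_h, 2) / C(n_c, 2)

over the distinct extended haplotypes h among the n_c carriers.  IHH is
the trapezoidal integral of EHH against distance (left + right), truncated
where EHH first drops below a cutoff (default 0.05, linearly interpolated
to the crossing).  The unstandardised score is ln(IHH_A / IHH_D)
(ancestral over derived); standardisation is a z-score within
derived-allele-frequency bins, so large |iHS| flags cores whose derived
(or ancestral) haplotypes are unusually long for their frequency.

Distance is physical bp under a constant genetic map (1 cM/Mb), the
conventional proxy for chip data without a pedigree map.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np
import pandas as pd

DEFAULT_EHH_CUTOFF = 0.05
DEFAULT_MAX_GAP_BP = 200_000
DEFAULT_MIN_MAF = 0.05
DEFAULT_N_BINS = 20


@dataclass
class HaplotypeSet:
    """Phased binary haplotypes with known ancestral/derived polarisation.

    ``haplotypes`` is (2*samples) x SNPs with 0 = ancestral, 1 = derived;
    no missing data is allowed (iHS input must be fully phased and
    called).  Positions are 1-based bp, strictly increasing within each
    chromosome.
    """

    haplotypes: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray

    def __post_init__(self):
        self.haplotypes = np.ascontiguousarray(self.haplotypes, dtype=np.int8)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise ValueError("haplotypes must be binary (no missing data)")
        for c in dict.fromkeys(self.chrom):
            p = self.pos[self.chrom == c]
            if not (np.diff(p) > 0).all():
                raise ValueError(f"positions not strictly increasing on chromosome {c}")

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def derived_freq(self) -> np.ndarray:
        return self.haplotypes.mean(axis=0)


def read_phased_vcf(path, samples=None, aa_tag: str = "AA") -> HaplotypeSet:
    """Phased biallelic VCF -> :class:`HaplotypeSet`.

    Alleles are polarised with the ancestral-allele INFO tag (default
    "AA"); records whose tag matches the ALT allele are flipped so 0 is
    always ancestral.  Records without the tag fall back to REF-as-
    ancestral with a single logged warning (results then approximate).
    ``samples`` optionally restricts to a subset of sample ids.
    """
    import logging

    from cyvcf2 import VCF

    vcf = VCF(str(path))
    if samples is not None:
        vcf.set_samples(list(samples))
    chroms, positions, cols = [], [], []
    n_no_tag = 0
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            continue
        gt = np.asarray(var.genotype.array())
        if (gt[:, :2] < 0).any() or not gt[:, 2].all():
            continue  # iHS input must be fully called and phased
        alleles = gt[:, :2].reshape(-1)
        anc = var.INFO.get(aa_tag)
        if anc is None:
            n_no_tag += 1
        elif anc == var.ALT[0]:
            alleles = 1 - alleles
        elif anc != var.REF:
            continue  # ancestral state is neither allele: unusable
        chroms.append(var.CHROM)
        positions.append(var.POS)
        cols.append(alleles.astype(np.int8))
    vcf.close()
    if n_no_tag:
        logging.getLogger(__name__).warning(
            "read_phased_vcf: %d records lack the %s tag; REF used as ancestral",
            n_no_tag, aa_tag,
        )
    if not cols:
        raise ValueError(f"no usable phased biallelic records in {path}")
    return HaplotypeSet(
        haplotypes=np.column_stack(cols),
        chrom=np.array(chroms, dtype=object),
        pos=np.array(positions),
    )


_EHH_BLOCK = 48  # markers encoded per uint64 word (exact log2 on float64)


def ehh_curve(haps: HaplotypeSet, core: int, allele: int, direction: str,
              stop_below: float | None = None):
    """EHH at each marker outward from the core for one core allele.

    EHH at marker m equals the fraction of carrier pairs identical over
    every marker from the core out to m (equivalently
    sum_h C(n_h,2)/C(n_c,2) over identical extended haplotypes), so it is
    computed as the survival function of each pair's first mismatch:
    markers are packed 48 at a time into integer words per carrier and a
    pair's first mismatch is located with an XOR low-bit trick.

    Returns an array of (distance_bp, ehh) rows starting at (0, 1).
    ``direction`` is "left" or "right".  Fewer than 2 carriers -> None.
    With ``stop_below`` set, the walk stops at the end of the first block
    whose EHH falls below it (the crossing marker is always included).
    """
    if direction not in ("left", "right"):
        raise ValueError("direction must be 'left' or 'right'")
    mat = haps.haplotypes
    carriers = np.flatnonzero(mat[:, core] == allele)
    n_c = carriers.size
    if n_c < 2:
        return None
    c = haps.chrom[core]
    on_c = np.flatnonzero(haps.chrom == c)
    local = np.searchsorted(on_c, core)
    idx = on_c[local + 1:] if direction == "right" else on_c[:local][::-1]

    sub = mat[np.ix_(carriers, idx)]  # n_c x M, markers ordered outward
    m_total = idx.size
    iu, ju = np.triu_indices(n_c, 1)
    n_pairs = iu.size
    first_mismatch = np.full(n_pairs, m_total + 1, dtype=np.int64)  # 1-based
    alive = np.arange(n_pairs)

    processed = 0
    while processed < m_total and alive.size:
        stop = min(processed + _EHH_BLOCK, m_total)
        blen = stop - processed
        weights = np.left_shift(np.uint64(1), np.arange(blen, dtype=np.uint64))
        codes = (sub[:, processed:stop].astype(np.uint64) * weights).sum(axis=1)
        ci, cj = codes[iu[alive]], codes[ju[alive]]
        dead = ci != cj
        if dead.any():
            xor = ci[dead] ^ cj[dead]
            low_bit = np.log2((xor & (~xor + np.uint64(1))).astype(np.float64))
            first_mismatch[alive[dead]] = processed + low_bit.astype(np.int64) + 1
            alive = alive[~dead]
        processed = stop
        if stop_below is not None and alive.size / n_pairs < stop_below:
            break

    # EHH at marker m (1-based outward) = fraction of pairs alive past m
    dead_at = np.bincount(
        np.minimum(first_mismatch, processed + 1), minlength=processed + 2
    )
    ehh_vals = (n_pairs - np.cumsum(dead_at[1:processed + 1])) / n_pairs
    core_pos = int(haps.pos[core])
    dists = np.abs(haps.pos[idx[:processed]].astype(np.int64) - core_pos)
    out = np.empty((processed + 1, 2))
    out[0] = (0, 1.0)
    out[1:, 0] = dists
    out[1:, 1] = ehh_vals
    return out


def ihh(curve, cutoff: float = DEFAULT_EHH_CUTOFF, max_gap: int = DEFAULT_MAX_GAP_BP):
    """Trapezoidal integral of one EHH curve, truncated at the cutoff.

    Integration stops at the linearly interpolated point where EHH crosses
    ``cutoff``.  The result is flagged unreliable when the chromosome ends
    (curve exhausted) before the cutoff is reached, or when an
    inter-marker gap exceeds ``max_gap`` bp first.

    Returns
    -------
    (ihh_bp, reliable)
    """
    curve = np.asarray(curve, dtype=float)
    if curve.size == 0:
        raise ValueError("empty EHH curve")
    total = 0.0
    for k in range(1, curve.shape[0]):
        d0, e0 = curve[k - 1]
        d1, e1 = curve[k]
        if d1 - d0 > max_gap:
            return total, False
        if e1 < cutoff:
            # interpolate to the crossing point
            frac = (e0 - cutoff) / (e0 - e1) if e0 > e1 else 0.0
            dx = (d1 - d0) * frac
            total += 0.5 * (e0 + cutoff) * dx
            return total, True
        total += 0.5 * (e0 + e1) * (d1 - d0)
    return total, False  # ran off the chromosome before reaching the cutoff


def unstandardized_ihs(ihh_a: float, ihh_d: float) -> float:
    """ln(IHH_ancestral / IHH_derived); both integrals must be positive."""
    if ihh_a <= 0 or ihh_d <= 0:
        raise ValueError("IHH values must be positive")
    return float(np.log(ihh_a / ihh_d))


@dataclass
class IhsResult:
    """Per-SNP iHS table: unstandardised score, z-score, frequency, flags."""

    frame: pd.DataFrame  # chrom, pos, derived_freq, unihs, ihs, freq_bin, reliable

    def __len__(self):
        return len(self.frame)


def _score_core(haps: HaplotypeSet, core: int, cutoff: float, max_gap: int):
    """unIHS for one core SNP, or None if either allele's IHH is unusable."""
    ihh_by_allele = {}
    for allele in (0, 1):
        parts = []
        for direction in ("left", "right"):
            curve = ehh_curve(haps, core, allele, direction, stop_below=cutoff)
            if curve is None:
                return None
            val, reliable = ihh(curve, cutoff=cutoff, max_gap=max_gap)
            if not reliable:
                return None
            parts.append(val)
        ihh_by_allele[allele] = parts[0] + parts[1]
    if ihh_by_allele[0] <= 0 or ihh_by_allele[1] <= 0:
        return None
    return unstandardized_ihs(ihh_by_allele[0], ihh_by_allele[1])


def scan_ihs(
    haps: HaplotypeSet,
    min_maf: float = DEFAULT_MIN_MAF,
    cutoff: float = DEFAULT_EHH_CUTOFF,
    max_gap: int = DEFAULT_MAX_GAP_BP,
    n_bins: int = DEFAULT_N_BINS,
) -> IhsResult:
    """Full scan: unIHS at every scored core, then frequency-bin z-scoring.

    Cores with minor-allele frequency below ``min_maf`` are not scored.
    SNPs whose integration fails (chromosome edge or gap) are kept in the
    table flagged unreliable, with no standardised score.
    """
    freq = haps.derived_freq
    rows = []
    for core in range(haps.n_snps):
        f = freq[core]
        if min(f, 1 - f) < min_maf:
            continue
        unihs = _score_core(haps, core, cutoff, max_gap)
        rows.append(
            {
                "chrom": haps.chrom[core],
                "pos": int(haps.pos[core]),
                "derived_freq": float(f),
                "unihs": unihs if unihs is not None else np.nan,
                "reliable": unihs is not None,
            }
        )
    frame = pd.DataFrame(rows)
    if frame.empty or not frame["reliable"].any():
        raise ValueError("no reliable cores to standardise")
    return standardize_ihs(frame, n_bins=n_bins)


def standardize_ihs(frame: pd.DataFrame, n_bins: int = DEFAULT_N_BINS) -> IhsResult:
    """Within-frequency-bin z-scoring of unIHS.

    Bins are equal-width over derived frequency [0.05, 0.95]; occupied
    bins with fewer than 2 reliable SNPs (or zero variance) are merged
    with their nearest occupied neighbour before scoring.
    """
    frame = frame.copy()
    edges = np.linspace(0.05, 0.95, n_bins + 1)
    binned = np.clip(np.digitize(frame["derived_freq"], edges) - 1, 0, n_bins - 1)
    frame["freq_bin"] = binned
    ok = frame["reliable"].values & np.isfinite(frame["unihs"].values)

    # merge undersized/degenerate bins into their nearest occupied neighbour
    merged = {b: b for b in range(n_bins)}

    def bin_values(b):
        members = [k for k, v in merged.items() if v == b]
        sel = ok & np.isin(binned, members)
        return frame.loc[sel, "unihs"].values

    changed = True
    while changed:
        changed = False
        active = sorted(set(merged.values()))
        for b in active:
            vals = bin_values(b)
            if vals.size == 0:
                continue
            if vals.size < 2 or np.std(vals) == 0:
                neighbours = [x for x in active if x != b and bin_values(x).size > 0]
                if not neighbours:
                    raise ValueError("cannot standardise: a single degenerate bin")
                target = min(neighbours, key=lambda x: abs(x - b))
                for k in list(merged):
                    if merged[k] == b:
                        merged[k] = target
                changed = True
                break

    frame["ihs"] = np.nan
    eff = np.array([merged[b] for b in binned])
    frame["freq_bin"] = eff
    for b in sorted(set(eff)):
        sel = ok & (eff == b)
        if not sel.any():
            continue
        vals = frame.loc[sel, "unihs"].values
        frame.loc[sel, "ihs"] = (vals - vals.mean()) / vals.std()
    return IhsResult(frame=frame.reset_index(drop=True))


def select_top_snps(results: IhsResult, fraction: float = 0.01) -> pd.DataFrame:
    """Top SNPs by |iHS|: ceil(fraction * N scored), boundary ties included."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    scored = results.frame.dropna(subset=["ihs"]).copy()
    if len(scored) < 1:
        raise ValueError("no scored SNPs")
    scored["abs_ihs"] = scored["ihs"].abs()
    n_top = ceil(fraction * len(scored))
    ordered = scored.sort_values("abs_ihs", ascending=False, kind="mergesort")
    threshold = ordered["abs_ihs"].iloc[n_top - 1]
    return ordered[ordered["abs_ihs"] >= threshold].reset_index(drop=True)
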