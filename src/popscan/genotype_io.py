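"""Genotype data model, VCF I/O, SNP-array quality control, and the
allele-frequency / Hardy-Weinberg primitives used by every downstream stage.

Genotypes are coded 0/1/2 copies of the alternate allele with ``MISSING``
(-1) for no-calls.  Positions are 1-based (VCF convention) and are sorted
within each chromosome at load time; all window arithmetic downstream
converts to half-open ``[start, end)`` intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

MISSING = -1

AUTOSOMES = tuple(str(c) for c in range(1, 27))


@dataclass
class GenotypeDataset:
    """Samples x biallelic SNPs with positions and population labels.

    Attributes
    ----------
    sample_ids : list of str
    populations : list of str
        Per-sample population label, parallel to ``sample_ids``.
    chrom : ndarray of str
        Per-SNP chromosome label (autosomes "1".."26" for sheep).
    pos : ndarray of int
        1-based physical positions, strictly increasing within a chromosome.
    snp_ids : list of str
    genotypes : ndarray, shape (n_samples, n_snps), int8
        0/1/2 alt-allele dosage, ``MISSING`` for no-call.
    phased : bool
    """

    sample_ids: list
    populations: list
    chrom: np.ndarray
    pos: np.ndarray
    snp_ids: list
    genotypes: np.ndarray
    phased: bool = False

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self._validate()
        self._sort_positions()

    def _validate(self):
        if len(self.sample_ids) < 2:
            raise ValueError("need at least 2 samples")
        if self.pos.size < 1:
            raise ValueError("need at least 1 SNP")
        if self.genotypes.shape != (len(self.sample_ids), self.pos.size):
            raise ValueError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{len(self.sample_ids)} samples x {self.pos.size} SNPs"
            )
        if len(self.populations) != len(self.sample_ids):
            raise ValueError("every sample needs a population label")
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype codes must be 0/1/2 or missing")

    def _sort_positions(self):
        # stable sort by (chromosome, position); keeps input chromosome order
        chrom_order = {c: i for i, c in enumerate(dict.fromkeys(self.chrom))}
        key = np.lexsort((self.pos, np.array([chrom_order[c] for c in self.chrom])))
        if not np.array_equal(key, np.arange(self.pos.size)):
            self.chrom = self.chrom[key]
            self.pos = self.pos[key]
            self.snp_ids = [self.snp_ids[i] for i in key]
            self.genotypes = self.genotypes[:, key]

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return self.pos.size

    def population_index(self, label: str) -> np.ndarray:
        idx = np.array([p == label for p in self.populations])
        if not idx.any():
            raise KeyError(f"unknown population label: {label!r}")
        return idx

    def subset_samples(self, mask: np.ndarray) -> "GenotypeDataset":
        mask = np.asarray(mask, bool)
        return GenotypeDataset(
            sample_ids=[s for s, m in zip(self.sample_ids, mask) if m],
            populations=[p for p, m in zip(self.populations, mask) if m],
            chrom=self.chrom.copy(),
            pos=self.pos.copy(),
            snp_ids=list(self.snp_ids),
            genotypes=self.genotypes[mask],
            phased=self.phased,
        )

    def subset_snps(self, mask: np.ndarray) -> "GenotypeDataset":
        mask = np.asarray(mask, bool)
        return GenotypeDataset(
            sample_ids=list(self.sample_ids),
            populations=list(self.populations),
            chrom=self.chrom[mask],
            pos=self.pos[mask],
            snp_ids=[s for s, m in zip(self.snp_ids, mask) if m],
            genotypes=self.genotypes[:, mask],
            phased=self.phased,
        )


@dataclass
class QCParams:
    """Quality-control thresholds (chip-study defaults)."""

    min_individual_call_rate: float = 0.95
    min_snp_call_rate: float = 0.95
    hwe_p_min: float = 1e-6
    autosomes_only: bool = True

    def __post_init__(self):
        for r in (self.min_individual_call_rate, self.min_snp_call_rate):
            if not 0 <= r <= 1:
                raise ValueError("call rates must be in [0, 1]")
        if not 0 <= self.hwe_p_min < 1:
            raise ValueError("hwe_p_min must be in [0, 1)")


@dataclass
class QCReport:
    n_samples_in: int = 0
    n_samples_out: int = 0
    n_snps_in: int = 0
    n_snps_out: int = 0
    removed_samples: list = field(default_factory=list)  # (sample_id, reason)
    removed_snps_by_rule: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_samples_in": self.n_samples_in,
            "n_samples_out": self.n_samples_out,
            "n_snps_in": self.n_snps_in,
            "n_snps_out": self.n_snps_out,
            "removed_samples": [list(t) for t in self.removed_samples],
            "removed_snps_by_rule": dict(self.removed_snps_by_rule),
        }


def read_popmap(path) -> dict:
    """Two-column whitespace text: sample_id  population."""
    popmap = {}
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            if len(parts) < 2:
                raise ValueError(f"malformed popmap line: {line!r}")
            popmap[parts[0]] = parts[1]
    return popmap


def read_vcf(path, popmap, allow_unlabelled: bool = False) -> GenotypeDataset:
    """Read a diploid VCF into a :class:`GenotypeDataset`.

    Only biallelic SNP records are kept; multiallelic and non-SNP records
    are dropped with a logged count.  ``popmap`` maps sample id to
    population label and must cover every sample unless *allow_unlabelled*.
    """
    from cyvcf2 import VCF

    if isinstance(popmap, (str, bytes)) or hasattr(popmap, "__fspath__"):
        popmap = read_popmap(popmap)

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    missing_labels = [s for s in samples if s not in popmap]
    if missing_labels and not allow_unlabelled:
        raise ValueError(f"samples absent from popmap: {missing_labels}")
    keep = [s in popmap for s in samples]

    chroms, positions, ids, rows = [], [], [], []
    phased = False
    n_dropped = 0
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            n_dropped += 1
            continue
        gt = np.asarray(var.genotype.array())
        dosage = np.where((gt[:, :2] < 0).any(axis=1), MISSING, gt[:, :2].clip(0).sum(axis=1))
        phased = phased or bool(gt[:, 2].any())
        chroms.append(var.CHROM)
        positions.append(var.POS)
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        rows.append(dosage.astype(np.int8))
    vcf.close()
    if n_dropped:
        logger.info("read_vcf: dropped %d multiallelic/non-SNP records", n_dropped)
    if not rows:
        raise ValueError(f"no usable biallelic SNP records in {path}")

    geno = np.vstack(rows).T  # samples x snps
    keep = np.array(keep)
    return GenotypeDataset(
        sample_ids=[s for s, k in zip(samples, keep) if k],
        populations=[popmap[s] for s, k in zip(samples, keep) if k],
        chrom=np.array(chroms, dtype=object),
        pos=np.array(positions),
        snp_ids=ids,
        genotypes=geno[keep],
        phased=phased,
    )


def write_vcf(dataset: GenotypeDataset, path) -> None:
    """Write a minimal VCF 4.2 with GT-only FORMAT.

    Phase separator is "|" iff ``dataset.phased``; heterozygotes are then
    written 0|1 (the dosage model does not retain phase order).  Missing
    genotypes are emitted as "./.".
    """
    sep = "|" if dataset.phased else "/"
    gt_strings = {0: f"0{sep}0", 1: f"0{sep}1", 2: f"1{sep}1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in dict.fromkeys(dataset.chrom):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(dataset.sample_ids) + "\n")
        for j in range(dataset.n_snps):
            calls = "\t".join(gt_strings[int(g)] for g in dataset.genotypes[:, j])
            fh.write(
                f"{dataset.chrom[j]}\t{dataset.pos[j]}\t{dataset.snp_ids[j]}"
                f"\tA\tG\t.\tPASS\t.\tGT\t{calls}\n"
            )


def hwe_chi2(n_hom_ref: int, n_het: int, n_hom_alt: int):
    """Pearson 1-df chi-square test of Hardy-Weinberg proportions.

    The allele frequency is estimated from the counts themselves, so the
    expected genotype counts are N*p^2, 2Npq, N*q^2.  A monomorphic input
    carries no information: chi2 = 0, p = 1.

    Returns
    -------
    (chi2, p)
    """
    counts = np.array([n_hom_ref, n_het, n_hom_alt], dtype=float)
    if (counts < 0).any():
        raise ValueError("genotype counts must be non-negative")
    n = counts.sum()
    if n < 1:
        raise ValueError("need at least one genotype")
    p = (2 * counts[0] + counts[1]) / (2 * n)
    q = 1 - p
    if p == 0 or q == 0:
        return 0.0, 1.0
    expected = n * np.array([p * p, 2 * p * q, q * q])
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


def allele_frequencies(dataset: GenotypeDataset, subset: str | None = None) -> np.ndarray:
    """Per-SNP alternate-allele frequency (missing excluded pairwise).

    With *subset* a population label, only that population's samples are
    used.  SNPs with no called genotype in the subset are NaN.
    """
    geno = dataset.genotypes
    if subset is not None:
        geno = geno[dataset.population_index(subset)]
    called = geno != MISSING
    n_called = called.sum(axis=0)
    alt = np.where(called, geno, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_called > 0, alt / (2 * n_called), np.nan)
    return freq


def _snp_hwe_pvalues(dataset: GenotypeDataset) -> np.ndarray:
    geno = dataset.genotypes
    pvals = np.empty(dataset.n_snps)
    for j in range(dataset.n_snps):
        col = geno[:, j]
        col = col[col != MISSING]
        if col.size == 0:
            pvals[j] = 1.0
            continue
        n_hom_ref = int((col == 0).sum())
        n_het = int((col == 1).sum())
        n_hom_alt = int((col == 2).sum())
        pvals[j] = hwe_chi2(n_hom_ref, n_het, n_hom_alt)[1]
    return pvals


def apply_qc(dataset: GenotypeDataset, params: QCParams | None = None):
    """Apply the chip QC filters in fixed order.

    1. drop non-autosomal SNPs (if ``autosomes_only``);
    2. drop samples with individual call rate below threshold;
    3. drop SNPs with call rate below threshold;
    4. drop SNPs failing Hardy-Weinberg (p < ``hwe_p_min``) on the whole
       retained sample (both populations pooled).

    Returns ``(filtered_dataset, QCReport)``; raises if everything is
    removed, with the report attached to the exception.
    """
    if params is None:
        params = QCParams()
    report = QCReport(
        n_samples_in=dataset.n_samples, n_snps_in=dataset.n_snps
    )
    ds = dataset

    if params.autosomes_only:
        keep = np.isin(ds.chrom.astype(str), AUTOSOMES)
        report.removed_snps_by_rule["non_autosomal"] = int((~keep).sum())
        if not keep.any():
            report.n_snps_out = 0
            raise QCError("all SNPs removed (non-autosomal)", report)
        if not keep.all():
            ds = ds.subset_snps(keep)
    else:
        report.removed_snps_by_rule["non_autosomal"] = 0

    call_rate = (ds.genotypes != MISSING).mean(axis=1)
    keep_samples = call_rate >= params.min_individual_call_rate
    for sid, cr, k in zip(ds.sample_ids, call_rate, keep_samples):
        if not k:
            report.removed_samples.append((sid, f"call rate {cr:.3f} < {params.min_individual_call_rate}"))
    if not keep_samples.any() or keep_samples.sum() < 2:
        report.n_samples_out = int(keep_samples.sum())
        raise QCError("fewer than 2 samples survive the individual call-rate filter", report)
    if not keep_samples.all():
        ds = ds.subset_samples(keep_samples)

    snp_call_rate = (ds.genotypes != MISSING).mean(axis=0)
    keep_snps = snp_call_rate >= params.min_snp_call_rate
    report.removed_snps_by_rule["snp_call_rate"] = int((~keep_snps).sum())
    if not keep_snps.any():
        report.n_snps_out = 0
        raise QCError("all SNPs removed by the SNP call-rate filter", report)
    if not keep_snps.all():
        ds = ds.subset_snps(keep_snps)

    if params.hwe_p_min > 0:
        pvals = _snp_hwe_pvalues(ds)
        keep_hwe = pvals >= params.hwe_p_min
        report.removed_snps_by_rule["hwe"] = int((~keep_hwe).sum())
        if not keep_hwe.any():
            report.n_snps_out = 0
            raise QCError("all SNPs removed by the HWE filter", report)
        if not keep_hwe.all():
            ds = ds.subset_snps(keep_hwe)
    else:
        report.removed_snps_by_rule["hwe"] = 0

    report.n_samples_out = ds.n_samples
    report.n_snps_out = ds.n_snps
    return ds, report


class QCError(ValueError):
    """Raised when QC removes everything; carries the partial report."""

    def __init__(self, message: str, report: QCReport):
        super().__init__(message)
        self.report = report
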