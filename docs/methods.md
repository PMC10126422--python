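# Methods

This note documents the statistical models, defaults and numerical
choices behind `popscan`, and what the synthetic-data calibrations do
and do not establish.

## Data model and conventions

Genotypes are 0/1/2 copies of the alternate allele with a missing code;
positions are 1-based (VCF convention) and sorted within chromosome at
load time; all window arithmetic converts to half-open `[start, end)`
internally.  Missing genotypes are excluded pairwise from every
frequency and statistic; nothing is imputed (PCA mean-imputes its input
matrix only, which is standard for genotype PCA).  Sheep autosomes are
labelled "1".."26".

## Quality control

Filters run in a fixed order so the report is deterministic:
(1) non-autosomal SNPs, (2) samples with call rate below 0.95,
(3) SNPs with call rate below 0.95, (4) SNPs with Hardy–Weinberg
p < 10⁻⁶.  HWE uses the Pearson 1-df χ² against expected counts
N·p², 2Npq, N·q² with p estimated from the same counts; a monomorphic
SNP is uninformative (χ² = 0, p = 1).  HWE is computed on the pooled
sample, matching a single combined QC pass; no MAF filter is applied at
QC (the iHS stage applies MAF ≥ 0.05 to its cores only).

## LD and Ne

r² is defined on haplotype frequencies.  Phased input is counted
directly.  For unphased genotypes the two-locus haplotype frequency is
the ML estimate from an EM over the double-heterozygote phase ambiguity
(initialised at linkage equilibrium, tolerance 1e-8, ≤ 100 iterations);
when both loci are heterozygous in every sample the likelihood is
symmetric and EM legitimately stays at its start.  Pair enumeration is
intra-chromosomal with 0 < distance ≤ 1 Mb; distance-0 pairs (duplicate
positions) are excluded; bins are left-open/right-closed, e.g. "0–10 Kb"
means (0, 10000].

Ne(t) uses the Sved relation: with the 1/(2n) sampling term removed,
N_e(c) = (1/r²_adj − 1)/(4c) at t = 1/(2c) generations, with c from
physical distance under a constant 1 cM/Mb map (a map file can override
this).  Bins whose mean r² is at or below the sampling floor 1/(2n) are
skipped with a warning.  This is a deliberately classical estimator; it
is not expected to reproduce coalescent-HMM trajectories.

## FST

The estimator is the allele-level ANOVA: with m_i alleles sampled and
frequency p_i in population i and p̄ the weighted mean,

    MSP = Σ m_i (p_i − p̄)² / (r − 1)
    MSG = Σ m_i p_i (1 − p_i) / Σ (m_i − 1)
    n_c = (Σ m_i − Σ m_i² / Σ m_i) / (r − 1)
    F_ST = (MSP − MSG) / (MSP + (n_c − 1) MSG)

It deliberately omits the individual-heterozygosity term of the full
Weir–Cockerham genotypic estimator.  Negative values are kept (no
clamping) so ratio-of-sums window aggregation stays unbiased.  Windows
are 50 Kb stepped 25 Kb, anchored at position 1 of each chromosome
(annotation-independent); window FST is Σ numerators / Σ denominators
over the defined SNPs in the window, with the unweighted mean emitted as
an alternative column.  Top-fraction selection takes ceil(f·N) windows
and includes boundary ties.  Because windows hold few SNPs at chip
density, the window-FST distribution is right-skewed: at a generating
F = 0.10 the per-SNP mean tracks 0.10 while the window median sits near
0.07.

## iHS

EHH for a core allele is the probability two random carrier haplotypes
are identical at every marker from the core to distance x
(Σ_h C(n_h,2)/C(n_c,2)).  It is computed as the survival function of
each carrier pair's first mismatching marker; markers are packed 48 at a
time into integer words so a pair's first mismatch is found with an XOR
low-bit trick — algebraically identical to partition refinement but an
order of magnitude faster.  Markers monomorphic among the carriers
cannot split groups but do count as data for the gap rule, matching how
haplotype scanners treat low-MAF sites.

IHH is the trapezoidal integral of EHH against physical distance
(1 cM/Mb proxy), truncated by linear interpolation where EHH first
crosses 0.05; left and right integrals are summed per allele.  A core is
unreliable — kept in the table, not scored — when the chromosome ends or
an inter-marker gap exceeds 200 kb before the cutoff is reached.
unIHS = ln(IHH_A/IHH_D); standardisation is a z-score within 20
equal-width derived-frequency bins on [0.05, 0.95], with undersized or
zero-variance bins merged into their nearest occupied neighbour.  Cores
need minor-allele frequency ≥ 0.05.  Cutoff, gap, MAF and bin count
follow field-standard scanner defaults; none are stated by the original
study.  Ancestral alleles come from the simulator truth or a VCF INFO
tag (default `AA`); REF is used as a fallback with a logged warning.

## Candidate genes

A gene is selected iff its interval overlaps a selected FST window or a
top iHS SNP by ≥ 1 bp (the most inclusive reproducible rule; minimum
overlap and flank padding are configurable).  iHS hits are mapped at SNP
resolution.  GFF3 parsing takes `gene` features by default
(configurable, e.g. `mRNA`); BED intervals are converted from 0-based
half-open to 1-based inclusive.  Intersection is an exact set operation
with sorted output.

## Structure

p-distance per pair is the per-site allele-sharing dissimilarity —
0 / 0.5 / 1 for identical / one-shared-allele / opposite-homozygote
genotypes, i.e. |g_i − g_j|/2 on dosage codes — averaged over sites
called in both samples.  NJ is the Saitou–Nei algorithm with the
Q-criterion, standard three-point branch lengths, a final unrooted
trifurcation, and lowest-index tie-breaking for determinism; on additive
matrices it reproduces path lengths to < 1e-9 (cross-checked against
scikit-bio in the tests).  PCA standardises each SNP by √(2p(1−p)),
mean-imputes missing entries, and fixes signs by making each
component's largest-magnitude loading positive.

## FecB statistics

Genotype frequencies are counts/N; the B allele frequency is
(2n_BB + n_B+)/(2N).  The HWE check delegates to the same 1-df χ².
The published table prints χ² = 1.1151 for these counts; the standard
1-df HWE χ² on the printed counts is ≈ 0.030 (p ≈ 0.86) and the
construction behind the printed value is unknown, so this package
reports the standard statistic and the conclusion-level result (in
equilibrium at α = 0.05), which agrees.  Litter sizes are compared with
pairwise Welch t-tests (no multiplicity correction by default, three
comparisons; Bonferroni optional) summarised as a compact letter
display: classes sharing no letter differ at α = 0.05.  The
"mean ± 0.063"-style values are interpreted as standard errors; the
simulator recovers per-class SD as se·√n.

## Synthetic data: what it emulates and what it does not

**Balding–Nichols genotypes.**  Ancestral frequencies Uniform(0.05,
0.95); population frequencies Beta(p(1−F)/F, (1−p)(1−F)/F), so
E[p_pop] = p and Var[p_pop] = F·p(1−p); genotypes Binomial(2, p_pop);
positions uniform over 26 autosomes.  This gives exact, fast truth for
FST, PCA and NJ calibration but has no LD and no shared drift between
SNPs.

**Wright–Fisher haplotypes.**  A forward discrete-generation simulation
on fixed SNP positions, vectorised over the whole population; crossovers
per gamete are Poisson with mean equal to the map length (1 cM/Mb by
default; the stated mutation-rate default 1.25 × 10⁻⁸ is carried as a
simulator constant).  Sites are initialised at linkage equilibrium with
Uniform(0.2, 0.8) frequencies — chip-like ascertainment of common
variants — and no new mutations arise; LD is built by drift during the
burn-in (default: Ne generations).  Consequences worth knowing:
short-range LD is below its stationary value unless the burn-in is a
few multiples of 1/(2c); background haplotype identity has a floor of
roughly 1/(1 + 4N_e r L), so EHH reaches the 0.05 cutoff only when
chromosome arms are long relative to 1/(4N_e r); and sites can fix by
drift (they are retained as markers — they carry gap information — but
cannot be cores).

**Sweeps.**  A derived allele at the core rises along a deterministic
logistic trajectory from one copy to a target frequency (default 0.7
over 200 generations), implemented by biased parent sampling with the
core site always inherited from the selected parent, so carriers share
recombination-limited segments around the core.  A slow sweep spreads
the signal over ~1/(τ·r) where τ is the carriers' effective coalescence
depth; the calibration uses a 1 Mb flank around the core as the
"sweep-adjacent" region.

**Two-population split.**  Both populations are copied from one burnt-in
ancestor and drift apart for T generations (F ≈ 1 − e^(−T/2N_e)); the
sweep acts in population 1 only, giving the swept region both an FST and
an iHS signal — this is the basis of the bundle's end-to-end check that
the sweep-spanning gene lands in the intersection of the two scans.  The
bundle defaults (N_e = 2000, 150-generation burn-in, 200-generation
split, four 10 Mb chromosomes, 5000 SNPs, 2 × 40 samples) match the iHS
calibration conditions; the cost is that background LD sits well below
the real chip's level (mean r² ≈ 0.09 rather than 0.23 at 0–10 Kb),
because iHS needs deep haplotype diversity to keep its EHH integrals
finite on desk-scale chromosomes.

**Litter records.**  Discretised normal draws per genotype class
(sd = se·√n, rounded, floored at one lamb).  Rounding to whole lambs
inflates within-class variance; Monte-Carlo over 300 seeds puts the
BB-vs-B+ Welch power near 0.60 (the other two contrasts ≈ 1.0), so the
tests assert those measured rates rather than full three-way separation.

**Calibration study conditions.**  The iHS calibrations use N_e = 2000,
a 150-generation burn-in, and n = 200 haplotypes over two 10 Mb
chromosomes (≈ 2000 SNPs) for the neutral null, and n = 100 haplotypes
over a 14 Mb sweep chromosome plus two 7 Mb neutral chromosomes
(≈ 2200 SNPs) for sweep detection, 50 replicates.  Multi-chromosome
simulation matters: standardisation bins are then dominated by neutral
background, as in a genome-wide scan.  These sizes keep the full
calibration under ten minutes on one CPU.

Passing these calibrations shows the estimators are correct and well
calibrated **under the simulator's assumptions** — random mating, no
ascertainment beyond common-variant initialisation, constant
recombination rate, known ancestral states, perfect phasing and no
genotyping error.  They do not establish power or calibration on real
chip data, where map heterogeneity, phasing error and polarisation error
all act.

## Known limitations

- The LD-based Ne trajectory is a Sved-type point estimate per distance
  bin; values are not comparable to coalescent-HMM reconstructions and
  the study's published Ne figures are not reproduction targets.
- Unphased r² via EM assumes Hardy–Weinberg within the sample when
  resolving double heterozygotes.
- The candidate-gene counts from the original study depend on its
  annotation build and assignment rule, neither fully specified; gene
  counts are therefore not targets, only the mechanics are tested.
- iHS on real data requires externally phased haplotypes and an
  ancestral-allele channel; REF-as-ancestral is an approximation.
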