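"""Synthetic study generator: two-population SNP genotypes with a known
differentiation level, phased haplotypes with known ancestral alleles and
an optional selective sweep, gene models, and litter-size records.

Every generator is seed-deterministic and serialises its parameters and
hidden truth (:class:`SimTruth`) alongside the data, so each pipeline
stage can be checked against what was actually simulated.

Genotypes come from the Balding-Nichols model: an ancestral frequency p
per SNP, each population's frequency drawn from
Beta(p(1-F)/F, (1-p)(1-F)/F) so that E[p_pop] = p and
Var[p_pop] = F p(1-p), then diploid genotypes Binomial(2, p_pop).

Haplotypes come from a discrete-generation forward Wright-Fisher
simulation with recombination, vectorised across the whole population.
Sites are pre-placed (chip-like ascertained SNPs) and initialised at
linkage equilibrium; drift during the burn-in builds the distance-
dependent LD that the decay and EHH statistics consume.  A sweep is a
deterministic logistic rise of a derived core allele, imposed by biased
parent sampling with the core site always inherited from the selected
parent, so carriers share recombination-limited haplotype segments.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .genotype_io import GenotypeDataset
from .ihs_scan import HaplotypeSet

DEFAULT_MUTATION_RATE = 1.25e-8  # per bp per generation (simulator default)
DEFAULT_RECOMB_RATE = 1e-8      # 1 cM/Mb
MAX_WORK = 8_000_000_000        # population-cells x generations bound


@dataclass
class SimTruth:
    """What the generator actually did: parameters, seed and hidden state."""

    kind: str
    seed: int
    params: dict = field(default_factory=dict)
    target_f: float | None = None
    true_freqs: dict | None = None  # population -> per-SNP frequency list
    sweep: dict | None = None       # chrom, pos, final_freq, core_index
    ne: float | None = None
    recomb_rate: float | None = None

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "SimTruth":
        p = Path(source)
        payload = json.loads(p.read_text() if p.exists() else source)
        return cls(**payload)


def _spread_positions(rng, n, chrom_names, chrom_length):
    """Sorted unique positions for n SNPs spread over the given chromosomes."""
    per = np.array_split(np.arange(n), len(chrom_names))
    chroms, positions = [], []
    for name, block in zip(chrom_names, per):
        k = len(block)
        if k == 0:
            continue
        pos = np.sort(rng.choice(np.arange(1, chrom_length), size=k, replace=False))
        chroms.extend([name] * k)
        positions.extend(pos.tolist())
    return np.array(chroms, dtype=object), np.array(positions, dtype=np.int64)


def simulate_two_pop_snp(
    F: float,
    n1: int,
    n2: int,
    L: int,
    seed: int,
    n_chromosomes: int = 26,
    chrom_length: int = 100_000_000,
    pop_names: tuple = ("pop1", "pop2"),
):
    """Balding-Nichols two-population genotype simulation.

    Ancestral frequencies are Uniform(0.05, 0.95); F is the target
    differentiation (F = 0 gives panmixia: both populations share the
    ancestral frequency exactly).

    Returns
    -------
    (GenotypeDataset, SimTruth)
    """
    if not 0 <= F < 1:
        raise ValueError("F must be in [0, 1)")
    if L < 1:
        raise ValueError("need at least one SNP")
    rng = np.random.default_rng(seed)
    p_anc = rng.uniform(0.05, 0.95, size=L)
    freqs = {}
    for name in pop_names:
        if F == 0:
            freqs[name] = p_anc.copy()
        else:
            a = p_anc * (1 - F) / F
            b = (1 - p_anc) * (1 - F) / F
            freqs[name] = rng.beta(a, b)

    chrom_names = [str(c + 1) for c in range(n_chromosomes)]
    chroms, positions = _spread_positions(rng, L, chrom_names, chrom_length)

    blocks, pops, sample_ids = [], [], []
    for name, n_dip in zip(pop_names, (n1, n2)):
        blocks.append(rng.binomial(2, freqs[name], size=(n_dip, L)).astype(np.int8))
        pops.extend([name] * n_dip)
        sample_ids.extend(f"{name}_{i:03d}" for i in range(n_dip))

    dataset = GenotypeDataset(
        sample_ids=sample_ids,
        populations=pops,
        chrom=chroms,
        pos=positions,
        snp_ids=[f"snp{j:06d}" for j in range(L)],
        genotypes=np.vstack(blocks),
        phased=False,
    )
    truth = SimTruth(
        kind="two_pop_snp",
        seed=seed,
        params={"F": F, "n1": n1, "n2": n2, "L": L, "n_chromosomes": n_chromosomes},
        target_f=F,
        true_freqs={k: v.tolist() for k, v in freqs.items()},
    )
    return dataset, truth


def _logistic_trajectory(f0: float, f_final: float, n_gens: int) -> np.ndarray:
    """Deterministic logistic frequency path from f0 to f_final (inclusive)."""
    logit = lambda x: np.log(x / (1 - x))
    return 1 / (1 + np.exp(-np.linspace(logit(f0), logit(f_final), n_gens)))


class _WrightFisher:
    """Vectorised haploid-gamete Wright-Fisher engine on fixed SNP sites.

    Crossovers per gamete are Poisson with mean equal to the chromosome's
    map length, placed along the genetic map between SNPs; most gametes
    carry none, so a generation is mostly row copies.
    """

    def __init__(self, pop: np.ndarray, pos: np.ndarray, recomb_rate: float, rng):
        self.pop = pop  # (2N, L) int8, 0=ancestral 1=derived
        self.pos = pos
        self.rng = rng
        gaps = np.diff(pos).astype(float)
        self.gap_map = gaps * recomb_rate          # Morgans per inter-SNP gap
        self.cum_map = np.cumsum(self.gap_map)
        self.map_length = float(self.cum_map[-1]) if gaps.size else 0.0

    def step(self, sweep_freq: float | None = None, core: int | None = None):
        n, L = self.pop.shape
        rng = self.rng
        pb = rng.integers(0, n, n)
        if sweep_freq is None:
            pa = rng.integers(0, n, n)
        else:
            carriers = np.flatnonzero(self.pop[:, core] == 1)
            others = np.flatnonzero(self.pop[:, core] == 0)
            if carriers.size == 0 or others.size == 0:
                pa = rng.integers(0, n, n)
            else:
                k = int(np.clip(round(sweep_freq * n), 1, n - 1))
                pa = np.concatenate(
                    [rng.choice(carriers, k), rng.choice(others, n - k)]
                )
        children = self.pop[pa]  # fancy indexing already yields a fresh array
        n_cross = rng.poisson(self.map_length, n)
        for i in np.flatnonzero(n_cross):
            # crossover points uniform on the genetic map; an even number
            # of hits within one gap cancels out, as in a real meiosis
            u = rng.random(n_cross[i]) * self.map_length
            gap_idx = np.searchsorted(self.cum_map, u)
            toggles = np.bincount(gap_idx + 1, minlength=L)[:L]
            mask = np.cumsum(toggles) % 2  # 0 = from pa, 1 = from pb
            if core is not None and sweep_freq is not None and mask[core]:
                mask = 1 - mask  # keep the core site on the selected parent
            seg = mask.astype(bool)
            children[i, seg] = self.pop[pb[i], seg]
        self.pop = children

    def evolve(self, n_gens: int, sweep_traj=None, core=None):
        for t in range(n_gens):
            f = sweep_traj[t] if sweep_traj is not None else None
            self.step(sweep_freq=f, core=core)


def simulate_haplotypes(
    n_haps: int,
    L: int,
    chrom_length: int = 10_000_000,
    Ne: int = 500,
    recomb_rate: float = DEFAULT_RECOMB_RATE,
    seed: int = 0,
    sweep: tuple | None = None,
    generations: int | None = None,
    sweep_generations: int = 150,
    chrom_name: str = "1",
    drop_monomorphic: bool = False,
):
    """Single-chromosome phased haplotypes from forward Wright-Fisher.

    ``sweep`` is an optional (position_bp, final_derived_frequency) pair:
    after the neutral burn-in the site nearest the position is reset to a
    single derived copy, then driven along a deterministic logistic
    trajectory to the target frequency over ``sweep_generations``.
    Ancestral alleles are known by construction (0 = ancestral).

    Returns
    -------
    (HaplotypeSet, SimTruth); sites fixed during the burn-in are dropped
    unless ``drop_monomorphic`` is False.
    """
    if n_haps % 2:
        raise ValueError("n_haps must be even (diploid samples)")
    if L < 2:
        raise ValueError("need at least 2 SNPs")
    if generations is None:
        generations = Ne
    two_n = 2 * Ne
    if two_n * L * (generations + sweep_generations) > MAX_WORK:
        raise ValueError("simulation work bound exceeded; reduce Ne, L or generations")
    if n_haps > two_n:
        raise ValueError("cannot sample more haplotypes than the population holds")

    rng = np.random.default_rng(seed)
    pos = np.sort(rng.choice(np.arange(1, chrom_length), size=L, replace=False))
    init_freq = rng.uniform(0.2, 0.8, size=L)
    pop = (rng.random((two_n, L)) < init_freq).astype(np.int8)

    wf = _WrightFisher(pop, pos, recomb_rate, rng)
    wf.evolve(generations)

    sweep_truth = None
    if sweep is not None:
        sweep_pos, final_freq = sweep
        core = int(np.argmin(np.abs(pos - sweep_pos)))
        wf.pop[:, core] = 0
        wf.pop[rng.integers(0, two_n), core] = 1
        traj = _logistic_trajectory(1 / two_n, final_freq, sweep_generations)
        wf.evolve(sweep_generations, sweep_traj=traj, core=core)
        sweep_truth = {
            "chrom": chrom_name,
            "pos": int(pos[core]),
            "final_freq": float(final_freq),
            "core_index": core,
        }

    take = rng.choice(two_n, size=n_haps, replace=False)
    haps = wf.pop[take]
    keep = np.ones(L, dtype=bool)
    if drop_monomorphic:
        freq = haps.mean(axis=0)
        keep = (freq > 0) & (freq < 1)
        if sweep_truth is not None:
            keep[sweep_truth["core_index"]] = (
                0 < haps[:, sweep_truth["core_index"]].mean() < 1
            )
        haps = haps[:, keep]
    kept_pos = pos[keep]
    if sweep_truth is not None and keep[sweep_truth["core_index"]]:
        sweep_truth["core_index"] = int(np.searchsorted(kept_pos, sweep_truth["pos"]))

    hap_set = HaplotypeSet(
        haplotypes=haps,
        chrom=np.array([chrom_name] * kept_pos.size, dtype=object),
        pos=kept_pos,
    )
    truth = SimTruth(
        kind="haplotypes",
        seed=seed,
        params={
            "n_haps": n_haps,
            "L": L,
            "L_polymorphic": int(kept_pos.size),
            "chrom_length": chrom_length,
            "generations": generations,
            "mutation_rate": DEFAULT_MUTATION_RATE,
        },
        sweep=sweep_truth,
        ne=float(Ne),
        recomb_rate=recomb_rate,
    )
    return hap_set, truth


def simulate_genome_haplotypes(
    chrom_specs,
    n_haps: int,
    Ne: int = 1000,
    recomb_rate: float = DEFAULT_RECOMB_RATE,
    generations: int | None = None,
    sweep_generations: int = 200,
    seed: int = 0,
):
    """Multi-chromosome haplotypes: independent Wright-Fisher runs per
    chromosome (chromosomes are unlinked) concatenated into one set.

    ``chrom_specs`` is a list of (name, chrom_length, L, sweep_or_None)
    where sweep is a (position_bp, final_derived_frequency) pair.  Useful
    for genome-scan calibrations where the iHS standardisation should be
    dominated by neutral background chromosomes.

    Returns
    -------
    (HaplotypeSet, SimTruth); SimTruth.sweep holds the (single) sweep
    location if one was requested.
    """
    rng = np.random.default_rng(seed)
    parts, sweep_truth = [], None
    for name, chrom_length, L, sweep in chrom_specs:
        h, tr = simulate_haplotypes(
            n_haps=n_haps,
            L=L,
            chrom_length=chrom_length,
            Ne=Ne,
            recomb_rate=recomb_rate,
            seed=int(rng.integers(0, 2**31 - 1)),
            sweep=sweep,
            generations=generations,
            sweep_generations=sweep_generations,
            chrom_name=name,
        )
        parts.append(h)
        if tr.sweep is not None:
            sweep_truth = tr.sweep
    hap_set = HaplotypeSet(
        haplotypes=np.hstack([p.haplotypes for p in parts]),
        chrom=np.concatenate([p.chrom for p in parts]),
        pos=np.concatenate([p.pos for p in parts]),
    )
    truth = SimTruth(
        kind="genome_haplotypes",
        seed=seed,
        params={
            "chrom_specs": [
                {"name": n, "chrom_length": cl, "L": L,
                 "sweep": list(sw) if sw else None}
                for n, cl, L, sw in chrom_specs
            ],
            "n_haps": n_haps,
            "generations": generations,
            "sweep_generations": sweep_generations,
        },
        sweep=sweep_truth,
        ne=float(Ne),
        recomb_rate=recomb_rate,
    )
    return hap_set, truth


def simulate_two_pop_haplotypes(
    n_haps_per_pop: int,
    L: int,
    chrom_length: int = 10_000_000,
    Ne: int = 500,
    recomb_rate: float = DEFAULT_RECOMB_RATE,
    split_generations: int = 100,
    seed: int = 0,
    sweep_in_pop1: tuple | None = None,
    chrom_name: str = "1",
    generations: int | None = None,
):
    """Two populations from a common Wright-Fisher ancestor.

    A single ancestral population is burnt in, duplicated, and the two
    copies drift apart for ``split_generations`` (differentiation
    F ~= 1 - exp(-T / 2Ne)).  An optional sweep acts in population 1
    only, so the swept region carries both an FST and an iHS signal.

    Returns
    -------
    (haps_pop1, haps_pop2, SimTruth) on a shared set of sites (sites
    monomorphic across both samples combined are dropped).
    """
    rng = np.random.default_rng(seed)
    two_n = 2 * Ne
    if n_haps_per_pop > two_n:
        raise ValueError("cannot sample more haplotypes than the population holds")
    pos = np.sort(rng.choice(np.arange(1, chrom_length), size=L, replace=False))
    init_freq = rng.uniform(0.2, 0.8, size=L)
    ancestor = (rng.random((two_n, L)) < init_freq).astype(np.int8)
    if generations is None:
        generations = Ne
    wf = _WrightFisher(ancestor, pos, recomb_rate, rng)
    wf.evolve(generations)

    pops = []
    sweep_truth = None
    for which in (1, 2):
        branch = _WrightFisher(wf.pop.copy(), pos, recomb_rate, rng)
        if which == 1 and sweep_in_pop1 is not None:
            sweep_pos, final_freq = sweep_in_pop1
            core = int(np.argmin(np.abs(pos - sweep_pos)))
            branch.pop[:, core] = 0
            branch.pop[rng.integers(0, two_n), core] = 1
            traj = _logistic_trajectory(1 / two_n, final_freq, split_generations)
            branch.evolve(split_generations, sweep_traj=traj, core=core)
            sweep_truth = {
                "chrom": chrom_name,
                "pos": int(pos[core]),
                "final_freq": float(final_freq),
            }
        else:
            branch.evolve(split_generations)
        take = rng.choice(two_n, size=n_haps_per_pop, replace=False)
        pops.append(branch.pop[take])

    sets = [
        HaplotypeSet(
            haplotypes=p,
            chrom=np.array([chrom_name] * L, dtype=object),
            pos=pos,
        )
        for p in pops
    ]
    truth = SimTruth(
        kind="two_pop_haplotypes",
        seed=seed,
        params={
            "n_haps_per_pop": n_haps_per_pop,
            "L": L,
            "L_polymorphic": int(((np.vstack([p.haplotypes for p in sets]).mean(axis=0) > 0) & (np.vstack([p.haplotypes for p in sets]).mean(axis=0) < 1)).sum()),
            "chrom_length": chrom_length,
            "split_generations": split_generations,
            "expected_f": float(1 - np.exp(-split_generations / (2 * Ne))),
        },
        sweep=sweep_truth,
        ne=float(Ne),
        recomb_rate=recomb_rate,
    )
    return sets[0], sets[1], truth


def simulate_litter_records(
    n_per_class: dict,
    class_means: dict,
    class_ses: dict,
    seed: int = 0,
):
    """Litter sizes per FecB genotype class from a discretised normal.

    Per class the record-level SD is recovered as se * sqrt(n); draws are
    rounded to the nearest integer and floored at 1 lamb.

    Returns
    -------
    (records, SimTruth)
    """
    from .fecb_stats import LitterRecord

    rng = np.random.default_rng(seed)
    records = []
    for cls, n in n_per_class.items():
        if n < 2:
            raise ValueError(f"class {cls}: need n >= 2")
        mean, se = class_means[cls], class_ses[cls]
        if mean <= 0 or se < 0:
            raise ValueError(f"class {cls}: invalid mean/se")
        sd = se * np.sqrt(n)
        draws = np.maximum(1, np.round(rng.normal(mean, sd, size=n))).astype(int)
        safe = cls.replace("+", "p")
        records.extend(
            LitterRecord(f"{safe}_{i:03d}", cls, int(v)) for i, v in enumerate(draws)
        )
    truth = SimTruth(
        kind="litter_records",
        seed=seed,
        params={
            "n_per_class": dict(n_per_class),
            "class_means": dict(class_means),
            "class_ses": dict(class_ses),
        },
    )
    return records, truth


# ---------------------------------------------------------------------------
# fixture bundle: a complete miniature two-population chip study
# ---------------------------------------------------------------------------

#: Table-3-shaped litter defaults used by the bundle
LITTER_DEFAULTS = {
    "n_per_class": {"BB": 34, "B+": 64, "++": 32},
    "class_means": {"BB": 1.735, "B+": 1.453, "++": 1.125},
    "class_ses": {"BB": 0.077, "B+": 0.063, "++": 0.059},
}


@dataclass
class BundleConfig:
    n_samples_per_pop: int = 40
    n_snps: int = 5000
    n_chromosomes: int = 4
    chrom_length: int = 10_000_000
    ne: int = 2000
    recomb_rate: float = DEFAULT_RECOMB_RATE
    generations: int = 150
    split_generations: int = 200
    sweep_chrom: str = "1"
    sweep_position: int = 5_000_000
    sweep_final_freq: float = 0.7
    n_genes: int = 50
    pop_names: tuple = ("pop1", "pop2")


def _write_phased_vcf(path, sample_ids, pops, chrom, pos, hap1, hap2):
    """Phased GT-only VCF with ancestral allele in INFO (AA=REF)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in dict.fromkeys(chrom):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_ids)
            + "\n"
        )
        for j in range(len(pos)):
            calls = "\t".join(
                f"{hap1[s, j]}|{hap2[s, j]}" for s in range(len(sample_ids))
            )
            fh.write(
                f"{chrom[j]}\t{pos[j]}\tsnp{j:06d}\tA\tG\t.\tPASS\tAA=A\tGT\t{calls}\n"
            )


def _write_gff3(path, genes):
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g['chrom']}\tpopscan_sim\tgene\t{g['start']}\t{g['end']}\t.\t+\t.\t"
                f"ID={g['gene_id']};Name={g['symbol']}\n"
            )


def make_fixture_bundle(config: BundleConfig | None = None, seed: int = 0,
                        out_dir="fixture_bundle", force: bool = False) -> dict:
    """Write a complete miniature study to ``out_dir``.

    Produces genotypes.vcf (phased, AA-annotated), popmap.txt, genes.gff3,
    litter.csv and truth.json.  The two populations split from a common
    Wright-Fisher ancestor; one sweep acts in population 1 and one gene
    model spans the sweep core.

    Returns a dict of written paths.
    """
    config = config or BundleConfig()
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} is not empty (use force=True)")
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    chrom_names = [str(c + 1) for c in range(config.n_chromosomes)]
    per_chrom = np.array_split(np.arange(config.n_snps), config.n_chromosomes)
    all_chrom, all_pos, hap_blocks = [], [], []
    chrom_truths = {}
    for ci, (name, block) in enumerate(zip(chrom_names, per_chrom)):
        sweep = None
        if name == config.sweep_chrom:
            sweep = (config.sweep_position, config.sweep_final_freq)
        h1, h2, truth = simulate_two_pop_haplotypes(
            n_haps_per_pop=2 * config.n_samples_per_pop,
            L=len(block),
            chrom_length=config.chrom_length,
            Ne=config.ne,
            recomb_rate=config.recomb_rate,
            split_generations=config.split_generations,
            seed=int(rng.integers(0, 2**31 - 1)),
            sweep_in_pop1=sweep,
            chrom_name=name,
            generations=config.generations,
        )
        chrom_truths[name] = asdict(truth)
        all_chrom.extend([name] * h1.n_snps)
        all_pos.extend(h1.pos.tolist())
        hap_blocks.append(np.vstack([h1.haplotypes, h2.haplotypes]))

    haps = np.hstack(hap_blocks)  # (2 * 2 * n_per_pop) x total_snps
    n_per = config.n_samples_per_pop
    sample_ids = [f"{config.pop_names[0]}_{i:03d}" for i in range(n_per)] + [
        f"{config.pop_names[1]}_{i:03d}" for i in range(n_per)
    ]
    pops = [config.pop_names[0]] * n_per + [config.pop_names[1]] * n_per
    # haplotype rows 2s, 2s+1 belong to sample s within each population block
    hap1 = np.vstack([haps[2 * s] for s in range(2 * n_per)])
    hap2 = np.vstack([haps[2 * s + 1] for s in range(2 * n_per)])

    vcf_path = out / "genotypes.vcf"
    _write_phased_vcf(vcf_path, sample_ids, pops, all_chrom, all_pos, hap1, hap2)
    popmap_path = out / "popmap.txt"
    popmap_path.write_text(
        "".join(f"{s}\t{p}\n" for s, p in zip(sample_ids, pops))
    )

    # gene models: evenly spread; one guaranteed to span the sweep core
    genes = []
    gene_length = 300_000
    per_gene_chrom = [chrom_names[i % len(chrom_names)] for i in range(config.n_genes)]
    for gi, gchrom in enumerate(per_gene_chrom):
        start = int(rng.integers(1, config.chrom_length - gene_length))
        genes.append(
            {
                "gene_id": f"G{gi:03d}",
                "symbol": f"GENE{gi:03d}",
                "chrom": gchrom,
                "start": start,
                "end": start + gene_length - 1,
            }
        )
    sweep_gene = {
        "gene_id": "G_SWEEP",
        "symbol": "SWEEPGENE",
        "chrom": config.sweep_chrom,
        "start": max(1, config.sweep_position - gene_length // 2),
        "end": config.sweep_position + gene_length // 2,
    }
    genes.append(sweep_gene)
    genes.sort(key=lambda g: (int(g["chrom"]), g["start"]))
    gff_path = out / "genes.gff3"
    _write_gff3(gff_path, genes)

    records, litter_truth = simulate_litter_records(
        seed=int(rng.integers(0, 2**31 - 1)), **LITTER_DEFAULTS
    )
    litter_path = out / "litter.csv"
    with open(litter_path, "w") as fh:
        fh.write("animal,genotype,litter_size\n")
        for r in records:
            fh.write(f"{r.animal_id},{r.genotype},{r.litter_size}\n")

    truth = {
        "kind": "fixture_bundle",
        "seed": seed,
        "config": asdict(config),
        "sweep_gene": sweep_gene,
        "chromosomes": chrom_truths,
        "litter": asdict(litter_truth),
    }
    truth_path = out / "truth.json"
    truth_path.write_text(json.dumps(truth, indent=2))
    return {
        "vcf": vcf_path,
        "popmap": popmap_path,
        "gff3": gff_path,
        "litter": litter_path,
        "truth": truth_path,
    }
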