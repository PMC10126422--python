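"""FecB (BMPR1B) genotype/allele frequencies, Hardy-Weinberg check, and
litter-size comparison across genotype classes.

The FecB locus has genotypes BB, B+ and ++ (two, one and zero copies of
the fecundity-raising B allele); extra B copies raise ovulation rate and
hence litter size, so the class means are compared with pairwise Welch
t-tests summarised as a compact letter display.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import hwe_chi2

GENOTYPE_CLASSES = ("BB", "B+", "++")


@dataclass
class GenotypeCountTable:
    n_bb: int
    n_bplus: int
    n_plusplus: int

    def __post_init__(self):
        if min(self.n_bb, self.n_bplus, self.n_plusplus) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return self.n_bb + self.n_bplus + self.n_plusplus


@dataclass
class LitterRecord:
    animal_id: str
    genotype: str
    litter_size: int

    def __post_init__(self):
        if self.genotype not in GENOTYPE_CLASSES:
            raise ValueError(f"genotype must be one of {GENOTYPE_CLASSES}")
        if self.litter_size < 1:
            raise ValueError("litter size must be a positive integer")


def genotype_allele_freqs(table: GenotypeCountTable) -> dict:
    """Genotype frequencies and B/+ allele frequencies from class counts."""
    n = table.n
    if n == 0:
        raise ValueError("empty count table")
    freq_b = (2 * table.n_bb + table.n_bplus) / (2 * n)
    return {
        "genotype_freq": {
            "BB": table.n_bb / n,
            "B+": table.n_bplus / n,
            "++": table.n_plusplus / n,
        },
        "allele_freq": {"B": freq_b, "+": 1 - freq_b},
    }


def fecb_hwe(table: GenotypeCountTable, alpha: float = 0.05):
    """1-df HWE chi-square on the FecB genotype counts.

    Returns (chi2, p, in_hwe) where in_hwe means p >= alpha.
    """
    chi2, p = hwe_chi2(table.n_bb, table.n_bplus, table.n_plusplus)
    return chi2, p, p >= alpha


def _letter_display(classes, differs) -> dict:
    """Compact letter display: classes sharing no letter differ at alpha.

    Insert-and-absorb over significantly-different pairs: start with one
    letter covering everything; for each differing pair, split any letter
    group containing both, then drop redundant groups.
    """
    groups = [set(classes)]
    for a, b in differs:
        new_groups = []
        for g in groups:
            if a in g and b in g:
                new_groups.append(g - {a})
                new_groups.append(g - {b})
            else:
                new_groups.append(g)
        # absorb subsets
        groups = []
        for g in sorted(new_groups, key=len, reverse=True):
            if g and not any(g <= h for h in groups):
                groups.append(g)
    letters = {c: "" for c in classes}
    for letter, g in zip("abcdefghijklmnopqrstuvwxyz", groups):
        for c in classes:
            if c in g:
                letters[c] += letter
    return letters


def litter_size_comparison(records, alpha: float = 0.05, bonferroni: bool = False):
    """Per-genotype litter-size mean +/- SE with pairwise Welch t-tests.

    Classes with fewer than 2 records are excluded with a warning; at
    least two usable classes are required.  The compact letter display
    assigns letters so that classes sharing no letter differ at ``alpha``
    (optionally Bonferroni-corrected over the pairs).

    Returns
    -------
    (summary, pairwise) : DataFrame of per-class n/mean/se/letters, and a
    DataFrame of pairwise Welch p-values.
    """
    by_class = {}
    for rec in records:
        by_class.setdefault(rec.genotype, []).append(rec.litter_size)
    usable = {}
    for cls in GENOTYPE_CLASSES:
        vals = by_class.get(cls, [])
        if 0 < len(vals) < 2:
            warnings.warn(f"genotype class {cls} has < 2 records; excluded")
        elif len(vals) >= 2:
            usable[cls] = np.asarray(vals, dtype=float)
    if len(usable) < 2:
        raise ValueError("need >= 2 genotype classes with >= 2 records each")

    pairs = list(itertools.combinations(usable, 2))
    threshold = alpha / len(pairs) if bonferroni else alpha
    rows, differs = [], []
    for a, b in pairs:
        t, p = stats.ttest_ind(usable[a], usable[b], equal_var=False)
        rows.append({"class_a": a, "class_b": b, "t": t, "p": p})
        if p < threshold:
            differs.append((a, b))
    letters = _letter_display(list(usable), differs)

    summary = pd.DataFrame(
        [
            {
                "genotype": cls,
                "n": vals.size,
                "mean_litter_size": vals.mean(),
                "se": vals.std(ddof=1) / np.sqrt(vals.size),
                "letters": letters[cls],
            }
            for cls, vals in usable.items()
        ]
    )
    return summary, pd.DataFrame(rows)


def read_litter_csv(path) -> list:
    """CSV of (animal, genotype, litter_size) -> list of LitterRecord."""
    frame = pd.read_csv(path)
    cols = [c.lower() for c in frame.columns]
    frame.columns = cols
    return [
        LitterRecord(str(r["animal"]), str(r["genotype"]), int(r["litter_size"]))
        for _, r in frame.iterrows()
    ]
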