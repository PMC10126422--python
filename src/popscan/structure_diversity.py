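"""Distance-based population structure: p-distance matrix, neighbor-joining
tree (Newick), and genotype PCA.

The p-distance between two diploid genotypes is the per-site allele-sharing
dissimilarity (0 when identical, 0.5 when the genotypes share exactly one
allele, 1 for opposite homozygotes) averaged over the sites called in both
samples; on 0/1/2 dosage codes this is |g_i - g_j| / 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotype_io import MISSING, GenotypeDataset


@dataclass
class DistanceMatrix:
    labels: list
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0):
            raise ValueError("diagonal must be zero")

    def to_phylip(self) -> str:
        lines = [f" {len(self.labels)}"]
        for lab, row in zip(self.labels, self.d):
            lines.append(lab + "  " + " ".join(f"{v:.6f}" for v in row))
        return "\n".join(lines) + "\n"


def p_distance_matrix(dataset: GenotypeDataset) -> DistanceMatrix:
    """Pairwise allele-sharing p-distance over shared non-missing sites."""
    geno = dataset.genotypes.astype(float)
    called = dataset.genotypes != MISSING
    n = dataset.n_samples
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = called[i] & called[j]
            if not both.any():
                raise ValueError(
                    f"samples {dataset.sample_ids[i]} and {dataset.sample_ids[j]} "
                    "share no called sites"
                )
            d[i, j] = d[j, i] = np.abs(geno[i, both] - geno[j, both]).mean() / 2
    return DistanceMatrix(labels=list(dataset.sample_ids), d=d)


class TreeNode:
    """Minimal unrooted-tree node for NJ output."""

    def __init__(self, name=None, children=None):
        self.name = name
        self.children = children or []  # list of (child, branch_length)

    def newick(self) -> str:
        return self._newick_inner() + ";"

    def _newick_inner(self):
        if not self.children:
            return self.name
        inner = ",".join(
            f"{child._newick_inner()}:{bl:.6f}" for child, bl in self.children
        )
        return f"({inner})" + (self.name or "")

    def leaf_path_lengths(self) -> dict:
        """Leaf-to-leaf path-length matrix as {(a, b): distance}."""
        # collect (leaf, depth) per child subtree of every node
        out = {}

        def walk(node):
            groups = []
            for child, bl in node.children:
                if not child.children:
                    groups.append([(child.name, bl)])
                else:
                    sub = walk(child)
                    groups.append([(n, d + bl) for n, d in sub])
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    for na, da in groups[gi]:
                        for nb, db in groups[gj]:
                            key = tuple(sorted((na, nb)))
                            out[key] = da + db
            return [x for g in groups for x in g]

        walk(self)
        return out


def nj_tree(matrix: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    At each step the pair (i, j) minimising
    Q(i,j) = (r-2) d(i,j) - R_i - R_j is joined (lowest (i, j) index pair
    on ties); branch lengths follow the standard three-point formulas.
    The final three nodes are joined into an unrooted trifurcation.
    """
    n = len(matrix.labels)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    d = matrix.d.copy()
    nodes = [TreeNode(name=lab) for lab in matrix.labels]
    active = list(range(n))

    while len(active) > 3:
        r = len(active)
        sub = d[np.ix_(active, active)]
        rowsum = sub.sum(axis=1)
        q = (r - 2) * sub - rowsum[:, None] - rowsum[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest-index tie-break: argmin on the flattened matrix scans rows
        flat = np.argmin(q)
        ai, aj = divmod(flat, r)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = d[i, j]
        li = 0.5 * dij + (rowsum[ai] - rowsum[aj]) / (2 * (r - 2))
        lj = dij - li
        parent = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        # distances from the new node to the remaining taxa
        new_row = 0.5 * (d[i, :] + d[j, :] - dij)
        d = np.vstack([d, new_row])
        new_col = np.append(new_row, 0.0)
        d = np.column_stack([d, new_col])
        nodes.append(parent)
        active = [a for a in active if a not in (i, j)] + [len(nodes) - 1]

    # join the last three around an unrooted central node
    i, j, k = active
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    return TreeNode(children=[(nodes[i], li), (nodes[j], lj), (nodes[k], lk)])


def pca_genotypes(dataset: GenotypeDataset, k: int = 2):
    """PCA of the frequency-standardised genotype matrix.

    Each SNP column is mean-centred and scaled by sqrt(2 p (1-p)) (unit
    variance under binomial sampling); missing entries are mean-imputed;
    monomorphic SNPs are dropped.  Sign convention: the largest-magnitude
    loading of each component is positive.

    Returns
    -------
    (coords, explained) : (n_samples, k) coordinates and the fraction of
    variance explained per component.
    """
    geno = dataset.genotypes.astype(float)
    geno[dataset.genotypes == MISSING] = np.nan
    freq = np.nanmean(geno, axis=0) / 2
    poly = (freq > 0) & (freq < 1)
    if not poly.any():
        raise ValueError("no polymorphic SNPs")
    geno = geno[:, poly]
    freq = freq[poly]
    centred = geno - 2 * freq
    centred = np.where(np.isnan(centred), 0.0, centred)  # mean imputation
    standardised = centred / np.sqrt(2 * freq * (1 - freq))

    u, s, vt = np.linalg.svd(standardised, full_matrices=False)
    rank = int((s > 1e-10).sum())
    if k > rank:
        import warnings

        warnings.warn(f"k={k} exceeds rank {rank}; truncated")
        k = rank
    coords = u[:, :k] * s[:k]
    explained = (s[:k] ** 2) / (s**2).sum()
    for comp in range(k):
        load = vt[comp]
        if load[np.argmax(np.abs(load))] < 0:
            coords[:, comp] *= -1
    return coords, explained
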