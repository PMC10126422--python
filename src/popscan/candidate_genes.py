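"""Gene-model loading and interval intersection of selection-scan hits.

Candidate genes are those whose interval overlaps a selected FST window
or top iHS SNP by at least one base pair (the most inclusive reproducible
rule; a minimum-overlap or flank padding can be configured).  Gene
coordinates are held 1-based inclusive; BED input (0-based half-open) is
converted on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from intervaltree import IntervalTree

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    symbol: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str = "."

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")


def _read_bed(path):
    genes, n_bad = [], 0
    with open(path) as fh:
        for line in fh:
            if line.startswith(("#", "track", "browser")) or not line.strip():
                continue
            parts = line.split()
            if len(parts) < 4:
                n_bad += 1
                continue
            try:
                start0, end0 = int(parts[1]), int(parts[2])
            except ValueError:
                n_bad += 1
                continue
            name = parts[3]
            strand = parts[5] if len(parts) > 5 else "."
            genes.append(
                GeneModel(
                    gene_id=name,
                    symbol=name,
                    chrom=parts[0],
                    start=start0 + 1,  # half-open 0-based -> 1-based inclusive
                    end=end0,
                    strand=strand,
                )
            )
    return genes, n_bad


def _read_gff3(path, feature_type):
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for feat in db.features_of_type(feature_type):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        symbol = feat.attributes.get("Name", [gene_id])[0]
        genes.append(
            GeneModel(
                gene_id=gene_id,
                symbol=symbol,
                chrom=feat.seqid,
                start=feat.start,  # gffutils keeps GFF3 1-based inclusive
                end=feat.end,
                strand=feat.strand or ".",
            )
        )
    return genes, 0


def read_gene_models(path, feature_type: str = "gene") -> list:
    """Load gene models from GFF3 or 4+-column BED (by file extension).

    GFF3 features of ``feature_type`` are used (configurable, e.g. "mRNA"
    when the annotation has no gene rows).  Output is deduplicated by
    gene_id, in file order.  Malformed BED lines are skipped and counted.
    """
    path_str = str(path)
    if path_str.endswith((".gff", ".gff3")):
        genes, n_bad = _read_gff3(path, feature_type)
    else:
        genes, n_bad = _read_bed(path)
    if n_bad:
        logger.warning("read_gene_models: skipped %d malformed lines", n_bad)
    seen, out = set(), []
    for g in genes:
        if g.gene_id not in seen:
            seen.add(g.gene_id)
            out.append(g)
    return out


def map_to_genes(regions, genes, min_overlap: int = 1, pad: int = 0) -> set:
    """Gene ids whose interval overlaps any region by >= ``min_overlap`` bp.

    ``regions`` is an iterable of (chrom, start, end) 1-based inclusive
    intervals or (chrom, pos) SNPs (treated as length-1 regions).
    ``pad`` widens every gene interval on both sides.
    """
    trees = {}
    for g in genes:
        # IntervalTree is half-open; store [start, end+1)
        trees.setdefault(str(g.chrom), IntervalTree()).addi(
            g.start - pad, g.end + 1 + pad, g.gene_id
        )
    hits = set()
    for region in regions:
        if len(region) == 2:
            chrom, start = region
            end = start
        else:
            chrom, start, end = region
        tree = trees.get(str(chrom))
        if tree is None:
            continue
        for iv in tree.overlap(start, end + 1):
            overlap = min(iv.end - 1, end) - max(iv.begin, start) + 1
            if overlap >= min_overlap:
                hits.add(iv.data)
    return hits


def intersect_gene_sets(set_fst, set_ihs) -> list:
    """Exact set intersection, returned sorted for determinism."""
    return sorted(set(set_fst) & set(set_ihs))
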