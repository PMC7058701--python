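"""Positional SNP-to-gene classification from a local GFF3/BED annotation.

A SNP is *genic* when its position falls inside a gene span, *upstream* /
*downstream* when within a flank of the nearest gene (respecting strand),
and *intergenic* otherwise.  Overlapping genes are all reported; the
primary gene is the one with the smallest span.
"""

from __future__ import annotations

import warnings
from bisect import bisect_right
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .genotype_io import SNPRecord

GENIC = "genic"
UPSTREAM = "upstream"
DOWNSTREAM = "downstream"
INTERGENIC = "intergenic"


@dataclass
class GeneRecord:
    gene_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str = "+"
    name: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")

    @property
    def span(self) -> int:
        return self.end - self.start + 1


class GeneIndex:
    """Per-chromosome sorted gene lists supporting overlap/nearest queries."""

    def __init__(self, genes: list[GeneRecord]):
        self._by_chrom: dict[str, list[GeneRecord]] = {}
        for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.end, g.gene_id)):
            self._by_chrom.setdefault(g.chrom, []).append(g)
        self._starts = {
            c: [g.start for g in gs] for c, gs in self._by_chrom.items()
        }

    @property
    def chromosomes(self) -> set[str]:
        return set(self._by_chrom)

    def overlapping(self, chrom: str, pos: int) -> list[GeneRecord]:
        genes = self._by_chrom.get(chrom, [])
        # genes are not interval-nested beyond toy scale here: linear scan of
        # candidates left of pos bounded by bisect keeps this simple and exact
        hi = bisect_right(self._starts.get(chrom, []), pos)
        return [g for g in genes[:hi] if g.end >= pos]

    def nearest(self, chrom: str, pos: int) -> GeneRecord | None:
        genes = self._by_chrom.get(chrom, [])
        if not genes:
            return None
        return min(
            genes,
            key=lambda g: (min(abs(pos - g.start), abs(pos - g.end)), g.gene_id),
        )


def read_gff3_genes(path: str | Path, feature_types: set[str] = {"gene"}) -> GeneIndex:
    genes = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 9 or parts[2] not in feature_types:
            continue
        attrs = dict(
            kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
        )
        gene_id = attrs.get("ID", attrs.get("gene_id", f"{parts[0]}:{parts[3]}"))
        genes.append(
            GeneRecord(
                gene_id=gene_id.removeprefix("gene:"),
                chrom=parts[0],
                start=int(parts[3]),
                end=int(parts[4]),
                strand=parts[6] if parts[6] in "+-" else "+",
                name=attrs.get("Name", ""),
            )
        )
    return GeneIndex(genes)


def read_bed6_genes(path: str | Path) -> GeneIndex:
    """BED is 0-based half-open; convert to 1-based inclusive."""
    genes = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 4:
            raise ValueError("BED annotation needs at least 4 columns (name)")
        strand = parts[5] if len(parts) >= 6 and parts[5] in "+-" else "+"
        genes.append(
            GeneRecord(
                gene_id=parts[3],
                chrom=parts[0],
                start=int(parts[1]) + 1,
                end=int(parts[2]),
                strand=strand,
            )
        )
    return GeneIndex(genes)


def read_annotation(path: str | Path) -> GeneIndex:
    path = Path(path)
    if path.suffix.lower() in {".gff", ".gff3"}:
        return read_gff3_genes(path)
    if path.suffix.lower() == ".bed":
        return read_bed6_genes(path)
    raise ValueError(f"unrecognized annotation format: {path.name}")


def classify_snp(
    snp: SNPRecord, gene_index: GeneIndex, flank_bp: int = 5000
) -> tuple[str, str, list[str]]:
    """Classify one SNP against the gene index.

    Returns (primary_class, primary_gene_id, all_overlapping_gene_ids);
    primary_gene_id is "" for intergenic SNPs.
    """
    if snp.chrom not in gene_index.chromosomes:
        warnings.warn(f"chromosome {snp.chrom!r} absent from annotation")
        return INTERGENIC, "", []
    hits = gene_index.overlapping(snp.chrom, snp.pos_bp)
    if hits:
        primary = min(hits, key=lambda g: (g.span, g.gene_id))
        return GENIC, primary.gene_id, [g.gene_id for g in hits]
    gene = gene_index.nearest(snp.chrom, snp.pos_bp)
    if gene is not None:
        if snp.pos_bp < gene.start and gene.start - snp.pos_bp <= flank_bp:
            cls = UPSTREAM if gene.strand == "+" else DOWNSTREAM
            return cls, gene.gene_id, []
        if snp.pos_bp > gene.end and snp.pos_bp - gene.end <= flank_bp:
            cls = DOWNSTREAM if gene.strand == "+" else UPSTREAM
            return cls, gene.gene_id, []
    return INTERGENIC, "", []


def annotate_hub_table(
    hub: pd.DataFrame,
    snps: list[SNPRecord],
    gene_index: GeneIndex,
    flank_bp: int = 5000,
) -> pd.DataFrame:
    """Append region class and gene columns to a hub-SNP table."""
    by_id = {s.snp_id: s for s in snps}
    classes, genes, all_genes = [], [], []
    for snp_id in hub["snp_id"]:
        rec = by_id.get(snp_id)
        if rec is None:
            classes.append(INTERGENIC)
            genes.append("")
            all_genes.append("")
            continue
        cls, gene, overlaps = classify_snp(rec, gene_index, flank_bp)
        classes.append(cls)
        genes.append(gene)
        all_genes.append(",".join(overlaps))
    out = hub.copy()
    out["region_class"] = classes
    out["gene_id"] = genes
    out["overlapping_genes"] = all_genes
    return out
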