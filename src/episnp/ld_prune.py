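"""LD-block construction and representative pruning.

Blocks are grown greedily left-to-right along each chromosome: a SNP joins
the open block while its squared genotype correlation with the block's
anchor (first member) meets the threshold and the block is below the size
cap.  One representative per block — the member with the smallest
association p — survives pruning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import MISSING
from .genotype_io import GenotypeMatrix


@dataclass
class LDBlock:
    block_id: int
    chrom: str
    member_snp_ids: list[str] = field(default_factory=list)
    representative_snp_id: str = ""
    max_internal_r2: float = 0.0


def genotype_r2(col_i: np.ndarray, col_j: np.ndarray) -> float:
    """Squared Pearson correlation of two coded genotype columns.

    Pairwise complete-case on missing entries; a constant column on the
    shared samples gives r2 = 0 (degenerate, not an error).
    """
    gi = np.asarray(col_i, dtype=float)
    gj = np.asarray(col_j, dtype=float)
    mask = (gi != MISSING) & (gj != MISSING)
    gi, gj = gi[mask], gj[mask]
    if gi.size < 2 or np.ptp(gi) == 0 or np.ptp(gj) == 0:
        return 0.0
    gi = gi - gi.mean()
    gj = gj - gj.mean()
    denom = float(gi @ gi) * float(gj @ gj)
    r2 = float(gi @ gj) ** 2 / denom
    return min(r2, 1.0)


def build_blocks(
    gm: GenotypeMatrix, threshold: float = 0.9, max_block_size: int = 1000
) -> list[LDBlock]:
    """Greedy per-chromosome LD chaining into blocks.

    Requires SNPs sorted by (chrom, pos); raises otherwise.
    """
    _check_sorted(gm)
    blocks: list[LDBlock] = []
    current: LDBlock | None = None
    anchor_col: np.ndarray | None = None
    for j, rec in enumerate(gm.snps):
        col = gm.values[:, j]
        if (
            current is not None
            and rec.chrom == current.chrom
            and len(current.member_snp_ids) < max_block_size
        ):
            r2 = genotype_r2(anchor_col, col)
            if r2 >= threshold:
                current.member_snp_ids.append(rec.snp_id)
                current.max_internal_r2 = max(current.max_internal_r2, r2)
                continue
        current = LDBlock(block_id=len(blocks), chrom=rec.chrom,
                          member_snp_ids=[rec.snp_id])
        anchor_col = col
        blocks.append(current)
    return blocks


def prune_blocks(blocks: list[LDBlock], assoc_results: pd.DataFrame) -> list[str]:
    """Keep the most-associated member per block, preserving genome order."""
    pmap = dict(zip(assoc_results["snp_id"], assoc_results["p"]))
    kept = []
    for block in blocks:
        missing = [s for s in block.member_snp_ids if s not in pmap]
        if missing:
            raise KeyError(f"no association record for block member(s) {missing[:3]}")
        best = min(enumerate(block.member_snp_ids), key=lambda t: (pmap[t[1]], t[0]))
        block.representative_snp_id = best[1]
        kept.append(best[1])
    return kept


def prune(
    gm: GenotypeMatrix,
    assoc_results: pd.DataFrame,
    threshold: float = 0.9,
    max_block_size: int = 1000,
) -> tuple[GenotypeMatrix, list[LDBlock]]:
    """Build blocks and subset the matrix to one representative per block."""
    blocks = build_blocks(gm, threshold=threshold, max_block_size=max_block_size)
    kept = set(prune_blocks(blocks, assoc_results))
    mask = np.array([s.snp_id in kept for s in gm.snps])
    return gm.subset(snp_mask=mask), blocks


def write_blocks(blocks: list[LDBlock], path: str | Path) -> None:
    rows = [
        (b.block_id, b.chrom, ",".join(b.member_snp_ids),
         b.representative_snp_id, f"{b.max_internal_r2:.4f}")
        for b in blocks
    ]
    pd.DataFrame(
        rows, columns=["block_id", "chrom", "members", "representative", "max_r2"]
    ).to_csv(path, sep="\t", index=False)


def _check_sorted(gm: GenotypeMatrix) -> None:
    seen: dict[str, int] = {}
    last_chrom = None
    last_pos = -1
    for rec in gm.snps:
        if rec.chrom != last_chrom:
            if rec.chrom in seen:
                raise ValueError("SNPs not sorted: chromosome blocks interleaved")
            seen[rec.chrom] = 1
            last_chrom, last_pos = rec.chrom, rec.pos_bp
        else:
            if rec.pos_bp < last_pos:
                raise ValueError(
                    f"SNPs not sorted by position on chromosome {rec.chrom}"
                )
            last_pos = rec.pos_bp
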