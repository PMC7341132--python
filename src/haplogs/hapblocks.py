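"""Fixed-length haplotype blocks over mapped, imputed genotypes.

A haplotype block is a run of L adjacent mapped markers on one chromosome,
treated downstream as a single multi-allelic locus: every distinct
L-length homozygous dosage vector observed among the lines is a
"haplotype allele".  Blocks never span chromosomes; each chromosome with
m markers yields floor(m/L) complete blocks and the trailing m mod L
markers are dropped (logged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genio import GeneticMap, GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = ["HaplotypeBlockSet", "build_blocks", "enumerate_alleles",
           "block_summary"]


@dataclass
class HaplotypeBlockSet:
    """Blocks, per-line haplotype-allele codes, and allele frequencies.

    ``allele_codes`` is a lines x blocks integer matrix with alleles
    numbered 1..n_alleles per block, in order of first appearance in line
    order.  Each inbred line carries two copies of exactly one allele per
    block, so allele frequency p_k is the fraction of lines carrying
    allele k.
    """

    block_size: int
    blocks: pd.DataFrame          # chrom, start_idx, end_idx, start_cM, end_cM
    line_ids: list
    allele_codes: np.ndarray      # (n_lines, n_blocks), int32, 1-based
    allele_freqs: list            # per block: np.ndarray of p_k, k = 1..n_alleles

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def n_alleles(self) -> np.ndarray:
        return np.array([len(f) for f in self.allele_freqs], dtype=int)


def enumerate_alleles(block_dosages: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Number distinct homozygous dosage vectors as haplotype alleles.

    ``block_dosages`` is a lines x L dosage matrix restricted to one block.
    Alleles are numbered 1..n by order of first appearance in line order;
    p_k = (lines carrying allele k)/n.  Heterozygous dosages are rejected:
    a block allele on an unphased heterozygote is ambiguous, so residual
    hets must be resolved during imputation first.
    """
    block_dosages = np.asarray(block_dosages)
    if not np.isin(block_dosages, (0, 2)).all():
        raise ValueError(
            "heterozygous or missing dosage inside a block; run imputation "
            "(which resolves residual hets to the nearest homozygote) first")
    _, first_idx, inverse = np.unique(
        block_dosages, axis=0, return_index=True, return_inverse=True)
    # renumber by order of first appearance in line order
    order = np.argsort(first_idx, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(order.size)
    codes = rank[inverse] + 1
    counts = np.bincount(codes - 1, minlength=order.size)
    freqs = counts / block_dosages.shape[0]
    return codes.astype(np.int32), freqs


def build_blocks(g: GenotypeMatrix, gmap: GeneticMap, L: int) -> HaplotypeBlockSet:
    """Cut each chromosome into consecutive non-overlapping blocks of L markers."""
    if L < 1:
        raise ValueError("block size L must be >= 1")
    if (g.dosages == -1).any():
        raise ValueError("genotypes must be fully imputed before block construction")
    chrom_of = np.array([gmap.chrom(mk) for mk in g.marker_ids], dtype=object)
    pos_of = np.array([gmap.pos(mk) for mk in g.marker_ids], dtype=float)

    records = []
    codes_cols = []
    freqs_all = []
    n_dropped = 0
    # preserve map order of chromosomes as they appear in the matrix
    seen = []
    for c in chrom_of:
        if c not in seen:
            seen.append(c)
    for chrom in seen:
        idx = np.flatnonzero(chrom_of == chrom)
        if np.any(np.diff(pos_of[idx]) < 0):
            raise ValueError(f"markers on {chrom} are not in map order; "
                             "apply order_by_map first")
        n_blocks_c = len(idx) // L
        n_dropped += len(idx) - n_blocks_c * L
        for b in range(n_blocks_c):
            span = idx[b * L:(b + 1) * L]
            codes, freqs = enumerate_alleles(g.dosages[:, span])
            records.append({
                "block_id": f"{chrom}_b{b + 1}",
                "chrom": chrom,
                "start_idx": int(span[0]),
                "end_idx": int(span[-1]),
                "start_cM": float(pos_of[span[0]]),
                "end_cM": float(pos_of[span[-1]]),
            })
            codes_cols.append(codes)
            freqs_all.append(freqs)
    if not records:
        raise ValueError(
            f"block size L={L} exceeds every chromosome's marker count")
    if n_dropped:
        logger.info("build_blocks(L=%d): dropped %d trailing markers", L, n_dropped)
    blocks = pd.DataFrame.from_records(records).set_index("block_id")
    return HaplotypeBlockSet(
        block_size=L,
        blocks=blocks,
        line_ids=list(g.line_ids),
        allele_codes=np.column_stack(codes_cols),
        allele_freqs=freqs_all,
    )


def block_summary(hbs: HaplotypeBlockSet) -> dict:
    """Genome-wide and per-chromosome block summaries.

    Mean block span is averaged within each chromosome first and then over
    chromosomes, matching per-chromosome supplementary reporting.
    """
    n_alleles = hbs.n_alleles
    blocks = hbs.blocks.assign(
        n_alleles=n_alleles,
        span_cM=hbs.blocks["end_cM"] - hbs.blocks["start_cM"],
    )
    per_chrom = blocks.groupby("chrom", sort=False).agg(
        n_blocks=("n_alleles", "size"),
        max_alleles=("n_alleles", "max"),
        mean_alleles=("n_alleles", "mean"),
        mean_span_cM=("span_cM", "mean"),
    )
    return {
        "block_size": hbs.block_size,
        "n_blocks_total": int(len(blocks)),
        "max_alleles": int(n_alleles.max()),
        "mean_alleles": float(n_alleles.mean()),
        "mean_span_cM": float(per_chrom["mean_span_cM"].mean()),
        "per_chromosome": per_chrom,
    }
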