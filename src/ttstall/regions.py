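"""TSS and gene-body windows derived from gene models.

Nascent-transcription signal is quantified in two windows per gene: a
promoter-proximal window of ``flank`` bp on each side of the TSS base
(2*flank + 1 bp wide, 501 bp at the default flank of 250) and the gene body
starting at the (flank+1)-th base downstream of the TSS and running to the
gene's 3' end. The two windows are disjoint and adjacent; the ratio of
signal between them is the stalling (pausing) index.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_FLANK = 250
DEFAULT_MIN_GENE_LENGTH = 500
CHIP_MIN_GENE_LENGTH = 2000

GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand"]


class RegionError(ValueError):
    """A gene model cannot yield a valid TSS/body region pair."""


@dataclass(frozen=True)
class GeneModel:
    """A single-TSS gene record (0-based half-open interval)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise RegionError(
                f"gene {self.gene_id}: start {self.start} must be < end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise RegionError(f"gene {self.gene_id}: invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class RegionPair:
    """TSS window and gene-body window for one gene.

    ``tss_start``/``tss_end`` and ``body_start``/``body_end`` are 0-based
    half-open. The windows are disjoint and share the boundary coordinate
    at the (flank+1)-th base downstream of the TSS.
    """

    gene_id: str
    chrom: str
    strand: str
    tss_start: int
    tss_end: int
    body_start: int
    body_end: int


def derive_region_pair(gene: GeneModel, flank: int = DEFAULT_FLANK) -> RegionPair:
    """Split a gene into its TSS window and gene body.

    For a + strand gene [s, e) the TSS base is ``s``: the TSS window is
    [s-flank, s+flank+1) and the body [s+flank+1, e). For a - strand gene the
    TSS base is ``e-1``, the TSS window [e-1-flank, e+flank) and the body
    [s, e-1-flank). The TSS window may extend past the gene boundary upstream
    of the TSS; windows extending below coordinate 0 are clipped at 0 with a
    logged warning.

    Raises
    ------
    RegionError
        If the gene is too short to leave a non-empty body
        (length <= flank + 1).
    """
    if flank < 0:
        raise RegionError(f"flank must be >= 0, got {flank}")
    if gene.length <= flank + 1:
        raise RegionError(
            f"gene {gene.gene_id}: length {gene.length} <= flank+1 ({flank + 1}); "
            "gene body would be empty"
        )
    if gene.strand == "+":
        tss_start, tss_end = gene.start - flank, gene.start + flank + 1
        body_start, body_end = gene.start + flank + 1, gene.end
    else:
        tss_base = gene.end - 1
        tss_start, tss_end = tss_base - flank, tss_base + flank + 1
        body_start, body_end = gene.start, tss_base - flank
    if tss_start < 0:
        logger.warning(
            "gene %s: TSS window start %d clipped at 0", gene.gene_id, tss_start
        )
        tss_start = 0
    return RegionPair(
        gene_id=gene.gene_id,
        chrom=gene.chrom,
        strand=gene.strand,
        tss_start=tss_start,
        tss_end=tss_end,
        body_start=body_start,
        body_end=body_end,
    )


def derive_regions(genes: pd.DataFrame, flank: int = DEFAULT_FLANK) -> pd.DataFrame:
    """Vectorised :func:`derive_region_pair` over a gene table.

    ``genes`` must carry columns ``gene_id, chrom, start, end, strand``.
    Returns a DataFrame with one row per gene and columns
    ``gene_id, chrom, strand, tss_start, tss_end, body_start, body_end``.
    Any gene too short for a non-empty body raises :class:`RegionError`.
    """
    rows = []
    for rec in genes.itertuples(index=False):
        pair = derive_region_pair(
            GeneModel(rec.gene_id, rec.chrom, int(rec.start), int(rec.end), rec.strand),
            flank=flank,
        )
        rows.append(pair)
    return pd.DataFrame(
        {
            "gene_id": [p.gene_id for p in rows],
            "chrom": [p.chrom for p in rows],
            "strand": [p.strand for p in rows],
            "tss_start": [p.tss_start for p in rows],
            "tss_end": [p.tss_end for p in rows],
            "body_start": [p.body_start for p in rows],
            "body_end": [p.body_end for p in rows],
        }
    )


def filter_short_genes(
    genes: pd.DataFrame, min_len: int = DEFAULT_MIN_GENE_LENGTH
) -> pd.DataFrame:
    """Drop genes shorter than ``min_len`` bp (strict), preserving order.

    The default threshold (500 bp) is the one used for nascent-transcription
    quantification; ChIP-style quantification uses the same operation with
    ``min_len=2000``.
    """
    lengths = genes["end"] - genes["start"]
    return genes.loc[lengths >= min_len].reset_index(drop=True)
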