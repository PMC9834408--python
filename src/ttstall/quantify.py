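"""Fragment-to-region assignment and count matrices.

A fragment overlaps a window if it shares at least one base with it
(half-open interval intersection). Fragments overlapping both the TSS
window and the gene body of the same gene are not counted for that gene —
they are tallied separately as discarded "straddlers". Gene-level counting
(used for the steady-state RNA arm) has no such exclusion rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

STRAND_MODES = ("same", "opposite", "ignore")

FRAGMENT_COLUMNS = ["chrom", "start", "end", "sample", "strand"]


class Category(str, Enum):
    TSS = "TSS"
    BODY = "BODY"
    BOTH = "BOTH"
    NONE = "NONE"


@dataclass
class RegionCounts:
    """Per-(gene, sample) TSS/body counts plus per-sample bookkeeping.

    ``tss`` and ``body`` are genes x samples integer DataFrames. ``tally``
    has one row per sample with columns ``assigned_tss, assigned_body,
    both_discarded, unassigned, n_fragments``; per sample,
    assigned + both_discarded + unassigned == n_fragments (a fragment is
    "assigned" if it was counted for at least one gene).
    """

    tss: pd.DataFrame
    body: pd.DataFrame
    tally: pd.DataFrame


def _strand_ok(frag_strand, region_strand: str, strand_mode: str):
    if strand_mode == "ignore":
        return np.ones(np.shape(frag_strand), dtype=bool) if np.ndim(frag_strand) else True
    if strand_mode == "same":
        return frag_strand == region_strand
    if strand_mode == "opposite":
        return frag_strand != region_strand
    raise ValueError(f"unknown strand_mode {strand_mode!r}; expected one of {STRAND_MODES}")


def classify_fragment(
    frag_start: int,
    frag_end: int,
    frag_strand: str,
    pair,
    strand_mode: str = "same",
) -> Category:
    """Classify one fragment against one TSS/body region pair.

    Returns TSS or BODY if the fragment overlaps exactly one window, BOTH if
    it overlaps both (such fragments are excluded from counting), and NONE
    if it overlaps neither or fails the strand test.
    """
    if strand_mode not in STRAND_MODES:
        raise ValueError(
            f"unknown strand_mode {strand_mode!r}; expected one of {STRAND_MODES}"
        )
    if not _strand_ok(frag_strand, pair.strand, strand_mode):
        return Category.NONE
    in_tss = frag_start < pair.tss_end and frag_end > pair.tss_start
    in_body = frag_start < pair.body_end and frag_end > pair.body_start
    if in_tss and in_body:
        return Category.BOTH
    if in_tss:
        return Category.TSS
    if in_body:
        return Category.BODY
    return Category.NONE


def _prep_fragments(frags: pd.DataFrame, samples) -> tuple[pd.DataFrame, list[str]]:
    if samples is not None:
        samples = list(samples)
        unknown = set(frags["sample"].unique()) - set(samples)
        if unknown:
            raise ValueError(
                f"fragments reference samples absent from the design: {sorted(unknown)}"
            )
    else:
        samples = sorted(frags["sample"].unique())
    return frags, samples


def count_fragments(
    frags: pd.DataFrame,
    pairs: pd.DataFrame,
    strand_mode: str = "same",
    samples=None,
) -> RegionCounts:
    """Count fragments per (gene, sample) in TSS and body windows.

    ``frags`` needs columns ``chrom, start, end, sample, strand``; ``pairs``
    is the output of :func:`ttstall.regions.derive_regions`. The result is
    deterministic and independent of fragment order. A fragment overlapping
    the windows of two different genes counts for both.
    """
    if strand_mode not in STRAND_MODES:
        raise ValueError(
            f"unknown strand_mode {strand_mode!r}; expected one of {STRAND_MODES}"
        )
    frags, samples = _prep_fragments(frags, samples)
    genes = list(pairs["gene_id"])
    sample_codes = pd.Categorical(frags["sample"], categories=samples).codes
    fs = frags["start"].to_numpy()
    fe = frags["end"].to_numpy()
    fchrom = frags["chrom"].to_numpy()
    fstrand = frags["strand"].to_numpy()
    n_frags = len(frags)

    tss = np.zeros((len(genes), len(samples)), dtype=np.int64)
    body = np.zeros_like(tss)
    assigned = np.zeros(n_frags, dtype=bool)
    hit_both = np.zeros(n_frags, dtype=bool)
    assigned_tss = np.zeros(n_frags, dtype=bool)
    assigned_body = np.zeros(n_frags, dtype=bool)

    for gi, pair in enumerate(pairs.itertuples(index=False)):
        mask = (fchrom == pair.chrom) & _strand_ok(fstrand, pair.strand, strand_mode)
        if not mask.any():
            continue
        in_tss = mask & (fs < pair.tss_end) & (fe > pair.tss_start)
        in_body = mask & (fs < pair.body_end) & (fe > pair.body_start)
        both = in_tss & in_body
        only_tss = in_tss & ~both
        only_body = in_body & ~both
        np.add.at(tss[gi], sample_codes[only_tss], 1)
        np.add.at(body[gi], sample_codes[only_body], 1)
        assigned |= only_tss | only_body
        assigned_tss |= only_tss
        assigned_body |= only_body
        hit_both |= both

    discarded = hit_both & ~assigned
    unassigned = ~assigned & ~discarded
    tally = pd.DataFrame(
        {
            "assigned_tss": np.bincount(
                sample_codes[assigned_tss & assigned], minlength=len(samples)
            ),
            "assigned_body": np.bincount(
                sample_codes[assigned_body & ~assigned_tss & assigned],
                minlength=len(samples),
            ),
            "both_discarded": np.bincount(sample_codes[discarded], minlength=len(samples)),
            "unassigned": np.bincount(sample_codes[unassigned], minlength=len(samples)),
            "n_fragments": np.bincount(sample_codes, minlength=len(samples)),
        },
        index=pd.Index(samples, name="sample"),
    )
    return RegionCounts(
        tss=pd.DataFrame(tss, index=pd.Index(genes, name="gene_id"), columns=samples),
        body=pd.DataFrame(body, index=pd.Index(genes, name="gene_id"), columns=samples),
        tally=tally,
    )


def count_gene_level(
    frags: pd.DataFrame,
    genes: pd.DataFrame,
    strand_mode: str = "same",
    samples=None,
) -> pd.DataFrame:
    """Gene x sample fragment counts by >=1 bp overlap with the gene interval.

    No straddler exclusion applies at gene level; a fragment overlapping two
    genes counts for both.
    """
    if strand_mode not in STRAND_MODES:
        raise ValueError(
            f"unknown strand_mode {strand_mode!r}; expected one of {STRAND_MODES}"
        )
    frags, samples = _prep_fragments(frags, samples)
    gene_ids = list(genes["gene_id"])
    sample_codes = pd.Categorical(frags["sample"], categories=samples).codes
    fs = frags["start"].to_numpy()
    fe = frags["end"].to_numpy()
    fchrom = frags["chrom"].to_numpy()
    fstrand = frags["strand"].to_numpy()

    counts = np.zeros((len(gene_ids), len(samples)), dtype=np.int64)
    for gi, gene in enumerate(genes.itertuples(index=False)):
        mask = (
            (fchrom == gene.chrom)
            & _strand_ok(fstrand, gene.strand, strand_mode)
            & (fs < gene.end)
            & (fe > gene.start)
        )
        np.add.at(counts[gi], sample_codes[mask], 1)
    return pd.DataFrame(
        counts, index=pd.Index(gene_ids, name="gene_id"), columns=samples
    )
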