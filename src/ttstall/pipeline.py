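"""End-to-end driver: regions -> quantify -> normalize -> differential.

``run_pipeline`` ties the stages together for a file-based input set
(annotation, per-sample fragment BED, spike-in tables, design table) and
writes every result table plus a manifest with parameters, seed and input
checksums. Reruns with identical inputs produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import io as tio
from .differential import (
    DEFAULT_ALPHA,
    DEFAULT_LFC_MIN,
    DEFAULT_PSEUDOCOUNT,
    diff_expression,
    diff_stalling,
    stability_shift,
    stability_summary,
)
from .normalize import (
    DEFAULT_LOW_COUNT_THRESHOLD,
    apply_size_factors,
    low_count_filter,
    size_factors_rna,
    size_factors_tt,
)
from .quantify import count_fragments, count_gene_level
from .regions import DEFAULT_FLANK, DEFAULT_MIN_GENE_LENGTH, derive_regions, filter_short_genes

logger = logging.getLogger(__name__)

_KNOWN_KEYS = None  # populated from the dataclass below


@dataclasses.dataclass
class PipelineConfig:
    """Paths and parameters for one pipeline run.

    ``spike_tt``/``spike_rna`` are spike-in count TSVs for the nascent and
    steady-state arms; ``fragments`` is a BED6 file with the sample id in
    the name column covering both assays. All thresholds default to the
    documented analysis rules (flank 250, min gene length 500, low-count
    threshold 5, |log2FC| >= 1 at BH-adjusted p < 0.05, stalling
    pseudocount 1).
    """

    annotation: str
    fragments: str
    spike_tt: str
    spike_rna: str
    design: str
    outdir: str
    ref_condition: str | None = None
    flank: int = DEFAULT_FLANK
    min_len: int = DEFAULT_MIN_GENE_LENGTH
    threshold: int = DEFAULT_LOW_COUNT_THRESHOLD
    lfc_min: float = DEFAULT_LFC_MIN
    alpha: float = DEFAULT_ALPHA
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    strand_mode: str = "same"
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        return cls.from_dict(tio.load_config_file(path))


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name: str):
    logger.info("stage %s", name)
    return time.perf_counter()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all stages on both assay arms and write result tables.

    Returns a dict of the in-memory results (count matrices, size factors,
    differential tables, stalling and stability tables, summary). Output
    files land in ``cfg.outdir``.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    t0 = _stage("load")
    genes = tio.read_gene_models(cfg.annotation)
    frags = tio.read_fragments_bed(cfg.fragments)
    design = tio.read_design_tsv(cfg.design)
    spike_tt = tio.read_spike_tsv(cfg.spike_tt)
    spike_rna = tio.read_spike_tsv(cfg.spike_rna)
    missing = set(frags["sample"].unique()) - set(design.index)
    if missing:
        raise ValueError(
            f"fragments reference sample(s) missing from the design: {sorted(missing)}"
        )
    logger.info(
        "loaded %d genes, %d fragments, %d samples (%.2fs)",
        len(genes), len(frags), len(design), time.perf_counter() - t0,
    )

    t0 = _stage("regions")
    genes_kept = filter_short_genes(genes, min_len=cfg.min_len)
    pairs = derive_regions(genes_kept, flank=cfg.flank)
    tio.write_regions_bed(pairs, outdir / "regions.bed")
    logger.info("%d/%d genes pass the length filter", len(genes_kept), len(genes))

    t0 = _stage("quantify")
    tt_samples = design.index[design["assay"] == "TT"]
    rna_samples = design.index[design["assay"] == "RNA"]
    tt_frags = frags[frags["sample"].isin(tt_samples)]
    rna_frags = frags[frags["sample"].isin(rna_samples)]
    region_counts = count_fragments(
        tt_frags, pairs, strand_mode=cfg.strand_mode, samples=list(tt_samples)
    )
    gene_counts = count_gene_level(
        rna_frags, genes_kept, strand_mode=cfg.strand_mode, samples=list(rna_samples)
    )
    tio.write_counts_tsv(region_counts.tss, outdir / "counts_tss.tsv")
    tio.write_counts_tsv(region_counts.body, outdir / "counts_body.tsv")
    tio.write_counts_tsv(gene_counts, outdir / "counts_gene.tsv")
    region_counts.tally.to_csv(outdir / "tally.tsv", sep="\t")
    logger.info(
        "counted %d TT and %d RNA fragments (%.2fs)",
        len(tt_frags), len(rna_frags), time.perf_counter() - t0,
    )

    t0 = _stage("normalize")
    s_tt = size_factors_tt(spike_tt)
    s_rna = size_factors_rna(spike_rna)
    tio.write_size_factors_tsv(s_tt, outdir / "size_factors_tt.tsv")
    tio.write_size_factors_tsv(s_rna, outdir / "size_factors_rna.tsv")

    ref = cfg.ref_condition or str(design["condition"].iloc[0])
    tt_design = design.loc[tt_samples]
    rna_design = design.loc[rna_samples]
    tt_gene_counts = region_counts.tss + region_counts.body

    mask_tt = low_count_filter(tt_gene_counts, tt_design, threshold=cfg.threshold)
    mask_rna = low_count_filter(gene_counts, rna_design, threshold=cfg.threshold)
    kept_tt = tt_gene_counts.loc[mask_tt["keep"]]
    kept_rna = gene_counts.loc[mask_rna["keep"]]
    logger.info(
        "low-count filter kept %d/%d TT genes, %d/%d RNA genes",
        len(kept_tt), len(tt_gene_counts), len(kept_rna), len(gene_counts),
    )

    t0 = _stage("differential")
    diff_tt = diff_expression(
        kept_tt, tt_design, s_tt, ref, lfc_min=cfg.lfc_min, alpha=cfg.alpha
    )
    diff_rna = diff_expression(
        kept_rna, rna_design, s_rna, ref, lfc_min=cfg.lfc_min, alpha=cfg.alpha
    )
    stalling = diff_stalling(
        region_counts.tss.loc[mask_tt["keep"]],
        region_counts.body.loc[mask_tt["keep"]],
        tt_design,
        s_tt,
        ref,
        pseudocount=cfg.pseudocount,
    )
    shift = stability_shift(diff_rna, diff_tt)
    summary = stability_summary(shift)
    for name, df in (
        ("diffexpr_tt", diff_tt),
        ("diffexpr_rna", diff_rna),
        ("stalling", stalling),
        ("stability", shift),
    ):
        df.to_csv(outdir / f"{name}.tsv", sep="\t", index_label="gene_id")
    with open(outdir / "stability_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    logger.info("differential stage done (%.2fs)", time.perf_counter() - t0)

    manifest = {
        "parameters": {
            k: v for k, v in dataclasses.asdict(cfg).items() if k != "outdir"
        },
        "inputs": {
            name: _sha256(getattr(cfg, name))
            for name in ("annotation", "fragments", "spike_tt", "spike_rna", "design")
        },
        "n_genes_annotation": int(len(genes)),
        "n_genes_quantified": int(len(genes_kept)),
        "n_genes_tested_tt": int(len(kept_tt)),
        "n_genes_tested_rna": int(len(kept_rna)),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return {
        "genes": genes_kept,
        "pairs": pairs,
        "region_counts": region_counts,
        "gene_counts": gene_counts,
        "size_factors_tt": s_tt,
        "size_factors_rna": s_rna,
        "diff_tt": diff_tt,
        "diff_rna": diff_rna,
        "stalling": stalling,
        "stability": shift,
        "stability_summary": summary,
    }


def write_simulation(sim_dir, cfg, straddler_rate: float = 0.0, intergenic_rate: float = 0.0) -> dict:
    """Generate a full synthetic input set on disk for ``run_pipeline``.

    Writes genes.bed, fragments.bed, spike_tt.tsv, spike_rna.tsv,
    design.tsv, truth.tsv and config.yaml under ``sim_dir`` and returns the
    in-memory objects.
    """
    from .simulate import generate_genes, generate_truth, make_samples, simulate_fragments

    sim_dir = Path(sim_dir)
    sim_dir.mkdir(parents=True, exist_ok=True)
    genes = generate_genes(cfg)
    truth = generate_truth(genes, cfg)
    samples = make_samples(truth, cfg)
    frags, counts = simulate_fragments(
        genes, truth, samples, cfg,
        straddler_rate=straddler_rate, intergenic_rate=intergenic_rate,
    )
    tio.write_genes_bed(genes, sim_dir / "genes.bed")
    tio.write_fragments_bed(frags, sim_dir / "fragments.bed")
    tio.write_spike_tsv(counts.spike_tt, sim_dir / "spike_tt.tsv")
    tio.write_spike_tsv(counts.spike_rna, sim_dir / "spike_rna.tsv")
    tio.write_design_tsv(samples[["assay", "condition", "replicate"]], sim_dir / "design.tsv")
    truth.to_csv(sim_dir / "truth.tsv", sep="\t")
    tio.dump_config_file(cfg.to_dict(), sim_dir / "config.yaml")
    return {
        "genes": genes,
        "truth": truth,
        "samples": samples,
        "fragments": frags,
        "counts": counts,
    }
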