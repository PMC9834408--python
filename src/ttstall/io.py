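"""File formats: BED6, minimal GTF, TSV matrices, titration CSV, configs.

Internal coordinates are 0-based half-open. BED is read and written
natively; GTF gene lines (1-based inclusive) are converted on read. All
writers round-trip exactly through their readers.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def write_genes_bed(genes: pd.DataFrame, path) -> None:
    """Gene table -> BED6 (name = gene_id, score = 0)."""
    bed = pd.DataFrame(
        {
            "chrom": genes["chrom"],
            "start": genes["start"],
            "end": genes["end"],
            "name": genes["gene_id"],
            "score": 0,
            "strand": genes["strand"],
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_genes_bed(path) -> pd.DataFrame:
    """BED6 -> gene table (gene_id, chrom, start, end, strand)."""
    bed = _read_bed6(path)
    return pd.DataFrame(
        {
            "gene_id": bed["name"],
            "chrom": bed["chrom"],
            "start": bed["start"],
            "end": bed["end"],
            "strand": bed["strand"],
        }
    )


def _read_bed6(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(
                    f"{path}: line {lineno}: expected >= 6 BED fields, got {len(parts)}"
                )
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as err:
                raise ValueError(f"{path}: line {lineno}: {err}") from None
            if parts[5] not in ("+", "-", "."):
                raise ValueError(f"{path}: line {lineno}: bad strand {parts[5]!r}")
            rows.append((parts[0], start, end, parts[3], parts[4], parts[5]))
    return pd.DataFrame(rows, columns=BED6_COLUMNS)


def write_fragments_bed(frags: pd.DataFrame, path) -> None:
    """Fragments -> BED6 with the sample id in the name column."""
    bed = pd.DataFrame(
        {
            "chrom": frags["chrom"],
            "start": frags["start"],
            "end": frags["end"],
            "name": frags["sample"],
            "score": 0,
            "strand": frags["strand"],
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_fragments_bed(path) -> pd.DataFrame:
    bed = _read_bed6(path)
    return pd.DataFrame(
        {
            "chrom": bed["chrom"],
            "start": bed["start"],
            "end": bed["end"],
            "sample": bed["name"],
            "strand": bed["strand"],
        }
    )


def write_regions_bed(pairs: pd.DataFrame, path) -> None:
    """Region pairs -> BED6 with names ``geneid:tss`` / ``geneid:body``."""
    rows = []
    for rec in pairs.itertuples(index=False):
        rows.append((rec.chrom, rec.tss_start, rec.tss_end, f"{rec.gene_id}:tss", 0, rec.strand))
        rows.append((rec.chrom, rec.body_start, rec.body_end, f"{rec.gene_id}:body", 0, rec.strand))
    pd.DataFrame(rows, columns=BED6_COLUMNS).to_csv(
        path, sep="\t", header=False, index=False
    )


def read_gtf_genes(path) -> pd.DataFrame:
    """Minimal GTF reader: gene feature lines with a gene_id attribute.

    GTF is 1-based inclusive; starts are converted to 0-based half-open.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(
                    f"{path}: line {lineno}: expected 9 GTF fields, got {len(parts)}"
                )
            if parts[2] != "gene":
                continue
            try:
                start, end = int(parts[3]), int(parts[4])
            except ValueError as err:
                raise ValueError(f"{path}: line {lineno}: {err}") from None
            attrs = parts[8]
            gene_id = None
            for chunk in attrs.split(";"):
                chunk = chunk.strip()
                if chunk.startswith("gene_id"):
                    gene_id = chunk.split(None, 1)[1].strip().strip('"')
                    break
            if gene_id is None:
                raise ValueError(f"{path}: line {lineno}: missing gene_id attribute")
            rows.append((gene_id, parts[0], start - 1, end, parts[6]))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])


def read_gene_models(path) -> pd.DataFrame:
    """Dispatch on extension: .bed -> BED6, .gtf/.gff -> minimal GTF."""
    suffix = Path(path).suffix.lower()
    if suffix == ".bed":
        return read_genes_bed(path)
    if suffix in (".gtf", ".gff"):
        return read_gtf_genes(path)
    raise ValueError(f"unsupported annotation format: {path}")


# ---------------------------------------------------------------------------
# matrices and tables


def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label=counts.index.name or "gene_id")


def read_counts_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_spike_tsv(spike: pd.DataFrame, path) -> None:
    out = spike.copy()
    out["labeled"] = out["labeled"].astype(int)
    out.to_csv(path, sep="\t", index_label="species")


def read_spike_tsv(path) -> pd.DataFrame:
    spike = pd.read_csv(path, sep="\t", index_col=0)
    if "labeled" not in spike.columns:
        raise ValueError(f"{path}: spike-in table lacks a 'labeled' column")
    spike["labeled"] = spike["labeled"].astype(bool)
    return spike


def write_design_tsv(design: pd.DataFrame, path) -> None:
    design.to_csv(path, sep="\t", index_label="sample_id")


def read_design_tsv(path) -> pd.DataFrame:
    design = pd.read_csv(path, sep="\t", index_col=0)
    required = {"assay", "condition", "replicate"}
    missing = required - set(design.columns)
    if missing:
        raise ValueError(f"{path}: design table lacks column(s) {sorted(missing)}")
    if design.index.duplicated().any():
        dupes = design.index[design.index.duplicated()].tolist()
        raise ValueError(f"{path}: duplicate sample id(s) {dupes}")
    return design


def write_size_factors_tsv(s: pd.Series, path) -> None:
    s.rename("size_factor").to_csv(path, sep="\t", index_label="sample_id")


def read_size_factors_tsv(path) -> pd.Series:
    return pd.read_csv(path, sep="\t", index_col=0)["size_factor"]


# ---------------------------------------------------------------------------
# titration CSV


def write_titration_csv(series: pd.DataFrame, path) -> None:
    """Titration series -> CSV with a ``# ligand_nM=...`` header line."""
    ligand = series.attrs.get("ligand_nM", 90.0)
    with open(path, "w") as fh:
        fh.write(f"# ligand_nM={ligand}\n")
        series.to_csv(fh, index=False)


def read_titration_csv(path) -> pd.DataFrame:
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("# ligand_nM="):
            raise ValueError(f"{path}: line 1: expected '# ligand_nM=' header")
        ligand = float(first.split("=", 1)[1])
        series = pd.read_csv(fh)
    series.attrs["ligand_nM"] = ligand
    return series


# ---------------------------------------------------------------------------
# config


def load_config_file(path) -> dict:
    """JSON or YAML config -> dict (YAML is a superset; dispatch on suffix)."""
    suffix = Path(path).suffix.lower()
    with open(path) as fh:
        if suffix == ".json":
            return json.load(fh)
        return yaml.safe_load(fh)


def dump_config_file(cfg: dict, path) -> None:
    suffix = Path(path).suffix.lower()
    with open(path, "w") as fh:
        if suffix == ".json":
            json.dump(cfg, fh, indent=2, sort_keys=True)
        else:
            yaml.safe_dump(cfg, fh, sort_keys=True)
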