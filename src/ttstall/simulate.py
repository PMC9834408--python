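"""Synthetic data generator for the nascent/steady-state pipeline.

The generator emulates the joint study design the pipeline assumes:

* a synthetic chromosome of non-overlapping genes on both strands;
* per-gene latent transcription parameters — synthesis rate kappa,
  degradation rate delta and a TSS-pausing fraction pi — with disjoint
  gene classes whose parameters change between conditions (transcription
  fold on kappa, stability fold on delta, pausing fold on the odds of pi,
  so pi stays inside (0, 1) for any fold);
* negative-binomial fragment counts with mean mu and dispersion alpha
  (Var = mu + alpha mu^2; alpha = 0 falls back to Poisson). The nascent
  (TT) arm sees kappa split between TSS window and gene body by pi; the
  steady-state (RNA) arm sees kappa/delta;
* a per-sample capture efficiency c_j that multiplies genes and spike-ins
  identically — the assumption spike-in normalization exploits;
* assay-matched spike-in species: a labeled synthetic set for the TT arm
  (three of six species 4sU-labeled, mirroring an in vitro transcribed
  ERCC-derived mix) and an unlabeled whole-transcriptome-like pool for the
  RNA arm;
* fragment intervals placed uniformly inside their generating region, with
  optional boundary-straddling and intergenic fragments whose true
  categories are recorded for oracle tests;
* noisy 1:1 binding titration curves for the anisotropy fitter.

Everything is deterministic given ``SimConfig.seed``; independent RNG
streams per stage keep each generator's draws stable under composition
(fragment placement never perturbs the count draws).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .binding import fraction_bound

CHROM = "chrSim"

# RNG stream tags (mixed with the config seed) so each stage draws from an
# independent, reproducible stream.
_STREAM_GENES = 1
_STREAM_TRUTH = 2
_STREAM_SAMPLES = 3
_STREAM_COUNTS = 4
_STREAM_FRAGMENTS = 5


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SpikeSpec:
    """One spike-in species: id, 4sU-labeled flag, relative abundance, assay."""

    species: str
    labeled: bool
    abundance: float
    assay: str = "TT"

    def __post_init__(self) -> None:
        if self.abundance <= 0:
            raise ConfigurationError(
                f"spike-in {self.species}: abundance must be > 0"
            )
        if self.assay not in ("TT", "RNA", "both"):
            raise ConfigurationError(
                f"spike-in {self.species}: assay must be TT, RNA or both"
            )


def default_spikein_spec() -> list[SpikeSpec]:
    """Six synthetic species (three labeled) for the TT arm and an
    unlabeled whole-transcriptome-like pool (20 species) for the RNA arm.

    The RNA pool is spread over many species because the real spike is a
    whole foreign transcriptome: its aggregate count has far smaller
    relative noise than any single transcript."""
    tt = [
        SpikeSpec("syn-00043", True, 500.0, "TT"),
        SpikeSpec("syn-00170", False, 500.0, "TT"),
        SpikeSpec("syn-00136", True, 500.0, "TT"),
        SpikeSpec("syn-00145", False, 500.0, "TT"),
        SpikeSpec("syn-00092", True, 500.0, "TT"),
        SpikeSpec("syn-00002", False, 500.0, "TT"),
    ]
    rna = [
        SpikeSpec(f"dmel-{i:02d}", False, 500.0, "RNA") for i in range(1, 21)
    ]
    return tt + rna


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic generator.

    Defaults describe a scaled two-condition three-replicate design:
    2000 genes of 1–20 kb, about 10^6 gene-derived fragments per sample,
    NB dispersion 0.05, 10% of genes per effect class with 2-fold effects
    (transcription halved, degradation doubled, pausing odds doubled), and
    per-sample capture efficiencies spanning 0.5–2.
    """

    n_genes: int = 2000
    gene_length_range: tuple[int, int] = (1000, 20000)
    gene_spacing: int = 1000
    n_replicates: int = 3
    conditions: tuple[str, ...] = ("WT", "KO")
    depth: float = 1_000_000.0
    capture_range: tuple[float, float] = (0.5, 2.0)
    dispersion: float = 0.05
    spike_dispersion: float = 0.005
    frac_txn_change: float = 0.1
    frac_stab_change: float = 0.1
    frac_pause_change: float = 0.1
    effect_txn: float = 0.5
    effect_stab: float = 2.0
    effect_pause: float = 2.0
    pi_range: tuple[float, float] = (0.1, 0.5)
    kappa_logmean: float = math.log(10.0)
    kappa_logsd: float = 1.0
    delta_logmean: float = 0.0
    delta_logsd: float = 0.5
    spikein_spec: list[SpikeSpec] = field(default_factory=default_spikein_spec)
    fragment_length: int = 150
    flank: int = 250
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.gene_length_range
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        if lo < 1 or lo > hi:
            raise ConfigurationError(
                f"invalid gene_length_range ({lo}, {hi}): need 1 <= min <= max"
            )
        if self.gene_spacing < 1:
            raise ConfigurationError("gene_spacing must be >= 1")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")
        if len(self.conditions) < 1:
            raise ConfigurationError("at least one condition (reference first)")
        if len(set(self.conditions)) != len(self.conditions):
            raise ConfigurationError("condition labels must be unique")
        if self.depth <= 0:
            raise ConfigurationError("depth must be > 0")
        clo, chi = self.capture_range
        if clo <= 0 or clo > chi:
            raise ConfigurationError("capture_range must be positive with min <= max")
        if self.dispersion < 0:
            raise ConfigurationError(f"dispersion must be >= 0, got {self.dispersion}")
        if self.spike_dispersion < 0:
            raise ConfigurationError(
                f"spike_dispersion must be >= 0, got {self.spike_dispersion}"
            )
        fracs = (self.frac_txn_change, self.frac_stab_change, self.frac_pause_change)
        if any(f < 0 or f > 1 for f in fracs):
            raise ConfigurationError("effect-class fractions must lie in [0, 1]")
        if sum(fracs) > 1 + 1e-12:
            raise ConfigurationError(
                f"effect-class fractions sum to {sum(fracs)} > 1; classes are disjoint"
            )
        for name, eff in (
            ("effect_txn", self.effect_txn),
            ("effect_stab", self.effect_stab),
            ("effect_pause", self.effect_pause),
        ):
            if eff <= 0:
                raise ConfigurationError(f"{name} must be > 0, got {eff}")
        plo, phi = self.pi_range
        if not (0 < plo <= phi < 1):
            raise ConfigurationError("pi_range must lie strictly inside (0, 1)")
        if self.fragment_length < 1:
            raise ConfigurationError("fragment_length must be >= 1")

    @property
    def reference(self) -> str:
        return self.conditions[0]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["spikein_spec"] = [asdict(s) for s in self.spikein_spec]
        return d


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(cfg.seed), stream])


# ---------------------------------------------------------------------------
# genes and truth


def generate_genes(cfg: SimConfig) -> pd.DataFrame:
    """Non-overlapping genes on a synthetic chromosome, both strands.

    Lengths are uniform in ``gene_length_range``; genes are laid end to end
    separated by ``gene_spacing`` bp, offset from 0 so upstream TSS windows
    never need clipping. Deterministic given the seed.
    """
    rng = _rng(cfg, _STREAM_GENES)
    lo, hi = cfg.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=cfg.n_genes)
    strands = rng.choice(["+", "-"], size=cfg.n_genes)
    if cfg.n_genes >= 2 and len(set(strands)) == 1:
        strands[-1] = "+" if strands[0] == "-" else "-"
    offset = cfg.flank + cfg.gene_spacing
    starts = offset + np.concatenate(
        [[0], np.cumsum(lengths[:-1] + cfg.gene_spacing)]
    )
    return pd.DataFrame(
        {
            "gene_id": [f"g{i:05d}" for i in range(cfg.n_genes)],
            "chrom": CHROM,
            "start": starts.astype(np.int64),
            "end": (starts + lengths).astype(np.int64),
            "strand": strands,
        }
    )


def generate_truth(genes: pd.DataFrame, cfg: SimConfig) -> pd.DataFrame:
    """Latent per-gene parameters and effect classes.

    Base rates: kappa lognormal, delta lognormal, pi uniform in
    ``pi_range``. Disjoint random gene subsets of sizes
    round(frac * n_genes) form the txn/stab/pause classes; every
    non-reference condition multiplies kappa by ``effect_txn`` (txn class),
    delta by ``effect_stab`` (stab class) and the pausing odds
    pi/(1 - pi) by ``effect_pause`` (pause class). The reference condition
    always carries the base parameters.
    """
    rng = _rng(cfg, _STREAM_TRUTH)
    n = len(genes)
    kappa = rng.lognormal(cfg.kappa_logmean, cfg.kappa_logsd, size=n)
    delta = rng.lognormal(cfg.delta_logmean, cfg.delta_logsd, size=n)
    pi = rng.uniform(cfg.pi_range[0], cfg.pi_range[1], size=n)

    n_txn = round(cfg.frac_txn_change * n)
    n_stab = round(cfg.frac_stab_change * n)
    n_pause = round(cfg.frac_pause_change * n)
    if n_txn + n_stab + n_pause > n:
        raise ConfigurationError("effect-class sizes exceed the number of genes")
    perm = rng.permutation(n)
    classes = np.array(["none"] * n, dtype=object)
    classes[perm[:n_txn]] = "txn"
    classes[perm[n_txn : n_txn + n_stab]] = "stab"
    classes[perm[n_txn + n_stab : n_txn + n_stab + n_pause]] = "pause"

    truth = pd.DataFrame(
        {"effect_class": classes}, index=pd.Index(genes["gene_id"], name="gene_id")
    )
    for ci, cond in enumerate(cfg.conditions):
        k, d, p = kappa.copy(), delta.copy(), pi.copy()
        if ci > 0:
            k[classes == "txn"] *= cfg.effect_txn
            d[classes == "stab"] *= cfg.effect_stab
            odds = p / (1.0 - p)
            odds[classes == "pause"] *= cfg.effect_pause
            p = np.where(classes == "pause", odds / (1.0 + odds), p)
        truth[f"kappa_{cond}"] = k
        truth[f"delta_{cond}"] = d
        truth[f"pi_{cond}"] = p
    return truth


# ---------------------------------------------------------------------------
# samples and counts


def make_samples(truth: pd.DataFrame, cfg: SimConfig) -> pd.DataFrame:
    """Sample sheet for both assays: TT and RNA x condition x replicate.

    The depth scalar d_j is chosen so that at capture 1 the expected total
    gene-derived fragment count of a reference-condition sample equals
    ``cfg.depth`` (per assay); capture efficiencies c_j are uniform in
    ``capture_range``. Condition-level global shifts therefore show up as
    genuine depth differences that only spike-ins can reveal.
    """
    rng = _rng(cfg, _STREAM_SAMPLES)
    ref = cfg.reference
    d_tt = cfg.depth / float(truth[f"kappa_{ref}"].sum())
    d_rna = cfg.depth / float((truth[f"kappa_{ref}"] / truth[f"delta_{ref}"]).sum())
    rows = []
    for assay, d in (("TT", d_tt), ("RNA", d_rna)):
        for cond in cfg.conditions:
            for rep in range(1, cfg.n_replicates + 1):
                rows.append(
                    {
                        "sample_id": f"{assay}_{cond}_rep{rep}",
                        "assay": assay,
                        "condition": cond,
                        "replicate": rep,
                        "capture": float(
                            rng.uniform(cfg.capture_range[0], cfg.capture_range[1])
                        ),
                        "depth_scalar": d,
                    }
                )
    return pd.DataFrame(rows).set_index("sample_id")


@dataclass
class CountBundle:
    """Gene x sample count matrices per assay plus spike-in counts.

    ``tss``/``body`` cover the TT samples, ``gene`` the RNA samples;
    ``spike_tt``/``spike_rna`` are species x sample tables with a boolean
    ``labeled`` column first. ``samples`` is the generating sample sheet.
    """

    tss: pd.DataFrame
    body: pd.DataFrame
    gene: pd.DataFrame
    spike_tt: pd.DataFrame
    spike_rna: pd.DataFrame
    samples: pd.DataFrame


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    if alpha == 0:
        return rng.poisson(mean)
    size = 1.0 / alpha
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def _mean_matrices(truth: pd.DataFrame, samples: pd.DataFrame, cfg: SimConfig):
    """Analytic NB means for every observable, keyed like CountBundle."""
    tt = samples[samples["assay"] == "TT"]
    rna = samples[samples["assay"] == "RNA"]
    tss_mu, body_mu, gene_mu = {}, {}, {}
    for sid, row in tt.iterrows():
        scale = row["depth_scalar"] * row["capture"]
        kappa = truth[f"kappa_{row['condition']}"]
        pi = truth[f"pi_{row['condition']}"]
        tss_mu[sid] = scale * kappa * pi
        body_mu[sid] = scale * kappa * (1.0 - pi)
    for sid, row in rna.iterrows():
        scale = row["depth_scalar"] * row["capture"]
        gene_mu[sid] = (
            scale * truth[f"kappa_{row['condition']}"] / truth[f"delta_{row['condition']}"]
        )
    spike_mu = {"TT": {}, "RNA": {}}
    for assay, subset in (("TT", tt), ("RNA", rna)):
        species = [sp for sp in cfg.spikein_spec if sp.assay in (assay, "both")]
        for sid, row in subset.iterrows():
            scale = row["depth_scalar"] * row["capture"]
            spike_mu[assay][sid] = pd.Series(
                {sp.species: scale * sp.abundance for sp in species}
            )
    return tss_mu, body_mu, gene_mu, spike_mu


def _spike_frame(cfg: SimConfig, assay: str, columns: dict) -> pd.DataFrame:
    species = [sp for sp in cfg.spikein_spec if sp.assay in (assay, "both")]
    df = pd.DataFrame(
        {"labeled": [sp.labeled for sp in species]},
        index=pd.Index([sp.species for sp in species], name="species"),
    )
    for sid, col in columns.items():
        df[sid] = col.reindex(df.index)
    return df


def expected_counts(
    truth: pd.DataFrame, samples: pd.DataFrame, cfg: SimConfig
) -> CountBundle:
    """The analytic mean of every count the generator would draw.

    Useful as a noise-free observable: applying the pipeline to these means
    isolates systematic behaviour (e.g. that spike-in size factors cancel
    capture efficiency exactly) from sampling noise.
    """
    tss_mu, body_mu, gene_mu, spike_mu = _mean_matrices(truth, samples, cfg)
    idx = truth.index
    return CountBundle(
        tss=pd.DataFrame(tss_mu, index=idx),
        body=pd.DataFrame(body_mu, index=idx),
        gene=pd.DataFrame(gene_mu, index=idx),
        spike_tt=_spike_frame(cfg, "TT", spike_mu["TT"]),
        spike_rna=_spike_frame(cfg, "RNA", spike_mu["RNA"]),
        samples=samples,
    )


def simulate_counts(
    truth: pd.DataFrame, samples: pd.DataFrame, cfg: SimConfig
) -> CountBundle:
    """Draw NB counts for every observable of the study design.

    For TT sample j and gene g with m = d_j c_j kappa_g: TSS ~ NB(m pi_g,
    alpha), body ~ NB(m (1 - pi_g), alpha); for RNA samples the gene count
    is NB(d_j c_j kappa_g / delta_g, alpha); spike-in species i draws
    NB(d_j c_j a_i, spike_dispersion) in every sample of its assay — spike
    material is purified exogenous RNA, so it carries technical noise only,
    not the biological dispersion of the genes. Deterministic given the
    seed and independent of whether fragments are also simulated.
    """
    rng = _rng(cfg, _STREAM_COUNTS)
    alpha = cfg.dispersion
    tss_mu, body_mu, gene_mu, spike_mu = _mean_matrices(truth, samples, cfg)
    idx = truth.index
    tss = {s: _nb_draw(rng, mu.to_numpy(), alpha) for s, mu in tss_mu.items()}
    body = {s: _nb_draw(rng, mu.to_numpy(), alpha) for s, mu in body_mu.items()}
    gene = {s: _nb_draw(rng, mu.to_numpy(), alpha) for s, mu in gene_mu.items()}
    spikes = {
        assay: {
            s: pd.Series(
                _nb_draw(rng, mu.to_numpy(), cfg.spike_dispersion), index=mu.index
            )
            for s, mu in cols.items()
        }
        for assay, cols in spike_mu.items()
    }
    return CountBundle(
        tss=pd.DataFrame(tss, index=idx),
        body=pd.DataFrame(body, index=idx),
        gene=pd.DataFrame(gene, index=idx),
        spike_tt=_spike_frame(cfg, "TT", spikes["TT"]),
        spike_rna=_spike_frame(cfg, "RNA", spikes["RNA"]),
        samples=samples,
    )


# ---------------------------------------------------------------------------
# fragments


def _place_uniform(
    rng: np.random.Generator, n: int, region_start: int, region_end: int, frag_len: int
):
    """n fragment intervals fully inside [region_start, region_end)."""
    width = region_end - region_start
    L = min(frag_len, width)
    starts = rng.integers(region_start, region_end - L + 1, size=n)
    return starts, starts + L


def simulate_fragments(
    genes: pd.DataFrame,
    truth: pd.DataFrame,
    samples: pd.DataFrame,
    cfg: SimConfig,
    straddler_rate: float = 0.0,
    intergenic_rate: float = 0.0,
) -> tuple[pd.DataFrame, CountBundle]:
    """Fragment intervals realising the count draws of :func:`simulate_counts`.

    The region counts are the *same* draws as ``simulate_counts`` under the
    same config (shared RNG stream), so quantifying the emitted fragments
    reproduces the count matrices exactly when ``straddler_rate`` and
    ``intergenic_rate`` are 0. ``straddler_rate`` is the expected number of
    extra TSS/body-boundary-spanning fragments per (gene, TT sample);
    ``intergenic_rate`` the expected number of fragments per sample placed
    in the gaps between genes. True categories are recorded in a
    ``category`` column (TSS, BODY, GENE, STRADDLE, INTERGENIC) for oracle
    tests.

    Returns ``(fragments, counts)`` with fragments as a BED-like DataFrame
    (chrom, start, end, sample, strand, category).
    """
    if cfg.fragment_length < 1:
        raise ConfigurationError("fragment_length must be >= 1")
    if straddler_rate < 0 or intergenic_rate < 0:
        raise ConfigurationError("straddler/intergenic rates must be >= 0")
    from .regions import GeneModel, derive_region_pair

    counts = simulate_counts(truth, samples, cfg)
    rng = _rng(cfg, _STREAM_FRAGMENTS)
    L = cfg.fragment_length
    pairs = {
        rec.gene_id: derive_region_pair(
            GeneModel(rec.gene_id, rec.chrom, int(rec.start), int(rec.end), rec.strand),
            flank=cfg.flank,
        )
        for rec in genes.itertuples(index=False)
    }
    strand_of = dict(zip(genes["gene_id"], genes["strand"]))

    chunks: list[pd.DataFrame] = []

    def emit(n, start, end, sample, strand, category):
        if n == 0:
            return
        chunks.append(
            pd.DataFrame(
                {
                    "chrom": CHROM,
                    "start": start,
                    "end": end,
                    "sample": sample,
                    "strand": strand,
                    "category": category,
                }
            )
        )

    tt_samples = [s for s in counts.tss.columns]
    for sid in tt_samples:
        for gid in counts.tss.index:
            pair = pairs[gid]
            strand = strand_of[gid]
            n_t = int(counts.tss.loc[gid, sid])
            n_b = int(counts.body.loc[gid, sid])
            if n_t:
                s0, s1 = _place_uniform(rng, n_t, pair.tss_start, pair.tss_end, L)
                emit(n_t, s0, s1, sid, strand, "TSS")
            if n_b:
                s0, s1 = _place_uniform(rng, n_b, pair.body_start, pair.body_end, L)
                emit(n_b, s0, s1, sid, strand, "BODY")
            if straddler_rate > 0:
                n_s = int(rng.poisson(straddler_rate))
                if n_s:
                    # boundary coordinate shared by TSS window and body
                    b = pair.body_start if strand == "+" else pair.tss_start
                    Ls = max(L, 2)
                    starts = rng.integers(b - Ls + 1, b, size=n_s)
                    emit(n_s, starts, starts + Ls, sid, strand, "STRADDLE")
    coords = {
        rec.gene_id: (int(rec.start), int(rec.end))
        for rec in genes.itertuples(index=False)
    }
    for sid in counts.gene.columns:
        for gid in counts.gene.index:
            n_g = int(counts.gene.loc[gid, sid])
            if n_g:
                g0, g1 = coords[gid]
                s0, s1 = _place_uniform(rng, n_g, g0, g1, L)
                emit(n_g, s0, s1, sid, strand_of[gid], "GENE")

    if intergenic_rate > 0:
        gaps = _intergenic_gaps(genes, pairs, L)
        if gaps:
            gap_starts = np.array([g[0] for g in gaps])
            gap_sizes = np.array([g[1] - g[0] - L + 1 for g in gaps])
            weights = gap_sizes / gap_sizes.sum()
            for sid in samples.index:
                n_i = int(rng.poisson(intergenic_rate))
                if n_i:
                    gi = rng.choice(len(gaps), size=n_i, p=weights)
                    offs = rng.integers(0, gap_sizes[gi])
                    starts = gap_starts[gi] + offs
                    emit(
                        n_i,
                        starts,
                        starts + L,
                        sid,
                        rng.choice(["+", "-"], size=n_i),
                        "INTERGENIC",
                    )

    if chunks:
        frags = pd.concat(chunks, ignore_index=True)
    else:
        frags = pd.DataFrame(
            columns=["chrom", "start", "end", "sample", "strand", "category"]
        )
    frags["start"] = frags["start"].astype(np.int64)
    frags["end"] = frags["end"].astype(np.int64)
    return frags, counts


def _intergenic_gaps(genes: pd.DataFrame, pairs: dict, frag_len: int):
    """Gaps that overlap no gene and no TSS window, wide enough for a fragment."""
    forbidden = []
    for rec in genes.itertuples(index=False):
        pair = pairs[rec.gene_id]
        lo = min(int(rec.start), pair.tss_start, pair.body_start)
        hi = max(int(rec.end), pair.tss_end, pair.body_end)
        forbidden.append((lo, hi))
    forbidden.sort()
    gaps = []
    cursor = 0
    for lo, hi in forbidden:
        if lo - cursor >= frag_len:
            gaps.append((cursor, lo))
        cursor = max(cursor, hi)
    gaps.append((cursor + 1, cursor + 1 + 10 * frag_len))
    return gaps


# ---------------------------------------------------------------------------
# titrations


def simulate_titration(
    kd: float,
    r_free: float,
    r_bound: float,
    conc_grid: np.ndarray,
    ligand_nM: float = 90.0,
    noise_sd: float = 0.0,
    n_reps: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Noisy 1:1 anisotropy titration series sharing one protein grid.

    anisotropy = r_free + (r_bound - r_free) * fraction_bound(P, L, Kd)
    + N(0, noise_sd). ``kd`` and ``conc_grid`` in µM, ligand in nM.
    """
    conc = np.asarray(conc_grid, dtype=float)
    if not (kd > 0):
        raise ConfigurationError(f"kd must be > 0, got {kd}")
    if r_bound < r_free:
        raise ConfigurationError("r_bound must be >= r_free")
    if np.any(conc < 0):
        raise ValueError("protein concentrations must be non-negative")
    if np.any(np.diff(conc) <= 0):
        raise ValueError("concentration grid must be strictly ascending")
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be >= 0")
    L = float(ligand_nM) / 1000.0
    rng = np.random.default_rng([int(seed), 6])
    clean = r_free + (r_bound - r_free) * fraction_bound(conc, L, kd)
    rows = []
    for rep in range(1, n_reps + 1):
        noisy = clean + rng.normal(0.0, noise_sd, size=len(conc)) if noise_sd else clean
        rows.append(
            pd.DataFrame(
                {
                    "replicate": rep,
                    "protein_conc_uM": conc,
                    "anisotropy": noisy,
                }
            )
        )
    out = pd.concat(rows, ignore_index=True)
    out.attrs["ligand_nM"] = float(ligand_nM)
    return out
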