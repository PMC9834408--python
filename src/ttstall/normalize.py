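"""Spike-in size factors and the low-count gene filter.

Both assays are normalized against exogenous spike-in material rather than
endogenous genes, because genome-wide expression shifts are expected and
median-of-ratios style normalization would absorb them. The steady-state
(RNA-seq) arm uses the total count over the unlabeled spike-in pool (a
Drosophila-like whole-transcriptome spike); the nascent (TT-seq) arm uses
the median count over the 4sU-labeled synthetic spike-in species, since
only labeled species pass the biotin enrichment the way nascent RNA does.

Size factors are rescaled to geometric mean 1 so normalized counts remain
on a counts-like scale; dividing raw counts by the size factor scales a
sample with higher spike-in recovery down.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DEFAULT_LOW_COUNT_THRESHOLD = 5

#: Non-sample columns allowed in a spike-in count table.
SPIKE_META_COLUMNS = ("labeled",)


def _sample_columns(spike: pd.DataFrame) -> list[str]:
    return [c for c in spike.columns if c not in SPIKE_META_COLUMNS]


def _geo_normalize(raw: pd.Series) -> pd.Series:
    log = np.log(raw.to_numpy(dtype=float))
    s = raw / np.exp(log.mean())
    s.name = "size_factor"
    return s


def size_factors_rna(spike: pd.DataFrame) -> pd.Series:
    """Size factors from the total spike-in count per sample.

    ``spike`` is indexed by species with a boolean ``labeled`` column and one
    column per sample. Raw factor r_j is the sample's total spike-in count;
    the returned s_j = r_j / geomean(r) has geometric mean 1.
    """
    samples = _sample_columns(spike)
    totals = spike[samples].sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(
            f"zero total spike-in count in sample(s): {list(zero.index)}"
        )
    return _geo_normalize(totals.astype(float))


def size_factors_tt(spike: pd.DataFrame) -> pd.Series:
    """Size factors from the median count over labeled spike-in species.

    Only 4sU-labeled species survive the biotin enrichment step of the
    nascent-RNA protocol, so the nascent arm is anchored on them: raw factor
    r_j = median over labeled species of count(species, j), rescaled to
    geometric mean 1. Unlabeled species never influence the result.
    """
    if "labeled" not in spike.columns:
        raise ValueError("spike-in table lacks a 'labeled' column")
    labeled = spike.loc[spike["labeled"].astype(bool)]
    if labeled.empty:
        raise ValueError("no labeled spike-in species; cannot normalize the TT arm")
    samples = _sample_columns(spike)
    medians = labeled[samples].median(axis=0)
    zero = medians[medians <= 0]
    if len(zero):
        raise ValueError(
            f"non-positive labeled spike-in median in sample(s): {list(zero.index)}"
        )
    return _geo_normalize(medians.astype(float))


def apply_size_factors(counts: pd.DataFrame, s: pd.Series) -> pd.DataFrame:
    """Divide each sample column by its size factor (counts -> normalized)."""
    missing = set(counts.columns) - set(s.index)
    if missing:
        raise ValueError(f"no size factor for sample(s): {sorted(missing)}")
    return counts / s.reindex(counts.columns)


def low_count_filter(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    threshold: int = DEFAULT_LOW_COUNT_THRESHOLD,
) -> pd.DataFrame:
    """Flag genes with fewer than ``threshold`` raw reads in every replicate
    of at least one condition.

    Operates on raw, pre-normalization counts (filtering precedes the
    differential analysis). ``design`` maps sample ids (index) to a
    ``condition`` column. Returns a DataFrame indexed like ``counts`` with a
    boolean ``keep`` column and a ``trigger_condition`` column naming the
    first condition whose replicates were all below threshold (empty string
    if kept).
    """
    conditions = design["condition"].unique()
    keep = pd.Series(True, index=counts.index)
    trigger = pd.Series("", index=counts.index)
    for cond in conditions:
        cond_samples = design.index[design["condition"] == cond]
        cond_samples = [s for s in cond_samples if s in counts.columns]
        if not cond_samples:
            raise ValueError(f"condition {cond!r} has no samples in the count table")
        all_below = (counts[cond_samples] < threshold).all(axis=1)
        newly = all_below & keep
        trigger[newly] = cond
        keep &= ~all_below
    return pd.DataFrame({"keep": keep, "trigger_condition": trigger})
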