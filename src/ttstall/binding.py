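"""Equilibrium binding quantification: anisotropy Kd fits and ChIP-qPCR %input.

Fluorescence anisotropy titrations track the bound fraction of a
fluorophore-labeled peptide (the ligand, held at a fixed low concentration,
typically 90 nM) as the protein domain is titrated. The model is the exact
1:1 binding isotherm from mass balance — the physically correct root of

    Kd = (P - LB)(L - LB) / LB,

for bound complex LB, which keeps ligand depletion exact. The hyperbolic
approximation f = P / (P + Kd) is only the L << Kd limit; for the tightest
interactions measured here (Kd a few-fold above the 90 nM ligand) depletion
is not negligible, so the quadratic form is the default and only model.

All concentrations are handled in µM internally; ligand inputs in nM are
converted on entry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

DEFAULT_LIGAND_NM = 90.0
MIN_POINTS = 5


def fraction_bound(P, L, Kd):
    """Exact 1:1 ligand-bound fraction at total protein P, total ligand L.

    f = ((L + P + Kd) - sqrt((L + P + Kd)^2 - 4 L P)) / (2 L), the root of
    the mass-balance quadratic that lies in [0, 1]. All concentrations in
    the same unit (µM by convention); for L << Kd this approaches
    P / (P + Kd).
    """
    P = np.asarray(P, dtype=float)
    if np.any(P < 0):
        raise ValueError("protein concentrations must be >= 0")
    if not (Kd > 0):
        raise ValueError(f"Kd must be > 0, got {Kd}")
    if not (L > 0):
        raise ValueError(f"ligand concentration must be > 0, got {L}")
    b = L + P + Kd
    disc = b * b - 4.0 * L * P
    f = (b - np.sqrt(np.maximum(disc, 0.0))) / (2.0 * L)
    return np.clip(f, 0.0, 1.0)


def anisotropy_model(P, Kd, r_free, r_bound, L):
    """Observed anisotropy for a 1:1 isotherm: r_free + span * fraction bound."""
    return r_free + (r_bound - r_free) * fraction_bound(P, L, Kd)


@dataclass
class BindingFit:
    """Result of fitting a set of replicate titration series.

    ``kd_mean``/``kd_sd`` summarise the per-replicate fits (the reporting
    convention for independent dilution series); ``kd_pooled`` is a single
    fit over all points. ``converged`` is False for degenerate (flat) or
    non-convergent data, in which case no Kd is reported.
    """

    ligand_uM: float
    kd_mean: float | None = None
    kd_sd: float | None = None
    kd_pooled: float | None = None
    r_free: float | None = None
    r_bound: float | None = None
    kd_se: float | None = None
    r_free_se: float | None = None
    r_bound_se: float | None = None
    converged: bool = False
    flag: str = ""
    replicate_kds: list = field(default_factory=list)


def _fit_single(P: np.ndarray, r: np.ndarray, L: float):
    """Fit (Kd, r_free, r_bound) to one series; returns (params, ses)."""
    if len(P) < MIN_POINTS:
        raise ValueError(f"need >= {MIN_POINTS} points per series, got {len(P)}")
    if np.any(np.diff(P) <= 0):
        raise ValueError("protein concentration grid must be strictly ascending")
    if np.any(P < 0):
        raise ValueError("protein concentrations must be >= 0")
    span = np.ptp(r)
    if span <= 1e-12 * max(1.0, float(np.abs(r).max())):
        raise _FlatSeries
    r_free0, r_bound0 = float(r.min()), float(r.max())
    half = r_free0 + 0.5 * span
    kd0 = float(np.interp(half, r, P)) if r[-1] > r[0] else float(np.median(P))
    kd0 = max(kd0, 1e-6)
    last_err: Exception | None = None
    for factor in (1.0, 0.1, 10.0, 0.01, 100.0):
        try:
            popt, pcov = curve_fit(
                lambda x, kd, rf, rb: anisotropy_model(x, kd, rf, rb, L),
                P,
                r,
                p0=(kd0 * factor, r_free0, r_bound0),
                bounds=([1e-12, -np.inf, -np.inf], [np.inf, np.inf, np.inf]),
                maxfev=20000,
            )
            ses = np.sqrt(np.diag(pcov))
            return popt, ses
        except (RuntimeError, ValueError) as err:  # non-convergence; retry
            last_err = err
    raise RuntimeError(f"Kd fit did not converge after restarts: {last_err}")


class _FlatSeries(Exception):
    pass


def fit_kd(series: pd.DataFrame, ligand_nM: float = DEFAULT_LIGAND_NM) -> BindingFit:
    """Fit the 1:1 isotherm to replicate titration series.

    ``series`` has columns ``replicate, protein_conc_uM, anisotropy``. Each
    replicate is fitted separately (Kd reported as mean ± sd across
    replicates) and a pooled fit over all points is reported alongside.
    Flat (non-identifiable) or non-convergent data yield a flagged fit with
    no Kd rather than a silent fallback.
    """
    L = float(ligand_nM) / 1000.0
    fit = BindingFit(ligand_uM=L)
    rep_kds = []
    try:
        for _rep, grp in series.groupby("replicate"):
            # grid validated in input order: a non-monotone series is an error
            popt, _ = _fit_single(
                grp["protein_conc_uM"].to_numpy(dtype=float),
                grp["anisotropy"].to_numpy(dtype=float),
                L,
            )
            rep_kds.append(float(popt[0]))
        # pooled fit over all points; concentrations repeat across
        # replicates so the ascending-grid check applies per replicate only
        pooled = series.sort_values("protein_conc_uM")
        P = pooled["protein_conc_uM"].to_numpy(dtype=float)
        r = pooled["anisotropy"].to_numpy(dtype=float)
        if np.ptp(r) <= 1e-12 * max(1.0, float(np.abs(r).max())):
            raise _FlatSeries
        popt, pcov = curve_fit(
            lambda x, kd, rf, rb: anisotropy_model(x, kd, rf, rb, L),
            P,
            r,
            p0=(float(np.mean(rep_kds)), float(r.min()), float(r.max())),
            bounds=([1e-12, -np.inf, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except _FlatSeries:
        fit.flag = "non-identifiable: flat anisotropy series"
        return fit
    except RuntimeError as err:
        fit.flag = f"non-convergent: {err}"
        return fit
    fit.replicate_kds = rep_kds
    fit.kd_mean = float(np.mean(rep_kds))
    fit.kd_sd = float(np.std(rep_kds, ddof=1)) if len(rep_kds) > 1 else 0.0
    fit.kd_pooled = float(popt[0])
    fit.r_free = float(popt[1])
    fit.r_bound = float(popt[2])
    ses = np.sqrt(np.diag(pcov))
    fit.kd_se, fit.r_free_se, fit.r_bound_se = (float(x) for x in ses)
    fit.converged = True
    if fit.r_bound < fit.r_free:
        fit.flag = "decreasing anisotropy: r_bound < r_free"
    return fit


def build_affinity_matrix(fits: dict, neg_log10_molar: bool = False) -> pd.DataFrame:
    """Assemble a domain x peptide Kd matrix from labelled fits.

    ``fits`` maps (domain, peptide) to a :class:`BindingFit`. Non-binders
    (flagged / non-converged fits) yield missing cells. With
    ``neg_log10_molar=True`` entries are -log10(Kd in M), so Kd = 1 µM maps
    to 6.0 and larger values mean tighter binding.
    """
    domains = sorted({d for d, _ in fits})
    peptides = sorted({p for _, p in fits})
    mat = pd.DataFrame(np.nan, index=domains, columns=peptides)
    for (dom, pep), fit in fits.items():
        if fit is None or not fit.converged:
            continue
        kd = fit.kd_mean
        mat.loc[dom, pep] = -np.log10(kd * 1e-6) if neg_log10_molar else kd
    mat.index.name = "domain"
    mat.columns.name = "peptide"
    return mat


def percent_input(cq_input: float, cq_chip: float, input_fraction: float) -> float:
    """ChIP-qPCR enrichment as percent of input chromatin.

    The input Cq is first adjusted to 100% of the chromatin
    (adjusted = Cq_input - log2(100 / input_fraction), where
    ``input_fraction`` is the percent of chromatin reserved as input);
    then %input = 100 * 2^(adjusted - Cq_chip). Each extra ChIP cycle
    halves the result.
    """
    if not (0 < input_fraction <= 100):
        raise ValueError(f"input_fraction must be in (0, 100], got {input_fraction}")
    if not (np.isfinite(cq_input) and np.isfinite(cq_chip)):
        raise ValueError("Cq values must be finite")
    adjusted = cq_input - np.log2(100.0 / input_fraction)
    return float(100.0 * 2.0 ** (adjusted - cq_chip))
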