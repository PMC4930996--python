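"""Variance decomposition of the isotopic niche.

Following the moment framework of Roughgarden and Bolnick, the total niche
width (TNW) of a population for one tissue x isotope splits into

    TNW = WIC + AIC

where WIC (within-individual component) is the unweighted average over
individuals of the variance of each individual's repeated measurements, and
AIC (among-individual component) is the variance of the per-individual mean
values.  The WIC/TNW ratio lies in [0, 1]; 1 is a true generalist population
and smaller values indicate stronger individual specialization.

The n vs n-1 variance denominator is a declared parameter
(``convention``): "population" (n) makes WIC + AIC equal the pooled variance
exactly on balanced designs (law of total variance); "sample" (n-1) is
available for comparability with software that defaults to it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from .types import Dataset, Isotope, Tissue

_DDOF = {"population": 0, "sample": 1}


def _per_individual(samples: pd.DataFrame, tissue: str, isotope: str) -> pd.core.groupby.SeriesGroupBy:
    sub = samples[samples["tissue"] == tissue]
    return sub.groupby("individual_id")[isotope]


def within_individual_component(
    ds: Dataset,
    tissue: Tissue | str,
    isotope: Isotope | str,
    convention: str = "population",
    min_samples: int = 2,
    on_few: str = "warn",
) -> float:
    """Mean over individuals of the per-individual isotope variance.

    Individuals with fewer than ``min_samples`` measurements of this tissue
    are dropped from this tissue's decomposition (``on_few="warn"``) or
    raise (``on_few="error"``).
    """
    tissue, isotope = Tissue(tissue).value, Isotope(isotope).value
    ddof = _DDOF[convention]
    groups = _per_individual(ds.samples, tissue, isotope)
    counts = groups.count()
    few = counts.index[counts < min_samples]
    if len(few):
        if on_few == "error":
            raise ValueError(
                f"{len(few)} individual(s) with < {min_samples} {tissue} samples: {list(few)[:5]}"
            )
        warnings.warn(
            f"excluding {len(few)} individual(s) with < {min_samples} {tissue} samples from WIC",
            stacklevel=2,
        )
    variances = groups.var(ddof=ddof)[counts >= min_samples]
    if variances.empty:
        raise ValueError(f"no individual with >= {min_samples} {tissue} samples")
    return float(variances.mean())


def among_individual_component(
    ds: Dataset,
    tissue: Tissue | str,
    isotope: Isotope | str,
    convention: str = "population",
) -> float:
    """Variance of the per-individual mean isotope values."""
    tissue, isotope = Tissue(tissue).value, Isotope(isotope).value
    means = _per_individual(ds.samples, tissue, isotope).mean()
    if len(means) < 2:
        raise ValueError(f"AIC undefined with {len(means)} individual(s); need >= 2")
    return float(means.var(ddof=_DDOF[convention]))


def total_niche_width(wic: float, aic_niche: float) -> float:
    """TNW = WIC + AIC (both in permil squared)."""
    if wic < 0 or aic_niche < 0:
        raise ValueError("variance components must be non-negative")
    return wic + aic_niche


def specialization_ratio(wic: float, tnw: float) -> float:
    """WIC/TNW in [0, 1]; decreases with increasing individual specialization."""
    if tnw <= 0:
        raise ValueError("WIC/TNW undefined for TNW <= 0")
    ratio = wic / tnw
    if not -1e-12 <= ratio <= 1 + 1e-12:
        raise ValueError(f"ratio {ratio} outside [0, 1]; inconsistent components")
    return min(max(ratio, 0.0), 1.0)


@dataclass
class NicheDecomposition:
    """WIC/AIC/TNW decomposition for one tissue x isotope.

    ``aic_niche`` is the among-individual component of the niche — named to
    avoid collision with the Akaike information criterion.
    """

    tissue: str
    isotope: str
    tnw: float
    wic: float
    aic_niche: float
    ratio: float
    n_individuals: int
    n_samples: int
    variance_convention: str


def decompose(
    ds: Dataset,
    tissue: Tissue | str,
    isotope: Isotope | str,
    convention: str = "population",
    min_samples: int = 2,
) -> NicheDecomposition:
    """Full WIC/AIC/TNW decomposition for one tissue x isotope."""
    tissue, isotope = Tissue(tissue).value, Isotope(isotope).value
    groups = _per_individual(ds.samples, tissue, isotope)
    counts = groups.count()
    used = counts[counts >= min_samples]
    wic = within_individual_component(ds, tissue, isotope, convention, min_samples)
    # AIC over the same individuals that enter WIC, so TNW is coherent
    sub = ds.samples[
        (ds.samples["tissue"] == tissue) & ds.samples["individual_id"].isin(used.index)
    ]
    means = sub.groupby("individual_id")[isotope].mean()
    if len(means) < 2:
        raise ValueError("need >= 2 individuals for a decomposition")
    aic = float(means.var(ddof=_DDOF[convention]))
    tnw = total_niche_width(wic, aic)
    return NicheDecomposition(
        tissue=tissue,
        isotope=isotope,
        tnw=tnw,
        wic=wic,
        aic_niche=aic,
        ratio=specialization_ratio(wic, tnw),
        n_individuals=int(len(used)),
        n_samples=int(used.sum()),
        variance_convention=convention,
    )


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (as tables are conventionally printed)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def niche_table(decomps: list[NicheDecomposition], ndigits: int = 2) -> pd.DataFrame:
    """Report table: rows TNW/WIC/AIC/WIC-TNW x columns tissue.isotope."""
    cols = {}
    foot_ind, foot_n = {}, {}
    for d in decomps:
        label = f"{d.tissue}.{d.isotope}"
        cols[label] = [
            round_half_up(d.tnw, ndigits),
            round_half_up(d.wic, ndigits),
            round_half_up(d.aic_niche, ndigits),
            round_half_up(d.ratio, ndigits),
        ]
        foot_ind[label] = d.n_individuals
        foot_n[label] = d.n_samples
    table = pd.DataFrame(cols, index=["TNW", "WIC", "AIC", "WIC/TNW"])
    table.loc["n_individuals"] = pd.Series(foot_ind)
    table.loc["n_samples"] = pd.Series(foot_n)
    return table


def write_niche_table(decomps: list[NicheDecomposition], path: str | Path) -> None:
    niche_table(decomps).to_csv(path, sep="\t")
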