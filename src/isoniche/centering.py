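"""Within-individual centering, standardization, and the two LMM sets.

Within-individual centering splits a covariate x_ij (individual j, year i)
into the individual's mean over its own observed years (the between/among-
individual effect, x_bar_j) and the per-observation deviation (the within-
individual effect, x_ij - x_bar_j).  Fitting both as separate fixed effects
separates phenotypic plasticity (within) from consistent among-individual
differences (between), the van de Pol & Wright decomposition.

Two model families are built on top of this:

* environment -> isotope: year-level environmental window means (SAM, SOI,
  SSTA) explaining tissue isotope values, with null / linear / quadratic
  fixed structures and crossed (bird identity x year) random intercepts;
* isotope -> breeding trait: red-blood-cell isotopes explaining body mass,
  clutch initiation date and total clutch mass, everything z-standardized
  within year first.

One environmental variable per model: the indices are mutually correlated,
so joint models are refused by design; pairwise correlations are reported
instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .lmm import (
    MixedModelFit,
    ModelSpec,
    RandomTerm,
    akaike_ic,
    fit_mixed_model,
    lrt_pvalue,
    r2_marginal_conditional,
)
from .types import Dataset, Isotope, Tissue

#: default two-month environmental windows per tissue (calendar months)
DEFAULT_WINDOWS = {Tissue.RED_BLOOD_CELL.value: (8, 9), Tissue.FEATHER.value: (2, 3)}


@dataclass
class CenteredDesign:
    """Within/between split of one covariate, aligned to an observation table."""

    covariate: str
    within: pd.Series
    between: pd.Series

    def reconstruct(self) -> pd.Series:
        return self.within + self.between


def center_within_individual(
    data: pd.DataFrame, covariate: str, individual_col: str = "individual_id"
) -> CenteredDesign:
    """Split ``covariate`` into within-individual and between-individual parts.

    The between part is the individual's mean over its observed rows only;
    single-observation individuals get within = 0.
    """
    between = data.groupby(individual_col)[covariate].transform("mean")
    within = data[covariate] - between
    return CenteredDesign(covariate=covariate, within=within, between=between)


def standardize_within_year(
    data: pd.DataFrame, column: str, year_col: str = "year"
) -> pd.Series:
    """z-score ``column`` within each year (sample, n-1, standard deviation)."""
    out = pd.Series(np.nan, index=data.index, dtype=float)
    for year, sub in data.groupby(year_col):
        vals = sub[column].astype(float)
        sd = vals.std(ddof=1)
        if len(vals) < 2 or vals.nunique() < 2 or not np.isfinite(sd) or sd == 0:
            raise ValueError(f"cannot z-standardize '{column}': constant stratum in year {year}")
        out.loc[sub.index] = (vals - vals.mean()) / sd
    return out


def env_window_mean(env: pd.DataFrame, index_name: str, year: int, months: tuple[int, ...]) -> float:
    """Mean of an environmental index over the given months of one year."""
    sub = env[(env["index_name"] == index_name) & (env["year"] == year)]
    vals = []
    for m in months:
        row = sub[sub["month"] == m]
        if row.empty:
            raise KeyError(f"missing environmental value ({index_name}, {year}, month {m})")
        vals.append(float(row["value"].iloc[0]))
    return float(np.mean(vals))


def env_year_series(
    env: pd.DataFrame, index_name: str, years: list[int], months: tuple[int, ...]
) -> pd.Series:
    """Window means for a set of years, indexed by year."""
    return pd.Series({y: env_window_mean(env, index_name, y, months) for y in years})


def env_window_correlations(
    env: pd.DataFrame, years: list[int], months: tuple[int, ...]
) -> pd.DataFrame:
    """Pairwise Pearson correlations between index window means (collinearity guard)."""
    indices = sorted(env["index_name"].unique())
    series = {ix: env_year_series(env, ix, years, months) for ix in indices}
    rows = []
    for i, a in enumerate(indices):
        for b in indices[i + 1 :]:
            r, p = stats.pearsonr(series[a], series[b])
            rows.append({"index_a": a, "index_b": b, "r": float(r), "p": float(p), "n": len(years)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# model sets


@dataclass
class ModelComparisonTable:
    """Rows (label, akaike_ic, delta_aic, r2_marginal, r2_conditional), AIC-sorted."""

    table: pd.DataFrame
    fits: dict[str, MixedModelFit]

    @classmethod
    def from_fits(
        cls, ml_fits: dict[str, MixedModelFit], reml_fits: dict[str, MixedModelFit]
    ) -> "ModelComparisonTable":
        rows = []
        for label, fit in ml_fits.items():
            try:
                ic = akaike_ic(fit)
            except ValueError:
                rows.append(
                    {"model": label, "akaike_ic": np.nan, "r2_marginal": np.nan,
                     "r2_conditional": np.nan, "converged": False}
                )
                continue
            rm, rc = r2_marginal_conditional(reml_fits[label])
            rows.append(
                {"model": label, "akaike_ic": ic, "r2_marginal": rm, "r2_conditional": rc,
                 "converged": fit.converged}
            )
        df = pd.DataFrame(rows).sort_values("akaike_ic", na_position="last").reset_index(drop=True)
        df.insert(2, "delta_aic", df["akaike_ic"] - df["akaike_ic"].iloc[0])
        return cls(table=df, fits=reml_fits)


def _fit_pair(data, response, fixed, random):
    """Fit the same structure by ML (for AIC) and REML (for R2)."""
    ml = fit_mixed_model(data, ModelSpec(response, tuple(fixed), tuple(random), "ML"))
    reml = fit_mixed_model(data, ModelSpec(response, tuple(fixed), tuple(random), "REML"))
    return ml, reml


def isotope_observation_table(
    ds: Dataset,
    tissue: Tissue | str,
    isotope: Isotope | str,
    env_name: str,
    months: tuple[int, ...] | None = None,
) -> pd.DataFrame:
    """Observation table for an environment model: isotope response plus the
    year-level environmental window mean, centered within individual."""
    tissue, isotope = Tissue(tissue).value, Isotope(isotope).value
    obs = ds.tissue_samples(tissue)[["individual_id", "year", isotope]].copy()
    obs = obs.rename(columns={isotope: "response"})
    months = months or DEFAULT_WINDOWS[tissue]
    years = sorted(obs["year"].unique())
    env_by_year = env_year_series(ds.env, env_name, years, months)
    obs["env"] = obs["year"].map(env_by_year)
    cd = center_within_individual(obs, "env")
    obs["env_within"] = cd.within
    obs["env_between"] = cd.between
    obs["env_within_sq"] = cd.within**2
    obs["env_between_sq"] = cd.between**2
    return obs.reset_index(drop=True)


_CROSSED = (RandomTerm("individual_id"), RandomTerm("year"))


def build_environment_model_set(
    ds: Dataset,
    tissue: Tissue | str,
    isotope: Isotope | str,
    env_name: str,
    quadratic: bool = True,
    months: tuple[int, ...] | None = None,
    include_null: bool = True,
) -> ModelComparisonTable:
    """Null / linear / quadratic models of one env index for one tissue x isotope.

    All models carry bird identity and year as independent (crossed) random
    intercepts.  AIC comes from ML fits; R2 from the matching REML fits.
    """
    obs = isotope_observation_table(ds, tissue, isotope, env_name, months)
    structures: dict[str, tuple[str, ...]] = {}
    if include_null:
        structures["null"] = ()
    structures[f"{env_name}_within+{env_name}_between"] = ("env_within", "env_between")
    if quadratic:
        structures[f"{env_name}_within+{env_name}_between+quadratic"] = (
            "env_within",
            "env_between",
            "env_within_sq",
            "env_between_sq",
        )
    ml_fits, reml_fits = {}, {}
    for label, fixed in structures.items():
        ml_fits[label], reml_fits[label] = _fit_pair(obs, "response", fixed, _CROSSED)
    return ModelComparisonTable.from_fits(ml_fits, reml_fits)


@dataclass
class GatedSlopeResult:
    """Outcome of the within-effect test and the gated random-slope stage."""

    within_p: float
    within_beta: float
    gate_alpha: float
    slopes_evaluated: bool
    slope_p: float | None = None
    slope_variance: float | None = None
    slope_delta_aic: float | None = None


def test_within_effect_then_slopes(
    obs: pd.DataFrame,
    response: str = "response",
    within: str = "env_within",
    between: str = "env_between",
    alpha: float = 0.05,
) -> GatedSlopeResult:
    """Two-stage validation of a within/between model.

    Stage 1: ML likelihood-ratio test of the within fixed effect (model with
    within + between vs between only).  Stage 2, only when stage 1 is
    significant at ``alpha``: add an individual random slope on the within
    covariate and test its support by boundary LRT and delta-AIC.  When the
    within effect is not significant the slope stage is marked not
    evaluated — fitting individual plasticity differences is then not
    indicated.
    """
    full_ml = fit_mixed_model(obs, ModelSpec(response, (within, between), _CROSSED, "ML"))
    red_ml = fit_mixed_model(obs, ModelSpec(response, (between,), _CROSSED, "ML"))
    p_within = lrt_pvalue(full_ml.loglik, red_ml.loglik, df_diff=1)
    full_reml = fit_mixed_model(obs, ModelSpec(response, (within, between), _CROSSED, "REML"))
    beta_w = float(full_reml.beta[within])
    if p_within >= alpha:
        return GatedSlopeResult(
            within_p=float(p_within), within_beta=beta_w, gate_alpha=alpha, slopes_evaluated=False
        )
    slope_random = _CROSSED + (RandomTerm("individual_id", slope=within),)
    slope_ml = fit_mixed_model(obs, ModelSpec(response, (within, between), slope_random, "ML"))
    slope_reml = fit_mixed_model(obs, ModelSpec(response, (within, between), slope_random, "REML"))
    p_slope = lrt_pvalue(slope_ml.loglik, full_ml.loglik, df_diff=1, boundary=True)
    return GatedSlopeResult(
        within_p=float(p_within),
        within_beta=beta_w,
        gate_alpha=alpha,
        slopes_evaluated=True,
        slope_p=float(p_slope),
        slope_variance=float(slope_reml.varcomp[f"{within}|individual_id"]),
        slope_delta_aic=float(akaike_ic(slope_ml) - akaike_ic(full_ml)),
    )


def trait_observation_table(
    ds: Dataset, trait: str, isotope: Isotope | str
) -> tuple[pd.DataFrame, int]:
    """Join traits with red-blood-cell isotopes on (individual, year),
    z-standardize both within year, and center the isotope covariate.

    Returns the table and the number of rows lost in the join.
    """
    isotope = Isotope(isotope).value
    blood = ds.tissue_samples(Tissue.RED_BLOOD_CELL)[["individual_id", "year", isotope]]
    traits = ds.traits[["individual_id", "year", trait]].dropna()
    merged = blood.merge(traits, on=["individual_id", "year"], how="inner")
    lost = max(len(blood), len(traits)) - len(merged)
    merged = merged.reset_index(drop=True)
    merged["response"] = standardize_within_year(merged, trait)
    merged["iso_z"] = standardize_within_year(merged, isotope)
    cd = center_within_individual(merged, "iso_z")
    merged["iso_within"] = cd.within
    merged["iso_between"] = cd.between
    return merged, lost


def build_trait_model_set(
    ds: Dataset,
    trait: str,
    isotope: Isotope | str,
    alpha: float = 0.05,
    include_null: bool = True,
) -> tuple[ModelComparisonTable, GatedSlopeResult, int]:
    """Null and within+between models of one isotope for one breeding trait.

    Everything is z-standardized within year before modelling, so inference
    is invariant to per-year positive rescaling of the trait.  Returns the
    comparison table, the within-effect/slope gate result, and the join-loss
    count.
    """
    isotope = Isotope(isotope).value
    obs, lost = trait_observation_table(ds, trait, isotope)
    structures: dict[str, tuple[str, ...]] = {}
    if include_null:
        structures["null"] = ()
    structures[f"{isotope}_within+{isotope}_between"] = ("iso_within", "iso_between")
    ml_fits, reml_fits = {}, {}
    for label, fixed in structures.items():
        ml_fits[label], reml_fits[label] = _fit_pair(obs, "response", fixed, _CROSSED)
    table = ModelComparisonTable.from_fits(ml_fits, reml_fits)
    gate = test_within_effect_then_slopes(
        obs, response="response", within="iso_within", between="iso_between", alpha=alpha
    )
    return table, gate, lost


def between_effect_pvalue(obs: pd.DataFrame, response="response",
                          within="iso_within", between="iso_between") -> float:
    """ML likelihood-ratio p-value for the between (among-individual) effect."""
    full = fit_mixed_model(obs, ModelSpec(response, (within, between), _CROSSED, "ML"))
    red = fit_mixed_model(obs, ModelSpec(response, (within,), _CROSSED, "ML"))
    return lrt_pvalue(full.loglik, red.loglik, df_diff=1)


def tissue_correlation(ds: Dataset, isotope: Isotope | str) -> dict:
    """Pearson correlation between tissues, matched on (individual, year)."""
    isotope = Isotope(isotope).value
    blood = ds.tissue_samples(Tissue.RED_BLOOD_CELL)[["individual_id", "year", isotope]]
    feather = ds.tissue_samples(Tissue.FEATHER)[["individual_id", "year", isotope]]
    pairs = blood.merge(feather, on=["individual_id", "year"], suffixes=("_rbc", "_feather"))
    if len(pairs) < 3:
        raise ValueError(f"need >= 3 matched (individual, year) pairs, got {len(pairs)}")
    r, p = stats.pearsonr(pairs[f"{isotope}_rbc"], pairs[f"{isotope}_feather"])
    return {"isotope": isotope, "r": float(r), "p": float(p), "n": int(len(pairs))}
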