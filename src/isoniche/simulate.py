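"""Synthetic study-design generator.

Emulates a multi-year isotope sampling campaign on a marked seabird colony:
30 females followed over eight calendar seasons with one season skipped
entirely and one season without feather sampling, yielding roughly 130 red-
blood-cell records (3-6 sampling years per female) and 110 feather records
(2-5 years).  Isotope values follow the additive model the analysis assumes,

    value = mu + a_j + b_i + beta_w (env_ij - env_bar_j) + beta_b env_bar_j
            + s_j (env_ij - env_bar_j) + eps,

with independent Gaussian individual effects a_j, year effects b_i, optional
individual slopes s_j, and residual noise.  Environmental indices are
monthly AR(1) series.  Breeding traits are linked to the realized
red-blood-cell isotope values on the z-scale and mapped back to realistic
units (grams, day-of-season).

Every draw goes through one ``numpy.random.Generator`` seeded from the
config, so identical config + seed gives byte-identical CSV output.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import write_dataset
from .types import Dataset, Tissue

#: tissue x isotope baseline means (permil); feathers run higher in d13C
DEFAULT_MU = {
    ("red_blood_cell", "d15N"): 13.0,
    ("red_blood_cell", "d13C"): -21.5,
    ("feather", "d15N"): 13.5,
    ("feather", "d13C"): -20.5,
}


@dataclass
class EnvModel:
    """Monthly AR(1) model for one environmental index."""

    mean: float = 0.0
    sd: float = 1.04
    ar1: float = 0.5


@dataclass
class TraitLink:
    """Linear link from the (z-scaled) blood isotope to the breeding traits."""

    beta_within: float = 0.0
    beta_between: float = 0.0
    noise_sd: float = 0.5
    isotope: str = "d15N"


@dataclass
class SyntheticConfig:
    """Design, variance components and effect sizes of the generator.

    Defaults reproduce the study design the analysis targets: years
    2006-2013 with no fieldwork in 2011 and no feathers in 2009; blood-year
    counts drawn from {3..6} with mean 4.3, feather-year counts from {2..5}
    with mean 3.67.
    """

    n_individuals: int = 30
    study_years: tuple[int, ...] = (2006, 2007, 2008, 2009, 2010, 2011, 2012, 2013)
    skip_years: tuple[int, ...] = (2011,)
    no_feather_years: tuple[int, ...] = (2009,)
    blood_years_pmf: dict[int, float] = field(
        default_factory=lambda: {3: 0.25, 4: 0.35, 5: 0.25, 6: 0.15}
    )
    feather_years_pmf: dict[int, float] = field(
        default_factory=lambda: {2: 0.13, 3: 0.27, 4: 0.40, 5: 0.20}
    )
    mu: dict[tuple[str, str], float] = field(default_factory=lambda: dict(DEFAULT_MU))
    sigma2_individual: float = 0.5
    sigma2_year: float = 0.3
    sigma2_residual: float = 0.3
    slope_sd: float = 0.0
    env_effect_index: str = "SAM"
    beta_within: float = 0.0
    beta_between: float = 0.0
    env_models: dict[str, EnvModel] = field(
        default_factory=lambda: {"SAM": EnvModel(), "SOI": EnvModel(), "SSTA": EnvModel(sd=0.6)}
    )
    trait_link: TraitLink = field(default_factory=TraitLink)
    trait_sigma2_individual: float = 0.5
    trait_sigma2_year: float = 0.3
    seed: int = 0

    def __post_init__(self):
        for v in (self.sigma2_individual, self.sigma2_year, self.sigma2_residual):
            if v < 0:
                raise ValueError("variance components must be >= 0")
        if not set(self.skip_years) <= set(self.study_years):
            raise ValueError("skip_years must be a subset of study_years")
        for pmf, label in ((self.blood_years_pmf, "blood"), (self.feather_years_pmf, "feather")):
            if abs(sum(pmf.values()) - 1.0) > 1e-9:
                raise ValueError(f"{label}_years_pmf must sum to 1")

    @property
    def sampled_years(self) -> list[int]:
        return [y for y in self.study_years if y not in self.skip_years]

    @property
    def feather_years(self) -> list[int]:
        return [y for y in self.sampled_years if y not in self.no_feather_years]


def _draw_counts(rng, pmf: dict[int, float], n: int, max_avail: int, what: str) -> np.ndarray:
    ks = np.array(sorted(pmf))
    if ks.max() > max_avail:
        raise ValueError(
            f"infeasible design: up to {ks.max()} {what} years requested, {max_avail} available"
        )
    ps = np.array([pmf[k] for k in ks])
    return rng.choice(ks, size=n, p=ps)


def _simulate_env(cfg: SyntheticConfig, rng) -> pd.DataFrame:
    rows = []
    for name, em in sorted(cfg.env_models.items()):
        innov_sd = em.sd * math.sqrt(1 - em.ar1**2)
        x = rng.normal(0.0, em.sd)
        for year in cfg.study_years:
            for month in range(1, 13):
                x = em.ar1 * x + rng.normal(0.0, innov_sd)
                rows.append({"index_name": name, "year": year, "month": month,
                             "value": em.mean + x})
    return pd.DataFrame(rows)


def generate_dataset(cfg: SyntheticConfig) -> tuple[Dataset, dict]:
    """Generate a synthetic :class:`Dataset` plus the latent ground truth.

    The truth record contains every latent draw (individual and year
    effects per tissue x isotope, slopes, per-year environmental window
    means) so recovery tests can compare estimates against it.
    """
    rng = np.random.default_rng(cfg.seed)
    years = cfg.sampled_years
    f_years = cfg.feather_years

    ids = [f"F{i + 1:02d}" for i in range(cfg.n_individuals)]

    # sampling pattern
    n_blood = _draw_counts(rng, cfg.blood_years_pmf, cfg.n_individuals, len(years), "blood")
    n_feather = _draw_counts(rng, cfg.feather_years_pmf, cfg.n_individuals, len(f_years), "feather")
    blood_years = {
        ind: sorted(rng.choice(years, size=k, replace=False)) for ind, k in zip(ids, n_blood)
    }
    feather_years = {
        ind: sorted(rng.choice(f_years, size=k, replace=False)) for ind, k in zip(ids, n_feather)
    }

    env = _simulate_env(cfg, rng)

    # environmental window means per year, as the analysis will compute them
    from .centering import DEFAULT_WINDOWS, env_year_series

    env_idx = cfg.env_effect_index
    windows = {
        "red_blood_cell": env_year_series(
            env, env_idx, years, DEFAULT_WINDOWS["red_blood_cell"]
        ),
        "feather": env_year_series(env, env_idx, f_years, DEFAULT_WINDOWS["feather"]),
    }

    truth: dict = {
        "config": _config_record(cfg),
        "individual_effects": {},
        "year_effects": {},
        "slopes": {},
        "env_windows": {t: {int(y): float(v) for y, v in s.items()} for t, s in windows.items()},
    }

    sample_rows: list[dict] = []
    series_values: dict[tuple[str, str], dict] = {}
    for tissue in (Tissue.RED_BLOOD_CELL.value, Tissue.FEATHER.value):
        yrs_by_ind = blood_years if tissue == "red_blood_cell" else feather_years
        win = windows[tissue]
        for isotope in ("d15N", "d13C"):
            a = rng.normal(0.0, math.sqrt(cfg.sigma2_individual), cfg.n_individuals)
            b = rng.normal(0.0, math.sqrt(cfg.sigma2_year), len(cfg.study_years))
            b_by_year = dict(zip(cfg.study_years, b))
            s = rng.normal(0.0, cfg.slope_sd, cfg.n_individuals) if cfg.slope_sd > 0 else np.zeros(
                cfg.n_individuals
            )
            key = f"{tissue}.{isotope}"
            truth["individual_effects"][key] = dict(zip(ids, map(float, a)))
            truth["year_effects"][key] = {int(y): float(b_by_year[y]) for y in cfg.study_years}
            truth["slopes"][key] = dict(zip(ids, map(float, s)))
            vals: dict[tuple[str, int], float] = {}
            for j, ind in enumerate(ids):
                yrs = yrs_by_ind[ind]
                if not yrs:
                    continue
                env_bar = float(np.mean([win[y] for y in yrs]))
                for y in yrs:
                    dev = win[y] - env_bar
                    value = (
                        cfg.mu[(tissue, isotope)]
                        + a[j]
                        + b_by_year[y]
                        + cfg.beta_within * dev
                        + cfg.beta_between * env_bar
                        + s[j] * dev
                        + rng.normal(0.0, math.sqrt(cfg.sigma2_residual))
                    )
                    vals[(ind, y)] = value
            series_values[(tissue, isotope)] = vals

    for tissue in (Tissue.RED_BLOOD_CELL.value, Tissue.FEATHER.value):
        d15 = series_values[(tissue, "d15N")]
        d13 = series_values[(tissue, "d13C")]
        for (ind, y), v15 in d15.items():
            sample_rows.append(
                {"individual_id": ind, "year": y, "tissue": tissue,
                 "d15N": v15, "d13C": d13[(ind, y)]}
            )
    samples = pd.DataFrame(sample_rows).sort_values(
        ["tissue", "individual_id", "year"]
    ).reset_index(drop=True)

    traits = _simulate_traits(cfg, rng, ids, blood_years, series_values, truth)

    ds = Dataset(samples=samples, traits=traits, env=env, study_years=list(cfg.study_years))
    return ds, truth


def _simulate_traits(cfg, rng, ids, blood_years, series_values, truth) -> pd.DataFrame:
    """Traits for every blood-sampled (individual, year), linked on the z-scale."""
    link = cfg.trait_link
    iso_vals = series_values[("red_blood_cell", link.isotope)]
    obs = [(ind, y) for ind in ids for y in blood_years[ind]]
    x = np.array([iso_vals[k] for k in obs])
    inds = np.array([k[0] for k in obs])
    yrs = np.array([k[1] for k in obs])
    # z-scale the isotope within year (as the analysis will)
    xz = np.empty_like(x)
    for y in np.unique(yrs):
        m = yrs == y
        sd = x[m].std(ddof=1) if m.sum() > 1 else 1.0
        xz[m] = (x[m] - x[m].mean()) / (sd if sd > 0 else 1.0)
    xbar = {ind: xz[inds == ind].mean() for ind in ids if (inds == ind).any()}
    within = xz - np.array([xbar[i] for i in inds])
    between = np.array([xbar[i] for i in inds])

    units = {  # z-scale -> reported units: (location, scale)
        "body_mass": (2450.0, 180.0),
        "clutch_initiation_date": (32.0, 4.0),
        "total_clutch_mass": (190.0, 15.0),
    }
    truth["trait_effects"] = {}
    zscores = {}
    for trait in units:
        u = rng.normal(0.0, math.sqrt(cfg.trait_sigma2_individual), len(ids))
        u_by_ind = dict(zip(ids, u))
        v = rng.normal(0.0, math.sqrt(cfg.trait_sigma2_year), len(cfg.study_years))
        v_by_year = dict(zip(cfg.study_years, v))
        z = (
            link.beta_within * within
            + link.beta_between * between
            + np.array([u_by_ind[i] for i in inds])
            + np.array([v_by_year[y] for y in yrs])
            + rng.normal(0.0, link.noise_sd, len(obs))
        )
        zscores[trait] = z
        truth["trait_effects"][trait] = {
            "individual": {i: float(u_by_ind[i]) for i in ids},
            "year": {int(y): float(v_by_year[y]) for y in cfg.study_years},
        }

    loc, scale = units["body_mass"]
    body_mass = loc + scale * zscores["body_mass"]
    loc, scale = units["clutch_initiation_date"]
    cid = np.maximum(np.rint(loc + scale * zscores["clutch_initiation_date"]), 1).astype(int)
    loc, scale = units["total_clutch_mass"]
    total = np.maximum(loc + scale * zscores["total_clutch_mass"], 20.0)
    frac = np.clip(rng.normal(0.42, 0.01, len(obs)), 0.3, 0.55)
    a_egg = total * frac
    b_egg = total - a_egg

    return pd.DataFrame(
        {
            "individual_id": inds,
            "year": yrs,
            "body_mass": body_mass,
            "clutch_initiation_date": cid,
            "a_egg_mass": a_egg,
            "b_egg_mass": b_egg,
            "total_clutch_mass": total,
        }
    ).sort_values(["individual_id", "year"]).reset_index(drop=True)


def generate_null_dataset(cfg: SyntheticConfig) -> tuple[Dataset, dict]:
    """No-specialization, no-effect variant: sigma2_individual = 0, all beta = 0."""
    null_cfg = dataclasses.replace(
        cfg,
        sigma2_individual=0.0,
        slope_sd=0.0,
        beta_within=0.0,
        beta_between=0.0,
        trait_link=dataclasses.replace(cfg.trait_link, beta_within=0.0, beta_between=0.0),
        trait_sigma2_individual=0.0,
    )
    return generate_dataset(null_cfg)


def _config_record(cfg: SyntheticConfig) -> dict:
    rec = dataclasses.asdict(cfg)
    rec["mu"] = {f"{t}.{i}": v for (t, i), v in cfg.mu.items()}
    return rec


def write_synthetic(cfg: SyntheticConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate and write samples.csv/traits.csv/env.csv plus truth.json."""
    ds, truth = generate_dataset(cfg)
    paths = write_dataset(ds, out_dir)
    truth_path = Path(out_dir) / "truth.json"
    truth_path.write_text(json.dumps(truth, indent=1, sort_keys=True))
    paths["truth"] = truth_path
    return paths
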