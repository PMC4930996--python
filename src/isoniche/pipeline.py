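"""End-to-end orchestration: filter -> niche decomposition -> repeatability
-> environment model sets -> trait model sets -> tissue correlations.

Configuration is a YAML mapping (see :class:`AnalysisConfig`); input is
either three CSV paths or a ``synthetic`` block handed to the generator.
All tables are written as TSV, plus a single structured ``report.json``
with provenance (config hash, seed, package version).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .centering import (
    DEFAULT_WINDOWS,
    build_environment_model_set,
    build_trait_model_set,
    env_window_correlations,
    isotope_observation_table,
    test_within_effect_then_slopes,
    tissue_correlation,
)
from .io import filter_minimum_years, read_dataset
from .lmm import repeatability
from .niche import decompose, niche_table
from .simulate import SyntheticConfig, generate_dataset
from .types import ENV_INDICES, TRAIT_RESPONSES, Dataset, EmptyDatasetError, Tissue

log = logging.getLogger("isoniche")

TISSUES = [Tissue.RED_BLOOD_CELL.value, Tissue.FEATHER.value]
ISOTOPES = ["d15N", "d13C"]


@dataclass
class AnalysisConfig:
    """Pipeline settings; every field has the study's default."""

    samples_csv: str | None = None
    traits_csv: str | None = None
    env_csv: str | None = None
    synthetic: dict | None = None
    min_blood_years: int = 3
    min_feather_years: int = 2
    variance_convention: str = "population"
    windows: dict[str, tuple[int, ...]] = field(
        default_factory=lambda: {t: tuple(m) for t, m in DEFAULT_WINDOWS.items()}
    )
    quadratic: bool = True
    alpha_gate: float = 0.05
    n_boot: int = 1000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "windows" in raw:
            raw["windows"] = {t: tuple(m) for t, m in raw["windows"].items()}
        return cls(**raw)

    def content_hash(self) -> str:
        canon = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class AnalysisReport:
    """Structured result of one full run."""

    niche: pd.DataFrame
    repeatability: pd.DataFrame
    env_models: dict[str, pd.DataFrame]
    env_gates: dict[str, dict]
    trait_models: pd.DataFrame
    trait_gates: dict[str, dict]
    tissue_correlations: pd.DataFrame
    env_correlations: dict[str, pd.DataFrame]
    provenance: dict

    def n_env_models(self) -> int:
        return int(sum(len(t) for t in self.env_models.values()))

    def n_trait_models(self) -> int:
        return int(len(self.trait_models))

    def to_json_dict(self) -> dict:
        return {
            "provenance": self.provenance,
            "niche": self.niche.to_dict(),
            "repeatability": self.repeatability.to_dict(orient="records"),
            "env_models": {k: v.to_dict(orient="records") for k, v in self.env_models.items()},
            "env_gates": self.env_gates,
            "trait_models": self.trait_models.to_dict(orient="records"),
            "trait_gates": self.trait_gates,
            "tissue_correlations": self.tissue_correlations.to_dict(orient="records"),
            "env_correlations": {
                k: v.to_dict(orient="records") for k, v in self.env_correlations.items()
            },
            "counts": {"env_models": self.n_env_models(), "trait_models": self.n_trait_models()},
        }


def _load_input(cfg: AnalysisConfig) -> Dataset:
    if cfg.synthetic is not None:
        syn = dict(cfg.synthetic)
        syn.setdefault("seed", cfg.seed)
        ds, _ = generate_dataset(SyntheticConfig(**syn))
        log.info("generated synthetic dataset (seed=%s)", syn["seed"])
        return ds
    if not (cfg.samples_csv and cfg.traits_csv and cfg.env_csv):
        raise ValueError("config must provide either CSV paths or a 'synthetic' block")
    return read_dataset(cfg.samples_csv, cfg.traits_csv, cfg.env_csv)


def run_full_analysis(cfg: AnalysisConfig, out_dir: str | Path | None = None) -> AnalysisReport:
    """Run the whole analysis; optionally write all tables under ``out_dir``."""
    started = datetime.now(timezone.utc).isoformat()
    ds = _load_input(cfg)
    ds = filter_minimum_years(ds, cfg.min_blood_years, cfg.min_feather_years)
    log.info("filtered dataset: %d individuals, %d samples", len(ds.individuals()), len(ds.samples))

    # niche decomposition: 4 tissue x isotope cells
    decomps = [
        decompose(ds, t, i, convention=cfg.variance_convention) for t in TISSUES for i in ISOTOPES
    ]
    niche = niche_table(decomps)

    # repeatability per tissue x isotope
    rep_rows = []
    for k, (t, i) in enumerate([(t, i) for t in TISSUES for i in ISOTOPES]):
        obs = ds.tissue_samples(t)
        res = repeatability(
            obs, response=i, grouping="individual_id", n_boot=cfg.n_boot,
            seed=(cfg.seed * 7919 + k) % (2**31 - 1),
        )
        log.info("repeatability %s %s: r=%.3f p=%.3g", t, i, res.r, res.p_value)
        rep_rows.append(
            {"tissue": t, "isotope": i, "r": res.r, "se": res.se, "p_value": res.p_value}
        )
    rep_table = pd.DataFrame(rep_rows)

    # environment model sets: per response one null + per index {linear, quadratic}
    env_models: dict[str, pd.DataFrame] = {}
    env_gates: dict[str, dict] = {}
    for t in TISSUES:
        months = tuple(cfg.windows[t])
        for i in ISOTOPES:
            frames = []
            for j, env_name in enumerate(ENV_INDICES):
                mct = build_environment_model_set(
                    ds, t, i, env_name, quadratic=cfg.quadratic, months=months,
                    include_null=(j == 0),
                )
                frames.append(mct.table.drop(columns="delta_aic"))
            tab = pd.concat(frames, ignore_index=True).sort_values("akaike_ic")
            tab["delta_aic"] = tab["akaike_ic"] - tab["akaike_ic"].iloc[0]
            env_models[f"{t}.{i}"] = tab.reset_index(drop=True)
            # gate on the best non-null environmental variable
            best = next(m for m in tab["model"] if m != "null")
            best_env = best.split("_")[0]
            obs = isotope_observation_table(ds, t, i, best_env, months)
            gate = test_within_effect_then_slopes(obs, alpha=cfg.alpha_gate)
            env_gates[f"{t}.{i}"] = {"best_model": best, **dataclasses.asdict(gate)}
            log.info(
                "env models %s.%s: best=%s within_p=%.3f slopes_evaluated=%s",
                t, i, best, gate.within_p, gate.slopes_evaluated,
            )

    # trait model set: per trait one null + per isotope within+between
    trait_frames = []
    trait_gates: dict[str, dict] = {}
    for trait in TRAIT_RESPONSES:
        for j, iso in enumerate(ISOTOPES):
            mct, gate, lost = build_trait_model_set(
                ds, trait, iso, alpha=cfg.alpha_gate, include_null=(j == 0)
            )
            sub = mct.table.drop(columns="delta_aic").copy()
            sub.insert(0, "trait", trait)
            trait_frames.append(sub)
            trait_gates[f"{trait}.{iso}"] = dataclasses.asdict(gate)
            if lost:
                log.info("trait join %s/%s lost %d rows", trait, iso, lost)
    trait_models = pd.concat(trait_frames, ignore_index=True)

    corr = pd.DataFrame([tissue_correlation(ds, i) for i in ISOTOPES])
    sampled = sorted(ds.tissue_samples(Tissue.RED_BLOOD_CELL)["year"].unique())
    f_sampled = sorted(ds.tissue_samples(Tissue.FEATHER)["year"].unique())
    env_corr = {
        "red_blood_cell": env_window_correlations(
            ds.env, sampled, tuple(cfg.windows["red_blood_cell"])
        ),
        "feather": env_window_correlations(ds.env, f_sampled, tuple(cfg.windows["feather"])),
    }

    report = AnalysisReport(
        niche=niche,
        repeatability=rep_table,
        env_models=env_models,
        env_gates=env_gates,
        trait_models=trait_models,
        trait_gates=trait_gates,
        tissue_correlations=corr,
        env_correlations=env_corr,
        provenance={
            "config_hash": cfg.content_hash(),
            "seed": cfg.seed,
            "version": __version__,
            "started": started,
            "finished": datetime.now(timezone.utc).isoformat(),
        },
    )
    if out_dir is not None:
        write_report(report, out_dir)
    return report


def write_report(report: AnalysisReport, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.niche.to_csv(out / "niche_table.tsv", sep="\t")
    report.repeatability.to_csv(out / "repeatability.tsv", sep="\t", index=False)
    for key, tab in report.env_models.items():
        tab.to_csv(out / f"env_models_{key}.tsv", sep="\t", index=False)
    report.trait_models.to_csv(out / "trait_models.tsv", sep="\t", index=False)
    report.tissue_correlations.to_csv(out / "tissue_correlations.tsv", sep="\t", index=False)

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (np.bool_,)):
            return bool(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    (out / "report.json").write_text(
        json.dumps(report.to_json_dict(), indent=1, sort_keys=True, default=_default)
    )
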