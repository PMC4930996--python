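"""Reading, validating and writing the three study CSV files.

Formats (RFC-4180, UTF-8, "." decimal):

* ``samples.csv`` — individual_id, year, tissue, d15N, d13C
* ``traits.csv``  — individual_id, year, body_mass, clutch_initiation_date,
  a_egg_mass, b_egg_mass
* ``env.csv``     — index_name, year, month, value

Clutch initiation dates are day-of-season integers (1 = 1 October) so that
laying dates are comparable across seasons.  ``total_clutch_mass`` is derived
on read as a_egg_mass + b_egg_mass.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    ENV_COLUMNS,
    SAMPLE_COLUMNS,
    TRAIT_COLUMNS,
    Dataset,
    EmptyDatasetError,
    IntegrityError,
    SchemaError,
    Tissue,
)


def _require_columns(df: pd.DataFrame, required: list[str], name: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing required column(s) {missing}")


def _coerce_numeric(df: pd.DataFrame, cols: list[str], name: str) -> pd.DataFrame:
    """Coerce columns to float, reporting offending cells with line numbers.

    Line numbers are 1-based data rows (header is line 1, first record line 2),
    matching what a user sees in an editor.
    """
    df = df.copy()
    for col in cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            cells = [
                f"line {i + 2}: {col}={df[col].iloc[i]!r}"
                for i in np.flatnonzero(bad.to_numpy())[:10]
            ]
            raise SchemaError(f"{name}: non-numeric value(s) in '{col}': " + "; ".join(cells))
        df[col] = coerced
    return df


def validate_samples(samples: pd.DataFrame, study_years: list[int] | None = None) -> pd.DataFrame:
    """Validate the isotope sample table and return a clean copy.

    Raises :class:`SchemaError` / :class:`IntegrityError` on structural
    problems.  Years outside ``study_years`` produce a warning but the rows
    are retained, so the tool generalizes beyond one study design.
    """
    _require_columns(samples, SAMPLE_COLUMNS, "samples")
    samples = _coerce_numeric(samples[SAMPLE_COLUMNS], ["d15N", "d13C"], "samples")
    samples["year"] = samples["year"].astype(int)
    samples["individual_id"] = samples["individual_id"].astype(str)

    bad_tissue = ~samples["tissue"].isin([t.value for t in Tissue])
    if bad_tissue.any():
        raise SchemaError(
            f"samples: unknown tissue value(s) {sorted(samples.loc[bad_tissue, 'tissue'].unique())}"
        )
    if not np.isfinite(samples[["d15N", "d13C"]].to_numpy()).all():
        raise SchemaError("samples: non-finite isotope value")

    key = ["individual_id", "year", "tissue"]
    dup = samples.duplicated(subset=key, keep=False)
    if dup.any():
        first = samples.loc[dup, key].iloc[0].tolist()
        raise IntegrityError(f"samples: duplicate (individual, year, tissue) key {tuple(first)}")

    if study_years:
        unknown = sorted(set(samples["year"]) - set(study_years))
        if unknown:
            warnings.warn(
                f"samples: year(s) {unknown} outside the configured study span "
                f"{min(study_years)}-{max(study_years)}; rows retained",
                stacklevel=2,
            )
    return samples.reset_index(drop=True)


def validate_traits(traits: pd.DataFrame) -> pd.DataFrame:
    """Validate breeding records; derives/checks ``total_clutch_mass``."""
    _require_columns(traits, TRAIT_COLUMNS, "traits")
    numeric = ["body_mass", "clutch_initiation_date", "a_egg_mass", "b_egg_mass"]
    keep = TRAIT_COLUMNS + (["total_clutch_mass"] if "total_clutch_mass" in traits.columns else [])
    traits = _coerce_numeric(traits[keep], numeric, "traits")
    traits["year"] = traits["year"].astype(int)
    traits["individual_id"] = traits["individual_id"].astype(str)

    masses = traits[["body_mass", "a_egg_mass", "b_egg_mass"]].to_numpy(float)
    if np.any(masses[np.isfinite(masses)] <= 0):
        raise IntegrityError("traits: non-positive mass value")

    derived = traits["a_egg_mass"] + traits["b_egg_mass"]
    if "total_clutch_mass" in traits.columns:
        stored = pd.to_numeric(traits["total_clutch_mass"], errors="coerce")
        both = stored.notna() & derived.notna()
        if not np.allclose(stored[both], derived[both], atol=1e-9):
            raise IntegrityError("traits: total_clutch_mass != a_egg_mass + b_egg_mass")
    traits["total_clutch_mass"] = derived

    dup = traits.duplicated(subset=["individual_id", "year"], keep=False)
    if dup.any():
        first = traits.loc[dup, ["individual_id", "year"]].iloc[0].tolist()
        raise IntegrityError(f"traits: duplicate (individual, year) key {tuple(first)}")
    return traits.reset_index(drop=True)


def validate_env(env: pd.DataFrame) -> pd.DataFrame:
    _require_columns(env, ENV_COLUMNS, "env")
    env = _coerce_numeric(env[ENV_COLUMNS], ["value"], "env")
    env["year"] = env["year"].astype(int)
    env["month"] = env["month"].astype(int)
    if ((env["month"] < 1) | (env["month"] > 12)).any():
        raise SchemaError("env: month outside 1-12")
    dup = env.duplicated(subset=["index_name", "year", "month"], keep=False)
    if dup.any():
        first = env.loc[dup, ["index_name", "year", "month"]].iloc[0].tolist()
        raise IntegrityError(f"env: duplicate (index, year, month) key {tuple(first)}")
    return env.reset_index(drop=True)


def read_dataset(
    samples_path: str | Path,
    traits_path: str | Path,
    env_path: str | Path,
    study_years: list[int] | None = None,
) -> Dataset:
    """Read and validate the three study CSVs into a :class:`Dataset`."""
    samples = validate_samples(pd.read_csv(samples_path), study_years)
    traits = validate_traits(pd.read_csv(traits_path))
    env = validate_env(pd.read_csv(env_path))
    if study_years is None:
        years = sorted(set(samples["year"]) | set(traits["year"]))
    else:
        years = sorted(study_years)
    return Dataset(samples=samples, traits=traits, env=env, study_years=years)


def write_dataset(ds: Dataset, out_dir: str | Path) -> dict[str, Path]:
    """Write samples.csv / traits.csv / env.csv; returns the paths written.

    Reals are written with repr-precision so read_dataset(write_dataset(ds))
    is the identity to 1e-12.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "samples": out / "samples.csv",
        "traits": out / "traits.csv",
        "env": out / "env.csv",
    }
    ds.samples[SAMPLE_COLUMNS].to_csv(paths["samples"], index=False, float_format="%.10g")
    ds.traits[TRAIT_COLUMNS].to_csv(paths["traits"], index=False, float_format="%.10g")
    ds.env[ENV_COLUMNS].to_csv(paths["env"], index=False, float_format="%.10g")
    return paths


def filter_minimum_years(
    ds: Dataset,
    min_blood_years: int = 3,
    min_feather_years: int = 2,
    required_traits: tuple[str, ...] = ("body_mass", "a_egg_mass", "b_egg_mass"),
) -> Dataset:
    """Keep only individuals with enough years of joint blood + trait data.

    An individual is retained when (a) it has at least ``min_blood_years``
    years with a red-blood-cell sample AND all ``required_traits`` recorded
    in those same years, and (b) at least ``min_feather_years`` years with a
    feather sample.  Retained individuals keep all their rows.  Idempotent.
    """
    if min_blood_years < 1 or min_feather_years < 1:
        raise ValueError("thresholds must be >= 1")

    blood = ds.tissue_samples(Tissue.RED_BLOOD_CELL)[["individual_id", "year"]]
    if required_traits:
        traits = ds.traits.dropna(subset=list(required_traits))
        blood = blood.merge(traits[["individual_id", "year"]], on=["individual_id", "year"])
    blood_years = blood.groupby("individual_id")["year"].nunique()

    feather = ds.tissue_samples(Tissue.FEATHER)
    feather_years = feather.groupby("individual_id")["year"].nunique()

    keep = set(blood_years.index[blood_years >= min_blood_years]) & set(
        feather_years.index[feather_years >= min_feather_years]
    )
    if not keep:
        raise EmptyDatasetError(
            f"no individual meets min_blood_years={min_blood_years}, "
            f"min_feather_years={min_feather_years} with traits {list(required_traits)}"
        )
    return Dataset(
        samples=ds.samples[ds.samples["individual_id"].isin(keep)].reset_index(drop=True),
        traits=ds.traits[ds.traits["individual_id"].isin(keep)].reset_index(drop=True),
        env=ds.env.copy(),
        study_years=list(ds.study_years),
    )
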