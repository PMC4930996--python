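"""Domain types shared across the pipeline.

The package is pandas-centric: samples, breeding traits and environmental
series live in long-format DataFrames inside a :class:`Dataset`.  The column
contracts below are the single source of truth for every reader, writer and
analysis stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import pandas as pd


class Tissue(str, Enum):
    """Tissue a stable-isotope sample was taken from.

    Red blood cells integrate diet over the weeks before sampling
    (prebreeding period); feathers are synthesized during molt and reflect
    the premolt foraging period.
    """

    RED_BLOOD_CELL = "red_blood_cell"
    FEATHER = "feather"


class Isotope(str, Enum):
    """Stable isotope ratio, in per-mil (permil) relative to a standard.

    d15N proxies trophic level; d13C proxies foraging area.
    """

    D15N = "d15N"
    D13C = "d13C"


#: Required columns of the isotope sample table.
SAMPLE_COLUMNS = ["individual_id", "year", "tissue", "d15N", "d13C"]

#: Required columns of the breeding-trait table (total_clutch_mass is derived).
TRAIT_COLUMNS = [
    "individual_id",
    "year",
    "body_mass",
    "clutch_initiation_date",
    "a_egg_mass",
    "b_egg_mass",
]

#: Required columns of the monthly environmental-index table.
ENV_COLUMNS = ["index_name", "year", "month", "value"]

#: Environmental indices the analysis knows about.
ENV_INDICES = ["SAM", "SOI", "SSTA"]

#: Breeding traits modelled as responses in the trait model set.
TRAIT_RESPONSES = ["body_mass", "clutch_initiation_date", "total_clutch_mass"]


class SchemaError(ValueError):
    """A required column is missing or a cell cannot be parsed."""


class IntegrityError(ValueError):
    """A structural invariant (e.g. key uniqueness) is violated."""


class EmptyDatasetError(ValueError):
    """A filtering step left no individuals; never silently propagated."""


@dataclass
class Dataset:
    """Validated long-format study data.

    Attributes
    ----------
    samples
        One row per (individual, year, tissue) isotope measurement with
        columns :data:`SAMPLE_COLUMNS`.
    traits
        One row per (individual, year) breeding record with columns
        :data:`TRAIT_COLUMNS` plus the derived ``total_clutch_mass``.
    env
        Monthly environmental index values, columns :data:`ENV_COLUMNS`.
    study_years
        Ordered list of calendar years covered by the study design,
        including years with no fieldwork.
    """

    samples: pd.DataFrame
    traits: pd.DataFrame
    env: pd.DataFrame
    study_years: list[int] = field(default_factory=list)

    def individuals(self) -> list[str]:
        ids = set(self.samples["individual_id"]) | set(self.traits["individual_id"])
        return sorted(ids)

    def tissue_samples(self, tissue: Tissue | str) -> pd.DataFrame:
        tissue = Tissue(tissue).value
        return self.samples[self.samples["tissue"] == tissue]

    def copy(self) -> "Dataset":
        return Dataset(
            samples=self.samples.copy(),
            traits=self.traits.copy(),
            env=self.env.copy(),
            study_years=list(self.study_years),
        )
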