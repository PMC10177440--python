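"""Patient-level cohort container and schema.

A cohort is one row per uveal-melanoma patient carrying the covariates used
for eligibility screening, the three 5-year metastasis-associated-mortality
(MAM) score channels (full information, chromosome-3 masked, all genetics
masked), the ordinal primary-tumour stage, the chromosome-3 status and the
binary 5-year endpoint (death from, or detection of, metastasis within five
years of primary treatment).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

#: Ordinal primary-tumour stages, lowest to highest risk.
STAGES: tuple[str, ...] = ("I", "IIA", "IIB", "IIIA", "IIIB", "IIIC")

#: Tumour chromosome-3 status; "unknown" is the only permitted missing value
#: in analysis inputs (no chromosome-3 result was obtained).
CHR3_STATUSES: tuple[str, ...] = ("monosomy", "disomy", "unknown")

#: The three risk-score channels, by information scenario.
SCORE_COLUMNS: tuple[str, ...] = ("mam5_full", "mam5_nochr3", "mam5_nogenetics")

#: Canonical column order for cohort CSV serialisation.
COLUMNS: tuple[str, ...] = (
    "patient_id",
    "age",
    "sex",
    "diameter_mm",
    "height_mm",
    "ciliary_body",
    "extraocular",
    "chr3_status",
    "mam5_full",
    "mam5_nochr3",
    "mam5_nogenetics",
    "stage",
    "endpoint",
)

SUBGROUPS: tuple[str, ...] = ("all", "chr3_known", "chr3_unknown")


@dataclass(frozen=True)
class PatientRecord:
    """One patient; see module docstring for field semantics."""

    patient_id: str
    age: float
    sex: str
    diameter_mm: float
    height_mm: float
    ciliary_body: bool
    extraocular: bool
    chr3_status: str
    mam5_full: float
    mam5_nochr3: float
    mam5_nogenetics: float
    stage: str
    endpoint: bool


class CohortError(ValueError):
    """A cohort table violates the schema or a record-level invariant."""


def stage_order(stage: str | pd.Series) -> int | pd.Series:
    """Ordinal rank of a stage label (I=0 ... IIIC=5)."""
    ranks = {s: i for i, s in enumerate(STAGES)}
    if isinstance(stage, pd.Series):
        return stage.map(ranks)
    try:
        return ranks[stage]
    except KeyError:
        raise CohortError(f"unknown stage label: {stage!r}") from None


@dataclass
class Cohort:
    """An ordered collection of patient records backed by a DataFrame.

    Parameters
    ----------
    df : pandas.DataFrame
        One row per patient with the columns in :data:`COLUMNS`.
    provenance : object
        The generator configuration or source filename the cohort came from.
    """

    df: pd.DataFrame
    provenance: object = field(default=None)

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise CohortError(f"cohort table is missing columns: {missing}")
        if self.df["patient_id"].duplicated().any():
            dup = self.df["patient_id"][self.df["patient_id"].duplicated()].iloc[0]
            raise CohortError(f"duplicate patient_id: {dup!r}")
        self.df = self.df.loc[:, list(COLUMNS)].reset_index(drop=True)

    @property
    def n(self) -> int:
        return len(self.df)

    def __len__(self) -> int:
        return len(self.df)

    def records(self) -> Iterator[PatientRecord]:
        for row in self.df.itertuples(index=False):
            yield PatientRecord(
                patient_id=row.patient_id,
                age=row.age,
                sex=row.sex,
                diameter_mm=row.diameter_mm,
                height_mm=row.height_mm,
                ciliary_body=bool(row.ciliary_body),
                extraocular=bool(row.extraocular),
                chr3_status=row.chr3_status,
                mam5_full=row.mam5_full,
                mam5_nochr3=row.mam5_nochr3,
                mam5_nogenetics=row.mam5_nogenetics,
                stage=row.stage,
                endpoint=bool(row.endpoint),
            )

    def subgroup_mask(self, subgroup: str) -> np.ndarray:
        """Boolean mask selecting a chromosome-3 availability subgroup."""
        if subgroup == "all":
            return np.ones(self.n, dtype=bool)
        known = (self.df["chr3_status"] != "unknown").to_numpy()
        if subgroup == "chr3_known":
            return known
        if subgroup == "chr3_unknown":
            return ~known
        raise CohortError(f"unknown subgroup {subgroup!r}; expected one of {SUBGROUPS}")

    def subgroup(self, subgroup: str) -> "Cohort":
        """Restrict the cohort to a chromosome-3 availability subgroup."""
        mask = self.subgroup_mask(subgroup)
        return Cohort(self.df.loc[mask].reset_index(drop=True), provenance=self.provenance)

    @property
    def endpoint(self) -> np.ndarray:
        return self.df["endpoint"].to_numpy().astype(bool)
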