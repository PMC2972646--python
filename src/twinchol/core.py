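"""Cohort data model and CSV/JSON plumbing.

The cohort is a long-format CSV: one row per individual, with columns
``person_id, family_id, zygosity`` followed by one column per phenotype and
one ``onset_age_<phenotype>`` column per phenotype.  Missing values are empty
cells — never ``0``, which is a real category.  Individuals are grouped into
:class:`TwinPairRecord` objects at read time; a family with a single row is a
singleton (incomplete pair), which the twin likelihood still uses.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

SPEC_VERSION = "1.0"

__all__ = [
    "Zygosity",
    "PhenotypeSchema",
    "Individual",
    "TwinPairRecord",
    "read_cohort",
    "write_cohort",
    "cohort_to_frame",
    "individuals",
    "write_results_json",
]


class Zygosity(str, Enum):
    MZ = "MZ"
    DZ = "DZ"


@dataclass(frozen=True)
class PhenotypeSchema:
    """Declares a phenotype column: binary or ordinal with a category count."""

    name: str
    kind: str  # "binary" | "ordinal"
    n_categories: int = 2
    description: str = ""

    def __post_init__(self):
        if self.kind not in ("binary", "ordinal"):
            raise ValueError(f"unknown phenotype kind {self.kind!r}")
        if self.kind == "binary" and self.n_categories != 2:
            raise ValueError("binary phenotype must have exactly 2 categories")
        if self.n_categories < 2:
            raise ValueError("need at least 2 categories")


@dataclass
class Individual:
    person_id: str
    family_id: str
    zygosity: Zygosity
    phenotypes: dict = field(default_factory=dict)  # name -> int | None
    onset_ages: dict = field(default_factory=dict)  # name -> int | None


@dataclass
class TwinPairRecord:
    """One family: two individuals, or one if the co-twin was not assessed."""

    family_id: str
    zygosity: Zygosity
    twin1: Individual
    twin2: Optional[Individual] = None

    @property
    def complete(self) -> bool:
        return self.twin2 is not None


def individuals(records: Iterable[TwinPairRecord]) -> list[Individual]:
    """Flatten pair records into a list of individuals (twin1 then twin2)."""
    out = []
    for rec in records:
        out.append(rec.twin1)
        if rec.twin2 is not None:
            out.append(rec.twin2)
    return out


def _parse_cell(raw: str, schema: PhenotypeSchema):
    if raw == "":
        return None, False
    try:
        v = int(raw)
    except ValueError:
        return None, True
    if not (0 <= v < schema.n_categories):
        return None, True
    return v, False


def _parse_age(raw: str):
    if raw == "":
        return None, False
    try:
        v = int(float(raw))
    except ValueError:
        return None, True
    return v, False


def read_cohort(path, schema: Sequence[PhenotypeSchema]) -> list[TwinPairRecord]:
    """Read a cohort CSV and group rows into twin-pair records.

    Unparseable or out-of-range cells become missing and are counted in a
    single logged warning.  Structural problems — duplicate person ids, more
    than two rows per family, unknown or discordant zygosity — are errors.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = ["person_id", "family_id", "zygosity"] + [s.name for s in schema]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise ValueError(f"cohort header missing columns: {missing_cols}")

    if df["person_id"].duplicated().any():
        dup = df.loc[df["person_id"].duplicated(), "person_id"].iloc[0]
        raise ValueError(f"duplicate person_id {dup!r}")

    n_bad = 0
    families: dict[str, list[Individual]] = {}
    order: list[str] = []
    for _, row in df.iterrows():
        zyg_raw = row["zygosity"]
        try:
            zyg = Zygosity(zyg_raw)
        except ValueError:
            raise ValueError(f"unknown zygosity code {zyg_raw!r}") from None
        phen, onset = {}, {}
        for s in schema:
            v, bad = _parse_cell(row[s.name], s)
            phen[s.name] = v
            n_bad += bad
            col = f"onset_age_{s.name}"
            if col in df.columns:
                a, bad = _parse_age(row[col])
                onset[s.name] = a
                n_bad += bad
            else:
                onset[s.name] = None
        ind = Individual(row["person_id"], row["family_id"], zyg, phen, onset)
        fam = families.setdefault(ind.family_id, [])
        if not fam:
            order.append(ind.family_id)
        if len(fam) >= 2:
            raise ValueError(f">2 individuals in family {ind.family_id!r}")
        if fam and fam[0].zygosity != zyg:
            raise ValueError(f"discordant zygosity in family {ind.family_id!r}")
        fam.append(ind)

    if n_bad:
        logger.warning("read_cohort: %d unparseable cells treated as missing", n_bad)

    records = []
    for fid in order:
        mem = families[fid]
        records.append(
            TwinPairRecord(fid, mem[0].zygosity, mem[0], mem[1] if len(mem) == 2 else None)
        )
    return records


def _columns(records, schema):
    if schema is not None:
        names = [s.name for s in schema]
    else:
        names, seen = [], set()
        for ind in individuals(records):
            for k in ind.phenotypes:
                if k not in seen:
                    seen.add(k)
                    names.append(k)
    return names


def cohort_to_frame(
    records: Sequence[TwinPairRecord], schema: Sequence[PhenotypeSchema] | None = None
) -> pd.DataFrame:
    """Long-format DataFrame view of a cohort (one row per individual).

    Phenotypes and onset ages come out as pandas nullable ``Int64`` so that
    missing stays missing rather than turning into 0 or NaN-float surprises.
    """
    names = _columns(records, schema)
    rows = []
    for ind in individuals(records):
        row = {
            "person_id": ind.person_id,
            "family_id": ind.family_id,
            "zygosity": ind.zygosity.value,
        }
        for n in names:
            row[n] = ind.phenotypes.get(n)
            row[f"onset_age_{n}"] = ind.onset_ages.get(n)
        rows.append(row)
    df = pd.DataFrame(rows, columns=["person_id", "family_id", "zygosity"]
                      + names + [f"onset_age_{n}" for n in names])
    for n in names:
        df[n] = df[n].astype("Int64")
        df[f"onset_age_{n}"] = df[f"onset_age_{n}"].astype("Int64")
    return df


def write_cohort(
    records: Sequence[TwinPairRecord],
    path,
    schema: Sequence[PhenotypeSchema] | None = None,
) -> None:
    """Write a cohort CSV (deterministic column order, missing = empty cell)."""
    df = cohort_to_frame(records, schema)
    df.to_csv(path, index=False)


def write_results_json(obj: dict, path) -> None:
    """Write a results document with the schema version stamped in."""
    doc = {"spec_version": SPEC_VERSION, **obj}
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=False) + "\n")
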