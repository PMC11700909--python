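"""Per-individual dietary intake records: I/O, validation, stratification.

The analysis operates on one row per surveyed adult, carrying the four
daily intakes the absorption model needs — zinc (mg), phytate (mg),
protein (g) and calcium (mg) — plus sex and age in years. Records are
stratified into the three adult age bands conventionally used in
dietary-reference-intake work (19–30, 31–50, 51–70), and the
phytate:zinc molar ratio, the standard screening marker for zinc
bioavailability, is computed per individual.

The external file format is a plain CSV with header
``id,sex,age,zinc,phytate,protein,calcium`` (any column order); zinc,
phytate and calcium are mg/day and protein is g/day. Internally a
cohort is either a list of :class:`IntakeRecord` or a
:class:`pandas.DataFrame` with explicit-unit column names
(``zinc_mg`` etc.); converters are provided both ways.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: Molar mass of phytic acid (myo-inositol hexakisphosphate), g/mol,
#: per the IZiNCG food-composition convention.
PHYTATE_MOLAR_MASS = 660.04
#: Molar mass of zinc, g/mol.
ZINC_MOLAR_MASS = 65.38
#: Molar mass of calcium, g/mol (used when calcium enters the model in mmol).
CALCIUM_MOLAR_MASS = 40.078

AGE_MIN = 19
AGE_MAX = 70

NUTRIENT_COLUMNS = ("zinc_mg", "phytate_mg", "protein_g", "calcium_mg")

#: External CSV header -> internal column name.
CSV_SCHEMA = {
    "id": "id",
    "sex": "sex",
    "age": "age_years",
    "zinc": "zinc_mg",
    "phytate": "phytate_mg",
    "protein": "protein_g",
    "calcium": "calcium_mg",
}


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"

    @classmethod
    def parse(cls, value: object) -> "Sex":
        """Parse a sex code; accepts case-insensitive M/F/male/female."""
        text = str(value).strip().lower()
        if text in ("m", "male"):
            return cls.MALE
        if text in ("f", "female"):
            return cls.FEMALE
        raise ValueError(f"unrecognised sex code: {value!r}")


class AgeBand(str, Enum):
    Y19_30 = "19-30"
    Y31_50 = "31-50"
    Y51_70 = "51-70"
    ALL = "all"


@dataclass(frozen=True)
class StratumKey:
    """A sex × age-band cell of the survey design."""

    sex: Sex
    age_band: AgeBand

    def label(self) -> str:
        return f"{self.sex.value} {self.age_band.value}"


#: The six elementary strata in reporting order (men first, youngest first).
STRATA: tuple[StratumKey, ...] = tuple(
    StratumKey(sex, band)
    for sex in (Sex.MALE, Sex.FEMALE)
    for band in (AgeBand.Y19_30, AgeBand.Y31_50, AgeBand.Y51_70)
)


@dataclass(frozen=True)
class MolarConstants:
    """Molar masses used to convert mg/day intakes to mmol/day."""

    phytate_molar_mass: float = PHYTATE_MOLAR_MASS
    zinc_molar_mass: float = ZINC_MOLAR_MASS

    def __post_init__(self) -> None:
        for name in ("phytate_molar_mass", "zinc_molar_mass"):
            value = getattr(self, name)
            if not (math.isfinite(value) and value > 0):
                raise ValueError(f"{name} must be strictly positive, got {value}")


@dataclass
class IntakeRecord:
    """One individual's daily nutrient intakes with sex and age."""

    id: str
    sex: Sex
    age_years: int
    zinc_mg: float
    phytate_mg: float
    protein_g: float
    calcium_mg: float

    def validate(self) -> None:
        """Raise ``ValueError`` on any invariant violation."""
        if not (AGE_MIN <= self.age_years <= AGE_MAX):
            raise ValueError(
                f"record {self.id!r}: age {self.age_years} outside "
                f"study range {AGE_MIN}-{AGE_MAX}"
            )
        for field in NUTRIENT_COLUMNS:
            value = getattr(self, field)
            if not (isinstance(value, (int, float)) and math.isfinite(value)):
                raise ValueError(f"record {self.id!r}: {field} is not finite ({value!r})")
            if value < 0:
                raise ValueError(f"record {self.id!r}: {field} is negative ({value})")


def assign_stratum(sex: Sex, age_years: int) -> StratumKey:
    """Map sex and age in completed years to the reporting stratum.

    Bands are closed integer intervals: 30 belongs to 19–30 and 50 to
    31–50. Ages outside 19–70 raise.
    """
    if not AGE_MIN <= age_years <= AGE_MAX:
        raise ValueError(f"age {age_years} outside study range {AGE_MIN}-{AGE_MAX}")
    if age_years <= 30:
        band = AgeBand.Y19_30
    elif age_years <= 50:
        band = AgeBand.Y31_50
    else:
        band = AgeBand.Y51_70
    return StratumKey(Sex(sex), band)


def to_millimoles(mass_mg: float, molar_mass: float):
    """Convert a mass in mg to an amount in mmol given a molar mass in g/mol.

    Works element-wise on arrays. ``mg / (g/mol) = mmol`` because the
    10³ factors cancel.
    """
    if np.any(np.asarray(molar_mass) <= 0):
        raise ValueError(f"molar mass must be positive, got {molar_mass}")
    return np.asarray(mass_mg) / molar_mass if np.ndim(mass_mg) else mass_mg / molar_mass


def pz_molar_ratio(
    phytate_mg: float, zinc_mg: float, constants: MolarConstants = MolarConstants()
) -> float:
    """Phytate:zinc molar ratio, the standard bioavailability marker.

    Ratios above ~15 indicate diets in which phytate chelation markedly
    impairs zinc absorption. Undefined (raises) when zinc intake is
    zero; such records are excluded from ratio summaries upstream.
    """
    if zinc_mg <= 0:
        raise ValueError("phytate:zinc molar ratio undefined for zero zinc intake")
    if phytate_mg < 0:
        raise ValueError("phytate intake must be non-negative")
    return (phytate_mg / constants.phytate_molar_mass) / (
        zinc_mg / constants.zinc_molar_mass
    )


# ---------------------------------------------------------------------------
# File I/O


def read_intake_table(path: str | Path, strict: bool = True) -> list[IntakeRecord]:
    """Read an intake CSV into validated :class:`IntakeRecord` objects.

    Parameters
    ----------
    path
        CSV file with header ``id,sex,age,zinc,phytate,protein,calcium``
        in any column order.
    strict
        If true (default), the first invalid row raises with the row
        number and offending field. If false, invalid rows are dropped
        and the drop count is logged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"intake table not found: {path}")
    df = pd.read_csv(path)
    missing = set(CSV_SCHEMA) - {c.strip().lower() for c in df.columns}
    if missing:
        raise ValueError(f"intake table {path} missing column(s): {sorted(missing)}")
    df.columns = [c.strip().lower() for c in df.columns]
    df = df.rename(columns=CSV_SCHEMA)
    if df.empty:
        log.warning("intake table %s has a header but no data rows", path)
        return []

    records: list[IntakeRecord] = []
    dropped = 0
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        try:
            record = IntakeRecord(
                id=str(row.id),
                sex=Sex.parse(row.sex),
                age_years=int(row.age_years),
                zinc_mg=float(row.zinc_mg),
                phytate_mg=float(row.phytate_mg),
                protein_g=float(row.protein_g),
                calcium_mg=float(row.calcium_mg),
            )
            record.validate()
        except (ValueError, TypeError) as exc:
            if strict:
                raise ValueError(f"{path} line {i}: {exc}") from exc
            dropped += 1
            log.warning("%s line %d dropped: %s", path, i, exc)
            continue
        records.append(record)
    log.info(
        "read %d record(s) from %s (%d dropped)", len(records), path, dropped
    )
    return records


def write_intake_table(records: Iterable[IntakeRecord], path: str | Path) -> None:
    """Write records to the external CSV schema (inverse of reading)."""
    df = records_to_frame(list(records))
    out = df.rename(columns={v: k for k, v in CSV_SCHEMA.items()})
    out[list(CSV_SCHEMA)].to_csv(path, index=False)


def records_to_frame(records: Sequence[IntakeRecord]) -> pd.DataFrame:
    """Convert records to the internal cohort DataFrame."""
    return pd.DataFrame(
        {
            "id": [r.id for r in records],
            "sex": [r.sex.value for r in records],
            "age_years": [r.age_years for r in records],
            "zinc_mg": [r.zinc_mg for r in records],
            "phytate_mg": [r.phytate_mg for r in records],
            "protein_g": [r.protein_g for r in records],
            "calcium_mg": [r.calcium_mg for r in records],
        }
    )


def frame_to_records(df: pd.DataFrame) -> list[IntakeRecord]:
    records = []
    for row in df.itertuples(index=False):
        record = IntakeRecord(
            id=str(row.id),
            sex=Sex.parse(row.sex),
            age_years=int(row.age_years),
            zinc_mg=float(row.zinc_mg),
            phytate_mg=float(row.phytate_mg),
            protein_g=float(row.protein_g),
            calcium_mg=float(row.calcium_mg),
        )
        record.validate()
        records.append(record)
    return records


def add_derived_columns(
    df: pd.DataFrame, constants: MolarConstants = MolarConstants()
) -> pd.DataFrame:
    """Return a copy with ``age_band`` and ``pz_ratio`` columns.

    ``pz_ratio`` is NaN for zero-zinc records (the ratio is undefined);
    the exclusion count is logged so summaries can report it.
    """
    out = df.copy()
    age = out["age_years"].to_numpy()
    if ((age < AGE_MIN) | (age > AGE_MAX)).any():
        bad = out.loc[(age < AGE_MIN) | (age > AGE_MAX), "id"].tolist()[:5]
        raise ValueError(f"ages outside {AGE_MIN}-{AGE_MAX} (e.g. records {bad})")
    out["age_band"] = np.select(
        [age <= 30, age <= 50],
        [AgeBand.Y19_30.value, AgeBand.Y31_50.value],
        default=AgeBand.Y51_70.value,
    )
    zinc = out["zinc_mg"].to_numpy(dtype=float)
    phytate = out["phytate_mg"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (phytate / constants.phytate_molar_mass) / (
            zinc / constants.zinc_molar_mass
        )
    ratio = np.where(zinc > 0, ratio, np.nan)
    n_excluded = int((zinc <= 0).sum())
    if n_excluded:
        log.warning(
            "%d record(s) with zero zinc intake excluded from P/Z ratio", n_excluded
        )
    out["pz_ratio"] = ratio
    return out
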