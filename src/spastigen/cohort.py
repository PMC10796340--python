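"""Synthetic patient cohort: 92 virtual individuals with demographic diversity.

The packaged reference cohort spans 4 phenotypes x 2 sexes x 3 adult ages
(plus two Latino individuals at age 33), with body-shape "mass" and muscle
"tone" slider percentages in {25, 50, 75}. Heights and right upper-limb
segment lengths (upper arm, forearm, hand, all cm) come from the character
generator's preset anthropometry for each (phenotype, sex, age) and are
carried here as reference data, not re-derived.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "Phenotype",
    "Sex",
    "PatientRecord",
    "Anthropometry",
    "load_reference_cohort",
    "anthropometry_for",
    "validate_cohort",
    "cohort_to_csv",
    "cohort_from_csv",
    "generic_anthropometry",
]

#: Column names of the reference table (and of CSV export/import).
COHORT_COLUMNS = [
    "ID", "Type", "Age", "Height", "Mass", "Tone",
    "Upperarm", "Forearm", "Hands",
]

#: Slider percentages admitted in the packaged cohort (extremes <25% or
#: >75% are excluded as non-representative body archetypes).
PCT_RANGE = (25.0, 75.0)

#: Ages tabulated in the packaged cohort.
TABULATED_AGES = (23, 33, 48, 68)


class Phenotype(str, enum.Enum):
    CAUCASIAN = "Caucasian"
    AFRICAN = "African"
    ASIAN = "Asian"
    LATINO = "Latino"


class Sex(str, enum.Enum):
    MALE = "Male"
    FEMALE = "Female"


@dataclass(frozen=True)
class Anthropometry:
    """Right upper-limb segment lengths and stature, all in cm."""

    height: float
    upperarm: float
    forearm: float
    hand: float

    def __post_init__(self) -> None:
        for name in ("height", "upperarm", "forearm", "hand"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.upperarm + self.forearm + self.hand >= self.height:
            raise ValueError(
                "limb segments sum to "
                f"{self.upperarm + self.forearm + self.hand:.2f} cm, "
                f"expected < height ({self.height:.2f} cm)"
            )


@dataclass(frozen=True)
class PatientRecord:
    """One synthetic individual (a row of the packaged cohort table).

    ``mass_pct`` and ``tone_pct`` are character-generator slider values in
    percent, NOT kilograms or any physical unit; they are bookkeeping only
    and do not alter kinematics.
    """

    id: int
    phenotype: Phenotype
    sex: Sex
    age: int
    height: float
    mass_pct: float
    tone_pct: float
    upperarm: float
    forearm: float
    hand: float

    @property
    def anthropometry(self) -> Anthropometry:
        return Anthropometry(self.height, self.upperarm, self.forearm, self.hand)


class CohortIntegrityError(RuntimeError):
    """Packaged reference table failed its own invariants."""


class AnthropometryLookupError(KeyError):
    """No tabulated row matches the requested combination."""


def _data_path(name: str) -> Path:
    return Path(str(resources.files("spastigen").joinpath("data", name)))


def _parse_row(row: pd.Series) -> PatientRecord:
    phen_str, _, sex_str = str(row["Type"]).partition(" ")
    return PatientRecord(
        id=int(row["ID"]),
        phenotype=Phenotype(phen_str),
        sex=Sex(sex_str),
        age=int(row["Age"]),
        height=float(row["Height"]),
        mass_pct=float(row["Mass"]),
        tone_pct=float(row["Tone"]),
        upperarm=float(row["Upperarm"]),
        forearm=float(row["Forearm"]),
        hand=float(row["Hands"]),
    )


def load_reference_cohort() -> list[PatientRecord]:
    """Load the packaged 92-row reference cohort, in id order.

    Raises
    ------
    CohortIntegrityError
        If the packaged table is corrupted (bad row, wrong count,
        non-contiguous ids, or any violated record invariant).
    """
    df = pd.read_csv(_data_path("cohort.csv"))
    records: list[PatientRecord] = []
    for _, row in df.iterrows():
        try:
            records.append(_parse_row(row))
        except (ValueError, KeyError) as exc:
            raise CohortIntegrityError(
                f"reference cohort row ID={row.get('ID', '?')} is invalid: {exc}"
            ) from exc
    report = validate_cohort(records)
    if report:
        raise CohortIntegrityError(
            "reference cohort violates its invariants: " + "; ".join(report)
        )
    return records


def validate_cohort(records: Iterable[PatientRecord]) -> list[str]:
    """Report (not raise) every violated cohort invariant.

    Returns a list of human-readable violation strings; empty for a valid
    cohort. Checks per-record positivity, slider ranges, tabulated ages,
    segment-sum sanity, and id uniqueness/contiguity across the cohort.
    """
    records = list(records)
    report: list[str] = []
    for rec in records:
        tag = f"record id={rec.id}"
        for field in ("height", "upperarm", "forearm", "hand"):
            if getattr(rec, field) <= 0:
                report.append(f"{tag}: {field} must be > 0 (got {getattr(rec, field)})")
        for field in ("mass_pct", "tone_pct"):
            v = getattr(rec, field)
            if not (PCT_RANGE[0] <= v <= PCT_RANGE[1]):
                report.append(f"{tag}: {field}={v} outside {PCT_RANGE}")
        if rec.age not in TABULATED_AGES:
            report.append(f"{tag}: age {rec.age} not in tabulated ages {TABULATED_AGES}")
        if min(rec.height, rec.upperarm, rec.forearm, rec.hand) > 0 and (
            rec.upperarm + rec.forearm + rec.hand >= rec.height
        ):
            report.append(f"{tag}: limb segments not shorter than height")
    ids = [rec.id for rec in records]
    seen: set[int] = set()
    for i in ids:
        if i in seen:
            report.append(f"duplicate id {i}")
        seen.add(i)
    if records and sorted(seen) != list(range(1, len(records) + 1)):
        report.append(
            f"ids not contiguous 1..{len(records)}: got {sorted(seen)[:5]}..."
        )
    return report


def anthropometry_for(
    phenotype: Phenotype | str,
    sex: Sex | str,
    age: float,
    mass_pct: float,
    tone_pct: float,
    records: Sequence[PatientRecord] | None = None,
) -> Anthropometry:
    """Anthropometry for a (phenotype, sex, age, mass, tone) combination.

    Exact table lookup when the age is tabulated for that combination;
    otherwise linear interpolation on age between the two nearest tabulated
    ages, clamped to the nearest tabulated age outside the tabulated range.
    """
    phenotype = Phenotype(phenotype)
    sex = Sex(sex)
    if records is None:
        records = load_reference_cohort()
    pool = [
        r for r in records
        if r.phenotype == phenotype and r.sex == sex
        and r.mass_pct == mass_pct and r.tone_pct == tone_pct
    ]
    if not pool:
        combos = sorted(
            {(r.phenotype.value, r.sex.value, r.mass_pct, r.tone_pct) for r in records}
        )
        raise AnthropometryLookupError(
            f"no tabulated rows for ({phenotype.value}, {sex.value}, "
            f"mass {mass_pct}%, tone {tone_pct}%); valid combinations: {combos}"
        )
    by_age = {r.age: r for r in pool}
    ages = sorted(by_age)
    if age in by_age:
        r = by_age[int(age)]
        return Anthropometry(r.height, r.upperarm, r.forearm, r.hand)
    # clamp outside the tabulated range
    if age <= ages[0]:
        r = by_age[ages[0]]
        return Anthropometry(r.height, r.upperarm, r.forearm, r.hand)
    if age >= ages[-1]:
        r = by_age[ages[-1]]
        return Anthropometry(r.height, r.upperarm, r.forearm, r.hand)
    lo = max(a for a in ages if a < age)
    hi = min(a for a in ages if a > age)
    w = (age - lo) / (hi - lo)
    rl, rh = by_age[lo], by_age[hi]

    def lerp(a: float, b: float) -> float:
        return a + w * (b - a)

    return Anthropometry(
        height=lerp(rl.height, rh.height),
        upperarm=lerp(rl.upperarm, rh.upperarm),
        forearm=lerp(rl.forearm, rh.forearm),
        hand=lerp(rl.hand, rh.hand),
    )


def generic_anthropometry(records: Sequence[PatientRecord] | None = None) -> Anthropometry:
    """Cohort-mean anthropometry, used as the generic model for scaling."""
    if records is None:
        records = load_reference_cohort()
    n = len(records)
    return Anthropometry(
        height=sum(r.height for r in records) / n,
        upperarm=sum(r.upperarm for r in records) / n,
        forearm=sum(r.forearm for r in records) / n,
        hand=sum(r.hand for r in records) / n,
    )


def cohort_to_csv(records: Sequence[PatientRecord], path) -> None:
    """Write a cohort as a CSV with the reference table's column names."""
    df = pd.DataFrame(
        [
            {
                "ID": r.id,
                "Type": f"{r.phenotype.value} {r.sex.value}",
                "Age": r.age,
                "Height": r.height,
                "Mass": r.mass_pct,
                "Tone": r.tone_pct,
                "Upperarm": r.upperarm,
                "Forearm": r.forearm,
                "Hands": r.hand,
            }
            for r in records
        ],
        columns=COHORT_COLUMNS,
    )
    # Integers where exact, general format otherwise: match the packaged file.
    df.to_csv(path, index=False, float_format="%g")


def cohort_from_csv(path) -> list[PatientRecord]:
    """Read a cohort CSV (column layout of the reference table)."""
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV missing columns: {missing}")
    return [_parse_row(row) for _, row in df.iterrows()]
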