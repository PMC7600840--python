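"""Specimen data model and malar-ratio computation.

Three North American bumble bees in the subgenus *Pyrobombus* —
*Bombus sandersoni*, *B. vagans* and *B. perplexus* — are routinely
misidentified from hair colour alone.  The discriminating statistics used
throughout this package are three unit-free ratios taken under a
stereomicroscope reticle:

* ``MRL`` — malar (cheek) length / malar width,
* ``MR1`` — malar length / flagellar segment 1 length,
* ``MR3`` — malar length / flagellar segment 3 length.

Raw measurements are kept in arbitrary reticle units and never converted
to millimetres; only the ratios are carried downstream.
"""

from __future__ import annotations

import csv
import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

SPECIES = ("sandersoni", "vagans", "perplexus")
SPECIES_OR_UNKNOWN = SPECIES + ("unknown",)
CASTES = ("queen", "worker")
REGIONS = ("Midwest", "Northeast")

MESIPISTERNUM_LEVELS = ("light", "dark", "dark-light", "unknown")
ABUNDANCE_LEVELS = ("none", "few", "many", "unknown")

#: column order of the canonical specimen CSV
CSV_COLUMNS = (
    "id", "species_dna", "species_visual", "caste", "region", "observer",
    "malar_length", "malar_width", "flag1_length", "flag3_length",
    "mesipisternum", "scutum_black", "t5_yellow", "t3_yellow",
)

MEASUREMENT_FIELDS = ("malar_length", "malar_width", "flag1_length", "flag3_length")
RATIO_NAMES = ("mr1", "mr3", "mrl")


class SpecimenValidationError(ValueError):
    """Raised when a specimen record violates the data contract."""


def _canon(value: str, levels: Sequence[str], fieldname: str, row: int | None = None) -> str:
    v = str(value).strip().lower()
    for level in levels:
        if v == level.lower():
            return level
    where = f" (row {row})" if row is not None else ""
    raise SpecimenValidationError(
        f"{fieldname}={value!r} not in {list(levels)}{where}"
    )


@dataclass(frozen=True)
class HairProfile:
    """Hair-colour traits used by the field identification rules.

    ``dark-light`` mesipisternum means light hair above and dark below
    (the common *B. perplexus* pattern); plain ``dark`` lower pleura is
    diagnostic for *B. perplexus* as the other two species lack it.
    Unknown values are allowed and flagged as ``"unknown"``.
    """

    mesipisternum: str = "unknown"
    scutum_black: str = "unknown"
    t5_yellow: str = "unknown"
    t3_yellow: bool | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "mesipisternum",
                           _canon(self.mesipisternum, MESIPISTERNUM_LEVELS, "mesipisternum"))
        object.__setattr__(self, "scutum_black",
                           _canon(self.scutum_black, ABUNDANCE_LEVELS, "scutum_black"))
        object.__setattr__(self, "t5_yellow",
                           _canon(self.t5_yellow, ABUNDANCE_LEVELS, "t5_yellow"))


@dataclass(frozen=True)
class RatioSet:
    """The three derived malar ratios for one bee (dimensionless)."""

    mr1: float
    mr3: float
    mrl: float

    def __post_init__(self) -> None:
        for name in RATIO_NAMES:
            v = getattr(self, name)
            if not (v > 0) or not math.isfinite(v):
                raise SpecimenValidationError(f"ratio {name}={v!r} must be a positive finite number")

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in RATIO_NAMES}


@dataclass(frozen=True)
class SpecimenRecord:
    """One measured bee.

    All four raw measurements are in the same (arbitrary) reticle units,
    which makes the derived ratios unit-free.  ``species_dna`` is the
    barcode-confirmed label, ``species_visual`` the pre-DNA field call;
    either may be ``"unknown"``.
    """

    id: str
    caste: str
    region: str
    malar_length: float
    malar_width: float
    flag1_length: float
    flag3_length: float
    species_dna: str = "unknown"
    species_visual: str = "unknown"
    observer: str = ""
    hair: HairProfile = field(default_factory=HairProfile)

    def __post_init__(self) -> None:
        object.__setattr__(self, "species_dna",
                           _canon(self.species_dna, SPECIES_OR_UNKNOWN, "species_dna"))
        object.__setattr__(self, "species_visual",
                           _canon(self.species_visual, SPECIES_OR_UNKNOWN, "species_visual"))
        object.__setattr__(self, "caste", _canon(self.caste, CASTES, "caste"))
        object.__setattr__(self, "region", _canon(self.region, REGIONS, "region"))
        for name in MEASUREMENT_FIELDS:
            v = getattr(self, name)
            try:
                v = float(v)
            except (TypeError, ValueError):
                raise SpecimenValidationError(f"{name}={getattr(self, name)!r} is not a number")
            if not math.isfinite(v) or v <= 0:
                raise SpecimenValidationError(
                    f"measurement {name}={v!r} must be strictly positive (specimen {self.id!r})"
                )
            object.__setattr__(self, name, v)


def compute_ratios(spec: SpecimenRecord) -> RatioSet:
    """Derive (MR1, MR3, MRL) from the four raw measurements.

    MRL = malar_length / malar_width, MR1 = malar_length / flag1_length,
    MR3 = malar_length / flag3_length.  Scale-invariant: multiplying all
    four measurements by any positive constant leaves the result unchanged.

    Empirically the malar space is shorter than wide in all three species,
    so MRL >= 1 triggers a warning (not an error — it is a regularity of
    the group, not a definition).
    """
    mrl = spec.malar_length / spec.malar_width
    if mrl >= 1:
        warnings.warn(
            f"specimen {spec.id!r}: MRL={mrl:.3f} >= 1; malar length usually "
            "shorter than width in this species group — check the measurement",
            stacklevel=2,
        )
    return RatioSet(
        mr1=spec.malar_length / spec.flag1_length,
        mr3=spec.malar_length / spec.flag3_length,
        mrl=mrl,
    )


def _parse_t3(value: str, row: int) -> bool | None:
    v = str(value).strip().lower()
    if v in {"", "na", "nan", "none", "unknown"}:
        return None
    if v in {"true", "t", "yes", "1"}:
        return True
    if v in {"false", "f", "no", "0"}:
        return False
    raise SpecimenValidationError(f"t3_yellow={value!r} is not a boolean (row {row})")


def read_specimen_table(path, **dialect) -> list[SpecimenRecord]:
    """Read a canonical specimen CSV into validated records.

    Closed-vocabulary fields are normalised case-insensitively; extra
    columns are ignored with a log line; every validation message carries
    the offending 1-based data row number.
    """
    records: list[SpecimenRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, **dialect)
        header = reader.fieldnames or []
        missing = [c for c in CSV_COLUMNS if c not in header]
        if missing:
            raise SpecimenValidationError(f"missing required columns: {missing}")
        extra = [c for c in header if c not in CSV_COLUMNS]
        if extra:
            logger.info("ignoring extra columns %s in %s", extra, path)
        for row_no, row in enumerate(reader, start=1):
            try:
                hair = HairProfile(
                    mesipisternum=row["mesipisternum"] or "unknown",
                    scutum_black=row["scutum_black"] or "unknown",
                    t5_yellow=row["t5_yellow"] or "unknown",
                    t3_yellow=_parse_t3(row["t3_yellow"], row_no),
                )
                records.append(SpecimenRecord(
                    id=row["id"],
                    species_dna=row["species_dna"] or "unknown",
                    species_visual=row["species_visual"] or "unknown",
                    caste=row["caste"],
                    region=row["region"],
                    observer=row["observer"] or "",
                    malar_length=row["malar_length"],
                    malar_width=row["malar_width"],
                    flag1_length=row["flag1_length"],
                    flag3_length=row["flag3_length"],
                    hair=hair,
                ))
            except SpecimenValidationError as exc:
                raise SpecimenValidationError(f"row {row_no}: {exc}") from None
    return records


def write_specimen_table(records: Iterable[SpecimenRecord], path) -> None:
    """Write records to the canonical CSV (inverse of :func:`read_specimen_table`)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for r in records:
            writer.writerow([
                r.id, r.species_dna, r.species_visual, r.caste, r.region, r.observer,
                repr(r.malar_length), repr(r.malar_width),
                repr(r.flag1_length), repr(r.flag3_length),
                r.hair.mesipisternum, r.hair.scutum_black, r.hair.t5_yellow,
                "" if r.hair.t3_yellow is None else str(r.hair.t3_yellow).lower(),
            ])


def visual_agreement(records: Sequence[SpecimenRecord]) -> float:
    """Fraction of specimens whose field (visual) identification matches DNA.

    Both labels must be present on every record; the study-scale analogue
    of this number is the ~70% success rate of key-based identification.
    """
    if not records:
        raise SpecimenValidationError("visual_agreement: empty record list")
    for r in records:
        if r.species_visual == "unknown" or r.species_dna == "unknown":
            raise SpecimenValidationError(
                f"specimen {r.id!r} lacks a DNA or visual species label"
            )
    return sum(r.species_visual == r.species_dna for r in records) / len(records)


def ratio_table(records: Sequence[SpecimenRecord]):
    """Records -> tidy pandas DataFrame of labels and the three ratios."""
    import pandas as pd

    rows = []
    for r in records:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ratios = compute_ratios(r)
        rows.append({
            "id": r.id, "species": r.species_dna, "caste": r.caste,
            "region": r.region, "observer": r.observer, **ratios.as_dict(),
        })
    return pd.DataFrame(rows)
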