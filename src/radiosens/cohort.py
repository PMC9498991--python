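"""Domain types, validation and CSV interchange for cohort endpoint tables.

A cohort is a collection of untransformed fibroblast cell lines, one per
radiotherapy patient, each annotated with the CTCAE toxicity grade of the
patient's tissue reaction (0 = no event ... 5 = death) and a set of cellular
and molecular radiosensitivity endpoints measured after 2 Gy X-rays:

``sf2``
    clonogenic surviving fraction at 2 Gy, in percent (measured on a subset
    of lines only -- the assay takes weeks);
``mn_spont`` / ``mn_24h``
    micronuclei per 100 cells, before and 24 h after irradiation;
``h2ax_10min`` / ``h2ax_1h`` / ``h2ax_24h``
    gamma-H2AX foci per cell (DSBs recognized by NHEJ) at the given repair
    times;
``patm_10min`` / ``patm_1h``
    pATM foci per cell (nuclear ATM kinase activity) at 10 min and 1 h.

The CSV dialect is comma-separated UTF-8 with a dot decimal separator, one
header row, fixed column names (:data:`CSV_COLUMNS`), and empty cells for
missing optional values.  Lines starting with ``#`` are treated as comments
(the pipeline writes provenance that way) and ignored on read.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from enum import Enum
from typing import Iterator, Optional

import pandas as pd

from .exceptions import (
    CohortValidationError,
    DataFormatError,
    MissingDataError,
)

__all__ = [
    "Genotype",
    "CellLineRecord",
    "Cohort",
    "CSV_COLUMNS",
    "read_cohort_csv",
    "write_cohort_csv",
    "patmmax",
]


class Genotype(str, Enum):
    """Genetic background relevant to the DSB-repair phenotype."""

    WILDTYPE_LIKE = "wildtype_like"
    ATM_HOMOZYGOUS = "atm_homozygous"
    LIG4_MUTATED = "lig4_mutated"
    OTHER_SYNDROME = "other_syndrome"


#: endpoint fields that may carry a per-triplicate standard error column
_SEM_ENDPOINTS = (
    "sf2",
    "mn_spont",
    "mn_24h",
    "h2ax_10min",
    "h2ax_1h",
    "h2ax_24h",
    "patm_10min",
    "patm_1h",
)

CSV_COLUMNS = (
    "id",
    "genotype",
    "ctcae_grade",
    "sf2",
    "plating_efficiency",
    "mn_spont",
    "mn_24h",
    "h2ax_10min",
    "h2ax_1h",
    "h2ax_24h",
    "patm_10min",
    "patm_1h",
) + tuple(f"sem_{name}" for name in _SEM_ENDPOINTS)

_MANDATORY_COLUMNS = ("id", "genotype", "ctcae_grade")


@dataclass
class CellLineRecord:
    """One cell line's genotype, CTCAE grade and endpoint measurements.

    Endpoint values are per-line means over (at least) three independent
    replicates; ``sem_*`` entries, when present, are the standard errors of
    those means.  Optional fields are ``None`` when not measured.
    """

    id: str
    genotype: Genotype = Genotype.WILDTYPE_LIKE
    ctcae_grade: int = 0
    sf2: Optional[float] = None
    plating_efficiency: Optional[float] = None
    mn_spont: Optional[float] = None
    mn_24h: Optional[float] = None
    h2ax_10min: Optional[float] = None
    h2ax_1h: Optional[float] = None
    h2ax_24h: Optional[float] = None
    patm_10min: Optional[float] = None
    patm_1h: Optional[float] = None
    sem: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.genotype = Genotype(self.genotype)
        if not self.id:
            raise CohortValidationError("record id must be a non-empty string")
        if not isinstance(self.ctcae_grade, int) or isinstance(self.ctcae_grade, bool):
            if isinstance(self.ctcae_grade, float) and self.ctcae_grade.is_integer():
                self.ctcae_grade = int(self.ctcae_grade)
            else:
                raise CohortValidationError(
                    f"record {self.id!r}: ctcae_grade must be an integer, "
                    f"got {self.ctcae_grade!r}"
                )
        if not 0 <= self.ctcae_grade <= 5:
            raise CohortValidationError(
                f"record {self.id!r}: ctcae_grade must be in 0..5, "
                f"got {self.ctcae_grade}"
            )
        if self.sf2 is not None and not 0.0 < self.sf2 <= 100.0:
            raise CohortValidationError(
                f"record {self.id!r}: sf2 must lie in (0, 100], got {self.sf2}"
            )
        if self.plating_efficiency is not None and not (
            0.0 < self.plating_efficiency <= 1.0
        ):
            raise CohortValidationError(
                f"record {self.id!r}: plating_efficiency must lie in (0, 1], "
                f"got {self.plating_efficiency}"
            )
        for name in (
            "mn_spont",
            "mn_24h",
            "h2ax_10min",
            "h2ax_1h",
            "h2ax_24h",
            "patm_10min",
            "patm_1h",
        ):
            value = getattr(self, name)
            if value is None:
                continue
            if not math.isfinite(value) or value < 0:
                raise CohortValidationError(
                    f"record {self.id!r}: {name} must be finite and >= 0, "
                    f"got {value}"
                )
        for name, value in self.sem.items():
            if name not in _SEM_ENDPOINTS:
                raise CohortValidationError(
                    f"record {self.id!r}: unknown SEM endpoint {name!r}"
                )
            if value is not None and (not math.isfinite(value) or value < 0):
                raise CohortValidationError(
                    f"record {self.id!r}: sem_{name} must be >= 0, got {value}"
                )


@dataclass
class Cohort:
    """A list of validated :class:`CellLineRecord` plus provenance metadata.

    ``provenance`` is free-form (generator parameters and seed, or the
    source file path); record ids must be unique.
    """

    records: list
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            seen, dupes = set(), set()
            for i in ids:
                (dupes if i in seen else seen).add(i)
            raise CohortValidationError(
                f"duplicate record ids: {sorted(dupes)}"
            )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[CellLineRecord]:
        return iter(self.records)

    def to_frame(self) -> pd.DataFrame:
        """Tabulate the cohort with the documented column order."""
        rows = []
        for rec in self.records:
            row = {
                "id": rec.id,
                "genotype": rec.genotype.value,
                "ctcae_grade": rec.ctcae_grade,
            }
            for name in CSV_COLUMNS[3:12]:
                row[name] = getattr(rec, name)
            for name in _SEM_ENDPOINTS:
                row[f"sem_{name}"] = rec.sem.get(name)
            rows.append(row)
        return pd.DataFrame(rows, columns=list(CSV_COLUMNS))


def patmmax(record: CellLineRecord) -> float:
    """Maximal pATM foci count reached at 10 min or 1 h post-irradiation.

    The maximum over the two sampling times tracks the peak of nuclear ATM
    kinase activity regardless of whether a line has fast (peak at 10 min)
    or delayed (peak at 1 h) ATM nucleoshuttling kinetics.
    """
    values = [v for v in (record.patm_10min, record.patm_1h) if v is not None]
    if not values:
        raise MissingDataError(
            f"record {record.id!r}: neither patm_10min nor patm_1h is present"
        )
    return max(values)


def _cell(value):
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    return value


def write_cohort_csv(cohort: Cohort, path, header_comment: Optional[str] = None) -> None:
    """Write a cohort to CSV with deterministic column order.

    Missing values become empty cells.  ``header_comment``, if given, is
    written as a leading ``# ...`` line (used for provenance) and skipped
    by :func:`read_cohort_csv`.
    """
    frame = cohort.to_frame()
    with open(path, "w", encoding="utf-8", newline="") as handle:
        if header_comment is not None:
            handle.write(f"# {header_comment}\n")
        # %.17g preserves float64 exactly across a write/read cycle
        frame.to_csv(handle, index=False, float_format="%.17g")


def read_cohort_csv(path) -> Cohort:
    """Read and validate a cohort endpoint table.

    Raises :class:`DataFormatError` when a mandatory column is absent and
    :class:`CohortValidationError` (naming row and field) when a value
    violates a record invariant.
    """
    try:
        frame = pd.read_csv(path, comment="#", dtype={"id": str},
                            float_precision="round_trip")
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise DataFormatError(f"cannot parse {path}: {exc}") from exc
    for column in _MANDATORY_COLUMNS:
        if column not in frame.columns:
            raise DataFormatError(
                f"{path}: missing mandatory column {column!r}"
            )
    records = []
    for index, row in frame.iterrows():
        grade = _cell(row["ctcae_grade"])
        if grade is None:
            raise CohortValidationError(
                f"{path} row {index + 2}: ctcae_grade is missing"
            )
        if float(grade) != int(float(grade)):
            raise CohortValidationError(
                f"{path} row {index + 2}: ctcae_grade must be an integer, "
                f"got {grade!r}"
            )
        kwargs = {
            "id": str(row["id"]),
            "genotype": _cell(row.get("genotype")) or "wildtype_like",
            "ctcae_grade": int(float(grade)),
        }
        for name in CSV_COLUMNS[3:12]:
            if name in frame.columns:
                value = _cell(row[name])
                kwargs[name] = None if value is None else float(value)
        sem = {}
        for name in _SEM_ENDPOINTS:
            column = f"sem_{name}"
            if column in frame.columns:
                value = _cell(row[column])
                if value is not None:
                    sem[name] = float(value)
        kwargs["sem"] = sem
        try:
            records.append(CellLineRecord(**kwargs))
        except (CohortValidationError, ValueError) as exc:
            raise CohortValidationError(
                f"{path} row {index + 2}: {exc}"
            ) from exc
    return Cohort(records=records, provenance={"source": str(path)})
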