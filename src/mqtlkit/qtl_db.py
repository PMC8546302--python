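"""QTL compilation domain model and I/O.

A compiled QTL record carries a trait code, the mapping population it was
detected in, a peak position with a 95% confidence interval on the source
genetic map, and at least one of the two effect statistics (LOD score,
explained variance R^2).  Records missing one statistic are completed from
the other through the logistic-likelihood relation

    R^2 = 1 - 10^(-2 LOD / n)

where ``n`` is the population size; records missing both are retained but
flagged unusable for weighting.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import InvalidInputError, SchemaError

__all__ = [
    "GENOMES",
    "GROUPS",
    "WHEAT_CHROMOSOMES",
    "parse_chromosome",
    "TraitCode",
    "TraitRegistry",
    "PopulationInfo",
    "QtlRecord",
    "LoadReport",
    "estimate_r2",
    "lod_from_r2",
    "complete_record",
    "load_qtl_table",
    "write_qtl_table",
    "QTL_TABLE_COLUMNS",
]

GROUPS = (1, 2, 3, 4, 5, 6, 7)
GENOMES = ("A", "B", "D")
#: the 21 chromosomes of hexaploid bread wheat (homoeologous group x genome)
WHEAT_CHROMOSOMES = tuple(f"{g}{s}" for g in GROUPS for s in GENOMES)

_CHROM_RE = re.compile(r"^([1-7])([ABD])$")

TRAIT_CATEGORIES = ("agronomic", "quality", "micronutrient")
CROSS_TYPES = ("RIL", "DH")


def parse_chromosome(label: str) -> tuple[int, str]:
    """Split a wheat chromosome label into (homoeologous group, genome).

    >>> parse_chromosome("5A")
    (5, 'A')
    """
    m = _CHROM_RE.match(str(label).strip())
    if not m:
        raise InvalidInputError(
            f"invalid wheat chromosome label {label!r}: expected digit 1-7 "
            "followed by genome letter A/B/D"
        )
    return int(m.group(1)), m.group(2)


@dataclass(frozen=True)
class TraitCode:
    """A registered trait abbreviation with its category."""

    code: str
    category: str
    name: str = ""

    def __post_init__(self) -> None:
        if self.category not in TRAIT_CATEGORIES:
            raise InvalidInputError(
                f"trait {self.code!r}: category {self.category!r} not in "
                f"{TRAIT_CATEGORIES}"
            )


class TraitRegistry:
    """Unique-code registry of trait abbreviations.

    The packaged registry (:func:`mqtlkit.fixtures.load_trait_registry`)
    covers the 70 agronomic, quality and micronutrient codes used by the
    wheat compilation; additional codes may be registered at run time.
    """

    def __init__(self, traits: Iterable[TraitCode] = ()) -> None:
        self._traits: dict[str, TraitCode] = {}
        for t in traits:
            self.register(t)

    def register(self, trait: TraitCode) -> None:
        if trait.code in self._traits:
            raise InvalidInputError(f"duplicate trait code {trait.code!r}")
        self._traits[trait.code] = trait

    def __contains__(self, code: str) -> bool:
        return code in self._traits

    def __getitem__(self, code: str) -> TraitCode:
        return self._traits[code]

    def __len__(self) -> int:
        return len(self._traits)

    def __iter__(self):
        return iter(self._traits.values())

    def codes(self) -> list[str]:
        return list(self._traits)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TraitRegistry":
        df = pd.read_csv(path, sep="\t", comment="#")
        missing = {"code", "category"} - set(df.columns)
        if missing:
            raise SchemaError(f"trait registry missing column(s) {sorted(missing)}")
        return cls(
            TraitCode(str(r["code"]), str(r["category"]), str(r.get("name", "")))
            for _, r in df.iterrows()
        )


@dataclass(frozen=True)
class PopulationInfo:
    """A biparental mapping population (RIL or DH design)."""

    id: str
    cross_type: str
    size: int

    def __post_init__(self) -> None:
        if self.cross_type not in CROSS_TYPES:
            raise InvalidInputError(
                f"population {self.id!r}: cross_type must be one of {CROSS_TYPES}"
            )
        if int(self.size) < 2:
            raise InvalidInputError(f"population {self.id!r}: size must be >= 2")


@dataclass(frozen=True)
class QtlRecord:
    """One published QTL on its source genetic map.

    ``flags`` records quality annotations (e.g. ``no_effect_statistic`` when
    neither LOD nor R^2 is available after completion).
    """

    qtl_id: str
    trait: str
    population: PopulationInfo
    chromosome: str
    peak: float
    ci_lo: float
    ci_hi: float
    lod: float | None = None
    r2: float | None = None
    flags: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        parse_chromosome(self.chromosome)
        if not (self.ci_lo <= self.peak <= self.ci_hi):
            raise InvalidInputError(
                f"QTL {self.qtl_id!r}: CI [{self.ci_lo}, {self.ci_hi}] must "
                f"bracket the peak {self.peak}"
            )
        if self.r2 is not None and not (0.0 <= self.r2 < 1.0):
            raise InvalidInputError(f"QTL {self.qtl_id!r}: R^2 must lie in [0, 1)")
        if self.lod is not None and self.lod < 0:
            raise InvalidInputError(f"QTL {self.qtl_id!r}: LOD must be >= 0")

    @property
    def ci_width(self) -> float:
        return self.ci_hi - self.ci_lo

    @property
    def usable(self) -> bool:
        return "no_effect_statistic" not in self.flags


def estimate_r2(lod: float, n: int) -> float:
    """Explained phenotypic variance from a LOD score and population size.

    Implements ``R^2 = 1 - 10^(-2 LOD / n)``: strictly increasing in LOD,
    strictly decreasing in ``n`` for positive LOD, and always in [0, 1).
    """
    if lod < 0:
        raise InvalidInputError(f"LOD must be >= 0, got {lod}")
    if n < 2:
        raise InvalidInputError(f"population size must be >= 2, got {n}")
    return 1.0 - 10.0 ** (-2.0 * lod / n)


def lod_from_r2(r2: float, n: int) -> float:
    """Inverse of :func:`estimate_r2`: ``LOD = -n log10(1 - R^2) / 2``."""
    if not (0.0 <= r2 < 1.0):
        raise InvalidInputError(f"R^2 must lie in [0, 1), got {r2}")
    if n < 2:
        raise InvalidInputError(f"population size must be >= 2, got {n}")
    return -n * math.log10(1.0 - r2) / 2.0


def complete_record(record: QtlRecord) -> QtlRecord:
    """Fill the missing effect statistic of a record, if any.

    A missing R^2 is estimated from LOD (and vice versa) through the same
    relation, so completion round-trips.  A record with neither statistic is
    returned flagged ``no_effect_statistic`` rather than dropped: the
    meta-analysis itself only needs positions and confidence intervals.
    """
    n = record.population.size
    if record.r2 is None and record.lod is not None:
        return replace(record, r2=estimate_r2(record.lod, n))
    if record.lod is None and record.r2 is not None:
        return replace(record, lod=lod_from_r2(record.r2, n))
    if record.lod is None and record.r2 is None:
        if "no_effect_statistic" in record.flags:
            return record
        return replace(record, flags=record.flags + ("no_effect_statistic",))
    return record


QTL_TABLE_COLUMNS = [
    "qtl_id",
    "trait",
    "population",
    "cross_type",
    "pop_size",
    "chrom",
    "peak_cM",
    "ci_lo_cM",
    "ci_hi_cM",
    "lod",
    "r2",
]


@dataclass
class LoadReport:
    """Row-level accounting for a table load."""

    n_accepted: int = 0
    n_rejected: int = 0
    rejections: list[tuple[int, str]] = field(default_factory=list)

    def reject(self, row: int, reason: str) -> None:
        self.n_rejected += 1
        self.rejections.append((row, reason))


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str) and value.strip() == "":
        return None
    return float(value)


def load_qtl_table(path: str | Path) -> tuple[list[QtlRecord], LoadReport]:
    """Read a tab-separated QTL compilation.

    Every row becomes a :class:`QtlRecord` or a reported rejection (row
    number + reason); a missing mandatory column raises :class:`SchemaError`
    naming the column.  Accepted records are completed via
    :func:`complete_record`.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"trait": str, "chrom": str})
    missing = [c for c in QTL_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"QTL table {path}: missing column(s) {missing}")

    records: list[QtlRecord] = []
    report = LoadReport()
    for i, row in df.iterrows():
        rowno = int(i) + 2  # 1-based, after the header line
        try:
            peak = float(row["peak_cM"])
            ci_lo = float(row["ci_lo_cM"])
            ci_hi = float(row["ci_hi_cM"])
        except (TypeError, ValueError):
            report.reject(rowno, "non_numeric_position")
            continue
        if ci_lo > ci_hi:
            report.reject(rowno, "inverted_ci")
            continue
        try:
            pop = PopulationInfo(
                str(row["population"]), str(row["cross_type"]), int(row["pop_size"])
            )
            rec = QtlRecord(
                qtl_id=str(row["qtl_id"]),
                trait=str(row["trait"]),
                population=pop,
                chromosome=str(row["chrom"]),
                peak=peak,
                ci_lo=ci_lo,
                ci_hi=ci_hi,
                lod=_opt_float(row["lod"]),
                r2=_opt_float(row["r2"]),
            )
        except (InvalidInputError, ValueError) as exc:
            report.reject(rowno, str(exc))
            continue
        records.append(complete_record(rec))
        report.n_accepted += 1
    return records, report


def write_qtl_table(records: Sequence[QtlRecord], path: str | Path) -> None:
    """Write records in the dialect read by :func:`load_qtl_table` (lossless
    for accepted rows)."""
    rows = [
        {
            "qtl_id": r.qtl_id,
            "trait": r.trait,
            "population": r.population.id,
            "cross_type": r.population.cross_type,
            "pop_size": r.population.size,
            "chrom": r.chromosome,
            "peak_cM": r.peak,
            "ci_lo_cM": r.ci_lo,
            "ci_hi_cM": r.ci_hi,
            "lod": r.lod,
            "r2": r.r2,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=QTL_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)
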