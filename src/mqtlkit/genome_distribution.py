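"""Genome-scale distribution summaries for QTLs and MQTLs.

Counts by genome (A/B/D), homoeologous group (1-7) and chromosome, Pearson
goodness-of-fit against uniformity, centromere-anchored density profiles in
50 cM bins, and the per-chromosome QTL/MQTL count correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidInputError
from .qtl_db import GENOMES, GROUPS, parse_chromosome

__all__ = [
    "chi2_uniform",
    "count_by_genome",
    "count_by_group",
    "count_by_chromosome",
    "DensityProfile",
    "density_profile",
    "correlate_counts",
]


def chi2_uniform(counts: Sequence[int]) -> dict[str, float]:
    """Pearson goodness-of-fit of category counts against equal expecteds.

    Returns ``{"statistic", "df", "p_value"}`` with ``df = k - 1``.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size < 2:
        raise InvalidInputError("need at least 2 categories")
    if counts.sum() <= 0:
        raise InvalidInputError("total count must be > 0")
    stat, p = stats.chisquare(counts)
    return {"statistic": float(stat), "df": int(counts.size - 1), "p_value": float(p)}


def _chromosome_of(item) -> str:
    if isinstance(item, str):
        return item
    return item.chromosome


def count_by_chromosome(items: Iterable) -> dict[str, int]:
    """Counts keyed by chromosome label; items are labels or objects with a
    ``chromosome`` attribute.  Malformed labels raise."""
    out: dict[str, int] = {}
    for item in items:
        label = _chromosome_of(item)
        parse_chromosome(label)
        out[label] = out.get(label, 0) + 1
    return out


def count_by_genome(items: Iterable) -> dict[str, int]:
    """Counts for the A, B and D genomes (all keys always present)."""
    out = {g: 0 for g in GENOMES}
    for item in items:
        _, genome = parse_chromosome(_chromosome_of(item))
        out[genome] += 1
    return out


def count_by_group(items: Iterable) -> dict[int, int]:
    """Counts for homoeologous groups 1..7 (all keys always present)."""
    out = {g: 0 for g in GROUPS}
    for item in items:
        group, _ = parse_chromosome(_chromosome_of(item))
        out[group] += 1
    return out


@dataclass
class DensityProfile:
    """Counts of loci per signed 50 cM centromere-offset bin.

    Bins are half-open ``[k*w, (k+1)*w)``; offset 0 (the centromere) falls
    in the first non-negative bin.  Negative offsets are positions on the
    centromere-proximal side (short arm).
    """

    trait: str
    bin_width: float
    counts: dict[int, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "trait": self.trait,
                "bin_lo_cM": k * self.bin_width,
                "bin_hi_cM": (k + 1) * self.bin_width,
                "count": c,
            }
            for k, c in sorted(self.counts.items())
        ]
        return pd.DataFrame(rows, columns=["trait", "bin_lo_cM", "bin_hi_cM", "count"])


def density_profile(
    positions: Sequence[tuple[str, float]] | Mapping[str, Sequence[float]],
    centromeres: Mapping[str, float],
    bin_width: float = 50.0,
    trait: str = "all",
) -> tuple[DensityProfile, list[str]]:
    """Bin located loci by signed cM offset from their chromosome's centromere.

    ``positions`` is either a sequence of ``(chromosome, position_cM)``
    pairs or a mapping chromosome -> positions.  Items whose chromosome is
    missing from ``centromeres`` are excluded and reported in the second
    return value.
    """
    if isinstance(positions, Mapping):
        pairs = [(c, p) for c, ps in positions.items() for p in ps]
    else:
        pairs = list(positions)
    profile = DensityProfile(trait=trait, bin_width=bin_width)
    excluded: list[str] = []
    for chrom, pos in pairs:
        centro = centromeres.get(chrom)
        if centro is None:
            excluded.append(chrom)
            continue
        k = math.floor((pos - centro) / bin_width)
        profile.counts[k] = profile.counts.get(k, 0) + 1
    return profile, excluded


def correlate_counts(
    x: Mapping[str, int] | Sequence[float], y: Mapping[str, int] | Sequence[float]
) -> dict[str, float]:
    """Pearson correlation between paired per-chromosome counts.

    Mappings are aligned on their shared keys; sequences positionally.
    Returns ``{"r", "p_value", "n"}``; zero variance on either side raises.
    """
    if isinstance(x, Mapping) and isinstance(y, Mapping):
        keys = sorted(set(x) & set(y))
        xv = np.array([x[k] for k in keys], dtype=float)
        yv = np.array([y[k] for k in keys], dtype=float)
    else:
        xv = np.asarray(x, dtype=float)
        yv = np.asarray(y, dtype=float)
    if xv.size < 3 or xv.size != yv.size:
        raise InvalidInputError("need paired vectors of length >= 3")
    if np.std(xv) == 0 or np.std(yv) == 0:
        raise InvalidInputError("zero variance: correlation undefined")
    r, p = stats.pearsonr(xv, yv)
    return {"r": float(r), "p_value": float(p), "n": int(xv.size)}
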