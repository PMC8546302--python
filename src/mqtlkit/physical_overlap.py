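"""Physical anchoring of MQTLs and overlap with GWAS signals and synteny.

MQTL genetic intervals are anchored to Mb coordinates through the physical
positions of their flanking markers.  Overlap conventions are closed
intervals on Mb reals: a GWAS SNP overlaps an interval iff it lies between
the bounds inclusive; a gene supports a syntenic pairing if it overlaps the
interval at all (any-overlap, so boundary genes rounded in published
tables are not dropped).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .errors import InvalidInputError
from .map_projection import GeneticMap
from .meta_analysis import MetaQtl

__all__ = [
    "PhysicalInterval",
    "GwasSignal",
    "OrthologPair",
    "anchor_mqtl",
    "gwas_overlap",
    "detect_ormqtl",
    "intervals_to_bed",
]


@dataclass(frozen=True)
class PhysicalInterval:
    """Mb-scale anchoring of one MQTL (closed interval)."""

    mqtl: str
    chromosome: str
    start: float
    end: float
    substituted_markers: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise InvalidInputError(
                f"interval {self.mqtl!r}: start must be <= end"
            )
        if self.start < 0:
            raise InvalidInputError(f"interval {self.mqtl!r}: negative coordinate")

    def contains(self, chromosome: str, position: float) -> bool:
        return chromosome == self.chromosome and self.start <= position <= self.end

    def overlaps(self, chromosome: str, start: float, end: float) -> bool:
        return (
            chromosome == self.chromosome
            and start <= self.end
            and end >= self.start
        )


@dataclass(frozen=True)
class GwasSignal:
    snp_id: str
    chromosome: str
    position: float
    trait: str
    study: str = ""


@dataclass(frozen=True)
class OrthologPair:
    """An ortholog gene pair across two species with Mb coordinates."""

    gene_a: str
    species_a: str
    chr_a: str
    start_a: float
    end_a: float
    gene_b: str
    species_b: str
    chr_b: str
    start_b: float
    end_b: float

    def __post_init__(self) -> None:
        if self.species_a == self.species_b:
            raise InvalidInputError(
                f"ortholog pair {self.gene_a}/{self.gene_b}: species must differ"
            )


def anchor_mqtl(
    mqtl: MetaQtl,
    marker_mb: Mapping[str, tuple[str, float]],
    consensus: GeneticMap | None = None,
) -> PhysicalInterval:
    """Anchor an MQTL to the physical interval spanned by its flanks.

    ``marker_mb`` maps marker name -> (chromosome, Mb).  A flanking marker
    without a physical position on the MQTL's chromosome is substituted by
    the nearest mapped consensus marker on the same side (recorded in
    ``substituted_markers``); with no consensus map or no mappable marker
    on a side, anchoring fails.
    """
    positions: list[float] = []
    substituted: list[str] = []
    for side, marker in (("left", mqtl.left_marker), ("right", mqtl.right_marker)):
        pos = _physical_position(marker, mqtl.chromosome, marker_mb)
        if pos is None:
            pos, used = _substitute(side, mqtl, marker_mb, consensus)
            if pos is None:
                raise InvalidInputError(
                    f"MQTL {mqtl.name!r}: no mappable marker on the {side} side"
                )
            substituted.append(used)
        positions.append(pos)
    return PhysicalInterval(
        mqtl=mqtl.name,
        chromosome=mqtl.chromosome,
        start=min(positions),
        end=max(positions),
        substituted_markers=tuple(substituted),
    )


def _physical_position(
    marker: str | None, chromosome: str, marker_mb: Mapping[str, tuple[str, float]]
) -> float | None:
    if marker is None:
        return None
    entry = marker_mb.get(marker)
    if entry is None or entry[0] != chromosome:
        return None
    return float(entry[1])


def _substitute(
    side: str,
    mqtl: MetaQtl,
    marker_mb: Mapping[str, tuple[str, float]],
    consensus: GeneticMap | None,
) -> tuple[float | None, str]:
    """Nearest mapped consensus marker at or outside the CI bound on ``side``."""
    if consensus is None or not consensus.has_group(mqtl.chromosome):
        return None, ""
    loci = consensus.loci(mqtl.chromosome)
    if side == "left":
        candidates = [m for m in reversed(loci) if m.position <= mqtl.ci_lo]
    else:
        candidates = [m for m in loci if m.position >= mqtl.ci_hi]
    for m in candidates:
        pos = _physical_position(m.name, mqtl.chromosome, marker_mb)
        if pos is not None:
            return pos, m.name
    return None, ""


def gwas_overlap(
    intervals: Sequence[PhysicalInterval],
    signals: Sequence[GwasSignal],
    trait_filter: bool = False,
    mqtl_traits: Mapping[str, frozenset[str]] | None = None,
) -> pd.DataFrame:
    """(MQTL, SNP, trait) triples where a signal falls inside an interval.

    Closed-interval convention: a SNP exactly at a bound overlaps.  With
    ``trait_filter`` the signal's trait must also belong to the MQTL's
    trait set (``mqtl_traits``: name -> trait set).
    """
    rows = []
    for iv in intervals:
        for sig in signals:
            if not iv.contains(sig.chromosome, sig.position):
                continue
            if trait_filter and mqtl_traits is not None:
                if sig.trait not in mqtl_traits.get(iv.mqtl, frozenset()):
                    continue
            rows.append(
                {
                    "mqtl": iv.mqtl,
                    "chromosome": iv.chromosome,
                    "start_mb": iv.start,
                    "end_mb": iv.end,
                    "snp": sig.snp_id,
                    "snp_mb": sig.position,
                    "trait": sig.trait,
                    "study": sig.study,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "mqtl", "chromosome", "start_mb", "end_mb",
            "snp", "snp_mb", "trait", "study",
        ],
    )


def detect_ormqtl(
    intervals_a: Sequence[PhysicalInterval],
    intervals_b: Sequence[PhysicalInterval],
    pairs: Sequence[OrthologPair],
) -> pd.DataFrame:
    """Orthologous MQTL pairs supported by shared ortholog genes.

    An (interval_a, interval_b) pair is reported iff at least one ortholog
    pair has its A-side gene overlapping interval_a and its B-side gene
    overlapping interval_b (any-overlap).  Symmetric in the two species:
    genes are matched to whichever side their interval set belongs to.
    Supporting gene pairs are grouped per interval pair.
    """
    rows = []
    for iva in intervals_a:
        for ivb in intervals_b:
            support = []
            for p in pairs:
                a_hit = iva.overlaps(p.chr_a, p.start_a, p.end_a)
                b_hit = ivb.overlaps(p.chr_b, p.start_b, p.end_b)
                # reversed orientation: pair's A side lives in species B
                a_hit_rev = iva.overlaps(p.chr_b, p.start_b, p.end_b)
                b_hit_rev = ivb.overlaps(p.chr_a, p.start_a, p.end_a)
                if a_hit and b_hit:
                    support.append(f"{p.gene_a}~{p.gene_b}")
                elif a_hit_rev and b_hit_rev:
                    support.append(f"{p.gene_b}~{p.gene_a}")
            if support:
                rows.append(
                    {
                        "mqtl_a": iva.mqtl,
                        "chr_a": iva.chromosome,
                        "mqtl_b": ivb.mqtl,
                        "chr_b": ivb.chromosome,
                        "n_support": len(support),
                        "supporting_pairs": ";".join(support),
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["mqtl_a", "chr_a", "mqtl_b", "chr_b", "n_support", "supporting_pairs"],
    )


def intervals_to_bed(intervals: Sequence[PhysicalInterval], path: str | Path) -> None:
    """Write intervals as BED (0-based half-open, coordinates in bp).

    The stored Mb reals are converted as start_bp = round(start * 1e6)
    (already 0-based inclusive) and end_bp = round(end * 1e6) + 1 (exclusive).
    """
    with open(path, "w") as fh:
        for iv in intervals:
            start_bp = int(round(iv.start * 1e6))
            end_bp = int(round(iv.end * 1e6)) + 1
            fh.write(f"{iv.chromosome}\t{start_bp}\t{end_bp}\t{iv.mqtl}\n")
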