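"""Consensus-map construction and QTL projection.

A consensus map is built around a fixed reference: reference marker
positions are preserved verbatim and component-only markers are placed by
linear interpolation between the nearest shared anchor markers.  QTL peaks
and confidence-interval endpoints travel from a component map to the
consensus through the same flanking-shared-anchor linear rule; points that
fall outside the outermost shared anchors are dropped (not extrapolated),
which is the mechanism behind projection attrition in compiled studies.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError, SchemaError
from .qtl_db import QtlRecord

__all__ = [
    "MarkerLocus",
    "GeneticMap",
    "ProjectedQtl",
    "ProjectionStatus",
    "build_consensus_map",
    "project_qtl",
    "project_all",
]

#: maximum disagreement (cM) between two components' interpolated placements
#: of the same new marker before the marker is flagged conflicting
CONFLICT_TOLERANCE_CM = 5.0


@dataclass(frozen=True)
class MarkerLocus:
    name: str
    linkage_group: str
    position: float

    def __post_init__(self) -> None:
        if self.position < 0:
            raise InvalidInputError(
                f"marker {self.name!r}: position must be >= 0 cM"
            )


class GeneticMap:
    """Ordered marker loci per linkage group.

    Positions are non-decreasing within a group; co-segregating markers may
    share a position.  ``(name, linkage_group)`` is unique within one map.
    """

    def __init__(self, map_id: str, loci: Iterable[MarkerLocus] = ()) -> None:
        self.map_id = map_id
        self._groups: dict[str, list[MarkerLocus]] = {}
        seen: set[tuple[str, str]] = set()
        for locus in loci:
            key = (locus.name, locus.linkage_group)
            if key in seen:
                raise InvalidInputError(
                    f"map {map_id!r}: duplicate marker {locus.name!r} on "
                    f"group {locus.linkage_group!r}"
                )
            seen.add(key)
            self._groups.setdefault(locus.linkage_group, []).append(locus)
        for group in self._groups.values():
            group.sort(key=lambda m: m.position)

    @property
    def linkage_groups(self) -> list[str]:
        return sorted(self._groups)

    @property
    def n_markers(self) -> int:
        return sum(len(g) for g in self._groups.values())

    @property
    def total_length(self) -> float:
        return float(
            sum(g[-1].position - g[0].position for g in self._groups.values() if g)
        )

    def loci(self, group: str) -> list[MarkerLocus]:
        return list(self._groups.get(group, []))

    def has_group(self, group: str) -> bool:
        return group in self._groups

    def position_of(self, name: str, group: str) -> float | None:
        for locus in self._groups.get(group, []):
            if locus.name == name:
                return locus.position
        return None

    def marker_names(self, group: str) -> set[str]:
        return {m.name for m in self._groups.get(group, [])}

    def shared_anchors(self, other: "GeneticMap", group: str) -> list[str]:
        """Markers present on ``group`` in both maps, ordered by this map."""
        other_names = other.marker_names(group)
        return [m.name for m in self._groups.get(group, []) if m.name in other_names]

    # ---- I/O -------------------------------------------------------------

    @classmethod
    def from_dataframe(cls, map_id: str, df: pd.DataFrame) -> "GeneticMap":
        required = {"marker", "linkage_group", "position_cM"}
        missing = required - set(df.columns)
        if missing:
            raise SchemaError(f"map table: missing column(s) {sorted(missing)}")
        return cls(
            map_id,
            (
                MarkerLocus(str(r["marker"]), str(r["linkage_group"]), float(r["position_cM"]))
                for _, r in df.iterrows()
            ),
        )

    @classmethod
    def from_tsv(cls, path: str | Path, map_id: str | None = None) -> "GeneticMap":
        df = pd.read_csv(path, sep="\t", comment="#", dtype={"linkage_group": str})
        return cls.from_dataframe(map_id or Path(path).stem, df)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"marker": m.name, "linkage_group": g, "position_cM": m.position}
            for g in self.linkage_groups
            for m in self._groups[g]
        ]
        return pd.DataFrame(rows, columns=["marker", "linkage_group", "position_cM"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


class ProjectionStatus:
    PROJECTED = "projected"
    NO_ANCHORS = "no_anchors"
    OUTSIDE_ANCHORS = "outside_anchors"
    INVERTED_ANCHOR_ORDER = "inverted_anchor_order"
    NO_MAP = "no_map"


@dataclass(frozen=True)
class ProjectedQtl:
    source: QtlRecord
    status: str
    consensus_peak: float | None = None
    consensus_ci_lo: float | None = None
    consensus_ci_hi: float | None = None
    left_anchor: str | None = None
    right_anchor: str | None = None


def _interp_point(
    x: float, comp_pos: np.ndarray, cons_pos: np.ndarray
) -> tuple[float, int] | None:
    """Map ``x`` through the flanking-anchor linear rule.

    Returns (mapped position, left-anchor index) or ``None`` when ``x`` lies
    outside the outermost shared anchors.  Anchor hits map exactly.
    """
    if x < comp_pos[0] or x > comp_pos[-1]:
        return None
    j = bisect_right(comp_pos, x) - 1
    if j >= len(comp_pos) - 1:  # x == last anchor
        return float(cons_pos[-1]), len(comp_pos) - 2
    lo, hi = comp_pos[j], comp_pos[j + 1]
    if hi == lo:  # co-segregating anchors
        return float(cons_pos[j]), j
    t = (x - lo) / (hi - lo)
    return float(cons_pos[j] + t * (cons_pos[j + 1] - cons_pos[j])), j


def _anchor_arrays(
    component: GeneticMap, consensus: GeneticMap, group: str
) -> tuple[np.ndarray, np.ndarray, list[str]] | str:
    """Shared-anchor coordinate arrays, or a failure status string."""
    names = component.shared_anchors(consensus, group)
    if len(names) < 2:
        return ProjectionStatus.NO_ANCHORS
    comp_pos = np.array([component.position_of(n, group) for n in names], dtype=float)
    cons_pos = np.array([consensus.position_of(n, group) for n in names], dtype=float)
    # component ordering is non-decreasing by construction; an order
    # inversion on the consensus side flags a rearranged group
    if np.any(np.diff(cons_pos) < 0):
        return ProjectionStatus.INVERTED_ANCHOR_ORDER
    return comp_pos, cons_pos, names


def build_consensus_map(
    reference: GeneticMap, components: Sequence[GeneticMap]
) -> tuple[GeneticMap, pd.DataFrame]:
    """Integrate component maps around a fixed reference.

    Reference positions are preserved verbatim.  A component-only marker
    between shared anchors is placed by linear interpolation; placements of
    the same marker proposed by several components are averaged when they
    agree to within ``CONFLICT_TOLERANCE_CM`` and flagged conflicting
    otherwise.  Markers outside the anchored span, and component groups with
    fewer than two shared anchors, are reported unplaced.

    Returns the consensus map and an integration report with one row per
    unplaced/conflicting marker or skipped group.
    """
    placements: dict[tuple[str, str], list[float]] = {}
    report_rows: list[dict] = []

    for comp in components:
        for group in comp.linkage_groups:
            if not reference.has_group(group):
                report_rows.append(
                    {"map": comp.map_id, "linkage_group": group, "marker": "*",
                     "reason": "group_absent_from_reference"}
                )
                continue
            arrays = _anchor_arrays(comp, reference, group)
            if isinstance(arrays, str):
                report_rows.append(
                    {"map": comp.map_id, "linkage_group": group, "marker": "*",
                     "reason": arrays}
                )
                continue
            comp_pos, cons_pos, shared = arrays
            shared_set = set(shared)
            for locus in comp.loci(group):
                if locus.name in shared_set or locus.name in reference.marker_names(group):
                    continue
                mapped = _interp_point(locus.position, comp_pos, cons_pos)
                if mapped is None:
                    report_rows.append(
                        {"map": comp.map_id, "linkage_group": group,
                         "marker": locus.name, "reason": "outside_anchors"}
                    )
                    continue
                placements.setdefault((locus.name, group), []).append(mapped[0])

    new_loci: list[MarkerLocus] = []
    for (name, group), positions in placements.items():
        if max(positions) - min(positions) > CONFLICT_TOLERANCE_CM:
            report_rows.append(
                {"map": "*", "linkage_group": group, "marker": name,
                 "reason": "conflicting_placements"}
            )
            continue
        new_loci.append(MarkerLocus(name, group, float(np.mean(positions))))

    consensus = GeneticMap(
        f"{reference.map_id}+consensus",
        [m for g in reference.linkage_groups for m in reference.loci(g)] + new_loci,
    )
    report = pd.DataFrame(
        report_rows, columns=["map", "linkage_group", "marker", "reason"]
    )
    return consensus, report


def project_qtl(
    qtl: QtlRecord, component: GeneticMap, consensus: GeneticMap
) -> ProjectedQtl:
    """Project one QTL's peak and CI endpoints onto the consensus map.

    Each of the three points uses its own bracketing shared-anchor pair
    (piecewise-linear consistency); any point outside the outermost shared
    anchors fails the whole projection with ``outside_anchors``.
    """
    group = qtl.chromosome
    if not component.has_group(group) or not consensus.has_group(group):
        raise InvalidInputError(
            f"QTL {qtl.qtl_id!r}: linkage group {group!r} absent from "
            "component or consensus map"
        )
    arrays = _anchor_arrays(component, consensus, group)
    if isinstance(arrays, str):
        return ProjectedQtl(source=qtl, status=arrays)
    comp_pos, cons_pos, names = arrays

    mapped = [_interp_point(x, comp_pos, cons_pos) for x in (qtl.ci_lo, qtl.peak, qtl.ci_hi)]
    if any(m is None for m in mapped):
        return ProjectedQtl(source=qtl, status=ProjectionStatus.OUTSIDE_ANCHORS)
    (lo, _), (peak, j), (hi, _) = mapped  # type: ignore[misc]
    return ProjectedQtl(
        source=qtl,
        status=ProjectionStatus.PROJECTED,
        consensus_peak=peak,
        consensus_ci_lo=min(lo, hi),
        consensus_ci_hi=max(lo, hi),
        left_anchor=names[j],
        right_anchor=names[j + 1],
    )


def project_all(
    qtls: Sequence[QtlRecord],
    maps: Mapping[str, GeneticMap],
    consensus: GeneticMap,
) -> tuple[list[ProjectedQtl], dict[str, int]]:
    """Project a compilation; ``maps`` keys are population ids.

    Returns the projections plus an attrition summary counting each status
    (QTLs citing an unknown map are counted under ``no_map``).
    """
    out: list[ProjectedQtl] = []
    summary = {
        ProjectionStatus.PROJECTED: 0,
        ProjectionStatus.NO_ANCHORS: 0,
        ProjectionStatus.OUTSIDE_ANCHORS: 0,
        ProjectionStatus.INVERTED_ANCHOR_ORDER: 0,
        ProjectionStatus.NO_MAP: 0,
    }
    for qtl in qtls:
        component = maps.get(qtl.population.id)
        if component is None:
            out.append(ProjectedQtl(source=qtl, status=ProjectionStatus.NO_MAP))
            summary[ProjectionStatus.NO_MAP] += 1
            continue
        proj = project_qtl(qtl, component, consensus)
        out.append(proj)
        summary[proj.status] += 1
    return out, summary
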