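"""Synthetic multi-population QTL compilations with known ground truth.

The generator emulates the structure of a literature QTL compilation: per
chromosome, a handful of true consensus loci; per locus, member QTLs whose
peaks scatter around the locus mean with heteroscedastic positional SDs
drawn from a log-normal CI-width distribution; per mapping population, a
component genetic map derived from the reference by a monotone
piecewise-linear distortion with marker subsampling.  Trait labels carry
configurable pairwise co-occurrence odds so co-localization statistics
have a known truth, and a configured fraction of QTLs is deliberately
placed beyond the shared-anchor span of its component map to force exact,
constructed projection attrition.

Because component-map distortions are piecewise-linear with knots at the
shared anchors, flanking-anchor projection inverts the distortion exactly:
recovery error in the pipeline comes from sampling noise alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .map_projection import GeneticMap, MarkerLocus
from .meta_analysis import CI_TO_SD_FACTOR, MetaQtl
from .qtl_db import PopulationInfo, QtlRecord, estimate_r2

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "SyntheticStudy",
    "generate_study",
    "recovery_report",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of the generator.

    Defaults mirror the compiled wheat study this toolkit targets: 21
    chromosomes, 27 biparental populations of 92-485 lines, log-normal CI
    widths with median ~13.7 cM, and a 20% constructed projection-attrition
    fraction.
    """

    seed: int
    n_chromosomes: int = 21
    chromosome_length_cm: float = 160.0
    n_populations: int = 27
    population_size_range: tuple[int, int] = (92, 485)
    n_true_clusters: int = 3
    members_per_cluster: int = 6
    min_cluster_separation_cm: float = 25.0
    #: log-normal parameters of the original 95% CI width (cM);
    #: median = exp(mu) ~ 13.7 cM
    ci_width_log_mu: float = math.log(13.7)
    ci_width_log_sigma: float = 0.35
    trait_base_rates: Mapping[str, float] = field(
        default_factory=lambda: {
            "TKW": 0.45, "GY": 0.40, "NG": 0.30, "PH": 0.25,
            "GPC": 0.20, "GFeC": 0.20, "GZnC": 0.15, "SNS": 0.20,
        }
    )
    #: designated trait pairs whose co-occurrence odds are multiplied
    cooccurrence_odds: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: {("GFeC", "GZnC"): 6.0, ("GY", "TKW"): 3.0}
    )
    anchor_spacing_cm: float = 10.0
    attrition_fraction: float = 0.2
    missing_stat_rate: float = 0.3
    stretch_range: tuple[float, float] = (0.85, 1.18)
    edge_margin_cm: float = 15.0

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1 or self.n_populations < 1:
            raise InvalidInputError("counts must be positive")
        if not (0.0 <= self.attrition_fraction < 1.0):
            raise InvalidInputError("attrition fraction must lie in [0, 1)")
        usable = self.chromosome_length_cm - 2 * self.edge_margin_cm
        if (self.n_true_clusters - 1) * self.min_cluster_separation_cm > usable:
            raise InvalidInputError(
                "infeasible separation: too many clusters for the chromosome length"
            )

    @property
    def chromosomes(self) -> list[str]:
        labels = [f"{g}{s}" for g in range(1, 8) for s in "ABD"]
        return labels[: self.n_chromosomes]


@dataclass
class SyntheticTruth:
    """Ground truth of one generated study."""

    cluster_means: dict[str, list[float]]  # chromosome -> true means (reference cM)
    qtl_cluster: dict[str, tuple[str, int]]  # qtl_id -> (chromosome, cluster index)
    qtl_attrition: dict[str, bool]  # qtl_id -> constructed-attrition flag
    map_stretch: dict[str, list[float]]  # population -> per-interval stretch factors

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        clusters = pd.DataFrame(
            [
                {"chromosome": c, "cluster": i, "mean_cM": m}
                for c, means in self.cluster_means.items()
                for i, m in enumerate(means)
            ]
        )
        qtls = pd.DataFrame(
            [
                {
                    "qtl_id": q,
                    "chromosome": cc[0],
                    "cluster": cc[1],
                    "attrition": self.qtl_attrition[q],
                }
                for q, cc in self.qtl_cluster.items()
            ]
        )
        return clusters, qtls


@dataclass
class SyntheticStudy:
    """Everything a pipeline run needs, plus the truth."""

    config: SimulationConfig
    reference: GeneticMap
    component_maps: dict[str, GeneticMap]  # population id -> map
    qtls: list[QtlRecord]
    truth: SyntheticTruth


def _place_cluster_means(
    rng: np.random.Generator, cfg: SimulationConfig
) -> list[float]:
    """Stratified placement with guaranteed pairwise separation."""
    lo = cfg.edge_margin_cm
    hi = cfg.chromosome_length_cm - cfg.edge_margin_cm
    k = cfg.n_true_clusters
    sep = cfg.min_cluster_separation_cm
    slack = (hi - lo) - (k - 1) * sep
    offsets = np.sort(rng.uniform(0.0, slack, size=k))
    return [float(lo + offsets[j] + j * sep) for j in range(k)]


def _component_map(
    rng: np.random.Generator,
    reference: GeneticMap,
    pop_id: str,
    cfg: SimulationConfig,
) -> tuple[GeneticMap, dict[str, tuple[np.ndarray, np.ndarray]], list[float]]:
    """Derive one component map by marker subsampling plus a monotone
    piecewise-linear stretch with knots at the retained anchors.

    Returns the map, per-chromosome (reference anchors, component anchors)
    arrays for coordinate transforms, and the stretch factors used.
    """
    loci: list[MarkerLocus] = []
    transforms: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    stretches: list[float] = []
    for chrom in reference.linkage_groups:
        ref_loci = reference.loci(chrom)
        # keep every other marker but always the terminal anchors
        keep = [m for i, m in enumerate(ref_loci) if i % 2 == 0 or i == len(ref_loci) - 1]
        ref_pos = np.array([m.position for m in keep])
        comp_pos = np.empty_like(ref_pos)
        comp_pos[0] = ref_pos[0]
        for j in range(1, len(ref_pos)):
            f = rng.uniform(*cfg.stretch_range)
            stretches.append(float(f))
            comp_pos[j] = comp_pos[j - 1] + f * (ref_pos[j] - ref_pos[j - 1])
        loci.extend(
            MarkerLocus(m.name, chrom, float(p)) for m, p in zip(keep, comp_pos)
        )
        transforms[chrom] = (ref_pos, comp_pos)
    return GeneticMap(pop_id, loci), transforms, stretches


def _ref_to_component(x: float, ref_pos: np.ndarray, comp_pos: np.ndarray) -> float:
    """Apply the piecewise-linear distortion (reference cM -> component cM)."""
    return float(np.interp(x, ref_pos, comp_pos))


def _draw_cluster_traits(
    rng: np.random.Generator, cfg: SimulationConfig
) -> list[str]:
    """Trait set of one true locus: base rates with pairwise odds boosts."""
    present: dict[str, bool] = {}
    rates = dict(cfg.trait_base_rates)
    for trait, rate in rates.items():
        present[trait] = bool(rng.random() < rate)
    for (a, b), mult in cfg.cooccurrence_odds.items():
        if a in present and b in rates and present.get(a):
            p = rates[b]
            boosted = mult * p / (1.0 - p + mult * p)
            present[b] = bool(rng.random() < boosted)
    chosen = [t for t, v in present.items() if v]
    if not chosen:
        chosen = [str(rng.choice(list(rates)))]
    return chosen


def generate_study(config: SimulationConfig) -> SyntheticStudy:
    """Generate a full synthetic study; byte-identical for equal seeds."""
    rng = np.random.default_rng(config.seed)
    cfg = config

    # reference map: evenly spaced anchors per chromosome
    ref_loci = []
    for chrom in cfg.chromosomes:
        positions = np.arange(0.0, cfg.chromosome_length_cm + 1e-9, cfg.anchor_spacing_cm)
        ref_loci.extend(
            MarkerLocus(f"M_{chrom}_{i:03d}", chrom, float(p))
            for i, p in enumerate(positions)
        )
    reference = GeneticMap("reference", ref_loci)

    populations = [
        PopulationInfo(
            f"POP{i+1:02d}",
            "RIL" if rng.random() < 20 / 27 else "DH",
            int(rng.integers(*cfg.population_size_range, endpoint=True)),
        )
        for i in range(cfg.n_populations)
    ]
    component_maps: dict[str, GeneticMap] = {}
    transforms: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
    stretch: dict[str, list[float]] = {}
    for pop in populations:
        cmap, tfm, fs = _component_map(rng, reference, pop.id, cfg)
        component_maps[pop.id] = cmap
        transforms[pop.id] = tfm
        stretch[pop.id] = fs

    cluster_means: dict[str, list[float]] = {}
    qtl_rows: list[dict] = []
    for chrom in cfg.chromosomes:
        means = _place_cluster_means(rng, cfg)
        cluster_means[chrom] = means
        for ci, mu in enumerate(means):
            traits = _draw_cluster_traits(rng, cfg)
            for _ in range(cfg.members_per_cluster):
                pop = populations[int(rng.integers(len(populations)))]
                ci_width = float(
                    rng.lognormal(cfg.ci_width_log_mu, cfg.ci_width_log_sigma)
                )
                s = ci_width / CI_TO_SD_FACTOR
                peak_ref = float(rng.normal(mu, s))
                # keep the true peak inside the anchored span
                peak_ref = float(
                    np.clip(peak_ref, 0.5, cfg.chromosome_length_cm - 0.5)
                )
                trait = str(rng.choice(traits))
                qtl_rows.append(
                    {
                        "chrom": chrom,
                        "cluster": ci,
                        "pop": pop,
                        "trait": trait,
                        "peak_ref": peak_ref,
                        "s": s,
                    }
                )

    # constructed attrition: exactly floor(frac * N) QTLs moved beyond the
    # outermost shared anchor of their component map
    n_total = len(qtl_rows)
    n_attrit = int(math.floor(cfg.attrition_fraction * n_total))
    attrit_idx = set(
        rng.choice(n_total, size=n_attrit, replace=False).tolist()
    )

    qtls: list[QtlRecord] = []
    truth = SyntheticTruth(
        cluster_means=cluster_means,
        qtl_cluster={},
        qtl_attrition={},
        map_stretch=stretch,
    )
    for i, row in enumerate(qtl_rows):
        chrom, pop, s = row["chrom"], row["pop"], row["s"]
        ref_pos, comp_pos = transforms[pop.id][chrom]
        attrition = i in attrit_idx
        if attrition:
            # beyond the last shared anchor on the component map
            peak_comp = float(comp_pos[-1] + 5.0 + rng.uniform(0.0, 10.0))
            lo_comp = peak_comp - 1.96 * s
            hi_comp = peak_comp + 1.96 * s
        else:
            lo_ref = max(row["peak_ref"] - 1.96 * s, 0.0)
            hi_ref = min(row["peak_ref"] + 1.96 * s, cfg.chromosome_length_cm)
            peak_comp = _ref_to_component(row["peak_ref"], ref_pos, comp_pos)
            lo_comp = _ref_to_component(lo_ref, ref_pos, comp_pos)
            hi_comp = _ref_to_component(hi_ref, ref_pos, comp_pos)
        lod = float(rng.uniform(2.5, 12.0))
        r2 = estimate_r2(lod, pop.size)
        # blank one statistic at the configured missingness rate
        if rng.random() < cfg.missing_stat_rate:
            if rng.random() < 0.5:
                lod = None  # type: ignore[assignment]
            else:
                r2 = None  # type: ignore[assignment]
        qtl_id = f"Q{i+1:04d}"
        qtls.append(
            QtlRecord(
                qtl_id=qtl_id,
                trait=row["trait"],
                population=pop,
                chromosome=chrom,
                peak=peak_comp,
                ci_lo=min(lo_comp, peak_comp),
                ci_hi=max(hi_comp, peak_comp),
                lod=lod,
                r2=r2,
            )
        )
        truth.qtl_cluster[qtl_id] = (chrom, row["cluster"])
        truth.qtl_attrition[qtl_id] = attrition

    return SyntheticStudy(
        config=cfg,
        reference=reference,
        component_maps=component_maps,
        qtls=qtls,
        truth=truth,
    )


def recovery_report(
    truth: SyntheticTruth, detected: Sequence[MetaQtl]
) -> dict[str, float]:
    """Compare detected MQTLs against the generator's ground truth.

    Returns per-study aggregates: the fraction of chromosomes whose
    detected K equals the true K, the RMSE between greedily matched true
    means and consensus positions, and the pair-counting (Rand) agreement
    between true and detected memberships of non-attrition QTLs.
    """
    by_chrom: dict[str, list[MetaQtl]] = {}
    for m in detected:
        by_chrom.setdefault(m.chromosome, []).append(m)
    unknown = set(by_chrom) - set(truth.cluster_means)
    if unknown:
        raise InvalidInputError(f"detected chromosomes absent from truth: {sorted(unknown)}")

    k_correct = 0
    n_chrom = 0
    sq_errors: list[float] = []
    for chrom, true_means in truth.cluster_means.items():
        det = sorted(by_chrom.get(chrom, []), key=lambda m: m.position)
        n_chrom += 1
        if len(det) == len(true_means):
            k_correct += 1
        # greedy nearest matching on position
        remaining = [(m.position, m) for m in det]
        for mu in sorted(true_means):
            if not remaining:
                break
            j = int(np.argmin([abs(pos - mu) for pos, _ in remaining]))
            pos, _ = remaining.pop(j)
            sq_errors.append((pos - mu) ** 2)

    # membership agreement (Rand index) over QTLs present in the detection
    assigned: dict[str, str] = {}
    for m in detected:
        for q in m.members:
            assigned[q] = m.name
    ids = [q for q in assigned if q in truth.qtl_cluster]
    agree = total = 0
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            same_true = truth.qtl_cluster[ids[a]] == truth.qtl_cluster[ids[b]]
            same_det = assigned[ids[a]] == assigned[ids[b]]
            agree += int(same_true == same_det)
            total += 1
    return {
        "k_accuracy": k_correct / n_chrom if n_chrom else float("nan"),
        "position_rmse_cm": float(np.sqrt(np.mean(sq_errors))) if sq_errors else float("nan"),
        "membership_agreement": agree / total if total else 1.0,
        "n_chromosomes": n_chrom,
    }
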