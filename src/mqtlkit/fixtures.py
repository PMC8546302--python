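"""Loaders for the packaged reference tables.

The package ships small TSV fixtures transcribed from the published wheat
meta-QTL catalog and its companion tables: the 100-locus MQTL catalog, the
trait registry, physical (Mb) intervals of the most stable MQTLs, GWAS
signals co-located with them, and the syntenic interval table used for
orthologous-MQTL detection (with a synthetic stand-in ortholog-pair table,
see ``ortholog_pairs_synthetic.tsv``).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .meta_analysis import MetaQtl
from .physical_overlap import GwasSignal, OrthologPair, PhysicalInterval
from .qtl_db import TraitRegistry

__all__ = [
    "fixture_path",
    "load_trait_registry",
    "load_mqtl_catalog",
    "catalog_dataframe",
    "load_physical_intervals",
    "load_gwas_signals",
    "load_ormqtl_table",
    "load_ormqtl_intervals",
    "load_ortholog_pairs",
]


def fixture_path(name: str) -> Path:
    return Path(resources.files("mqtlkit") / "fixtures" / name)


def _read(name: str) -> pd.DataFrame:
    return pd.read_csv(fixture_path(name), sep="\t", comment="#")


def load_trait_registry() -> TraitRegistry:
    return TraitRegistry.from_tsv(fixture_path("trait_registry.tsv"))


def catalog_dataframe() -> pd.DataFrame:
    """The MQTL catalog as a raw table (one row per consensus locus)."""
    return _read("mqtl_catalog.tsv")


def load_mqtl_catalog() -> list[MetaQtl]:
    """The catalog as :class:`MetaQtl` objects.

    The published table reports the full 95% CI width; it is centred on the
    position here.  Member QTL identities are not published, so ``members``
    is empty and only the trait sets drive downstream statistics.
    """
    df = catalog_dataframe()
    out = []
    for _, r in df.iterrows():
        half = float(r["ci_cM"]) / 2.0
        pos = float(r["position_cM"])
        out.append(
            MetaQtl(
                name=str(r["name"]),
                chromosome=str(r["chromosome"]),
                position=pos,
                ci_lo=max(pos - half, 0.0),
                ci_hi=pos + half,
                members=(),
                traits=frozenset(str(r["traits"]).split(";")),
                left_marker=str(r["left_marker"]),
                right_marker=str(r["right_marker"]),
            )
        )
    return out


def load_physical_intervals() -> tuple[list[PhysicalInterval], pd.DataFrame]:
    """Mb intervals of the most stable MQTLs (plus the raw table)."""
    df = _read("mqtl_physical_intervals.tsv")
    intervals = [
        PhysicalInterval(
            mqtl=str(r["mqtl"]),
            chromosome=str(r["chromosome"]),
            start=float(r["start_mb"]),
            end=float(r["end_mb"]),
        )
        for _, r in df.iterrows()
    ]
    return intervals, df


def load_gwas_signals() -> tuple[list[GwasSignal], pd.DataFrame]:
    """GWAS signals; the table's ``mqtl`` column records the published
    co-location for cross-checking."""
    df = _read("gwas_signals.tsv")
    signals = [
        GwasSignal(
            snp_id=str(r["snp"]),
            chromosome=str(r["chromosome"]),
            position=float(r["mb"]),
            trait=str(r["trait"]),
            study=str(r["study"]),
        )
        for _, r in df.iterrows()
    ]
    return signals, df


def load_ormqtl_table() -> pd.DataFrame:
    return _read("ormqtl_intervals.tsv")


def load_ormqtl_intervals() -> tuple[list[PhysicalInterval], list[PhysicalInterval]]:
    """Wheat-side and other-species-side interval lists for synteny matching.

    Wheat sub-intervals of the same MQTL are merged to their union; rice and
    maize chromosomes are namespaced ``<species>:<chr>`` so numeric labels
    cannot collide across species.
    """
    df = load_ormqtl_table()
    wheat: dict[str, PhysicalInterval] = {}
    for _, r in df.iterrows():
        name = str(r["wheat_mqtl"])
        lo, hi = float(r["wheat_start_mb"]), float(r["wheat_end_mb"])
        if name in wheat:
            prev = wheat[name]
            lo, hi = min(lo, prev.start), max(hi, prev.end)
        wheat[name] = PhysicalInterval(
            mqtl=name, chromosome=str(r["wheat_chr"]), start=lo, end=hi
        )
    other = [
        PhysicalInterval(
            mqtl=str(r["other_mqtl"]),
            chromosome=f"{r['other_species']}:{r['other_chr']}",
            start=float(r["other_start_mb"]),
            end=float(r["other_end_mb"]),
        )
        for _, r in df.iterrows()
    ]
    return list(wheat.values()), other


def load_ortholog_pairs() -> list[OrthologPair]:
    """Synthetic stand-in ortholog pairs (one per syntenic row)."""
    df = _read("ortholog_pairs_synthetic.tsv")
    return [
        OrthologPair(
            gene_a=str(r["gene_a"]),
            species_a=str(r["species_a"]),
            chr_a=str(r["chr_a"]),
            start_a=float(r["start_a"]),
            end_a=float(r["end_a"]),
            gene_b=str(r["gene_b"]),
            species_b=str(r["species_b"]),
            chr_b=f"{r['species_b']}:{r['chr_b']}",
            start_b=float(r["start_b"]),
            end_b=float(r["end_b"]),
        )
        for _, r in df.iterrows()
    ]
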