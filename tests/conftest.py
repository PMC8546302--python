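import numpy as np
import pytest

from mqtlkit.map_projection import GeneticMap, MarkerLocus
from mqtlkit.qtl_db import PopulationInfo, QtlRecord


@pytest.fixture
def pop():
    return PopulationInfo("POP01", "RIL", 150)


@pytest.fixture
def make_qtl(pop):
    def _make(qtl_id="Q1", trait="GY", chrom="1A", peak=15.0, ci=(12.0, 18.0), lod=3.0):
        return QtlRecord(
            qtl_id=qtl_id, trait=trait, population=pop, chromosome=chrom,
            peak=peak, ci_lo=ci[0], ci_hi=ci[1], lod=lod,
        )
    return _make


@pytest.fixture
def two_anchor_maps():
    """Component anchors at 10 and 20 mapping to consensus 20 and 40
    (local scale factor 2)."""
    component = GeneticMap(
        "comp", [MarkerLocus("A", "1A", 10.0), MarkerLocus("B", "1A", 20.0)]
    )
    consensus = GeneticMap(
        "cons", [MarkerLocus("A", "1A", 20.0), MarkerLocus("B", "1A", 40.0)]
    )
    return component, consensus


@pytest.fixture
def dense_map():
    """A 0-100 cM single-group map with markers every 10 cM."""
    return GeneticMap(
        "dense",
        [MarkerLocus(f"M{i:02d}", "2B", float(10 * i)) for i in range(11)],
    )


def random_observations(rng, n, n_clusters=2, spread=40.0):
    """Clustered 1-D instances for mixture tests: returns (y, s)."""
    centers = rng.uniform(0.0, spread, size=n_clusters)
    labels = rng.integers(n_clusters, size=n)
    s = rng.lognormal(np.log(1.5), 0.4, size=n)
    y = rng.normal(centers[labels], s)
    return y, s


def separated_instance(rng):
    """Small instance with cluster separation >= 5x the largest SD;
    returns (y, s, true number of clusters)."""
    n = int(rng.integers(4, 9))
    k = int(rng.integers(1, 4))
    s = rng.lognormal(np.log(1.2), 0.3, size=n)
    sep = 5.0 * s.max()
    centers = np.cumsum(rng.uniform(sep, 2 * sep, size=k))
    y = rng.normal(centers[rng.integers(k, size=n)], s)
    return y, s, min(k, n)
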