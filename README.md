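# mqtlkit

Meta-QTL analysis for multi-study QTL compilations in hexaploid wheat
(*Triticum aestivum*), and for any crop where published QTLs from
independent biparental populations must be consolidated onto a consensus
genetic map.

Individual QTL mapping studies report broad, inconsistent positional
intervals for traits such as grain yield (GY), thousand kernel weight
(TKW), grain protein (GPC) and grain Fe/Zn content (GFeC/GZnC).
Meta-QTL analysis pools those reports: QTL peaks projected onto a common
map are modelled per chromosome as a one-dimensional Gaussian mixture

```
y_i ~ Σ_k π_k N(μ_k, s_i²),      s_i = CI_i / 3.92
```

where each observation's variance is **known**, derived from its 95%
confidence interval. The number of consensus loci K is chosen by majority
vote among AIC, AICc, AIC3, BIC and AWE, and each hard cluster becomes a
meta-QTL (MQTL) with inverse-variance position
`Σ(y_i/s_i²)/Σ(1/s_i²)` and pooled 95% CI of width `3.92/√(Σ 1/s_i²)` —
always narrower than any member interval.

The package covers the full chain:

- `qtl_db` — QTL compilation I/O, the `R² = 1 − 10^(−2·LOD/n)`
  completion rule, wheat chromosome nomenclature;
- `map_projection` — consensus-map construction around a fixed reference
  and flanking-anchor linear projection of peaks and CIs;
- `meta_analysis` — the mixture model (`QtlMixtureModel.fit()` →
  `QtlMixtureResults`), five-criterion selection, MQTL summaries;
- `genome_distribution` — genome/group/chromosome counts, chi-squared
  uniformity tests, centromere-anchored 50 cM density profiles;
- `trait_matrix` — MQTL × trait binary incidence and co-localization
  statistics;
- `physical_overlap` — Mb anchoring via flanking markers, GWAS signal
  containment, orthologous-MQTL detection through shared gene pairs;
- `synthetic_data` — ground-truth study generator for validation;
- a `mqtlkit` command-line pipeline over all of it.

A transcription of the published 100-locus wheat MQTL catalog (plus its
GWAS and synteny companion tables) ships as package fixtures.

## Worked example

Fit a two-locus mixture to four projected peaks with unit positional SD:

```python
>>> import mqtlkit as mk
>>> model = mk.QtlMixtureModel([10, 10, 50, 50], [1, 1, 1, 1])
>>> res = model.fit(2, seed=0)
>>> res.means
array([10., 50.])
>>> res.weights
array([0.5, 0.5])
```

Pool one cluster into an MQTL — two members at 10 and 14 cM, both with
s = 1 cM, give position 12 cM and a CI width of `3.92/√2` ≈ 2.77 cM:

```python
>>> obs = [mk.QtlObservation(10, 1, "qA"), mk.QtlObservation(14, 1, "qB")]
>>> m = mk.summarize_mqtl(obs, "1A")
>>> round(m.position, 2), round(m.ci_width, 2)
(12.0, 2.77)
```

Summaries of the packaged catalog:

```sh
$ mqtlkit report-fixture
catalog loci    100
mean CI (cM)    4.63
CI < 1 cM       11
per-chromosome range    2-8
MQTLs with GFeC 19
MQTLs with GZnC 12
MQTLs with GY   38
...
coloc GFeC->GZnC        66%
coloc GY->GFeC  52%
```

The mean MQTL interval of 4.63 cM (vs ~13.7 cM for the original QTLs) is
the roughly three-fold refinement that motivates the consolidation; the
66% Fe/Zn co-localization is the basis for simultaneous biofortification
breeding.

A full synthetic run, from simulation through physical overlap:

```sh
mqtlkit run-all --seed 5 --out out/demo
```

writes `qtl_table.tsv`, `projected.tsv`, `mqtl.tsv`, `criterion_trace.tsv`,
`distribution.tsv`, `trait_matrix.tsv`, `colocalization.tsv`,
`gwas_overlap.tsv` and a checksummed `manifest.tsv`; re-running with the
same seed reproduces every checksum.

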