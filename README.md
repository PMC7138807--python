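# soilbiogeo

Downstream statistics for continental-scale soil microbiome surveys: who
drives bacterial community assembly across a landscape, how fast do
communities turn over with distance, which taxa form the habitat's core,
and which taxa hold the co-occurrence network together.

The package targets the post-clustering state of a 16S amplicon survey —
an OTU count table, per-site coordinates and environmental covariates, and
optionally a phylogeny — and implements the analysis chain such surveys
use, end to end and reproducibly:

* **Diversity.** Seeded rarefaction to even depth, observed richness and
  Shannon–Wiener H (nats), Bray–Curtis and weighted UniFrac
  dissimilarities.
* **Distance decay (DDR).** Great-circle (haversine, R = 6371 km) distance
  matrices and the ordinary least-squares fit of community similarity
  `s = 1 − d` on distance over all sample pairs; the slope *w*
  (similarity/km) is the spatial turnover rate, also computed per phylum.
* **Environment–community tests.** Mantel tests, PERMANOVA (sequential
  terms, pseudo-F from Gower-centered trace forms), ANOSIM, and CAP/db-RDA
  (PCoA axes regressed on constraints), all with seeded permutation nulls
  and the +1 p-value correction.
* **Core microbiome.** Taxa at 100% prevalence, and the partitioned
  Bray–Curtis statistic
  `BC_core(j,k) = Σ_{i∈core} |x_ij − x_ik| / Σ_{i∈all} (x_ij + x_ik)`,
  whose ratio to the full Bray–Curtis is additive over taxon partitions —
  each pair's dissimilarity decomposes into shares that sum to 1.
* **Co-occurrence networks.** Spearman correlations on relative
  abundances thresholded at r > 0.6 and BH-FDR q < 0.01, topology
  (average path length, diameter, density, mean local clustering),
  uniform Erdős–Rényi G(n, m) null ensembles, betweenness-centrality
  keystone taxa, and core-vs-other sub-network contrasts.
* **Synthetic surveys with planted truth.** A generator that emulates a
  21-site continental survey (latitude-driven climate, spatially
  autocorrelated composition, core OTUs, correlated guilds, environmental
  responders, uneven 18–37k library sizes) and returns the planted
  parameters, so every stage is testable without raw sequence data.

A bundled dataset carries the environmental table of 21 maize-field soil
sites across China (pH, available K/N/P, organic C, total N, mean annual
precipitation and temperature, coordinates, soil texture).

## Worked example

```python
from soilbiogeo import haversine_matrix, load_maize_soil_metadata

geo = haversine_matrix(load_maize_soil_metadata())
pairs = geo.condensed()
print(f"{pairs.min():.0f} - {pairs.max():.0f} km")   # 87 - 4125 km
```

The pairwise site distances span 87–4125 km: the survey covers local to
continental scales, which is what makes the distance-decay fit meaningful.

On a synthetic survey (`examples/03_diversity_and_ddr.py`):

```text
rarefied to 22766 sequences/sample
mean OTU richness S = 225.8, mean Shannon H = 2.767 nats
DDR: w = -1.021e-04 similarity/km (planted -1.023e-04), R^2 = 0.421, P = 1.89e-26, 210 pairs
  Acidobacteria      w = -4.546e-05  P = 2.49e-07
  Actinobacteria     w = -9.132e-05  P = 6.88e-12
```

The fitted community slope recovers the planted turnover rate to the third
significant digit; per-phylum slopes differ, reflecting the phyla's
different effective dispersal in the generator. The environment tests on
the same data (`examples/04_environment_tests.py`):

```text
PERMANOVA  PRE: pseudo-F = 9.52, R^2 = 0.297, P = 0.001
PERMANOVA   pH: pseudo-F = 4.59, R^2 = 0.143, P = 0.003
CAP (PRE + pH): constrained inertia fraction = 0.421, pseudo-F = 6.55, P = 0.001
ANOSIM by soil type (19 samples): R = -0.096, P = 0.834
```

Precipitation and pH (the planted responder covariates) structure the
community; soil texture (not planted) does not. The network stage
(`examples/06_cooccurrence_network.py`) prints the observed topology, the
G(n, m) null comparison, and the seven highest-betweenness keystone
genera with their core membership.

Each script in `examples/` is a short, self-contained narrative for one
capability; `examples/07_full_pipeline.py` runs the whole chain through
`run_pipeline` and writes a results bundle (TSV tables, GraphML networks,
`results.json`, and a manifest sufficient to reproduce the run
bit-identically).

## Command line

```bash
soilbiogeo synth --seed 3 --out-dir survey/            # synthetic survey
soilbiogeo run --config cfg.yaml --out-dir out/        # full pipeline
soilbiogeo ddr --otu otu.tsv --meta meta.tsv --per-phylum --out ddr.tsv
soilbiogeo network --otu otu.tsv --level genus --out-prefix net
soilbiogeo core --otu otu.tsv --meta meta.tsv --out-prefix core
soilbiogeo ordinate --dist d.tsv --meta meta.tsv --terms "PRE,pH" --test cap
```

The YAML config mirrors `PipelineConfig` (input paths or a `synthetic:`
block, rarefaction policy, network thresholds `r_min`/`q_max`, core
prevalence, keystone k, permutation counts, master seed).

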