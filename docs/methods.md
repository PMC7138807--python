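# Methods

This note records the statistical model behind each stage, the defaults
and why, what the synthetic generator does and does not emulate, and the
numerical choices a maintainer would otherwise have to reverse-engineer.

## Diversity

Rarefaction is a single multivariate-hypergeometric draw per sample
(subsampling without replacement) to a common depth — by default the
minimum library size — under a stage seed. A single draw, rather than
averaging many, matches standard amplicon practice at these depths;
repeated-draw averaging can be layered on by the caller. Alpha diversity
is observed richness S and Shannon–Wiener H = −Σ p ln p in nats (natural
log, the QIIME-era convention; base-2 users can divide by ln 2).

Bray–Curtis is computed on total-sum-scaled relative abundances by
default; a counts mode exists because the partitioned core statistic is
conventionally run on rarefied counts. Weighted UniFrac (scikit-bio
backend) weights each branch by its length times the difference in
descendant abundance fractions; the normalized variant, which divides by
the pair's maximum attainable value, is the pipeline default because
distance-decay fits work on similarity 1 − d and need a [0, 1] scale.
Both variants are exposed since surveys rarely report which they used.

## Distance decay

Distances are haversine great-circle with Earth mean radius 6,371 km;
at continental scales this deviates from ellipsoidal geodesics by well
under 0.5%, which is also the tolerance used in tests of the bundled
survey's 87–4,125 km pairwise range. The DDR is ordinary least squares of
similarity on distance over all n(n−1)/2 unordered pairs. Pairs sharing a
site are not independent, so the reported slope t-test p-value is the
conventional descriptive significance; a Mantel permutation on the same
matrices is available when a valid test is needed. Per-phylum DDRs subset
the table to one phylum, re-normalize within the subset, use Bray–Curtis
(building per-phylum UniFrac subtrees would demand a phylogeny
decomposition the data rarely supports), and drop — with a reported
count — samples where the phylum is absent.

## Permutation tests

All dissimilarity tests work from the Gower-centered matrix
G = J(−D²/2)J. PCoA eigendecomposes G, keeps eigenvalues above 1e-10,
and scales scores by √λ. Negative eigenvalues from semi-metric
dissimilarities are dropped, not Lingoes/Cailliez-corrected, keeping the
inertia accounting simple and matching default capscale behaviour.

PERMANOVA uses trace forms: for hat matrix H of the cumulative design,
pseudo-F = [tr(HGH)/df_model] / [tr((I−H)G(I−H))/df_resid], with terms
added sequentially (Type I) in the order given, and p-values from raw
row/column permutation of D. ANOSIM ranks all pairwise dissimilarities
(average ties) and uses R = (r̄_between − r̄_within)/(M/2). CAP regresses
the positive-eigenvalue PCoA axis scores on the centered constraint
matrix; the SVD of the fitted values gives the constrained axes, and the
constrained-inertia pseudo-F is tested by permuting score rows. The CAP
constrained-inertia fraction is verified against R vegan's capscale to
1e-12 on a frozen geometry (vegan scales inertia by 1/(n−1); the
proportions coincide).

Every permutation engine takes a seed, uses the +1 correction
p = (1 + hits)/(1 + n_perm) so p is never 0, and offers `exact=True`
full enumeration of the n! relabelings for small n (used by the
oracle-equivalence tests). Default permutation count is 999. With
n_perm = 99 the null rejection probability at α = 0.05 is exactly 0.05
(p is uniform on {1/100, …, 1}), which is what the 1,000-simulation
calibration tests exercise for Mantel, PERMANOVA and CAP.

## Core microbiome

The core is the taxa present in every sample (prevalence threshold 1.0;
the threshold is a parameter but lower values are deliberately not the
default). The partitioned Bray–Curtis keeps the numerator sum on a taxon
subset while the denominator scales over all taxa; the contribution
fraction BC_subset/BC_all is therefore additive over disjoint partitions
and sums to 1 per pair — the property the acceptance suite checks at
1e-12. Pairs with BC_all = 0 have an undefined fraction and are excluded
with a warning. The statistic runs on rarefied counts by default, with a
relative-abundance mode retained. Genus-level environment screens sum
counts over OTUs sharing an assigned genus (unassigned-genus OTUs are
excluded at genus level only), correlate each genus with each covariate
by Spearman, adjust the whole genus × covariate family by
Benjamini–Hochberg, and mask cells unless |r| > 0.6 and q < 0.05 — the
heatmap contract.

## Co-occurrence networks

Correlations are Spearman on relative abundances (total-sum scaling);
zero-variance taxa are excluded and reported. Compositional closure can
induce spurious correlations — the known caveat that motivates
SparCC-style methods, which are out of scope here. Edges require
r > 0.6 strictly positive (an |r| option exists for sensitivity
analysis) and BH-FDR q < 0.01 over the upper-triangle family.

Topology: average path length and diameter are computed over connected
node pairs only (the excluded fraction is reported; a
largest-component-only view can be had by subgraphing); graph density is
2m/(n(n−1)); the clustering coefficient is the mean local clustering
with degree-<2 nodes contributing 0 — chosen over global transitivity
because its Erdős–Rényi expectation equals the edge probability
2m/(n(n−1)), which is the analytic check the null comparison relies on.

The null ensemble is uniform G(n, m): m distinct edges drawn by seeded
numpy sampling of pair indices, with per-replicate shortest-path metrics
computed through igraph's C core so that survey-size graphs (5,312
nodes, 181,157 edges) take a few seconds per replicate; a test pins the
igraph and networkx topology routes to each other on small graphs. At
that size the analytic null clustering is 0.012843 and the simulated
modal diameter is 3.

Betweenness is unweighted, unnormalized, endpoints excluded; keystone
taxa are the top k by betweenness (ties broken by degree then id), with
k = 7 as the conventional reporting depth for genus-level soil networks.
The core-vs-other contrast computes induced-subgraph topology per group
and a two-sided Wilcoxon rank-sum test on the full-network betweenness
values.

## Synthetic generator

Per OTU i and site s the log expected abundance is

    log λ_is = b_i + g_i(s) + γ f_{guild(i)}(s) + β_i z_c(s) + ε_is

with b_i ~ N(0, 1.5²) log-normal base abundances (core OTUs boosted by
+3), g_i a per-OTU Gaussian-process draw over sites with squared-
exponential kernel of range 1,500 km (marginal SD 1), f a shared latent
factor per guild (loading 2.0), β_i = ±1.5 per covariate SD for the
environmental responders (drawn from the core so genus screens can see
them), and iid noise ε with SD 0.5. Site profiles are the softmax of
log λ; counts are multinomial at lognormal library sizes clipped to
[18,000, 37,000], the depth range of the reference survey. Core OTUs are
floor-repaired post-draw (a zero cell takes one count from the site's
most abundant OTU), preserving library sizes exactly. The landscape
draws sites in a China-like bounding box with precipitation and
temperature strictly decreasing in latitude plus noise, and pH uniform
in [5.2, 8.9]. The phylogeny is a random binary coalescent over the
OTUs. Default 21 sites mirrors the reference survey; the default OTU
count is 800, a scale chosen so the full default pipeline runs in
minutes on one CPU while preserving all planted structure (the reference
survey's 5,318 OTUs run fine, just slower).

The planted DDR slope is not an a-priori constant: the generator fits
the DDR on the exact multinomial sampling probabilities, so recovery
tests compare the count-sampled fit against the latent structure's
implied slope and isolate count-sampling error. Slope recovery is
asserted within 2 standard errors of the pairwise OLS fit.

What the generator does not emulate: mechanistic ecology (niche/neutral
dynamics, dispersal kernels), sequencing error and chimeras, taxonomic
mis-assignment, and — importantly for network tests — compositional
effects are present but unlabeled. The spatial field and the
environmental responders create *genuine* positive co-variation between
OTUs that is not in the planted guild list, so the guild-recovery
precision scenario turns those two components off (spatial SD 0, no
responders, guild latent SD 1.0 = 2× the noise SD 0.5, 21 samples):
precision against planted edges is only meaningful when the guilds are
the sole planted positive associations. For the same reason the
"no spatial field ⇒ flat DDR" check also disables responders: climate
tracks latitude, so responders alone produce a real distance decay.
Passing recovery tests on these data show the estimators recover the
structure the generator plants; they do not certify performance under
real-data artefacts (compositional bias, sparsity at great depth
differences, taxonomic noise).

## Degenerate inputs and tie-breaks

Zero-total samples are rejected wherever relative abundances are needed;
constant covariates error in designs and are dropped with a warning in
correlation screens; constant distance vectors error in DDR and Mantel;
a constant similarity vector returns a flat DDR fit (slope 0, R² 0,
p 1). Keystone ties break by degree then lexical id so reports are
deterministic. Missing newick branch lengths default to 0 with a
warning; negative lengths are errors. Stage seeds are derived from the
master seed by hashing the stage name into a SeedSequence, so stages can
be re-run in isolation and whole bundles are byte-reproducible.

## Problem sizes in tests

The test suite runs synthetic surveys at 120–300 OTUs (the structure,
not the scale, is what the assertions exercise), 1,000-simulation
calibrations at 20 samples × 50 dimensions with 99 permutations, and a
10-replicate full-size G(5312, 181157) ensemble; the acceptance script
uses 5 replicates at that size.
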