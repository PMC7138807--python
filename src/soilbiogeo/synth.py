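"""Synthetic survey generator with planted, recoverable structure.

Emulates the post-clustering state of a continental 16S soil survey:

* a landscape of sites whose climatic covariates (mean annual
  precipitation PRE, temperature TEM) decrease with latitude plus noise,
  pH within the 5.2–8.9 survey range;
* an OTU table with log-normal base abundances, a spatially
  autocorrelated log-abundance field (Gaussian process over great-circle
  distance) that produces an approximately linear distance-decay of
  community similarity, core OTUs guaranteed present in every sample,
  "guilds" sharing a latent factor (positive cross-sample correlations a
  co-occurrence network should recover as edges), and environmental
  responder OTUs whose log abundance is linear in a named covariate;
* multinomial counts per site at log-normal library sizes (uneven depths
  in the survey's 18,000–37,000 range, motivating rarefaction);
* a random-coalescent phylogeny over the OTUs for weighted UniFrac.

Everything stochastic flows from ``config.seed``; regeneration with the
same config is bit-identical.  The planted parameters are returned as a
``SyntheticTruth`` for recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from io import StringIO
from pathlib import Path

import numpy as np
import pandas as pd
import skbio

from .diversity import bray_curtis
from .io import Lineage, OtuTable, SiteMetadata, RANKS

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_landscape",
    "generate_community",
    "generate_dataset",
]

_PHYLA = ("Proteobacteria", "Actinobacteria", "Acidobacteria", "Chloroflexi",
          "Gemmatimonadetes", "Bacteroidetes", "Planctomycetes", "Firmicutes")
# dominant-phylum mix of a typical agricultural soil survey
_PHYLUM_P = np.array([0.431, 0.244, 0.107, 0.060, 0.055, 0.045, 0.033, 0.025])
_SOIL_TYPES = ("sandy clay loam", "clay loam", "loamy clay",
               "sandy loam", "silty clay loam", "loam")


@dataclass
class SyntheticConfig:
    """Generator knobs; defaults mirror the 21-site survey's scale."""

    n_sites: int = 21
    n_otus: int = 800
    n_core: int = 40
    n_guilds: int = 5
    guild_size: int = 5
    n_env_responders: int = 10
    env_covariates: tuple[str, ...] = ("pH", "PRE")
    env_effect: float = 1.5          # log-abundance units per covariate SD
    spatial_range_km: float = 1500.0  # GP correlation length
    spatial_sd: float = 1.0          # GP marginal SD (log-abundance units)
    guild_strength: float = 2.0      # shared latent-factor loading
    noise_sd: float = 0.5            # iid log-abundance noise
    base_log_mean: float = 0.0
    base_log_sd: float = 1.5
    core_boost: float = 3.0          # added log abundance for core OTUs
    library_log_mean: float = 10.2   # lognormal library sizes ~ exp(N(mu, sd))
    library_log_sd: float = 0.15
    library_min: int = 18000
    library_max: int = 37000
    lat_range: tuple[float, float] = (18.0, 47.0)
    lon_range: tuple[float, float] = (77.0, 127.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_sites", "n_otus", "n_core", "n_guilds", "guild_size"):
            if getattr(self, name) < 0 or (name in ("n_sites", "n_otus") and getattr(self, name) == 0):
                raise ValueError(f"{name} must be positive")
        if self.n_core > self.n_otus:
            raise ValueError("n_core cannot exceed n_otus")
        if self.n_sites < 3:
            raise ValueError("need at least 3 sites")
        if self.lat_range[0] >= self.lat_range[1] or self.lon_range[0] >= self.lon_range[1]:
            raise ValueError("degenerate bounding box")
        if self.library_min < self.n_otus // 10:
            raise ValueError("library sizes too small for the OTU count")


@dataclass
class SyntheticTruth:
    """Planted parameters for recovery tests."""

    core_otu_ids: list[str]
    guilds: list[list[str]]
    guild_edges: list[tuple[str, str]]
    ddr_slope_target: float
    env_effects: dict[str, tuple[str, float]]  # otu -> (covariate, effect)
    seed: int

    def __post_init__(self) -> None:
        members = [o for g in self.guilds for o in g]
        for a, b in self.guild_edges:
            if a == b:
                raise ValueError("self-pair in guild edges")
            if a not in members or b not in members:
                raise ValueError("guild edge references unknown OTU")
        if self.ddr_slope_target > 0:
            raise ValueError("planted DDR slope must be <= 0")

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["guild_edges"] = [list(e) for e in self.guild_edges]
        payload["env_effects"] = {k: [c, float(b)] for k, (c, b) in self.env_effects.items()}
        Path(path).write_text(json.dumps(payload, indent=1))


def generate_landscape(config: SyntheticConfig) -> SiteMetadata:
    """Sites in the bounding box with latitude-driven climate.

    PRE and TEM are strictly decreasing functions of latitude plus
    Gaussian noise scaled by ``noise_sd`` (noise_sd = 0 gives a perfect
    monotone gradient); pH is uniform in [5.2, 8.9].
    """
    rng = np.random.default_rng([config.seed, 0])
    n = config.n_sites
    lat = np.sort(rng.uniform(*config.lat_range, size=n))
    lon = rng.uniform(*config.lon_range, size=n)
    lat0 = config.lat_range[0]
    pre = 2200.0 * np.exp(-(lat - lat0) / 12.0) + 120.0 * config.noise_sd * rng.normal(size=n)
    pre = np.clip(pre, 20.0, None)
    tem = 26.0 - 0.55 * (lat - lat0) + 1.2 * config.noise_sd * rng.normal(size=n)
    env = pd.DataFrame({
        "pH": np.round(rng.uniform(5.2, 8.9, size=n), 2),
        "AK": np.round(rng.lognormal(np.log(150), 0.4, size=n), 1),
        "OC": np.round(rng.lognormal(np.log(16), 0.5, size=n), 2),
        "TN": np.round(rng.lognormal(np.log(0.65), 0.4, size=n), 2),
        "AN": np.round(rng.lognormal(np.log(45), 0.7, size=n), 2),
        "AP": np.round(rng.lognormal(np.log(30), 0.8, size=n), 2),
        "PRE": np.round(pre, 1),
        "TEM": np.round(tem, 1),
    })
    return SiteMetadata(
        sample_ids=[f"SYN{i+1:02d}" for i in range(n)],
        latitude=lat,
        longitude=lon,
        env=env,
        soil_type=list(rng.choice(_SOIL_TYPES, size=n)),
    )


def _random_coalescent_newick(otu_ids: list[str], rng: np.random.Generator) -> str:
    """Random binary coalescent over the ids; exponential waiting heights."""
    if len(otu_ids) == 1:
        return f"({otu_ids[0]}:1.0);"
    nodes = [(name, 0.0) for name in otu_ids]
    height = 0.0
    while len(nodes) > 1:
        k = len(nodes)
        height += rng.exponential(2.0 / (k * (k - 1)))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        (na, ha), (nb, hb) = nodes[i], nodes[j]
        merged = f"({na}:{height - ha:.6f},{nb}:{height - hb:.6f})"
        nodes = [nodes[t] for t in range(k) if t not in (i, j)] + [(merged, height)]
    return nodes[0][0] + ";"


def _assign_taxonomy(otu_ids: list[str], special: dict[str, str],
                     rng: np.random.Generator) -> list[Lineage]:
    """Phylum mix per the dominant-soil-phyla profile; genera shared in
    small groups, ~5% left unassigned; ``special`` forces a unique genus."""
    lineages = []
    phyla = rng.choice(len(_PHYLA), size=len(otu_ids), p=_PHYLUM_P / _PHYLUM_P.sum())
    for otu, ph in zip(otu_ids, phyla):
        phylum = _PHYLA[ph]
        if otu in special:
            genus = special[otu]
        elif rng.random() < 0.05:
            genus = None
        else:
            genus = f"{phylum[:4]}_gen{int(rng.integers(max(1, len(otu_ids) // 6)))}"
        names = ["Bacteria", phylum, f"{phylum}_c", f"{phylum}_o", f"{phylum}_f", genus]
        lineages.append(Lineage(tuple(names)))
    return lineages


def generate_community(config: SyntheticConfig, landscape: SiteMetadata,
                       ) -> tuple[OtuTable, skbio.TreeNode, SyntheticTruth]:
    """Counts, tree and planted truth for a landscape.

    Log expected abundance per OTU and site is the sum of a log-normal
    base (core OTUs boosted), a site-correlated Gaussian-process field
    with range ``spatial_range_km``, a shared guild factor, a linear
    environmental response, and iid noise; counts are multinomial per site
    at lognormal library sizes.  The planted DDR slope is the fit of
    1 - Bray-Curtis on distance over the exact sampling probabilities, so
    recovery tests isolate count-sampling error.
    """
    from .spatial import ddr_fit, haversine_matrix  # local import avoids a cycle

    rng = np.random.default_rng([config.seed, 1])
    n_sites, n_otus = landscape.n_samples, config.n_otus
    otu_ids = [f"OTU{i+1:04d}" for i in range(n_otus)]

    core_ids = list(rng.choice(otu_ids, size=config.n_core, replace=False))
    # responders come from the core so genus-level environment screens see them
    responder_pool = core_ids if config.n_core >= config.n_env_responders else otu_ids
    responders = list(rng.choice(responder_pool, size=config.n_env_responders, replace=False))
    non_guild_pool = [o for o in otu_ids if o not in set(core_ids)]
    n_guild_members = config.n_guilds * config.guild_size
    guild_members = list(rng.choice(non_guild_pool, size=n_guild_members, replace=False))
    guilds = [guild_members[g * config.guild_size:(g + 1) * config.guild_size]
              for g in range(config.n_guilds)]
    guild_edges = [(a, b) for guild in guilds
                   for ai, a in enumerate(guild) for b in guild[ai + 1:]]

    col = {o: j for j, o in enumerate(otu_ids)}
    base = rng.normal(config.base_log_mean, config.base_log_sd, size=n_otus)
    base[[col[o] for o in core_ids]] += config.core_boost

    geo = haversine_matrix(landscape)
    if config.spatial_range_km > 0:
        cov = config.spatial_sd ** 2 * np.exp(-(geo.values / config.spatial_range_km) ** 2 / 2.0)
    else:  # range 0: spatially uncorrelated field
        cov = config.spatial_sd ** 2 * np.eye(n_sites)
    chol = np.linalg.cholesky(cov + 1e-10 * np.eye(n_sites))
    spatial = rng.normal(size=(n_otus, n_sites)) @ chol.T  # per-OTU GP over sites

    loglam = base[None, :] + spatial.T  # sites x otus

    for guild in guilds:
        factor = rng.normal(size=n_sites)
        for o in guild:
            loglam[:, col[o]] += config.guild_strength * factor

    env_effects: dict[str, tuple[str, float]] = {}
    for i, o in enumerate(responders):
        covname = config.env_covariates[i % len(config.env_covariates)]
        covariate = landscape.env[covname].to_numpy(float)
        z = (covariate - covariate.mean()) / covariate.std()
        beta = config.env_effect * (1 if i % 2 == 0 else -1)
        loglam[:, col[o]] += beta * z
        env_effects[o] = (covname, beta)

    loglam += rng.normal(0.0, config.noise_sd, size=(n_sites, n_otus))

    probs = np.exp(loglam - loglam.max(axis=1, keepdims=True))
    probs /= probs.sum(axis=1, keepdims=True)

    libs = np.exp(rng.normal(config.library_log_mean, config.library_log_sd, size=n_sites))
    libs = np.clip(libs, config.library_min, config.library_max).astype(np.int64)
    counts = np.vstack([rng.multinomial(libs[s], probs[s]) for s in range(n_sites)])

    # floor: core OTUs must be present everywhere; repair zero cells while
    # preserving the library size by borrowing from the site's top OTU
    core_cols = [col[o] for o in core_ids]
    for s in range(n_sites):
        for c in core_cols:
            if counts[s, c] == 0:
                donor = int(np.argmax(counts[s]))
                counts[s, donor] -= 1
                counts[s, c] = 1

    special = {o: f"Responder_{o}" for o in responders}
    special.update({o: f"Guild{g+1}_{o}" for g, guild in enumerate(guilds) for o in guild})
    lineages = _assign_taxonomy(otu_ids, special, rng)

    table = OtuTable(list(landscape.sample_ids), otu_ids, counts, lineages)

    tree_rng = np.random.default_rng([config.seed, 2])
    tree = skbio.TreeNode.read(StringIO(_random_coalescent_newick(otu_ids, tree_rng)))

    # planted DDR slope: similarity of the exact sampling probabilities
    prob_table = OtuTable(list(landscape.sample_ids), otu_ids,
                          np.round(probs * 10 ** 9).astype(np.int64))
    fit = ddr_fit(geo, bray_curtis(prob_table, on="counts"))
    slope = min(fit.slope, 0.0)

    truth = SyntheticTruth(core_otu_ids=sorted(core_ids), guilds=guilds,
                           guild_edges=guild_edges, ddr_slope_target=slope,
                           env_effects=env_effects, seed=config.seed)
    return table, tree, truth


def generate_dataset(config: SyntheticConfig,
                     ) -> tuple[SiteMetadata, OtuTable, skbio.TreeNode, SyntheticTruth]:
    """Landscape + community in one call."""
    landscape = generate_landscape(config)
    table, tree, truth = generate_community(config, landscape)
    return landscape, table, tree, truth
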