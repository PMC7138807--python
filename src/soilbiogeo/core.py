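"""Core microbiome: detection, partitioned Bray–Curtis contribution, and
environment correlations.

The core microbiome is the set of taxa present in every sample (100%
prevalence by default).  Its share of community dissimilarity is measured
by the partitioned Bray–Curtis statistic: for a sample pair (j, k),

    BC_core(j, k) = sum_{i in core} |x_ij - x_ik| / sum_{i in all} (x_ij + x_ik)

i.e. the numerator runs over the core taxa while the denominator scales
over all taxa.  The contribution fraction BC_core / BC_all is additive
over any disjoint partition of the taxa, so partitions of the community
decompose each pair's dissimilarity into shares that sum to one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import OtuTable, SiteMetadata
from .network import fdr_adjust

__all__ = [
    "CoreSet",
    "CoreContribution",
    "find_core",
    "core_contribution",
    "core_env_correlations",
]


@dataclass
class CoreSet:
    """OTUs meeting the prevalence threshold, with genus roll-up."""

    core_otu_ids: list[str]
    prevalence_threshold: float
    genera: dict[str, list[str]] = field(default_factory=dict)  # genus -> member OTUs

    def __contains__(self, otu_id: str) -> bool:
        return otu_id in set(self.core_otu_ids)

    def __len__(self) -> int:
        return len(self.core_otu_ids)


@dataclass
class CoreContribution:
    """Per-pair partitioned dissimilarity and contribution fraction."""

    pair_index: list[tuple[str, str]]
    bc_partition: np.ndarray  # partitioned Bray-Curtis per pair
    bc_full: np.ndarray
    fraction: np.ndarray  # bc_partition / bc_full, in [0, 1]
    n_pairs_excluded: int = 0

    @property
    def mean_fraction(self) -> float:
        return float(self.fraction.mean())

    @property
    def fraction_range(self) -> tuple[float, float]:
        return float(self.fraction.min()), float(self.fraction.max())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "sample_a": [a for a, _ in self.pair_index],
            "sample_b": [b for _, b in self.pair_index],
            "bc_partition": self.bc_partition,
            "bc_full": self.bc_full,
            "fraction": self.fraction,
        })


def find_core(table: OtuTable, prevalence: float = 1.0) -> CoreSet:
    """OTUs whose prevalence (fraction of samples with count > 0) >= threshold."""
    if table.n_otus == 0:
        raise ValueError("empty table")
    if not 0 < prevalence <= 1:
        raise ValueError("prevalence threshold must be in (0, 1]")
    prev = table.prevalence()
    core_ids = [o for o, p in zip(table.otu_ids, prev) if p >= prevalence]
    genera: dict[str, list[str]] = {}
    if table.lineages is not None:
        lin = dict(zip(table.otu_ids, table.lineages))
        for o in core_ids:
            genus = lin[o].genus
            if genus is not None:
                genera.setdefault(genus, []).append(o)
    return CoreSet(core_ids, prevalence, genera)


def core_contribution(table: OtuTable, core: CoreSet | list[str],
                      on: str = "counts") -> CoreContribution:
    """Partitioned Bray–Curtis contribution of a taxon subset, per pair.

    ``on='counts'`` (default, intended for rarefied tables) or
    ``on='relative'``.  Pairs with BC_all = 0 (identical samples) have an
    undefined fraction and are excluded with a warning.
    """
    core_ids = core.core_otu_ids if isinstance(core, CoreSet) else list(core)
    index = {o: i for i, o in enumerate(table.otu_ids)}
    missing = [o for o in core_ids if o not in index]
    if missing:
        raise ValueError(f"core OTUs not in table: {missing[:5]}")
    if on == "relative":
        data = table.relative_abundance()
    elif on == "counts":
        data = table.counts.astype(float)
    else:
        raise ValueError(f"unknown mode {on!r}")
    mask = np.zeros(table.n_otus, dtype=bool)
    mask[[index[o] for o in core_ids]] = True

    pairs, bc_part, bc_all = [], [], []
    excluded = 0
    n = table.n_samples
    for j in range(n):
        for k in range(j + 1, n):
            diff = np.abs(data[j] - data[k])
            denom = (data[j] + data[k]).sum()
            if denom == 0:
                raise ValueError("sample pair with zero combined total")
            full = diff.sum() / denom
            if full == 0:
                excluded += 1
                continue
            pairs.append((table.sample_ids[j], table.sample_ids[k]))
            bc_part.append(diff[mask].sum() / denom)
            bc_all.append(full)
    if excluded:
        warnings.warn(f"{excluded} identical sample pair(s) excluded "
                      "(contribution fraction undefined)", stacklevel=2)
    bc_part = np.asarray(bc_part)
    bc_all = np.asarray(bc_all)
    return CoreContribution(pairs, bc_part, bc_all, bc_part / bc_all, excluded)


def core_env_correlations(table: OtuTable, core: CoreSet, metadata: SiteMetadata,
                          r_min: float = 0.6, alpha: float = 0.05,
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman correlations of core genera with environmental covariates.

    Genus relative abundances (summed over member OTUs) are correlated with
    every covariate; p-values are BH-FDR-adjusted across the whole
    genus x covariate family.  Returns ``(masked, full)``: the masked frame
    keeps only strong (|r| > r_min) and significant (q < alpha) cells
    (others NaN) — the heatmap contract — while the full frame carries all
    r and q values.
    """
    if not core.genera:
        raise ValueError("core set has no genus assignments")
    if list(metadata.sample_ids) != list(table.sample_ids):
        raise ValueError("metadata samples do not match table samples")
    rel = table.relative_abundance()
    index = {o: i for i, o in enumerate(table.otu_ids)}
    genus_ab = {g: rel[:, [index[o] for o in otus]].sum(axis=1)
                for g, otus in sorted(core.genera.items())}
    env = metadata.env
    covs = []
    for c in env.columns:
        if np.ptp(env[c].to_numpy(float)) == 0:
            warnings.warn(f"constant covariate {c!r} dropped", stacklevel=2)
        else:
            covs.append(c)
    genera = list(genus_ab)
    r = np.empty((len(genera), len(covs)))
    p = np.empty_like(r)
    for i, g in enumerate(genera):
        for j, c in enumerate(covs):
            res = stats.spearmanr(genus_ab[g], env[c].to_numpy(float))
            r[i, j], p[i, j] = res.statistic, res.pvalue
    q = fdr_adjust(p.ravel()).reshape(p.shape)
    masked = np.where((np.abs(r) > r_min) & (q < alpha), r, np.nan)
    full = pd.DataFrame(r, index=genera, columns=covs)
    full_q = pd.DataFrame(q, index=genera, columns=covs)
    full = pd.concat({"r": full, "q": full_q}, axis=1)
    return pd.DataFrame(masked, index=genera, columns=covs), full
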