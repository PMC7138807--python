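"""Rarefaction, alpha diversity, and beta-diversity dissimilarities.

Alpha diversity is observed OTU richness and the Shannon–Wiener index in
nats (natural log).  Beta diversity is Bray–Curtis (on total-sum-scaled
relative abundances by default) and weighted UniFrac, raw or normalized;
the normalized variant is the pipeline default because downstream
distance-decay regressions work on similarity = 1 - dissimilarity and
need a [0, 1] scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import skbio
from scipy.spatial.distance import pdist, squareform

from .io import OtuTable

__all__ = [
    "DistanceMatrix",
    "AlphaDiversity",
    "rarefy",
    "alpha_diversity",
    "bray_curtis",
    "weighted_unifrac",
]

_SYM_TOL = 1e-12


@dataclass
class DistanceMatrix:
    """Symmetric pairwise matrix with a units tag (``dissimilarity`` or ``km``)."""

    ids: list[str]
    values: np.ndarray
    units: str = "dissimilarity"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} does not match {n} ids")
        if np.any(np.abs(self.values - self.values.T) > _SYM_TOL):
            raise ValueError("matrix is not symmetric")
        self.values = (self.values + self.values.T) / 2.0
        if np.any(np.diagonal(self.values) != 0):
            raise ValueError("diagonal must be exactly zero")
        if self.units == "dissimilarity" and (self.values.min() < -_SYM_TOL
                                              or self.values.max() > 1 + 1e-9):
            raise ValueError("dissimilarity values must lie in [0, 1]")

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        """Upper-triangle vector in scipy ``pdist`` order."""
        return squareform(self.values, checks=False)

    def reorder(self, ids: list[str]) -> "DistanceMatrix":
        pos = {s: i for i, s in enumerate(self.ids)}
        idx = [pos[s] for s in ids]
        return DistanceMatrix(list(ids), self.values[np.ix_(idx, idx)], self.units)

    def to_skbio(self) -> skbio.DistanceMatrix:
        return skbio.DistanceMatrix(self.values, ids=self.ids)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(
            path, sep="\t", lineterminator="\n")

    @classmethod
    def from_tsv(cls, path: str | Path, units: str = "dissimilarity") -> "DistanceMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        return cls([str(i) for i in frame.index], frame.to_numpy(float), units)


@dataclass
class AlphaDiversity:
    """Observed richness S and Shannon–Wiener H (nats) per sample."""

    sample_ids: list[str]
    richness: np.ndarray
    shannon: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"richness": self.richness, "shannon": self.shannon},
                            index=self.sample_ids)


def rarefy(table: OtuTable, depth: int | None = None, seed: int = 0) -> OtuTable:
    """Subsample every sample to exactly ``depth`` counts without replacement.

    ``depth=None`` uses the minimum library size.  A single seeded draw, the
    standard even-depth normalization before diversity estimation.
    """
    totals = table.sample_totals()
    if depth is None:
        depth = int(totals.min())
    for sid, total in zip(table.sample_ids, totals):
        if depth > total:
            raise ValueError(
                f"rarefaction depth {depth} exceeds total {total} of sample {sid!r}")
    rng = np.random.default_rng(seed)
    out = np.empty_like(table.counts)
    for i in range(table.n_samples):
        out[i] = rng.multivariate_hypergeometric(table.counts[i], depth)
    return OtuTable(list(table.sample_ids), list(table.otu_ids), out,
                    list(table.lineages) if table.lineages is not None else None)


def alpha_diversity(table: OtuTable) -> AlphaDiversity:
    """Observed richness and Shannon H = -sum p ln p over nonzero proportions."""
    totals = table.sample_totals()
    if np.any(totals == 0):
        bad = [s for s, t in zip(table.sample_ids, totals) if t == 0]
        raise ValueError(f"all-zero samples: {bad}")
    richness = (table.counts > 0).sum(axis=1)
    p = table.counts / totals[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    return AlphaDiversity(list(table.sample_ids), richness.astype(np.int64),
                          -plogp.sum(axis=1))


def bray_curtis(table: OtuTable, on: str = "relative") -> DistanceMatrix:
    """Pairwise Bray–Curtis, BC = sum|x-y| / sum(x+y).

    ``on='relative'`` (default) uses total-sum-scaled abundances;
    ``on='counts'`` uses the raw (e.g. rarefied) counts.
    """
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples")
    if on == "relative":
        data = table.relative_abundance()
    elif on == "counts":
        data = table.counts.astype(float)
        if np.any(table.sample_totals() == 0):
            raise ValueError("sample with zero total counts")
    else:
        raise ValueError(f"unknown mode {on!r}")
    values = squareform(pdist(data, metric="braycurtis"))
    return DistanceMatrix(list(table.sample_ids), values, "dissimilarity")


def weighted_unifrac(table: OtuTable, tree: skbio.TreeNode,
                     normalized: bool = True) -> DistanceMatrix:
    """Weighted UniFrac between all sample pairs.

    Each branch contributes its length times the absolute difference of the
    abundance fractions descending from it in the two samples; the
    normalized variant rescales by the pair's maximum attainable value so
    distances lie in [0, 1].
    """
    missing = set(table.otu_ids) - {t.name for t in tree.tips()}
    if missing:
        raise ValueError(f"OTUs absent from tree: {sorted(missing)[:5]}")
    dm = skbio.diversity.beta_diversity(
        "weighted_unifrac", table.counts, ids=table.sample_ids,
        taxa=table.otu_ids, tree=tree, normalized=normalized)
    values = dm.data.copy()
    if normalized:
        values = np.clip(values, 0.0, 1.0)
        units = "dissimilarity"
    else:
        units = "branch_length"
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(list(table.sample_ids), values, units)
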