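"""Geographic distances and distance-decay of community similarity.

The distance-decay relationship (DDR) is the ordinary least-squares fit of
community similarity (1 - dissimilarity) on great-circle distance over all
unordered sample pairs; its slope w (similarity per km) is the spatial
turnover rate.  Per-phylum DDRs re-normalize abundances within the phylum
to estimate phylum-specific turnover.  The Mantel test correlates two
distance matrices with a simultaneous row/column permutation null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial.distance import squareform

from .diversity import DistanceMatrix, bray_curtis
from .io import OtuTable, SiteMetadata

__all__ = [
    "EARTH_RADIUS_KM",
    "DdrFit",
    "MantelResult",
    "haversine_matrix",
    "ddr_fit",
    "ddr_by_phylum",
    "mantel",
]

#: Earth mean radius, km (haversine great-circle convention).
EARTH_RADIUS_KM = 6371.0


@dataclass
class DdrFit:
    """OLS fit of similarity on distance over all unordered pairs."""

    slope: float
    intercept: float
    p_value: float
    r_squared: float
    n_pairs: int
    stderr: float = float("nan")  # standard error of the slope
    n_samples_dropped: int = 0


@dataclass
class MantelResult:
    statistic: float
    p_value: float
    n_permutations: int
    method: str


def haversine_matrix(metadata: SiteMetadata) -> DistanceMatrix:
    """Great-circle distance (km) between all site pairs, R = 6371 km."""
    lat = np.radians(metadata.latitude)
    lon = np.radians(metadata.longitude)
    if np.any(~np.isfinite(lat)) or np.any(~np.isfinite(lon)):
        raise ValueError("missing coordinates")
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    a = (np.sin(dlat / 2) ** 2
         + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2)
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2
    return DistanceMatrix(list(metadata.sample_ids), d, "km")


def ddr_fit(geo: DistanceMatrix, dissim: DistanceMatrix) -> DdrFit:
    """Fit similarity = 1 - dissimilarity against geographic distance (OLS).

    The model p-value is the slope t-test of the pairwise regression; pairs
    are not independent, so treat it as the conventional descriptive
    significance rather than an exact test (a Mantel permutation on the
    same matrices is the permutation alternative).
    """
    if geo.ids != dissim.ids:
        dissim = dissim.reorder(geo.ids)
    if geo.n < 3:
        raise ValueError("need at least 3 samples")
    x = geo.condensed()
    y = 1.0 - dissim.condensed()
    if np.ptp(x) == 0:
        raise ValueError("constant distance vector; DDR undefined")
    if np.ptp(y) == 0:  # constant similarity: flat fit, no explained variance
        return DdrFit(slope=0.0, intercept=float(y[0]), p_value=1.0,
                      r_squared=0.0, n_pairs=len(x), stderr=0.0)
    res = stats.linregress(x, y)
    return DdrFit(slope=float(res.slope), intercept=float(res.intercept),
                  p_value=float(res.pvalue), r_squared=float(res.rvalue ** 2),
                  n_pairs=len(x), stderr=float(res.stderr))


def ddr_by_phylum(table: OtuTable, geo: DistanceMatrix, phylum: str) -> DdrFit:
    """DDR restricted to one phylum's OTUs (within-phylum Bray–Curtis).

    Abundances are re-normalized over the phylum subset; samples where the
    phylum is entirely absent are dropped (count reported on the fit).
    """
    if table.lineages is None:
        raise ValueError("per-phylum DDR requires lineages")
    keep = [o for o, lin in zip(table.otu_ids, table.lineages) if lin.phylum == phylum]
    if not keep:
        raise ValueError(f"phylum {phylum!r} absent from table")
    sub = table.subset_otus(keep)
    present = sub.sample_totals() > 0
    dropped = int((~present).sum())
    sample_ids = [s for s, ok in zip(sub.sample_ids, present) if ok]
    if len(sample_ids) < 3:
        raise ValueError(f"phylum {phylum!r} present in fewer than 3 samples")
    sub = sub.subset_samples(sample_ids)
    fit = ddr_fit(geo.reorder(sample_ids), bray_curtis(sub, on="relative"))
    fit.n_samples_dropped = dropped
    return fit


def mantel(d1: DistanceMatrix, d2: DistanceMatrix, method: str = "spearman",
           n_perm: int = 999, seed: int = 0, exact: bool = False) -> MantelResult:
    """Mantel correlation of two distance matrices with permutation p-value.

    p = (1 + #{|r*| >= |r|}) / (1 + n_perm), two-sided, permuting rows and
    columns of the second matrix simultaneously.  ``exact=True`` enumerates
    all n! relabelings (identity included, which gives the +1) — feasible
    only for small n.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    if not exact and n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    if d1.ids != d2.ids:
        d2 = d2.reorder(d1.ids)
    x = d1.condensed()
    y = squareform(d2.values, checks=False)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance distance vector")
    # a simultaneous row/column permutation only permutes the condensed
    # entries among themselves, so ranks and moments can be computed once
    if method == "spearman":
        x, y = stats.rankdata(x), stats.rankdata(y)
    zx = (x - x.mean()) / x.std()
    zmat = squareform((y - y.mean()) / y.std(), checks=False)
    m = len(x)

    def corr(perm) -> float:
        return float(zx @ squareform(zmat[np.ix_(perm, perm)], checks=False)) / m

    n = d1.n
    identity = list(range(n))
    r_obs = corr(identity)
    if exact:
        from itertools import permutations
        hits = count = 0
        for perm in permutations(range(n)):
            hits += abs(corr(list(perm))) >= abs(r_obs) - 1e-12
            count += 1
        return MantelResult(statistic=r_obs, p_value=hits / count,
                            n_permutations=count, method=method)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if abs(corr(rng.permutation(n))) >= abs(r_obs) - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return MantelResult(statistic=r_obs, p_value=p, n_permutations=n_perm, method=method)
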