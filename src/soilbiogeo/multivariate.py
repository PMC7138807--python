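"""Ordination and permutation tests on dissimilarity matrices.

All methods operate on the Gower-centered matrix G = J(-D^2/2)J, J the
centering projector.  PCoA eigendecomposes G; PERMANOVA partitions tr(G)
by a design matrix via hat-matrix traces (pseudo-F); ANOSIM contrasts
between- vs within-group rank dissimilarities; CAP (db-RDA) regresses the
positive-eigenvalue PCoA axes on environmental constraints and tests the
constrained inertia fraction by permutation.

Permutation p-values carry the +1 correction (never exactly 0) and every
engine is reproducible under its seed.  Negative PCoA eigenvalues (from
semi-metric dissimilarities like Bray–Curtis) are dropped, not corrected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diversity import DistanceMatrix

__all__ = [
    "Ordination",
    "PermTestResult",
    "pcoa",
    "permanova",
    "anosim",
    "cap",
]

_EIG_TOL = 1e-10


@dataclass
class Ordination:
    sample_ids: list[str]
    scores: np.ndarray  # n_samples x n_axes, scaled by sqrt(eigenvalue)
    eigenvalues: np.ndarray  # non-increasing
    proportion_explained: np.ndarray
    kind: str  # "unconstrained" | "constrained"


@dataclass
class PermTestResult:
    term: str
    statistic: float  # pseudo-F or ANOSIM R
    p_value: float
    n_permutations: int
    r_squared: float | None = None
    df: int | None = None


def _gower_center(values: np.ndarray) -> np.ndarray:
    a = -0.5 * values ** 2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


def pcoa(d: DistanceMatrix) -> Ordination:
    """Principal coordinates: eigendecomposition of the Gower matrix.

    Axes with eigenvalue > 1e-10 are retained, ordered by decreasing
    eigenvalue, scores scaled by sqrt(eigenvalue).  Proportions explained
    are relative to the sum of positive eigenvalues.
    """
    g = _gower_center(d.values)
    eigval, eigvec = np.linalg.eigh(g)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    keep = eigval > _EIG_TOL
    pos_sum = eigval[keep].sum()
    scores = eigvec[:, keep] * np.sqrt(eigval[keep])
    return Ordination(
        sample_ids=list(d.ids),
        scores=scores,
        eigenvalues=eigval[keep],
        proportion_explained=eigval[keep] / pos_sum if pos_sum > 0 else eigval[keep],
        kind="unconstrained",
    )


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

def _encode_term(series: pd.Series) -> np.ndarray:
    """Numeric column as-is; categorical as treatment-coded dummies."""
    if pd.api.types.is_numeric_dtype(series):
        col = series.to_numpy(float)[:, None]
        if np.ptp(col) == 0:
            raise ValueError(f"constant covariate {series.name!r}")
        return col
    dummies = pd.get_dummies(series.astype(str), drop_first=True)
    if dummies.shape[1] == 0:
        raise ValueError(f"constant covariate {series.name!r}")
    return dummies.to_numpy(float)


def _hat(x: np.ndarray) -> tuple[np.ndarray, int]:
    """Orthogonal projector onto col(X) and its rank (via thin QR/SVD)."""
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    rank = int((s > s[0] * 1e-10).sum()) if s.size else 0
    u = u[:, :rank]
    return u @ u.T, rank


def permanova(d: DistanceMatrix, design: pd.DataFrame, n_perm: int = 999,
              seed: int = 0, exact: bool = False) -> list[PermTestResult]:
    """Permutational MANOVA (ADONIS) with sequential (Type I) terms.

    Each column of ``design`` is one term, added in column order; pseudo-F
    per term uses the residual of the full model.  p-values come from raw
    permutation of the dissimilarity matrix's rows/columns; ``exact=True``
    enumerates all n! relabelings (small n only), identity included.
    """
    if list(design.index) != list(d.ids):
        if set(design.index) != set(d.ids):
            raise ValueError("design rows do not match distance matrix samples")
        design = design.loc[list(d.ids)]
    if not exact and n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    n = d.n
    g = _gower_center(d.values)
    ss_total = np.trace(g)

    ones = np.ones((n, 1))
    blocks = [ones]
    term_names = list(design.columns)
    projectors: list[np.ndarray] = []
    ranks: list[int] = []
    for name in term_names:
        blocks.append(_encode_term(design[name]))
        h, r = _hat(np.hstack(blocks))
        projectors.append(h)
        ranks.append(r)
    if ranks and ranks[-1] >= n:
        raise ValueError("design is saturated (no residual degrees of freedom)")
    dfs = np.diff([1] + ranks)
    if np.any(dfs == 0):
        raise ValueError("rank-deficient design: a term adds no independent columns")
    h_prev = _hat(ones)[0]
    diffs = []
    for h in projectors:
        diffs.append(h - h_prev)
        h_prev = h
    h_full = projectors[-1]
    df_resid = n - ranks[-1]
    resid_proj = np.eye(n) - h_full

    def term_stats(gmat: np.ndarray) -> tuple[np.ndarray, float]:
        ss_terms = np.array([np.sum(diff * gmat) for diff in diffs])  # tr(diff @ G)
        ss_resid = float(np.sum(resid_proj * gmat))
        return ss_terms, ss_resid

    ss_terms, ss_resid = term_stats(g)
    f_obs = (ss_terms / dfs) / (ss_resid / df_resid)

    def f_of(perm) -> np.ndarray:
        ss_t, ss_r = term_stats(g[np.ix_(perm, perm)])
        return (ss_t / dfs) / (ss_r / df_resid)

    if exact:
        from itertools import permutations
        hits = np.zeros(len(term_names), dtype=int)
        count = 0
        for perm in permutations(range(n)):
            hits += f_of(list(perm)) >= f_obs - 1e-12
            count += 1
        p = hits / count
        n_perm = count
    else:
        rng = np.random.default_rng(seed)
        hits = np.zeros(len(term_names), dtype=int)
        for _ in range(n_perm):
            hits += f_of(rng.permutation(n)) >= f_obs - 1e-12
        p = (1 + hits) / (1 + n_perm)

    return [
        PermTestResult(term=name, statistic=float(f_obs[k]), p_value=float(p[k]),
                       n_permutations=n_perm, r_squared=float(ss_terms[k] / ss_total),
                       df=int(dfs[k]))
        for k, name in enumerate(term_names)
    ]


def anosim(d: DistanceMatrix, groups, n_perm: int = 999, seed: int = 0,
           exact: bool = False) -> PermTestResult:
    """ANOSIM: R = (mean between-group rank - mean within-group rank) / (M/2).

    M = n(n-1)/2 pairwise dissimilarities, ranked with average ties;
    p-value by group-label permutation (``exact=True`` enumerates all n!
    relabelings, identity included).
    """
    groups = np.asarray(list(groups))
    n = d.n
    if len(groups) != n:
        raise ValueError("groups must align with samples")
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    if counts.min() < 2:
        raise ValueError("every group needs at least 2 samples")
    ranks = stats.rankdata(d.condensed())
    iu, ju = np.triu_indices(n, k=1)
    m = len(ranks)
    denom = m / 2.0

    def r_stat(lab: np.ndarray) -> float:
        within = lab[iu] == lab[ju]
        return float((ranks[~within].mean() - ranks[within].mean()) / denom)

    r_obs = r_stat(groups)
    if exact:
        from itertools import permutations
        hits = count = 0
        for perm in permutations(range(n)):
            hits += r_stat(groups[list(perm)]) >= r_obs - 1e-12
            count += 1
        return PermTestResult(term="groups", statistic=r_obs, p_value=hits / count,
                              n_permutations=count)
    rng = np.random.default_rng(seed)
    hits = sum(r_stat(groups[rng.permutation(n)]) >= r_obs - 1e-12 for _ in range(n_perm))
    return PermTestResult(term="groups", statistic=r_obs,
                          p_value=(1 + hits) / (1 + n_perm), n_permutations=n_perm)


def cap(d: DistanceMatrix, constraints: pd.DataFrame, n_perm: int = 999,
        seed: int = 0) -> tuple[Ordination, PermTestResult]:
    """Constrained analysis of principal coordinates (db-RDA).

    The positive-eigenvalue PCoA axes are regressed on the centered
    constraint matrix; the eigen-analysis of the fitted values yields the
    constrained axes, and the constrained-inertia pseudo-F is tested by
    permuting the rows of the axis scores.
    """
    if list(constraints.index) != list(d.ids):
        if set(constraints.index) != set(d.ids):
            raise ValueError("constraint rows do not match distance matrix samples")
        constraints = constraints.loc[list(d.ids)]
    ord_u = pcoa(d)
    y = ord_u.scores  # centered: eigenvectors of the centered Gower matrix
    total_inertia = float(ord_u.eigenvalues.sum())
    n = d.n
    x = np.hstack([_encode_term(constraints[c]) for c in constraints.columns])
    if x.shape[1] > n - 1:
        raise ValueError("more constraints than samples - 1")
    x = x - x.mean(axis=0, keepdims=True)
    h, q = _hat(x)

    fitted = h @ y
    constrained = float(np.sum(fitted ** 2))
    residual = total_inertia - constrained
    df_resid = n - 1 - q
    f_obs = (constrained / q) / (residual / df_resid) if df_resid > 0 else np.inf

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        yp = y[rng.permutation(n)]
        ci = float(np.sum((h @ yp) ** 2))
        ri = total_inertia - ci
        f_perm = (ci / q) / (ri / df_resid) if df_resid > 0 else np.inf
        hits += f_perm >= f_obs - 1e-12
    p = (1 + hits) / (1 + n_perm)

    u, s, _ = np.linalg.svd(fitted, full_matrices=False)
    eig = s ** 2
    keep = eig > _EIG_TOL
    ord_c = Ordination(
        sample_ids=list(d.ids),
        scores=u[:, keep] * s[keep],
        eigenvalues=eig[keep],
        proportion_explained=eig[keep] / total_inertia if total_inertia > 0 else eig[keep],
        kind="constrained",
    )
    test = PermTestResult(term="constraints", statistic=float(f_obs), p_value=float(p),
                          n_permutations=n_perm,
                          r_squared=float(constrained / total_inertia), df=q)
    return ord_c, test
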