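"""Distance-based community analysis: Bray-Curtis dissimilarity, principal
coordinates analysis (PCoA), non-metric multidimensional scaling (NMDS) and
one-way PERMANOVA with pairwise Bonferroni-corrected contrasts.

PERMANOVA follows Anderson's pseudo-F on squared dissimilarities:

    SS_total  = (1/N) sum_{i<j} d_ij^2
    SS_within = sum_g (1/n_g) sum_{i<j in g} d_ij^2
    F = (SS_among/(g-1)) / (SS_within/(N-g))

with the p-value estimated as (1 + #{F_perm >= F_obs}) / (1 + n_perm) under
random relabelling (never exactly zero). Labels are permuted freely by
default; a ``strata`` argument restricts permutations within strata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist
from sklearn.isotonic import IsotonicRegression
from skbio import DistanceMatrix

__all__ = [
    "OrdinationResult",
    "PermanovaResult",
    "bray_curtis",
    "pcoa",
    "nmds",
    "permanova",
    "pairwise_permanova",
]


def bray_curtis(table: pd.DataFrame, mode: str = "relative") -> DistanceMatrix:
    """Bray-Curtis dissimilarity between samples (rows).

    Modes: ``"relative"`` normalizes each sample to proportions first (the
    standard choice for read-count tables; invariant to sequencing depth);
    ``"presence_absence"`` binarizes first (equivalent to Sorensen
    dissimilarity); ``"raw"`` uses the counts as given.
    """
    if table.shape[0] < 2:
        raise ValueError("need >= 2 samples")
    X = table.to_numpy(float)
    zero = np.flatnonzero(X.sum(axis=1) == 0)
    if zero.size:
        bad = list(table.index[zero])
        raise ValueError(f"all-zero sample(s): {bad}")
    if mode == "relative":
        X = X / X.sum(axis=1, keepdims=True)
    elif mode == "presence_absence":
        X = (X > 0).astype(float)
    elif mode != "raw":
        raise ValueError(f"unknown mode {mode!r}")
    d = pdist(X, metric="braycurtis")
    return DistanceMatrix(squareform(d), ids=[str(i) for i in table.index])


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame
    method: str
    eigenvalues: np.ndarray | None = None
    stress: float | None = None
    converged: bool = True
    n_starts: int = 1
    negative_eigenvalues: np.ndarray | None = field(default=None, repr=False)


def pcoa(dm: DistanceMatrix, k: int = 2) -> OrdinationResult:
    """Classical (metric) multidimensional scaling of a distance matrix.

    Double-centers -d^2/2, eigendecomposes and returns the top-k coordinate
    axes scaled by the square root of their eigenvalues. Axes with negative
    eigenvalues (non-Euclidean input) are reported but never returned as
    coordinates; if fewer than k positive axes exist the result has fewer
    columns and ``converged`` is False to flag the reduction.
    """
    D = dm.data
    n = D.shape[0]
    if n < k + 1:
        raise ValueError(f"need n >= k+1 samples, got n={n}, k={k}")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(1e-10, 1e-8 * abs(evals[0])) if n else 0.0
    pos = evals > tol
    n_pos = int(pos.sum())
    k_eff = min(k, n_pos)
    coords = evecs[:, :k_eff] * np.sqrt(evals[:k_eff])
    cols = [f"PC{i + 1}" for i in range(k_eff)]
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=list(dm.ids), columns=cols),
        method="PCoA",
        eigenvalues=evals[:n_pos],
        negative_eigenvalues=evals[evals < -tol],
        converged=k_eff == k,
    )


def _stress1(dhat: np.ndarray, dist: np.ndarray) -> float:
    denom = float(np.sum(dist ** 2))
    if denom == 0:
        return 0.0
    return float(np.sqrt(np.sum((dhat - dist) ** 2) / denom))


def _nmds_single(d: np.ndarray, X0: np.ndarray, max_iter: int, tol: float):
    """One NMDS start: alternate isotonic regression of disparities on the
    input dissimilarity ranks with Guttman configuration updates. Returns the
    configuration, final stress-1 and the per-iteration stress trace (which is
    non-increasing across accepted iterations)."""
    n = X0.shape[0]
    iu = np.triu_indices(n, 1)
    dvec = d[iu]
    order = np.argsort(dvec, kind="mergesort")
    iso = IsotonicRegression(increasing=True)
    X = X0.copy()
    trace = []
    prev = np.inf
    converged = False
    for _ in range(max_iter):
        dist = squareform(pdist(X))
        dist_vec = dvec_dist = dist[iu]
        # monotone regression: disparities follow the rank order of the input
        dhat_sorted = iso.fit_transform(np.arange(dvec.size), dvec_dist[order])
        dhat = np.empty_like(dvec)
        dhat[order] = dhat_sorted
        s = _stress1(dhat, dist_vec)
        trace.append(s)
        if prev - s < tol:
            converged = True
            break
        prev = s
        # Guttman transform toward the disparities
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio_vec = np.where(dvec_dist > 0, dhat / dvec_dist, 0.0)
        Bmat = np.zeros((n, n))
        Bmat[iu] = -ratio_vec
        Bmat = Bmat + Bmat.T
        np.fill_diagonal(Bmat, -Bmat.sum(axis=1))
        X = Bmat @ X / n
        X -= X.mean(axis=0)
    return X, trace[-1], trace, converged


def nmds(
    dm: DistanceMatrix,
    k: int = 2,
    n_starts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-6,
    seed: int = 0,
) -> OrdinationResult:
    """Non-metric MDS minimizing Kruskal stress-1.

    Runs ``n_starts`` random configurations plus a PCoA start and keeps the
    lowest-stress solution. ``converged`` is False only if no start converged
    within ``max_iter`` iterations; the best configuration is still returned.
    Ties in the monotone regression are averaged (primary treatment).
    """
    D = dm.data
    n = D.shape[0]
    if n < k + 2:
        raise ValueError(f"need n >= k+2 samples for k={k}")
    rng = np.random.default_rng(seed)
    inits = []
    try:
        p = pcoa(dm, k)
        if p.coordinates.shape[1] == k:
            inits.append(p.coordinates.to_numpy())
    except ValueError:
        pass
    for _ in range(n_starts):
        inits.append(rng.normal(size=(n, k)))
    best = None
    any_converged = False
    for X0 in inits:
        X, s, trace, conv = _nmds_single(D, np.asarray(X0, float), max_iter, tol)
        any_converged = any_converged or conv
        if best is None or s < best[1]:
            best = (X, s, trace, conv)
    X, s, trace, conv = best
    res = OrdinationResult(
        coordinates=pd.DataFrame(X, index=list(dm.ids),
                                 columns=[f"NMDS{i + 1}" for i in range(k)]),
        method="NMDS", stress=s, converged=any_converged, n_starts=len(inits),
    )
    res.stress_trace = trace  # per-iteration stress of the winning start
    return res


@dataclass
class PermanovaResult:
    pseudo_f: float
    r2: float
    p_value: float
    permutations: int
    df_among: int
    df_within: int
    grouping: str = "group"
    pairwise: pd.DataFrame | None = None


def _f_stats(d2: np.ndarray, labels: np.ndarray, uniq: np.ndarray) -> tuple[float, float, float]:
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in uniq:
        idx = np.flatnonzero(labels == g)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_among = ss_total - ss_within
    g = len(uniq)
    f = (ss_among / (g - 1)) / (ss_within / (n - g))
    return f, ss_among, ss_total


def permanova(
    dm: DistanceMatrix,
    groups,
    n_perm: int = 10_000,
    seed: int = 0,
    strata=None,
    grouping: str = "group",
) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    ``groups`` is a label per sample in the order of ``dm.ids``. ``strata``
    optionally restricts permutations to occur within each stratum.
    """
    labels = np.asarray(pd.Series(groups).to_numpy())
    d2 = dm.data ** 2
    n = d2.shape[0]
    if labels.size != n:
        raise ValueError("groups length must match the distance matrix")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need >= 2 groups")
    if counts.min() < 2:
        small = uniq[counts < 2]
        raise ValueError(f"groups with a single sample: {list(small)}")
    if n_perm < 99:
        raise ValueError("n_perm >= 99 required")
    f_obs, ss_among, ss_total = _f_stats(d2, labels, uniq)
    rng = np.random.default_rng(seed)
    strata_idx = None
    if strata is not None:
        strata = np.asarray(pd.Series(strata).to_numpy())
        strata_idx = [np.flatnonzero(strata == s) for s in np.unique(strata)]
    count = 0
    perm = np.arange(n)
    for _ in range(n_perm):
        if strata_idx is None:
            perm = rng.permutation(n)
        else:
            perm = np.arange(n)
            for idx in strata_idx:
                perm[idx] = idx[rng.permutation(len(idx))]
        f_p, _, _ = _f_stats(d2, labels[perm], uniq)
        if f_p >= f_obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return PermanovaResult(
        pseudo_f=float(f_obs), r2=float(ss_among / ss_total), p_value=float(p),
        permutations=n_perm, df_among=len(uniq) - 1, df_within=n - len(uniq),
        grouping=grouping,
    )


def pairwise_permanova(
    dm: DistanceMatrix,
    groups,
    n_perm: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """PERMANOVA on every group pair's sub-matrix with Bonferroni-adjusted
    p-values (p_adj = min(1, p * number of pairs))."""
    labels = np.asarray(pd.Series(groups).to_numpy())
    ids = np.asarray(list(dm.ids))
    uniq = list(dict.fromkeys(labels))
    pairs = list(combinations(uniq, 2))
    n_comp = len(pairs)
    rows = []
    for i, (ga, gb) in enumerate(pairs):
        mask = (labels == ga) | (labels == gb)
        sub = dm.filter(ids[mask])
        res = permanova(sub, labels[mask], n_perm=n_perm, seed=seed + i)
        rows.append({
            "group_a": ga, "group_b": gb, "pseudo_f": res.pseudo_f,
            "r2": res.r2, "p": res.p_value,
            "p_bonferroni": min(1.0, res.p_value * n_comp),
        })
    return pd.DataFrame(rows)
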