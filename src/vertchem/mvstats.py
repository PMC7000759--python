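"""Distance-based multivariate statistics for elemental signatures.

Implements the test battery used to evaluate maternal elemental tags:

* one-way PERMANOVA on a distance matrix (pseudo-F with label-permutation
  p-value; on Euclidean distances of univariate data the pseudo-F reduces
  exactly to the classical one-way ANOVA F),
* canonical analysis of principal coordinates (CAP): PCoA of the distance
  matrix, canonical correlation of the first m axes with the group factor,
  trace statistic with a permutation test, and leave-one-out
  cross-validation classification by nearest group centroid in canonical
  space,
* the proportional chance criterion (PCC): expected classification accuracy
  under proportional random assignment, sum(p_i^2), with an exact binomial
  tail test for the observed number of correct assignments.

Permutation p-values follow the (b+1)/(B+1) convention and are seeded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import binom

__all__ = [
    "DistanceMatrix",
    "PermanovaResult",
    "CapResult",
    "PccResult",
    "euclidean_dm",
    "permanova",
    "cap_fit",
    "pcc_test",
]

_EIG_TOL = 1e-9


@dataclass(frozen=True)
class DistanceMatrix:
    ids: tuple[str, ...]
    values: np.ndarray  # (N, N) symmetric, zero diagonal, nonnegative

    def __post_init__(self) -> None:
        D = np.asarray(self.values, dtype=float)
        if D.ndim != 2 or D.shape[0] != D.shape[1]:
            raise ValueError("distance matrix must be square")
        if len(self.ids) != D.shape[0]:
            raise ValueError("ids length must match matrix size")
        if not np.allclose(D, D.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(D) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(D < 0):
            raise ValueError("distances must be nonnegative")
        object.__setattr__(self, "values", D)

    def __len__(self) -> int:
        return len(self.ids)


def euclidean_dm(X, ids) -> DistanceMatrix:
    """Pairwise Euclidean distance matrix from a samples-by-features matrix."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("feature matrix must be 2-D")
    ids = tuple(str(i) for i in ids)
    if len(ids) != X.shape[0]:
        raise ValueError("ids length must match number of rows")
    bad = [ids[i] for i in np.where(~np.isfinite(X).all(axis=1))[0]]
    if bad:
        raise ValueError(f"missing/non-finite values in rows: {bad}")
    return DistanceMatrix(ids=ids, values=squareform(pdist(X, metric="euclidean")))


def _group_indices(groups) -> tuple[list[np.ndarray], np.ndarray]:
    groups = np.asarray(groups)
    labels = sorted(set(groups.tolist()))
    codes = np.array([labels.index(g) for g in groups])
    return [np.where(codes == k)[0] for k in range(len(labels))], codes


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_f: float
    df_between: int
    df_within: int
    n_permutations: int
    p_value: float
    seed: int


def _pseudo_f(D2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    n = len(codes)
    ss_total = D2.sum() / (2 * n)
    ss_within = 0.0
    for k in range(n_groups):
        idx = np.where(codes == k)[0]
        if len(idx) > 1:
            ss_within += D2[np.ix_(idx, idx)].sum() / (2 * len(idx))
    ss_among = ss_total - ss_within
    df_b, df_w = n_groups - 1, n - n_groups
    if ss_within <= 0:
        return np.inf if ss_among > 0 else 0.0
    return (ss_among / df_b) / (ss_within / df_w)


def permanova(dm: DistanceMatrix, groups, n_perm: int = 999, seed: int = 0) -> PermanovaResult:
    """One-way PERMANOVA: pseudo-F and seeded label-permutation p-value."""
    idx_lists, codes = _group_indices(groups)
    a, n = len(idx_lists), len(dm)
    if len(codes) != n:
        raise ValueError("groups length must match distance matrix")
    if a < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    if max(len(ix) for ix in idx_lists) < 2:
        raise ValueError("at least one group must have size >= 2")
    D2 = dm.values**2
    f_obs = _pseudo_f(D2, codes, a)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if _pseudo_f(D2, codes[perm], a) >= f_obs:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return PermanovaResult(
        pseudo_f=float(f_obs), df_between=a - 1, df_within=n - a,
        n_permutations=n_perm, p_value=p, seed=seed,
    )


# ---------------------------------------------------------------------------
# CAP


def _pcoa(D: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Principal coordinates: positive eigenvalues and orthonormal axes.

    Returns (eigenvalues, eigenvectors) of the centered Gower matrix, sorted
    descending, negative/near-zero eigenvalues discarded.
    """
    n = D.shape[0]
    A = -0.5 * D**2
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ A @ J
    w, V = np.linalg.eigh(G)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    keep = w > _EIG_TOL * max(w.max(), 1.0)
    return w[keep], V[:, keep]


def _project_point(D_sub: np.ndarray, d_new: np.ndarray, w: np.ndarray,
                   V: np.ndarray) -> np.ndarray:
    """Gower projection of an unseen point onto existing PCoA axes.

    ``d_new`` holds distances from the new point to the n training points.
    Returns coordinates on the orthonormal-axis scale of ``V``.
    """
    A = -0.5 * D_sub**2
    a = -0.5 * d_new**2
    g = a - a.mean() - A.mean(axis=1) + A.mean()
    return (V.T @ g) / w


def _hat_matrix(codes: np.ndarray, n_groups: int) -> np.ndarray:
    n = len(codes)
    X = np.zeros((n, n_groups))
    X[np.arange(n), codes] = 1.0
    X = X - X.mean(axis=0)
    return X @ np.linalg.pinv(X)


def _canonical(Qm: np.ndarray, codes: np.ndarray, n_groups: int):
    """Canonical axes of the group factor on orthonormal PCoA scores.

    Returns (squared canonical correlations, axis matrix U). The trace
    statistic is the sum of the squared canonical correlations.
    """
    H = _hat_matrix(codes, n_groups)
    M = Qm.T @ H @ Qm
    vals, U = np.linalg.eigh(M)
    order = np.argsort(vals)[::-1]
    vals, U = np.clip(vals[order], 0.0, 1.0), U[:, order]
    n_axes = min(Qm.shape[1], n_groups - 1)
    return vals[:n_axes], U[:, :n_axes]


def _nearest_centroid(z: np.ndarray, centroids: np.ndarray) -> int:
    d = np.linalg.norm(centroids - z, axis=1)
    # ties resolved to the lowest group index
    return int(np.argmin(np.round(d, 12)))


def _loo_predictions(D: np.ndarray, codes: np.ndarray, n_groups: int, m: int) -> np.ndarray:
    """Leave-one-out CAP classification with m PCoA axes held fixed."""
    n = D.shape[0]
    pred = np.empty(n, dtype=int)
    for i in range(n):
        keep = np.delete(np.arange(n), i)
        D_sub = D[np.ix_(keep, keep)]
        w, V = _pcoa(D_sub)
        m_i = min(m, V.shape[1])
        w_m, V_m = w[:m_i], V[:, :m_i]
        q_new = _project_point(D_sub, D[i, keep], w_m, V_m)
        vals, U = _canonical(V_m, codes[keep], n_groups)
        Z = V_m @ U
        z_new = U.T @ q_new
        centroids = np.vstack([
            Z[codes[keep] == k].mean(axis=0) if np.any(codes[keep] == k)
            else np.full(Z.shape[1], np.inf)
            for k in range(n_groups)
        ])
        pred[i] = _nearest_centroid(z_new, centroids)
    return pred


@dataclass(frozen=True)
class CapResult:
    m: int
    g_prop: float                 # % of positive eigenvalue mass in the m axes
    trace_stat: float             # sum of squared canonical correlations
    p_value: float
    n_permutations: int
    canonical_scores: np.ndarray  # (N, n_axes)
    group_labels: tuple
    confusion: np.ndarray         # (a, a) rows = true group, cols = predicted
    loo_accuracy: float           # %
    seed: int
    pcc: "PccResult" = field(repr=False, default=None)


def cap_fit(dm: DistanceMatrix, groups, m: int | None = None,
            n_perm: int = 999, seed: int = 0) -> CapResult:
    """Canonical analysis of principal coordinates with LOO classification.

    ``m`` is the number of PCoA axes retained; ``None`` selects the m in
    [1, N-2] maximizing LOO accuracy (ties to the smallest m).
    """
    idx_lists, codes = _group_indices(groups)
    a, n = len(idx_lists), len(dm)
    if a < 2:
        raise ValueError("CAP needs at least 2 groups")
    if m is not None and m >= n - 1:
        raise ValueError(f"m={m} over-parameterized for N={n} (need m <= N-2)")
    labels = sorted(set(np.asarray(groups).tolist()))

    D = dm.values
    w_all, V_all = _pcoa(D)
    max_m = min(n - 2, V_all.shape[1])

    if m is None:
        best_m, best_acc = 1, -1.0
        for m_try in range(1, max_m + 1):
            acc = float(np.mean(_loo_predictions(D, codes, a, m_try) == codes))
            if acc > best_acc + 1e-12:
                best_m, best_acc = m_try, acc
        m = best_m
    m_eff = min(m, V_all.shape[1])

    Qm = V_all[:, :m_eff]
    vals, U = _canonical(Qm, codes, a)
    trace = float(vals.sum())
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        vals_p, _ = _canonical(Qm, codes[perm], a)
        if vals_p.sum() >= trace:
            hits += 1
    p = (hits + 1) / (n_perm + 1)

    pred = _loo_predictions(D, codes, a, m_eff)
    confusion = np.zeros((a, a), dtype=int)
    for t, q in zip(codes, pred):
        confusion[t, q] += 1
    correct = int(np.trace(confusion))
    accuracy = 100.0 * correct / n
    g_prop = 100.0 * w_all[:m_eff].sum() / w_all.sum()
    pcc = pcc_test([len(ix) for ix in idx_lists], correct)
    return CapResult(
        m=m_eff, g_prop=float(g_prop), trace_stat=trace, p_value=p,
        n_permutations=n_perm, canonical_scores=Qm @ U, group_labels=tuple(labels),
        confusion=confusion, loo_accuracy=accuracy, seed=seed, pcc=pcc,
    )


@dataclass(frozen=True)
class PccResult:
    group_sizes: tuple[int, ...]
    chance_accuracy: float    # %
    observed_accuracy: float  # %
    p_value: float            # one-sided exact binomial tail


def pcc_test(group_sizes, observed_correct: int) -> PccResult:
    """Proportional chance criterion for a classification success count.

    Chance proportion is sum((n_i/N)^2); significance is the exact binomial
    upper-tail probability of observing at least ``observed_correct``
    successes in N trials at the chance rate.
    """
    sizes = tuple(int(s) for s in group_sizes)
    if any(s < 1 for s in sizes):
        raise ValueError("group sizes must be >= 1")
    n = sum(sizes)
    if not 0 <= observed_correct <= n:
        raise ValueError("observed_correct must be in [0, N]")
    p0 = sum((s / n) ** 2 for s in sizes)
    p_value = float(binom.sf(observed_correct - 1, n, p0))
    return PccResult(
        group_sizes=sizes,
        chance_accuracy=100.0 * p0,
        observed_accuracy=100.0 * observed_correct / n,
        p_value=p_value,
    )
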