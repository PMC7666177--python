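"""Reverse graph embedding by exact block-coordinate descent.

The model learns, jointly: a d-dimensional latent coordinate z_i for every
sample, K latent cluster centers y_k lying on a spanning tree, a soft
assignment r_{ik} of samples to centers, and an orthonormal inverse map W
from latent to gene space.  The objective is

    J = sum_i ||x_i - W z_i||^2
      + (lambda/2) * sum_{k,k'} b_{kk'} ||W y_k - W y_{k'}||^2
      + gamma * [ sum_{i,k} r_{ik} ||z_i - y_k||^2
                  + sigma * r_{ik} log r_{ik} ]   (0 log 0 = 0)

subject to B being a spanning tree over the centers, W^T W = I, and each
row of R lying on the simplex.  Every block update below is the exact
minimizer of J in its block, so each sweep can only decrease J.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from ._utils import check_finite, sub_seed

__all__ = [
    "DDRTreeParams",
    "LatentTreeModel",
    "objective",
    "update_R",
    "update_B",
    "update_Y",
    "update_Z",
    "update_W",
    "initialize",
    "fit",
]


@dataclass
class DDRTreeParams:
    """Hyperparameters of the reverse-graph-embedding objective.

    ``K`` defaults to min(N, ceil(2 sqrt(N))) at fit time when left None.
    ``lambda_`` (tree smoothness) defaults to N / 5 at fit time when None:
    strong enough to keep the center tree smooth, weak enough that the
    tree spans the data cloud (large values contract the tree so far that
    distal samples pile up on the leaf vertices and pseudotime degenerates
    into a few atoms).
    """

    d: int = 2
    K: int | None = None
    lambda_: float | None = None
    gamma_: float = 10.0
    sigma_: float = 1e-3
    max_iter: int = 100
    tol: float = 1e-5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d < 1:
            raise ValueError("d must be >= 1")
        if self.K is not None and self.K < 1:
            raise ValueError("K must be >= 1")
        if self.lambda_ is not None and self.lambda_ < 0:
            raise ValueError("lambda_ must be >= 0")
        if self.gamma_ <= 0:
            raise ValueError("gamma_ must be > 0")
        if self.sigma_ <= 0:
            raise ValueError("sigma_ must be > 0")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")

    def resolved(self, n_samples: int) -> "DDRTreeParams":
        K = self.K if self.K is not None else min(n_samples, int(np.ceil(2 * np.sqrt(n_samples))))
        lam = self.lambda_ if self.lambda_ is not None else n_samples / 5.0
        return DDRTreeParams(
            d=self.d, K=K, lambda_=lam, gamma_=self.gamma_, sigma_=self.sigma_,
            max_iter=self.max_iter, tol=self.tol, seed=self.seed,
        )


@dataclass
class LatentTreeModel:
    """Fitted state: W (genes x d), Z (d x N), Y (d x K), B (K x K
    spanning-tree adjacency), R (N x K soft assignments), the centering
    vector removed from X, and the per-sweep objective trace."""

    W: np.ndarray
    Z: np.ndarray
    Y: np.ndarray
    B: np.ndarray
    R: np.ndarray
    params: DDRTreeParams
    gene_means: np.ndarray | None = None
    objective_trace: list[float] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return self.Z.shape[1]

    @property
    def n_centers(self) -> int:
        return self.Y.shape[1]


def _is_spanning_tree(B: np.ndarray) -> bool:
    K = B.shape[0]
    if B.shape != (K, K) or not np.array_equal(B, B.T):
        return False
    if not np.isin(B, (0, 1)).all() or np.any(np.diag(B) != 0):
        return False
    edges = int(B.sum() // 2)
    if K == 1:
        return edges == 0
    if edges != K - 1:
        return False
    # connectivity by union-find
    parent = list(range(K))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i, j in zip(*np.nonzero(np.triu(B))):
        ri, rj = find(int(i)), find(int(j))
        if ri == rj:
            return False
        parent[ri] = rj
    return len({find(a) for a in range(K)}) == 1


def check_model(model: LatentTreeModel, atol_orth: float = 1e-8, atol_rows: float = 1e-10) -> None:
    """Raise if the model violates the optimization constraints."""
    WtW = model.W.T @ model.W
    if np.abs(WtW - np.eye(model.W.shape[1])).max() > atol_orth:
        raise ValueError("W columns are not orthonormal")
    if np.any(model.R < 0) or np.abs(model.R.sum(axis=1) - 1).max() > atol_rows:
        raise ValueError("R rows are not on the probability simplex")
    if not _is_spanning_tree(model.B):
        raise ValueError("B is not a spanning tree")


def objective(X: np.ndarray, model: LatentTreeModel, params: DDRTreeParams) -> float:
    """Evaluate J for gene-centered data X (genes x N)."""
    check_model(model)
    W, Z, Y, B, R = model.W, model.Z, model.Y, model.B, model.R
    term1 = float(np.sum((X - W @ Z) ** 2))
    # ||W y_k - W y_k'||^2 = ||y_k - y_k'||^2 because W^T W = I
    D2_centers = cdist(Y.T, Y.T, "sqeuclidean")
    term2 = 0.5 * params.lambda_ * float(np.sum(B * D2_centers))
    D2 = cdist(Z.T, Y.T, "sqeuclidean")
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = np.where(R > 0, R * np.log(R), 0.0)  # 0 log 0 = 0
    term3 = params.gamma_ * float(np.sum(R * D2) + params.sigma_ * np.sum(ent))
    return term1 + term2 + term3


def update_R(Z: np.ndarray, Y: np.ndarray, sigma_: float) -> np.ndarray:
    """Exact minimizer of the entropy-regularized assignment term: a
    softmax over negative squared distances at temperature sigma, computed
    with a max shift for overflow safety."""
    if sigma_ <= 0:
        raise ValueError("sigma_ must be > 0")
    D2 = cdist(Z.T, Y.T, "sqeuclidean")
    M = -D2 / sigma_
    M -= M.max(axis=1, keepdims=True)
    R = np.exp(M)
    R /= R.sum(axis=1, keepdims=True)
    return R


def update_B(Y: np.ndarray) -> np.ndarray:
    """Exact minimizer of the tree term: the minimum spanning tree of the
    complete graph on centers under squared Euclidean edge weights.
    Kruskal with edges sorted by (weight, i, j) for deterministic ties."""
    K = Y.shape[1]
    B = np.zeros((K, K), dtype=int)
    if K <= 1:
        return B
    D2 = cdist(Y.T, Y.T, "sqeuclidean")
    iu, ju = np.triu_indices(K, k=1)
    order = np.lexsort((ju, iu, D2[iu, ju]))
    parent = list(range(K))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    added = 0
    for idx in order:
        i, j = int(iu[idx]), int(ju[idx])
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            B[i, j] = B[j, i] = 1
            added += 1
            if added == K - 1:
                break
    return B


def update_Y(
    Z: np.ndarray, R: np.ndarray, B: np.ndarray, lambda_: float, gamma_: float
) -> np.ndarray:
    """Stationary point in Y: solves Y (lambda L + gamma Gamma) = gamma Z R
    with L the tree Laplacian and Gamma = diag(R^T 1)."""
    L = np.diag(B.sum(axis=1)) - B
    Gamma = np.diag(R.sum(axis=0))
    A = lambda_ * L + gamma_ * Gamma
    try:
        Y = np.linalg.solve(A, (gamma_ * (Z @ R)).T).T
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular system in Y update (check gamma_ > 0 and R)") from exc
    return Y


def update_Z(
    X: np.ndarray, W: np.ndarray, Y: np.ndarray, R: np.ndarray, gamma_: float
) -> np.ndarray:
    """Stationary point in Z given orthonormal W:
    Z = (W^T X + gamma Y R^T) / (1 + gamma)."""
    return (W.T @ X + gamma_ * (Y @ R.T)) / (1.0 + gamma_)


def update_W(X: np.ndarray, Z: np.ndarray, d: int, seed: int = 0) -> np.ndarray:
    """Stiefel-constrained minimizer of the reconstruction term via
    orthogonal Procrustes on X Z^T: with thin SVD X Z^T = U S V^T, the
    optimum is W = U V^T.  A rank-deficient X Z^T is completed with
    deterministic (seeded) orthonormal columns."""
    M = X @ Z.T
    U, S, Vt = np.linalg.svd(M, full_matrices=False)
    rank = int(np.sum(S > S[0] * 1e-12)) if S.size and S[0] > 0 else 0
    if rank < d:
        rng = np.random.default_rng(seed)
        extra = rng.standard_normal((X.shape[0], d - rank))
        extra -= U[:, :rank] @ (U[:, :rank].T @ extra)
        Q, _ = np.linalg.qr(extra)
        U = np.concatenate([U[:, :rank], Q[:, : d - rank]], axis=1)
    return U @ Vt


def initialize(X: np.ndarray, params: DDRTreeParams) -> tuple[np.ndarray, LatentTreeModel]:
    """Deterministic initialization: gene-center X, take the top-d
    principal subspace for W/Z (signs fixed on rows of Z so the result is
    invariant to rotations of the gene space), seeded k-means centers for
    Y, then R and B by their exact updates.

    Returns the centered matrix alongside the model.
    """
    check_finite(X, "X")
    params = params.resolved(X.shape[1])
    N = X.shape[1]
    if params.K > N:
        raise ValueError(f"K={params.K} exceeds N={N}")
    gene_means = X.mean(axis=1, keepdims=True)
    Xc = X - gene_means
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    W = U[:, : params.d]
    Z = W.T @ Xc
    # sign convention on latent rows: largest-|entry| of each Z row positive
    for j in range(params.d):
        i = int(np.argmax(np.abs(Z[j])))
        if Z[j, i] < 0:
            Z[j] *= -1
            W[:, j] *= -1
    km = KMeans(
        n_clusters=params.K,
        n_init=10,
        random_state=sub_seed(params.seed, "kmeans_init"),
    ).fit(Z.T)
    Y = km.cluster_centers_.T.copy()
    R = update_R(Z, Y, params.sigma_)
    B = update_B(Y)
    model = LatentTreeModel(
        W=W, Z=Z, Y=Y, B=B, R=R, params=params, gene_means=gene_means.ravel()
    )
    return Xc, model


def fit(X: np.ndarray, params: DDRTreeParams | None = None) -> LatentTreeModel:
    """Alternating minimization: sweeps of (R, B, Y, Z, W) until the
    relative objective change drops below ``tol`` or ``max_iter`` sweeps.

    X is genes x samples on a log scale; it is gene-centered internally.
    The recorded objective trace is non-increasing (each block update is
    exact), and the fitted model satisfies all model constraints.
    """
    if params is None:
        params = DDRTreeParams()
    Xc, model = initialize(np.asarray(X, dtype=float), params)
    p = model.params
    J = objective(Xc, model, p)
    model.objective_trace = [J]
    eps = np.finfo(float).tiny
    for sweep in range(p.max_iter):
        for name in ("R", "B", "Y", "Z", "W"):
            if name == "R":
                model.R = update_R(model.Z, model.Y, p.sigma_)
            elif name == "B":
                model.B = update_B(model.Y)
            elif name == "Y":
                model.Y = update_Y(model.Z, model.R, model.B, p.lambda_, p.gamma_)
            elif name == "Z":
                model.Z = update_Z(Xc, model.W, model.Y, model.R, p.gamma_)
            else:
                model.W = update_W(Xc, model.Z, p.d, seed=p.seed)
            if not np.all(np.isfinite(getattr(model, name))):
                raise FloatingPointError(
                    f"non-finite values after {name} update in sweep {sweep + 1}"
                )
        J_new = objective(Xc, model, p)
        if not np.isfinite(J_new):
            raise FloatingPointError(f"non-finite objective after sweep {sweep + 1}")
        model.objective_trace.append(J_new)
        if abs(J - J_new) / max(J, eps) < p.tol:
            break
        J = J_new
    check_model(model)
    return model
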