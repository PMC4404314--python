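"""Matrix factorizations under a common contract: reduced SVD, NMF and ICA.

The embedding used for scoring is the reduced singular value decomposition
M = U Σ Vᵀ of the samples × genes matrix: columns of U hold the per-sample
component scores u_ip, columns of V the per-gene loadings, and σ_i the
singular values. NMF and FastICA are provided with the same result shape so
the mixture benchmark can compare the three factorizations head-to-head.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import NMF, FastICA
from sklearn.exceptions import ConvergenceWarning

from .io import ExpressionMatrix

logger = logging.getLogger("peacs")

#: singular values below this fraction of σ1 are treated as numerically zero
RANK_TOL = 1e-10


@dataclass
class FactorizationResult:
    """Common container for SVD / NMF / ICA factorizations.

    ``U`` (m × k) holds sample coordinates, ``V`` (n × k) gene loadings,
    ``weights`` the per-component scale (singular values for SVD, factor
    norms for NMF, all ones for ICA). ``explained_variance`` entries are
    fractions in [0, 1]; for SVD entry i is σ_i²/Σσ_j² over the full
    spectrum, which is kept in ``spectrum`` for Scree plots.
    """

    method: str
    U: np.ndarray
    weights: np.ndarray
    V: np.ndarray
    explained_variance: np.ndarray
    k: int
    gene_ids: list = field(default_factory=list)
    sample_ids: list = field(default_factory=list)
    spectrum: np.ndarray | None = None
    offset: float = 0.0
    converged: bool = True


def _extract(M) -> tuple[np.ndarray, list, list]:
    if isinstance(M, ExpressionMatrix):
        return M.values, list(M.gene_ids), list(M.sample_ids)
    X = np.asarray(M, dtype=float)
    m, n = X.shape
    return X, [f"g{j}" for j in range(n)], [f"s{i}" for i in range(m)]


def _sign_align(U: np.ndarray, V: np.ndarray) -> None:
    """Flip each component so its largest-magnitude gene loading is positive.

    Embedding distances are invariant to per-component sign; this convention
    only makes loadings and heatmap reports reproducible.
    """
    for i in range(V.shape[1]):
        j = int(np.argmax(np.abs(V[:, i])))
        if V[j, i] < 0:
            V[:, i] *= -1.0
            U[:, i] *= -1.0


def svd_factor(M, k="auto") -> FactorizationResult:
    """Reduced SVD of the matrix, truncated to k components.

    ``k='auto'`` selects the Scree elbow via :func:`select_k_elbow`. The
    rank-k reconstruction is ``U @ diag(weights) @ V.T`` with the classical
    optimal-approximation property.
    """
    X, gene_ids, sample_ids = _extract(M)
    if not np.isfinite(X).all():
        raise ValueError("matrix has non-finite entries; impute or drop them first")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    total = float((s**2).sum())
    ev = s**2 / total if total > 0 else np.zeros_like(s)
    if k == "auto":
        k = select_k_elbow(s)
    k = int(k)
    if not 1 <= k <= len(s):
        raise ValueError(f"k must be in [1, {len(s)}], got {k}")
    Uk, Vk = U[:, :k].copy(), Vt[:k].T.copy()
    _sign_align(Uk, Vk)
    return FactorizationResult(
        method="svd",
        U=Uk,
        weights=s[:k].copy(),
        V=Vk,
        explained_variance=ev[:k].copy(),
        k=k,
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        spectrum=s.copy(),
    )


def select_k_elbow(weights, override: int | None = None) -> int:
    """Scree-elbow choice of the number of components.

    The elbow is the point of largest discrete curvature of the descending
    weight curve: k = argmax_j (w_j − 2·w_{j+1} + w_{j+2}) + 1, clamped to
    [1, len−1]. With an explicit ``override`` that value is returned
    unchecked against the curve (but validated against the range).
    """
    w = np.asarray(weights, dtype=float)
    if w.ndim != 1 or len(w) < 2:
        raise ValueError("need at least two weights to find an elbow")
    if override is not None:
        override = int(override)
        if not 1 <= override <= len(w):
            raise ValueError(f"override k={override} outside [1, {len(w)}]")
        return override
    if np.ptp(w) <= 1e-12 * max(abs(w[0]), 1.0):
        warnings.warn("all weights equal; no elbow, using k=1", stacklevel=2)
        return 1
    if len(w) == 2:
        return 1
    d2 = w[:-2] - 2 * w[1:-1] + w[2:]
    k = int(np.argmax(d2)) + 1
    return int(np.clip(k, 1, len(w) - 1))


def shift_nonnegative(M) -> tuple[np.ndarray, float]:
    """Add one global offset so the matrix is entry-wise non-negative.

    Returns ``(shifted, offset)`` with ``offset = max(0, −min(M))``; already
    non-negative input is returned unchanged with offset 0.
    """
    X, _, _ = _extract(M)
    if not np.isfinite(X).all():
        raise ValueError("matrix has non-finite entries")
    lo = float(X.min())
    offset = max(0.0, -lo)
    return X + offset, offset


def nmf_factor(M, k: int, seed: int = 0, max_iter: int = 1000) -> FactorizationResult:
    """Seeded non-negative matrix factorization (multiplicative updates).

    Explained variance is reported on the reconstruction convention
    ``1 − ‖M − WH‖_F² / ‖M‖_F²`` (the fraction explained by all components
    together); per-component entries split that total in proportion to each
    rank-one term's squared Frobenius norm.
    """
    X, gene_ids, sample_ids = _extract(M)
    if (X < 0).any():
        raise ValueError("NMF requires non-negative input; apply shift_nonnegative first")
    norm2 = float((X**2).sum())
    if norm2 == 0:
        raise ValueError("zero matrix: NMF explained variance is undefined")
    model = NMF(
        n_components=int(k),
        init="nndsvda",
        solver="mu",
        beta_loss="frobenius",
        max_iter=max_iter,
        tol=1e-7,
        random_state=int(seed),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        W = model.fit_transform(X)
    H = model.components_
    resid2 = float(((X - W @ H) ** 2).sum())
    ev_total = max(0.0, 1.0 - resid2 / norm2)
    contrib = (W**2).sum(axis=0) * (H**2).sum(axis=1)
    share = contrib / contrib.sum() if contrib.sum() > 0 else np.full(int(k), 1.0 / int(k))
    order = np.argsort(-share, kind="stable")
    W, H, share = W[:, order], H[order], share[order]
    wn = np.linalg.norm(W, axis=0)
    hn = np.linalg.norm(H, axis=1)
    weights = wn * hn
    safe_w = np.where(wn > 0, wn, 1.0)
    safe_h = np.where(hn > 0, hn, 1.0)
    return FactorizationResult(
        method="nmf",
        U=W / safe_w,
        weights=weights,
        V=(H / safe_h[:, None]).T,
        explained_variance=ev_total * share,
        k=int(k),
        gene_ids=gene_ids,
        sample_ids=sample_ids,
    )


def nmf_explained_variance(F: FactorizationResult) -> float:
    """Total explained variance of an NMF result (sum of component shares)."""
    return float(F.explained_variance.sum())


def svd_rank_ev(M, k: int) -> float:
    """Explained variance of the best rank-k approximation, 1 − Σ_{i>k}σ²/Σσ².

    This is the optimal-approximation upper bound that no other rank-k
    factorization (NMF included) can exceed on the same matrix.
    """
    X, _, _ = _extract(M)
    s = np.linalg.svd(X, compute_uv=False)
    total = float((s**2).sum())
    if total == 0:
        raise ValueError("zero matrix")
    return float((s[: int(k)] ** 2).sum() / total)


def ica_factor(M, k: int, seed: int = 0, max_iter: int = 1000) -> FactorizationResult:
    """Seeded FastICA: whitening plus an independence-maximizing rotation.

    Sample coordinates (the estimated sources) go in U and the mixing
    vectors (gene loadings) in V. ICA has no canonical component order or
    scale, so components are ordered by the variance their rank-one
    reconstruction explains and sign-aligned like the SVD; ``weights`` are
    all ones. Non-convergence is a warning, not an error, and the result is
    flagged via ``converged=False``.
    """
    X, gene_ids, sample_ids = _extract(M)
    k = int(k)
    if k > min(X.shape):
        raise ValueError(f"k={k} exceeds min(m, n)={min(X.shape)}")
    model = FastICA(
        n_components=k, random_state=int(seed), max_iter=max_iter, whiten="unit-variance"
    )
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        S = model.fit_transform(X)
    for w in caught:
        if issubclass(w.category, ConvergenceWarning):
            converged = False
            warnings.warn(
                "FastICA did not converge; result flagged as partial", stacklevel=2
            )
    A = model.mixing_  # n × k
    Xc = X - model.mean_
    total = float((Xc**2).sum())
    ev = np.array(
        [
            (S[:, i] ** 2).sum() * (A[:, i] ** 2).sum() / total if total > 0 else 0.0
            for i in range(k)
        ]
    )
    ev = np.clip(ev, 0.0, 1.0)
    order = np.argsort(-ev, kind="stable")
    S, A, ev = S[:, order].copy(), A[:, order].copy(), ev[order]
    _sign_align(S, A)
    return FactorizationResult(
        method="ica",
        U=S,
        weights=np.ones(k),
        V=A,
        explained_variance=ev,
        k=k,
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        converged=converged,
    )


def reconstruct(F: FactorizationResult) -> np.ndarray:
    """Rank-k reconstruction U diag(w) Vᵀ (on the shifted scale for NMF)."""
    return F.U @ np.diag(F.weights) @ F.V.T


def top_loadings(F: FactorizationResult, component: int, n_top: int = 10) -> pd.DataFrame:
    """Genes ranked by |loading| in the given 1-based component, sign retained.

    Ties in magnitude break on gene id, so reports are stable.
    """
    if not 1 <= int(component) <= F.k:
        raise ValueError(f"component must be in [1, {F.k}], got {component}")
    load = F.V[:, int(component) - 1]
    order = sorted(range(len(load)), key=lambda j: (-abs(load[j]), F.gene_ids[j]))
    top = order[: int(n_top)]
    return pd.DataFrame(
        {"gene": [F.gene_ids[j] for j in top], "loading": [float(load[j]) for j in top]}
    )


def scree_table(F: FactorizationResult) -> pd.DataFrame:
    """Component / weight / explained-variance table (full SVD spectrum if kept)."""
    if F.spectrum is not None:
        s = F.spectrum
        total = float((s**2).sum())
        ev = s**2 / total if total > 0 else np.zeros_like(s)
        w = s
    else:
        ev = F.explained_variance
        w = F.weights
    return pd.DataFrame(
        {
            "component": np.arange(1, len(w) + 1),
            "weight": w,
            "explained_variance": ev,
            "cumulative": np.cumsum(ev),
        }
    )
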