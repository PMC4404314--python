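"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths (and, where feasible, the linear
algebra routines) used by the package: explicit loops, sort-based medians,
and an eigendecomposition-of-Gram-matrix route to the SVD.
"""

import numpy as np


def sort_median(xs):
    """Median by explicit sort; even counts use the midpoint convention."""
    xs = sorted(float(x) for x in xs)
    n = len(xs)
    if n % 2:
        return xs[n // 2]
    return 0.5 * (xs[n // 2 - 1] + xs[n // 2])


def center_columns_by_median(X):
    X = [list(map(float, row)) for row in X]
    m, n = len(X), len(X[0])
    for j in range(n):
        med = sort_median([X[i][j] for i in range(m)])
        for i in range(m):
            X[i][j] -= med
    return X


def svd_via_gram(X):
    """SVD from the eigendecomposition of XᵀX (columns of U = X v / σ).

    An independent route to the same factorization: right singular vectors
    are eigenvectors of the Gram matrix, singular values the square roots of
    its eigenvalues.
    """
    X = np.asarray(X, dtype=float)
    G = np.zeros((X.shape[1], X.shape[1]))
    for a in range(X.shape[1]):
        for b in range(X.shape[1]):
            G[a, b] = sum(X[i, a] * X[i, b] for i in range(X.shape[0]))
    evals, evecs = np.linalg.eigh(G)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    s = np.sqrt(np.clip(evals, 0.0, None))
    U = np.zeros((X.shape[0], X.shape[1]))
    for i in range(len(s)):
        if s[i] > 0:
            U[:, i] = (X @ evecs[:, i]) / s[i]
    return U, s, evecs


def brute_force_scores(X, groups, k, centroid_method="median", se_floor=1e-8):
    """Loop-based reimplementation of the full scoring pipeline.

    ``X`` is a samples × genes matrix (rows i), ``groups`` maps a label to
    its row indices. Median-centers genes, embeds via the Gram-matrix SVD,
    and computes distance / SE / score with explicit loops. Scores are
    invariant to per-component sign, so no sign alignment is needed.
    """
    Xc = np.array(center_columns_by_median(X))
    U, s, V = svd_via_gram(Xc)
    coords = U[:, :k]
    m = coords.shape[0]
    if centroid_method == "median":
        centroid = [sort_median(coords[:, i]) for i in range(k)]
    else:
        centroid = [sum(coords[:, i]) / m for i in range(k)]
    scores = {}
    for label, rows in groups.items():
        n = len(rows)
        if n < 2:
            scores[label] = float("nan")
            continue
        mean = [sum(coords[r, i] for r in rows) / n for i in range(k)]
        d = sum((mean[i] - centroid[i]) ** 2 for i in range(k)) ** 0.5
        se2 = 0.0
        for i in range(k):
            var = sum((coords[r, i] - mean[i]) ** 2 for r in rows) / (n - 1)
            se2 += var / n
        denom = se2**0.5
        if d == 0.0:
            scores[label] = 0.0
        else:
            scores[label] = d / max(denom, se_floor)
    return scores


def pearson_r2(x, y):
    """Textbook Pearson correlation squared, by explicit sums."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return (sxy * sxy) / (sxx * syy)


def knockdown_filter_rule(folds_by_gene, min_hairpins=3, min_fold=2.0):
    """Exhaustive application of the '≥ min_hairpins hairpins at ≥ min_fold' rule."""
    kept = set()
    for gene, folds in folds_by_gene.items():
        n_qual = sum(1 for f in folds if f >= min_fold)
        if n_qual >= min_hairpins:
            kept.add(gene)
    return kept
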