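"""Head-to-head factorization benchmark on designed state mixtures.

Given a mixture experiment with known per-sample state fractions, score how
well each factorization's sample coordinates track the true fractions: the
squared Pearson correlation r² between every component and every state
fraction (sign-agnostic — a component may anti-correlate with a state and
still identify it), the explained-variance/Scree profile, and a replicate
clustering score (mean within-design-group distance over mean between-group
distance in component 1–2 space; < 1 means replicates sit closer to each
other than to other designs).

SVD and ICA run on the per-gene median-centered log2 matrix; NMF runs on
the non-negative linear scale (with a recorded global shift if needed).
The SVD rank-k explained variance on the NMF input is reported alongside as
the optimal-approximation bound that NMF cannot exceed.
"""

from __future__ import annotations

import json
import warnings

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .factorization import (
    ica_factor,
    nmf_explained_variance,
    nmf_factor,
    shift_nonnegative,
    svd_factor,
    svd_rank_ev,
)
from .io import ExpressionMatrix, median_center_genes
from .simulate import StateMixtureTruth

METHODS = ("svd", "nmf", "ica")


def component_state_r2(component, fraction) -> float:
    """Squared Pearson correlation between a component score and a state fraction.

    Affine-invariant and sign-agnostic. Constant input has no defined
    correlation: returns NaN with a warning.
    """
    x = np.asarray(component, dtype=float)
    y = np.asarray(fraction, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("component and fraction must be equal-length vectors (≥3)")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant vector: correlation undefined", stacklevel=2)
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def replicate_clustering_score(coords: np.ndarray, labels) -> float:
    """Mean within-group distance / mean between-group distance (components 1–2)."""
    labels = np.asarray(labels)
    D = squareform(pdist(coords[:, :2]))
    same = labels[:, None] == labels[None, :]
    iu = np.triu_indices(len(labels), k=1)
    within = D[iu][same[iu]]
    between = D[iu][~same[iu]]
    if len(within) == 0 or len(between) == 0:
        raise ValueError("need at least two groups with replicates")
    return float(within.mean() / between.mean())


def _linear_values(M: ExpressionMatrix) -> np.ndarray:
    if M.scale == "linear_expr":
        return M.values
    if M.scale == "log2_expr":
        return 2.0**M.values
    return 2.0 ** (-M.values)  # ct: abundance falls with cycle number


def benchmark_factorizations(
    M: ExpressionMatrix,
    truth: StateMixtureTruth,
    methods=METHODS,
    k: int = 2,
    seed: int = 0,
    center: bool = True,
) -> dict:
    """Run each factorization and score it against the known fractions.

    Returns ``{method: {"r2": DataFrame (component × state), "best_r2":
    per-state max over components, "explained_variance": array,
    "clustering_score": float, ...}}`` plus a ``"svd_bound_linear"`` entry,
    the rank-k SVD explained variance on the NMF input matrix.
    """
    fractions = np.asarray(truth.fractions, dtype=float)
    if fractions.shape[0] != M.n_samples:
        raise ValueError(
            f"truth has {fractions.shape[0]} rows for {M.n_samples} samples"
        )
    if fractions.shape[1] < 2 or all(np.ptp(fractions[:, j]) == 0 for j in range(fractions.shape[1])):
        raise ValueError("degenerate design: all fraction columns are constant")

    X_signed = median_center_genes(M) if center else M
    linear, offset = shift_nonnegative(_linear_values(M))
    report: dict = {"k": int(k), "seed": int(seed), "nmf_offset": offset}
    state_cols = list(truth.state_names)
    for method in methods:
        if method == "svd":
            F = svd_factor(X_signed, k=k)
            ev = F.explained_variance
        elif method == "ica":
            F = ica_factor(X_signed.values, k=k, seed=seed)
            F.sample_ids = list(M.sample_ids)
            ev = F.explained_variance
        elif method == "nmf":
            F = nmf_factor(linear, k=k, seed=seed)
            F.sample_ids = list(M.sample_ids)
            ev = F.explained_variance
        else:
            raise ValueError(f"unknown method {method!r}")
        coords = F.U[:, :k]
        r2 = np.empty((k, fractions.shape[1]))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for i in range(k):
                for j in range(fractions.shape[1]):
                    r2[i, j] = component_state_r2(coords[:, i], fractions[:, j])
        r2_df = pd.DataFrame(
            r2, index=[f"component_{i + 1}" for i in range(k)], columns=state_cols
        )
        entry = {
            "r2": r2_df,
            "best_r2": r2_df.max(axis=0),
            "explained_variance": np.asarray(ev, dtype=float),
            "clustering_score": replicate_clustering_score(coords, truth.labels),
            "converged": getattr(F, "converged", True),
        }
        if method == "nmf":
            entry["explained_variance_total"] = nmf_explained_variance(F)
        if method == "svd":
            entry["spectrum"] = F.spectrum
        report[method] = entry
    report["svd_bound_linear"] = svd_rank_ev(linear, k)
    return report


def fraction_span_r2(M: ExpressionMatrix, truth: StateMixtureTruth) -> np.ndarray:
    """R² of regressing each centered fraction column on the first s−1 SVD components.

    Genes are centered at their *mean* here: mean centering annihilates
    exactly the offset direction, so for noise-free linear mixtures of s
    states the centered matrix has rank s−1 and the centered fraction
    vectors lie exactly in the span of its first s−1 left singular vectors.
    (Median centering, used by the scoring pipeline, removes the offset only
    approximately and leaves a small residual dimension.)
    """
    s = truth.fractions.shape[1]
    X = M.values - M.values.mean(axis=0)
    F = svd_factor(X, k=s - 1)
    U = F.U
    out = np.empty(s)
    for j in range(s):
        y = truth.fractions[:, j] - truth.fractions[:, j].mean()
        total = float(y @ y)
        if total == 0:
            out[j] = np.nan
            continue
        beta, *_ = np.linalg.lstsq(U, y, rcond=None)
        resid = y - U @ beta
        out[j] = 1.0 - float(resid @ resid) / total
    return out


def report_to_frame(report: dict) -> pd.DataFrame:
    """Flat per-method summary table of the benchmark report."""
    rows = []
    for method in METHODS:
        if method not in report:
            continue
        entry = report[method]
        row = {
            "method": method,
            "clustering_score": entry["clustering_score"],
            "explained_variance_k": float(np.sum(entry["explained_variance"])),
        }
        for state, v in entry["best_r2"].items():
            row[f"best_r2_{state}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def report_to_json(report: dict, path) -> None:
    out = {"k": report["k"], "seed": report["seed"], "nmf_offset": report["nmf_offset"],
           "svd_bound_linear": report["svd_bound_linear"]}
    for method in METHODS:
        if method not in report:
            continue
        entry = report[method]
        out[method] = {
            "r2": entry["r2"].to_dict(),
            "best_r2": entry["best_r2"].to_dict(),
            "explained_variance": np.asarray(entry["explained_variance"]).tolist(),
            "clustering_score": entry["clustering_score"],
            "converged": bool(entry["converged"]),
        }
    with open(path, "w") as fh:
        json.dump(out, fh, indent=1)
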