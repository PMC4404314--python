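"""The perturbation score: replicate-centroid distance over replicate error.

Each perturbation's samples are embedded as rows of the SVD left-factor U
(component scores u_ip, unscaled by the singular values, so every component
counts equally in the distance). The score for a perturbation with *repl*
replicates is

    score = d / sqrt(Σ_i S.E._i²),

where d is the Euclidean distance between the replicate centroid (the mean
of the replicate coordinates, component-wise) and a global centroid taken
across *all* embedded samples (component-wise median by default), and
S.E._i is the standard error of the replicate coordinates in component i.
It reads as a signal-to-noise ratio for a shift in cell-state proportions.

Empirical p-values come from a Monte Carlo null: draw n samples uniformly
without replacement from all embedded rows, ignoring labels, score the draw
against the same fixed global centroid, and repeat. The reported p-value is
the add-one estimator (count of null scores ≥ observed + 1)/(iterations + 1),
which is never exactly zero; the raw top-rank convention (count/iterations)
is available as an option.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as pio
from .factorization import (
    FactorizationResult,
    scree_table,
    svd_factor,
    top_loadings,
)
from .io import ExpressionMatrix, PerturbationDesign

logger = logging.getLogger("peacs")

DEFAULT_SE_FLOOR = 1e-8
DEFAULT_ITERATIONS = 10_000


@dataclass
class PerturbationEmbedding:
    """Per-sample coordinates in the first k SVD components (rows of U)."""

    coords: np.ndarray
    sample_ids: list
    k: int

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.sample_ids), self.k):
            raise ValueError("coords shape does not match sample_ids and k")

    def rows_for(self, sample_ids) -> np.ndarray:
        index = {s: i for i, s in enumerate(self.sample_ids)}
        return np.array([index[s] for s in sample_ids], dtype=int)


@dataclass
class Centroid:
    values: np.ndarray
    method: str = "median"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)


def embed(F: FactorizationResult, k: int | None = None) -> PerturbationEmbedding:
    """First k columns of U as the scoring space (k defaults to F.k)."""
    k = F.k if k is None else int(k)
    if not 1 <= k <= F.k:
        raise ValueError(f"k={k} exceeds the {F.k} available components")
    return PerturbationEmbedding(coords=F.U[:, :k].copy(), sample_ids=list(F.sample_ids), k=k)


def global_centroid(E: PerturbationEmbedding, method: str = "median") -> Centroid:
    """Component-wise median (default) or mean over all embedded samples."""
    if E.coords.shape[0] == 0:
        raise ValueError("cannot take the centroid of an empty embedding")
    if method == "median":
        values = np.median(E.coords, axis=0)
    elif method == "mean":
        values = E.coords.mean(axis=0)
    else:
        raise ValueError("centroid method must be 'median' or 'mean'")
    return Centroid(values=values, method=method)


def _group_score(coords: np.ndarray, centroid: np.ndarray, se_floor: float):
    """distance, per-component SE, combined SE, score and flag for one group."""
    n = coords.shape[0]
    repl_centroid = coords.mean(axis=0)
    d = float(np.linalg.norm(repl_centroid - centroid))
    se = coords.std(axis=0, ddof=1) / np.sqrt(n)
    denom = float(np.sqrt((se**2).sum()))
    flags = []
    if d == 0.0:
        score = 0.0
    elif denom < se_floor:
        score = d / se_floor
        flags.append("se_floored")
    else:
        score = d / denom
    return repl_centroid, d, se, denom, score, flags


def score_perturbation(
    E: PerturbationEmbedding,
    design: PerturbationDesign,
    label: str,
    centroid: Centroid,
    se_floor: float = DEFAULT_SE_FLOOR,
    group_by: str = "perturbation",
) -> dict:
    """Score one replicate group; groups with <2 replicates are unscorable."""
    groups = design.groups(by=group_by)
    if label not in groups:
        raise KeyError(f"no samples for perturbation {label!r}")
    return _score_row(E, design, label, groups[label], centroid, se_floor)


def _score_row(E, design, label, sample_ids, centroid, se_floor) -> dict:
    tab = design.table
    sub = tab[tab["sample_id"].isin(set(sample_ids))]
    is_control = bool(sub["is_control"].all())
    n = len(sample_ids)
    row = {
        "perturbation": label,
        "n_replicates": n,
        "is_control": is_control,
        "d": np.nan,
        "se": np.nan,
        "score": np.nan,
        "flags": "",
    }
    if n < 2:
        row["flags"] = "unscorable"
        logger.info("perturbation %s has %d replicate(s); unscorable", label, n)
        return row
    coords = E.coords[E.rows_for(sample_ids)]
    repl_centroid, d, se, denom, score, flags = _group_score(coords, centroid.values, se_floor)
    row.update({"d": d, "se": denom, "score": score, "flags": ";".join(flags)})
    for i in range(E.k):
        row[f"centroid_{i + 1}"] = float(repl_centroid[i])
        row[f"se_{i + 1}"] = float(se[i])
    return row


def score_all(
    E: PerturbationEmbedding,
    design: PerturbationDesign,
    centroid: Centroid,
    se_floor: float = DEFAULT_SE_FLOOR,
    group_by: str = "perturbation",
) -> pd.DataFrame:
    """Score every replicate group; one row per perturbation label."""
    design_ids = set(design.table["sample_id"])
    if not design_ids.issubset(set(E.sample_ids)):
        raise ValueError("design contains samples absent from the embedding")
    rows = [
        _score_row(E, design, label, samples, centroid, se_floor)
        for label, samples in design.groups(by=group_by).items()
    ]
    return pd.DataFrame(rows)


def _null_scores(coords, centroid, n, iterations, rng, se_floor) -> np.ndarray:
    """Null score distribution for replicate count n, drawn without replacement."""
    m = coords.shape[0]
    if n > m:
        raise ValueError(f"cannot draw {n} distinct samples from {m}")
    idx = rng.random((iterations, m)).argsort(axis=1)[:, :n]
    sub = coords[idx]  # (iterations, n, k)
    mean = sub.mean(axis=1)
    d = np.linalg.norm(mean - centroid, axis=1)
    sd = sub.std(axis=1, ddof=1)
    denom = np.sqrt((sd**2).sum(axis=1) / n)
    scores = d / np.maximum(denom, se_floor)
    scores[d == 0.0] = 0.0
    return scores


def empirical_pvalue(null: np.ndarray, observed: float, raw_rank: bool = False) -> float:
    """Rank-based p-value of an observed score in a null sample (ties count as ≥)."""
    null = np.asarray(null, dtype=float)
    count = int((null >= observed).sum())
    if raw_rank:
        return count / len(null)
    return (count + 1) / (len(null) + 1)


def monte_carlo_pvalues(
    E: PerturbationEmbedding,
    design: PerturbationDesign,
    scores: pd.DataFrame,
    centroid: Centroid,
    iterations: int = DEFAULT_ITERATIONS,
    seed: int = 0,
    se_floor: float = DEFAULT_SE_FLOOR,
    raw_rank: bool = False,
) -> pd.DataFrame:
    """Attach Monte Carlo p-values and Bonferroni-adjusted p-values.

    One null distribution is computed per distinct replicate count and cached;
    the global centroid stays fixed (it is a property of the experiment, not
    of a draw). Bonferroni multiplies by the number of scored perturbations.
    """
    if iterations < 100:
        raise ValueError("use at least 100 Monte Carlo iterations")
    rng = np.random.default_rng(seed)
    scored = scores["n_replicates"] >= 2
    nulls: dict[int, np.ndarray] = {}
    for n in sorted(scores.loc[scored, "n_replicates"].unique()):
        nulls[int(n)] = _null_scores(
            E.coords, centroid.values, int(n), int(iterations), rng, se_floor
        )
    out = scores.copy()
    out["p_value"] = np.nan
    out["p_bonferroni"] = np.nan
    n_tests = int(scored.sum())
    for i in out.index[scored]:
        n = int(out.at[i, "n_replicates"])
        p = empirical_pvalue(nulls[n], float(out.at[i, "score"]), raw_rank=raw_rank)
        out.at[i, "p_value"] = p
        out.at[i, "p_bonferroni"] = min(1.0, p * n_tests)
    return out


@dataclass
class PEACSRun:
    """Everything a full run produces: scores, embedding, loadings, metadata."""

    table: pd.DataFrame
    embedding: PerturbationEmbedding
    factorization: FactorizationResult
    centroid: Centroid
    loadings: dict
    scree: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def embedding_frame(self) -> pd.DataFrame:
        cols = [f"component_{i + 1}" for i in range(self.embedding.k)]
        return pd.DataFrame(
            self.embedding.coords, index=self.embedding.sample_ids, columns=cols
        )


def run_peacs(
    M: ExpressionMatrix,
    design: PerturbationDesign,
    *,
    ref_gene: str | None = None,
    drop_ref: bool = True,
    orient_expression: bool = True,
    impute: bool = True,
    filter_kd: bool | None = None,
    min_hairpins: int = 3,
    min_fold: float = 2.0,
    keep_all_hairpins: bool = False,
    k="auto",
    centroid_method: str = "median",
    group_by: str = "perturbation",
    iterations: int = DEFAULT_ITERATIONS,
    seed: int = 0,
    se_floor: float = DEFAULT_SE_FLOOR,
    raw_rank: bool = False,
    n_top: int = 10,
) -> PEACSRun:
    """The full pipeline: normalize → filter → SVD → embed → score → p-values.

    Stages
    ------
    1. Reference (ΔCT) normalization if ``ref_gene`` is given; CT-scale data
       are then flipped to log2 expression unless ``orient_expression=False``
       (scores are invariant to the flip).
    2. Knockdown filter: hairpin fold-changes vs. controls, genes kept when
       ``min_hairpins`` hairpins reach ``min_fold``. ``filter_kd=None`` applies
       the filter whenever the design has control samples; ``False`` skips it.
    3. Per-gene median centering and (optional) median imputation of missing
       cells.
    4. Reduced SVD with ``k`` components (``'auto'`` = Scree elbow).
    5. Score every replicate group against the global centroid, then Monte
       Carlo p-values and Bonferroni adjustment over the scored groups.

    Returns a :class:`PEACSRun`; the score table is sorted by decreasing
    score with unscorable groups last.
    """
    design.validate_against(M)
    meta: dict = {
        "seed": int(seed),
        "iterations": int(iterations),
        "centroid": centroid_method,
        "group_by": group_by,
        "se_floor": se_floor,
        "ref_gene": ref_gene,
        "n_samples_in": M.n_samples,
        "n_genes_in": M.n_genes,
    }

    if ref_gene is not None:
        M = pio.normalize_reference(M, ref_gene, drop_ref=drop_ref)
        logger.info("normalized to reference gene %s (dropped=%s)", ref_gene, drop_ref)
    if M.scale == "ct" and orient_expression:
        M = pio.ct_to_expression(M)

    do_filter = filter_kd
    if do_filter is None:
        do_filter = bool(design.table["is_control"].any()) and bool(
            (~design.table["is_control"]).any()
        )
    retained = None
    if do_filter:
        kd = pio.compute_fold_change(M, design, None)
        M, design, retained = pio.filter_by_knockdown(
            M,
            design,
            kd,
            min_hairpins=min_hairpins,
            min_fold=min_fold,
            keep_all_hairpins=keep_all_hairpins,
        )
        meta["retained_genes"] = {g: list(h) for g, h in retained.items()}
        logger.info(
            "knockdown filter kept %d genes, %d samples", len(retained), M.n_samples
        )
    meta["kd_filter"] = bool(do_filter)
    meta["min_hairpins"], meta["min_fold"] = int(min_hairpins), float(min_fold)

    if impute:
        M, n_imputed = pio.impute_gene_median(M)
        meta["n_imputed"] = n_imputed
    M = pio.median_center_genes(M)

    F = svd_factor(M, k="auto" if k == "auto" else int(k))
    meta["k"] = F.k
    meta["k_source"] = "elbow" if k == "auto" else "user"
    E = embed(F)
    centroid = global_centroid(E, method=centroid_method)
    table = score_all(E, design, centroid, se_floor=se_floor, group_by=group_by)
    table = monte_carlo_pvalues(
        E,
        design,
        table,
        centroid,
        iterations=iterations,
        seed=seed,
        se_floor=se_floor,
        raw_rank=raw_rank,
    )
    table = table.sort_values(
        ["score", "perturbation"], ascending=[False, True], na_position="last"
    ).reset_index(drop=True)
    loadings = {c: top_loadings(F, c, n_top=n_top) for c in range(1, F.k + 1)}
    meta["n_scored"] = int((table["n_replicates"] >= 2).sum())
    return PEACSRun(
        table=table,
        embedding=E,
        factorization=F,
        centroid=centroid,
        loadings=loadings,
        scree=scree_table(F),
        metadata=meta,
    )
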