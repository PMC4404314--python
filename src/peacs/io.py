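"""Expression tables, design sheets, qPCR normalization and knockdown filtering.

Expression matrices are stored samples-by-genes (one row per perturbed
population, one column per profiled gene), on one of three scales:

``ct``
    Raw or reference-normalized qPCR cycle-threshold values. CT is
    *inversely* log2-related to abundance: one extra cycle means half
    the transcript.
``log2_expr``
    log2 expression units, higher = more transcript.
``linear_expr``
    Linear-scale abundances (non-negative).

The normalization pipeline mirrors standard ΔCT practice: subtract a
reference (housekeeping) gene per sample, then center every gene at its
median so each gene's median value is 0 across the experiment.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("peacs")

SCALES = ("ct", "log2_expr", "linear_expr")

#: Required design-sheet columns, in canonical order.
DESIGN_COLUMNS = (
    "sample_id",
    "perturbation",
    "target_gene",
    "hairpin",
    "replicate",
    "is_control",
)


@dataclass
class ExpressionMatrix:
    """A samples × genes expression matrix with identifiers and a scale tag.

    Parameters
    ----------
    values
        Float matrix, shape ``(n_samples, n_genes)``. Missing measurements
        are NaN.
    gene_ids, sample_ids
        Unique identifiers matching the matrix dimensions.
    scale
        One of :data:`SCALES`.
    """

    values: np.ndarray
    gene_ids: list = field(default_factory=list)
    sample_ids: list = field(default_factory=list)
    scale: str = "log2_expr"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D samples × genes matrix")
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        m, n = self.values.shape
        if len(self.gene_ids) != n:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {n} columns")
        if len(self.sample_ids) != m:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {m} rows")
        if len(set(self.gene_ids)) != n:
            raise ValueError("duplicate gene ids")
        if len(set(self.sample_ids)) != m:
            raise ValueError("duplicate sample ids")
        if self.scale not in SCALES:
            raise ValueError(f"scale must be one of {SCALES}, got {self.scale!r}")
        if n >= m:
            warnings.warn(
                f"matrix has {n} genes for only {m} samples; the SVD embedding "
                "is intended for more samples than genes",
                RuntimeWarning,
                stacklevel=2,
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(
                f"gene {gene!r} not found; available genes: {', '.join(self.gene_ids)}"
            ) from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, scale: str = "log2_expr") -> "ExpressionMatrix":
        return cls(
            values=df.to_numpy(dtype=float),
            gene_ids=list(df.columns),
            sample_ids=list(df.index),
            scale=scale,
        )

    def _with(self, **kw) -> "ExpressionMatrix":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return replace(self, **kw)


@dataclass
class PerturbationDesign:
    """Sample → (perturbation, target gene, hairpin, replicate, control) map."""

    table: pd.DataFrame

    def __post_init__(self):
        df = self.table.copy()
        missing = [c for c in DESIGN_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"design sheet missing required columns: {missing}")
        extra = [c for c in df.columns if c not in DESIGN_COLUMNS]
        if extra:
            warnings.warn(f"ignoring unknown design columns: {extra}", stacklevel=2)
            df = df.drop(columns=extra)
        df = df.loc[:, list(DESIGN_COLUMNS)].reset_index(drop=True)
        for col in ("sample_id", "perturbation", "target_gene", "hairpin"):
            df[col] = df[col].astype(str)
        df["replicate"] = df["replicate"].astype(int)
        df["is_control"] = df["is_control"].map(_as_bool)
        if df["sample_id"].duplicated().any():
            dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValueError(f"duplicate sample ids in design sheet: {dups}")
        self.table = df

    def validate_against(self, M: ExpressionMatrix) -> None:
        unknown = set(self.table["sample_id"]) - set(M.sample_ids)
        if unknown:
            raise ValueError(f"design samples absent from matrix: {sorted(unknown)}")

    def groups(self, by: str = "perturbation") -> dict:
        """Replicate groups as ``label -> [sample_id, ...]``.

        ``by='perturbation'`` groups each hairpin's biological replicates;
        ``by='gene'`` pools all hairpins targeting the same gene.
        """
        if by == "perturbation":
            key = "perturbation"
        elif by == "gene":
            key = "target_gene"
        else:
            raise ValueError("group level must be 'perturbation' or 'gene'")
        return {
            label: list(sub["sample_id"]) for label, sub in self.table.groupby(key, sort=True)
        }

    def control_samples(self) -> list:
        return list(self.table.loc[self.table["is_control"], "sample_id"])

    def subset(self, sample_ids) -> "PerturbationDesign":
        keep = self.table["sample_id"].isin(set(sample_ids))
        return PerturbationDesign(self.table.loc[keep].reset_index(drop=True))


def _as_bool(x) -> bool:
    if isinstance(x, str):
        v = x.strip().lower()
        if v in ("true", "t", "yes", "1"):
            return True
        if v in ("false", "f", "no", "0"):
            return False
        raise ValueError(f"cannot interpret {x!r} as a control flag")
    return bool(x)


def _sep(dialect: str) -> str:
    if dialect == "tsv":
        return "\t"
    if dialect == "csv":
        return ","
    raise ValueError("dialect must be 'tsv' or 'csv'")


def load_expression_table(
    path,
    dialect: str = "tsv",
    scale: str = "ct",
    transpose: bool = False,
) -> ExpressionMatrix:
    """Read an expression table (first row = gene header, first column = sample ids).

    Non-numeric cells (e.g. qPCR ``Undetermined`` wells) become NaN and are
    counted in the log. ``transpose=True`` reads genes-as-rows tables.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(_sep(dialect))[1:]
    if len(set(header)) != len(header):
        dups = sorted({h for h in header if header.count(h) > 1})
        raise ValueError(f"duplicate column ids in {path}: {dups}")
    df = pd.read_csv(path, sep=_sep(dialect), index_col=0)
    if transpose:
        df = df.T
    numeric = df.apply(pd.to_numeric, errors="coerce")
    n_coerced = int((numeric.isna() & df.notna()).sum().sum())
    if n_coerced:
        logger.info("load_expression_table: %d non-numeric cells set to missing", n_coerced)
    M = ExpressionMatrix.from_frame(numeric, scale=scale)
    frac_missing = np.isnan(M.values).mean(axis=0)
    bad = [g for g, f in zip(M.gene_ids, frac_missing) if f > 0.20]
    if bad:
        warnings.warn(f"genes with >20% missing values: {bad}", stacklevel=2)
    return M


def write_expression_table(M: ExpressionMatrix, path, dialect: str = "tsv") -> None:
    M.to_frame().to_csv(path, sep=_sep(dialect), index_label="sample_id")


def load_design(path) -> PerturbationDesign:
    return PerturbationDesign(pd.read_csv(path, sep="\t"))


def write_design(design: PerturbationDesign, path) -> None:
    design.table.to_csv(path, sep="\t", index=False)


def normalize_reference(
    M: ExpressionMatrix, ref_gene: str, drop_ref: bool = True
) -> ExpressionMatrix:
    """Subtract the reference gene's value from every gene, per sample (ΔCT).

    On the CT scale this is the classical ΔCT = CT(gene) − CT(reference);
    on the log2 scale it is expression relative to the housekeeping gene.
    The reference column becomes identically zero and is dropped by default.
    """
    if M.scale == "linear_expr":
        raise ValueError("reference normalization requires ct or log2_expr scale")
    j = M.gene_index(ref_gene)
    ref = M.values[:, j]
    if np.isnan(ref).any():
        raise ValueError(f"reference gene {ref_gene!r} has missing values")
    values = M.values - ref[:, None]
    gene_ids = list(M.gene_ids)
    if drop_ref:
        values = np.delete(values, j, axis=1)
        gene_ids.pop(j)
    return M._with(values=values, gene_ids=gene_ids)


def ct_to_expression(M: ExpressionMatrix) -> ExpressionMatrix:
    """Flip CT-scale values to log2 expression (−ΔCT; higher = more transcript).

    Distances and scores downstream are invariant to this global sign flip;
    it only makes loadings reports read in the intuitive direction.
    """
    if M.scale != "ct":
        raise ValueError("ct_to_expression expects a ct-scale matrix")
    return M._with(values=-M.values, scale="log2_expr")


def median_center_genes(M: ExpressionMatrix) -> ExpressionMatrix:
    """Center each gene at its median (NaN-aware).

    Even-length columns use the midpoint of the two central values. A gene
    with no observed values cannot be centered and is an error.
    """
    all_missing = np.isnan(M.values).all(axis=0)
    if all_missing.any():
        bad = [g for g, b in zip(M.gene_ids, all_missing) if b]
        raise ValueError(f"genes with all values missing: {bad}")
    med = np.nanmedian(M.values, axis=0)
    return M._with(values=M.values - med)


def impute_gene_median(M: ExpressionMatrix) -> tuple[ExpressionMatrix, int]:
    """Fill missing cells with the gene's median; returns (matrix, #imputed).

    After median centering this imputes 0, i.e. a neutral value that keeps
    the sample without inventing signal.
    """
    mask = np.isnan(M.values)
    n = int(mask.sum())
    if n == 0:
        return M, 0
    if mask.all(axis=0).any():
        raise ValueError("cannot impute a gene with no observed values")
    med = np.nanmedian(M.values, axis=0)
    values = np.where(mask, np.broadcast_to(med, M.values.shape), M.values)
    rows, cols = np.nonzero(mask)
    for r, c in zip(rows, cols):
        logger.info("imputed %s / %s to gene median", M.sample_ids[r], M.gene_ids[c])
    return M._with(values=values), n


def compute_fold_change(
    M: ExpressionMatrix,
    design: PerturbationDesign,
    target_map: dict | None = None,
) -> pd.DataFrame:
    """Per-hairpin linear fold-knockdown of its own target gene vs. controls.

    Convention: ``fold_knockdown = 2**ΔΔCT`` where ΔΔCT = mean CT(hairpin) −
    mean CT(control) for the target gene (CT up ⇒ expression down ⇒ fold > 1).
    On the log2-expression scale the equivalent is
    ``2**(mean log2 control − mean log2 hairpin)``; on the linear scale the
    ratio of means. Pass the reference-normalized matrix so that sample-level
    loading differences cancel.

    Returns a table with columns ``target_gene, hairpin_id, fold_knockdown``.
    """
    design.validate_against(M)
    tab = design.table
    controls = tab.loc[tab["is_control"], "sample_id"]
    if controls.empty:
        raise ValueError("design marks no control samples; cannot compute fold changes")
    row_of = {s: i for i, s in enumerate(M.sample_ids)}
    ctrl_rows = [row_of[s] for s in controls]
    records = []
    for hairpin, sub in tab.loc[~tab["is_control"]].groupby("hairpin", sort=True):
        targets = set(sub["target_gene"])
        target = target_map.get(hairpin) if target_map else targets.pop()
        if target is None:
            warnings.warn(f"hairpin {hairpin!r} has no target mapping; skipped", stacklevel=2)
            continue
        if target not in M.gene_ids:
            warnings.warn(
                f"target gene {target!r} of hairpin {hairpin!r} not profiled; skipped",
                stacklevel=2,
            )
            continue
        rows = [row_of[s] for s in sub["sample_id"]]
        if not rows:
            warnings.warn(f"hairpin {hairpin!r} has no samples; skipped", stacklevel=2)
            continue
        j = M.gene_index(target)
        h_mean = np.nanmean(M.values[rows, j])
        c_mean = np.nanmean(M.values[ctrl_rows, j])
        if M.scale == "ct":
            fold = 2.0 ** (h_mean - c_mean)
        elif M.scale == "log2_expr":
            fold = 2.0 ** (c_mean - h_mean)
        else:
            fold = c_mean / h_mean
        records.append({"target_gene": target, "hairpin_id": hairpin, "fold_knockdown": fold})
    return pd.DataFrame.from_records(
        records, columns=["target_gene", "hairpin_id", "fold_knockdown"]
    )


def filter_by_knockdown(
    M: ExpressionMatrix,
    design: PerturbationDesign,
    kd: pd.DataFrame,
    min_hairpins: int = 3,
    min_fold: float = 2.0,
    keep_all_hairpins: bool = False,
) -> tuple[ExpressionMatrix, PerturbationDesign, dict]:
    """Keep perturbations whose gene was knocked down by enough hairpins.

    A target gene is retained if at least ``min_hairpins`` distinct hairpins
    achieved ``fold_knockdown >= min_fold`` (inclusive boundary). By default
    only the qualifying hairpins' samples are kept, which gives clean
    replicate groups; ``keep_all_hairpins=True`` keeps every hairpin of a
    retained gene. Control samples are always retained.

    Returns ``(matrix, design, retained)`` where ``retained`` maps each kept
    gene to its kept hairpin list.
    """
    design.validate_against(M)
    tab = design.table
    hairpins_in_design = set(tab.loc[~tab["is_control"], "hairpin"])
    missing = hairpins_in_design - set(kd["hairpin_id"])
    if missing:
        raise ValueError(f"knockdown table missing hairpins: {sorted(missing)}")
    retained: dict[str, list] = {}
    for gene, sub in kd.groupby("target_gene", sort=True):
        qual = sorted(sub.loc[sub["fold_knockdown"] >= min_fold, "hairpin_id"])
        if len(qual) >= min_hairpins:
            retained[gene] = sorted(sub["hairpin_id"]) if keep_all_hairpins else qual
    kept_hairpins = {h for hs in retained.values() for h in hs}
    keep = tab["is_control"] | tab["hairpin"].isin(kept_hairpins)
    if not (keep & ~tab["is_control"]).any():
        raise ValueError(
            "no perturbation passes the knockdown filter; relax min_fold "
            f"(={min_fold}) or min_hairpins (={min_hairpins})"
        )
    kept_samples = list(tab.loc[keep, "sample_id"])
    dropped = [s for s in tab["sample_id"] if s not in set(kept_samples)]
    for s in dropped:
        logger.info("filter_by_knockdown: dropped sample %s", s)
    row_of = {s: i for i, s in enumerate(M.sample_ids)}
    order = [s for s in M.sample_ids if s in set(kept_samples)]
    rows = [row_of[s] for s in order]
    M2 = M._with(values=M.values[rows], sample_ids=order)
    return M2, design.subset(order), retained
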