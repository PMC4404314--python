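"""Synthetic mixtures and knockdown screens with known ground truth.

The generative model follows the linear-mixing premise: a heterogeneous
population's linear-scale expression vector is the proportion-weighted sum
of the (unknown, here known) pure cell-state profiles. Mixing happens on
the linear scale; samples are then log2-transformed and i.i.d. Gaussian
noise is added per cell on the log2 scale (multiplicative on abundance,
the way qPCR replicate noise behaves). The mild non-linearity this creates
in log space is intentional: it is the regime a CT-scale analysis faces.

Two presets emulate the canonical study designs:

``idealized``
    3 cell states sharing a baseline with 2 disjoint marker genes per state
    (|log2FC| = 2), 17 genes plus one housekeeping gene, 10 fixed mixture
    designs (including 1:1:1, 1:2:2 and 1:1:0) spanning pure, binary and
    ternary mixtures, 3 replicates each.
``screen``
    3 latent states, 39 profiled genes plus housekeeping, every profiled
    gene targeted by 3–5 hairpins with 2 biological replicates, knockdown
    folds 2–8× with 15 hairpins that fail to knock down (< 2-fold), plus
    control hairpins.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, PerturbationDesign

DEFAULT_NOISE_SD_LOG2 = 0.1
DEFAULT_BASELINE_LEVEL = 100.0
DEFAULT_MARKER_LOG2FC = 2.0

#: The fixed 10-mixture design used by the idealized preset: the three
#: printed designs (1:1:1, 1:2:2, 1:1:0) plus pure, binary and ternary
#: fill-ins. This is a documented reconstruction of a partially published
#: design, not the original.
IDEALIZED_DESIGN = (
    (1, 0, 0),
    (0, 1, 0),
    (0, 0, 1),
    (1, 1, 0),
    (1, 0, 1),
    (0, 1, 1),
    (1, 1, 1),
    (1, 2, 2),
    (2, 1, 1),
    (1, 1, 2),
)


@dataclass
class StateProfiles:
    """Pure-state linear expression profiles plus the marker map."""

    profiles: np.ndarray  # s × n, linear scale, > 0
    gene_ids: list
    state_names: list
    markers: dict  # state -> [(gene_id, ±1), ...]
    baseline_level: float


@dataclass
class StateMixtureTruth:
    """Ground truth of a mixture experiment: profiles and per-sample fractions."""

    state_profiles: np.ndarray
    fractions: np.ndarray  # m × s, rows on the simplex
    labels: list
    state_names: list
    gene_ids: list

    def __post_init__(self):
        self.state_profiles = np.asarray(self.state_profiles, dtype=float)
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.fractions.ndim != 2 or self.fractions.shape[1] < 2:
            raise ValueError("fractions must be m × s with s ≥ 2")
        if (self.fractions < 0).any():
            raise ValueError("fractions must be non-negative")
        if not np.allclose(self.fractions.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("fraction rows must sum to 1")
        if not (self.fractions.max(axis=0) > 0).all():
            raise ValueError("every state must appear in at least one sample")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "state_profiles": self.state_profiles.tolist(),
                    "fractions": self.fractions.tolist(),
                    "labels": list(self.labels),
                    "state_names": list(self.state_names),
                    "gene_ids": list(self.gene_ids),
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "StateMixtureTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            state_profiles=np.array(d["state_profiles"]),
            fractions=np.array(d["fractions"]),
            labels=d["labels"],
            state_names=d["state_names"],
            gene_ids=d["gene_ids"],
        )


@dataclass
class ScreenTruth:
    """Ground truth of a perturbation screen.

    ``effects`` maps a targeted gene to the state-shift vector added to the
    baseline fractions (then clipped at 0 and renormalized); null
    perturbations map to None. Each hairpin's knockdown fold divides the
    measured linear expression of its own target gene only.
    """

    baseline_fractions: np.ndarray
    effects: dict
    hairpins: dict  # gene -> [hairpin ids]
    kd_fold: dict  # hairpin id -> linear fold
    noise_sd_log2: float
    state_names: list = field(default_factory=list)
    gene_ids: list = field(default_factory=list)

    def to_json(self, path) -> None:
        d = asdict(self)
        d["baseline_fractions"] = np.asarray(self.baseline_fractions).tolist()
        d["effects"] = {
            g: (None if v is None else np.asarray(v).tolist()) for g, v in self.effects.items()
        }
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)


def _normalize_fractions(row) -> np.ndarray:
    f = np.asarray(row, dtype=float)
    if (f < 0).any():
        raise ValueError(f"negative mixing fractions: {f}")
    total = f.sum()
    if total <= 0:
        raise ValueError("mixing fractions sum to zero")
    return f / total


def generate_state_profiles(
    n_states: int = 3,
    n_genes: int = 18,
    n_marker: int = 2,
    marker_log2fc: float = DEFAULT_MARKER_LOG2FC,
    baseline_level: float = DEFAULT_BASELINE_LEVEL,
    seed: int = 0,
    housekeeping_gene: str | None = "GAPDH",
) -> StateProfiles:
    """Pure-state profiles: a shared baseline plus disjoint marker genes.

    Marker positions are a seeded permutation of the non-housekeeping genes;
    state j takes the j-th block of ``n_marker`` positions, with signs
    alternating up/down within the block (up first). A marker sits at
    ``baseline_level * 2**(±marker_log2fc)``; ``marker_log2fc=0`` makes all
    states identical. The housekeeping gene, if any, is the last column and
    is never a marker.
    """
    gene_ids = [f"G{j + 1:02d}" for j in range(n_genes - (1 if housekeeping_gene else 0))]
    if housekeeping_gene:
        gene_ids.append(housekeeping_gene)
    candidates = np.arange(len(gene_ids) - (1 if housekeeping_gene else 0))
    if n_marker * n_states > len(candidates):
        raise ValueError(
            f"cannot place {n_marker} markers × {n_states} states in "
            f"{len(candidates)} assignable genes"
        )
    rng = np.random.default_rng(seed)
    positions = rng.permutation(candidates)[: n_marker * n_states]
    profiles = np.full((n_states, len(gene_ids)), float(baseline_level))
    state_names = [chr(ord("A") + j) for j in range(n_states)]
    markers: dict = {}
    for j, state in enumerate(state_names):
        block = positions[j * n_marker : (j + 1) * n_marker]
        markers[state] = []
        for rank, g in enumerate(block):
            sign = 1 if rank % 2 == 0 else -1
            profiles[j, g] = baseline_level * 2.0 ** (sign * marker_log2fc)
            markers[state].append((gene_ids[int(g)], sign))
    return StateProfiles(
        profiles=profiles,
        gene_ids=gene_ids,
        state_names=state_names,
        markers=markers,
        baseline_level=float(baseline_level),
    )


def generate_mixtures(
    profiles: StateProfiles,
    fraction_rows,
    replicates: int = 3,
    noise_sd_log2: float = DEFAULT_NOISE_SD_LOG2,
    seed: int = 0,
    labels: list | None = None,
) -> tuple[ExpressionMatrix, StateMixtureTruth]:
    """Designed mixtures of the pure states, log2-transformed plus noise.

    ``fraction_rows`` may be ratios (e.g. ``(1, 2, 2)``); each row is
    normalized to the simplex. Replicate rows share fractions and differ
    only by noise. Returns the log2-scale matrix and the expanded truth.
    """
    P = profiles.profiles
    F = np.vstack([_normalize_fractions(r) for r in fraction_rows])
    if F.shape[1] != P.shape[0]:
        raise ValueError("fraction rows do not match the number of states")
    if labels is None:
        labels = [":".join(str(x) for x in row) for row in fraction_rows]
    linear = F @ P  # n_mix × n_genes, strictly positive
    rng = np.random.default_rng(seed)
    rows, sample_ids, frac_rows, row_labels = [], [], [], []
    for i in range(F.shape[0]):
        for r in range(replicates):
            rows.append(np.log2(linear[i]))
            sample_ids.append(f"mix{i + 1:02d}_r{r + 1}")
            frac_rows.append(F[i])
            row_labels.append(labels[i])
    values = np.vstack(rows)
    if noise_sd_log2 > 0:
        values = values + rng.normal(0.0, noise_sd_log2, size=values.shape)
    M = ExpressionMatrix(
        values=values,
        gene_ids=list(profiles.gene_ids),
        sample_ids=sample_ids,
        scale="log2_expr",
    )
    truth = StateMixtureTruth(
        state_profiles=P,
        fractions=np.vstack(frac_rows),
        labels=row_labels,
        state_names=list(profiles.state_names),
        gene_ids=list(profiles.gene_ids),
    )
    return M, truth


def idealized_preset(
    seed: int = 0,
    noise_sd_log2: float = DEFAULT_NOISE_SD_LOG2,
    replicates: int = 3,
    marker_log2fc: float = DEFAULT_MARKER_LOG2FC,
) -> tuple[ExpressionMatrix, StateMixtureTruth]:
    """The 3-state, 10-mixture, 3-replicate designed-mixing experiment."""
    profiles = generate_state_profiles(
        n_states=3,
        n_genes=18,
        n_marker=2,
        marker_log2fc=marker_log2fc,
        seed=seed,
    )
    return generate_mixtures(
        profiles,
        IDEALIZED_DESIGN,
        replicates=replicates,
        noise_sd_log2=noise_sd_log2,
        seed=seed,
    )


def shifted_fractions(baseline, shift) -> np.ndarray:
    """Baseline fractions plus a shift vector, clipped at 0 and renormalized."""
    f = np.clip(np.asarray(baseline, dtype=float) + np.asarray(shift, dtype=float), 0.0, None)
    if f.sum() <= 0:
        raise ValueError("shift drives all fractions to zero")
    return f / f.sum()


def generate_screen(
    profiles: StateProfiles,
    n_perturbed: int | None = None,
    hairpins_range: tuple = (3, 5),
    replicates: int = 2,
    baseline_fractions=None,
    effects: dict | None = None,
    kd_fold_range: tuple = (2.0, 8.0),
    n_failed: int = 0,
    failed_fold_range: tuple = (1.0, 1.8),
    n_control_hairpins: int = 2,
    noise_sd_log2: float = DEFAULT_NOISE_SD_LOG2,
    seed: int = 0,
) -> tuple[ExpressionMatrix, PerturbationDesign, ScreenTruth]:
    """A knockdown screen over the profiled genes, with design sheet and truth.

    Every perturbed gene gets a seeded number of hairpins in
    ``hairpins_range`` (inclusive), each with ``replicates`` biological
    replicates and a seeded knockdown fold in ``kd_fold_range``;
    ``n_failed`` hairpins instead draw a fold from ``failed_fold_range`` to
    exercise the knockdown filter. A sample's fractions are the baseline
    plus the gene's effect shift (clipped, renormalized); its target gene's
    measured linear expression is divided by the hairpin's fold; then log2
    and per-cell noise. Control hairpins (is_control=True) sit at the
    baseline with fold 1.
    """
    rng = np.random.default_rng(seed)
    hk = profiles.gene_ids[-1] if profiles.gene_ids[-1] == "GAPDH" else None
    assignable = [g for g in profiles.gene_ids if g != hk]
    if n_perturbed is None:
        n_perturbed = len(assignable)
    if n_perturbed > len(assignable):
        raise ValueError(f"cannot perturb {n_perturbed} of {len(assignable)} genes")
    perturbed = assignable[:n_perturbed]
    baseline = _normalize_fractions(
        baseline_fractions
        if baseline_fractions is not None
        else np.full(profiles.profiles.shape[0], 1.0)
    )
    effects = dict(effects or {})
    unknown = set(effects) - set(perturbed)
    if unknown:
        raise ValueError(f"effects for unperturbed genes: {sorted(unknown)}")

    lo, hi = hairpins_range
    n_hp = rng.integers(int(lo), int(hi) + 1, size=n_perturbed)
    hairpins: dict = {}
    hairpin_list = []
    for g, cnt in zip(perturbed, n_hp):
        hairpins[g] = [f"sh{g}_{i + 1}" for i in range(int(cnt))]
        hairpin_list.extend((h, g) for h in hairpins[g])
    folds = rng.uniform(kd_fold_range[0], kd_fold_range[1], size=len(hairpin_list))
    if n_failed:
        if n_failed > len(hairpin_list):
            raise ValueError("more failed hairpins than hairpins")
        failed_idx = rng.choice(len(hairpin_list), size=int(n_failed), replace=False)
        folds[failed_idx] = rng.uniform(
            failed_fold_range[0], failed_fold_range[1], size=int(n_failed)
        )
    kd_fold = {h: float(f) for (h, _), f in zip(hairpin_list, folds)}

    gene_idx = {g: j for j, g in enumerate(profiles.gene_ids)}
    rows, design_rows = [], []
    for (h, g) in hairpin_list:
        eff = effects.get(g)
        fr = baseline if eff is None else shifted_fractions(baseline, eff)
        linear = fr @ profiles.profiles
        linear = linear.copy()
        linear[gene_idx[g]] /= kd_fold[h]
        for r in range(replicates):
            sid = f"{h}_r{r + 1}"
            rows.append(np.log2(linear))
            design_rows.append((sid, h, g, h, r + 1, False))
    ctrl_linear = baseline @ profiles.profiles
    for c in range(int(n_control_hairpins)):
        h = f"shCTRL_{c + 1}"
        kd_fold[h] = 1.0
        for r in range(replicates):
            sid = f"{h}_r{r + 1}"
            rows.append(np.log2(ctrl_linear))
            design_rows.append((sid, h, "none", h, r + 1, True))
    values = np.vstack(rows)
    if noise_sd_log2 > 0:
        values = values + rng.normal(0.0, noise_sd_log2, size=values.shape)
    M = ExpressionMatrix(
        values=values,
        gene_ids=list(profiles.gene_ids),
        sample_ids=[r[0] for r in design_rows],
        scale="log2_expr",
    )
    design = PerturbationDesign(pd.DataFrame(design_rows, columns=list(
        ("sample_id", "perturbation", "target_gene", "hairpin", "replicate", "is_control")
    )))
    truth = ScreenTruth(
        baseline_fractions=baseline,
        effects={g: effects.get(g) for g in perturbed},
        hairpins=hairpins,
        kd_fold=kd_fold,
        noise_sd_log2=float(noise_sd_log2),
        state_names=list(profiles.state_names),
        gene_ids=list(profiles.gene_ids),
    )
    return M, design, truth


def screen_preset(
    seed: int = 0,
    noise_sd_log2: float = DEFAULT_NOISE_SD_LOG2,
    effects: dict | None = None,
) -> tuple[ExpressionMatrix, PerturbationDesign, ScreenTruth]:
    """The 39-gene knockdown screen: 3–5 hairpins per gene, 2 replicates,
    folds 2–8×, 15 failed hairpins, plus controls."""
    profiles = generate_state_profiles(
        n_states=3,
        n_genes=40,
        n_marker=3,
        marker_log2fc=DEFAULT_MARKER_LOG2FC,
        seed=seed,
    )
    return generate_screen(
        profiles,
        n_perturbed=39,
        hairpins_range=(3, 5),
        replicates=2,
        effects=effects,
        kd_fold_range=(2.0, 8.0),
        n_failed=15,
        noise_sd_log2=noise_sd_log2,
        seed=seed,
    )


def null_screen(
    n_perturbations: int = 60,
    hairpins_per_gene: int = 3,
    replicates: int = 2,
    n_genes: int = 40,
    noise_sd_log2: float = DEFAULT_NOISE_SD_LOG2,
    seed: int = 0,
) -> tuple[ExpressionMatrix, PerturbationDesign, ScreenTruth]:
    """An exchangeable all-null screen for p-value calibration studies.

    No perturbation shifts state fractions and all knockdown folds are 1,
    so every sample is i.i.d. noise around the baseline mixture and
    replicate groups are exchangeable with unlabeled draws — the regime in
    which empirical p-values must be uniform.
    """
    if n_perturbations % hairpins_per_gene:
        raise ValueError("n_perturbations must be a multiple of hairpins_per_gene")
    n_target = n_perturbations // hairpins_per_gene
    profiles = generate_state_profiles(
        n_states=3, n_genes=n_genes, n_marker=3, seed=seed
    )
    return generate_screen(
        profiles,
        n_perturbed=n_target,
        hairpins_range=(hairpins_per_gene, hairpins_per_gene),
        replicates=replicates,
        kd_fold_range=(1.0, 1.0),
        n_failed=0,
        noise_sd_log2=noise_sd_log2,
        seed=seed,
    )
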