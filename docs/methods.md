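# Methods

## The problem and the model

Populations of cultured stem cells are heterogeneous: stem, progenitor and
more differentiated cells coexist. A perturbation that changes how cells
move between these states changes their *proportions*, and — because the
bulk expression vector of a mixed population is, to good approximation, the
proportion-weighted linear combination of the pure states' expression
vectors — that proportion change is visible in bulk expression without any
marker of the states themselves. The package scores perturbations for such
proportion shifts.

The pipeline:

1. **Normalization.** For qPCR input, ΔCT against a housekeeping gene
   (per-sample subtraction; the reference column becomes zero and is
   dropped by default), optional orientation flip to −ΔCT so that higher =
   more transcript, then per-gene median centering so every gene's median
   is 0 across the experiment. Even-length medians use the midpoint of the
   two central values. Missing wells are imputed to the gene median (0
   after centering) by default — this preserves the sample without
   inventing signal; a drop-sample mode exists.
2. **Knockdown filter.** For each hairpin, the linear fold-knockdown of its
   own target gene is `2^(mean ΔCT_hairpin − mean ΔCT_control)`; a targeted
   gene is retained when at least `min_hairpins` (default 3) distinct
   hairpins reach `min_fold` (default 2.0, boundary inclusive). Only the
   qualifying hairpins' samples are kept by default (cleaner replicate
   groups); a flag keeps every hairpin of a retained gene. Controls are
   always kept.
3. **Embedding.** Reduced SVD `M = U Σ Vᵀ` of the samples × genes matrix.
   Samples are embedded as the first k rows-of-U coordinates `u_ip`,
   *unscaled* by the singular values, so each retained component counts
   equally in distances (a σ-weighted variant is available as an explicit
   deviation). k comes from the Scree elbow: the point of largest discrete
   curvature of the singular-value curve, `argmax_j (σ_j − 2σ_{j+1} +
   σ_{j+2}) + 1`, clamped to `[1, len−1]`; a flat spectrum returns 1 with
   a warning, and `--k` overrides. Each component is sign-flipped so its
   largest-magnitude gene loading is positive — scores are invariant to
   this, it only stabilizes loadings reports.
4. **Score.** With the global centroid `ū` (component-wise median over all
   embedded samples by default; mean available) and a perturbation's
   replicate coordinates, the score is

       d = ‖ mean(replicate coords) − ū ‖₂
       score = d / sqrt(Σᵢ S.E.ᵢ²),   S.E.ᵢ = sdᵢ / √repl

   a signal-to-noise ratio for the displacement. `d = 0` scores 0; a zero
   standard error (identical replicates off-centroid) is floored at
   `se_floor = 1e-8` and flagged `se_floored`.
5. **Inference.** Empirical p-values by Monte Carlo: for each replicate
   count n, draw n rows uniformly *without replacement* from all embedded
   samples, score the draw against the same fixed global centroid (the
   centroid is a property of the experiment, not of a draw), repeat
   (default 10,000 iterations, one cached null per distinct n). The
   p-value is the add-one estimator `(#{null ≥ observed} + 1)/(N + 1)`, so
   p is never exactly 0 and never below `1/(N+1)`; ties count toward the
   null. A raw top-rank convention (`#/N`) is available. Bonferroni
   multiplies by the number of scored perturbations (groups with ≥ 2
   replicates); 1-replicate groups are flagged unscorable and excluded
   from the correction count.

Replicate groups default to the perturbation label (a hairpin's biological
replicates); `group_by="gene"` pools all hairpins targeting a gene.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `min_hairpins`, `min_fold` | 3, 2.0 | knockdown filter: distinct hairpins at ≥ fold (linear) |
| `k` | `auto` (Scree elbow) | embedding dimensions |
| `centroid` | median | global centroid statistic (component-wise) |
| `iterations` | 10,000 | Monte Carlo null size; p ≥ 1/(N+1) |
| `se_floor` | 1e-8 | guard against zero replicate SE |
| `group_by` | perturbation | replicate-group level (hairpin vs gene) |

## The synthetic generators

`generate_state_profiles` builds pure-state profiles on the linear scale: a
shared baseline (default 100, an arbitrary abundance unit — it is a log2
offset downstream) with disjoint marker genes per state at
`baseline · 2^(±marker_log2fc)` (default |log2FC| = 2, one up and one down
marker alternating within each state's block; positions are a seeded
permutation so allocations are re-derivable from the seed). The
housekeeping gene is never a marker.

`generate_mixtures` mixes the states *linearly* — the premise of the whole
method — then log2-transforms and adds i.i.d. Gaussian noise per cell on
the log2 scale (default sd 0.1, multiplicative on abundance, the way qPCR
replicate noise behaves). The `idealized` preset uses a fixed 10-design set
(3 pure, 3 binary, 4 ternary, including 1:1:1, 1:2:2 and 1:1:0) with 3
replicates over 17 genes + housekeeping; it is a documented reconstruction
of a partially published design, not the original.

`generate_screen` targets each profiled gene with a seeded number of
hairpins (preset: 3–5, 2 replicates, folds 2–8×, 15 failed hairpins below
2-fold, plus controls). A hairpin's sample mixes at the baseline fractions
plus its gene's effect shift (clipped at 0, renormalized), then its own
target gene's measured linear value is divided by the knockdown fold — no
trans-effects by default.

**What the generators do not emulate:** amplification-efficiency
differences between probes, count noise and dropout, correlated
(batch-like) noise, trans-effects of a knockdown on other measured genes,
and real states' broad expression differences (synthetic states differ in a
few markers only). Passing tests therefore demonstrate the statistical
machinery under the linear-mixing model, not performance on any particular
real dataset.

## Calibration and power study conditions

A hairpin's knockdown of its own *measured* target gene is a real,
systematic per-hairpin expression signal (log2 shift 1–3 at folds 2–8,
versus replicate noise sd 0.1). Replicate groups carrying such signal are
genuinely displaced from the population centroid — detecting them is a true
positive of the statistic, not a calibration property. The null-calibration
and power studies therefore use screens with knockdown fold 1 on the
measured panel (`null_screen`, and `generate_screen(kd_fold_range=(1, 1))`
with a state-shift effect), which makes all-null samples i.i.d. and
replicate groups exchangeable with unlabeled draws — the regime in which
empirical p-values must be uniform, and in which power against a pure
state-proportion shift is measured in isolation. The `screen` preset keeps
realistic folds for the filter and end-to-end paths.

Problem sizes: calibration uses 60 perturbations (20 genes × 3 hairpins ×
2 replicates) at 2,000 Monte Carlo iterations over 3 seeds; the power grid
(state-A shift δ ∈ {0, 0.1, 0.2, 0.4}) uses 10-gene screens over 20 seeds
per δ. These sizes give stable averages while keeping the default test run
fast.

## Numerical choices

- **Median vs mean centering.** The pipeline median-centers genes. Note
  that the exact low-rank identities of noise-free linear mixtures (rank
  s−1 after centering; centered fraction vectors inside the first s−1
  components) hold under *mean* centering only — the median removes the
  offset direction approximately, leaving a few percent of variance in
  component s. `fraction_span_r2` and the corresponding tests mean-center
  for this reason; the analysis pipeline keeps the median as its robust
  default.
- Singular values below `1e-10 · σ₁` are treated as numerical rank
  deficiency.
- NMF (scikit-learn, multiplicative updates, deterministic `nndsvda`
  initialization, seeded) requires non-negative input; signed matrices get
  a single recorded global offset (`shift_nonnegative`). Its explained
  variance is the reconstruction convention `1 − ‖M−WH‖_F²/‖M‖_F²`, split
  per component by each rank-one term's squared Frobenius norm; it can
  never exceed the rank-k SVD bound on the same matrix, which the benchmark
  reports alongside.
- FastICA has no canonical component order, sign or scale: components are
  ordered by the variance their rank-one reconstruction explains,
  sign-aligned like the SVD, with unit weights; non-convergence is a
  warning plus a `converged=False` flag.
- Loadings ties break on gene id; all randomness flows from a single
  `numpy` Generator per entry point, so fixed seeds give bit-identical
  outputs.

## Benchmark conventions

r² between components and state fractions is squared Pearson correlation —
sign-agnostic, because a component may anti-correlate with a state and
still identify it — computed for every (component, state) pair with the
per-state maximum reported, which avoids manual component↔state
assignment. The replicate-clustering score is the mean within-design-group
pairwise distance divided by the mean between-group distance in component
1–2 space; < 1 means replicates cluster.

## Known limitations

- The Scree-elbow rule is a curvature argmax; on spectra without a clear
  knee (e.g. screens whose variance is spread over many knockdown axes) it
  can pick a large k. The Scree table is always written and `--k` overrides.
- Bulk linear mixing is assumed exactly; strong trans-effects of a
  perturbation on the measured panel violate it and will surface as large
  scores regardless of any state shift.
- Bonferroni is the only multiplicity correction offered.
- With 10,000 iterations the smallest attainable p is ≈ 1e-4; significance
  claims below that resolution require more iterations.
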