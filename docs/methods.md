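# Methods

## Inference model

popinfer assumes a single static GRN drives a one-dimensional cell-state
transition sampled by snapshot multiome data.  Cells ordered by
pseudotime are averaged into pseudocells, and for each target gene a
LASSO regression predicts pseudocell accessibility from pseudocell
expression of candidate regulators.  The premise is temporal: regulator
expression co-varies with target accessibility contemporaneously,
whereas target *expression* responds only after a delay, so the
accessibility-on-expression regression captures regulatory signal that
an expression-on-expression regression blurs.

The regression for target g minimizes
(1/n)Σ(y^p_i − β0 − (x^p_i)ᵀβ)² + λ‖β‖₁ along a geometric path of 200
penalties from λ_max (the smallest penalty with an all-zero solution,
max_j|⟨x̃_j, ỹ⟩|/n on standardized data) down to λ_max·10⁻⁴.  The
gene-specific penalty balances relative training error against relative
model density through the tradeoff parameter α; the selected
coefficients are sign-binarized and averaged over
α ∈ {0.001, ..., 0.4} (step 0.001).  A preset extends the grid to 0.6
for steeper transitions where denser networks are tolerated.

### Canonical readings where the procedure is underdetermined

* **Training MSE, not cross-validated.**  The selection rule consumes
  error *relative* to the trivial model on the same n = 80 pseudocells;
  CV folds at this sample size would be fragile and are not part of the
  rule.
* **Same-index pairing.**  Pseudocell i's accessibility is predicted
  from pseudocell i's expression.  An optional integer `lag` shifts
  predictors earlier for sensitivity analysis only (default 0).
* **Ties in the selection objective go to the largest λ** (sparsest
  model), consistent with the method's sparsity bias.
* **The target's own expression is excluded from its predictor set**
  (`exclude_self=True`); the network is defined off-diagonal, and a
  self-predictor would absorb coefficient mass.  Switchable.
* **α = 0 is excluded from the default grid**: it always yields the
  empty network and would only rescale all weights by s/(s+1).
* **Edge calls use |W| > 0.4 strictly**, so strong inhibitions count the
  same as strong activations.
* **Degenerate targets** (response constant across pseudocells up to
  float rounding, or orthogonal to every predictor) get an all-zero
  column with a logged warning: the selection rule's normalizers are
  undefined there and the trivial model is the only safe output.

## Numerical choices

Predictors are standardized (zero mean, unit variance) for fitting and
coefficients mapped back to the original scale, which preserves signs —
the only thing binarization keeps.  Coordinate descent runs at tolerance
1e-10 so that the training-MSE monotonicity along the path holds to
1e-8 relative; duality gaps at the 1e-8 level are accepted.  Constant
predictors stay at coefficient zero.  Responses whose variance is below
(1e-12·scale)² are treated as constant.

Gene accessibility scores, when computed here rather than supplied, are
unweighted sums of peak counts over the gene body plus 5 kb upstream of
the TSS (strand-aware, clipped at the chromosome start), with strict
half-open interval overlap; a peak overlapping k gene windows counts
fully toward each.  Upstream toolkits use distance-weighted scores; the
unweighted window sum is this package's simplification, and a
precomputed score matrix is the preferred input.  No per-cell depth
normalization is applied by default (pseudocell averaging plus predictor
standardization absorb scale); a counts-per-10k flag exists.

Pseudotime ties are broken by input cell order (stable sort).  The
cluster-random control shuffles cells within clusters with a seeded
generator and partitions them with the same remainder rule as the
pseudotime mode, so the bin-size profile is comparable.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `n_pseudocells` | 80 | pseudotime bins; aim for ~30–40 cells per bin — too many bins keep single-cell noise, too few over-smooth |
| `alpha_max`, `alpha_step` | 0.4, 0.001 | tradeoff grid averaged over (0.6 preset for denser networks) |
| `n_lambda` | 200 | path resolution per target |
| `lambda_min_ratio` | 1e-4 | smallest/largest penalty on the path |
| `weight_threshold` | 0.4 | strict |W| cutoff for edge calls |
| `mode` | multiome | `rna_only` predicts expression from expression |
| `lag` | 0 | optional predictor shift in pseudocells (sensitivity only) |

## Evaluation

Benchmarking follows the standard GRN-evaluation convention: candidate
edges are restricted to pairs whose regulator and target both occur in
the reference network, ranked by |W|, and scored by the area under the
early precision-recall curve over recall ∈ [0, r_max], normalized by
r_max (AUEPRC).  The curve uses the step convention with equal-score
predictions entering as one atomic tie group and the final recall
increment truncated at r_max; this convention is pinned by exhaustive
small-instance oracle tests rather than claimed identical to any other
implementation.  Typical restricted ranges are [0, 0.1] and [0, 0.015]
for sparse references; the simulator experiments use the full range.

## Synthetic data generator

The simulator operationalizes the model's temporal premise with a known
ground truth; it is a statistical caricature, not a kinetic simulation.
With latent time t ~ Uniform(0, 1) per cell:

* **Regulator expression** r_k(t): mixtures of logistic ramps whose
  dominant component is a transient activation pulse with stratified
  centers — successive waves of regulator activity along the
  trajectory.  Stratification is deliberate: all profiles are functions
  of the same scalar t, and fully random placement makes regulators
  nearly collinear and the network unidentifiable for any method.
* **Target accessibility** a_g(t) = softplus(0.5 + Σ_k s w r_k(t)),
  contemporaneous; softplus keeps scores positive and preserves signs.
* **Target expression** e_g(t) = a_g(t − τ), default τ = 0.15 of the
  trajectory, clipped at t = 0 — the expression lag.
* Regulator accessibility and parentless-target profiles are constant
  baselines, so they act as guaranteed negatives.
* Gaussian measurement noise (sd 0.2, floored at 0) and independent
  dropout (rate 0.1) caricature sparse single-nucleus counts.

Default scale: 20 genes, 8 regulators, edge density 0.15 with per-target
in-degree capped at 2, 30% inhibitory edges, 2000 cells.  The in-degree
cap reflects the sparse-regulation regime in which the tradeoff rule's
selected models (1–3 predictors per target at α ≤ 0.4) can represent the
truth; with unbounded in-degree the weakest parents of dense targets are
unidentifiable at these sparsity levels.  Edge magnitudes are
Uniform(1, 2).

What passing the simulation-based tests does **not** show about real
data: real pseudotime is estimated, not exact (the generator feeds true
latent time to inference by default; a jittered ordering can be supplied
instead); real regulator profiles are not cleanly separated pulses; real
counts are integer, zero-inflated and depth-confounded rather than
Gaussian-noised; and real regulation is combinatorial beyond in-degree
2.  The experiments establish correctness of the machinery and the
direction of the method's claimed contrasts (multiome over RNA-only,
pseudotime over random pseudocells), not field performance.

## Experiment sizes

The recovery experiments run at the default generator scale (20 genes,
2000 cells, 80 pseudocells, the full 400-point α grid); the
multiome-vs-RNA-only comparison uses 10 simulation seeds and the
random-pseudocell control 50 replicates, with medians reported.  One
full inference run takes well under a second, the complete acceptance
computation 1–2 minutes.

## Known limitations

* The LASSO can return indirect as well as direct interactions; no
  motif/base-GRN priors are used (by design).
* Relative-MSE selection keeps models very sparse on low-noise data;
  secondary regulators of a target may be missed at α ≤ 0.4.
* A single static network is assumed; branching or time-varying
  regulation violates the premise.
* Results can be sensitive to the number of pseudocells (noise vs
  over-smoothing); the ~30–40 cells-per-bin guidance is a heuristic.
* The gene score is an unweighted window sum and ignores enhancers and
  distal elements.
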