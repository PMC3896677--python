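# Methods

## Models and the unified objective

Both inference models are linear. The steady-state model assumes each
sample sits near dynamic equilibrium of `dx_i/dt = Σ_j W_ij x_j`; setting
the self term to a unit decay and moving it across the equality yields the
regression `x_i ≈ Σ_{j≠i} W_ij x_j`, so the estimated diagonal is fixed at
zero. The first-order Markov model assumes `x^{k+1} ≈ W x^k` between
consecutive time points of one series, with the diagonal free (a gene's
concentration may carry into its own next value).

Both fits minimize, independently per target gene `i`,

    w D^i w' − 2 w·u_i + Σ_j (α + β W0_ij) |w_j|

with `D^i = Σ_k x̄^k (x̄^k)'` and `u_i = Σ_k x̄^k x_i^k` accumulated over
samples (steady state) or over all transitions `k → k+1` of all series
(Markov). The masked regressor `x̄` zeroes knocked-down genes — a knocked
gene cannot drive targets, while its own measured level remains a valid
regression target — and zeroes unavailable measurements. Samples where the
*target* `x_i` is unavailable are dropped from `D^i` only; because missing
targets enter `u_i` as zeros, `U` can be accumulated over all samples
unchanged. For the steady-state model the regressor position `i` is also
zeroed (the `j ≠ i` restriction), which is implemented by zeroing row and
column `i` of `D^i`; the solver then keeps that coordinate at zero because
it carries no quadratic weight.

## Solver

Cyclic coordinate descent from a zero start with the soft-threshold update
`w_j ← S(u_j − Σ_{l≠j} D_jl w_l, λ_j/2) / D_jj` (the 1/2 from the
2-multiplier in the quadratic gradient), stopping when the largest
coordinate change in a sweep falls below `tol` (default 1e-5). Coordinates
with `D_jj = 0` are fixed at zero and reported. The objective is convex and
non-increasing per sweep. When the penalty vector is identically zero the
problem is a smooth quadratic and the normal equations are solved exactly
(min-norm via LAPACK lstsq) instead of iterating: backward-recursion series
put their early time points many orders of magnitude below the late ones,
giving quadratic forms with condition numbers around 1e8 on which
coordinate descent stalls far from the optimum; the exact solve makes the
unregularized floor and the noise-free recovery property well defined. The
hot paths (coordinate descent and the CV grid scan) are numba-compiled.

## Cross-validation

`(α, β)` are selected per gene — incoming edges of different genes are
independent — by leave-one-observation-out CV, where an observation is one
sample (steady state) or one complete series (Markov). The grid is a
descending exponential ladder `λ_max · 2^-t, t = 0..depth` plus an exact 0,
anchored at `λ_max = max |U_ij|`, scanned fully in two dimensions; genes
with no exempt prior entries skip the `β` dimension. The per-gene CV error
is the summed held-out squared prediction error; the network-level number
reported is the sum over genes (the per-gene mean is also exposed). Exact
ties resolve to the largest `α`, then the largest `β` (sparsest model). The
final network is refit on all data at the chosen pair. The default ladder
depth is 20; the simulation sweeps and tests use 12, which is past the
point where the selected minima stop moving on 10-gene problems.

The proportional error divides the total CV error by the in-sample error
of the exact unregularized fit on the full data. In-sample was chosen over
a cross-validated baseline because the observation-count sweep then
approaches 1 from above, matching the intended normalization ("minimal
possible error achievable through linear regression").

## Synthetic benchmark

Benchmark networks have 10 genes, exactly 25 directed edges, per-node
in-degrees of 2–3 drawn among the other nodes (no self edges, since the
steady-state convention reserves the diagonal), and i.i.d. N(0, 100)
weights; matrices with reciprocal condition number below 1e-10 are
regenerated with an incremented seed. Series are built backward: the final
latent state is standard normal, earlier latent states are
`y^k = W^{-1} y^{k+1}` (so clean series satisfy `y^{k+1} = W y^k` exactly),
and reported values add intrinsic N(0, 0.1²) noise per backward step plus
extrinsic N(0, 0.3²) measurement noise at every point. The large weight
variance keeps `W^{-1}` small so the recursion does not blow up — at the
cost of early time points carrying weak signal, which is why the noisy
benchmark is hard at few observations and why the low-noise demo fixtures
use sd 0.001. A steady-state convenience generator
`x = (I − W)^{-1} ε, ε ~ N(0, σ²)` is provided for the ODE-shaped model; it
is a reconstruction for testing, not part of the time-series benchmark.
Sweep outputs carry per-replicate seeds sufficient to re-run bit-identically.

What the generator does *not* emulate: count noise of the measurement
platform, normalization artifacts, unmodeled nonlinearity, and hidden
regulators. Passing recovery and trend tests therefore shows the estimator
is correct under its own model assumptions, not that real embryo data meet
them.

## Forward knockout simulation

Steady-state networks run as `dx/dt = Wx − x` under classical RK4
(defaults `t_end = 10`, `dt = 0.01`); Markov networks iterate `n_steps = 10`
times. The published analyses do not state horizons, so these defaults were
fixed once as round numbers long enough for the linear ODE flow (unit decay)
to settle. Knocked genes are clamped to zero at the start and after every
step; clamping commutes with the linear update, so pre-clamping the initial
state changes nothing. Divergence (non-finite state, or Markov norm above
1e12 when the spectral radius exceeds 1) raises with the offending step.
Fold changes use a pseudo-value of 1e-6 against zero expression and log
base 2; a gene is called regulated when `|log2 FC| > log2(1.5)`, with a
negative log fold change (drop upon knockout) read as positive regulation.

## Spatial prediction

Categories map to canonical region triples (left = ventral, middle =
vegetal, right = dorsal): d (0.1, 0.4, 1.0), v (1.0, 0.4, 0.1),
b (1.0, 0.1, 1.0), m (0.1, 1.0, 0.1), u (0.4, 0.4, 0.4). The multi-valued
categories (b, m, u) admit other triples; the single canonical choice above
is used for constraints.

The steady-state predictor solves, independently per region (the objective
decouples over positions), `min ‖(I − W_offdiag) x‖²` with known genes
fixed and free genes nonnegative (scipy NNLS). The Markov predictor fixes
time-1 values for the seeded genes, draws the remaining time-1 values
i.i.d. uniform on [0, 1] (a categorical variant drawing random canonical
triples is available), computes the time-2 value as the nonnegative clamp
`max(0, W x¹)` — the exact constrained minimizer — and averages 1000 runs
before classifying. Leaving the unseeded time-1 values free instead would
make the problem underdetermined.

Classification uses the pairwise region differences with one threshold
`TH = 0.5` and the low level 0.1 as printed: uniform if `min/max ≥ TH` or
`max < 0.1`; both if the middle is smallest and `|l−r|` is at most `TH` of
`|m−r|` and of `|l−m|` (a zero denominator counts as satisfied only when
`|l−r|` is also zero — the limit of the ratio test); then vegetal/ventral/
dorsal by strict largest region; anything else returns a sentinel and
counts as incorrect in evaluations. The ratio bound in the "both" rule is
tied to `TH` since a single threshold governs the cascade.

Evaluation: leave-one-out over the annotated genes for the steady-state
model; for the Markov model, prediction from a small seeded time-1 set
scored over all annotated genes. Significance uses null networks built by
uniformly permuting the off-diagonal weight multiset (diagonal preserved;
a row/column-permutation variant was considered and rejected as it
preserves each gene's weight profile), with the add-one p-value
`(1 + #{null ≥ observed}) / (n_perm + 1)`. Spatial prediction consumes the
full pre-threshold `W`; the edge thresholds (0.25 steady state, 0.2
Markov) are treated as visualization-only.

## Numerical and design notes

* Normalization divides each gene row by its own maximum (all-zero rows are
  an error naming the gene); note that row scaling conjugates the Markov
  `W` by the scale factors, so truth-recovery checks on simulated data skip
  it.
* Expression values are validated nonnegative only for count-like data read
  from TSV pipelines; simulated benchmark series are signed by
  construction.
* The prior-overlap permutation p-value shuffles off-diagonal entries only,
  matching the spatial null and keeping constant matrices exactly invariant.
* Degenerate genes (target unavailable in every usable sample) yield a zero
  row plus a warning rather than an error.
* All stochastic entry points take an integer seed; grid-scan CV is fully
  deterministic and takes none.

## Known limitations

Linear models cannot represent saturating or combinatorial regulation; the
steady-state model misattributes dynamics near sharp transitions; recovery
guarantees hold only when the design spans the coefficient space (backward-
recursion data at few observations do not); the spatial abstraction reduces
a 3-D embryo to three scalar regions and inherits any coarseness of the
expert categorization; and the benchmark's proportional-error curves are
Monte-Carlo estimates over 5 networks x 5 edge sets, so only their trends,
not absolute values, are meaningful.
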