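# Methods

## Data model

The input is a matrix D of m steady-state expression profiles over n
genes. Each profile is assumed to arise from one "multifactorial"
perturbation: every gene's basal activation is simultaneously increased
or decreased by a small random amount, the system relaxes, and the new
equilibrium is measured. The data carry equilibrium information only —
no dynamics — and the goal is a ranking of all n(n−1) ordered gene pairs
by confidence that the row gene directly regulates the column gene.
Throughout the package a weight matrix W has **rows = regulators,
columns = targets** (entry (j, i) scores j → i); normalization therefore
acts on columns. Predictions and gold standards use gene names; indices
are 0-based internally.

## Pairwise weights

For each pair, the target is regressed on the regulator alone through a
polynomial design [1, x, …, x^order] with order 1 (default) or 3. Order
3 exists for heterogeneous real compendia where a straight line
underfits; order 4 is excluded because its normal equations become
numerically infeasible on expression data. The weight is

    w = (|r| * SST / max(SSR, floor * SST)) ^ c

with r the Pearson correlation, SSR/SST the residual/total sum of
squares, and c >= 1 a sharpening exponent. Contracts that matter (and
are the tested surface): w strictly decreases in SSR, strictly increases
in |r|, ignores the correlation sign (repression counts as regulation),
and is invariant to affine rescaling of either gene. The relative floor
(`ssr_floor`, default 1e−12) caps exactly collinear pairs at a large
finite weight instead of infinity. Degenerate pairs — constant columns,
designs with condition number above 1e10 — carry no evidence and score
0; the pipeline counts and logs them instead of aborting.

For order 1 the identity SSR/SST = 1 − r² makes the weight a strictly
increasing function of |r| alone, so within one target column the weight
ranking equals the |r| ranking, and the raw weight is symmetric in
direction (w_ji = w_ij). Directionality in the final ranking comes from
the per-target normalization, not from the raw pairwise score.

## q-norm normalization

Each nonzero column of W is divided by its vector q-norm
(Σ|w|^q)^(1/q), default q = 3.5. Genes differ in how easily they are
regulated, so raw incoming-weight columns sit at different magnitude
orders; normalization puts targets on a common scale while preserving
every within-column ranking exactly (positive scalar division). The
operation is idempotent, leaves zero columns (isolated or constant
genes) untouched, and deliberately changes cross-column interleaving —
that is its purpose. On synthetic data the recovery AUROC rises with q
from 1 and plateaus past roughly 3.5, matching the rationale for the
default; q stays exposed on the CLI.

## In-degree refinement

The pairwise fits treat every target as having one regulator. The
refinement step estimates a per-target in-degree under a sparsity prior:
P(k) ∝ k^(−γ) · e^(−k/k̄) for k = 1..k_max, defaults γ = 1.5 (low end
of the exponent range reported for biological networks), k̄ = 3.3,
k_max = 5. In-degree 0 is not modeled; every gene gets at least one
candidate regulator.

Per target, candidates are ordered by non-decreasing pairwise SSR (ties
by index), and for each k the target is regressed jointly on its top-k
candidates (first-order multivariate fit). The loss is
L(k) = SSR_k / F_k with F_k = ((SST − SSR_k)/k) / (SSR_k/(m − k − 1)):
small residuals and a large F statistic both argue for k. A perfect
combinatorial fit (SSR below the relative floor) gets L = 0; a fit no
better than the mean gets a large finite penalty (explained variance
floored at 1e−12·SST) so loss tables stay finite. Collinear candidate
sets are handled by the rank-revealing solver — the minimum-norm
solution has the same SSR as dropping dependent columns — with the
effective regressor count (rank − 1) in F, and a logged flag. When m or
the candidate pool cannot support k_max, k_max is lowered with a warning
rather than failing.

The prior fixes how many genes may take each in-degree: n·P(k),
integerized by largest-remainder rounding so the counts sum to n exactly
(ties in the remainders go to smaller k). Minimizing the total loss
subject to those counts is the 0–1 integer program

    min Σ_i Σ_k L_i(k) x_ik   s.t.  Σ_k x_ik = 1,  Σ_i x_ik = n_k

solved with HiGHS branch-and-bound (`scipy.optimize.milp`). The
constraint matrix is a transportation polytope, so the LP relaxation is
integral in practice; an exhaustive-enumeration oracle guards the
optimum in the tests. Finally, each target's selected regulators (its
top-d̂ candidates) are shifted up by δ = (max_unselected −
min_selected) + ε, with ε = 1e−6 × column max, exactly when the
selected set does not already strictly dominate; this enforces strict
separation while preserving both within-group orderings, and leaves
already-separated columns byte-identical.

Two practical caveats. First, for order-1 weights the SSR ordering and
the within-column weight ranking coincide, so the selected regulators
already dominate their columns and the shift is a no-op — the
refinement visibly reorders only order-3/exponent-sharpened weight
matrices or externally supplied ones. Second, F-statistic losses are
only weakly parsimonious: when the top-k fit is already near-perfect,
k + 1 can win by absorbing noise. In a frozen simulation study (m = 20,
3-regulator target, 30 seeded replicates) the loss argmin lands on the
true in-degree 20 times and is the modal choice, but per-run guarantees
are not attainable with this family of losses. The step is therefore
optional (off by default) and worth enabling only when the in-degree
prior is believed; with a badly wrong prior it can hurt. Estimating γ,
k̄ from data is out of scope.

## Evaluation

AUROC uses the Mann–Whitney formulation (P(score_pos > score_neg) + ½
P(equal)), delegated to scikit-learn. AUPR uses the average-precision
convention — mean over positives of the precision at that positive's
rank — with tied scores expanded in the deterministic (regulator,
target) enumeration order used everywhere in this package; this
stepwise convention avoids the optimism of trapezoidal interpolation
on PR curves and, absent ties, agrees with scikit-learn's
average_precision_score (cross-checked in the tests). Pairs missing
from a gold standard count as negatives; when a TF list restricted
inference, only those rows are scored. The DREAM organizers' p-values
and aggregated "score" depend on their empirical null-distribution
files and are not computed. Note that average precision of a random
ranking exceeds the positive prevalence at small list sizes (≈ 0.23 vs
0.20 at 100 items); the prevalence limit is asymptotic.

## Synthetic data

The generator emulates the benchmark setting the method targets: a
sparse directed network whose in-degree histogram exactly realizes the
truncated-power-law counts (shuffled over genes), regulators drawn
uniformly without replacement, interaction strengths uniform on
±[0.2, 1.0], |adjacency| rescaled onto spectral radius 0.8 when it
exceeds it, basal activations uniform on [0.5, 1.5]. Kinetics are
linear: x = Aᵀx + b, equilibrium x = (I − Aᵀ)⁻¹b, which exists and is
stable under the spectral bound and gives closed-form sanity checks. An
optional saturating variant (tanh on the regulatory input) produces the
curvature that motivates order-3 fits. Per experiment, b = basal ∘
(1 + η) with η ~ N(0, perturb_sd²), default 0.2 ("slight" simultaneous
perturbation); observations are the steady state times (1 + ξ),
ξ ~ N(0, noise_sd²), default 0.05, clipped at zero.

Because the linear kinetics are a local linearization, strong repression
can push a steady-state "level" negative, which no concentration can be;
genes whose realized steady state dips below 0.1 are shifted by a
per-gene constant restoring that floor before noise. A per-gene affine
shift is a change of baseline units — invisible to intercept-carrying
regression and to correlation — and keeps the emitted matrix a valid
nonnegative expression data set. (Without it, clipping hard-zeroes about
a sixth of all measurements and creates constant-zero genes, an artifact
of the linearization rather than a property of expression data.)

What the generator deliberately does **not** emulate: saturating
Hill-type production kinetics with basins and bistability, transcription
/ translation time-scale separation, biological replicates, or the
module structure of real E. coli / yeast subnetworks (GeneNetWeaver-style
ODE simulation is out of scope). Passing recovery tests on this
generator therefore shows the pipeline recovers linear(ized) sparse
networks from equilibrium perturbation data; absolute AUROC/AUPR values
on real benchmark files will differ.

## Benchmark problem sizes and expectations

The recovery study (tests and `scripts/acceptance.py`) uses n = 50
genes, 10 replicates: the noisy arm at m = 100 experiments with the
default perturbation/noise levels, the noise-free arm at m = 500. These
sizes keep a full study in the tens of seconds while leaving the
qualitative conclusions stable across seeds: mean AUROC of the
normalized pipeline ≈ 0.89, normalization lifts mean AUPR by roughly a
quarter over the raw weights (≈ 0.40 vs ≈ 0.32), and the noise-free
m = 500 arm averages just above 0.9 — the residual gap to 1.0 is
indirect-correlation confusion inherent to pairwise scoring, not noise
(the population-|r| ranking itself plateaus near 0.93 at spectral
radius 0.8). Replicate-level AUROC varies by roughly ±0.05, so all
recovery claims are about 10-seed means.

## Determinism and numerical conventions

Every stochastic component takes an explicit integer seed
(`numpy.random.default_rng`); identical inputs and configuration
reproduce byte-identical prediction files. Equal weights are ordered by
ascending (regulator, target) index everywhere a total order is needed.
q-norms factor out the column maximum before exponentiation so large q
cannot overflow. Design matrices with condition number above 1e10 take
the degenerate path. The ILP is exact, not heuristic; infeasible count
vectors raise an error rather than being repaired.
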