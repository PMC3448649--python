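"""Synthetic networks and multifactorial perturbation data.

The generator emulates the DREAM4 "Size 100 Multifactorial" setting well
enough to exercise and benchmark every pipeline stage without external
downloads: a sparse directed network whose in-degrees follow the
exponentially truncated power law, steady-state expression under small
simultaneous multiplicative perturbations of every gene's basal
activation, and multiplicative measurement noise.

Kinetics are linear: each gene's steady-state level satisfies

    x_i = b_i + sum_j A[j, i] * x_j        i.e.   x = A^T x + b

so the equilibrium is the closed form x = (I - A^T)^{-1} b, which exists
and is stable because |A| is rescaled to spectral radius <= 0.8.  An
optional saturating variant (tanh on the regulatory input) produces the
kind of curvature that motivates the third-order fits.  This is a
deliberately analyzable stand-in for full nonlinear ODE simulators such as
GeneNetWeaver, not a replica of them.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .data_io import EdgeSet, ExpressionData
from .evaluation import EvaluationResult, evaluate
from .indegree_refinement import PowerLawParams, indegree_counts, refine
from .normalization import NormalizationConfig, normalize_columns
from .pairwise_weights import WeightConfig, weight_matrix

__all__ = [
    "SyntheticNetwork",
    "SimulationConfig",
    "sample_network",
    "simulate_multifactorial",
    "recovery_benchmark",
]

#: spectral-radius bound on |adjacency| guaranteeing a stable steady state
SPECTRAL_BOUND = 0.8

#: minimum reported expression level for genes whose linear steady state
#: dips below it (per-gene affine shift; see simulate_multifactorial)
POSITIVITY_MARGIN = 0.1


@dataclasses.dataclass
class SyntheticNetwork:
    """Ground-truth network: signed strengths, basal activations, in-degrees.

    ``adjacency[j, i]`` is the signed effect of regulator j on target i;
    the diagonal is zero (no auto-regulation) and column i holds exactly
    ``indegrees[i]`` nonzeros.
    """

    adjacency: np.ndarray
    basal: np.ndarray
    indegrees: np.ndarray

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    def edge_set(self) -> EdgeSet:
        """Gold-standard edges (label 1) from the adjacency support."""
        regs, targs = np.nonzero(self.adjacency)
        return EdgeSet(
            labels={(int(j), int(i)): 1 for j, i in zip(regs, targs)}, n=self.n
        )


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one multifactorial data set.

    m experiments; each perturbs every basal activation by a relative
    N(0, perturb_sd^2) factor (default 0.2 — "slight" simultaneous
    perturbation of all genes) and observes the new steady state under
    relative N(0, noise_sd^2) measurement noise (default 0.05).
    ``squash`` switches on the saturating (tanh) regulation variant.
    """

    m: int = 100
    perturb_sd: float = 0.2
    noise_sd: float = 0.05
    seed: int = 0
    squash: bool = False

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("need m >= 2 experiments")
        if self.perturb_sd < 0 or self.noise_sd < 0:
            raise ValueError("standard deviations must be nonnegative")


def sample_network(
    n: int, p: PowerLawParams = PowerLawParams(), seed: int = 0
) -> SyntheticNetwork:
    """Draw a random sparse network with power-law in-degrees.

    In-degrees exactly realize ``indegree_counts(n, p)`` (shuffled over
    genes); each target's regulators are drawn uniformly without
    replacement; interaction strengths are uniform on +/-[0.2, 1.0];
    |adjacency| is rescaled onto the spectral-radius bound if it exceeds
    it.  Fully reproducible from ``seed``.
    """
    if n <= p.k_max:
        raise ValueError(f"need n > k_max (n={n}, k_max={p.k_max})")
    rng = np.random.default_rng(seed)
    counts = indegree_counts(n, p)
    indegrees = np.repeat(np.arange(1, p.k_max + 1), counts)
    rng.shuffle(indegrees)
    A = np.zeros((n, n))
    for i in range(n):
        others = np.delete(np.arange(n), i)
        regulators = rng.choice(others, size=indegrees[i], replace=False)
        magnitudes = rng.uniform(0.2, 1.0, size=indegrees[i])
        signs = rng.choice([-1.0, 1.0], size=indegrees[i])
        A[regulators, i] = magnitudes * signs
    rho = float(np.max(np.abs(np.linalg.eigvals(np.abs(A)))))
    if rho > SPECTRAL_BOUND:
        A *= SPECTRAL_BOUND / rho
    basal = rng.uniform(0.5, 1.5, size=n)
    return SyntheticNetwork(adjacency=A, basal=basal, indegrees=indegrees)


def _steady_state(net: SyntheticNetwork, b: np.ndarray, squash: bool) -> np.ndarray:
    """Equilibrium of x = A^T x + b (or x = tanh(A^T x) + b when squashing).

    ``b`` has experiments in columns.  The linear solve is exact; the
    saturating variant iterates the contraction to 1e-12.
    """
    At = net.adjacency.T
    if not squash:
        x = np.linalg.solve(np.eye(net.n) - At, b)
        residual = np.max(np.abs(x - (At @ x + b)))
        assert residual <= 1e-8, "steady-state solve lost accuracy"
        return x
    x = np.linalg.solve(np.eye(net.n) - At, b)  # linear solution as warm start
    for _ in range(1000):
        x_next = np.tanh(At @ x) + b
        if np.max(np.abs(x_next - x)) < 1e-12:
            return x_next
        x = x_next
    raise RuntimeError("saturating steady state did not converge")


def simulate_multifactorial(
    net: SyntheticNetwork, cfg: SimulationConfig = SimulationConfig()
) -> ExpressionData:
    """Simulate ``cfg.m`` steady-state experiments from ``net``.

    Per experiment: basal activations are multiplied by (1 + eta) with
    i.i.d. eta ~ N(0, perturb_sd^2), the steady state is computed, and the
    observation is the state times (1 + xi), xi ~ N(0, noise_sd^2),
    clipped at zero.

    The linear kinetics are a local linearization, so steady-state
    "levels" are really deviations around an operating point and strong
    repression can push them negative, which no concentration can be.
    Genes whose realized steady state dips below ``POSITIVITY_MARGIN``
    are therefore shifted by a per-gene constant that restores that
    floor before noise is applied.  A per-gene affine shift is a change
    of baseline units: it is invisible to every inference step (the
    regressions carry intercepts and correlation is shift-invariant) and
    keeps the emitted matrix a valid nonnegative expression data set.
    Networks whose steady states are already positive are untouched.
    """
    rng = np.random.default_rng(cfg.seed)
    eta = rng.normal(0.0, cfg.perturb_sd, size=(cfg.m, net.n))
    B = (net.basal[np.newaxis, :] * (1.0 + eta)).T  # genes x experiments
    X = _steady_state(net, B, cfg.squash)
    levels = X.T  # experiments x genes
    shift = np.maximum(0.0, POSITIVITY_MARGIN - levels.min(axis=0))
    levels = levels + shift
    xi = rng.normal(0.0, cfg.noise_sd, size=(cfg.m, net.n))
    observed = np.clip(levels * (1.0 + xi), 0.0, None)
    names = [f"G{i + 1}" for i in range(net.n)]
    return ExpressionData(gene_names=names, values=observed)


def recovery_benchmark(
    n: int = 50,
    p: PowerLawParams = PowerLawParams(),
    sim: SimulationConfig = SimulationConfig(),
    weights: WeightConfig = WeightConfig(),
    norm: NormalizationConfig | None = NormalizationConfig(),
    do_refine: bool = False,
) -> EvaluationResult:
    """End-to-end recovery test: sample, simulate, infer, evaluate.

    ``norm=None`` skips normalization (scores the raw weight matrix);
    ``do_refine=True`` additionally runs the in-degree refinement.  The
    gold standard is the sampled adjacency's support.
    """
    net = sample_network(n, p, seed=sim.seed)
    data = simulate_multifactorial(net, sim)
    W = weight_matrix(data, weights)
    if norm is not None:
        W = normalize_columns(W, norm)
    if do_refine:
        W, _ = refine(data, W, p, weights)
    return evaluate(W, net.edge_set(), weights.candidate_regulators)
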