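"""Learning the residue kernel K1 from structure-similarity supervision.

Given pairs of sequences with a structural distance score Y (e.g. a SAS
value from a structure alignment, lower = more similar) and the normalized
string-kernel score X computed from K1, the objective is the Pearson
correlation P between X and Y.  X is similarity-like and Y distance-like,
so the optimization pushes P toward -1.

K1 is parametrized by its Cholesky factor, K1 = L L^T, so every iterate is
symmetric positive definite by construction; invertibility of L is kept by
clamping each |L(i, i)| to at least ``EPS_DIAG`` (sign-preserving).  During
optimization the Hadamard exponent is fixed at beta = 1: the learned object
is K1 itself, and beta is not identifiable jointly with the entries.

Derivatives are fully analytic.  The kernel K3 is a polynomial in the
entries of K1; its gradient is accumulated with a division-free
forward/backward dynamic program (prefix products of k-mer runs ending
before a position, suffix products starting after it), so the identity
start — which has many exactly-zero entries — poses no difficulty.  The
chain to the factor is dK1(a,b)/dL(p,q) = delta_ap L(b,q) + delta_bp
L(a,q), i.e. grad_L = tril((G + G^T) L) for G = dP/dK1 with entries treated
as independent.  All gradients are validated against central finite
differences in the test suite.

The optimizer is plain gradient descent with Armijo backtracking line
search: the procedure needs only a monotone method that keeps
the positive-definiteness handling transparent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .matrices import (
    EPS_DIAG,
    CholeskyFactor,
    SubstitutionMatrix,
    reconstruct,
)
from .string_kernel import (
    KernelParams,
    SequenceRecord,
    k3_weighted,
    kmer_profile_dp,
    weight_vector,
)

__all__ = [
    "TrainingPair",
    "TrainingSet",
    "OptimConfig",
    "OptimizationTrace",
    "pearson_objective",
    "pearson_gradient",
    "kernel_gradient_wrt_K1",
    "objective_and_gradient",
    "objective_gradient_wrt_L",
    "optimize_matrix",
]

logger = logging.getLogger(__name__)


@dataclass
class TrainingPair:
    """One supervision record: a sequence pair with its structure score Y."""

    seq1: SequenceRecord
    seq2: SequenceRecord
    Y: float
    X: float | None = None  # last computed Khat3, refreshed every iteration

    def __post_init__(self) -> None:
        if not np.isfinite(self.Y):
            raise ValueError(f"structure score for ({self.seq1.id}, {self.seq2.id}) is not finite")


@dataclass
class TrainingSet:
    """Supervision pairs plus the kernel parameters used during learning."""

    pairs: list[TrainingPair]
    params: KernelParams = field(default_factory=lambda: KernelParams(beta=1.0, kmax=2, scheme="mean"))

    def __post_init__(self) -> None:
        if len(self.pairs) < 3:
            raise ValueError(f"need at least 3 training pairs, got {len(self.pairs)}")
        y = np.array([p.Y for p in self.pairs])
        if np.ptp(y) == 0:
            raise ValueError("all structure scores are equal; Pearson correlation undefined")

    @property
    def Y(self) -> np.ndarray:
        return np.array([p.Y for p in self.pairs])


@dataclass(frozen=True)
class OptimConfig:
    """Stopping rules and line-search constants for matrix learning."""

    max_iter: int = 500
    tol_dP: float = 1e-6
    tol_grad: float = 1e-6
    armijo_c: float = 1e-4
    shrink: float = 0.5
    step0: float = 1.0
    max_backtracks: int = 40
    eps_diag: float = EPS_DIAG


@dataclass
class IterationRecord:
    iteration: int
    P: float
    grad_norm: float
    step: float


@dataclass
class OptimizationTrace:
    """Per-iteration objective values plus the learned factor and kernel."""

    iterations: list[IterationRecord]
    final_L: CholeskyFactor
    final_K1: SubstitutionMatrix
    converged: bool

    @property
    def P_values(self) -> np.ndarray:
        return np.array([r.P for r in self.iterations])


def pearson_objective(X: np.ndarray, Y: np.ndarray) -> float:
    """Pearson correlation P of two length-N vectors, N >= 3."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape or X.ndim != 1:
        raise ValueError("X and Y must be 1-d vectors of equal length")
    if X.size < 3:
        raise ValueError(f"need at least 3 observations, got {X.size}")
    xt = X - X.mean()
    yt = Y - Y.mean()
    vx = xt @ xt
    vy = yt @ yt
    if vx == 0 or vy == 0:
        raise ValueError("Pearson correlation undefined for a constant vector")
    return float((xt @ yt) / np.sqrt(vx * vy))


def pearson_gradient(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """dP/dX_n in closed form (Y held fixed)."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    xt = X - X.mean()
    yt = Y - Y.mean()
    vx = xt @ xt
    vy = yt @ yt
    if vx == 0 or vy == 0:
        raise ValueError("Pearson correlation undefined for a constant vector")
    p = (xt @ yt) / np.sqrt(vx * vy)
    return yt / np.sqrt(vx * vy) - p * xt / vx


def kernel_gradient_wrt_K1(K1: SubstitutionMatrix, s: SequenceRecord,
                           t: SequenceRecord, params: KernelParams) -> np.ndarray:
    """Gradient of K3(S, T) with respect to every entry of K1.

    Entries K1(a, b) and K1(b, a) are treated as independent: entry (a, b)
    of the result accumulates exactly the aligned positions with residue a
    in S and residue b in T.  Division-free forward/backward scheme: with
    E(i, j) = K1(s_i, t_j), prefix products F_u (runs of length u ending
    just before (i, j)) and suffix products B_v (runs starting just after),
    the sensitivity of E(i, j) is
    sum_{u+v+1 = k <= kmax} omega(k) F_u(i-1, j-1) B_v(i+1, j+1).
    """
    if s.alphabet.letters != K1.alphabet.letters or t.alphabet.letters != K1.alphabet.letters:
        raise ValueError("sequence alphabets must match the kernel matrix alphabet")
    si = s.encoded()
    tj = t.encoded()
    n, m = len(si), len(tj)
    keff = min(params.kmax, n, m)
    w = np.zeros(params.kmax + 1)
    w[1 : keff + 1] = weight_vector(params.scheme, params.kmax, n, m)
    E = K1.values[np.ix_(si, tj)]

    # F[u][i, j]: product of the u entries ending at (i-1, j-1); 1 for u = 0.
    # B[v][i, j]: product of the v entries starting at (i, j);    1 for v = 0.
    # Both padded to (n+1, m+1) with zeros where a run would leave the grid.
    F = [np.ones((n + 1, m + 1))]
    B = [np.ones((n + 1, m + 1))]
    for u in range(1, keff):
        f = np.zeros((n + 1, m + 1))
        f[1:, 1:] = F[u - 1][:-1, :-1] * E
        F.append(f)
        b = np.zeros((n + 1, m + 1))
        b[:-1, :-1] = E * B[u - 1][1:, 1:]
        B.append(b)

    dE = np.zeros((n, m))
    for u in range(keff):
        pref = F[u][:n, :m]  # run ending at (i-1, j-1)
        acc = np.zeros((n, m))
        for v in range(keff - u):
            k = u + v + 1
            if w[k] != 0.0:
                acc += w[k] * B[v][1 : n + 1, 1 : m + 1]
        dE += pref * acc

    grad = np.zeros((K1.n, K1.n))
    np.add.at(grad, (np.repeat(si, m), np.tile(tj, n)), dE.ravel())
    return grad


def _khat_and_gradient(K1: SubstitutionMatrix, pair: TrainingPair, params: KernelParams,
                       self_cache: dict[str, tuple[float, np.ndarray]]) -> tuple[float, np.ndarray]:
    """Khat3 of a pair and its gradient w.r.t. K1, caching per-sequence self terms."""
    s, t = pair.seq1, pair.seq2

    def self_terms(rec: SequenceRecord) -> tuple[float, np.ndarray]:
        if rec.id not in self_cache:
            k3 = k3_weighted(K1, rec, rec, params)
            g = kernel_gradient_wrt_K1(K1, rec, rec, params)
            self_cache[rec.id] = (k3, g)
        return self_cache[rec.id]

    k3_ss, g_ss = self_terms(s)
    k3_tt, g_tt = self_terms(t)
    if k3_ss <= 0 or k3_tt <= 0:
        raise FloatingPointError(
            f"non-positive self-kernel for pair ({s.id}, {t.id}); K1 is degenerate"
        )
    k3_st = k3_weighted(K1, s, t, params)
    g_st = kernel_gradient_wrt_K1(K1, s, t, params)
    denom = np.sqrt(k3_ss * k3_tt)
    x = k3_st / denom
    # quotient rule on X = K3(S,T) / sqrt(K3(S,S) K3(T,T))
    g_x = g_st / denom - 0.5 * x * (g_ss / k3_ss + g_tt / k3_tt)
    return float(x), g_x


def _evaluate_P(K1: SubstitutionMatrix, training: TrainingSet) -> tuple[float, np.ndarray]:
    """Objective P at K1; also returns the X vector.  Self-kernels cached by id."""
    params = training.params
    self_k3: dict[str, float] = {}

    def self_kernel(rec: SequenceRecord) -> float:
        if rec.id not in self_k3:
            self_k3[rec.id] = k3_weighted(K1, rec, rec, params)
        return self_k3[rec.id]

    X = np.empty(len(training.pairs))
    for i, pair in enumerate(training.pairs):
        k3_ss = self_kernel(pair.seq1)
        k3_tt = self_kernel(pair.seq2)
        if k3_ss <= 0 or k3_tt <= 0:
            raise FloatingPointError(
                f"non-positive self-kernel for pair ({pair.seq1.id}, {pair.seq2.id})"
            )
        X[i] = k3_weighted(K1, pair.seq1, pair.seq2, params) / np.sqrt(k3_ss * k3_tt)
    return pearson_objective(X, training.Y), X


def objective_and_gradient(training: TrainingSet, factor: CholeskyFactor) -> tuple[float, np.ndarray, np.ndarray]:
    """P, dP/dL (lower triangular), and the X vector at K1 = L L^T."""
    K1 = reconstruct(factor, name="optim")
    params = training.params
    self_cache: dict[str, tuple[float, np.ndarray]] = {}
    X = np.empty(len(training.pairs))
    grads = []
    for i, pair in enumerate(training.pairs):
        X[i], g = _khat_and_gradient(K1, pair, params, self_cache)
        pair.X = float(X[i])
        grads.append(g)
    P = pearson_objective(X, training.Y)
    dP_dX = pearson_gradient(X, training.Y)
    G = np.zeros_like(K1.values)
    for c, g in zip(dP_dX, grads):
        G += c * g
    grad_L = np.tril((G + G.T) @ factor.L)
    return P, grad_L, X


def objective_gradient_wrt_L(training: TrainingSet, factor: CholeskyFactor) -> np.ndarray:
    """dP/dL(p, q): the full chain through X, K1 = L L^T."""
    return objective_and_gradient(training, factor)[1]


def optimize_matrix(training: TrainingSet, L0: CholeskyFactor,
                    config: OptimConfig = OptimConfig()) -> OptimizationTrace:
    """Minimize P toward -1 by gradient descent on the Cholesky factor.

    Every accepted step satisfies the Armijo decrease condition, so the
    objective trace is non-increasing; after each step the diagonal of L is
    clamped away from zero, so every iterate's K1 = L L^T stays positive
    definite.  The customary start is the identity matrix, which carries no
    information about residue similarity.
    """
    L = L0.clamp_diagonal(config.eps_diag)
    P, grad, _ = objective_and_gradient(training, L)
    gnorm = float(np.linalg.norm(grad))
    trace = [IterationRecord(0, P, gnorm, 0.0)]
    logger.info("iter 0: P=%.6f |grad|=%.3g", P, gnorm)
    converged = gnorm < config.tol_grad
    step = config.step0

    for it in range(1, config.max_iter + 1):
        if converged:
            break
        accepted = False
        trial = step
        for _ in range(config.max_backtracks):
            cand = CholeskyFactor(L.alphabet, L.L - trial * grad).clamp_diagonal(config.eps_diag)
            try:
                P_new, _ = _evaluate_P(reconstruct(cand, name="optim"), training)
            except (FloatingPointError, ValueError):
                trial *= config.shrink
                continue
            if P_new <= P - config.armijo_c * trial * gnorm**2:
                accepted = True
                break
            trial *= config.shrink
        if not accepted:
            logger.info("iter %d: no descent step found; stopping", it)
            converged = True
            break
        L = cand
        dP = P - P_new
        P, grad, _ = objective_and_gradient(training, L)
        gnorm = float(np.linalg.norm(grad))
        trace.append(IterationRecord(it, P, gnorm, trial))
        logger.info("iter %d: P=%.6f |grad|=%.3g step=%.3g", it, P, gnorm, trial)
        step = min(trial / config.shrink, config.step0)  # allow the step to grow back
        if dP < config.tol_dP or gnorm < config.tol_grad:
            converged = True

    K1 = reconstruct(L, name="Optim")
    return OptimizationTrace(trace, L, K1, converged)
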