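"""The weighted string kernel, its normalization, and the induced distance.

Given a residue-level kernel K1 (a symmetric positive-definite substitution
matrix, usually an entrywise power SM**beta), two sequences S and T of
lengths n and m are compared gap-free through all their contiguous k-mers:

* a pair of k-mers scores the product of K1 over aligned positions,
* K3^k(S, T) sums that score over all (n-k+1)(m-k+1) k-mer pairs,
* K3(S, T) = sum_k omega(k) * K3^k(S, T) for k = 1..min(kmax, n, m),
* Khat3(S, T) = K3(S, T) / sqrt(K3(S, S) * K3(T, T)), so Khat3(S, S) = 1,
* D(S, T) = sqrt(2 - 2 * Khat3(S, T)), a distance in [0, sqrt(2)].

Three weighting schemes are supported: ``uniform`` (omega = 1), ``degree``
(omega(k) = 2(kmax - k + 1) / (kmax (kmax + 1)), summing to 1), and ``mean``
(omega(k) = 1 / ((n - k + 1)(m - k + 1)), the average k-mer contribution,
which removes the sequence-length bias).  The recommended parameters are
beta = 0.2, kmax = 10 with the mean scheme.

The per-k values are computed by a dynamic program in O(n m kmax) time and
O(n m) memory; an exhaustive brute-force enumeration is provided as an
independent oracle for small instances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .matrices import AminoAlphabet, CANONICAL_ALPHABET, SubstitutionMatrix

__all__ = [
    "SequenceRecord",
    "KernelParams",
    "KernelProfile",
    "WEIGHT_SCHEMES",
    "sanitize_residues",
    "weight_of",
    "weight_vector",
    "k2_kmer",
    "k3_fixed_k_bruteforce",
    "kmer_profile_dp",
    "k3_weighted",
    "correlation_kernel",
    "kernel_distance",
]

logger = logging.getLogger(__name__)

WEIGHT_SCHEMES = ("uniform", "degree", "mean")

#: Tolerance above 1 accepted for Khat3 before clamping (floating-point jitter).
KHAT_TOL = 1e-10


def sanitize_residues(residues: str, alphabet: AminoAlphabet = CANONICAL_ALPHABET,
                      *, drop_unknown: bool = False, seq_id: str = "") -> str:
    """Uppercase a residue string and enforce the alphabet.

    Strict by default: a letter outside the alphabet raises, naming the
    offending letter and its 1-based position.  With ``drop_unknown`` such
    residues are removed and the count is logged.
    """
    residues = residues.upper()
    bad = [(i, c) for i, c in enumerate(residues) if c not in alphabet]
    if not bad:
        return residues
    if not drop_unknown:
        i, c = bad[0]
        where = f" in sequence {seq_id!r}" if seq_id else ""
        raise ValueError(f"illegal residue {c!r} at position {i + 1}{where}")
    logger.info("dropped %d unknown residue(s)%s", len(bad),
                f" from {seq_id!r}" if seq_id else "")
    drop = {i for i, _ in bad}
    return "".join(c for i, c in enumerate(residues) if i not in drop)


@dataclass(frozen=True)
class SequenceRecord:
    """A named protein sequence over an amino-acid alphabet."""

    id: str
    residues: str
    alphabet: AminoAlphabet = CANONICAL_ALPHABET

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = next((c for c in self.residues if c not in self.alphabet), None)
        if bad is not None:
            raise ValueError(
                f"sequence {self.id!r} contains letter {bad!r} outside the alphabet; "
                "apply sanitize_residues first"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def encoded(self) -> np.ndarray:
        return self.alphabet.encode(self.residues)


@dataclass(frozen=True)
class KernelParams:
    """Kernel hyper-parameters: Hadamard exponent, k-mer cap, weight scheme."""

    beta: float = 0.2
    kmax: int = 10
    scheme: str = "mean"

    def __post_init__(self) -> None:
        if not self.beta > 0:
            raise ValueError(f"beta must be strictly positive, got {self.beta}")
        if not (isinstance(self.kmax, (int, np.integer)) and self.kmax >= 1):
            raise ValueError(f"kmax must be a positive integer, got {self.kmax}")
        if self.scheme not in WEIGHT_SCHEMES:
            raise ValueError(f"unknown weight scheme {self.scheme!r}; choose from {WEIGHT_SCHEMES}")


@dataclass(frozen=True)
class KernelProfile:
    """Full result of comparing one sequence pair."""

    id1: str
    id2: str
    per_k: np.ndarray  # K3^k for the (S, T) pair, k = 1..min(kmax, n, m)
    K3: float
    K3_SS: float
    K3_TT: float
    Khat3: float
    D: float


def weight_of(scheme: str, k: int, kmax: int, n: int, m: int) -> float:
    """The weight omega(k) of the k-mer level under a scheme."""
    if not 1 <= k <= min(kmax, n, m):
        raise ValueError(f"k={k} out of range 1..min(kmax={kmax}, n={n}, m={m})")
    if scheme == "uniform":
        return 1.0
    if scheme == "degree":
        return 2.0 * (kmax - k + 1) / (kmax * (kmax + 1))
    if scheme == "mean":
        return 1.0 / ((n - k + 1) * (m - k + 1))
    raise ValueError(f"unknown weight scheme {scheme!r}")


def weight_vector(scheme: str, kmax: int, n: int, m: int) -> np.ndarray:
    """omega(k) for k = 1..min(kmax, n, m) as an array."""
    keff = min(kmax, n, m)
    return np.array([weight_of(scheme, k, kmax, n, m) for k in range(1, keff + 1)])


def _check_k1(K1: SubstitutionMatrix, *records: SequenceRecord) -> None:
    for r in records:
        if r.alphabet.letters != K1.alphabet.letters:
            raise ValueError(
                f"sequence {r.id!r} alphabet does not match the kernel matrix alphabet"
            )


def k2_kmer(K1: SubstitutionMatrix, sk: str, tk: str) -> float:
    """Kernel of two equal-length k-mers: product of K1 over aligned positions."""
    if len(sk) != len(tk) or len(sk) < 1:
        raise ValueError(f"k-mers must have equal positive length, got {len(sk)} and {len(tk)}")
    si = K1.alphabet.encode(sk)
    ti = K1.alphabet.encode(tk)
    return float(np.prod(K1.values[si, ti]))


def k3_fixed_k_bruteforce(K1: SubstitutionMatrix, s: SequenceRecord,
                          t: SequenceRecord, k: int) -> float:
    """Exact K3^k by enumerating every k-mer pair (oracle for the DP).

    Returns 0 when k exceeds either sequence length: there are no k-mers to
    sum over, which keeps the weighted sum well defined for short sequences.
    """
    _check_k1(K1, s, t)
    n, m = len(s), len(t)
    if k > min(n, m):
        return 0.0
    total = 0.0
    for i in range(n - k + 1):
        for j in range(m - k + 1):
            total += k2_kmer(K1, s.residues[i : i + k], t.residues[j : j + k])
    return total


def kmer_profile_dp(K1: SubstitutionMatrix, s: SequenceRecord,
                    t: SequenceRecord, kmax: int) -> np.ndarray:
    """All per-k kernel values K3^k, k = 1..min(kmax, n, m), by dynamic programming.

    Recurrence: with E(i, j) = K1(s_i, t_j), the array of k-mer products
    ending at (i, j) satisfies M_k(i, j) = M_{k-1}(i-1, j-1) * E(i, j); each
    K3^k is the sum of the valid layer.  Time O(n m kmax), memory O(n m)
    (one rolling layer).
    """
    _check_k1(K1, s, t)
    if kmax < 1:
        raise ValueError(f"kmax must be >= 1, got {kmax}")
    E = K1.values[np.ix_(s.encoded(), t.encoded())]
    keff = min(kmax, len(s), len(t))
    per_k = np.empty(keff)
    layer = E
    per_k[0] = layer.sum()
    for k in range(2, keff + 1):
        layer = layer[:-1, :-1] * E[k - 1 :, k - 1 :]
        per_k[k - 1] = layer.sum()
    return per_k


def k3_weighted(K1: SubstitutionMatrix, s: SequenceRecord, t: SequenceRecord,
                params: KernelParams, per_k: np.ndarray | None = None) -> float:
    """The weighted kernel K3(S, T) = sum_k omega(k) K3^k(S, T)."""
    if per_k is None:
        per_k = kmer_profile_dp(K1, s, t, params.kmax)
    w = weight_vector(params.scheme, params.kmax, len(s), len(t))
    return float(w @ per_k)


def kernel_distance(khat3: float) -> float:
    """Distance D = sqrt(2 - 2 Khat3) induced by the normalized kernel."""
    if khat3 > 1.0 + KHAT_TOL:
        raise ValueError(f"normalized kernel value {khat3!r} exceeds 1 beyond tolerance")
    return float(np.sqrt(max(2.0 - 2.0 * khat3, 0.0)))


def correlation_kernel(K1: SubstitutionMatrix, s: SequenceRecord, t: SequenceRecord,
                       params: KernelParams,
                       k3_ss: float | None = None, k3_tt: float | None = None) -> KernelProfile:
    """Normalized kernel Khat3 and distance D for a sequence pair.

    Runs the dynamic program three times — for (S, T), (S, S) and (T, T) —
    unless the self-kernels are supplied (callers computing many pairs cache
    them).  Khat3 is clamped to [0, 1] after a 1e-10 tolerance check.
    """
    per_k = kmer_profile_dp(K1, s, t, params.kmax)
    k3_st = k3_weighted(K1, s, t, params, per_k=per_k)
    if k3_ss is None:
        k3_ss = k3_weighted(K1, s, s, params)
    if k3_tt is None:
        k3_tt = k3_weighted(K1, t, t, params)
    if k3_ss <= 0 or k3_tt <= 0:
        raise FloatingPointError(
            f"non-positive self-kernel (K3({s.id},{s.id})={k3_ss:g}, "
            f"K3({t.id},{t.id})={k3_tt:g}); the residue kernel K1 is degenerate"
        )
    khat = k3_st / np.sqrt(k3_ss * k3_tt)
    if khat > 1.0 + KHAT_TOL:
        raise FloatingPointError(f"Khat3({s.id},{t.id}) = {khat!r} exceeds 1 beyond tolerance")
    khat = float(min(max(khat, 0.0), 1.0))
    return KernelProfile(
        id1=s.id, id2=t.id, per_k=per_k, K3=k3_st, K3_SS=float(k3_ss),
        K3_TT=float(k3_tt), Khat3=khat, D=kernel_distance(khat),
    )
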