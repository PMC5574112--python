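"""Amino-acid similarity matrices and their transformations.

A substitution matrix on the raw (odds-ratio, non-logarithmic) scale acts as
the residue-level kernel K1 of the string kernel: K1(a, b) = SM(a, b)**beta.
K1 is a valid kernel as long as SM is symmetric positive definite and
beta > 0.  This module provides the labeled-matrix container, text I/O,
the entrywise (Hadamard) power, positive-definiteness checks, and the
Cholesky factorization K1 = L L^T used to parametrize matrix learning.

The bundled ``bl62()`` matrix is the raw-scale odds-ratio kernel matrix
underlying BLOSUM62 (often called BLOSUM62-2): entry (a, b) equals
q_ab / (p_a p_b), the joint substitution frequency of a and b in the
BLOSUM62 training alignments divided by the product of their background
frequencies.  It is symmetric and positive definite, with entries between
roughly 0.05 and 38.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "CANONICAL_LETTERS",
    "AminoAlphabet",
    "SubstitutionMatrix",
    "CholeskyFactor",
    "MatrixFormatError",
    "EPS_DIAG",
    "load_matrix",
    "write_matrix",
    "hadamard_power",
    "is_positive_definite",
    "cholesky_factor",
    "reconstruct",
    "normalize_rows",
    "bl62",
]

#: Canonical residue order: the 20 one-letter codes, alphabetically.
CANONICAL_LETTERS = "ACDEFGHIKLMNPQRSTVWY"

#: Relative tolerance for the symmetry check on loaded/constructed matrices.
SYMMETRY_RTOL = 1e-12

#: Relative eigenvalue tolerance for positive definiteness (scale-free).
PD_RTOL = 1e-10

#: Minimum allowed magnitude of a Cholesky diagonal entry.  Keeping every
#: |L(i,i)| above this bound keeps L invertible, hence L L^T positive
#: definite, throughout matrix optimization.
EPS_DIAG = 1e-8


class MatrixFormatError(ValueError):
    """Raised when a matrix text file cannot be parsed or is inconsistent."""


@dataclass(frozen=True)
class AminoAlphabet:
    """Ordered residue alphabet with letter -> index lookup.

    The default is the canonical 20-letter amino-acid alphabet in
    alphabetical order.  Smaller alphabets (2-5 letters) are accepted so
    that exhaustive oracles stay cheap in tests.
    """

    letters: tuple[str, ...] = tuple(CANONICAL_LETTERS)
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        letters = tuple(self.letters)
        if len(letters) == 0:
            raise ValueError("alphabet must contain at least one letter")
        if len(set(letters)) != len(letters):
            raise ValueError("alphabet letters must be distinct")
        for ch in letters:
            if len(ch) != 1 or not ch.isalpha() or not ch.isupper():
                raise ValueError(f"invalid alphabet letter {ch!r}")
        object.__setattr__(self, "letters", letters)
        object.__setattr__(self, "_index", {c: i for i, c in enumerate(letters)})

    def __len__(self) -> int:
        return len(self.letters)

    def __contains__(self, letter: str) -> bool:
        return letter in self._index

    def index(self, letter: str) -> int:
        try:
            return self._index[letter]
        except KeyError:
            raise KeyError(f"letter {letter!r} not in alphabet") from None

    def encode(self, residues: str) -> np.ndarray:
        """Map a residue string to an integer index array."""
        try:
            return np.array([self._index[c] for c in residues], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(f"residue {exc.args[0]} not in alphabet") from None


#: The canonical alphabet, shared by default.
CANONICAL_ALPHABET = AminoAlphabet()


@dataclass(frozen=True)
class SubstitutionMatrix:
    """Labeled square symmetric similarity matrix over an alphabet."""

    alphabet: AminoAlphabet
    values: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        n = len(self.alphabet)
        if values.shape != (n, n):
            raise ValueError(
                f"matrix shape {values.shape} does not match alphabet size {n}"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("matrix contains non-finite entries")
        scale = np.max(np.abs(values))
        if scale > 0 and np.max(np.abs(values - values.T)) > SYMMETRY_RTOL * scale:
            raise ValueError("matrix is not symmetric within tolerance")
        values = 0.5 * (values + values.T)  # exact symmetry
        values.setflags(write=False)
        object.__setattr__(self, "values", values)

    def entry(self, a: str, b: str) -> float:
        return float(self.values[self.alphabet.index(a), self.alphabet.index(b)])

    @property
    def n(self) -> int:
        return len(self.alphabet)


@dataclass(frozen=True)
class CholeskyFactor:
    """Lower-triangular factor L with K1 = L L^T.

    Strictly zero above the diagonal; a diagonal entry of magnitude below
    ``EPS_DIAG`` violates the invertibility invariant (checked by
    :meth:`validate`, enforced during optimization by sign-preserving
    clamping).
    """

    alphabet: AminoAlphabet
    L: np.ndarray

    def __post_init__(self) -> None:
        L = np.asarray(self.L, dtype=float)
        n = len(self.alphabet)
        if L.shape != (n, n):
            raise ValueError(f"factor shape {L.shape} does not match alphabet size {n}")
        if not np.all(np.isfinite(L)):
            raise ValueError("factor contains non-finite entries")
        if np.any(np.triu(L, k=1) != 0.0):
            raise ValueError("factor has nonzero entries above the diagonal")
        L = L.copy()
        L.setflags(write=False)
        object.__setattr__(self, "L", L)

    def validate(self, eps_diag: float = EPS_DIAG) -> None:
        small = np.abs(np.diag(self.L)) < eps_diag
        if np.any(small):
            i = int(np.nonzero(small)[0][0])
            raise ValueError(
                f"diagonal entry L({i},{i}) = {self.L[i, i]:.3g} below {eps_diag:g}"
            )

    def clamp_diagonal(self, eps_diag: float = EPS_DIAG) -> "CholeskyFactor":
        """Return a factor whose diagonal magnitudes are >= eps_diag.

        Signs are preserved; an exactly zero entry is pushed to +eps_diag.
        """
        L = np.array(self.L)
        d = np.diag(L).copy()
        small = np.abs(d) < eps_diag
        d[small] = np.where(d[small] >= 0.0, eps_diag, -eps_diag)
        np.fill_diagonal(L, d)
        return CholeskyFactor(self.alphabet, L)


def _canonical_order(letters: Sequence[str]) -> list[str]:
    return sorted(letters)


def load_matrix(path: str | Path, name: str | None = None) -> SubstitutionMatrix:
    """Read a labeled square matrix from whitespace-delimited text.

    Format: optional ``#`` comment lines, a header line of residue letters,
    then one row per residue: the letter followed by the full row of numeric
    values.  Rows and columns are reordered into canonical (alphabetical)
    order, so files with any consistent letter order load identically.
    """
    path = Path(path)
    lines = [
        ln for ln in path.read_text().splitlines() if ln.strip() and not ln.lstrip().startswith("#")
    ]
    if not lines:
        raise MatrixFormatError(f"{path}: no content")
    header = lines[0].split()
    n = len(header)
    if len(set(header)) != n:
        raise MatrixFormatError(f"{path}: duplicate letters in header")
    if len(lines) - 1 != n:
        raise MatrixFormatError(
            f"{path}: expected {n} data rows for {n} letters, found {len(lines) - 1}"
        )
    raw = np.empty((n, n), dtype=float)
    row_letters = []
    for ln in lines[1:]:
        fields = ln.split()
        letter, cells = fields[0], fields[1:]
        if letter not in header:
            raise MatrixFormatError(f"{path}: row letter {letter!r} missing from header")
        if len(cells) != n:
            raise MatrixFormatError(
                f"{path}: row {letter!r} has {len(cells)} values, expected {n}"
            )
        try:
            raw[header.index(letter)] = [float(c) for c in cells]
        except ValueError as exc:
            raise MatrixFormatError(f"{path}: non-numeric cell in row {letter!r}: {exc}") from None
        row_letters.append(letter)
    if set(row_letters) != set(header):
        missing = sorted(set(header) - set(row_letters))
        raise MatrixFormatError(f"{path}: missing rows for letters {missing}")
    scale = np.max(np.abs(raw))
    asym = np.abs(raw - raw.T)
    if scale > 0 and asym.max() > 1e-8 * scale:
        i, j = np.unravel_index(int(asym.argmax()), asym.shape)
        raise MatrixFormatError(
            f"{path}: asymmetric entries ({header[i]},{header[j]})="
            f"{raw[i, j]:g} vs ({header[j]},{header[i]})={raw[j, i]:g}"
        )
    order = _canonical_order(header)
    perm = [header.index(a) for a in order]
    values = raw[np.ix_(perm, perm)]
    return SubstitutionMatrix(AminoAlphabet(tuple(order)), values, name or path.stem)


def write_matrix(sm: SubstitutionMatrix, path: str | Path, fmt: str = "%.10g",
                 comments: Iterable[str] = ()) -> None:
    """Write a matrix in the text dialect read by :func:`load_matrix`."""
    path = Path(path)
    out = [f"# {c}" for c in comments]
    out.append(" ".join(sm.alphabet.letters))
    for i, a in enumerate(sm.alphabet.letters):
        out.append(a + " " + " ".join(fmt % v for v in sm.values[i]))
    path.write_text("\n".join(out) + "\n")


def hadamard_power(sm: SubstitutionMatrix, beta: float) -> SubstitutionMatrix:
    """Entrywise power SM**beta (the exponent applies to entries, not the matrix)."""
    if not beta > 0:
        raise ValueError(f"beta must be strictly positive, got {beta}")
    if np.any(sm.values < 0):
        raise ValueError("Hadamard power requires nonnegative entries")
    name = f"{sm.name}^{beta:g}" if sm.name else f"^{beta:g}"
    return SubstitutionMatrix(sm.alphabet, np.power(sm.values, beta), name)


def is_positive_definite(sm: SubstitutionMatrix) -> tuple[bool, float]:
    """Whether SM is positive definite, plus its smallest eigenvalue.

    The test is scale-free: lambda_min > -PD_RTOL * lambda_max.
    """
    eigvals = np.linalg.eigvalsh(sm.values)
    lo, hi = float(eigvals[0]), float(eigvals[-1])
    return lo > -PD_RTOL * max(hi, 0.0), lo


def cholesky_factor(sm: SubstitutionMatrix) -> CholeskyFactor:
    """Cholesky factorization SM = L L^T with positive diagonal."""
    try:
        L = np.linalg.cholesky(sm.values)
    except np.linalg.LinAlgError:
        # locate the failing pivot for the error message
        v = sm.values
        for k in range(sm.n + 1):
            try:
                np.linalg.cholesky(v[: k + 1, : k + 1])
            except np.linalg.LinAlgError:
                raise np.linalg.LinAlgError(
                    f"matrix {sm.name or '<unnamed>'} is not positive definite: "
                    f"factorization fails at pivot {k} "
                    f"(letter {sm.alphabet.letters[min(k, sm.n - 1)]})"
                ) from None
        raise
    return CholeskyFactor(sm.alphabet, L)


def reconstruct(factor: CholeskyFactor, name: str = "") -> SubstitutionMatrix:
    """Assemble K1 = L L^T (positive definite whenever all |L(i,i)| > 0)."""
    return SubstitutionMatrix(factor.alphabet, factor.L @ factor.L.T, name)


def normalize_rows(sm: SubstitutionMatrix) -> tuple[np.ndarray, bool]:
    """Scale each row to sum to 1.

    Row normalization generally destroys symmetry, so the result is returned
    as a plain array together with a flag telling whether it is still
    symmetric (and hence still usable as a kernel).
    """
    sums = sm.values.sum(axis=1)
    if np.any(sums <= 0):
        i = int(np.nonzero(sums <= 0)[0][0])
        raise ValueError(f"row {sm.alphabet.letters[i]!r} has non-positive sum {sums[i]:g}")
    out = sm.values / sums[:, None]
    scale = np.max(np.abs(out))
    symmetric = bool(np.max(np.abs(out - out.T)) <= 1e-12 * scale)
    return out, symmetric


def bl62() -> SubstitutionMatrix:
    """The bundled raw-scale BLOSUM62 odds-ratio matrix (BLOSUM62-2)."""
    with resources.as_file(resources.files("wseqkernel.data") / "bl62.txt") as p:
        return load_matrix(p, name="BL62")
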