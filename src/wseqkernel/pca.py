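"""Principal component analysis of a substitution/kernel matrix.

A 20x20 substitution matrix is read as a data matrix: 20 amino-acid
"objects" described by 20 substitution-score "features".  Each feature
(column) is centered by subtracting its mean; the covariance of the
centered rows, C = Kc Kc^T / (N - 1), is eigendecomposed.  Eigenvectors
give the principal directions, eigenvalues the variance carried by each,
and the projections of the centered rows onto the top directions give
low-dimensional amino-acid coordinates — the 3-D "vector representation"
of the residues.  Components can be interpreted by correlating their
coordinates against amino-acid property scales (hydrophobicity, burial,
etc.); the correlation is reported in absolute value since a component's
sign is arbitrary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .matrices import SubstitutionMatrix
from .optimization import pearson_objective

__all__ = ["PCAResult", "center_columns", "covariance", "pca_of_matrix", "index_correlation"]


@dataclass(frozen=True)
class PCAResult:
    """Eigendecomposition summary of a matrix seen as amino-acid data."""

    letters: tuple[str, ...]
    eigenvalues: np.ndarray       # non-increasing, >= -1e-10 (variance units)
    components: np.ndarray        # (N, N) orthonormal columns
    variance_fraction: np.ndarray # eigenvalue / sum(eigenvalues)
    coordinates: np.ndarray       # (N, n_components) projections of centered rows
    n_components: int


def center_columns(K: np.ndarray) -> np.ndarray:
    """Subtract each column's mean; every column of the result sums to 0."""
    K = np.asarray(K, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {K.shape}")
    if not np.all(np.isfinite(K)):
        raise ValueError("matrix contains non-finite entries")
    return K - K.mean(axis=0, keepdims=True)


def covariance(Kc: np.ndarray) -> np.ndarray:
    """Row covariance C = Kc Kc^T / (N - 1) of a column-centered matrix.

    N - 1 rather than N because the feature means were estimated from the
    matrix itself.
    """
    Kc = np.asarray(Kc, dtype=float)
    n = Kc.shape[0]
    if n < 2:
        raise ValueError("covariance needs at least 2 rows")
    return Kc @ Kc.T / (n - 1)


def pca_of_matrix(sm: SubstitutionMatrix | np.ndarray, n_components: int = 3,
                  letters: tuple[str, ...] | None = None) -> PCAResult:
    """PCA of a (substitution) matrix: eigenvalues, components, coordinates.

    Sign convention: each component is flipped so that its largest-magnitude
    amino-acid coordinate is positive, making coordinates reproducible.
    """
    if isinstance(sm, SubstitutionMatrix):
        K = sm.values
        letters = sm.alphabet.letters
    else:
        K = np.asarray(sm, dtype=float)
        if letters is None:
            letters = tuple(chr(ord("A") + i) for i in range(K.shape[0]))
    n = K.shape[0]
    n_components = min(n_components, n)
    Kc = center_columns(K)
    C = covariance(Kc)
    eigvals, eigvecs = np.linalg.eigh(C)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    total = eigvals.sum()
    fractions = eigvals / total if total > 0 else np.full(n, np.nan)
    coords = Kc @ eigvecs
    for j in range(n):
        i = int(np.argmax(np.abs(coords[:, j])))
        if coords[i, j] < 0:
            coords[:, j] = -coords[:, j]
            eigvecs[:, j] = -eigvecs[:, j]
    return PCAResult(
        letters=tuple(letters),
        eigenvalues=eigvals,
        components=eigvecs,
        variance_fraction=fractions,
        coordinates=coords[:, :n_components],
        n_components=n_components,
    )


def index_correlation(result: PCAResult, component: int,
                      index: Mapping[str, float]) -> float:
    """|Pearson correlation| between a component's coordinates and a residue scale.

    ``component`` is 0-based; ``index`` must provide one value per residue of
    the analyzed alphabet.  The absolute value is reported because the sign
    of a principal component is arbitrary.
    """
    if not 0 <= component < result.coordinates.shape[1]:
        raise ValueError(f"component {component} not in 0..{result.coordinates.shape[1] - 1}")
    missing = [a for a in result.letters if a not in index]
    if missing:
        raise ValueError(f"index is missing residues {missing}")
    values = np.array([float(index[a]) for a in result.letters])
    return abs(pearson_objective(result.coordinates[:, component], values))
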