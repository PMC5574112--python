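"""All-vs-all kernel computation and ROC analysis of fold recognition.

Fold recognition is cast as a ranking problem: a pair of proteins is a
positive if both carry the same fold label (e.g. the same CATH
class/architecture/topology string) and a negative otherwise.  A good
similarity measure ranks positive pairs above negative pairs; the area
under the ROC curve (AUC) quantifies this, with 1 for a perfect ranking
and 0.5 for random behavior — e.g. for the all-ones substitution matrix
under the mean weight scheme, which scores every pair identically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_curve as _sk_roc_curve

from .matrices import SubstitutionMatrix
from .string_kernel import KernelParams, SequenceRecord, correlation_kernel, k3_weighted

__all__ = [
    "LabeledSequenceSet",
    "ROCResult",
    "pairwise_kernel_matrix",
    "pair_scores_and_labels",
    "roc_auc",
]


@dataclass(frozen=True)
class LabeledSequenceSet:
    """Sequences with one fold label per record; ids must be unique."""

    records: tuple[SequenceRecord, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        records = tuple(self.records)
        labels = tuple(str(l) for l in self.labels)
        if len(records) != len(labels):
            raise ValueError("one label per record required")
        ids = [r.id for r in records]
        if len(set(ids)) != len(ids):
            raise ValueError("sequence ids must be unique")
        object.__setattr__(self, "records", records)
        object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class ROCResult:
    """AUC, the ROC curve, and the pair counts behind them."""

    auc: float
    curve: np.ndarray  # (n_points, 2) array of (FPR, TPR), from (0,0) to (1,1)
    n_pos: int
    n_neg: int


def pairwise_kernel_matrix(seqset: LabeledSequenceSet, K1: SubstitutionMatrix,
                           params: KernelParams) -> np.ndarray:
    """Symmetric matrix of normalized kernel values Khat3 over a sequence set.

    Each sequence's self-kernel K3(S, S) is computed once and reused across
    the N(N-1)/2 pair evaluations; the diagonal is exactly 1.
    """
    records = seqset.records
    n = len(records)
    self_k3 = np.array([k3_weighted(K1, r, r, params) for r in records])
    out = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            prof = correlation_kernel(K1, records[i], records[j], params,
                                      k3_ss=self_k3[i], k3_tt=self_k3[j])
            out[i, j] = out[j, i] = prof.Khat3
    return out


def pair_scores_and_labels(kernel_matrix: np.ndarray,
                           labels: tuple[str, ...] | list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle pair scores and same-fold indicators (self-pairs excluded)."""
    labels = np.asarray(labels, dtype=object)
    iu, ju = np.triu_indices(len(labels), k=1)
    return kernel_matrix[iu, ju], labels[iu] == labels[ju]


def roc_auc(scores: np.ndarray, positives: np.ndarray,
            higher_is_similar: bool = True) -> ROCResult:
    """Tie-corrected Mann-Whitney AUC and the ROC curve.

    The AUC is (wins + 0.5 * ties) / (n_pos * n_neg), computed from mid-rank
    data, so all-tied scores give exactly 0.5.  For distance-like scores set
    ``higher_is_similar=False``; orientation is then inverted.
    """
    scores = np.asarray(scores, dtype=float)
    positives = np.asarray(positives, dtype=bool)
    if scores.shape != positives.shape or scores.ndim != 1:
        raise ValueError("scores and positives must be 1-d arrays of equal length")
    n_pos = int(positives.sum())
    n_neg = int(scores.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError(f"need both positive and negative pairs (got {n_pos} and {n_neg})")
    if not higher_is_similar:
        scores = -scores
    ranks = rankdata(scores)  # mid-ranks: ties get half credit
    auc = (ranks[positives].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    fpr, tpr, _ = _sk_roc_curve(positives.astype(int), scores, drop_intermediate=False)
    return ROCResult(float(auc), np.column_stack([fpr, tpr]), n_pos, n_neg)
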