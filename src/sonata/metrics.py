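"""Integration-quality metrics: average FOSCTTM and label-transfer accuracy.

FOSCTTM (Fraction Of Samples Closer Than the True Match) scores how well
an alignment preserves known cell-cell correspondence: for each cell, the
fraction of other-modality cells strictly closer than its true match,
averaged over all cells in both directions.  0 is perfect, 0.5 is the
random-pairing expectation.

LTA (Label Transfer Accuracy) scores how well cell labels transfer across
the aligned modalities by k-nearest-neighbor majority vote; 1 is perfect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .selfalign import Coupling

__all__ = [
    "AlignedEmbeddings",
    "foscttm",
    "label_transfer_accuracy",
    "barycentric_projection",
    "score_coupling",
]


@dataclass
class AlignedEmbeddings:
    """Two modalities placed in a shared d-dimensional space.

    ``correspondence[k] = (i, j)`` states that cell ``i`` of x matches
    cell ``j`` of y; defaults to the identity pairing when both modalities
    have equally many cells.
    """

    x_aligned: np.ndarray
    y_aligned: np.ndarray
    correspondence: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.x_aligned = np.atleast_2d(np.asarray(self.x_aligned, dtype=float))
        self.y_aligned = np.atleast_2d(np.asarray(self.y_aligned, dtype=float))
        if self.x_aligned.shape[1] != self.y_aligned.shape[1]:
            raise ValueError("embeddings must share their dimension")
        if self.correspondence is None:
            if self.x_aligned.shape[0] != self.y_aligned.shape[0]:
                raise ValueError(
                    "correspondence required when modalities differ in size"
                )
            self.correspondence = np.column_stack(
                [np.arange(self.x_aligned.shape[0])] * 2
            )
        else:
            self.correspondence = np.asarray(self.correspondence, dtype=int)
            if self.correspondence.ndim != 2 or self.correspondence.shape[1] != 2:
                raise ValueError("correspondence must be an (m, 2) index array")


def foscttm(emb: AlignedEmbeddings) -> float:
    """Average fraction of samples strictly closer than the true match.

    Distance ties count as not closer; the fraction for a cell is over the
    other modality's non-match cells; directions x->y and y->x are both
    scored and averaged.
    """
    if emb.correspondence is None or emb.correspondence.size == 0:
        raise ValueError("FOSCTTM is undefined without correspondence")
    D = cdist(emb.x_aligned, emb.y_aligned)
    ii, jj = emb.correspondence[:, 0], emb.correspondence[:, 1]
    ny, nx = D.shape[1], D.shape[0]
    d_true = D[ii, jj]
    # x -> y: among y cells, how many are strictly closer than the match
    closer_xy = (D[ii] < d_true[:, None]).sum(axis=1)  # match never strictly closer
    frac_xy = closer_xy / max(ny - 1, 1)
    closer_yx = (D[:, jj].T < d_true[:, None]).sum(axis=1)
    frac_yx = closer_yx / max(nx - 1, 1)
    return float(np.concatenate([frac_xy, frac_yx]).mean())


def label_transfer_accuracy(
    emb: AlignedEmbeddings,
    labels_src: np.ndarray,
    labels_dst: np.ndarray,
    k: int = 5,
    direction: str = "both",
) -> float:
    """k-NN label transfer accuracy in the aligned space.

    Each destination cell receives the majority label of its ``k``
    nearest source cells; majority ties are broken by the larger summed
    inverse distance (deterministic).  ``direction`` is ``"x_to_y"``
    (x donates labels to y), ``"y_to_x"``, or ``"both"`` (mean of the
    two).
    """
    labels_src = np.asarray(labels_src)
    labels_dst = np.asarray(labels_dst)
    if labels_src.shape[0] != emb.x_aligned.shape[0]:
        raise ValueError("labels_src must have one label per x cell")
    if labels_dst.shape[0] != emb.y_aligned.shape[0]:
        raise ValueError("labels_dst must have one label per y cell")
    if not set(np.unique(labels_src)) & set(np.unique(labels_dst)):
        raise ValueError("label vocabularies are disjoint; accuracy undefined")

    def one_direction(src_emb, src_lab, dst_emb, dst_lab):
        if not 1 <= k < src_emb.shape[0]:
            raise ValueError(f"k={k} must satisfy 1 <= k < n_src={src_emb.shape[0]}")
        D = cdist(dst_emb, src_emb)
        nn = np.argpartition(D, k - 1, axis=1)[:, :k]
        correct = 0
        for r in range(dst_emb.shape[0]):
            votes: dict = {}
            for c in nn[r]:
                lab = src_lab[c]
                w = votes.setdefault(lab, [0, 0.0])
                w[0] += 1
                d = D[r, c]
                w[1] += np.inf if d == 0 else 1.0 / d
            best = max(votes.items(), key=lambda kv: (kv[1][0], kv[1][1]))
            correct += best[0] == dst_lab[r]
        return correct / dst_emb.shape[0]

    if direction == "x_to_y":
        return float(one_direction(emb.x_aligned, labels_src, emb.y_aligned, labels_dst))
    if direction == "y_to_x":
        return float(one_direction(emb.y_aligned, labels_dst, emb.x_aligned, labels_src))
    if direction == "both":
        a = one_direction(emb.x_aligned, labels_src, emb.y_aligned, labels_dst)
        b = one_direction(emb.y_aligned, labels_dst, emb.x_aligned, labels_src)
        return float((a + b) / 2)
    raise ValueError(f"unknown direction {direction!r}")


def barycentric_projection(
    coupling: Coupling | np.ndarray, y_embedding: np.ndarray
) -> np.ndarray:
    """Place x cells in y's space at their coupling-weighted mean partner.

    ``x_aligned[i] = sum_j gamma[i, j] * y[j] / sum_j gamma[i, j]`` — the
    standard bridge from a transport plan to an embedding.
    """
    gamma = coupling.gamma if isinstance(coupling, Coupling) else np.asarray(coupling)
    y_embedding = np.asarray(y_embedding, dtype=float)
    rows = gamma.sum(axis=1, keepdims=True)
    rows[rows == 0] = 1.0
    return (gamma / rows) @ y_embedding


def score_coupling(
    coupling: Coupling | np.ndarray,
    y_embedding: np.ndarray,
    correspondence: np.ndarray | None = None,
    labels_x: np.ndarray | None = None,
    labels_y: np.ndarray | None = None,
    k: int = 5,
) -> dict:
    """FOSCTTM (and LTA when labels are given) of a coupling.

    X cells are barycentrically projected into ``y_embedding`` and scored
    against the known correspondence.
    """
    x_aligned = barycentric_projection(coupling, y_embedding)
    emb = AlignedEmbeddings(x_aligned, y_embedding, correspondence)
    out = {"foscttm": foscttm(emb)}
    if labels_x is not None and labels_y is not None:
        out["lta"] = label_transfer_accuracy(emb, labels_x, labels_y, k=k)
    return out
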