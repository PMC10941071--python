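"""Gradient decomposition of connectivity matrices via Laplacian eigenmaps.

A connectivity matrix is row-thresholded to its strongest positive edges,
converted to a normalized-angle affinity (similarity of connectivity
profiles), and decomposed into the low-frequency eigenvectors of the graph
Laplacian.  Each eigenvector — a "gradient" — assigns every parcel a
position along a continuous axis of connectivity-profile similarity.
Embeddings from different modalities are made comparable by orthogonal
Procrustes alignment, which resolves eigenvector order and sign without
distorting the manifold.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.linalg import orthogonal_procrustes
from scipy.sparse.csgraph import connected_components

from .core import AdjacencyMatrix
from .exceptions import DegenerateInputError, DegenerateParcelError, InvalidDataError


@dataclass
class GradientSet:
    """Parcels x k eigenvector embedding with its spectrum and provenance.

    ``variance_explained`` is the transition-operator eigenvalue share
    (1 - lambda_i) / sum_j (1 - lambda_j) over the retained components:
    nonincreasing, summing to one.  ``rotation`` is the orthogonal matrix
    applied by Procrustes alignment, when any.
    """

    embedding: np.ndarray
    eigenvalues: np.ndarray
    variance_explained: np.ndarray
    modality: str = ""
    aligned_to: str | None = None
    rotation: np.ndarray | None = None

    @property
    def n_parcels(self) -> int:
        return self.embedding.shape[0]

    @property
    def n_components(self) -> int:
        return self.embedding.shape[1]

    def gradient(self, i: int) -> np.ndarray:
        """The i-th gradient (0-based) as a parcels-vector."""
        return self.embedding[:, i]

    def to_tsv(self, path) -> None:
        path = Path(path)
        df = pd.DataFrame(self.embedding,
                          columns=[f"G{i+1}" for i in range(self.n_components)])
        df.insert(0, "parcel_id", np.arange(self.n_parcels))
        df.to_csv(path, sep="\t", index=False, float_format="%.12g")
        meta = {
            "eigenvalues": self.eigenvalues.tolist(),
            "variance_explained": self.variance_explained.tolist(),
            "modality": self.modality,
            "aligned_to": self.aligned_to,
            "rotation": None if self.rotation is None else self.rotation.tolist(),
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(meta, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "GradientSet":
        path = Path(path)
        df = pd.read_csv(path, sep="\t")
        emb = df[[c for c in df.columns if c != "parcel_id"]].to_numpy(dtype=float)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        rot = meta.get("rotation")
        return cls(
            embedding=emb,
            eigenvalues=np.asarray(meta["eigenvalues"], dtype=float),
            variance_explained=np.asarray(meta["variance_explained"], dtype=float),
            modality=meta.get("modality", ""),
            aligned_to=meta.get("aligned_to"),
            rotation=None if rot is None else np.asarray(rot, dtype=float),
        )


def threshold_rows(adj: AdjacencyMatrix | np.ndarray, density: float = 0.10
                   ) -> np.ndarray:
    """Keep, per row, the strongest positive off-diagonal edges.

    Retains the ``ceil(density * (P-1))`` largest strictly-positive entries
    of each row (ties at the cutoff broken toward the lower parcel index);
    everything else, including all negative edges, is set to zero.  The
    result is generally asymmetric — each row is one parcel's trimmed
    connectivity profile.
    """
    if not (0.0 < density <= 1.0):
        raise ValueError("density must be in (0, 1]")
    m = adj.values if isinstance(adj, AdjacencyMatrix) else np.asarray(adj, float)
    P = m.shape[0]
    keep = int(np.ceil(density * (P - 1)))
    out = np.zeros_like(m)
    degenerate = []
    for i in range(P):
        row = m[i].copy()
        row[i] = 0.0
        pos = np.flatnonzero(row > 0.0)
        if len(pos) == 0:
            degenerate.append(i)
            continue
        # sort by descending value, then ascending index (tie-break rule)
        order = pos[np.lexsort((pos, -row[pos]))]
        sel = order[: min(keep, len(order))]
        out[i, sel] = row[sel]
    if degenerate:
        warnings.warn(f"rows with no positive edges kept empty: {degenerate}")
    return out


def normalized_angle(s: np.ndarray) -> np.ndarray:
    """Normalized-angle affinity between row connectivity profiles.

    a(i, j) = 1 - arccos(cos_sim(row_i, row_j)) / pi, in [0, 1] with unit
    diagonal.  Zero rows have no direction and raise
    :class:`DegenerateParcelError`.
    """
    s = np.asarray(s, dtype=float)
    norms = np.linalg.norm(s, axis=1)
    dead = np.flatnonzero(norms == 0.0)
    if len(dead):
        raise DegenerateParcelError(
            f"all-zero rows at parcels: {dead.tolist()}", parcels=dead)
    c = (s @ s.T) / np.outer(norms, norms)
    np.clip(c, -1.0, 1.0, out=c)
    a = 1.0 - np.arccos(c) / np.pi
    a = 0.5 * (a + a.T)
    np.fill_diagonal(a, 1.0)
    return a


def laplacian_embedding(w: np.ndarray, k: int = 10) -> GradientSet:
    """Laplacian-eigenmap embedding of a symmetric affinity matrix.

    Solves the symmetric normalized Laplacian
    ``L = I - D^(-1/2) W D^(-1/2)``, takes the eigenvectors of the k
    smallest nonzero eigenvalues, and back-transforms by ``D^(-1/2)``
    (random-walk convention); the constant eigenvector is discarded.  Each
    column's sign is fixed so its largest-magnitude entry is positive.
    The affinity graph must be connected.
    """
    w = np.asarray(w, dtype=float)
    P = w.shape[0]
    if w.ndim != 2 or w.shape[1] != P:
        raise ValueError("affinity must be square")
    if np.max(np.abs(w - w.T)) > 1e-10:
        raise ValueError("affinity must be symmetric")
    if not (0 < k < P):
        raise ValueError("k must satisfy 0 < k < P")
    off = w.copy()
    np.fill_diagonal(off, 0.0)
    n_comp, comp = connected_components(sparse.csr_matrix(off > 0), directed=False)
    if n_comp > 1:
        sizes = np.bincount(comp)
        raise InvalidDataError(
            f"affinity graph is disconnected: {n_comp} components "
            f"with sizes {sizes.tolist()}")

    d = w.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d)
    lap = -(w * inv_sqrt[:, None]) * inv_sqrt[None, :]
    lap[np.diag_indices(P)] += 1.0
    lap = 0.5 * (lap + lap.T)
    evals, evecs = np.linalg.eigh(lap)
    # index 0 is the trivial (constant after back-transform) eigenvector
    lam = evals[1 : k + 1]
    emb = inv_sqrt[:, None] * evecs[:, 1 : k + 1]

    flip = np.sign(emb[np.argmax(np.abs(emb), axis=0), np.arange(k)])
    flip[flip == 0] = 1.0
    emb = emb * flip[None, :]

    share = 1.0 - lam
    total = share.sum()
    var = share / total if total != 0 else np.full(k, 1.0 / k)
    return GradientSet(embedding=emb, eigenvalues=lam, variance_explained=var)


def variance_profile(g: GradientSet, cumulative_threshold: float | None = None):
    """Variance-explained fractions, and optionally the smallest number of
    gradients whose cumulative fraction exceeds the threshold."""
    frac = np.asarray(g.variance_explained, dtype=float)
    if cumulative_threshold is None:
        return frac
    if not (0.0 < cumulative_threshold < 1.0):
        raise ValueError("cumulative_threshold must be in (0, 1)")
    cum = np.cumsum(frac)
    above = np.flatnonzero(cum > cumulative_threshold)
    k = int(above[0]) + 1 if len(above) else None
    return frac, k


def procrustes_align(source: GradientSet, target: GradientSet,
                     target_id: str = "target") -> GradientSet:
    """Rotate the source embedding onto the target (no scaling/translation).

    The orthogonal matrix R minimizing ||source R - target||_F (closed form
    via SVD of target^T source) resolves eigenvector order and sign between
    modalities while preserving all pairwise distances in embedding space.
    """
    if source.embedding.shape != target.embedding.shape:
        raise ValueError("source and target must share parcel set and k")
    r, _ = orthogonal_procrustes(source.embedding, target.embedding)
    return GradientSet(
        embedding=source.embedding @ r,
        eigenvalues=source.eigenvalues.copy(),
        variance_explained=source.variance_explained.copy(),
        modality=source.modality,
        aligned_to=target_id,
        rotation=r,
    )


def adjacency_gradients(adj: AdjacencyMatrix, density: float = 0.10,
                        k: int = 10) -> GradientSet:
    """threshold_rows -> normalized_angle -> laplacian_embedding in one call."""
    gs = laplacian_embedding(normalized_angle(threshold_rows(adj, density)), k)
    gs.modality = adj.modality
    return gs


def subject_gradients(subject_graph: AdjacencyMatrix, group_template: GradientSet,
                      density: float = 0.10, k: int = 10) -> GradientSet:
    """Individual embedding aligned to the group template by Procrustes."""
    gs = adjacency_gradients(subject_graph, density=density, k=k)
    return procrustes_align(gs, group_template, target_id="group")


def spatial_corr(x, y, method: str = "spearman") -> float:
    """Spatial correlation between two parcel maps (ties: average ranks)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("x and y must be equal-length vectors of length >= 3")
    if x.std() == 0.0 or y.std() == 0.0:
        raise DegenerateInputError("zero-variance input map")
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    raise ValueError(f"unknown method: {method}")


def corr_difference_test(r1: float, r2: float, n1: int, n2: int | None = None,
                         dependent: bool = False, overlap_r: float | None = None):
    """Test the difference between two correlation coefficients.

    Independent samples: two-sample Fisher-z test,
    ``Z = (z1 - z2) / sqrt(1/(n1-3) + 1/(n2-3))``.
    Dependent correlations sharing one variable (r1 = r(x, y1),
    r2 = r(x, y2) in one sample of size n1): Steiger's Z using the
    correlation ``overlap_r`` between y1 and y2.

    Returns ``(Z, p)`` with a two-tailed normal p-value.
    """
    for r in (r1, r2):
        if not np.isfinite(r) or abs(r) >= 1.0:
            raise ValueError("correlations must satisfy |r| < 1")
    z1, z2 = np.arctanh(r1), np.arctanh(r2)
    if not dependent:
        if n2 is None:
            raise ValueError("independent test needs both sample sizes")
        if n1 <= 3 or n2 <= 3:
            raise ValueError("sample sizes must exceed 3")
        z = (z1 - z2) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    else:
        if overlap_r is None:
            raise ValueError("dependent test requires overlap_r "
                             "(correlation between the two non-shared variables)")
        if n1 <= 3:
            raise ValueError("sample size must exceed 3")
        r23 = overlap_r
        rbar = 0.5 * (r1 + r2)
        psi = r23 * (1.0 - 2.0 * rbar**2) - 0.5 * rbar**2 * (
            1.0 - 2.0 * rbar**2 - r23**2)
        sbar = psi / (1.0 - rbar**2) ** 2
        z = (z1 - z2) * np.sqrt((n1 - 3) / (2.0 - 2.0 * sbar))
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)
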