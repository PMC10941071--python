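"""Network- and edge-level statistics on covariance and connectivity graphs.

Covers the system-level questions downstream of the gradient analyses:
where the seven canonical networks sit along a gradient axis (centers of
mass), whether subjects with a more hierarchical receptor distribution show
shifted network positions (nuisance-adjusted regressions with FDR), whether
covariance is organized by network boundaries (within/between summaries,
nodal density), and whether edgewise receptor covariance tracks functional
connectivity once spatial proximity — and optionally the similarity of
other receptor systems — is controlled (partial Spearman correlations,
threshold matching, Sobel mediation with commonality analysis).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import NETWORKS, AdjacencyMatrix, ParcelAtlas, symmetrize_zero_diag
from .exceptions import DegenerateInputError, InvalidDataError


@dataclass
class EdgeMask:
    """Within- vs between-network partition of the strictly-upper-triangle."""

    iu: tuple                 # (rows, cols) upper-triangle indices
    within: np.ndarray        # bool per edge: endpoints share a network
    pair_labels: np.ndarray   # "NetA|NetB" per edge (sorted pair)

    @property
    def between(self) -> np.ndarray:
        return ~self.within

    @property
    def n_edges(self) -> int:
        return self.within.size


def edge_masks(labels) -> EdgeMask:
    """Partition all parcel-pair edges by shared network membership."""
    labels = np.asarray(labels, dtype=object)
    unknown = set(np.unique(labels)) - set(NETWORKS)
    if unknown:
        raise InvalidDataError(f"unknown network labels: {sorted(unknown)}")
    P = len(labels)
    iu = np.triu_indices(P, k=1)
    li, lj = labels[iu[0]], labels[iu[1]]
    within = li == lj
    pairs = np.array(["|".join(sorted((a, b))) for a, b in zip(li, lj)],
                     dtype=object)
    return EdgeMask(iu=iu, within=within, pair_labels=pairs)


def network_center_of_mass(gradient: np.ndarray, labels) -> pd.Series:
    """Per-network median of the gradient values of its parcels."""
    gradient = np.asarray(gradient, dtype=float)
    labels = np.asarray(labels, dtype=object)
    out = {}
    for net in NETWORKS:
        sel = labels == net
        if not sel.any():
            raise InvalidDataError(f"network {net} has no parcels")
        out[net] = float(np.median(gradient[sel]))
    return pd.Series(out, name="center_of_mass")


def hierarchy_score(subject_maps: np.ndarray, reference_gradient: np.ndarray
                    ) -> np.ndarray:
    """Pearson correlation of each subject's parcel map with a reference
    gradient: one scalar per subject quantifying how strongly that
    subject's map follows the reference axis."""
    maps = np.atleast_2d(np.asarray(subject_maps, dtype=float))
    ref = np.asarray(reference_gradient, dtype=float)
    if maps.shape[1] != len(ref):
        raise ValueError("maps and reference must share the parcel set")
    if ref.std() == 0.0 or np.any(maps.std(axis=1) == 0.0):
        raise DegenerateInputError("zero-variance map or reference")
    mc = maps - maps.mean(axis=1, keepdims=True)
    rc = ref - ref.mean()
    scores = (mc @ rc) / (np.linalg.norm(mc, axis=1) * np.linalg.norm(rc))
    return scores if subject_maps.ndim == 2 else float(scores[0])


def network_position_regression(com: pd.DataFrame, scores: np.ndarray,
                                covariates: pd.DataFrame,
                                fdr_alpha: float = 0.05) -> pd.DataFrame:
    """Regress each network's center of mass on the hierarchy score.

    Per network, OLS of the subject-wise center of mass on
    [1, score, age, sex, FD]; the score coefficient's T and p are reported
    and Benjamini-Hochberg adjusted across the seven networks.
    """
    scores = np.asarray(scores, dtype=float)
    n = len(scores)
    if n <= 10:
        raise ValueError("need more than 10 subjects")
    cols = [np.ones(n), scores]
    names = ["intercept", "score"]
    for c in ("age", "sex", "fd"):
        if c in covariates.columns:
            cols.append(covariates[c].to_numpy(dtype=float))
            names.append(c)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise InvalidDataError("rank-deficient design in network regression")

    rows = []
    dof = n - X.shape[1]
    xtx_inv = np.linalg.inv(X.T @ X)
    for net in NETWORKS:
        y = com[net].to_numpy(dtype=float)
        beta = xtx_inv @ (X.T @ y)
        resid = y - X @ beta
        sigma2 = float(resid @ resid) / dof
        se = np.sqrt(sigma2 * np.diag(xtx_inv))
        t = beta[1] / se[1]
        p = 2.0 * stats.t.sf(abs(t), dof)
        rows.append({"network": net, "beta": float(beta[1]), "T": float(t),
                     "p": float(p)})
    res = pd.DataFrame(rows)
    reject, p_adj, *_ = multipletests(res["p"], alpha=fdr_alpha, method="fdr_bh")
    res["p_fdr"] = p_adj
    res["significant"] = reject
    return res


def within_between_summary(adj: AdjacencyMatrix | np.ndarray, masks: EdgeMask):
    """Mean +/- SD of within- and between-network edges and their difference."""
    edges = (adj.upper_edges() if isinstance(adj, AdjacencyMatrix)
             else np.asarray(adj)[masks.iu])
    if edges.size != masks.n_edges:
        raise ValueError("mask does not match the adjacency")
    if not masks.within.any() or not masks.between.any():
        raise InvalidDataError("empty within or between mask")
    w, b = edges[masks.within], edges[masks.between]
    return {
        "within_mean": float(w.mean()), "within_sd": float(w.std(ddof=1)),
        "between_mean": float(b.mean()), "between_sd": float(b.std(ddof=1)),
        "difference": float(w.mean() - b.mean()),
    }


def within_minus_between(labels):
    """Statistic factory for :func:`molgrad.spin_perm.spin_matrix_test`:
    mean within-network minus mean between-network edge weight."""
    masks = edge_masks(labels)

    def stat(edge_matrix: np.ndarray) -> float:
        edges = edge_matrix[masks.iu]
        return float(np.nanmean(edges[masks.within])
                     - np.nanmean(edges[masks.between]))

    return stat


def nodal_density(adj: AdjacencyMatrix | np.ndarray, labels):
    """Per-parcel mean edge weight, with a one-way ANOVA across networks.

    Returns ``(density, F, p)`` where density[p] is the mean of parcel p's
    off-diagonal edges.
    """
    m = adj.values if isinstance(adj, AdjacencyMatrix) else np.asarray(adj, float)
    P = m.shape[0]
    density = (m.sum(axis=1) - np.diag(m)) / (P - 1)
    labels = np.asarray(labels, dtype=object)
    groups = [density[labels == net] for net in NETWORKS if (labels == net).any()]
    with np.errstate(invalid="ignore", divide="ignore"):
        f, p = stats.f_oneway(*groups)
    if not np.isfinite(f):
        means = np.array([g.mean() for g in groups])
        if np.ptp(means) < 1e-12:   # identical densities everywhere
            f, p = 0.0, 1.0
        else:                       # zero within-group variance, real contrast
            f, p = np.inf, 0.0
    return density, float(f), float(p)


def euclidean_distances(atlas: ParcelAtlas) -> np.ndarray:
    """Pairwise Euclidean distances (mm) between volumetric centroids."""
    xyz = atlas.centroid_xyz
    diff = xyz[:, None, :] - xyz[None, :, :]
    return np.sqrt(np.sum(diff**2, axis=-1))


def _residual(v: np.ndarray, X: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(X, v, rcond=None)
    return v - X @ beta


def partial_spearman_edges(x_edges, y_edges, covariate_edge_sets,
                           spins=None, x_matrix=None, mask: EdgeMask | None = None,
                           edge_subset=None, tail: str = "two"):
    """Partial Spearman correlation between two edge vectors.

    All variables — the two edge vectors and every covariate edge set
    (typically Euclidean distance and its square, optionally receptor
    similarity) — are average-rank transformed; x and y ranks are then
    OLS-residualized on the centered covariate ranks and the Pearson
    correlation of the residuals is returned (rank-then-residualize
    convention; equivalently, Spearman partial correlation).

    When ``spins``, ``x_matrix`` (the full P x P matrix the x edges came
    from), ``mask`` (the :class:`EdgeMask` of the atlas) and ``edge_subset``
    (boolean over upper-triangle edges selecting the analyzed set, e.g.
    ``mask.within``) are supplied, a spin p-value is computed by reindexing
    ``x_matrix`` under each rotation, re-extracting the subset edges and
    recomputing the partial correlation (y and the covariates stay tied to
    the fixed parcel geometry).  Returns ``rho`` or ``(rho, p)``.
    """
    x = np.asarray(x_edges, dtype=float)
    y = np.asarray(y_edges, dtype=float)
    if x.shape != y.shape:
        raise ValueError("edge vectors must share the edge mask")
    covs = []
    for c in covariate_edge_sets:
        c = np.asarray(c, dtype=float)
        if c.std() == 0.0:
            warnings.warn("constant covariate edge set dropped")
            continue
        rc = stats.rankdata(c)
        covs.append(rc - rc.mean())
    X = np.column_stack([np.ones_like(x)] + covs)
    ry = _residual(stats.rankdata(y), X)
    # a residual that is float noise (variable in the covariate span) has
    # no direction: treat it as exactly zero
    tiny = 1e-9 * len(x) ** 1.5

    def _partial(xv: np.ndarray) -> float:
        rx = _residual(stats.rankdata(xv), X)
        nx, ny = np.linalg.norm(rx), np.linalg.norm(ry)
        if nx < tiny or ny < tiny:
            return 0.0
        return float((rx @ ry) / (nx * ny))

    rho = _partial(x)
    if spins is None:
        return rho
    if x_matrix is None or mask is None:
        raise ValueError("spin p-value needs x_matrix and mask")
    if edge_subset is None:
        edge_subset = np.ones(mask.n_edges, dtype=bool)
    sub = np.asarray(x_matrix, dtype=float).copy()
    np.fill_diagonal(sub, 1.0)
    nulls = np.empty(spins.n_perm)
    for i in range(spins.n_perm):
        a = spins.assignments[i]
        perm = sub[np.ix_(a, a)]
        nulls[i] = _partial(perm[mask.iu][edge_subset])
    from .spin_perm import spin_pvalue
    return rho, spin_pvalue(rho, nulls, tail=tail)


def receptor_similarity(receptor_maps: np.ndarray, weights=None) -> AdjacencyMatrix:
    """Receptor-similarity matrix: weighted Pearson correlation between the
    M-receptor profiles of every parcel pair.

    Maps (columns) are z-scored across parcels; zero-variance maps are
    dropped with a warning.  Excluding the receptor under study from the
    panel is the caller's responsibility.
    """
    maps = np.asarray(receptor_maps, dtype=float)
    P, M = maps.shape
    if M < 2:
        raise ValueError("need at least two receptor maps")
    sd = maps.std(axis=0)
    keep = sd > 0.0
    if not keep.all():
        warnings.warn(f"dropping zero-variance receptor maps: "
                      f"{np.flatnonzero(~keep).tolist()}")
    maps = maps[:, keep]
    maps = (maps - maps.mean(axis=0)) / maps.std(axis=0)
    w = np.ones(maps.shape[1]) if weights is None else np.asarray(
        weights, dtype=float)[keep]
    w = w / w.sum()

    mean_w = maps @ w
    centered = maps - mean_w[:, None]
    cov = (centered * w[None, :]) @ centered.T
    var = np.diag(cov).copy()
    edges = cov / np.sqrt(np.outer(var, var))
    return AdjacencyMatrix(symmetrize_zero_diag(edges), modality="receptor_sim",
                           confound_model="zscore", scale="r")


def match_threshold(between_edges: np.ndarray, target_mean: float):
    """Remove weakest edges until the retained mean first reaches the target.

    Returns ``(retained_mask, fraction_removed)`` over the input order.
    No-op (with a warning) when the mean already meets the target.
    """
    edges = np.asarray(between_edges, dtype=float)
    n = edges.size
    if edges.mean() >= target_mean:
        if edges.mean() > target_mean:
            warnings.warn("edge mean already exceeds target; nothing removed")
        return np.ones(n, dtype=bool), 0.0
    order = np.argsort(edges, kind="stable")
    sorted_edges = edges[order]
    totals = sorted_edges.sum() - np.concatenate([[0.0], np.cumsum(sorted_edges)[:-1]])
    counts = n - np.arange(n)
    means = totals / counts
    ok = np.flatnonzero(means >= target_mean)
    if len(ok) == 0 or counts[ok[0]] == 0:
        raise InvalidDataError("target mean unreachable before removing all edges")
    n_removed = int(ok[0])
    mask = np.ones(n, dtype=bool)
    mask[order[:n_removed]] = False
    return mask, n_removed / n


@dataclass
class MediationResult:
    """Sobel mediation with commonality decomposition of the outcome R^2."""

    a: float                 # predictor -> mediator
    b: float                 # mediator -> outcome, adjusted for predictor
    direct: float            # predictor -> outcome, adjusted for mediator
    sobel_z: float
    sobel_p: float
    r2_full: float
    r2_adj: float
    unique_x: float
    unique_m: float
    shared: float


def _ols_stats(y: np.ndarray, X: np.ndarray):
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = len(y) - X.shape[1]
    sigma2 = float(resid @ resid) / dof
    se = np.sqrt(sigma2 * np.diag(np.linalg.inv(X.T @ X)))
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(resid @ resid) / sst if sst > 0 else 0.0
    return beta, se, r2, dof


def mediation_sobel(x_edges, m_edges, y_edges, covariates=None) -> MediationResult:
    """Does the mediator m carry the association between x and y?

    Path a from ``m ~ x`` and path b plus the direct effect from
    ``y ~ x + m`` (all models residualized on covariates first, when
    given).  Sobel ``z = a*b / sqrt(b^2 SEa^2 + a^2 SEb^2)`` with a
    two-tailed normal p.  The outcome R^2 of the full model is decomposed
    into unique(x), unique(m) and their shared part (commonality analysis);
    the three sum to the full-model R^2 by construction.
    """
    x = np.asarray(x_edges, dtype=float).copy()
    m = np.asarray(m_edges, dtype=float).copy()
    y = np.asarray(y_edges, dtype=float).copy()
    n = len(y)
    if covariates is not None and len(covariates):
        C = np.column_stack([np.ones(n)] +
                            [np.asarray(c, float) - np.mean(c) for c in covariates])
        x, m, y = _residual(x, C), _residual(m, C), _residual(y, C)
    if abs(np.corrcoef(x, m)[0, 1]) > 0.999:
        raise InvalidDataError("predictor and mediator are collinear")

    ones = np.ones(n)
    Xa = np.column_stack([ones, x])
    beta_a, se_a, _, _ = _ols_stats(m, Xa)
    Xf = np.column_stack([ones, x, m])
    beta_f, se_f, r2_full, dof = _ols_stats(y, Xf)
    a, sea = beta_a[1], se_a[1]
    b, seb = beta_f[2], se_f[2]
    direct = beta_f[1]

    denom = np.sqrt(b**2 * sea**2 + a**2 * seb**2)
    z = a * b / denom if denom > 0 else 0.0
    p = 2.0 * stats.norm.sf(abs(z))

    _, _, r2_m, _ = _ols_stats(y, np.column_stack([ones, m]))
    _, _, r2_x, _ = _ols_stats(y, np.column_stack([ones, x]))
    unique_x = r2_full - r2_m
    unique_m = r2_full - r2_x
    shared = r2_full - unique_x - unique_m
    k = Xf.shape[1] - 1
    r2_adj = 1.0 - (1.0 - r2_full) * (n - 1) / (n - k - 1)
    return MediationResult(float(a), float(b), float(direct), float(z), float(p),
                           float(r2_full), float(r2_adj), float(unique_x),
                           float(unique_m), float(shared))


def bh_fdr(pvalues, alpha: float = 0.05):
    """Benjamini-Hochberg adjusted p-values and rejections."""
    reject, p_adj, *_ = multipletests(np.asarray(pvalues, float), alpha=alpha,
                                      method="fdr_bh")
    return p_adj, reject
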