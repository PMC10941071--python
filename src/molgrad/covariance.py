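"""Inter-regional correlation analysis (IRCA) of parcel feature matrices.

Correlating a regional measure (receptor binding potential, cortical
thickness) across subjects yields a parcels x parcels covariance network.
Before correlating, univariate outliers are fenced per age-decade x sex
stratum and imputed from age-matched peers, and nuisance variation (linear
and quadratic age, sex) is removed by per-parcel least squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import AdjacencyMatrix, ParcelFeatureMatrix, symmetrize_zero_diag
from .exceptions import DegenerateParcelError, InvalidDataError

_DECADES = np.arange(2, 8)  # bins [20,30) .. [70,80]


def _decade_of(age: np.ndarray) -> np.ndarray:
    dec = np.floor(np.asarray(age, dtype=float) / 10.0).astype(int)
    return np.clip(dec, _DECADES[0], _DECADES[-1])  # 80 joins [70,80]


def _stratify(age: np.ndarray, sex: np.ndarray, min_size: int = 4) -> np.ndarray:
    """Integer stratum label per subject: age decade x sex, with decades of
    fewer than ``min_size`` subjects merged into the neighboring decade of
    the same sex (fences are unstable below n=4)."""
    dec = _decade_of(age)
    sex = np.asarray(sex)
    labels = np.full(len(dec), -1, dtype=int)
    next_id = 0
    for sx in np.unique(sex):
        sel = sex == sx
        present = sorted(set(dec[sel]))
        groups = [[d] for d in present]

        def count(grp):
            return int(np.sum(sel & np.isin(dec, grp)))

        while len(groups) > 1 and min(count(g) for g in groups) < min_size:
            i = int(np.argmin([count(g) for g in groups]))
            if i == 0:
                j = 1
            elif i == len(groups) - 1:
                j = i - 1
            else:
                j = i - 1 if count(groups[i - 1]) <= count(groups[i + 1]) else i + 1
            a, b = sorted((i, j))
            groups[a] = groups[a] + groups[b]
            del groups[b]
        for g in groups:
            if count(g) < min_size:
                raise InvalidDataError(
                    f"stratum for sex={sx} has fewer than {min_size} subjects "
                    "even after merging all decades"
                )
            labels[sel & np.isin(dec, g)] = next_id
            next_id += 1
    return labels


def detect_outliers(fm: ParcelFeatureMatrix) -> np.ndarray:
    """Boolean subjects x parcels mask of box-plot (1.5*IQR) outliers.

    Fences are computed per parcel within each age-decade x sex stratum,
    quartiles by linear interpolation (type 7), strict inequalities:
    a cell is flagged iff value < Q1 - 1.5*IQR or value > Q3 + 1.5*IQR.
    """
    cov = fm.covariates
    strata = _stratify(cov["age"].to_numpy(), cov["sex"].to_numpy())
    mask = np.zeros_like(fm.values, dtype=bool)
    for s in np.unique(strata):
        rows = np.flatnonzero(strata == s)
        vals = fm.values[rows, :]
        q1, q3 = np.percentile(vals, [25, 75], axis=0)  # type-7 default
        iqr = q3 - q1
        lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        mask[rows, :] = (vals < lo[None, :]) | (vals > hi[None, :])
    return mask


def impute_outliers(fm: ParcelFeatureMatrix, mask: np.ndarray) -> ParcelFeatureMatrix:
    """Replace flagged cells by the age-decade mean of non-flagged subjects
    at the same parcel (parcel identity already fixes the hemisphere; sexes
    pooled within decade).  Falls back to the parcel's all-decade
    non-flagged mean (with a warning) when a whole decade is flagged.
    """
    if mask.shape != fm.values.shape:
        raise ValueError("mask shape must match the feature matrix")
    out = fm.values.copy()
    dec = _decade_of(fm.covariates["age"].to_numpy())
    for r, c in zip(*np.nonzero(mask)):
        peers = np.flatnonzero((dec == dec[r]) & ~mask[:, c])
        if len(peers) == 0:
            peers = np.flatnonzero(~mask[:, c])
            warnings.warn(
                f"all subjects in decade {dec[r]*10}s flagged at parcel {c}; "
                "imputing from all decades"
            )
        if len(peers) == 0:
            peers = np.arange(fm.n_subjects)  # pathological: everything flagged
        out[r, c] = fm.values[peers, c].mean()
    return fm.copy_with(out)


_TERMS = ("age_linear", "age_quadratic", "sex")


def _design(fm: ParcelFeatureMatrix, terms) -> tuple[np.ndarray, list]:
    cov = fm.covariates
    age_c = cov["age"].to_numpy(dtype=float)
    age_c = age_c - age_c.mean()
    cols, names = [np.ones(fm.n_subjects)], ["intercept"]
    if "age_linear" in terms:
        cols.append(age_c)
        names.append("age_linear")
    if "age_quadratic" in terms:
        cols.append(age_c**2)
        names.append("age_quadratic")
    if "sex" in terms:
        cols.append(cov["sex"].to_numpy(dtype=float))
        names.append("sex")
    if "fd" in terms:
        cols.append(cov["fd"].to_numpy(dtype=float))
        names.append("fd")
    return np.column_stack(cols), names


def residualize(fm: ParcelFeatureMatrix, terms=_TERMS) -> ParcelFeatureMatrix:
    """Per-parcel OLS residuals of values on [1, age_c, age_c^2, sex].

    Age is centered (years) before the polynomial is formed.  Residuals at
    every parcel sum to zero and are orthogonal to each design column.
    Raises :class:`InvalidDataError` naming the collinear term when the
    design is rank deficient (e.g. a single-sex cohort).
    """
    X, names = _design(fm, terms)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        for j in range(1, X.shape[1]):
            sub = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(sub) == np.linalg.matrix_rank(X):
                raise InvalidDataError(f"design is rank deficient; term "
                                       f"'{names[j]}' is collinear")
        raise InvalidDataError("design is rank deficient")
    beta, *_ = np.linalg.lstsq(X, fm.values, rcond=None)
    return fm.copy_with(fm.values - X @ beta)


def irca_matrix(fm: ParcelFeatureMatrix, residualize_first: bool = True,
                terms=_TERMS) -> AdjacencyMatrix:
    """Cross-subject Pearson correlation between every pair of parcels.

    ``residualize_first=True`` correlates confound-residualized values
    (the age-regressed matrix); ``False`` correlates per-parcel z-scored
    values (the age-preserved control, identical to plain correlation).
    """
    if fm.n_subjects < 3:
        raise ValueError("need at least 3 subjects for a correlation matrix")
    values = residualize(fm, terms).values if residualize_first else fm.values
    sd = values.std(axis=0)
    # constant parcels leave O(eps) float residue in the std
    dead = np.flatnonzero(sd <= 1e-12 * (1.0 + np.abs(values).mean(axis=0)))
    if len(dead):
        raise DegenerateParcelError(
            f"zero-variance parcels: {dead.tolist()}", parcels=dead)
    edges = np.corrcoef(values.T)
    model = "+".join(t for t in terms) if residualize_first else "zscore"
    return AdjacencyMatrix(symmetrize_zero_diag(edges), modality=fm.modality,
                           confound_model=model, scale="r")


@dataclass(frozen=True)
class MatrixComparison:
    """Edgewise agreement of two adjacency matrices."""

    spearman_rho: float
    dissimilarity_variance_fraction: float


def compare_matrices(a: AdjacencyMatrix, b: AdjacencyMatrix) -> MatrixComparison:
    """Spearman rank correlation over upper-triangle edges, and the share of
    B's edgewise variance not explained by a linear fit on A's edges
    (1 - R^2 of the edgewise least-squares regression)."""
    if a.n_parcels != b.n_parcels:
        raise ValueError("matrices must share the parcel set")
    x, y = a.upper_edges(), b.upper_edges()
    rho = stats.spearmanr(x, y).statistic
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sst = np.sum((y - y.mean()) ** 2)
    frac = 0.0 if sst == 0.0 else float(np.sum(resid**2) / sst)
    return MatrixComparison(float(rho), frac)
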