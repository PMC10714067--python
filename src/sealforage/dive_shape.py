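"""Functional PCA of normalized dive profiles and model-based clustering.

Each dive profile is centered and reduced on depth and time: time is
rescaled to [0, 1] and resampled onto a common grid (101 points), depth is
z-scored within the dive, so clustering sees dive *shape* rather than
magnitude or duration.  Curves are smoothed on a cubic B-spline basis
(15 functions by default) and decomposed by functional PCA under the L2
inner product; the leading component scores are clustered with Gaussian
mixtures over several covariance families, the number of components and
family selected by BIC.  A dive is assigned to its maximum-posterior
cluster only when that posterior reaches the assignment threshold (0.8),
otherwise it stays unclassified.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from sklearn.mixture import GaussianMixture

__all__ = [
    "DiveCurve",
    "FPCAModel",
    "ClusterModel",
    "normalize_dive",
    "denormalize_curve",
    "fit_fpca",
    "fit_cluster_model",
    "mixture_posteriors",
    "assign_with_threshold",
    "summarize_clusters",
]

N_GRID = 101
N_BASIS = 15


@dataclass
class DiveCurve:
    """A dive profile normalized to the unit square (time in [0,1], depth
    z-scored within the dive)."""

    dive_id: int
    values: np.ndarray = field(repr=False)  # (F,)
    grid: np.ndarray = field(repr=False)  # (F,) uniform on [0, 1]
    duration_s: float = np.nan
    depth_mean: float = np.nan
    depth_sd: float = np.nan
    individual: str = ""


def normalize_dive(
    profile: np.ndarray,
    duration_s: float | None = None,
    n_points: int = N_GRID,
    dive_id: int = -1,
    individual: str = "",
) -> DiveCurve:
    """Center and reduce a dive profile on depth and time.

    Time is rescaled to [0, 1] and the profile linearly interpolated onto
    ``n_points`` uniform points; depth is z-scored with the dive's own mean
    and standard deviation.  Raises for profiles with fewer than 4 samples
    or constant depth.
    """
    p = np.asarray(profile, dtype=float)
    if p.size < 4:
        raise ValueError("profile must have at least 4 samples")
    mu, sd = float(p.mean()), float(p.std(ddof=0))
    if sd == 0:
        raise ValueError("constant-depth profile cannot be normalized")
    grid = np.linspace(0.0, 1.0, n_points)
    u = np.linspace(0.0, 1.0, p.size)
    vals = np.interp(grid, u, (p - mu) / sd)
    return DiveCurve(dive_id=dive_id, values=vals, grid=grid,
                     duration_s=float(duration_s) if duration_s else np.nan,
                     depth_mean=mu, depth_sd=sd, individual=individual)


def denormalize_curve(curve: DiveCurve, n_samples: int) -> np.ndarray:
    """Invert :func:`normalize_dive` back to depth samples (m) on the
    original sampling grid (up to interpolation error)."""
    u = np.linspace(0.0, 1.0, n_samples)
    return np.interp(u, curve.grid, curve.values) * curve.depth_sd + curve.depth_mean


# ---------------------------------------------------------------------------
# functional PCA on a B-spline basis


def _bspline_design(u: np.ndarray, n_basis: int) -> tuple[np.ndarray, np.ndarray]:
    """Design matrix of a cubic B-spline basis with ``n_basis`` functions on
    [0, 1] (uniform interior knots)."""
    k = 3
    n_interior = n_basis - (k + 1)
    if n_interior < 0:
        raise ValueError("n_basis must be at least 4 for cubic splines")
    interior = np.linspace(0, 1, n_interior + 2)[1:-1]
    knots = np.concatenate([[0.0] * (k + 1), interior, [1.0] * (k + 1)])
    design = BSpline.design_matrix(u, knots, k, extrapolate=False).toarray()
    return design, knots


@dataclass
class FPCAModel:
    """Functional PCA of dive curves on a B-spline basis."""

    grid: np.ndarray = field(repr=False)
    knots: np.ndarray = field(repr=False)
    mean_coef: np.ndarray = field(repr=False)
    eigen_coefs: np.ndarray = field(repr=False)  # (n_basis, n_components)
    eigenvalues: np.ndarray = field(repr=False)
    var_fractions: np.ndarray = field(repr=False)  # kept components
    var_fractions_all: np.ndarray = field(repr=False)
    scores: np.ndarray = field(repr=False)  # (n_curves, n_components)
    gram: np.ndarray = field(repr=False)
    n_basis: int = N_BASIS
    n_components: int = 3

    def eigenfunctions(self, u: Optional[np.ndarray] = None) -> np.ndarray:
        """Eigenfunction values, shape (len(u), n_components)."""
        u = self.grid if u is None else np.asarray(u, float)
        design, _ = _bspline_design(u, self.n_basis)
        return design @ self.eigen_coefs

    def mean_curve(self, u: Optional[np.ndarray] = None) -> np.ndarray:
        u = self.grid if u is None else np.asarray(u, float)
        design, _ = _bspline_design(u, self.n_basis)
        return design @ self.mean_coef

    def reconstruct(self, scores: np.ndarray, u: Optional[np.ndarray] = None) -> np.ndarray:
        """Rebuild curves from kept component scores plus the mean curve."""
        return self.mean_curve(u) + self.eigenfunctions(u) @ np.atleast_2d(scores).T


def fit_fpca(
    curves: Sequence[DiveCurve] | np.ndarray,
    n_basis: int = N_BASIS,
    n_components: int = 3,
) -> FPCAModel:
    """Fit functional PCA to normalized dive curves.

    Curves are projected onto a cubic B-spline basis by least squares; the
    eigenproblem of the coefficient covariance under the basis Gram matrix
    yields orthonormal eigenfunctions (L2 inner product), component scores
    and explained-variance fractions ordered non-increasingly.
    """
    if len(curves) and isinstance(curves[0], DiveCurve):
        grid = curves[0].grid
        X = np.vstack([c.values for c in curves])
    else:
        X = np.asarray(curves, dtype=float)
        grid = np.linspace(0.0, 1.0, X.shape[1])
    n, F = X.shape
    if n < n_components + 1:
        raise ValueError("need at least n_components + 1 curves")

    design, knots = _bspline_design(grid, n_basis)
    # least-squares basis coefficients per curve
    gram_d = design.T @ design
    coefs = np.linalg.solve(gram_d, design.T @ X.T).T  # (n, n_basis)

    # Gram matrix of the basis under the L2 inner product on [0, 1]
    u_fine = np.linspace(0.0, 1.0, 1001)
    design_fine, _ = _bspline_design(u_fine, n_basis)
    w = np.full(u_fine.size, u_fine[1] - u_fine[0])
    w[0] *= 0.5
    w[-1] *= 0.5
    W = design_fine.T @ (w[:, None] * design_fine)

    mean_coef = coefs.mean(axis=0)
    centered = coefs - mean_coef
    cov = centered.T @ centered / (n - 1)

    # symmetric eigenproblem: W^(1/2) K W^(1/2)
    lam_w, U_w = np.linalg.eigh(W)
    sqrt_w = U_w @ np.diag(np.sqrt(np.clip(lam_w, 1e-12, None))) @ U_w.T
    inv_sqrt_w = U_w @ np.diag(1.0 / np.sqrt(np.clip(lam_w, 1e-12, None))) @ U_w.T
    M = sqrt_w @ cov @ sqrt_w
    evals, evecs = np.linalg.eigh(M)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]

    fractions_all = evals / evals.sum() if evals.sum() > 0 else evals
    eigen_coefs = inv_sqrt_w @ evecs[:, :n_components]
    scores = centered @ W @ eigen_coefs

    return FPCAModel(
        grid=grid, knots=knots, mean_coef=mean_coef, eigen_coefs=eigen_coefs,
        eigenvalues=evals[:n_components], var_fractions=fractions_all[:n_components],
        var_fractions_all=fractions_all, scores=scores, gram=W,
        n_basis=n_basis, n_components=n_components,
    )


# ---------------------------------------------------------------------------
# model-based clustering of fPCA scores

COVARIANCE_FAMILIES = ("spherical", "tied", "diag", "full")


@dataclass
class ClusterModel:
    """Gaussian-mixture clustering of score vectors with threshold-gated
    assignment (unclassified dives get label -1)."""

    n_components: int
    covariance_type: str
    weights: np.ndarray = field(repr=False)
    means: np.ndarray = field(repr=False)
    covariances: np.ndarray = field(repr=False)  # (K, d, d), expanded
    posteriors: np.ndarray = field(repr=False)  # (n, K)
    threshold: float = 0.8
    selection: pd.DataFrame = field(default=None, repr=False)

    @property
    def assignments(self) -> np.ndarray:
        return assign_with_threshold(self.posteriors, self.threshold)

    def posteriors_for(self, x: np.ndarray) -> np.ndarray:
        return mixture_posteriors(x, self.weights, self.means, self.covariances)


def _expand_covariances(gmm: GaussianMixture) -> np.ndarray:
    K, d = gmm.means_.shape
    ct = gmm.covariance_type
    if ct == "full":
        return gmm.covariances_
    if ct == "tied":
        return np.repeat(gmm.covariances_[None], K, axis=0)
    if ct == "diag":
        return np.stack([np.diag(c) for c in gmm.covariances_])
    return np.stack([np.eye(d) * c for c in gmm.covariances_])  # spherical


def mixture_posteriors(x, weights, means, covariances) -> np.ndarray:
    """Bayes responsibilities of a Gaussian mixture with full covariances:
    ``p(k|x) = w_k N(x; mu_k, S_k) / sum_j w_j N(x; mu_j, S_j)``."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != np.shape(means)[1]:
        x = x.T
    K = len(weights)
    log_p = np.empty((x.shape[0], K))
    for k in range(K):
        d = x.shape[1]
        cov = np.asarray(covariances[k], dtype=float)
        diff = x - np.asarray(means[k], dtype=float)
        sign, logdet = np.linalg.slogdet(cov)
        sol = np.linalg.solve(cov, diff.T).T
        maha = np.einsum("ij,ij->i", diff, sol)
        log_p[:, k] = np.log(weights[k]) - 0.5 * (d * np.log(2 * np.pi) + logdet + maha)
    log_p -= log_p.max(axis=1, keepdims=True)
    p = np.exp(log_p)
    return p / p.sum(axis=1, keepdims=True)


def fit_cluster_model(
    scores: np.ndarray,
    k_range: Sequence[int] = range(1, 10),
    covariance_families: Sequence[str] = COVARIANCE_FAMILIES,
    threshold: float = 0.8,
    n_init: int = 5,
    random_state: int = 0,
) -> ClusterModel:
    """Fit Gaussian mixtures for every (K, covariance family) pair with
    EM restarts and select the model with the lowest BIC.

    The selection trace (every fitted candidate and its BIC) is kept on the
    returned model.  Degenerate fits are skipped.
    """
    X = np.asarray(scores, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] < 2 * max(k_range):
        raise ValueError("need at least 2 * max(K) score vectors")

    best = None
    trace = []
    for ct in covariance_families:
        for k in k_range:
            try:
                gmm = GaussianMixture(
                    n_components=k, covariance_type=ct, n_init=n_init,
                    max_iter=500, tol=1e-6, reg_covar=1e-6,
                    random_state=random_state,
                ).fit(X)
                bic = gmm.bic(X)
            except (ValueError, np.linalg.LinAlgError):
                continue
            trace.append({"K": k, "covariance": ct, "bic": bic,
                          "converged": bool(gmm.converged_)})
            if best is None or bic < best[0]:
                best = (bic, gmm)
    if best is None:
        raise RuntimeError("no mixture model could be fitted")
    gmm = best[1]
    covs = _expand_covariances(gmm)
    posteriors = mixture_posteriors(X, gmm.weights_, gmm.means_, covs)
    return ClusterModel(
        n_components=gmm.n_components, covariance_type=gmm.covariance_type,
        weights=gmm.weights_, means=gmm.means_, covariances=covs,
        posteriors=posteriors, threshold=threshold,
        selection=pd.DataFrame(trace),
    )


def assign_with_threshold(posteriors: np.ndarray, threshold: float = 0.8) -> np.ndarray:
    """Assign each dive to its argmax cluster iff the maximum posterior
    reaches ``threshold``; otherwise -1 (unclassified)."""
    p = np.atleast_2d(np.asarray(posteriors, dtype=float))
    arg = p.argmax(axis=1)
    return np.where(p.max(axis=1) >= threshold, arg, -1)


def summarize_clusters(
    assignments: np.ndarray,
    curves: Sequence[DiveCurve],
    dive_individuals: Optional[Sequence[str]] = None,
    prca_dive_ids: Optional[Sequence[int]] = None,
    dive_ids: Optional[Sequence[int]] = None,
    quantiles: Sequence[float] = (2.5, 25.0, 75.0, 97.5),
):
    """Cluster summary table and per-cluster pointwise quantile envelopes.

    Returns ``(table, envelopes)``: per cluster the number of dives (per
    individual and total) and of PrCAs occurring in those dives, plus a
    DataFrame per cluster with the mean curve and the requested quantile
    curves over the normalized grid.
    """
    assignments = np.asarray(assignments)
    n = assignments.size
    individuals = np.asarray(dive_individuals if dive_individuals is not None
                             else [""] * n)
    ids = np.asarray(dive_ids if dive_ids is not None
                     else [c.dive_id for c in curves])
    prca_dives = np.asarray(prca_dive_ids if prca_dive_ids is not None else [])

    rows = []
    envelopes = {}
    X = np.vstack([c.values for c in curves])
    grid = curves[0].grid
    for k in sorted(set(assignments.tolist())):
        sel = assignments == k
        label = "unclassified" if k == -1 else f"cluster_{k + 1}"
        row = {"cluster": label, "n_dives": int(sel.sum())}
        for ind in np.unique(individuals):
            if ind != "":
                row[f"n_dives_{ind}"] = int((sel & (individuals == ind)).sum())
        row["n_prcas"] = int(np.isin(prca_dives, ids[sel]).sum()) if prca_dives.size else 0
        rows.append(row)
        if k == -1 or not sel.any():
            continue
        sub = X[sel]
        env = pd.DataFrame({"u": grid, "mean": sub.mean(axis=0)})
        for q in quantiles:
            env[f"q{q:g}"] = np.percentile(sub, q, axis=0)
        envelopes[label] = env
    return pd.DataFrame(rows), envelopes
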