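"""Sliding-window correlation baselines with graphical-lasso sparsification.

SWCGL computes a Pearson correlation matrix in every length-L window (sliding
step fixed at one sample), converts it to a covariance via
cov_ij = cor_ij * sigma_i * sigma_j, and sparsifies each window's covariance
with the graphical lasso at an AIC-selected penalty.  T-SWCGL is identical
except that all window moments are computed with one-sided exponentially
decaying weights so that recent samples contribute more.  Each window's
network is assigned to the window's centre sample for comparison against a
per-timepoint ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.base import BaseEstimator
from sklearn.covariance import graphical_lasso as _sk_graphical_lasso

from .data import DfcTensor, RoiTimeSeriesMatrix

__all__ = [
    "WindowSpec",
    "WindowedConnectivity",
    "num_windows",
    "taper_weights",
    "weighted_correlation",
    "corr_to_cov",
    "graphical_lasso_sparsify",
    "SlidingWindowGraphicalLasso",
    "run_swc_pipeline",
]

_DEFAULT_RHO_GRID = (0.05, 0.1, 0.2, 0.4, 0.7)
_SUPPORT_TOL = 1e-8


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry; lengths are given in seconds and converted to
    samples by rounding against the repetition time."""

    length_seconds: float
    tr: float = 1.0
    taper: str = "none"  # 'none' | 'exponential'
    half_life_frac: float = 0.25  # taper half-life as a fraction of L

    @property
    def length_samples(self) -> int:
        return int(round(self.length_seconds / self.tr))


@dataclass(frozen=True)
class WindowedConnectivity:
    """Per-window correlation and covariance stacks (W x p x p)."""

    corr: np.ndarray
    cov: np.ndarray
    window_centers: np.ndarray


def num_windows(T: int, L: int) -> int:
    """Number of maximally overlapping windows, T - L + 1."""
    if L < 2 or L > T:
        raise ValueError(f"window length must satisfy 2 <= L <= T, got L={L}, T={T}")
    return T - L + 1


def taper_weights(L: int, decay: float) -> np.ndarray:
    """One-sided exponential taper over a window of L samples.

    The most recent sample (last index) has the largest weight and weights
    fall off as exp(-decay * distance); they are normalised to sum to one.
    decay -> 0 recovers the uniform window.
    """
    if L < 2:
        raise ValueError("window must contain at least two samples")
    if decay < 0:
        raise ValueError("decay rate must be nonnegative")
    w = np.exp(-decay * (L - 1 - np.arange(L)))
    return w / w.sum()


def _weighted_moments(X: np.ndarray, w: np.ndarray):
    """Weighted means, covariance and SDs of one window (columns = variables)."""
    w = np.asarray(w, float)
    w = w / w.sum()
    mu = w @ X
    Xc = X - mu
    cov = (Xc * w[:, None]).T @ Xc
    sds = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    return mu, cov, sds


def weighted_correlation(X: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted Pearson correlation matrix of the columns of ``X``.

    Uniform weights reproduce the plain (population-normalised) Pearson
    correlation.  Columns with zero weighted variance get zero correlations
    (diagonal kept at one) and a warning.
    """
    X = np.asarray(X, float)
    mu, cov, sds = _weighted_moments(X, w)
    zero = sds <= 1e-12 * np.maximum(1.0, np.abs(mu))
    if np.any(zero):
        warnings.warn("zero weighted variance; correlations set to 0", RuntimeWarning, stacklevel=2)
    safe = np.where(zero, 1.0, sds)
    corr = cov / np.outer(safe, safe)
    corr[zero, :] = 0.0
    corr[:, zero] = 0.0
    np.fill_diagonal(corr, 1.0)
    corr = np.clip(corr, -1.0, 1.0)
    return corr


def corr_to_cov(corr: np.ndarray, sds: np.ndarray) -> np.ndarray:
    """cov_ij = cor_ij * sigma_i * sigma_j."""
    sds = np.asarray(sds, float)
    if np.any(sds < 0):
        raise ValueError("standard deviations must be nonnegative")
    return np.asarray(corr, float) * np.outer(sds, sds)


def graphical_lasso_sparsify(
    cov: np.ndarray,
    rho_grid=_DEFAULT_RHO_GRID,
    n_eff: float | None = None,
    support_tol: float = _SUPPORT_TOL,
):
    """Sparse precision estimate with AIC selection of the l1 penalty.

    For each penalty rho the l1-penalised Gaussian log-likelihood precision
    estimate is computed; the Gaussian profile log-likelihood at the estimate,
    (n_eff/2) * (logdet P - tr(S P)), enters AIC = -2 loglik + 2 * (number of
    off-diagonal nonzero entries / 2).  Returns (precision, adjacency,
    chosen_rho); an edge is present when the off-diagonal precision entry
    exceeds ``support_tol`` in magnitude.  Penalties whose solver fails are
    skipped.
    """
    S = np.asarray(cov, float)
    p = S.shape[0]
    if n_eff is None:
        n_eff = float(p + 1)
    eig_min = np.linalg.eigvalsh(S).min()
    if eig_min < 1e-10:
        S = S + (1e-6 + max(0.0, -eig_min)) * np.eye(p)
    single = len(rho_grid) == 1
    best = None
    for rho in rho_grid:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, P = _sk_graphical_lasso(S, alpha=float(rho), tol=1e-3, max_iter=100)
        except (FloatingPointError, np.linalg.LinAlgError, ValueError):
            continue
        off = np.abs(P - np.diag(np.diag(P))) > support_tol
        if single:
            return P, off, float(rho)
        sign, logdet = np.linalg.slogdet(P)
        if sign <= 0:
            continue
        loglik = 0.5 * n_eff * (logdet - np.trace(S @ P))
        k = off.sum() / 2.0
        score = -2.0 * loglik + 2.0 * k
        if best is None or score < best[0]:
            best = (score, P, off, float(rho))
    if best is None:
        raise RuntimeError("graphical lasso failed for every penalty in the grid")
    _, P, off, rho = best
    return P, off, rho


class SlidingWindowGraphicalLasso(BaseEstimator):
    """SWCGL / T-SWCGL dynamic-connectivity estimator.

    Parameters
    ----------
    window_seconds : window length in seconds (samples = round(sec / TR)).
    tr : repetition time in seconds.
    taper : 'none' for the plain sliding window, 'exponential' for the tapered
        variant (one-sided exponential, half-life ``half_life_frac * L``).
    rho_grid : graphical-lasso penalties searched per window by AIC.

    Attributes (after ``fit``)
    --------------------------
    dfc_ : (W, p, p) symmetric zero-diagonal networks; entry values are
        partial correlations from the sparsified precision matrix.
    corr_, cov_ : per-window moment stacks.
    window_centers_ : 0-based sample index each window maps to (centre sample
        for odd L, left-of-centre for even L).
    rhos_ : per-window selected penalty (frozen and reused when the estimator
        is applied to surrogate data).
    """

    def __init__(
        self,
        window_seconds: float = 100.0,
        tr: float = 1.0,
        taper: str = "none",
        half_life_frac: float = 0.25,
        rho_grid=_DEFAULT_RHO_GRID,
        support_tol: float = _SUPPORT_TOL,
    ):
        self.window_seconds = window_seconds
        self.tr = tr
        self.taper = taper
        self.half_life_frac = half_life_frac
        self.rho_grid = rho_grid
        self.support_tol = support_tol

    # -- internals ---------------------------------------------------------

    def _window_weights(self, L: int) -> np.ndarray:
        if self.taper == "none":
            return np.full(L, 1.0 / L)
        if self.taper == "exponential":
            decay = np.log(2.0) / (self.half_life_frac * L)
            return taper_weights(L, decay)
        raise ValueError("taper must be 'none' or 'exponential'")

    def _moments(self, X: np.ndarray):
        """Vectorised per-window weighted correlations, covariances and SDs."""
        T, p = X.shape
        L = int(round(self.window_seconds / self.tr))
        W = num_windows(T, L)
        w = self._window_weights(L)
        Sw = sliding_window_view(X, L, axis=0)  # W x p x L
        mu = Sw @ w  # W x p
        Xc = Sw - mu[:, :, None]
        cov = np.einsum("wpl,l,wql->wpq", Xc, w, Xc)
        sds = np.sqrt(np.clip(np.einsum("wpp->wp", cov.copy()), 0.0, None))
        safe = np.where(sds == 0, 1.0, sds)
        corr = cov / (safe[:, :, None] * safe[:, None, :])
        corr = np.clip(corr, -1.0, 1.0)
        for k in range(W):
            np.fill_diagonal(corr[k], 1.0)
        centers = np.arange(W) + (L - 1) // 2
        return corr, sds, centers, w, L

    def _sparsify(self, corr, sds, n_eff, rhos=None):
        """Graphical-lasso pass over all windows.

        ``rhos``: optional per-window penalties to reuse (surrogate mode);
        otherwise each window selects its own penalty by AIC.
        """
        W, p, _ = corr.shape
        theta = np.zeros((W, p, p))
        chosen = np.zeros(W)
        for k in range(W):
            cov = corr_to_cov(corr[k], sds[k])
            grid = self.rho_grid if rhos is None else (rhos[k],)
            P, off, rho = graphical_lasso_sparsify(cov, grid, n_eff, self.support_tol)
            d = np.sqrt(np.diag(P))
            pc = -P / np.outer(d, d)
            net = np.where(off, (pc + pc.T) / 2.0, 0.0)
            np.fill_diagonal(net, 0.0)
            theta[k] = net
            chosen[k] = rho
        return theta, chosen

    # -- sklearn API -------------------------------------------------------

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be a (T, p) matrix")
        corr, sds, centers, w, L = self._moments(X)
        # effective sample size per window: taper weights and the series'
        # lag-1 autocorrelation both reduce the information the Gaussian
        # likelihood may claim (AIC assumes independent samples)
        n_taper = 1.0 / float((w**2).sum())
        r1 = float(np.mean([np.corrcoef(X[:-1, j], X[1:, j])[0, 1] for j in range(X.shape[1])]))
        r1 = min(max(r1, 0.0), 0.95)
        n_eff = max(n_taper * (1.0 - r1) / (1.0 + r1), 8.0)
        theta, rhos = self._sparsify(corr, sds, n_eff)
        self.corr_ = corr
        self.cov_ = corr * (sds[:, :, None] * sds[:, None, :])
        self.dfc_ = theta
        self.window_centers_ = centers
        self.rhos_ = rhos
        self.window_samples_ = L
        self.n_eff_ = n_eff
        self.n_features_in_ = X.shape[1]
        return self

    def refit_with_frozen_penalties(self, X) -> np.ndarray:
        """Re-estimate networks on new data reusing the fitted per-window
        penalties (the 'same settings' convention for surrogate testing)."""
        X = np.asarray(X, dtype=float)
        corr, sds, _, _, _ = self._moments(X)
        theta, _ = self._sparsify(corr, sds, self.n_eff_, rhos=self.rhos_)
        return theta

    def to_tensor(self, roi_names=()) -> DfcTensor:
        return DfcTensor(
            theta=self.dfc_, roi_names=tuple(roi_names), tr=self.tr, times=self.window_centers_
        )


def run_swc_pipeline(
    raw: RoiTimeSeriesMatrix | np.ndarray,
    spec: WindowSpec | None = None,
    rho_grid=_DEFAULT_RHO_GRID,
) -> DfcTensor:
    """Windows -> (weighted) correlation -> covariance -> graphical lasso.

    ``taper='none'`` gives SWCGL; ``taper='exponential'`` gives T-SWCGL.
    """
    spec = spec or WindowSpec(length_seconds=100.0)
    if isinstance(raw, RoiTimeSeriesMatrix):
        X, tr, names = raw.values, raw.tr, raw.roi_names
    else:
        X, tr, names = np.asarray(raw, dtype=float), spec.tr, ()
    est = SlidingWindowGraphicalLasso(
        window_seconds=spec.length_seconds,
        tr=tr,
        taper=spec.taper,
        half_life_frac=spec.half_life_frac,
        rho_grid=rho_grid,
    ).fit(X)
    return est.to_tensor(roi_names=names)
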