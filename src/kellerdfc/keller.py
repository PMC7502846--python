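"""Kernel-reweighted l1-penalised logistic-regression networks (KELLER).

The model is a time-indexed pairwise Markov random field over ROI activity:
each ROI's dichotomised activity d_n in {-1, +1} is conditionally logistic in
the normalised activity of the remaining ROIs,

    P(d_n | y_rest) = 1 / (1 + exp(-2 d_n <theta, y_rest>)),

and the coupling vector theta (the "neighbourhood" of ROI n) is re-estimated
at every time point by minimising a Gaussian-kernel-weighted negative
log-likelihood with an l1 penalty delta * ||theta||_1 (equivalently, subject
to an l1-ball constraint ||theta||_1 <= C_delta; the two forms correspond
one-to-one per fit).  Kernel weights concentrate the fit on temporally
adjacent samples (temporal smoothness); the l1 term yields exact zeros
(sparsity).  Per-timepoint networks are assembled from the p directed
neighbourhood fits by a symmetrisation rule, and the kernel bandwidth h and
penalty delta are chosen on a grid by AIC.

The estimator fits the penalty form by proximal gradient descent
(soft-thresholding) with backtracking; the ball-constrained form is provided
by :func:`fit_neighborhood` via projected gradient with an exact sort-based
Euclidean l1-ball projection.  All T anchor time points of one ROI are
fitted simultaneously as a batched problem, which is numerically identical
to fitting them one at a time (they are independent).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator

from .data import (
    ActivityLabels,
    DfcTensor,
    NormalizedSeries,
    RoiTimeSeriesMatrix,
    dichotomize,
    minmax_normalize,
)

__all__ = [
    "KernelWeights",
    "NeighborhoodVector",
    "KellerConfig",
    "KellerFit",
    "kernel_weights",
    "conditional_prob",
    "weighted_negloglik",
    "loss_gradient",
    "project_l1_ball",
    "fit_neighborhood",
    "assemble_dfc",
    "aic",
    "KellerEstimator",
    "fit_keller",
]

_DEFAULT_H_GRID = tuple(range(10, 151, 10))
_DEFAULT_DELTA_GRID = (0.01, 0.02, 0.05, 0.1, 0.2)
_SUPPORT_TOL = 1e-8


# ---------------------------------------------------------------------------
# kernel weights
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KernelWeights:
    """Normalised Gaussian kernel weights for one anchor time point."""

    w: np.ndarray
    anchor: int
    bandwidth: float


def _anchor_weight_matrix(T: int, h: float, tr: float = 1.0) -> np.ndarray:
    """All-anchors weight matrix ``W[a, t] = k_h((t - a) * tr)``, rows normalised."""
    if h <= 0:
        raise ValueError("bandwidth h must be positive")
    d = (np.arange(T)[None, :] - np.arange(T)[:, None]) * tr
    W = np.exp(-((d / h) ** 2))
    return W / W.sum(axis=1, keepdims=True)


def kernel_weights(t: int, T: int, h: float, tr: float = 1.0) -> KernelWeights:
    """Gaussian kernel weights k_h(u) = k(u / h), k(u) = exp(-u^2).

    ``h`` is the bandwidth in seconds (the kernel analogue of a sliding-window
    length); ``t`` is the 0-based anchor index and distances are measured in
    seconds (index difference times TR) so that h is comparable across
    repetition times.  Weights are normalised to sum to one over t = 0..T-1.
    """
    if not 0 <= t < T:
        raise ValueError("anchor index out of range")
    if h <= 0:
        raise ValueError("bandwidth h must be positive")
    d = (np.arange(T) - t) * tr
    w = np.exp(-((d / h) ** 2))
    w /= w.sum()
    return KernelWeights(w=w, anchor=t, bandwidth=h)


# ---------------------------------------------------------------------------
# logistic loss pieces
# ---------------------------------------------------------------------------

def conditional_prob(theta: np.ndarray, d_n: int, y_rest: np.ndarray) -> float:
    """P(d_n | y_rest) = 1 / (1 + exp(-2 d_n <theta, y_rest>))."""
    margin = 2.0 * d_n * float(np.dot(np.asarray(theta, float), np.asarray(y_rest, float)))
    return float(expit(margin))


def weighted_negloglik(theta, labels, predictors, w) -> float:
    """Kernel-weighted negative log-likelihood sum_t w_t * (-log P(d_t | x_t)).

    Convex in theta; equals log 2 at theta = 0 because all probabilities are
    one half and the weights sum to one.
    """
    theta = np.asarray(theta, float)
    d = np.asarray(labels, float)
    X = np.asarray(predictors, float)
    wv = w.w if isinstance(w, KernelWeights) else np.asarray(w, float)
    z = -2.0 * d * (X @ theta)
    return float(np.dot(wv, np.logaddexp(0.0, z)))


def loss_gradient(theta, labels, predictors, w) -> np.ndarray:
    """Exact gradient of :func:`weighted_negloglik` with respect to theta."""
    theta = np.asarray(theta, float)
    d = np.asarray(labels, float)
    X = np.asarray(predictors, float)
    wv = w.w if isinstance(w, KernelWeights) else np.asarray(w, float)
    z = -2.0 * d * (X @ theta)
    s = expit(z)  # d/dz log(1 + e^z) evaluated at z
    return (wv * s * (-2.0 * d)) @ X


# ---------------------------------------------------------------------------
# Euclidean projection onto the l1 ball
# ---------------------------------------------------------------------------

def project_l1_ball(v: np.ndarray, C: float) -> np.ndarray:
    """Euclidean projection onto {x : ||x||_1 <= C} (sort-based, exact).

    Accepts a single vector or a 2-D array of row vectors.  Vectors already
    inside the ball are returned unchanged; the projection is idempotent.
    """
    if C < 0:
        raise ValueError("radius C must be nonnegative")
    arr = np.asarray(v, dtype=float)
    single = arr.ndim == 1
    V = np.atleast_2d(arr).copy()
    if C == 0:
        V[:] = 0.0
        return V[0] if single else V
    norms = np.abs(V).sum(axis=1)
    need = norms > C
    if np.any(need):
        U = np.abs(V[need])
        q = U.shape[1]
        s = -np.sort(-U, axis=1)
        css = np.cumsum(s, axis=1)
        k = np.arange(1, q + 1)
        cond = s - (css - C) / k > 0  # cond[:, 0] is always True for C > 0
        rho = q - 1 - np.argmax(cond[:, ::-1], axis=1)
        lam = (css[np.arange(U.shape[0]), rho] - C) / (rho + 1)
        V[need] = np.sign(V[need]) * np.maximum(U - lam[:, None], 0.0)
    return V[0] if single else V


# ---------------------------------------------------------------------------
# projected-gradient solver (batched over anchors)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KellerConfig:
    """Grid and projected-gradient settings for the KELLER estimator."""

    h_grid: tuple[float, ...] = _DEFAULT_H_GRID
    delta_grid: tuple[float, ...] = _DEFAULT_DELTA_GRID
    eta0: float = 1.0
    alpha: float = 0.5
    sigma: float = 1e-4
    eps: float = 1e-6
    max_iters: int = 500
    seed: int = 0

    def __post_init__(self):
        if len(self.h_grid) == 0 or len(self.delta_grid) == 0:
            raise ValueError("parameter grids must be non-empty")
        if self.eta0 <= 0 or not (0 < self.alpha < 1) or self.eps <= 0:
            raise ValueError("invalid projected-gradient settings")


@dataclass(frozen=True)
class NeighborhoodVector:
    """Fitted coupling vector of one ROI at one anchor time point."""

    coeffs: np.ndarray
    target_roi: int
    anchor: int
    objective: float
    n_iter: int
    converged: bool


def _pg_fit_anchors(
    X: np.ndarray,
    d: np.ndarray,
    W: np.ndarray,
    C: float,
    eta0: float = 1.0,
    alpha: float = 0.5,
    sigma: float = 1e-4,
    eps: float = 1e-6,
    max_iters: int = 500,
):
    """Projected-gradient fit of all anchors of one ROI at once.

    X : (T, q) predictors, d : (T,) labels in {-1, +1}, W : (A, T) per-anchor
    kernel weights.  Returns (Theta (A, q), obj (A,), n_iter (A,),
    converged (A,), max_increase) where max_increase is the largest observed
    objective increase across accepted steps (should be ~0; recorded as a
    diagnostic of descent monotonicity).
    """
    d = np.asarray(d, float)
    A, T = W.shape
    q = X.shape[1]
    Theta = np.zeros((A, q))
    Xd = (-2.0 * d)[:, None] * X  # T x q
    Z = np.zeros((A, T))  # -2 d (X theta^T)^T rows per anchor
    obj = (W * np.logaddexp(0.0, Z)).sum(axis=1)  # = log 2 at theta = 0
    eta = np.full(A, float(eta0))
    active = np.ones(A, dtype=bool)
    n_iter = np.zeros(A, dtype=int)
    max_increase = 0.0

    if C == 0:
        return Theta, obj, n_iter, np.ones(A, bool), 0.0

    for _ in range(max_iters):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        S = expit(Z[idx])  # A' x T
        G = (W[idx] * S) @ Xd
        th = Theta[idx]
        ob = obj[idx].copy()
        et = eta[idx].copy()
        new_th = th.copy()
        new_ob = ob.copy()
        new_Z = Z[idx].copy()
        pending = np.ones(idx.size, dtype=bool)
        for _bt in range(80):
            sub = np.flatnonzero(pending)
            if sub.size == 0:
                break
            cand = project_l1_ball(th[sub] - et[sub, None] * G[sub], C)
            Zc = -2.0 * d[None, :] * (cand @ X.T)
            oc = (W[idx][sub] * np.logaddexp(0.0, Zc)).sum(axis=1)
            dec = np.einsum("ij,ij->i", G[sub], cand - th[sub])
            ok = oc <= ob[sub] + sigma * dec + 1e-12
            acc = sub[ok]
            new_th[acc] = cand[ok]
            new_ob[acc] = oc[ok]
            new_Z[acc] = Zc[ok]
            pending[acc] = False
            if _bt == 0:
                # step accepted without shrinking: allow it to grow again
                et[acc] = np.minimum(et[acc] * 2.0, 64.0 * eta0)
            rej = sub[~ok]
            et[rej] *= alpha
            stuck = rej[et[rej] < 1e-14]
            pending[stuck] = False  # keep previous iterate
        if new_ob.size:
            max_increase = max(max_increase, float(np.max(new_ob - ob, initial=0.0)))
        rel = np.abs(ob - new_ob) / np.maximum(np.abs(ob), 1e-12)
        Theta[idx] = new_th
        obj[idx] = new_ob
        Z[idx] = new_Z
        eta[idx] = et
        n_iter[idx] += 1
        done = (rel < eps) | (et < 1e-14)
        active[idx[done]] = False

    return Theta, obj, n_iter, ~active, max_increase


def _ista_fit_anchors(
    X: np.ndarray,
    d: np.ndarray,
    W: np.ndarray,
    delta: float,
    eta0: float = 2.0,
    alpha: float = 0.5,
    eps: float = 1e-6,
    max_iters: int = 500,
):
    """Proximal-gradient (soft-threshold) fit of all anchors of one ROI.

    Minimises F(theta) = sum_t w(t) * softplus(-2 d_t <theta, x_t>)
    + delta * ||theta||_1 per anchor.  Backtracking uses the standard
    quadratic-majorisation acceptance test, which makes the penalised
    objective non-increasing.  Returns (Theta, nll, n_iter, converged,
    max_increase) with ``nll`` the smooth (unpenalised) part at the solution.
    """
    d = np.asarray(d, float)
    A, T = W.shape
    q = X.shape[1]
    Theta = np.zeros((A, q))
    Xd = (-2.0 * d)[:, None] * X
    Z = np.zeros((A, T))
    nll = (W * np.logaddexp(0.0, Z)).sum(axis=1)
    F = nll.copy()  # penalty is zero at theta = 0
    eta = np.full(A, float(eta0))
    active = np.ones(A, dtype=bool)
    n_iter = np.zeros(A, dtype=int)
    max_increase = 0.0

    for _ in range(max_iters):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        Wi = W[idx]
        Zi = Z[idx]
        S = expit(Zi)
        G = (Wi * S) @ Xd
        th = Theta[idx]
        fs = nll[idx]  # smooth part, maintained exactly across iterations
        et = eta[idx].copy()
        new_th = th.copy()
        new_F = F[idx].copy()
        new_nll = nll[idx].copy()
        new_Z = Zi.copy()
        pending = np.ones(idx.size, dtype=bool)
        for _bt in range(80):
            sub = np.flatnonzero(pending)
            if sub.size == 0:
                break
            step = th[sub] - et[sub, None] * G[sub]
            cand = np.sign(step) * np.maximum(np.abs(step) - et[sub, None] * delta, 0.0)
            Zc = -2.0 * d[None, :] * (cand @ X.T)
            fc = (Wi[sub] * np.logaddexp(0.0, Zc)).sum(axis=1)
            diff = cand - th[sub]
            quad = fs[sub] + np.einsum("ij,ij->i", G[sub], diff) + (diff**2).sum(axis=1) / (
                2.0 * et[sub]
            )
            ok = fc <= quad + 1e-12
            acc = sub[ok]
            new_th[acc] = cand[ok]
            new_nll[acc] = fc[ok]
            new_F[acc] = fc[ok] + delta * np.abs(cand[ok]).sum(axis=1)
            new_Z[acc] = Zc[ok]
            pending[acc] = False
            if _bt == 0:
                et[acc] = np.minimum(et[acc] * 2.0, 64.0 * eta0)
            rej = sub[~ok]
            et[rej] *= alpha
            stuck = rej[et[rej] < 1e-14]
            pending[stuck] = False
        ob = F[idx]
        if new_F.size:
            max_increase = max(max_increase, float(np.max(new_F - ob, initial=0.0)))
        rel = np.abs(ob - new_F) / np.maximum(np.abs(ob), 1e-12)
        Theta[idx] = new_th
        F[idx] = new_F
        nll[idx] = new_nll
        Z[idx] = new_Z
        eta[idx] = et
        n_iter[idx] += 1
        done = (rel < eps) | (et < 1e-14)
        active[idx[done]] = False

    return Theta, nll, n_iter, ~active, max_increase


def fit_neighborhood(
    n: int,
    t: int,
    labels: ActivityLabels | np.ndarray,
    predictors: NormalizedSeries | np.ndarray,
    h: float,
    C_delta: float,
    config: KellerConfig | None = None,
    tr: float = 1.0,
) -> NeighborhoodVector:
    """Fit the coupling vector of ROI ``n`` at anchor time ``t`` (0-based)."""
    cfg = config or KellerConfig()
    L = labels.values if isinstance(labels, ActivityLabels) else np.asarray(labels)
    Y = predictors.values if isinstance(predictors, NormalizedSeries) else np.asarray(predictors, float)
    T, p = Y.shape
    mask = np.arange(p) != n
    w = kernel_weights(t, T, h, tr=tr)
    Theta, obj, n_iter, conv, _ = _pg_fit_anchors(
        Y[:, mask],
        L[:, n],
        w.w[None, :],
        C_delta,
        eta0=cfg.eta0,
        alpha=cfg.alpha,
        sigma=cfg.sigma,
        eps=cfg.eps,
        max_iters=cfg.max_iters,
    )
    return NeighborhoodVector(
        coeffs=Theta[0],
        target_roi=n,
        anchor=t,
        objective=float(obj[0]),
        n_iter=int(n_iter[0]),
        converged=bool(conv[0]),
    )


# ---------------------------------------------------------------------------
# assembly and model selection
# ---------------------------------------------------------------------------

def assemble_dfc(
    neighborhoods: np.ndarray,
    symmetrize: str = "and",
    support_tol: float = _SUPPORT_TOL,
) -> np.ndarray:
    """Combine directed neighbourhood estimates into symmetric networks.

    ``neighborhoods`` has shape (p, T, p-1): coefficients of ROI m in the
    model of ROI n, for every anchor t.  Under the default AND rule an edge
    (m, n) is kept only when both directed estimates are nonzero, with weight
    equal to their mean; the OR rule keeps the edge when either is nonzero.
    """
    p, T, _ = neighborhoods.shape
    E = np.zeros((T, p, p))
    for n in range(p):
        others = np.delete(np.arange(p), n)
        E[:, n, others] = neighborhoods[n]
    Et = np.swapaxes(E, 1, 2)
    nz = np.abs(E) > support_tol
    nzt = np.abs(Et) > support_tol
    if symmetrize == "and":
        keep = nz & nzt
    elif symmetrize == "or":
        keep = nz | nzt
    else:
        raise ValueError("symmetrize must be 'and' or 'or'")
    theta = np.where(keep, (E + Et) / 2.0, 0.0)
    theta[:, np.arange(p), np.arange(p)] = 0.0
    return theta


def _edge_count_total(theta: np.ndarray, support_tol: float = _SUPPORT_TOL) -> int:
    """N = sum_t Nz(theta^(t)) / 2, i.e. undirected edges summed over time."""
    p = theta.shape[1]
    iu = np.triu_indices(p, k=1)
    return int((np.abs(theta[:, iu[0], iu[1]]) > support_tol).sum())


def aic(objectives: np.ndarray, theta: np.ndarray, support_tol: float = _SUPPORT_TOL) -> float:
    """AIC(h, delta) = (2/T) sum_n sum_t sum_t* w gamma + 2 N.

    ``objectives`` holds the fitted kernel-weighted negative log-likelihoods,
    one per (ROI, anchor) pair, shape (p, T); ``theta`` is the assembled
    symmetric network stack used to count degrees of freedom
    N = sum_t Nz(theta^(t)) / 2.  An all-zero estimate gives exactly
    2 p log 2 (every gamma term equals log 2, weights sum to one, N = 0).
    """
    T = objectives.shape[1]
    N = _edge_count_total(theta, support_tol)
    return float((2.0 / T) * objectives.sum() + 2.0 * N)


def _aic_ess(objectives: np.ndarray, theta: np.ndarray, ess: float, support_tol: float = _SUPPORT_TOL) -> float:
    """Effective-sample-size-scaled AIC used for grid selection.

    Standard per-sample AIC of each anchor model, 2*gamma_bar + 2*k/ESS, summed
    over ROIs and anchors and divided by T.  This keeps the likelihood and
    degrees-of-freedom terms on the same scale regardless of T (the raw count
    N grows with T while each anchor's weighted likelihood is an average).
    """
    T = objectives.shape[1]
    N = _edge_count_total(theta, support_tol)
    return float((2.0 / T) * objectives.sum() + 4.0 * N / (T * ess))


@dataclass(frozen=True)
class KellerFit:
    """Grid-search result: chosen bandwidth/radius, networks, diagnostics."""

    dfc: DfcTensor
    chosen_h: float
    chosen_delta: float
    aic_surface: np.ndarray
    h_grid: tuple[float, ...]
    delta_grid: tuple[float, ...]
    diagnostics: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

class KellerEstimator(BaseEstimator):
    """Per-timepoint sparse network estimator with AIC-selected (h, C_delta).

    Parameters
    ----------
    tr : repetition time in seconds; kernel distances are index difference
        times TR so bandwidths are comparable across sampling rates.
    h_grid : candidate Gaussian-kernel bandwidths (units of seconds squared in
        the kernel exponent exp(-u^2/h); defaults to 10..150 step 10).
    delta_grid : candidate l1 penalty strengths; larger values give sparser
        networks.  The penalty corresponds one-to-one (per fit) with an
        l1-ball radius C_delta; :func:`fit_neighborhood` exposes the
        equivalent ball-constrained single fit.
    symmetrize : 'or' (default) keeps an edge when either directed
        neighbourhood estimate is nonzero; 'and' requires both (conservative,
        but over-prunes when the dependence is asymmetric, e.g. when one
        region drives another).
    predictor_mode : 'centered' (default) regresses each ROI's labels on the
        mean-centred normalised values y - 1/2 of the others; 'raw' uses the
        uncentred values in [0, 1] and 'binary' the dichotomised labels
        (Ising-style sensitivity check).  Centring is required for the
        intercept-free conditional to represent both activity levels
        symmetrically.
    aic_scale : grid-selection score.  'loo' (default) uses the
        leave-self-out kernel-weighted likelihood with a per-effective-sample
        degrees-of-freedom penalty (each anchor's own observation is removed
        from its kernel average, which is what makes small bandwidths pay for
        overfitting); 'ess' keeps the self term; 'printed' uses the raw
        degrees-of-freedom count penalty 2N.

    Attributes (after ``fit``)
    --------------------------
    dfc_ : (T, p, p) symmetric zero-diagonal network stack.
    h_, delta_ : selected grid point.
    aic_surface_ : selection score over the (h, delta) grid.
    objectives_ : (p, T) fitted weighted negative log-likelihoods at the
        selected grid point.
    n_bad_fits_ : number of neighbourhood fits that hit the iteration cap.
    """

    def __init__(
        self,
        tr: float = 1.0,
        h_grid: tuple[float, ...] = _DEFAULT_H_GRID,
        delta_grid: tuple[float, ...] = _DEFAULT_DELTA_GRID,
        eta0: float = 1.0,
        alpha: float = 0.5,
        sigma: float = 1e-4,
        eps: float = 1e-6,
        max_iters: int = 500,
        symmetrize: str = "or",
        support_tol: float = _SUPPORT_TOL,
        predictor_mode: str = "centered",
        aic_scale: str = "loo",
    ):
        self.tr = tr
        self.h_grid = h_grid
        self.delta_grid = delta_grid
        self.eta0 = eta0
        self.alpha = alpha
        self.sigma = sigma
        self.eps = eps
        self.max_iters = max_iters
        self.symmetrize = symmetrize
        self.support_tol = support_tol
        self.predictor_mode = predictor_mode
        self.aic_scale = aic_scale

    # -- internal ----------------------------------------------------------

    def _design(self, X: np.ndarray):
        norm = minmax_normalize(X)
        labels = dichotomize(norm).values.astype(float)
        if self.predictor_mode == "binary":
            preds = labels
        elif self.predictor_mode == "raw":
            preds = norm.values
        elif self.predictor_mode == "centered":
            preds = norm.values - 0.5
        else:
            raise ValueError("predictor_mode must be 'centered', 'raw' or 'binary'")
        return preds, labels

    def _fit_all_rois(self, preds, labels, W, delta):
        """Fit every (ROI, anchor) neighbourhood at fixed (h, delta).

        Returns the stacked coefficients, the fitted weighted negative
        log-likelihoods, their leave-self-out correction (each anchor's own
        sample removed from its kernel average; used for bandwidth/sparsity
        selection), the directed nonzero-coefficient count, the number of
        non-converged fits and the largest observed objective increase.
        """
        T, p = preds.shape
        square = W.shape[0] == T
        coeffs = np.zeros((p, T, p - 1))
        objectives = np.zeros((p, W.shape[0]))
        loo = np.zeros((p, W.shape[0]))
        k_dir = 0
        bad = 0
        max_inc = 0.0
        w_self = np.diag(W) if square else None
        for n in range(p):
            mask = np.arange(p) != n
            Th, ob, _, conv, inc = _ista_fit_anchors(
                preds[:, mask],
                labels[:, n],
                W,
                delta,
                eta0=self.eta0,
                alpha=self.alpha,
                eps=self.eps,
                max_iters=self.max_iters,
            )
            coeffs[n] = Th
            objectives[n] = ob
            if square:
                z_self = -2.0 * labels[:, n] * np.einsum("tq,tq->t", Th, preds[:, mask])
                ell_self = np.logaddexp(0.0, z_self)
                loo[n] = (ob - w_self * ell_self) / np.maximum(1.0 - w_self, 1e-12)
            k_dir += int((np.abs(Th) > self.support_tol).sum())
            bad += int((~conv).sum())
            max_inc = max(max_inc, inc)
        return coeffs, objectives, loo, k_dir, bad, max_inc

    # -- sklearn API -------------------------------------------------------

    def fit(self, X, y=None):
        if len(self.h_grid) == 0 or len(self.delta_grid) == 0:
            raise ValueError("parameter grids must be non-empty")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be a (T, p) matrix")
        T, p = X.shape
        preds, labels = self._design(X)

        surface = np.full((len(self.h_grid), len(self.delta_grid)), np.inf)
        best = None
        n_bad = 0
        max_inc = 0.0
        results = {}
        ses = np.zeros_like(surface)
        for i, h in enumerate(self.h_grid):
            W = _anchor_weight_matrix(T, h, tr=self.tr)
            ess = float(np.mean(1.0 / (W**2).sum(axis=1)))
            for j, delta in enumerate(self.delta_grid):
                coeffs, objectives, loo, k_dir, bad, inc = self._fit_all_rois(
                    preds, labels, W, delta
                )
                theta = assemble_dfc(coeffs, self.symmetrize, self.support_tol)
                if self.aic_scale == "printed":
                    score = aic(objectives, theta, self.support_tol)
                elif self.aic_scale == "ess":
                    score = _aic_ess(objectives, theta, ess, self.support_tol)
                else:  # 'loo': leave-self-out likelihood + per-sample df penalty
                    score = float((2.0 / T) * loo.sum() + 2.0 * k_dir / (T * ess))
                # SE of the score mean, counting one independent block per
                # kernel width (anchors within a bandwidth share the data)
                per_anchor = 2.0 * loo.sum(axis=0)
                n_blocks = max(T / ess, 1.0)
                ses[i, j] = float(per_anchor.std(ddof=1) / np.sqrt(n_blocks)) if T > 1 else 0.0
                surface[i, j] = score
                results[(i, j)] = (theta, objectives, h, delta)
                n_bad += bad
                max_inc = max(max_inc, inc)

        # one-standard-error rule: among grid points whose score is within
        # one SE of the minimum, prefer the sparsest (largest delta), then the
        # smallest bandwidth; exact ties resolve the same way.
        i_min, j_min = np.unravel_index(int(np.argmin(surface)), surface.shape)
        cutoff = surface[i_min, j_min] + ses[i_min, j_min]
        candidates = [
            (-j, i, j) for (i, j) in results if surface[i, j] <= cutoff + 1e-12
        ]
        _, i_sel, j_sel = min(candidates)
        theta, objectives, h, delta = results[(i_sel, j_sel)]

        self.dfc_ = theta
        self.objectives_ = objectives
        self.h_ = float(h)
        self.delta_ = float(delta)
        self.aic_surface_ = surface
        self.aic_se_ = ses
        self.aic_ = float(surface[i_sel, j_sel])
        self.n_bad_fits_ = n_bad
        self.max_objective_increase_ = max_inc
        self.n_features_in_ = p
        return self

    def to_tensor(self, roi_names=()) -> DfcTensor:
        return DfcTensor(theta=self.dfc_, roi_names=tuple(roi_names), tr=self.tr)


def keller_theta_at(
    X: np.ndarray,
    h: float,
    delta: float,
    tr: float = 1.0,
    **params,
) -> np.ndarray:
    """Network stack at a fixed (h, C_delta) pair, without grid search.

    Used when re-estimating surrogate data with the settings selected on the
    observed data.
    """
    est = KellerEstimator(tr=tr, h_grid=(h,), delta_grid=(delta,), **params)
    X = np.asarray(X, dtype=float)
    preds, labels = est._design(X)
    W = _anchor_weight_matrix(X.shape[0], h, tr=tr)
    coeffs = est._fit_all_rois(preds, labels, W, delta)[0]
    return assemble_dfc(coeffs, est.symmetrize, est.support_tol)


def fit_keller(raw: RoiTimeSeriesMatrix | np.ndarray, config: KellerConfig | None = None, tr: float | None = None) -> KellerFit:
    """Functional wrapper: grid-search fit returning a :class:`KellerFit`."""
    cfg = config or KellerConfig()
    if isinstance(raw, RoiTimeSeriesMatrix):
        X = raw.values
        tr_ = raw.tr
        names = raw.roi_names
    else:
        X = np.asarray(raw, dtype=float)
        tr_ = tr if tr is not None else 1.0
        names = ()
    est = KellerEstimator(
        tr=tr_,
        h_grid=tuple(cfg.h_grid),
        delta_grid=tuple(cfg.delta_grid),
        eta0=cfg.eta0,
        alpha=cfg.alpha,
        sigma=cfg.sigma,
        eps=cfg.eps,
        max_iters=cfg.max_iters,
    ).fit(X)
    return KellerFit(
        dfc=DfcTensor(theta=est.dfc_, roi_names=names, tr=tr_),
        chosen_h=est.h_,
        aic_surface=est.aic_surface_,
        h_grid=tuple(cfg.h_grid),
        delta_grid=tuple(cfg.delta_grid),
        diagnostics={
            "n_bad_fits": est.n_bad_fits_,
            "max_objective_increase": est.max_objective_increase_,
            "aic": est.aic_,
        },
    )
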