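"""Surrogate-data hypothesis testing for dynamic connections.

The null hypothesis for every node pair is that its estimated connectivity
time series is static, i.e. its fluctuation is pure estimation noise.  The
test measure is the sample SD of the edge's dFC series.  The null
distribution is built from amplitude-adjusted phase-randomised (AAPR)
surrogates of the ROI time series: each surrogate preserves every column's
amplitude distribution exactly and, because one common random phase vector
rotates all columns, preserves the cross-spectra and hence the static
correlation structure.  Re-estimating the dFC on each surrogate with the
same estimator and settings yields per-edge null SDs; right-tailed empirical
p-values (add-one rule) and an optional Bonferroni correction flag
significantly dynamic pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import DfcTensor, RoiTimeSeriesMatrix, upper_triangle_pairs

__all__ = [
    "SurrogateEnsemble",
    "DynamicsTestResult",
    "aapr_surrogates",
    "sd_statistic",
    "empirical_p_right",
    "bonferroni_flags",
    "averaged_case_test",
    "detect_dynamic_edges",
]


@dataclass(frozen=True)
class SurrogateEnsemble:
    """Stack of surrogate series (n_surr x T x p)."""

    series: np.ndarray
    seed: object = None
    method: str = "aapr"


@dataclass(frozen=True)
class DynamicsTestResult:
    """Per-edge SD statistic, surrogate null, p-value and significance flag."""

    observed_sd: np.ndarray
    null_sds: np.ndarray  # n_edges x n_surr
    p_values: np.ndarray
    significant: np.ndarray
    edge_index: tuple = field(default_factory=tuple)
    alpha: float = 0.05
    correction: str = "none"


def _phase_randomize_common(G: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Rotate all columns' spectra by one common random phase vector."""
    T = G.shape[0]
    F = np.fft.rfft(G, axis=0)
    n_freq = F.shape[0]
    phases = rng.uniform(0.0, 2.0 * np.pi, size=n_freq)
    rot = np.exp(1j * phases)
    rot[0] = 1.0  # DC untouched
    if T % 2 == 0:
        rot[-1] = 1.0  # Nyquist bin kept real
    return np.fft.irfft(F * rot[:, None], n=T, axis=0)


def aapr_surrogates(
    raw: RoiTimeSeriesMatrix | np.ndarray, n_surr: int, seed=None
) -> SurrogateEnsemble:
    """Amplitude-adjusted phase-randomised surrogates of a T x p series.

    Per surrogate: (1) each column is Gaussianised by rank-remapping onto
    sorted Gaussian deviates; (2) the Gaussian series is phase-randomised with
    a common phase vector across columns; (3) values are rank-remapped back
    onto the original column amplitudes, so every surrogate column is a
    permutation of the original one.
    """
    values = raw.values if isinstance(raw, RoiTimeSeriesMatrix) else np.asarray(raw, float)
    T, p = values.shape
    if T < 8:
        raise ValueError("need at least 8 time points for phase randomisation")
    rng = np.random.default_rng(seed)
    order = np.argsort(values, axis=0, kind="stable")
    ranks = np.empty_like(order)
    cols = np.arange(p)
    ranks[order, cols] = np.arange(T)[:, None]
    sorted_orig = np.take_along_axis(values, order, axis=0)

    out = np.empty((n_surr, T, p))
    for k in range(n_surr):
        g = np.sort(rng.standard_normal((T, p)), axis=0)
        gauss = np.take_along_axis(g, ranks, axis=0)
        s = _phase_randomize_common(gauss, rng)
        ranks_s = np.argsort(np.argsort(s, axis=0, kind="stable"), axis=0, kind="stable")
        out[k] = np.take_along_axis(sorted_orig, ranks_s, axis=0)
    return SurrogateEnsemble(series=out, seed=seed, method="aapr")


def sd_statistic(edge_series: np.ndarray) -> float:
    """Sample SD (T-1 denominator) of one edge's dFC time series."""
    x = np.asarray(edge_series, float)
    if x.size < 2:
        raise ValueError("need at least two time points")
    return float(np.std(x, ddof=1))


def empirical_p_right(observed: float, null: np.ndarray) -> float:
    """Right-tailed empirical p-value with the add-one rule.

    p = (1 + #{null >= observed}) / (1 + n_null); rejection at level alpha
    corresponds to the observed statistic exceeding the empirical
    (1 - alpha) percentile of the null.
    """
    null = np.asarray(null, float)
    if null.size == 0:
        raise ValueError("null sample is empty")
    return float((1.0 + np.sum(null >= observed)) / (1.0 + null.size))


def bonferroni_flags(p_values: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Flag p <= alpha / N across the family of N tests."""
    p = np.asarray(p_values, float)
    if p.size < 1:
        raise ValueError("need at least one p-value")
    return p <= alpha / p.size


def _edge_sds(theta: np.ndarray) -> np.ndarray:
    """SD over time of every i<j edge series in a (T, p, p) stack."""
    p = theta.shape[1]
    iu = np.triu_indices(p, k=1)
    return theta[:, iu[0], iu[1]].std(axis=0, ddof=1)


def _flags_from_pvalues(p_values: np.ndarray, alpha: float, correction: str) -> np.ndarray:
    if correction == "bonferroni":
        return bonferroni_flags(p_values, alpha)
    if correction == "none":
        return np.asarray(p_values) <= alpha
    raise ValueError("correction must be 'none' or 'bonferroni'")


def averaged_case_test(
    observed: np.ndarray,
    null: np.ndarray,
    alpha: float = 0.05,
    correction: str = "bonferroni",
    edge_index=(),
) -> DynamicsTestResult:
    """Across-subject averaged test.

    ``observed``: (n_subjects, n_edges) per-subject SD statistics;
    ``null``: (n_subjects, n_edges, n_surr) per-subject surrogate SDs.
    Observed and surrogate statistics are averaged across subjects per edge
    (surrogate k of each subject is paired with surrogate k of the others)
    before the right-tailed empirical test.
    """
    observed = np.asarray(observed, float)
    null = np.asarray(null, float)
    if observed.ndim != 2 or null.ndim != 3 or observed.shape != null.shape[:2]:
        raise ValueError("observed (S, N) and null (S, N, n_surr) must align")
    obs_mean = observed.mean(axis=0)
    null_mean = null.mean(axis=0)  # n_edges x n_surr
    p_values = np.array(
        [empirical_p_right(obs_mean[e], null_mean[e]) for e in range(obs_mean.size)]
    )
    flags = _flags_from_pvalues(p_values, alpha, correction)
    return DynamicsTestResult(
        observed_sd=obs_mean,
        null_sds=null_mean,
        p_values=p_values,
        significant=flags,
        edge_index=tuple(edge_index),
        alpha=alpha,
        correction=correction,
    )


def detect_dynamic_edges(
    raw: RoiTimeSeriesMatrix | np.ndarray,
    method: str = "keller",
    n_surr: int = 1000,
    alpha: float = 0.05,
    correction: str = "none",
    seed=None,
    tr: float | None = None,
    keller_params: dict | None = None,
    swc_params: dict | None = None,
    series: str = "correlation",
    pool_null: bool = False,
) -> DynamicsTestResult:
    """Full dynamics test: estimate, re-estimate on surrogates, compare SDs.

    The chosen estimator is fitted on the observed series (including its
    model selection: the AIC grid for KELLER, the per-window penalty for the
    sliding-window methods).  Each AAPR surrogate is then re-estimated with
    those selected settings frozen, giving per-edge null SDs.  For
    window-based estimators the SD runs over the window-centre series; for
    KELLER over all T time points.

    ``series`` selects which per-window values the SD statistic measures for
    the sliding-window methods: ``'correlation'`` (default) uses the
    (weighted) Pearson correlation series, ``'precision'`` the
    graphical-lasso-sparsified partial-correlation series.
    """
    from .keller import KellerEstimator, keller_theta_at
    from .swc import SlidingWindowGraphicalLasso

    if n_surr < 1:
        raise ValueError("need at least one surrogate")
    if isinstance(raw, RoiTimeSeriesMatrix):
        values, tr_ = raw.values, raw.tr
    else:
        values, tr_ = np.asarray(raw, float), (tr if tr is not None else 1.0)
    p = values.shape[1]
    pairs = upper_triangle_pairs(p)

    if method == "keller":
        params = dict(keller_params or {})
        est = KellerEstimator(tr=tr_, **params).fit(values)
        observed = _edge_sds(est.dfc_)
        fixed = dict(params)
        fixed.pop("h_grid", None)
        fixed.pop("delta_grid", None)
        refit = lambda s: keller_theta_at(s, est.h_, est.delta_, tr=tr_, **fixed)
    elif method in ("swcgl", "tswcgl"):
        params = dict(swc_params or {})
        params.setdefault("taper", "exponential" if method == "tswcgl" else "none")
        est = SlidingWindowGraphicalLasso(tr=tr_, **params).fit(values)
        if series == "correlation":
            observed = _edge_sds(est.corr_)
            refit = lambda s: est._moments(s)[0]
        elif series == "precision":
            observed = _edge_sds(est.dfc_)
            refit = est.refit_with_frozen_penalties
        else:
            raise ValueError("series must be 'correlation' or 'precision'")
    else:
        raise ValueError("method must be 'keller', 'swcgl' or 'tswcgl'")

    ens = aapr_surrogates(values, n_surr, seed=seed)
    null = np.empty((len(pairs), n_surr))
    for k in range(n_surr):
        null[:, k] = _edge_sds(refit(ens.series[k]))

    # per-edge nulls by default; pool_null compares every edge against the
    # test-measure values pooled over all pairs and surrogates
    if pool_null:
        pooled = null.ravel()
        p_values = np.array([empirical_p_right(observed[e], pooled) for e in range(len(pairs))])
    else:
        p_values = np.array(
            [empirical_p_right(observed[e], null[e]) for e in range(len(pairs))]
        )
    flags = _flags_from_pvalues(p_values, alpha, correction)
    return DynamicsTestResult(
        observed_sd=observed,
        null_sds=null,
        p_values=p_values,
        significant=flags,
        edge_index=pairs,
        alpha=alpha,
        correction=correction,
    )
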