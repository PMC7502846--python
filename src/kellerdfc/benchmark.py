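"""End-to-end benchmark study: simulate, estimate, test, score.

One replicate of the reference study draws a 5-node Erdos-Renyi scenario
(3 states x 100 samples, ramped couplings), labels its benchmark-dynamic
pairs with 500 surrogates, then scores three estimators against the truth:

* KELLER with an AIC grid over (h, delta);
* T-SWCGL: tapered sliding-window correlation (100 s window) + graphical lasso;
* SWCGL: plain sliding-window correlation (100 s window) + graphical lasso.

Per-timepoint F1 against the true support is averaged over time (window
centres for the window methods); detection power is the percentage of
benchmark-dynamic pairs flagged by the surrogate SD test with the fitted
settings frozen on each surrogate.

The grid defaults here are a deliberately coarse subset of the estimator
defaults so that a multi-replicate study runs at desk scale; the methods
note documents the choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .evaluation import detection_power, matrix_cell_scores
from .keller import KellerEstimator, keller_theta_at
from .simulate import BenchmarkScenario, label_benchmark_dynamic, simulate_benchmark
from .surrogates import _edge_sds, aapr_surrogates
from .swc import SlidingWindowGraphicalLasso

__all__ = ["StudyConfig", "ReplicateResult", "run_replicate", "run_benchmark_study"]

COARSE_H_GRID = (20.0, 60.0, 100.0, 140.0)
COARSE_DELTA_GRID = (0.02, 0.05, 0.1)


@dataclass(frozen=True)
class StudyConfig:
    """Study-level settings (scenario defaults are the reference conditions)."""

    scenario: BenchmarkScenario = field(default_factory=BenchmarkScenario)
    h_grid: tuple[float, ...] = COARSE_H_GRID
    delta_grid: tuple[float, ...] = COARSE_DELTA_GRID
    window_seconds: float = 100.0
    n_label_surrogates: int = 500
    n_test_surrogates: int = 100
    alpha: float = 0.05
    run_power: bool = True


@dataclass(frozen=True)
class ReplicateResult:
    f1: dict
    power: dict
    n_dynamic: int
    chosen_h: float
    chosen_delta: float


def _truth_support(traj, times=None):
    sup = traj.support
    if times is not None:
        sup = sup[np.asarray(times)]
    return sup


def _power_from_null(observed, null, dynamic, alpha):
    # flag rule: observed SD exceeds the empirical (1 - alpha) percentile of
    # the per-edge surrogate null
    thresh = np.percentile(null, 100.0 * (1.0 - alpha), axis=1)
    return detection_power(observed > thresh, dynamic)


def run_replicate(seed: int, config: StudyConfig | None = None) -> ReplicateResult:
    """One full benchmark replicate (simulation, labels, three estimators)."""
    cfg = config or StudyConfig()
    rng = np.random.default_rng(seed)
    sc = BenchmarkScenario(**{**cfg.scenario.__dict__, "seed": int(rng.integers(2**31 - 1))})
    traj, Y = simulate_benchmark(sc)
    X = Y.values

    f1 = {}
    power = {}

    # --- KELLER -----------------------------------------------------------
    keller = KellerEstimator(
        tr=sc.tr, h_grid=cfg.h_grid, delta_grid=cfg.delta_grid
    ).fit(X)
    f1["keller"] = matrix_cell_scores(
        np.abs(keller.dfc_) > 1e-8, _truth_support(traj)
    ).mean_f1

    # --- sliding-window baselines ----------------------------------------
    swc_fits = {}
    for name, taper in (("tswcgl", "exponential"), ("swcgl", "none")):
        est = SlidingWindowGraphicalLasso(
            window_seconds=cfg.window_seconds, tr=sc.tr, taper=taper
        ).fit(X)
        swc_fits[name] = est
        f1[name] = matrix_cell_scores(
            np.abs(est.dfc_) > 1e-8, _truth_support(traj, est.window_centers_)
        ).mean_f1

    n_dynamic = 0
    if cfg.run_power:
        labels = label_benchmark_dynamic(
            traj,
            X,
            n_surrogates=cfg.n_label_surrogates,
            seed=int(rng.integers(2**31 - 1)),
        )
        n_dynamic = int(labels.dynamic.sum())
        ens = aapr_surrogates(X, cfg.n_test_surrogates, seed=int(rng.integers(2**31 - 1)))
        n_surr = cfg.n_test_surrogates
        n_pairs = labels.dynamic.size

        obs_k = _edge_sds(keller.dfc_)
        null_k = np.empty((n_pairs, n_surr))
        for k in range(n_surr):
            theta = keller_theta_at(ens.series[k], keller.h_, keller.delta_, tr=sc.tr)
            null_k[:, k] = _edge_sds(theta)
        power["keller"] = _power_from_null(obs_k, null_k, labels.dynamic, cfg.alpha)

        # window methods: the SD statistic runs over the windowed correlation
        # series (the graphical lasso is the structure-recovery step, not the
        # dFC value series the dynamics test measures)
        for name, est in swc_fits.items():
            obs = _edge_sds(est.corr_)
            null = np.empty((n_pairs, n_surr))
            for k in range(n_surr):
                corr_k = est._moments(ens.series[k])[0]
                null[:, k] = _edge_sds(corr_k)
            power[name] = _power_from_null(obs, null, labels.dynamic, cfg.alpha)

    return ReplicateResult(
        f1=f1,
        power=power,
        n_dynamic=n_dynamic,
        chosen_h=keller.h_,
        chosen_delta=keller.delta_,
    )


def run_benchmark_study(
    n_replicates: int = 10, seed: int = 0, config: StudyConfig | None = None, verbose: bool = False
) -> dict:
    """Aggregate F1 and detection power over seeded replicates."""
    cfg = config or StudyConfig()
    seeds = np.random.default_rng(seed).integers(2**31 - 1, size=n_replicates)
    reps = []
    for i, s in enumerate(seeds):
        rep = run_replicate(int(s), cfg)
        reps.append(rep)
        if verbose:
            print(f"replicate {i + 1}/{n_replicates}: f1={rep.f1} power={rep.power}", flush=True)
    out = {"replicates": reps, "n_replicates": n_replicates}
    for key in ("keller", "tswcgl", "swcgl"):
        vals = np.array([r.f1[key] for r in reps])
        out[f"f1_{key}_mean"] = float(vals.mean())
        out[f"f1_{key}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        if cfg.run_power:
            pw = np.array([r.power[key] for r in reps])
            out[f"power_{key}_mean"] = float(pw.mean())
            out[f"power_{key}_sd"] = float(pw.std(ddof=1)) if len(pw) > 1 else 0.0
    return out
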