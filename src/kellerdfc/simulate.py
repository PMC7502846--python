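"""Ground-truth benchmark simulator: piecewise-ramped VAR(1) networks.

Each scenario draws one random topology per state (Erdos-Renyi or
Barabasi-Albert preferential attachment, sparsity constrained to a target
range), ramps every active edge's coupling strength linearly up ("emerging")
or down ("disappearing") across the state, and drives a first-order vector
autoregression y^(t) = A^(t) y^(t-1) + eps^(t) with the resulting coefficient
trajectory.  Each undirected edge is realised by default as one directed
coefficient (upper triangle); together with a positive diagonal
self-coupling (the BOLD-like temporal autocorrelation) the coefficient
matrix is triangular-plus-diagonal and therefore stable for any coupling
strength, so the strengths stay exactly inside the stated range.  A fully
symmetric realisation is available, in which case one uniform rescaling
caps the spectral radius.  Edge trajectories are continuous across state
boundaries (a continuing edge starts where it left off; edges entering or
leaving the support do so at the activation floor, the lower end of the
strength range).  Every coefficient matrix is stabilised to spectral radius
<= 0.95 by one uniform rescaling, which preserves support and relative ramps.

Benchmark "dynamic" labels are assigned by the same surrogate logic used for
real data: the SD over time of an edge's true modulation is compared with the
95th percentile of SDs of VAR coefficient trajectories re-estimated (sliding
ordinary-least-squares windows) from amplitude-adjusted phase-randomised
surrogates of the simulated series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .data import RoiTimeSeriesMatrix, upper_triangle_pairs

__all__ = [
    "BenchmarkScenario",
    "TrueCoefficientTrajectory",
    "BenchmarkLabels",
    "generate_topology",
    "build_trajectory",
    "simulate_var1",
    "sliding_var_coefficients",
    "label_benchmark_dynamic",
    "simulate_benchmark",
]

_SPECTRAL_CAP = 0.95
_MAX_TOPOLOGY_TRIES = 200


@dataclass(frozen=True)
class BenchmarkScenario:
    """Study conditions for one simulated data set.

    Defaults reproduce the reference benchmark frame: 5 nodes, 3 states of
    100 samples each at TR = 1 s (T = 300 with change points at t = 100 and
    200), state sparsity in [0.4, 0.7] and coupling strengths ramped within
    [0.1, 0.75].
    """

    p: int = 5
    topology_kind: str = "erdos_renyi"  # or 'scale_free'
    n_states: int = 3
    samples_per_state: int = 100
    sparsity_range: tuple[float, float] = (0.4, 0.7)
    strength_range: tuple[float, float] = (0.1, 0.75)
    self_coupling: float = 0.7
    modulation_prob: float = 0.5
    coupling: str = "directed"  # 'directed' (triangular, always stable) | 'symmetric'
    noise_sd: float = 1.0
    tr: float = 1.0
    burn_in: int = 100
    seed: int = 0

    @property
    def T(self) -> int:
        return self.n_states * self.samples_per_state


@dataclass(frozen=True)
class TrueCoefficientTrajectory:
    """Time-resolved VAR(1) coefficients A (T x p x p) and boolean support."""

    A: np.ndarray
    support: np.ndarray
    scale: float = 1.0  # stabilisation factor applied uniformly


@dataclass(frozen=True)
class BenchmarkLabels:
    """Per-pair benchmark dynamics labels with the surrogate null behind them."""

    dynamic: np.ndarray  # bool, one per i<j pair
    observed_sd: np.ndarray
    null_sds: np.ndarray  # n_pairs x n_surrogates
    edge_index: tuple = field(default_factory=tuple)


def _sparsity(adj: np.ndarray) -> float:
    p = adj.shape[0]
    iu = np.triu_indices(p, k=1)
    return 1.0 - adj[iu].mean()


def generate_topology(kind: str, p: int, sparsity_range=(0.4, 0.7), seed=None) -> np.ndarray:
    """Symmetric boolean adjacency with sparsity (fraction of absent pairs)
    inside ``sparsity_range``.

     'erdos_renyi' draws the absence probability uniformly from the range and
    resamples until the realised sparsity lands inside it; 'scale_free' uses
    Barabasi-Albert preferential attachment (attachment power one) with the
    attachment count chosen to make the target sparsity attainable.
    """
    if p < 2:
        raise ValueError("need at least two nodes")
    lo, hi = sparsity_range
    rng = np.random.default_rng(seed)
    for _ in range(_MAX_TOPOLOGY_TRIES):
        if kind == "erdos_renyi":
            absent = rng.uniform(lo, hi)
            g = nx.gnp_random_graph(p, 1.0 - absent, seed=int(rng.integers(2**31 - 1)))
        elif kind == "scale_free":
            n_pairs = p * (p - 1) // 2
            target_edges = n_pairs * (1.0 - (lo + hi) / 2.0)
            m = max(1, min(p - 1, int(round(target_edges / max(p - 1, 1)))))
            g = nx.barabasi_albert_graph(p, m, seed=int(rng.integers(2**31 - 1)))
        else:
            raise ValueError("topology kind must be 'erdos_renyi' or 'scale_free'")
        adj = nx.to_numpy_array(g, dtype=bool)
        if lo <= _sparsity(adj) <= hi:
            return adj
    raise RuntimeError(f"could not reach sparsity in {sparsity_range} after {_MAX_TOPOLOGY_TRIES} tries")


def build_trajectory(scenario: BenchmarkScenario) -> TrueCoefficientTrajectory:
    """Piecewise-linear symmetric coefficient trajectory over all states."""
    rng = np.random.default_rng(scenario.seed)
    p, S, L = scenario.p, scenario.n_states, scenario.samples_per_state
    lo, hi = scenario.strength_range
    pairs = upper_triangle_pairs(p)

    supports = [
        generate_topology(
            scenario.topology_kind,
            p,
            scenario.sparsity_range,
            seed=rng.integers(2**31 - 1),
        )
        for _ in range(S)
    ]

    A = np.zeros((S * L, p, p))
    support = np.zeros((S * L, p, p), dtype=bool)
    prev_end: dict[tuple[int, int], float] = {}
    for s in range(S):
        t0 = s * L
        ramp = np.linspace(0.0, 1.0, L)
        nxt = supports[s + 1] if s + 1 < S else None
        for i, j in pairs:
            if not supports[s][i, j]:
                prev_end.pop((i, j), None)
                continue
            entering = (i, j) not in prev_end
            # first-state edges start at a random strength; edges entering
            # the support later start at the activation floor
            start = prev_end.get((i, j), lo if s > 0 else rng.uniform(lo, hi))
            if nxt is not None and not nxt[i, j]:
                end = lo  # edge leaves next state: disappearing
            elif entering and s > 0:
                end = hi  # newly emerging edge ramps up
            elif rng.random() < scenario.modulation_prob:
                end = hi if rng.random() < 0.5 else lo
            else:
                end = start  # static within this state
            vals = start + (end - start) * ramp
            A[t0 : t0 + L, i, j] = vals
            if scenario.coupling == "symmetric":
                A[t0 : t0 + L, j, i] = vals
            support[t0 : t0 + L, i, j] = True
            support[t0 : t0 + L, j, i] = True
            prev_end[(i, j)] = end

    A[:, np.arange(p), np.arange(p)] = scenario.self_coupling
    radius = max(np.abs(np.linalg.eigvals(A[t])).max() for t in range(A.shape[0]))
    scale = 1.0
    if radius > _SPECTRAL_CAP:
        scale = _SPECTRAL_CAP / radius
        A = A * scale
    return TrueCoefficientTrajectory(A=A, support=support, scale=scale)


def simulate_var1(
    traj: TrueCoefficientTrajectory,
    noise_sd: float = 1.0,
    seed=None,
    burn_in: int = 100,
    tr: float = 1.0,
) -> RoiTimeSeriesMatrix:
    """Drive y^(t) = A^(t) y^(t-1) + eps, eps ~ N(0, noise_sd^2 I).

    The burn-in period runs under the first coefficient matrix and is
    discarded, so the returned series starts in (approximate) stationarity.
    """
    rng = np.random.default_rng(seed)
    T, p, _ = traj.A.shape
    eps = rng.normal(0.0, noise_sd, size=(burn_in + T, p))
    y = np.zeros(p)
    out = np.empty((T, p))
    for t in range(burn_in):
        y = traj.A[0] @ y + eps[t]
    for t in range(T):
        y = traj.A[t] @ y + eps[burn_in + t]
        out[t] = y
    return RoiTimeSeriesMatrix(values=out, tr=tr)


def sliding_var_coefficients(Y: np.ndarray, window: int = 50, ridge: float = 1e-8) -> np.ndarray:
    """Sliding-window ordinary-least-squares VAR(1) coefficient trajectory.

    Returns an array of shape (T - window, p, p): for each window of
    ``window`` consecutive transitions, the OLS solution of
    y^(t+1) ~ A y^(t).  Implemented with cumulative Gram matrices so that all
    windows cost one batched solve.
    """
    Y = np.asarray(Y, float)
    T, p = Y.shape
    if window >= T:
        raise ValueError("window must be shorter than the series")
    X, Z = Y[:-1], Y[1:]
    G = np.einsum("ti,tj->tij", X, X)
    Cz = np.einsum("ti,tj->tij", Z, X)
    Gc = np.concatenate([np.zeros((1, p, p)), np.cumsum(G, axis=0)])
    Cc = np.concatenate([np.zeros((1, p, p)), np.cumsum(Cz, axis=0)])
    n_win = T - window  # windows of `window` transitions
    starts = np.arange(n_win)
    Sxx = Gc[starts + window] - Gc[starts]
    Szx = Cc[starts + window] - Cc[starts]
    Sxx = Sxx + ridge * np.eye(p)
    # A = Szx Sxx^{-1}  =>  solve Sxx^T A^T = Szx^T (Sxx symmetric)
    At = np.linalg.solve(Sxx, np.swapaxes(Szx, 1, 2))
    return np.swapaxes(At, 1, 2)


def label_benchmark_dynamic(
    traj: TrueCoefficientTrajectory,
    Y: RoiTimeSeriesMatrix | np.ndarray,
    n_surrogates: int = 500,
    window: int = 50,
    seed=None,
    percentile: float = 95.0,
) -> BenchmarkLabels:
    """Label node pairs whose true modulation exceeds the surrogate null.

    Observed measure: SD over time of the true coupling trajectory of each
    pair.  Null: SDs of symmetrised sliding-window OLS VAR(1) coefficient
    trajectories re-estimated from amplitude-adjusted phase-randomised
    surrogates of the simulated series.
    """
    from .surrogates import aapr_surrogates

    if n_surrogates < 20:
        raise ValueError("need at least 20 surrogates for a stable percentile")
    values = Y.values if isinstance(Y, RoiTimeSeriesMatrix) else np.asarray(Y, float)
    p = traj.A.shape[1]
    pairs = upper_triangle_pairs(p)
    iu = np.triu_indices(p, k=1)

    observed = traj.A[:, iu[0], iu[1]].std(axis=0, ddof=1)

    ens = aapr_surrogates(values, n_surrogates, seed=seed)
    null = np.empty((len(pairs), n_surrogates))
    for k in range(n_surrogates):
        Ahat = sliding_var_coefficients(ens.series[k], window=window)
        sym = (Ahat + np.swapaxes(Ahat, 1, 2)) / 2.0
        null[:, k] = sym[:, iu[0], iu[1]].std(axis=0, ddof=1)

    thresh = np.percentile(null, percentile, axis=1)
    dynamic = observed > thresh
    return BenchmarkLabels(
        dynamic=dynamic, observed_sd=observed, null_sds=null, edge_index=pairs
    )


def simulate_benchmark(scenario: BenchmarkScenario | None = None):
    """Convenience wrapper: (trajectory, series) for one scenario."""
    sc = scenario or BenchmarkScenario()
    rng = np.random.default_rng(sc.seed)
    traj_seed = int(rng.integers(2**31 - 1))
    noise_seed = int(rng.integers(2**31 - 1))
    traj = build_trajectory(
        BenchmarkScenario(**{**sc.__dict__, "seed": traj_seed})
    )
    Y = simulate_var1(traj, noise_sd=sc.noise_sd, seed=noise_seed, burn_in=sc.burn_in, tr=sc.tr)
    return traj, Y
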