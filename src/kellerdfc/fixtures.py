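"""Programmatic generation of small standard datasets.

Everything here is synthetic, produced by the benchmark simulator at run
time: a 5-node/300-sample benchmark with truth and dynamics labels, a 2-node
static control, and a small multi-subject cohort for the averaged-case test.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .data import upper_triangle_pairs, write_timeseries
from .simulate import (
    BenchmarkScenario,
    TrueCoefficientTrajectory,
    label_benchmark_dynamic,
    simulate_benchmark,
    simulate_var1,
)

__all__ = ["make_fixtures", "static_control", "mini_cohort"]


def static_control(T: int = 300, seed=0):
    """Two-node series with a constant coupling (no dynamics)."""
    A = np.zeros((T, 2, 2))
    A[:, 0, 0] = A[:, 1, 1] = 0.6
    A[:, 0, 1] = 0.5
    support = np.zeros((T, 2, 2), bool)
    support[:, 0, 1] = support[:, 1, 0] = True
    traj = TrueCoefficientTrajectory(A=A, support=support)
    return traj, simulate_var1(traj, seed=seed)


def mini_cohort(n_subjects: int = 10, seed=0, scenario: BenchmarkScenario | None = None):
    """Subjects sharing one true trajectory with independent noise draws."""
    sc = scenario or BenchmarkScenario(seed=seed)
    traj, _ = simulate_benchmark(sc)
    rng = np.random.default_rng(seed)
    subjects = [
        simulate_var1(traj, noise_sd=sc.noise_sd, seed=int(rng.integers(2**31 - 1)), burn_in=sc.burn_in)
        for _ in range(n_subjects)
    ]
    return traj, subjects


def make_fixtures(seed: int, out_dir, n_label_surrogates: int = 200) -> dict:
    """Write the standard fixture bundle; returns the file map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}

    sc = BenchmarkScenario(seed=seed)
    traj, Y = simulate_benchmark(sc)
    write_timeseries(Y, out / "benchmark.tsv")
    labels = label_benchmark_dynamic(traj, Y.values, n_surrogates=n_label_surrogates, seed=seed + 1)
    (out / "benchmark_truth.json").write_text(
        json.dumps(
            {
                "seed": seed,
                "support": traj.support.astype(int).tolist(),
                "edge_index": [list(pr) for pr in upper_triangle_pairs(sc.p)],
                "dynamic": labels.dynamic.astype(bool).tolist(),
                "observed_sd": labels.observed_sd.tolist(),
            }
        )
    )
    files["benchmark"] = out / "benchmark.tsv"
    files["benchmark_truth"] = out / "benchmark_truth.json"

    ctrl_traj, ctrl = static_control(seed=seed + 2)
    write_timeseries(ctrl, out / "static_control.tsv")
    ctrl_labels = label_benchmark_dynamic(ctrl_traj, ctrl.values, n_surrogates=n_label_surrogates, seed=seed + 3)
    (out / "static_control_labels.json").write_text(
        json.dumps({"dynamic": ctrl_labels.dynamic.astype(bool).tolist()})
    )
    files["static_control"] = out / "static_control.tsv"

    _, subjects = mini_cohort(n_subjects=10, seed=seed + 4)
    for s, subj in enumerate(subjects):
        path = out / f"cohort_subject{s + 1:02d}.tsv"
        write_timeseries(subj, path)
        files[f"subject{s + 1}"] = path
    return files
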