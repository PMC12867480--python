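"""Shared helpers for the test suite."""

import numpy as np

from smresidence import (
    classify_states,
    extract_dwells,
    filter_precision,
    fit_koff,
    km_survival,
    link_trajectories,
)
from smresidence.simulate import SimConfig, simulate_condition


def apparent_rate(cfg: SimConfig, bootstrap_reps: int = 200, fit_seed: int = 1):
    """Full analysis chain (filter → link → segment → KM → fit) on one simulation.

    Long-exposure movies treat every localized molecule as bound (motion
    blur removes the free state before detection).
    """
    table, truth = simulate_condition(cfg)
    filtered = filter_precision(table, 40.0)
    trajs = link_trajectories(filtered, 400.0)
    assume_bound = cfg.frame_interval >= 0.1
    labels = [classify_states(t, 5, 220.0, assume_bound) for t in trajs]
    dwells = extract_dwells(trajs, labels, cfg.frame_interval)
    curve = km_survival(dwells, t_min=1.5)
    return fit_koff(curve, bootstrap_reps=bootstrap_reps, seed=fit_seed)


def brute_force_overlap_count(a, b):
    """Per-base oracle for interval-set overlap counting.

    Marks every base covered by ``b`` in a boolean array per chromosome
    and scans each interval of ``a`` for a shared base.
    """
    cover = {}
    for iv in b:
        arr = cover.setdefault(iv.chrom, np.zeros(0, dtype=bool))
        if iv.end > len(arr):
            arr = np.concatenate([arr, np.zeros(iv.end - len(arr), dtype=bool)])
            cover[iv.chrom] = arr
        arr[iv.start : iv.end] = True
    count = 0
    for iv in a:
        arr = cover.get(iv.chrom)
        if arr is not None and np.any(arr[iv.start : min(iv.end, len(arr))]):
            count += 1
    return count


def random_interval_set(rng, n, n_chroms=3, genome=10_000):
    from smresidence.regions import GenomicInterval

    out = []
    for _ in range(n):
        chrom = f"chr{rng.integers(1, n_chroms + 1)}"
        start = int(rng.integers(0, genome - 2))
        end = int(start + 1 + rng.integers(0, 200))
        out.append(GenomicInterval(chrom, start, min(end, genome)))
    return out
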