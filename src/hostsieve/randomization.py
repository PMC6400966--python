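"""Randomization test for feature-subset overlap, and related arithmetic.

When several independent selection methods each return a feature subset,
the number of features present in *all* subsets measures their agreement.
To test whether an observed overlap could arise by chance, each subset is
replaced by a uniformly random subset of the same size, the subsets are
intersected, and the intersection size recorded; repeating this many times
yields a Monte-Carlo null distribution and an estimate of
P(intersection >= observed).

Also provided: the exact count of non-empty feature combinations 2**n - 1
(why exhaustive subset search is infeasible at full scale) and the Pearson
correlation between feature-weight vectors of different models.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "IntersectionTestResult",
    "intersection_test",
    "expected_intersection_size",
    "count_nonempty_subsets",
    "weight_correlation",
    "write_intersection_report",
]

#: subset cardinalities of the eight selected feature sets at full scale
#: (the two searches that converged to an identical subset count once)
DEFAULT_SUBSET_SIZES = (49, 17, 37, 28, 32, 95, 58, 60)
DEFAULT_UNIVERSE = 101


@dataclass
class IntersectionTestResult:
    """Monte-Carlo null for the size of the all-subsets intersection."""

    threshold: int
    p_value: float
    histogram: np.ndarray  # histogram[k] = number of reps with intersection size k
    mean_size: float
    expected_mean: float
    reps: int
    seed: int


def expected_intersection_size(
    subset_sizes: Sequence[int], universe_size: int
) -> float:
    """Closed-form mean intersection size: U * prod(n_i / U).

    Each feature is in subset i with probability n_i/U, independently
    across subsets, so by linearity of expectation the mean size is the
    product of inclusion probabilities times the universe size.
    """
    p = 1.0
    for n in subset_sizes:
        p *= n / universe_size
    return universe_size * p


def intersection_test(
    subset_sizes: Sequence[int] = DEFAULT_SUBSET_SIZES,
    universe_size: int = DEFAULT_UNIVERSE,
    threshold: int = 2,
    reps: int = 10**6,
    seed: int = 0,
    batch_size: int = 50_000,
) -> IntersectionTestResult:
    """Monte-Carlo estimate of P(|intersection of random subsets| >= threshold).

    Every repetition draws each subset uniformly without replacement from
    the universe (vectorised in batches: the n smallest of U random keys
    form a uniform size-n subset), intersects all of them and records the
    size.  Deterministic given ``seed``.
    """
    sizes = [int(n) for n in subset_sizes]
    if any(n < 0 or n > universe_size for n in sizes):
        raise ValueError("subset sizes must lie in [0, universe_size]")
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if reps < 1:
        raise ValueError("reps must be >= 1")

    rng = np.random.default_rng(seed)
    counts = np.zeros(universe_size + 1, dtype=np.int64)
    done = 0
    while done < reps:
        b = min(batch_size, reps - done)
        member = np.ones((b, universe_size), dtype=bool)
        for n in sizes:
            if n == universe_size:
                continue
            if n == 0:
                member[:] = False
                break
            keys = rng.random((b, universe_size))
            picked = np.argpartition(keys, n, axis=1)[:, :n]
            mask = np.zeros((b, universe_size), dtype=bool)
            np.put_along_axis(mask, picked, True, axis=1)
            member &= mask
        counts += np.bincount(member.sum(axis=1), minlength=universe_size + 1)
        done += b

    tail = int(counts[threshold:].sum())
    mean_size = float((np.arange(universe_size + 1) * counts).sum() / reps)
    return IntersectionTestResult(
        threshold=threshold,
        p_value=tail / reps,
        histogram=counts,
        mean_size=mean_size,
        expected_mean=expected_intersection_size(sizes, universe_size),
        reps=reps,
        seed=seed,
    )


def count_nonempty_subsets(n: int) -> int:
    """Number of non-empty feature combinations of n features, exactly 2**n - 1.

    Equals sum over k=1..n of C(n, k); computed in exact integer arithmetic
    so it does not overflow for any practical n.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    return 2**n - 1


def weight_correlation(w1: Sequence[float], w2: Sequence[float]) -> tuple[float, float]:
    """Pearson correlation (r, two-tailed p) between two feature-weight vectors."""
    a = np.asarray(w1, dtype=float)
    b = np.asarray(w2, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 3:
        raise ValueError("need two equal-length 1-D vectors with >= 3 entries")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("weight vectors must have non-zero variance")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)


def write_intersection_report(path: str | Path, result: IntersectionTestResult) -> None:
    nonzero = {
        str(k): int(v) for k, v in enumerate(result.histogram) if v > 0
    }
    report = {
        "threshold": result.threshold,
        "p_value": result.p_value,
        "mean_size": result.mean_size,
        "expected_mean": result.expected_mean,
        "reps": result.reps,
        "seed": result.seed,
        "histogram": nonzero,
    }
    Path(path).write_text(json.dumps(report, indent=2) + "\n")
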