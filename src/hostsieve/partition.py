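"""Lineage-aware labelling and partitioning of a viral corpus.

Class labels derive from the host lineage: viruses whose host lineage is
rooted at Bacteria or Archaea are "phage"; hosts rooted at Eukaryota give
"eukaryote-infecting" viruses, further grouped into seed-plant
(Spermatophyta), vertebrate (Vertebrata), arthropod (Arthropoda) or other.

Partitioning works per class on lineage-sorted records so that similar
viruses (same host lineage) stay together: every m-th lineage block goes to
the held-out test set (m = round(1/test_fraction)); the remaining phages
all enter cross-validation, while eukaryote-infecting viruses - typically
far more numerous - are thinned per lineage with the exponential sampling
rule P(v_i) = exp(-i**alpha), i being the virus's 1-based rank within its
lineage.  The exponent alpha (0.217 by default) can be re-fitted with
:func:`optimize_alpha` so the expected eukaryote CV count matches the phage
count, balancing the classes without discarding rare lineages.  CV members
of each class are finally split, still lineage-sorted, into 5 contiguous
folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

__all__ = [
    "LabeledVirus",
    "PartitionResult",
    "LineageError",
    "label_from_lineage",
    "sampling_probability",
    "expected_cv_count",
    "optimize_alpha",
    "partition",
    "write_partition",
    "read_partition",
]

DEFAULT_ALPHA = 0.217

PHAGE = "phage"
EUKARYOTE = "eukaryote-infecting"

_GROUP_MARKERS = (
    ("seed-plant", "Spermatophyta"),
    ("vertebrate", "Vertebrata"),
    ("arthropod", "Arthropoda"),
)


class LineageError(ValueError):
    """Raised when a host lineage cannot be mapped to a class."""


@dataclass(frozen=True)
class LabeledVirus:
    id: str
    host_lineage: str
    label: str
    group: str | None = None


def _tokens(lineage: str) -> list[str]:
    return [t.strip() for t in lineage.split(";") if t.strip()]


def label_from_lineage(lineage: str) -> tuple[str, str | None]:
    """Map a semicolon-delimited host lineage to (class, group).

    The lineage must be rooted at a superkingdom: Bacteria/Archaea hosts
    give the "phage" class; Eukaryota hosts give "eukaryote-infecting" with
    a group of seed-plant, vertebrate, arthropod or other.
    """
    toks = _tokens(lineage or "")
    if not toks:
        raise LineageError("empty host lineage")
    root = toks[0]
    if root in ("Bacteria", "Archaea"):
        return PHAGE, None
    if root == "Eukaryota":
        for group, marker in _GROUP_MARKERS:
            if marker in toks:
                return EUKARYOTE, group
        return EUKARYOTE, "other"
    raise LineageError(f"unrecognized superkingdom {root!r} in lineage {lineage!r}")


def label_viruses(
    records: Iterable, skip_unlabeled: bool = True
) -> list[LabeledVirus]:
    """Label a batch of sequence records; unlabelable records are skipped."""
    out = []
    for rec in records:
        lineage = getattr(rec, "host_lineage", None)
        try:
            label, group = label_from_lineage(lineage or "")
        except LineageError:
            if skip_unlabeled:
                warnings.warn(f"skipping record {rec.id!r}: unlabelable lineage")
                continue
            raise
        out.append(LabeledVirus(rec.id, lineage, label, group))
    return out


def sampling_probability(i: int, alpha: float = DEFAULT_ALPHA) -> float:
    """P(v_i) = exp(-i**alpha): chance the i-th virus of a lineage enters CV."""
    if i < 1:
        raise ValueError("rank i must be >= 1")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    return float(np.exp(-float(i) ** alpha))


def expected_cv_count(lineage_sizes: Sequence[int], alpha: float) -> float:
    """Expected number of sampled viruses: sum over lineages of sum_i P(v_i)."""
    total = 0.0
    for size in lineage_sizes:
        if size < 1:
            raise ValueError("lineage sizes must be positive")
        ranks = np.arange(1, size + 1, dtype=float)
        total += float(np.exp(-(ranks**alpha)).sum())
    return total


def optimize_alpha(
    lineage_sizes: Sequence[int],
    target_count: int,
    bounds: tuple[float, float] = (1e-3, 10.0),
) -> float:
    """Fit the sampling exponent so the expected CV count hits ``target_count``.

    Scalar bounded minimisation of (E[count](alpha) - target)^2.  Because
    P(v_1) = e^-1 regardless of alpha, targets outside the attainable range
    return the boundary alpha with a warning.
    """
    if target_count < 1:
        raise ValueError("target_count must be positive")
    sizes = list(lineage_sizes)

    def objective(a: float) -> float:
        return (expected_cv_count(sizes, a) - target_count) ** 2

    res = minimize_scalar(objective, bounds=bounds, method="bounded")
    alpha = float(res.x)
    lo, hi = expected_cv_count(sizes, bounds[1]), expected_cv_count(sizes, bounds[0])
    if not (lo <= target_count <= hi):
        warnings.warn(
            f"target {target_count} outside attainable expected-count range "
            f"[{lo:.3g}, {hi:.3g}]; returning boundary alpha {alpha:.4g}"
        )
    return alpha


@dataclass
class PartitionResult:
    """CV fold assignment (1-5 per record id), test ids, and the settings used."""

    cv_folds: dict[str, int]
    test_ids: list[str]
    alpha: float
    seed: int

    def fold_array(self, ids: Sequence[str]) -> np.ndarray:
        return np.array([self.cv_folds[i] for i in ids], dtype=int)


def _lineage_blocks(viruses: list[LabeledVirus]) -> list[list[LabeledVirus]]:
    """Group records by lineage; blocks sorted alphabetically by lineage."""
    by_lineage: dict[str, list[LabeledVirus]] = {}
    for v in viruses:
        by_lineage.setdefault(v.host_lineage, []).append(v)
    blocks = []
    for lineage in sorted(by_lineage):
        blocks.append(sorted(by_lineage[lineage], key=lambda v: v.id))
    return blocks


def partition(
    viruses: Sequence[LabeledVirus],
    test_fraction: float = 0.2,
    alpha: float = DEFAULT_ALPHA,
    seed: int = 0,
    n_folds: int = 5,
) -> PartitionResult:
    """Split a labelled corpus into lineage-sorted CV folds and a test set.

    Deterministic given ``seed``; permuting the input order does not change
    the result because lineages and ids are sorted first.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    labels = {v.label for v in viruses}
    if labels != {PHAGE, EUKARYOTE}:
        raise ValueError(f"need both classes present, got {sorted(labels)}")
    rng = np.random.default_rng(seed)
    every = max(2, round(1 / test_fraction))

    cv_folds: dict[str, int] = {}
    test_ids: list[str] = []
    for label in (PHAGE, EUKARYOTE):
        members = [v for v in viruses if v.label == label]
        blocks = _lineage_blocks(members)
        cv_members: list[LabeledVirus] = []
        for b, block in enumerate(blocks):
            if b % every == every - 1:  # every m-th lineage block is held out
                test_ids.extend(v.id for v in block)
                continue
            if label == PHAGE:
                cv_members.extend(block)
            else:
                for i, v in enumerate(block, start=1):
                    if rng.random() < sampling_probability(i, alpha):
                        cv_members.append(v)
        if len(cv_members) < n_folds:
            raise ValueError(
                f"class {label!r} has only {len(cv_members)} CV members; "
                f"need >= {n_folds}"
            )
        # lineage-sorted contiguous folds keep same-lineage viruses adjacent
        for f, chunk in enumerate(
            np.array_split(np.arange(len(cv_members)), n_folds), start=1
        ):
            for idx in chunk:
                cv_folds[cv_members[idx].id] = f

    return PartitionResult(
        cv_folds=cv_folds, test_ids=sorted(test_ids), alpha=alpha, seed=seed
    )


def write_partition(path: str | Path, result: PartitionResult, viruses: Sequence[LabeledVirus]) -> None:
    info = {v.id: v for v in viruses}
    rows = []
    for vid, fold in sorted(result.cv_folds.items()):
        v = info[vid]
        rows.append((vid, v.label, v.group or "", f"cv{fold}"))
    for vid in result.test_ids:
        v = info[vid]
        rows.append((vid, v.label, v.group or "", "test"))
    pd.DataFrame(rows, columns=["id", "class", "group", "split"]).to_csv(
        path, sep="\t", index=False
    )


def read_partition(path: str | Path) -> tuple[dict[str, int], list[str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    cv = {
        r["id"]: int(r["split"][2:])
        for _, r in df.iterrows()
        if r["split"].startswith("cv")
    }
    test = [r["id"] for _, r in df.iterrows() if r["split"] == "test"]
    return cv, test
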