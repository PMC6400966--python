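"""Seeded synthetic viral corpora for end-to-end testing without downloads.

Real phage and eukaryotic-virus genomes differ in oligonucleotide
composition; the generator emulates that with class-conditional first-order
Markov chains over {A, C, G, T}.  First-order chains (rather than i.i.d.
draws) are used deliberately: they plant signal at the dinucleotide level,
which is exactly where the relative-frequency features look.  Each class
also has its own DNA/RNA mix (phage-like genomes are almost all DNA,
mirroring the strong skew in sequence databases) and a set of synthetic
host lineages, so that lineage-aware partitioning is exercisable.

The default conditions: 60 genomes per class of 1000-3000 bases, the
phage-like class with stationary GC content 0.65 and strong base
persistence, the eukaryote-like class with GC 0.35 and weaker persistence,
95% / 50% DNA respectively, and 6 host lineages per class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .features import BASES, NucleicAcid, SequenceRecord

__all__ = [
    "CorpusSpec",
    "transition_matrix",
    "stationary_distribution",
    "generate_corpus",
    "corpus_metadata",
    "add_noise_features",
    "planted_dataset",
]

#: synthetic eukaryote host lineages, one per group plus extras
_EUK_LINEAGES = (
    "Eukaryota; Viridiplantae; Streptophyta; Spermatophyta; Magnoliopsida",
    "Eukaryota; Metazoa; Chordata; Craniata; Vertebrata; Mammalia",
    "Eukaryota; Metazoa; Ecdysozoa; Arthropoda; Insecta",
    "Eukaryota; Fungi; Dikarya; Ascomycota",
    "Eukaryota; Metazoa; Chordata; Craniata; Vertebrata; Aves",
    "Eukaryota; Viridiplantae; Streptophyta; Spermatophyta; Liliopsida",
)
_PHAGE_LINEAGES = (
    "Bacteria; Proteobacteria; Gammaproteobacteria; Enterobacterales",
    "Bacteria; Firmicutes; Bacilli; Lactobacillales",
    "Bacteria; Actinobacteria; Actinomycetia; Streptomycetales",
    "Bacteria; Bacteroidetes; Bacteroidia; Bacteroidales",
    "Archaea; Euryarchaeota; Halobacteria; Halobacteriales",
    "Bacteria; Cyanobacteria; Synechococcales",
)


def transition_matrix(gc: float = 0.5, persistence: float = 0.0) -> np.ndarray:
    """First-order transition matrix with stationary GC content ``gc``.

    Rows mix the stationary distribution (AT split evenly, GC split evenly)
    with the identity: T = (1 - persistence) * 1 pi^T + persistence * I.
    ``persistence`` > 0 makes same-base dinucleotides over-represented
    relative to composition, giving the chain genuine second-order structure.
    """
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    if not 0 <= persistence < 1:
        raise ValueError("persistence must be in [0, 1)")
    pi = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return (1 - persistence) * np.tile(pi, (4, 1)) + persistence * np.eye(4)


def stationary_distribution(T: np.ndarray) -> np.ndarray:
    """Stationary distribution of a 4x4 transition matrix (left eigenvector)."""
    vals, vecs = np.linalg.eig(T.T)
    v = np.real(vecs[:, np.argmin(np.abs(vals - 1))])
    v = np.abs(v)
    return v / v.sum()


@dataclass
class CorpusSpec:
    """Study conditions for one synthetic two-class corpus."""

    n_per_class: int = 60
    length_range: tuple[int, int] = (1000, 3000)
    phage_transitions: np.ndarray = field(
        default_factory=lambda: transition_matrix(gc=0.65, persistence=0.30)
    )
    eukaryote_transitions: np.ndarray = field(
        default_factory=lambda: transition_matrix(gc=0.35, persistence=0.10)
    )
    phage_dna_fraction: float = 0.95
    eukaryote_dna_fraction: float = 0.50
    n_lineages_per_class: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("phage_transitions", "eukaryote_transitions"):
            T = np.asarray(getattr(self, name), dtype=float)
            if T.shape != (4, 4) or (T < 0).any() or not np.allclose(
                T.sum(axis=1), 1.0, atol=1e-9
            ):
                raise ValueError(f"{name} must be a 4x4 row-stochastic matrix")
            setattr(self, name, T)
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.length_range[0] < 3 or self.length_range[0] > self.length_range[1]:
            raise ValueError("invalid length_range")
        if not 1 <= self.n_lineages_per_class <= 6:
            raise ValueError("n_lineages_per_class must be in 1..6")


def _markov_sequence(T: np.ndarray, length: int, rng: np.random.Generator) -> str:
    pi = stationary_distribution(T)
    cum = np.cumsum(T, axis=1)
    u = rng.random(length)
    states = np.empty(length, dtype=np.int64)
    states[0] = np.searchsorted(np.cumsum(pi), u[0])
    for t in range(1, length):
        states[t] = np.searchsorted(cum[states[t - 1]], u[t])
    return "".join(BASES[s] for s in states)


def generate_corpus(spec: CorpusSpec) -> list[SequenceRecord]:
    """Generate the two-class corpus; byte-identical for identical specs."""
    rng = np.random.default_rng(spec.seed)
    records: list[SequenceRecord] = []
    classes = (
        ("phage", spec.phage_transitions, spec.phage_dna_fraction, _PHAGE_LINEAGES),
        ("euk", spec.eukaryote_transitions, spec.eukaryote_dna_fraction, _EUK_LINEAGES),
    )
    lo, hi = spec.length_range
    for tag, T, dna_frac, lineages in classes:
        lineages = lineages[: spec.n_lineages_per_class]
        for i in range(spec.n_per_class):
            length = int(rng.integers(lo, hi + 1))
            seq = _markov_sequence(T, length, rng)
            na = NucleicAcid.DNA if rng.random() < dna_frac else NucleicAcid.RNA
            if na is NucleicAcid.RNA:
                seq = seq.replace("T", "U")
            records.append(
                SequenceRecord(
                    id=f"{tag}_{i:04d}",
                    residues=seq,
                    nucleic_acid=na,
                    host_lineage=lineages[i % len(lineages)],
                )
            )
    return records


def corpus_metadata(records: Sequence[SequenceRecord]) -> pd.DataFrame:
    """Metadata table (id, nucleic_acid, host_lineage) for a generated corpus."""
    return pd.DataFrame(
        {
            "id": [r.id for r in records],
            "nucleic_acid": [r.nucleic_acid.value for r in records],
            "host_lineage": [r.host_lineage or "" for r in records],
        }
    )


def add_noise_features(
    X: np.ndarray, n_noise: int, seed: int = 0
) -> tuple[np.ndarray, list[str]]:
    """Append standard-normal noise columns; returns (matrix, noise names).

    Used by selection tests: informative columns come from real extracted
    features, appended columns carry no class signal by construction.
    """
    rng = np.random.default_rng(seed)
    X = np.asarray(X, dtype=float)
    noise = rng.standard_normal((X.shape[0], n_noise))
    names = [f"noise_{i}" for i in range(n_noise)]
    return np.hstack([X, noise]), names


def planted_dataset(
    n_samples: int = 80,
    n_informative: int = 2,
    n_noise: int = 3,
    effect_size: float = 2.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Small Gaussian dataset with known informative columns.

    Informative columns have class means separated by ``effect_size`` SDs;
    noise columns are pure N(0, 1) in both classes.  Returns
    (X, y, informative_indices); used to verify that subset searches recover
    planted signal.
    """
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n_samples // 2)
    X = rng.standard_normal((len(y), n_informative + n_noise))
    X[:, :n_informative] += np.outer(y, np.full(n_informative, effect_size))
    return X, y, list(range(n_informative))
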