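"""Simulator of metagenomic sequence fragments.

Fragments of a fixed length ``s`` emulate the reads/contigs produced by
NGS platforms and assemblers.  A source genome of length ``S`` is drawn
with probability proportional to its number of valid windows, ``S - s + 1``
(only genomes with ``S >= s`` are eligible), the start offset is uniform
over those windows, and each base is substituted independently with
probability ``r`` by one of the three other bases - a symmetric stand-in
for both viral mutation and sequencing error.  Fragments never wrap around
the sequence end (genomes are treated as linear) and sources are sampled
with replacement.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .features import SequenceRecord

__all__ = ["FragmentSpec", "Fragment", "DEFAULT_LENGTHS", "DEFAULT_RATES",
           "simulate_fragments", "write_fragments"]

#: fragment lengths spanning the read-to-long-contig range
DEFAULT_LENGTHS = (100, 250, 500, 1000, 3000, 10000)
#: substitution rates: error-free and a 2% noise condition
DEFAULT_RATES = (0.0, 0.02)

_BASES = np.frombuffer(b"ACGT", dtype="S1").astype("U1")
_ALTS = {b: [a for a in "ACGT" if a != b] for b in "ACGT"}


@dataclass(frozen=True)
class FragmentSpec:
    """Length ``s``, substitution rate ``r`` and count of one simulation run."""

    s: int
    r: float = 0.0
    n_fragments: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.s < 1:
            raise ValueError("fragment length s must be >= 1")
        if not 0.0 <= self.r <= 1.0:
            raise ValueError("substitution rate r must be in [0, 1]")
        if self.n_fragments < 1:
            raise ValueError("n_fragments must be >= 1")


@dataclass(frozen=True)
class Fragment:
    residues: str
    source_id: str
    start: int
    n_substitutions: int


def simulate_fragments(
    corpus: Sequence[SequenceRecord], spec: FragmentSpec
) -> list[Fragment]:
    """Draw ``spec.n_fragments`` fragments from a corpus; seeded, with replacement."""
    eligible = [rec for rec in corpus if len(rec.residues) >= spec.s]
    if not eligible:
        raise ValueError(
            f"no sequence of length >= {spec.s} in a corpus of {len(corpus)} records"
        )
    rng = np.random.default_rng(spec.seed)
    weights = np.array(
        [len(rec.residues) - spec.s + 1 for rec in eligible], dtype=float
    )
    probs = weights / weights.sum()

    fragments = []
    choices = rng.choice(len(eligible), size=spec.n_fragments, p=probs)
    for src_idx in choices:
        rec = eligible[src_idx]
        start = int(rng.integers(0, len(rec.residues) - spec.s + 1))
        piece = rec.residues[start : start + spec.s]
        n_sub = 0
        if spec.r > 0:
            chars = list(piece)
            hits = np.flatnonzero(rng.random(spec.s) < spec.r)
            for pos in hits:
                original = chars[pos].upper().replace("U", "T")
                alts = _ALTS.get(original)
                if alts is None:
                    continue  # ambiguity codes are left untouched
                chars[pos] = alts[int(rng.integers(3))]
                n_sub += 1
            piece = "".join(chars)
        fragments.append(
            Fragment(
                residues=piece,
                source_id=rec.id,
                start=start,
                n_substitutions=n_sub,
            )
        )
    return fragments


def write_fragments(
    fasta_path: str | Path, manifest_path: str | Path, fragments: Sequence[Fragment],
    spec: FragmentSpec,
) -> None:
    """FASTA with provenance-encoding headers plus a TSV manifest."""
    from .io import write_fasta

    names = [
        f"{frag.source_id}|start={frag.start}|s={spec.s}|r={spec.r}|i={i}"
        for i, frag in enumerate(fragments)
    ]
    write_fasta(fasta_path, zip(names, (f.residues for f in fragments)))
    pd.DataFrame(
        {
            "fragment": names,
            "source_id": [f.source_id for f in fragments],
            "start": [f.start for f in fragments],
            "length": spec.s,
            "substitution_rate": spec.r,
            "n_substitutions": [f.n_substitutions for f in fragments],
        }
    ).to_csv(manifest_path, sep="\t", index=False)
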