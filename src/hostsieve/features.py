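"""Composition feature vectors for viral genomic sequences.

A genome is summarised by a fixed, 101-element vector of single-strand
composition statistics:

* 4 mononucleotide absolute frequencies ``f_X``,
* 16 dinucleotide absolute frequencies ``f_XY``,
* 16 relative dinucleotide frequencies ``rho_XY = f_XY / (f_X * f_Y)``,
* 64 relative trinucleotide frequencies
  ``gamma_XYZ = f_XYZ * f_X * f_Y * f_Z / (f_XY * f_YZ * f_XNZ)``
  where ``N`` stands for any nucleotide in the gapped frequency ``f_XNZ``,
* 1 nucleic-acid indicator (+1 for DNA genomes, -1 for RNA genomes).

The relative frequencies are odds-ratio-style statistics that are ~1 when a
k-mer is exactly as abundant as expected from lower-order composition; they
capture the dinucleotide/trinucleotide "bias" signature that differs between
viruses of distinct host taxa.  Only the given strand is counted - no
reverse-complement symmetrisation.

Absolute frequencies are counts divided by the number of fully unambiguous
windows of the corresponding length; windows containing any IUPAC ambiguity
code are skipped entirely.  ``U`` is mapped to ``T`` so DNA and RNA genomes
share one 4-letter alphabet; the chemistry is carried by the indicator
feature instead.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NucleicAcid",
    "SequenceRecord",
    "FEATURE_NAMES",
    "N_FEATURES",
    "FEATURE_BLOCKS",
    "extract_features",
    "extract_matrix",
    "relative_dinucleotide_frequency",
    "relative_trinucleotide_frequency",
    "StandardizationParams",
]

BASES = "ACGT"
DINUCLEOTIDES = tuple(a + b for a in BASES for b in BASES)
TRINUCLEOTIDES = tuple(a + b + c for a in BASES for b in BASES for c in BASES)

#: Canonical feature order: mononucleotide frequencies (A,C,G,T), absolute
#: dinucleotide frequencies (AA..TT), relative dinucleotide frequencies,
#: relative trinucleotide frequencies (AAA..TTT), nucleic-acid indicator.
FEATURE_NAMES: tuple[str, ...] = (
    tuple(f"f_{b}" for b in BASES)
    + tuple(f"f_{d}" for d in DINUCLEOTIDES)
    + tuple(f"rho_{d}" for d in DINUCLEOTIDES)
    + tuple(f"gamma_{t}" for t in TRINUCLEOTIDES)
    + ("nucleic_acid",)
)
N_FEATURES = len(FEATURE_NAMES)

#: (name, size) of the contiguous blocks making up the schema.
FEATURE_BLOCKS: tuple[tuple[str, int], ...] = (
    ("mononucleotide", 4),
    ("dinucleotide", 16),
    ("relative_dinucleotide", 16),
    ("relative_trinucleotide", 64),
    ("nucleic_acid", 1),
)

# byte-value lookup: A=0, C=1, G=2, T/U=3, every IUPAC ambiguity code = -1,
# anything else = -2 (rejected)
_LUT = np.full(256, -2, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _LUT[ord(_b)] = _i
    _LUT[ord(_b.lower())] = _i
_LUT[ord("U")] = _LUT[ord("u")] = 3
for _c in "RYSWKMBDHVN":
    _LUT[ord(_c)] = _LUT[ord(_c.lower())] = -1


class NucleicAcid(str, Enum):
    """Genome chemistry of the virus; supplied as metadata, never inferred."""

    DNA = "DNA"
    RNA = "RNA"

    @classmethod
    def coerce(cls, value: "NucleicAcid | str") -> "NucleicAcid":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).upper())
        except ValueError:
            raise ValueError(
                f"unknown nucleic acid type {value!r}; expected DNA or RNA"
            ) from None


@dataclass(frozen=True)
class SequenceRecord:
    """One viral genomic sequence plus the metadata the pipeline needs."""

    id: str
    residues: str
    nucleic_acid: NucleicAcid
    host_lineage: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "nucleic_acid", NucleicAcid.coerce(self.nucleic_acid))
        if not self.residues:
            raise ValueError(f"record {self.id!r}: empty sequence")


def encode_sequence(residues: str) -> np.ndarray:
    """Map residues to integer codes (A=0, C=1, G=2, T/U=3, ambiguity=-1)."""
    raw = np.frombuffer(residues.encode("ascii"), dtype=np.uint8)
    codes = _LUT[raw]
    if (codes == -2).any():
        bad = sorted({chr(b) for b in raw[codes == -2]})
        raise ValueError(f"invalid residue characters: {bad}")
    return codes


def _check_fractions(*values: float) -> None:
    for v in values:
        if v < 0:
            raise ValueError(f"frequencies must be non-negative, got {v}")


def relative_dinucleotide_frequency(f_xy: float, f_x: float, f_y: float) -> float:
    """Dinucleotide odds ratio f_XY / (f_X * f_Y); 0 if the denominator is 0."""
    _check_fractions(f_xy, f_x, f_y)
    denom = f_x * f_y
    return f_xy / denom if denom > 0 else 0.0


def relative_trinucleotide_frequency(
    f_xyz: float,
    f_xy: float,
    f_yz: float,
    f_xnz: float,
    f_x: float,
    f_y: float,
    f_z: float,
) -> float:
    """Trinucleotide ratio corrected for all first- and second-order effects.

    gamma_XYZ = f_XYZ * f_X * f_Y * f_Z / (f_XY * f_YZ * f_XNZ), where f_XNZ
    is the frequency of length-3 windows with X first, Z third and any middle
    base.  Returns 0 whenever a denominator factor vanishes.
    """
    _check_fractions(f_xyz, f_xy, f_yz, f_xnz, f_x, f_y, f_z)
    denom = f_xy * f_yz * f_xnz
    if denom == 0:
        return 0.0
    return f_xyz * f_x * f_y * f_z / denom


def _window_frequencies(codes: np.ndarray):
    """Absolute k-mer frequencies over unambiguous windows, k = 1, 2, 3."""
    valid = codes >= 0
    n1 = int(valid.sum())
    if n1 == 0:
        raise ValueError("sequence has no unambiguous bases")
    mono = np.bincount(codes[valid], minlength=4) / n1

    ok2 = valid[:-1] & valid[1:]
    idx2 = 4 * codes[:-1] + codes[1:]
    n2 = int(ok2.sum())
    di = (
        np.bincount(idx2[ok2], minlength=16) / n2
        if n2 > 0
        else np.zeros(16)
    )

    ok3 = valid[:-2] & valid[1:-1] & valid[2:]
    idx3 = 16 * codes[:-2] + 4 * codes[1:-1] + codes[2:]
    n3 = int(ok3.sum())
    if n3 == 0:
        raise ValueError("sequence has no unambiguous trinucleotide window")
    tri = np.bincount(idx3[ok3], minlength=64) / n3
    return mono, di, tri


def extract_features(record: SequenceRecord) -> np.ndarray:
    """Transform one sequence record into the 101-element feature vector.

    Requires at least one fully unambiguous trinucleotide window (i.e. three
    consecutive plain A/C/G/T bases).
    """
    codes = encode_sequence(record.residues)
    if len(codes) < 3:
        raise ValueError(
            f"record {record.id!r}: need >=3 bases for trinucleotide windows, "
            f"got {len(codes)}"
        )
    mono, di, tri = _window_frequencies(codes)

    tri3 = tri.reshape(4, 4, 4)
    # gapped frequency f_XNZ: sum over the (unambiguous) middle base
    gap = tri3.sum(axis=1)

    rho = np.zeros(16)
    for i, (x, y) in enumerate(itertools.product(range(4), repeat=2)):
        rho[i] = relative_dinucleotide_frequency(di[i], mono[x], mono[y])

    gamma = np.zeros(64)
    di3 = di.reshape(4, 4)
    for i, (x, y, z) in enumerate(itertools.product(range(4), repeat=3)):
        gamma[i] = relative_trinucleotide_frequency(
            tri3[x, y, z], di3[x, y], di3[y, z], gap[x, z],
            mono[x], mono[y], mono[z],
        )

    indicator = 1.0 if record.nucleic_acid is NucleicAcid.DNA else -1.0
    return np.concatenate([mono, di, rho, gamma, [indicator]])


def extract_matrix(records: Iterable[SequenceRecord]) -> pd.DataFrame:
    """Feature matrix for a collection of records (rows indexed by record id)."""
    records = list(records)
    data = np.vstack([extract_features(r) for r in records])
    return pd.DataFrame(data, index=[r.id for r in records], columns=FEATURE_NAMES)


@dataclass
class StandardizationParams:
    """Per-feature mean/SD for zero-mean unit-variance scaling.

    Features that are constant on the fitting data (sigma = 0) are mapped to
    exactly 0 rather than divided by zero.
    """

    mean: np.ndarray
    std: np.ndarray
    feature_names: tuple[str, ...] = field(default=FEATURE_NAMES)

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.std = np.asarray(self.std, dtype=float)
        if self.mean.shape != self.std.shape:
            raise ValueError("mean/std length mismatch")
        if (self.std < 0).any():
            raise ValueError("standard deviations must be non-negative")

    @classmethod
    def fit(
        cls, X: np.ndarray, feature_names: Sequence[str] | None = None
    ) -> "StandardizationParams":
        X = np.asarray(X, dtype=float)
        names = tuple(feature_names) if feature_names is not None else tuple(
            f"x{i}" for i in range(X.shape[1])
        )
        if len(names) != X.shape[1]:
            raise ValueError("feature_names length does not match matrix width")
        return cls(mean=X.mean(axis=0), std=X.std(axis=0), feature_names=names)

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[-1] != self.mean.shape[0]:
            raise ValueError(
                f"expected {self.mean.shape[0]} features, got {X.shape[-1]}"
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (X - self.mean) / self.std
        return np.where(self.std == 0, 0.0, z)
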