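"""Composition descriptors: AAC, PAAC (dipeptide), and PseAAC.

Component ordering is fixed and documented so serialized vectors are
portable: AAC components follow the alphabetical residue order A..Y;
PAAC components are the 400 ordered residue pairs in row-major
alphabetical order (AA, AC, ..., YY); PseAAC is the 20 AAC-ordered
composition terms followed by the lambda sequence-order terms
theta_1..theta_lambda.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .seqio import AMINO_ACIDS, ProteinSequence

logger = logging.getLogger(__name__)

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

AAC_COMPONENTS: tuple[str, ...] = tuple(f"AAC_{aa}" for aa in AMINO_ACIDS)
PAAC_COMPONENTS: tuple[str, ...] = tuple(
    f"PAAC_{a}{b}" for a, b in itertools.product(AMINO_ACIDS, repeat=2)
)


def pseaac_components(lam: int) -> tuple[str, ...]:
    return tuple(f"PseAAC_{aa}" for aa in AMINO_ACIDS) + tuple(
        f"PseAAC_theta{j}" for j in range(1, lam + 1)
    )


# Per-residue physicochemical property tables used by the sequence-order
# correlation terms. Hydrophobicity after Tanford (1962); hydrophilicity
# after Hopp & Woods (1981); side-chain masses in daltons (glycine's H
# side chain = 1). Values are the raw (unstandardized) scales.
TANFORD_HYDROPHOBICITY: dict[str, float] = {
    "A": 0.62, "C": 0.29, "D": -0.90, "E": -0.74, "F": 1.19,
    "G": 0.48, "H": -0.40, "I": 1.38, "K": -1.50, "L": 1.06,
    "M": 0.64, "N": -0.78, "P": 0.12, "Q": -0.85, "R": -2.53,
    "S": -0.18, "T": -0.05, "V": 1.08, "W": 0.81, "Y": 0.26,
}
HOPP_WOODS_HYDROPHILICITY: dict[str, float] = {
    "A": -0.5, "C": -1.0, "D": 3.0, "E": 3.0, "F": -2.5,
    "G": 0.0, "H": -0.5, "I": -1.8, "K": 3.0, "L": -1.8,
    "M": -1.3, "N": 0.2, "P": 0.0, "Q": 0.2, "R": 3.0,
    "S": 0.3, "T": -0.4, "V": -1.5, "W": -3.4, "Y": -2.3,
}
SIDE_CHAIN_MASS: dict[str, float] = {
    "A": 15.0, "C": 47.0, "D": 59.0, "E": 73.0, "F": 91.0,
    "G": 1.0, "H": 82.0, "I": 57.0, "K": 73.0, "L": 57.0,
    "M": 75.0, "N": 58.0, "P": 42.0, "Q": 72.0, "R": 101.0,
    "S": 31.0, "T": 45.0, "V": 43.0, "W": 130.0, "Y": 107.0,
}


class DescriptorError(ValueError):
    """Raised for descriptor precondition violations."""


@dataclass(frozen=True)
class PropertyTable:
    """Per-residue values of one physicochemical property (20 entries)."""

    name: str
    values: dict[str, float]
    standardized: bool = False

    def __post_init__(self) -> None:
        if set(self.values) != set(AMINO_ACIDS):
            raise DescriptorError(
                f"property table {self.name!r} must cover exactly the 20 amino acids"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.values[aa] for aa in AMINO_ACIDS], dtype=float)

    def __getitem__(self, aa: str) -> float:
        return self.values[aa]


def standardize_property(raw: PropertyTable) -> PropertyTable:
    """Center by the 20-residue mean, scale by the population (÷20) sd.

    The output has mean 0 and population variance 1 by construction.
    A constant input table has zero variance and is rejected.
    """
    vals = raw.as_array()
    mean = vals.mean()
    sd = math.sqrt(np.mean((vals - mean) ** 2))
    if sd == 0.0:
        raise DescriptorError(f"property table {raw.name!r} is constant; cannot standardize")
    std = (vals - mean) / sd
    return PropertyTable(
        name=raw.name,
        values={aa: float(v) for aa, v in zip(AMINO_ACIDS, std)},
        standardized=True,
    )


def default_property_tables() -> tuple[PropertyTable, PropertyTable, PropertyTable]:
    """Standardized (hydrophobicity, hydrophilicity, side-chain mass) tables."""
    return (
        standardize_property(PropertyTable("hydrophobicity", TANFORD_HYDROPHOBICITY)),
        standardize_property(PropertyTable("hydrophilicity", HOPP_WOODS_HYDROPHILICITY)),
        standardize_property(PropertyTable("side_chain_mass", SIDE_CHAIN_MASS)),
    )


@dataclass(frozen=True)
class PseAACParams:
    """Sequence-order depth lambda and weight omega for PseAAC.

    ``clamp`` controls behaviour for sequences with L <= lambda: error by
    default, or reduce lambda to L-1 with a logged warning when True.
    """

    lam: int = 30
    omega: float = 0.05
    clamp: bool = False

    def __post_init__(self) -> None:
        if self.lam < 1:
            raise DescriptorError(f"lambda must be >= 1, got {self.lam}")
        if not (0.05 <= self.omega <= 0.7):
            raise DescriptorError(f"omega must lie in [0.05, 0.7], got {self.omega}")


@dataclass(frozen=True)
class CompositionVector:
    """A fixed-length composition descriptor with a kind tag.

    kind is one of ``AAC`` (length 20), ``PAAC`` (length 400) or
    ``PseAAC`` (length 20 + lambda).
    """

    kind: str
    values: np.ndarray
    components: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.shape != (len(self.components),):
            raise DescriptorError(
                f"{self.kind}: {len(self.values)} values for {len(self.components)} components"
            )

    def __len__(self) -> int:
        return len(self.values)

    def sum(self) -> float:
        return float(self.values.sum())


def compute_aac(seq: ProteinSequence) -> CompositionVector:
    """Amino acid composition: the 20 residue fractions F_i / L."""
    counts = np.zeros(20)
    for c in seq.residues:
        counts[_AA_INDEX[c]] += 1
    return CompositionVector("AAC", counts / len(seq), AAC_COMPONENTS)


def compute_paac(seq: ProteinSequence) -> CompositionVector:
    """Pair (dipeptide) composition over the L-1 overlapping adjacent pairs."""
    if len(seq) < 2:
        raise DescriptorError(f"PAAC needs L >= 2, got L={len(seq)} for {seq.id!r}")
    counts = np.zeros((20, 20))
    r = seq.residues
    for a, b in zip(r, r[1:]):
        counts[_AA_INDEX[a], _AA_INDEX[b]] += 1
    return CompositionVector("PAAC", counts.ravel() / (len(seq) - 1), PAAC_COMPONENTS)


def _effective_lambda(seq: ProteinSequence, params: PseAACParams) -> int:
    if params.lam < len(seq):
        return params.lam
    if params.clamp:
        lam = len(seq) - 1
        logger.warning(
            "sequence %s has L=%d <= lambda=%d; clamping lambda to %d",
            seq.id, len(seq), params.lam, lam,
        )
        return lam
    raise DescriptorError(
        f"lambda={params.lam} must be < L={len(seq)} for sequence {seq.id!r}"
    )


def theta_factors(
    seq: ProteinSequence,
    props: tuple[PropertyTable, PropertyTable, PropertyTable],
    lam: int,
) -> np.ndarray:
    """Sequence-order correlation factors theta_1..theta_lam.

    theta_j is the mean over i of the correlation function of residue
    pairs (R_i, R_{i+j}); the correlation function is the mean of squared
    standardized-property differences, so every theta_j >= 0.
    """
    if lam >= len(seq):
        raise DescriptorError(f"lambda={lam} must be < L={len(seq)}")
    for p in props:
        if not p.standardized:
            raise DescriptorError(f"property table {p.name!r} is not standardized")
    arrs = [p.as_array() for p in props]
    idx = np.array([_AA_INDEX[c] for c in seq.residues])
    L = len(idx)
    thetas = np.empty(lam)
    for j in range(1, lam + 1):
        left, right = idx[: L - j], idx[j:]
        acc = np.zeros(L - j)
        for a in arrs:
            acc += (a[right] - a[left]) ** 2
        thetas[j - 1] = acc.mean() / 3.0
    return thetas


def compute_pseaac(
    seq: ProteinSequence,
    params: PseAACParams | None = None,
    props: tuple[PropertyTable, PropertyTable, PropertyTable] | None = None,
) -> CompositionVector:
    """Pseudo amino acid composition of size 20 + lambda.

    The first 20 components are f_i / (sum_r f_r + omega * sum_j theta_j)
    with f the normalized residue frequencies (so sum_r f_r = 1); the tail
    components are omega * theta_j over the same denominator. The full
    vector therefore sums to 1.
    """
    params = params or PseAACParams()
    props = props or default_property_tables()
    lam = _effective_lambda(seq, params)
    freqs = compute_aac(seq).values  # normalized: sums to 1
    thetas = theta_factors(seq, props, lam)
    denom = freqs.sum() + params.omega * thetas.sum()
    values = np.concatenate([freqs / denom, params.omega * thetas / denom])
    # pad with zeros if lambda was clamped, keeping the declared length
    if lam < params.lam:
        values = np.concatenate([values, np.zeros(params.lam - lam)])
    return CompositionVector("PseAAC", values, pseaac_components(params.lam))


_COMPUTE = {
    "AAC": lambda seq, params, props: compute_aac(seq),
    "PAAC": lambda seq, params, props: compute_paac(seq),
    "PseAAC": lambda seq, params, props: compute_pseaac(seq, params, props),
}


def compute_descriptor(
    seq: ProteinSequence,
    kind: str,
    params: PseAACParams | None = None,
    props: tuple[PropertyTable, PropertyTable, PropertyTable] | None = None,
) -> CompositionVector:
    """Dispatch to compute_aac / compute_paac / compute_pseaac by kind tag."""
    if kind not in _COMPUTE:
        raise DescriptorError(f"unknown descriptor kind {kind!r}")
    return _COMPUTE[kind](seq, params, props)
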