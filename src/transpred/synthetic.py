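"""Seeded generators for every input the pipeline consumes.

These produce protein datasets with class-specific residue biases,
homolog sets at a target percent identity, and mock hit tables in the
exact tabular dialects the other modules read — so the whole pipeline is
exercisable without external search tools or databases. Every generator
is a pure function of its configuration, seed included.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .homologs import HomologSet
from .seqio import (
    AMINO_ACIDS,
    LabeledDataset,
    ProteinSequence,
    write_fasta,
    write_label_table,
)
from .tcdb_transfer import BlastHit, ThresholdProfile, builtin_profiles

# hydrophobic residues enriched in membrane-spanning segments
HYDROPHOBIC = "AILMFVW"


@dataclass
class SimulationConfig:
    """Knobs for the two-class dataset generator."""

    seed: int = 0
    n_per_class: int = 50
    min_length: int = 80
    max_length: int = 400
    # per-residue frequency multipliers applied to the uniform base
    transporter_bias: dict[str, float] = field(
        default_factory=lambda: {aa: 3.0 for aa in HYDROPHOBIC}
    )
    non_transporter_bias: dict[str, float] = field(
        default_factory=lambda: {"D": 2.5, "E": 2.5, "K": 2.5, "N": 2.0, "S": 2.0}
    )

    def __post_init__(self) -> None:
        if self.min_length < 1 or self.max_length < self.min_length:
            raise ValueError(
                f"bad length bounds ({self.min_length}, {self.max_length})"
            )
        for bias in (self.transporter_bias, self.non_transporter_bias):
            if any(v <= 0 for v in bias.values()):
                raise ValueError("bias multipliers must be positive")


def _class_probs(bias: dict[str, float]) -> np.ndarray:
    weights = np.array([bias.get(aa, 1.0) for aa in AMINO_ACIDS])
    return weights / weights.sum()


def _random_sequence(
    rng: np.random.Generator, seq_id: str, length: int, probs: np.ndarray
) -> ProteinSequence:
    idx = rng.choice(20, size=length, p=probs)
    return ProteinSequence(seq_id, "".join(AMINO_ACIDS[i] for i in idx))


def simulate_dataset(config: SimulationConfig) -> LabeledDataset:
    """Two classes with distinct residue-frequency profiles."""
    rng = np.random.default_rng(config.seed)
    records: list[tuple[ProteinSequence, str]] = []
    for label, bias, prefix in (
        ("T", config.transporter_bias, "T"),
        ("NT", config.non_transporter_bias, "NT"),
    ):
        probs = _class_probs(bias)
        for i in range(config.n_per_class):
            length = int(rng.integers(config.min_length, config.max_length + 1))
            seq = _random_sequence(rng, f"{prefix}{i:04d}", length, probs)
            records.append((seq, label))
    return LabeledDataset(records)


def write_dataset(
    data: LabeledDataset, fasta_path: str | Path, label_path: str | Path
) -> None:
    write_fasta(data.sequences, fasta_path)
    write_label_table({seq.id: label for seq, label in data}, label_path)


def simulate_homolog_set(
    query: ProteinSequence,
    n_hits: int,
    identity: float,
    seed: int = 0,
    min_region_fraction: float = 1.0,
) -> HomologSet:
    """Homolog regions as point-mutated (optionally truncated) query copies.

    Each region mutates every position independently with probability
    1 - identity, substituting uniformly among the other 19 residues.
    ``min_region_fraction`` < 1 emulates partial alignments by keeping a
    random contiguous window of at least that fraction of the query.
    """
    if n_hits < 0:
        raise ValueError("n_hits must be >= 0")
    if not (0.0 <= identity <= 1.0):
        raise ValueError("identity must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    regions: list[ProteinSequence] = []
    residues = query.residues
    L = len(residues)
    for h in range(n_hits):
        chars = list(residues)
        for pos in range(L):
            if rng.random() > identity:
                alternatives = AMINO_ACIDS.replace(chars[pos], "")
                chars[pos] = alternatives[rng.integers(len(alternatives))]
        mutated = "".join(chars)
        if min_region_fraction < 1.0:
            min_len = max(1, int(np.ceil(min_region_fraction * L)))
            length = int(rng.integers(min_len, L + 1))
            start = int(rng.integers(0, L - length + 1))
            mutated = mutated[start : start + length]
        regions.append(ProteinSequence(f"{query.id}|hom{h}", mutated))
    return HomologSet(query=query, regions=regions)


def simulate_search_artifacts(
    data: LabeledDataset,
    n_hits: int = 3,
    identity: float = 0.8,
    seed: int = 0,
) -> dict[str, HomologSet]:
    """One simulated homolog set per sequence, seeded per-query."""
    rng = np.random.default_rng(seed)
    out: dict[str, HomologSet] = {}
    for seq in data.sequences:
        out[seq.id] = simulate_homolog_set(
            seq, n_hits, identity, seed=int(rng.integers(2**31))
        )
    return out


def _passing_hit(
    rng: np.random.Generator, qid: str, qlen: int, profile: ThresholdProfile
) -> BlastHit:
    """A hit constructed to satisfy every set threshold of ``profile``."""
    evalue = 0.0 if profile.max_evalue == 0.0 else min(
        profile.max_evalue if profile.max_evalue is not None else 1e-30, 1e-30
    )
    pident = 100.0 if profile.min_pident == 100.0 else float(
        rng.uniform(max(profile.min_pident or 40.0, 40.0), 99.0)
    )
    slen = qlen  # zero length difference passes any bound
    return BlastHit(
        qseqid=qid, sseqid=f"db|{qid}|match",
        pident=pident, length=qlen, evalue=evalue,
        bitscore=float(rng.uniform(200, 900)),
        qstart=1, qend=qlen, sstart=1, send=slen,
        qlen=qlen, slen=slen,
    )


def _failing_hit(rng: np.random.Generator, qid: str, qlen: int) -> BlastHit:
    """A hit failing every built-in profile: weak e-value, low identity,
    poor coverage, large length difference."""
    slen = qlen * 3
    span = max(1, qlen // 4)
    start = int(rng.integers(1, qlen - span + 1)) if qlen > span else 1
    return BlastHit(
        qseqid=qid, sseqid=f"db|{qid}|weak",
        pident=float(rng.uniform(15, 30)), length=span,
        evalue=float(rng.uniform(1e-6, 1e-3)),
        bitscore=float(rng.uniform(20, 40)),
        qstart=start, qend=start + span - 1,
        sstart=1, send=span, qlen=qlen, slen=slen,
    )


def simulate_blast_hits(
    data: LabeledDataset,
    profile_aware: bool = True,
    seed: int = 0,
    profile: ThresholdProfile | None = None,
) -> dict[str, list[BlastHit]]:
    """Mock transporter-database hits keyed by query id.

    Profile-aware mode gives every T-labeled query one hit passing the
    chosen profile (default: the high-confidence profile) plus noise, and
    NT-labeled queries only failing hits — so homology predictions under
    that profile reproduce the labels exactly. Non-aware mode draws
    unconstrained random hits.
    """
    rng = np.random.default_rng(seed)
    profile = profile or builtin_profiles()[1]
    out: dict[str, list[BlastHit]] = {}
    for seq, label in data:
        qlen = len(seq)
        hits: list[BlastHit] = []
        if profile_aware:
            if label == "T":
                hits.append(_passing_hit(rng, seq.id, qlen, profile))
            n_noise = int(rng.integers(0, 3))
            hits.extend(_failing_hit(rng, seq.id, qlen) for _ in range(n_noise))
        else:
            for _ in range(int(rng.integers(0, 5))):
                if rng.random() < 0.5:
                    hits.append(_passing_hit(rng, seq.id, qlen, profile))
                else:
                    hits.append(_failing_hit(rng, seq.id, qlen))
        out[seq.id] = hits
    return out
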