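"""Homolog collection via (PSI-)BLAST and psi-/blast-composition features.

A psi-composition is the arithmetic mean of a plain composition descriptor
over the query and the gap-free aligned regions of its search hits:
(1/(n+1)) * sum of descriptor(x) for x in {Q, h_1..h_n}.

The search backend is an interface with two implementations: an external
BLAST+ subprocess runner and an in-memory stub fed by tabular fixture
files. All unit tests use the stub; results are deterministic given a
fixed hit table.
"""

from __future__ import annotations

import logging
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol

import numpy as np

from .descriptors import CompositionVector, PseAACParams, compute_descriptor
from .seqio import ProteinSequence, SequenceError, sanitize, write_fasta

logger = logging.getLogger(__name__)

# Tabular dialect shared by live searches and fixture files: the 12
# standard columns plus the aligned query/subject strings for region
# extraction.
TABULAR_COLUMNS: tuple[str, ...] = (
    "qseqid", "sseqid", "pident", "length", "evalue", "bitscore",
    "qstart", "qend", "sstart", "send", "qlen", "slen", "qseq", "sseq",
)
OUTFMT = "6 " + " ".join(TABULAR_COLUMNS)


class SearchError(RuntimeError):
    """External search tool failure or unparseable output."""


@dataclass(frozen=True)
class SearchConfig:
    """Parameters for homolog retrieval.

    mode ``psi`` runs iterated search (default 3 iterations); mode
    ``blast`` runs a single-pass search. Both use an e-value cutoff of
    0.001 by default.
    """

    mode: str = "psi"
    iterations: int = 3
    evalue_cutoff: float = 0.001
    database: str | None = None
    executable: str | None = None
    exclude_self_hits: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("psi", "blast"):
            raise ValueError(f"mode must be 'psi' or 'blast', got {self.mode!r}")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.evalue_cutoff <= 0:
            raise ValueError("evalue cutoff must be > 0")


@dataclass
class HomologSet:
    """A query plus the sanitized gap-free aligned regions of its hits."""

    query: ProteinSequence
    regions: list[ProteinSequence] = field(default_factory=list)
    mode: str = "psi"
    iterations: int = 3
    evalue_cutoff: float = 0.001

    @property
    def n(self) -> int:
        return len(self.regions)


@dataclass(frozen=True)
class AlignedHit:
    """One tabular alignment record with aligned sequence strings."""

    qseqid: str
    sseqid: str
    pident: float
    length: int
    evalue: float
    bitscore: float
    qstart: int
    qend: int
    sstart: int
    send: int
    qlen: int
    slen: int
    qseq: str
    sseq: str


def parse_aligned_tabular(path: str | Path) -> list[AlignedHit]:
    """Parse the 14-column tabular dialect (12 standard columns + qseq, sseq)."""
    hits: list[AlignedHit] = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            if line.strip() == "Search has CONVERGED!":  # psiblast sentinel
                continue
            parts = line.split("\t")
            if len(parts) != len(TABULAR_COLUMNS):
                raise SearchError(
                    f"{path}:{lineno}: expected {len(TABULAR_COLUMNS)} columns, "
                    f"got {len(parts)}"
                )
            try:
                hits.append(
                    AlignedHit(
                        qseqid=parts[0], sseqid=parts[1],
                        pident=float(parts[2]), length=int(parts[3]),
                        evalue=float(parts[4]), bitscore=float(parts[5]),
                        qstart=int(parts[6]), qend=int(parts[7]),
                        sstart=int(parts[8]), send=int(parts[9]),
                        qlen=int(parts[10]), slen=int(parts[11]),
                        qseq=parts[12], sseq=parts[13],
                    )
                )
            except ValueError as exc:
                raise SearchError(f"{path}:{lineno}: unparseable field ({exc})") from exc
    return hits


class SearchBackend(Protocol):
    """Produces raw aligned hits for a query under a search configuration."""

    def search(self, query: ProteinSequence, config: SearchConfig) -> list[AlignedHit]:
        ...


class StubSearchBackend:
    """In-memory backend returning pre-loaded hits, keyed by query id."""

    def __init__(self, hits_by_query: dict[str, list[AlignedHit]] | None = None):
        self.hits_by_query = hits_by_query or {}

    @classmethod
    def from_file(cls, path: str | Path) -> "StubSearchBackend":
        table: dict[str, list[AlignedHit]] = {}
        for hit in parse_aligned_tabular(path):
            table.setdefault(hit.qseqid, []).append(hit)
        return cls(table)

    def search(self, query: ProteinSequence, config: SearchConfig) -> list[AlignedHit]:
        return list(self.hits_by_query.get(query.id, []))


class BlastBackend:
    """Runs psiblast/blastp as a subprocess against a formatted database."""

    def search(self, query: ProteinSequence, config: SearchConfig) -> list[AlignedHit]:
        if config.database is None:
            raise SearchError("search config has no database path")
        exe = config.executable or ("psiblast" if config.mode == "psi" else "blastp")
        with tempfile.TemporaryDirectory() as tmp:
            qpath = Path(tmp) / "query.fasta"
            opath = Path(tmp) / "hits.tsv"
            write_fasta([query], qpath)
            cmd = [
                exe,
                "-query", str(qpath),
                "-db", str(config.database),
                "-evalue", str(config.evalue_cutoff),
                "-outfmt", OUTFMT,
                "-out", str(opath),
            ]
            if config.mode == "psi":
                cmd += ["-num_iterations", str(config.iterations)]
            proc = subprocess.run(cmd, capture_output=True, text=True)
            if proc.returncode != 0:
                raise SearchError(
                    f"{exe} exited with status {proc.returncode}: {proc.stderr.strip()}"
                )
            hits = parse_aligned_tabular(opath)
        if config.mode == "psi":
            hits = _final_iteration_hits(hits)
        return hits


def _final_iteration_hits(hits: list[AlignedHit]) -> list[AlignedHit]:
    """Keep only the last PSI-BLAST iteration's block of hits.

    psiblast concatenates per-iteration tables; iterations are separated by
    the subject-id sequence restarting. We detect restarts by tracking seen
    (sseqid, sstart, send) keys: a repeat of the first key starts a new block.
    Single-iteration output passes through unchanged.
    """
    if not hits:
        return hits
    blocks: list[list[AlignedHit]] = [[]]
    seen: set[tuple] = set()
    for hit in hits:
        key = (hit.sseqid, hit.sstart, hit.send, hit.evalue, hit.bitscore)
        if key in seen:
            blocks.append([])
            seen = set()
        seen.add(key)
        blocks[-1].append(hit)
    return blocks[-1]


def extract_regions(
    query: ProteinSequence,
    hits: list[AlignedHit],
    exclude_self_hits: bool = False,
) -> list[ProteinSequence]:
    """Gap-free aligned subject regions, one per subject (best HSP only).

    The subject's aligned segment (``sseq``) has alignment gap characters
    stripped and is then sanitized. Hits whose aligned region is empty
    after filtering are dropped. With ``exclude_self_hits``, full-length
    100%-identity hits are removed (mirrors searching a database scrubbed
    of the query itself).
    """
    best: dict[str, AlignedHit] = {}
    for hit in hits:
        cur = best.get(hit.sseqid)
        if cur is None or hit.bitscore > cur.bitscore:
            best[hit.sseqid] = hit
    regions: list[ProteinSequence] = []
    for sseqid in sorted(best, key=lambda s: (-best[s].bitscore, s)):
        hit = best[sseqid]
        if exclude_self_hits and hit.pident == 100.0 and hit.length == hit.qlen == hit.slen:
            logger.debug("dropping self hit %s for query %s", sseqid, query.id)
            continue
        stripped = hit.sseq.replace("-", "").replace(".", "")
        try:
            regions.append(sanitize(stripped, f"{query.id}|{sseqid}"))
        except SequenceError:
            logger.warning(
                "hit %s for query %s empty after gap stripping/sanitation; skipped",
                sseqid, query.id,
            )
    return regions


def collect_homologs(
    query: ProteinSequence,
    config: SearchConfig,
    backend: SearchBackend | None = None,
) -> HomologSet:
    """Run the configured search and keep sanitized aligned subject regions.

    The query itself is never placed in ``regions``; it enters the
    psi-composition average separately.
    """
    backend = backend or BlastBackend()
    hits = backend.search(query, config)
    regions = extract_regions(query, hits, exclude_self_hits=config.exclude_self_hits)
    return HomologSet(
        query=query,
        regions=regions,
        mode=config.mode,
        iterations=config.iterations,
        evalue_cutoff=config.evalue_cutoff,
    )


def psi_compose(
    homologs: HomologSet,
    kind: str,
    params: PseAACParams | None = None,
) -> CompositionVector:
    """Mean descriptor over the query and its n homolog regions.

    For PseAAC, regions shorter than lambda+1 cannot contribute a theta
    vector; they are skipped with a warning and the divisor counts only
    contributing sequences. The query must always satisfy lambda < L.
    """
    contributors: list[ProteinSequence] = [homologs.query]
    skipped = 0
    if kind == "PseAAC":
        params = params or PseAACParams()
        for region in homologs.regions:
            if len(region) > params.lam:
                contributors.append(region)
            else:
                skipped += 1
        if skipped:
            logger.warning(
                "query %s: skipped %d region(s) shorter than lambda+1=%d for psiPseAAC",
                homologs.query.id, skipped, params.lam + 1,
            )
    else:
        contributors.extend(homologs.regions)

    vectors = [compute_descriptor(s, kind, params) for s in contributors]
    mean = np.mean([v.values for v in vectors], axis=0)
    return CompositionVector(kind, mean, vectors[0].components)


def blast_compose(
    query: ProteinSequence,
    config: SearchConfig,
    kind: str,
    params: PseAACParams | None = None,
    backend: SearchBackend | None = None,
) -> CompositionVector:
    """Single-pass-search variant of the psi-composition."""
    if config.mode != "blast":
        config = SearchConfig(
            mode="blast",
            iterations=1,
            evalue_cutoff=config.evalue_cutoff,
            database=config.database,
            executable=None,
            exclude_self_hits=config.exclude_self_hits,
        )
    return psi_compose(collect_homologs(query, config, backend), kind, params)
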