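"""Rule-based transporter prediction by homology transfer.

A query is labeled T when any BLAST hit against the curated transporter
database satisfies every threshold set in a profile; otherwise NT. Three
built-in profiles of increasing tolerance are provided: an exact-match
rule, a multi-constraint high-confidence rule, and an e-value-only
medium rule.

Coverage is computed from the inclusive alignment coordinate spans, not
gap-adjusted alignment lengths, so predictions are reproducible from the
12 standard tabular columns alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

PROFILE_EXACT = "TCDB_exact"
PROFILE_HIGH = "TCDB_high"
PROFILE_MED = "TCDB_med"
PROFILE_NAMES: tuple[str, ...] = (PROFILE_EXACT, PROFILE_HIGH, PROFILE_MED)


class HitTableError(ValueError):
    """Malformed tabular hit input."""


@dataclass(frozen=True)
class BlastHit:
    """One 12-column tabular hit record."""

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

    def __post_init__(self) -> None:
        if not (1 <= self.qstart <= self.qend <= self.qlen):
            raise HitTableError(
                f"hit {self.qseqid}->{self.sseqid}: bad query coordinates "
                f"({self.qstart}, {self.qend}, qlen={self.qlen})"
            )
        if not (1 <= self.sstart <= self.send <= self.slen):
            raise HitTableError(
                f"hit {self.qseqid}->{self.sseqid}: bad subject coordinates "
                f"({self.sstart}, {self.send}, slen={self.slen})"
            )

    @property
    def query_coverage(self) -> float:
        return (self.qend - self.qstart + 1) / self.qlen

    @property
    def subject_coverage(self) -> float:
        return (self.send - self.sstart + 1) / self.slen

    @property
    def length_difference_fraction(self) -> float:
        return abs(self.qlen - self.slen) / max(self.qlen, self.slen)


_COLUMNS = ("qseqid", "sseqid", "pident", "length", "evalue", "bitscore",
            "qstart", "qend", "sstart", "send", "qlen", "slen")


def parse_blast_tabular(path: str | Path) -> list[BlastHit]:
    """Parse a 12-column tab-delimited hit table, preserving line order."""
    hits: list[BlastHit] = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise HitTableError(
                    f"{path}:{lineno}: expected 12 columns, got {len(parts)}"
                )
            try:
                hits.append(
                    BlastHit(
                        qseqid=parts[0], sseqid=parts[1],
                        pident=float(parts[2]), length=int(parts[3]),
                        evalue=float(parts[4]), bitscore=float(parts[5]),
                        qstart=int(parts[6]), qend=int(parts[7]),
                        sstart=int(parts[8]), send=int(parts[9]),
                        qlen=int(parts[10]), slen=int(parts[11]),
                    )
                )
            except ValueError as exc:
                raise HitTableError(f"{path}:{lineno}: {exc}") from exc
    return hits


def write_blast_tabular(hits: list[BlastHit], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    str(getattr(h, c)) if c not in ("pident", "evalue", "bitscore")
                    else repr(getattr(h, c))
                    for c in _COLUMNS
                )
                + "\n"
            )


@dataclass(frozen=True)
class ThresholdProfile:
    """A named rule set; ``None`` fields are unset (not enforced)."""

    name: str
    max_evalue: float | None = None
    min_pident: float | None = None
    min_query_coverage: float | None = None
    min_subject_coverage: float | None = None
    max_length_difference_fraction: float | None = None

    def passes(self, hit: BlastHit) -> bool:
        if self.max_evalue is not None and hit.evalue > self.max_evalue:
            return False
        if self.min_pident is not None and hit.pident < self.min_pident:
            return False
        if self.min_query_coverage is not None and hit.query_coverage < self.min_query_coverage:
            return False
        if (
            self.min_subject_coverage is not None
            and hit.subject_coverage < self.min_subject_coverage
        ):
            return False
        if (
            self.max_length_difference_fraction is not None
            and hit.length_difference_fraction > self.max_length_difference_fraction
        ):
            return False
        return True


def builtin_profiles() -> tuple[ThresholdProfile, ThresholdProfile, ThresholdProfile]:
    """The three canonical profiles, strictest first.

    Exact: the reported e-value is exactly 0.0 (below representable range)
    and percent identity is 100. High: e-value <= 1e-20, identity >= 40%,
    query and subject coverage >= 70%, length difference <= 10% of the
    longer sequence. Medium: e-value <= 1e-8 only.
    """
    return (
        ThresholdProfile(PROFILE_EXACT, max_evalue=0.0, min_pident=100.0),
        ThresholdProfile(
            PROFILE_HIGH,
            max_evalue=1e-20,
            min_pident=40.0,
            min_query_coverage=0.70,
            min_subject_coverage=0.70,
            max_length_difference_fraction=0.10,
        ),
        ThresholdProfile(PROFILE_MED, max_evalue=1e-8),
    )


@dataclass(frozen=True)
class Prediction:
    """A single T/NT call with its source classifier."""

    sequence_id: str
    label: str
    source: str
    passing_hit: str | None = None


def predict_by_homology(
    hits: list[BlastHit],
    profile: ThresholdProfile,
    query_id: str | None = None,
) -> Prediction:
    """Label T iff any hit satisfies every set threshold of ``profile``.

    All hits must share one qseqid; pass ``query_id`` explicitly to allow
    an empty hit list (which always yields NT).
    """
    qids = {h.qseqid for h in hits}
    if len(qids) > 1:
        raise HitTableError(f"hits span multiple queries: {sorted(qids)}")
    if qids:
        qid = qids.pop()
        if query_id is not None and query_id != qid:
            raise HitTableError(f"hits are for {qid!r}, expected {query_id!r}")
    elif query_id is not None:
        qid = query_id
    else:
        raise HitTableError("empty hit list and no query_id given")

    for hit in hits:
        if profile.passes(hit):
            return Prediction(qid, "T", profile.name, passing_hit=hit.sseqid)
    return Prediction(qid, "NT", profile.name)


def predict_all_profiles(
    hits_by_query: dict[str, list[BlastHit]],
    query_ids: list[str],
    profiles: tuple[ThresholdProfile, ...] | None = None,
) -> dict[str, dict[str, Prediction]]:
    """Per-query predictions under every profile; absent queries get NT."""
    profiles = profiles or builtin_profiles()
    out: dict[str, dict[str, Prediction]] = {}
    for qid in query_ids:
        hits = hits_by_query.get(qid, [])
        out[qid] = {p.name: predict_by_homology(hits, p, query_id=qid) for p in profiles}
    return out
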