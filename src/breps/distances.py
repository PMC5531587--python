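"""All-vs-all pairwise distances keyed by alignment E-value.

Highly similar sequence pairs are reported by BLAST-style aligners with an
E-value of exactly zero (anything below 1e-180 underflows the report
format), which would make their clustering order arbitrary. Zero E-values
are therefore substituted using the bit score s as

    E = 10^(-180) * 10^(-s)

so that more similar pairs remain strictly closer. Because 10^(-180-s)
underflows IEEE doubles for s > ~128, all distances are stored and compared
on the log10 scale internally.
"""

from __future__ import annotations

import logging
import math
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Protocol, Sequence

from .records import SequenceRecord

logger = logging.getLogger(__name__)

#: log10 of the smallest E-value BLAST-style tools report as non-zero.
LOG10_EVALUE_FLOOR = -180.0

#: Sentinel for "no reported hit"; sorts strictly after every real distance.
NO_HIT = math.inf


@dataclass(frozen=True)
class Hit:
    """One directional aligner hit (tabular-output row)."""

    query: str
    subject: str
    evalue: float
    score: float


def substitute_log10_evalue(reported_evalue: float, score: float) -> float:
    """Return log10 of the E-value after the zero-substitution rule.

    If the reported E-value is zero (or below 1e-180, i.e. at the report
    floor), it is replaced by ``10^(-180) * 10^(-score)``; otherwise it is
    passed through unchanged. Working in log space keeps large scores
    representable (score 5000 maps to -5180.0, not to an underflowed zero).
    """
    if reported_evalue < 0:
        raise ValueError(f"negative E-value: {reported_evalue}")
    if score < 0:
        raise ValueError(f"negative score: {score}")
    if reported_evalue == 0.0 or reported_evalue < 10.0**LOG10_EVALUE_FLOOR:
        return LOG10_EVALUE_FLOOR - score
    return math.log10(reported_evalue)


def substitute_evalue(reported_evalue: float, score: float) -> float:
    """Linear-scale convenience wrapper around :func:`substitute_log10_evalue`.

    Note the linear value underflows to 0.0 for scores above ~128; the
    pipeline itself always works with the log10 form.
    """
    return 10.0 ** substitute_log10_evalue(reported_evalue, score)


class DistanceMatrix:
    """Symmetric pairwise distance lookup on the log10-E-value scale.

    Missing pairs carry the :data:`NO_HIT` sentinel (treated as maximal
    distance); the self-distance is minimal (-inf). Hits reported in both
    directions are symmetrized by taking the minimum E-value.
    """

    def __init__(self, items: Sequence[str]):
        self.items: list[str] = list(items)
        self._index = {a: i for i, a in enumerate(self.items)}
        if len(self._index) != len(self.items):
            raise ValueError("duplicate accessions in distance matrix")
        self._d: dict[tuple[str, str], float] = {}

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def add_hit(self, a: str, b: str, log10_evalue: float) -> None:
        """Record a hit, keeping the minimum distance seen for the pair."""
        if a not in self._index or b not in self._index:
            raise KeyError(f"unknown accession in hit ({a}, {b})")
        if a == b:
            return
        k = self._key(a, b)
        prev = self._d.get(k, NO_HIT)
        if log10_evalue < prev:
            self._d[k] = log10_evalue

    def get(self, a: str, b: str) -> float:
        if a == b:
            return -math.inf
        return self._d.get(self._key(a, b), NO_HIT)

    def pairs(self) -> Iterator[tuple[str, str, float]]:
        for (a, b), d in self._d.items():
            yield a, b, d


class AlignerAdapter(Protocol):
    """Contract for pluggable pairwise aligners (BLAST-style)."""

    def pairwise_hits(self, records: Sequence[SequenceRecord]) -> Iterable[Hit]:
        """Yield directional hits (query, subject, evalue, bit score)."""
        ...


class IdentityStubAligner:
    """Deterministic aligner stub based on edit-distance identity.

    Scores a pair by the number of matching positions in an optimal global
    alignment (via edlib); the E-value is derived from the score, and pairs
    above ``zero_identity`` identity are reported with E-value 0 to exercise
    the substitution rule. Pairs below ``min_identity`` produce no hit.
    Needs no external binary and is fully reproducible.
    """

    def __init__(self, min_identity: float = 0.3, zero_identity: float = 0.9):
        self.min_identity = min_identity
        self.zero_identity = zero_identity

    def pairwise_hits(self, records: Sequence[SequenceRecord]) -> Iterator[Hit]:
        import edlib

        for i, a in enumerate(records):
            for b in records[i + 1 :]:
                longer = max(len(a.sequence), len(b.sequence))
                if longer == 0:
                    continue
                dist = edlib.align(a.sequence, b.sequence)["editDistance"]
                matches = longer - dist
                identity = matches / longer
                if identity < self.min_identity:
                    continue
                score = float(matches)
                evalue = 0.0 if identity >= self.zero_identity else 10.0 ** (-score / 4.0)
                # emit both directions, as a real all-vs-all run would
                yield Hit(a.accession, b.accession, evalue, score)
                yield Hit(b.accession, a.accession, evalue, score)


class TableStubAligner:
    """Aligner stub replaying a fixed hit table (for tests/fixtures)."""

    def __init__(self, hits: Iterable[Hit]):
        self._hits = list(hits)

    def pairwise_hits(self, records: Sequence[SequenceRecord]) -> list[Hit]:
        return list(self._hits)


class NcbiBlastAligner:
    """All-vs-all protein BLAST through the ``makeblastdb``/``blastp`` CLIs.

    Reads hits from tabular output (outfmt 6: qseqid, sseqid, ...,
    evalue, bitscore).
    """

    def __init__(self, blastp: str = "blastp", makeblastdb: str = "makeblastdb",
                 evalue_ceiling: float = 1e-3, threads: int = 1):
        self.blastp = blastp
        self.makeblastdb = makeblastdb
        self.evalue_ceiling = evalue_ceiling
        self.threads = threads

    def available(self) -> bool:
        return shutil.which(self.blastp) is not None and shutil.which(self.makeblastdb) is not None

    def pairwise_hits(self, records: Sequence[SequenceRecord]) -> list[Hit]:
        from .data_selection import write_fasta

        with tempfile.TemporaryDirectory(prefix="breps_blast_") as tmp:
            fasta = Path(tmp) / "seqs.fasta"
            with open(fasta, "w") as fh:
                write_fasta(records, fh)
            db = Path(tmp) / "db"
            out = Path(tmp) / "hits.tsv"
            try:
                subprocess.run(
                    [self.makeblastdb, "-in", str(fasta), "-dbtype", "prot",
                     "-out", str(db)],
                    check=True, capture_output=True, text=True,
                )
                subprocess.run(
                    [self.blastp, "-query", str(fasta), "-db", str(db),
                     "-outfmt", "6 qseqid sseqid evalue bitscore",
                     "-evalue", str(self.evalue_ceiling),
                     "-num_threads", str(self.threads), "-out", str(out)],
                    check=True, capture_output=True, text=True,
                )
            except subprocess.CalledProcessError as exc:  # pragma: no cover
                raise RuntimeError(
                    f"BLAST failed (exit {exc.returncode}): {exc.stderr}"
                ) from exc
            hits = []
            for line in out.read_text().splitlines():
                q, s, ev, bs = line.split("\t")
                hits.append(Hit(q, s, float(ev), float(bs)))
            return hits


def parse_tabular_hits(stream: Iterable[str]) -> list[Hit]:
    """Parse BLAST outfmt-6-like TSV; E-value and bit score are the last
    two columns (the standard 12-column layout), query/subject the first two."""
    hits = []
    for raw in stream:
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        hits.append(Hit(cols[0], cols[1], float(cols[-2]), float(cols[-1])))
    return hits


def all_vs_all(
    records: Sequence[SequenceRecord],
    aligner: AlignerAdapter,
    evalue_ceiling: float = 1e-3,
) -> DistanceMatrix:
    """Build the symmetric distance matrix from an all-vs-all aligner run.

    Every reported hit passes through the E-value substitution; hits whose
    (substituted) E-value exceeds ``evalue_ceiling`` are discarded; absent
    pairs keep the no-hit sentinel.
    """
    matrix = DistanceMatrix([r.accession for r in records])
    log_ceiling = math.log10(evalue_ceiling)
    for hit in aligner.pairwise_hits(records):
        log_e = substitute_log10_evalue(hit.evalue, hit.score)
        if log_e > log_ceiling:
            continue
        matrix.add_hit(hit.query, hit.subject, log_e)
    return matrix
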