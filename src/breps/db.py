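"""Single-file SQLite pattern database and batch FASTA search.

The final step of the pipeline persists every verified pattern together
with its proposed EC annotation, enzyme names, occurrence counts and the
contributing accessions into one self-contained SQLite file. The search
side loads the database back into memory and scans FASTA queries against
every pattern, reporting 1-based inclusive match coordinates.
"""

from __future__ import annotations

import json
import logging
import sqlite3
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping, Sequence

from .ec import ECNumber, ProposedEC, annotate_name
from .patterns import Pattern, parse_prosite
from .verification import VerificationStats, match_pattern

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1"

_SCHEMA = """
CREATE TABLE patterns (
    id TEXT NOT NULL,
    flavor TEXT NOT NULL,
    pattern TEXT NOT NULL,
    complexity REAL NOT NULL,
    ppv REAL,
    proposed_ec TEXT NOT NULL,
    name TEXT NOT NULL,
    PRIMARY KEY (id, flavor)
);
CREATE TABLE pattern_ec (
    pattern_id TEXT NOT NULL,
    flavor TEXT NOT NULL,
    ec TEXT NOT NULL,
    occurrence_count INTEGER NOT NULL,
    group_id INTEGER NOT NULL
);
CREATE TABLE pattern_accessions (
    pattern_id TEXT NOT NULL,
    flavor TEXT NOT NULL,
    accession TEXT NOT NULL
);
CREATE TABLE metadata (
    key TEXT PRIMARY KEY,
    value TEXT NOT NULL
);
"""


@dataclass(frozen=True)
class PatternEntry:
    """One database row group: a pattern plus its annotation."""

    pattern: Pattern
    proposed: ProposedEC
    ppv: float | None
    names: tuple[str, ...]


def build_database(
    entries: Sequence[tuple[Pattern, ProposedEC, VerificationStats]],
    path: str | Path,
    metadata: Mapping[str, object] | None = None,
    name_table: Mapping[str, str] | None = None,
) -> Path:
    """Write verified patterns into a fresh single-file database.

    ``metadata`` (e.g. the build-parameter snapshot and source release tag)
    is stored as JSON values in the metadata table. An existing file at
    ``path`` is replaced.
    """
    path = Path(path)
    if path.exists():
        path.unlink()
    conn = sqlite3.connect(path)
    try:
        conn.executescript(_SCHEMA)
        for pattern, proposed, stats in entries:
            names = annotate_name(proposed, name_table)
            conn.execute(
                "INSERT INTO patterns VALUES (?, ?, ?, ?, ?, ?, ?)",
                (
                    pattern.id,
                    pattern.flavor,
                    pattern.to_prosite(),
                    pattern.complexity,
                    stats.ppv,
                    proposed.text,
                    "; ".join(names),
                ),
            )
            for group_id, group in enumerate(proposed.groups):
                for e in group:
                    count = proposed.occurrences.get(
                        e.text, sum(proposed.occurrences.values()) if not e.is_full else 0
                    )
                    conn.execute(
                        "INSERT INTO pattern_ec VALUES (?, ?, ?, ?, ?)",
                        (pattern.id, pattern.flavor, e.text, count, group_id),
                    )
            for acc in proposed.accessions:
                conn.execute(
                    "INSERT INTO pattern_accessions VALUES (?, ?, ?)",
                    (pattern.id, pattern.flavor, acc),
                )
        meta = {"schema_version": SCHEMA_VERSION}
        if metadata:
            meta.update({k: v for k, v in metadata.items()})
        for k, v in meta.items():
            conn.execute(
                "INSERT INTO metadata VALUES (?, ?)",
                (k, v if isinstance(v, str) else json.dumps(v)),
            )
        conn.commit()
    finally:
        conn.close()
    return path


def load_patterns(path: str | Path) -> list[PatternEntry]:
    """Load every pattern row back into memory (round-trips the build)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"pattern database not found: {path}")
    conn = sqlite3.connect(path)
    try:
        entries = []
        for pid, flavor, text, _complexity, ppv, proposed_ec, name in conn.execute(
            "SELECT id, flavor, pattern, complexity, ppv, proposed_ec, name "
            "FROM patterns ORDER BY id, flavor"
        ):
            pattern = parse_prosite(text, pattern_id=pid, flavor=flavor)
            groups: dict[int, list[ECNumber]] = {}
            occurrences: dict[str, int] = {}
            for ec, count, group_id in conn.execute(
                "SELECT ec, occurrence_count, group_id FROM pattern_ec "
                "WHERE pattern_id=? AND flavor=? ORDER BY rowid",
                (pid, flavor),
            ):
                groups.setdefault(group_id, []).append(ECNumber.parse(ec))
                occurrences[ec] = count
            accessions = tuple(
                row[0]
                for row in conn.execute(
                    "SELECT accession FROM pattern_accessions "
                    "WHERE pattern_id=? AND flavor=? ORDER BY rowid",
                    (pid, flavor),
                )
            )
            proposed = ProposedEC(
                groups=tuple(tuple(g) for _, g in sorted(groups.items())),
                occurrences=occurrences,
                accessions=accessions,
            )
            entries.append(
                PatternEntry(
                    pattern=pattern,
                    proposed=proposed,
                    ppv=ppv,
                    names=tuple(name.split("; ")) if name else (),
                )
            )
        return entries
    finally:
        conn.close()


def read_metadata(path: str | Path) -> dict[str, str]:
    conn = sqlite3.connect(Path(path))
    try:
        return dict(conn.execute("SELECT key, value FROM metadata"))
    finally:
        conn.close()


@dataclass(frozen=True)
class SearchHit:
    """One reported pattern match (1-based inclusive coordinates)."""

    query_id: str
    pattern_id: str
    flavor: str
    start: int
    end: int
    proposed_ec: str
    name: str
    ppv: float | None

    def as_row(self) -> tuple:
        return (
            self.query_id,
            self.pattern_id,
            self.flavor,
            self.start,
            self.end,
            self.proposed_ec,
            self.name,
            "" if self.ppv is None else f"{self.ppv:.4f}",
        )


REPORT_COLUMNS = (
    "query_id", "pattern_id", "flavor", "start", "end",
    "proposed_ec", "name", "ppv",
)


def _read_fasta(path: str | Path) -> Iterator[tuple[str, str]]:
    from Bio import SeqIO

    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("*", "")
        if not rec.id or not seq:
            logger.warning("skipping unreadable FASTA record: %r", rec.id)
            continue
        yield rec.id, seq


def search(
    db_path: str | Path,
    fasta_path: str | Path,
    flavor: str = "both",
) -> list[SearchHit]:
    """Match every query sequence against every database pattern.

    Results are deterministic: query order, then pattern id, then flavor.
    Coordinates are 1-based inclusive (the usual reporting convention;
    matching itself is 0-based half-open internally).
    """
    if flavor not in ("standard", "extended", "both"):
        raise ValueError(f"unknown flavor filter: {flavor!r}")
    entries = load_patterns(db_path)
    if flavor != "both":
        entries = [e for e in entries if e.pattern.flavor == flavor]
    hits: list[SearchHit] = []
    for query_id, seq in _read_fasta(fasta_path):
        for entry in entries:
            for start, end in match_pattern(entry.pattern, seq):
                hits.append(
                    SearchHit(
                        query_id=query_id,
                        pattern_id=entry.pattern.id,
                        flavor=entry.pattern.flavor,
                        start=start + 1,
                        end=end,
                        proposed_ec=entry.proposed.text,
                        name="; ".join(entry.names),
                        ppv=entry.ppv,
                    )
                )
    return hits


def write_report(hits: Sequence[SearchHit], handle) -> None:
    """Write the hit report as TSV with a header row."""
    handle.write("\t".join(REPORT_COLUMNS) + "\n")
    for h in hits:
        handle.write("\t".join(str(c) for c in h.as_row()) + "\n")
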