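"""Selection of curated sequence data for pattern generation.

Parses UniProt-style flat files (the DAT dialect: ID/AC/DE/PE/RX/SQ lines,
records terminated by ``//``), applies the seed filters, enriches seeds with
similar sequences via 50%-identity reference clusters, and assembles the
working set used by the rest of the pipeline.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, TextIO

from .records import SequenceRecord, WorkingSet

logger = logging.getLogger(__name__)

_EC_RE = re.compile(r"EC=([0-9n][0-9n.\-]*)")


@dataclass(frozen=True)
class FilterConfig:
    """Seed-sequence filter settings.

    Defaults implement the curated-seed criteria: length 100-7000 aa, no
    uncertainty keyword in the description, at least one EC number, and
    protein-level evidence (PE 1).
    """

    min_length: int = 100
    max_length: int = 7000
    banned_keywords: tuple[str, ...] = (
        "putative",
        "hypothetical",
        "fragment",
        "probable",
        "possible",
        "potential",
    )
    require_ec: bool = True
    evidence_level: int = 1


def parse_flatfile(stream: TextIO | Iterable[str]) -> list[SequenceRecord]:
    """Parse a UniProt-DAT-dialect stream into sequence records.

    EC numbers are extracted from ``EC=`` tokens on DE lines; all ECs of one
    entry form a single AND-joined set (multi-functional enzyme). The
    evidence level comes from the integer prefix of the PE line, and
    ``has_publication`` is true iff at least one RX line is present.
    Records missing an ID or a sequence are skipped with a warning.
    """
    records: list[SequenceRecord] = []
    lines: list[str] = []
    for raw in stream:
        line = raw.rstrip("\n")
        if line.strip() == "//":
            rec = _parse_record(lines)
            if rec is not None:
                records.append(rec)
            lines = []
        else:
            lines.append(line)
    if any(l.strip() for l in lines):
        rec = _parse_record(lines)
        if rec is not None:
            records.append(rec)
    return records


def _parse_record(lines: list[str]) -> SequenceRecord | None:
    entry_id = None
    accession = None
    de_parts: list[str] = []
    evidence = 5
    has_rx = False
    in_sq = False
    seq_parts: list[str] = []
    for line in lines:
        code = line[:2]
        body = line[5:].strip() if len(line) > 5 else ""
        if in_sq and line.startswith("  "):
            seq_parts.append(line.replace(" ", ""))
            continue
        in_sq = False
        if code == "ID":
            entry_id = body.split()[0] if body else None
        elif code == "AC":
            if accession is None and body:
                accession = body.split(";")[0].strip()
        elif code == "DE":
            de_parts.append(body)
        elif code == "PE":
            m = re.match(r"(\d+)", body)
            if m:
                evidence = int(m.group(1))
        elif code == "RX":
            has_rx = True
        elif code == "SQ":
            in_sq = True
    sequence = "".join(seq_parts).upper()
    if entry_id is None or not sequence:
        if any(l.strip() for l in lines):
            logger.warning(
                "skipping malformed record (missing %s): %r",
                "ID" if entry_id is None else "SQ",
                lines[0] if lines else "",
            )
        return None
    description = " ".join(de_parts)
    ecs = frozenset(tok.rstrip(";.") for tok in _EC_RE.findall(description))
    return SequenceRecord(
        accession=accession or entry_id,
        sequence=sequence,
        description=description,
        ec_sets=(ecs,) if ecs else (),
        evidence_level=evidence,
        has_publication=has_rx,
        source="seed",
    )


def apply_seed_filters(
    records: Iterable[SequenceRecord], cfg: FilterConfig | None = None
) -> list[SequenceRecord]:
    """Keep records satisfying all seed criteria.

    A record is kept iff its length is within ``[min_length, max_length]``
    (inclusive), its description contains none of the banned keywords
    (case-insensitive substring), it carries at least one EC number, and its
    evidence level equals the configured level. Filtering never raises and
    is idempotent.
    """
    cfg = cfg or FilterConfig()
    kept = []
    for rec in records:
        if not cfg.min_length <= rec.length <= cfg.max_length:
            continue
        desc = rec.description.lower()
        if any(kw in desc for kw in cfg.banned_keywords):
            continue
        if cfg.require_ec and not rec.is_enzyme:
            continue
        if rec.evidence_level != cfg.evidence_level:
            continue
        kept.append(rec)
    return kept


def select_similar(
    seed: SequenceRecord,
    cluster_members: Iterable[SequenceRecord],
    max_length_deviation: float = 0.25,
) -> list[SequenceRecord]:
    """Select enrichment sequences from the seed's reference cluster.

    Cluster co-membership stands in for the >=50% identity criterion. A
    member is selected iff its length deviates from the seed length by at
    most ``max_length_deviation`` (relative to the seed, inclusive) and it
    has a literature reference. Selected members receive the seed's EC
    annotation verbatim (annotation transfer) and ``source="enriched"``.
    The seed itself is never returned.

    Raises
    ------
    ValueError
        If the seed is absent from its own cluster (inconsistent input).
    """
    members = list(cluster_members)
    if not any(m.accession == seed.accession for m in members):
        raise ValueError(
            f"seed {seed.accession} not found in its own cluster member list"
        )
    out = []
    for m in members:
        if m.accession == seed.accession:
            continue
        if abs(m.length - seed.length) / seed.length > max_length_deviation:
            continue
        if not m.has_publication:
            continue
        out.append(m.as_enriched(seed))
    return out


def read_uniref_table(stream: TextIO | Iterable[str]) -> dict[str, list[str]]:
    """Read a two-column headerless TSV (cluster_id, member accession)."""
    clusters: dict[str, list[str]] = {}
    for raw in stream:
        line = raw.strip()
        if not line:
            continue
        cluster_id, accession = line.split("\t")[:2]
        clusters.setdefault(cluster_id, []).append(accession)
    return clusters


def enrich_seeds(
    seeds: Iterable[SequenceRecord],
    all_records: Iterable[SequenceRecord],
    clusters: Mapping[str, list[str]],
    max_length_deviation: float = 0.25,
) -> list[SequenceRecord]:
    """Run :func:`select_similar` for every seed over a cluster table.

    Seeds not listed in any cluster are silently skipped (a seed may simply
    have no similar sequences); duplicates across seeds are resolved later
    by :func:`build_working_set`.
    """
    by_acc = {r.accession: r for r in all_records}
    membership: dict[str, str] = {}
    for cid, members in clusters.items():
        for acc in members:
            membership[acc] = cid
    enriched: list[SequenceRecord] = []
    for seed in seeds:
        cid = membership.get(seed.accession)
        if cid is None:
            continue
        members = [by_acc[a] for a in clusters[cid] if a in by_acc]
        enriched.extend(select_similar(seed, members, max_length_deviation))
    return enriched


def build_working_set(
    seeds: Iterable[SequenceRecord],
    enriched: Iterable[SequenceRecord],
    all_records: Iterable[SequenceRecord],
) -> WorkingSet:
    """Merge seeds and enriched sequences; collect non-enzymes.

    Deduplicates by accession with seeds taking precedence over enriched
    duplicates. Non-enzymes are all parsed records with protein-level
    evidence (PE 1) and no EC number; they are kept for verification.

    Raises
    ------
    ValueError
        If one accession appears with two different sequences.
    """
    seen: dict[str, SequenceRecord] = {}
    seed_list: list[SequenceRecord] = []
    for rec in seeds:
        prev = seen.get(rec.accession)
        if prev is not None:
            if prev.sequence != rec.sequence:
                raise ValueError(f"conflicting sequences for {rec.accession}")
            continue
        seen[rec.accession] = rec
        seed_list.append(rec)
    enriched_list: list[SequenceRecord] = []
    for rec in enriched:
        prev = seen.get(rec.accession)
        if prev is not None:
            if prev.sequence != rec.sequence:
                raise ValueError(f"conflicting sequences for {rec.accession}")
            continue  # seed (or earlier enrichment) takes precedence
        seen[rec.accession] = rec
        enriched_list.append(rec)
    non_enzymes: list[SequenceRecord] = []
    for rec in all_records:
        if rec.accession in seen:
            if seen[rec.accession].sequence != rec.sequence:
                raise ValueError(f"conflicting sequences for {rec.accession}")
            continue
        if rec.evidence_level == 1 and not rec.is_enzyme:
            seen[rec.accession] = rec
            non_enzymes.append(rec)
    return WorkingSet(seeds=seed_list, enriched=enriched_list, non_enzymes=non_enzymes)


def write_fasta(records: Iterable[SequenceRecord], handle: TextIO) -> None:
    """Write records as FASTA with the accession as header (aligner input)."""
    for rec in records:
        handle.write(f">{rec.accession}\n")
        seq = rec.sequence
        for i in range(0, len(seq), 60):
            handle.write(seq[i : i + 60] + "\n")
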