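"""Synthetic enzyme families with known ground truth.

Generates desk-scale stand-ins for curated sequence data: per family a
random ancestor protein with designated conserved blocks, mutated copies
as family members, plus unrelated uniform-random decoys standing in for
non-enzymes. Emits the same formats the data-selection step consumes
(UniProt-DAT-dialect flatfile, two-column reference-cluster TSV, truth
table TSV), so the whole pipeline can be exercised end to end without any
downloads. Everything is reproducible from the per-spec seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, TextIO

import numpy as np

from .records import STANDARD_AA, SequenceRecord


@dataclass(frozen=True)
class FamilySpec:
    """Recipe for one mutated enzyme family.

    ``conserved_blocks`` are (start, length) intervals of the ancestor that
    are never mutated — they become the fully conserved pattern core.
    ``ec_numbers`` holds one EC for a mono-functional family or two for a
    multi-functional one (both annotated on every member). Substitutions
    happen per non-conserved site with probability ``substitution_rate``;
    ``indel_rate`` optionally deletes/inserts at non-conserved sites to
    exercise gapped alignments and wildcard-span widening.
    """

    family_id: str
    ec_numbers: tuple[str, ...]
    ancestor_length: int = 300
    n_members: int = 6
    substitution_rate: float = 0.03
    indel_rate: float = 0.0
    conserved_blocks: tuple[tuple[int, int], ...] = ((20, 12), (100, 12), (200, 12))
    seed: int = 0

    def __post_init__(self) -> None:
        spans = sorted((s, s + l) for s, l in self.conserved_blocks)
        prev_end = 0
        for s, e in spans:
            if s < prev_end or e > self.ancestor_length:
                raise ValueError("conserved blocks must be disjoint and in range")
            prev_end = e


@dataclass
class SyntheticDataset:
    records: list[SequenceRecord]
    truth: dict[str, frozenset[str]]  # accession -> true EC numbers
    clusters: dict[str, list[str]]  # cluster id -> member accessions
    families: dict[str, list[str]] = field(default_factory=dict)


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(STANDARD_AA), size=length))


def _mutate(
    rng: np.random.Generator,
    ancestor: str,
    conserved: set[int],
    substitution_rate: float,
    indel_rate: float,
) -> str:
    out: list[str] = []
    for i, residue in enumerate(ancestor):
        if i in conserved:
            out.append(residue)
            continue
        if indel_rate > 0 and rng.random() < indel_rate:
            if rng.random() < 0.5:
                continue  # deletion
            out.append(residue)
            out.append(_random_sequence(rng, 1))  # insertion
            continue
        if rng.random() < substitution_rate:
            alternatives = STANDARD_AA.replace(residue, "")
            out.append(str(rng.choice(list(alternatives))))
        else:
            out.append(residue)
    return "".join(out)


def generate_families(
    specs: Sequence[FamilySpec],
    n_decoys: int = 50,
    decoy_length: int = 300,
    decoy_seed: int = 999,
) -> SyntheticDataset:
    """Generate family members, decoys, truth table and cluster table.

    Members carry their family's EC annotation (multi-EC families annotate
    all ECs on every member as one AND set), protein-level evidence and a
    publication reference, so they pass the seed filters. Decoys are
    uniform-random non-enzymes with protein-level evidence. Each family
    forms one reference cluster.
    """
    records: list[SequenceRecord] = []
    truth: dict[str, frozenset[str]] = {}
    clusters: dict[str, list[str]] = {}
    families: dict[str, list[str]] = {}
    for spec in specs:
        rng = np.random.default_rng(spec.seed)
        ancestor = _random_sequence(rng, spec.ancestor_length)
        conserved = {
            i for start, length in spec.conserved_blocks
            for i in range(start, start + length)
        }
        ecs = frozenset(spec.ec_numbers)
        members = []
        for m in range(spec.n_members):
            acc = f"{spec.family_id}M{m:03d}"
            seq = _mutate(
                rng, ancestor, conserved, spec.substitution_rate, spec.indel_rate
            )
            records.append(
                SequenceRecord(
                    accession=acc,
                    sequence=seq,
                    description=(
                        f"RecName: Full=Synthetic enzyme {spec.family_id}; "
                        + " ".join(f"EC={ec};" for ec in spec.ec_numbers)
                    ),
                    ec_sets=(ecs,),
                    evidence_level=1,
                    has_publication=True,
                )
            )
            truth[acc] = ecs
            members.append(acc)
        clusters[f"UniRef50_{spec.family_id}"] = members
        families[spec.family_id] = members
    rng = np.random.default_rng(decoy_seed)
    for d in range(n_decoys):
        acc = f"DEC{d:04d}"
        records.append(
            SequenceRecord(
                accession=acc,
                sequence=_random_sequence(rng, decoy_length),
                description="SubName: Full=Synthetic non-enzyme;",
                ec_sets=(),
                evidence_level=1,
                has_publication=False,
            )
        )
    return SyntheticDataset(
        records=records, truth=truth, clusters=clusters, families=families
    )


def default_benchmark_specs(seed: int = 1) -> list[FamilySpec]:
    """The packaged benchmark conditions: five families of six members,
    substitution rate 0.03, one of them multi-functional."""
    ec_assignments: list[tuple[str, ...]] = [
        ("1.1.1.1",),
        ("2.7.1.1",),
        ("3.1.1.3",),
        ("4.1.1.39",),
        ("6.4.1.2", "6.3.4.14"),
    ]
    return [
        FamilySpec(
            family_id=f"FAM{i}",
            ec_numbers=ecs,
            ancestor_length=300,
            n_members=6,
            substitution_rate=0.03,
            seed=(seed * 1000 + i) % (2**31),
        )
        for i, ecs in enumerate(ec_assignments)
    ]


def emit_flatfile(
    records: Iterable[SequenceRecord],
    handle: TextIO,
    putative_accessions: Iterable[str] = (),
) -> None:
    """Write records as a UniProt-DAT-dialect stream.

    ``putative_accessions`` get the word "Putative" injected into their DE
    line, a hook for exercising the keyword filter downstream.
    """
    putative = set(putative_accessions)
    for rec in records:
        handle.write(f"ID   {rec.accession}_SYN   Reviewed;   {rec.length} AA.\n")
        handle.write(f"AC   {rec.accession};\n")
        desc = rec.description
        if rec.accession in putative:
            desc = desc.replace("Full=", "Full=Putative ", 1)
        handle.write(f"DE   {desc}\n")
        handle.write(f"PE   {rec.evidence_level}: synthetic evidence level;\n")
        if rec.has_publication:
            handle.write("RX   PubMed=1; DOI=10.0/synthetic;\n")
        handle.write(f"SQ   SEQUENCE   {rec.length} AA;  0 MW;  0 CRC64;\n")
        seq = rec.sequence
        for i in range(0, len(seq), 60):
            chunk = seq[i : i + 60]
            spaced = " ".join(chunk[j : j + 10] for j in range(0, len(chunk), 10))
            handle.write(f"     {spaced}\n")
        handle.write("//\n")


def emit_uniref(clusters: Mapping[str, Sequence[str]], handle: TextIO) -> None:
    """Write the cluster table as headerless two-column TSV."""
    for cluster_id in clusters:
        for acc in clusters[cluster_id]:
            handle.write(f"{cluster_id}\t{acc}\n")


def emit_truth_table(truth: Mapping[str, Iterable[str]], handle: TextIO) -> None:
    """Write the (accession, EC) truth table as TSV, one row per EC."""
    for acc in truth:
        for ec in sorted(truth[acc]):
            handle.write(f"{acc}\t{ec}\n")


def read_truth_table(stream: TextIO | Iterable[str]) -> dict[str, frozenset[str]]:
    out: dict[str, set[str]] = {}
    for raw in stream:
        line = raw.strip()
        if not line:
            continue
        acc, ec = line.split("\t")[:2]
        out.setdefault(acc, set()).add(ec)
    return {k: frozenset(v) for k, v in out.items()}
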