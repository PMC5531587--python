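"""Core sequence record containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, replace


#: The 20 standard amino acids. Non-standard residues (X, B, Z, U) are
#: tolerated in sequences but never matched by pattern positions.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SequenceRecord:
    """One protein entry.

    Parameters
    ----------
    accession:
        Primary accession (unique key across a working set).
    sequence:
        Amino-acid string; the 20-letter alphabet plus X/B/Z/U tolerated.
    description:
        Concatenated free text of the DE lines (used for keyword filtering).
    ec_sets:
        One frozenset of EC-number strings per catalytic-function annotation.
        A multi-functional entry carries all of its EC numbers in a single
        set (they are AND-joined: one enzyme, several functions).
    evidence_level:
        UniProt protein-existence (PE) level, 1-5; 1 means evidence at
        protein level.
    has_publication:
        True iff the entry has at least one literature cross reference (RX).
    source:
        ``"seed"`` for a curated entry that passed the seed filters,
        ``"enriched"`` for a similar sequence added via cluster co-membership.
    """

    accession: str
    sequence: str
    description: str = ""
    ec_sets: tuple[frozenset[str], ...] = ()
    evidence_level: int = 5
    has_publication: bool = False
    source: str = "seed"

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def is_enzyme(self) -> bool:
        return any(self.ec_sets)

    @property
    def ec_numbers(self) -> frozenset[str]:
        """Union of all EC numbers annotated on this entry."""
        out: set[str] = set()
        for s in self.ec_sets:
            out |= s
        return frozenset(out)

    def as_enriched(self, seed: "SequenceRecord") -> "SequenceRecord":
        """Copy of this record carrying the seed's annotation (transfer)."""
        return replace(self, ec_sets=seed.ec_sets, source="enriched")


@dataclass
class WorkingSet:
    """Merged sequence database used for pattern generation and verification.

    ``seeds`` are the curated, protein-level-evidence enzymes; ``enriched``
    are similar sequences that inherited a seed's annotation; ``non_enzymes``
    are protein-level-evidence entries without any EC number, kept for
    pattern verification.
    """

    seeds: list[SequenceRecord] = field(default_factory=list)
    enriched: list[SequenceRecord] = field(default_factory=list)
    non_enzymes: list[SequenceRecord] = field(default_factory=list)

    @property
    def pattern_records(self) -> list[SequenceRecord]:
        """Sequences used for clustering and pattern generation."""
        return list(self.seeds) + list(self.enriched)

    @property
    def verification_records(self) -> list[SequenceRecord]:
        """Sequences used for pattern verification (seeds + non-enzymes)."""
        return list(self.seeds) + list(self.non_enzymes)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.seeds + self.enriched + self.non_enzymes:
            if rec.accession in seen:
                raise ValueError(f"duplicate accession in working set: {rec.accession}")
            seen.add(rec.accession)
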