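"""Multiple sequence alignment adapters and consensus-line computation.

The pattern engine consumes an alignment plus its Clustal-style consensus
line ('*' fully conserved, ':' strong group, '.' weak group, ' ' none).
Aligners are pluggable: the deterministic stub handles the equal-length
case without any external binary, while external adapters shell out to a
real MSA tool. Consensus symbols are recomputed here in all cases, using
the standard Clustal residue groups, so the downstream pattern rules do
not depend on a particular tool's annotation row.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Protocol, Sequence

from .records import SequenceRecord

GAP = "-"

# Clustal conservation groups (strong: ':', weak: '.').
STRONG_GROUPS = ("STA", "NEQK", "NHQK", "NDEQ", "QHRK", "MILV", "MILF", "HY", "FYW")
WEAK_GROUPS = (
    "CSA", "ATV", "SAG", "STNK", "STPA", "SGND", "SDEQN", "NDEQHK",
    "NEQHRK", "FVLIM", "HFY",
)
_STRONG = tuple(frozenset(g) for g in STRONG_GROUPS)
_WEAK = tuple(frozenset(g) for g in WEAK_GROUPS)


@dataclass(frozen=True)
class ConsensusColumn:
    """One alignment column summarised for pattern construction."""

    index: int
    symbol: str  # one of '*', ':', '.', ' '
    residues: frozenset[str]
    gap_fraction: float


@dataclass
class Alignment:
    """Equal-length aligned rows keyed by accession, plus consensus."""

    accessions: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.accessions) != len(self.rows):
            raise ValueError("row/accession count mismatch")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("aligned rows must have equal length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def consensus_line(self) -> str:
        return "".join(c.symbol for c in self.columns())

    def columns(self) -> list[ConsensusColumn]:
        """Consensus columns under the Clustal group rules.

        '*' — one residue, no gap; ':' — all residues within one strong
        group, no gap; '.' — all within one weak group, no gap; ' '
        otherwise (any gapped column is unconserved).
        """
        out = []
        n_rows = len(self.rows)
        for i in range(self.n_columns):
            col = [row[i] for row in self.rows]
            gaps = sum(1 for c in col if c == GAP)
            residues = frozenset(c for c in col if c != GAP)
            if gaps == 0 and len(residues) == 1:
                symbol = "*"
            elif gaps == 0 and any(residues <= g for g in _STRONG):
                symbol = ":"
            elif gaps == 0 and any(residues <= g for g in _WEAK):
                symbol = "."
            else:
                symbol = " "
            out.append(
                ConsensusColumn(
                    index=i,
                    symbol=symbol,
                    residues=residues,
                    gap_fraction=gaps / n_rows,
                )
            )
        return out


class MsaAdapter(Protocol):
    def align(self, records: Sequence[SequenceRecord]) -> Alignment: ...


class StubMsaAligner:
    """Deterministic gap-free aligner for equal-length sequences.

    Sequences of one synthetic (substitution-only) family are already
    positionally homologous, so stacking them IS their correct alignment.
    Refuses unequal lengths rather than guessing gaps.
    """

    def align(self, records: Sequence[SequenceRecord]) -> Alignment:
        if len(records) < 2:
            raise ValueError("alignment needs at least 2 sequences")
        if len({r.length for r in records}) > 1:
            raise ValueError(
                "stub aligner requires equal-length sequences; "
                "use an external MSA adapter for gapped input"
            )
        return Alignment(
            accessions=[r.accession for r in records],
            rows=[r.sequence for r in records],
        )


class PrealignedMsaAligner:
    """Adapter passing through a pre-computed alignment (test fixtures)."""

    def __init__(self, alignment: Alignment):
        self._alignment = alignment

    def align(self, records: Sequence[SequenceRecord]) -> Alignment:
        return self._alignment


class ExternalMsaAligner:
    """MSA through an external command reading/writing FASTA on stdio.

    Works with any tool following the ``tool [args] input.fasta`` + aligned
    FASTA on stdout convention (e.g. ``mafft --auto``, ``clustalo -i ... -o -``).
    """

    def __init__(self, argv: Sequence[str] = ("mafft", "--auto", "--quiet")):
        self.argv = list(argv)

    def available(self) -> bool:
        return shutil.which(self.argv[0]) is not None

    def align(self, records: Sequence[SequenceRecord]) -> Alignment:
        from Bio import AlignIO

        from .data_selection import write_fasta

        if len(records) < 2:
            raise ValueError("alignment needs at least 2 sequences")
        with tempfile.TemporaryDirectory(prefix="breps_msa_") as tmp:
            fasta = Path(tmp) / "in.fasta"
            with open(fasta, "w") as fh:
                write_fasta(records, fh)
            try:
                proc = subprocess.run(
                    self.argv + [str(fasta)],
                    check=True, capture_output=True, text=True,
                )
            except subprocess.CalledProcessError as exc:  # pragma: no cover
                raise RuntimeError(
                    f"MSA tool failed (exit {exc.returncode}): {exc.stderr}"
                ) from exc
            out = Path(tmp) / "out.fasta"
            out.write_text(proc.stdout)
            msa = AlignIO.read(str(out), "fasta")
        return Alignment(
            accessions=[r.id for r in msa],
            rows=[str(r.seq).upper() for r in msa],
        )


def run_msa(records: Sequence[SequenceRecord], aligner: MsaAdapter) -> Alignment:
    """Align the records of one cluster node (>=2 sequences required)."""
    if len(records) < 2:
        raise ValueError("alignment needs at least 2 sequences")
    return aligner.align(records)
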