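"""Pattern verification: matching, EC comparison, PPV/DR, exclusion.

Every generated pattern (standard and extended) is matched against the
verification set — the curated seed enzymes plus the protein-level-evidence
non-enzymes. A hit on a non-enzyme is a false positive; a hit on an enzyme
is a true positive iff the pattern's proposed EC matches the sequence's
annotation. Quality is summarised per pattern by the positive predictive
value

    PPV = TP / (TP + FP)

and at run level by the detection rate

    DR = (TP + FP) / (TP + FP + N)

where N counts sequences hit by no pattern at all. Patterns with PPV below
the cutoff (default 1.0, i.e. any false positive excludes) are removed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .ec import ECNumber, ProposedEC
from .patterns import Pattern
from .records import SequenceRecord, WorkingSet


@dataclass(frozen=True)
class VerificationStats:
    """Per-pattern outcome counts; N is carried at run level."""

    pattern_id: str
    flavor: str
    tp: int
    fp: int

    @property
    def hits(self) -> int:
        return self.tp + self.fp

    @property
    def ppv(self) -> float | None:
        """PPV, or None when the pattern hit nothing (undefined)."""
        if self.hits == 0:
            return None
        return self.tp / self.hits


def match_pattern(pattern: Pattern, sequence: str) -> list[tuple[int, int]]:
    """All non-overlapping leftmost matches as 0-based half-open intervals."""
    rx = pattern.compiled()
    return [(m.start(), m.end()) for m in rx.finditer(sequence)]


def ec_match(
    predicted: ProposedEC, truth: ECNumber | str, mode: str = "fuzzy"
) -> bool:
    """Compare a proposed annotation against a truth EC number.

    strict: some proposed EC equals the truth exactly, all four digits
    defined (partial ECs never match). fuzzy: some proposed EC agrees with
    the truth on every position defined on both sides; undefined positions
    act as wildcards.
    """
    if mode not in ("strict", "fuzzy"):
        raise ValueError(f"unknown match mode: {mode!r}")
    t = truth if isinstance(truth, ECNumber) else ECNumber.parse(truth)
    for e in predicted.all_ecs():
        if mode == "strict":
            if e.is_full and t.is_full and e.digits == t.digits:
                return True
        else:
            if all(
                a == b
                for a, b in zip(e.digits, t.digits)
                if a is not None and b is not None
            ):
                return True
    return False


@dataclass
class VerificationReport:
    per_pattern: dict[tuple[str, str], VerificationStats]
    n_missed: int  # sequences hit by no pattern (run-level N)
    n_sequences: int

    @property
    def total_tp(self) -> int:
        return sum(s.tp for s in self.per_pattern.values())

    @property
    def total_fp(self) -> int:
        return sum(s.fp for s in self.per_pattern.values())


def verify_all(
    patterns: Sequence[tuple[Pattern, ProposedEC]],
    working_set: WorkingSet,
    mode: str = "fuzzy",
) -> VerificationReport:
    """Match every pattern against the verification set and classify hits.

    A sequence is hit or not hit by a pattern (overlapping matches count
    once). Enzyme truth uses the sequence's own EC annotation; a hit is a
    TP iff any of its EC numbers matches the pattern's proposal under
    ``mode``.
    """
    records = working_set.verification_records
    stats: dict[tuple[str, str], VerificationStats] = {}
    hit_by_any = [False] * len(records)
    for pattern, proposed in patterns:
        tp = 0
        fp = 0
        for i, rec in enumerate(records):
            if not match_pattern(pattern, rec.sequence):
                continue
            hit_by_any[i] = True
            if rec.is_enzyme and any(
                ec_match(proposed, t, mode) for t in rec.ec_numbers
            ):
                tp += 1
            else:
                fp += 1
        stats[(pattern.id, pattern.flavor)] = VerificationStats(
            pattern_id=pattern.id, flavor=pattern.flavor, tp=tp, fp=fp
        )
    n_missed = sum(1 for h in hit_by_any if not h)
    return VerificationReport(
        per_pattern=stats, n_missed=n_missed, n_sequences=len(records)
    )


def ppv(tp: int, fp: int) -> float:
    """Positive predictive value TP/(TP+FP); undefined for zero hits."""
    if tp < 0 or fp < 0:
        raise ValueError("counts must be non-negative")
    if tp + fp == 0:
        raise ValueError("PPV undefined: no hits")
    return tp / (tp + fp)


def detection_rate(tp: int, fp: int, n: int) -> float:
    """Detection rate (TP+FP)/(TP+FP+N)."""
    if tp < 0 or fp < 0 or n < 0:
        raise ValueError("counts must be non-negative")
    if tp + fp + n == 0:
        raise ValueError("detection rate undefined: empty evaluation set")
    return (tp + fp) / (tp + fp + n)


def filter_patterns(
    stats: Iterable[VerificationStats] | Mapping[tuple[str, str], VerificationStats],
    cutoff: float = 1.0,
) -> list[tuple[str, str]]:
    """Keep patterns with PPV >= cutoff; at cutoff 1.0 this equals FP == 0.

    Patterns with zero verification hits have undefined PPV and are
    excluded (their precision cannot be certified).
    """
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError("cutoff must be in [0, 1]")
    items = stats.values() if isinstance(stats, Mapping) else stats
    kept = []
    for s in items:
        if s.ppv is not None and s.ppv >= cutoff:
            kept.append((s.pattern_id, s.flavor))
    return kept


def evaluate_truth_set(
    patterns: Sequence[tuple[Pattern, ProposedEC]],
    records: Sequence[SequenceRecord],
    truth: Mapping[str, Iterable[str]],
    mode: str = "strict",
) -> tuple[int, int, int]:
    """Run-level evaluation against an external truth table.

    ``truth`` maps accession to its annotated EC numbers. Returns (TP, FP,
    N): a sequence hit by at least one pattern whose proposal matches any
    truth EC (under ``mode``) counts as TP, hit without a match as FP,
    and unhit sequences as N.
    """
    tp = fp = n = 0
    for rec in records:
        hit = False
        correct = False
        for pattern, proposed in patterns:
            if not match_pattern(pattern, rec.sequence):
                continue
            hit = True
            if any(ec_match(proposed, t, mode) for t in truth.get(rec.accession, ())):
                correct = True
                break
        if not hit:
            n += 1
        elif correct:
            tp += 1
        else:
            fp += 1
    return tp, fp, n
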