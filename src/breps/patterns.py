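"""Pattern construction from MSA consensus columns, and PAM250 extension.

A pattern is an ordered list of position specifications:

* ``literal`` — exactly one residue (fully conserved column),
* ``residue_set`` — one of several residues (semi-conserved column),
* ``wildcard`` — any standard residue, repeated within a bounded span.

Standard patterns come straight from the consensus line. Extended patterns
additionally widen every semi-conserved position with the similarity set of
each residue pair present: for a pair (a, b) scoring above a threshold in
the Gonnet PAM250 matrix, the set holds every third residue at least as
similar to both a and b as they are to each other. Extension can only add
residues, so an extended pattern matches a superset of what its standard
parent matches.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, replace
from functools import lru_cache
from itertools import combinations
from typing import Iterable, Mapping, Sequence

from .msa import ConsensusColumn
from .records import STANDARD_AA

_AA_CLASS = "[" + STANDARD_AA + "]"


@dataclass(frozen=True)
class PositionSpec:
    """One pattern position: literal, residue set, or bounded wildcard."""

    kind: str  # 'literal' | 'residue_set' | 'wildcard'
    residues: frozenset[str] = frozenset()
    min_repeat: int = 1
    max_repeat: int = 1

    def __post_init__(self) -> None:
        if self.kind == "literal" and len(self.residues) != 1:
            raise ValueError("literal position needs exactly one residue")
        if self.kind == "residue_set" and len(self.residues) < 2:
            raise ValueError("residue_set position needs >=2 residues")
        if self.kind == "wildcard" and self.residues:
            raise ValueError("wildcard position carries no residues")
        if not 0 <= self.min_repeat <= self.max_repeat:
            raise ValueError("invalid repeat bounds")

    def to_regex(self) -> str:
        if self.kind == "wildcard":
            if self.min_repeat == self.max_repeat:
                return f"{_AA_CLASS}{{{self.min_repeat}}}"
            return f"{_AA_CLASS}{{{self.min_repeat},{self.max_repeat}}}"
        ordered = "".join(sorted(self.residues))
        if self.kind == "literal":
            return ordered
        return f"[{ordered}]"

    def to_prosite(self) -> str:
        if self.kind == "wildcard":
            if self.min_repeat == self.max_repeat:
                return f"x({self.min_repeat})" if self.min_repeat != 1 else "x"
            return f"x({self.min_repeat},{self.max_repeat})"
        ordered = "".join(sorted(self.residues))
        return ordered if self.kind == "literal" else f"[{ordered}]"


@dataclass(frozen=True)
class Pattern:
    """An ordered sequence pattern, standard or extended."""

    id: str
    positions: tuple[PositionSpec, ...]
    flavor: str = "standard"  # 'standard' | 'extended'
    origin_node: str = ""

    @property
    def complexity(self) -> float:
        return pattern_complexity(self)

    @property
    def n_informative(self) -> int:
        return sum(1 for p in self.positions if p.kind != "wildcard")

    @property
    def min_span(self) -> int:
        return sum(p.min_repeat for p in self.positions)

    def to_regex(self) -> str:
        return "".join(p.to_regex() for p in self.positions)

    def to_prosite(self) -> str:
        return "-".join(p.to_prosite() for p in self.positions)

    def compiled(self) -> re.Pattern:
        return _compile(self.to_regex())


@lru_cache(maxsize=4096)
def _compile(expr: str) -> re.Pattern:
    return re.compile(expr)


@dataclass(frozen=True)
class PatternConfig:
    """Consensus-to-pattern rules.

    ``min_informative`` is a quality gate: patterns with fewer literal+set
    positions are dropped (6 informative positions keep the per-window
    random match probability below roughly 20^-6). ``weak_as_set`` controls
    whether weakly conserved ('.') columns become residue sets (default:
    wildcard, to limit false positives).
    """

    min_informative: int = 6
    weak_as_set: bool = False


def build_pattern(
    columns: Sequence[ConsensusColumn],
    cfg: PatternConfig | None = None,
    pattern_id: str = "P1",
    origin_node: str = "",
) -> Pattern | None:
    """Derive a standard pattern from one alignment's consensus columns.

    '*' columns become literals; ':' columns (and '.' columns when
    ``weak_as_set``) become residue sets of the observed residues; all
    other columns become wildcards. Consecutive wildcard columns merge into
    one spanning position whose repeat count is the run length; gap columns
    inside the run lower the minimum repeat (a row with gaps there covers
    fewer sequence residues than the run has columns). Leading and trailing
    wildcards are trimmed. Returns ``None`` when the informative-position
    gate is not met.
    """
    cfg = cfg or PatternConfig()
    set_symbols = {":", "."} if cfg.weak_as_set else {":"}

    specs: list[PositionSpec] = []
    run_len = 0
    run_gapped = 0  # columns in the current wildcard run containing any gap

    def flush_run() -> None:
        nonlocal run_len, run_gapped
        if run_len:
            specs.append(
                PositionSpec(
                    kind="wildcard",
                    min_repeat=run_len - run_gapped,
                    max_repeat=run_len,
                )
            )
            run_len = 0
            run_gapped = 0

    for col in columns:
        residues = col.residues & set(STANDARD_AA)
        if col.symbol == "*" and len(residues) == 1:
            flush_run()
            specs.append(PositionSpec(kind="literal", residues=frozenset(residues)))
        elif col.symbol in set_symbols and len(residues) >= 2:
            flush_run()
            specs.append(PositionSpec(kind="residue_set", residues=frozenset(residues)))
        else:
            run_len += 1
            if col.gap_fraction > 0:
                run_gapped += 1
    flush_run()

    while specs and specs[0].kind == "wildcard":
        specs.pop(0)
    while specs and specs[-1].kind == "wildcard":
        specs.pop()

    pattern = Pattern(
        id=pattern_id,
        positions=tuple(specs),
        flavor="standard",
        origin_node=origin_node,
    )
    if pattern.n_informative < cfg.min_informative:
        return None
    return pattern


class SimilaritySets:
    """Per-amino-acid-pair extension sets from a similarity matrix.

    For every unordered pair (a, b) scoring above ``threshold``, the set
    contains each third residue c with score(c, a) >= score(a, b) and
    score(c, b) >= score(a, b) — i.e. at least as similar to both pair
    members as they are to each other. Pairs with empty sets are omitted.
    """

    def __init__(
        self,
        mapping: Mapping[frozenset[str], frozenset[str]],
        matrix_id: str = "GONNET_PAM250",
        threshold: float = 0.5,
    ):
        for pair, extra in mapping.items():
            if extra & pair:
                raise ValueError(f"similarity set for {set(pair)} contains a member")
        self._map = dict(mapping)
        self.matrix_id = matrix_id
        self.threshold = threshold

    def get(self, a: str, b: str) -> frozenset[str]:
        return self._map.get(frozenset((a, b)), frozenset())

    def items(self):
        return self._map.items()

    def __len__(self) -> int:
        return len(self._map)


def load_gonnet_pam250():
    """Gonnet PAM250 amino-acid similarity matrix (as used by Clustal)."""
    from Bio.Align import substitution_matrices

    return substitution_matrices.load("GONNET1992")


def derive_similarity_sets(
    matrix=None, threshold: float = 0.5
) -> SimilaritySets:
    """Brute-force derivation of similarity sets over all 190 residue pairs.

    Raises
    ------
    ValueError
        If the score table is not symmetric.
    """
    if matrix is None:
        matrix = load_gonnet_pam250()
    for a in STANDARD_AA:
        for b in STANDARD_AA:
            if matrix[a, b] != matrix[b, a]:
                raise ValueError(f"asymmetric score table at ({a}, {b})")
    mapping: dict[frozenset[str], frozenset[str]] = {}
    for a, b in combinations(STANDARD_AA, 2):
        s = matrix[a, b]
        if s <= threshold:
            continue
        extra = frozenset(
            c
            for c in STANDARD_AA
            if c not in (a, b) and matrix[c, a] >= s and matrix[c, b] >= s
        )
        if extra:
            mapping[frozenset((a, b))] = extra
    return SimilaritySets(mapping, threshold=threshold)


def extend_pattern(p: Pattern, sets: SimilaritySets) -> Pattern:
    """Widen every semi-conserved position with its pairs' similarity sets.

    For a residue-set position the similarity sets of all unordered residue
    pairs present are combined and unioned into the position; literals and
    wildcards are untouched. Extension is defined as a single application
    to a standard pattern (the result keeps the id, with flavor
    ``extended``).

    Raises
    ------
    ValueError
        If ``p`` is not a standard pattern.
    """
    if p.flavor != "standard":
        raise ValueError("extension applies to standard patterns only")
    new_positions = []
    for pos in p.positions:
        if pos.kind == "residue_set":
            extra: set[str] = set()
            for a, b in combinations(sorted(pos.residues), 2):
                extra |= sets.get(a, b)
            new_positions.append(
                replace(pos, residues=frozenset(pos.residues | extra))
            )
        else:
            new_positions.append(pos)
    return Pattern(
        id=p.id,
        positions=tuple(new_positions),
        flavor="extended",
        origin_node=p.origin_node,
    )


def pattern_complexity(p: Pattern) -> float:
    """Specificity measure: sum over informative positions of
    log20(20 / set size). An all-literal pattern of length n scores n; a
    widened position strictly lowers the score."""
    total = 0.0
    for pos in p.positions:
        if pos.kind == "wildcard":
            continue
        total += math.log(20.0 / len(pos.residues)) / math.log(20.0)
    return total


_PROSITE_TOKEN = re.compile(
    r"^(?:x(?:\((\d+)(?:,(\d+))?\))?|\[([A-Z]+)\]|([A-Z]))$"
)


def parse_prosite(text: str, pattern_id: str = "P1", flavor: str = "standard",
                  origin_node: str = "") -> Pattern:
    """Parse the PROSITE-like serialization (``A-x(2)-[FWY]-C``) back into a
    pattern; inverse of :meth:`Pattern.to_prosite`."""
    specs: list[PositionSpec] = []
    if text.strip():
        for token in text.strip().split("-"):
            m = _PROSITE_TOKEN.match(token)
            if not m:
                raise ValueError(f"bad pattern token: {token!r}")
            lo, hi, group, lit = m.groups()
            if lit is not None:
                specs.append(PositionSpec(kind="literal", residues=frozenset(lit)))
            elif group is not None:
                specs.append(PositionSpec(kind="residue_set", residues=frozenset(group)))
            else:
                n_min = int(lo) if lo is not None else 1
                n_max = int(hi) if hi is not None else n_min
                specs.append(
                    PositionSpec(kind="wildcard", min_repeat=n_min, max_repeat=n_max)
                )
    return Pattern(id=pattern_id, positions=tuple(specs), flavor=flavor,
                   origin_node=origin_node)
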