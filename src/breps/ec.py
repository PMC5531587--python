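"""EC-number algebra: positional consensus, AND/OR proposals, naming.

Patterns are built from clusters whose member sequences need not share one
EC number. The proposed annotation of a pattern is a consensus over the
members' EC numbers: digits agreeing across members are kept, the first
disagreeing digit and everything after it become undefined ('-'). When not
even the top-level class agrees, all functions are proposed as
alternatives (OR). Multi-functional enzymes (several EC numbers on one
entry, assumed to stem from distinct domains) yield AND-joined proposals,
kept only where the functions co-occur.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence


@dataclass(frozen=True)
class ECNumber:
    """A full or partial EC number; undefined trailing positions are None.

    Defined positions always form a prefix (``1.-.1.1`` is invalid).
    Preliminary "n" serial numbers are treated as ordinary integers.
    """

    digits: tuple[int | None, int | None, int | None, int | None]

    def __post_init__(self) -> None:
        seen_undef = False
        for d in self.digits:
            if d is None:
                seen_undef = True
            elif seen_undef:
                raise ValueError(f"defined positions must form a prefix: {self.digits}")

    @classmethod
    def parse(cls, text: str) -> "ECNumber":
        parts = text.strip().split(".")
        if not 1 <= len(parts) <= 4:
            raise ValueError(f"bad EC number: {text!r}")
        digits: list[int | None] = []
        for p in parts:
            p = p.strip()
            if p in ("-", ""):
                digits.append(None)
            else:
                digits.append(int(p.lstrip("nN")))
        digits += [None] * (4 - len(digits))
        return cls(tuple(digits))

    @property
    def depth(self) -> int:
        """Number of defined positions (0-4)."""
        return sum(1 for d in self.digits if d is not None)

    @property
    def sort_key(self) -> tuple[int, int, int, int]:
        """Lexicographic key; undefined positions sort before any digit."""
        return tuple(-1 if d is None else d for d in self.digits)

    @property
    def is_full(self) -> bool:
        return self.depth == 4

    @property
    def text(self) -> str:
        return ".".join("-" if d is None else str(d) for d in self.digits)

    def __str__(self) -> str:
        return self.text


def positional_consensus(ecs: Iterable[ECNumber | str]) -> ECNumber:
    """Longest common defined prefix of the given EC numbers.

    ``{1.1.1.1, 1.1.2.1}`` gives ``1.1.-.-``; total disagreement gives
    ``-.-.-.-``. Raises on empty input.
    """
    parsed = [e if isinstance(e, ECNumber) else ECNumber.parse(e) for e in ecs]
    if not parsed:
        raise ValueError("positional consensus of no EC numbers")
    digits: list[int | None] = []
    for i in range(4):
        vals = {e.digits[i] for e in parsed}
        if len(vals) == 1 and None not in vals:
            digits.append(vals.pop())
        else:
            break
    digits += [None] * (4 - len(digits))
    return ECNumber(tuple(digits))


@dataclass(frozen=True)
class ProposedEC:
    """Consensus annotation: OR-alternatives of AND-joined EC numbers.

    ``groups`` is a tuple of alternatives; each alternative is a tuple of
    EC numbers assumed to be distinct functions of one enzyme (AND).
    ``occurrences`` counts every (sequence, EC) annotation instance that
    went into the proposal; ``accessions`` lists the contributing entries.
    """

    groups: tuple[tuple[ECNumber, ...], ...]
    occurrences: Mapping[str, int]
    accessions: tuple[str, ...] = ()

    @property
    def text(self) -> str:
        return " OR ".join(
            " AND ".join(e.text for e in group) for group in self.groups
        )

    def all_ecs(self) -> list[ECNumber]:
        return [e for group in self.groups for e in group]

    def __str__(self) -> str:
        return self.text


def _ordered_unique(ecs: Iterable[ECNumber]) -> list[ECNumber]:
    seen: set[ECNumber] = set()
    out: list[ECNumber] = []
    for e in ecs:
        if e not in seen:
            seen.add(e)
            out.append(e)
    return out


def consensus_annotation(
    ec_sets_per_sequence: Sequence[Iterable[ECNumber | str]],
    accessions: Sequence[str] = (),
) -> ProposedEC:
    """Propose the consensus EC annotation for one pattern.

    Input is one EC collection per contributing sequence (a
    multi-functional entry contributes several ECs in one collection).
    The proposal is computed in five steps: (1) every distinct input EC
    seeds a candidate, folded through the other sequences by always
    pairing with the member EC that preserves the deepest consensus;
    (2) candidates strictly less specific than a compatible deeper
    candidate are dropped; (3) candidates with no defined position are
    replaced by their contributing full ECs as alternatives; (4) candidates
    whose contributing ECs co-occur within a single sequence are AND-joined
    (distinct functions of one enzyme); the rest are OR-alternatives;
    (5) every input EC instance is counted. Ordering of alternatives and
    AND members follows first appearance in the input.
    """
    if not ec_sets_per_sequence:
        raise ValueError("consensus annotation needs at least one sequence")
    seqs: list[list[ECNumber]] = []
    for s in ec_sets_per_sequence:
        items = [e if isinstance(e, ECNumber) else ECNumber.parse(e) for e in s]
        if isinstance(s, (set, frozenset)):
            items.sort(key=lambda e: e.sort_key)
        if not items:
            raise ValueError("every contributing sequence needs >=1 EC number")
        seqs.append(_ordered_unique(items))

    appearance: dict[ECNumber, int] = {}
    occurrences: Counter[str] = Counter()
    for seq in seqs:
        for e in seq:
            appearance.setdefault(e, len(appearance))
            occurrences[e.text] += 1

    # (1) greedy max-depth folding, one candidate per distinct input EC
    candidates: dict[ECNumber, dict[int, ECNumber]] = {}
    for seed in appearance:
        running = seed
        contrib: dict[int, ECNumber] = {}
        for si, seq in enumerate(seqs):
            depths = [(positional_consensus([running, f]).depth, f) for f in seq]
            best_depth = max(d for d, _ in depths)
            # tie-break by lexicographically smallest EC at equal depth
            best = min(
                (f for d, f in depths if d == best_depth),
                key=lambda e: e.sort_key,
            )
            contrib[si] = best
            running = positional_consensus([running, best])
        prev = candidates.get(running)
        if prev is None:
            candidates[running] = contrib
        else:
            for si, f in contrib.items():
                prev.setdefault(si, f)

    # (2) drop candidates strictly less specific than a compatible deeper one
    def less_specific(x: ECNumber, y: ECNumber) -> bool:
        if y.depth <= x.depth:
            return False
        return all(
            xd == yd for xd, yd in zip(x.digits, y.digits) if xd is not None
        )

    pruned = {
        c: contrib
        for c, contrib in candidates.items()
        if not any(less_specific(c, other) for other in candidates if other != c)
    }

    # (3) expand zero-consensus candidates into their contributing full ECs
    expanded: dict[ECNumber, dict[int, ECNumber]] = {}
    for c, contrib in pruned.items():
        if c.depth > 0:
            cur = expanded.setdefault(c, {})
            for si, f in contrib.items():
                cur.setdefault(si, f)
        else:
            for si, f in contrib.items():
                cur = expanded.setdefault(f, {})
                cur.setdefault(si, f)

    # (4) AND-group candidates that co-occur within a single sequence
    ordered = sorted(
        expanded,
        key=lambda c: min(appearance.get(f, len(appearance))
                          for f in expanded[c].values()),
    )
    parent = {c: c for c in ordered}

    def find(c: ECNumber) -> ECNumber:
        while parent[c] != c:
            parent[c] = parent[parent[c]]
            c = parent[c]
        return c

    for i, a in enumerate(ordered):
        for b in ordered[i + 1 :]:
            shared = set(expanded[a]) & set(expanded[b])
            if any(expanded[a][si] != expanded[b][si] for si in shared):
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[rb] = ra

    grouped: dict[ECNumber, list[ECNumber]] = {}
    for c in ordered:
        grouped.setdefault(find(c), []).append(c)
    groups = tuple(tuple(members) for members in grouped.values())

    return ProposedEC(
        groups=groups, occurrences=dict(occurrences), accessions=tuple(accessions)
    )


def load_name_table() -> dict[str, str]:
    """Packaged mapping from (partial) EC numbers to enzyme names.

    Full ECs map to recommended names; 1-3 level keys map to class /
    subclass / sub-subclass descriptions. The table is a small curated
    subset of the enzyme nomenclature, sufficient for the packaged
    examples; unknown ECs get a placeholder at lookup time.
    """
    from importlib.resources import files

    table: dict[str, str] = {}
    data = files("breps.data").joinpath("ec_names.tsv").read_text()
    for line in data.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        ec, name = line.split("\t")[:2]
        table[ec] = name
    return table


def annotate_name(
    proposed: ProposedEC, name_table: Mapping[str, str] | None = None
) -> list[str]:
    """Names for every EC in the proposal, in proposal order.

    A full EC maps to its recommended name; a partial EC to the deepest
    available class description; an unknown EC to a placeholder string.
    """
    if name_table is None:
        name_table = load_name_table()
    names = []
    for e in proposed.all_ecs():
        defined = [str(d) for d in e.digits if d is not None]
        name = None
        for depth in range(len(defined), 0, -1):
            name = name_table.get(".".join(defined[:depth]))
            if name is not None:
                break
        names.append(name if name is not None else f"unknown enzyme ({e.text})")
    return names
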