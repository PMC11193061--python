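"""Pre-enumerated variant dictionary for O(1) error-tolerant tag lookup.

All error tolerance is paid at build time: for every tag, every sequence
reachable within its substitution budget and its indel budget (the two
compose, each counted against its own cap) is inserted as a key of a plain
hash map.  At scan time a window lookup is a single dictionary access; query
cost is independent of the configured tolerances.

This dictionary approach suits short technical sequences; for long
sequences the enumeration is combinatorially infeasible, which is why a
configurable variant-count ceiling aborts construction with advice to lower
the tolerance (alignment-style tools remain the right choice there).
"""

from __future__ import annotations

from dataclasses import dataclass

from .config_model import TagRecord
from .errors import TagIndexError

__all__ = [
    "Candidate",
    "TagIndex",
    "enumerate_hamming",
    "enumerate_indel",
    "build_index",
    "lookup",
    "DEFAULT_VARIANT_CEILING",
]

_BASES = "ACGT"

#: Abort index construction past this many (variant, tag) entries.
DEFAULT_VARIANT_CEILING = 10_000_000


@dataclass(frozen=True)
class Candidate:
    """One possible origin of a variant key: a tag and the errors used.

    ``order`` is the tag's row position in the config, the deterministic
    tie-break between equal-error candidates.
    """

    tag: TagRecord
    order: int
    substitutions: int
    indels: int

    @property
    def total_errors(self) -> int:
        return self.substitutions + self.indels


class TagIndex:
    """Map from variant sequence to candidates, plus the distinct key lengths.

    ``lengths`` is sorted descending: the scanner probes the longest window
    first at each position.
    """

    def __init__(self, table: dict[str, tuple[Candidate, ...]]):
        self.table = table
        self.lengths: tuple[int, ...] = tuple(
            sorted({len(k) for k in table}, reverse=True)
        )

    def __len__(self) -> int:
        return len(self.table)

    def dump_tsv(self) -> str:
        """Debug dump: one row per (variant, candidate)."""
        rows = []
        for key in sorted(self.table):
            for cand in self.table[key]:
                rows.append(
                    f"{key}\t{cand.tag.tag_id}\t{cand.substitutions}\t{cand.indels}"
                )
        return "\n".join(rows) + ("\n" if rows else "")


def enumerate_hamming(sequence: str, d: int) -> set[str]:
    """All sequences of the same length within Hamming distance ``d``.

    Includes the original; for ACGT input of length L and d=1 the result has
    exactly 3L+1 elements.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    if d < 0:
        raise ValueError("d must be >= 0")
    variants = {sequence}
    frontier = {sequence}
    for _ in range(d):
        nxt = set()
        for s in frontier:
            for i, base in enumerate(s):
                for b in _BASES:
                    if b != base:
                        v = s[:i] + b + s[i + 1 :]
                        if v not in variants:
                            nxt.add(v)
        variants |= nxt
        frontier = nxt
    return variants


def enumerate_indel(sequence: str, budget: int) -> set[str]:
    """All sequences reachable by at most ``budget`` single-base
    insertions/deletions (no substitutions).  Includes the original."""
    if budget < 0:
        raise ValueError("budget must be >= 0")
    variants = {sequence}
    frontier = {sequence}
    for _ in range(budget):
        nxt = set()
        for s in frontier:
            for i in range(len(s)):  # deletions
                v = s[:i] + s[i + 1 :]
                if v and v not in variants:
                    nxt.add(v)
            for i in range(len(s) + 1):  # insertions
                for b in _BASES:
                    v = s[:i] + b + s[i:]
                    if v not in variants:
                        nxt.add(v)
        variants |= nxt
        frontier = nxt
    return variants


def _tag_variants(tag: TagRecord) -> dict[str, tuple[int, int]]:
    """Variant -> minimal (substitutions, indels) for one tag.

    Breadth-first over total errors, so the first time a variant is reached
    it carries a minimum-total-error attribution (a variant reachable by
    several paths is stored once, at its cheapest).
    """
    seen: dict[str, tuple[int, int]] = {tag.sequence: (0, 0)}
    frontier = [tag.sequence]
    for _ in range(tag.distance + tag.indels):
        nxt: list[str] = []
        for s in frontier:
            subs, inds = seen[s]
            if subs < tag.distance:
                for i, base in enumerate(s):
                    for b in _BASES:
                        if b != base:
                            v = s[:i] + b + s[i + 1 :]
                            if v not in seen:
                                seen[v] = (subs + 1, inds)
                                nxt.append(v)
            if inds < tag.indels:
                for i in range(len(s)):
                    v = s[:i] + s[i + 1 :]
                    if v and v not in seen:
                        seen[v] = (subs, inds + 1)
                        nxt.append(v)
                for i in range(len(s) + 1):
                    for b in _BASES:
                        v = s[:i] + b + s[i:]
                        if v not in seen:
                            seen[v] = (subs, inds + 1)
                            nxt.append(v)
        frontier = nxt
    return seen


def build_index(
    tags: list[TagRecord] | tuple[TagRecord, ...],
    variant_ceiling: int = DEFAULT_VARIANT_CEILING,
) -> TagIndex:
    """Build the variant dictionary for a config's tag list.

    Cross-tag key collisions are kept as multi-candidate lists ordered by
    (total errors, config row order); they are resolved at scan time.
    """
    table: dict[str, list[Candidate]] = {}
    entries = 0
    for order, tag in enumerate(tags):
        for variant, (subs, inds) in _tag_variants(tag).items():
            entries += 1
            if entries > variant_ceiling:
                raise TagIndexError(
                    f"variant enumeration exceeds {variant_ceiling} entries; "
                    "reduce distance/indels budgets for long sequences"
                )
            table.setdefault(variant, []).append(Candidate(tag, order, subs, inds))
    frozen = {
        key: tuple(sorted(cands, key=lambda c: (c.total_errors, c.order)))
        for key, cands in table.items()
    }
    return TagIndex(frozen)


def lookup(index: TagIndex, window: str) -> tuple[Candidate, ...]:
    """Candidates for a window, in (total errors, config order); empty if none.

    Pure dictionary access — no fuzzy computation happens at query time.
    """
    return index.table.get(window, ())
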