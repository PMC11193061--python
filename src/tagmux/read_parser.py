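"""Greedy left-to-right scanner that turns reads into ordered tag hits.

Files of a fragment set are scanned in input order; within a file a cursor
moves left to right.  At each position, windows of every indexed length are
probed longest-first; the first window with an eligible candidate yields a
hit (minimum total errors, config row order breaking ties), the cursor jumps
to the hit's end (hits never overlap), and any ``next`` directive on the hit
tag replaces the searchable group set for the remainder of the fragment set.

Eligibility combines three constraint families: the tag's group must be in
the currently searchable set, the hit's start must lie inside the tag's
location window (when one is configured), and per-tag / per-group find
counts must be below their caps.  Positions at which no tag could possibly
be eligible are skipped without dictionary probes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .config_model import Config, TagRecord
from .tag_index import Candidate, TagIndex

__all__ = [
    "FragmentSet",
    "TagHit",
    "ParseState",
    "ParseResult",
    "eligible",
    "resolve_candidates",
    "parse_fragment_set",
]


@dataclass
class FragmentSet:
    """Co-indexed reads (one per input file) for a single record.

    ``headers`` are FASTQ title lines without the leading ``@``.
    """

    headers: list[str]
    sequences: list[str]
    qualities: list[str]

    def __post_init__(self):
        for seq, qual in zip(self.sequences, self.qualities):
            if len(seq) != len(qual):
                raise ValueError("sequence/quality length mismatch")


@dataclass(frozen=True)
class TagHit:
    """One identified tag occurrence: ``[start, end)`` in file ``file_index``."""

    tag_id: str
    group: str
    file_index: int
    start: int
    end: int
    substitutions: int
    indels: int


@dataclass
class ParseState:
    """Mutable scan state: searchable groups and find counters."""

    active_groups: set[str]
    tag_counts: dict[str, int] = field(default_factory=dict)
    group_counts: dict[str, int] = field(default_factory=dict)


@dataclass
class ParseResult:
    """Ordered hits for one fragment set plus routing status.

    ``combination`` is the tuple of tag ids in (file, start) hit order —
    the identity later mapped to a numerical ID and final barcode.
    ``extractions`` is filled in by the read editor.
    """

    hits: list[TagHit]
    combination: tuple[str, ...]
    assigned: bool
    extractions: dict[str, tuple[str, str]] = field(default_factory=dict)


def eligible(tag: TagRecord, state: ParseState, file_index: int, position: int) -> bool:
    """May ``tag`` be identified starting at (file_index, position) now?"""
    if tag.group not in state.active_groups:
        return False
    loc = tag.location
    if loc is not None and not (
        loc.file_index == file_index and loc.start <= position < loc.end
    ):
        return False
    if tag.max_finds is not None and state.tag_counts.get(tag.tag_id, 0) >= tag.max_finds:
        return False
    if (
        tag.max_finds_group is not None
        and state.group_counts.get(tag.group, 0) >= tag.max_finds_group
    ):
        return False
    return True


def resolve_candidates(
    cands: tuple[Candidate, ...] | list[Candidate],
    state: ParseState,
    file_index: int,
    position: int,
) -> Candidate | None:
    """Best eligible candidate of one lookup window, or None.

    Candidates are ordered (total errors, config row order) at index build,
    so the first eligible one is the winner; the ordering is a total order
    over distinct tags, leaving no residual ties.
    """
    for cand in cands:
        if eligible(cand.tag, state, file_index, position):
            return cand
    return None


def _any_searchable(
    tags: tuple[TagRecord, ...], state: ParseState, file_index: int, position: int
) -> bool:
    return any(eligible(t, state, file_index, position) for t in tags)


def parse_fragment_set(
    frag: FragmentSet,
    index: TagIndex,
    config: Config,
    keep_groups: set[str] | frozenset[str] | None = None,
) -> ParseResult:
    """Scan one fragment set and return its ordered hits and routing status.

    A read is *assigned* when its combination is non-empty, every tag's
    ``minFinds`` requirement is met, and (when ``keep_groups`` is given)
    every required group appears among the hits.  Reads matching nothing
    yield an empty-combination, unassigned result — never an error.
    """
    state = ParseState(active_groups=set(config.groups))
    hits: list[TagHit] = []

    for file_index, seq in enumerate(frag.sequences):
        n = len(seq)
        cursor = 0
        while cursor < n:
            if not _any_searchable(config.tags, state, file_index, cursor):
                cursor += 1
                continue
            best: Candidate | None = None
            for length in index.lengths:
                if cursor + length > n:
                    continue
                cands = index.table.get(seq[cursor : cursor + length])
                if not cands:
                    continue
                best = resolve_candidates(cands, state, file_index, cursor)
                if best is not None:
                    break
            if best is None:
                cursor += 1
                continue
            tag = best.tag
            # hit span is the window that matched, not the reference length
            end = cursor + length
            hits.append(
                TagHit(
                    tag_id=tag.tag_id,
                    group=tag.group,
                    file_index=file_index,
                    start=cursor,
                    end=end,
                    substitutions=best.substitutions,
                    indels=best.indels,
                )
            )
            state.tag_counts[tag.tag_id] = state.tag_counts.get(tag.tag_id, 0) + 1
            state.group_counts[tag.group] = state.group_counts.get(tag.group, 0) + 1
            if tag.next_groups is not None:
                state.active_groups = set(tag.next_groups)
            cursor = end

    combination = tuple(h.tag_id for h in hits)
    assigned = bool(combination)
    if assigned:
        for tag in config.tags:
            if tag.min_finds and state.tag_counts.get(tag.tag_id, 0) < tag.min_finds:
                assigned = False
                break
    if assigned and keep_groups:
        present = {h.group for h in hits}
        assigned = keep_groups <= present
    return ParseResult(hits=hits, combination=combination, assigned=assigned)
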