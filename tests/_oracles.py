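"""Independent brute-force oracles used by the tests.

Deliberately naive: exhaustive enumeration and direct distance computation,
sharing no code with the package's pre-enumerated dictionary path.
"""

from itertools import product

BASES = "ACGT"


def hamming(a: str, b: str) -> int:
    assert len(a) == len(b)
    return sum(x != y for x, y in zip(a, b))


def hamming_ball_brute(s: str, d: int) -> set[str]:
    """Filter all 4^|s| sequences by Hamming distance <= d."""
    return {
        "".join(v) for v in product(BASES, repeat=len(s)) if hamming("".join(v), s) <= d
    }


def _lcs_len(a: str, b: str) -> int:
    prev = [0] * (len(b) + 1)
    for x in a:
        cur = [0]
        for j, y in enumerate(b, 1):
            cur.append(prev[j - 1] + 1 if x == y else max(prev[j], cur[-1]))
        prev = cur
    return prev[-1]


def indel_ball_brute(s: str, budget: int) -> set[str]:
    """All sequences reachable by <= budget insertions/deletions: the
    minimal indel-only edit count is |a| + |b| - 2*LCS(a, b)."""
    out = set()
    for length in range(max(1, len(s) - budget), len(s) + budget + 1):
        for v in product(BASES, repeat=length):
            v = "".join(v)
            if len(s) + len(v) - 2 * _lcs_len(s, v) <= budget:
                out.add(v)
    return out


def scan_brute(sequences: list[str], config) -> list[tuple]:
    """Greedy left-to-right scan with direct Hamming computation.

    Substitution-only configs. Returns hits as tuples
    (tag_id, file_index, start, end, errors). Mirrors the documented
    semantics: longest window first, minimum (errors, config order),
    location constrains the start, counts capped, cursor jumps to hit end,
    'next' replaces the searchable group set.
    """
    groups = []
    for t in config.tags:
        if t.group not in groups:
            groups.append(t.group)
    active = set(groups)
    tag_counts: dict[str, int] = {}
    group_counts: dict[str, int] = {}
    lengths = sorted({len(t.sequence) for t in config.tags}, reverse=True)
    hits = []

    def ok(tag, fi, pos):
        if tag.group not in active:
            return False
        loc = tag.location
        if loc is not None and not (loc.file_index == fi and loc.start <= pos < loc.end):
            return False
        if tag.max_finds is not None and tag_counts.get(tag.tag_id, 0) >= tag.max_finds:
            return False
        if (
            tag.max_finds_group is not None
            and group_counts.get(tag.group, 0) >= tag.max_finds_group
        ):
            return False
        return True

    for fi, seq in enumerate(sequences):
        cursor = 0
        while cursor < len(seq):
            best = None
            for length in lengths:
                if cursor + length > len(seq):
                    continue
                window = seq[cursor : cursor + length]
                for order, tag in enumerate(config.tags):
                    if len(tag.sequence) != length:
                        continue
                    errs = hamming(window, tag.sequence)
                    if errs <= tag.distance and ok(tag, fi, cursor):
                        if best is None or (errs, order) < best[:2]:
                            best = (errs, order, tag, length)
                if best is not None:
                    break
            if best is None:
                cursor += 1
                continue
            errs, _, tag, length = best
            hits.append((tag.tag_id, fi, cursor, cursor + length, errs))
            tag_counts[tag.tag_id] = tag_counts.get(tag.tag_id, 0) + 1
            group_counts[tag.group] = group_counts.get(tag.group, 0) + 1
            if tag.next_groups is not None:
                active = set(tag.next_groups)
            cursor += length
    return hits
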