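"""In-situ read editing: extractions, tag substitution/removal, end trims.

Processing order per read is identify → extract → substitute/remove →
global trim.  Extraction coordinates refer to the original, unedited read,
so configured edits can never shift an extraction anchor; per-hit edits are
applied right-to-left so earlier coordinates stay valid; global 5'/3' trims
come last.  Quality strings are edited in lockstep with sequences at every
step.
"""

from __future__ import annotations

from .config_model import Config, ExtractionSpec, REMOVE
from .errors import ExtractionFailed
from .read_parser import FragmentSet, ParseResult, TagHit

__all__ = ["apply_extractions", "apply_edits", "QUALITY_FILL"]

#: Quality character for bases introduced by a replacement longer than the
#: span it replaces (and for synthetic barcode records downstream).
QUALITY_FILL = "K"


def apply_extractions(
    frag: FragmentSet, result: ParseResult, specs: tuple[ExtractionSpec, ...]
) -> dict[str, tuple[str, str]]:
    """Extract every configured subsequence from the original read.

    Anchored specs use the first hit (scan order) whose tag id or group
    matches the anchor and take ``[hit.end + offset, hit.end + offset +
    length)`` in that hit's file.  Positional specs use a fixed window.
    Raises :class:`~tagmux.errors.ExtractionFailed` when the anchor is
    absent or the window leaves the read; the caller routes such reads to
    the unassigned stream.
    """
    out: dict[str, tuple[str, str]] = {}
    for spec in specs:
        if spec.anchor is not None:
            hit = _find_anchor(result.hits, spec.anchor)
            if hit is None:
                raise ExtractionFailed(spec.name, f"anchor {spec.anchor!r} not found")
            file_index = hit.file_index
            start = hit.end + spec.offset
        else:
            file_index = spec.file_index
            start = spec.start
        if file_index >= len(frag.sequences):
            raise ExtractionFailed(spec.name, f"file #{file_index} not among inputs")
        seq = frag.sequences[file_index]
        end = start + spec.length
        if end > len(seq):
            raise ExtractionFailed(
                spec.name, f"window {start}:{end} exceeds read length {len(seq)}"
            )
        out[spec.name] = (seq[start:end], frag.qualities[file_index][start:end])
    return out


def _find_anchor(hits: list[TagHit], anchor: str) -> TagHit | None:
    for hit in hits:
        if hit.tag_id == anchor or hit.group == anchor:
            return hit
    return None


def apply_edits(frag: FragmentSet, result: ParseResult, config: Config) -> FragmentSet:
    """Apply per-hit substitutions and global end trims; returns a new set.

    A hit whose tag carries ``subst='-'`` is deleted; an ACGT value replaces
    the matched span (replacement quality is the original span's quality,
    truncated or padded with :data:`QUALITY_FILL`); absent means keep.
    Trims longer than the read truncate it to an empty, retained record.
    """
    actions = {t.tag_id: t.substitution for t in config.tags}
    sequences = list(frag.sequences)
    qualities = list(frag.qualities)

    by_file: dict[int, list[TagHit]] = {}
    for hit in result.hits:
        if actions.get(hit.tag_id) is not None:
            by_file.setdefault(hit.file_index, []).append(hit)

    for file_index, hits in by_file.items():
        seq, qual = sequences[file_index], qualities[file_index]
        for hit in sorted(hits, key=lambda h: h.start, reverse=True):
            action = actions[hit.tag_id]
            if action == REMOVE:
                seq = seq[: hit.start] + seq[hit.end :]
                qual = qual[: hit.start] + qual[hit.end :]
            else:  # replace
                span_qual = qual[hit.start : hit.end]
                new_qual = (span_qual + QUALITY_FILL * len(action))[: len(action)]
                seq = seq[: hit.start] + action + seq[hit.end :]
                qual = qual[: hit.start] + new_qual + qual[hit.end :]
        sequences[file_index], qualities[file_index] = seq, qual

    trim5, trim3 = config.header.trim5, config.header.trim3
    for file_index in range(len(sequences)):
        lo = trim5[file_index] if file_index < len(trim5) else 0
        hi = trim3[file_index] if file_index < len(trim3) else 0
        seq, qual = sequences[file_index], qualities[file_index]
        if lo + hi >= len(seq):
            seq, qual = "", ""
        else:
            end = len(seq) - hi
            seq, qual = seq[lo:end], qual[lo:end]
        sequences[file_index], qualities[file_index] = seq, qual

    return FragmentSet(headers=list(frag.headers), sequences=sequences, qualities=qualities)
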