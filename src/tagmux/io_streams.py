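"""FASTQ streaming: paired files, gzip, interleaved standard streams.

Input records are read with Biopython's low-level FASTQ iterator (titles,
sequences and qualities as plain strings); gzip is autodetected from the
magic bytes on read and selected by a ``.gz`` suffix on write.  Paired
files are kept synchronized: a record-count mismatch or a header
disagreement (after stripping ``/1``/``/2`` and anything past the first
whitespace) is a hard error naming the record index.

Outputs: assigned reads to the main per-file sinks, everything else to the
unassigned sinks (or dropped when none are configured), the final-barcode
FASTQ, per-extraction FASTQ streams, and the mapping TSV.  ``--pipe`` mode
interleaves the main fragments round-robin on standard output so the stream
can be piped into downstream tools, including another invocation of this
tool.
"""

from __future__ import annotations

import gzip
import io
import sys
from dataclasses import dataclass, field
from typing import IO, Callable, Iterable, Iterator

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .barcode_registry import BARCODE_LENGTH
from .errors import StreamError
from .read_parser import FragmentSet

__all__ = [
    "StreamSpec",
    "Summary",
    "OutputSinks",
    "read_fragment_sets",
    "write_outputs",
    "open_input",
    "open_output",
]

_GZIP_MAGIC = b"\x1f\x8b"
BARCODE_QUALITY_FILL = "K"


@dataclass(frozen=True)
class StreamSpec:
    """An input or output stream: a path, or ``-`` for a standard stream.

    ``interleave`` is the number of logical files multiplexed on a single
    stream (1 for ordinary files).
    """

    path: str
    interleave: int = 1


def open_input(path: str) -> IO[str]:
    """Open a FASTQ source for text reading, transparently ungzipping."""
    if path == "-":
        return sys.stdin
    raw = open(path, "rb")
    if raw.peek(2)[:2] == _GZIP_MAGIC:
        return io.TextIOWrapper(gzip.GzipFile(fileobj=raw))
    return io.TextIOWrapper(raw)


def open_output(path: str) -> IO[str]:
    """Open a text sink; ``.gz`` suffix selects gzip, ``-`` means stdout."""
    if path == "-":
        return sys.stdout
    if path.endswith(".gz"):
        return gzip.open(path, "wt")
    return open(path, "w")


def _records(path: str) -> Iterator[tuple[str, str, str]]:
    handle = open_input(path)
    index = 0
    try:
        for title, seq, qual in FastqGeneralIterator(handle):
            yield title, seq, qual
            index += 1
    except ValueError as exc:  # malformed record ('@'/'+' markers, line count)
        raise StreamError(f"{path}: malformed FASTQ at record {index}: {exc}") from exc
    finally:
        if handle not in (sys.stdin,):
            handle.close()


def _record_key(title: str) -> str:
    key = title.split()[0] if title.split() else title
    if key.endswith("/1") or key.endswith("/2"):
        key = key[:-2]
    return key


def read_fragment_sets(inputs: list[StreamSpec] | list[str]) -> Iterator[FragmentSet]:
    """Yield co-indexed :class:`FragmentSet` records from the input files.

    A single input with an interleave factor > 1 is de-interleaved into that
    many logical files.  Desynchronized inputs (one ends early, or headers
    disagree) raise :class:`~tagmux.errors.StreamError`.
    """
    specs = [s if isinstance(s, StreamSpec) else StreamSpec(s) for s in inputs]
    if not specs:
        raise StreamError("no input streams")

    if len(specs) == 1 and specs[0].interleave > 1:
        factor = specs[0].interleave
        buffer: list[tuple[str, str, str]] = []
        count = 0
        for rec in _records(specs[0].path):
            buffer.append(rec)
            if len(buffer) == factor:
                yield _to_fragment_set(buffer, count)
                count += 1
                buffer = []
        if buffer:
            raise StreamError(
                f"interleaved stream ended mid-record-set at record {count} "
                f"({len(buffer)}/{factor} fragments)"
            )
        return

    iterators = [_records(s.path) for s in specs]
    count = 0
    while True:
        batch: list[tuple[str, str, str] | None] = []
        for it in iterators:
            batch.append(next(it, None))
        if all(b is None for b in batch):
            return
        if any(b is None for b in batch):
            short = [specs[i].path for i, b in enumerate(batch) if b is None]
            raise StreamError(
                f"input desynchronized at record {count}: {', '.join(short)} ended early"
            )
        yield _to_fragment_set(batch, count)  # type: ignore[arg-type]
        count += 1


def _to_fragment_set(records: list[tuple[str, str, str]], index: int) -> FragmentSet:
    keys = {_record_key(title) for title, _, _ in records}
    if len(keys) > 1:
        raise StreamError(
            f"record {index}: identifiers disagree across files: {sorted(keys)}"
        )
    return FragmentSet(
        headers=[r[0] for r in records],
        sequences=[r[1] for r in records],
        qualities=[r[2] for r in records],
    )


def _write_record(handle: IO[str], title: str, seq: str, qual: str) -> None:
    handle.write(f"@{title}\n{seq}\n+\n{qual}\n")


@dataclass
class Summary:
    """Run tally: conservation requires reads == assigned + unassigned."""

    reads: int = 0
    assigned: int = 0
    unassigned: int = 0
    combinations: int = 0


@dataclass
class OutputSinks:
    """Where each routing class goes.  Any member may be empty/None.

    ``pipe`` replaces the per-file main sinks by round-robin interleaving on
    one stream (normally stdout).  ``extract_to_header`` appends
    ``name=SEQ`` to output read titles instead of writing per-extraction
    FASTQ files.
    """

    main: list[str] = field(default_factory=list)
    unassigned: list[str] = field(default_factory=list)
    barcode: str | None = None
    mapping: str | None = None
    extractions: dict[str, str] = field(default_factory=dict)
    pipe: str | None = None
    extract_to_header: bool = False


def write_outputs(
    results: Iterable[tuple[FragmentSet, bool, str | None, dict[str, tuple[str, str]]]],
    sinks: OutputSinks,
    mapping_provider: Callable[[], str] | None = None,
) -> Summary:
    """Route a stream of processed records to the configured sinks.

    Each item is ``(edited fragment set, assigned, barcode or None,
    extractions)``.  Returns the conservation summary; the mapping file is a
    rendering of the registry known only once the stream is exhausted, so it
    is obtained from ``mapping_provider`` after the loop.
    """
    summary = Summary()
    barcodes_seen: set[str] = set()

    main_handles = [open_output(p) for p in sinks.main] if not sinks.pipe else []
    pipe_handle = open_output(sinks.pipe) if sinks.pipe else None
    unassigned_handles = [open_output(p) for p in sinks.unassigned]
    barcode_handle = open_output(sinks.barcode) if sinks.barcode else None
    extraction_handles = (
        {name: open_output(p) for name, p in sinks.extractions.items()}
        if not sinks.extract_to_header
        else {}
    )

    try:
        for frag, assigned, barcode, extractions in results:
            summary.reads += 1
            if assigned:
                summary.assigned += 1
                titles = list(frag.headers)
                if sinks.extract_to_header and extractions:
                    suffix = " ".join(f"{n}={s}" for n, (s, _) in sorted(extractions.items()))
                    titles = [f"{t} {suffix}" for t in titles]
                if pipe_handle is not None:
                    for t, s, q in zip(titles, frag.sequences, frag.qualities):
                        _write_record(pipe_handle, t, s, q)
                else:
                    for h, t, s, q in zip(main_handles, titles, frag.sequences, frag.qualities):
                        _write_record(h, t, s, q)
                if barcode_handle is not None and barcode is not None:
                    _write_record(
                        barcode_handle,
                        frag.headers[0],
                        barcode,
                        BARCODE_QUALITY_FILL * BARCODE_LENGTH,
                    )
                if barcode is not None:
                    barcodes_seen.add(barcode)
                for name, handle in extraction_handles.items():
                    if name in extractions:
                        seq, qual = extractions[name]
                        _write_record(handle, frag.headers[0], seq, qual)
            else:
                summary.unassigned += 1
                for h, t, s, q in zip(
                    unassigned_handles, frag.headers, frag.sequences, frag.qualities
                ):
                    _write_record(h, t, s, q)
    finally:
        for h in (
            main_handles
            + unassigned_handles
            + ([barcode_handle] if barcode_handle else [])
            + list(extraction_handles.values())
        ):
            h.close()
        if pipe_handle is not None and pipe_handle is not sys.stdout:
            pipe_handle.close()
        elif pipe_handle is sys.stdout:
            pipe_handle.flush()

    summary.combinations = len(barcodes_seen)
    if sinks.mapping and mapping_provider is not None:
        mh = open_output(sinks.mapping)
        mh.write(mapping_provider())
        if mh is not sys.stdout:
            mh.close()
    return summary
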