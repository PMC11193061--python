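"""Configuration dialect: header ``@``-options plus a tab-separated tag table.

A config file drives everything downstream: which technical sequences
("tags") are searched for, with what error tolerance, where in which read
they may occur, which groups become searchable after a hit, how often a tag
or group may be found, what gets extracted (UMIs), and how reads are edited.

The dialect::

    @extract umi=<grp_B>+3:8
    @trim-3 0,4
    id<TAB>group<TAB>sequence<TAB>distance<TAB>...
    Barcode_A1<TAB>grp_A<TAB>TTAGTT<TAB>1<TAB>...

Header lines are ``@key value``; ``@trim-3``/``@trim-5`` take one
comma-separated count per input file.  ``@extract`` takes one or more
comma-separated extraction expressions, each either anchored
(``name=<anchor>+offset:length`` — *anchor* is a tag or group name, *offset*
bases are skipped after the hit's end) or positional
(``name=file:start:length``).  The table's first row names its columns; the
recognized names are ``id``, ``group``, ``sequence``, ``distance``,
``indels``, ``location``, ``next``, ``maxFinds``, ``maxFindsG``,
``minFinds``, ``subst``.  An empty cell means the default.  All coordinates
are 0-based, half-open.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import ConfigError

__all__ = [
    "FileWindow",
    "TagRecord",
    "ExtractionSpec",
    "HeaderOptions",
    "Config",
    "parse_config",
    "serialize_config",
    "COLUMNS",
]

#: Substitution action sentinel: remove the identified tag from the read.
REMOVE = "-"

#: Recognized table columns, in canonical (serialization) order.
COLUMNS = (
    "id",
    "group",
    "sequence",
    "distance",
    "indels",
    "location",
    "next",
    "maxFinds",
    "maxFindsG",
    "minFinds",
    "subst",
)

_ACGT = re.compile(r"[ACGT]+\Z")


@dataclass(frozen=True)
class FileWindow:
    """Half-open position window ``[start, end)`` in input file ``file_index``."""

    file_index: int
    start: int
    end: int

    def __post_init__(self):
        if self.file_index < 0:
            raise ConfigError(f"negative file index {self.file_index}")
        if not (0 <= self.start < self.end):
            raise ConfigError(
                f"window must satisfy 0 <= start < end, got {self.start}:{self.end}"
            )

    def __str__(self) -> str:
        return f"{self.file_index}:{self.start}:{self.end}"


@dataclass(frozen=True)
class TagRecord:
    """One tag definition: a known technical sequence and its search rules.

    ``distance`` is the substitution (Hamming) tolerance, ``indels`` the
    insertion/deletion tolerance; both budgets are independent.  ``location``
    constrains where the hit may *start*.  ``next_groups``, when set,
    replaces the searchable group set after this tag is found.
    ``substitution`` is ``None`` (keep the matched bases), :data:`REMOVE`
    (delete them), or a replacement ACGT string.
    """

    tag_id: str
    group: str
    sequence: str
    distance: int = 0
    indels: int = 0
    location: FileWindow | None = None
    next_groups: tuple[str, ...] | None = None
    max_finds: int | None = None
    max_finds_group: int | None = None
    min_finds: int = 0
    substitution: str | None = None


@dataclass(frozen=True)
class ExtractionSpec:
    """A named subsequence to pull out of each read.

    Anchored mode (``anchor`` set): extract ``length`` bases starting
    ``offset`` bases after the end of the first hit whose tag id or group
    equals ``anchor``.  Positional mode (``file_index``/``start`` set):
    extract ``length`` bases at a fixed window.
    """

    name: str
    length: int
    anchor: str | None = None
    offset: int = 0
    file_index: int | None = None
    start: int | None = None

    @property
    def mode(self) -> str:
        return "anchored" if self.anchor is not None else "positional"

    def __str__(self) -> str:
        if self.anchor is not None:
            return f"{self.name}=<{self.anchor}>+{self.offset}:{self.length}"
        return f"{self.name}={self.file_index}:{self.start}:{self.length}"


@dataclass(frozen=True)
class HeaderOptions:
    """Global ``@``-options: per-file end trims and extraction specs."""

    trim3: tuple[int, ...] = ()
    trim5: tuple[int, ...] = ()
    extract: tuple[ExtractionSpec, ...] = ()


@dataclass(frozen=True)
class Config:
    """A validated configuration: header options plus ordered tag records.

    Tag order is the file order and is used for tie-breaking during
    identification, so it is preserved exactly.
    """

    header: HeaderOptions = field(default_factory=HeaderOptions)
    tags: tuple[TagRecord, ...] = ()

    @property
    def groups(self) -> tuple[str, ...]:
        """Group names in first-appearance order."""
        seen: dict[str, None] = {}
        for t in self.tags:
            seen.setdefault(t.group, None)
        return tuple(seen)

    def tag_by_id(self, tag_id: str) -> TagRecord:
        for t in self.tags:
            if t.tag_id == tag_id:
                return t
        raise KeyError(tag_id)


# ---------------------------------------------------------------------------
# parsing


def _parse_int(cell: str, what: str, line: int, minimum: int = 0) -> int:
    try:
        v = int(cell)
    except ValueError:
        raise ConfigError(f"{what} must be an integer, got {cell!r}", line) from None
    if v < minimum:
        raise ConfigError(f"{what} must be >= {minimum}, got {v}", line)
    return v


def _parse_window(cell: str, line: int) -> FileWindow:
    parts = cell.split(":")
    if len(parts) != 3:
        raise ConfigError(f"malformed location {cell!r} (expected f:start:end)", line)
    try:
        f, s, e = (int(p) for p in parts)
    except ValueError:
        raise ConfigError(f"malformed location {cell!r} (non-integer field)", line) from None
    try:
        return FileWindow(f, s, e)
    except ConfigError as exc:
        raise ConfigError(str(exc), line) from None


_EXTRACT_ANCHORED = re.compile(r"(?P<name>[\w.-]+)=<(?P<anchor>[\w.-]+)>\+(?P<offset>\d+):(?P<length>\d+)\Z")
_EXTRACT_POSITIONAL = re.compile(r"(?P<name>[\w.-]+)=(?P<file>\d+):(?P<start>\d+):(?P<length>\d+)\Z")


def _parse_extract(expr: str, line: int) -> ExtractionSpec:
    m = _EXTRACT_ANCHORED.match(expr)
    if m:
        length = int(m["length"])
        if length < 1:
            raise ConfigError(f"extraction length must be >= 1 in {expr!r}", line)
        return ExtractionSpec(m["name"], length, anchor=m["anchor"], offset=int(m["offset"]))
    m = _EXTRACT_POSITIONAL.match(expr)
    if m:
        length = int(m["length"])
        if length < 1:
            raise ConfigError(f"extraction length must be >= 1 in {expr!r}", line)
        return ExtractionSpec(
            m["name"], length, file_index=int(m["file"]), start=int(m["start"])
        )
    raise ConfigError(
        f"malformed @extract expression {expr!r} "
        "(expected name=<anchor>+offset:length or name=file:start:length)",
        line,
    )


def _parse_header_line(text: str, line: int, opts: dict) -> None:
    parts = text[1:].split(None, 1)
    if not parts:
        raise ConfigError("empty @-option", line)
    key = parts[0]
    value = parts[1].strip() if len(parts) > 1 else ""
    if key in ("trim-3", "trim-5"):
        if not value:
            raise ConfigError(f"@{key} needs comma-separated counts", line)
        counts = tuple(
            _parse_int(c.strip(), f"@{key} count", line) for c in value.split(",")
        )
        opts["trim3" if key == "trim-3" else "trim5"] = counts
    elif key == "extract":
        if not value:
            raise ConfigError("@extract needs at least one expression", line)
        opts.setdefault("extract", []).extend(
            _parse_extract(e.strip(), line) for e in value.split(",")
        )
    else:
        raise ConfigError(f"unknown header option @{key}", line)


def parse_config(text: str) -> Config:
    """Parse config-file content into a validated :class:`Config`.

    Raises :class:`~tagmux.errors.ConfigError` (with a line number) on any
    violation of the dialect; never returns a partial config.
    """
    opts: dict = {}
    columns: list[str] | None = None
    tags: list[TagRecord] = []
    seen_ids: set[str] = set()

    for lineno, raw in enumerate(text.splitlines(), start=1):
        stripped = raw.strip()
        if not stripped or stripped.startswith("#"):
            continue
        if stripped.startswith("@"):
            if columns is not None:
                raise ConfigError("@-options must precede the tag table", lineno)
            _parse_header_line(stripped, lineno, opts)
            continue
        cells = raw.rstrip("\n").split("\t")
        if columns is None:
            columns = [c.strip() for c in cells]
            unknown = set(columns) - set(COLUMNS)
            if unknown:
                raise ConfigError(f"unknown column(s): {', '.join(sorted(unknown))}", lineno)
            for required in ("id", "group", "sequence"):
                if required not in columns:
                    raise ConfigError(f"missing required column {required!r}", lineno)
            if len(set(columns)) != len(columns):
                raise ConfigError("duplicate column name", lineno)
            continue
        if len(cells) > len(columns):
            raise ConfigError(
                f"row has {len(cells)} cells but table has {len(columns)} columns", lineno
            )
        cells += [""] * (len(columns) - len(cells))
        row = {col: cell.strip() for col, cell in zip(columns, cells)}
        tags.append(_parse_row(row, lineno, seen_ids))

    if not tags:
        raise ConfigError("config defines no tags")

    config = Config(
        header=HeaderOptions(
            trim3=opts.get("trim3", ()),
            trim5=opts.get("trim5", ()),
            extract=tuple(opts.get("extract", ())),
        ),
        tags=tuple(tags),
    )
    _validate(config)
    return config


def _parse_row(row: dict[str, str], lineno: int, seen_ids: set[str]) -> TagRecord:
    tag_id = row.get("id", "")
    if not tag_id:
        raise ConfigError("empty tag id", lineno)
    if tag_id in seen_ids:
        raise ConfigError(f"duplicate tag id {tag_id!r}", lineno)
    seen_ids.add(tag_id)
    group = row.get("group", "")
    if not group:
        raise ConfigError(f"tag {tag_id!r} has no group", lineno)
    sequence = row.get("sequence", "")
    if not _ACGT.match(sequence):
        raise ConfigError(
            f"tag {tag_id!r} sequence must be non-empty over ACGT, got {sequence!r}", lineno
        )

    distance = _parse_int(row["distance"], "distance", lineno) if row.get("distance") else 0
    if distance >= len(sequence):
        raise ConfigError(
            f"tag {tag_id!r}: distance {distance} must be < sequence length {len(sequence)}",
            lineno,
        )
    indels = _parse_int(row["indels"], "indels", lineno) if row.get("indels") else 0
    location = _parse_window(row["location"], lineno) if row.get("location") else None
    next_groups = None
    if row.get("next"):
        next_groups = tuple(g.strip() for g in row["next"].split(","))
        if any(not g for g in next_groups):
            raise ConfigError(f"tag {tag_id!r}: empty group name in next", lineno)
    max_finds = (
        _parse_int(row["maxFinds"], "maxFinds", lineno, minimum=1)
        if row.get("maxFinds")
        else None
    )
    max_finds_group = (
        _parse_int(row["maxFindsG"], "maxFindsG", lineno, minimum=1)
        if row.get("maxFindsG")
        else None
    )
    min_finds = _parse_int(row["minFinds"], "minFinds", lineno) if row.get("minFinds") else 0
    substitution: str | None = None
    if row.get("subst"):
        cell = row["subst"]
        if cell == REMOVE:
            substitution = REMOVE
        elif _ACGT.match(cell):
            substitution = cell
        else:
            raise ConfigError(
                f"tag {tag_id!r}: subst must be '-' or an ACGT string, got {cell!r}", lineno
            )

    return TagRecord(
        tag_id=tag_id,
        group=group,
        sequence=sequence,
        distance=distance,
        indels=indels,
        location=location,
        next_groups=next_groups,
        max_finds=max_finds,
        max_finds_group=max_finds_group,
        min_finds=min_finds,
        substitution=substitution,
    )


def _validate(config: Config) -> None:
    groups = set(config.groups)
    names = groups | {t.tag_id for t in config.tags}
    for t in config.tags:
        if t.next_groups is not None:
            for g in t.next_groups:
                if g not in groups:
                    raise ConfigError(
                        f"tag {t.tag_id!r}: next names undefined group {g!r}"
                    )
    for spec in config.header.extract:
        if spec.anchor is not None and spec.anchor not in names:
            raise ConfigError(
                f"extraction {spec.name!r}: anchor {spec.anchor!r} is neither "
                "a tag id nor a group"
            )


# ---------------------------------------------------------------------------
# serialization


def _render_cell(tag: TagRecord, col: str) -> str:
    if col == "id":
        return tag.tag_id
    if col == "group":
        return tag.group
    if col == "sequence":
        return tag.sequence
    if col == "distance":
        return str(tag.distance) if tag.distance else ""
    if col == "indels":
        return str(tag.indels) if tag.indels else ""
    if col == "location":
        return str(tag.location) if tag.location else ""
    if col == "next":
        return ",".join(tag.next_groups) if tag.next_groups else ""
    if col == "maxFinds":
        return str(tag.max_finds) if tag.max_finds is not None else ""
    if col == "maxFindsG":
        return str(tag.max_finds_group) if tag.max_finds_group is not None else ""
    if col == "minFinds":
        return str(tag.min_finds) if tag.min_finds else ""
    if col == "subst":
        return tag.substitution if tag.substitution is not None else ""
    raise AssertionError(col)


def serialize_config(config: Config) -> str:
    """Render a :class:`Config` back to file content.

    ``parse_config(serialize_config(c))`` is structurally identical to ``c``.
    """
    lines: list[str] = []
    for spec in config.header.extract:
        lines.append(f"@extract {spec}")
    if config.header.trim5:
        lines.append("@trim-5 " + ",".join(str(n) for n in config.header.trim5))
    if config.header.trim3:
        lines.append("@trim-3 " + ",".join(str(n) for n in config.header.trim3))
    lines.append("\t".join(COLUMNS))
    for tag in config.tags:
        lines.append("\t".join(_render_cell(tag, c) for c in COLUMNS))
    return "\n".join(lines) + "\n"
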