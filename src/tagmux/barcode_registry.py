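"""Combination IDs and their 16-bp final-barcode encoding.

Every distinct ordered tag combination receives a numerical ID: 0 for the
first combination ever seen, incremented for each newly encountered one.
An ID is a 32-bit unsigned integer and interconverts with a 16-character
nucleotide string by the 2-bit code A=00, C=01, G=10, T=11, most significant
pair leftmost: ID 0 is AAAAAAAAAAAAAAAA and ID 30 (binary 11110) is
AAAAAAAAAAAAACTG.  The barcode is what downstream tools see in the
final-barcode FASTQ; the mapping file recovers the combination and its read
count from it.
"""

from __future__ import annotations

from .errors import BarcodeFormatError, CapacityError

__all__ = [
    "BarcodeRegistry",
    "encode_id",
    "decode_barcode",
    "write_mapping",
    "BARCODE_LENGTH",
]

BARCODE_LENGTH = 16
_ID_SPACE = 1 << 32
_BASES = "ACGT"
_BASE_VALUE = {b: i for i, b in enumerate(_BASES)}


def encode_id(numerical_id: int) -> str:
    """16-character ACGT encoding of a 32-bit combination ID."""
    if not (0 <= numerical_id < _ID_SPACE):
        raise ValueError(f"ID {numerical_id} outside [0, 2^32)")
    return "".join(
        _BASES[(numerical_id >> (2 * (BARCODE_LENGTH - 1 - k))) & 3]
        for k in range(BARCODE_LENGTH)
    )


def decode_barcode(barcode: str) -> int:
    """Inverse of :func:`encode_id`."""
    if len(barcode) != BARCODE_LENGTH:
        raise BarcodeFormatError(
            f"barcode must be {BARCODE_LENGTH} characters, got {len(barcode)}"
        )
    value = 0
    for ch in barcode:
        if ch not in _BASE_VALUE:
            raise BarcodeFormatError(f"non-ACGT character {ch!r} in barcode")
        value = (value << 2) | _BASE_VALUE[ch]
    return value


class BarcodeRegistry:
    """Dense first-encounter-order ID assignment with per-combination counts."""

    def __init__(self):
        self.combo_to_id: dict[tuple[str, ...], int] = {}
        self.counts: dict[tuple[str, ...], int] = {}
        self.next_id = 0

    def get_or_assign_id(self, combo: tuple[str, ...]) -> int:
        """ID for ``combo``, assigning the next free one on first encounter.

        The observation count is incremented on every call.
        """
        if not combo:
            raise ValueError("empty combination receives no ID")
        combo = tuple(combo)
        cid = self.combo_to_id.get(combo)
        if cid is None:
            if self.next_id >= _ID_SPACE:
                raise CapacityError("combination ID space (2^32) exhausted")
            cid = self.next_id
            self.combo_to_id[combo] = cid
            self.next_id += 1
        self.counts[combo] = self.counts.get(combo, 0) + 1
        return cid

    def __len__(self) -> int:
        return self.next_id


def write_mapping(registry: BarcodeRegistry) -> str:
    """Mapping-file content: barcode, comma-joined tag ids, read count.

    Rows are ordered by ID, so the file is stable across identical runs.
    """
    rows = []
    for combo, cid in sorted(registry.combo_to_id.items(), key=lambda kv: kv[1]):
        rows.append(f"{encode_id(cid)}\t{','.join(combo)}\t{registry.counts[combo]}")
    return "\n".join(rows) + ("\n" if rows else "")
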