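"""Synthetic reads with planted tag structures and ground truth.

The generator realizes a config's structure record by record: for each
group (in first-appearance order) it places one randomly chosen tag of that
group in the group's file, at a start compatible with the tag's location
window, separated from the previous feature by random padding; anchored
extractions planted after their anchor group get the configured offset of
random bases followed by a random UMI; every file is then padded to its
target length with random bases.  Stagger — variable-length padding before
the first tag of the first file — emulates the nucleotide-diversity inserts
real libraries use, which shift all downstream positions.

In recoverable mode each planted tag carries at most its own substitution
budget of errors, so a correct scanner must recover 100% of planted
combinations.  To make that guarantee hold exactly, padding that would by
chance create a tag-index hit outside the planted intervals is rejected and
the record regenerated; the check consults only the variant dictionary,
never the scanner under test.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .config_model import Config, TagRecord, parse_config
from .errors import GeneratorError
from .read_parser import FragmentSet
from .tag_index import build_index

__all__ = [
    "GeneratorSpec",
    "TruthRecord",
    "SimulatedReads",
    "generate",
    "plant_substitutions",
    "demo_config",
    "DEMO_CONFIG_TEXT",
]

_BASES = "ACGT"

#: Two-round combinatorial demo configuration: three first-round barcodes
#: (distance-1 tolerant, found within the first 5 positions of R1, after
#: which only the second round is searched, each round found at most once),
#: two second-round barcodes, an 8-bp UMI extracted 3 bases after the
#: second-round hit, and 4 bases trimmed from the 3' end of R2.
DEMO_CONFIG_TEXT = """\
@extract umi=<grp_B>+3:8
@trim-3 0,4
id\tgroup\tsequence\tdistance\tnext\tmaxFindsG\tlocation
Barcode_A1\tgrp_A\tTTAGTT\t1\tgrp_B\t1\t0:0:5
Barcode_A2\tgrp_A\tGTGCCG\t1\tgrp_B\t1\t0:0:5
Barcode_A3\tgrp_A\tCAGCGA\t1\tgrp_B\t1\t0:0:5
Barcode_B1\tgrp_B\tAGTAGT\t1\t\t1\t0:5:100
Barcode_B2\tgrp_B\tGCTTGA\t1\t\t1\t0:5:100
"""


def demo_config() -> Config:
    """The two-round demo configuration, parsed fresh."""
    return parse_config(DEMO_CONFIG_TEXT)


@dataclass(frozen=True)
class GeneratorSpec:
    """What to synthesize.

    ``error_rate`` is the per-tag probability of planting substitutions;
    in recoverable mode the planted count is uniform on [1, distance] so
    every error stays within tolerance.  ``stagger_range`` is inclusive.
    """

    config: Config
    n_records: int
    seed: int
    error_rate: float = 0.0
    recoverable: bool = True
    stagger_range: tuple[int, int] = (0, 4)
    max_gap: int = 6
    n_files: int = 2
    read_lengths: tuple[int, ...] | None = None
    tail_pad: int = 10


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one synthesized record."""

    index: int
    combination: tuple[str, ...]
    umis: tuple[tuple[str, str], ...]  # (extraction name, planted sequence)
    errors: tuple[tuple[str, int], ...]  # (tag id, planted substitutions)
    stagger: int


@dataclass
class SimulatedReads:
    """Generated fragment sets plus their truth table."""

    spec: GeneratorSpec
    fragments: list[FragmentSet] = field(default_factory=list)
    truth: list[TruthRecord] = field(default_factory=list)

    def fastq_texts(self) -> list[str]:
        """One FASTQ text per logical input file."""
        n_files = self.spec.n_files
        texts = []
        for fi in range(n_files):
            chunks = []
            for frag in self.fragments:
                chunks.append(
                    f"@{frag.headers[fi]}\n{frag.sequences[fi]}\n+\n{frag.qualities[fi]}\n"
                )
            texts.append("".join(chunks))
        return texts

    def truth_tsv(self) -> str:
        rows = ["index\tcombination\tumis\terrors\tstagger"]
        for t in self.truth:
            umis = ",".join(f"{n}={s}" for n, s in t.umis)
            errs = ",".join(f"{tid}={k}" for tid, k in t.errors)
            rows.append(f"{t.index}\t{','.join(t.combination)}\t{umis}\t{errs}\t{t.stagger}")
        return "\n".join(rows) + "\n"

    def write(self, prefix: str, gzipped: bool = False) -> list[str]:
        """Write per-file FASTQ (``<prefix>_R<k>.fastq[.gz]``) and the truth
        TSV (``<prefix>_truth.tsv``); returns the FASTQ paths."""
        import gzip as _gzip

        paths = []
        for fi, text in enumerate(self.fastq_texts()):
            path = f"{prefix}_R{fi + 1}.fastq" + (".gz" if gzipped else "")
            if gzipped:
                with _gzip.open(path, "wt") as fh:
                    fh.write(text)
            else:
                with open(path, "w") as fh:
                    fh.write(text)
            paths.append(path)
        with open(f"{prefix}_truth.tsv", "w") as fh:
            fh.write(self.truth_tsv())
        return paths


def plant_substitutions(sequence: str, k: int, rng: random.Random) -> str:
    """Return ``sequence`` with exactly ``k`` substitutions at random
    distinct positions, each to a different base."""
    if k > len(sequence):
        raise ValueError("cannot plant more substitutions than bases")
    positions = rng.sample(range(len(sequence)), k)
    out = list(sequence)
    for pos in positions:
        out[pos] = rng.choice([b for b in _BASES if b != out[pos]])
    return "".join(out)


def _random_seq(length: int, rng: random.Random) -> str:
    return "".join(rng.choice(_BASES) for _ in range(length))


def _group_plan(config: Config, n_files: int) -> list[tuple[str, int, list[TagRecord]]]:
    """(group, file, tags) in first-appearance order; file from location."""
    plan = []
    for group in config.groups:
        tags = [t for t in config.tags if t.group == group]
        files = {t.location.file_index for t in tags if t.location is not None}
        if len(files) > 1:
            raise GeneratorError(f"group {group!r} spans several files; cannot plan")
        fi = files.pop() if files else 0
        if fi >= n_files:
            raise GeneratorError(f"group {group!r} located in file #{fi} beyond n_files")
        plan.append((group, fi, tags))
    return plan


def _default_lengths(spec: GeneratorSpec, plan) -> tuple[int, ...]:
    need = [40] * spec.n_files
    per_file = [spec.stagger_range[1] + spec.tail_pad] * spec.n_files
    anchored = [e for e in spec.config.header.extract if e.anchor is not None]
    for group, fi, tags in plan:
        per_file[fi] += max(len(t.sequence) for t in tags) + spec.max_gap
        for e in anchored:
            if e.anchor == group or any(e.anchor == t.tag_id for t in tags):
                per_file[fi] += e.offset + e.length
    for e in spec.config.header.extract:
        if e.anchor is None and e.file_index < spec.n_files:
            per_file[e.file_index] = max(per_file[e.file_index], e.start + e.length + 4)
    return tuple(max(n, p) for n, p in zip(need, per_file))


def generate(spec: GeneratorSpec) -> SimulatedReads:
    """Synthesize reads per ``spec``; deterministic for a fixed seed."""
    rng = random.Random(spec.seed)
    plan = _group_plan(spec.config, spec.n_files)
    lengths = spec.read_lengths or _default_lengths(spec, plan)
    if len(lengths) != spec.n_files:
        raise GeneratorError("read_lengths must have one entry per file")
    index = build_index(spec.config.tags)
    anchored = [e for e in spec.config.header.extract if e.anchor is not None]

    out = SimulatedReads(spec=spec)
    for i in range(spec.n_records):
        for _attempt in range(200):
            record = _one_record(spec, plan, lengths, anchored, rng, i)
            if record is None:
                continue
            frag, truth, planted = record
            if _clean_of_spurious_hits(frag, index, planted):
                out.fragments.append(frag)
                out.truth.append(truth)
                break
        else:
            raise GeneratorError(
                "config structure unrealizable or sequence space saturated: "
                "could not place every tag inside its location window within "
                "the read length with padding free of spurious tag matches"
            )
    return out


def _one_record(spec, plan, lengths, anchored, rng, record_index):
    seqs = [""] * spec.n_files
    planted: list[tuple[int, int, int]] = []  # (file, start, end) of planted tags
    combination: list[str] = []
    errors: list[tuple[str, int]] = []
    umis: list[tuple[str, str]] = []
    stagger = rng.randint(*spec.stagger_range)
    first_in_file0 = True
    umi_done: set[str] = set()

    for group, fi, tags in plan:
        tag = rng.choice(tags)
        cursor = len(seqs[fi])
        if fi == 0 and first_in_file0:
            # the stagger *is* the first tag's start in file 0
            first_in_file0 = False
            start = stagger
            if tag.location is not None and not (
                tag.location.start <= start < tag.location.end
            ):
                return None
        else:
            start = cursor + rng.randint(0, spec.max_gap)
            if tag.location is not None:
                lo = max(start, tag.location.start, cursor)
                hi = tag.location.end - 1
                if lo > hi:  # window already passed; structure unrealizable here
                    return None
                start = lo if lo == hi else rng.randint(lo, min(hi, lo + spec.max_gap))
        seqs[fi] += _random_seq(start - cursor, rng)

        k = 0
        if tag.distance > 0 and rng.random() < spec.error_rate:
            k = rng.randint(1, tag.distance) if spec.recoverable else tag.distance + 1
        planted_seq = plant_substitutions(tag.sequence, k, rng) if k else tag.sequence
        seqs[fi] += planted_seq
        planted.append((fi, start, start + len(planted_seq)))
        combination.append(tag.tag_id)
        errors.append((tag.tag_id, k))

        for e in anchored:
            if e.name in umi_done:
                continue
            if e.anchor == group or e.anchor == tag.tag_id:
                seqs[fi] += _random_seq(e.offset, rng)
                umi = _random_seq(e.length, rng)
                seqs[fi] += umi
                umis.append((e.name, umi))
                umi_done.add(e.name)

    for fi in range(spec.n_files):
        if len(seqs[fi]) > lengths[fi]:  # structure overflows the read
            return None
        seqs[fi] += _random_seq(lengths[fi] - len(seqs[fi]), rng)

    frag = FragmentSet(
        headers=[f"sim_{record_index} /{fi + 1}" for fi in range(spec.n_files)],
        sequences=seqs,
        qualities=["I" * lengths[fi] for fi in range(spec.n_files)],
    )
    truth = TruthRecord(
        index=record_index,
        combination=tuple(combination),
        umis=tuple(umis),
        errors=tuple(errors),
        stagger=stagger,
    )
    return frag, truth, planted


def _clean_of_spurious_hits(frag: FragmentSet, index, planted) -> bool:
    """True when no window outside the planted intervals is an index key."""
    planted_set = set(planted)
    for fi, seq in enumerate(frag.sequences):
        for length in index.lengths:
            for start in range(len(seq) - length + 1):
                if (fi, start, start + length) in planted_set:
                    continue
                if seq[start : start + length] in index.table:
                    return False
    return True
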