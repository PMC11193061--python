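# Methods

## Identification model

Tag identification is dictionary lookup, not alignment. At index build
time, every sequence reachable from a tag within its substitution budget
`distance` and its indel budget `indels` is a key of one hash map; the two
budgets compose (a variant may spend both) but are counted independently,
and a variant reachable by several error paths is stored once with its
minimum-total-error attribution (breadth-first enumeration over total
errors guarantees this). Keys colliding across tags keep all candidates,
ordered by (total errors, config row order). Query time is a single
dictionary access per window and is therefore independent of the configured
tolerances; the price is enumeration, which grows as O(L^d), so a ceiling
(default 10^7 entries) aborts construction for long sequences or large
budgets — those cases belong to dynamic-programming trimmers, not to a
lookup table.

Scanning is greedy and leftmost: files in input order, a cursor moving left
to right, windows of every indexed length probed longest-first at each
position, cursor jumping to a hit's end so hits never overlap. Tie-breaks
are total: fewest errors first, then config row order. Greedy-leftmost was
chosen over any globally optimal assignment because it is deterministic,
single-pass, and matches how staggered combinatorial reads are actually
laid out; the brute-force reference scanner used in the tests implements
the same contract directly from definitions.

Three semantic choices were genuinely open and are fixed as follows:

* **Location windows constrain the hit's start** (`f:x:y` admits starts in
  `[x, y)` of file `f`). The alternative — whole-hit containment — breaks
  the variable-length-stagger use case this tool exists for, since a 6-bp
  tag could then never start at the window's last positions.
* **`next` acts globally** across the remaining files of the fragment set,
  not per file: combinatorial rounds are ordered chemically, not per
  FASTQ.
* **Initially every group is searchable**; sequencing of rounds is imposed
  by `location`, `maxFindsG`, and `next`, not by table order.

## Combination IDs and final barcodes

Ordered tag combinations (hit order, which round order makes meaningful)
map to dense 32-bit IDs in first-encounter order. An ID's 32-bit value is
split big-endian into sixteen 2-bit fields mapped A=00, C=01, G=10, T=11;
encode and decode are exact inverses over the full ID space. Reads with an
empty combination, an unmet `minFinds`, a missing `--keep` group, or a
failed extraction get no ID and go to the unassigned outputs.

## Editing pipeline

Per read: identify → extract → substitute/remove → global trim. Extraction
coordinates refer to the original read, so edits can never shift an anchor;
per-hit edits are applied right-to-left so earlier coordinates stay valid;
`@trim-5`/`@trim-3` run last. Quality strings track sequences at every
step; a replacement longer than the span it replaces pads quality with the
constant `K` (also the quality fill of the synthetic barcode FASTQ — any
fixed high-quality character serves, since these bases carry no measured
quality). Over-long trims yield an empty but retained record, preserving
pairing. Anchored extraction uses the first matching hit in scan order.

## Synthetic reads

The generator realizes a config's structure: per record, one tag per group
(first-appearance order), placed in its file at a start compatible with its
location window, preceded by a variable-length stagger (default 0–4 bp,
the first tag's start in file 0) and separated by random padding (gaps up
to 6 bp); anchored extractions plant the offset filler plus a uniform
random UMI; remaining bases are uniform random padding to the target read
length. In recoverable mode (the default) planted substitutions never
exceed a tag's own budget, so a correct scanner must recover 100% of
planted combinations — and to make that exact rather than probabilistic,
padding whose windows collide with the variant dictionary is rejected and
the record redrawn (the check consults only the index, never the scanner
being tested). The generator emulates structure, not physics: qualities
are constant, errors are substitutions only, there is no indel noise, PCR
duplication, or quality decay — so passing recovery tests demonstrates
parsing correctness under the declared error model, not robustness to real
instrument noise.

Default problem sizes in the tests (10^4 records for the end-to-end run,
10^3 reads for oracle equivalence, 10^5 IDs for the codec round trip) keep
the full suite under a few seconds while leaving every property
statistically trivial to violate if the code were wrong.

## Numerical and degenerate-input choices

* Duplicate tag sequences are legal; row order resolves every tie, so no
  ambiguous window can survive to output.
* Empty reads, empty inputs, and empty registries are well-defined no-ops.
* Interleaved input must end on a whole fragment set; a desynchronized
  pair fails loudly with the record index rather than truncating.
* `--threads` is accepted for interface stability, but records are
  committed in input order regardless, which is what makes ID assignment
  and output bytes reproducible; peak throughput was deliberately traded
  for determinism.

## Known limitations

No reverse-complement search, no IUPAC ambiguity codes in tags, no
quality-aware matching, no SAM/BAM output, and no attempt at byte
compatibility with any other tool's config files — the dialect here is
defined by `config_model` alone.
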