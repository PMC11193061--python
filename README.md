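# tagmux

Sequencing libraries embed synthetic constructs — sample and cell barcodes,
ligation linkers, unique molecular identifiers (UMIs), staggers — that must
be identified, interpreted, and often removed before any downstream
analysis. Assays with combinatorial indexing (SPLiT-seq-style split-pool
rounds, SPRITE, and similar) are the hard case: several short known
sequences per read, variable in position because of variable-length
staggers, with UMIs defined only *relative to* other technical sequences.

`tagmux` is a config-driven preprocessor for exactly this situation. A
tab-separated config file declares the **tags** (known technical sequences)
to search for; reads are scanned left to right and tags are identified by
dictionary lookup against a pre-enumerated variant table, so error
tolerance costs nothing at query time. Each ordered combination of
identified tags receives a dense numerical ID (0, 1, 2, … in first-encounter
order); the 32-bit ID is rendered as a 16-bp **final barcode** via the
2-bit code A=00, C=01, G=10, T=11 (most significant pair leftmost), so
ID 0 ↔ `AAAAAAAAAAAAAAAA` and ID 30 ↔ `AAAAAAAAAAAAACTG`. Anchored
subsequences such as UMIs are extracted relative to tag hits, reads are
edited/trimmed in situ, and everything streams back out as FASTQ (plain,
gzip, or interleaved stdout for piping into other tools — including
`tagmux` itself).

## The matching model

For every tag with sequence `s`, substitution budget `d` and indel budget
`i`, all sequences reachable within both budgets are inserted into one hash
map keyed by variant (for `d = 1` and length `L` that is the Hamming ball of
size `3L + 1`). Scanning probes each read position with windows of every
indexed length, longest first; among eligible candidates the winner
minimizes (total errors, config row order). Eligibility is where the
combinatorics live:

* `location f:x:y` — the hit must *start* in `[x, y)` of file `f`
  (stagger-tolerant by construction);
* `next` — after this tag is found, only the named groups remain
  searchable;
* `maxFinds` / `maxFindsG` — per-tag and per-group find caps;
* `minFinds` — required counts for a read to be *assigned* (routed to the
  main outputs rather than the unassigned ones).

## Worked example

Simulate reads for the built-in two-round demo config (three first-round
barcodes found in positions 0–4 of R1 with one substitution tolerated, two
second-round barcodes after position 5, an 8-bp UMI extracted 3 bases after
the second-round hit, 4 bases trimmed from the 3′ end of R2), then run it:

```
$ tagmux simulate -n 20 --seed 3 -o sim
$ tagmux run demo.cfg sim_R1.fastq sim_R2.fastq -o out -u un
reads   20
assigned        20
unassigned      0
combinations    6
```

All 20 records parsed (`assigned 20`), and 6 distinct barcode-A × barcode-B
combinations were seen. The outputs:

```
$ head -2 out_barcodes.fastq        # 16-bp final barcode per assigned read
@sim_0 /1
AAAAAAAAAAAAAAAA
$ head -2 out_umi.fastq             # the extracted 8-bp UMI
@sim_0 /1
TGGCAGAC
$ head -2 out_mapping.tsv           # barcode -> combination -> read count
AAAAAAAAAAAAAAAA        Barcode_A3,Barcode_B2   8
AAAAAAAAAAAAAAAC        Barcode_A1,Barcode_B2   3
```

The first combination encountered got ID 0 (`AAAA…A`); its 8 reads are the
first mapping row. `out_R2.fastq` reads are 4 bp shorter than the input
(the `@trim-3 0,4` header option), and `--pipe` would interleave the edited
reads on stdout instead of writing files.

A config file looks like:

```
@extract umi=<grp_B>+3:8
@trim-3 0,4
id          group   sequence  distance  next    maxFindsG  location
Barcode_A1  grp_A   TTAGTT    1         grp_B   1          0:0:5
...
Barcode_B1  grp_B   AGTAGT    1                 1          0:5:100
```

(columns are tab-separated; see `src/tagmux/config_model.py` for the full
dialect).

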