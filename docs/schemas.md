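# Table schemas

All tables are tab-separated with a header row. Coordinates in tables are
**1-based inclusive** (VCF convention); the library converts to 0-based
half-open at the I/O boundary (`l1mosaic.io.to_internal` / `to_external`).

## events

One row per insertion call (per sample).

| column | type | meaning |
|---|---|---|
| sample_id | str | clone / sample identifier |
| chrom | str | target chromosome |
| target_pos | int | 1-based insertion breakpoint |
| strand | str | insertion strand |
| insertion_class | str | solo / partnered / orphan / unresolved |
| polyA_len | int | poly-A tail length (bp), 0 if absent |
| tsd_len | int | target-site duplication length (bp), 0 if absent |
| supporting_pairs | int | breakpoint-informative pairs supporting the insertion |
| reference_pairs | int | informative pairs supporting the reference allele |

## variants

Long format: one row per variant per sample.

| column | type |
|---|---|
| chrom, pos, ref, alt | str, int, str, str |
| sample | str |
| depth, var_reads | int |

## methylation

| column | type | meaning |
|---|---|---|
| clone | str | clone identifier |
| source | str | L1 source element |
| rel_pos | int | CpG position relative to the L1 TSS (+1 = first downstream base) |
| meth, unmeth | int | methylated / unmethylated read counts |

## registry

| column | type | meaning |
|---|---|---|
| source_id | str | cytoband-style label |
| chrom, start, end | str, int, int | element locus (1-based inclusive in tables) |
| strand | str | element strand; the 3′ end is `end` on `+`, `start` on `−` |

## panel

Matrix TSV: rows = sources, columns = individuals, values = supporting
evidence fractions in [0, 1]. Presence is called at ≥ 0.15.

## Trees

Newick with branch lengths equal to mutation counts; internal node labels are
the joined sample sets (or simulation node ids), leaf labels are sample ids.
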