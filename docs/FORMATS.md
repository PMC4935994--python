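# File formats

All TSV outputs are tab-separated with a single header row. Coordinates
are 0-based half-open inside the library and 1-based inclusive where a
human-readable table says so explicitly.

## Annotation table (input to `satkit stats`)

One row per satellite family. Columns:

| column | meaning |
|---|---|
| `family` | family name, e.g. `LmiSat01-193` |
| `superfamily` | superfamily number or empty |
| `monomer_length` | consensus monomer length (bp), most abundant variant |
| `at_content` | % A+T of that variant |
| `n_variants` | number of sequence variants |
| `abundance_sl`, `abundance_nl` | genome proportion (%) per sample; empty when the family was not detected in that sample |
| `divergence_sl`, `divergence_nl` | weighted mean K2P divergence (%) |
| `n_contigs` | draft-assembly contigs carrying ≥ 200 aligned bp |
| `mnrpc` | maximum number of repeats per contig |
| `L1 … S11` | location tokens per chromosome: `p` proximal, `i` interstitial, `d` distal, `t` telomeric; multiple loci comma-separated (`i,d`) |
| `pattern` | `c` clustered, `nc` non-clustered, `m` mixed, `none` unmapped |
| `in_working_set` | include the family in the 58-family statistics |
| `note` | free-text exclusion reason |

## Cluster report (`satkit cluster`)

`cluster_id, n_reads, density, shape, genome_proportion, candidate` —
density is mean links per read (2E/V), shape ∈ {globular, ring, linear},
genome_proportion the cluster's % of sampled nucleotides, candidate
whether the cluster passes the shape + density selection.

## Mining report (`satkit mine --report`, pipeline `mining.tsv`)

`iteration, reads_used, clusters_examined, new_satellites` — reads_used
counts mates (2 × pairs), clusters_examined the candidate clusters of
that round.

## Catalog (`catalog.fasta`, `catalog.tsv`)

FASTA records are named `<family>#<variant>` (e.g. `LmiSat01-193#1`),
sequences in canonical rotation. The TSV carries
`family, variant, monomer_length, at_content, superfamily, abundance`.

## Quantification (`quantification.tsv`)

`family, abundance_pct, mean_divergence_pct` — abundance as % of sampled
nucleotides; the divergence cell is empty when the family received no
unsaturated hits.

## Landscape (`landscape.tsv`)

One row per family, columns `bin_0 … bin_50`: abundance (% of sampled
nucleotides) whose K2P divergence falls in [i, i+1); `bin_50` collects
saturated hits. Row sums equal the family's abundance.

## Assembly scan / random occurrence summaries

`family, n_contigs, mnrpc, total_aligned_nt` per scan;
`family, mean_contigs, sd_contigs, mean_aligned_nt, sd_aligned_nt`
across shuffle replicates.

## Exit codes (CLI)

`0` success — `2` bad input (missing/malformed files, invalid
parameters) — `3` finished but the mining schedule was exhausted before
convergence.
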