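# File formats

All files are plain text. Internally, intervals are 0-based half-open;
GTF I/O converts from/to the format's 1-based inclusive coordinates.

## Expression matrix (TSV)

Features as rows, samples as columns, log2 relative abundance (for protein
data) or TPM (for mRNA data, positive scale).

- Header row: `feature_id` (any label) followed by the sample ids.
- First column: unique feature identifiers (protein or gene symbols).
- Missing quantifications: empty cell, `NA`, or `NaN`.
- Ragged rows and duplicate feature ids are errors.

## Sample annotations (TSV)

One row per sample with columns:

| column            | values                                            |
|-------------------|---------------------------------------------------|
| `sample_id`       | must match a matrix column                        |
| `line_id`         | cell line / patient identifier                    |
| `replicate_index` | integer >= 1                                      |
| `group`           | `gsc`, `control`, `tumor`, `normal`               |
| `subtype`         | `proneural`, `classical`, `mesenchymal`, `none`   |
| `age`, `sex`      | optional                                          |

## Gene sets (GMT)

Standard MSigDB exchange format: tab-separated `name`, `description`,
members... (>= 3 fields per line). Duplicate members within a line are
deduplicated with a warning.

## Survival table (CSV)

Columns `id`, `event` (1 = death, 0 = censored), `age`, `sex`, plus either
a precomputed `os_months` column or the pair `diagnosis_date` / `last_date`
(ISO dates), in which case OS = (last − diagnosis) days / 30.44. Sex accepts
`M`/`F`, `male`/`female`, or `1`/`2` codes; the reader normalizes to
`male`/`female`. Records with uncomputable OS are dropped and counted.

## Sequences (FASTA)

Standard FASTA for transcripts (DNA) and the canonical proteome (protein).

## Transcript models (GTF)

`exon` and `CDS` features with `gene_id`, `transcript_id` and `gene_biotype`
attributes (`protein_coding`, `pseudogene`, `lncRNA`, or other). Transcript
abundance comes from an optional `tpm` attribute or from a side TSV with
columns `transcript_id`, `tpm`; transcripts lacking both get TPM 0 with a
warning.

## Signature (TSV)

Two columns: `protein_id`, `arm` (`gpc_like` or `gm_like`).

## Results

- GSEA / ssGSEA: TSV with `set` (and `sample_id` for ssGSEA), `es`, `nes`,
  `p`, `q`, and the boolean `enriched_call` for ssGSEA.
- Region enrichment: TSV with the 2x2 table counts, odds ratio, `p`, `q`.
- Cox / Kaplan-Meier: JSON with hazard ratio, 95% CI, likelihood-ratio p,
  per-group median OS and log-rank p.
- Peptide database: one FASTA per pI fraction with `key=value` headers
  (`transcript`, `gene`, `pi`, `class`) plus TSV tables of all retained and
  of novel candidate peptides.
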