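# gscproteo

Proteogenomic analysis of glioblastoma stem-cell (GSC) panels: derivation
and refinement of a two-arm protein signature, rank-based enrichment
subtyping, prognostic sum-score survival analysis, mRNA-protein correlation
agreement, and in-silico construction of a non-canonical peptide search
database.

## The problem

Glioblastoma stem cells cultured from patient tumors occupy two mutually
exclusive phenotypic conditions along the proneural-to-mesenchymal axis:
one marked by proteins up in proneural/classical GSCs (the **GPC-like**
arm) and one by proteins up in mesenchymal GSCs (the **GM-like** arm).
This package implements, for researchers working with multiplexed isobaric
(TMT-style) proteome panels of such lines, the full statistical pipeline
that derives such a signature, validates it on an independent panel,
quantifies its prognostic value in tumor-tissue cohorts, and mines the
matched transcriptome for peptides absent from the canonical proteome
(pseudogene products, lncRNA ORFs, 5'-UTR extensions, exon variants).
Because the underlying study data are cohort-scale deposits, a first-class
synthetic-data module generates panels with the same design and planted
ground truth, so every stage is testable on a laptop.

## Methods at a glance

- **Signature derivation** — for every (GSC line, control line) pair, a
  two-sided Welch t-test per protein with Benjamini-Hochberg adjustment
  within the comparison; a protein joins an arm only if significant
  (q < α) with a consistent direction in *all* pairs. Refinement on an
  independent panel keeps members whose fold-change sign
  (proneural/classical − mesenchymal) matches the arm.
- **Enrichment** — weighted Kolmogorov-Smirnov running sum (w = 1):
  ES = max deviation of Σ hits |s|/Σ_hits|s| − Σ misses 1/(N−N_hit);
  gene-label permutation null with add-one smoothing,
  NES = ES / mean|ES_perm| (same sign). Single-sample subtype calls rank a
  sample's log2 values and call an arm enriched when ES > 0, p < 0.05,
  q < 0.05 across all (sample × set) tests.
- **Scoring and survival** — arm sum score log2(Σ 2^v); log2 GPC/GM ratio;
  quartile stratification; Cox proportional hazards (hazard
  ~ score + age + sex, Efron ties) with a likelihood-ratio test, and
  Kaplan-Meier curves with log-rank tests.
- **Correlation agreement** — per-gene Spearman ρ between mRNA (summed
  TPM) and protein (mean log2) across samples; Bland-Altman limits
  (bias ± 1.96 sd) on two cohorts' ρ profiles with hypergeometric
  overrepresentation of the outlier genes.
- **Proteogenomics** — TPM ≥ 1 transcripts → all forward-frame ATG ORFs →
  fully tryptic peptides of 8-40 residues → isoelectric point (Bjellqvist
  pKa, bisection) and 72-fraction binning on pI 3-10 → subtraction of
  canonical matches (I/L equivalent) → novelty classification and
  single-mismatch flagging for spectral validation.

See `docs/methods.md` for assumptions, conventions, and limitations, and
`FORMATS.md` for every file format.

## Worked example

Simulate a 2000-protein discovery panel (120/180 planted proteins, effect
1.5 log2 units, replicate noise 0.1) plus validation panel with 25%
direction flips, and run every stage:

```sh
cat > demo.yaml <<'EOF'
n_proteins: 2000
n_gpc_planted: 120
n_gm_planted: 180
effect_size: 1.5
noise_sd: 0.1
flip_fraction_gpc: 0.25
flip_fraction_gm: 0.25
EOF
gscproteo run-all --config demo.yaml --seed 1 --n-perm 500 --out demo
```

prints

```
fixtures written to demo/sim
gpc_like=118 gm_like=174
retained: GPC 89 (75.424%), GM 130 (74.713%)
12 enriched calls -> demo/ssgsea_calls.tsv
HR=0.452 (95% CI 0.400-0.512), LRT p=4.7e-37
median rho = 0.483
12 peptides, 5 novel candidates -> demo/peptide_db
run complete; manifest at demo/run_manifest.json
```

Reading the numbers: the consistency intersection recovers 118 of the 120
planted GPC-like and 174 of the 180 GM-like proteins; refinement on the
flipped validation panel retains close to the expected 75% of each arm.
Single-sample enrichment calls the correct arm in all 11 validation lines;
the 12th call is one mesenchymal line additionally called for the GPC-like
arm, which is expected here because this demo flips a quarter of the
GPC-like arm into the mesenchymal program (on an unflipped panel the two
arms' calls are mutually exclusive — see `demo/ssgsea_calls.tsv`). The survival stage fits a planted protective
score (true hazard ratio 0.5 per score unit) at HR = 0.452 (95% CI
0.400-0.512). The paired-omics stage estimates a median Spearman ρ of
0.483 against a target of 0.5 at 18 samples. The toy transcriptome yields
12 retained peptides of which exactly the 5 planted non-canonical ones
survive canonical subtraction, each with its planted class
(`demo/peptide_db/novel_candidates.tsv`).

Every stage is also available as its own subcommand (`simulate`,
`derive-signature`, `refine-signature`, `gsea`, `ssgsea`, `region-enrich`,
`score`, `survival`, `correlate`, `agreement`, `build-db`,
`classify-novel`) operating on the serialized outputs of the previous one;
`run_manifest.json` records the seed, parameters and SHA-256 digests of all
outputs, and a rerun with the same seed reproduces them bit for bit.

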