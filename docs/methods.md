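# Methods

`gscproteo` re-implements, as a tested library, the statistical core of a
proteogenomic characterization of glioblastoma stem cells (GSCs): a two-arm
protein signature separating a proneural/classical-like (GPC-like) from a
mesenchymal-like (GM-like) cellular program, rank-based single-sample
enrichment subtyping, signature sum-score survival analysis, mRNA-protein
correlation agreement, and construction of a customized peptide search
database for non-canonical peptide discovery. Real study data (multiplexed
isobaric-label proteomes, RNA-seq, clinical tables) are replaced by a
synthetic-data module that emulates the study designs, so every stage is
verifiable at desk scale.

## Synthetic study conditions

The generators are pure functions of a configuration and one global seed;
sub-streams are derived deterministically by name.

**Discovery panel.** Six GSC lines and two non-stem control lines, three
replicates each, on a log2 relative-abundance scale. Entries are the sum of
a per-(line, protein) offset ~ N(0, `noise_sd`/2), which creates the line
structure seen in real panels, and replicate noise ~ N(0, `noise_sd`). The
first control line models a technical-replicate control and gets half the
replicate noise. Two disjoint planted programs shift `n_gpc_planted`
proteins by +`effect_size` in every GSC line and `n_gm_planted` proteins by
+`effect_size` in every control line. Defaults mirror the emulated design:
5000 proteins, 200/300 planted, effect 1.0 log2 units, noise sd 0.25 log2
units (TMT-style log-ratio data are approximately Gaussian after
normalization, and the replicate spread is of this order), missingness 0.
The generator emits already-normalized values; normalization chains, batch
effects, isotopic impurity and ratio compression are not simulated, so a
passing recovery test speaks to the statistics, not to raw-data processing.

**Validation panel.** Eleven single-sample lines with a mesenchymal
subgroup (4 of 11 by default). GPC-planted proteins are up in the
non-mesenchymal lines, GM-planted in the mesenchymal lines. An exact
fraction of each arm can be direction-flipped to exercise refinement
filtering; flips are chosen by count (`round(fraction * n)`), so refinement
exactness is testable without tolerance.

**Paired omics.** Per gene, latent bivariate-normal pairs across samples.
The latent Pearson correlation is set to r = 2·sin(π·ρ_s/6), the inverse of
the Gaussian-copula relation ρ_s = (6/π)·asin(r/2), so the induced Spearman
correlation matches the target. mRNA is exponentiated to a TPM-like
positive scale. Targets above |0.99| are capped with a warning; |ρ| ≥ 1 is
an error.

**Survival cohort.** Score ~ N(0,1), age ~ N(60,10), sex ~ Bernoulli(0.5);
event times are exponential with hazard h0·exp(β·score + 0.02·(age−60)),
h0 = 0.03 per month. Censoring is an independent exponential whose rate is
calibrated on the mean hazard so the expected censored fraction matches the
requested rate.

**Toy transcriptome.** Twelve predicted-ORF peptide groups over seven
single-exon transcripts planting one element of each novelty class:
a 5'-UTR extension (upstream in-frame start of a coding gene), a processed
pseudogene with a single-residue variant, a translatable lncRNA ORF, a
single-residue exon variant of a coding gene, and a sub-TPM transcript
(TPM < 1) whose peptides must never reach the database. Sequences are
deterministic by construction: one fixed codon per residue, chosen so no
ATG can arise outside the intended start codons in any forward frame
(no codon starts with `TG`, none ends with `AT`, untranslated filler
contains no adenine). The generator asserts that no planted peptide
collides with the canonical proteome even after I/L folding.

## Signature derivation and refinement

Differential expression per (GSC line, control line) pair uses a two-sided
Welch t-test on replicate values (the safer default for 3-vs-3 groups; the
pooled-variance Student variant is available by flag), log2 fold-change =
mean(GSC) − mean(control), and Benjamini-Hochberg adjustment within each
comparison. Zero-variance-in-both-groups rows get p = 1 when the means
agree and p = 0 otherwise, with a warning.

A protein enters the GPC-like arm when q < α (strict) and direction +1 in
*every* comparison, and the GM-like arm with direction −1 throughout;
α defaults to 0.05. A looser mode (significant in ≥ k comparisons,
direction-consistent in all) is available by flag. Refinement on the
validation panel computes fc = mean log2 in proneural/classical lines −
mean in mesenchymal lines and keeps GPC-like members with fc > 0 and
GM-like members with fc < 0; fc = 0 drops the protein, and members absent
from the panel are dropped with a reported count. Retention is reported as
count and percent with three decimals, e.g. `157 (75.845%)`.

Note on operating characteristics: under the default synthetic conditions
(effect 1.0, noise sd 0.25, triplicates), a 3-vs-3 Welch test has roughly
4 denominator degrees of freedom and a noncentrality near 4.9, giving
p-values around 8×10⁻³ that do not survive BH adjustment across 5000
proteins; the all-comparison intersection is then essentially empty. The
intersection machinery itself is validated at higher signal-to-noise, where
recovery is near-perfect, and by a monotonicity check (sensitivity never
decreases with effect size).

## Enrichment

The enrichment score is the weighted Kolmogorov-Smirnov running-sum
statistic with weight w = 1 (the canonical published default): members
increment by |s|^w normalized over the member scores, non-members decrement
by 1/(N − N_hit); the ES is the running sum's maximal deviation from zero.
Ties in ranking scores break by stable feature-id order; a totally tied
ranking is an error, as is a set that is empty in, or equal to, the list.

Significance uses a gene-label permutation null preserving set size
(appropriate for preranked analyses), with add-one smoothing so p is never
0: p = (1 + #{|ES_perm| ≥ |ES|, same sign}) / (1 + #same-sign perms).
NES divides ES by the mean |ES_perm| of the same sign; n_perm defaults to
1000. For single-sample calls, each sample's features are ordered by their
log2 values but the walk weights are the ranks N..1, so calls depend only
on the within-sample ordering and are invariant to positive-slope affine
transforms; a set is called enriched when ES > 0, p < 0.05 and q < 0.05,
with q over all (sample × set) tests. Proteins whose gene maps to more
than one protein are excluded from rankings (ambiguous rank), whereas
gene-level matrices average them — two documented conventions used where
each applies.

Region enrichment builds a 2×2 table (region membership × fold-change
direction) over the universe of genes present in at least one region set,
excluding fc = 0 genes, and applies a two-sided Fisher exact test. The
Fisher p sums, over the hypergeometric support of the fixed margins, the
probabilities of tables at most as probable as the observed one; table
probabilities are compared as exact integers over the common denominator,
so ties need no floating-point tolerance.

## Scores and survival

The per-sample sum score is log2(Σ_members 2^v): "summing relative
expression values and log2-normalizing" is read as de-log, sum, re-log —
summing log2 values would be a product on the raw scale, and normalizing an
already-log2 sum is otherwise ill-defined. The alternative (plain sum of
log2 values, z-scaled) is available by flag. The GPC/GM log2 ratio is the
difference of arm scores; inverting the ratio exactly negates it and
inverts the fitted hazard ratio.

Stratification uses linear-interpolation quantiles (the convention is
documented because none is standard): two-level low (≤ Q1) vs high/medium,
or three-level low ≤ Q1 < medium ≤ Q3 < high; boundary scores fall in the
lower category. Cox proportional-hazards fits (Efron ties, via lifelines)
adjust for age (years, untransformed) and sex (binary indicator), with a
likelihood-ratio test against the covariate-only model; Kaplan-Meier curves
report per-group median OS with a log-rank test. Overall survival derives
from dates as days / 30.44 when not supplied directly.

## Correlation and agreement

Protein expression collapses to genes as the mean of log2 values; mRNA as
the sum of TPMs per gene (median-collapse exposed as an option, since both
conventions circulate). Spearman correlation uses average ranks with the
two-sided t-approximation p-value and BH adjustment across genes.
Bland-Altman agreement of two per-gene correlation profiles uses limits at
bias ± 1.96·sd of the differences (normal-theory 95% limits); genes beyond
a limit disagree strongly, and the outlier lists feed a local
hypergeometric overrepresentation test (upper tail, BH across sets).

## Proteogenomics database

Transcripts with TPM < 1 are removed (TPM = 1 retained). ORF policy: all
ATG-initiated ORFs of ≥ 8 residues in the three forward frames (transcripts
are stranded), run to the first in-frame stop or flagged partial at the
transcript end — a superset policy that guarantees representability of
upstream starts and non-canonical ORFs. Trypsin cleaves C-terminal to K/R
except before P, fully tryptic, 0 missed cleavages by default
(configurable); peptides of 8-40 residues (inclusive) are kept and
duplicates collapse to their first occurrence.

Isoelectric points solve Z(pH) = Σ_basic 1/(1+10^(pH−pKa)) −
Σ_acidic 1/(1+10^(pKa−pH)) = 0 over the termini and D/E/C/Y/H/K/R side
chains by bisection on (0, 14) to |Z| < 10⁻⁶, under a Bjellqvist-style pKa
table shipped as data and swappable. Fractionation uses equal-width bins on
the configured pI range (default 3-10, 72 fractions, mirroring
isoelectric-focusing practice); index = 1 + floor((pI − low)·n/(high −
low)) with a 10⁻⁹ guard so a pI exactly on a bin edge lands in the upper
bin despite floating-point edge representation, clamped to the edge bins
with a flag for out-of-range peptides.

Canonical subtraction is substring search against the concatenated
canonical proteome with I/L folded together (isobaric residues are
indistinguishable to the MS workflow this database feeds); exact and
I/L-equivalent matches are distinguished. Remaining candidates classify by
gene biotype first (pseudogene, lncRNA), then by position against the
annotated CDS for coding genes: starting ≥ 1 nt upstream of the CDS start
is a 5'-UTR extension, past the CDS end a 3'-UTR extension, inside the CDS
(and sequence-divergent, by precondition) an exon variant. Candidates at
I/L-folded Hamming distance 1 from a canonical window carry a mismatch
record — the input a downstream spectral validator would receive; spectral
validation itself is out of scope, as are database search and target-decoy
FDR.

## Problem sizes and numerical choices

The test suite and the acceptance script run the synthetic conditions at
their stated sizes (5000-protein discovery panel, 11-line validation panel,
2000 genes × 18 samples, 500-patient cohorts, 1000 permutations for
single-sample calls); unit tests of the machinery use smaller panels
(hundreds of proteins) chosen for near-certain recovery so they test
correctness rather than power. Exact oracles (running-sum enumeration,
rational-arithmetic Fisher, BH step-up, fine-grid pI scan) are compared at
10⁻¹² or the method's stated tolerance. All randomness flows from explicit
seeds; permutation p-values are never zero by construction.

## Known limitations

The generators draw Gaussian, homoscedastic noise with complete-case
missingness placed uniformly — no missing-not-at-random structure, no
normalization artefacts, no multi-set batch effects. Single-sample calls
use rank weights rather than the exponential-weight (w = 0.25) variant.
The survival generator's exponential event times satisfy proportional
hazards by construction, so the Cox checks do not probe model
misspecification. The toy transcriptome is single-exon and forward-strand;
the coordinate mapping supports spliced and reverse-strand models, but the
planted fixtures do not exercise splice-junction peptides.
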