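"""Synthetic fixtures with the statistical structure the analysis assumes.

Every generator is a pure function of its configuration and a seed; sub-streams
are derived deterministically by name so adding one generator never perturbs
another.  The discovery panel emulates a multiplexed isobaric-labelling design:
a handful of stem-cell lines and two non-stem control lines measured in
triplicate on a log2 relative-abundance scale, with two mutually exclusive
planted expression programs (one up in the stem lines, one up in the controls).
"""
from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    ExpressionMatrix,
    GenomeAnnotation,
    SampleAnnotation,
    SequenceRecord,
    SurvivalRecord,
    TranscriptModel,
)

__all__ = [
    "SimulationConfig",
    "PanelTruth",
    "ValidationTruth",
    "NoveltyRecord",
    "generate_discovery_panel",
    "generate_validation_panel",
    "generate_paired_omics",
    "generate_survival_cohort",
    "generate_toy_transcriptome",
]


def _rng(seed: int, name: str) -> np.random.Generator:
    """Named deterministic sub-stream of the global seed."""
    return np.random.default_rng([zlib.crc32(name.encode()) & 0x7FFFFFFF, seed])


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of the synthetic discovery panel.

    Defaults mirror the analysed design: six stem-cell (GSC) lines and two
    control lines in triplicate, log2-scale Gaussian noise.
    """

    n_proteins: int = 5000
    n_gsc_lines: int = 6
    n_control_lines: int = 2
    replicates_per_line: int = 3
    n_gpc_planted: int = 200
    n_gm_planted: int = 300
    effect_size: float = 1.0  # log2 units
    noise_sd: float = 0.25  # log2 units
    missing_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_gpc_planted + self.n_gm_planted > self.n_proteins:
            raise ValueError("planted programs exceed protein count")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not 0 <= self.missing_fraction < 1:
            raise ValueError("missing_fraction must be in [0, 1)")
        if self.n_gsc_lines < 1 or self.n_control_lines < 1:
            raise ValueError("need at least one GSC and one control line")
        if self.replicates_per_line < 2:
            raise ValueError("need >= 2 replicates per line")


@dataclass(frozen=True)
class PanelTruth:
    """Ground truth of the planted programs."""

    gpc_true: tuple[str, ...]
    gm_true: tuple[str, ...]
    null_ids: tuple[str, ...]
    activity: dict = field(default_factory=dict)  # sample_id -> (gpc, gm) scalars

    def __post_init__(self):
        if set(self.gpc_true) & set(self.gm_true):
            raise ValueError("planted programs must be mutually exclusive")


@dataclass(frozen=True)
class ValidationTruth:
    """Which planted proteins had their direction flipped in the validation panel."""

    flipped_gpc: tuple[str, ...]
    flipped_gm: tuple[str, ...]


def _protein_ids(n: int) -> list[str]:
    width = max(5, len(str(n)))
    return [f"P{i:0{width}d}" for i in range(1, n + 1)]


def generate_discovery_panel(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, list[SampleAnnotation], PanelTruth]:
    """Discovery panel: GSC lines vs control lines, two planted programs.

    Entries are line offset N(0, noise_sd/2) per (line, protein) plus replicate
    noise N(0, noise_sd).  The first control line stands for a technical-
    replicate control and gets half the replicate noise.  Planted GPC proteins
    are shifted +effect_size in every GSC line; planted GM proteins are shifted
    +effect_size in every control line.  Missingness is uniform.
    """
    rng = _rng(config.seed, "discovery")
    ids = _protein_ids(config.n_proteins)
    planted = rng.choice(
        config.n_proteins, config.n_gpc_planted + config.n_gm_planted, replace=False
    )
    gpc_idx = np.sort(planted[: config.n_gpc_planted])
    gm_idx = np.sort(planted[config.n_gpc_planted:])

    lines = [(f"GSC{i + 1:02d}", "gsc") for i in range(config.n_gsc_lines)] + [
        (f"CTRL{i + 1:02d}", "control") for i in range(config.n_control_lines)
    ]
    columns: list[str] = []
    blocks: list[np.ndarray] = []
    annotations: list[SampleAnnotation] = []
    activity: dict[str, tuple[float, float]] = {}
    subtype_cycle = ["proneural", "classical"]
    for li, (line_id, group) in enumerate(lines):
        offsets = rng.normal(0.0, config.noise_sd / 2, config.n_proteins)
        # the first control line models a technical-replicate control
        residual_sd = config.noise_sd * (
            0.5 if group == "control" and line_id.endswith("01") else 1.0
        )
        block = offsets[:, None] + rng.normal(
            0.0, residual_sd, (config.n_proteins, config.replicates_per_line)
        )
        if group == "gsc":
            block[gpc_idx] += config.effect_size
        else:
            block[gm_idx] += config.effect_size
        subtype = subtype_cycle[li % 2] if group == "gsc" else "none"
        for r in range(config.replicates_per_line):
            sid = f"{line_id}_R{r + 1}"
            columns.append(sid)
            annotations.append(
                SampleAnnotation(sid, line_id, r + 1, group, subtype)
            )
            activity[sid] = (
                (config.effect_size, 0.0) if group == "gsc"
                else (0.0, config.effect_size)
            )
        blocks.append(block)

    values = np.concatenate(blocks, axis=1)
    if config.missing_fraction > 0:
        mask = rng.random(values.shape) < config.missing_fraction
        values = np.where(mask, np.nan, values)
    frame = pd.DataFrame(values, index=ids, columns=columns)
    truth = PanelTruth(
        gpc_true=tuple(np.array(ids)[gpc_idx]),
        gm_true=tuple(np.array(ids)[gm_idx]),
        null_ids=tuple(
            np.array(ids)[np.setdiff1d(np.arange(config.n_proteins), planted)]
        ),
        activity=activity,
    )
    return ExpressionMatrix(frame), annotations, truth


def generate_validation_panel(
    config: SimulationConfig,
    truth: PanelTruth,
    n_lines: int = 11,
    n_mesenchymal: int = 4,
    flip_fraction_gpc: float = 0.0,
    flip_fraction_gm: float = 0.0,
    replicates_per_line: int = 1,
) -> tuple[ExpressionMatrix, list[SampleAnnotation], ValidationTruth]:
    """Independent validation panel with a mesenchymal subgroup.

    GPC-planted proteins go up in the non-mesenchymal lines, GM-planted in the
    mesenchymal lines.  An exact fraction of each planted arm is flipped in
    direction, to exercise fold-change refinement filtering downstream.
    """
    if n_mesenchymal <= 0 or n_mesenchymal >= n_lines:
        raise ValueError("validation panel requires both phenotypes")
    for frac in (flip_fraction_gpc, flip_fraction_gm):
        if not 0 <= frac <= 1:
            raise ValueError("flip fractions must be in [0, 1]")
    rng = _rng(config.seed, "validation")
    ids = _protein_ids(config.n_proteins)
    index = {pid: i for i, pid in enumerate(ids)}

    def pick_flips(members: tuple[str, ...], frac: float) -> tuple[str, ...]:
        k = round(frac * len(members))
        if k == 0:
            return ()
        chosen = rng.choice(len(members), k, replace=False)
        return tuple(np.array(members)[np.sort(chosen)])

    flipped_gpc = pick_flips(truth.gpc_true, flip_fraction_gpc)
    flipped_gm = pick_flips(truth.gm_true, flip_fraction_gm)

    subtypes = ["mesenchymal"] * n_mesenchymal + [
        ("proneural" if i % 2 == 0 else "classical")
        for i in range(n_lines - n_mesenchymal)
    ]
    rng.shuffle(subtypes)

    up_nonmes = np.zeros(config.n_proteins, dtype=float)
    for pid in truth.gpc_true:
        up_nonmes[index[pid]] = config.effect_size
    for pid in flipped_gpc:
        up_nonmes[index[pid]] = -config.effect_size
    up_mes = np.zeros(config.n_proteins, dtype=float)
    for pid in truth.gm_true:
        up_mes[index[pid]] = config.effect_size
    for pid in flipped_gm:
        up_mes[index[pid]] = -config.effect_size

    columns, blocks, annotations = [], [], []
    for li, subtype in enumerate(subtypes):
        line_id = f"HG{li + 1:02d}"
        offsets = rng.normal(0.0, config.noise_sd / 2, config.n_proteins)
        block = offsets[:, None] + rng.normal(
            0.0, config.noise_sd, (config.n_proteins, replicates_per_line)
        )
        block += (up_mes if subtype == "mesenchymal" else up_nonmes)[:, None]
        for r in range(replicates_per_line):
            sid = f"{line_id}_R{r + 1}" if replicates_per_line > 1 else line_id
            columns.append(sid)
            annotations.append(SampleAnnotation(sid, line_id, r + 1, "gsc", subtype))
        blocks.append(block)
    frame = pd.DataFrame(np.concatenate(blocks, axis=1), index=ids, columns=columns)
    return (
        ExpressionMatrix(frame),
        annotations,
        ValidationTruth(flipped_gpc=flipped_gpc, flipped_gm=flipped_gm),
    )


def generate_paired_omics(
    n_genes: int,
    n_samples: int,
    target_rho,
    seed: int = 0,
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Paired mRNA (TPM scale) and protein (log2 scale) matrices.

    Per gene, latent bivariate-normal pairs whose Pearson correlation
    r = 2 sin(pi * rho_s / 6) induces the requested Spearman correlation
    rho_s.  Targets above 0.99 in magnitude are capped with a warning;
    |target| >= 1 is an error.  mRNA is exponentiated to a TPM-like scale.
    """
    rho = np.broadcast_to(np.asarray(target_rho, dtype=float), (n_genes,)).copy()
    if np.any(np.abs(rho) >= 1):
        raise ValueError("|target_rho| must be < 1")
    if np.any(np.abs(rho) > 0.99):
        warnings.warn("target_rho capped at |0.99|", stacklevel=2)
        rho = np.clip(rho, -0.99, 0.99)
    r = 2.0 * np.sin(np.pi * rho / 6.0)
    rng = _rng(seed, "paired_omics")
    z1 = rng.normal(size=(n_genes, n_samples))
    z2 = rng.normal(size=(n_genes, n_samples))
    x = z1
    y = r[:, None] * z1 + np.sqrt(1.0 - r[:, None] ** 2) * z2
    gene_ids = [f"G{i:05d}" for i in range(1, n_genes + 1)]
    samples = [f"S{i:02d}" for i in range(1, n_samples + 1)]
    base = rng.normal(4.0, 2.0, n_genes)[:, None]
    tpm = np.power(2.0, base + x)  # TPM-like positive scale
    mrna = ExpressionMatrix(pd.DataFrame(tpm, index=gene_ids, columns=samples))
    protein = ExpressionMatrix(pd.DataFrame(y, index=gene_ids, columns=samples))
    return mrna, protein


def generate_survival_cohort(
    n: int,
    beta: float,
    censor_rate: float,
    seed: int = 0,
    baseline_hazard: float = 0.03,
) -> tuple[list[SurvivalRecord], pd.Series]:
    """Survival cohort whose hazard depends on a planted per-patient score.

    Event times are exponential with hazard h0 * exp(beta*score +
    0.02*(age-60)); censoring is an independent exponential calibrated so the
    expected censored fraction is about ``censor_rate``.
    """
    if n < 20:
        raise ValueError("n must be >= 20")
    if not 0 <= censor_rate <= 0.9:
        raise ValueError("censor_rate must be in [0, 0.9]")
    rng = _rng(seed, "survival")
    score = rng.normal(0.0, 1.0, n)
    age = rng.normal(60.0, 10.0, n)
    sex = rng.random(n) < 0.5
    hazard = baseline_hazard * np.exp(beta * score + 0.02 * (age - 60.0))
    t_event = rng.exponential(1.0 / hazard)
    if censor_rate > 0:
        # P(censor) = lc / (lc + h) per subject; calibrate lc on the mean hazard
        lc = censor_rate / (1.0 - censor_rate) * hazard.mean()
        t_cens = rng.exponential(1.0 / lc, n)
    else:
        t_cens = np.full(n, np.inf)
    os_months = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    ids = [f"PT{i:04d}" for i in range(1, n + 1)]
    records = [
        SurvivalRecord(
            ids[i],
            float(os_months[i]),
            int(event[i]),
            age=float(age[i]),
            sex="male" if sex[i] else "female",
        )
        for i in range(n)
    ]
    return records, pd.Series(score, index=ids, name="score")


# ---------------------------------------------------------------------------
# Toy transcriptome with planted non-canonical elements
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NoveltyRecord:
    """A peptide expected to survive the proteogenomics pipeline."""

    sequence: str
    novelty_class: str
    transcript_id: str


# One codon per residue, chosen so that no ATG can arise outside the intended
# start codons: no codon starts with "TG" (C and W excluded from bodies), none
# ends with "AT", and untranslated filler contains no adenine at all.
_CODON = {
    "A": "GCT", "R": "CGT", "N": "AAC", "D": "GAC", "Q": "CAA", "E": "GAA",
    "G": "GGT", "H": "CAC", "I": "ATT", "K": "AAA", "L": "CTT", "F": "TTT",
    "P": "CCT", "S": "TCT", "T": "ACT", "V": "GTT", "Y": "TAC", "M": "ATG",
}


def _encode(protein: str) -> str:
    return "".join(_CODON[aa] for aa in protein)


_UTR5 = "CTTCCTTCCTTC"       # no adenine -> cannot form ATG with any junction
_UTR3 = "CTCCTTCC"

# canonical proteins (tryptic peptides of length 8-40, internal M only at starts)
_PA = "M" + "AGELSDFTNK" + "VLDPETGQHR" + "SYNAEFGHTK" + "ALDNESVR"
_PB = "M" + "TEVDSLGNHK" + "FPAGDSETLR" + "QNVHDAYSGK"

_EXT = "QDFSAGETVK"          # 5'-UTR extension body (ends K: clean tryptic break)
_PSEUDO_VARIANT = _PB.replace("FPAGDSETLR", "FPAGNSETLR")  # D -> N
_EXON_VARIANT = _PA.replace("VLDPETGQHR", "VLDPETGEHR")    # Q -> E
_LNC_ORF = "M" + "SEDGAVNPTK" + "TVGDNPESFK"
_LOW_ORF = "M" + "GNDFSEPTAK" + "HQVESDGTFK"


def generate_toy_transcriptome(
    seed: int = 0,
) -> tuple[
    list[SequenceRecord], GenomeAnnotation, list[SequenceRecord], list[NoveltyRecord]
]:
    """Toy transcriptome planting one element of each novelty class.

    Transcripts (all single-exon, + strand, one per chromosome):
      TA, TB      canonical coding transcripts (their proteins form the
                  canonical proteome)
      TA_EXT      TA with an upstream in-frame start: one tryptic peptide
                  upstream of the annotated CDS start (5'-UTR extension)
      TPS1        processed pseudogene of TB with a single-residue variant
      TLNC1       lncRNA carrying a translatable ORF
      TA_VAR      coding transcript of TA's gene with one exon variant residue
      TLOW        sub-TPM transcript (tpm < 1); contributes nothing

    The sequences are deterministic by construction; ``seed`` only feeds the
    TPM draws of the retained transcripts.  Returns transcript FASTA records,
    the annotation, the canonical proteome, and the manifest of peptides (with
    classes) expected to survive the full database build.
    """
    rng = _rng(seed, "toy_transcriptome")

    def tpm_hi() -> float:
        return float(np.round(rng.uniform(5.0, 50.0), 2))

    transcripts: list[SequenceRecord] = []
    annotation = GenomeAnnotation()

    def add(tid: str, gene: str, biotype: str, utr5: str, orf_protein: str | None,
            utr3: str, tpm: float, cds_span: tuple[int, int] | None):
        body = _encode(orf_protein) + "TAA" if orf_protein else ""
        seq = utr5 + body + utr3
        transcripts.append(SequenceRecord(tid, seq, "dna"))
        model = TranscriptModel(
            transcript_id=tid, gene_id=gene, gene_biotype=biotype,
            chrom=f"chr_{tid}", strand="+", exons=[(0, len(seq))], tpm=tpm,
        )
        if cds_span is not None:
            model.cds = [cds_span]
        model.validate()
        annotation.transcripts[tid] = model

    # canonical transcripts: CDS = the full ORF
    add("TA", "GA", "protein_coding", _UTR5, _PA, _UTR3, tpm_hi(),
        (len(_UTR5), len(_UTR5) + 3 * len(_PA) + 3))
    add("TB", "GB", "protein_coding", _UTR5, _PB, _UTR3, tpm_hi(),
        (len(_UTR5), len(_UTR5) + 3 * len(_PB) + 3))

    # 5'-UTR extension: upstream ATG + extension codons, then the canonical ORF
    # in frame; annotated CDS stays at the canonical start.
    ext_protein = "M" + _EXT + _PA
    cds_start = len(_UTR5) + 3 * (1 + len(_EXT))  # canonical ATG position
    add("TA_EXT", "GA", "protein_coding", _UTR5, ext_protein, _UTR3, tpm_hi(),
        (cds_start, len(_UTR5) + 3 * len(ext_protein) + 3))

    add("TPS1", "GB_P1", "pseudogene", _UTR5, _PSEUDO_VARIANT, _UTR3, tpm_hi(), None)
    add("TLNC1", "GL1", "lncRNA", _UTR5, _LNC_ORF, _UTR3, tpm_hi(), None)
    add("TA_VAR", "GA", "protein_coding", _UTR5, _EXON_VARIANT, _UTR3, tpm_hi(),
        (len(_UTR5), len(_UTR5) + 3 * len(_EXON_VARIANT) + 3))
    add("TLOW", "GL2", "lncRNA", _UTR5, _LOW_ORF, _UTR3, 0.5, None)

    canonical = [
        SequenceRecord("PROT_A", _PA, "protein"),
        SequenceRecord("PROT_B", _PB, "protein"),
    ]
    manifest = [
        NoveltyRecord("M" + _EXT, "utr5_extension", "TA_EXT"),
        NoveltyRecord("FPAGNSETLR", "pseudogene", "TPS1"),
        NoveltyRecord("MSEDGAVNPTK", "lncRNA", "TLNC1"),
        NoveltyRecord("TVGDNPESFK", "lncRNA", "TLNC1"),
        NoveltyRecord("VLDPETGEHR", "exon_variant", "TA_VAR"),
    ]
    # construction guarantees: planted peptides never match canonicals, even
    # after folding isoleucine onto leucine
    folded_canon = "|".join(c.sequence for c in canonical).replace("I", "L")
    for record in manifest:
        if record.sequence.replace("I", "L") in folded_canon:
            raise AssertionError("planted peptide collides with canonical proteome")
    return transcripts, annotation, canonical, manifest
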