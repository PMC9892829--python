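"""In-silico construction of a customized peptide search database from
transcripts, and classification of candidate non-canonical peptides.

The pipeline drops weakly expressed transcripts (TPM < 1), translates every
ATG-initiated open reading frame in the three forward frames, digests the
predicted proteins with trypsin (cleave after K/R, suppressed before P,
fully tryptic), keeps peptides of 8-40 residues, assigns each an isoelectric
point (Bjellqvist pKa set, bisection on the net-charge curve) and a
fractionation bin, removes peptides matching the canonical proteome (with
isoleucine and leucine treated as indistinguishable, as they are to the mass
spectrometer), classifies the remaining candidates by the source gene's
biotype and the peptide's position relative to the annotated CDS, and flags
single-mismatch candidates for downstream spectral validation.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

from Bio.Seq import Seq

from .io import GenomeAnnotation, SequenceRecord, TranscriptModel

log = logging.getLogger(__name__)

__all__ = [
    "PKA_BJELLQVIST",
    "PeptideRecord",
    "MismatchInfo",
    "PredictedOrf",
    "DatabaseBuild",
    "filter_transcripts",
    "translate_orfs",
    "digest",
    "length_filter",
    "compute_pi",
    "fractionate",
    "subtract_canonical",
    "classify_novel",
    "flag_single_mismatch",
    "build_database",
    "write_fraction_fastas",
]

#: Bjellqvist pKa values for the ionizable groups (termini and side chains).
PKA_BJELLQVIST: dict[str, float] = {
    "n_term": 7.50,
    "c_term": 3.55,
    "D": 4.05,
    "E": 4.45,
    "C": 9.00,
    "Y": 10.00,
    "H": 5.98,
    "K": 10.00,
    "R": 12.00,
}

_ACIDIC = ("c_term", "D", "E", "C", "Y")
_BASIC = ("n_term", "H", "K", "R")


@dataclass(frozen=True)
class MismatchInfo:
    canonical_id: str
    peptide_position: int  # 1-based position within the peptide
    canonical_residue: str
    observed_residue: str


@dataclass(frozen=True)
class PredictedOrf:
    """An ATG-initiated ORF: protein sequence plus transcript coordinates."""

    id: str
    transcript_id: str
    protein: str
    nt_start: int  # 0-based, transcript coordinates, at the A of ATG
    nt_end: int    # exclusive, end of last codon (stop excluded)
    frame: int
    partial: bool  # no in-frame stop before the transcript end


@dataclass
class PeptideRecord:
    sequence: str
    source_transcript_id: str
    source_gene_id: str
    start: int  # 0-based residue offset within the predicted protein
    end: int
    nt_start: int  # transcript coordinates of the peptide's codons
    nt_end: int
    pi: float = float("nan")
    fraction_index: int = 0
    out_of_range: bool = False
    canonical_match: str = "none"  # exact | il_equivalent | none
    novelty_class: str = "other_noncoding"
    mismatch_info: MismatchInfo | None = None

    def __post_init__(self):
        if not (0 < self.pi < 14) and self.pi == self.pi:
            raise ValueError("pi must lie in (0, 14)")


def filter_transcripts(annotation: GenomeAnnotation, tpm_min: float = 1.0) -> list[str]:
    """Transcript ids with tpm >= tpm_min (strict ``< tpm_min`` removal)."""
    return [t.transcript_id for t in annotation if t.tpm >= tpm_min]


def translate_orfs(
    transcript: SequenceRecord, min_aa: int = 8
) -> list[PredictedOrf]:
    """All ATG-initiated ORFs in the three forward frames, standard code.

    Each ORF runs from its ATG to the first in-frame stop (or to the
    transcript end, flagged partial) and must reach ``min_aa`` residues.
    """
    if transcript.moltype != "dna":
        raise ValueError("translate_orfs expects a DNA record")
    seq = transcript.sequence
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"{transcript.id}: non-ACGTN characters {sorted(bad)}")
    orfs: list[PredictedOrf] = []
    pos = seq.find("ATG")
    count = 0
    while pos != -1:
        tail = seq[pos:]
        usable = len(tail) - len(tail) % 3
        protein = str(Seq(tail[:usable]).translate())
        stop = protein.find("*")
        partial = stop == -1
        aa = protein if partial else protein[:stop]
        if len(aa) >= min_aa:
            count += 1
            orfs.append(
                PredictedOrf(
                    id=f"{transcript.id}|orf{count}",
                    transcript_id=transcript.id,
                    protein=aa,
                    nt_start=pos,
                    nt_end=pos + 3 * len(aa),
                    frame=pos % 3,
                    partial=partial,
                )
            )
        pos = seq.find("ATG", pos + 1)
    return orfs


def _cleavage_sites(protein: str) -> list[int]:
    # trypsin: after K or R, suppressed when the next residue is P
    return [
        i + 1
        for i, aa in enumerate(protein[:-1])
        if aa in "KR" and protein[i + 1] != "P"
    ]


def digest(protein, missed_cleavages: int = 0) -> list[str]:
    """Fully tryptic peptides, in sequence order, with up to
    ``missed_cleavages`` concatenated fragments appended after the base set."""
    return [p for p, _ in digest_with_positions(protein, missed_cleavages)]


def digest_with_positions(
    protein, missed_cleavages: int = 0
) -> list[tuple[str, int]]:
    seq = protein.sequence if isinstance(protein, SequenceRecord) else protein
    bounds = [0, *_cleavage_sites(seq), len(seq)]
    frags = [
        (seq[bounds[i]: bounds[i + 1]], bounds[i])
        for i in range(len(bounds) - 1)
    ]
    out = list(frags)
    for mc in range(1, missed_cleavages + 1):
        for i in range(len(frags) - mc):
            start = frags[i][1]
            end_idx = i + mc
            merged = seq[start: frags[end_idx][1] + len(frags[end_idx][0])]
            out.append((merged, start))
    return out


def length_filter(peptides, min_len: int = 8, max_len: int = 40):
    """Keep peptides with min_len <= length <= max_len (inclusive bounds)."""
    return [p for p in peptides if min_len <= len(p) <= max_len]


def _net_charge(ph: float, counts: dict[str, int], pka: dict[str, float]) -> float:
    pos = sum(
        counts.get(g, 0) / (1.0 + 10.0 ** (ph - pka[g])) for g in _BASIC
    )
    neg = sum(
        counts.get(g, 0) / (1.0 + 10.0 ** (pka[g] - ph)) for g in _ACIDIC
    )
    return pos - neg


def compute_pi(
    peptide: str,
    pka: dict[str, float] | None = None,
    tol: float = 1e-6,
) -> float:
    """Isoelectric point: the pH where the peptide's net charge vanishes.

    Charge sums proton occupancies of the termini and the D/E/C/Y/H/K/R side
    chains under the active pKa table (Bjellqvist by default); the root is
    bracketed on (0, 14) and found by bisection to |Z| < tol.
    """
    pka = PKA_BJELLQVIST if pka is None else pka
    counts = {"n_term": 1, "c_term": 1}
    for aa in peptide:
        if aa in pka:
            counts[aa] = counts.get(aa, 0) + 1
    lo, hi = 0.0, 14.0
    for _ in range(200):
        mid = (lo + hi) / 2.0
        z = _net_charge(mid, counts, pka)
        if abs(z) < tol:
            return mid
        if z > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def fractionate(
    pis,
    range_low: float = 3.0,
    range_high: float = 10.0,
    n_fractions: int = 72,
) -> list[tuple[int, bool]]:
    """Equal-width pI bins on [range_low, range_high].

    Returns (1-based fraction index, out_of_range flag) per peptide; out-of-
    range peptides clamp to the edge bins.
    """
    if range_high <= range_low:
        raise ValueError("range_high must exceed range_low")
    if n_fractions < 1:
        raise ValueError("n_fractions must be >= 1")
    width = (range_high - range_low) / n_fractions
    out = []
    for pi in pis:
        # small guard so a pI exactly on a bin edge lands in the upper bin
        # despite floating-point representation of the edge
        raw = int(math.floor((pi - range_low) / width + 1e-9)) + 1
        clamped = min(max(raw, 1), n_fractions)
        out.append((clamped, not (range_low <= pi <= range_high)))
    return out


def _fold(seq: str) -> str:
    return seq.replace("I", "L")


def subtract_canonical(
    peptides: list[PeptideRecord], canonical: list[SequenceRecord]
) -> tuple[list[PeptideRecord], list[PeptideRecord]]:
    """Label peptides found as substrings of the canonical proteome.

    Isoleucine and leucine are treated as equivalent (isobaric); an exact
    match is distinguished from an I/L-equivalent one.  Returns
    (novel_candidates, canonical_matched).
    """
    joined = "|".join(c.sequence for c in canonical)
    folded = _fold(joined)
    novel, matched = [], []
    for pep in peptides:
        if pep.sequence in joined:
            pep.canonical_match, pep.novelty_class = "exact", "none"
            matched.append(pep)
        elif _fold(pep.sequence) in folded:
            pep.canonical_match, pep.novelty_class = "il_equivalent", "none"
            matched.append(pep)
        else:
            novel.append(pep)
    return novel, matched


def _transcript_to_genomic(model: TranscriptModel, offset: int) -> int:
    """Map a transcript coordinate to a genomic one via the exon chain."""
    lengths = [hi - lo for lo, hi in model.exons]
    if model.strand == "-":
        exons = list(reversed(model.exons))
        remaining = offset
        for (lo, hi), ln in zip(exons, reversed(lengths)):
            if remaining < ln:
                return hi - 1 - remaining
            remaining -= ln
    else:
        remaining = offset
        for (lo, hi), ln in zip(model.exons, lengths):
            if remaining < ln:
                return lo + remaining
            remaining -= ln
    raise ValueError(f"offset {offset} beyond transcript {model.transcript_id}")


def classify_novel(
    peptide: PeptideRecord, annotation: GenomeAnnotation
) -> str:
    """Novelty class from gene biotype, then position relative to the CDS.

    Pseudogene and lncRNA transcripts classify by biotype.  For coding
    transcripts the peptide's coding interval is compared with the annotated
    CDS: starting >= 1 nt upstream of the CDS start gives a 5'-UTR extension,
    starting past the CDS end a 3'-UTR extension, and a (sequence-divergent)
    peptide inside the CDS an exon variant.
    """
    if peptide.canonical_match != "none":
        raise ValueError("classify_novel expects canonical_match == 'none'")
    model = annotation.transcripts.get(peptide.source_transcript_id)
    if model is None:
        log.warning("peptide %s: unmapped transcript %s",
                    peptide.sequence, peptide.source_transcript_id)
        return "other_noncoding"
    biotype = model.gene_biotype
    if biotype == "pseudogene":
        return "pseudogene"
    if biotype == "lncRNA":
        return "lncRNA"
    if biotype != "protein_coding" or not model.cds:
        return "other_noncoding"
    cds_lo = min(lo for lo, _ in model.cds)
    cds_hi = max(hi for _, hi in model.cds)
    g_first = _transcript_to_genomic(model, peptide.nt_start)
    g_last = _transcript_to_genomic(model, peptide.nt_end - 1)
    lo, hi = min(g_first, g_last), max(g_first, g_last) + 1
    # 5' side in genomic coordinates depends on strand
    if model.strand == "-":
        upstream = lo >= cds_hi
        downstream = hi <= cds_lo
    else:
        upstream = lo < cds_lo
        downstream = lo >= cds_hi
    if upstream:
        return "utr5_extension"
    if downstream:
        return "utr3_extension"
    if cds_lo <= lo and hi <= cds_hi:
        return "exon_variant"
    return "other_noncoding"


def flag_single_mismatch(
    peptide: PeptideRecord | str, canonical: list[SequenceRecord]
) -> MismatchInfo | None:
    """Scan equal-length canonical windows for a Hamming-distance-1 match.

    I and L fold together before comparison.  Returns the mismatch position
    (1-based within the peptide) and substitution, or None when the minimum
    distance exceeds 1.  These records feed a downstream spectral validator.
    """
    seq = peptide.sequence if isinstance(peptide, PeptideRecord) else peptide
    folded_pep = _fold(seq)
    k = len(folded_pep)
    best: MismatchInfo | None = None
    for rec in canonical:
        folded_ref = _fold(rec.sequence)
        for i in range(len(folded_ref) - k + 1):
            window = folded_ref[i: i + k]
            mismatches = [j for j in range(k) if window[j] != folded_pep[j]]
            if len(mismatches) == 1:
                j = mismatches[0]
                return MismatchInfo(
                    canonical_id=rec.id,
                    peptide_position=j + 1,
                    canonical_residue=rec.sequence[i + j],
                    observed_residue=seq[j],
                )
    return best


@dataclass
class DatabaseBuild:
    """Outcome of a database build: all retained peptides plus derived lists."""

    peptides: list[PeptideRecord]
    novel: list[PeptideRecord]
    canonical_matched: list[PeptideRecord]
    retained_transcripts: list[str]
    canonical_proteome: list[SequenceRecord] = field(default_factory=list)


def build_database(
    transcripts: list[SequenceRecord],
    annotation: GenomeAnnotation,
    canonical: list[SequenceRecord],
    tpm_min: float = 1.0,
    min_len: int = 8,
    max_len: int = 40,
    min_aa: int = 8,
    missed_cleavages: int = 0,
    pi_range: tuple[float, float] = (3.0, 10.0),
    n_fractions: int = 72,
) -> DatabaseBuild:
    """Full database construction from transcripts to classified candidates.

    Duplicate peptide sequences are collapsed to their first occurrence.
    The canonical proteome is carried along for appending to search output.
    """
    retained = set(filter_transcripts(annotation, tpm_min))
    by_id = {t.id: t for t in transcripts}
    seen: dict[str, PeptideRecord] = {}
    for tid in (t for t in by_id if t in retained):
        transcript = by_id[tid]
        model = annotation.transcripts.get(tid)
        gene = model.gene_id if model else "unknown"
        for orf in translate_orfs(transcript, min_aa=min_aa):
            for pep, aa_start in digest_with_positions(
                orf.protein, missed_cleavages
            ):
                if not (min_len <= len(pep) <= max_len):
                    continue
                if pep not in seen:
                    seen[pep] = PeptideRecord(
                        sequence=pep,
                        source_transcript_id=tid,
                        source_gene_id=gene,
                        start=aa_start,
                        end=aa_start + len(pep),
                        nt_start=orf.nt_start + 3 * aa_start,
                        nt_end=orf.nt_start + 3 * (aa_start + len(pep)),
                    )
    peptides = list(seen.values())
    lo, hi = pi_range
    pis = [compute_pi(p.sequence) for p in peptides]
    for pep, pi, (idx, out_of_range) in zip(
        peptides, pis, fractionate(pis, lo, hi, n_fractions)
    ):
        pep.pi = pi
        pep.fraction_index = idx
        pep.out_of_range = out_of_range
    novel, matched = subtract_canonical(peptides, canonical)
    for pep in novel:
        pep.novelty_class = classify_novel(pep, annotation)
        pep.mismatch_info = flag_single_mismatch(pep, canonical)
    return DatabaseBuild(
        peptides=peptides,
        novel=novel,
        canonical_matched=matched,
        retained_transcripts=sorted(retained),
        canonical_proteome=list(canonical),
    )


def write_fraction_fastas(build: DatabaseBuild, out_dir: str | Path) -> list[Path]:
    """One peptide FASTA per occupied fraction; headers carry key=value fields."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    by_fraction: dict[int, list[PeptideRecord]] = {}
    for pep in build.peptides:
        by_fraction.setdefault(pep.fraction_index, []).append(pep)
    paths = []
    for idx in sorted(by_fraction):
        path = out_dir / f"fraction_{idx:03d}.fasta"
        with open(path, "w") as fh:
            for pep in by_fraction[idx]:
                fh.write(
                    f">pep|transcript={pep.source_transcript_id}"
                    f"|gene={pep.source_gene_id}|pi={pep.pi:.3f}"
                    f"|class={pep.novelty_class}\n{pep.sequence}\n"
                )
        paths.append(path)
    return paths
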