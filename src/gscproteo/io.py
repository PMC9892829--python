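"""Domain data model and readers/writers for the standard formats the pipeline touches.

Expression matrices are TSV (features x samples, log2 relative abundance, ``NA``
or empty cells for missing quantifications); gene sets are GMT; survival tables
are CSV; sequences are FASTA; transcript models are GTF.  Internally intervals
are 0-based half-open; GTF I/O converts from/to 1-based inclusive coordinates.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord
from gffutils.feature import feature_from_line

log = logging.getLogger(__name__)

#: Number of days per month used when deriving overall survival from dates.
DAYS_PER_MONTH = 30.44

#: Cell values parsed as a missing quantification.
MISSING_TOKENS = ("", "NA", "NaN", "nan", "na")


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

class ExpressionMatrix:
    """Log2 relative abundance matrix (features as rows, samples as columns).

    Missing quantifications are held as NaN; ``missing_mask`` exposes them as a
    boolean frame.  Row and column identifiers must be unique.
    """

    def __init__(self, values: pd.DataFrame):
        if values.index.duplicated().any():
            dup = values.index[values.index.duplicated()][0]
            raise ValueError(f"duplicate feature id: {dup!r}")
        if values.columns.duplicated().any():
            dup = values.columns[values.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        self.values = values.astype(float)

    @property
    def row_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def col_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def complete_case(self) -> "ExpressionMatrix":
        """Rows quantified in every sample, in their original order."""
        return ExpressionMatrix(self.values.dropna(axis=0, how="any"))

    def n_complete(self) -> int:
        return int((~self.values.isna().any(axis=1)).sum())

    def __eq__(self, other) -> bool:  # mask equality is implied by NaN equality
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        a, b = self.values, other.values
        return (
            list(a.index) == list(b.index)
            and list(a.columns) == list(b.columns)
            and bool(((a == b) | (a.isna() & b.isna())).all().all())
        )


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a features-x-samples TSV with a header row of sample ids.

    Empty cells, ``NA`` and ``NaN`` parse as missing.  Duplicate feature ids
    and ragged rows raise with the offending id / line number.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        n_cols = len(header)
        ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != n_cols:
                raise ValueError(
                    f"{path.name}: ragged row at line {lineno} "
                    f"({len(parts)} fields, expected {n_cols})"
                )
            ids.append(parts[0])
            rows.append(
                [math.nan if p in MISSING_TOKENS else float(p) for p in parts[1:]]
            )
    frame = pd.DataFrame(rows, index=ids, columns=header[1:], dtype=float)
    return ExpressionMatrix(frame)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    out = matrix.values.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t", na_rep="NA")


# ---------------------------------------------------------------------------
# Sample annotations
# ---------------------------------------------------------------------------

GROUPS = ("gsc", "control", "tumor", "normal")
SUBTYPES = ("proneural", "classical", "mesenchymal", "none")


@dataclass(frozen=True)
class SampleAnnotation:
    sample_id: str
    line_id: str
    replicate_index: int
    group: str
    subtype: str = "none"
    age: float | None = None
    sex: str | None = None

    def __post_init__(self):
        if self.replicate_index < 1:
            raise ValueError("replicate_index must be >= 1")
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.subtype not in SUBTYPES:
            raise ValueError(f"unknown subtype {self.subtype!r}")


def check_annotations(
    matrix: ExpressionMatrix, annotations: Sequence[SampleAnnotation]
) -> None:
    """Every matrix sample must carry exactly one annotation."""
    ids = [a.sample_id for a in annotations]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate sample annotations")
    missing = set(matrix.col_ids) - set(ids)
    if missing:
        raise ValueError(f"samples without annotation: {sorted(missing)}")


def samples_of_line(
    annotations: Sequence[SampleAnnotation], line_id: str
) -> list[str]:
    return [a.sample_id for a in annotations if a.line_id == line_id]


def lines_in_group(
    annotations: Sequence[SampleAnnotation], group: str
) -> list[str]:
    seen: dict[str, None] = {}
    for a in annotations:
        if a.group == group:
            seen.setdefault(a.line_id)
    return list(seen)


def write_annotations(
    annotations: Sequence[SampleAnnotation], path: str | Path
) -> None:
    pd.DataFrame([vars(a) for a in annotations]).to_csv(path, sep="\t", index=False)


def read_annotations(path: str | Path) -> list[SampleAnnotation]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for rec in df.to_dict("records"):
        age = rec.get("age")
        sex = rec.get("sex")
        out.append(
            SampleAnnotation(
                sample_id=str(rec["sample_id"]),
                line_id=str(rec["line_id"]),
                replicate_index=int(rec["replicate_index"]),
                group=str(rec["group"]),
                subtype=str(rec.get("subtype", "none")),
                age=None if pd.isna(age) else float(age),
                sex=None if (sex is None or pd.isna(sex)) else str(sex),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    """Named gene sets with one-line descriptions (GMT semantics)."""

    sets: dict[str, list[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for name, members in self.sets.items():
            if len(members) < 1:
                raise ValueError(f"empty gene set {name!r}")
            if len(members) != len(set(members)):
                raise ValueError(f"duplicate members in gene set {name!r}")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()


def read_gmt(path: str | Path) -> GeneSetCollection:
    sets: dict[str, list[str]] = {}
    desc: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"GMT line {lineno}: expected >= 3 fields")
            name, description, *members = parts
            members = [m for m in members if m]
            deduped = list(dict.fromkeys(members))
            if len(deduped) != len(members):
                log.warning("GMT set %s: %d duplicate member(s) removed",
                            name, len(members) - len(deduped))
            sets[name] = deduped
            desc[name] = description
    return GeneSetCollection(sets=sets, descriptions=desc)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            description = collection.descriptions.get(name, "")
            fh.write("\t".join([name, description, *members]) + "\n")


# ---------------------------------------------------------------------------
# Survival tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SurvivalRecord:
    patient_id: str
    os_months: float
    event: int
    age: float | None = None
    sex: str | None = None

    def __post_init__(self):
        if self.os_months < 0:
            raise ValueError("os_months must be >= 0")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")


# Accepted encodings for sex in clinical tables; normalized to "male"/"female".
_SEX_MAP = {
    "m": "male", "male": "male", "1": "male",
    "f": "female", "female": "female", "2": "female", "0": "female",
}


def _norm_sex(value) -> str | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return _SEX_MAP.get(str(value).strip().lower(), str(value).strip().lower())


def read_survival_table(path: str | Path) -> tuple[list[SurvivalRecord], int]:
    """Read a survival CSV, returning records and the count of dropped rows.

    Accepts either a precomputed ``os_months`` column or a pair of
    ``diagnosis_date``/``last_date`` columns (ISO dates), in which case
    OS = (last - diagnosis) days / 30.44.  Rows whose OS cannot be computed
    are dropped and counted; a last date before diagnosis raises.
    """
    df = pd.read_csv(path)
    records: list[SurvivalRecord] = []
    dropped = 0
    for rec in df.to_dict("records"):
        pid = str(rec["id"])
        age = rec.get("age")
        age = None if age is None or pd.isna(age) else float(age)
        sex = _norm_sex(rec.get("sex"))
        if "os_months" in rec and not pd.isna(rec["os_months"]):
            os_months = float(rec["os_months"])
        elif "diagnosis_date" in rec:
            d0, d1 = rec.get("diagnosis_date"), rec.get("last_date")
            if pd.isna(d0) or pd.isna(d1) or d0 is None or d1 is None:
                dropped += 1
                continue
            t0, t1 = date.fromisoformat(str(d0)), date.fromisoformat(str(d1))
            if t1 < t0:
                raise ValueError(f"patient {pid}: last_date precedes diagnosis_date")
            os_months = (t1 - t0).days / DAYS_PER_MONTH
        else:
            dropped += 1
            continue
        if pd.isna(rec.get("event")):
            dropped += 1
            continue
        records.append(
            SurvivalRecord(pid, os_months, int(rec["event"]), age=age, sex=sex)
        )
    if dropped:
        log.info("survival table: dropped %d record(s) with uncomputable OS", dropped)
    return records, dropped


def write_survival_table(records: Sequence[SurvivalRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"id": r.patient_id, "os_months": r.os_months, "event": r.event,
             "age": r.age, "sex": r.sex}
            for r in records
        ]
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Sequences (FASTA)
# ---------------------------------------------------------------------------

_DNA_ALPHABET = set("ACGTN")
_AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY*X")


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    sequence: str
    moltype: str  # "dna" | "protein"

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"{self.id}: empty sequence")
        seq = self.sequence
        if seq != seq.upper():
            raise ValueError(f"{self.id}: sequence must be uppercase")
        alphabet = _DNA_ALPHABET if self.moltype == "dna" else _AA_ALPHABET
        bad = set(seq) - alphabet
        if bad:
            raise ValueError(f"{self.id}: invalid characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


def read_fasta(path: str | Path, moltype: str) -> list[SequenceRecord]:
    return [
        SequenceRecord(rec.id, str(rec.seq).upper(), moltype)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    SeqIO.write(
        [_BioSeqRecord(Seq(r.sequence), id=r.id, description="") for r in records],
        str(path),
        "fasta",
    )


# ---------------------------------------------------------------------------
# Genome annotation (GTF)
# ---------------------------------------------------------------------------

@dataclass
class TranscriptModel:
    """One transcript: exon/CDS intervals are 0-based half-open, in genomic order."""

    transcript_id: str
    gene_id: str
    gene_biotype: str  # protein_coding | pseudogene | lncRNA | other
    chrom: str
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)
    tpm: float = 0.0

    def validate(self) -> None:
        for lo, hi in self.cds:
            if not any(elo <= lo and hi <= ehi for elo, ehi in self.exons):
                raise ValueError(
                    f"transcript {self.transcript_id}: CDS [{lo}, {hi}) outside exons"
                )


@dataclass
class GenomeAnnotation:
    transcripts: dict[str, TranscriptModel] = field(default_factory=dict)

    def __iter__(self):
        return iter(self.transcripts.values())

    def __getitem__(self, transcript_id: str) -> TranscriptModel:
        return self.transcripts[transcript_id]

    def __len__(self) -> int:
        return len(self.transcripts)


def read_gtf(path: str | Path, tpm: Mapping[str, float] | None = None) -> GenomeAnnotation:
    """Read exon/CDS features of a GTF into transcript models.

    GTF coordinates (1-based, inclusive) convert to internal 0-based half-open.
    TPM comes from a ``tpm`` attribute on the transcript's features or from the
    ``tpm`` mapping; transcripts lacking both get tpm = 0 with a warning.
    """
    annotation = GenomeAnnotation()
    saw_tpm: set[str] = set()
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            feat = feature_from_line(line.rstrip("\n"))
            if feat.featuretype not in ("exon", "CDS"):
                continue
            tid = feat.attributes["transcript_id"][0]
            model = annotation.transcripts.get(tid)
            if model is None:
                biotype = (feat.attributes.get("gene_biotype") or ["other"])[0]
                model = TranscriptModel(
                    transcript_id=tid,
                    gene_id=feat.attributes["gene_id"][0],
                    gene_biotype=biotype,
                    chrom=feat.seqid,
                    strand=feat.strand,
                )
                annotation.transcripts[tid] = model
            interval = (feat.start - 1, feat.end)  # to 0-based half-open
            if feat.featuretype == "exon":
                model.exons.append(interval)
            else:
                model.cds.append(interval)
            if "tpm" in feat.attributes:
                model.tpm = float(feat.attributes["tpm"][0])
                saw_tpm.add(tid)
    for tid, model in annotation.transcripts.items():
        if tpm is not None and tid in tpm:
            model.tpm = float(tpm[tid])
            saw_tpm.add(tid)
        if tid not in saw_tpm:
            log.warning("transcript %s lacks tpm; treated as 0", tid)
        model.exons.sort()
        model.cds.sort()
        model.validate()
    return annotation


def write_gtf(annotation: GenomeAnnotation, path: str | Path) -> None:
    """Write transcript models back to GTF (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        for model in annotation:
            attrs = (
                f'gene_id "{model.gene_id}"; transcript_id "{model.transcript_id}"; '
                f'gene_biotype "{model.gene_biotype}"; tpm "{model.tpm:g}";'
            )
            for kind, ivals in (("exon", model.exons), ("CDS", model.cds)):
                for lo, hi in ivals:
                    fh.write(
                        "\t".join(
                            [model.chrom, "gscproteo", kind, str(lo + 1), str(hi),
                             ".", model.strand, ".", attrs]
                        )
                        + "\n"
                    )


def read_tpm_table(path: str | Path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["transcript_id"].astype(str), df["tpm"].astype(float)))
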