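"""Two-arm stem-cell protein signature: consistency intersection and refinement.

The signature is derived from per-line differential tests: a protein enters
the GPC-like arm (up in proneural/classical stem lines) when it is significant
and up in *every* (GSC line, control line) comparison, and the GM-like arm
(up in mesenchymal/control context) when significant and down in every
comparison.  Refinement on an independent panel keeps only proteins whose
fold-change direction between the non-mesenchymal and mesenchymal phenotypes
agrees with the arm.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    ExpressionMatrix,
    SampleAnnotation,
    check_annotations,
    lines_in_group,
    samples_of_line,
)
from .stats import bh_adjust, rowwise_ttest

log = logging.getLogger(__name__)

__all__ = [
    "Signature",
    "differential_test",
    "derive_signature",
    "refine_signature",
    "marker_ratio",
    "format_retention",
]


@dataclass
class Signature:
    """Disjoint GPC-like ("up") and GM-like ("down") protein sets with evidence."""

    gpc_like: list[str]
    gm_like: list[str]
    provenance: dict[str, pd.DataFrame] = field(default_factory=dict)
    refined: bool = False

    def __post_init__(self):
        overlap = set(self.gpc_like) & set(self.gm_like)
        if overlap:
            raise ValueError(f"signature arms overlap: {sorted(overlap)[:5]}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "protein_id": list(self.gpc_like) + list(self.gm_like),
                "arm": ["gpc_like"] * len(self.gpc_like)
                + ["gm_like"] * len(self.gm_like),
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, refined: bool = False) -> "Signature":
        return cls(
            gpc_like=list(frame.loc[frame["arm"] == "gpc_like", "protein_id"]),
            gm_like=list(frame.loc[frame["arm"] == "gm_like", "protein_id"]),
            refined=refined,
        )


def differential_test(
    matrix: ExpressionMatrix,
    annotations: list[SampleAnnotation],
    line_a: str,
    line_b: str,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per-protein two-sided t-test of line_a replicates against line_b.

    Welch by default (3-vs-3 replicate groups rarely justify pooling).
    Restricted to complete-case proteins; log2_fc = mean(a) - mean(b);
    q-values are BH-adjusted across all proteins within this comparison.
    """
    check_annotations(matrix, annotations)
    cols_a = samples_of_line(annotations, line_a)
    cols_b = samples_of_line(annotations, line_b)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError(
            f"comparison {line_a} vs {line_b}: both lines need >= 2 replicates"
        )
    complete = matrix.complete_case().values
    a = complete[cols_a].to_numpy()
    b = complete[cols_b].to_numpy()
    t, p = rowwise_ttest(a, b, equal_var=equal_var)
    log2_fc = a.mean(axis=1) - b.mean(axis=1)
    return pd.DataFrame(
        {
            "protein_id": complete.index,
            "comparison": f"{line_a}_vs_{line_b}",
            "log2_fc": log2_fc,
            "t": t,
            "p_value": p,
            "q_value": bh_adjust(p),
            "direction": np.sign(log2_fc).astype(int),
        }
    ).set_index("protein_id", drop=False)


def derive_signature(
    matrix: ExpressionMatrix,
    annotations: list[SampleAnnotation],
    alpha: float = 0.05,
    equal_var: bool = False,
    min_significant: int | None = None,
) -> Signature:
    """Consistency-intersection signature over all (GSC line, control line) pairs.

    Strict mode (default): a protein must have q < alpha (strict) and the same
    direction in every comparison.  With ``min_significant`` = k, significance
    is required in only >= k comparisons while the direction must still be
    consistent in all of them.
    """
    gsc_lines = lines_in_group(annotations, "gsc")
    control_lines = lines_in_group(annotations, "control")
    if not gsc_lines or not control_lines:
        raise ValueError("need >= 1 GSC line and >= 1 control line")

    results = {
        f"{g}_vs_{c}": differential_test(matrix, annotations, g, c, equal_var)
        for g in gsc_lines
        for c in control_lines
    }
    frames = list(results.values())
    index = frames[0].index
    sig = np.stack([(f["q_value"] < alpha).to_numpy() for f in frames])
    up = np.stack([(f["direction"] > 0).to_numpy() for f in frames])
    down = np.stack([(f["direction"] < 0).to_numpy() for f in frames])
    n_required = len(frames) if min_significant is None else min_significant
    enough = sig.sum(axis=0) >= n_required
    gpc_mask = up.all(axis=0) & enough
    gm_mask = down.all(axis=0) & enough
    gpc = list(index[gpc_mask])
    gm = list(index[gm_mask])
    provenance = {
        label: frame.loc[frame["protein_id"].isin(gpc + gm)]
        for label, frame in results.items()
    }
    return Signature(gpc_like=gpc, gm_like=gm, provenance=provenance)


def refine_signature(
    signature: Signature,
    matrix: ExpressionMatrix,
    annotations: list[SampleAnnotation],
) -> tuple[Signature, dict]:
    """Filter the signature by fold-change direction on an independent panel.

    fc = mean log2 over proneural/classical samples - mean over mesenchymal
    samples.  GPC-like members are kept when fc > 0, GM-like when fc < 0;
    fc = 0 drops the protein.  Members absent from the panel are dropped with
    a reported count.  Returns the refined signature and a retention report.
    """
    check_annotations(matrix, annotations)
    nonmes = [
        a.sample_id for a in annotations if a.subtype in ("proneural", "classical")
    ]
    mes = [a.sample_id for a in annotations if a.subtype == "mesenchymal"]
    if not nonmes or not mes:
        raise ValueError("validation panel requires both phenotypes")
    values = matrix.values
    fc = values[nonmes].mean(axis=1) - values[mes].mean(axis=1)

    def keep(members: list[str], positive: bool) -> tuple[list[str], int]:
        present = [m for m in members if m in fc.index]
        absent = len(members) - len(present)
        if absent:
            log.warning("refinement: %d signature protein(s) absent from panel",
                        absent)
        if positive:
            kept = [m for m in present if fc[m] > 0]
        else:
            kept = [m for m in present if fc[m] < 0]
        return kept, absent

    gpc_kept, gpc_absent = keep(signature.gpc_like, positive=True)
    gm_kept, gm_absent = keep(signature.gm_like, positive=False)
    report = {
        "gpc_like": format_retention(len(gpc_kept), len(signature.gpc_like)),
        "gm_like": format_retention(len(gm_kept), len(signature.gm_like)),
        "gpc_absent": gpc_absent,
        "gm_absent": gm_absent,
    }
    refined = Signature(gpc_like=gpc_kept, gm_like=gm_kept, refined=True)
    return refined, report


def format_retention(n_kept: int, n_total: int) -> str:
    """Count-and-percent retention string, e.g. ``"157 (75.845%)"``."""
    pct = 100.0 * n_kept / n_total if n_total else 0.0
    return f"{n_kept} ({pct:.3f}%)"


def marker_ratio(
    matrix: ExpressionMatrix, numerator_id: str, denominator_id: str
) -> pd.Series:
    """Per-sample log2 marker ratio (e.g. EGFR to MET): value(num) - value(den)."""
    for pid in (numerator_id, denominator_id):
        if pid not in matrix.values.index:
            raise KeyError(f"marker {pid!r} absent from matrix")
    ratio = matrix.values.loc[numerator_id] - matrix.values.loc[denominator_id]
    ratio.name = f"log2_{numerator_id}_over_{denominator_id}"
    return ratio
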