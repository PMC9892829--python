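"""Per-gene mRNA-protein correlation and Bland-Altman agreement between cohorts.

Protein expression collapses to gene level as the mean of the log2 values of
the proteins mapping to a gene; mRNA collapses as the sum of TPMs per gene
(a median-collapse variant is exposed for sensitivity analysis).  Correlation
is Spearman with average ranks and a two-sided t-approximation p-value.
Agreement between two cohorts' per-gene correlation profiles uses
Bland-Altman limits at bias +/- 1.96 sd of the differences.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import ExpressionMatrix, GeneSetCollection
from .stats import bh_adjust

__all__ = [
    "collapse_protein_to_gene",
    "collapse_mrna_to_gene",
    "mrna_protein_correlation",
    "bland_altman",
    "AgreementResult",
    "overrepresentation",
]


def _collapse(matrix: ExpressionMatrix, mapping: dict[str, str], how: str):
    values = matrix.values
    genes = pd.Series({r: mapping.get(r) for r in values.index})
    unmapped = int(genes.isna().sum())
    kept = values.loc[genes.notna()]
    grouped = kept.groupby(genes.dropna())
    if how == "mean":
        out = grouped.mean()
    elif how == "sum":
        out = grouped.sum()
    elif how == "median":
        out = grouped.median()
    else:
        raise ValueError(f"unknown collapse {how!r}")
    return ExpressionMatrix(out), unmapped


def collapse_protein_to_gene(
    matrix: ExpressionMatrix, protein_to_gene: dict[str, str]
) -> tuple[ExpressionMatrix, int]:
    """Mean of log2 protein values per gene; returns (matrix, n_unmapped_rows)."""
    return _collapse(matrix, protein_to_gene, "mean")


def collapse_mrna_to_gene(
    matrix: ExpressionMatrix,
    transcript_to_gene: dict[str, str],
    how: str = "sum",
) -> tuple[ExpressionMatrix, int]:
    """Sum (default) or median of transcript TPMs per gene."""
    return _collapse(matrix, transcript_to_gene, how)


def _spearman_rowwise(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    rx = sps.rankdata(x, axis=1)
    ry = sps.rankdata(y, axis=1)
    rx = rx - rx.mean(axis=1, keepdims=True)
    ry = ry - ry.mean(axis=1, keepdims=True)
    denom = np.sqrt((rx**2).sum(axis=1) * (ry**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rx * ry).sum(axis=1) / denom
    return rho


def mrna_protein_correlation(
    gene_mrna: ExpressionMatrix,
    gene_protein: ExpressionMatrix,
    gene_sets: GeneSetCollection | None = None,
) -> tuple[pd.DataFrame, float, dict[str, float]]:
    """Per-gene Spearman correlation of mRNA and protein across shared samples.

    Returns (per-gene frame with rho/p/q, overall median rho, per-set median
    rho for each supplied gene set).  p is the two-sided t-approximation,
    q is BH across genes.
    """
    samples = [s for s in gene_mrna.col_ids if s in set(gene_protein.col_ids)]
    if len(samples) < 5:
        raise ValueError("need >= 5 shared samples")
    genes = [g for g in gene_mrna.row_ids if g in set(gene_protein.row_ids)]
    if not genes:
        raise ValueError("no shared genes")
    x = gene_mrna.values.loc[genes, samples].to_numpy()
    y = gene_protein.values.loc[genes, samples].to_numpy()
    n = len(samples)
    rho = _spearman_rowwise(x, y)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = np.where(np.abs(rho) >= 1.0, 0.0, 2.0 * sps.t.sf(np.abs(t), df=n - 2))
    frame = pd.DataFrame(
        {"gene_id": genes, "rho": rho, "p_value": p,
         "q_value": bh_adjust(p), "n_samples": n}
    ).set_index("gene_id", drop=False)
    median_rho = float(np.nanmedian(rho))
    set_medians: dict[str, float] = {}
    if gene_sets is not None:
        for name, members in gene_sets.items():
            sub = frame.loc[frame.index.isin(members), "rho"]
            set_medians[name] = float(sub.median()) if len(sub) else float("nan")
    return frame, median_rho, set_medians


@dataclass
class AgreementResult:
    mean: pd.Series       # per-gene mean of the two estimates
    difference: pd.Series  # per-gene a - b
    bias: float
    lower_limit: float
    upper_limit: float
    above_limit: list[str]
    below_limit: list[str]


def bland_altman(rho_a: pd.Series, rho_b: pd.Series) -> AgreementResult:
    """Bland-Altman agreement of two per-gene correlation profiles.

    Limits are bias +/- 1.96 sd of the per-gene differences; genes beyond a
    limit disagree strongly (below the lower limit: lower correlation in
    cohort a).
    """
    genes = rho_a.index.intersection(rho_b.index)
    if len(genes) < 10:
        raise ValueError("need >= 10 shared genes")
    d = (rho_a.loc[genes] - rho_b.loc[genes]).astype(float)
    m = (rho_a.loc[genes] + rho_b.loc[genes]) / 2.0
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0:
        warnings.warn("zero variance of differences: limits collapse",
                      stacklevel=2)
        return AgreementResult(m, d, bias, bias, bias, [], [])
    lower, upper = bias - 1.96 * sd, bias + 1.96 * sd
    return AgreementResult(
        mean=m,
        difference=d,
        bias=bias,
        lower_limit=lower,
        upper_limit=upper,
        above_limit=list(d.index[d > upper]),
        below_limit=list(d.index[d < lower]),
    )


def overrepresentation(
    outliers, universe, annotation_sets: GeneSetCollection
) -> pd.DataFrame:
    """Hypergeometric overrepresentation of an outlier gene list in each set.

    p = P(overlap >= observed) under sampling |outliers| genes from the
    universe; q is BH across sets.  An empty outlier list yields an empty
    table.
    """
    outliers = set(outliers)
    universe = set(universe)
    if not outliers <= universe:
        raise ValueError("outliers must be a subset of the universe")
    if not outliers:
        return pd.DataFrame(
            columns=["set_name", "overlap", "set_size", "p_value", "q_value"]
        )
    rows = []
    M, n_draw = len(universe), len(outliers)
    for name, members in annotation_sets.items():
        in_universe = universe & set(members)
        k = len(outliers & in_universe)
        p = float(sps.hypergeom.sf(k - 1, M, len(in_universe), n_draw))
        rows.append({"set_name": name, "overlap": k,
                     "set_size": len(in_universe), "p_value": p})
    frame = pd.DataFrame(rows)
    frame["q_value"] = bh_adjust(frame["p_value"].to_numpy())
    return frame
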