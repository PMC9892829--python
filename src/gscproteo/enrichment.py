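"""Preranked GSEA (weighted Kolmogorov-Smirnov), single-sample subtype calling,
and contingency-table region enrichment.

The enrichment score walks the ranked list top-down: features in the query set
increment the running sum by |score|^w normalized over the set's scores
(w = 1), features outside decrement by 1/(N - N_hit); the score is the running
sum's maximal deviation from zero.  Significance comes from a gene-label
permutation null preserving set size, with add-one smoothing so permutation
p-values are never 0; the normalized score divides by the mean |ES| of
same-sign permutations.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneSetCollection
from .stats import bh_adjust, fisher_exact_two_sided

__all__ = [
    "RankedList",
    "EnrichmentResult",
    "ContingencyTable",
    "build_ranked_list",
    "gsea_es",
    "gsea_preranked",
    "ssgsea_subtype",
    "region_enrichment",
]


@dataclass
class RankedList:
    """Feature ids ordered by descending ranking score."""

    ids: list[str]
    scores: np.ndarray
    ranking_mode: str = "per_sample_log2"
    excluded_duplicates: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.ids) != len(self.scores):
            raise ValueError("ids and scores differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("ranked ids must be unique")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("ranking scores must be finite")
        if np.any(np.diff(self.scores) > 0):
            raise ValueError("scores must be in descending order")

    def __len__(self) -> int:
        return len(self.ids)


def build_ranked_list(
    values: pd.Series,
    ranking_mode: str = "per_sample_log2",
    protein_to_gene: dict[str, str] | None = None,
) -> RankedList:
    """Rank features by score, descending; ties break by feature-id order.

    With a protein-to-gene map, proteins whose gene maps to more than one
    protein are excluded entirely (ambiguous ranking), and surviving features
    are relabelled to gene ids.
    """
    excluded: list[str] = []
    if protein_to_gene is not None:
        genes = pd.Series({p: protein_to_gene.get(p) for p in values.index})
        counts = genes.value_counts()
        ambiguous = set(counts[counts > 1].index)
        excluded = sorted(p for p, g in genes.items() if g in ambiguous)
        keep = [p for p in values.index if genes[p] is not None
                and genes[p] not in ambiguous]
        values = values.loc[keep].rename(index=protein_to_gene)
    values = values.dropna()
    if values.nunique() <= 1:
        raise ValueError("ranking undefined under total ties")
    ordered = values.sort_index(kind="mergesort").sort_values(
        ascending=False, kind="mergesort"
    )
    return RankedList(
        ids=list(ordered.index),
        scores=ordered.to_numpy(),
        ranking_mode=ranking_mode,
        excluded_duplicates=excluded,
    )


def _es_running(scores: np.ndarray, hit_mask: np.ndarray, weight: float = 1.0):
    n = len(scores)
    n_hit = int(hit_mask.sum())
    if n_hit == 0:
        raise ValueError("set not represented in ranked list")
    if n_hit == n:
        raise ValueError("degenerate miss denominator: set covers entire list")
    w = np.abs(scores) ** weight
    total = w[hit_mask].sum()
    if total == 0:
        raise ValueError("zero total hit weight: all set members score 0")
    step = np.where(hit_mask, w / total, -1.0 / (n - n_hit))
    running = np.cumsum(step)
    es = running[np.argmax(np.abs(running))]
    return float(es), running


def gsea_es(
    ranked: RankedList, gene_set, weight: float = 1.0
) -> tuple[float, np.ndarray]:
    """Enrichment score and full running-sum profile for one gene set."""
    members = set(gene_set)
    hit_mask = np.fromiter((i in members for i in ranked.ids), bool, len(ranked))
    return _es_running(ranked.scores, hit_mask, weight)


def _es_from_positions(
    positions: np.ndarray, w_hits_cum: np.ndarray, n: int
) -> np.ndarray:
    """Vectorized ES for many hit-position sets (rows), used by the permutation null.

    ``positions``: (B, K) sorted hit indices; ``w_hits_cum``: (B, K) cumulative
    normalized hit weights; the running sum between hits decays linearly, so
    its extrema occur just after a hit or just before the next one.
    """
    B, K = positions.shape
    miss_den = n - K
    ranks = np.arange(K)[None, :]
    after = w_hits_cum - (positions - ranks) / miss_den
    before = np.concatenate(
        [np.zeros((B, 1)), w_hits_cum[:, :-1]], axis=1
    ) - (positions - ranks) / miss_den
    cand = np.concatenate([after, before], axis=1)
    idx = np.argmax(np.abs(cand), axis=1)
    return cand[np.arange(B), idx]


@dataclass
class EnrichmentResult:
    set_name: str
    es: float
    nes: float
    p_value: float
    q_value: float
    leading_edge: list[str]
    n_permutations: int
    enriched_call: bool | None = None
    sample_id: str | None = None


def gsea_preranked(
    ranked: RankedList,
    collection: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
) -> list[EnrichmentResult]:
    """Preranked GSEA with a gene-label permutation null per set.

    p = (1 + #{|ES_perm| >= |ES|, same sign}) / (1 + #same-sign permutations);
    NES = ES / mean(|ES_perm| of the same sign); q is BH across the sets.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    n = len(ranked)
    w_abs = np.abs(ranked.scores) ** weight
    results: list[EnrichmentResult] = []
    for name, members in collection.items():
        es, running = gsea_es(ranked, members, weight)
        member_set = set(members)
        hit_positions = np.flatnonzero(
            np.fromiter((i in member_set for i in ranked.ids), bool, n)
        )
        k = len(hit_positions)
        # permutation null: random size-k label sets
        perm = np.argpartition(rng.random((n_perm, n)), k - 1, axis=1)[:, :k]
        perm.sort(axis=1)
        w_perm = w_abs[perm]
        totals = w_perm.sum(axis=1, keepdims=True)
        ok = totals[:, 0] > 0
        es_perm = np.zeros(n_perm)
        if ok.any():
            es_perm[ok] = _es_from_positions(
                perm[ok].astype(float),
                np.cumsum(w_perm[ok], axis=1) / totals[ok],
                n,
            )
        same_sign = es_perm * np.sign(es) > 0
        n_same = int(same_sign.sum())
        p = (1 + int((np.abs(es_perm[same_sign]) >= abs(es)).sum())) / (1 + n_same)
        nes = es / np.abs(es_perm[same_sign]).mean() if n_same else float("nan")
        if es >= 0:
            extremum = int(np.argmax(running))
            leading = [ranked.ids[i] for i in hit_positions if i <= extremum]
        else:
            extremum = int(np.argmin(running))
            leading = [ranked.ids[i] for i in hit_positions if i >= extremum]
        results.append(
            EnrichmentResult(
                set_name=name, es=es, nes=nes, p_value=p, q_value=float("nan"),
                leading_edge=leading, n_permutations=n_perm,
            )
        )
    qs = bh_adjust(np.array([r.p_value for r in results]))
    for r, q in zip(results, qs):
        r.q_value = float(q)
    return results


def ssgsea_subtype(
    matrix: ExpressionMatrix,
    collection: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    protein_to_gene: dict[str, str] | None = None,
    weight: float = 1.0,
) -> pd.DataFrame:
    """Single-sample enrichment calls: rank each sample's log2 values, run
    preranked GSEA, and call a set enriched when ES > 0, p < 0.05 and q < 0.05,
    with q computed across all (sample x set) tests.

    The walk weights use the features' ranks (N..1) rather than the raw log2
    values, so calls depend only on the within-sample ordering and are
    invariant to any positive-slope affine transform of a sample.
    """
    rows = []
    for j, sample in enumerate(matrix.col_ids):
        ranked = build_ranked_list(
            matrix.values[sample].dropna(),
            ranking_mode="per_sample_log2",
            protein_to_gene=protein_to_gene,
        )
        ranked.scores = np.arange(len(ranked), 0, -1, dtype=float)
        for res in gsea_preranked(
            ranked, collection, n_perm=n_perm, seed=seed + j, weight=weight
        ):
            rows.append(
                {"sample_id": sample, "set_name": res.set_name, "es": res.es,
                 "nes": res.nes, "p_value": res.p_value}
            )
    frame = pd.DataFrame(rows)
    frame["q_value"] = bh_adjust(frame["p_value"].to_numpy())
    frame["enriched_call"] = (
        (frame["es"] > 0) & (frame["p_value"] < 0.05) & (frame["q_value"] < 0.05)
    )
    return frame


@dataclass
class ContingencyTable:
    region: str
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p_value: float
    q_value: float = float("nan")


def region_enrichment(
    fc_by_gene: pd.Series,
    region_sets: GeneSetCollection,
    fc_threshold: float = 0.0,
) -> list[ContingencyTable]:
    """Two-sided Fisher tests of direction (up-GPC vs up-GM) against region
    membership, over the universe of genes present in >= 1 region set.

    Genes with |fc| <= fc_threshold (at the default, fc exactly 0) are
    excluded; q is BH across regions.
    """
    universe = set().union(*(set(m) for m in region_sets.sets.values()))
    fc = fc_by_gene[fc_by_gene.index.isin(universe)]
    fc = fc[np.abs(fc) > fc_threshold]
    if fc.empty:
        raise ValueError("empty universe: no genes overlap the region sets")
    up_gpc = set(fc.index[fc > 0])
    up_gm = set(fc.index[fc < 0])
    results = []
    for region, members in region_sets.items():
        mem = set(members)
        a = len(up_gpc & mem)
        b = len(up_gm & mem)
        c = len(up_gpc - mem)
        d = len(up_gm - mem)
        odds, p = fisher_exact_two_sided(((a, b), (c, d)))
        results.append(
            ContingencyTable(region=region, table=((a, b), (c, d)),
                             odds_ratio=odds, p_value=p)
        )
    qs = bh_adjust(np.array([r.p_value for r in results]))
    for r, q in zip(results, qs):
        r.q_value = float(q)
    return results
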