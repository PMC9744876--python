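"""Rank-based and over-representation enrichment statistics.

The rank statistic is sign(log2FC) x 1/adjP; the enrichment score is the
classic (unweighted) running-sum statistic with a seeded gene-set
permutation p-value; over-representation uses the upper-tail
hypergeometric test reported on a -log10(p) scale.

Gene-set permutation is used for the p-value (rather than phenotype
permutation) because it needs no sample-level expression; this is a
documented deviation from the desktop GSEA application's default null.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

ADJP_FLOOR = 1e-300


@dataclass
class RankedGeneList:
    """Gene ids ordered by descending statistic, ties broken by gene id."""

    genes: list[str]
    stats: np.ndarray

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.stats):
            raise ValueError("genes and stats length mismatch")
        if not np.isfinite(self.stats).all():
            raise ValueError("rank statistics must be finite")

    def __len__(self) -> int:
        return len(self.genes)


def build_rank_statistic(de_table: pd.DataFrame) -> RankedGeneList:
    """Build a ranked gene list from a DE table.

    ``de_table`` needs columns ``gene_id``, ``log2FC``, ``adjP``.  The
    statistic is sign(log2FC) x (1/adjP); adjusted p-values of zero are
    floored at 1e-300.  Sorted descending, ties broken by gene id.
    """
    for col in ("gene_id", "log2FC", "adjP"):
        if col not in de_table.columns:
            raise ValueError(f"DE table missing column {col!r}")
    adjp = de_table["adjP"].to_numpy(dtype=float)
    if ((adjp < 0) | (adjp > 1)).any():
        raise ValueError("adjP values must lie in [0, 1]")
    adjp = np.maximum(adjp, ADJP_FLOOR)
    stat = np.sign(de_table["log2FC"].to_numpy(dtype=float)) / adjp
    df = pd.DataFrame({"gene_id": de_table["gene_id"].astype(str), "stat": stat})
    if df["gene_id"].duplicated().any():
        raise ValueError("duplicate gene ids in DE table")
    df = df.sort_values(["stat", "gene_id"], ascending=[False, True], kind="mergesort")
    return RankedGeneList(genes=df["gene_id"].tolist(), stats=df["stat"].to_numpy())


def enrichment_score_classic(
    ranked: RankedGeneList | Sequence[str], gene_set: Iterable[str]
) -> tuple[float, np.ndarray]:
    """Classic (unweighted) running-sum enrichment score.

    Walking the ranked list, the running sum gains 1/|hits| at each gene
    in the set and loses 1/(N - |hits|) otherwise; the score is the
    running-sum value of maximal absolute deviation from zero (signed).
    Set members absent from the list are ignored.

    Returns ``(es, running_sum)``.
    """
    genes = ranked.genes if isinstance(ranked, RankedGeneList) else list(ranked)
    members = set(gene_set)
    n = len(genes)
    hits = np.fromiter((g in members for g in genes), dtype=bool, count=n)
    n_hit = int(hits.sum())
    if n_hit == 0:
        raise ValueError("gene set has no member in the ranked list")
    if n_hit == n:
        raise ValueError("gene set covers the entire ranked list")
    steps = np.where(hits, 1.0 / n_hit, -1.0 / (n - n_hit))
    running = np.cumsum(steps)
    idx = int(np.argmax(np.abs(running)))
    return float(running[idx]), running


def permutation_pvalue(
    ranked: RankedGeneList | Sequence[str],
    gene_set: Iterable[str],
    n_perm: int = 1000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Gene-set permutation p-value for the classic enrichment score.

    Draws ``n_perm`` random same-size gene sets from the ranked list and
    reports ``p = (1 + #{|ES_perm| >= |ES_obs|}) / (1 + n_perm)``.

    Returns ``(es_observed, p)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    genes = ranked.genes if isinstance(ranked, RankedGeneList) else list(ranked)
    members = set(gene_set) & set(genes)
    es_obs, _ = enrichment_score_classic(genes, members)
    n, k = len(genes), len(members)
    rng = np.random.default_rng(seed)
    # vectorized: ES only depends on hit positions
    exceed = 0
    inc, dec = 1.0 / k, -1.0 / (n - k)
    for _ in range(n_perm):
        pos = rng.choice(n, size=k, replace=False)
        steps = np.full(n, dec)
        steps[pos] = inc
        running = np.cumsum(steps)
        if np.max(np.abs(running)) >= abs(es_obs):
            exceed += 1
    return es_obs, (1 + exceed) / (1 + n_perm)


def ora_hypergeometric(
    hit_list: Iterable[str], gene_set: Iterable[str], universe: Iterable[str]
) -> tuple[float, float]:
    """Upper-tail hypergeometric over-representation test.

    Returns ``(p, -log10(p))`` for the probability of observing at least
    the realized overlap between ``hit_list`` and ``gene_set`` when the
    hits are drawn without replacement from ``universe``.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    hits = set(hit_list)
    members = set(gene_set)
    if not members <= uni:
        raise ValueError("gene set not contained in universe")
    if not hits <= uni:
        raise ValueError("hit list not contained in universe")
    m, n_set, n_hits = len(uni), len(members), len(hits)
    overlap = len(hits & members)
    # P(X >= overlap), X ~ Hypergeom(M=m, n=n_set, N=n_hits)
    p = float(stats.hypergeom.sf(overlap - 1, m, n_set, n_hits))
    p = min(max(p, 0.0), 1.0)
    score = -np.log10(p) if p > 0 else np.inf
    return p, float(score)
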