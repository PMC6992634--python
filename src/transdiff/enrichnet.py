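"""Preranked gene-set enrichment and the overlap ("enrichment map") network.

The enrichment score is the classical weighted Kolmogorov–Smirnov running
sum: walking down a ranking of genes by a signed metric, members of the set
push the sum up by |metric|^p normalized over in-set genes, non-members pull
it down by 1/(N − n_set), and the score is the excursion of largest
magnitude.  Significance comes from a gene-label permutation null.  Scored
sets become nodes of an undirected graph whose edges connect sets whose
overlap coefficient |A∩B| / min(|A|, |B|) reaches a cutoff.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "filter_sets",
    "preranked_es",
    "permutation_p",
    "score_sets",
    "build_network",
    "overlap_coefficient",
]


def filter_sets(
    sets: Mapping[str, set[str]], candidates: set[str]
) -> dict[str, set[str]]:
    """Keep only gene sets containing at least one candidate gene."""
    return {name: set(members) for name, members in sets.items() if set(members) & candidates}


def _running_sum(
    order: Sequence[str], metric: np.ndarray, member_mask: np.ndarray, p: float
) -> np.ndarray:
    n = len(order)
    n_hit = int(member_mask.sum())
    if n_hit == 0:
        raise ValueError("gene set is disjoint from the ranking")
    if n_hit == n:
        # every position is a hit; no miss decrement exists
        weights = np.abs(metric) ** p
        total = weights.sum()
        if total == 0:
            return np.linspace(1.0 / n, 1.0, n)
        return np.cumsum(weights / total)
    weights = np.where(member_mask, np.abs(metric) ** p, 0.0)
    total = weights.sum()
    if total == 0:  # all in-set metrics are exactly 0: fall back to equal hit weights
        weights = member_mask / n_hit
    else:
        weights = weights / total
    steps = np.where(member_mask, weights, -1.0 / (n - n_hit))
    return np.cumsum(steps)


def preranked_es(
    ranking: pd.Series | Sequence[tuple[str, float]],
    gene_set: set[str],
    p: float = 1.0,
) -> float:
    """Weighted KS enrichment score of ``gene_set`` against a ranked list.

    ``ranking`` maps genes to a real-valued metric (e.g. a log2 fold change)
    and is sorted by metric descending (ties: gene ID ascending, for
    determinism).  Returns the running-sum extremum of largest magnitude,
    always in [−1, 1]; a positive-magnitude tie resolves to the positive
    extremum, the usual convention.
    """
    series = pd.Series(dict(ranking)) if not isinstance(ranking, pd.Series) else ranking
    if not np.isfinite(series.to_numpy(float)).all():
        raise ValueError("ranking metric must be finite")
    series = series.sort_index().sort_values(ascending=False, kind="mergesort")
    order = series.index.to_numpy()
    mask = np.isin(order, list(gene_set))
    rs = _running_sum(order, series.to_numpy(float), mask, p)
    hi, lo = rs.max(), rs.min()
    return float(np.clip(hi if abs(hi) >= abs(lo) else lo, -1.0, 1.0))


def permutation_p(
    ranking: pd.Series,
    gene_set: set[str],
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    p: float = 1.0,
) -> float:
    """Gene-label permutation p-value for :func:`preranked_es`.

    The null resamples which ranking positions belong to the set (set size
    preserved); p = (1 + #{|ES_perm| ≥ |ES_obs|}) / (n_perm + 1), the
    add-one estimator that can never return 0.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    series = ranking.sort_index().sort_values(ascending=False, kind="mergesort")
    metric = series.to_numpy(float)
    order = series.index.to_numpy()
    mask = np.isin(order, list(gene_set))
    n, n_hit = len(order), int(mask.sum())
    if n_hit == 0:
        raise ValueError("gene set is disjoint from the ranking")

    def es_of(m: np.ndarray) -> float:
        rs = _running_sum(order, metric, m, p)
        hi, lo = rs.max(), rs.min()
        return float(np.clip(hi if abs(hi) >= abs(lo) else lo, -1.0, 1.0))

    observed = abs(es_of(mask))
    exceed = 0
    for _ in range(n_perm):
        perm = np.zeros(n, dtype=bool)
        perm[rng.choice(n, size=n_hit, replace=False)] = True
        if abs(es_of(perm)) >= observed:
            exceed += 1
    return (1 + exceed) / (n_perm + 1)


def score_sets(
    rankings: Mapping[str, pd.Series],
    sets: Mapping[str, set[str]],
    n_perm: int = 1000,
    seed: int = 0,
    p: float = 1.0,
) -> pd.DataFrame:
    """ES and permutation p per gene set for each named ranking (contrast).

    Returns a DataFrame indexed by set name with ``size`` plus ``es_<name>``
    and ``p_<name>`` columns per contrast.  Each (contrast, set) pair gets an
    independent child seed so results do not depend on iteration order.
    """
    root = np.random.default_rng(seed)
    pairs = [(c, s) for c in rankings for s in sets]
    streams = dict(zip(pairs, root.spawn(len(pairs))))
    rows = {}
    for sname, members in sets.items():
        row: dict[str, float] = {"size": len(members)}
        for cname, ranking in rankings.items():
            row[f"es_{cname}"] = preranked_es(ranking, members, p)
            row[f"p_{cname}"] = permutation_p(
                ranking, members, n_perm, streams[(cname, sname)], p
            )
        rows[sname] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def overlap_coefficient(a: set[str], b: set[str]) -> float:
    """|A ∩ B| / min(|A|, |B|), the similarity used for enrichment-map edges."""
    if not a or not b:
        return 0.0
    return len(a & b) / min(len(a), len(b))


def build_network(
    scored: pd.DataFrame,
    sets: Mapping[str, set[str]],
    overlap_cutoff: float = 0.375,
) -> nx.Graph:
    """Undirected enrichment-map graph.

    One node per scored set, carrying its size and every ``es_*``/``p_*``
    column as attributes; an edge joins two sets iff their overlap
    coefficient is ≥ ``overlap_cutoff`` (0.375, the conventional
    enrichment-map default).  No self-loops.
    """
    if scored.empty:
        raise ValueError("need at least one scored set")
    graph = nx.Graph()
    for name, row in scored.iterrows():
        graph.add_node(name, **row.to_dict())
    names = list(scored.index)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            coeff = overlap_coefficient(sets[a], sets[b])
            if coeff >= overlap_cutoff and coeff > 0:
                graph.add_edge(a, b, overlap=coeff)
    return graph
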