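"""Signed excess-over-random target-overlap network and enrichment tests.

Two knockdowns are connected when their significant-gene sets overlap more
than expected under a hypergeometric null on the recurrently-regulated gene
universe. Edges are signed: positive when the shared genes move in the same
direction in both experiments, negative when they move oppositely; the edge
weight rescales the excess overlap linearly between 0 (at or below random)
and 1 (the maximum possible overlap of the two sets).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist

from .config import AnalysisConfig
from .diffexpr import SignificantSet


@dataclass
class OverlapEdge:
    experiment_a: str
    experiment_b: str
    sign: int                  # +1 same-direction, -1 opposite-direction
    observed: int
    expected: float
    weight: float
    tie: bool = False          # same- and opposite-direction counts equal

    def as_tuple(self):
        return (self.experiment_a, self.experiment_b, self.sign,
                self.observed, self.expected, self.weight)


@dataclass
class OverlapNetwork:
    graph: nx.Graph
    universe: set
    pruning_log: list
    pruned: bool = True

    @property
    def universe_size(self) -> int:
        return len(self.universe)


# ---------------------------------------------------------------------------


def expected_overlap(size_a: int, size_b: int, universe: int) -> float:
    """Hypergeometric mean overlap of two random sets: ``a * b / N``."""
    if universe <= 0:
        raise ValueError("universe must be positive")
    if size_a > universe or size_b > universe:
        raise ValueError("set sizes cannot exceed the universe")
    return size_a * size_b / universe


def signed_overlap_weight(
    set_a: SignificantSet, set_b: SignificantSet, universe: set,
) -> OverlapEdge:
    """Signed 0-1 excess-overlap statistic for one experiment pair.

    Both signed sets are restricted to the universe; same- and opposite-
    direction overlaps are counted over the shared genes, the larger count
    chosen (ties resolve to +1 and are flagged), and the weight computed as

        max(0, (observed - expected) / (max_possible - expected))

    with ``expected = |A| * |B| / |U|`` and
    ``max_possible = min(|A|, |B|)``, clipped to [0, 1].
    """
    if not universe:
        raise ValueError("empty universe")
    a = {g: s for g, s in set_a.entries.items() if g in universe}
    b = {g: s for g, s in set_b.entries.items() if g in universe}
    shared = set(a) & set(b)
    same = sum(1 for g in shared if a[g] == b[g])
    opp = len(shared) - same
    tie = same == opp and len(shared) > 0
    if same >= opp:
        sign, observed = 1, same
    else:
        sign, observed = -1, opp
    expected = expected_overlap(len(a), len(b), len(universe))
    max_possible = min(len(a), len(b))
    if max_possible <= expected:
        weight = 1.0 if observed >= max_possible and observed > expected else 0.0
    else:
        weight = (observed - expected) / (max_possible - expected)
    weight = float(np.clip(weight, 0.0, 1.0))
    if observed == 0 and same == opp == 0:
        sign, weight = 1, 0.0
    return OverlapEdge(set_a.experiment_id, set_b.experiment_id,
                       sign, observed, expected, weight, tie)


def regulated_universe(
    sig_sets: dict[str, SignificantSet], min_experiments: int,
) -> set:
    """Genes significant (any direction) in at least ``min_experiments``."""
    counts: dict[str, int] = {}
    for ss in sig_sets.values():
        for g in ss.entries:
            counts[g] = counts.get(g, 0) + 1
    return {g for g, c in counts.items() if c >= min_experiments}


def build_network(
    sig_sets: dict[str, SignificantSet], config: AnalysisConfig,
    universe: set | None = None,
) -> OverlapNetwork:
    """All positive-weight pairwise edges, then iterative degree pruning.

    Nodes whose degree falls below ``config.min_node_degree`` are removed
    round by round until a fixed point (a single pass can leave low-degree
    nodes behind once their neighbours vanish). Removals are logged.
    """
    if universe is None:
        universe = regulated_universe(sig_sets, config.min_experiments)
    g = nx.Graph()
    ids = sorted(sig_sets)
    for e in ids:
        n_sig = len({x for x in sig_sets[e].entries if x in universe})
        g.add_node(e, n_significant_genes=n_sig)
    if universe:
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                edge = signed_overlap_weight(sig_sets[a], sig_sets[b], universe)
                if edge.weight > 0:
                    g.add_edge(a, b, sign=edge.sign, observed=edge.observed,
                               expected=edge.expected, weight=edge.weight,
                               tie=edge.tie)
    pruning_log = []
    while True:
        doomed = [n for n in g.nodes if g.degree[n] < config.min_node_degree]
        if not doomed:
            break
        g.remove_nodes_from(doomed)
        pruning_log.append(sorted(doomed))
    return OverlapNetwork(graph=g, universe=universe, pruning_log=pruning_log)


# ---------------------------------------------------------------------------
# percent-overlap clustering


def percent_overlap_matrix(
    sig_sets: dict[str, SignificantSet], min_sig_genes: int,
) -> pd.DataFrame:
    """Direction-sensitive percent-overlap matrix M[a, b] = |A & B| / |A|.

    Only experiments with at least ``min_sig_genes`` significant genes
    qualify; the matrix is asymmetric by construction.
    """
    qualifying = sorted(e for e, s in sig_sets.items() if len(s) >= min_sig_genes)
    if len(qualifying) < 2:
        raise ValueError(
            f"fewer than 2 experiments with >= {min_sig_genes} significant genes"
        )
    sets = {e: sig_sets[e].genes() for e in qualifying}
    m = pd.DataFrame(0.0, index=qualifying, columns=qualifying)
    for a in qualifying:
        for b in qualifying:
            m.loc[a, b] = len(sets[a] & sets[b]) / len(sets[a])
    return m


def percent_overlap_clustering(
    sig_sets: dict[str, SignificantSet], config: AnalysisConfig,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Cluster the percent-overlap rows by cosine distance, average linkage."""
    m = percent_overlap_matrix(sig_sets, config.min_sig_genes_percent_overlap)
    d = pdist(m.to_numpy(), metric="cosine")
    z = linkage(d, method="average")
    return m, z


# ---------------------------------------------------------------------------
# enrichment and ChIP direct targets


def hypergeometric_enrichment(
    target_set: set, annotation_set: set, universe: set,
) -> float:
    """Upper-tail hypergeometric P of at least the observed overlap."""
    if not universe:
        raise ValueError("empty universe")
    t = set(target_set) & universe
    a = set(annotation_set) & universe
    k = len(t & a)
    return float(stats.hypergeom.sf(k - 1, len(universe), len(a), len(t)))


def chip_tss_targets(
    peaks: pd.DataFrame, tss: pd.DataFrame, config: AnalysisConfig,
) -> set:
    """Genes with a significant peak within the symmetric TSS window.

    A gene qualifies when at least one peak with ``p < adj_p_threshold``
    overlaps ``[TSS - w, TSS + w)`` on its chromosome (half-open interval
    arithmetic; strand ignored).
    """
    w = config.tss_window
    sig = peaks[peaks["p"] < config.adj_p_threshold]
    by_chrom = {c: grp[["start", "end"]].to_numpy() for c, grp in sig.groupby("chrom")}
    hits = set()
    for _, row in tss.iterrows():
        intervals = by_chrom.get(row["chrom"])
        if intervals is None:
            continue
        win_lo, win_hi = row["pos"] - w, row["pos"] + w
        if ((intervals[:, 0] < win_hi) & (intervals[:, 1] > win_lo)).any():
            hits.add(row["gene"])
    return hits
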